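"""GPR scoring, expression scaling, clinical bounds, fasting policy."""

import warnings

import numpy as np
import pytest

from hepatoflux import (
    GLUCOSE_EXPORT_ID,
    GLYCOGEN_BREAKDOWN_ID,
    ContextConfig,
    apply_fasting_exchange_policy,
    body_composition,
    expression_bounds,
    fba,
    fva,
    glycogenolysis_bound,
    parse_gpr,
    personalize,
    reaction_activity_scores,
    substrate_uptake_bounds,
)
from hepatoflux.contextualize import ContextError
from hepatoflux.gem import GPRTree, MetabolicModel, Metabolite, Reaction

from conftest import make_subject


def brute_force_score(tree, expr):
    """Independent recursive evaluator mirroring the min/max semantics."""
    if tree.kind == "gene":
        return expr.get(tree.gene)
    vals = [brute_force_score(c, expr) for c in tree.children]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return min(vals) if tree.kind == "and" else max(vals)


def random_tree(rng, genes, depth):
    if depth == 0 or rng.random() < 0.3:
        return GPRTree("gene", gene=str(rng.choice(genes)))
    kind = "and" if rng.random() < 0.5 else "or"
    k = int(rng.integers(2, 4))
    return GPRTree(kind, children=tuple(
        random_tree(rng, genes, depth - 1) for _ in range(k)))


class TestActivityScores:
    def test_min_max_example(self, toy_model):
        m = MetabolicModel(
            metabolites=[Metabolite("x")],
            reactions=[Reaction("r", {"x": 1.0}, 0, 1, gpr=parse_gpr("(g1 and g2) or g3"))],
            objective_id="r",
            exchange_ids={"r"},
        )
        scores = reaction_activity_scores(m, {"g1": 5.0, "g2": 2.0, "g3": 4.0})
        assert scores["r"] == 4.0

    def test_single_gene_identity(self):
        m = MetabolicModel(
            metabolites=[Metabolite("x")],
            reactions=[Reaction("r", {"x": 1.0}, 0, 1, gpr=parse_gpr("g1"))],
            objective_id="r",
            exchange_ids={"r"},
        )
        assert reaction_activity_scores(m, {"g1": 7.0})["r"] == 7.0

    def test_no_gpr_is_absent(self, toy_model):
        expr = {g: 1.0 for g in toy_model.genes()}
        scores = reaction_activity_scores(toy_model, expr)
        assert scores[GLYCOGEN_BREAKDOWN_ID] is None
        assert scores["UPT_lac"] is None

    def test_missing_gene_does_not_constrain(self):
        tree = parse_gpr("(a and b) or c")
        # b missing: AND reduces to a; c missing elsewhere: OR ignores it
        assert tree.evaluate({"a": 3.0, "c": 1.0}) == 3.0
        assert tree.evaluate({"a": 3.0}) == 3.0
        assert tree.evaluate({}) is None

    def test_random_trees_match_brute_force(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(8)]
        for _ in range(1000):
            tree = random_tree(rng, genes, depth=4)
            expr = {g: float(rng.uniform(0, 10)) for g in genes
                    if rng.random() > 0.2}
            assert tree.evaluate(expr) == brute_force_score(tree, expr)

    def test_negative_expression_rejected(self, toy_model):
        with pytest.raises(ContextError, match="negative"):
            reaction_activity_scores(toy_model, {"G6PC": -1.0})


class TestExpressionBounds:
    def _scored_model(self):
        return MetabolicModel(
            metabolites=[Metabolite("x")],
            reactions=[
                Reaction("in", {"x": 1.0}, 0, 10),
                Reaction("r", {"x": -1.0}, 0, 10, gpr=parse_gpr("g1")),
            ],
            objective_id="r",
            exchange_ids={"in"},
        )

    def test_zero_score_switches_off(self, ctx_cfg):
        m = self._scored_model()
        cs = expression_bounds(m, {"r": 0.0, "in": None}, ctx_cfg,
                               cap_scores={"r": 5.0})
        assert cs.bounds["r"].ub == 0.0
        assert cs.bounds["r"].provenance == "expression"

    def test_saturation_at_cap(self, ctx_cfg):
        m = self._scored_model()
        cs = expression_bounds(m, {"r": 9.0, "in": None}, ctx_cfg,
                               cap_scores={"r": 5.0})
        assert cs.bounds["r"].ub == 10.0

    def test_cap_invariance_when_saturated(self, ctx_cfg):
        m = self._scored_model()
        a = expression_bounds(m, {"r": 6.0, "in": None}, ctx_cfg, cap_scores={"r": 5.0})
        b = expression_bounds(m, {"r": 12.0, "in": None}, ctx_cfg, cap_scores={"r": 5.0})
        assert a.bounds["r"].ub == b.bounds["r"].ub == 10.0

    def test_nonpositive_cap_rejected(self, ctx_cfg):
        m = self._scored_model()
        with pytest.raises(ContextError, match="cap"):
            expression_bounds(m, {"r": 1.0, "in": None}, ctx_cfg, cap_scores={"r": 0.0})


class TestClinicalBounds:
    def _bounds_for(self, t2d, bmi, cfg):
        subj = make_subject(t2d=t2d, bmi=bmi)
        bc = body_composition(subj["weight"], subj["height"], subj["sex"])
        return substrate_uptake_bounds(subj, bc, cfg)

    @pytest.mark.parametrize("substrate,rxn,factor", [
        ("lactate", "UPT_lac", 2.0),
        ("glutamine", "UPT_gln", 2.0),
        ("alanine", "UPT_ala", 1.5),
        ("glycerol", "UPT_glyc", 1.0),
    ])
    def test_t2d_multipliers_below_bmi30(self, ctx_cfg, substrate, rxn, factor):
        diabetic = self._bounds_for(True, 28.0, ctx_cfg)
        control = self._bounds_for(False, 28.0, ctx_cfg)
        ratio = diabetic.bounds[rxn].ub / control.bounds[rxn].ub
        assert ratio == pytest.approx(factor, rel=1e-12)

    def test_no_multiplier_at_high_bmi(self, ctx_cfg):
        diabetic = self._bounds_for(True, 35.0, ctx_cfg)
        control = self._bounds_for(False, 35.0, ctx_cfg)
        assert diabetic.bounds["UPT_lac"].ub == pytest.approx(
            control.bounds["UPT_lac"].ub)

    def test_provenance_tag(self, ctx_cfg):
        cs = self._bounds_for(False, 28.0, ctx_cfg)
        assert all(b.provenance == "clinical" for b in cs.bounds.values())

    def test_missing_body_composition(self, ctx_cfg):
        with pytest.raises(ContextError, match="body composition"):
            substrate_uptake_bounds(make_subject(), None, ctx_cfg)


class TestGlycogenolysisStrata:
    def test_bmi_threshold_is_inclusive_above(self, ctx_cfg):
        below = glycogenolysis_bound(make_subject(bmi=26.9), ctx_cfg)
        at = glycogenolysis_bound(make_subject(bmi=27.0), ctx_cfg)
        assert below == ctx_cfg.glycogenolysis_ub[(False, False)]
        assert at == ctx_cfg.glycogenolysis_ub[(False, True)]
        assert below != at

    def test_t2d_toggles_row(self, ctx_cfg):
        a = glycogenolysis_bound(make_subject(t2d=False, bmi=25), ctx_cfg)
        b = glycogenolysis_bound(make_subject(t2d=True, bmi=25), ctx_cfg)
        assert a != b

    def test_degenerate_table_subject_independent(self):
        cfg = ContextConfig(glycogenolysis_ub={
            (False, False): 4.0, (False, True): 4.0,
            (True, False): 4.0, (True, True): 4.0,
        })
        vals = {glycogenolysis_bound(make_subject(t2d=t, bmi=b), cfg)
                for t in (False, True) for b in (24.0, 30.0)}
        assert vals == {4.0}

    def test_missing_cell_is_config_error(self):
        cfg = ContextConfig(glycogenolysis_ub={(False, False): 4.0})
        with pytest.raises(ContextError, match="missing cell"):
            glycogenolysis_bound(make_subject(t2d=True, bmi=30.0), cfg)


class TestFastingPolicy:
    def test_glucose_import_blocked_export_open(self, toy_model, ctx_cfg):
        cs = apply_fasting_exchange_policy(toy_model, ctx_cfg)
        b = cs.bounds[GLUCOSE_EXPORT_ID]
        assert b.lb == 0.0 and b.ub > 0 and b.provenance == "policy"

    def test_oxygen_open(self, toy_model, ctx_cfg):
        cs = apply_fasting_exchange_policy(toy_model, ctx_cfg)
        assert cs.bounds["UPT_o2"].ub > 0

    def test_without_policy_glucose_uptake_feasible(self, toy_model, ctx_cfg):
        # the template allows import (lb < 0); the policy removes it
        assert fva(toy_model, reactions=[GLUCOSE_EXPORT_ID]).range_of(
            GLUCOSE_EXPORT_ID)[0] < 0
        subj = make_subject()
        pm, _ = personalize(toy_model, subj, None, ctx_cfg)
        assert fva(pm, reactions=[GLUCOSE_EXPORT_ID]).range_of(
            GLUCOSE_EXPORT_ID)[0] >= 0

    def test_absent_reaction_named(self, toy_model):
        cfg = ContextConfig(open_exchanges=("UPT_unobtainium",))
        with pytest.raises(ContextError, match="UPT_unobtainium"):
            apply_fasting_exchange_policy(toy_model, cfg)


class TestPersonalize:
    def test_feasible_with_positive_hgp(self, toy_model, ctx_cfg):
        pm, cs = personalize(toy_model, make_subject(), None, ctx_cfg)
        assert fba(pm).objective_value > 0
        # provenance completeness: every reaction tagged
        assert set(cs.bounds) == set(toy_model.reaction_ids)

    def test_zero_expression_leaves_glycogen_route(self, toy_model, ctx_cfg):
        subj = make_subject()
        expr = {g: 0.0 for g in toy_model.genes()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pm, _ = personalize(toy_model, subj, expr, ctx_cfg,
                                cap_scores={r.id: 1.0 for r in toy_model.reactions})
        bc = body_composition(subj["weight"], subj["height"], subj["sex"])
        expected = glycogenolysis_bound(subj, ctx_cfg) * bc.lbm * 0.06
        assert fba(pm).objective_value == pytest.approx(expected, rel=1e-8)

    def test_deterministic(self, toy_model, ctx_cfg):
        subj = make_subject()
        expr = {g: 2.0 for g in toy_model.genes()}
        caps = {r.id: 3.0 for r in toy_model.reactions}
        _, a = personalize(toy_model, subj, expr, ctx_cfg, cap_scores=caps)
        _, b = personalize(toy_model, subj, expr, ctx_cfg, cap_scores=caps)
        assert {k: (v.lb, v.ub, v.provenance) for k, v in a.items()} == \
               {k: (v.lb, v.ub, v.provenance) for k, v in b.items()}

    def test_conflicting_bounds_reported(self, toy_model, ctx_cfg):
        m = toy_model.copy()
        m.get_reaction("R2").lb = 0.5  # forced flux conflicts with score 0
        expr = {g: 0.0 for g in m.genes()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ContextError, match="R2"):
                personalize(m, make_subject(), expr, ctx_cfg,
                            cap_scores={r.id: 1.0 for r in m.reactions})

    def test_uptake_monotonicity(self, toy_model, ctx_cfg):
        """LP monotonicity: relaxing the lactate bound never lowers max HGP."""
        subj = make_subject()
        pm, _ = personalize(toy_model, subj, None, ctx_cfg)
        prev = -np.inf
        for ub in (0.0, 5.0, 10.0, 20.0, 40.0):
            m = pm.copy()
            m.get_reaction("UPT_lac").ub = ub
            val = fba(m).objective_value
            assert val >= prev - 1e-9
            prev = val

    def test_t2d_never_decreases_hgp_when_lactate_binds(self, toy_model, ctx_cfg):
        # binding lactate constraint: T2D doubles it, so max HGP must not drop
        cfg = ContextConfig(glycogenolysis_ub={k: 4.0 for k in
                                               ctx_cfg.glycogenolysis_ub})
        s_ctrl = make_subject(t2d=False, bmi=28.0)
        s_t2d = make_subject(t2d=True, bmi=28.0)
        a, _ = personalize(toy_model, s_ctrl, None, cfg)
        b, _ = personalize(toy_model, s_t2d, None, cfg)
        assert fba(b).objective_value >= fba(a).objective_value - 1e-9
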