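"""LP machinery for personalized hepatic models.

Flux balance analysis (FBA) with dual values, flux variability analysis
(FVA), the FVA-midpoint estimate of hepatic glucose production (HGP), the
shadow-price decomposition of HGP into glycogenolysis and gluconeogenesis,
per-precursor contributions, the 3-SD outlier filter, and a brute-force
vertex-enumeration oracle used to verify the LP path on small models.

All LPs are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`.  Duals follow the maximization sign
convention: the shadow price of an upper bound is >= 0 when the bound binds
and equals the marginal gain in the objective per unit of relaxation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem import (
    GLUCOSE_EXPORT_ID,
    GLYCOGEN_BREAKDOWN_ID,
    REVERSE_SUFFIX,
    MetabolicModel,
    split_reversible,
)

__all__ = [
    "FBAResult",
    "FVAResult",
    "HGPDecomposition",
    "FluxAnalysisError",
    "InfeasibleError",
    "fba",
    "fva",
    "hgp_from_fva",
    "decompose_hgp",
    "precursor_contributions",
    "exclude_outliers",
    "lp_oracle",
    "shadow_price_range",
]

FEASIBILITY_TOL = 1e-9
COMPARISON_TOL = 1e-6
ORACLE_MAX_REACTIONS = 12


class FluxAnalysisError(RuntimeError):
    pass


class InfeasibleError(FluxAnalysisError):
    """The LP has no feasible point under the given constraints."""


@dataclass
class FBAResult:
    """Optimal FBA solution with primal fluxes and dual values.

    ``fluxes`` report net flux per *original* reaction id (forward minus
    reverse for split pairs); ``split_fluxes`` and the dual maps are keyed
    by the split (irreversible) reaction ids.
    """

    objective_value: float
    fluxes: dict[str, float]
    split_fluxes: dict[str, float]
    dual_upper: dict[str, float]
    dual_lower: dict[str, float]
    metabolite_duals: dict[str, float]
    solver_status: str = "optimal"


@dataclass
class FVAResult:
    """Per-original-reaction feasible flux ranges and their midpoints."""

    ranges: pd.DataFrame  # index: reaction id; columns vmin, vmax, midpoint

    def range_of(self, rid: str) -> tuple[float, float]:
        row = self.ranges.loc[rid]
        return float(row["vmin"]), float(row["vmax"])

    def midpoint(self, rid: str) -> float:
        return float(self.ranges.loc[rid, "midpoint"])


@dataclass
class HGPDecomposition:
    """HGP split into glycogenolysis and gluconeogenesis via the shadow
    price of the glycogen-breakdown upper bound (gng = hgp - glycogenolysis
    by construction)."""

    hgp: float
    glycogenolysis: float
    gng: float
    glycogen_flux: float
    shadow_price: float
    shadow_price_range: tuple[float, float] | None = None
    precursor_contribs: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal LP assembly
# ---------------------------------------------------------------------------


class _SplitLP:
    """Cached split representation of a model for repeated LP solves."""

    def __init__(self, model: MetabolicModel):
        if any(r.lb < 0 for r in model.reactions):
            model = split_reversible(model)
        elif not model.split_map:
            model = split_reversible(model)  # builds the identity map
        self.model = model
        self.S, self.met_idx, self.rxn_idx = model.stoichiometric_matrix()
        self.lb, self.ub = model.bounds_arrays()
        self.split_map = model.split_map

    def net_vector(self, original_id: str) -> np.ndarray:
        """Objective vector selecting the net flux of an original reaction."""
        c = np.zeros(self.S.shape[1])
        fwd, rev = self._pair(original_id)
        c[self.rxn_idx[fwd]] = 1.0
        if rev is not None:
            c[self.rxn_idx[rev]] = -1.0
        return c

    def _pair(self, original_id: str) -> tuple[str, str | None]:
        if original_id in self.split_map:
            return self.split_map[original_id]
        if original_id in self.rxn_idx:
            return original_id, None
        raise KeyError(f"no reaction {original_id!r} in model")

    def solve(self, c: np.ndarray, sense: int = 1,
              extra_A_ub=None, extra_b_ub=None):
        """Optimize ``sense * c . v`` (sense=+1 maximizes)."""
        res = linprog(
            c=-sense * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=list(zip(self.lb, self.ub)),
            method="highs",
            options={"presolve": True,
                     "primal_feasibility_tolerance": FEASIBILITY_TOL,
                     "dual_feasibility_tolerance": FEASIBILITY_TOL},
        )
        if res.status == 2:
            raise InfeasibleError("LP infeasible: check bound conflicts "
                                  "(lb > ub after personalization?)")
        if res.status == 3:
            raise FluxAnalysisError("LP unbounded: missing finite bounds")
        if res.status != 0:
            raise FluxAnalysisError(f"LP solver failure: {res.message}")
        return res

    def net_fluxes(self, v: np.ndarray) -> dict[str, float]:
        out = {}
        for orig, (fwd, rev) in self.split_map.items():
            val = v[self.rxn_idx[fwd]]
            if rev is not None:
                val -= v[self.rxn_idx[rev]]
            out[orig] = float(val)
        return out


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------


def fba(model: MetabolicModel, objective_id: str | None = None) -> FBAResult:
    """Maximize the objective flux subject to S.v=0 and bounds.

    Returns primal fluxes plus shadow prices for every bound constraint
    (``dual_upper[rid]`` >= 0 is the marginal objective gain per unit of
    upper-bound relaxation) and the metabolite (mass-balance row) duals.
    """
    lp = _SplitLP(model)
    obj = objective_id or model.objective_id
    c = lp.net_vector(obj)
    res = lp.solve(c, sense=1)
    rids = lp.model.reaction_ids
    # linprog minimizes -c.v: negate marginals to express sensitivities of
    # the maximized objective.
    dual_upper = {rid: float(-res.upper.marginals[i]) for i, rid in enumerate(rids)}
    dual_lower = {rid: float(-res.lower.marginals[i]) for i, rid in enumerate(rids)}
    met_duals = {mid: float(-res.eqlin.marginals[i])
                 for mid, i in lp.met_idx.items()}
    return FBAResult(
        objective_value=float(c @ res.x),
        fluxes=lp.net_fluxes(res.x),
        split_fluxes={rid: float(res.x[i]) for i, rid in enumerate(rids)},
        dual_upper=dual_upper,
        dual_lower=dual_lower,
        metabolite_duals=met_duals,
    )


def fva(
    model: MetabolicModel,
    objective_id: str | None = None,
    objective_fraction: float = 0.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Per-reaction feasible flux ranges (net per original reaction).

    With ``objective_fraction > 0`` the objective is additionally required
    to reach that fraction of its FBA optimum; the default 0 reports pure
    feasibility ranges, which leaves the objective reaction itself with a
    non-degenerate range.  ``reactions`` restricts the scan (default: all).
    """
    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in [0, 1]")
    lp = _SplitLP(model)
    obj = objective_id or model.objective_id
    A_ub = b_ub = None
    if objective_fraction > 0:
        c_obj = lp.net_vector(obj)
        opt = float(c_obj @ lp.solve(c_obj, sense=1).x)
        A_ub = -c_obj[None, :]
        b_ub = np.array([-objective_fraction * opt])
    targets = reactions if reactions is not None else list(lp.split_map)
    rows = []
    for rid in targets:
        c = lp.net_vector(rid)
        vmax = float(c @ lp.solve(c, sense=1, extra_A_ub=A_ub, extra_b_ub=b_ub).x)
        vmin = float(c @ lp.solve(c, sense=-1, extra_A_ub=A_ub, extra_b_ub=b_ub).x)
        if vmin > vmax:  # numerical noise on pinned ranges
            vmin, vmax = vmax, vmin
        rows.append((rid, vmin, vmax, 0.5 * (vmin + vmax)))
    df = pd.DataFrame(rows, columns=["reaction", "vmin", "vmax", "midpoint"])
    return FVAResult(ranges=df.set_index("reaction"))


def hgp_from_fva(
    fva_result: FVAResult,
    glucose_export_id: str = GLUCOSE_EXPORT_ID,
) -> float:
    """HGP point estimate: the midpoint of the FVA range of the glucose
    export reaction, in model units (mmol/h).  Use
    :func:`hepatoflux.tracer.normalize_by_lbm` to convert per kg LBM."""
    if glucose_export_id not in fva_result.ranges.index:
        raise KeyError(f"glucose export {glucose_export_id!r} not in FVA result")
    return fva_result.midpoint(glucose_export_id)


# ---------------------------------------------------------------------------
# shadow-price decomposition
# ---------------------------------------------------------------------------


def shadow_price_range(
    model: MetabolicModel,
    reaction_id: str,
    objective_id: str | None = None,
    eps: float = 1e-4,
) -> tuple[float, float]:
    """Finite-difference bracket on the shadow price of a reaction's upper
    bound, via +/- eps perturbations.  For a unique dual both one-sided
    slopes agree; at degenerate optima they bracket the dual interval."""
    base = fba(model, objective_id).objective_value

    def perturbed(delta: float) -> float:
        m = model.copy()
        r = m.get_reaction(reaction_id)
        r.ub = r.ub + delta
        if r.ub < r.lb:
            return base
        return fba(m, objective_id).objective_value

    up = (perturbed(eps) - base) / eps
    down = (base - perturbed(-eps)) / eps
    return (min(up, down), max(up, down))


def decompose_hgp(
    model: MetabolicModel,
    glycogen_reaction_id: str = GLYCOGEN_BREAKDOWN_ID,
    objective_id: str | None = None,
    check_degeneracy: bool = True,
    eps: float = 1e-4,
) -> HGPDecomposition:
    """Split the FBA-optimal HGP into glycogenolysis and gluconeogenesis.

    The glycogenolysis contribution is the FBA-predicted glycogen breakdown
    flux multiplied by the shadow price (Lagrange multiplier) of its upper
    bound -- the marginal HGP gained per extra unit of glycogen consumed.
    Gluconeogenesis is the remainder, so gng + glycogenolysis = hgp exactly.
    """
    sol = fba(model, objective_id)
    if glycogen_reaction_id not in sol.split_fluxes:
        raise KeyError(f"no glycogen breakdown reaction {glycogen_reaction_id!r}")
    v_gly = sol.split_fluxes[glycogen_reaction_id]
    sp = sol.dual_upper[glycogen_reaction_id]
    msgs: list[str] = []
    sp_range = None
    if check_degeneracy:
        lo, hi = shadow_price_range(model, glycogen_reaction_id, objective_id, eps)
        sp_range = (lo, hi)
        if hi - lo > 1e-6 * max(1.0, abs(sp)):
            msgs.append(
                f"degenerate shadow price for {glycogen_reaction_id}: "
                f"dual in [{lo:.6g}, {hi:.6g}]"
            )
            warnings.warn(msgs[-1], RuntimeWarning, stacklevel=2)
    contrib = v_gly * sp
    hgp = sol.objective_value
    gng = hgp - contrib
    if gng < -COMPARISON_TOL:
        msgs.append(f"negative gluconeogenesis residual ({gng:.3g}); "
                    "shadow price exceeds marginal yield")
        warnings.warn(msgs[-1], RuntimeWarning, stacklevel=2)
    return HGPDecomposition(
        hgp=hgp,
        glycogenolysis=contrib,
        gng=gng,
        glycogen_flux=v_gly,
        shadow_price=sp,
        shadow_price_range=sp_range,
        warnings=msgs,
    )


def precursor_contributions(
    model: MetabolicModel,
    substrate_uptake_ids: list[str],
    objective_id: str | None = None,
) -> dict[str, float]:
    """Per-precursor contribution to HGP: uptake flux times the shadow price
    of the uptake upper bound, for each listed substrate uptake reaction.

    Subject to the same caveats as the glycogen decomposition: at degenerate
    optima the dual (and hence the contribution) is one point of an interval.
    """
    sol = fba(model, objective_id)
    out: dict[str, float] = {}
    for rid in substrate_uptake_ids:
        if rid not in sol.split_fluxes:
            raise KeyError(f"unknown substrate uptake reaction {rid!r}")
        out[rid] = sol.split_fluxes[rid] * sol.dual_upper[rid]
    return out


# ---------------------------------------------------------------------------
# outlier filter
# ---------------------------------------------------------------------------


def exclude_outliers(
    values: pd.Series,
    k: float = 3.0,
    two_sided: bool = True,
) -> tuple[pd.Series, dict]:
    """Drop flux values deviating from the mean by more than ``k`` sample
    standard deviations (default 3, two-sided).

    Returns the filtered series plus a report listing removed ids.  With
    fewer than 3 values, or zero SD, nothing is removed.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 3:
        raise ValueError("outlier filter requires at least 3 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        removed = values.iloc[0:0]
    else:
        dev = values - mean
        mask = dev.abs() > k * sd if two_sided else dev > k * sd
        removed = values[mask]
    kept = values.drop(removed.index)
    report = {
        "n_input": int(len(values)),
        "n_removed": int(len(removed)),
        "removed_ids": list(removed.index),
        "mean": float(mean),
        "sd": float(sd),
        "k": k,
        "two_sided": two_sided,
    }
    return kept, report


# ---------------------------------------------------------------------------
# vertex-enumeration oracle (test support)
# ---------------------------------------------------------------------------


def lp_oracle(
    model: MetabolicModel,
    objective_id: str | None = None,
    tol: float = 1e-9,
) -> dict:
    """Brute-force oracle for small models: enumerate the vertices of the
    flux polytope {v : S.v=0, lb <= v <= ub} and read off the exact optimum
    and per-reaction net-flux min/max.

    Vertices have at least n - rank(S) variables fixed at a bound; every
    such fixing is enumerated and the remaining system solved exactly.
    Limited to models with <= 12 reactions after reversible splitting.
    """
    lp = _SplitLP(model)
    S, lb, ub = lp.S, lp.lb, lp.ub
    n = S.shape[1]
    if n > ORACLE_MAX_REACTIONS:
        raise ValueError(
            f"oracle limited to small models (<= {ORACLE_MAX_REACTIONS} "
            f"reactions after splitting, got {n})"
        )
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - r
    vertices: list[np.ndarray] = []
    for free_cols in itertools.combinations(range(n), r):
        fixed_cols = [j for j in range(n) if j not in free_cols]
        S_free = S[:, list(free_cols)]
        S_fixed = S[:, fixed_cols]
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            v_fixed = np.array(
                [lb[j] if p == 0 else ub[j] for j, p in zip(fixed_cols, pattern)]
            )
            rhs = -S_fixed @ v_fixed if n_fixed else np.zeros(S.shape[0])
            if r:
                v_free, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            else:
                v_free = np.zeros(0)
            v = np.empty(n)
            v[list(free_cols)] = v_free
            v[fixed_cols] = v_fixed
            if np.max(np.abs(S @ v)) > 1e-7 if S.size else False:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            if not any(np.allclose(v, w, atol=1e-8) for w in vertices):
                vertices.append(v)
    if not vertices:
        return {"feasible": False, "optimum": None, "vertices": [],
                "ranges": {}}
    V = np.array(vertices)
    obj = objective_id or model.objective_id
    c = lp.net_vector(obj)
    objective_values = V @ c
    ranges = {}
    for orig in lp.split_map:
        cv = V @ lp.net_vector(orig)
        ranges[orig] = (float(cv.min()), float(cv.max()))
    return {
        "feasible": True,
        "optimum": float(objective_values.max()),
        "vertices": vertices,
        "ranges": ranges,
    }
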