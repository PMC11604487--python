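"""Seeded synthetic cohorts, expression profiles and tracer series.

The generator emulates the statistical structure the downstream analysis
assumes for a MASLD cohort stratified by histology (MASL, MASH F0-F1,
MASH F2, MASH F3-F4) and T2D status: a programmed stepwise increase of
fasting hepatic glucose production (HGP) and insulin resistance with
fibrosis stage, lipolysis coupled to HGP, and transcript expression only
weakly -- and for some genes inversely -- coupled to the latent fluxes.

Each subject carries its latent ("true") HGP, lipolysis and
gluconeogenesis fraction alongside the noisy observables, so parameter-
recovery tests can compare pipeline output against the programmed truth.
Concentrations receive lognormal noise (positivity); enrichments receive
normal noise.  Every generator is fully determined by the config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracer import TracerSeries

__all__ = [
    "GROUPS",
    "EffectConfig",
    "SyntheticError",
    "default_group_weights",
    "generate_cohort",
    "generate_expression",
    "generate_tracer_series",
]

GROUPS = ("MASL", "MASH_F0F1", "MASH_F2", "MASH_F3F4")

#: default sign/magnitude of expression-to-latent-flux coupling for the
#: genes of the toy hepatocyte network.  Gluconeogenic capacity genes track
#: the latent flux; PCK2 is inversely coupled (transcript down while flux
#: up), mirroring the RNA-flux divergence the analysis must tolerate.
DEFAULT_GENE_COUPLING = {
    "FBP1": 0.6,
    "G6PC": 0.6,
    "PC": 0.5,
    "ENO1": 0.5,
    "GK": 0.3,
    "GPT": 0.3,
    "GLS": 0.3,
    "PCK2": -0.4,
}


class SyntheticError(ValueError):
    pass


@dataclass
class EffectConfig:
    """Programmed effect sizes and noise levels of the generator.

    ``fibrosis_effect`` is the additive HGP increment per histology group
    (umol/min/kg LBM), non-decreasing from MASL to MASH F3-F4;
    ``t2d_effect`` adds on top for diabetic subjects;
    ``lipolysis_coupling`` is the slope tying the latent glycerol Ra to the
    latent HGP.  ``expression_coupling`` maps gene -> coupling of log-
    expression to the latent HGP deviation from baseline, in units of
    ``expression_reference_scale`` (may be negative); ``None`` uses
    :data:`DEFAULT_GENE_COUPLING` restricted to the requested genes.
    """

    baseline_hgp: float = 9.0            # umol/min/kg LBM
    fibrosis_effect: dict = field(default_factory=lambda: {
        "MASL": 0.0, "MASH_F0F1": 1.2, "MASH_F2": 2.4, "MASH_F3F4": 3.6,
    })
    t2d_effect: float = 1.5
    baseline_lipolysis: float = 2.5      # umol/min/kg LBM (glycerol Ra)
    lipolysis_coupling: float = 0.25
    noise_sd: dict = field(default_factory=lambda: {
        "hgp": 1.0, "lipolysis": 0.5, "expression": 0.25,
    })
    expression_coupling: dict | None = None
    #: latent-HGP spread (umol/min/kg) that maps to one coupling unit of
    #: log-expression; fixed so expression depends on the subject's own
    #: latent flux, not on cohort composition
    expression_reference_scale: float = 2.0
    seed: int = 0

    def __post_init__(self):
        effects = [self.fibrosis_effect[g] for g in GROUPS]
        if any(b < a for a, b in zip(effects, effects[1:])):
            raise SyntheticError(
                "fibrosis_effect must be non-decreasing from MASL to MASH_F3F4"
            )

    def null(self) -> "EffectConfig":
        """Copy with every group/T2D effect and coupling set to zero."""
        return EffectConfig(
            baseline_hgp=self.baseline_hgp,
            fibrosis_effect={g: 0.0 for g in GROUPS},
            t2d_effect=0.0,
            baseline_lipolysis=self.baseline_lipolysis,
            lipolysis_coupling=self.lipolysis_coupling,
            noise_sd=dict(self.noise_sd),
            expression_coupling=self.expression_coupling,
            expression_reference_scale=self.expression_reference_scale,
            seed=self.seed,
        )


def default_group_weights(t2d_fraction: float = 0.3) -> np.ndarray:
    """Weights over the 8 group x T2D cells, ordered (group, t2d) with t2d
    minor: (MASL,0), (MASL,1), (MASH_F0F1,0), ..."""
    group_p = np.array([0.30, 0.30, 0.20, 0.20])
    w = np.empty(8)
    w[0::2] = group_p * (1 - t2d_fraction)
    w[1::2] = group_p * t2d_fraction
    return w


def _validate_weights(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (8,):
        raise SyntheticError("group_weights must have 8 cells (4 groups x T2D)")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise SyntheticError("group_weights must lie on the probability simplex")
    return w


def generate_cohort(
    n: int,
    group_weights=None,
    cfg: EffectConfig | None = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort table with latent truth columns.

    One row per subject with the clinical covariates, histology grouping and
    the latent ``true_hgp`` (umol/min/kg LBM), ``true_lipolysis`` and
    ``true_gng_fraction`` used by recovery tests.  Deterministic under
    ``cfg.seed``.
    """
    cfg = cfg or EffectConfig()
    if group_weights is None:
        group_weights = default_group_weights()
    w = _validate_weights(group_weights)
    n_cells = int(np.sum(w > 0))
    if n < 8 or n < n_cells:
        raise SyntheticError("cohort too small")

    rng = np.random.default_rng([int(cfg.seed), 0])
    cells = rng.choice(8, size=n, p=w)
    group_idx = cells // 2
    t2d = (cells % 2).astype(bool)

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    height = np.where(sex == "male", rng.normal(176, 7, n), rng.normal(163, 6, n))
    height = np.clip(height, 145, 205)
    bmi = np.clip(np.exp(rng.normal(np.log(29.0), 0.15, n)), 18.5, 45.0)
    weight = bmi * (height / 100.0) ** 2
    age = np.clip(np.round(rng.normal(52, 10, n)), 20, 78).astype(int)

    fibrosis = np.empty(n, dtype=int)
    activity = np.empty(n, dtype=int)
    steatosis = np.empty(n, dtype=int)
    for i in range(n):
        g = GROUPS[group_idx[i]]
        if g == "MASL":
            fibrosis[i] = rng.choice([0, 1], p=[0.7, 0.3])
            activity[i] = 0
        elif g == "MASH_F0F1":
            fibrosis[i] = rng.choice([0, 1])
            activity[i] = rng.integers(2, 6)
        elif g == "MASH_F2":
            fibrosis[i] = 2
            activity[i] = rng.integers(2, 7)
        else:
            fibrosis[i] = rng.choice([3, 4], p=[0.6, 0.4])
            activity[i] = rng.integers(3, 9)
        steatosis[i] = rng.integers(1, 4)

    fib_eff = np.array([cfg.fibrosis_effect[GROUPS[g]] for g in group_idx])
    true_hgp = (
        cfg.baseline_hgp + fib_eff + cfg.t2d_effect * t2d
        + rng.normal(0, cfg.noise_sd["hgp"], n)
    )
    true_hgp = np.clip(true_hgp, 0.5, None)
    true_lip = (
        cfg.baseline_lipolysis
        + cfg.lipolysis_coupling * (true_hgp - cfg.baseline_hgp)
        + rng.normal(0, cfg.noise_sd["lipolysis"], n)
    )
    true_lip = np.clip(true_lip, 0.1, None)
    gng_frac = np.clip(
        0.50 + 0.04 * group_idx + 0.05 * t2d + rng.normal(0, 0.06, n),
        0.25, 0.95,
    )

    glucose = (88 + 10 * t2d + 1.5 * group_idx) * np.exp(rng.normal(0, 0.06, n))
    insulin = (9 + 2.2 * group_idx + 5 * t2d) * np.exp(rng.normal(0, 0.25, n))
    ffa = (0.35 + 0.08 * true_lip) * np.exp(rng.normal(0, 0.15, n))
    alt = (25 + 6 * activity) * np.exp(rng.normal(0, 0.30, n))
    ast = (22 + 4 * activity) * np.exp(rng.normal(0, 0.30, n))

    df = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "weight": np.round(weight, 6),
        "height": np.round(height, 6),
        "bmi": np.round(weight / (height / 100.0) ** 2, 6),
        "t2d": t2d,
        "fibrosis": fibrosis,
        "steatosis": steatosis,
        "activity_score": activity,
        "group": [GROUPS[g] for g in group_idx],
        "glucose": np.round(glucose, 6),
        "insulin": np.round(insulin, 6),
        "ffa": np.round(ffa, 6),
        "alt": np.round(alt, 6),
        "ast": np.round(ast, 6),
        "true_hgp": np.round(true_hgp, 6),
        "true_lipolysis": np.round(true_lip, 6),
        "true_gng_fraction": np.round(gng_frac, 6),
    })
    return df


def generate_expression(
    cohort: pd.DataFrame,
    genes: list[str],
    cfg: EffectConfig | None = None,
) -> pd.DataFrame:
    """Subjects x genes non-negative expression matrix.

    Log-expression of each gene is a gene-specific baseline (a stable
    function of the gene name, so separately generated cohort arms share
    one "platform") plus ``coupling * z``, where z is the subject's latent
    HGP deviation from the configured baseline in units of
    ``expression_reference_scale``, plus lognormal noise.  A negative
    coupling makes the gene anticorrelated with the latent flux.  An
    explicitly configured coupling for a gene not in ``genes`` is an error.
    """
    cfg = cfg or EffectConfig()
    if len(genes) == 0:
        raise SyntheticError("gene list must be non-empty")
    if len(cohort) == 0:
        raise SyntheticError("cohort must be non-empty")
    if cfg.expression_coupling is not None:
        unknown = sorted(set(cfg.expression_coupling) - set(genes))
        if unknown:
            raise SyntheticError(
                f"coupling configured for unknown genes: {unknown}")
        coupling = {g: cfg.expression_coupling.get(g, 0.0) for g in genes}
    else:
        coupling = {g: DEFAULT_GENE_COUPLING.get(g, 0.0) for g in genes}

    rng = np.random.default_rng([int(cfg.seed), 1])
    latent = cohort["true_hgp"].to_numpy(dtype=float)
    z = (latent - cfg.baseline_hgp) / cfg.expression_reference_scale
    sd_expr = cfg.noise_sd.get("expression", 0.3)

    data = {}
    for g in genes:
        gene_rng = np.random.default_rng(zlib.crc32(g.encode()))
        log_base = gene_rng.normal(2.0, 0.4)
        eps = rng.normal(0, sd_expr, len(cohort))
        data[g] = np.exp(log_base + coupling[g] * z + eps)
    expr = pd.DataFrame(data, index=cohort["id"].to_numpy())
    expr.index.name = "id"
    return expr


def generate_tracer_series(
    true_ra: float,
    infusion_rate: float,
    n_plateau: int = 5,
    noise_cv: float = 0.05,
    seed: int = 0,
    infusate_enrichment: float = 1.0,
    tracer: str = "glucose_d2",
) -> TracerSeries:
    """Plateau enrichment samples for a primed-continuous co-infusion.

    The noiseless plateau is the steady-state dilution value
    E = F * E_inf / (Ra_endo + F); samples get additive normal noise with
    coefficient of variation ``noise_cv``.
    """
    if true_ra <= 0 or infusion_rate <= 0:
        raise SyntheticError("true_ra and infusion_rate must be positive")
    if infusion_rate >= true_ra:
        raise SyntheticError(
            "tracer infusion must be small relative to turnover "
            f"(infusion_rate={infusion_rate} >= true_ra={true_ra})")
    if noise_cv < 0:
        raise SyntheticError("noise_cv must be non-negative")
    if n_plateau < 1:
        raise SyntheticError("need at least one plateau sample")
    e0 = infusion_rate * infusate_enrichment / (true_ra + infusion_rate)
    rng = np.random.default_rng([int(seed), 2])
    samples = e0 + rng.normal(0, noise_cv * e0, n_plateau)
    samples = np.clip(samples, 1e-12, 1 - 1e-12)
    return TracerSeries(
        tracer=tracer,
        infusion_rate=infusion_rate,
        plateau_enrichments=[float(s) for s in samples],
        infusate_enrichment=infusate_enrichment,
    )
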