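"""Steady-state stable-isotope dilution fluxomics.

Hepatic glucose production (HGP) from a primed-continuous 6,6-2H2-glucose
infusion and whole-body lipolysis from U-2H5-glycerol, both at isotopic
steady state: the rate of appearance Ra follows from dilution of the
infused tracer, Ra_total = F * E_inf / E_plateau, with the tracer infusion
F subtracted to give the endogenous rate (subtraction is configurable; the
two conventions differ by the infusion rate, under 2% at typical
enrichments).  The gluconeogenesis fraction is the product-to-precursor
enrichment ratio, gluconeogenesis flux its product with HGP, and fluxes are
normalized to lean body mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TracerSeries",
    "FluxEstimate",
    "TracerError",
    "NonSteadyStateError",
    "steady_state_ra",
    "gng_fraction",
    "gng_flux",
    "normalize_by_lbm",
    "mmol_h_from_umol_min",
]

#: accepted tracer labels
TRACERS = ("glucose_d2", "glycerol_d5")


class TracerError(ValueError):
    pass


class NonSteadyStateError(TracerError):
    """Plateau samples too variable to accept isotopic steady state."""


@dataclass
class TracerSeries:
    """One subject's tracer record: infusion rate (umol/min) and plateau
    enrichment samples (mole fraction, open interval (0, 1))."""

    tracer: str
    infusion_rate: float
    plateau_enrichments: list[float]
    infusate_enrichment: float = 1.0

    def __post_init__(self):
        if self.tracer not in TRACERS:
            raise TracerError(f"unknown tracer {self.tracer!r}; one of {TRACERS}")
        if self.infusion_rate <= 0:
            raise TracerError("infusion rate must be positive")
        if len(self.plateau_enrichments) == 0:
            raise TracerError("at least one plateau enrichment sample required")
        for e in self.plateau_enrichments:
            if not 0.0 < e < 1.0:
                raise TracerError(
                    f"plateau enrichment {e} outside the open interval (0, 1)"
                )
        if not 0.0 < self.infusate_enrichment <= 1.0:
            raise TracerError("infusate enrichment must be in (0, 1]")


@dataclass
class FluxEstimate:
    """Ra estimates in umol/min; per-LBM values in umol/min/kg."""

    ra_total: float
    ra_endogenous: float
    ra_per_lbm: float | None = None
    gng_fraction: float | None = None
    gng_flux: float | None = None


def steady_state_ra(
    series: TracerSeries,
    cv_threshold: float = 0.15,
    subtract_infusion: bool = True,
) -> FluxEstimate:
    """Rate of appearance from tracer dilution at isotopic steady state.

    The plateau is the mean of the provided samples; a sample CV above
    ``cv_threshold`` (default 15%) rejects steady state.  With
    ``subtract_infusion`` (default) the infusion rate F is removed:
    Ra_endo = F * E_inf / E_bar - F.
    """
    e = np.asarray(series.plateau_enrichments, dtype=float)
    e_bar = float(e.mean())
    if e_bar <= 0:
        raise TracerError("zero plateau enrichment: dilution undefined")
    if len(e) > 1:
        cv = float(e.std(ddof=1) / e_bar)
        if cv > cv_threshold:
            raise NonSteadyStateError(
                f"plateau CV {cv:.3f} exceeds threshold {cv_threshold:.3f}: "
                "non-steady-state"
            )
    f = series.infusion_rate
    ra_total = f * series.infusate_enrichment / e_bar
    ra_endo = ra_total - f if subtract_infusion else ra_total
    if ra_endo < 0:
        raise TracerError(
            "negative endogenous Ra: plateau enrichment exceeds infusate"
        )
    return FluxEstimate(ra_total=ra_total, ra_endogenous=ra_endo)


def gng_fraction(product_enrichment: float, precursor_enrichment: float) -> float:
    """Fractional gluconeogenesis: the product-to-precursor enrichment
    ratio, clipped to [0, 1] (a warning is emitted above 1)."""
    if precursor_enrichment <= 0:
        raise TracerError(
            "precursor enrichment must be positive "
            f"(got precursor_enrichment={precursor_enrichment})"
        )
    if product_enrichment < 0:
        raise TracerError("product enrichment must be non-negative")
    frac = product_enrichment / precursor_enrichment
    if frac > 1.0:
        warnings.warn(
            f"product/precursor ratio {frac:.3f} > 1; clipping to 1",
            stacklevel=2,
        )
        frac = 1.0
    return frac


def gng_flux(fraction: float, hgp_per_lbm: float) -> tuple[float, float]:
    """Gluconeogenesis flux = %GNG x HGP; glycogenolysis follows by
    difference.  Returns (gng, glycogenolysis) in the units of the HGP
    input."""
    if fraction < 0 or hgp_per_lbm < 0:
        raise TracerError("fraction and HGP must be non-negative")
    if fraction > 1:
        raise TracerError(f"gluconeogenesis fraction {fraction} exceeds 1")
    gng = fraction * hgp_per_lbm
    return gng, hgp_per_lbm - gng


def normalize_by_lbm(flux: float, lbm: float, to_mmol_h: bool = False) -> float:
    """Normalize a flux to lean body mass: umol/min -> umol/min/kg LBM, or
    with ``to_mmol_h`` to mmol/h/kg LBM (x 60 / 1000)."""
    if lbm <= 0:
        raise TracerError(f"lean body mass must be positive (got {lbm})")
    out = flux / lbm
    if to_mmol_h:
        out *= 60.0 / 1000.0
    return out


def mmol_h_from_umol_min(flux_umol_min: float) -> float:
    """Unit helper: umol/min -> mmol/h."""
    return flux_umol_min * 60.0 / 1000.0
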