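"""Body composition estimates and insulin-resistance indices.

Lean body mass from Hume's (1966) sex-specific anthropometric formula,
muscle mass as 0.63 * LBM - 4.1 kg, and the three fasting indices used in
hepatic insulin-resistance phenotyping:

* Hep-IR  = HGP x insulin          (flux unit x mU/L)
* Adipo-IR = FFA x insulin         (mmol/L x mU/L)
* HOMA-IR = glucose(mmol/L) x insulin(mU/L), optionally divided by the
  conventional 22.5.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BodyComposition",
    "IndexConfig",
    "IndicesError",
    "hume_lbm",
    "muscle_mass",
    "body_composition",
    "homa_ir",
    "hep_ir",
    "adipo_ir",
]


class IndicesError(ValueError):
    pass


#: mg/dL -> mmol/L conversion factor for glucose
GLUCOSE_MGDL_TO_MMOLL = 0.0555


@dataclass
class IndexConfig:
    """Coefficients live in config, sourced from Hume (1966): LBM =
    a*weight + b*height + c per sex; anthropometry outside the plausibility
    ranges raises unless ``clamp`` is enabled."""

    hume_male: tuple = (0.32810, 0.33929, -29.5336)
    hume_female: tuple = (0.29569, 0.41813, -43.2933)
    weight_range: tuple = (30.0, 250.0)   # kg
    height_range: tuple = (120.0, 220.0)  # cm
    muscle_slope: float = 0.63
    muscle_offset: float = 4.1
    homa_divisor: float = 1.0  # printed product form; set 22.5 for conventional
    clamp: bool = False


DEFAULT_CONFIG = IndexConfig()


@dataclass
class BodyComposition:
    lbm: float
    muscle_mass: float
    source: str = "hume"


def hume_lbm(weight: float, height: float, sex: str,
             cfg: IndexConfig = DEFAULT_CONFIG) -> float:
    """Lean body mass (kg) from weight (kg), height (cm) and sex via Hume's
    sex-specific linear formula."""
    lo_w, hi_w = cfg.weight_range
    lo_h, hi_h = cfg.height_range
    if not lo_w <= weight <= hi_w or not lo_h <= height <= hi_h:
        if cfg.clamp:
            import warnings

            warnings.warn(
                f"anthropometry out of range (weight={weight}, height={height});"
                " clamping", stacklevel=2)
            weight = min(max(weight, lo_w), hi_w)
            height = min(max(height, lo_h), hi_h)
        else:
            raise IndicesError(
                f"anthropometry out of range: weight={weight} kg, "
                f"height={height} cm")
    sex = str(sex).lower()
    if sex in ("male", "m"):
        a, b, c = cfg.hume_male
    elif sex in ("female", "f"):
        a, b, c = cfg.hume_female
    else:
        raise IndicesError(f"unknown sex {sex!r}")
    return a * weight + b * height + c


def muscle_mass(lbm: float, cfg: IndexConfig = DEFAULT_CONFIG) -> float:
    """Muscle mass (kg) = 0.63 * LBM - 4.1."""
    mm = cfg.muscle_slope * lbm - cfg.muscle_offset
    if mm <= 0:
        raise IndicesError(f"implausible LBM {lbm} kg: non-positive muscle mass")
    return mm


def body_composition(weight: float, height: float, sex: str,
                     lbm: float | None = None,
                     cfg: IndexConfig = DEFAULT_CONFIG) -> BodyComposition:
    """LBM (measured if provided, else Hume) plus derived muscle mass."""
    if lbm is None:
        lbm_val = hume_lbm(weight, height, sex, cfg)
        source = "hume"
    else:
        lbm_val = float(lbm)
        source = "measured"
    return BodyComposition(lbm=lbm_val, muscle_mass=muscle_mass(lbm_val, cfg),
                           source=source)


def homa_ir(glucose_mgdl: float, insulin_mul: float,
            cfg: IndexConfig = DEFAULT_CONFIG) -> float:
    """HOMA-IR = glucose(mmol/L) x insulin(mU/L) / divisor.

    The default divisor 1 reproduces the plain product form; 22.5 gives the
    conventional index.
    """
    if glucose_mgdl <= 0 or insulin_mul <= 0:
        raise IndicesError("glucose and insulin must be positive")
    return glucose_mgdl * GLUCOSE_MGDL_TO_MMOLL * insulin_mul / cfg.homa_divisor


def hep_ir(hgp: float, insulin_mul: float) -> float:
    """Hepatic insulin-resistance index: HGP x insulin.  Carries the flux
    unit of the HGP input (umol/min/kg LBM x mU/L in the tracer arm)."""
    if hgp < 0 or insulin_mul < 0:
        raise IndicesError("HGP and insulin must be non-negative")
    return hgp * insulin_mul


def adipo_ir(ffa_mmoll: float, insulin_mul: float) -> float:
    """Adipose-tissue insulin-resistance index: FFA (mmol/L) x insulin (mU/L)."""
    if ffa_mmoll < 0 or insulin_mul < 0:
        raise IndicesError("FFA and insulin must be non-negative")
    return ffa_mmoll * insulin_mul
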