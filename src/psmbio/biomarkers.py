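"""Imaging and clinical scores: ROI statistics, sFF, CEFR, SMI, MELD, CCC.

All biomarker formulas operate on ROI *mean* signals. The bilateral
paraspinous muscles are by default pooled by averaging the two per-muscle
mean signals first and applying the formula once (``bilateral="pool"``);
``bilateral="per_muscle"`` applies the formula per side and averages the two
fractions instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from psmbio.phantom import LABEL_MAP, MaskSet, PhaseImageSet

__all__ = [
    "RoiPanel",
    "BiomarkerPanel",
    "roi_stats",
    "compute_sff",
    "compute_cefr",
    "compute_smi",
    "compute_meld",
    "lin_ccc",
    "measure_biomarkers",
]

MM2_PER_CM2 = 100.0


@dataclass
class RoiStructureStats:
    """Per-structure ROI summary: mean signal per phase, area, voxel count."""

    mean_signal: dict[str, float]  # phase name -> mean voxel signal
    area_cm2: float
    voxel_count: int


@dataclass
class RoiPanel:
    """ROI summaries for left PSM, right PSM and aorta.

    The aortic means are recorded for completeness (the ROI protocol places
    one in the central aorta) but no downstream biomarker uses them.
    """

    structures: dict[str, RoiStructureStats]

    def __getitem__(self, name: str) -> RoiStructureStats:
        return self.structures[name]


@dataclass
class BiomarkerPanel:
    """Per-patient imaging biomarkers."""

    sff: float
    cefr_art: float
    cefr_pv: float
    cefr_del: float
    smi: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "sff": self.sff,
            "cefr_art": self.cefr_art,
            "cefr_pv": self.cefr_pv,
            "cefr_del": self.cefr_del,
            "smi": self.smi,
        }


def roi_stats(images: PhaseImageSet, masks: MaskSet) -> RoiPanel:
    """Per-structure, per-phase arithmetic mean signal and area.

    Area is ``voxel_count * voxel_area`` in cm^2. Raises a structured error
    naming the label if any of psm_left / psm_right / aorta is missing, and
    on image/mask shape mismatch.
    """
    if masks.labels.shape != images.shape:
        raise ValueError(
            f"mask shape {masks.labels.shape} does not match image shape {images.shape}"
        )
    voxel_area_cm2 = images.voxel_area_mm2 / MM2_PER_CM2
    structures: dict[str, RoiStructureStats] = {}
    for value, name in LABEL_MAP.items():
        mask = masks.labels == value
        count = int(mask.sum())
        if count == 0:
            raise ValueError(f"required ROI label {name!r} (value {value}) is missing")
        means = {
            phase: float(img[mask].mean()) for phase, img in images.phases.items()
        }
        structures[name] = RoiStructureStats(
            mean_signal=means,
            area_cm2=count * voxel_area_cm2,
            voxel_count=count,
        )
    return RoiPanel(structures=structures)


def compute_sff(si_inphase: float, si_outofphase: float) -> float:
    """Signal fat fraction from in-/out-of-phase mean signals.

    ``sFF = (SI_in - SI_out) / (2 * SI_in)``. The result is *not* clipped:
    ``si_outofphase > si_inphase`` is arithmetically valid but physically
    implies a negative fraction, so it is flagged with a warning and
    returned as-is.
    """
    if si_inphase <= 0:
        raise ValueError(f"in-phase signal must be positive, got {si_inphase}")
    if si_outofphase < 0:
        raise ValueError(f"out-of-phase signal must be non-negative, got {si_outofphase}")
    if si_outofphase > si_inphase:
        warnings.warn(
            "out-of-phase signal exceeds in-phase signal: sFF is negative "
            "(noise or non-Dixon input?)",
            stacklevel=2,
        )
    return (si_inphase - si_outofphase) / (2.0 * si_inphase)


def compute_cefr(si_noncontrast: float, si_enhanced: float) -> float:
    """Contrast enhancement fraction ``(SI_ce - SI_nc) / SI_nc``.

    A non-positive baseline means the exam shows no usable pre-contrast
    signal (the study design rejects non-enhancing exams rather than
    emitting NaN), so it raises.
    """
    if si_noncontrast <= 0:
        raise ValueError(
            f"non-contrast baseline must be positive, got {si_noncontrast}; "
            "non-enhancing exams are rejected, not silently NaN'd"
        )
    return (si_enhanced - si_noncontrast) / si_noncontrast


def compute_smi(area_left_cm2: float, area_right_cm2: float, height_m: float) -> float:
    """Skeletal muscle index: mean bilateral PSM area over height squared.

    Returns cm^2 m^-2.
    """
    if area_left_cm2 <= 0 or area_right_cm2 <= 0:
        raise ValueError("PSM areas must be positive")
    if height_m <= 0:
        raise ValueError("height must be positive")
    return ((area_left_cm2 + area_right_cm2) / 2.0) / height_m**2


def compute_meld(
    creatinine: float,
    tbili: float,
    inr: float,
    dialysis: bool = False,
) -> int:
    """Classic (pre-sodium) UNOS MELD score.

    Each laboratory value is clamped to >= 1.0; creatinine is capped at 4.0
    mg/dL and set to 4.0 if the patient is on dialysis. The raw score
    ``10 * (0.957 ln Cr + 0.378 ln Tbili + 1.120 ln INR + 0.643)`` is rounded
    half-up to the nearest integer and bounded to [6, 40].
    """
    if creatinine <= 0 or tbili <= 0 or inr <= 0:
        raise ValueError("laboratory values must be positive")
    cr = 4.0 if dialysis else min(creatinine, 4.0)
    cr = max(cr, 1.0)
    tb = max(tbili, 1.0)
    rn = max(inr, 1.0)
    raw = 10.0 * (0.957 * math.log(cr) + 0.378 * math.log(tb) + 1.120 * math.log(rn) + 0.643)
    score = int(math.floor(raw + 0.5))
    return int(min(max(score, 6), 40))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``
    with 1/n denominators. Measures agreement (precision x accuracy)
    between two measurement series, e.g. two observers segmenting the same
    muscles.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("concordance undefined: zero variance and equal means")
    return float(2.0 * cov / denom)


def measure_biomarkers(
    panel: RoiPanel,
    height_m: float,
    bilateral: str = "pool",
) -> BiomarkerPanel:
    """Full biomarker panel from ROI statistics and patient height.

    ``bilateral="pool"`` (default) averages the left/right PSM mean signals
    before applying the sFF and CEFR formulas; ``"per_muscle"`` applies the
    formula per side and averages the two fractions.
    """
    if bilateral not in ("pool", "per_muscle"):
        raise ValueError(f"unknown bilateral mode {bilateral!r}")
    left = panel["psm_left"]
    right = panel["psm_right"]
    flags: list[str] = []

    def _paired(fn, phase_a: str, phase_b: str) -> float:
        if bilateral == "pool":
            a = 0.5 * (left.mean_signal[phase_a] + right.mean_signal[phase_a])
            b = 0.5 * (left.mean_signal[phase_b] + right.mean_signal[phase_b])
            return fn(a, b)
        return 0.5 * (
            fn(left.mean_signal[phase_a], left.mean_signal[phase_b])
            + fn(right.mean_signal[phase_a], right.mean_signal[phase_b])
        )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sff = _paired(compute_sff, "inphase", "outofphase")
        cefr_art = _paired(compute_cefr, "noncontrast", "art")
        cefr_pv = _paired(compute_cefr, "noncontrast", "pv")
        cefr_del = _paired(compute_cefr, "noncontrast", "del")
    flags.extend(str(w.message) for w in caught)
    if not 0.0 <= sff <= 0.5:
        flags.append(f"sFF {sff:.4f} outside the water-dominant range [0, 0.5]")

    smi = compute_smi(left.area_cm2, right.area_cm2, height_m)
    return BiomarkerPanel(
        sff=sff,
        cefr_art=cefr_art,
        cefr_pv=cefr_pv,
        cefr_del=cefr_del,
        smi=smi,
        flags=flags,
    )
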