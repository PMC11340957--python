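"""Synthetic multi-phase abdominal MR phantom.

Renders a 2-D (single-slice) set of six co-registered phase images --
in-phase, out-of-phase, non-contrast T1 fat-sat, arterial, portal-venous and
delayed -- from elliptical structures with known water/fat composition and
known per-phase enhancement, plus an integer label mask. Because the ground
truth (fat fraction, enhancement fractions, analytic areas) is known exactly,
biomarker extraction can be validated by parameter recovery.

Signal model
------------
Magnitude two-point Dixon: ``SI_in = W + F`` and ``SI_out = |W - F|`` for
water density ``W`` and fat density ``F``. The fat-sat series uses a
multiplicative enhancement fraction on a baseline signal ``S0``:
``SI_phase = S0 * (1 + E_phase)``; there is no pharmacokinetic time curve,
the three post-contrast phases are fixed sampling points.

Note the inherent two-point Dixon ambiguity: ``(W, F)`` and ``(F, W)``
produce identical image pairs, so a downstream fat fraction computed from
the images recovers ``min(W, F) / (W + F)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "StructureSpec",
    "PhantomSpec",
    "PhaseImageSet",
    "MaskSet",
    "PHASE_NAMES",
    "PHASE_SUFFIXES",
    "LABEL_MAP",
    "dixon_pair",
    "render_phantom",
    "write_phantom",
    "read_phase_images",
    "read_mask",
]

#: canonical phase order used everywhere in the package
PHASE_NAMES = ("inphase", "outofphase", "noncontrast", "art", "pv", "del")

#: file suffixes for NIfTI export, one per phase
PHASE_SUFFIXES = {
    "inphase": "IP",
    "outofphase": "OOP",
    "noncontrast": "NC",
    "art": "ART",
    "pv": "PV",
    "del": "DEL",
}

#: integer labels of the mask image
LABEL_MAP = {1: "psm_left", 2: "psm_right", 3: "aorta"}

StructureLabel = Literal[
    "psm_left", "psm_right", "aorta", "background", "subcutaneous_fat"
]


class StructureSpec(BaseModel):
    """One elliptical structure with known composition and enhancement.

    Geometry is given in millimetres in slice coordinates (row axis = y,
    column axis = x). ``water_density`` / ``fat_density`` are arbitrary
    signal units feeding the Dixon pair; ``s0`` is the non-contrast fat-sat
    baseline and ``enhancement`` the (E_art, E_pv, E_del) fractions applied
    multiplicatively to it.
    """

    label: StructureLabel
    center_mm: tuple[float, float]  # (y, x) in mm
    semi_axes_mm: tuple[float, float]  # (a_y, a_x) in mm
    water_density: float = Field(ge=0.0)
    fat_density: float = Field(ge=0.0)
    s0: float = Field(gt=0.0)
    enhancement: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @model_validator(mode="after")
    def _check(self) -> "StructureSpec":
        if self.label != "background" and self.water_density + self.fat_density <= 0:
            raise ValueError(
                f"structure {self.label!r}: water + fat density must be > 0"
            )
        if any(e < -1.0 for e in self.enhancement):
            raise ValueError("enhancement fractions must be >= -1")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        return self

    @property
    def fat_fraction(self) -> float:
        """Ground-truth fat fraction F / (W + F)."""
        return self.fat_density / (self.water_density + self.fat_density)

    @property
    def area_mm2(self) -> float:
        """Analytic ellipse area pi * a * b in mm^2."""
        return float(np.pi * self.semi_axes_mm[0] * self.semi_axes_mm[1])


class PhantomSpec(BaseModel):
    """Full phantom description: grid, structures, noise model, seed."""

    shape: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (1.0, 1.0)  # (row, col)
    structures: list[StructureSpec]
    noise_sd: float = Field(default=0.0, ge=0.0)
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")
        labels = [s.label for s in self.structures if s.label != "background"]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate non-background structure labels")
        return self


@dataclass
class PhaseImageSet:
    """The six co-registered phase images plus voxel spacing (mm)."""

    inphase: np.ndarray
    outofphase: np.ndarray
    noncontrast: np.ndarray
    art: np.ndarray
    pv: np.ndarray
    del_: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.phases.values()}
        if len(shapes) != 1:
            raise ValueError(f"phase images have mismatched shapes: {shapes}")

    @property
    def phases(self) -> dict[str, np.ndarray]:
        return {
            "inphase": self.inphase,
            "outofphase": self.outofphase,
            "noncontrast": self.noncontrast,
            "art": self.art,
            "pv": self.pv,
            "del": self.del_,
        }

    @property
    def shape(self) -> tuple[int, ...]:
        return self.inphase.shape

    @property
    def voxel_area_mm2(self) -> float:
        return float(self.spacing_mm[0] * self.spacing_mm[1])


@dataclass
class MaskSet:
    """Integer label image aligned with a :class:`PhaseImageSet`."""

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(LABEL_MAP))

    def voxels(self, name: str) -> np.ndarray:
        """Boolean mask for a named structure; raises if the label is absent."""
        for value, label in self.label_map.items():
            if label == name:
                mask = self.labels == value
                if not mask.any():
                    raise ValueError(f"label {name!r} has no voxels in the mask")
                return mask
        raise KeyError(f"label {name!r} not in label map {self.label_map}")


def dixon_pair(water: float, fat: float) -> tuple[float, float]:
    """In-/out-of-phase magnitude signals for given water and fat densities.

    ``SI_in = W + F``, ``SI_out = |W - F|``. The pair is symmetric in
    (W, F): fat-dominant voxels alias onto their water-dominant mirror.
    """
    if water < 0 or fat < 0:
        raise ValueError("water and fat densities must be non-negative")
    if water + fat <= 0:
        raise ValueError("water + fat must be positive")
    return (water + fat, abs(water - fat))


def _ellipse_mask(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    center_mm: tuple[float, float],
    semi_axes_mm: tuple[float, float],
) -> np.ndarray:
    """Voxel-center-inside-ellipse rasterization.

    A voxel (i, j) belongs to the ellipse iff its center
    ((i + 0.5) * dy, (j + 0.5) * dx) lies strictly inside or on the boundary.
    """
    dy, dx = spacing
    yy = (np.arange(shape[0]) + 0.5) * dy
    xx = (np.arange(shape[1]) + 0.5) * dx
    cy, cx = center_mm
    ay, ax = semi_axes_mm
    y2 = ((yy - cy) / ay) ** 2
    x2 = ((xx - cx) / ax) ** 2
    return (y2[:, None] + x2[None, :]) <= 1.0


def render_phantom(
    spec: PhantomSpec,
) -> tuple[PhaseImageSet, MaskSet, dict[str, dict]]:
    """Render the six phase images, the label mask, and the ground truth.

    Structures are painted over the background; non-background structures
    must not overlap each other. Noise is additive Gaussian or Rician
    (magnitude of a complex Gaussian perturbation), seeded from the spec.

    Returns
    -------
    (images, masks, ground_truth) where ``ground_truth`` maps structure
    label to ``{"ff", "enhancement", "area_mm2", "voxel_count"}``.
    """
    shape = tuple(spec.shape)
    rng = np.random.default_rng(spec.seed)

    background = next(
        (s for s in spec.structures if s.label == "background"), None
    )
    foreground = [s for s in spec.structures if s.label != "background"]

    images = {name: np.zeros(shape, dtype=np.float64) for name in PHASE_NAMES}
    if background is not None:
        _paint(images, np.ones(shape, dtype=bool), background)

    labels = np.zeros(shape, dtype=np.int16)
    occupied = np.zeros(shape, dtype=bool)
    name_to_value = {v: k for k, v in LABEL_MAP.items()}
    ground_truth: dict[str, dict] = {}

    for struct in foreground:
        mask = _ellipse_mask(shape, spec.spacing_mm, struct.center_mm, struct.semi_axes_mm)
        if not mask.any():
            raise ValueError(f"structure {struct.label!r} covers no voxels")
        if (mask & occupied).any():
            raise ValueError(
                f"structure {struct.label!r} overlaps another non-background structure"
            )
        occupied |= mask
        _paint(images, mask, struct)
        if struct.label in name_to_value:
            labels[mask] = name_to_value[struct.label]
        ground_truth[struct.label] = {
            "ff": struct.fat_fraction,
            "enhancement": list(struct.enhancement),
            "area_mm2": struct.area_mm2,
            "voxel_count": int(mask.sum()),
        }

    if spec.noise_sd > 0:
        for name in PHASE_NAMES:
            if spec.noise_model == "gaussian":
                images[name] = images[name] + rng.normal(0.0, spec.noise_sd, shape)
            else:  # rician: magnitude of (signal + n1) + i*n2
                n1 = rng.normal(0.0, spec.noise_sd, shape)
                n2 = rng.normal(0.0, spec.noise_sd, shape)
                images[name] = np.hypot(images[name] + n1, n2)

    image_set = PhaseImageSet(
        inphase=images["inphase"],
        outofphase=images["outofphase"],
        noncontrast=images["noncontrast"],
        art=images["art"],
        pv=images["pv"],
        del_=images["del"],
        spacing_mm=tuple(spec.spacing_mm),
    )
    return image_set, MaskSet(labels=labels), ground_truth


def _paint(images: dict[str, np.ndarray], mask: np.ndarray, struct: StructureSpec) -> None:
    si_in, si_out = dixon_pair(struct.water_density, struct.fat_density)
    e_art, e_pv, e_del = struct.enhancement
    images["inphase"][mask] = si_in
    images["outofphase"][mask] = si_out
    images["noncontrast"][mask] = struct.s0
    images["art"][mask] = struct.s0 * (1.0 + e_art)
    images["pv"][mask] = struct.s0 * (1.0 + e_pv)
    images["del"][mask] = struct.s0 * (1.0 + e_del)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    return aff


def write_phantom(
    images: PhaseImageSet,
    masks: MaskSet,
    ground_truth: dict,
    out_dir: str | Path,
    prefix: str = "phantom",
) -> dict[str, Path]:
    """Write six phase NIfTIs, one integer mask NIfTI and a ground-truth JSON.

    Files are named ``{prefix}_{IP,OOP,NC,ART,PV,DEL}.nii.gz``,
    ``{prefix}_mask.nii.gz`` and ``{prefix}_truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(images.spacing_mm)
    written: dict[str, Path] = {}
    for name, img in images.phases.items():
        path = out / f"{prefix}_{PHASE_SUFFIXES[name]}.nii.gz"
        nib.save(nib.Nifti1Image(img.astype(np.float64), aff), path)
        written[name] = path
    mask_path = out / f"{prefix}_mask.nii.gz"
    nib.save(nib.Nifti1Image(masks.labels.astype(np.int16), aff), mask_path)
    written["mask"] = mask_path
    truth_path = out / f"{prefix}_truth.json"
    truth_path.write_text(json.dumps(ground_truth, indent=2))
    written["truth"] = truth_path
    return written


def read_phase_images(directory: str | Path, prefix: str = "phantom") -> PhaseImageSet:
    """Read the six phase NIfTIs written by :func:`write_phantom`.

    Values are returned as stored; negative voxels (possible under additive
    Gaussian noise) are preserved, never clipped.
    """
    directory = Path(directory)
    arrays: dict[str, np.ndarray] = {}
    spacing: Optional[tuple[float, float]] = None
    for name, suffix in PHASE_SUFFIXES.items():
        path = directory / f"{prefix}_{suffix}.nii.gz"
        if not path.exists():
            path = directory / f"{prefix}_{suffix}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing phase image {path}")
        img = nib.load(path)
        arrays[name] = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:2]
        if spacing is None:
            spacing = (float(zooms[0]), float(zooms[1]))
    assert spacing is not None
    return PhaseImageSet(
        inphase=arrays["inphase"],
        outofphase=arrays["outofphase"],
        noncontrast=arrays["noncontrast"],
        art=arrays["art"],
        pv=arrays["pv"],
        del_=arrays["del"],
        spacing_mm=spacing,
    )


def read_mask(path: str | Path) -> MaskSet:
    """Read an integer label NIfTI into a :class:`MaskSet`."""
    img = nib.load(path)
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("mask image contains non-integer labels")
    return MaskSet(labels=labels.astype(np.int16))
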