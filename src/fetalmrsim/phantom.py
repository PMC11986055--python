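"""Procedural fetal-brain-like numerical phantom.

The generator builds a deliberately simple but fully labeled anatomy:
concentric ellipsoidal shells (outer extra-axial CSF, a cortical grey
matter rim, a white matter bulk) enclosing deep grey nuclei, lateral
ventricles filled with intra-axial CSF, a corpus callosum slab, a
brainstem and a cerebellum, so that all eight label classes of the fine
dictionary occur.  Within the white matter, concentric intensity bands at
increasing distance from the ventricles emulate the multilayer appearance
of the maturing fetal white matter (migrating neurons leave a bright
germinal zone next to the ventricles); the band contrast shrinks with
gestational age.  Everything is deterministic given the seed.

The phantom is an engineering fixture: it reproduces the *structure* the
downstream pipeline needs (ordered T2w class contrast, banded WM,
ventricles that can be dilated), not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._errors import DegenerateInputError, ValidationError
from .anatomy import HRAnatomy

# T2w-like class base intensities (arbitrary units); CSF > GM > WM.
CLASS_INTENSITY = {
    0: 0.0,      # background
    1: 200.0,    # white matter (banding applied on top)
    2: 440.0,    # intra-axial CSF
    3: 290.0,    # cerebellum
    4: 440.0,    # extra-axial CSF
    5: 280.0,    # cortical GM
    6: 265.0,    # deep GM
    7: 225.0,    # brainstem
    8: 175.0,    # corpus callosum (dense fibers, hypointense)
}

WM_BASE = CLASS_INTENSITY[1]


def default_layer_contrast(ga_weeks: float) -> float:
    """Peak-to-peak WM band contrast (fraction of the WM mean) at a GA.

    Decays linearly from 0.35 at 21 weeks to 0.05 at 38 weeks, mirroring
    the fading of the layered WM appearance as maturation progresses.
    """
    t = np.clip((float(ga_weeks) - 21.0) / (38.0 - 21.0), 0.0, 1.0)
    return float(0.35 * (1.0 - t) + 0.05 * t)


@dataclass
class PhantomSpec:
    """Parameters of the procedural phantom.

    ``layer_contrast=None`` selects the GA-dependent default schedule.
    ``ventricle_dilation`` > 1 emulates a ventriculomegaly-like lesion.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    ga_weeks: float = 28.0
    n_wm_layers: int = 3
    layer_contrast: float | None = None
    noise_sd: float = 0.05
    seed: int = 0
    ventricle_dilation: float = 1.0
    subject_id: str = "phantom"
    condition: str = "neurotypical"

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.grid_shape) != 3 or any(n < 32 for n in self.grid_shape):
            raise ValidationError("grid_shape must be 3D with every axis >= 32")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive")
        if self.n_wm_layers < 1:
            raise ValidationError("n_wm_layers must be >= 1")
        if self.layer_contrast is not None and not (0 <= self.layer_contrast <= 1):
            raise ValidationError("layer_contrast must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.ventricle_dilation <= 0:
            raise ValidationError("ventricle_dilation must be positive")

    @property
    def contrast(self) -> float:
        if self.layer_contrast is not None:
            return float(self.layer_contrast)
        return default_layer_contrast(self.ga_weeks)


def _ellipsoid(coords_mm: Sequence[np.ndarray], center_mm: Sequence[float],
               semi_axes_mm: Sequence[float]) -> np.ndarray:
    r2 = sum(((c - mu) / a) ** 2
             for c, mu, a in zip(coords_mm, center_mm, semi_axes_mm))
    return r2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> HRAnatomy:
    """Build the labeled phantom anatomy described by ``spec``."""
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    # world coordinates (mm) centered on the volume
    axes = [(np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    half_extent = np.array([(n - 1) / 2.0 * d for n, d in zip(shape, spacing)])
    # head semi-axes: slightly oblate, leave a background margin
    a_head = half_extent * np.array([0.92, 0.88, 0.84])
    r = np.sqrt(sum((c / a) ** 2 for c, a in zip(coords, a_head)))

    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= 1.0] = 4                       # extra-axial CSF shell
    labels[r <= 0.88] = 5                      # cortical GM rim
    labels[r <= 0.78] = 1                      # WM bulk
    a_wm = a_head * 0.78

    def place(center_frac, semi_frac, code, within=1):
        center = np.asarray(center_frac) * a_wm
        semi = np.asarray(semi_frac) * a_wm
        m = _ellipsoid(coords, center, semi) & (labels == within)
        labels[m] = code
        return center, semi

    # cerebellum: posterior-inferior blob; brainstem: central-inferior
    place((0.0, -0.55, -0.55), (0.42, 0.30, 0.26), code=3)
    place((0.0, -0.05, -0.62), (0.22, 0.22, 0.34), code=7)
    # lateral ventricles (intra-axial CSF), dilation-scaled
    v_semi = np.array([0.16, 0.34, 0.18]) * spec.ventricle_dilation
    v_off = 0.30
    for sx in (-1.0, 1.0):
        center = np.array([sx * v_off, 0.05, 0.10]) * a_wm
        semi = v_semi * a_wm
        if np.any(np.abs(center) + semi > a_wm):
            raise ValidationError(
                "ventricle_dilation pushes the ventricles beyond the WM extent")
        m = _ellipsoid(coords, center, semi) & (labels == 1)
        labels[m] = 2
    # deep GM nuclei lateral to the ventricles
    for sx in (-1.0, 1.0):
        place((sx * 0.55, 0.05, 0.05), (0.16, 0.22, 0.16), code=6)
    # corpus callosum: thin midline slab above the ventricles
    cc = (np.abs(coords[0]) <= 0.16 * a_wm[0]) \
        & (np.abs(coords[1] - 0.05 * a_wm[1]) <= 0.30 * a_wm[1]) \
        & (np.abs(coords[2] - 0.38 * a_wm[2]) <= 0.08 * a_wm[2]) \
        & (labels == 1)
    labels[cc] = 8

    intensity = np.zeros(shape, dtype=np.float64)
    for code, value in CLASS_INTENSITY.items():
        intensity[labels == code] = value

    # WM banding by distance to the nearest ventricle voxel
    wm = labels == 1
    if spec.n_wm_layers > 1 and spec.contrast > 0 and wm.any():
        dist = ndimage.distance_transform_edt(labels != 2, sampling=spacing)
        dmax = dist[wm].max()
        t = np.clip(dist / max(dmax, 1e-9), 0.0, 1.0 - 1e-9)
        band = np.floor(t * spec.n_wm_layers).astype(int)
        # innermost band (next to the ventricles) is the brightest
        rel = 0.5 - band / (spec.n_wm_layers - 1)
        intensity[wm] = WM_BASE * (1.0 + spec.contrast * rel[wm])

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sd * WM_BASE, size=shape)
        np.maximum(intensity, 0.0, out=intensity)

    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = -half_extent
    return HRAnatomy(intensity=intensity, labels=labels, affine=affine,
                     ga_weeks=spec.ga_weeks, subject_id=spec.subject_id,
                     condition=spec.condition)


def wm_intensity_sd(anatomy: HRAnatomy, wm_mask: np.ndarray) -> float:
    """Sample standard deviation of the intensity over a WM mask."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise DegenerateInputError("WM mask is empty")
    vals = anatomy.intensity[wm_mask]
    if vals.size < 2:
        return 0.0
    return float(np.std(vals, ddof=1))


def synthetic_sigma_table(ga_range=range(21, 39), grid: int = 48,
                          spacing: float = 0.5, seed: int = 0) -> dict[int, float]:
    """WM intensity spread per integer GA, measured on phantoms.

    Synthetic stand-in for an atlas-derived sigma table (the band contrast
    schedule makes it monotonically shrink with GA); it feeds the default
    maturation schedule and is labeled non-authoritative.
    """
    table = {}
    for ga in ga_range:
        spec = PhantomSpec(grid_shape=(grid,) * 3,
                           spacing_mm=(spacing,) * 3,
                           ga_weeks=float(np.clip(ga, 18, 40)),
                           seed=seed)
        anat = generate_phantom(spec)
        table[int(ga)] = wm_intensity_sd(anat, anat.labels == 1)
    return table
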