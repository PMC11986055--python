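"""Single-shot fast spin echo (HASTE / SS-FSE) acquisition simulator.

From voxelwise T1/T2/PD maps the module produces clinical-style stacks of
thick 2D slices: the echo-train signal is computed with the extended
phase graph (EPG) recursion, slices are boxcar averages of the
high-resolution volume over the slice thickness, and k-space is filled
line by line with the image of the echo at which each phase-encode line
is acquired (half/partial Fourier, phase oversampling, parallel-imaging
acceleration with fully sampled reference lines, complex Gaussian noise,
zero-filled magnitude reconstruction).

Acquisition presets encode the published clinical protocols of the two
sequence families at 1.5 T and 3 T; ranged protocol entries default to
their midpoints and can be sampled uniformly for cohort diversity.

Conventions
-----------
* Fourier transforms are orthonormal and centered (DC at ``n // 2``), so
  Parseval holds exactly and k-space/image noise scales coincide.
* Acceleration is idealized: skipped lines are filled with their exact
  simulated values (a single-coil simulation cannot produce parallel-
  imaging residuals); the contrast effect of the shorter train remains.
* Partial Fourier is reconstructed by zero-filling plus magnitude.
* Inter-shot saturation is ``1 - exp(-(TR - ETL*esp)/T1)``; a missing TR
  means a fully relaxed single shot (factor 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from ._errors import (
    DegenerateInputError,
    GeometryError,
    ParameterError,
    ValidationError,
)
from .relaxometry import QuantitativeMaps

ORIENTATION_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}


# ---------------------------------------------------------------------------
# Sequence parameters and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceParams:
    """One acquisition's parameter set.

    ``ranges`` records protocol entries given as (min, max); the scalar
    fields hold the active (default: midpoint) value.
    """

    name: str
    field_tesla: float
    te_eff_ms: float
    echo_spacing_ms: float
    etl: int
    flip_exc_deg: float = 90.0
    flip_refoc_deg: float = 180.0
    tr_ms: float | None = None
    slice_thickness_mm: float = 3.0
    slice_gap_mm: float = 0.0
    phase_oversampling_pct: float = 0.0
    fov_shift_mm: float = 0.0
    fov_read_mm: float = 300.0
    base_resolution: int = 256
    phase_resolution_pct: float = 100.0
    recon_matrix: int = 256
    zero_fill: bool = False
    accel_factor: int = 1
    reference_lines: int = 0
    noise_mean: float = 0.0
    noise_sd: float = 0.05
    sampling_pct: float | None = None
    slice_padding: int = 2
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.etl < 1 or self.echo_spacing_ms <= 0:
            raise ValidationError("need etl >= 1 and echo spacing > 0")
        if not (0 < self.flip_refoc_deg <= 180) or not (0 < self.flip_exc_deg <= 180):
            raise ValidationError("flip angles must lie in (0, 180] degrees")
        if self.accel_factor < 1 or self.reference_lines < 0:
            raise ValidationError("invalid acceleration settings")

    @property
    def n_phase_nominal(self) -> int:
        return int(round(self.base_resolution * self.phase_resolution_pct / 100.0))

    @property
    def n_phase_full(self) -> int:
        """Phase lines including the oversampled band."""
        return int(round(self.n_phase_nominal
                         * (1.0 + self.phase_oversampling_pct / 100.0)))

    @property
    def slice_pitch_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    def sample(self, rng: np.random.Generator) -> "SequenceParams":
        """Draw ranged entries uniformly (cohort diversity)."""
        draws = {}
        for name, (lo, hi) in self.ranges.items():
            v = float(rng.uniform(lo, hi))
            if name in ("fov_read_mm",):
                v = float(round(v))
            draws[name] = v
        return replace(self, **draws)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "name", "field_tesla", "te_eff_ms", "echo_spacing_ms", "etl",
            "flip_exc_deg", "flip_refoc_deg", "tr_ms", "slice_thickness_mm",
            "slice_gap_mm", "phase_oversampling_pct", "fov_shift_mm",
            "fov_read_mm", "base_resolution", "phase_resolution_pct",
            "recon_matrix", "zero_fill", "accel_factor", "reference_lines",
            "noise_mean", "noise_sd", "sampling_pct")}
        d["ranges"] = {k: list(v) for k, v in self.ranges.items()}
        return d


def _mid(lo, hi):
    return 0.5 * (lo + hi)


_PRESETS = {
    ("HASTE", 1.5): dict(
        te_eff_ms=_mid(82, 90), echo_spacing_ms=4.08, etl=134,
        flip_refoc_deg=_mid(149, 180), tr_ms=None,
        slice_thickness_mm=3.0, slice_gap_mm=0.3,
        phase_oversampling_pct=80.0, fov_shift_mm=0.0, fov_read_mm=360.0,
        base_resolution=320, phase_resolution_pct=70.0, recon_matrix=320,
        zero_fill=False, accel_factor=2, reference_lines=42,
        noise_mean=0.0, noise_sd=0.05, sampling_pct=None,
        ranges={"te_eff_ms": (82.0, 90.0), "flip_refoc_deg": (149.0, 180.0)},
    ),
    ("HASTE", 3.0): dict(
        te_eff_ms=101.0, echo_spacing_ms=10.0, etl=126,
        flip_refoc_deg=180.0, tr_ms=None,
        slice_thickness_mm=3.0, slice_gap_mm=0.0,
        phase_oversampling_pct=63.0, fov_shift_mm=0.0, fov_read_mm=350.0,
        base_resolution=320, phase_resolution_pct=75.0, recon_matrix=640,
        zero_fill=True, accel_factor=2, reference_lines=24,
        noise_mean=0.0, noise_sd=0.004, sampling_pct=None,
        ranges={},
    ),
    ("SSFSE", 1.5): dict(
        te_eff_ms=_mid(116, 124), echo_spacing_ms=10.0, etl=224,
        flip_refoc_deg=_mid(150, 180), tr_ms=3000.0,
        slice_thickness_mm=3.0, slice_gap_mm=0.0,
        phase_oversampling_pct=0.0, fov_shift_mm=1.6, fov_read_mm=270.0,
        base_resolution=256, phase_resolution_pct=100.0, recon_matrix=512,
        zero_fill=True, accel_factor=1, reference_lines=0,
        noise_mean=0.0, noise_sd=0.05, sampling_pct=55.0,
        ranges={"te_eff_ms": (116.0, 124.0), "flip_refoc_deg": (150.0, 180.0),
                "fov_read_mm": (240.0, 300.0), "noise_sd": (0.03, 0.07),
                "tr_ms": (2000.0, 3500.0)},
    ),
    ("SSFSE", 3.0): dict(
        te_eff_ms=_mid(117, 123), echo_spacing_ms=10.0, etl=224,
        flip_refoc_deg=_mid(150, 180), tr_ms=3000.0,
        slice_thickness_mm=3.0, slice_gap_mm=0.0,
        phase_oversampling_pct=0.0, fov_shift_mm=1.6, fov_read_mm=280.0,
        base_resolution=256, phase_resolution_pct=100.0, recon_matrix=512,
        zero_fill=True, accel_factor=1, reference_lines=0,
        noise_mean=0.0, noise_sd=0.004, sampling_pct=55.0,
        ranges={"te_eff_ms": (117.0, 123.0), "flip_refoc_deg": (150.0, 180.0),
                "fov_read_mm": (240.0, 320.0), "noise_sd": (0.002, 0.006),
                "tr_ms": (2000.0, 3500.0)},
    ),
}


def sequence_preset(name: str, field_tesla: float, **overrides) -> SequenceParams:
    """Clinical acquisition preset for (sequence, field) with optional
    overrides of individual fields."""
    key = (str(name).upper().replace("-", ""), float(field_tesla))
    if key not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r} at {field_tesla} T; available: "
            f"{sorted(_PRESETS)}")
    kw = dict(_PRESETS[key])
    ranges = dict(kw.pop("ranges"))
    for k, v in overrides.items():
        if k in ranges:
            ranges.pop(k)
        kw[k] = v
    return SequenceParams(name=key[0], field_tesla=key[1], ranges=ranges, **kw)


# ---------------------------------------------------------------------------
# Extended phase graph
# ---------------------------------------------------------------------------

def _rf_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    a = math.radians(flip_deg)
    phi = math.radians(phase_deg)
    c2, s2, s = math.cos(a / 2) ** 2, math.sin(a / 2) ** 2, math.sin(a)
    ep, e2p = np.exp(1j * phi), np.exp(2j * phi)
    return np.array([
        [c2, e2p * s2, -1j * ep * s],
        [np.conj(e2p) * s2, c2, 1j * np.conj(ep) * s],
        [-0.5j * np.conj(ep) * s, 0.5j * ep * s, math.cos(a)],
    ])


def _epg_batch(t1_ms: np.ndarray, t2_ms: np.ndarray, esp_ms: float, etl: int,
               flip_exc_deg: float, flip_refoc_deg: float,
               max_states: int | None = None) -> np.ndarray:
    """EPG echo amplitudes, vectorized over (T1, T2) pairs.

    Returns an (etl, P) array of echo magnitudes.  Excitation phase is 90
    degrees ahead of the refocusing pulses (CPMG condition).
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if np.any(t2 <= 0) or np.any(t1 <= t2):
        raise ValidationError("require t1 > t2 > 0 for every pair")
    n_states = etl + 1
    if max_states is not None and n_states > max_states:
        raise ParameterError(
            f"echo train of {etl} needs {n_states} configuration states, "
            f"more than the configured maximum {max_states}")
    P = t1.size
    fp = np.zeros((n_states, P), dtype=complex)
    fm = np.zeros((n_states, P), dtype=complex)
    z = np.zeros((n_states, P), dtype=complex)
    z[0] = 1.0

    def apply_rf(T):
        nonlocal fp, fm, z
        fp, fm, z = (T[0, 0] * fp + T[0, 1] * fm + T[0, 2] * z,
                     T[1, 0] * fp + T[1, 1] * fm + T[1, 2] * z,
                     T[2, 0] * fp + T[2, 1] * fm + T[2, 2] * z)

    e2 = np.exp(-esp_ms / 2.0 / t2)[None, :]
    e1 = np.exp(-esp_ms / 2.0 / t1)[None, :]

    def relax_half():
        nonlocal fp, fm, z
        fp *= e2
        fm *= e2
        z *= e1
        z[0] += 1.0 - e1[0]

    def grad_shift():
        nonlocal fp, fm
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fp[1:] = fp[:-1]
        fp[0] = np.conj(fm[0])

    apply_rf(_rf_matrix(flip_exc_deg, 90.0))
    refoc = _rf_matrix(flip_refoc_deg, 0.0)
    echoes = np.empty((etl, P))
    for n in range(etl):
        relax_half()
        grad_shift()
        apply_rf(refoc)
        relax_half()
        grad_shift()
        echoes[n] = np.abs(fp[0])
    return echoes


def epg_echo_amplitudes(t1_ms: float, t2_ms: float, esp_ms: float, etl: int,
                        flip_exc_deg: float = 90.0,
                        flip_refoc_deg: float = 180.0,
                        max_states: int | None = None) -> np.ndarray:
    """Echo-train amplitudes for a single (T1, T2) pair, length ``etl``."""
    return _epg_batch(np.array([t1_ms]), np.array([t2_ms]), esp_ms, etl,
                      flip_exc_deg, flip_refoc_deg, max_states)[:, 0]


# ---------------------------------------------------------------------------
# Phase-encode line ordering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineOrder:
    """Which k-space rows are acquired, at which echo, and which skipped
    rows are filled by idealized parallel imaging."""

    n_full: int
    n_nominal: int
    center_row: int
    acquired_rows: np.ndarray       # ascending k-row indices
    echo_of_acquired: np.ndarray    # 1-based echo index per acquired row
    filled_rows: np.ndarray
    echo_of_filled: np.ndarray
    realized_te_ms: float

    def echoes_used(self) -> np.ndarray:
        return np.unique(np.concatenate(
            [self.echo_of_acquired, self.echo_of_filled])).astype(int)


def effective_te_line_order(params: SequenceParams) -> LineOrder:
    """Derive the acquired-line set and the line-to-echo mapping.

    Lines are acquired in linearly increasing k-row order so that the
    central row falls on echo ``round(te_eff / esp)``; half/partial
    Fourier omits the early rows, acceleration skips every
    ``accel_factor``-th row outside the fully sampled reference band.
    """
    n_full = params.n_phase_full
    c = n_full // 2
    esp = params.echo_spacing_ms
    e_c = int(round(params.te_eff_ms / esp))
    max_te = params.etl * esp
    if e_c < 1 or params.te_eff_ms > max_te:
        raise ParameterError(
            f"te_eff={params.te_eff_ms} ms unreachable; feasible range is "
            f"[{esp:.2f}, {max_te:.2f}] ms with esp={esp} ms, etl={params.etl}")
    half_ref = params.reference_lines // 2

    def sampled(row: int) -> bool:
        if params.reference_lines > 0 and abs(row - c) <= half_ref:
            return True
        return (row - c) % params.accel_factor == 0

    below = [r for r in range(c - 1, -1, -1) if sampled(r)]
    if len(below) < e_c - 1:
        feasible_max = (len(below) + 1) * esp
        raise ParameterError(
            f"te_eff={params.te_eff_ms} ms needs {e_c - 1} lines before the "
            f"k-space center but only {len(below)} exist; feasible range is "
            f"[{esp:.2f}, {feasible_max:.2f}] ms")
    start = below[e_c - 2] if e_c > 1 else c
    rows = [r for r in range(start, n_full) if sampled(r)]
    # cap the covered band: echo-train length, and the partial-Fourier
    # sampling percentage for SS-FSE
    rows = rows[: params.etl]
    if params.sampling_pct is not None:
        n_target = int(round(n_full * params.sampling_pct / 100.0))
        rows = [r for r in rows if r - start < n_target]
    acquired = np.asarray(rows, dtype=int)
    if c not in set(rows):
        raise ParameterError("k-space center excluded by the sampling caps")
    echo_of_acquired = np.arange(1, acquired.size + 1)
    assert echo_of_acquired[acquired == c][0] == e_c
    filled = np.array([r for r in range(start, acquired[-1] + 1)
                       if r not in set(rows)], dtype=int)
    if filled.size:
        d = np.abs(filled[:, None] - acquired[None, :])
        donor = np.argmin(d, axis=1)  # ties resolve to the earlier echo
        echo_of_filled = echo_of_acquired[donor]
    else:
        echo_of_filled = np.empty(0, dtype=int)
    return LineOrder(n_full=n_full, n_nominal=params.n_phase_nominal,
                     center_row=c, acquired_rows=acquired,
                     echo_of_acquired=echo_of_acquired,
                     filled_rows=filled, echo_of_filled=echo_of_filled,
                     realized_te_ms=e_c * esp)


# ---------------------------------------------------------------------------
# Centered orthonormal Fourier helpers
# ---------------------------------------------------------------------------

def fft2c(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ksp), norm="ortho"))


# ---------------------------------------------------------------------------
# Slab resampling
# ---------------------------------------------------------------------------

@dataclass
class SlabStack:
    """Per-slice T1/T2/PD grids on the acquisition matrix.

    Arrays are indexed ``[slice, phase, read]``; geometry records the HR
    axes and sampling coordinates so annotations can follow the same
    mapping.
    """

    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    geometry: dict


def _inplane_sample(plane2d: np.ndarray, read_axis_first: bool,
                    read_idx: np.ndarray, phase_idx: np.ndarray,
                    fill: float) -> np.ndarray:
    """Nearest-neighbor sample of a 2D HR plane at LR grid coordinates.

    ``plane2d`` axes follow the HR axis order of the two in-plane axes.
    Returns a [phase, read] array.
    """
    if read_axis_first:
        nr, npx = plane2d.shape
    else:
        npx, nr = plane2d.shape
    r_ok = (read_idx >= 0) & (read_idx < nr)
    p_ok = (phase_idx >= 0) & (phase_idx < npx)
    r = np.clip(read_idx, 0, nr - 1)
    p = np.clip(phase_idx, 0, npx - 1)
    if read_axis_first:
        out = plane2d[np.ix_(r, p)].T      # -> [phase, read]
    else:
        out = plane2d[np.ix_(p, r)]
    out = np.array(out, dtype=float)
    out[~p_ok, :] = fill
    out[:, ~r_ok] = fill
    return out


def _slab_plane_indices(center_mm: float, thickness: float, spacing: float,
                        n: int) -> np.ndarray:
    lo = int(math.ceil((center_mm - thickness / 2.0) / spacing - 1e-9))
    hi = int(math.floor((center_mm + thickness / 2.0) / spacing + 1e-9))
    return np.arange(max(lo, 0), min(hi, n - 1) + 1)


def resample_to_slices(qmaps: QuantitativeMaps, orientation: str,
                       params: SequenceParams, run_index: int) -> SlabStack:
    """Boxcar-average the quantitative maps into thick slices and sample
    them onto the acquisition grid.

    Run 2 is offset along the slice axis by half a pitch ("partially
    overlapping" series); the FOV shift is applied along the phase axis
    with a sign alternating between runs.
    """
    if orientation not in ORIENTATION_AXES:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if run_index not in (1, 2):
        raise ValidationError("run_index must be 1 or 2")
    s_ax = ORIENTATION_AXES[orientation]
    r_ax, p_ax = [a for a in range(3) if a != s_ax]
    spacing = qmaps.spacing
    brain = qmaps.pd_map > 0
    if not brain.any():
        raise DegenerateInputError("empty proton-density volume")
    idx = np.argwhere(brain)
    bb_min, bb_max = idx.min(axis=0), idx.max(axis=0)
    center_mm = (bb_min + bb_max) / 2.0 * spacing
    extent_mm = (bb_max - bb_min + 1) * spacing

    fov = params.fov_read_mm
    if extent_mm[r_ax] > fov or extent_mm[p_ax] > fov * (
            1 + params.phase_oversampling_pct / 100.0):
        warnings.warn("brain extent exceeds the field of view; cropping",
                      stacklevel=2)
    pitch = params.slice_pitch_mm
    n_slices = int(math.ceil(extent_mm[s_ax] / pitch)) + params.slice_padding
    offset = pitch / 2.0 if run_index == 2 else 0.0
    slice_centers = (center_mm[s_ax] + offset
                     + (np.arange(n_slices) - (n_slices - 1) / 2.0) * pitch)

    shift = params.fov_shift_mm * (1.0 if run_index == 1 else -1.0)
    base = params.base_resolution
    n_full = params.n_phase_full
    pix_read = fov / base
    pix_phase = fov / params.n_phase_nominal
    read_mm = (np.arange(base) - base // 2) * pix_read + center_mm[r_ax]
    phase_mm = ((np.arange(n_full) - n_full // 2) * pix_phase
                + center_mm[p_ax] + shift)
    read_idx = np.rint(read_mm / spacing[r_ax]).astype(int)
    phase_idx = np.rint(phase_mm / spacing[p_ax]).astype(int)
    read_axis_first = r_ax < p_ax

    shape = (n_slices, n_full, base)
    t1 = np.ones(shape)
    t2 = np.ones(shape)
    pd = np.zeros(shape)
    n_along = qmaps.shape[s_ax]
    for s, sc in enumerate(slice_centers):
        planes = _slab_plane_indices(sc, params.slice_thickness_mm,
                                     spacing[s_ax], n_along)
        if planes.size == 0:
            continue
        for vol, out, fill in ((qmaps.t1_map, t1, 1.0),
                               (qmaps.t2_map, t2, 1.0),
                               (qmaps.pd_map, pd, 0.0)):
            slab = vol.take(planes, axis=s_ax).mean(axis=s_ax)
            out[s] = _inplane_sample(slab, read_axis_first,
                                     read_idx, phase_idx, fill)
    geometry = {
        "orientation": orientation, "run_index": run_index,
        "slice_axis": s_ax, "read_axis": r_ax, "phase_axis": p_ax,
        "slice_centers_mm": slice_centers, "center_mm": center_mm,
        "shift_mm": shift, "pitch_mm": pitch,
        "hr_shape": qmaps.shape, "hr_affine": qmaps.affine,
        "hr_spacing": spacing,
    }
    return SlabStack(t1=t1, t2=t2, pd=pd, geometry=geometry)


# ---------------------------------------------------------------------------
# k-space synthesis and reconstruction
# ---------------------------------------------------------------------------

class EPGLookup:
    """Echo-amplitude table over quantized (T1, T2) pairs."""

    def __init__(self, params: SequenceParams,
                 t1_quant_ms: float = 10.0, t2_quant_ms: float = 1.0):
        self.params = params
        self.t1_quant = t1_quant_ms
        self.t2_quant = t2_quant_ms
        self._table: dict[tuple[float, float], np.ndarray] = {}

    def quantize(self, t1: np.ndarray, t2: np.ndarray):
        t1q = np.round(np.asarray(t1) / self.t1_quant) * self.t1_quant
        t2q = np.round(np.asarray(t2) / self.t2_quant) * self.t2_quant
        t1q = np.maximum(t1q, t2q + self.t1_quant)  # keep T1 > T2
        return t1q, t2q

    def amplitudes(self, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
        """(etl, ...) echo amplitudes for quantized voxelwise T1/T2."""
        t1q, t2q = self.quantize(t1, t2)
        pairs = np.stack([t1q.ravel(), t2q.ravel()], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        p = self.params
        table = _epg_batch(uniq[:, 0], uniq[:, 1], p.echo_spacing_ms, p.etl,
                           p.flip_exc_deg, p.flip_refoc_deg)
        return table[:, inverse].reshape((p.etl,) + t1q.shape)


def _saturation(t1: np.ndarray, params: SequenceParams) -> np.ndarray:
    if params.tr_ms is None:
        return np.ones_like(t1)
    recovery = max(params.tr_ms - params.etl * params.echo_spacing_ms, 0.0)
    return 1.0 - np.exp(-recovery / np.maximum(t1, 1e-6))


def simulate_kspace_slice(slab_t1: np.ndarray, slab_t2: np.ndarray,
                          slab_pd: np.ndarray, params: SequenceParams,
                          order: LineOrder, rng: np.random.Generator,
                          echo_amplitudes: np.ndarray | None = None):
    """Fill one slice's k-space line by line.

    Each acquired row takes the matching row of the centered orthonormal
    2D FFT of the echo image ``PD * E_n(T1, T2) * saturation``; skipped
    accelerated rows are filled with their exact values at the nearest
    acquired echo; unacquired partial-Fourier rows stay zero.  Complex
    Gaussian noise (per-channel sd ``noise_sd``) is added to acquired
    samples only.  Returns ``(kspace, acquired_row_mask)``.
    """
    if slab_t1.shape != (order.n_full, params.base_resolution):
        raise GeometryError("slab grid does not match the acquisition matrix")
    if echo_amplitudes is None:
        echo_amplitudes = EPGLookup(params).amplitudes(slab_t1, slab_t2)
    base_img = slab_pd * _saturation(slab_t1, params)
    ksp = np.zeros((order.n_full, params.base_resolution), dtype=complex)
    rows_by_echo: dict[int, list[int]] = {}
    for r, e in zip(order.acquired_rows, order.echo_of_acquired):
        rows_by_echo.setdefault(int(e), []).append(int(r))
    for r, e in zip(order.filled_rows, order.echo_of_filled):
        rows_by_echo.setdefault(int(e), []).append(int(r))
    for e, rows in rows_by_echo.items():
        img = base_img * echo_amplitudes[e - 1]
        k = fft2c(img)
        ksp[rows, :] = k[rows, :]
    if params.noise_sd > 0 or params.noise_mean != 0:
        nshape = (order.acquired_rows.size, params.base_resolution)
        noise = (rng.normal(params.noise_mean, params.noise_sd, nshape)
                 + 1j * rng.normal(params.noise_mean, params.noise_sd, nshape))
        ksp[order.acquired_rows, :] += noise
    mask = np.zeros(order.n_full, dtype=bool)
    mask[order.acquired_rows] = True
    return ksp, mask


def reconstruct_slice(kspace: np.ndarray, params: SequenceParams) -> np.ndarray:
    """Zero-filled magnitude reconstruction onto the recon matrix.

    The phase-oversampled band is cropped to the nominal FOV in image
    space, then k-space is zero-padded to ``recon_matrix`` squared (the
    zero-interpolation filling of the protocols) and the magnitude taken.
    """
    n_full, base = kspace.shape
    n_nom = params.n_phase_nominal
    img = ifft2c(kspace)
    r0 = n_full // 2 - n_nom // 2
    img = img[r0:r0 + n_nom, :]
    recon = params.recon_matrix
    if (n_nom, base) != (recon, recon):
        k2 = fft2c(img)
        kpad = np.zeros((recon, recon), dtype=complex)
        p0 = recon // 2 - n_nom // 2
        q0 = recon // 2 - base // 2
        kpad[p0:p0 + n_nom, q0:q0 + base] = k2
        img = ifft2c(kpad) * math.sqrt(recon * recon / (n_nom * base))
    return np.abs(img)


# ---------------------------------------------------------------------------
# Series assembly
# ---------------------------------------------------------------------------

@dataclass
class LRSeries:
    """A simulated low-resolution series: [read, phase, slice] magnitude
    stack with its world affine and full provenance."""

    data: np.ndarray
    affine: np.ndarray
    orientation: str
    run_index: int
    params: SequenceParams
    seed: int
    subject_id: str = "unknown"
    geometry: dict = field(default_factory=dict)


def _series_affine(geometry: dict, params: SequenceParams,
                   recon_coords_read: np.ndarray,
                   recon_coords_phase: np.ndarray) -> np.ndarray:
    r_ax, p_ax, s_ax = (geometry["read_axis"], geometry["phase_axis"],
                        geometry["slice_axis"])
    spacing = geometry["hr_spacing"]
    pitch = geometry["pitch_mm"]
    centers = geometry["slice_centers_mm"]
    pix = params.fov_read_mm / params.recon_matrix
    lr_to_hr = np.zeros((4, 4))
    lr_to_hr[3, 3] = 1.0
    lr_to_hr[r_ax, 0] = pix / spacing[r_ax]
    lr_to_hr[p_ax, 1] = pix / spacing[p_ax]
    lr_to_hr[s_ax, 2] = pitch / spacing[s_ax]
    lr_to_hr[r_ax, 3] = recon_coords_read[0] / spacing[r_ax]
    lr_to_hr[p_ax, 3] = recon_coords_phase[0] / spacing[p_ax]
    lr_to_hr[s_ax, 3] = centers[0] / spacing[s_ax]
    return np.asarray(geometry["hr_affine"]) @ lr_to_hr


def _recon_coords(geometry: dict, params: SequenceParams):
    recon = params.recon_matrix
    pix = params.fov_read_mm / recon
    center = geometry["center_mm"]
    read = ((np.arange(recon) - recon // 2) * pix
            + center[geometry["read_axis"]])
    phase = ((np.arange(recon) - recon // 2) * pix
             + center[geometry["phase_axis"]] + geometry["shift_mm"])
    return read, phase


def simulate_lr_series(qmaps: QuantitativeMaps, params: SequenceParams,
                       orientation: str, run_index: int,
                       seed: int) -> LRSeries:
    """Simulate one low-resolution series (all slices of one orientation
    and run) with a per-series seeded generator.  No inter-slice motion
    is modeled."""
    order = effective_te_line_order(params)
    slabs = resample_to_slices(qmaps, orientation, params, run_index)
    lookup = EPGLookup(params)
    rng = np.random.default_rng(seed)
    n_slices = slabs.pd.shape[0]
    recon = params.recon_matrix
    data = np.zeros((recon, recon, n_slices), dtype=np.float64)
    for s in range(n_slices):
        amps = lookup.amplitudes(slabs.t1[s], slabs.t2[s])
        ksp, _ = simulate_kspace_slice(slabs.t1[s], slabs.t2[s], slabs.pd[s],
                                       params, order, rng,
                                       echo_amplitudes=amps)
        img = reconstruct_slice(ksp, params)      # [phase, read]
        data[:, :, s] = img.T
    read_c, phase_c = _recon_coords(slabs.geometry, params)
    affine = _series_affine(slabs.geometry, params, read_c, phase_c)
    geometry = dict(slabs.geometry)
    geometry["recon_read_mm"] = read_c
    geometry["recon_phase_mm"] = phase_c
    geometry["realized_te_ms"] = order.realized_te_ms
    return LRSeries(data=data, affine=affine, orientation=orientation,
                    run_index=run_index, params=params, seed=seed,
                    geometry=geometry)


def downsample_annotations(labels: np.ndarray, series: LRSeries):
    """Majority-vote label stack and brain mask on the series grid.

    For every LR voxel the label is the majority class over the
    contributing HR slab (thickness-deep, nearest in-plane column); ties
    resolve to the smallest class code.  The brain mask is the
    non-background support of the LR labels.
    """
    geo = series.geometry
    labels = np.asarray(labels)
    if labels.shape != tuple(geo["hr_shape"]):
        raise GeometryError("label volume does not match the HR grid of "
                            "this series")
    s_ax, r_ax, p_ax = geo["slice_axis"], geo["read_axis"], geo["phase_axis"]
    spacing = geo["hr_spacing"]
    read_idx = np.rint(geo["recon_read_mm"] / spacing[r_ax]).astype(int)
    phase_idx = np.rint(geo["recon_phase_mm"] / spacing[p_ax]).astype(int)
    read_axis_first = r_ax < p_ax
    codes = np.unique(labels)
    n_along = labels.shape[s_ax]
    recon = series.params.recon_matrix
    centers = geo["slice_centers_mm"]
    out = np.zeros((recon, recon, len(centers)), dtype=labels.dtype)
    for s, sc in enumerate(centers):
        planes = _slab_plane_indices(sc, series.params.slice_thickness_mm,
                                     spacing[s_ax], n_along)
        if planes.size == 0:
            continue
        frac = np.zeros((len(codes), recon, recon))
        for ci, code in enumerate(codes):
            ind = (labels == code).astype(float)
            slab = ind.take(planes, axis=s_ax).mean(axis=s_ax)
            fill = 1.0 if code == 0 else 0.0
            frac[ci] = _inplane_sample(slab, read_axis_first,
                                       read_idx, phase_idx, fill)
        winner = np.argmax(frac, axis=0)          # ties -> smallest code
        out[:, :, s] = codes[winner].T
    brain_mask = out != 0
    return out, brain_mask
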