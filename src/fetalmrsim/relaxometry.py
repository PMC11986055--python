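"""Tissue relaxometry: reference values, subject sampling and WM modulation.

Reference T1/T2 values of the three merged classes come from published
fetal/preterm measurements at 1.5 T; 3 T values keep T2 and raise T1 by
25 % in grey matter and 10 % in white matter and CSF:

===============  ================  ================  =============
class            T1 at 1.5 T (ms)  T1 at 3 T (ms)    T2 (ms)
===============  ================  ================  =============
grey matter      2200 +/- 150      2750 +/- 150      182 +/- 10
white matter     2700 +/- 300      2970 +/- 300      285 +/- 15
CSF              4000              4400              2000
===============  ================  ================  =============

Per-subject diversity is obtained by drawing T2 as an integer uniform in
mean +/- sd (spreadsheet RANDBETWEEN semantics, inclusive bounds) and
coupling T1 to the drawn T2: T1 = (T2/T2_ref) * T1_ref +/- U{0..sd_T1},
the sign following the direction of the T2 deviation.

White matter heterogeneity enters through voxelwise reward maps computed
from the partial-volume maps,

    w+ = 1 + max(0, PV_hydrated - PV_intermediate)
    w- = 1 - max(0, PV_intermediate - PV_fibers),

and a gestational-age-dependent control value ``alpha`` bounding a
sigmoid modulation

    f(w) = alpha * (2 / (1 + exp(-2 w / alpha)) - 1) + 1
         = 1 + alpha * tanh(w / alpha),

applied multiplicatively to the reference T1 and T2 of WM voxels.  The
scalar fed to the sigmoid is the signed deviation
``(w+ - 1) - (1 - w-)`` so that neutral voxels are unmodified and the two
reward maps pull in opposite directions.  ``alpha`` follows the recursion

    alpha[21] = 0.2
    alpha[GA] = alpha[GA-1] * (2 - sigma_WM[GA] / sigma_WM[GA-1])

over integer GA 22..38, interpolated with a shape-preserving piecewise
cubic (PCHIP) for continuous GA in [20.0, 38.0].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from ._errors import GeometryError, ValidationError
from .anatomy import CLASS_CSF, CLASS_GM, CLASS_WM, TissueClassMap
from .ghmrf import PVMaps

ALPHA_FLOOR = 1e-3
ALPHA_GA_DOMAIN = (20.0, 38.0)

#: proton-density fractions per merged class (not part of the relaxometry
#: tables; configurable defaults from the simulator lineage)
DEFAULT_PD = {"GM": 0.86, "WM": 0.77, "CSF": 1.0}

_REFERENCE_15T = {
    # class: (t1_mean, t1_sd, t2_mean, t2_sd)
    "GM": (2200.0, 150.0, 182.0, 10.0),
    "WM": (2700.0, 300.0, 285.0, 15.0),
    "CSF": (4000.0, 0.0, 2000.0, 0.0),
}
_T1_SCALE_3T = {"GM": 1.25, "WM": 1.10, "CSF": 1.10}


@dataclass(frozen=True)
class TissueProperties:
    t1_ms: float
    t2_ms: float
    pd: float

    def __post_init__(self):
        if not (self.t1_ms > self.t2_ms > 0):
            raise ValidationError(
                f"require t1 > t2 > 0, got t1={self.t1_ms}, t2={self.t2_ms}")
        if not (0 < self.pd <= 1):
            raise ValidationError("proton density must lie in (0, 1]")


@dataclass(frozen=True)
class TissuePropertySet:
    """T1/T2/PD per merged class at one field strength."""

    gm: TissueProperties
    wm: TissueProperties
    csf: TissueProperties
    field_tesla: float
    t1_sd: Mapping[str, float] = field(default_factory=dict)
    t2_sd: Mapping[str, float] = field(default_factory=dict)

    def by_class(self) -> dict[int, TissueProperties]:
        return {CLASS_GM: self.gm, CLASS_WM: self.wm, CLASS_CSF: self.csf}

    def to_dict(self) -> dict:
        return {
            "field_tesla": self.field_tesla,
            **{name: {"t1_ms": p.t1_ms, "t2_ms": p.t2_ms, "pd": p.pd}
               for name, p in
               (("GM", self.gm), ("WM", self.wm), ("CSF", self.csf))},
        }


def _check_field(field_tesla: float) -> float:
    if float(field_tesla) not in (1.5, 3.0):
        raise ValidationError(
            f"unsupported field strength {field_tesla}; expected 1.5 or 3")
    return float(field_tesla)


def reference_properties(field_tesla: float,
                         pd: Mapping[str, float] | None = None
                         ) -> TissuePropertySet:
    """Mean reference properties (and sds) at 1.5 T or 3 T."""
    f = _check_field(field_tesla)
    pd = dict(DEFAULT_PD if pd is None else pd)
    props, t1_sd, t2_sd = {}, {}, {}
    for name, (t1, s1, t2, s2) in _REFERENCE_15T.items():
        scale = _T1_SCALE_3T[name] if f == 3.0 else 1.0
        props[name] = TissueProperties(t1_ms=t1 * scale, t2_ms=t2, pd=pd[name])
        t1_sd[name], t2_sd[name] = s1, s2
    return TissuePropertySet(gm=props["GM"], wm=props["WM"], csf=props["CSF"],
                             field_tesla=f, t1_sd=t1_sd, t2_sd=t2_sd)


def sample_subject_properties(field_tesla: float, seed: int,
                              pd: Mapping[str, float] | None = None
                              ) -> TissuePropertySet:
    """Draw a per-subject property set (integer-uniform T2, coupled T1).

    CSF keeps its fixed reference values.  Deterministic given ``seed``.
    """
    ref = reference_properties(field_tesla, pd=pd)
    rng = np.random.default_rng(seed)
    sampled = {}
    for name, p in (("GM", ref.gm), ("WM", ref.wm)):
        s2, s1 = ref.t2_sd[name], ref.t1_sd[name]
        t2 = float(rng.integers(int(p.t2_ms - s2), int(p.t2_ms + s2) + 1))
        t1 = (t2 / p.t2_ms) * p.t1_ms
        if t2 != p.t2_ms:
            sign = 1.0 if t2 > p.t2_ms else -1.0
            t1 = t1 + sign * float(rng.integers(0, int(s1) + 1))
        sampled[name] = TissueProperties(t1_ms=t1, t2_ms=t2, pd=p.pd)
    return TissuePropertySet(gm=sampled["GM"], wm=sampled["WM"], csf=ref.csf,
                             field_tesla=ref.field_tesla,
                             t1_sd=ref.t1_sd, t2_sd=ref.t2_sd)


# ---------------------------------------------------------------------------
# Reward maps and sigmoid modulation
# ---------------------------------------------------------------------------

@dataclass
class RewardMaps:
    """Voxelwise positive (w+) and negative (w-) reward maps.

    w+ in [1, 2] rewards hydrated-over-intermediate excess; w- in [0, 1]
    penalizes intermediate-over-fibers excess; both are 1 (neutral)
    outside the WM mask and wherever the PV maps are uniform.
    """

    w_plus: np.ndarray
    w_minus: np.ndarray
    mask: np.ndarray

    @property
    def deviation(self) -> np.ndarray:
        """Signed scalar fed to the sigmoid: (w+ - 1) - (1 - w-)."""
        return (self.w_plus - 1.0) - (1.0 - self.w_minus)


def compute_reward_maps(pv: PVMaps) -> RewardMaps:
    """Evaluate the reward maps from the WM partial-volume maps."""
    w_plus = 1.0 + np.maximum(0.0, pv.pv_hydrated - pv.pv_intermediate)
    w_minus = 1.0 - np.maximum(0.0, pv.pv_intermediate - pv.pv_fibers)
    outside = ~np.asarray(pv.mask, dtype=bool)
    w_plus[outside] = 1.0
    w_minus[outside] = 1.0
    return RewardMaps(w_plus=w_plus, w_minus=w_minus, mask=pv.mask)


def sigmoid_modulation(w, alpha: float):
    """f(w) = alpha * (2 / (1 + exp(-2 w / alpha)) - 1) + 1.

    Algebraically 1 + alpha * tanh(w / alpha); the tanh form is used for
    numerical stability.  f(0) = 1; the image of f is (1-alpha, 1+alpha).
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    return 1.0 + alpha * np.tanh(np.asarray(w, dtype=np.float64) / alpha)


def modulate_relaxation(t_ref_ms: float, rewards: RewardMaps,
                        alpha: float) -> np.ndarray:
    """Modulated relaxation-time volume t_ref * f(deviation)."""
    return t_ref_ms * sigmoid_modulation(rewards.deviation, alpha)


# ---------------------------------------------------------------------------
# Alpha schedule
# ---------------------------------------------------------------------------

@dataclass
class AlphaSchedule:
    """GA -> alpha lookup built on integer GA 21..38 with PCHIP in between.

    Outside [20.0, 38.0] the value is clamped to the boundary (with a
    warning); recursion outputs <= 0 are clamped to 1e-3.
    """

    base_table: dict[int, float]
    sigma_source: str = "user"
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        gas = sorted(self.base_table)
        if gas != list(range(21, 39)):
            raise ValidationError("alpha table must cover integer GA 21..38")
        vals = np.array([self.base_table[g] for g in gas], dtype=float)
        if np.any(vals <= 0):
            raise ValidationError("alpha values must be positive")
        self._interp = PchipInterpolator(gas, vals, extrapolate=True)

    def __call__(self, ga_weeks: float) -> float:
        lo, hi = ALPHA_GA_DOMAIN
        ga = float(ga_weeks)
        if ga < lo or ga > hi:
            warnings.warn(f"GA {ga} outside alpha domain [{lo}, {hi}]; "
                          "clamping", stacklevel=2)
            ga = min(max(ga, lo), hi)
        return float(max(self._interp(ga), ALPHA_FLOOR))

    def to_json(self) -> str:
        return json.dumps({"sigma_source": self.sigma_source,
                           "alpha": {str(g): v for g, v in
                                     sorted(self.base_table.items())}})

    @classmethod
    def from_json(cls, text: str) -> "AlphaSchedule":
        obj = json.loads(text)
        return cls(base_table={int(g): float(v)
                               for g, v in obj["alpha"].items()},
                   sigma_source=obj.get("sigma_source", "user"))


def build_alpha_schedule(sigma_by_ga: Mapping[int, float],
                         alpha_21: float = 0.2,
                         sigma_source: str = "user") -> AlphaSchedule:
    """Run the alpha recursion over a GA -> sigma_WM table.

    The table must cover integer GA 21..38 with positive sigma.  A sigma
    ratio >= 2 would drive alpha non-positive; such values are clamped to
    1e-3 with a warning.
    """
    missing = [g for g in range(21, 39) if g not in sigma_by_ga]
    if missing:
        raise ValidationError(f"sigma table misses GA {missing}")
    if any(sigma_by_ga[g] <= 0 for g in range(21, 39)):
        raise ValidationError("sigma values must be positive")
    alpha = {21: float(alpha_21)}
    for ga in range(22, 39):
        a = alpha[ga - 1] * (2.0 - sigma_by_ga[ga] / sigma_by_ga[ga - 1])
        if a <= 0:
            warnings.warn(f"alpha recursion non-positive at GA {ga}; "
                          f"clamped to {ALPHA_FLOOR}", stacklevel=2)
            a = ALPHA_FLOOR
        alpha[ga] = a
    return AlphaSchedule(base_table=alpha, sigma_source=sigma_source)


def read_sigma_table(path) -> dict[int, float]:
    """Read a (GA, sigma) CSV into the sigma table."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "ga" not in cols or "sigma" not in cols:
        raise ValidationError("sigma CSV needs 'ga' and 'sigma' columns")
    return {int(g): float(s) for g, s in
            zip(df[cols["ga"]], df[cols["sigma"]])}


# ---------------------------------------------------------------------------
# Quantitative map assembly
# ---------------------------------------------------------------------------

@dataclass
class QuantitativeMaps:
    """Voxelwise T1 (ms), T2 (ms) and proton-density maps."""

    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1_map.shape


def build_quantitative_maps(classes: TissueClassMap, pv: PVMaps,
                            props: TissuePropertySet,
                            schedule: AlphaSchedule,
                            ga_weeks: float) -> QuantitativeMaps:
    """Assemble T1/T2/PD volumes from the class map and the WM PV maps.

    GM and CSF voxels take class-constant values; WM voxels are modulated
    by the sigmoid with alpha = schedule(ga_weeks).  Background voxels
    get zero proton density (T1/T2 set to 1 ms to stay well-defined).
    """
    if classes.shape != pv.pv_hydrated.shape:
        raise GeometryError("class map and PV maps are on different grids")
    alpha = schedule(ga_weeks)
    rewards = compute_reward_maps(pv)
    t1 = np.ones(classes.shape)
    t2 = np.ones(classes.shape)
    pd_map = np.zeros(classes.shape)
    for code, tissue in props.by_class().items():
        sel = classes.classes == code
        t1[sel] = tissue.t1_ms
        t2[sel] = tissue.t2_ms
        pd_map[sel] = tissue.pd
    wm = (classes.classes == CLASS_WM) & np.asarray(pv.mask, dtype=bool)
    f = sigmoid_modulation(rewards.deviation[wm], alpha)
    t1[wm] = props.wm.t1_ms * f
    t2[wm] = props.wm.t2_ms * f
    return QuantitativeMaps(
        t1_map=t1, t2_map=t2, pd_map=pd_map, affine=classes.affine.copy(),
        provenance={"alpha": alpha, "ga_weeks": float(ga_weeks),
                    "properties": props.to_dict()})


def default_alpha_schedule(seed: int = 0) -> AlphaSchedule:
    """Schedule built from the synthetic phantom sigma table.

    Non-authoritative: the sigma values are measured on the procedural
    phantom, not on a normative atlas.
    """
    from .phantom import synthetic_sigma_table

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = synthetic_sigma_table(seed=seed)
    return build_alpha_schedule(table, sigma_source="synthetic-phantom")
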