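"""Synthetic tract-profile cohorts and streamline bundles with known truth.

Cohorts emulate the study design the pipeline targets: two MCI groups
(34 converters "C", 53 non-converters "NC" by default), 100-node profiles
of FA/MD/RD/AxD along canonical tracts, smooth along-tract noise, and
*implanted* group effects — additive mean shifts of a chosen standardized
size over a chosen node interval of one tract/property. Because the effect
location and size are known, every downstream stage (RFE node selection,
screening, FDR node tests, region recovery) has a ground truth to be tested
against.

Noise model: a stationary Gaussian process along nodes with a
squared-exponential correlation ``corr(i, j) = exp(-(i-j)^2 / (2 l^2))``,
``l`` the correlation length in nodes. Real tract profiles vary smoothly at
roughly this scale; ``l = 0`` gives white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .profiling import StreamlineBundle, fiber_length, resample_fiber
from .tracts import CANONICAL_TRACTS, PROPERTIES, check_property, check_tract

__all__ = [
    "EffectSpec",
    "SimConfig",
    "generate_cohort",
    "generate_demographics",
    "generate_bundle",
    "benchmark_config",
    "BENCHMARK_EFFECTS",
]

#: Typical white-matter baselines: FA dimensionless, diffusivities 10^-3 mm^2/s.
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "FA": (0.45, 0.06),
    "MD": (0.80, 0.06),
    "RD": (0.60, 0.06),
    "AxD": (1.20, 0.08),
}


@dataclass(frozen=True)
class EffectSpec:
    """A localized group effect: C-group mean shift over a node interval.

    ``effect_size_d`` is the standardized mean difference (C minus NC) in
    units of the property's baseline SD; positive values raise converter
    values (e.g. elevated diffusivity in converters).
    """

    tract_id: str
    property: str
    node_range: tuple[int, int]  # inclusive, 1-based
    effect_size_d: float

    def __post_init__(self) -> None:
        check_tract(self.tract_id)
        check_property(self.property)
        lo, hi = self.node_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid node_range {self.node_range}")

    def nodes(self) -> np.ndarray:
        lo, hi = self.node_range
        return np.arange(lo, hi + 1)


@dataclass
class SimConfig:
    """Conditions for one synthetic cohort."""

    n_C: int = 34
    n_NC: int = 53
    tracts: tuple[str, ...] = CANONICAL_TRACTS
    properties: tuple[str, ...] = PROPERTIES
    n_nodes: int = 100
    baselines: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    correlation_length: float = 5.0
    effects: tuple[EffectSpec, ...] = ()
    demographics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_C < 2 or self.n_NC < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        self.tracts = tuple(check_tract(t) for t in self.tracts)
        self.properties = tuple(check_property(p) for p in self.properties)
        for prop, (mean, sd) in self.baselines.items():
            check_property(prop)
            if sd <= 0:
                raise ValueError(f"baseline SD for {prop} must be > 0")
        self.effects = tuple(self.effects)
        for eff in self.effects:
            if eff.node_range[1] > self.n_nodes:
                raise ValueError(
                    f"effect node_range {eff.node_range} exceeds n_nodes={self.n_nodes}"
                )
            if eff.tract_id not in self.tracts or eff.property not in self.properties:
                raise ValueError(
                    f"effect targets ({eff.tract_id}, {eff.property}) which is not simulated"
                )

    def to_dict(self) -> dict:
        return {
            "n_C": self.n_C,
            "n_NC": self.n_NC,
            "tracts": list(self.tracts),
            "properties": list(self.properties),
            "n_nodes": self.n_nodes,
            "baselines": {k: list(v) for k, v in self.baselines.items()},
            "correlation_length": self.correlation_length,
            "effects": [
                {
                    "tract_id": e.tract_id,
                    "property": e.property,
                    "node_range": list(e.node_range),
                    "effect_size_d": e.effect_size_d,
                }
                for e in self.effects
            ],
            "demographics": self.demographics,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = tuple(
                EffectSpec(
                    tract_id=e["tract_id"],
                    property=e["property"],
                    node_range=tuple(e["node_range"]),
                    effect_size_d=e["effect_size_d"],
                )
                for e in d["effects"]
            )
        if "baselines" in d:
            d["baselines"] = {k: tuple(v) for k, v in d["baselines"].items()}
        for key in ("tracts", "properties"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _gp_cholesky(n_nodes: int, corr_len: float) -> np.ndarray:
    if corr_len <= 0:
        return np.eye(n_nodes)
    idx = np.arange(n_nodes)
    diff = idx[:, None] - idx[None, :]
    corr = np.exp(-(diff**2) / (2.0 * corr_len**2))
    return np.linalg.cholesky(corr + 1e-10 * np.eye(n_nodes))


def generate_cohort(config: SimConfig, seed: int | None = None) -> Cohort:
    """Draw one cohort under ``config``; deterministic given the seed.

    Each subject gets one ``n_nodes`` profile per (tract, property):
    ``baseline_mean + baseline_sd * z`` with ``z`` a unit-variance GP draw,
    plus ``effect_size_d * baseline_sd`` over each effect's node range for
    converters. FA is clipped to (0, 1) and diffusivities to > 0; with the
    default baselines the clip is essentially never active.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_C + config.n_NC
    subjects = [f"C{i + 1:03d}" for i in range(config.n_C)] + [
        f"NC{i + 1:03d}" for i in range(config.n_NC)
    ]
    groups = np.array(["C"] * config.n_C + ["NC"] * config.n_NC, dtype=object)
    chol = _gp_cholesky(config.n_nodes, config.correlation_length)
    is_c = groups == "C"
    data: dict[tuple[str, str], np.ndarray] = {}
    for tract in config.tracts:
        for prop in config.properties:
            mean, sd = config.baselines[prop]
            z = rng.standard_normal((n, config.n_nodes)) @ chol.T
            vals = mean + sd * z
            for eff in config.effects:
                if eff.tract_id == tract and eff.property == prop:
                    lo, hi = eff.node_range
                    vals[is_c, lo - 1 : hi] += eff.effect_size_d * sd
            if prop == "FA":
                vals = vals.clip(1e-6, 1.0 - 1e-6)
            else:
                vals = vals.clip(1e-6, None)
            data[(tract, prop)] = vals
    demo = None
    if config.demographics:
        demo = generate_demographics(config.n_C, config.n_NC, rng=rng, subjects=subjects)
    return Cohort(
        subjects=subjects,
        groups=groups,
        data=data,
        n_nodes=config.n_nodes,
        demographics=demo,
        meta={"sim_config": config.to_dict()},
    )


def generate_demographics(
    n_C: int,
    n_NC: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Age/sex/MMSE covariates, drawn independently of the profiles.

    Group-level distributions mirror a typical MCI conversion cohort
    (converters slightly older, lower MMSE, fewer women).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_C + n_NC
    if subjects is None:
        subjects = [f"C{i + 1:03d}" for i in range(n_C)] + [
            f"NC{i + 1:03d}" for i in range(n_NC)
        ]
    age = np.concatenate(
        [rng.normal(76.3, 7.7, n_C), rng.normal(74.3, 8.1, n_NC)]
    ).round(1)
    sex = np.concatenate(
        [
            rng.choice(["F", "M"], n_C, p=[9 / 34, 25 / 34]),
            rng.choice(["F", "M"], n_NC, p=[23 / 53, 30 / 53]),
        ]
    )
    mmse = np.concatenate(
        [rng.normal(26.7, 1.7, n_C), rng.normal(28.2, 1.7, n_NC)]
    ).round().clip(20, 30)
    return pd.DataFrame(
        {"age": age, "sex": sex, "mmse": mmse.astype(int)},
        index=pd.Index(subjects, name="subject_id"),
    )


def generate_bundle(
    n_fibers: int,
    centerline: np.ndarray,
    dispersion_sd: float = 1.0,
    length_jitter: float = 0.05,
    outlier_spec: dict | None = None,
    field=None,
    seed: int = 0,
    n_points: int = 60,
    tract_id: str | None = None,
) -> StreamlineBundle:
    """Noisy copies of a centerline, with optional constructed outliers.

    Base fibers are the centerline resampled with a small arc-length scale
    jitter (``length_jitter`` fractional SD) and displaced by a constant
    random offset of per-axis SD ``dispersion_sd`` plus light per-point
    jitter. ``outlier_spec = {"n_long": ..., "n_far": ...}`` appends fibers
    built to violate the cleaning rules with wide margin: over-length fibers
    about three times the centerline length, and far fibers displaced tens
    of dispersion SDs from the core. Per-point scalars are ``field(t)`` of
    the normalized arc position ``t`` in [0, 1] (default constant 1).
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    centerline = np.asarray(centerline, dtype=float)
    if centerline.shape[0] < 2 or fiber_length(centerline) <= 0:
        raise ValueError("degenerate centerline")
    if field is None:
        field = lambda t: np.ones_like(t)  # noqa: E731
    outlier_spec = outlier_spec or {}
    n_long = int(outlier_spec.get("n_long", 0))
    n_far = int(outlier_spec.get("n_far", 0))
    rng = np.random.default_rng(seed)

    base, _ = resample_fiber(centerline, n_points)
    t = np.linspace(0.0, 1.0, n_points)
    offset_scale = max(dispersion_sd, 1e-6)

    def make_fiber(arc_scale: float, offset: np.ndarray) -> np.ndarray:
        mid = (n_points - 1) / 2.0
        idx = mid + arc_scale * (np.arange(n_points) - mid)
        pts = np.column_stack(
            [np.interp(idx, np.arange(n_points), base[:, k]) for k in range(3)]
        )
        # linear extrapolation beyond the ends for over-length fibers
        if arc_scale > 1.0:
            d0 = base[1] - base[0]
            d1 = base[-1] - base[-2]
            below = idx < 0
            above = idx > n_points - 1
            pts[below] = base[0] + np.outer(idx[below], d0)
            pts[above] = base[-1] + np.outer(idx[above] - (n_points - 1), d1)
        wiggle = rng.normal(0.0, 0.1 * offset_scale, (n_points, 3))
        # mild smoothing keeps per-point jitter from dominating curvature
        kernel = np.ones(5) / 5.0
        for k in range(3):
            wiggle[:, k] = np.convolve(wiggle[:, k], kernel, mode="same")
        return pts + offset + wiggle

    fibers, values = [], []
    for _ in range(n_fibers):
        scale = float(np.clip(rng.normal(1.0, length_jitter), 0.5, 1.5))
        offset = rng.normal(0.0, dispersion_sd, 3)
        fibers.append(make_fiber(scale, offset))
    for _ in range(n_long):
        offset = rng.normal(0.0, dispersion_sd, 3)
        fibers.append(make_fiber(3.0, offset))
    for _ in range(n_far):
        direction = rng.normal(0.0, 1.0, 3)
        direction /= np.linalg.norm(direction)
        fibers.append(make_fiber(1.0, 30.0 * offset_scale * direction))
    for pts in fibers:
        values.append(np.asarray(field(t), dtype=float) * np.ones(n_points))
    return StreamlineBundle(fibers, values, tract_id=tract_id)


#: The canonical implanted-effect benchmark: three affected tracts with
#: localized axial-diffusivity elevations in converters.
BENCHMARK_EFFECTS: tuple[EffectSpec, ...] = (
    EffectSpec("right_cingulum_hippocampus", "AxD", (90, 100), 1.5),
    EffectSpec("right_ifof", "AxD", (37, 45), 1.5),
    EffectSpec("left_ilf", "AxD", (1, 10), 1.5),
    EffectSpec("left_ilf", "AxD", (80, 90), 1.5),
)


def benchmark_config(seed: int = 0) -> SimConfig:
    """The standard signal-recovery benchmark cohort.

    34 C / 53 NC subjects; the three tracts carrying implanted effects
    (right cingulum-hippocampus terminal nodes 90-100, right IFOF central
    nodes 37-45, left ILF posterior 1-10 and anterior 80-90), all on axial
    diffusivity at d = 1.5.
    """
    return SimConfig(
        tracts=("right_cingulum_hippocampus", "right_ifof", "left_ilf"),
        properties=("AxD",),
        effects=BENCHMARK_EFFECTS,
        seed=seed,
    )
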