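"""Synthetic stride datasets with the structure the analysis assumes.

Stride velocities are drawn from a normal distribution (mean 9 cm/s, SD
6 cm/s, as reported for mouse walking) truncated to the walking range
[3, 16] cm/s.  Stride length and swing duration are generated from stated
parameter-vs-velocity curves plus independent Gaussian noise; stride
duration, stance, cadence and swing speed are then derived so every stride
satisfies the kinematic identities exactly.  Strides are organised into a
per-subject, per-trial structure mirroring runway sessions.

The module also provides the two hypothetical constructions used to
illustrate curve shifting (a velocity split that leaves gait quality
unchanged, and a +5 mm stride-length offset), plus parameterized
signature-shift injections with parkinsonism-like presets.

Default generating curves are plausible shapes for mouse walking, not
estimates from any particular cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import STRIDE_COLUMNS, StrideTable
from .regression import (
    LINEAR,
    ONE_PHASE,
    WALKING_RANGE,
    ModelForm,
    VelocityRange,
    fit_curve,
)

__all__ = [
    "GeneratorConfig",
    "ShiftSpec",
    "generate_cohort",
    "split_by_velocity",
    "split_random_halves",
    "add_offset",
    "apply_signature_shift",
    "mptp_like_shifts",
    "ohda_like_shifts",
]


def _default_curves() -> dict:
    # Shapes chosen to qualitatively match mouse walking: stride length
    # rises toward a plateau with velocity; swing duration declines gently.
    return {
        "stride_length_mm": (ONE_PHASE, (30.0, 80.0, 0.15)),
        "swing_s": (LINEAR, (0.18, -0.004)),
    }


def _default_noise() -> dict:
    return {"stride_length_mm": 3.0, "swing_s": 0.01}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``generating_curves`` maps a gait parameter to ``(ModelForm, true
    parameter values)``; only ``stride_length_mm`` and ``swing_s`` are
    generative (everything else is derived from them and velocity so the
    stride identities hold).  ``noise_sd`` gives the additive Gaussian noise
    SD per generative parameter, in response units.
    """

    n_subjects: int = 10
    trials_per_subject: int = 4
    strides_per_trial: int = 10
    velocity_mean_cm_s: float = 9.0
    velocity_sd_cm_s: float = 6.0
    truncation: VelocityRange = field(default_factory=lambda: WALKING_RANGE)
    generating_curves: dict = field(default_factory=_default_curves)
    noise_sd: dict = field(default_factory=_default_noise)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "trials_per_subject", "strides_per_trial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.velocity_sd_cm_s <= 0:
            raise ValueError("velocity SD must be positive")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be non-negative")
        for par in ("stride_length_mm", "swing_s"):
            if par not in self.generating_curves:
                raise ValueError(f"generating_curves must include {par!r}")

    @property
    def n_strides(self) -> int:
        return self.n_subjects * self.trials_per_subject * self.strides_per_trial

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncation"] = [self.truncation.lower, self.truncation.upper]
        d["generating_curves"] = {
            k: {"family": form.family, "params": list(p)}
            for k, (form, p) in self.generating_curves.items()
        }
        return d


def _curve_values(config: GeneratorConfig, parameter: str, v: np.ndarray) -> np.ndarray:
    form, params = config.generating_curves[parameter]
    return form.predict(params, v)


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> StrideTable:
    """Draw one cohort of strides; fully reproducible from ``config.seed``.

    Velocity is the primary variable; stride length and swing duration are
    their generating curves plus noise; stride duration, stance, cadence
    and swing speed are derived so the per-stride identities hold exactly.
    Configurations whose curves (with noise) produce non-positive lengths or
    a swing that does not fit inside the stride are rejected.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    n = config.n_strides
    lo, hi = config.truncation.lower, config.truncation.upper
    a = (lo - config.velocity_mean_cm_s) / config.velocity_sd_cm_s
    b = (hi - config.velocity_mean_cm_s) / config.velocity_sd_cm_s
    v = stats.truncnorm.rvs(
        a,
        b,
        loc=config.velocity_mean_cm_s,
        scale=config.velocity_sd_cm_s,
        size=n,
        random_state=rng,
    )

    length = _curve_values(config, "stride_length_mm", v) + rng.normal(
        0.0, config.noise_sd.get("stride_length_mm", 0.0), n
    )
    if np.any(length <= 0):
        raise ValueError("generating curve produced non-positive stride lengths")
    stride_s = length / 10.0 / v
    swing = _curve_values(config, "swing_s", v) + rng.normal(
        0.0, config.noise_sd.get("swing_s", 0.0), n
    )
    if np.any(swing <= 0) or np.any(swing >= stride_s):
        raise ValueError(
            "generating curves produced swing durations outside (0, stride duration)"
        )

    subjects = np.repeat(
        [f"m{i:02d}" for i in range(config.n_subjects)],
        config.trials_per_subject * config.strides_per_trial,
    )
    trials = np.tile(
        np.repeat(
            [f"t{j}" for j in range(config.trials_per_subject)],
            config.strides_per_trial,
        ),
        config.n_subjects,
    )
    paw = np.where(np.arange(n) % 2 == 0, "LH", "RH")

    data = pd.DataFrame(
        {
            "subject_id": subjects,
            "trial_id": trials,
            "paw": paw,
            "cue": "uncued",
            "stride_velocity_cm_s": v,
            "stride_length_mm": length,
            "stride_s": stride_s,
            "swing_s": swing,
            "stance_s": stride_s - swing,
            "cadence_per_s": 1.0 / stride_s,
            "swing_speed_mm_s": length / swing,
            "base_width_mm": np.full(n, np.nan),
        },
        columns=list(STRIDE_COLUMNS),
    )
    return StrideTable(data, {"source": "synthetic", "generator": config.to_dict()})


def split_by_velocity(table: StrideTable, seed: int = 0) -> tuple[StrideTable, StrideTable]:
    """Split a dataset into slower and faster halves without changing gait quality.

    One quarter of the records is randomly assigned to the faster group and
    one quarter to the slower group; the remaining half is ranked by
    velocity, slower records to the slower group and faster to the faster
    group (remainders land in the ranked half so each output holds n/2 +- 1
    records).  The two halves therefore differ in velocity but are drawn
    from identical generating curves.
    """
    n = len(table)
    if n < 8:
        raise ValueError("velocity split requires at least 8 strides")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    q = n // 4
    rand_fast = perm[:q]
    rand_slow = perm[q : 2 * q]
    rest = perm[2 * q :]
    v = table.data["stride_velocity_cm_s"].to_numpy(float)
    rest_sorted = rest[np.argsort(v[rest], kind="stable")]
    n_slow_ranked = n // 2 - q
    slow_idx = np.concatenate([rand_slow, rest_sorted[:n_slow_ranked]])
    fast_idx = np.concatenate([rand_fast, rest_sorted[n_slow_ranked:]])
    meta = dict(table.metadata)
    slow = StrideTable(
        table.data.iloc[np.sort(slow_idx)].reset_index(drop=True),
        {**meta, "split": "slow", "split_seed": seed},
    )
    fast = StrideTable(
        table.data.iloc[np.sort(fast_idx)].reset_index(drop=True),
        {**meta, "split": "fast", "split_seed": seed},
    )
    return slow, fast


def split_random_halves(table: StrideTable, seed: int = 0) -> tuple[StrideTable, StrideTable]:
    """Random half split with identical velocity distributions in expectation.

    Used by the offset construction: one half stays unmodified while the
    other half's parameter is shifted.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least two strides to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    h = n // 2
    meta = dict(table.metadata)
    first = StrideTable(
        table.data.iloc[np.sort(perm[:h])].reset_index(drop=True),
        {**meta, "half": "first", "split_seed": seed},
    )
    second = StrideTable(
        table.data.iloc[np.sort(perm[h:])].reset_index(drop=True),
        {**meta, "half": "second", "split_seed": seed},
    )
    return first, second


def add_offset(
    table: StrideTable,
    parameter: str,
    delta: float,
    hold_velocity_fixed: bool = True,
) -> StrideTable:
    """Shift one gait parameter by ``delta`` in every record.

    By default velocity (and the temporal parameters) are held fixed: the
    construction alters the parameter as plotted against the original
    velocities, deliberately breaking the velocity identity, exactly as the
    illustrative +5 mm stride-length dataset does.  With
    ``hold_velocity_fixed=False`` and ``parameter='stride_length_mm'``,
    velocity and swing speed are re-derived from the shifted lengths at
    unchanged durations.  Shifts that produce non-positive values are
    refused.
    """
    if parameter not in table.data.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    d = table.data.copy()
    d[parameter] = d[parameter] + delta
    if (d[parameter] <= 0).any():
        raise ValueError("offset would produce non-positive values")
    if not hold_velocity_fixed:
        if parameter != "stride_length_mm":
            raise ValueError("identity re-derivation implemented for stride length only")
        d["stride_velocity_cm_s"] = d["stride_length_mm"] / 10.0 / d["stride_s"]
        d["swing_speed_mm_s"] = d["stride_length_mm"] / d["swing_s"]
    meta = dict(table.metadata)
    meta.setdefault("offsets", []).append(
        {"parameter": parameter, "delta": delta, "velocity_fixed": hold_velocity_fixed}
    )
    return StrideTable(d, meta)


@dataclass(frozen=True)
class ShiftSpec:
    """Affine signature shift for one parameter: y -> intercept_delta + slope_scale * y."""

    parameter: str
    intercept_delta: float = 0.0
    slope_scale: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        if not self.slope_scale > 0:
            raise ValueError("slope_scale must be positive")


def apply_signature_shift(
    table: StrideTable,
    shifts: Sequence[ShiftSpec],
    seed: int | None = None,
    noise_sd: dict | None = None,
) -> StrideTable:
    """Apply affine shifts to named parameters, optionally re-drawing noise.

    Each named parameter is transformed ``y -> intercept_delta +
    slope_scale * y``.  When a ``noise_sd`` mapping is given, fresh Gaussian
    noise of the stated SD is added to the transformed values (seeded).
    Velocity is held fixed, matching the offset construction.  An empty
    shift list is the identity.
    """
    d = table.data.copy()
    rng = np.random.default_rng(seed)
    for spec in shifts:
        if spec.parameter not in d.columns:
            raise ValueError(f"unknown parameter {spec.parameter!r}")
        y = spec.intercept_delta + spec.slope_scale * d[spec.parameter]
        if noise_sd and spec.parameter in noise_sd:
            y = y + rng.normal(0.0, noise_sd[spec.parameter], len(d))
        if (y <= 0).any():
            raise ValueError(f"shift on {spec.parameter!r} produced non-positive values")
        d[spec.parameter] = y
    meta = dict(table.metadata)
    meta.setdefault("signature_shifts", []).extend(
        {
            "parameter": s.parameter,
            "intercept_delta": s.intercept_delta,
            "slope_scale": s.slope_scale,
            "description": s.description,
        }
        for s in shifts
    )
    return StrideTable(d, meta)


def mptp_like_shifts(
    stride_length_delta_mm: float = -8.0,
    swing_delta_s: float = -0.02,
    cadence_delta_per_s: float = 0.25,
) -> list[ShiftSpec]:
    """Bilateral-dopamine-loss-like signature: shorter strides at every
    speed (downward stride-length intercept), shorter swing, higher cadence."""
    return [
        ShiftSpec("stride_length_mm", stride_length_delta_mm, 1.0, "stride length down"),
        ShiftSpec("swing_s", swing_delta_s, 1.0, "swing duration down"),
        ShiftSpec("cadence_per_s", cadence_delta_per_s, 1.0, "cadence up"),
    ]


def ohda_like_shifts(
    table: StrideTable,
    slope_scale: float = 0.8,
    vrange: VelocityRange = WALKING_RANGE,
) -> list[ShiftSpec]:
    """Unilateral-lesion-like signature: stride length reduced only at higher
    speeds (slope change with an unchanged intercept).

    The shift pivots the stride-length-vs-velocity line about v = 0: the
    compensating intercept delta is computed from a linear fit to the input
    table, so downstream classification sees a slope-only change.
    """
    fit = fit_curve(table, "stride_length_mm", LINEAR, vrange)
    b0 = float(fit.params[0])
    return [
        ShiftSpec(
            "stride_length_mm",
            (1.0 - slope_scale) * b0,
            slope_scale,
            "stride length slope reduced, intercept preserved",
        )
    ]
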