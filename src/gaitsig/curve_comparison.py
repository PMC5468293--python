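"""Shared-curve testing between stride datasets: the gait-signature detector.

For a chosen gait parameter and model family, the fit of one curve to two
datasets combined is compared with the fit of individual curves to each
dataset by the extra sum-of-squares F-test

    F = ((SScombined - (SSA + SSB)) / (DFcombined - (DFA + DFB)))
        / ((SSA + SSB) / (DFA + DFB))

A p-value below alpha means the datasets are so different that they are
best described by two separate curves -- the gait signature has shifted.
The same family is imposed on both datasets and the pooled fit; it should
be chosen upstream on baseline data with
:func:`gaitsig.regression.select_model`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import StrideTable
from .regression import (
    WALKING_RANGE,
    FittedCurve,
    ModelForm,
    VelocityRange,
    extra_ss_f_test,
    fit_curve,
)

__all__ = [
    "CurveComparisonResult",
    "ShiftClassification",
    "compare_two",
    "compare_groups",
    "classify_shift",
]


@dataclass
class CurveComparisonResult:
    """Outcome of the shared-vs-separate-curves F-test for one parameter."""

    parameter: str
    model_form: ModelForm
    fit_a: FittedCurve
    fit_b: FittedCurve
    fit_combined: FittedCurve
    F: float
    df_numerator: int
    df_denominator: int
    p: float
    alpha: float
    shared: bool
    degenerate: bool = False
    #: per-parameter differences (B minus A) with Wald 95% CIs; populated
    #: only when the curves are not shared.
    shift_summary: dict | None = None

    @property
    def ss_a(self) -> float:
        return self.fit_a.ss

    @property
    def ss_b(self) -> float:
        return self.fit_b.ss

    @property
    def ss_combined(self) -> float:
        return self.fit_combined.ss

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "family": self.model_form.family,
            "SS_A": self.ss_a,
            "SS_B": self.ss_b,
            "SS_combined": self.ss_combined,
            "DF_A": self.fit_a.df,
            "DF_B": self.fit_b.df,
            "DF_combined": self.fit_combined.df,
            "F": self.F,
            "df_numerator": self.df_numerator,
            "df_denominator": self.df_denominator,
            "p": self.p,
            "alpha": self.alpha,
            "shared": self.shared,
            "degenerate": self.degenerate,
            "shift_summary": self.shift_summary,
            "fit_A": self.fit_a.to_dict(),
            "fit_B": self.fit_b.to_dict(),
            "fit_combined": self.fit_combined.to_dict(),
        }


def _shift_summary(fit_a: FittedCurve, fit_b: FittedCurve) -> dict:
    """Wald differences (B - A) per curve parameter; approximate CIs."""
    z = stats.norm.ppf(0.975)
    out = {}
    for i, name in enumerate(fit_a.model_form.param_names):
        diff = float(fit_b.params[i] - fit_a.params[i])
        se = float(np.hypot(fit_a.se[i], fit_b.se[i]))
        out[name] = {
            "difference": diff,
            "se": se,
            "ci_low": diff - z * se,
            "ci_high": diff + z * se,
        }
    return out


def compare_two(
    table_a: StrideTable,
    table_b: StrideTable,
    parameter: str,
    model_form: ModelForm,
    vrange: VelocityRange = WALKING_RANGE,
    alpha: float = 0.05,
    **fit_kwargs,
) -> CurveComparisonResult:
    """Test whether two stride datasets share one velocity-dependence curve.

    Three fits are performed (A, B, and the pooled data) with the same
    family and range, and the extra-SS F statistic decides between one
    shared curve (p > alpha) and separate curves.  When the curves are
    separate, ``shift_summary`` reports per-parameter differences (B - A)
    with Wald 95% intervals.  Perfect separate fits (SSA + SSB = 0) are
    flagged degenerate with F = inf, p = 0.
    """
    fit_a = fit_curve(table_a, parameter, model_form, vrange, **fit_kwargs)
    fit_b = fit_curve(table_b, parameter, model_form, vrange, **fit_kwargs)
    if not (fit_a.converged and fit_b.converged):
        raise RuntimeError("comparison refused: individual fit did not converge")
    pooled = StrideTable(
        pd.concat([table_a.data, table_b.data], ignore_index=True),
        {"pooled_from": [table_a.metadata, table_b.metadata]},
    )
    fit_c = fit_curve(pooled, parameter, model_form, vrange, **fit_kwargs)
    if not fit_c.converged:
        raise RuntimeError("comparison refused: pooled fit did not converge")

    ss_sep = fit_a.ss + fit_b.ss
    df_sep = fit_a.df + fit_b.df
    df_num = fit_c.df - df_sep
    y = pooled.data[parameter].to_numpy(float)
    y = y[np.isfinite(y) & vrange.contains(pooled.data["stride_velocity_cm_s"].to_numpy(float))]
    tss = float(np.sum((y - y.mean()) ** 2)) if len(y) else 0.0
    degenerate = ss_sep <= 1e-12 * max(tss, 1e-300)
    if degenerate:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat, p = extra_ss_f_test(fit_c.ss, fit_c.df, ss_sep, df_sep)
    shared = p > alpha
    result = CurveComparisonResult(
        parameter=parameter,
        model_form=model_form,
        fit_a=fit_a,
        fit_b=fit_b,
        fit_combined=fit_c,
        F=f_stat,
        df_numerator=df_num,
        df_denominator=df_sep,
        p=p,
        alpha=alpha,
        shared=shared,
        degenerate=degenerate,
    )
    if not shared:
        result.shift_summary = _shift_summary(fit_a, fit_b)
    return result


def compare_groups(
    tables: Mapping[str, StrideTable],
    parameter: str,
    model_form: ModelForm,
    vrange: VelocityRange = WALKING_RANGE,
    alpha: float = 0.05,
    **fit_kwargs,
) -> dict:
    """All pairwise shared-curve tests among named datasets.

    No family-wise adjustment is applied by default; pass ``alpha=0.001``
    for the conservative variant.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to compare")
    results = {}
    for (name_a, a), (name_b, b) in itertools.combinations(tables.items(), 2):
        results[(name_a, name_b)] = compare_two(
            a, b, parameter, model_form, vrange, alpha, **fit_kwargs
        )
    return results


@dataclass
class ShiftClassification:
    """Descriptor of how a non-shared pair of curves differs."""

    label: str
    details: dict = field(default_factory=dict)


def classify_shift(result: CurveComparisonResult) -> ShiftClassification:
    """Label a detected signature shift.

    For linear curves the shift is classified as ``intercept-shift``,
    ``slope-shift`` or ``both`` depending on which per-parameter difference
    CIs exclude zero (``indeterminate`` if neither does despite the overall
    F-test).  For nonlinear families the raw parameter differences are
    reported without further labelling.
    """
    if result.shared:
        raise ValueError("classify_shift requires a non-shared comparison")
    summary = result.shift_summary or _shift_summary(result.fit_a, result.fit_b)
    if result.model_form.family != "linear":
        return ShiftClassification("parameter-shift", dict(summary))
    excl = {
        name: not (d["ci_low"] <= 0.0 <= d["ci_high"]) for name, d in summary.items()
    }
    if excl["intercept"] and excl["slope"]:
        label = "both"
    elif excl["intercept"]:
        label = "intercept-shift"
    elif excl["slope"]:
        label = "slope-shift"
    else:
        label = "indeterminate"
    return ShiftClassification(label, dict(summary))
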