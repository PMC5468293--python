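"""Velocity-dependence regression models for gait parameters.

Each gait parameter is modelled as a function of stride velocity over a
restricted walking range (default 3-16 cm/s in mice).  Three candidate
families are fit by least squares:

* ``linear``:     Y = b0 + b1 * v                                (2 parameters)
* ``one_phase``:  Y = Y0 + (Plateau - Y0) * (1 - exp(-K v))      (3 parameters)
* ``two_phase``:  Y = Y0 + SpanFast (1 - exp(-KFast v))
                      + SpanSlow (1 - exp(-KSlow v))             (5 parameters)

with rate constants strictly positive and KFast > KSlow.  These are the
standard parameterizations of the exponential association families used by
commercial curve-fitting software, so fitted parameters are directly
comparable with that software's output.

The simplest adequate family is chosen by the extra sum-of-squares F-test

    F = ((SS1 - SS2) / (DF1 - DF2)) / (SS2 / DF2)

where model 1 is the simpler fit.  The families are treated as quasi-nested
through their degree-of-freedom differences (linear is not a strict
submodel of one_phase); F is clipped at zero when the complex model happens
to fit worse, with p reported as 1.

Nonlinear fits use variable projection: for fixed rate constants both
families are linear in the remaining parameters, so the optimizer searches
only over log rate constants (multi-start, log-spaced) while the linear
parameters are profiled out exactly.  This keeps fits fast and makes the
sum of squares reliably the global minimum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .kinematics import StrideTable

__all__ = [
    "VelocityRange",
    "WALKING_RANGE",
    "ModelForm",
    "LINEAR",
    "ONE_PHASE",
    "TWO_PHASE",
    "DEFAULT_CANDIDATES",
    "FittedCurve",
    "ModelSelectionResult",
    "ModelSelection",
    "restrict_range",
    "fit_curve",
    "select_model",
    "range_scan",
    "extra_ss_f_test",
    "residual_diagnostics",
    "runs_test",
]

_K_BOUNDS = (1e-6, 100.0)  # admissible rate-constant range, per cm/s
_SS_RTOL = 1e-10  # relative SS change treated as a tie between starts


@dataclass(frozen=True)
class VelocityRange:
    """Closed velocity interval [lower, upper] in cm/s."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper):
            raise ValueError(f"invalid velocity range [{self.lower}, {self.upper}]")

    def contains(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        return (v >= self.lower) & (v <= self.upper)

    @property
    def span(self) -> float:
        return self.upper - self.lower


#: Default walking range: the slowest 0-3 cm/s and >16 cm/s are omitted,
#: with both boundary values retained.
WALKING_RANGE = VelocityRange(3.0, 16.0)

_FAMILY_PARAMS = {
    "linear": ("intercept", "slope"),
    "one_phase": ("Y0", "Plateau", "K"),
    "two_phase": ("Y0", "SpanFast", "KFast", "SpanSlow", "KSlow"),
}


@dataclass(frozen=True)
class ModelForm:
    """A candidate curve family plus the response scale it is fit on."""

    family: str
    response_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.response_transform not in ("identity", "log"):
            raise ValueError(f"unknown response transform {self.response_transform!r}")

    @property
    def n_params(self) -> int:
        return len(_FAMILY_PARAMS[self.family])

    @property
    def param_names(self) -> tuple[str, ...]:
        return _FAMILY_PARAMS[self.family]

    def predict(self, params: Sequence[float], v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        p = np.asarray(params, float)
        if self.family == "linear":
            return p[0] + p[1] * v
        if self.family == "one_phase":
            y0, plateau, k = p
            return y0 + (plateau - y0) * (1.0 - np.exp(-k * v))
        y0, sf, kf, ss, ks = p
        return y0 + sf * (1.0 - np.exp(-kf * v)) + ss * (1.0 - np.exp(-ks * v))

    def jacobian(self, params: Sequence[float], v: np.ndarray) -> np.ndarray:
        """d(prediction)/d(params), one row per point."""
        v = np.asarray(v, float)
        p = np.asarray(params, float)
        if self.family == "linear":
            return np.column_stack([np.ones_like(v), v])
        if self.family == "one_phase":
            y0, plateau, k = p
            e = np.exp(-k * v)
            return np.column_stack([e, 1.0 - e, (plateau - y0) * v * e])
        y0, sf, kf, ss, ks = p
        ef, es = np.exp(-kf * v), np.exp(-ks * v)
        return np.column_stack(
            [np.ones_like(v), 1.0 - ef, sf * v * ef, 1.0 - es, ss * v * es]
        )


LINEAR = ModelForm("linear")
ONE_PHASE = ModelForm("one_phase")
TWO_PHASE = ModelForm("two_phase")
DEFAULT_CANDIDATES: tuple[ModelForm, ...] = (LINEAR, ONE_PHASE, TWO_PHASE)


@dataclass
class FittedCurve:
    """Least-squares fit of one model form to one gait parameter."""

    model_form: ModelForm
    parameter: str
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    ss: float
    df: int
    n_points: int
    vrange: VelocityRange
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def predict(self, v: np.ndarray) -> np.ndarray:
        """Fitted values on the (possibly transformed) response scale."""
        return self.model_form.predict(self.params, v)

    def confidence_band(self, v: np.ndarray, level: float = 0.95):
        """Pointwise confidence band from the estimate covariance (delta method)."""
        v = np.asarray(v, float)
        yhat = self.predict(v)
        j = self.model_form.jacobian(self.params, v)
        var = np.einsum("ij,jk,ik->i", j, self.cov, j)
        half = stats.t.ppf(0.5 + level / 2.0, self.df) * np.sqrt(np.maximum(var, 0))
        return yhat - half, yhat + half

    def to_dict(self) -> dict:
        return {
            "family": self.model_form.family,
            "response_transform": self.model_form.response_transform,
            "parameter": self.parameter,
            "param_names": list(self.model_form.param_names),
            "estimates": [float(x) for x in self.params],
            "standard_errors": [float(x) for x in self.se],
            "ss": float(self.ss),
            "df": int(self.df),
            "n_points": int(self.n_points),
            "range": [self.vrange.lower, self.vrange.upper],
            "converged": bool(self.converged),
            "diagnostics": {
                k: (None if v is None else float(v))
                for k, v in self.diagnostics.items()
                if not isinstance(v, str)
            },
        }


@dataclass
class RangeReport:
    n_slow_excluded: int
    n_fast_excluded: int
    n_retained: int
    empty: bool


def restrict_range(
    table: StrideTable, vrange: VelocityRange
) -> tuple[StrideTable, RangeReport]:
    """Keep strides with velocity inside the closed interval; report the tails."""
    v = table.data["stride_velocity_cm_s"].to_numpy(float)
    slow = v < vrange.lower
    fast = v > vrange.upper
    kept = table.data[~(slow | fast)].reset_index(drop=True)
    report = RangeReport(
        n_slow_excluded=int(slow.sum()),
        n_fast_excluded=int(fast.sum()),
        n_retained=len(kept),
        empty=len(kept) == 0,
    )
    return StrideTable(kept, dict(table.metadata)), report


# ---------------------------------------------------------------------------
# fitting


def _fit_linear(v: np.ndarray, y: np.ndarray):
    x = np.column_stack([np.ones_like(v), v])
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return coef, float(resid @ resid), True


def _profile_exp(v: np.ndarray, y: np.ndarray, ks: np.ndarray):
    """Solve the linear subproblem for fixed rate constants.

    one_phase (one k):  Y = Y0 exp(-k v) + Plateau (1 - exp(-k v))
    two_phase (two ks): Y = Y0 + SpanFast (1-exp(-kf v)) + SpanSlow (1-exp(-ks v))
    Returns (linear coefficients, residual vector).
    """
    if len(ks) == 1:
        e = np.exp(-ks[0] * v)
        x = np.column_stack([e, 1.0 - e])
    else:
        kf, ksl = ks
        x = np.column_stack(
            [np.ones_like(v), 1.0 - np.exp(-kf * v), 1.0 - np.exp(-ksl * v)]
        )
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    return coef, y - x @ coef


def _varpro_fit(v, y, n_rates: int, starts: list[np.ndarray]):
    """Multi-start variable-projection fit over log rate constants."""
    log_lo, log_hi = np.log(_K_BOUNDS[0]), np.log(_K_BOUNDS[1])

    def resid(theta):
        _, r = _profile_exp(v, y, np.exp(theta))
        return r

    best = None
    any_converged = False
    for x0 in starts:
        try:
            res = optimize.least_squares(
                resid,
                np.log(x0),
                bounds=([log_lo] * n_rates, [log_hi] * n_rates),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        ss = 2.0 * res.cost
        k = np.exp(res.x)
        conv = bool(res.status > 0)
        any_converged |= conv
        if best is None:
            best = (ss, k)
        else:
            # tie-break equal-SS starts toward the lowest rate constant
            if ss < best[0] * (1 - _SS_RTOL):
                best = (ss, k)
            elif abs(ss - best[0]) <= _SS_RTOL * max(best[0], 1e-300):
                if k.min() < best[1].min():
                    best = (ss, k)
    return best, any_converged


def _fit_one_phase(v, y, n_starts: int):
    k_starts = np.geomspace(0.05, 2.0, n_starts)
    best, converged = _varpro_fit(v, y, 1, [np.array([k]) for k in k_starts])
    ss, k = best
    coef, _ = _profile_exp(v, y, k)
    # linear coefficients are (Y0, Plateau) in the profiled design
    params = np.array([coef[0], coef[1], k[0]])
    return params, ss, converged


def _fit_two_phase(v, y, n_starts: int):
    slow_starts = np.geomspace(0.02, 0.4, max(2, n_starts // 3))
    ratios = (8.0, 40.0)
    starts = [
        np.array([ks * r, ks]) for ks, r in itertools.product(slow_starts, ratios)
    ][:n_starts]
    best, converged = _varpro_fit(v, y, 2, starts)
    ss, k = best
    kf, ksl = k
    coef, _ = _profile_exp(v, y, k)
    y0, sf, ssl = coef
    if kf < ksl:  # enforce KFast > KSlow by relabelling
        kf, ksl, sf, ssl = ksl, kf, ssl, sf
    params = np.array([y0, sf, kf, ssl, ksl])
    return params, ss, converged


def fit_curve(
    table: StrideTable,
    parameter: str,
    model_form: ModelForm,
    vrange: VelocityRange = WALKING_RANGE,
    n_starts: int = 10,
    min_extra_points: int = 5,
    min_span_cm_s: float = 5.0,
    compute_diagnostics: bool = True,
) -> FittedCurve:
    """Least-squares fit of ``model_form`` to ``parameter`` vs stride velocity.

    The table is restricted to ``vrange`` first.  Requires at least
    ``n_params + min_extra_points`` strides spanning at least
    ``min_span_cm_s`` of velocity.  The 95% confidence band is available
    from the returned curve via :meth:`FittedCurve.confidence_band`.
    """
    if parameter not in table.data.columns:
        raise ValueError(f"unknown gait parameter {parameter!r}")
    restricted, _ = restrict_range(table, vrange)
    v = restricted.data["stride_velocity_cm_s"].to_numpy(float)
    y = restricted.data[parameter].to_numpy(float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]

    n_min = model_form.n_params + min_extra_points
    if len(v) < n_min:
        raise ValueError(
            f"insufficient points: {len(v)} < {n_min} required for "
            f"{model_form.family} on [{vrange.lower}, {vrange.upper}]"
        )
    if v.max() - v.min() < min_span_cm_s:
        raise ValueError(
            f"velocity span {v.max() - v.min():.2f} cm/s below the "
            f"{min_span_cm_s} cm/s required for a stable fit"
        )

    if model_form.response_transform == "log":
        if np.any(y <= 0):
            raise ValueError("log response transform requires positive values")
        y = np.log(y)

    if model_form.family == "linear":
        params, ss, converged = _fit_linear(v, y)
    elif model_form.family == "one_phase":
        params, ss, converged = _fit_one_phase(v, y, n_starts)
    else:
        params, ss, converged = _fit_two_phase(v, y, n_starts)

    df = len(v) - model_form.n_params
    if df < 1:
        raise ValueError("fewer points than parameters plus one")
    j = model_form.jacobian(params, v)
    s2 = ss / df
    cov = s2 * np.linalg.pinv(j.T @ j)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    fit = FittedCurve(
        model_form=model_form,
        parameter=parameter,
        params=params,
        se=se,
        cov=cov,
        ss=float(ss),
        df=int(df),
        n_points=len(v),
        vrange=vrange,
        converged=converged,
    )
    if compute_diagnostics:
        order = np.argsort(v, kind="stable")
        resid = (y - model_form.predict(params, v))[order]
        fit.diagnostics = residual_diagnostics(resid)
    return fit


# ---------------------------------------------------------------------------
# model selection


def extra_ss_f_test(ss1: float, df1: int, ss2: float, df2: int):
    """Extra sum-of-squares F-test of a simpler (1) vs more complex (2) fit.

    Returns ``(F, p)``.  F is clipped at 0 (p = 1) when the complex model
    fits no better, which can happen with quasi-nested families.
    """
    if df1 <= df2:
        raise ValueError("the simpler model must have more degrees of freedom")
    if ss2 < 0 or ss1 < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss1 <= ss2:
        return 0.0, 1.0
    if ss2 == 0:
        return float("inf"), 0.0
    f = ((ss1 - ss2) / (df1 - df2)) / (ss2 / df2)
    p = float(stats.f.sf(f, df1 - df2, df2))
    return float(f), p


@dataclass
class ModelSelectionResult:
    """One pairwise simpler-vs-complex comparison in the selection chain."""

    simpler: ModelForm
    complex: ModelForm
    ss1: float
    df1: int
    ss2: float
    df2: int
    F: float
    p: float
    preferred: ModelForm

    def to_dict(self) -> dict:
        return {
            "simpler": self.simpler.family,
            "complex": self.complex.family,
            "SS1": self.ss1,
            "DF1": self.df1,
            "SS2": self.ss2,
            "DF2": self.df2,
            "F": self.F,
            "p": self.p,
            "preferred": self.preferred.family,
        }


@dataclass
class ModelSelection:
    """Full chain of pairwise tests plus the final preferred fit."""

    steps: list
    preferred: ModelForm
    preferred_fit: FittedCurve
    fits: dict

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "preferred": self.preferred.family,
            "preferred_fit": self.preferred_fit.to_dict(),
        }


def select_model(
    table: StrideTable,
    parameter: str,
    candidates: Sequence[ModelForm] = DEFAULT_CANDIDATES,
    vrange: VelocityRange = WALKING_RANGE,
    alpha: float = 0.05,
    **fit_kwargs,
) -> ModelSelection:
    """Choose the simplest adequate family by sequential extra-SS F-tests.

    Candidates must be ordered by increasing parameter count.  At each step
    the more complex model is preferred only when p <= alpha; otherwise the
    chain stops at the simpler model.  A non-converged fit aborts selection
    with an explicit error.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate model")
    counts = [m.n_params for m in candidates]
    if counts != sorted(counts) or len(set(counts)) != len(counts):
        raise ValueError("candidates must be ordered by increasing parameter count")

    restricted, _ = restrict_range(table, vrange)
    y_all = restricted.data[parameter].to_numpy(float)
    y_all = y_all[np.isfinite(y_all)]
    tss = float(np.sum((y_all - y_all.mean()) ** 2)) if len(y_all) else 0.0

    fits: dict[str, FittedCurve] = {}
    current = candidates[0]
    fits[current.family] = fit_curve(table, parameter, current, vrange, **fit_kwargs)
    steps: list[ModelSelectionResult] = []
    for nxt in candidates[1:]:
        # a numerically perfect simpler fit cannot be improved upon; stop
        # before the F ratio degenerates to 0/0
        if fits[current.family].ss <= 1e-12 * max(tss, 1e-300):
            break
        fits[nxt.family] = fit_curve(table, parameter, nxt, vrange, **fit_kwargs)
        f1, f2 = fits[current.family], fits[nxt.family]
        if not (f1.converged and f2.converged):
            raise RuntimeError(
                f"model selection aborted: non-converged fit for "
                f"{current.family if not f1.converged else nxt.family}"
            )
        f_stat, p = extra_ss_f_test(f1.ss, f1.df, f2.ss, f2.df)
        preferred = nxt if p <= alpha else current
        steps.append(
            ModelSelectionResult(
                simpler=current,
                complex=nxt,
                ss1=f1.ss,
                df1=f1.df,
                ss2=f2.ss,
                df2=f2.df,
                F=f_stat,
                p=p,
                preferred=preferred,
            )
        )
        if preferred is current:
            break
        current = nxt
    return ModelSelection(
        steps=steps,
        preferred=current,
        preferred_fit=fits[current.family],
        fits=fits,
    )


def range_scan(
    table: StrideTable,
    parameter: str,
    candidates: Sequence[ModelForm] = DEFAULT_CANDIDATES,
    lower_bounds: Sequence[float] | None = None,
    upper_bounds: Sequence[float] | None = None,
    alpha: float = 0.05,
    **fit_kwargs,
) -> pd.DataFrame:
    """Model selection across systematically narrowed velocity ranges.

    Lower bounds increase from 0 by 1 cm/s and upper bounds decrease from
    25 by 1 cm/s by default.  The report carries the preferred family, SS
    and residual diagnostics per range; it supports a user's choice of
    range (conventionally [3, 16]) rather than deciding automatically.
    Ranges with insufficient data are marked ``skipped``.
    """
    if lower_bounds is None:
        lower_bounds = list(range(0, 9))
    if upper_bounds is None:
        upper_bounds = list(range(25, 15, -1))
    rows = []
    for lo in lower_bounds:
        for hi in upper_bounds:
            if not lo < hi:
                continue
            vrange = VelocityRange(float(lo), float(hi))
            row = {"lower": float(lo), "upper": float(hi)}
            try:
                sel = select_model(
                    table, parameter, candidates, vrange, alpha, **fit_kwargs
                )
            except (ValueError, RuntimeError) as exc:
                row.update(
                    status="skipped",
                    reason=str(exc),
                    n=np.nan,
                    preferred=None,
                    ss=np.nan,
                    runs_test_p=np.nan,
                    normality_p=np.nan,
                )
            else:
                fit = sel.preferred_fit
                row.update(
                    status="ok",
                    reason="",
                    n=fit.n_points,
                    preferred=sel.preferred.family,
                    ss=fit.ss,
                    runs_test_p=fit.diagnostics.get("runs_test_p", np.nan),
                    normality_p=fit.diagnostics.get("normality_p", np.nan),
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# residual diagnostics


def _runs_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact distribution of the number of runs given n1 and n2 signs.

    pmf[r] for r = 0..n1+n2; computed with log-gamma binomials so it stays
    stable for large samples.
    """

    def logc(n, k):
        k = np.asarray(k, float)
        out = np.full_like(k, -np.inf, dtype=float)
        valid = (k >= 0) & (k <= n)
        kv = k[valid]
        out[valid] = (
            special.gammaln(n + 1)
            - special.gammaln(kv + 1)
            - special.gammaln(n - kv + 1)
        )
        return out

    n = n1 + n2
    log_total = float(logc(n, np.array([n1]))[0])
    pmf = np.zeros(n + 1)
    r = np.arange(2, n + 1)
    k = r // 2
    even = r % 2 == 0
    log_even = (
        np.log(2.0) + logc(n1 - 1, k - 1) + logc(n2 - 1, k - 1) - log_total
    )
    a = logc(n1 - 1, k) + logc(n2 - 1, k - 1)
    b = logc(n1 - 1, k - 1) + logc(n2 - 1, k)
    log_odd = np.logaddexp(a, b) - log_total
    pmf[r] = np.where(even, np.exp(log_even), np.exp(log_odd))
    return pmf


def runs_test(x: Sequence[float]) -> dict:
    """Wald-Wolfowitz runs test on the signs of a sequence.

    Zeros are dropped.  The p-value is two-sided from the exact conditional
    runs distribution given the sign counts: ``2 * min(P(R <= r), P(R >= r))``
    capped at 1.  If every value has the same sign the arrangement is
    degenerate; that indicates systematic misfit, reported as p = 0 with a
    ``degenerate`` note.
    """
    x = np.asarray(x, float)
    s = np.sign(x)
    s = s[s != 0]
    n1 = int((s > 0).sum())
    n2 = int((s < 0).sum())
    if n1 + n2 < 2:
        return {"runs": len(s), "p": None, "note": "too few signed residuals"}
    runs = int(1 + (np.diff(s) != 0).sum())
    if n1 == 0 or n2 == 0:
        return {"runs": runs, "p": 0.0, "note": "degenerate: all one sign"}
    pmf = _runs_pmf(n1, n2)
    lower = float(pmf[: runs + 1].sum())
    upper = float(pmf[runs:].sum())
    p = min(1.0, 2.0 * min(lower, upper))
    return {"runs": runs, "p": p, "note": ""}


def residual_diagnostics(residuals: Sequence[float]) -> dict:
    """Runs test plus D'Agostino-Pearson omnibus normality on residuals.

    Residuals should be ordered by velocity before calling so the runs test
    probes systematic lack of fit along the predictor.  The normality test
    is refused (None, flagged) below 8 residuals.
    """
    residuals = np.asarray(residuals, float)
    rt = runs_test(residuals)
    out = {"runs": rt["runs"], "runs_test_p": rt["p"], "runs_note": rt["note"]}
    if len(residuals) < 8:
        out["normality_p"] = None
        out["normality_note"] = "refused: fewer than 8 residuals"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out["normality_p"] = float(stats.normaltest(residuals).pvalue)
        out["normality_note"] = ""
    return out
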