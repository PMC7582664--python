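"""Six-coefficient phenology curve models and least-squares fitting.

Three model families, each with exactly six free coefficients so their fits
are comparable:

* AG — asymmetric Gaussian, a piecewise function sharing base level c1,
  amplitude c2 and peak position a1, with separate left/right widths a2, a3
  and a common flatness exponent a4:

      f(t) = c1 + c2 * exp(-(((a1 - t)/a2)**a4))   for t <= a1
      f(t) = c1 + c2 * exp(-(((t - a1)/a3)**a4))   for t >  a1

* DL — double logistic, the difference of two logistic terms with left/right
  inflection positions a1, a3 and rates a2, a4:

      f(t) = c1 + c2 * (1/(1 + exp((a1 - t)/a2)) - 1/(1 + exp((a3 - t)/a4)))

* TF — two-term Fourier (harmonic) series with fitted fundamental frequency
  w, initialised at 2*pi/365 (~0.017 rad/day, one cycle per year):

      f(t) = c + a1*cos(wt) + b1*sin(wt) + a2*cos(2wt) + b2*sin(2wt)

t is the day of the year. Fitting is bounded nonlinear least squares
(trust-region reflective) with data-driven initialisation; it is fully
deterministic. Fit quality is the coefficient of determination R^2, and
groups of R^2 values are compared with one-way ANOVA plus Tukey HSD.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .timeseries import MIN_OBSERVATIONS, ViSeries

logger = logging.getLogger(__name__)

METHODS = ("AG", "DL", "TF")

#: Annual fundamental frequency in rad/day; rounds to the conventional 0.017.
W_ANNUAL = 2.0 * np.pi / 365.0

COEF_NAMES = {
    "AG": ("c1", "c2", "a1", "a2", "a3", "a4"),
    "DL": ("c1", "c2", "a1", "a2", "a3", "a4"),
    "TF": ("c", "w", "a1", "b1", "a2", "b2"),
}

# Bounds keep fits inside a single annual cycle: AG/DL widths and rates in
# days, TF frequency within [0.5, 2] cycles per year (unconstrained w is
# routinely overestimated when the dormant season is unobserved).
DEFAULT_BOUNDS = {
    "AG": {"c1": (-2.0, 2.0), "c2": (1e-6, 3.0), "a1": (1.0, 365.0),
           "a2": (3.0, 200.0), "a3": (3.0, 200.0), "a4": (0.5, 10.0)},
    "DL": {"c1": (-2.0, 2.0), "c2": (1e-6, 3.0), "a1": (1.0, 365.0),
           "a2": (0.5, 60.0), "a3": (1.0, 365.0), "a4": (0.5, 60.0)},
    "TF": {"c": (-2.0, 2.0), "w": (0.5 * W_ANNUAL, 2.0 * W_ANNUAL),
           "a1": (-2.0, 2.0), "b1": (-2.0, 2.0), "a2": (-2.0, 2.0),
           "b2": (-2.0, 2.0)},
}


@dataclass
class FittedCurve:
    """A fitting-method tag plus six named coefficients and diagnostics."""

    method: str
    coefficients: dict[str, float]
    r2: float
    n_obs: int
    converged: bool

    @property
    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[k] for k in COEF_NAMES[self.method]])

    def __call__(self, t):
        return eval_model(self.method, self.coefficients, t)


def _coef_vector(method: str, coefficients) -> np.ndarray:
    names = COEF_NAMES[method]
    if isinstance(coefficients, dict):
        return np.array([float(coefficients[k]) for k in names])
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (6,):
        raise ValueError(f"{method} needs exactly 6 coefficients, got shape {c.shape}")
    return c


def eval_model(method: str, coefficients, t):
    """Evaluate one of the three model families at day(s)-of-year ``t``."""
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    c = _coef_vector(method, coefficients)
    t = np.asarray(t, dtype=float)

    if method == "AG":
        c1, c2, a1, a2, a3, a4 = c
        if a2 <= 0 or a3 <= 0:
            raise ValueError("AG widths a2, a3 must be > 0")
        left = (np.maximum(a1 - t, 0.0) / a2) ** a4
        right = (np.maximum(t - a1, 0.0) / a3) ** a4
        out = c1 + c2 * np.exp(-np.where(t <= a1, left, right))
    elif method == "DL":
        c1, c2, a1, a2, a3, a4 = c
        if a2 <= 0 or a4 <= 0:
            raise ValueError("DL rates a2, a4 must be > 0")
        with np.errstate(over="ignore"):  # saturated logistic tails are exact 0/1
            out = c1 + c2 * (1.0 / (1.0 + np.exp((a1 - t) / a2))
                             - 1.0 / (1.0 + np.exp((a3 - t) / a4)))
    else:  # TF
        cc, w, a1, b1, a2, b2 = c
        if w <= 0:
            raise ValueError("TF frequency w must be > 0")
        out = (cc + a1 * np.cos(w * t) + b1 * np.sin(w * t)
               + a2 * np.cos(2.0 * w * t) + b2 * np.sin(2.0 * w * t))

    if not np.all(np.isfinite(out)):
        names = COEF_NAMES[method]
        bad = {n: v for n, v in zip(names, c) if not np.isfinite(v)}
        raise ValueError(f"{method} evaluation produced non-finite values "
                         f"(suspect coefficients: {bad or dict(zip(names, c))})")
    return float(out) if out.ndim == 0 else out


def model_jacobian(method: str, coefficients, t) -> np.ndarray:
    """Analytic Jacobian d f / d coefficients, shape (len(t), 6).

    Columns follow ``COEF_NAMES[method]``. At the AG peak (t == a1) the
    width/position partials are taken as their one-sided zero limit.
    """
    method = method.upper()
    c = _coef_vector(method, coefficients)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    J = np.empty((len(t), 6))

    if method == "AG":
        c1, c2, a1, a2, a3, a4 = c
        left = t <= a1
        r = np.where(left, np.maximum(a1 - t, 0.0) / a2,
                     np.maximum(t - a1, 0.0) / a3)
        s = r ** a4
        e = np.exp(-s)
        pos = r > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ds_dr = np.where(pos, a4 * r ** (a4 - 1.0), 0.0)
            dlog = np.where(pos, s * np.log(np.where(pos, r, 1.0)), 0.0)
        dr_da1 = np.where(left, 1.0 / a2, -1.0 / a3)
        J[:, 0] = 1.0
        J[:, 1] = e
        J[:, 2] = -c2 * e * ds_dr * dr_da1
        J[:, 3] = np.where(left, c2 * e * ds_dr * r / a2, 0.0)
        J[:, 4] = np.where(left, 0.0, c2 * e * ds_dr * r / a3)
        J[:, 5] = -c2 * e * dlog
    elif method == "DL":
        c1, c2, a1, a2, a3, a4 = c
        with np.errstate(over="ignore"):
            u = 1.0 / (1.0 + np.exp((a1 - t) / a2))
            v = 1.0 / (1.0 + np.exp((a3 - t) / a4))
        J[:, 0] = 1.0
        J[:, 1] = u - v
        J[:, 2] = -c2 * u * (1.0 - u) / a2
        J[:, 3] = c2 * u * (1.0 - u) * (a1 - t) / a2**2
        J[:, 4] = c2 * v * (1.0 - v) / a4
        J[:, 5] = -c2 * v * (1.0 - v) * (a3 - t) / a4**2
    else:  # TF
        cc, w, a1, b1, a2, b2 = c
        J[:, 0] = 1.0
        J[:, 1] = t * (-a1 * np.sin(w * t) + b1 * np.cos(w * t)
                       - 2.0 * a2 * np.sin(2 * w * t) + 2.0 * b2 * np.cos(2 * w * t))
        J[:, 2] = np.cos(w * t)
        J[:, 3] = np.sin(w * t)
        J[:, 4] = np.cos(2 * w * t)
        J[:, 5] = np.sin(2 * w * t)
    return J


def harmonic_least_squares(days, values, w: float = W_ANNUAL) -> dict[str, float]:
    """Closed-form linear least squares for the TF model with frozen w.

    With the fundamental frequency fixed the two-term Fourier model is
    linear in its remaining five coefficients; this solves the normal
    system directly and is the initialiser (and an independent oracle) for
    the nonlinear TF fit.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(days), np.cos(w * days), np.sin(w * days),
                         np.cos(2 * w * days), np.sin(2 * w * days)])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return {"c": beta[0], "w": w, "a1": beta[1], "b1": beta[2],
            "a2": beta[3], "b2": beta[4]}


def _initial_guess(method: str, days: np.ndarray, values: np.ndarray) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    amp = max(vmax - vmin, 1e-3)
    peak_day = float(days[int(np.argmax(values))])  # earliest day of max
    if method == "AG":
        return np.array([vmin, amp, peak_day, 40.0, 40.0, 2.0])
    if method == "DL":
        level = vmin + 0.5 * amp
        above = values >= level
        a1 = float(days[above][0]) if above.any() else peak_day - 40.0
        a3 = float(days[above][-1]) if above.any() else peak_day + 40.0
        if a3 <= a1:
            a1, a3 = peak_day - 40.0, peak_day + 40.0
        return np.array([vmin, amp, a1, 10.0, a3, 10.0])
    beta = harmonic_least_squares(days, values)
    return np.array([beta["c"], W_ANNUAL, beta["a1"], beta["b1"],
                     beta["a2"], beta["b2"]])


def fit_curve(series: ViSeries, method: str, *, bounds=None,
              freeze_w: bool = False, ftol: float = 1e-10,
              xtol: float = 1e-10) -> FittedCurve:
    """Fit one model family to a VI series by bounded least squares.

    Deterministic given the series and settings (no multistart). On
    non-convergence the best iterate is returned with ``converged=False``,
    never an exception. ``freeze_w`` pins the TF fundamental frequency at
    2*pi/365 (one annual cycle) and optimises the remaining five
    coefficients only.

    Requires at least 6 observations (the minimum-observation rule).
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if len(series) < MIN_OBSERVATIONS:
        raise ValueError(f"series has {len(series)} < {MIN_OBSERVATIONS} observations; "
                         "use the all-zero fallback vector instead of fitting")
    days = series.days
    values = series.values
    names = COEF_NAMES[method]
    bnds = dict(DEFAULT_BOUNDS[method])
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[k][0] for k in names])
    hi = np.array([bnds[k][1] for k in names])
    x0 = np.clip(_initial_guess(method, days, values), lo, hi)

    free = np.ones(6, dtype=bool)
    if freeze_w:
        if method != "TF":
            raise ValueError("freeze_w only applies to the TF method")
        free[names.index("w")] = False

    def residuals(xfree):
        x = x0.copy()
        x[free] = xfree
        return eval_model(method, x, days) - values

    def jac(xfree):
        x = x0.copy()
        x[free] = xfree
        return model_jacobian(method, x, days)[:, free]

    result = optimize.least_squares(residuals, x0[free], jac=jac,
                                    bounds=(lo[free], hi[free]),
                                    method="trf", ftol=ftol, xtol=xtol, gtol=1e-10,
                                    max_nfev=2000 * 6)
    x = x0.copy()
    x[free] = result.x
    converged = bool(result.success)
    if not converged:
        logger.warning("pixel %s: %s fit did not converge (%s)",
                       series.pixel_id, method, result.message)
    coefficients = dict(zip(names, (float(v) for v in x)))
    fit = FittedCurve(method=method, coefficients=coefficients, r2=np.nan,
                      n_obs=len(series), converged=converged)
    fit.r2 = r_squared(series, fit)
    return fit


def r_squared(series: ViSeries, fit) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot over the series.

    A zero-variance series gives 0 with a warning; worse-than-mean fits are
    allowed to go negative.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    predicted = np.asarray(fit(series.days) if callable(fit)
                           else eval_model(fit.method, fit.coefficients, series.days))
    ss_res = float(np.sum((series.values - predicted) ** 2))
    ss_tot = float(np.sum((series.values - series.values.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero-variance series: R^2 defined as 0", stacklevel=2)
        return 0.0
    return 1.0 - ss_res / ss_tot


@dataclass
class FitComparison:
    """Omnibus ANOVA plus all pairwise Tukey HSD rows.

    ``table`` columns: class1, class2, lower (CI), estimate (mean
    difference class2 - class1), upper (CI), p.
    """

    anova_f: float
    anova_p: float
    table: pd.DataFrame


def compare_fit_accuracy(groups: dict) -> FitComparison:
    """Compare labeled R^2 collections: one-way ANOVA, then Tukey HSD.

    ``groups`` maps label -> sequence of R^2 values (each of length >= 2).
    Raises on fewer than two groups or zero within-group variance
    everywhere (the comparison is then degenerate).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    if all(np.var(v) == 0.0 for v in arrays.values()):
        raise ValueError("zero within-group variance in every group: "
                         "ANOVA/Tukey comparison is degenerate")

    f_stat, p_val = stats.f_oneway(*arrays.values())
    endog = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    res = pairwise_tukeyhsd(endog, labels)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    table = pd.DataFrame({
        "class1": [p[0] for p in pairs],
        "class2": [p[1] for p in pairs],
        "lower": res.confint[:, 0],
        "estimate": res.meandiffs,
        "upper": res.confint[:, 1],
        "p": res.pvalues,
    })
    return FitComparison(anova_f=float(f_stat), anova_p=float(p_val), table=table)
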