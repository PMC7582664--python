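"""Threshold-based phenological metrics from a fitted curve.

Six metrics summarise one annual cycle of a fitted phenology curve:

* BV, MV — base (minimum) and maximum value of the curve over days 1-365;
* SOS, EOS — start/end of season: the days the curve crosses
  BV + 0.5 (MV - BV) going up before the seasonal maximum and going down
  after it (the 50% threshold; a 10-90% grid is available for sweeps);
* ROI, ROD — rates of increase/decrease: the slope between the 20% and 80%
  threshold crossings on the green-up and senescence limbs, stored as
  magnitudes in VI units per day.

Crossings are bracketed on a 1-day grid and refined by bisection to 0.01
day. Multi-peak curves (possible with the Fourier family) are handled by
working around the global maximum only — the metric set presumes a single
growing season. A pixel with fewer than six observations never reaches this
module's extractor: its feature vector is the all-zero fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import MIN_OBSERVATIONS, ViSeries

#: Feature vector assigned to pixels that fail the minimum-observation rule
#: or whose curve has no usable seasonal crossing (under the "zero" policy).
FALLBACK_VECTOR = np.zeros(6)

METRIC_NAMES = ("bv", "mv", "sos", "eos", "roi", "rod")

_GRID_STEP = 1.0       # day; crossing bracketing
_DENSE_STEP = 0.1      # day; extrema location
_BISECT_TOL = 0.01     # day; crossing refinement


@dataclass
class PhenoMetrics:
    """The six-element phenology feature set for one fitted curve.

    ``flags`` lists metrics that could not be computed (missing crossing on
    a flat or monotone curve) and were set by the fallback policy.
    """

    bv: float
    mv: float
    sos: float
    eos: float
    roi: float
    rod: float
    flags: list = field(default_factory=list)


def _bisect_crossing(f, level, t_lo, t_hi) -> float:
    """Refine a sign-change bracket of f - level to 0.01-day precision."""
    g_lo = f(t_lo) - level
    while t_hi - t_lo > _BISECT_TOL:
        mid = 0.5 * (t_lo + t_hi)
        g_mid = f(mid) - level
        if (g_mid < 0.0) == (g_lo < 0.0):
            t_lo, g_lo = mid, g_mid
        else:
            t_hi = mid
    return 0.5 * (t_lo + t_hi)


def _crossings(f, grid, level):
    """All (t, rising) crossings of ``level`` on the grid, refined."""
    vals = np.asarray(f(grid), dtype=float) - level
    out = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            out.append((float(grid[i]), b > a))
        elif (a < 0.0 < b) or (a > 0.0 > b):
            out.append((_bisect_crossing(f, level, grid[i], grid[i + 1]), b > a))
    return out


def extract_metrics(fit, *, sos_eos_threshold: float = 0.5,
                    rate_thresholds: tuple = (0.2, 0.8),
                    fallback: str = "zero") -> PhenoMetrics:
    """Extract the six phenological metrics from a fitted curve.

    Parameters
    ----------
    fit
        A ``FittedCurve`` (or any callable of day-of-year).
    sos_eos_threshold
        Fraction q of the seasonal range defining the SOS/EOS level
        BV + q (MV - BV); default 0.5, the value that best matches observed
        field phenology. Any value in (0, 1) supports threshold sweeps.
    rate_thresholds
        The (low, high) fractions bounding the rate computation; default
        (0.2, 0.8).
    fallback
        Policy for metrics with no crossing: "zero" (value 0, flagged) or
        "nan".
    """
    if not (0.0 < sos_eos_threshold < 1.0):
        raise ValueError("sos_eos_threshold must lie in (0, 1)")
    q_lo, q_hi = rate_thresholds
    if not (0.0 < q_lo < q_hi < 1.0):
        raise ValueError("rate_thresholds must satisfy 0 < low < high < 1")
    fill = 0.0 if fallback == "zero" else np.nan

    f = fit if callable(fit) else (lambda t: fit)
    dense = np.arange(1.0, 365.0 + _DENSE_STEP / 2, _DENSE_STEP)
    dense_vals = np.asarray(f(dense), dtype=float)
    bv = float(dense_vals.min())
    mv = float(dense_vals.max())
    peak_t = float(dense[int(np.argmax(dense_vals))])  # global maximum only

    flags = []
    if mv - bv <= 1e-12:
        flags = ["sos", "eos", "roi", "rod"]
        return PhenoMetrics(bv=bv, mv=mv, sos=fill, eos=fill, roi=fill,
                            rod=fill, flags=flags)

    grid = np.arange(1.0, 365.0 + _GRID_STEP / 2, _GRID_STEP)

    def level(q):
        return bv + q * (mv - bv)

    def last_rising_before(q):
        ts = [t for t, rising in _crossings(f, grid, level(q)) if rising and t < peak_t]
        return ts[-1] if ts else None

    def first_falling_after(q):
        ts = [t for t, rising in _crossings(f, grid, level(q)) if not rising and t > peak_t]
        return ts[0] if ts else None

    sos = last_rising_before(sos_eos_threshold)
    eos = first_falling_after(sos_eos_threshold)
    t_lo_up, t_hi_up = last_rising_before(q_lo), last_rising_before(q_hi)
    t_hi_dn, t_lo_dn = first_falling_after(q_hi), first_falling_after(q_lo)

    if sos is None:
        flags.append("sos")
        sos = fill
    if eos is None:
        flags.append("eos")
        eos = fill
    if t_lo_up is None or t_hi_up is None or t_hi_up <= t_lo_up:
        flags.append("roi")
        roi = fill
    else:
        roi = (level(q_hi) - level(q_lo)) / (t_hi_up - t_lo_up)
    if t_hi_dn is None or t_lo_dn is None or t_lo_dn <= t_hi_dn:
        flags.append("rod")
        rod = fill
    else:
        rod = (level(q_hi) - level(q_lo)) / (t_lo_dn - t_hi_dn)  # magnitude

    return PhenoMetrics(bv=bv, mv=mv, sos=float(sos), eos=float(eos),
                        roi=float(roi), rod=float(rod), flags=flags)


def metrics_vector(metrics) -> np.ndarray:
    """Ordered feature vector [BV, MV, SOS, EOS, ROI, ROD].

    ``None`` (a pixel that failed the minimum-observation rule) yields the
    all-zero fallback vector.
    """
    if metrics is None:
        return FALLBACK_VECTOR.copy()
    return np.array([metrics.bv, metrics.mv, metrics.sos, metrics.eos,
                     metrics.roi, metrics.rod], dtype=float)


def series_to_vector(series: ViSeries, method: str, **fit_kwargs) -> np.ndarray:
    """Fit + extract in one step, honouring the minimum-observation rule:
    series with fewer than 6 points get the all-zero vector directly."""
    from .curvefit import fit_curve
    from .timeseries import meets_min_observations

    if not meets_min_observations(series):
        return FALLBACK_VECTOR.copy()
    fit = fit_curve(series, method, **fit_kwargs)
    return metrics_vector(extract_metrics(fit))
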