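"""Pixel-differential VI time series construction.

Cloud/shadow masking with the scene-classification (SC) band removes a
different subset of acquisition dates for every pixel, so each pixel carries
its own irregular observation calendar ("pixel-differential" series). This
module holds the per-pixel containers and the three construction steps:
mask flagged SC codes, compute the requested vegetation index in
chronological order, and apply the minimum-observation rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import indices

logger = logging.getLogger(__name__)

#: SC codes removed before any analysis: 3 cloud shadow, 8-10 cloud/cirrus
#: at different confidences, 11 snow.
FLAGGED_SC_CODES = frozenset({3, 8, 9, 10, 11})

#: Minimum observations a pixel needs for curve fitting; below this the
#: phenological feature vector falls back to all zeros.
MIN_OBSERVATIONS = 6

LONG_COLUMNS = ["pixel_id", "day", "blue", "green", "red", "nir", "sc_code"]


@dataclass
class ObservationSeries:
    """One pixel's irregular time series of band reflectances + SC codes."""

    pixel_id: str
    days: np.ndarray
    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    sc_codes: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        for name in ("blue", "green", "red", "nir"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.sc_codes = np.asarray(self.sc_codes, dtype=int)
        n = len(self.days)
        for name in ("blue", "green", "red", "nir", "sc_codes"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length != days length {n}")

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pixel_id": self.pixel_id, "day": self.days,
            "blue": self.blue, "green": self.green,
            "red": self.red, "nir": self.nir, "sc_code": self.sc_codes,
        })


@dataclass
class ViSeries:
    """Masked, chronologically sorted VI values for one pixel."""

    pixel_id: str
    days: np.ndarray
    values: np.ndarray
    vi_name: str

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.days) != len(self.values):
            raise ValueError("days and values lengths differ")

    def __len__(self) -> int:
        return len(self.days)


def apply_sc_mask(series: ObservationSeries) -> ObservationSeries:
    """Drop observations whose SC code is flagged (cloud shadow, cloud/cirrus,
    snow); all other codes are retained and order is preserved. Idempotent."""
    keep = ~np.isin(series.sc_codes, list(FLAGGED_SC_CODES))
    n_masked = int((~keep).sum())
    if n_masked:
        logger.info("pixel %s: masked %d flagged observations", series.pixel_id, n_masked)
    return ObservationSeries(
        pixel_id=series.pixel_id,
        days=series.days[keep], blue=series.blue[keep], green=series.green[keep],
        red=series.red[keep], nir=series.nir[keep], sc_codes=series.sc_codes[keep],
    )


def build_vi_series(series: ObservationSeries, vi_name: str,
                    evi_blue_coef: float = indices.DEFAULT_EVI_BLUE_COEF) -> ViSeries:
    """Compute one VI per retained observation, in chronological order.

    The input is assumed already masked. Observations where the index is
    undefined (zero denominator) are dropped with a logged count. Duplicate
    acquisition days (overlapping tiles) are kept as repeated x-values, in
    stable input order.
    """
    order = np.argsort(series.days, kind="stable")
    days = series.days[order]
    values = indices.compute_vi(series.blue[order], series.green[order],
                                series.red[order], series.nir[order],
                                vi_name, evi_blue_coef)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    ok = np.isfinite(values)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("pixel %s: dropped %d observations with undefined %s",
                       series.pixel_id, n_dropped, vi_name)
    return ViSeries(pixel_id=series.pixel_id, days=days[ok], values=values[ok],
                    vi_name=vi_name.upper())


def meets_min_observations(series: ViSeries) -> bool:
    """True iff the series has at least ``MIN_OBSERVATIONS`` (= 6) points.

    Callers must substitute the all-zero six-element phenology vector for
    pixels that fail this rule instead of fitting a curve.
    """
    return len(series) >= MIN_OBSERVATIONS


def series_from_frame(table: pd.DataFrame) -> list[ObservationSeries]:
    """Split a long-format table (one row = pixel, day, bands, sc_code) into
    per-pixel ObservationSeries, preserving row order within a pixel."""
    out = []
    for pid, grp in table.groupby("pixel_id", sort=False):
        out.append(ObservationSeries(
            pixel_id=str(pid), days=grp["day"].to_numpy(),
            blue=grp["blue"].to_numpy(), green=grp["green"].to_numpy(),
            red=grp["red"].to_numpy(), nir=grp["nir"].to_numpy(),
            sc_codes=grp["sc_code"].to_numpy(),
        ))
    return out
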