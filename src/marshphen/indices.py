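"""Vegetation indices computed from surface reflectance.

Five indices are supported, chosen for salt-marsh work because none of them
needs bands coarser than 10 m and together they cover soil-background
(SAVI), atmosphere/biomass (EVI), chlorophyll (GNDVI) and open-water (WAVI)
adjustments on top of the plain NDVI:

    NDVI  = (nir - red) / (nir + red)
    SAVI  = (1 + L) (nir - red) / (nir + red + L),      L = 0.5
    GNDVI = (nir - green) / (nir + green)
    EVI   = 2.5 (nir - red) / (nir + 6 red - C_blue * blue + 1)
    WAVI  = (1 + L) (nir - blue) / (nir + blue + L),    L = 0.5

The EVI blue-band coefficient ``C_blue`` is 7.5 in the canonical definition,
but 7.0 also circulates in the applied literature; it is exposed as
``evi_blue_coef`` so either convention can be reproduced.

All functions are pure and vectorised: scalars in, scalar out; arrays in,
arrays out. A zero denominator yields NaN (an explicit undefined value),
never an infinity.
"""

from __future__ import annotations

import numpy as np

#: Canopy background adjustment factor shared by SAVI and WAVI (read-only).
L = 0.5

#: Default EVI blue-band coefficient (canonical definition).
DEFAULT_EVI_BLUE_COEF = 7.5

#: Supported vegetation-index names, in canonical order.
VI_NAMES = ("NDVI", "SAVI", "EVI", "GNDVI", "WAVI")


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / np.where(den != 0.0, den, np.nan)


def ndvi(red, nir):
    return _safe_ratio(np.asarray(nir, float) - red, np.asarray(nir, float) + red)


def savi(red, nir):
    return (1.0 + L) * _safe_ratio(np.asarray(nir, float) - red,
                                   np.asarray(nir, float) + red + L)


def gndvi(green, nir):
    return _safe_ratio(np.asarray(nir, float) - green, np.asarray(nir, float) + green)


def evi(blue, red, nir, evi_blue_coef: float = DEFAULT_EVI_BLUE_COEF):
    den = np.asarray(nir, float) + 6.0 * np.asarray(red, float) \
        - evi_blue_coef * np.asarray(blue, float) + 1.0
    return 2.5 * _safe_ratio(np.asarray(nir, float) - red, den)


def wavi(blue, nir):
    return (1.0 + L) * _safe_ratio(np.asarray(nir, float) - blue,
                                   np.asarray(nir, float) + blue + L)


def compute_vi(blue, green, red, nir, vi_name: str,
               evi_blue_coef: float = DEFAULT_EVI_BLUE_COEF):
    """Evaluate one named vegetation index from the four 10 m bands.

    Parameters
    ----------
    blue, green, red, nir
        Surface reflectances in [0, 1] (scalars or broadcastable arrays).
    vi_name
        One of ``VI_NAMES``.
    evi_blue_coef
        Blue-band coefficient for EVI only (7.5 canonical, 7.0 variant).

    Returns
    -------
    float or ndarray
        Index value(s); NaN where the denominator is zero.
    """
    name = vi_name.upper()
    if name == "NDVI":
        out = ndvi(red, nir)
    elif name == "SAVI":
        out = savi(red, nir)
    elif name == "GNDVI":
        out = gndvi(green, nir)
    elif name == "EVI":
        out = evi(blue, red, nir, evi_blue_coef)
    elif name == "WAVI":
        out = wavi(blue, nir)
    else:
        raise ValueError(f"unknown vegetation index {vi_name!r}; expected one of {VI_NAMES}")
    if np.ndim(out) == 0:
        return float(out)
    return out


def add_vi_columns(table, vi_names=VI_NAMES,
                   evi_blue_coef: float = DEFAULT_EVI_BLUE_COEF):
    """Append one column per requested index to a long-format table.

    The table must carry ``blue``, ``green``, ``red`` and ``nir`` columns;
    a lower-cased column per index name is added. Returns a copy.
    """
    out = table.copy()
    for name in vi_names:
        out[name.lower()] = compute_vi(out["blue"].to_numpy(),
                                       out["green"].to_numpy(),
                                       out["red"].to_numpy(),
                                       out["nir"].to_numpy(),
                                       name, evi_blue_coef)
    return out
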