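"""Fit the three phenology curve families to one pixel's NDVI series.

Simulates a single pixel with realistic noise, masks flagged scene-
classification codes, builds the chronological NDVI series and fits the
asymmetric Gaussian (AG), double logistic (DL) and two-term Fourier (TF)
models, reporting R-squared for each.
"""

from marshphen import (CONTINENTAL, NoiseConfig, PhenologyTemplate,
                       apply_sc_mask, build_vi_series, fit_curve,
                       sample_observation_dates, simulate_observations)

template = PhenologyTemplate("S_alterniflora", base_level=0.18, amplitude=0.55,
                             peak_day=235, green_up_width=55,
                             senescence_width=55, cycle_shift=25)
dates = sample_observation_dates(CONTINENTAL, n_nominal=73, seed=7)
noise = NoiseConfig(tide_event_rate=0.05, cloud_omission_rate=0.05,
                    gaussian_sigma=0.01, seed=7)
series = build_vi_series(apply_sc_mask(
    simulate_observations(template, dates, noise)), "NDVI")

print(f"{len(series)} usable observations")
for method in ("AG", "DL", "TF"):
    fit = fit_curve(series, method)
    coef = ", ".join(f"{k}={v:.3g}" for k, v in fit.coefficients.items())
    print(f"{method}: R^2 = {fit.r2:.4f}  ({coef})")

# Under event noise the three families score similarly; note the fitted TF
# frequency w drifting above 2*pi/365 ~ 0.0172 rad/day when the winter gap
# leaves the dormant season under-observed -- the overestimation that the
# bounded-w design limits.
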