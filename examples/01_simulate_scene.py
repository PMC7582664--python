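"""Simulate a labeled coastal scene and write its observation tables.

Generates six salt-marsh vegetation classes on a winter-gap (continental)
observation calendar with tide and omitted-cloud noise, then writes the
long-format observation table and the sample-label table as CSV.
"""

from pathlib import Path

from marshphen import synth

samples = synth.generate_sample_set(
    synth.DEFAULT_CLASSES, n_per_class=5,
    regime=synth.CONTINENTAL, noise=synth.CONTINENTAL_NOISE, seed=1)

obs = synth.samples_to_frame(samples)
labels = synth.labels_to_frame(samples)

out = Path("scene_out")
out.mkdir(exist_ok=True)
obs.to_csv(out / "observations.csv", index=False)
labels.to_csv(out / "labels.csv", index=False)

print(f"{len(samples)} pixels, {len(obs)} observations "
      f"({len(obs) / len(samples):.1f} per pixel after winter thinning)")
print(labels.groupby("class")["peak_day"].mean().round(1).to_string())
# The per-class mean peak days reflect each species' cycle: the lagged
# invasive cordgrass peaks ~3 weeks later than the advanced common reed.
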