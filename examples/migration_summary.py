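"""The full pipeline and its Table-1-style migration summary.

Simulates ten birds (eight Pacific-like, two Atlantic-like), runs the
complete chain - geolocation, SST correction, speed filter, smoothing,
segmentation, wintering contours, phase splitting - and prints the
per-bird summary plus the between-basin Welch tests.
"""
from xema import BirdInput, PipelineConfig, run_pipeline, simulate_cohort

config = PipelineConfig()
cohort = simulate_cohort(config, n_pacific=8, n_atlantic=2, seed=5)
inputs = [
    BirdInput(b.itinerary.bird_id, b.twilights, b.sst_samples, b.itinerary.sex, b.itinerary.deployment_year)
    for b in cohort.birds
]
result = run_pipeline(config, inputs, cohort.grids)

print(result.summary_frame.to_string(index=False))

for name, t in result.tests.items():
    print(f"\n{name}: t = {t.statistic:.3f}, df = {t.df[0]:.1f}, p = {t.p_value:.3f}")
print("\nDuration ~80-95 d, distances ~13-14,000 km and speeds ~300-350 km/d per")
print("bird; the Welch tests compare Pacific vs Atlantic migrants (no difference")
print("is expected: both basins are simulated with the same movement rules).")
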