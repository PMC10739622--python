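"""The full noise-vs-bias study on a small phantom.

Runs the complete workflow — simulation, ANN training, all denoisers, kinetic
fitting, and the EnNSD/RE/NR evaluation — at a reduced problem size and prints
the method comparison table. Expect a few minutes of runtime.
"""

from petdenoise import DemoProfile, run_demo

profile = DemoProfile(
    shape=(32, 32, 20),
    k_pairs=10_000,
    high_variance_count=5_000,
    iterations=10_000,
    n_realizations=4,
    dose_fraction=0.25,  # partition into 4 disjoint quarter-count realizations
    nlm_h=(1.0,),
)
result = run_demo(seed=1, profile=profile)

summary = (
    result.table
    .groupby(["method", "parameter", "target"])[["ennsd_pct", "re_pct", "nr_pct"]]
    .mean()
    .round(1)
)
print(summary.to_string())
print(f"\ntrained on frame {result.train_frame_index + 1} (1-based)")
print("noise-matched Gaussian FWHM per ANN pass (mm):",
      {k: round(v, 2) for k, v in result.matched_fwhm.items()})
# EnNSD is the ensemble noise across realizations (%), RE the regional bias
# against the full-count reference (%), NR the noise reduction relative to the
# raw reduced-count data (%). The chained ANN+HYPR row shows the largest NR on
# frames and on the K1/VT maps at a few percent bias.
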