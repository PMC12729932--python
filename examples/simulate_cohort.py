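"""Simulate a small synthetic MER cohort and inspect its structure.

Each patient contributes 2 hemispheres x 3 electrodes x 16 depth levels;
traces whose depth falls inside the trajectory's STN interval are labeled
STN and carry higher firing, noise and spike amplitude.
"""

from mer_pipelines import CohortConfig, simulate_cohort

cfg = CohortConfig(n_patients=2, fs=8000, trace_duration=10.0, seed=0)
traces, manifest = simulate_cohort(cfg)

print(f"traces: {len(traces)} "
      f"({cfg.n_patients} patients x 2 hemispheres x "
      f"{len(cfg.electrodes)} electrodes x {len(cfg.edt_levels)} depths)")
print("class balance:", manifest["label"].value_counts().to_dict())
print("traces with injected artifacts:", int(manifest["has_artifact"].sum()))

t = traces[0]
print(f"\nfirst trace: {t.trace_id}")
print(f"  {len(t.samples)} samples at {t.fs} Hz = {t.duration:.0f} s, "
      f"label {t.label}")
# The label follows the simulated anatomy: depths inside the per-trajectory
# STN interval are STN, and the class balance varies with the drawn spans.
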