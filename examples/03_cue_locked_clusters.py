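"""Cue-locked time-frequency contrast with cluster-based permutation stats.

Simulates a small cohort of TMR nights in which memory cues evoke a theta
transient and a later spindle burst more often than control cues, runs the
full per-participant analysis, and tests the memory-vs-control contrast with
the max-statistic cluster permutation test.
"""

from sleeptmr import synthgen
from sleeptmr.pipeline import RunConfig, run_full

sim = synthgen.SimConfig(duration_s=1800.0,
                         cue=synthgen.CueSpec(start_after_s=120.0))
cfg = RunConfig(sim=sim, n_participants=8, n_perm=500, seed=2)
report = run_full(cfg)

print("memory vs control TFR clusters (corrected):")
for c in report["tfr_clusters"][:3]:
    print(f"  t_sum={c['t_sum']:9.1f}  p={c['p']:.3f}  "
          f"freq {c['freq_hz'][0]:.1f}-{c['freq_hz'][1]:.1f} Hz  "
          f"time {c['time_s'][0]:.2f}-{c['time_s'][1]:.2f} s")
print("spindle-probability clusters:")
for c in report["spindle_prob_clusters"][:3]:
    print(f"  t_sum={c['t_sum']:9.1f}  p={c['p']:.3f}  "
          f"time {c['time_s'][0]:.2f}-{c['time_s'][1]:.2f} s")
# At this small scale the theta-band response and the post-cue rise in
# spindle probability reach corrected significance; the spindle-band power
# cluster needs a larger cohort and longer nights (the test suite checks it
# at 12 participants x 1 h). All p-values are corrected for every
# time-frequency comparison via the permutation max-statistic.
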