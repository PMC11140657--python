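"""Score emotional memory trade-off behavior and test the cueing benefit.

Simulates item-level recognition responses for 31 participants around the
study-design group means (hit and false-alarm rates per emotion x component
x cue condition), computes corrected recognition (hit - FA) and the cueing
benefit (cued - uncued), and runs one-sample t tests with FDR adjustment.
"""

import numpy as np

from sleeptmr import synthgen
from sleeptmr.memstats import fdr_adjust, one_sample_t, score_behavior

items, _ = synthgen.gen_behavior(31, synthgen.BehaviorSpec(), seed=8)
scores = score_behavior(items)

print("corrected recognition, cued (group means):")
for (emo, comp), d in scores.groupby(["emotion", "component"]):
    print(f"  {emo:8s} {comp:10s}: {d.cr_cued.mean():.3f} "
          f"(uncued {d.cr_uncued.mean():.3f})")

print("cueing benefit (cued - uncued corrected recognition):")
pvals, labels, means = [], [], []
for (emo, comp), d in scores.groupby(["emotion", "component"]):
    t, df, p = one_sample_t(d.cueing_benefit.to_numpy())
    labels.append(f"{emo} {comp}")
    means.append(d.cueing_benefit.mean())
    pvals.append(p)
for lab, m, p, padj in zip(labels, means, pvals,
                           fdr_adjust(np.array(pvals))):
    print(f"  {lab:22s}: {m:+.3f}  p={p:.4f}  p_fdr={padj:.4f}")
# With the default condition means, the expected cueing benefit is +0.08
# for neutral objects, -0.04 for neutral backgrounds (their configured hit
# rates differ in that direction), and ~+0.01 elsewhere; a 31-participant cohort
# estimates each benefit with a Monte-Carlo standard error of about 0.03,
# so single-run p-values move from seed to seed.
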