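"""Information transfer rate and accuracy statistics.

ITR uses the Wolpaw bits-per-decision formula; one decision needs n_avg
stimuli at each of the two sites, 700 ms apart.  The statistics harness
compares accuracy panels (subject x classifier x averaging) with two-way
repeated-measures ANOVA and Bonferroni-corrected Wilcoxon post-hoc tests.
"""

import numpy as np
import pandas as pd

from serpbci.evaluate import (
    ItrParams, decision_time, itr_bpm, rm_anova_2way, wilcoxon_posthoc,
)

print("ITR at perfect accuracy (2 targets):")
for n_avg in (3, 5, 10):
    t = decision_time(n_avg)
    print(f"  SEP{n_avg:<2d}: decision time {t:4.1f} s -> "
          f"{itr_bpm(ItrParams(accuracy=1.0, decision_time_s=t)):5.2f} bits/min")

# a synthetic accuracy panel: 8 subjects, accuracy rising with averaging
rng = np.random.default_rng(0)
rows = []
for s in range(8):
    offset = rng.normal(0, 4)
    for clf in ("SVM", "LDA"):
        for n_avg, base in ((3, 62), (5, 68), (10, 76)):
            bonus = 3 if clf == "SVM" else 0
            rows.append(dict(subject=s, classifier=clf, n_avg=n_avg,
                             accuracy_pct=base + bonus + offset + rng.normal(0, 3)))
panel = pd.DataFrame(rows)

print("\ntwo-way repeated-measures ANOVA (classifier x averaging):")
for eff in rm_anova_2way(panel):
    df_txt = (f"F({eff.df1_gg:.2f}, {eff.df2_gg:.1f})" if eff.p_gg is not None
              else f"F({eff.df1:.0f}, {eff.df2:.0f})")
    p = eff.p_gg if eff.p_gg is not None else eff.p
    print(f"  {eff.source:22s} {df_txt} = {eff.F:6.2f}, p = {p:.4f}")

wide = panel.pivot_table(index=["subject", "classifier"], columns="n_avg",
                         values="accuracy_pct")
pairs = [(f"SEP{a} vs SEP{b}", wide[a].to_numpy(), wide[b].to_numpy())
         for a, b in ((3, 5), (3, 10), (5, 10))]
print("\nWilcoxon post-hoc (Bonferroni, 3 comparisons -> p < 0.017):")
for v in wilcoxon_posthoc(pairs):
    print(f"  {v.name:14s} p = {v.p:.4f}  "
          f"{'significant' if v.significant else 'n.s.'}")
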