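"""Group x session inference on the metric AUCs.

Mixed-design ANOVA per metric and node (Bonferroni m=29 for nodal
metrics), post-hoc paired/two-sample t-tests where the interaction
survives, plus the ALFF-change vs degree-change correlation at the LF
target.  Writes results/anova.csv, results/posthoc.csv and
results/significant_interactions.csv, and prints what was found.
"""
from pathlib import Path

import pandas as pd

from smnet import LEFT_PCL_ROI, load_atlas, pearson_r, roi_labels
from smnet.pipeline import anova_tables

root = Path(__file__).resolve().parents[1] / "results"
mtab = pd.read_csv(root / "metrics_auc.csv")
anova, posthoc = anova_tables(mtab[mtab.metric.isin(("degree", "betweenness", "nodal_eff", "e_glob", "e_loc"))])
anova.to_csv(root / "anova.csv", index=False)
posthoc.to_csv(root / "posthoc.csv", index=False)
labels = roi_labels(load_atlas())
sig = anova[(anova.node >= 0) & (anova.p_interaction_bonf < 0.05)]
print("significant group x session interactions (Bonferroni m=29):")
for _, r in sig.iterrows():
    print(f"  {r.metric:12s} {labels[int(r.node)]:30s} F({int(r.df1)},{int(r.df2)})={r.F_interaction:.3f} p={r.p_interaction:.4f}")
sig.assign(region=[labels[int(n)] for n in sig.node]).to_csv(root / "significant_interactions.csv", index=False)

target = LEFT_PCL_ROI - 1
deg = mtab[(mtab.metric == "degree") & (mtab.node == target) & (mtab.group == "LF")]
alff = pd.read_csv(root / "alff.csv")
alff = alff[(alff.node == target) & (alff.group == "LF")]
dw = deg.pivot_table(index="subject", columns="session", values="auc")
aw = alff.pivot_table(index="subject", columns="session", values="alff")
r, p = pearson_r((dw["post"] - dw["pre"]).to_numpy(), (aw.loc[dw.index, "post"] - aw.loc[dw.index, "pre"]).to_numpy())
print(f"LF target ({labels[target]}): degree-change vs ALFF-change r={r:.3f}, p={p:.4f}")
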