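"""Graph metrics over the sparsity grid (0.04-0.40, step 0.02).

Computes global/local efficiency, degree, nodal efficiency and
betweenness per sparsity, their AUCs, and normalized efficiencies
against 20 degree-preserving null networks per threshold (scaled down
from 100 for runtime; see docs/methods.md).  Reports the small-world
fraction and writes the tidy AUC table to results/metrics_auc.csv.
"""
import numpy as np
import pandas as pd
from pathlib import Path

from smnet import ConnectivityMatrix, curves_and_auc, sparsity_grid
from smnet.metrics import classify_small_world

root = Path(__file__).resolve().parents[1] / "results"
manifest = pd.read_csv(root / "cohort" / "manifest.csv")
grid = sparsity_grid()
rows, sw = [], []
for k, row in manifest.iterrows():
    df = pd.read_csv(root / "connectivity" / row["path"].replace(".tsv", ".csv"), index_col=0)
    C = ConnectivityMatrix(df.to_numpy(float), tuple(df.columns))
    cs = curves_and_auc(C, grid, n_null=20, seed=k)
    sw.append(classify_small_world(cs))
    base = dict(subject=row["subject_id"], group=row["group"], session=row["session"])
    rows.append({**base, "metric": "e_glob", "node": -1, "auc": cs.auc["e_glob"]})
    rows.append({**base, "metric": "e_loc", "node": -1, "auc": cs.auc["e_loc"]})
    rows.append({**base, "metric": "e_glob_norm_mean", "node": -1, "auc": float(np.nanmean(cs.e_glob_norm))})
    rows.append({**base, "metric": "e_loc_norm_mean", "node": -1, "auc": float(np.nanmean(cs.e_loc_norm))})
    for m in ("degree", "betweenness", "nodal_eff"):
        for node, v in enumerate(cs.auc[m]):
            rows.append({**base, "metric": m, "node": node, "auc": float(v)})
tab = pd.DataFrame(rows)
tab.to_csv(root / "metrics_auc.csv", index=False)
frac = np.mean(sw)
eg = tab[tab.metric == "e_glob_norm_mean"].auc
el = tab[tab.metric == "e_loc_norm_mean"].auc
print(f"small-world: {frac:.0%} of {len(sw)} sessions (E~glob {eg.mean():.2f}, E~loc {el.mean():.2f})")
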