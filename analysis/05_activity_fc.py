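"""ALFF per node and seed FC from the stimulation-target analogs.

Writes results/alff.csv and results/fc_z.csv (Fisher-z connectivity
from the left-PCL and right-SMA analogs to all other nodes).
"""
from pathlib import Path

import pandas as pd

from smnet import LEFT_PCL_ROI, RIGHT_SMA_ROI, alff_all_nodes, fc_vector

root = Path(__file__).resolve().parents[1] / "results"
manifest = pd.read_csv(root / "cohort" / "manifest.csv")
alff_rows, fc_rows = [], []
for _, row in manifest.iterrows():
    data = pd.read_csv(root / "preprocessed" / row["path"], sep="\t").to_numpy(float)
    base = dict(subject=row["subject_id"], group=row["group"], session=row["session"])
    for node, v in enumerate(alff_all_nodes(data, 2.0)):
        alff_rows.append({**base, "node": node, "alff": float(v)})
    for seed in (LEFT_PCL_ROI - 1, RIGHT_SMA_ROI - 1):
        z = fc_vector(data, seed)
        for node in range(data.shape[1]):
            if node != seed:
                fc_rows.append({**base, "seed": seed, "target": node, "z": float(z[node])})
pd.DataFrame(alff_rows).to_csv(root / "alff.csv", index=False)
pd.DataFrame(fc_rows).to_csv(root / "fc_z.csv", index=False)
print(f"wrote ALFF ({len(alff_rows)} rows) and FC ({len(fc_rows)} rows)")
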