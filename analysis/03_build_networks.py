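"""Build the 29x29 Pearson connectivity matrix per session.

Writes one square CSV per subject-session under results/connectivity/.
"""
from pathlib import Path

import pandas as pd

from smnet import correlation_matrix, load_atlas, roi_labels

root = Path(__file__).resolve().parents[1] / "results"
manifest = pd.read_csv(root / "cohort" / "manifest.csv")
labels = tuple(roi_labels(load_atlas()))
out = root / "connectivity"
out.mkdir(parents=True, exist_ok=True)
for _, row in manifest.iterrows():
    data = pd.read_csv(root / "preprocessed" / row["path"], sep="\t").to_numpy(float)
    C = correlation_matrix(data, labels)
    C.to_frame().to_csv(out / row["path"].replace(".tsv", ".csv"))
print(f"wrote {len(manifest)} connectivity matrices -> {out}")
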