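"""Temporal preprocessing of every simulated session.

Discards 5 volumes, detrends, band-passes 0.01-0.08 Hz and regresses
the band-passed Friston-24 + WM + CSF nuisance set; writes cleaned TSVs
to results/preprocessed/.
"""
from pathlib import Path

import pandas as pd

from smnet import NuisanceSet, preprocess_session
from smnet.cohort import read_session

root = Path(__file__).resolve().parents[1] / "results"
manifest = pd.read_csv(root / "cohort" / "manifest.csv")
out = root / "preprocessed"
out.mkdir(parents=True, exist_ok=True)
for _, row in manifest.iterrows():
    sess = read_session(root / "cohort" / row["path"], row["subject_id"], row["group"], row["session"])
    ndf = pd.read_csv(root / "cohort" / f"{row['subject_id']}_{row['session']}_nuisance.csv")
    nuis = NuisanceSet(ndf[[f"mot{i}" for i in range(1, 7)]].to_numpy(), ndf["wm"].to_numpy(), ndf["csf"].to_numpy())
    clean = preprocess_session(sess, nuis)
    pd.DataFrame(clean.data).to_csv(out / row["path"], sep="\t", index=False, float_format="%.6f")
print(f"preprocessed {len(manifest)} sessions -> {out} (235 x 29 each)")
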