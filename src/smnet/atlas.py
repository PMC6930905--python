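"""Bundled 29-ROI sensorimotor atlas.

The atlas is a functional parcellation of the sensorimotor system into 29
non-overlapping regions with MNI peak coordinates.  Two regions carry no
anatomical label and several lack a Brodmann assignment; those fields are
kept empty rather than imputed.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: 1-based ROI indices of the designated stimulation-effect nodes.
LEFT_PCL_ROI = 5  # left paracentral lobule, target analog for 1 Hz (LF) rTMS
RIGHT_SMA_ROI = 28  # right supplementary motor area, target analog for 3 Hz (HF) rTMS


def load_atlas() -> pd.DataFrame:
    """Return the 29-ROI atlas table.

    Columns: ``roi`` (1..29), ``x``/``y``/``z`` (MNI mm), ``region``,
    ``side`` (L/R) and ``brodmann``.  Missing labels are empty strings.
    """
    ref = resources.files("smnet.data").joinpath("sensorimotor_atlas_29.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, dtype={"region": "string", "brodmann": "string"})
    df["region"] = df["region"].fillna("")
    df["brodmann"] = df["brodmann"].fillna("")
    if df["roi"].nunique() != 29 or len(df) != 29:
        raise ValueError("atlas must contain 29 unique ROIs")
    return df


def roi_labels(atlas: pd.DataFrame | None = None) -> list[str]:
    """Short unique node labels like ``ROI05_Paracentral_lobule_L``."""
    if atlas is None:
        atlas = load_atlas()
    labels = []
    for _, row in atlas.iterrows():
        name = str(row["region"]).strip().replace(" ", "_") or "unlabeled"
        labels.append(f"ROI{int(row['roi']):02d}_{name}_{row['side']}")
    return labels


def default_modules(atlas: pd.DataFrame | None = None) -> np.ndarray:
    """Three-community partition used by the synthetic ground truth.

    Nodes within 15 mm of the midline form a medial community (SMA,
    paracentral lobule, cingulate); the remainder split into left and
    right lateral sensorimotor communities by the sign of x.
    """
    if atlas is None:
        atlas = load_atlas()
    x = atlas["x"].to_numpy()
    assignment = np.where(np.abs(x) <= 15, 0, np.where(x < 0, 1, 2))
    return assignment.astype(int)
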