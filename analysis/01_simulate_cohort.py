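"""Simulate the synthetic rTMS cohort.

Generates 3 groups (HF, LF, SHAM) x 15 subjects x 2 sessions of
29-node BOLD-like time series (240 volumes, TR = 2 s) with the planted
post-stimulation effects (LF -> left paracentral lobule, HF -> right
SMA), and writes TSV series, a manifest and the ground truth under
results/cohort/.
"""
import sys
from pathlib import Path

from smnet import CohortConfig, default_effects, default_ground_truth, generate_cohort, write_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
out = Path(__file__).resolve().parents[1] / "results" / "cohort"
cohort = generate_cohort(CohortConfig(seed=seed), default_ground_truth(), default_effects())
write_cohort(cohort, out)
print(f"wrote {len(cohort.sessions)} subject-sessions to {out} (seed={seed})")
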