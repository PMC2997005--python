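"""Relative quantification of a simulated qPCR microRNA card.

Generates a synthetic 10-sample study, writes its Ct table to disk, reads it
back, normalizes to the RNU48 endogenous control (RQ = 2^-dCt) and applies
the per-period detection quorum.
"""

import tempfile
from pathlib import Path

from pancmir import (
    apply_detection_quorum,
    assign_periods,
    compute_rq,
    read_ct_table,
    simulate_study,
)

out = Path(tempfile.mkdtemp(prefix="pancmir_example_"))
study = simulate_study(seed=42, out_dir=out, dropout_rate=0.02)

ct = read_ct_table(out / "ct_table.tsv", control_id="RNU48", undetermined_threshold=35.0)
print(f"Ct table: {len(ct.mirna_ids) - 1} microRNAs x {len(ct.sample_ids)} samples")
print(f"undetermined wells: {int(ct.ct.drop(index=ct.control_id).isna().sum().sum())}")

rq = assign_periods(compute_rq(ct), study.mirna_scheme)
result = apply_detection_quorum(rq, study.mirna_scheme)
n_retained = len(result.retained.rq)
print(f"positively expressed after the 2/3, 4/5, 2/2 quorum: {n_retained}")
print(result.log[~result.log["retained"]].head(3))

# Each retained microRNA amplified (Ct < 35) in enough samples of every
# gestational period; RQ > 1 means more abundant than the RNU48 control.
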