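"""Classify uridine modifications into their subtypes.

Beyond detecting that a uridine is modified, separate models distinguish
pseudouridine (Y), dihydrouridine (D) and 5-methyl-uridine (T) from all
other uridine modifications; a fourth model flags the "other" class.
Candidates for these tasks are modified uridines only.
"""

from urimod import WindowConfig, cross_validate, default_table, windows_for_task
from urimod.synthetic import generate, strong_signal_spec

table = default_table()
corpus = generate(strong_signal_spec(seed=1, n_records=60))

for task, name in [
    ("Y", "pseudouridine"),
    ("D", "dihydrouridine"),
    ("T", "5-methyl-uridine"),
    ("OTHER_UM", "other modifications"),
]:
    windows = windows_for_task(
        corpus, table, WindowConfig(L=17, task=task, L_struct=19)
    )
    rep = cross_validate(windows, "hybrid", seed=0)
    print(
        f"{name:20s} {rep.n_pos:3d} positives vs {rep.n_neg:3d} negatives: "
        f"AUC {rep.auc:.3f}, max MCC {max(r.mcc for r in rep.rows):.2f}"
    )
# each subtype has its own planted context (D-loop adenines, the GUUC
# T-loop motif, anticodon-loop G/A flanks), so all four separate well
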