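"""Train on an annotated corpus, then score new plain sequences.

Prediction emits one row per uridine with the raw SVM decision score and
its 0–9 probability display (raw scores are clipped to ±1.5 and mapped
affinely, so 4.5 means "on the decision boundary").
"""

import numpy as np

from urimod import (
    WindowConfig,
    decision_scores,
    default_table,
    encode_windows,
    extract_windows,
    probability_score,
    train,
    windows_for_task,
)
from urimod.records import AnnotatedTRNA
from urimod.synthetic import generate, strong_signal_spec

table = default_table()
corpus = generate(strong_signal_spec(seed=1, n_records=60))
windows = windows_for_task(corpus, table, WindowConfig(L=17, task="UM"))
X = encode_windows(windows, "bpp")
y = np.array([1 if w.label == "positive" else 0 for w in windows])
model = train(X, y, scheme="bpp", window_len=17, task="UM")

# a fresh record the model has never seen (generated with another seed)
query = generate(strong_signal_spec(seed=99, n_records=1))[0]
query_plain = AnnotatedTRNA(
    id=query.id, sequence="".join(table.parent_of(c) for c in query.sequence)
)
candidates = [
    w for w in extract_windows(query_plain, table, 17) if w.seq_window[8] == "U"
]
scores = decision_scores(model, encode_windows(candidates, "bpp"))

truth = {i for i, c in enumerate(query.sequence) if table.is_modified(c)}
print("pos  base  raw     0-9  truly modified?")
for w, s in zip(candidates, scores):
    if s >= 0.0 or w.center in truth:
        p = probability_score(s)
        print(
            f"{w.center + 1:3d}   U   {s:+.3f}  {p.display:4.1f}  "
            f"{'yes' if w.center in truth else 'no'}"
        )
# high-scoring positions should coincide with the planted modifications
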