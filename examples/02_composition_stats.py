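"""Corpus composition statistics: how much of the tRNA is modified, and where.

Reports the base composition, the share of all modifications carried by
each parent base, and each base's modification rate — the quantities used
to justify focusing the classifiers on uridine.
"""

from urimod import composition_stats, default_table
from urimod.synthetic import generate, strong_signal_spec

table = default_table()
corpus = generate(strong_signal_spec(seed=1, n_records=60))
rep = composition_stats(corpus, table)

print(f"records: {rep.n_records}, bases: {rep.n_bases}, modified: {rep.n_modified}")
print(f"overall modification rate: {100 * rep.n_modified / rep.n_bases:.2f}%")
for base in ("A", "C", "G", "U"):
    print(
        f"  {base}: composition {100 * rep.per_base_composition[base]:5.2f}%  "
        f"share of modifications {100 * rep.per_parent_modified_share[base]:5.2f}%  "
        f"modified rate {100 * rep.per_parent_modified_rate[base]:5.2f}%"
    )
print("per-code counts:", rep.per_modification_counts)
# uridine carries every planted modification here, so its share is 100%;
# in real corpora uridine dominates but shares spread over all four bases
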