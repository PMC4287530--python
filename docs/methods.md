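# Methods

## Problem and model

Given a tRNA sequence in which each position is a single character — a
canonical base or a one-letter modification code resolving to a parent
base — the task is binary classification of uridine centres: is this
uridine post-transcriptionally modified (task `UM`), and if modified, is
it pseudouridine (`Y`), dihydrouridine (`D`), 5-methyl-uridine (`T`), or
something else (`OTHER_UM`)? The four subtype tasks draw their candidate
sets from modified uridines only; `UM` uses every uridine.

The classifier is deliberately local: a fixed-length window around the
centre, one-hot or composition features, and an RBF-kernel SVM. The
assumptions this encodes are (i) modification status is largely decided
by the local sequence neighbourhood (the recognition footprint of the
modifying enzyme) and (ii) secondary-structure context (loop vs stem)
carries additional, partly independent information — hence the hybrid
encoding that concatenates an 85-dim binary sequence profile (17-mer)
with a 76-dim structure one-hot (19-mer, angle-bracket dialect, 4 symbols
per position) into 161 features.

## Windows and labels

Padding appends (L−1)/2 dummy `X` per terminus so every position has a
full window; L is odd and restricted to 3–25 (tRNAs average ~77 nt, and
larger windows would span multiple arms). Window text is demodified to
the parent-base alphabet {A,C,G,U,X}: the annotation must never be
visible to the feature encoder, otherwise prediction is circular.
Positions whose code cannot be resolved by the nomenclature table render
as `X` in window context and are never candidate centres, keeping the
five-letter alphabet closed. Sequence and structure windows are padded
independently, each by its own (L−1)/2 rule, and share the centre
position.

## Nomenclature

The built-in table covers the canonical bases, `Y`/`D`/`T`, inosine and
the lowercase 2'-O-methyl codes; real corpora should load their full
code table from TSV (`load_nomenclature`), which injects canonical
self-mappings and rejects duplicate codes or parents outside {A,C,G,U}.
Codes are case-significant; no case folding anywhere.

## SVM

`SVC(kernel="rbf")` from scikit-learn with gamma = 0.05, C = 2 and
class_weight {positive: 2} — the positive-class multiplier offsets the
roughly 1:4 imbalance between modified and unmodified uridines.
Convergence tolerance is set to 1e-7 so decision scores are invariant
(to ~1e-6) under permutation of the training set. No probability
calibration: the raw decision score is the ranking statistic, and the
0–9 display score is the affine map `3·(clip(raw, −1.5, 1.5) + 1.5)` —
the unique affine bijection [−1.5, 1.5] → [0, 9]. It is monotone,
saturates exactly at ±1.5, and exists purely for display; thresholding
happens on the raw score (default 0.0).

## Evaluation

Threshold sweeps use the fixed grid −1.0 … 1.0 step 0.1 (21 rows) with
the tie rule score ≥ t → positive. Sn, Sp and Acc are percentages; MCC
uses the standard four-marginal formula with the 0/0 → 0 convention. Two
rows are flagged: maximum MCC (ties resolved toward the threshold
nearest 0) and minimum |Sn − Sp|. AUC is computed from the continuous
scores (equivalently the Mann–Whitney pairwise statistic, ties counted
half), never from the 21-point grid.

Cross-validation deals items round-robin after a seeded shuffle: in
window mode positives and negatives are dealt separately (exact
stratification); in sequence mode whole records are dealt, so no tRNA's
windows ever straddle a fold — the stricter protocol when near-identical
windows from one molecule could otherwise inflate performance.
Out-of-fold scores are pooled into a single report (per-fold AUCs kept
alongside); every window is scored exactly once.

## Dataset construction

Taxon splits produce the eight standard groups (all, archaea, bacteria,
eukaryote-all/-cyto/-mito/-plastid, virus) plus `unassigned`.
Organism-name comparison trims, collapses whitespace and lowercases, and
applies the built-in synonym *Halobacterium volcanii* → *Haloferax
volcanii* (the organism was renamed). Redundancy reduction is greedy
clustering on global-alignment identity (match 1, mismatch 0, linear gap
−1 shape the alignment; identity = matches / alignment length) over
demodified sequences, visiting records sorted by (length desc, id asc)
and keeping the longest member per cluster; it approximates, not
replicates, BLASTCLUST, and a two-column cluster file can be imported to
reproduce an external clustering exactly. Balanced subsampling draws a
fixed count per modification class without replacement from a seeded
generator.

## Synthetic corpora

The generator emulates the *shape* of real modification signal, not
MODOMICS content. Each record is a cloverleaf: 7-bp acceptor stem, 4-bp
D-stem with 8-nt loop, 5-bp anticodon stem with 7-nt loop, 6–9-nt
variable loop, 5-bp T-stem with 7-nt loop, NCCA tail — 77–80 nt overall,
with a consistent angle-bracket structure string. Default planting rules
(probability 0.9 per site unless noted): `D` at a D-loop site flanked by
`AA`/`AA`; `Y` at an anticodon-loop site flanked by `GU`/`AA`; `T`
inside a `GUUCA` motif at the T-loop start (followed by a planted `Y`,
echoing the GTΨC site); `u` (2'-O-methyluridine, the "other" class) at a
variable-loop site flanked by `CC`/`CC` (probability 0.85). Unplanted
rule sites are rewritten as ordinary decoys, and decoy unmodified loop
uridines carry a `C`/`G` neighbourhood, so positives and negatives are
separable by construction; two-base contexts keep chance collisions with
random stem uridines negligible. The default corpus is 60 records
(~1 200 uridine windows, ~18 % positive — a class balance and problem
size at which five-fold CV is stable and runs in seconds).

The null variant modifies uridines with probability 0.3 uniformly at
random, independent of context: any classifier's cross-validated AUC on
it should sit near 0.5 (with 200 windows the sampling standard deviation
of AUC is ≈ 0.04, so values in roughly 0.4–0.6 are expected).

What passing on these corpora shows: the pipeline is leak-free, the
encodings expose planted context, structure features add the loop/stem
signal, and the evaluation machinery is calibrated. What it does not
show: performance on real tRNAs, whose signal is weaker, kingdom-specific
and entangled with sequence phylogeny — real-corpus numbers must be
produced by running the same pipeline on an annotated MODOMICS-style
export.

## Numerical and degenerate-input choices

- Tie at threshold: score ≥ t → positive, fixed everywhere.
- MCC, Sn, Sp: 0/0 → 0.
- Unknown sequence codes: flagged, rendered `X`, never fatal.
- Deeper pseudoknot brackets than `[ ]`: folded to `.` with a warning
  (ipknot dialect only); the ipknot one-hot is 6-dim per position (five
  structure symbols + `X`).
- Records lacking structures are partitioned out before hybrid pipelines
  and the drop count logged; prediction can fall back to a sequence-only
  model per record.
- Model files are versioned joblib archives storing the encoding recipe;
  loads refuse unknown versions and scoring refuses mismatched feature
  dimensions.

## Known limitations

- Local windows cannot represent long-range determinants (e.g. identity
  elements elsewhere in the molecule) beyond what the structure string
  encodes.
- Greedy identity clustering is order-dependent by design (deterministic,
  but not globally optimal) and is not a BLASTCLUST replica.
- The generator plants at most one site per rule region per record and
  models no phylogenetic correlation between records; kingdom labels on
  synthetic records are uniform decoration, so kingdom-wise evaluation on
  synthetic data exercises the bookkeeping, not biology.
- No probability calibration of SVM scores; the 0–9 scale is a display
  convention, not a posterior.
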