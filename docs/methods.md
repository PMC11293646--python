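# Methods

This note documents the models, parameters and design choices behind
`premir`, and what the synthetic test data do and do not demonstrate.

## Pipeline model

A candidate pre-miRNA locus is any region of the input resembling a
known mature miRNA.  Reference matures are locally aligned against both
strands of every input sequence; each alignment carries the query length
Q, the alignment length Qa (columns, gaps included), the gap positions G
and mismatches M, and the dissimilarity `LD = Q − Qa + G + M` (unaligned
query nucleotides + gaps + mismatches).  Selection modes:

| mode       | keeps                                   | used for              |
|------------|------------------------------------------|----------------------|
| prediction | E ≤ 0.001 and LD ≤ 3 (both configurable) | genome-wide prediction |
| positive   | perfect full-length matches (LD = 0)     | positive dataset      |
| decoy      | E ≤ 0.001 and 5 ≤ LD ≤ 6                 | negative dataset      |

The decoy band rests on two observations: closer copies (LD < 5) may be
functional miRNAs, and more distant ones (LD > 6) rarely reach E ≤ 0.001.

Hits are extended by a flank on each side — 200 nt for prediction (a
`n+400` window covers the large majority of known plant precursor
lengths), 20 nt for dataset compilation (the loop-distal ~15 bp adjacent
to the duplex carry the informative structure).  Minus-strand windows
are reverse-complemented so the hit always reads 5'→3'.  Redundant
windows are collapsed by greedy longest-first clustering (glocal
identity of the shorter onto the longer, both strands, default
threshold 0.9; ties broken lexicographically on the id).

Windows are then screened: a window is *coding* when any stop-free
six-frame translation segment of ≥ 20 aa aligns to the protein set with
E ≤ 0.001 (BLOSUM62 local alignment; Karlin–Altschul λ = 0.267,
K = 0.041).  Prediction and positive compilation drop coding windows;
decoy compilation keeps only them.  A second filter removes windows
matching an rRNA/tRNA family sequence at ≥ 0.85 identity over ≥ 0.8 of
the family record (the source data state no thresholds for either
filter; both are exposed in the configuration).

## Alignment backends

The built-in aligner is an exhaustive Gotoh local alignment (Biopython's
C implementation) with BLASTn-like scoring: match +1, mismatch −2, a gap
of length k costs 5 + 2k.  Expectation values use
`E = K·m·n·e^(−λS)` with the ungapped +1/−2 parameters λ = 1.28,
K = 0.46, where n is the total searched length (both strands).  Multiple
hits per query/strand are found by iterated best-alignment with
N-masking of found loci.  An `NCBI blastn` adapter (task `blastn-short`,
tabular output) is available as an external backend and is used as an
independent cross-check in the tests.

A consequence of this parameterization worth knowing: a ~21-nt query
can only reach E ≤ 0.001 in the 5–6 dissimilarity band when the
dissimilarity is concentrated as an end-truncation (an exact core of
≥ 15–16 nt) and the searched subject is modest (≈ 40 kb or less);
scattered-mismatch copies score too low.  The synthetic decoys are
planted accordingly (below).

## Folding engines

`fold_all` returns one or more valid structures sorted by energy:

* `rnafold` — ViennaRNA adapter (MFE structure with its energy).
  Adapter slots for Mfold, CONTRAfold and MXFold2 exist and fall back to
  the built-in folder with a logged notice when no binary is found.
* `builtin` — the reference folder: dynamic-programming maximum-weight
  nested pairing (GC = 3, AU = 2, GU = 1, minimum hairpin loop 3 nt) with
  a co-optimal traceback capped at 20 structures.  The traceback prefers
  the pairing branch on ties, so contiguous helices are reconstructed
  first; energies are then assigned by the built-in energy model and the
  list is sorted.
* `auto` (default) — the RNAfold MFE plus built-in co-optimals, merged
  and deduplicated.  Analyzing several optimal structures per window
  matters: a thermodynamic MFE can leave a duplex-terminal pair open
  ("breathing") when a mismatch sits near the duplex end, which inflates
  the measured 3' overhang; a co-optimal structure that forms the pair
  restores the candidate.  Downstream stages evaluate *every* returned
  structure and a window is accepted if any structure qualifies.

The built-in energy model (`eval_energy`, `param_set="builtin"`) is a
simplified additive nearest-neighbor set: a stack of two pairs
contributes −(w(p1) + w(p2)) kcal/mol with pair strengths w(GC) = 1.6,
w(AU) = 0.9, w(GU) = 0.45; hairpin loops pay 4.5 + 1.75·ln(n/3), bulges
3.3 + 1.75·ln(n), internal loops 1.8 + 1.3·ln(l+r) + 0.5·|l−r|, and
multibranch loops 3.4 + 0.4·branches + 0.1·unpaired.  An unpaired chain
has energy 0.  `param_set="rnaeval"` delegates to ViennaRNA's RNAeval.
The model is for ranking and for the energy features; it is not a
thermodynamic parameter fit.

## Hairpin qualification

Positions on a folded window are 1-based.  Disqualification evaluates
six structural rules on the hit context — not in a stem (< 20 % of hit
positions paired); too few residues in complementarity (< 60 % paired);
no continuous complementary region (an unpaired run > 5 nt); inner
branches (a complete pair inside the hit); a branched complementary
region; and a hit straddling the terminal loop — followed by the primary
filter: at most 3 terminal structures (hairpin loops distal to the hit
on its branch) and no internal loop with > 5 nt on either side within
the duplex.  All violations are accumulated for diagnostics, never
short-circuited.  The 60 % / 5-nt / 3-structure thresholds interpret
qualitative wording ("near-perfect complementarity", "a few residues",
"simple terminal loop") and are configurable.

The passenger (miRNA\*) span is inferred from the 2-nt 3'-overhang
geometry: star 3' end = partner(mature 5' end) + 2, star 5' end =
partner(mature 3' end − 2); unpaired mature end positions are resolved
by scanning inward to the nearest paired position and re-applying the
offset, and the result is clipped to the structure.  Duplex statistics
walk the gaps between consecutive duplex pairs: a gap with l unpaired
guide and r passenger nucleotides contributes min(l, r) symmetric
mismatches and |l − r| asymmetric nucleotides, giving
`n_mismatch = Σl + Σmax(0, r−l)` and `n_asym = Σ|l−r|`.  G:U wobbles
count as paired by default (folding engines pair them; configurable).
A duplex-region position paired outside the opposite strand span marks a
secondary stem.  Overhangs are measured from each strand's 3' end to its
last duplex pair.

The final rule engine checks, with configurable thresholds: both 3'
overhangs exactly 2 nt; no secondary stems; n_mismatch ≤ 6 with
n_asym ≤ 3; precursor ≤ 300 nt; mature 20–24 nt; and optional banned
mismatch positions on the mature (e.g. 9–11, off by default).

## Feature schema

Each qualified structure yields 170 features in 8 families sized
7 / 4 / 5 / 4 / 8 / 23 / 36 / 83 (primary, reference query, genomic
positions, nucleotide composition, energy, linear sequence, pair
composition, major structural).  The family sizes and the row
descriptions are the binding contract; the exact member list is fixed by
this package and shipped as `src/premir/data/feature_schema.tsv`.
Interpretation choices worth stating:

* the 4-feature composition family holds GC contents (window, main
  branch, precursor, mature); full tetranucleotide frequencies cannot
  fit in 4 features and are emitted to an optional side table;
* the reference-query family describes the *mature* reference (length,
  GC, LD, −log10 E) in every compilation mode — in positive compilation
  the homology hit is the stem-loop, but carrying stem-loop query
  statistics there would give training and prediction rows different
  feature semantics;
* linear positions are anchored on the precursor start rather than the
  raw window, so they do not scale with the configurable flank (training
  uses 20-nt flanks, prediction 200-nt); the hit start is expressed as a
  percentage of the window;
* "crucial positions" of the pair-composition family are mature
  positions 1–11 (5' end, seed 2–8, central 9–11), the mature 3'-end
  triplet and the first/last two star positions — 18 positions × (pair
  state, partner base);
* undefined numeric values carry the sentinel −1, documented per
  feature.

## Classifier

`DenseHairpinClassifier` is a scikit-learn estimator: seven SELU dense
layers (widths geometric from 256 down to 8), alpha dropout 0.1, batch
normalization, 2-way softmax, cross-entropy loss, adaptive-moment
updates (batch 128, learning rate 1e-3, decoupled weight decay 1e-3),
early stopping on an internal 10 % validation split (patience 12, at
most 100 epochs by default).  Features are z-scored with statistics of
the training data only; zero-variance training features are zeroed at
train and predict time and standardized values are clipped to ±6 — both
guard against out-of-distribution saturation when prediction windows
differ in scale from compilation windows.  Training is deterministic
given the seed.

Evaluation: k-fold cross-validation partitions positives and negatives
into k folds separately (paired folds), reports the seven metrics
(accuracy, sensitivity, specificity, precision, F1, MCC, AUC — the AUC
by the rank statistic with tie correction) per fold and as mean ± sd;
the versatility harness trains on all groups but one and tests on the
held-out group.  The decision threshold is 0.5, configurable.

## Dataset compilation

Positive: perfect stem-loop hits → 20-nt-flank windows → redundancy
removal → coding drop-filter → rRNA/tRNA filter → folding → the six
disqualification rules and primary filter → features, label 1.  A
precursor may contribute several rows (one per distinct qualified
structure).  Negative: decoy-band mature hits → windows with lengths
drawn (seeded, with replacement) from the positive window-length list →
coding keep-filter → the same structural qualification → features → a
seeded uniform subsample without replacement down to the positive count,
label 0.

## Synthetic fixtures

`make_hairpin` emits a precursor sequence *and its intended structure*
directly from parameters (mature sequence, loop size, optional perfectly
paired lower stem, symmetric mismatch positions, one-sided bulges with
sizes and sides, 3'-overhang lengths, arm), plus a truth record of every
planted quantity.  Mismatch star bases reuse the mature base (a base
never pairs or wobbles with itself), so planted mismatches are
unambiguous.

`make_genome` plants into random background sequence: clean pre-miRNA
loci (per-locus variation: loop 5–8 nt, lower stem 12–16 bp, 0–2
mismatches, flanks 10–14 nt — all well inside the duplex rule bounds);
CDS-embedded hairpins spliced between the two halves of an ORF whose
half-translations (60 aa each) populate the protein set; decoys — copies
of reference matures with the first 5 (or 6) bases replaced
position-wise, paired with their reverse complement around a short loop
and substituted into a 150-codon ORF, so the locus folds like a
pre-miRNA, carries an exact 16-nt core (LD exactly 5) and overlaps
coding sequence; and optional tRNA-like segments mirrored into the
rRNA/tRNA set.  In-frame stop codons are mutated away outside the
protected decoy core.  Default problem sizes: 30-kb genomes with 12
loci + 12 decoys for training fixtures (three pooled genomes ≈ 160
rows/class), a 100-kb genome with 5 clean + 5 CDS-embedded + 5 decoy
loci for end-to-end evaluation.

What the fixtures do **not** emulate: genome-scale repeat content,
biased base composition, miRNA gene families and clusters, introns,
untranslated regions, or decoys that resemble miRNAs by chance rather
than by construction.  Passing tests therefore demonstrate that the
machinery is correct and internally consistent — planted truth is
recovered exactly, boundaries sit where the rules place them, the
learner separates what is separable — not that real-genome precision
matches these numbers.

`make_feature_table` draws two 170-dimensional unit-variance Gaussian
clusters whose means differ by `class_sep` along a random unit direction
(optionally shared across tables via `direction_seed` to emulate
species-like groups), with an optional label-noise rate.

## Numerical and degenerate-input choices

* Coordinates: BED-style 0-based half-open for genomic intervals,
  1-based inclusive on folded sequences (CT convention); the conversions
  are inverses.  T and U compare equal; structures always store U; N is
  the only accepted ambiguity code.
* CT reader accepts `dG = x` and `ENERGY = x` headers and emits `dG`.
* MFEI is defined as 0 when GC = 0; empty sequence segments yield the
  −1 sentinel.
* Co-optimal enumeration deduplicates pair tables; ties in the energy
  sort break on the dot-bracket string (deterministic output order).
* An empty candidate set at any stage produces a report with the
  attrition table, never an error; seeded runs are byte-reproducible.

## Known limitations

* The built-in energy model is a caricature of a nearest-neighbor
  parameter set; absolute energies are not comparable to ViennaRNA's.
* The expectation-value parameterization is the ungapped +1/−2 set
  applied to gapped alignments; E-values are indicative, not calibrated.
* The star-inference offset extrapolates across unpaired mature end
  positions; on structures with frayed duplex ends the measured overhang
  reflects the fold, not the annotation.
* Training sets compiled from desk-scale fixtures are small (hundreds of
  rows); the classifier's real-data behaviour depends on compiling
  datasets from real genomes and reference sets.
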