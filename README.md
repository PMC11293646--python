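# premir

Ab initio prediction of plant pre-miRNAs from raw genomic or
transcriptomic sequence.

Plant microRNA discovery from sequence alone is hard because plant
precursors are heterogeneous in length and structure, and because many
hairpin-shaped loci are not miRNAs at all.  `premir` implements a
homology-guided pipeline: known mature miRNAs are aligned against the
input, candidate windows are extended around acceptable hits, windows
overlapping protein-coding sequence or rRNA/tRNA are removed, secondary
structures are predicted, each structure is qualified against structural
rules, a 170-feature record is extracted per candidate, a dense neural
network separates genuine pre-miRNA structures from decoys, and a final
rule engine verifies the predicted miRNA/miRNA\* duplex.

It is written for computational biologists who have a genome (or
transcriptome) FASTA and a reference set of mature miRNAs, and want
candidate pre-miRNA loci with their mature sequences, structures,
features and probabilities — no sequencing reads required.

## The quantities at the core

* **Level of dissimilarity** of a homology hit:
  `LD = Q − Qa + G + M`, where `Q` is the query length, `Qa` the
  alignment length, `G` the gap count and `M` the mismatch count.
  Prediction keeps hits with `E ≤ 0.001` and `LD ≤ 3`; decoy compilation
  keeps the band `5 ≤ LD ≤ 6`; positive compilation keeps perfect
  full-length matches only.
* **Duplex rules** (defaults of the rule engine): two-nucleotide 3'
  overhangs on both duplex ends; no secondary stems; at most 6
  mismatched positions with at most 3 of them in asymmetric bulges;
  precursor ≤ 300 nt; mature length 20–24 nt; optionally banned mismatch
  positions (e.g. 9–11).
* **Energy indices** per structure: `AMFE = (MFE / L) · 100` and
  `MFEI = AMFE / GC%`.
* **Classifier**: seven SELU dense layers with alpha dropout and batch
  normalization, softmax output, trained on paired positive/decoy
  feature datasets; evaluated by paired 10-fold cross-validation and
  leave-one-group-out (versatility) analysis with accuracy, sensitivity,
  specificity, precision, F1, MCC and AUC.

## Worked example

Everything below runs from scratch with no downloads — the fixture
generator plants hairpin loci, coding regions and decoys with known
coordinates:

```sh
premir simulate --outdir fixture --n-loci 3 --n-cds 1 --n-decoys 1 \
    --genome-len 20000 --seed 5
premir predict --input fixture/genome.fasta --mirna fixture/matures.fasta \
    --proteins fixture/proteins.fasta --outdir out --seed 5
```

which prints

```
10 candidate(s); report written to out
  hits: 20
  selected_hits: 5
  windows: 5
  representative_windows: 4
  after_coding_filter: 3
  after_rna_family_filter: 3
  folded_structures: 15
  qualified_structures: 15
  classified: 15
  rule_passed: 10
```

Reading the attrition table: 20 raw alignments shrink to 5 acceptable
hits (`E ≤ 0.001`, `LD ≤ 3`) and 4 non-redundant windows, of which 1 is
removed for overlapping the planted coding region; the 3 surviving
windows yield 15 optimal structures, and 10 candidate structures
(grouped by window — a window reports every qualifying structure)
satisfy all duplex rules.  `out/predictions.bed` locates each candidate on the input,
`out/matures.fasta` / `out/precursors.fasta` carry the sequences,
`out/structures.ct` and `out/structures.dbn` the structures, and
`out/features.tsv` the 170-feature records.  Here all three planted
clean loci are recovered and the CDS-embedded locus is (correctly)
absent.

The library surface mirrors the pipeline: `find_hits` / `select_hits` /
`extract_window` (homology), `coding_overlap_filter` /
`rna_family_filter` (annotation), `fold_all` / `eval_energy` (folding),
`decompose` / `disqualify` / `infer_star` / `duplex_stats` /
`apply_rules` (hairpin analysis), `extract_features` (feature records),
`DenseHairpinClassifier` — a scikit-learn estimator — with `kfold_cv`
and `leave_one_group_out` (classification), and `build_positive` /
`build_negative` (dataset compilation).

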