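# Methods

This note documents the models, conventions and numerical choices
behind `tapredict`, what the synthetic generators do and do not
emulate, and the known limitations.

## The problem and the model

Tail-anchored (TA) proteins expose two physicochemical signals that
together determine organelle selection: the hydrophobicity of the
C-terminal transmembrane domain (TMD) and the net charge of the tail
downstream of it. The package treats targeting prediction as a
three-class classification problem over the feature pair
`(tail_charge, tmd_gravy)` with classes PO (peroxisome), MITO
(mitochondrion) and ER. Proteins with shared localization (PO_MITO,
PO_MITO_ER, MITO_ER) are real and informative — they occupy the
overlap between the PO and MITO feature clouds — but the classifier is
defined over the three unique classes, so shared entries are excluded
from training by default (a flag duplicates them into their component
classes instead). They can still be scored at prediction time.

## TMD detection

External TM-helix servers (HMM- or profile-based) cannot be rebuilt
from their published descriptions, and their exact output is not what
matters downstream — only the TMD window over which GRAVY is averaged
and the boundary that defines the tail. The package therefore uses a
deterministic surrogate:

* among all windows of length 17–25 whose last residue lies within 30
  residues of the C-terminus, take the one maximizing mean
  Kyte–Doolittle hydropathy;
* require that maximum to reach `min_score = 1.6`, else report no TMD;
* break score ties (within 1e−9) toward the longer window, then the
  more C-terminal start, so results are identical across platforms.

Window bounds 17–25 and the 30-residue tail allowance encode the
canonical TA-protein geometry (a single helix close to the
C-terminus); 1.6 separates credible membrane-spanning stretches from
polar sequence while still detecting moderately hydrophobic organellar
TMDs (the bundled ACBD5 TMD scores 1.87). All four are configurable.
The detector is property-tested against an exhaustive brute-force
search over all admissible windows.

Dataset- or user-supplied coordinates (1-based inclusive, within the
stored C-terminal fragment) always take precedence over detection.
One consequence worth knowing: on the ACBD5 TMD-tail peptide the
maximal-mean window ends at residue 21, two residues short of the
annotated 23-residue helix, so the detected tail gains two tyrosines.
Tyrosine is effectively non-ionized at pH 7 (pKa 10), so the tail
charge is unchanged at one decimal — the feature the classifier
consumes is robust to this boundary fuzz, which is exactly why the
surrogate is acceptable.

## GRAVY

Mean Kyte–Doolittle hydropathy over the sequence; the scale is fixed
(A 1.8 … V 4.2). Defined only over the 20 standard residues;
ambiguity codes (B, Z, X, U) are rejected rather than guessed, because
both hydropathy and charge are undefined for them.

## Net charge

Henderson–Hasselbalch summation at the analysis pH (default 7.0).
The pKa set is a Sillero-type table: N-terminus 8.0, C-terminus 3.1,
side chains H 6.5, K 10.0, R 12.0 (basic) and D 4.4, E 4.4, C 8.5,
Y 10.0 (acidic). Calculators differ in their pKa sets; this one is
validated by reproducing the known one-decimal tail charges of the
ACBD5 tail-variant series (+4.9 / +2.9 / +0.9), which is also the
calibration check in the test suite. Tail fragments are treated as
free peptides with both termini ionizable — this is required to obtain
+4.9 rather than +4.0 for the wild-type tail — and both termini can be
switched off per call. The table is a config object and can be loaded
from a `key=value` file.

Reported charges are rounded half-away-from-zero to one decimal;
full precision is kept internally. Upstream-region features use the
10 residues immediately N-terminal of the TMD (length is a flag; no
published convention exists for it).

## Group statistics

Per-group mean ± s.e.m. (`sd/√n`, undefined at n = 1) and a
five-number summary with linear-interpolation quantiles (box =
25th–75th percentile, whiskers = sample range). Pairwise comparisons
use the two-tailed unpaired Student t-test with pooled variance and
`df = na + nb − 2` (the Prism-style default; Welch is a flag), with
stars at p < 0.05 / 0.01 / 0.001. Zero pooled variance with equal
means yields t = 0, p = 1; with unequal means the statistic is
undefined and raises. No multiple-testing correction is applied —
pairs are reported individually, matching the reporting convention of
the group analyses this mirrors; users comparing many features should
correct externally.

## Classifier

One-vs-one RBF SVMs with Platt sigmoid calibration per class pair and
pairwise coupling into three probabilities (libsvm via scikit-learn's
`SVC(probability=True)`, the same lineage as R's e1071). Features are
standardized on the training set (mean/sd stored in the model).
Defaults are the libsvm defaults for two features: `C = 1`,
`gamma = 1/n_features = 0.5`. Platt calibration uses internal
cross-validation; its seed is a fixed, exposed parameter so that
refits are byte-identical. Argmax ties break by the fixed order
PO > MITO > ER; predictions whose top-two probabilities differ by
less than 0.1 carry an ambiguity note.

Leave-one-out cross-validation refits standardization and the SVM on
every fold. A fold that leaves a class with fewer than two points
drops that class from the fold (logged) and counts the held-out point
as misclassified when its own label was dropped; a fold with fewer
than two trainable classes is an error.

Models persist as versioned JSON (standardization, support vectors,
dual coefficients, intercepts, Platt A/B constants, class order,
training-set fingerprint, seed); loading restores the estimator
exactly (round-trip asserted at 1e−12). Evaluating a loaded model on
data whose fingerprint differs from the training set produces a
warning, not an error.

Misclassified points are reported, never patched: a mitochondrial
protein whose features sit in the ER cloud (high-GRAVY, uncharged
tail — the TOMM22 situation) is simply counted wrong.

## Synthetic data

Two generators, used at different test levels:

* **Feature-level** (`synth_feature_dataset`): Gaussian draws per
  class. The default layout centres the classes at published
  tail-charge group means (PO 6.03, shared 2.5, MITO 1.12, ER 0.21)
  with spreads equal to the published s.e.m. values scaled to the
  realized group sizes (9 / 8 / 13 / 21); GRAVY centres (1.9 / 1.9 /
  1.85 / 2.2, sd 0.35–0.4) encode the moderately hydrophobic PO/MITO
  versus more hydrophobic ER TMDs. Fast and exact; used for
  classifier tests.
* **Sequence-level** (`synth_tmd`, `synth_tail`, `synth_record`):
  plants a TMD of target GRAVY between a polar Ser/Gly context and a
  tail of target integer charge. The TMD is a two-letter mix from
  {I, L, V, A, G, S} bracketing the target (achievable range 1.0–4.5,
  tolerance 0.1), with the hydrophobic letters alternated onto the two
  span ends; since a 17–25 window can drop at most four edge residues
  of the 21-mer, this balanced end-placement guarantees no subwindow
  out-scores the planted span. Tails use Arg as the only charged
  residue (mirroring the Arg/Ala mutant-design logic), start with Gln
  and fill with {Q, A, N} (Leu avoided so the tail never resembles a
  hydrophobic window); the realized free-peptide charge is sharp:
  `target − 0.09`. Planted TMDs are recovered exactly by the detector
  for targets ≥ 2.0 with tails ≤ 30 residues; the end-to-end test
  corpus is drawn inside that regime.

What the generators do **not** emulate: real amino-acid composition
(no W/F/M in TMDs, no Lys/His/acidic residues in tails), helicity,
length variation of real TMDs, or any sequence context beyond a polar
spacer. Passing tests therefore demonstrate correctness of the
computational pipeline under controlled truth, not biological accuracy
on real proteomes.

## The fixture dataset

`load_fixture_dataset()` returns a deterministic, versioned table of
51 entries (43 single-location: 9 PO, 13 MITO, 21 ER; 6 PO_MITO,
2 PO_MITO_ER) regenerable by `scripts/build_fixture.py` from a fixed
master seed. Provenance, recorded per entry in the `source` column:

* **ACBD5** — the experimentally characterized TMD-tail peptide
  (terminal Asn restored), annotated TMD 1–23; the only entry with a
  verbatim real sequence.
* **FALDH-PO / FALDH-ER** — synthetic TMD at the reported GRAVY
  neighbourhood with hand-built tails reproducing the reported
  charges (+9.1 via nine Arg plus His; −1.1 via a single Glu).
* Other named proteins (FIS1, GDAP1, BAK, SEC61B, TOMM22, …) —
  synthetic sequences emulating each protein's reported feature
  neighbourhood; membership and sequences are **not** verified against
  any database and are flagged accordingly.
* `synth_*` entries — fillers matching the group feature
  distributions.

The fixture exists so every pipeline stage is testable offline; it is
not a substitute for the real curated table. Analyses of the real
table run by supplying it in the same TSV schema (the test suite
additionally looks for it at `tests/data/dataset_s1.tsv` and skips
its published-value checks when absent).

## Problem sizes and tolerances

Detector/oracle equivalence is checked on 1,000 random sequences of
length 17–100 plus property tests up to length 200; planted-TMD
recovery on 100 records; t-test type-I calibration on 10,000 null
replicates at n = 10 per group (acceptance band 3–7% at α = 0.05);
classifier probability normalization at 1e−9, persistence round-trip
at 1e−12. These sizes keep the full suite in the low seconds while
estimating each property well.

## Known limitations

* The TMD surrogate is not an HMM; on real multi-pass or
  signal-anchored proteins it can report a spurious C-terminal window.
  It is intended for sequences already believed to be tail-anchored.
* Tail charge ignores structural context, phosphorylation and any
  pKa shifts from the membrane surface.
* The classifier uses two features only; tail-residue positioning and
  helical propensity are known to carry additional signal and are
  deliberately out of scope.
* Group sizes within the fixture are a design choice, not measured
  class frequencies; statistics computed on the fixture characterize
  the fixture.
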