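# Methods

## Problem and model

The package addresses binary activity classification of small molecules
against five nuclear receptors (AR, ER, AhR, ARO, PPAR) and, more
importantly, the extraction of *structural alerts*: substructures that
repeatedly receive high positive explanation weight among confidently
predicted actives. The classifier is a random forest over 1024-bit
extended-connectivity fingerprints; the explanation layer is a locally
fitted linear surrogate over fingerprint bits; the mining layer filters
and aggregates per-fragment attributions into a ranked alert table.

## Curation

Per task, records are removed in a fixed order: missing label →
unparseable SMILES → multi-component (salt/complex) → structural
duplicates. Duplicate grouping treats Tanimoto = 1.0 between Morgan
fingerprints (radius 2, 2048 bits — wider than the model fingerprint to
reduce false identity collisions) as structural identity; the default
implementation groups by canonical SMILES, which is equivalent for
identity purposes and O(n), with a full O(n²) pairwise-Tanimoto mode
retained behind `pairwise_identity=True` for fidelity audits. Groups with
disagreeing labels are dropped whole; otherwise the first occurrence in
input order survives. Multi-component records are dropped, not
salt-stripped, so they appear as removed compounds in the audit. The
removal order makes the audit columns independent, and
`initial − Σremoved = final` is asserted on every call. Removed duplicate
records are split into two columns by group size — groups of exactly two
("duplicates") versus larger groups ("multiple occurrences") — a package
convention for the two-number accounting style common in curation tables.

## Fingerprints and fragments

ECFP radius 2 (ECFP4-equivalent, the community default) folded to 1024
bits, with the generator's bit-info map retained: each active bit carries
its list of (center atom, radius) environments. A bit's fragment is the
subgraph of bonds within the stated radius of the center (radius 0 is the
single atom), exported as canonical fragment SMILES with the parent's
aromaticity flags; dangling bonds are not capped with dummy atoms, so the
displayed fragments read as plain substructures. Fragment SMILES are
re-parsed without sanitisation for substructure matching (a bare aromatic
path such as `ccc` is not a valid standalone molecule). All environments
of a colliding bit are retained and attributed.

## Modelling protocol

Class imbalance is treated by upsampling the minority class with
replacement to parity. The default protocol upsamples *before* the 80/20
stratified split — the classical but leaky order, under which duplicated
minority rows can appear on both sides of the split and inflate internal
validation scores; the leakage-safe after-split order is available
(`resampling_order="after"`), and `resampling_protocol_auc` measures the
optimism of the default directly (it is asserted non-negative in the
acceptance suite, mean over ten seeds). Hyperparameters are drawn
uniformly from trees ∈ [50, 500] and depth ∈ [1, 20] (20 draws by
default; the orchestrated pipeline uses fewer, see problem sizes below)
and scored by mean stratified k-fold ROC-AUC with k = 5; k ∈ {3, 5, 10}
stability (range < 0.05 on clean data) is exercised in the tests.
Cross-validation runs inside the 80% training portion.

Exact ties in mean CV ROC-AUC — routine on well-separated synthetic data,
where even a depth-2 forest ranks perfectly — are broken by the lower
mean cross-validated Brier score. This matters because the alert-mining
stage consumes the forest's vote-fraction probabilities through a fixed
0.8 confidence filter: a well-ranked but poorly calibrated shallow forest
caps its probabilities near 0.75 and would silently starve the miner.
Probability for all downstream thresholds is the raw forest vote fraction
(no recalibration); the prediction threshold is 0.5.

## Local surrogate explainer

For an instance x ∈ {0,1}^1024 and training bit frequencies p_j:

- `num_samples` rows are drawn with z_ij ~ Bernoulli(p_j) independently;
  row 0 is x itself.
- The interpretable representation is z′_ij = 1[z_ij = x_j]; proximity is
  exp(−D²/σ²) with D the Euclidean distance of z′ from the all-ones row
  (D² = the mismatch count) and σ = 0.75·√d by default (d = 1024 → σ = 24),
  the conventional width for this kernel.
- A ridge regression (α = 1) on z′ against the model's class-1
  probability, weighted by proximity, pre-selects the `num_features`
  (default 100) largest-magnitude coefficients; the surrogate is refit on
  the selected bits and its coefficients, clipped to [−1, 1], are the
  reported weights. The proximity-weighted R² of the refit is the local
  fit quality.
- A constant model output in the neighbourhood yields an explicitly
  flagged all-zero explanation rather than an error.

A positive weight on bit j means "the observed state of bit j pushes the
prediction toward disruption". One explanation is produced per molecule —
the predicted class's — which is how the "number of explanations = 1"
setting is interpreted here. Defaults: `num_samples` = 5000 (neighbourhood
bit-frequency moments are stable at that size; the tests verify 3-SE
agreement), `num_features` = 100.

## Alert mining

Molecules explained from the validation set pass to mining if their true
label is 1, the model predicts 1, and the vote-fraction probability is
≥ 0.8. Each weighted bit active in the molecule is attributed to every
environment fragment behind it (collisions share the bit's weight). The
verdict rule classifies a molecule as a disruptor iff Σ positive weights
> Σ negative weights; an empty attribution list is a non-disruptor.
Attributions with weight ≤ 0.1 are discarded *per attribution* before
aggregation (the alternative — flooring aggregated totals — is available
via `floor_on_totals=True`). Occurrences count distinct (molecule,
fragment) pairs so that bit collisions cannot double-count one motif in
one molecule (`count_rows=True` restores raw-row counting). Entries are
ranked by total weight, ties by occurrences then fragment SMILES. An
empty table is a valid outcome, not an error.

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes:
binary labels *caused* by substructures. Carriers are ~30 simple
carbon/oxygen scaffolds (shipped in `data/scaffolds.smi`); actives attach
exactly one alert fragment (default set: thiophosphate, sulfamate ester,
anilide, carbamate, sulfamide, thiocyanate) by a single bond at a ring or
terminal carbon; benign C/O/halogen decorations add diversity. Because no
carrier or decoration contains N, S or P, alerts cannot arise by
accident, so at zero label noise the label ⇔ alert-presence equivalence
is exact. Labels are flipped independently with probability
`label_noise` after construction; the truth sidecar records the pre-noise
state. Generated SMILES are unique, single-component and deterministic
given the seed. `inject_duplicates` plants exact duplicates, conflicting
label pairs, and counter-ion salt forms on disjoint records so each
defect maps to exactly one curation removal.

What the generator does *not* emulate: realistic chemistry-space
coverage, property-matched decoys, correlated assay panels, or activity
cliffs. Passing the synthetic recovery tests shows the machinery is
correct end to end; it does not certify performance on real assay data,
whose signal is weaker and whose duplicate structure is messier.

**Recovery criterion.** A mined fragment "recovers" a planted alert if it
matches inside the alert capped onto representative carriers (benzene,
cyclohexane, methyl) with at least one matched atom belonging to the
alert substructure. A literal subgraph-of-the-bare-fragment test would be
wrong: fingerprint environments centred on the alert's boundary atoms
legitimately include the attachment-point scaffold atom.

## Problem sizes and seeds

The acceptance script and end-to-end tests use desk-scale sizes chosen to
exercise every stage: 500 molecules (100 actives, 4:1 imbalance) per
pipeline run, ten seeded pipeline repetitions for the recovery rate, four
search draws per run, 1000 perturbation samples and 25 explained
molecules per run; the surrogate-recovery study uses 20 seeds at 2000
samples; the leakage experiment uses 300 molecules at 15% label noise
over ten seeds. One seed flows from the configuration into the generator,
resampler, splitter, search, forest and explainer, making every output
byte-reproducible.

## Known limitations

- Correlated alert bits split surrogate weight among themselves; the
  aggregation across molecules compensates, but per-bit weights on very
  small datasets can fall below the 0.1 floor wholesale (shallow forests
  aggravate this; see the tie-break above).
- The duplicate-identity default (canonical SMILES) does not merge
  distinct structures with colliding 2048-bit fingerprints; the pairwise
  mode does, at O(n²).
- No tautomer/charge standardisation, stereochemistry reconciliation,
  count fingerprints, physicochemical descriptors or calibration curves.
- The explainer assumes binary features; continuous descriptors would
  need a different perturbation and kernel.
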