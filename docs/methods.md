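# Methods

This note records the model, its assumptions, the parameter choices, and
the limits of what the synthetic test conditions establish.

## Structure representation

A pHLA conformation is reduced to two ordered residue lists — peptide and
HLA receptor — each residue carrying only its heavy-atom (non-hydrogen)
coordinates in Å. Everything downstream consumes minimum heavy-atom
distances, so atom identities beyond the element are deliberately not
retained.

Parsing (Bio.PDB): hydrogens are dropped (element column, with an
atom-name fallback for files lacking it); non-standard residues (waters,
ligands, modified amino acids) are skipped with a warning; for disordered
atoms the highest-occupancy alternate location wins, ties broken by altloc
identifier. Peptide positions are renumbered contiguously from 1.

Chain assignment: without an explicit map, the shortest protein chain is
the peptide. With exactly two protein chains the other is the HLA; with
more, only the longest non-peptide chain is kept — this excludes
β2-microglobulin (~100 aa vs ~275 aa for the heavy chain) and any other
accessory chain, since the interactions of interest are peptide ↔ binding
cleft. Files where this heuristic is wrong (equal-length chains, unusual
constructs) need an explicit chain map; ambiguity is not guessed at
silently beyond the documented rule.

## Featurization

210 features, one per unordered amino-acid pair (20 choose 2 plus 20
same-type pairs), ordered lexicographically on the sorted one-letter codes
((A,A)=0 … (Y,Y)=209); the ordering is arbitrary but frozen. For each of
the |peptide|×|HLA| residue pairs, the minimum heavy-atom distance d is
transformed by one of:

| kind | f(d) | notes |
|---|---|---|
| `reciprocal` | 1/d | diverges at contact; clamped below 0.1 Å |
| `reciprocal_squared` | 1/d² | same clamp |
| `sigmoid` | 1/(1+exp(κ(d−5 Å))) | 0.5 at 5 Å exactly, any κ>0 |

and summed into the pair-type entry. Choices:

- **No distance cutoff by default.** All cross-interface pairs contribute;
  the transforms decay naturally. An optional cutoff exists for speed only.
- **Sigmoid steepness κ = 2 Å⁻¹ by default,** placing the 0.1–0.9
  transition across ≈ 3.9–6.1 Å, consistent with the usual 4.5–5 Å
  residue-contact definition. The parameter is exposed because reasonable
  contact definitions vary; results at this scale are insensitive to κ in
  1–5 Å⁻¹.
- **Clash floor 0.1 Å** for the reciprocal transforms only (the sigmoid is
  bounded); clamping is logged, and never occurs in valid structures.
- Distances are computed with `scipy.spatial.distance.cdist`; the test
  suite verifies equivalence against a pure-Python double-loop
  implementation.

## Labels and training matrices

Positives are eluted peptides (label 1, stable); negatives are
affinity-assayed pairs kept only above **20,000 nM** — a deliberately
conservative cut (the usual binder threshold is 500 nM) so the negative
class contains only confidently non-presented peptides. Sub-threshold rows
are ambiguous and dropped, with the count logged. Duplicate
(peptide, allele) pairs are deduplicated; pairs appearing in both tables
conflict and are dropped with a warning. A peptide-length filter defaults
to 9 (the representation itself is length-agnostic).

Two matrix modes: `single` (one row per pHLA — its best-scoring
conformation, where "best" needs an external per-conformation score such
as a docking energy, lower better; absent scores the lexicographically
first conformation is taken with a warning) and `ensemble` (one row per
conformation, all rows carrying the pHLA's label). Per-sample weights are
0.5/n_class, making the weighted class masses exactly 0.5/0.5 (at the
source data's ~70:30 imbalance the per-sample weights stand 3:7).

Cross-validation folds are **grouped by pHLA**: in ensemble mode,
row-level folds would place conformations of the same complex on both
sides of a split, which is leakage; ungrouped folds exist behind a flag
for comparison only.

## Models

`StablePeptideClassifier` wraps scikit-learn learners behind one surface:

- `rf` (default): 1,000 trees, Gini impurity, `max_features =
  ⌊log₂ n_features⌋` (7 of 210; floor vs round is moot — both give 7),
  bootstrap on. A no-bootstrap mode exists because it makes every tree's
  root class distribution exactly the weighted training distribution,
  pinning the interpretation bias to 0.5 precisely.
- `gb`: gradient boosting, 1,000 stages, depth 3, learning rate 0.1.
- `lr`: logistic regression, C = 1. These are documented small defaults,
  not a tuned grid.

Every stochastic component takes an explicit seed (default 0). A pHLA's
prediction is the arithmetic mean of its conformations'
positive-class probabilities; classification thresholds the mean at 0.5.
AUROC (via `sklearn.metrics.roc_auc_score`, cross-checked in tests against
the Mann–Whitney pairwise statistic with ties at 0.5) is always computed
on pHLA-level averaged probabilities. Leave-one-allele-out reports one
AUROC per allele possessing both classes; single-class alleles are
reported as skipped, not silently dropped.

## Contribution decomposition

For each tree, the root-to-leaf path of x is walked; a split on feature j
transfers (child − parent) positive-class node fraction to contrib_j, and
the tree's bias is its root fraction. Forest values are means over trees,
and bias + Σ contrib_j = P(x) holds to machine precision (asserted at
1e-6 internally, tested at 1e-9). Node values come from sklearn's
`tree_.value`, which stores weighted class fractions (sklearn ≥ 1.3).

Contact-level allocation divides contrib_j across the contacts of pair
type j **proportionally to each contact's transformed amount** — the
unique allocation that is linear in the amounts, conserves contrib_j, and
is symmetric under contact reordering. One subtlety: trees also split on
pair types *absent* from a structure (x_j = 0 satisfies "x_j ≤
threshold"), so absent features legitimately carry contribution with no
contact to receive it. That mass is reported separately as
`absent_feature_contrib`, keeping the contact-level balance exact:
bias + Σ contact contributions + absent mass = P. Passing contacts that do
not match the decomposed vector remains a hard error in strict mode.

Summaries report, per peptide position and for the anchor set (positions 2
and the C-terminus by default, overridable per allele), the share of total
positive and of total negative contribution mass; both contact-level and
feature-level positive shares are emitted, since either granularity can be
the relevant one. All-zero contributions make shares undefined; the report
is flagged degenerate rather than inventing numbers. For multi-conformation
pHLAs, per-conformation reports are produced and also averaged; by
linearity the averaged decomposition matches the averaged probability.

## Synthetic data: what it emulates, and what it does not

Real conformations come from expensive docking/modeling pipelines, so the
generator fabricates minimal complexes in which the only quantity
featurization consumes — the minimum heavy-atom distance — is controlled
exactly. Residues are rigid idealized templates with the true heavy-atom
count of each amino acid (4 for Gly … 14 for Trp) and a designated contact
atom; peptide residues sit 7 Å apart along an axis, targeted HLA residues
are placed head-on at their target distance (realized within 0.1 Å,
verified, conflicts are errors naming the offending pairs), untargeted HLA
residues sit on a back plane ≥ 14 Å away. Coordinates are jittered
(default SD 0.3 Å) per conformation and quantized to PDB precision
(10⁻³ Å) so written files re-parse losslessly.

Planted-signal datasets follow the conditions of the real data: 70:30
stable:unstable per allele (default 28:12 across 3 alleles),
Poisson-distributed conformation counts with mean 18 per pHLA, negative
affinities log-uniform on (20,001, 50,000] nM, plus a contaminating 10% of
sub-threshold rows so the label filter is exercised against known ground
truth. The class signal is geometric, not compositional: both classes
contain the signal amino-acid pair (R–D by default, peptide position 3 /
HLA position 5), at 3 Å in stable vs 9 Å in unstable complexes; anchor-like
4 Å contacts at positions 2 and 9 are present in both classes; background
residues are drawn from the alphabet excluding the signal letters.
Optional label noise flips recorded labels while leaving geometry at the
true class.

What passing tests on this generator establishes: the pipeline's
bookkeeping (labels, grouping, weighting), the exactness of featurization
and decomposition, and that the learning machinery recovers a geometric
interface signal across alleles. What they do not establish: performance
on real pHLA structures — real interfaces have correlated contacts,
rotameric variability, modeling error, and per-class conformation-count
bias (docking pipelines emit more conformations for true binders; the
generator deliberately uses the same count distribution for both classes),
none of which the toys contain. Note also that displacing the signal
residue makes *all* of its contacts informative, so attribution mass
spreads over that residue's pair types rather than concentrating solely on
the planted pair — visible in the explanation reports and itself a correct
reflection of the geometry.

## Problem sizes and numerics

The test suite runs the recovery checks at 3 alleles × 40 pHLAs × ~18
conformations (~2,200 rows) with 300-tree forests, and smaller fixtures
(2 alleles × 20 pHLAs, 60–100 trees) elsewhere — sizes chosen so the whole
suite completes in well under a minute on one CPU while leaving the
recovery margins wide (planted-signal AUROCs exceed 0.99 against the 0.9
assertion). The acceptance script uses 3 alleles × 20 pHLAs × ~6
conformations and 200/500-tree forests. Tolerances: decomposition
conservation 1e-9 (float64 exact up to accumulation), featurization vs
brute force 1e-12 relative, toy geometric equalities 2e-3 (set by the
10⁻³ Å coordinate quantization), bootstrap bias 0.5 ± 0.02 over ≥ 500
trees.

## Known limitations

- Structure generation, homology modeling, and scoring are out of scope;
  conformations and (optionally) their scores are inputs.
- mmCIF is not supported; PDB only.
- The `single`-mode "best conformation" degrades to lexicographic choice
  when no scores are supplied (warned).
- Equal-length chains defeat shortest-chain peptide autodetection; pass an
  explicit chain map.
- Attribution is path-based (decision-path value differences), not
  interventional; contributions are conditional on the trained forest and
  training distribution, and should be read comparatively, not causally.
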