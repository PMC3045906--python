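# Methods

`nichesig` re-implements, as a tested pipeline, an analysis showing that
prokaryotic proteome sequences carry classifiable signatures of the
organism's environmental niche. This note documents the model behind each
stage, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## The analysis

Three supervised classification cases are studied on the same feature set:

* **domain of life** — bacteria vs archaea;
* **halophilicity** — halophile vs non-halophile (binary label);
* **thermophilicity** — mesophile / mesothermophile / thermophile, derived
  from the optimal growth temperature range (min, max in °C) against a
  55 °C threshold: mesophile if the whole range is ≤ 55 °C, thermophile if
  the whole range is > 55 °C, mesothermophile if the range straddles the
  threshold. A range touching the threshold exactly (max = 55) counts as
  mesophile, since the thermophilic region is defined as strictly above the
  threshold. Organisms with a missing range are `unknown` and excluded from
  this case only.

## Feature extraction

All descriptors are computed **per protein** and averaged (unweighted
arithmetic mean over proteins) to the proteome level — including the
isoelectric point and the length. The proteome composition is therefore the
mean of per-protein compositions, *not* the pooled-residue frequency; the
two differ whenever protein lengths differ. With the bundled index table
the full set has 79 features:

| block | count | definition |
|---|---|---|
| composition | 20 | residue frequencies f(aa) = count/length |
| index means | 48 | mean amino-acid-index value, = Σ f(aa)·value(aa) |
| isoelectric point | 1 | pH where the modeled net charge crosses zero |
| protein length | 1 | residues; proteome value = average protein size |
| frequency ratios | 8 | see below |
| charge | 1 | total charged fraction f(D)+f(E)+f(K)+f(R) |

The eight ratios: f(charged)/f(non-charged), f(charged)/f(all),
f(polar)/f(non-polar), f(polar)/f(all), f(disorder)/f(order),
f(disorder)/f(all), f(neg)/f(pos), f(neg)/f(all). Since f(all) = 1 the
/f(all) entries are plain set frequencies; f(neg)/f(all) = f(D)+f(E) is the
"negative charge" feature. "Charge" is the *total* charged fraction, not
net charge — the net balance is carried by f(neg)/f(pos). Positive charge
f(K)+f(R) is available on the per-protein record but is not a default
matrix column (it would duplicate information already in the ratio block).

Residue classes (one config object, `ResidueSetDefinitions`): acidic =
negative {D,E}; basic = positive {K,R} — His is treated as neutral at
physiological pH, its content being a separate composition feature; charged
{D,E,K,R}; polar {R,N,D,C,Q,E,H,K,S,T,Y} with the non-polar complement;
disorder-promoting {A,R,G,Q,S,P,E,K} vs order-promoting {W,C,F,I,Y,V,L,N}
(Dunker convention). A zero ratio denominator gets a pseudocount of
1/(length+1) so the matrix stays complete; occurrences are logged.

**Amino-acid index table.** The bundled default holds 48 scales from the
AAindex database, including the ones that matter most for niche signatures
(normalized frequency of extended structure BURA740102, normalized
frequency of beta-turn CHOP780101, information measure for loop ROBB760113,
Chou–Fasman coil parameter CHAM830101, Hopp–Woods hydrophilicity
HOPT810101, Grantham polarity GRAR740102) plus 42 further classic
interpretable scales (hydrophobicity, volume, secondary-structure
propensity, flexibility, accessibility). The table is a plain TSV and fully
user-replaceable; pipeline correctness is defined relative to the
configured table.

**Isoelectric point.** Net charge is modeled with Henderson–Hasselbalch
terms over ionizable side chains (K, R, H positive; D, E, C, Y negative)
plus one free N- and C-terminus, with EMBOSS pKa values by default
(configurable). Z(pH) is monotonically non-increasing and the termini
guarantee Z(0) > 0 > Z(14), so the crossing is unique; it is found by
bisection on [0, 14] to 1e-4 pH. Tests verify agreement with a 1e-4-step
dense grid scan within 2e-3 pH on 500 random sequences.

**Sanitization.** FASTA input is uppercased; characters outside the 20
canonical residues (B, J, O, U, X, Z, stops, gaps) are removed — not
redistributed — and counted, so composition denominators are explicit.
Sequences that become empty are dropped with a warning.

## Redundancy reduction (79 → ~40 features)

Spearman rank correlations (average ranks on ties; constant features get
ρ = 0 and are flagged) are computed for all feature pairs across organisms.
Features are clustered on d = 1 − |ρ| with unweighted pair-group average
(UPGMA) agglomeration and the dendrogram is cut at height 1 − 0.9, i.e.
merges are allowed while the average absolute correlation stays ≥ 0.9.
Each cluster is represented by its **medoid** — the member with the highest
mean |ρ| to the other members ("closest to the center"; no coordinate
centroid exists in correlation space) — with lexicographic tie-breaks for
determinism. A single reduced feature set, computed once, feeds all three
classification cases. Rank correlation makes monotone normalization
irrelevant, so the reduction is computed on raw feature values.

## Evaluation protocol

Per repeat (default 10): a stratified 2/3–1/3 split without replacement
(per-class train counts within one organism of the fraction); per-feature
min–max normalization **fitted on the training portion only** and applied
to the test portion (test values may leave [0, 1]; constant training
features map to 0); adapter training; test scoring with class-probability
outputs; ROC by threshold sweep over distinct scores with trapezoidal AUC
(provably equal to the Mann–Whitney pair-count statistic, verified against
exhaustive pair counting). A per-class normalization variant that fits the
scaling inside each class is available (`per_class_minmax`) for comparison
only — it uses the labels of the instances being normalized, including test
labels, and therefore leaks label information at prediction time.

Adapters: a 1000-tree random forest (other parameters at library defaults)
and an RBF-kernel SVM with C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2³} (step 2²) grid
search under internal stratified cross-validation on the training split
(up to 10-fold, clamped to the smallest class). SVM class scores come from
Platt sigmoid calibration of the decision values fitted by the same
internal CV — the construction behind LibSVM-style probability outputs.
The learning algorithms are scikit-learn's; the package contributes the
protocol, not the learners.

The three-class thermophilicity case is reduced one-against-one (three
pairwise binary problems; the headline AUC is the mean of the three
pairwise means) with one-against-all curves also reported.

**Permutation controls.** Two decoys must fall to chance: independently
permuting each feature column across organisms (destroys all feature–label
association, preserves marginals) and permuting the label vector. By
default each of the 10 repeats draws a *fresh* permutation, so the reported
mean estimates the mean of the null distribution (≈ 0.5 tightly). Using a
single fixed permutation for all repeats is supported but discouraged: the
overlapping splits repeatedly relearn the same spurious dataset-level
associations, so that mean is one noisy draw from the null (scatter of
roughly ±0.1 around 0.5 at n = 64).

## Permutation feature importance

importance(f) = mean increase in held-out prediction error after shuffling
feature f's values, averaged over the repeated splits and (default 3–5)
shuffles; the model is never refitted and the input is never modified in
place. The error metric is the **Brier score** of the class-probability
outputs (for three classes, with one-hot targets). A rank-based metric
(1 − AUC) is selectable but degenerates on strongly separated data: when
the test AUC saturates at 1.0, permuting one of several redundant features
leaves the score *ranking* intact and every importance collapses to exactly
zero. The margin-sensitive Brier score still registers the degradation of
the probabilities, which is what makes planted-signal recovery measurable
at desk scale. Importance is computed on held-out test folds rather than
out-of-bag samples, keeping the measure identical for both adapters.

Case signatures: from the three per-case top-10 lists, *shared* features
appear in all three; *unique* features (default) are a case's top-10 minus
the union of the other two lists. Box-and-whisker summaries use
linear-interpolation (type-7) quartiles and Tukey 1.5·IQR whiskers, with
optional pooled min–max normalization to [0, 1] for figure-style output.

## Synthetic data: what is emulated, what is not

Each organism belongs to a composite class (domain | halophilicity |
thermophilicity). A class tilts a baseline residue distribution
(approximate averages over annotated proteomes) by per-residue
multiplicative factors, renormalized to the simplex; the per-dimension
effects combine multiplicatively across the three label dimensions:

* halophile: E ×2.35, D ×2.15 (Glu tilt > Asp tilt; after renormalization
  the acidic fraction roughly doubles), K ×0.60, F ×0.75, Q ×0.85;
* thermophile: V ×1.38, Y ×1.40, E ×1.30, Q ×0.65 (mesothermophile:
  intermediate values);
* archaea: H ×0.70, Q ×0.78, E ×1.22, and shorter proteins (median 255 vs
  300 residues).

Only the *directions* of these effects are constrained by what is reported
for real proteomes; the magnitudes are tunable model parameters, not
claims. Protein lengths are lognormal (log-sd 0.45) truncated below at 30
residues. Proteins are i.i.d. residue draws — every downstream descriptor
is an order-independent function of residue counts, so sequence order
carries no signal and none is simulated. A per-organism lognormal frequency
jitter (log-sd 0.05) emulates between-organism variation (lineage, GC
pressure). Growth-temperature ranges are sampled uniformly inside the
region consistent with the class label, so the label-derivation code is
exercised nontrivially.

Not emulated: phylogenetic correlation between organisms, codon/GC-level
structure, within-proteome distribution shapes beyond the lognormal length,
domain architecture, or any real database content. Passing tests therefore
demonstrate that the *pipeline* recovers what was planted under this
generative model — they do not certify accuracy on real proteomes, where
correlated phylogenetic structure can inflate apparent signatures.

Desk-scale defaults: 32 organisms per class for two-class cases (32/16/16
for the three temperature classes), 300 proteins per organism, median
length 300 — the full pipeline runs in minutes on one CPU. Ground truth
(class labels, tilted target frequencies, length parameters, tilted
residues) is returned alongside the data; the planted-signal recovery test
counts a tilted residue as recovered when its *cluster representative*
reaches the importance top-10, since the reduction deliberately collapses
correlated features.

## Problem sizes used in the test suite

Oracle suites run at full stated size (1000 random score/label sets for
AUC, 500 sequences for the pI grid scan, 50 random ≤ 6-feature matrices
for UPGMA). Control and recovery checks run on 2 × 32 organisms × 300
proteins; recovery uses 5 evaluation repeats with 500-tree forests and 2
shuffles per feature, and direction checks run on 12-organism-per-class,
100-protein datasets across 10 seeds. End-to-end pipeline tests use
smaller smoke-scale configurations (8 organisms per class, 30 proteins).

## Known limitations

* The bundled 48-scale table is one defensible choice; results depend on
  the configured table, which is why it is user-replaceable.
* Importance under redundancy is diluted: correlated survivors of the
  reduction share credit, so absolute importance values are not comparable
  across feature sets — only rankings within one run are interpreted.
* The pI model ignores charged-residue interactions, cystine bridges and
  post-translational modification; it is a sequence-composition proxy.
* The SVM grid search at desk scale (≈ 21 training organisms per class)
  selects hyperparameters with high variance; the forest adapter is the
  default for that reason.
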