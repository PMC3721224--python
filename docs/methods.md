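# Methods

## Scope and data model

The pipeline starts at vendor-exported peak tables (retention time, height,
optional base mass and isotope envelope per peak) and pre-aligned DNA
sequences; peak picking from raw signal and sequence alignment are outside its
contract. Its core objects are a samples × features matrix of
base-peak-relative heights, a Bray-Curtis resemblance matrix and group-average
dendrogram over samples, per-marker p-distance matrices and neighbor-joining
trees, and three partitions of the sample set (chemogroup, phylogroup, site)
that the integration layer compares.

## Isotope envelope model

Theoretical envelopes are the convolution of per-atom isotope binomials for
Cl and Br only, at nominal 2 amu spacing, normalised to a lightest peak of 1.
Constants: ³⁵Cl/³⁷Cl = 0.7576/0.2424, ⁷⁹Br/⁸¹Br = 0.5069/0.4931 (overridable
arguments for audit runs). ¹³C/²H contributions are ignored by default — at
unit mass resolution the halogen comb dominates and the ¹³C shoulders fall
between the 2 amu peaks; an optional carbon count folds them in at 1 amu
spacing for sensitivity checks.

Observed envelopes are matched by cosine similarity after zero-padding the
shorter vector, which is scale-invariant (instrument counts need no
normalisation) and tolerant of the rough integer ratios practitioners read
off spectra; both vectors are pre-scaled by their maximum so extreme
magnitudes cannot underflow. `infer_halogens` scores every composition with
at most 8 halogens (the practical ceiling for monoterpenes) and breaks exact
score ties toward fewer total halogens, then more Cl, making the ranking
deterministic. A feature is called polyhalogenated when the rank-1
composition has ≥2 halogens and score ≥0.95. The 0.95 default is deliberately
forgiving: a perfect-binomial match scores ≥0.999, while envelopes distorted
by co-eluting ions still clear 0.95 when the halogen comb is present.

A caveat on inference from padded envelopes: when an observed cluster is not
proportional to any exact-length theoretical envelope, a longer composition
whose leading peaks fit better can legitimately outrank all exact-length
candidates. Peak count therefore bounds the halogen count from below
(k+1 peaks ⇒ ≥k halogens) but the rank-1 composition should not be
over-interpreted for distorted envelopes.

## Feature table construction

Heights are divided by the chromatogram's base peak (×100, so the base peak
is exactly 100); retention is strictly >10% within the closed window
[10, 30] min, applied per sample *before* cross-sample matching — a compound
below threshold in one sample is genuinely absent (0) there even if recurring
elsewhere, and retained values are not re-normalised, preserving their
base-peak-relative meaning.

Matching is greedy single-linkage binning: peaks are processed in global
(rt, mass, sample) order and join the nearest bin within 0.10 min of the
bin's running-mean rt (and within 1 amu of its mean base mass when both are
known); one peak per sample per bin, closest-rt wins, the displaced peak
seeds a new bin. The global ordering makes the result independent of sample
input order. The 0.10 min tolerance is a conservative fraction of the ~0.3
min spacing between named features in this chromatography; features per bin
can only merge, never split, as the tolerance grows. A `min_occurrence`
filter exists for stricter definitions of "recurring" but defaults to 1.

## Chemogrouping

Quantitative Bray-Curtis on the relative heights with no transform: the
upstream normalisation already bounds values to [0, 100] and the study design
reads peak heights directly. Clustering is UPGMA proper (unweighted group
average: leaf-count-weighted update, equivalently the mean over all
cross-pairs), implemented in-package so that equal-height merges break ties
deterministically (smallest leaf indices first) — this makes dendrograms
invariant to input order even on ultrametric inputs full of ties, which
library implementations do not guarantee. Heights are validated against a
brute-force between-cluster-mean oracle and scipy's average linkage in the
test suite.

Cutting at similarity s keeps every merge with dissimilarity strictly below
1 − s/100, so "grouped above 50% similarity" means cophenetic similarity
strictly greater than 50%. Group labels CG1…CGk follow first appearance in
sample order; every downstream statistic is invariant to the labelling.

## Phylogrouping

p-distance uses pairwise deletion: sites with a gap or any non-ACGT symbol in
either sequence are excluded (ambiguity codes are treated as missing, not
guessed). Jukes-Cantor correction −(3/4)ln(1 − 4p/3) is provided for
reporting; at the ≤2.1% divergences involved it changes distances by <1%, so
trees are built on p-distances. Neighbor joining follows the standard
Q-criterion with ties broken by smallest index pair; negative branch lengths
are clamped to zero with the deficit moved to the sibling edge so the joined
pair's distance is preserved. Phylogroups come from deleting the k−1 longest
internal edges (k = 2 by default: the deepest split), labelled A, B, … by
decreasing size. The NJ route is sufficient because the downstream object is
the two-clade partition, which is identifiable from distances alone; model
selection, likelihood search and bootstrap support are out of scope.

Divergence reports state the per-marker sample coverage explicitly rather
than assuming every collected individual was sequenced, and cross-marker
phylogroup conflicts (an individual changing clade between cox1 and rbcL)
are reported, not resolved.

## Integration

Crosstabs count only samples present in every partition (dropped ids are
logged); site purity is the modal-chemogroup fraction per site; partition
agreement uses the pair-counting Rand index and its chance-adjusted form
(scikit-learn, verified against a direct pair-enumeration oracle in tests).
Nesting exceptions list each chemogroup spanning more than one phylogroup
with its minority members. Depth and site names are carried as descriptive
metadata only; no environmental model is fitted, since seven sites at one
depth each cannot separate site from depth effects.

## Synthetic study generator

The generator's defaults are the study conditions: 7 sites × 3 replicates,
43 recurring features in 10–30 min, 5 chemogroups nested in 2 phylogroups
(CG1, CG5 → A; CG2–CG4 → B), chemical exceptions 1B→CG2 and 6C→CG5 injected
by reassignment after template draw, and the rbcL-only 6A→A conflict.

Chemistry: each chemogroup's template has exclusive features (intensity
30–100) plus features shared with a neighbouring group (15–25), with 20% of
the pool shared; this keeps expected between-group Bray-Curtis similarity
below 40% (realised ~3–8%) while multiplicative lognormal replicate noise
(σ = 0.25) keeps within-group similarity above 70% (realised ~85%). The
generator *verifies* both targets at build time and raises on infeasible
configurations rather than silently emitting an unusable study. Retention
times get Gaussian jitter (sd 0.02 min, small against the 0.10 min matching
tolerance); every feature carries a sampled (n_Cl, n_Br) with ≥2 halogens and
its exact theoretical envelope.

Genetics: per marker, the two clade ancestors differ at
⌊L·p_between⌋ − 2·⌊L·p_within/2⌋ sites and each leaf carries at most
⌊L·p_within/2⌋ private substitutions, so the realised maximum pairwise
p-distance can never exceed the configured ceiling (the reported divergences
are maxima, "x% or less") while within-clade divergence stays ≤0.5%.
Substitution placement is uniform (Jukes-Cantor-like); no rate heterogeneity,
realistic codon structure, or coalescent within-clade genealogy is modelled.

What passing recovery tests therefore show: the pipeline exactly recovers
block-structured partitions separated as the study reports, across 100 seeds.
What they do not show: robustness to co-eluting peaks, missing features,
retention drift between batches, heteroscedastic detector noise, or
recombination/introgression — real-data phenomena the generator does not
emulate.

## Reference study fixture

The 21-sample group structure (memberships, site map, and merge similarities
40/30/30/10% with >70% site cohesion) is reconstructed from the reported
group descriptions; leaf order inside groups is unrecoverable and all
statistics computed from the fixture are invariant to it. The reported
similarity levels are internally inconsistent about the CG1–CG5 merge (10%
by one statement, 30% by another); the fixture uses the ultrametric reading in
which CG5 joins the CG2–CG4 cluster at 30% and CG1 is the outgroup at 10%,
which reproduces the five-group cut at 50%. Within-site similarity is set to
75% (any value >70% gives the same partition) and cross-site same-group
similarity to 60% (any value in (50, 70) does).

## Numerical conventions

Matrices are written to disk at 4 decimal places; full precision is kept in
memory and feature tables serialise with full-precision reprs (bit-exact
round trip, `float_precision="round_trip"` on read). All randomness flows
through one `numpy.random.Generator` seeded per study; identical seed and
configuration produce byte-identical bundles. Problem sizes throughout the
test suite are the study's own (21 samples, 43 features, 660/890 bp), with
100-seed recovery sweeps and 200-trial NJ exactness checks.
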