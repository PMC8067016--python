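# Methods

This note documents the models and procedures `bdellocomp` implements, the
parameter defaults and why they are set where they are, what the synthetic
data does and does not emulate, and the numerical conventions that make the
pipeline deterministic.

## Genome quality gate and dereplication

Genomes and MAGs enter the comparison only if CheckM-style completeness is
strictly above 70%, contamination strictly below 10%, and the conserved
protein count is at least 22. The three values are consumed as metadata;
the marker-set semantics behind the conserved-protein count are opaque to
this package, which treats it as a non-negative integer. All three
comparisons follow the wording of the originating protocol exactly
("more than", "less than", "at least"), and the boundary behaviour
(70.0 fails, 10.0 fails, 22 passes) is pinned by tests.

Redundancy removal clusters genomes whose pairwise ANI is at least 0.985
and keeps one representative per cluster. ANI is estimated without
alignment, from the Jaccard index *J* of canonical k-mer sets (lexicographic
minimum of each k-mer and its reverse complement; k-mers containing N are
skipped) through the Mash distance transform

    ANI = 1 + (1/k) · ln( 2J / (1+J) ),   clamped to [0, 1],

with k = 16. k = 16 keeps random 16-mer collisions negligible at genome
scale while leaving enough shared k-mers at the 98.5% decision boundary;
on 100 kb substitution-mutated pairs the estimator tracks 1 − p within
0.005 for p up to 0.02 (tested). J = 0 leaves ANI undefined rather than 0:
disjoint k-mer sets carry no identity signal. Clustering is single-linkage
— the decision threshold is a species-boundary heuristic, and
single-linkage is the only scheme for which "some path of ≥98.5% links"
has a clean interpretation; the representative is chosen by highest
completeness, then lowest contamination, then smallest id, making the
output invariant to input order.

## 16S miTag classification and depth profiles

Reads are matched to a labeled 16S reference set by seed-and-extend
semi-global alignment implemented in the package (numba-compiled dynamic
program): a shared 12-mer between read and reference nominates diagonal
windows; within each window a three-state affine-gap (Gotoh) recurrence
aligns the read end-to-end while reference overhangs are free. Scores are
match +2, mismatch −3, gap of length L −5 − 2L. Identity is match columns
over aligned columns with gap columns in the denominator. Both strands are
aligned and the better score kept. The diagonal pad of ±8 around the seeded
diagonals covers any plausible indel drift at the >97% identity this
pipeline accepts; an oracle-equivalence suite checks banded scores against
an unrestricted full-matrix dynamic program on 500 random pairs.

A read is assigned to the group of its best-scoring reference (ties broken
by identity, alignment length, then reference id) only if it is longer
than 100 bp and identity is strictly above 0.97 — both filters strict, as
in the original protocol wording. The original search's E-value cutoff
(1e-5) is replaced by a raw-score floor of 60: any alignment passing the
length and identity filters scores far above it, so the substitution never
changes the decision boundary; it only prunes junk seeds early.

Relative abundance of a group in a sample is 100 × (assigned reads) /
(total 16S miTags in the sample). Samples are stratified into layers by
depth with half-open bins: epipelagic [0, 200) m, mesopelagic
[200, 1000) m, deep [1000, ∞) m. 1000 m goes to the deep layer because
the deep-sea sample set is defined as ≥ 1000 m. Between-layer differences
per group use Welch's unequal-variance two-sided t-test (each layer needs
≥ 2 samples), annotated "****" below 1e-4 and "*" below 0.05.

## Presence/absence analytics

Long-form annotation tables (genome, namespace ∈ {KEGG, COG, MEROPS,
CAZy}, gene, copies) are pivoted into a boolean presence matrix and an
integer copy-number matrix (copies summed over duplicate rows; presence
⇔ copies > 0).

Two deliberately different thresholds govern the group rules:

* group-level presence is **inclusive**: a group has a gene when at least
  50% of its genomes carry it (fraction 0.5 flags present);
* group specificity is **strict**: a gene is specific to a group when
  strictly more than 50% of that group's genomes carry it and every other
  group is at or below 50%. Specificity is deliberately not "absent
  elsewhere": minority presence in other groups is allowed, matching how
  enrichment tables show non-zero minority percentages.

Marine enrichment splits one group's genomes into marine and non-marine by
the environment label and reports, per gene, the presence percentage on
each side together with the underlying counts. Percentages are computed
from exact integer ratios and rounded half-away-from-zero — to two
decimals for the analytic column and to whole percent for the display
column. Rounding is the only lossy step; the counts are always carried so
every percentage is recomputable. A side with zero genomes yields NaN and
is flagged rather than silently dropped.

The peptidase Venn partition assigns each MEROPS family the set of groups
that carry it under the inclusive ≥50% rule and counts the 15 non-empty
group combinations; families below 50% everywhere have an empty signature
and are excluded, and region counts always sum to the number of families
with a non-empty signature (conservation, tested as a property).

CAZy genes are classed by their leading alphabetic prefix (GH, PL, GT, CE,
CBM, AA); an unrecognized prefix warns and is excluded. Class profiles are
the per-group mean of per-genome summed copy numbers.

Copy-number differences between groups use the two-sample Wilcoxon
rank-sum test with midrank ties: the null is exact when min(nA, nB) ≤ 8
and there are no ties, and a normal approximation with continuity and tie
correction otherwise (the scipy Mann–Whitney implementation stands behind
this surface; an independent full-permutation enumeration oracle pins its
exact branch in the tests). P-values are reported raw and
Benjamini–Hochberg adjusted, since the original protocol names no
correction — emitting both leaves the choice explicit.

## Motif scanning

The chitinase catalytic motif `DXXDXDXE` is scanned with X matching any of
the 20 standard amino acids; non-standard residues (B, Z, U, *) match
neither X nor a literal. All matches are reported, including overlaps —
downstream counts deduplicate per protein. On uniform background the
expected hit rate is (1/20)⁴ per eligible offset (four literal positions),
which the stochastic sanity test confirms. Signal-peptide calls are
consumed as an optional annotation column, never computed.

## Synthetic data: what it emulates, what it does not

The worked-example fixtures are deterministic genome collections whose
carrier counts are the smallest integers that reproduce, under
half-away-from-zero rounding, the headline percentages the pipeline is
designed to compute (e.g. 7/9 → 77.78%, 4/19 → 21.05%, 17/19 → 89.47%,
41/46 → 89.13%, 23/53 → 43.40%, 22/47 → 46.81%). Different fixtures encode
different sub-analyses and are intentionally *not* forced into one global
genome set: the source tallies, the enrichment table, and the cheB
presence figures imply mutually inconsistent group sizes, so each fixture
is self-consistent for the quantities it serves. One known truncation
artefact (10/14 = 71.43% rounded, 71.42% truncated) is avoided entirely:
no fixture-backed quantity depends on it.

The simulators generate: Bernoulli presence/absence with per-(gene, group,
environment) probabilities and 1 + Poisson copy numbers; layered miTag
read sets in which each read is a substring of its group's reference with
i.i.d. substitutions at the error rate (default 0.5%), group references
diverge ~10% from a common ancestor (inter-group identity ≈ 81%, far below
the 97% filter), and background mass comes from decoy references kept at
≥ 15% divergence from every group reference so truth labels stay clean;
substitution-mutated genome pairs for the ANI estimator; and proteins with
planted motifs at recorded positions. Background gene ids carry the
reserved `BGK` prefix so truth tables are unambiguous.

Simulations deliberately omit: indel and quality-score error profiles,
chimeras, amplification bias, real 16S secondary-structure conservation,
real genome composition, assembly and binning artefacts. Passing the
recovery suites therefore demonstrates the estimators are correct under
their stated error model, not that they are robust to every artefact of
real metagenomes.

Every stochastic component draws from `numpy.random.default_rng(seed)`;
the same seed reproduces byte-identical TSV/FASTA serializations (tested).

## Problem sizes

The parameter-recovery suite runs the layered design at 3 layers × 10
samples × 10⁴ reads with 0.5% error (the package's standard verification
design), the aligner-equivalence suite uses 500 read/reference pairs up to
200 bp at ≤ 5% divergence, ANI recovery uses 100 kb pairs, and the motif
oracle comparison uses 10⁴-residue sequences. The analysis drivers under
`analysis/` use reduced read counts (2000/sample) purely as quick
demonstrations.

## Known limitations

* The ANI estimator is a sketch method: it is calibrated for the
  dereplication decision at ~98.5%, not for reporting ANI between distant
  genomes (J → 0 is reported as undefined).
* The aligner is built for short reads against a small curated 16S
  reference set; it indexes references in memory and is not a general
  homology search tool.
* Group-specific gene counts on real annotation compendia depend on the
  underlying genome set; the fixtures pin the rules, not those counts.
* The Venn membership criterion (≥ 50% rule) is a design choice where the
  original protocol is silent; alternatives (any-genome membership) would
  change region counts.
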