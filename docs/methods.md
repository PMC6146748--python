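# Methods

This note documents the models behind each analysis, the parameters that
matter, what the synthetic generators do and do not emulate, and the design
choices made where the published analysis conventions leave room.

## Fragment-based ANI and conserved DNA

**Model.** Species delineation between two genomes uses two directional
statistics computed from the query's fragments. The query is cut, within
contigs, into consecutive non-overlapping windows of 1020 b (a terminal
remainder is kept only when ≥ 100 b, so no fragment is shorter than the
minimum a 15-mer seeded alignment can anchor reliably). Each fragment is
aligned to the subject genome on both strands and its best local alignment
retained.

* **ANI** is the unweighted mean percent identity over *qualifying*
  fragments — best alignment with identity ≥ 30% over ≥ 70% of the fragment
  length. With no qualifying fragment, ANI is reported as 0 with a
  `no_homology` flag.
* **conDNA** is 100 × (query bases inside fragment alignments at ≥ 90%
  identity) / (total query length), capped at 100.

Identity is matches / aligned columns, so gap columns count against
identity. The decision matrix maps (ANI, conDNA) to 1 / −1 / 0 as described
in the README; the quadrant ANI < 95 ∧ conDNA ≥ 69 is not covered by the
published rule and is mapped to 0 with an `unspecified_quadrant` flag
rather than silently.

**Aligner.** Seed-and-extend: exact 15-mer seeds against a subject k-mer
index are clustered by diagonal (bins of half the band width); for up to 4
candidate diagonals per strand, a banded local affine-gap dynamic program
is run in a window around the diagonal. Scores: match +2, mismatch −3, a
gap of length *n* costs −5 − 2*n*; band half-width 0.2 × query length
(minimum 16). These constants are fixed so that results are reproducible
bit-for-bit, and the banded optimum is verified in the tests against an
independent exhaustive (unbanded, unseeded) Smith–Waterman implementation
on instances up to 2 kb. Ties between equally scoring candidates resolve
to the forward strand and the better-supported diagonal, making outputs
platform-independent.

**Error characteristics.** Local alignment trims negative-scoring ends, so
estimated fragment identity carries a small upward bias (observed ≈ +0.05
points at 5% divergence, well inside the ±1-point recovery tolerance the
tests enforce). ANI is directional; for indel-free pairs the two directions
agree within 1 point.

## Read recruitment and RPKG

Reads are treated as singletons. A read is recruited to a MAG when its
best alignment (same aligner, band minimum 8, every 4th k-mer used for
seeding) spans ≥ 50 aligned bases at ≥ 95% identity; both cutoffs are
parameters. Each read counts at most once per MAG. Two mapping universes
are provided: the default maps every read independently onto each MAG
("mapped onto each MAG"); a competitive mode assigns a read only to its
best-scoring MAG, ties broken by lexicographic MAG id.

RPKG = count / (MAG length / 10³) / (mapped bases / 10⁹). The denominator
is per dataset: total bases of reads mapped to *any* MAG (each read
contributing its largest aligned span once), with a `sampled`
alternative that uses all subsampled read bases instead. Zero mapped bases
yields RPKG 0 with a flag. Subsampling is uniform without replacement
(default cap 10⁷ reads) and deterministic per seed.

## Salinity preference score

With M MAGs and datasets labelled high or moderate salinity: the summed
RPKG over high-salinity datasets is ranked descending and the MAG at rank
r receives the positive score M − r + 1 (top = M, bottom = 1); the
moderate-salinity sums are ranked the same way with negative sign (top =
−M). The salinity score is the sum of both. Consequences (property-tested):
positive scores are a permutation of 1..M, scores sum to zero, and the
statistic is invariant to rescaling all RPKG values within one group by a
positive constant. All ties break by descending value then ascending MAG
id.

## Species-averaged abundance summaries

For figure-style summaries the top-N (default 10) most abundant MAGs per
dataset are pooled and clustered: MAG pairs whose decision code is 1 *or*
−1 are joined and clusters are the connected components (transitive
closure), so "likely same species" chains collapse into one population.
Per cluster and dataset the RPKG values are averaged arithmetically;
singleton clusters reproduce their input values exactly.

## Quality tiers and phylogeny eligibility

Near-complete: completeness ≥ 90% and contamination < 5%; medium:
completeness ≥ 50% and contamination < 10%; otherwise fail. The
contamination boundaries are strict (<) by default — the wording of the
tier definitions — with an inclusive (≤) switch, since "≤ 10%" also
appears as a bin-selection criterion. Every near-complete record
necessarily satisfies the medium thresholds.

Concatenated ribosomal-protein phylogeny eligibility uses the fixed
16-marker panel (L2–L6, L14–L16, L18, L22, L24, S3, S8, S10, S17, S19): a
MAG qualifies when ≥ 8 distinct markers are present at ≥ 80 aa; duplicate
copies of a marker count once, since the rule concerns presence.

## Isoelectric points

Net charge at a given pH is the Henderson–Hasselbalch sum over ionizable
groups — basic: N-terminus, Lys, Arg, His; acidic: C-terminus, Asp, Glu,
Cys, Tyr — with terminal groups counted once per protein. The default pKa
set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1) ships as an editable JSON data file; published pI predictors
differ in their constants, so the file, not the code, is the authority.
The charge is strictly decreasing in pH, so the pI is the unique root in
[0, 14]; bisection narrows the bracket to 10⁻⁹ pH units, which keeps
|net charge| at the reported pI (6 decimals) below the 10⁻⁴ tolerance even
for proteins with hundreds of ionizable groups.

Histograms use half-open bins [left, right) of width 0.2 over [0, 14];
median and acidic fraction are computed from the unbinned values. The
"pronounced acidic peak" call is operationalised as: modal bin center
< 5.5 *and* ≥ 50% of proteins with pI < 5.5 (both thresholds are
parameters and are reported alongside the call; modal ties resolve to the
most acidic bin). Ambiguous residues (B, Z, X, …) are rejected by default
rather than silently approximated; a skip-with-warning mode exists.

## KO pathway screening

Pathway definitions are configuration, not code: a YAML file maps each
pathway to required (and optional) KO sets and a presence threshold
(fraction of required KOs). Completeness = |required ∩ annotated| /
|required|; presence calls are binary per KO — copy number never matters.
Only four KO ids are anchored in the source analyses (acsB K14138, cdhC
K00193, nrfA K03385, PRK K00855); the packaged memberships for the
Wood–Ljungdahl eastern branch, EMP glycolysis, PFOR and pta/ack are
best-effort selections from the corresponding KEGG modules and are
commented as such in the file. The marker screen with a product-length
floor (default use case: acsB at ≥ 500 aa) excludes genes lacking length
data from length-screened queries with a warning.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analyses rely on,
with all randomness flowing from one explicit integer seed per call:

* genomes — i.i.d. bases at a target GC; no repeats, gene structure or
  compositional heterogeneity;
* divergent pairs — independent per-site substitutions, uniform over the
  three alternative bases (no transition/transversion bias), plus
  geometric-length indels (mean 2, insertions and deletions equiprobable,
  so expected length drift is ≈ 0). With indels disabled the per-site
  alignment is the identity, which is what makes ANI recovery exactly
  checkable against the mutation record;
* read sets — source genome drawn ∝ copy-number weight × genome length
  (so length-normalised RPKG recovery is the natural test), uniform start
  and strand, i.i.d. base errors; no quality-score profiles, coverage
  bias, chimeras or paired-end structure;
* proteomes — i.i.d. residues with a controlled Asp+Glu fraction split
  evenly between D and E, the rest uniform; no domain structure;
* annotation tables — a planned fraction of each pathway's required KOs,
  floored to an integer count and chosen uniformly.

Passing tests therefore demonstrate that the *computations* recover known
truth under these idealised conditions; they do not certify behaviour on
real data with repeats, strain mixtures, conserved cross-species regions
or annotation noise.

## Problem sizes and numerical choices

The test suite and demo pipeline run at desk scale by design: ANI recovery
uses 100-kb genome pairs (98 fragments per direction), aligner-oracle
equivalence uses 200 instances ≤ 2 kb, abundance recovery uses a 5-genome
community of 30-kb genomes with 50,000 error-free 150-b reads, and the
demo pipeline defaults to five 20-kb MAGs with 1,000 reads per dataset.
These sizes recover the target statistics with comfortable margins (the
binomial standard-error envelopes checked in the tests are < 10% relative)
while keeping a full run in tens of seconds on one core.

All genomic coordinates are 0-based half-open. Output tables are
tab-separated with a parameter header comment and 4-decimal floats;
reruns under the same configuration are byte-identical (timestamps only
appear in the run log). One global seed derives per-stage seeds by hashing
the stage name, so stages can be rerun in isolation.

## Known limitations

* The fragment qualification thresholds (30% identity over 70% coverage)
  and the 1020-b fragment length follow the common fragment-ANI
  convention; other choices shift ANI slightly for distant pairs.
* The seed-and-extend aligner can miss homology with no exact shared
  15-mer (possible above ~20% divergence); for the species-boundary
  regime (≤ 5% divergence) seeds are abundant.
* RPKG's "mapped reads" denominator is defined against the supplied MAG
  set; profiles computed against different reference sets are therefore
  not directly comparable unless the `sampled` denominator is used.
* pI prediction uses a single global pKa set and ignores structure,
  modification and local-environment effects; absolute pI values shift
  with the pKa table, though the acid/neutral contrast is robust.
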