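# Methods

This note records the models, conventions and numerical choices behind
`cenbarcode`, in the order the pipeline applies them.

## Synthetic study conditions

The generator emulates a soybean-like centromeric satellite system with
known ground truth; its defaults are the conditions under which every
recovery claim in the test suite is made.

**Consensus monomers.** The family registry fixes the biology-bearing
lengths — CentGm-1 92 bp, CentGm-2 91 bp, CentGm-4 413 bp — but the
consensus sequences themselves are synthetic stand-ins drawn uniformly at
random from fixed seeds (`DEFAULT_CONSENSUS_SEEDS`); the real deposited
sequences are not shipped. Everything downstream treats the consensus as
opaque, so only the lengths matter for the recovery results.

**Arrays.** A tandem array is `n_copies` monomers emitted cyclically
along an HOR pattern of 1–5 variant labels. Each label beyond the first
carries a fixed marker-substitution set drawn once per variant at
`variant_divergence` (default 0.08) per base — this is what makes the
HOR phase detectable above copy-level noise, as distinguishable monomer
classes within one repeat family imply. Each emitted copy is then mutated
at `sub_rate` (default 0.05) per base, with optional indels
(`indel_rate`, default 0). Truncated ("partial") copies are 5′ prefixes
of length round(fraction × L); the canonical fractions are 209/413,
252/413 and 317/413. Truncations are placed at random internal copy
positions, never the first copy: partial units are features *inside* an
HOR array, and a leading truncation would be indistinguishable from an
array-boundary artifact (it also leaves the chunk phase of consensus
derivation undefined). Which end of a truncated unit is lost is not
observable from length alone; 5′ retention is this package's convention.

**Karyotype.** The default karyotype has 20 chromosome sets (2n = 40),
each one flank + a single CentGm-4-type satellite array + flank. The HOR
class counts follow the rank order reported for soybean CentGm-4
(monomeric arrays most common, a single pentamer chromosome): 8 monomer,
5 dimer, 3 trimer, 2 tetramer, 1 pentamer, plus 1 two-variant chromosome
(a monomeric segment followed by a trimeric one) and three chromosomes
carrying one partial unit at each canonical fraction. Published
chromosome-set tallies overlap across two-variant chromosomes and do not
resolve to exactly 20, so these counts are this package's own
rank-preserving choice. Single-class chromosomes carry 36 copies
(the two-variant one 24+24): enough monomers for stable consistency
statistics and changepoint detection while keeping a full 10-seed
karyotype recovery run around two minutes on one CPU.

**Flanks.** `build_hor_array`/`build_karyotype` default to total flanking
sequence of 20 % of the array length (uniform random bases), enough to
exercise read-assignment specificity. The *pipeline* instead passes
`flank_frac = 20` (total flank = 20× the array, repeat fraction ≈ 5 %):
at the dense default the genome is 83 % repeat and the enrichment ratio
saturates near 1 regardless of the true enrichment, which would make the
ChIP stage uninformative.

**Reads.** Paired-end reads are 2×300 bp (the MiSeq protocol the assay
uses), insert length Normal(500, 50) clipped at the read length, fixed
quality "I". The ChIP library oversamples fragment *midpoints* inside
ground-truth repeat intervals by the factor ρ (default 8); the input
library is uniform; ρ = 1 makes the two indistinguishable. Read ids
encode the true origin and the midpoint-in-repeat flag, so tests compare
against the exact weight-vector expectation rather than an approximation.
No sequencing-error model, quality simulation or PCR duplication is
included; the mock/IgG fraction is treated as input-like.

**qPCR panel.** The synthetic qPCR table draws mock amounts lognormally
around 1 and antibody amounts at the target's true fold times lognormal
noise (σ = 0.15 by default). The default panel uses the study-scale folds
7.3 / 12.8 / 8.0 / 6.1 for the centromeric targets, 3.0 for the
retrotransposon target with a larger σ = 0.5 (so its significance is
marginal, as a weakly/noisily enriched target behaves), and 1.0 for the
non-centromeric negative control.

## Monomer decomposition

**Period detection** maximizes the self-match fraction
m(p) = #{i : s[i] = s[i+p]} / (|s| − p), preferring the smallest p within
0.02 of the maximum, because every multiple of the true period scores
identically on clean arrays. The pipeline searches p ∈ [10, 500]. A
caveat follows from the near-tie window: on an HOR array the lag equal to
k·L scores ≈ variant_divergence higher than the monomer lag L, so with
unbounded search the detector would return the HOR unit length rather
than the monomer; capping the search at 500 bp excludes multiples of the
413-bp monomer. For short-monomer families (92 bp) with HOR structure the
same effect would return 184 bp — HOR-of-short-monomer arrays are outside
the default pipeline's conditions and noted as a limitation.

**Consensus derivation** chunks the array into period-length windows,
aligns each chunk to a reference by its best circular rotation, and takes
the per-column majority (ties toward the lexicographically smaller base).
The reference is the *medoid* of the first ten chunks — the chunk with
the highest total best-rotation agreement with the others — because a
chunk spanning a truncated copy is a phase mosaic and would poison the
consensus if used as reference.

**Tiling decomposition** is a greedy left-to-right scan. At each cursor
the consensus is aligned to the window [cursor, cursor + 2L] by an
anchored affine-gap DP (match +1, mismatch −1, gap open −2, extend −1)
with both left ends fixed and both right ends free. Three numerical
devices matter:

* *Band.* The path is constrained to |window offset − consensus offset|
  ≤ max(10, 0.1 L). Under this scoring, gapped alignment of unrelated DNA
  drifts mildly positive, so an unconstrained optimum can wander through
  the neighbouring copy via long spurious gaps; genuine monomer homology
  never strays far off-diagonal. The band also makes a window of
  L + 2·band equivalent to the nominal 2L window, which is what the
  implementation computes.
* *Drift-penalized endpoint.* The number of consensus bases consumed is
  chosen to maximize (best row score) − 0.45·(bases consumed). Unrelated
  in-band sequence still climbs at ≈ +0.1 per consensus base while true
  homology climbs at ≥ +0.8 at usable identity, so the penalized score
  peaks where homology ends — an absolute-score rule cannot find that
  point. An endpoint consuming the full consensus is preferred within a
  slack of max(4, 0.02 L), which covers the few points gained by trimming
  mutated terminal bases without letting a genuine truncation be forced
  through the whole consensus.
* *Junction repair.* A truncated copy can still absorb a few
  chance-matching bases of the following copy (visible as a leading
  consensus offset on the next hit), or lose its own mutated tail
  (visible as a leading window gap on the next hit); in both cases the
  junction is re-placed from the next hit's leading offset. With all
  three devices the canonical 209/252/317 partials are recovered exactly
  across test seeds.

Hits shorter than 0.9 L are flagged partial, shorter than 0.3 L
discarded, and accepted at identity ≥ 60 % (identity = matches /
alignment columns over the aligned span). The window between the partial
and discard thresholds comfortably contains the canonical partial
fractions (0.51–0.77 L).

## Variant labeling and HOR calling

`cluster_variants` is deterministic greedy centroid clustering in array
order (assign to the first centroid at ≥ threshold, else open a cluster;
relabel by size, A = largest). Its default threshold of 95 % suits
low-noise monomer sets. At the default simulation noise the within-variant
copy-to-copy identity is only ≈ 89–90 % (two independently mutated copies
differ at ≈ 2·sub_rate) while cross-variant identity is ≈ 83 %, so the
pipeline clusters at 87 % — between the two populations — and then runs
`refine_variant_clusters`: clusters holding ≥ max(2, 5 % of monomers)
members are kept as candidates, each gets a column-majority consensus
from its modal-length members, and every monomer is reassigned to the
nearest candidate consensus. A consensus is far closer to its variant
than any single mutated copy, so the refinement removes the spurious
singleton clusters that single-copy centroids produce.

`infer_hor` scores each unit size k = 1..5 by the symbol autocorrelation
c(k) — the fraction of unmasked position pairs (i, i+k) with equal
symbols — and calls the smallest k with c(k) ≥ τ (default τ = 0.8);
partial positions are masked and excluded from the counts. If no k
passes, the argmax-c(k) unit is returned flagged low-confidence. If the
modal unit pattern is itself periodic (e.g. "AAAA" at k = 4, which can
pass τ under symbol noise when c(1) dips just below it), the call
collapses to the pattern's minimal string period; noise-free input can
never trigger the collapse, preserving exact equivalence with brute-force
minimal-period search.

`segment_and_call` allows at most one changepoint per array (at most two
HOR variants coexist on a chromosome). Local unit sizes are estimated in
sliding windows of 12 monomers; a changepoint is declared where the modal
windowed k differs between the two flanks with ≥ 75 % modal agreement on
each flank (strict run equality is too fragile at the ~2 % symbol-noise
level the default conditions produce, because windows straddling the
junction yield unstable local calls). The boundary is then refined
exactly by maximizing c(k_left | left segment) + c(k_right | right
segment) over candidate split points — absorbing foreign symbols into
either segment depresses its consistency, so the sum peaks at the true
junction (within ±3 monomers in the constructed-junction test, exact on
the default two-variant chromosome).

Subfamily classification is by monomer length alone (92 → CentGm-1,
91 → CentGm-2, 395–437 → CentGm-4), matching how the subfamilies are
defined by conserved monomer-length change; motif-level classification is
an open extension.

## Phylogenetics

The star alignment aligns each monomer globally to the family consensus
and projects onto consensus columns (insertions relative to the consensus
are dropped); monomers are near-consensus-length, so the projection loses
little. Distances use pairwise gap deletion. The TN93 estimator uses the
two observed transition proportions, the transversion proportion, and
base frequencies pooled over the two rows of each pair (an implementation
detail that differs from tools which pool over the whole alignment);
any non-positive logarithm argument raises a saturation error, and
saturated bootstrap replicates are dropped and counted. No gamma rate
heterogeneity is applied. Neighbor joining is the canonical Saitou–Nei
algorithm with lowest-index tie-breaking and negative branch lengths
clamped to zero with the excess moved to the sibling. Bootstrap supports
are bipartition frequencies over column-resampled replicates (default
1000; pipeline runs use fewer for speed) and are written as internal node
labels in Newick.

## Enrichment statistics

Reads are assigned to repeat families by exact canonical 21-mers against
the circularized reference monomer (the monomer plus its first k−1 bases,
so junction-spanning k-mers of a tandem array are indexed); k-mers shared
between families are removed from all of them. A pair goes to the family
sharing the most k-mers over both mates; zero or tied counts leave it
unassigned. ER is computed on library *proportions* —
(chip_count/chip_total)/(input_count/input_total) — making it invariant
to sequencing depth; a raw-count ratio would conflate depth with
enrichment. Families below 0.01 % abundance in both libraries are
dropped; retention requires ER strictly greater than 2.0. Under
midpoint-weighted sampling the expected ER at repeat fraction f is
ρ/(ρf + 1 − f) → ρ as f → 0; the enrichment recovery test uses f ≈ 0.9 % in a
5 Mb genome with ~22 kb arrays, where the closed form predicts 7.54 for
ρ = 8 and reads overlapping array edges (assigned in both libraries at
flank rate) cost a few further percent — the measured pooled mean is
within 10 % of ρ.

The qPCR path computes per-replicate RE = antibody/mock, its mean and SE,
and compares each target's REs against the negative control's with a
Welch (unequal-variance) t-test — the safer default at n = 4 replicates —
labelled ** for P < 0.01 and * for P < 0.05. Degenerate inputs follow
fixed conventions: zero variance in both groups gives p = 1 for equal
means and p = 0 (flagged) otherwise. Whether the original assay paired
replicates across reactions is not stated; the test here is unpaired.

## Reproducibility and problem sizes

A single pipeline seed fans out to per-stage seeds by fixed offsets, so
stages rerun in isolation reproduce their outputs; identical seeds give
byte-identical FASTA/FASTQ/TSV. Every run writes a manifest (config hash,
seed, version) and run.log. Problem sizes in the shipped tests — 36-copy
arrays, 20-chromosome karyotypes over 10 seeds, 20 000 read pairs per
library over 10 seeds, bootstrap 200 where supports are asserted — were
chosen so the full suite completes in a few minutes on one CPU while
keeping every statistical check at ≥3σ separation from its threshold.

## What passing tests do and do not show

The generator produces substitution/indel noise on random-sequence
consensus monomers with ideal tandem structure, uniform flanks and
error-free reads. Passing recovery tests therefore demonstrates the
correctness of the algorithms under controlled divergence, not
performance on real centromeres, which add sequencing error, transposon
insertions nested in arrays, array-internal gradients of divergence,
strand inversions (v1 assumes forward orientation throughout) and
assembly artifacts. Real-data constants — the published mean pairwise
similarities around 70 %, cluster counts, and per-chromosome HOR tallies
— depend on the deposited genomes and are intentionally not asserted;
the similarity value serves only as a plausibility window for the
simulated divergence checks.
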