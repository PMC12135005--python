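# Methods

## Model and estimand

Every copy of a derived allele descends from the single haplotype on which
the mutation arose. Around the focal site, all k carriers therefore share a
haplotype inherited from their most recent common ancestor; the depth of
that ancestor, the time of first coalescence t_c (generations before
present), is the estimand and serves as a proxy for allele age. For common
alleles t_c lies below the mutation's true age (the mutation arose on the
branch above the carriers' MRCA), which is the main driver of the
underestimation of old alleles that the evaluation stage measures. For a
singleton, t_c is the time at which its lineage first coalesces with any
other sampled lineage; the mutation age lies below that, so the youngest
alleles tend to be overestimated.

## The msh observation

For k ≥ 2 the maximum shared haplotype is the allele-level tract: from the
focal position outward, per side, to the nearest assayed site at which the
carrier set is not monomorphic (some pair of carriers differs). It is the
maximal region over which all copies still share one haplotype, is
identical for every copy, and the focal site itself is excluded from the
comparison. For k = 1 the tract is measured against the single
best-matching partner among all other haplotypes (maximum combined
left+right physical length; ties go to the lowest haplotype index, which
leaves the estimate unchanged). A side with no discordant site before the
region boundary is censored at the boundary ([1, L]).

An alternative per-copy reading — each copy paired with its *nearest*
carrier — was evaluated and rejected: each copy's tract then reflects the
shallowest pair coalescence, which shrinks with k while true age grows with
k, and the resulting estimates anticorrelate with truth across the
frequency spectrum (Spearman ≈ −0.2 at the benchmark scale, versus ≈ +0.86
for the allele-level tract).

## Likelihood and MLE

Tract ends arise from recombination or mutation anywhere on the two lineage
paths from tract to ancestor, both with intensity proportional to t_c per
unit of their respective lengths. With weighted exposure
S = μ·(ℓ_left + ℓ_right) + (g_left + g_right) (physical bp and Morgans;
cM/100 = Morgans, treated as expected crossovers per generation) and n
observed ends, events are modeled as Poisson with rate 2t per unit S, so up
to constants ℓ(t) = n ln t − 2tS and t̂_c = n/(2S), verified against
numeric maximization to 1e-6 relative error. Censored sides contribute
exposure but no event; with n = 0 the likelihood is maximized at t → 0 and
the estimate is flagged undefined and excluded downstream (never floored).
Observation lists pool through a composite rule (`pooled_mle` default —
sums n and S; `min`/`mean` reduce per-copy MLEs); for k ≥ 2 the per-copy
observations coincide, so all rules agree there.

## Singleton phasing

Statistical phasing cannot place singletons, so before estimation each
singleton is re-placed on whichever of its carrier individual's two
haplotypes shares the longer two-sided tract with its best match among the
*other individuals'* haplotypes (the carrier's own sibling copy is excluded
from the comparison — against it the two placements always tie wherever the
individual is homozygous, degenerating the rule to a coin flip). Exact ties
are broken by a fair coin seeded per variant position. Placements are
decided against the unmodified input matrix, so the result is independent
of the order singletons are visited.

## Whole-exome adjustment

With assayed sites confined to exons, a tract is observed to end at the
first discordant exonic site although the terminating event lies somewhere
in the unassayed gap before it. Each non-censored tract end is therefore
re-drawn uniformly on the open gap between the exon where the tract was
observed to end and the next exon toward the focal site, and S is
recomputed from the drawn position. Ends in the focal site's own exon
(empty gap) and censored ends are unchanged. A tract end outside the mask
is rejected as a signal that non-exome data were passed in exome mode.
Intervals are merged on load (including bookended ones) so every inter-exon
gap has positive width.

## Randomness

One master seed fans out to named sub-seeds through a SHA-256 counter
scheme (`_rng.subseed`): simulation (ancestry, mutations, branch-age
fallback), singleton phasing (per variant position), and adjustment draws
(per variant position and side). Draws are therefore independent of
iteration order and individually replayable; all derived seeds lie in
[1, 2^31 − 1]. In the paired pipeline the two arms share the simulation and
the phasing seed, so the WES arm is literally a masked copy of the WGS arm
and the comparison is paired; with a mask covering the whole region the two
arms produce identical reports.

## Synthetic data

The simulator emulates two neutral scenarios: a constant-size panmictic
population (diploid Ne = 10,000, μ = 1e-8/bp/gen) and the Gutenkunst et al.
(2009) three-population out-of-Africa expansion (ancestral Ne = 7,300,
μ = 2.35e-8) sampled from the CEU-like deme, built directly as an msprime
demography. Mutations use a binary 0/1 model so polarity is exact; no
sequencing error or mispolarization is injected. True ages are the
simulator-recorded mutation times; if a backend leaves a time unknown it is
drawn uniformly on the branch interval (seeded). Sites hit by more than one
mutation violate the infinite-sites assumption and are removed before
analysis; non-segregating sites are dropped. Recombination comes from a
HapMap-format genetic map (cumulative-cM column authoritative, terminal
clamping ⇒ zero recombination outside the anchored range) or a flat rate.
What the generator does **not** emulate — genotyping error, phasing error
beyond singletons, gene conversion, selection, mutation-rate heterogeneity —
means passing tests demonstrate correct behavior of the pipeline under its
own model assumptions, not performance on real cohorts.

## Scales and defaults

The reference study conditions are 7,242 sampled haploid genomes over a
51 Mb chromosome-22-like region. The package's standing benchmark uses a
scaled configuration chosen to keep full paired runs interactive: 500
genomes over 5 Mb, flat recombination 1e-8, and a synthetic exome mask of
200 bp exons every 10 kb (2% coverage, the order of genome-wide exome
density). At that scale the paired benchmark reproduces the qualitative
full-scale findings: strong positive rank correlation on both arms, WGS
consistently above WES, near-zero log bias on WGS, and strong
underestimation of alleles older than ~10,000 generations (most pronounced
on WES, where missing inter-exon discordances lengthen apparent tracts).
Sample-size sweeps are available through `run-all --n-grid`.

## Numerical and interface choices

* Coordinates: variant positions 1-based (VCF dialect); BED 0-based
  half-open; a variant at position p is exonic iff start ≤ p−1 < end.
* VCF export: phased, REF = ancestral (`A`), ALT = derived (`T`), diploid by
  default (consecutive haplotype pairing; haploid available), byte-level
  deterministic.
* Logs use base e throughout (recorded in every report); correlations are
  base-invariant, RMSLE/bias scale by a constant.
* Frequency bins are half-open on the left, closed on the right; bin
  membership uses exact integer arithmetic (bin = ⌈100k/n⌉), so for
  n = 7,242 the sub-1% bin is exactly k ∈ 1..72. Empty bins are emitted
  with n = 0 and null statistics.
* Undefined or nonpositive estimates are excluded from evaluation with the
  count reported.
* Numba kernels implement the discordance scans; everything else is
  numpy/pandas/scipy.

## Known limitations

* t_c is a lower-bound proxy for allele age; no correction for the gap
  between the carriers' MRCA and the mutation time is attempted.
* The exome adjustment assumes the terminating event is uniform on the
  inter-exon gap; the true distribution depends on local rates and t.
* The WES arm inherits the simple-model assumption that exome capture is
  exact (no off-target reads, no coverage variation).
* Selection (e.g. background selection) is out of scope for the simulator.
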