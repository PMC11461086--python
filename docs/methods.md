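# Methods

This note describes the models the package implements, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real data.

## Synthetic nuclear panel

The generator is a hierarchical Balding–Nichols model. Each site draws an
ancestral alternate-allele frequency uniformly from the configured
minor-allele band (default 0.05–0.5) or its mirror image. Population
frequencies descend in two stages — river, then spawning season — each stage
drawing from Beta(p(1−F)/F, (1−p)(1−F)/F) around its parent frequency.
Genotypes are two independent allele draws (Hardy–Weinberg within
populations). Under this parameterisation the Weir–Cockerham estimand for a
pair of daughter populations equals the stage's F, which is what makes
simulated differentiation targets directly verifiable.

Defaults are the study conditions: four populations (James and Great Pee
Dee rivers × spring and fall runs) of 25 diploids, 45 603 variant sites,
between-river F = 0.0060, between-season F = 0.0079. Because the data do not
resolve whether rivers or seasons split first, both topologies are exposed
(`split_order`), with river-first as default.

Ancient samples are fresh diploids drawn by default from the pre-split
ancestral pool — the null hypothesis that they pre-date the modern seasonal
structure — or, by override, from a named modern population (the
alternative, e.g. a fall-run origin). Each is pseudohaploidized (one allele
sampled per site; heterozygotes contribute each allele with probability
1/2) and masked uniformly at random to the configured missingness (default
1 − 503/45 603 ≈ 98.9%, the best-case archaeological recovery). Masking is
uniform: no deamination-damage or fragment-length modelling, which is out
of scope here (damage authentication belongs upstream of genotype data).

## Synthetic mitogenome alignment

A Kingman coalescent genealogy with infinite-sites mutations (Poisson per
branch at `mito_mu` = 10⁻³ per site per coalescent unit over 16.5 kb,
giving ~150 segregating sites and π ≈ 0.002 per site across 70 tips —
typical mitogenome diversity for a long-lived fish). The alignment carries
a designated "historic" clade (default 28 of 70 tips) built as its own
subtree with branches stretched ×2, emulating the longer branches and
greater haplotype richness of a clade that preserves pre-collapse
variation. The six ancient tips each graft independently onto a random
lineage of the modern clade subtree and receive one coalescent unit of
private branch length: ancient lineages are *dispersed* across the clade
rather than forming their own recent subcluster, which is the observed
configuration the analysis conditions on. A configurable fraction of
modern tips (default 0.45, applied within group × clade cells) are exact
copies of a cell-mate, producing the terminal polytomies characteristic of
post-bottleneck founder expansion.

The clade is carried as an input flag on the alignment, never inferred:
tree inference is out of scope, and the clade-restriction test conditions
on a given clade exactly as the source analysis conditions on its
phylogeny.

What passing tests on these alignments do **not** show: robustness to
alignment error, recombination (assumed absent for mtDNA), selection,
sequencing error, or reference bias. The generator produces clean,
equal-length, fully resolved haplotypes; real mitogenome alignments need
the complete-deletion handling exercised separately in the IO tests.

## Filters and LD pruning

Site filtering keeps sites genotyped in ≥ 50% of samples with MAF ≥ 0.05
(MAF over called alleles only, boundary values retained); sample filtering
tolerates up to 90% missingness. Site filtering is applied before sample
filtering in the pipeline; the reverse order is available by calling the
functions directly, since neither order is canonical.

LD pruning follows windowed variance-inflation semantics ("50 5 2"):
within each 50-variant window advanced by 5, variants are scanned left to
right and removed when their VIF = 1/(1−R²) against the other
still-retained window variants exceeds 2. Dosages are mean-imputed; a
ridge term of 1e−8 guards singular regressions; removal order is fixed by
the scan so the result is deterministic, and re-pruning a pruned panel
removes nothing.

## PCA and Procrustes projection

PCA uses Patterson scaling: dosages centred at 2p and divided by
√(p(1−p)), missing values mean-imputed, zero-variance sites dropped with a
warning. Component signs are fixed by forcing each component's
largest-magnitude loading positive, making scores fully reproducible.

Fragmentary samples are projected by reduced-panel re-PCA: restrict the
reference to the target's genotyped sites (refusing below 50 shared sites),
recompute the PCA there, find the least-squares similarity transform
(rotation — reflections allowed, since PC signs are arbitrary — plus
isotropic scale and translation) from reduced-panel scores to full-panel
scores, and carry the target through it. Pseudohaploid calls enter as
homozygous dosages {0, 2}: a single sampled allele carries no
heterozygosity information. An alternative (loading-projection with
shrinkage correction) exists in the literature and is not implemented
here; for complete targets the two coincide, and the self-consistency test
(complete samples reproject onto their own scores within 1e−6) pins that
anchor.

## Weir–Cockerham F_ST

The two-level variance-components estimator with the multi-site value
formed as a ratio of sums, Σa/Σ(a+b+c). Per-site components may be
negative; sites monomorphic across both populations contribute zero. A
delete-one-site jackknife provides the standard error used by the recovery
tests. Sample sizes are per-site called counts, so missingness is handled
per site.

"Relative nuclear diversity" is summarized as mean expected
heterozygosity 2p(1−p) over called sites — a deliberate, simple proxy for
tool-derived "relative diversity" panels whose exact statistic varies;
it is compared across populations with Welch's t on per-site values.

## Pseudohaploid likelihood assignment

Population frequencies are additively smoothed, f = (alt + s)/(called + 2s)
with s = 0.5 (Jeffreys-style), so no allele has frequency exactly 0 or 1
and log-likelihoods stay finite; a site with no called alleles is flagged
uninformative and skipped. The per-site contribution of a pseudohaploid
call is ln f (alternate) or ln(1−f) (reference). "Normalized" lnL is the
per-site mean — the interpretation that makes values comparable across
variant sets of different sizes, which is the evident purpose of
normalizing.

A sample-optimized variant set is the intersection of the target's called
sites with panel sites passing MAF ≥ 0.1 and missingness ≤ 10%. Samples
are summarized by downsampling: draws of 200 sites without replacement
(100 draws for the main variant set, 50 per sample-optimized set), each
contributing its per-site mean lnL. Draw indices are sorted before
summation so that an exhaustive draw is bit-identical across replicates.

The reference distribution for a population is the per-member mean draw of
each modern member, scored with leave-one-out frequencies. Leave-one-out
is applied *consistently*: each member's variant set is recomputed with
that member excluded from the panel's MAF/missingness statistics as well.
This matters. If members are scored on a site set whose frequency filter
their own genotypes helped satisfy, filter-passing boundary sites are
enriched for the member's minor alleles, which depresses member scores by
roughly 0.004 per site in the default configuration — enough to shift the
null Z of an outside target by ~+0.8 standard deviations and to mask most
of the real membership deficit of a non-member. With consistent
leave-one-out the null Z is centred (mean ≈ 0.02 over 200 replicates) and
an ancestral-pool target at the default differentiation shows E[Z] ≈ −2.2
against either seasonal population.

The Z-test places the target's mean draw on the reference distribution:
Z = (x̄ − μ_ref)/σ_ref, with one-sided p = Φ(Z) for the membership-deficit
direction (two-sided by flag). The 10%-quantile mode replaces μ_ref with
the empirical 10% quantile of the reference values — one reading of a
marginal-quantile comparison; because such constructions vary between
analyses, both modes are reported and the mode is recorded in the result.
Whether reference distributions should pool
draws instead of per-sample means is likewise unstated; per-sample means
are used because they estimate the between-individual spread that the
membership question is about.

Power note: at ~500 usable sites (the archaeological best case) the
per-site deficit of an ancestral target (~0.013) meets a reference spread
of ~0.025, so single-sample rejections are not expected there; the power
checks in the acceptance suite therefore use complete pseudohaploid
targets, isolating the machinery's calibration and power from the
missingness question, which the projection tests cover.

The rank-sum test delegates to the Mann–Whitney implementation: exact
enumeration when the smaller sample has ≤ 10 values and no ties, otherwise
the tie-corrected normal approximation.

## Mitogenome diversity and permutation tests

Columns containing a gap, N, or any ambiguity code in an analysed sequence
are excluded (complete deletion, the convention of the classical diversity
software); a pairwise-deletion option pools differences as a ratio of sums
over per-pair resolved columns. π is mean pairwise differences per used
site; θ_W = S/(a₍ₙ₋₁₎ L); haplotype diversity uses exact full-length
identity over used columns with the n/(n−1) correction.

Clade-internal resampling draws sets of k = 6 modern clade members
(without replacement, 10 repetitions by default) and compares their π to
the ancient members' π by a one-sample t-test; a zero-spread resample is
flagged degenerate rather than producing a spurious statistic (and returns
t = 0, p = 1 when it exactly equals the reference). Between-group
diversity differences use label permutations with
p = (#{|Δperm| ≥ |Δobs|} + 1)/(reps + 1); the +1 correction means p never
returns 0, and exact ties count as exceedances (with a 1e−12 float guard).

The clade-restriction test is exchangeable-label placement: the count of
focal (ancient) tips inside a fixed clade is hypergeometric, so the exact
upper tail is always reported; a seeded permutation estimate with the same
+1 correction is reported alongside and converges to it. Shuffling tip
labels on a fixed tree and resampling clade membership reduce to the same
null under exchangeability, which is what is implemented.

## Determinism and problem sizes

Every stochastic operation takes a seed or Generator; the pipeline derives
all stage streams from one global seed, and outputs contain no timestamps,
so identical configuration yields byte-identical artifacts.

The test suite runs the statistical checks at the following scales, chosen
to give decisive margins at desk runtime: F_ST recovery at 5 000 sites ×
25 diploids per population, averaged over three fixed seed replicates per
target (jackknife SE ≈ 2×10⁻⁴ for the mean, so targets 0.0051/0.0060/
0.0079 order reliably); assignment power and calibration at the full
45 603-site panel (100 replicates) and 3 000-site panels (200 replicates)
respectively; projection recovery at 20 000 sites with 99% target
missingness (100 replicates); diversity oracles exactly, at closed form.

## Known limitations

- Uniform missingness understates the site-bias structure of real ancient
  DNA (coverage clustering, damage-driven miscalls).
- The assignment model treats sites as independent; linked sites inflate
  the effective information of a 200-site draw slightly less than assumed,
  which is why the pipeline prunes for LD first.
- Mean expected heterozygosity is a coarse nuclear diversity summary,
  adequate for rank comparisons between populations only.
- The mitogenome simulator's coalescent times are in arbitrary units with
  no clock calibration; nothing here estimates effective population size
  over time (the percent-decline helper only formats externally obtained
  trajectory endpoints).
- Single-sample assignment at ≳99% missingness is underpowered by design
  of the data, not of the method; conclusions at that coverage should rest
  on grouped tests and projection, as the analyses here do.
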