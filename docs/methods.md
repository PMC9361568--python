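# Methods

This note documents the models implemented in `admixne`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Admixture simulator (`admixne.simulate`)

**Model.**  One chromosome per run (multi-chromosome cohorts share a
pedigree via `simulate_admixture_genome`; otherwise chromosomes are
independent runs).  The admixed population holds N diploids per generation.
Each offspring draws two parents; a parent slot is filled by a migrant
diploid of source ancestry *s* with the per-generation fraction of any
active gene-flow event, otherwise by a resident of the previous generation
(distinct residents; no selfing).  Migrant diploids are drawn with
replacement from the founder panel of that ancestry.  Each offspring
haplotype is one gamete of one parent: crossover count ~ Poisson(map
Morgans), positions uniform on the genetic axis (no interference — the
standard choice when the copying model is otherwise unconstrained).  Blocks
carry founder-haplotype identity throughout, so truth ancestry tracts and
truth IBD are exact, not inferred.

**Gene-flow accounting.**  An event starting g₀ generations ago feeds the
g₀ mating rounds that produce the final g₀ cohorts, so a single event with
fraction f gives an expected present-day migrant fraction 1 − (1−f)^g₀.
With several concurrent events the expectations follow the coupled
recursion m_s ← f_s + (1 − Σ f) m_s, implemented in
`GeneFlowSchedule.expected_fractions`; for the default three-way schedule
(European 1 %/gen for 8 generations, West-African 2 %/gen for 14, Khoe-San
base) the European expectation is ≈ 0.072 — slightly below the
single-event closed form 1 − 0.99⁸ ≈ 0.077 because concurrent West-African
gene flow dilutes it.

**Founders.**  Balding–Nichols differentiation: ancestral frequency
p ~ U(0.05, 0.95) per site, per-ancestry frequency
Beta(p(1−F)/F, (1−p)(1−F)/F).  Default panel size is 11 diploids per
ancestry.  Sites are fixed (no mutation); positions uniform and
deduplicated.

**Truth IBD.**  `extract_true_ibd` reports maximal intervals over which two
haplotypes carry the same founder haplotype, merging contiguous matching
runs across founder-id changes (a junction inherited by both copies from a
common ancestor does not interrupt descent).  Genetic lengths come from the
simulation's own map.

**Tract corruption.**  `corrupt_tracts` emulates local-ancestry miscalls:
window seeds follow a Poisson process at a per-Mb rate; each window
(default 500 kb) shifts every underlying label by a random nonzero offset
in the alphabet, so a flipped label always differs from the truth and the
tiling invariant is preserved.  This mimics block-wise miscalling, not the
marker-level posterior smoothing of a real local-ancestry caller.

**What the generator does not emulate:** mutation, phasing/switch error in
the haplotypes themselves, sex-specific maps, crossover interference,
selection, and overlapping-generation demography.  Tests passing on these
cohorts validate the pipeline's logic and calibration; they do not certify
accuracy on real data with those extra error modes.

## Local-ancestry scoring (`admixne.tracts`)

Accuracy is length-weighted over bp (invariant to marker density) and
haplotypes are compared as phased — the simulator controls phase, so no
diploid-unordered rescoring is needed; for real data with switch error the
phased comparison is a lower bound.  Global accuracy, per-ancestry recall
(agreeing length within truth tracts of an ancestry over that ancestry's
truth length) and per-individual inferred ancestry fractions are reported;
both the genome-weighted and the individual-averaged global accuracy are
computed since averaging conventions differ between studies.

## IBD handling (`admixne.ibd`)

Gap merging fuses same-pair segments whose gap passes both a genetic
(default 0.6 cM) and a physical threshold; no genotype-discordance rule is
applied because genotypes are deliberately not carried at this stage.
Ancestry assignment is by **dual coverage**: for each ancestry, the length
of the segment over which *both* haplotypes carry it; the segment takes the
ancestry whose dual-coverage fraction is ≥ `min_fraction` (default 0.9),
ties and sub-threshold cases are `unassigned`.  Segments are labelled
whole, never split at ancestry switch-points — splitting would distort the
length spectrum the N_e model consumes.  Partitioning drops `unassigned`
and segments shorter than 3 cM, the conventional reliability floor for IBD
detection.  For per-ancestry spectra the effective pair count is
C(H, 2) scaled by the mean pairwise dual-ancestry genome fraction,
computed exactly from carrier counts; this is what makes a per-ancestry
N_e interpretable and it is recorded with the outputs.

## Recent N_e from the IBD length spectrum (`admixne.ne`)

**Expectation.**  Coalescence mass
q_g = (2N_g)⁻¹ Π_{k<g} (1 − (2N_k)⁻¹); conditional on g, segment-length
density on a chromosome of C Morgans is
(2g)²(C−u)e^(−2gu) + 2·2g·e^(−2gu) for u < C plus an atom e^(−2gC) at C
(total 2gC + 1 segments, as it must be).  When chromosome lengths are not
supplied the interior approximation L(2g)²e^(−2gu) over the pooled genome
length is used.  The finite-chromosome form matters at these scales: on
35 cM chromosomes the end terms shift enough mass into the 3–20 cM window
to bias fits by tens of percent if ignored.  Coalescence beyond the fitted
grid is closed by a constant epoch at N_{g_max} (`tail="constant"`;
`"truncate"` is available).

**Fit.**  Poisson negative log-likelihood of the binned counts over log
N_g plus a smoothness penalty λ·(total segment count)·Σ(Δ log N)².
Scaling the penalty with the data makes the fit exactly invariant under
joint scaling of counts and pairs and keeps the effective smoothing level
independent of study size; λ defaults to 0.02 per segment, set by
calibration on constant-size recovery experiments.  The objective is
normalized per segment; optimization is L-BFGS-B with an analytic gradient
(verified against finite differences in the tests), started from a flat
method-of-moments size, bounds 2 ≤ N ≤ 10⁸, relative tolerance 1e-6.
Default bins: 0.5 cM from 3 to 20 cM plus one open tail; default grid
4–50 generations.

**Close relatives.**  Very recent coalescences (siblings, avuncular pairs)
produce long segments the 4–50 grid cannot explain.  Two mitigations are
provided: `exclude_related` drops haplotype pairs sharing more than a
fraction of the genome (default 10 %, appropriate for large cohorts), and —
used by the recovery experiments, where the sample is a sizeable fraction
of a tiny population and any such threshold would remove a third of all
pairs — extending the fit grid down to generation 1 so genealogical
coalescences get their own parameters while generations 4–50 are reported.

**Known limitation.**  The composite-likelihood expectation treats pairs
independently.  In very small populations (N of a few hundred) the realized
pedigree is shared by all pairs: bin counts are overdispersed, and total
counts in a single cohort can sit 10–30 % away from the expectation.
Recovery experiments therefore average fitted log-trajectories over
replicate cohorts; single-cohort fits at N = 200 carry a downward bias of
roughly 10–25 % with seed-to-seed wobble of similar size.

**Bootstrap.**  Chromosome-chunk resampling with replacement; percentile
2.5/97.5 bounds per generation, point estimate from the full data,
deterministic given the seed.

## Demography merge (`admixne.demography`)

The recent (IBD-based) and distant (sequence-based) trajectories must not
overlap; the gap is bridged by `"hold"` (last recent value, concatenation
semantics) or `"geometric"` (default; log-size linear in log-generation
between the boundary values, sampled at 16 geometrically spaced knots, with
`bridge_value` giving the exact analytic bridge).  Sizes are treated as
diploid N_e on both sides; a years column is only accepted with an explicit
generation time.  Output is a two-column linear CSV plus an epochs JSON
(sizes and change times).

## Genetic maps (`admixne.maps`)

Internal representation: contiguous 0-based half-open intervals with
per-bp per-generation rates; cumulative cM is exact from the rates, and the
HapMap dialect's Map column is cross-checked on read to 1e-6 cM.  Binning
anchors at position 0 and computes mean rate per bin from cumulative-cM
differences, so the bin values conserve total cM exactly and are
independent of interval alignment; uncovered bins are missing (NaN), never
zero, and excluded pairwise from correlations.  Spearman correlation uses
mid-ranks and requires ≥ 100 jointly covered bins by default; clustering is
average linkage on 1 − ρ.  Hotspot calling compares each interval's rate to
the length-weighted median rate in a flanking window (default 100 kb,
fold 10, minimum width 500 bp) — scale-invariant by construction; two-map
concordance counts reciprocal overlap ≥ 50 %.

**Sibling maps.**  `derive_sibling_map` keeps each hotspot independently
with probability `shared_fraction` and replaces dropped ones at uniform
positions, preserving the count.  Keep decisions and replacement positions
are coupled to per-hotspot uniform draws, so siblings at increasing shared
fraction (same seed) form a nested family — the right construction for
monotonicity experiments.  For sensitivity experiments the base map
concentrates roughly half its genetic length in hotspots (0.5 cM/Mb
background, 1.5 hotspots/Mb at 400-fold over 2 kb), the empirically
realistic regime in which fine-scale map differences can move
haplotype-length integrals; with weak hotspots all siblings are nearly the
same map and the comparison is vacuous.

## iHS (`admixne.ihs`)

EHH among the n carriers of a core allele is Σ_h C(n_h, 2)/C(n, 2) over
distinct extended haplotypes, computed by incremental group refinement
(numba-accelerated when available, with an identical pure-python fallback);
sites monomorphic in the full sample are skipped as uninformative, which
also merges their physical gaps.  Curves stop when EHH < 0.05.  iHH is the
trapezoidal integral of EHH over genetic distance, truncated by linear
interpolation at the 0.05 crossing; physical gaps > 200 kb censor the
site, gaps > 20 kb are down-weighted by 20 kb/gap.  These defaults mirror
the conventional scan-tool settings and are all exposed.
iHS_unstd = ln(iHH_ancestral/iHH_derived) (positive after standardization
marks extended derived haplotypes; top-|iHS| results are
convention-invariant), standardized within 20 equal-width derived-frequency
bins (bins with < 2 sites merge with their nearest occupied neighbor).
Top hits take |iHS_std| at or above the (1 − fraction) empirical quantile,
ties included; candidate genes are deduplicated symbols whose (optionally
flanked) range contains a hit.  `scan_with_maps` computes every EHH curve
once and integrates it under each map, making multi-map comparisons cheap
and exactly curve-matched.

## Validation experiments (`admixne.experiments`)

Problem sizes were chosen to exercise the method end to end at desk scale:
calibration uses 20 replicate cohorts of 200 diploids; constant-N recovery
uses N = 200 with 100 diploids sampled over ten 35 cM chromosomes simulated
for 100 generations (so founder-generation truncation is negligible at
3 cM) with three replicate cohorts averaged on the log scale; the
two-ancestry experiment merges sources of N = 150 and N = 450 (100
generations) into one population of 600 for three generations with initial
composition proportional to the source sizes, so each ancestry's
coalescence rate matches its source for every generation older than the
short admixed phase, and evaluates the geometric-mean fitted N over
generations 10–40; the map-sensitivity experiment scans 64 diploids at
4000 sites over 40 Mb against a nested sibling-map family and reports
candidate-gene overlap and per-SNP Pearson r.

## Known limitations

* The N_e expectation is a composite likelihood; confidence from the
  Poisson model alone is anti-conservative — use the chunk bootstrap.
* Ancestry assignment labels whole segments; heavily admixed regions lose
  boundary-straddling segments to `unassigned`, thinning long segments near
  tract boundaries slightly.
* The simulator's truth IBD is defined by founder descent; pairs that fail
  to coalesce within the simulated horizon never become IBD, so horizons
  must comfortably exceed the oldest generation probed (100 generations for
  a 3 cM threshold).
* iHS on unphased or polarity-unknown data is out of scope.
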