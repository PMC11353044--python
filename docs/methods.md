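# Methods

`stemdrift` models and analyses the genetic drift of human pluripotent
stem-cell (hPSC) lines under serial passaging: the takeover of cultures by
clones carrying recurrent chromosomal gains, the accumulation of point
mutations in cancer-associated genes, and the statistics that separate
*cumulative* mutation load from a *changing* mutation rate.  This note
records the models, the defaults and why they were chosen, and what the
synthetic data can and cannot establish.

## The culture model

A culture is a set of clones with population fractions summing to 1.  One
passage applies, in order:

1. **Selection.** Each clone's fraction is multiplied by its fitness, the
   product of `1 + s` over its mutations, then fractions are renormalized.
   Recurrent CNVs (gain of 20q11.21, distal 1q, chromosome 12, 17q; loss
   of 18q) carry `s = s_recurrent`; rare CNVs and SNVs are neutral by
   default (`s = 0`).
2. **Drift.** Multinomial resampling of `bottleneck_size` cells — the
   effective number of replated founders after a 1:10–1:100 split.
3. **Mutation.** Each surviving clone independently spawns at most one
   child per event class with per-passage probabilities
   `p_cnv_recurrent`, `p_cnv_rare`, `p_snv`; the child starts at one cell
   (`1/bottleneck_size`) and inherits its parent's full event list.

Within-passage cell-division granularity is not modelled: the observables
are per-passage snapshots, so a discrete selection–drift–mutation
generation per passage is the natural resolution.

Because genotypes are nested along the clone tree, an SNV arising in a
clone that already carries a driver CNV hitchhikes with the driver's
sweep.  This is the mechanism by which de novo SNVs preferentially reach
detectable cell fractions in karyotypically abnormal cultures — no
explicit SNV–CNV coupling is built in (the optional
`snv_rate_multiplier_given_driver`, default 1, exists only to let users
simulate a genuine rate coupling and test its detection).

### Haplotype bookkeeping and allele fractions

Every locus starts with one copy per haplotype.  A CNV gain duplicates one
copy of one haplotype (carrying any variant already on it); a loss removes
one.  A de novo SNV enters with a single copy on its haplotype *at its
position in the clone's event order*, so an SNV acquired after a gain is a
single copy in a triplicated locus (expected AF 1/3 at full clonality),
while a germline heterozygote whose haplotype is later duplicated sits on
2 of 3 copies (expected AF 2/3).  The population allele fraction at any
passage is

    AF = Σ_k f_k · m_k / Σ_k f_k · c_k

over clones k with fraction f_k, mutant copies m_k, and total copies c_k.
For a two-population culture (mutant clone at fraction f vs diploid rest
with m0 mutant copies) this reduces to the model used by the integration
stage:

    AF = (f·m + (1−f)·m0) / (f·c + (1−f)·2)

A locus homozygously deleted culture-wide has no copy mass and the variant
is reported unobservable (AF 0).

### Simulation defaults and their provenance

| parameter | default | basis |
|---|---|---|
| `n_passages` | 50 | typical span between first and last tested passages of a line |
| `bottleneck_size` | 500 cells | order of magnitude for the effective founder population of a split; sets drift strength |
| `p_cnv_recurrent` | 0.05 /clone/passage | calibrated so ~80% of simulated lines establish a recurrent driver CNV, the published line prevalence |
| `p_cnv_rare` | 0.01 | rare CNVs appear mostly as passengers in driver clones, matching their observed co-occurrence |
| `p_snv` | 0.15 | calibrated so detected de novo SNVs average ~0.85 per sample (28 over 33 samples published) |
| `s_recurrent` | 0.3 | sweep from one cell to dominance in ~20–30 passages, the gap span between consecutive tested passages in which takeovers are observed |
| `s_rare` | 0 | rare CNVs are treated as passengers |
| germline SNVs per line | uniform 6–17 | published per-line range |
| panel | 380 genes, 100 kb loci | published panel size; positions synthetic |
| panel depth | 1500× (Poisson per site) | published target coverage |
| shallow WGS | ~113 reads per 50 kb bin | 7M 50 bp reads ≈ 0.1× genome coverage |

Per-passage event probabilities are *not* identifiable from published
summaries; they are order-of-magnitude choices fixed once against the
cohort descriptives above and documented here.  Rendered variants below
0.5% allele fraction are dropped — low-grade mosaicism below panel
sensitivity is deliberately invisible, as in real panels.

Coverage noise is negative binomial (gamma–Poisson) with an extra
dispersion parameter expressed as an added coefficient of variation
(default 0.03 above the ~9% Poisson CV of a 113-read bin).  Setting
dispersion to 0 selects a deterministic limit (counts equal their
expectation exactly), which the tests use to verify exact breakpoint
recovery.  GC bias defaults to a smooth quadratic peaking at GC 0.45 with
a 20% amplitude, user-overridable.

Random streams: one master seed; per-line, per-passage and per-purpose
substreams are derived by CRC-hashing `(line_id, passage, purpose)` into a
`SeedSequence`, so adding samples never perturbs existing ones.

### What the synthetic data does not emulate

Read-level artifacts (mappability, duplicate structure, microsatellite
noise), sequencing batch effects, sub-single-copy CNVs, whole-genome
ploidy shifts, culture-condition changes over time, and phylogenetically
structured sublines.  Passing tests therefore establish the *logic* of the
pipeline — scoring, segmentation, filtering, classification, statistics —
not robustness to platform-specific artifacts in real data.

## CNV calling from shallow coverage

GC correction fits per-GC-stratum medians (deciles, or exact values when
the track is discretized) linearly interpolated; medians make the fit
robust to CNV contamination.  Corrected counts are normalized to a unit
autosomal median — a self-normalization that makes whole-genome ploidy
shifts invisible (no panel of normals is assumed).  Scores per bin:
fold change; log2 ratio (fold change floored at a pseudocount of
0.5/median raw count); z score against the autosomal MAD × 1.4826.

Segmentation is run-based: maximal same-direction runs of |z| > 3,
bridging interruptions of up to `merge_gap = 4` sub-threshold bins, kept
at ≥ 10 bins (0.5 Mb), so the smallest published recurrent gain (0.725 Mb)
is callable while single-bin noise is not.  The gap of 4 is chosen because
a clonal single-copy gain leaves each bin sub-threshold with probability
p ≈ 0.07 at default noise, and a gap limit g splits a long segment at rate
~p^(g+1) per bin: g = 2 fragments multi-Mb segments about once per 40 Mb,
while g = 4 makes splits negligible without extending boundaries
(breakpoints are always the outermost threshold-crossing bins) or
admitting diploid false positives.  All three knobs are arguments.

Degenerate scale: a zero MAD with all bins exactly on the reference gives
z ≡ 0; a zero MAD with a deviating *minority* is the noiseless limit and
deviating bins get z = ±∞ (segments recover exactly); a deviating majority
is rejected as unusable.  X/Y bins are excluded from scale estimation and
default calling since line sexes differ.

Recurrence annotation labels a segment when its direction matches a
catalog entry and it overlaps the entry's driver locus (BCL2L1 for
20q11.21, MDM4 for distal 1q, SALL3 for 18q) or, for arm/chromosome
entries without a named driver (12, 17q), the catalog interval.  A gain in
the 20q11.21 region that stops short of BCL2L1 is deliberately *not*
labelled recurrent.

## SNV filtering

Five independent predicates (population frequency > 1% in any of gnomAD /
1000g / ESP6500 — "any" being the conservative reading; non-hotspot AF
< 3%; facility recurrence > 0.01%; alt reads < 25; gene on the exclusion
list, default CDC27).  An optional sixth removes calls inside user-supplied
exclusion regions, standing in for manual review of problematic loci.
Rule independence makes retention order-invariant and monotone under
threshold relaxation, both property-tested.  The `deleterious` flag is
consumed (SIFT-style annotation), never computed; an absent flag is
treated as non-deleterious and logged.

## Origin, trajectory, zygosity

A variant detected at a line's earliest tested rank is germline; first
detection at a later rank is de novo with that rank recorded.  "Detected"
means surviving the filter cascade in that sample, so loss and
sub-threshold mosaicism are indistinguishable — as in the underlying
assay.  Classification is provably exact for events arising at or after
the first sampled passage; events predating it are inherently
unresolvable and are the only permitted mismatch class in the
ground-truth tests.  Trajectories compare last and first detected AF
against δ = 0.15, an order of magnitude above binomial noise at 1500×
(σ ≈ 0.013); absence at the final rank after detection is "lost".
Zygosity at diploid loci uses tol = 0.10: AF ∈ [0.40, 0.60] heterozygous,
AF ≥ 0.90 homozygous (intervals exact by construction); at CNV loci a call
is "cn_adjusted" when the AF matches any copy-configuration expectation
within tolerance, else ambiguous.

## Integration and statistics

Copy number at a variant locus comes from the single overlapping called
segment (3 for a gain, 1 for a loss, 2 otherwise).  `match_af` grid-searches
mutant copies m ∈ [0, c], background copies m0 ∈ {0, 1} (restricted to 0
for known de novo variants), and clonal fraction f ∈ {0.1, …, 1.0}; an
observation is CNV-explained when the best |obs − exp| ≤ 0.10, a tolerance
matching the loose verbal matching the AF model is asked to reproduce
(0.25 vs an analytic 1/3 is explainable only through sub-clonality, which
the f-grid operationalizes).

Fisher's exact test sums hypergeometric probabilities of all tables with
the observed margins whose probability does not exceed the observed
table's (relative slack 1e-12), computed in log space; it matches exact
integer enumeration on every table with n ≤ 40.  GLMs (Poisson
log-linear for load, binary logistic for acquisition) are fit by IRLS with
step-halving and deviance-change convergence (tol 1e-8, ≤ 100 iterations).
The default p-value is Wald; a likelihood-ratio option exists because
cohorts whose early ranks have all-zero loads are quasi-separated — the
slope MLE diverges and the Wald statistic collapses toward p ≈ 1 while the
LRT remains calibrated — and the cohort-level load analysis uses the LRT
for exactly this reason.  "Load" is the count of de novo variants detected
in a sample; an "acquisition event" is a sample showing at least one de
novo variant not detected at any earlier rank.  `refit_without_outliers`
re-runs a fit with a caller-specified exclusion predicate and records the
excluded points.

Lines are pooled in all regressions (no random effect for line), mirroring
the analysis design this package reproduces; with strong per-line
clustering a mixed model would be more appropriate.  That, back-mutation,
phylogenetic subline reconstruction, and allele-specific copy number are
out of scope.

## Problem sizes used in checks

The packaged checks use 100 injected CNV samples plus 20 diploid samples
at whole-genome scale, 200 lines for origin classification, and 200
cohorts of 10 lines × 3 ranks for the statistical signature; the
acceptance script uses 60/20, 100 and 100 respectively.  These sizes give
binomial standard errors of 2–4 percentage points on the reported rates.
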