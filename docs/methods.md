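# Methods

This note records the models implemented in famseg, the conventions and
numerical choices behind them, and what the synthetic-data generators do
and do not emulate.

## Pedigree likelihood

A single autosomal biallelic locus with genotypes coded by risk-allele
dosage g ∈ {0, 1, 2}. The joint probability of a pedigree's observations
factorises into Hardy–Weinberg founder priors at allele frequency p
(default 0.001), Mendelian transmission terms P(g_child | g_father,
g_mother), and per-individual evidence: carrier tests restrict the state
space as hard evidence (carrier ⇒ g ≥ 1, non-carrier ⇒ g = 0; no
genotyping-error term, since cascade tests are treated as definitive), and
phenotypes contribute the liability-class probability — cumulative risk F
for affected individuals, 1 − F for unaffected, 1 for unknown. The
dominant model gives heterozygotes and homozygotes the same carrier
penetrance, but the three genotype states are kept so founder priors stay
exact. Under the `neutral` hypothesis every individual's phenotype uses
non-carrier penetrance regardless of genotype.

An affected individual contributes cumulative risk *by* the recorded age,
not an onset-age density. Both conventions exist in the co-segregation
literature; the cumulative form matches the survival-model penetrance used
here and is the more conservative choice. Age at diagnosis should be
recorded for affected members, age at last observation otherwise.

The sum over unobserved genotypes is computed by variable elimination on
the factor graph — equivalent to Elston–Stewart peeling on loop-free
pedigrees, and exact on small marriage loops via a greedy smallest-scope
elimination order. Intermediate factors are rescaled by their maximum and
the log-scale accumulated, so likelihoods are effectively computed in log
space and do not underflow on deep pedigrees. If an elimination step would
involve more than 10 variables (heavily looped pedigrees), the engine
falls back to exhaustive enumeration when at most 12 members are untyped
and otherwise raises — correctness over generality, since the intended
scale is clinical families of tens of members.

## Penetrance construction

Incidence tables hold events per person-year in contiguous half-open
5-year age groups [a, a+5), separately per sex and for carriers (e.g. a
Prospective Lynch Syndrome Database-style cohort) vs the general
population (e.g. Cancer Incidence in Five Continents). Cumulative risk at
the end of group k is the piecewise-constant-hazard survival model

    F_k = 1 − exp(−Σ_{j≤k} λ_j · 5).

Conventions chosen where more than one was defensible (all covered by
tests): the regression covariate for smoothing is the group midpoint; an
individual's liability class is the group containing their age, with risk
indexed at the group *end*; beyond the last tabulated group the hazard is
held constant at the last group's rate; individuals of unknown age receive
the unweighted mean of F across age groups for their (sex, carrier) class
(a person-year-weighted mean is available via `average_weighting`, but the
uniform mean is the default since averaging weights are rarely published).

**Pre-smoothing.** Raw age-specific rates from moderate cohorts are noisy,
so carrier tables can be pre-smoothed by penalized Poisson spline
regression of event counts on age-group midpoints with a log person-years
offset: a B-spline basis of dimension k (default 3, degree min(3, k−1),
interior knots at covariate quantiles) with a second-order
difference penalty; the penalty weight is selected by generalized
cross-validation over a log-spaced grid (0 and 1e−6…1e6). On one
covariate this penalized low-rank smoother is the practical equivalent of
a thin-plate-regression-spline fit. Because the basis is a partition of
unity and the constant vector lies in the penalty null space, the total
fitted event count equals the observed total (canonical-link Poisson score
identity) — verified to 1 % in tests, as is 5 % recovery of noiseless
log-linear rates and exact reproduction of data in the saturated,
unpenalized case. The IRLS is safeguarded by clipping the linear predictor
to ±30 and damping steps to max-norm 5, which handles all-zero age groups.

## Full-likelihood Bayes factor

FLB = [P(D | causal)/P(D_proband | causal)] / [P(D | neutral)/P(D_proband
| neutral)], where D_proband is the proband's own phenotype *and* carrier
status, evaluated with everyone else's evidence removed. Conditioning on
the proband's full data is what removes ascertainment bias — the family
was collected because of the proband — and makes a singleton pedigree
exactly uninformative (FLB = 1). Evidence thresholds: supporting above 8,
strong above 16; both configurable since other schemes exist. Independent
families combine by multiplication of FLBs (addition of logs).

**Sensitivity surface.** Over a grid (default 21 × 21) of
(f, e) ∈ [0.50, 1.50] × [0, 1]: non-carrier rates are scaled by f on the
hazard scale, and carrier rates are replaced by
(1 − e)·(scaled non-carrier) + e·(original carrier) — the weighted average
uses the *scaled* non-carrier rates by default (`weight_scaled=False`
switches to the originals; the two readings differ only off f = 1).
Working on the hazard scale makes e = 0 collapse carrier and non-carrier
classes exactly, so FLB ≡ 1 along that axis — a structural identity the
tests assert. The iso-FLB contour is extracted by marching squares with
linear interpolation along cell edges; corners lying exactly on the level
are nudged by a 1e−12 relative perturbation (simulation of simplicity) so
crossings are strict sign changes, and returned points re-evaluate under
bilinear interpolation to the level within 1e−6.

## IBD segment detection

Order of operations: hard filter first (PASS, both DP > 10, both GQ > 50,
both genotypes called, biallelic SNV — strict inequalities), then the
w-statistic on the *filtered* sites only. w at a site is the fraction of
same-chromosome filtered sites within ±1 Mb (the site itself included;
switchable) whose IBS state is 0; it is computed in O(n) by prefix sums
and verified against a quadratic recount. Segments are maximal runs of
consecutive sites with w ≤ 0.5 %, reported when they contain ≥ 100
variants and span ≥ 1 cM. Runs separated by even a single failing site are
not merged. Physical coordinates are 1-based inclusive (VCF); BED export
converts at the boundary. Genetic positions come from linear interpolation
of a HapMap-style map, extrapolated beyond the mapped range at the
terminal interval's rate; without a map a uniform 1 cM/Mb (the genome-wide
average) is assumed and logged.

**Resolution limit.** Near a true segment edge the ±1 Mb window mixes
segment interior (w ≈ 0) with background, where the opposite-homozygote
rate under Hardy–Weinberg is w_bg = 2·E[p²(1−p)²] (~7 % for allele
frequencies uniform on [0.05, 0.5]). The run therefore ends where
w_bg·(1 Mb − d)/(2 Mb) crosses the 0.5 % threshold, i.e. ~0.86 Mb inside
the true edge: called segments are shortened by ~1.7 cM in total, and true
segments below ~2.8 cM fall under the 1 cM span rule and are undetectable.
This is a property of the window-smoothed statistic itself, not of the
implementation; the recovery study and the acceptance scenario both
account for it explicitly (the acceptance script plants segments whose
true lengths add the analytically derived attenuation to the intended
called lengths).

## Founder age

A segment inherited from a common ancestor g generations back survives
m = 2g meioses, so its genetic length is approximately exponential with
mean 100/m cM; conditioned on exceeding the caller's detection threshold
t, the density is r·exp(−r(L − t)) with r = 2g/100. The estimate is the
integer g maximising this likelihood, with a relative-likelihood curve
(max normalised to 1) and the contiguous half-maximum range as the
reported uncertainty; the half-max cutoff is configurable since no
standard convention exists. The model is intentionally minimal: one
observed segment, no chromosome-end correction, no correction for the
probability of observing at least one segment, no multi-segment
(ERSA-style) likelihood. Under it, a 17 cM segment above a 1 cM threshold
gives ML g = 3 (continuous optimum 50/16 ≈ 3.1) with a half-max range of
1–8 — richer models with different detection assumptions can prefer
somewhat larger g, which is within this flat likelihood's uncertainty.
Single-draw ML estimates from an exponential are heavily right-skewed, so
the simulation-recovery test uses the pooled log-likelihood over 10,000
draws (a consistent estimator) rather than averaging per-draw MLs.

## SV annotation

All coordinates are 1-based inclusive (HGVS). `insertion_pos` is the first
reference base after the insertion point — the conventional
single-coordinate breakpoint — so the HGVS flanks are
(insertion_pos − 1, insertion_pos). Insertion length is donor_end −
donor_start + 1; locus distance donor_start − insertion_pos, signed.
Donor orientation is recorded for display but never enters arithmetic.

## Synthetic data

The generators define the study conditions for all tests; they are
deterministic under a fixed seed (byte-identical serialisations).

*Pedigrees* are gene-dropped on nuclear or three-generation templates
(custom structures accepted): founder genotypes from Hardy–Weinberg with
an optional forced carrier founder, Mendelian transmission, ages uniform
within per-generation ranges (defaults 65–90 / 40–65 / 15–40), affection
sampled from the liability class given genotype (causal) or the
non-carrier class (neutral), carrier status observed with probability 0.9
by default, and the proband drawn from the affected carriers (error after
1000 retries if none can arise).

*Genotype pairs* emulate the WGS comparison of two distantly related
individuals: default 50 Mb chromosome at ~1 variant/kb, allele frequencies
uniform on [0.05, 0.5] (common variants — the regime in which the 0.5 %
w-threshold separates IBD from background), four independent haplotypes
per site with exactly one haplotype shared inside planted segments (which
forbids opposite homozygotes there, up to error), symmetric
adjacent-dosage genotype errors at 0.2 %, DP ~ Poisson(30), GQ = 99 with
probability 0.9 else uniform, FILTER = PASS with probability 0.98. Sites
are independent given the IBD state: no linkage disequilibrium, no
coalescent population history, no site-frequency-spectrum realism. Tests
passing on these data show the *caller* behaves as specified; they do not
certify performance on real WGS, where rare variants and LD change the
background w distribution.

*Incidence tables* are log-linear in age (rate = base·exp(slope·age)) on a
0–85 grid with 1e5 person-years per group and optional Poisson noise. The
default carrier table (base 1e−3, slope 0.07) gives ~85 % cumulative
any-cancer risk by 70, emulating a high-risk MSH2 cohort; the default
population table (base 1.8e−4, same slope) gives ~29 % by 70, in line with
Nordic general-population incidence.

## Problem sizes

The shipped test-suite and acceptance-script workloads are desk-scale by
design: 100+ random pedigrees of ≤ 8 members against exhaustive
enumeration, 20 recovery replicates of 60 Mb chromosome pairs (two planted
segments of 2–20 cM each), a nine-chromosome shared-segment scenario
(~150k sites), 10,000 founder-age draws, and 9–21-point sensitivity grids.
The whole suite runs in well under a minute on one core.

## Known limitations

Autosomal dominant inheritance only; no genotyping-error model in the
pedigree likelihood; no competing-mortality adjustment in penetrance; no
phased or HMM-based IBD; founder dating from a single segment is
inherently weak, as the reported likelihood curves make explicit.
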