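# Methods

This note documents the models, statistical procedures, defaults and
numerical choices behind `cisbreak`, and what its synthetic-data validation
does and does not establish.

## Coordinates and orientation conventions

All internal coordinates are 0-based, half-open (BED). BEDPE `start`
columns are taken as breakpoint positions; RepeatMasker `.out` rows
(1-based, inclusive) are converted on read. Every SV is canonicalized so
its two ends are ordered by (chromosome, position); duplicate rows within a
sample collapse to one call, and an optional filter drops SVs whose exact
breakpoint geometry recurs across samples (likely germline or artifact;
exact match, 0 bp tolerance, since no principled tolerance is available).

Breakpoint strand encodes the **retained side**: `+` keeps sequence at
coordinates ≤ pos, `-` keeps ≥ pos. This single convention defines
derivative-chromosome walks: which side of a gene survives a local
breakpoint, and which direction from the mate breakpoint contributes
translocated sequence. SV callers differ here; convert on ingest.

## Breakpoint matrices

Fixed windows (gene body; 100 kb upstream/downstream, strand-aware, so
"upstream" of a minus-strand gene lies right of its end) yield binary
occupancy: 1 iff any breakpoint of any SV falls in the window. Both ends of
every SV count independently — the unit is the breakpoint, not the event.

The weighted ±1 Mb window anchors on the strand-aware gene start (TSS
proxy). Per gene×sample, *d* is the minimum distance from a breakpoint to
the gene start, with breakpoints inside the gene body assigned *d* = 0, and
the entry is *s* = log₂(*W*+1) − log₂(*d*+1) for *d* ≤ *W*, else 0. *s*
decreases strictly in *d* and is exactly 0 at *d* = *W* (the formula is
continuous at the boundary). Ties for the nearest breakpoint break by
smaller position, then sv_id, so matrices are independent of input order.
The weight is monotone in −log₂(*d*+1), which is also the survival scan's
"log₂-transformed relative distance" covariate; using one construct for
both keeps the association and survival analyses commensurable.

## Association scan

Per gene: OLS of log₂(TPM + 1) on [breakpoint term, gene-level integer
copy number, cancer-type indicators (most frequent level as reference;
levels with < 2 samples merged into "other")]. Two-sided t-test on the
breakpoint coefficient. The engine residualizes all gene rows against the
cancer-type design once (thin QR) and solves the remaining per-gene 2×2
normal equations array-wide; this is algebraically identical to per-gene
OLS and is cross-checked against statsmodels in the tests. Degenerate
designs (constant expression, constant breakpoint term, CNA constant
within strata) fall back or are flagged with (β, t, p) = (0, 0, 1).

Gene universe: TPM > 1 in ≥ 10 % of samples (configurable) — a surrogate
for the usual "expressed genes" filter. Fixed windows additionally require
≥ 3 carrier tumors. FDR per scan: *q*(*pᵢ*) = *pᵢ*·*N*/#{*pⱼ* ≤ *pᵢ*},
monotone-adjusted upward in *p* and capped at 1; tied *p* receive
identical *q*. Windows are corrected independently; a gene is significant
overall if significant in any window.

Subgroup scans restrict samples (minimum 20 for therapy, 19 for
cancer-type subgroups; smaller subgroups are refused), and drop significant
genes lacking at least one carrier whose normalized expression
((x − median)/SD on log₂ scale, computed within the subgroup) exceeds
+0.4 SD (positive associations) or falls below −0.4 SD (negative).

## Mechanism annotation

A TAD-disrupting SV is one whose two breakpoints do not lie within one and
the same TAD interval; interchromosomal SVs always qualify, and a
breakpoint in a gap between TADs shares a TAD with nothing, so such SVs
also qualify.

Hijack detection considers, per gene×sample, only the breakpoint closest
to the gene start among breakpoints strictly upstream within the class
window (1 Mb for enhancers; 20 kb for LINE/SINE elements, reflecting the
shorter reach of promoter-like effects). Requirements: (i) the local
breakpoint retains the gene-containing side; (ii) walking from the mate
breakpoint along its retained direction, an element of the class occurs
within the budget (class window − *d*<sub>gene</sub>), distances measured
from the mate position to the nearest element edge (0 if the element
contains the mate); (iii) the effective distance
*d*<sub>gene</sub> + walk beats the nearest native same-class element
upstream of the gene — strictly, so ties are not hijacks. Only upstream
windows are scanned by default. Enrichment of context events among
altered-expression associations uses Pearson chi-square without continuity
correction (expected counts preserve the table total); zero-margin tables
return p = 1 with a warning.

## Chromothripsis

Per sample×chromosome, the caller computes: the largest
crossing-connected cluster of intrachromosomal SV intervals (two intervals
"interleave" iff a₁ < b₁ < a₂ < b₂ — overlap without nesting; union-find
over pairs); the longest run of contiguous copy-number segments
alternating between exactly two states; a chi-square goodness-of-fit of
the four join types (deletion-like (+,−), duplication-like (−,+),
head-to-head (+,+), tail-to-tail (−,−)) against equal proportions (random
joins ⇒ high p; passes when p > 0.05); a binomial upper-tail test of the
chromosome's share of genome-wide breakpoints given length-proportional
rates (passes when p < 0.05); and a Kolmogorov–Smirnov test of
inter-breakpoint gaps against an exponential with rate 1/mean gap (passes
when p > 0.05; fitting the rate from the data makes this slightly
conservative). Criterion 1: ≥ 6 interleaved intra-SVs, oscillation ≥ 7,
joins pass, and either distribution test passes. Criterion 2: ≥ 3
interleaved intra-SVs, ≥ 4 interchromosomal SVs, oscillation ≥ 7, joins
pass. The component tests' formulas and thresholds are principled
stand-ins for the original caller's (which are not fully specified
anywhere we can implement from); all thresholds are configurable, and
calls carry their component statistics so verdicts are re-derivable.
Missing copy-number data yields no call, flagged. Note that a caller
honoring the joins test can never exceed ~95 % sensitivity on truly random
joins: the test itself rejects ~5 % of genuinely random join sets.

## Burden and survival

SV burden is the deduplicated per-sample event count; the burden scan
regresses log₂(TPM+1) on log₂(burden+1) with CNA and cancer type, via the
same OLS engine.

Survival scans fit, per gene, a Cox model stratified by cancer type with
Efron tie handling: covariate = the weighted breakpoint score (tumors with
no nearby breakpoint keep score 0 rather than being dropped) plus
gene-level CNA, or the gene's log₂ expression alone. Coefficients and SEs
come from a Newton fit of the stratified partial likelihood (implemented
in `cisbreak._cox`, verified against lifelines to ~10⁻⁶). The p-value is
**not** the Wald test: with a zero-inflated, right-skewed covariate and a
few dozen carriers, the partial-likelihood MLE is biased away from zero
and Wald p-values are measurably anticonservative; even the analytic score
test overdisperses because the score and its estimated information are
correlated under skew. Instead, the score of the covariate at the
restricted (nuisance-only) fit — which is exactly linear in the covariate
— is compared to its within-stratum permutation distribution, with the
covariate residualized on CNA first so the reference spread matches the
efficient information (otherwise the test is conservative when breakpoints
and copy gain co-occur). Default 1,999 permutations, so the smallest
attainable p is 5×10⁻⁴; deterministic given the scan seed. Measured on
null cohorts this is calibrated (fraction p < 0.05 ≈ 0.048, KS p ≈ 0.7
over 2,000 pooled null genes).

Follow-up capping censors observations beyond the cap (idempotent).
The survival signature intersects {positive SV-expression association,
p < 0.05} with {worse survival by both breakpoint score and expression,
positive coefficient, p < 0.05 each}; its size is tested against chance by
one-sided Fisher over the common gene universe. Signature scores are
per-sample means over signature genes of (x − median)/SD on log₂
expression (zero-SD genes excluded with a warning); tertile boundaries use
empirical 1/3 quantiles with boundary ties assigned to the lower group,
compared by log-rank.

## Pathway alterations

Per sample×gene, the first matching class in the order SNV/indel → fusion
→ deep deletion (0 copies) → amplification (≥ 5 copies) → cis-acting SV is
recorded. SNV and fusion calls are external input tables; oncogene SNVs
are restricted to a hotspot whitelist when one is provided, tumor-suppressor
SNVs/indels to inactivating classes. The SV rule requires the gene to be
FDR < 10 % significant in any window of the association scan, plus a
breakpoint within 1 Mb and expression > +0.4 SD (oncogenes) or a gene-body
breakpoint and expression < −0.4 SD (tumor suppressors). The shipped
catalog covers RTK, HIPPO, chromatin modification, SWI/SNF, PI3K/AKT/mTOR,
MYC family, TERT, Wnt/β-catenin and p53/Rb pathway genes with default
roles; any-window significance is accepted for the gate (rather than
requiring the role-matched window), the more permissive reading.

## Synthetic cohorts

Defaults describe a 300-tumor, 2,000-gene cohort on a 5×50 Mb toy genome
with four cancer types. Per-sample SV counts are negative binomial
(mean 10, dispersion 1.2) clipped to [3, 813]: the mean is chosen so the
per-Mb breakpoint density matches a real ~120-SV tumor on a 3 Gb genome —
density, not raw count, is what 1 Mb windows experience — while the clip
keeps counts inside the plausible per-tumor range. Breakpoints place
uniformly or around per-sample cluster centers (weight 0.3); intrachromosomal
classes get strand pairs consistent with their class under the join-type
convention. Copy number starts at 2; each breakpoint triggers a +1..+3
gain of genes within 1 Mb with probability 0.3 (the central confounder),
plus sparse background events and rare deep deletions. Expression is built
on the log₂(TPM+1) scale: lognormal per-gene baseline (mean 5, SD 1.5) +
cancer-type shifts (SD 0.5) + 0.35·(CN − 2) + planted effects + N(0, 1)
noise, then back-transformed. Genes carrying planted effects have their
baseline floored at the population mean so planted SD-unit effects are
exact rather than attenuated by the TPM = 0 floor. Planted cis carriers
receive an upstream translocation oriented so the derivative chromosome
juxtaposes mate sequence with the gene. Survival is exponential (median
24 months) with planted log-hazard ratios acting on SD-normalized
expression, censored uniformly on [6, 120] months; therapy labels are
logistic in centered log₂ burden (base rate 0.35, one unit of log-odds per
log₂ unit). Shattered chromosomes tile a 30 % region with n fragments,
alternate copy states 2/1, and connect fragment boundaries by a staircase
of mutually crossing SVs with uniform random join types.

Randomness flows through named SeedSequence substreams in the fixed order
genes → tracks → sv_counts → therapy → svs → cna → expression → survival
(therapy precedes SV placement because subgroup-restricted planted effects
choose carriers by label, and follows counts because labels depend on
burden). Identical seed and config reproduce every file byte for byte.

**What passing tests show — and what they do not.** The generator's
expression model is Gaussian on the log scale with linear CNA dose and
homoscedastic noise; real tumors have heavier tails, expression-dependent
variance, subclonality, purity variation, and correlated gene programs.
Calibration and recovery results therefore demonstrate that the
implementation is correct and well-calibrated *under its stated model*,
not that effect sizes or FDRs transfer quantitatively to any real cohort.
Mechanism detection is validated on exactly-constructed derivative
chromosomes; real SV calls carry positional uncertainty that is not
modeled. Chromothripsis sensitivity is measured against canonical
alternating-retention shattering, the easiest realistic case.

## Numerical choices and degenerate inputs

Pseudocount 1 in all log₂ expression transforms (configurable). OLS rank
tolerances are relative (10⁻¹⁰ of the squared data scale). Exact fits
(zero residual) report p = 0 rather than degenerate. Cox Newton iterations
stop when the parameter step falls below 10⁻⁹ (relative), with
step-halving on likelihood decrease; non-converged fits report
(coef, p) = (0, 1) rather than propagating garbage. Empty inputs return
empty outputs except where the contract demands an error (empty sample
intersection, empty gene universe, negative survival times). Scan outputs
order by (q, gene_id) so equal results serialize identically.

## Known limitations

- The weighted-matrix formula is a documented reconstruction with the
  stated ordering behaviour (closer ⇒ larger weight, zero beyond 1 Mb);
  the original tool's exact weight is not published.
- The chromothripsis component tests are stand-ins with configurable
  thresholds, not a reimplementation of the original caller.
- Permutation score tests bound p from below at 1/(B+1); rank-based
  downstream analyses that need finer tails should raise `n_perm`.
- GTF gene models, VCF-format SVs and genome-build liftover are out of
  scope; inputs must share one build.
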