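# Methods

## Discovery and filtering

Candidate DNMs are Mendelian violations (parents hom-ref, child het) among
autosomal biallelic SNVs. Coordinates are 1-based VCF convention; records
whose FILTER column is not PASS are dropped at parse time (upstream
caller-level hard filters are honored, not re-evaluated, since their
annotations are caller-specific). The autosome filter is configuration: by
default everything not named like X/Y/MT is kept, because reference
genomes do not share a canonical autosome list.

Six stringent filters separate high-confidence DNMs from genotyping error:
per-member depth in [20, 60] (bounds inclusive — "between" is read as a
closed interval; this is stated explicitly because an off-by-one changes
counts), per-member GQ strictly above 70, alternate reads on both strands
in the child (ADF, ADR > 0), zero alternate reads in both parents, absence
of the alternate allele from cohort samples outside the trio parents'
descendant closure, and child allelic balance strictly above 0.35.
Allelic balance is alt/(ref+alt) from AD — the evidence pair the filter
names — not alt/DP. The non-descendant check consults genotype calls, not
raw reads, because the pipeline consumes a VCF only; descendants are
exempt since they may legitimately inherit the DNM. All six verdicts are
always evaluated and recorded (no short-circuiting), so filter attrition
is auditable per candidate, and the verdict map is independent of
evaluation order by construction.

## Callability and rates

The per-trio rate is N_mut / (2·C·G). C = C_c·C_p·C_m assumes the three
members' calls are disturbed independently. Child callability is the pass
fraction of parental hom-ref × hom-alt crosses (sites where the child is a
confident heterozygote, the same call a DNM requires) under the
child-specific filters. The informative-site definition for parents is
genuinely open; the choice here is a parent's confident hom-ref calls at
cohort-polymorphic sites, filtered on depth, GQ and zero alternate reads —
the exact call a DNM demands of a parent. G is taken from upstream
coverage accounting (a column of the trio table), never recomputed from
the VCF, which does not carry it.

The aggregate point estimate is the unweighted mean of per-trio rates (the
pooled ratio ΣN / Σ2CG is computed alongside; the two coincide when trios
share N and G). Confidence intervals assume Poisson variance in the total
count: the headline interval applies the relative factor (1 ± z/√N) to the
point estimate, and a pooled Wald interval (N ± z√N)/Σ2CG is reported for
transparency. The per-year conversion divides by the mean over **all**
recorded parental ages, both sexes pooled. Subset rates (e.g. CpG sites)
use the same formula with a caller-supplied subset span; the package does
not enumerate CpG sites from a reference genome.

## Phasing

Transmission phasing uses a ±25 kb window centered on the DNM ("50 kb
region", centering assumed). Sites where the carrier's parents are
opposite homozygotes label the carrier's haplotypes; grandoffspring
genotypes (with the mate's genotype subtracted; mate-het sites are
uninformative and skipped) reveal the transmitted block. A window is
undetermined below two informative sites. "Multiple genotype mismatches"
(recombination) is operationalized as ≥ 2 votes against the majority
block; a single mismatch is tolerated as genotyping error — an
undetermined outcome is always preferred over a misassignment, and the
simulation tests check exactly that. Read-based phasing is consumed as an
external table, never re-implemented; merged assignments that disagree
between routes are omitted entirely. The male-bias test is the exact
two-sided binomial test against 0.5.

## Age regression

The identity-link Poisson likelihood is maximized by Fisher scoring with
step-halving against the mean-positivity boundary, started from a
non-negative least squares solution (exposures are non-negative, so the
start is feasible); the identity link is not globally log-concave, but on
these designs the step-halved ascent converges to the same optimum as a
brute-force likelihood grid (tested to 4 significant digits). Convergence
demands a relative score below 1e-10; standard errors come from the
inverse Fisher information. The maternal term can be included; it is
excluded from the headline model.

The "total additional mutations per year" scaling multiplies beta_p by a
diploid genome length of 5×10⁹ bp (2 × 2.5 Gb reference length), exposed
as a parameter. Rate-at-age predictions use the delta method. The
unadjusted per-parent model (b0 + b1·age on phased counts, slope rescaled
by the inverse phased fraction) is provided for phased-mutation analyses.

The two longevity models map a reference-species fit to target-species
ages: total longevity evaluates at calendar age; reproductive longevity at
(age − puberty_target) + puberty_reference, i.e. equal post-puberty
elapsed time (defaults 0.5 y and 13 y). Model comparison is a paired
two-sided t-test on absolute residuals — the construction behind the
published comparison is not fully specified, and paired absolute residuals
is the choice made here.

## Spectrum

Twelve independent identity-link Poisson fits (6 classes × 2 parents) of
per-proband class counts on the relevant parent's age. Probands with zero
mutations in a class contribute zeros — dropping them would bias
intercepts upward — so the fit accepts an explicit proband universe.
Only phased mutations feed the per-parent fits (how unphased mutations
should enter is not derivable; an inverse-phased-fraction scaling is
available). Spectrum predictions sum per-class counts over both parents
and normalize; per-class negatives (possible far outside the fitted age
range) are floored at zero before normalizing.

The reproductive-longevity spectrum mapping is a pure +13-year shift of
both parental ages, matching the target ages (15.92, 17.68) that pair with
cat means (2.92, 4.68); note this differs from the rate model's mapping,
which also subtracts the cat's 0.5-year puberty age — both behaviors
exist, and the spectrum default is the pure shift. RMSE between predicted
and observed spectra is reported in percentage points over the six
classes; its CI is a percentile bootstrap (method not otherwise dictated)
resampling probands with replacement and refitting all twelve regressions
per replicate, deterministic given a seed. Observed spectra carry Wilson
score intervals.

## Synthetic data

The cohort generator runs the rate model forwards: per-trio DNM counts are
Poisson with mean 2·span·(beta_N + beta_p·X_p); defaults (11 trios, 1.8 Gb
span, beta_N = 5.4×10⁻⁹, beta_p = 6.4×10⁻¹⁰, paternal ages 1.7–12 y,
maternal 1.4–4.4 y, mean depth 40) mirror the cat study's design. Depth is
negative-binomial (gamma-Poisson) around the mean, or constant when
dispersion is disabled; GQ is a deterministic map of depth and call
correctness (min(99, 2.5·DP) for correct calls, 25 for errors) plus
optional noise, which makes quality failures covary with depth as they do
in real callers. Per-member dropout degrades a site's evidence (low depth
or low GQ, chosen at random) so it fails the filters — the attrition that
callability correction must undo. Background polymorphic sites (founders
iid hom-ref/het/hom-alt at 0.45/0.20/0.35, children Mendelian) exist so
callability can be estimated from the cohort itself; the genome span is an
accounting parameter, not an enumerated sequence. An even-allele-split
mode makes het allelic depths deterministic for noiseless exact-recovery
checks.

What the generator does **not** emulate: linkage disequilibrium beyond
perfect co-transmission inside a phasing window, repetitive-region depth
pathologies, indels, multi-allelic sites, reference bias, and cell-line
artifacts. Passing tests therefore demonstrate the estimators' internal
consistency under the stated noise model, not robustness to every real
sequencing failure mode.

The reference-cohort generator draws per-parent, per-class counts from the
linear Poisson model with parental ages centered near 30 years. Default
class coefficients split a paternal slope of 1.51/year (intercept 7) and a
maternal slope of 0.37/year (intercept 2.5) across classes by a fixed
illustrative spectrum; they are configuration for exercising the
machinery, not empirical claims. The three-generation phasing scenario
plants a DNM of known origin with configurable informative-site counts and
recombination.

## Problem sizes and numerical choices

Calibration tests use sizes chosen to make their statistical assertions
sharp while staying cheap: coefficient-recovery coverage runs 1000
replicates at 500 probands; the longevity-model spectrum comparison 100
replicates at 400 probands against 233-mutation observed spectra; the
end-to-end rate recovery 100 replicates of 20 trios × 1.5 Gb with
per-member dropout 0.3 and 800 background sites. Coverage assertions use
the 90–98% band around the nominal 95%. GLM convergence tolerance is
1e-10 relative score; bootstrap replicates that fail to converge are
dropped and more than 5% dropped is an error; chi-square tests use no
continuity correction; ties in phasing votes resolve to undetermined via
the mismatch rule.

## Known limitations

Parental callability's informative-site definition is a modeling choice
(see above); transmission phasing assumes the mate's genotypes are
available and treats mate-het sites as uninformative rather than modeling
them; the identity-link GLM offers no overdispersion handling (a
negative-binomial variant is out of scope); CpG sub-classing of C>T and
signature-style context expansion are out of scope; the spectrum's
longevity mapping inherits the +shift convention ambiguity noted above.
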