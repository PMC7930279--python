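# Methods

This note documents the statistical model, the generative model behind
the synthetic cohorts, the numerical choices, and the limits of what the
package's validation studies demonstrate.

## Edge-wise group model and cluster inference

Connectivity is Fisher-z transformed Pearson correlation between voxel
time series, z = atanh(r) with r clamped to ±(1 − 10⁻⁷) so numerically
perfect correlations stay finite. Per edge, ordinary least squares fits
an intercept, a patient/control indicator, and nuisance covariates
(age, sex, education in years, mean framewise displacement in mm). The
group t statistic on n − p degrees of freedom is mapped to a z statistic
by matching one-sided tail probability with the sign preserved; the
mapping uses log-scale survival functions (`t.logsf` → `ndtri_exp`) so
extreme statistics do not underflow.

The cluster-defining threshold (CDT) is specified as a one-sided tail
probability and applied to |z|, because the standard p↔z pairings in
this literature (2×10⁻⁸ ↔ 5.5, 3×10⁻⁷ ↔ 5.0) correspond to one-sided
tails. A two-sided mode is available (`sided="two"` halves the tail).
Clusters may mix increased and decreased edges; sign counts are
reported per cluster.

FC-cluster formation: endpoint voxels of supra-threshold edges are
clustered by spatial 26-connectivity (the standard neuroimaging
neighbourhood; the choice matters only for touching clusters). Every
unordered pair of two *distinct* voxel clusters joined by at least one
supra-threshold edge becomes an FC cluster whose size is its edge
count. Edges internal to one voxel cluster are excluded from clusters
but logged, since the definition requires two distinct endpoints.

Cluster-size FWER correction uses a Freedman–Lane max-statistic
permutation null rather than a closed-form random-field-theory
cluster-size distribution: the data are residualized on the nuisance
design, residual rows are permuted and added back to the nuisance fit,
the full model is refit and re-clustered, and corrected
p = (1 + #{perm max size ≥ observed size}) / (1 + n_perm). This
controls FWER by construction under exchangeability of
covariate-adjusted residuals, needs no smoothness assumptions, and is
exact up to Monte-Carlo error; the API keeps the null-model stage
separate so an analytic backend could be slotted in later. Permutation
statistics are computed on the t scale with the threshold mapped from
the z-scale CDT through the same tail matching, which is equivalent and
avoids converting every permuted statistic.

A caveat discovered during validation and worth knowing at small voxel
counts: because FC clusters require two *distinct* spatial components,
a single spurious supra-threshold edge whose endpoints lie between two
true clusters can spatially bridge them, reclassifying every
connecting edge as within-cluster. On a whole-brain grid this is
vanishingly unlikely; on toy grids the planted blobs must be separated
by ≥ 4 voxels (the synthetic defaults are).

## Clinical associations and staging

Cluster strength is the per-subject mean Fisher z over the cluster's
edges. Symptom association uses partial correlation (both variables
residualized on covariates plus intercept) with a two-sided permutation
p obtained by permuting the residualized symptom vector —
Freedman–Lane again, so nuisance structure does not inflate the null.
An input that is numerically constant raises an error; an input exactly
absorbed by the covariates (residual norm below 10⁻¹⁰ of its scale)
yields r = 0 rather than correlating rounding noise.
Benjamini–Hochberg FDR is computed by the usual step-up with enforced
monotonicity, capped at 1.

Illness-duration staging splits patients at the sample median
(midpoint convention for even n); ties go to the short-duration group.
Each patient subgroup is compared against *all* controls with the full
cluster inference at the (laxer) stage CDT. Replication in an
independent cohort tests each discovery cluster's mean strength with
the same GLM, BH across clusters, and requires the validation effect to
carry the discovery sign.

## Pathway PRS arm

Per-SNP association is an allelic 2×2 chi-square (ALT vs REF × case vs
control) with continuity correction; odds ratios use the cross-product
with a Haldane–Anscombe 0.5 correction when any cell is zero, and
monomorphic SNPs are excluded with a warning record. A per-SNP
logistic-regression backend is available for sensitivity analysis. The
effect allele is the VCF ALT allele and weights are signed log odds
ratios — no orientation flipping, since a weighted sum with log(OR)
weights is sign-coherent by itself.

Gene co-expression clustering standardizes each gene's regional profile
(z-score across regions, so clustering reflects shape rather than
level) and runs best-of-50-restarts K-means at a fixed seed; k defaults
to 5 so a ~20-gene panel can yield a cluster of roughly six genes
around the anchor. The pathway PRS is Σ log(OR)·dosage over the SNPs in
the anchor cluster's genes with association p < 0.05. PRS–connectivity
correlations are unadjusted by default (an `adjust` flag residualizes on
the demographic covariates); the correlation-set contrast between
stages reports both pooled-variance and Welch t with a one-sided p, and
defaults to comparing |r| values because the specificity question is
about correlation magnitude, not direction.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not fMRI physics. Each spatial blob has one shared standard-normal
regional factor per subject; for a planted blob pair the two factors
are drawn bivariate normal with per-subject correlation

    rho_i = rho0 + Δr·affected_i + g·liability_i + N(0, σ_subj)

with rho0 = 0.10 (baseline coupling), σ_subj = 0.10 (between-subject
spread), and `affected_i` either all patients or one duration stratum
(`stage_effect`). A voxel's series mixes its blob factor with white
noise, variance share 0.30, so the voxel-level correlation is
attenuated by 0.70 relative to rho (recorded in
`GroundTruth.attenuation`); blob-*mean* series recover rho almost
unattenuated, which is the oracle the tests use. Off-blob voxels are
pure noise.

Phenotypes mirror a first-episode case–control cohort: 138 patients vs
112 controls by default, ages ~24 ± 7 years with mild group imbalance
in sex and education, mean framewise displacement folded-normal around
0.18 mm (a small tail exceeds the 0.5 mm exclusion cut on purpose),
illness duration uniform on 1–100 weeks, and a symptom score
15 + 20·(rho_i − rho0) + N(0, 3) for patients so that symptom–coupling
correlations are recoverable but not degenerate.

Genotypes are Hardy–Weinberg within group at a per-SNP MAF drawn from
U(0.05, 0.40); for effect SNPs the case/control allele frequencies are
solved (Brent's method on the logit mixture) so the allelic log-OR
equals the requested value while the pooled frequency stays at the
drawn MAF. Five effect SNPs at log-OR 0.7 is the default panel, inside
an 88-SNP / 20-gene layout with the effect SNPs placed in the anchor
co-expression block so pathway-specificity analyses have a planted
truth. Genetic liability is the standardized true-weight dosage score;
it feeds back into connectivity only through the planted couplings.
There is no linkage disequilibrium — every SNP is drawn independently —
and no imputation structure. Expression is block-structured: genes in a
block share a standard-normal regional profile plus N(0, 0.3) noise
over 60 regions; the anchor gene always sits in block 0 of size
`anchor_cluster_size` (default 6).

Because the cohort generator needs the liability when a genetic→
connectivity slope is requested but genotypes are formally generated
after phenotypes, all generator streams are keyed by (seed, stream-id):
the cohort's internal genotype draw and a later explicit
`generate_genotypes` call produce bit-identical matrices.

What passing tests therefore show: correct thresholding, clustering and
FWER control *given* exchangeable Gaussian-factor data; correct
recovery of planted effect sizes, stages and genetic pathways. What
they do not show: robustness to hemodynamic autocorrelation, motion
artifacts, LD, population stratification, or atlas misregistration —
none of which the generator models.

## Cleaning

Band-pass filtering is a zero-phase frequency-mask projection (default
0.01–0.1 Hz at TR = 2 s) — deterministic, with exact passband semantics,
rather than an IIR filter whose transition band would need documenting.
Confounds are passed through the same filter before being regressed
out; filtering both signal and confounds keeps the whole cleaning step
a single orthogonal projection, so reapplying it is a no-op
(idempotence), and it avoids reintroducing confound energy outside the
band. DC is always removed, so cleaned series are mean-zero.

## Validation study sizes

The packaged studies (`bwaskit.validation`) use: 300 null cohorts of
30 voxels and 15+15 subjects at CDT z = 3.1 with 199 permutations for
FWER calibration; 50 runs of 40+40 subjects on 60 voxels at CDT z = 4
for planted-effect recovery (Δr = 0.35) and stage specificity
(Δr = 0.4, short stratum only); 50 replicates of 1,000+1,000 subjects
for PRS–liability recovery; 100 seeds for K-means block recovery; and
50 runs of 200+200 subjects for the pathway-specificity contrast.
These sizes give Monte-Carlo standard errors small enough for the rate
thresholds being checked while keeping each study in the tens of
seconds on one CPU.

## Known limitations

* The permutation null assumes exchangeable covariate-adjusted
  residuals; heavy-tailed or heteroscedastic edge noise is handled only
  asymptotically.
* Cluster formation is sensitive to spatial bridging at toy grid
  scales (see above).
* The allelic chi-square assumes HWE within groups (true of the
  generator by construction; real exome data would warrant the logistic
  backend).
* `compare_correlation_sets` treats per-cluster correlations as
  independent observations; overlapping clusters on real data violate
  this, which is why both pooled and Welch variants are reported.
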