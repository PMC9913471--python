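# Methods

This note records the statistical model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Repeatability model and relationship matrices

Records are modelled as `y = Xβ + Za + Wp + e` with additive effects
`a ~ N(0, K σa²)`, a permanent-environment effect per boar
`p ~ N(0, I σp²)` capturing non-genetic covariance among that boar's
repeated collections, and i.i.d. residuals. Fixed effects are
year–season (12 levels over a three-year span: years × spring =
March–May, summer = June–August, autumn = September–November, winter =
December–February) and birth parity (1–6), both dummy-coded against a
reference level; age at collection (months) and the interval since the
previous collection (days) enter as linear covariates. Modelling age
and interval as regressions rather than class effects is a design
choice: both are continuous measurements and the data would thinly
populate fine classes.

The pedigree matrix **A** is built by the tabular method in topological
order; its sparse inverse comes from Henderson's per-animal rules with
Mendelian-sampling variances `dᵢ = ½ − ¼(F_s + F_d)` and inbreeding
coefficients from the Meuwissen–Luo recursion (`F = −1` convention for
unknown parents). `log|A| = Σ log dᵢ` falls out of the same
factorisation and feeds the REML likelihood. Genotyped animals missing
from the pedigree are attached as unknown-parent founders with a
warning, since the single-step matrix needs every genotyped animal
inside **A**.

The genomic matrix is `G = Z D Z′ / Σ 2pᵢ(1−pᵢ)` with `Z` centered by
`2pᵢ`. Allele frequencies are computed once from the post-QC genotyped
sample and reused everywhere (centering, λ, weight updates) so that
`G`, the back-solve and the window decomposition are internally
consistent. Centering by `2p` rather than observed column means follows
the standard genomic-relationship construction. The blend
`Gw = 0.9 G + 0.1 A22` is fixed; it guarantees invertibility and
controls bias between genomic and pedigree information. `Gw` is used
wherever the genomic block appears downstream, including the SNP-effect
back-solve — a deliberate choice for invertibility; with sample-centered
`Z`, raw `G` is structurally singular (`G·1 = 0`). One jitter retry
(1e-8 × mean diagonal × dimension) is permitted if a Cholesky fails.

`H⁻¹ = A⁻¹ + embed(Gw⁻¹ − A22⁻¹)` is assembled sparsely with the dense
correction confined to the genotyped block, and carries
`log|H| = log|A| + log|Gw| − log|A22|` for REML.

## AI-REML

Variance components are estimated by average-information REML on
Henderson's mixed-model equations. Per iteration the MME coefficient
matrix `C = M′M + diag(0, A⁻¹·σe²/σa², I·σe²/σp²)` is factorised by
dense Cholesky (the system is assembled sparse, but the AI update needs
traces of inverse blocks, and at the dimensions this package targets —
a few thousand equations — a dense inverse is cheap and simple). The
score vector uses the standard trace identities, e.g.
`tr(P Z K Z′) = q_a/σa² − tr(K⁻¹ C^{aa}) σe²/σa⁴`; the analytic score
is verified against numerical differentiation of the likelihood in the
test suite. The AI matrix is `½ F′PF` for the three vectors
`F = [Zâ/σa², Wp̂/σp², ê/σe²]`, each `P·f` obtained by one extra solve
against the cached factor.

Numerical safeguards, all of which proved necessary on small or
boundary-prone datasets:

* start values σe² = ½ var(y), σa² = σp² = ¼ var(y);
* three EM warm-up iterations before the first AI step;
* a trust region — no component may shrink below 5 % of its current
  value in a single Newton step — plus step-halving (12 halvings max)
  on any likelihood decrease, with the EM update as fallback;
* active-set pinning: a component at the boundary (≤ 1e-4 × var(y))
  whose score is non-positive is fixed at the floor (1e-8 × var(y)) and
  removed from the AI system until its score turns positive. Without
  this, the near-zero row makes the AI matrix ill-conditioned and the
  algorithm stalls on EM fallbacks;
* convergence at relative parameter change < 1e-8, max 100 iterations;
  non-convergence raises an error carrying the trajectory.

Standard errors come from the inverse AI matrix at convergence
(restricted to non-boundary components); h² and repeatability SEs use
the delta method. A component pinned at the boundary triggers a warning
and its SE is reported as NaN.

## Weighted iteration and windows

The loop runs Steps `D(1) = I` → GEBV → `ĝ = λD Z′Gw⁻¹â` →
`dᵢ = ĝᵢ² 2pᵢ(1−pᵢ)` → trace renormalisation → new `G`, three times by
default. Variance components are estimated once and held fixed across
iterations (re-estimation per iteration is available via
`reestimate_vc=True`); λ is defined at `D = I` and not recomputed. No
weight floor is applied by default — trace renormalisation handles the
scale and zero weights are legitimate.

Windows are non-overlapping runs of consecutive SNPs: a window closes
when the next SNP would put the span at ≥ 0.4 Mb. This partition (as
opposed to per-SNP sliding windows) matches the window counts reported
for comparable chip densities: the default 38,054-SNP map over an
≈ 2.26 Gb, 18-autosome genome partitions into ≈ 4,900 windows. "Var" in
the window share `Var(Σ Zⱼĝⱼ)/σa² × 100` is the population (denominator
*n*) variance across genotyped individuals; window shares do not sum to
100 % because between-window covariances are ignored. Candidate regions
use a strict > 1 % threshold; the top three windows are extended
±0.4 Mb around their midpoints (floored at 1 bp). Gene overlap is
any-intersection on 1-based inclusive intervals, strand ignored; the
enrichment test is a one-sided hypergeometric upper tail per
user-supplied gene set with Benjamini–Hochberg adjustment, with the
universe defaulting to all genes in the annotation.

## Quality control

Phenotypes: same-day duplicate collections drop the later record; then
records with ejaculate volume ≤ 50 mL, motility < 10 %, or
inter-collection interval > 60 days are removed; finally boars left
with fewer than 5 usable records are dropped entirely. Applying the
count rule last makes it reflect usable records and renders the whole
filter idempotent; rules are order-independent at the record level.

Genotypes: unmapped/sex-chromosome/position-less SNPs out first, then
individual call rate < 0.9, SNP call rate < 0.9, MAF < 0.01, and the
conditional exact Hardy–Weinberg test at p < 1e-6 (MAF and HWE computed
on the call-rate-passing sample). Residual missing codes are imputed to
the per-SNP mean rounded to {0,1,2} — deterministic and
dependency-free; haplotype-based imputation is out of scope.

## Synthetic data

The generator emulates an AI-stud dataset: a four-generation
random-mating pedigree over 120 founders with 40 sires and 200 dams per
generation (one mate per dam, so litters contribute full sibs;
retaining ~1–3 AI boars per litter mirrors nucleus-herd practice), a
final cohort of 583 phenotyped-and-genotyped boars, 38,054 SNPs placed
uniformly on 18 autosomes with approximate pig chromosome lengths
(≈ 2.26 Gb), founder allele frequencies Beta(2,2) truncated at MAF
0.05, and gene-dropped descendants with Poisson crossovers at 1 cM/Mb
(no interference). True breeding values combine 5 planted QTL —
variance fractions (0.06, 0.05, 0.04, 0.04, 0.03) of σa², each rescaled
to its exact share over the boar cohort — with a polygenic remainder
spread over all remaining SNPs (or flowing through the pedigree under
the infinitesimal option used when no markers are simulated). Records
per boar follow a shifted negative binomial (min 5, mean ≈ 44,
max 103) over 2020–2022 with ≈ 7-day collection intervals; fixed-effect
levels get small random effects (year–season SD 3, parity SD 1.5) and
the covariate slopes default to small non-zero values so fixed-effect
estimation is genuinely exercised. Default variance scale
(σa², σp², σe²) = (30, 35, 111) — a motility-like percentage trait with
h² ≈ 0.17 and repeatability ≈ 0.37.

What the generator does **not** emulate: founder linkage
disequilibrium calibrated to real pig haplotypes (founders are in
linkage equilibrium; all LD arises from pedigree structure and drift),
selection or assortative mating, genotyping error, and multi-trait
genetic correlations. Passing tests therefore demonstrate correctness
of the machinery and calibration under this idealised architecture, not
performance on real chip data with block LD.

## Problem sizes used in the test suite

The full-scale configuration (583 boars, 38,054 SNPs) is used where it
is cheap: weight-trace conservation over three iterations runs at full
scale. Seeded replication studies use reduced sizes chosen to keep the
suite quick while preserving the estimation regime: variance-component
recovery uses 300 boars × ~40 records (the ±2-SE criterion
self-calibrates with cohort size), and QTL localisation uses 583 boars
on a 3,000-SNP, six-chromosome genome (fewer windows than full scale,
which if anything favours localisation).

## Known limitations

* **QTL localisation power.** With ≈ 600 genotyped boars at h² ≈ 0.17
  (GEBV accuracy ≈ 0.77 in this regime), a window carrying 3–6 % of σa²
  has a signal-to-noise ratio near the genome-wide detection limit:
  feeding *true* breeding values through the same back-solve/weighting
  loop ranks all planted QTL near the top, but estimated GEBV leave a
  substantial fraction of 3–6 % QTL outside the top 10 windows. The
  corresponding seeded acceptance test documents this honestly rather
  than relaxing its threshold. Larger cohorts, more records, or larger
  QTL move windows into reliable detection.
* Single-trait analyses only; genetic correlations between semen traits
  are out of scope.
* The AI-REML solver inverts the MME densely; beyond ~10⁴ equations a
  sparse factorisation with selected inversion would be needed.
* The exact HWE test is two-sided via probability ordering; borderline
  SNPs near the 1e-6 threshold can differ from mid-p variants of the
  test.
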