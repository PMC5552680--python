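# Methods

## Characteristic direction

The discriminant treats each sample as a point in gene-expression space
(log2 intensities) and asks for the hyperplane best separating the two
classes; its unit normal b is the "characteristic direction", and the
component b_i is gene i's contribution to the separation. We use the
shrinkage-regularized form

b ∝ ((1 − γ) Σ_pooled + γ I)⁻¹ (μ_case − μ_ctrl),

with Σ_pooled the pooled within-class sample covariance (denominator
n − 2). γ interpolates between classical LDA (γ = 0, singular whenever
genes outnumber within-class degrees of freedom) and the raw class-mean
difference (γ = 1). The default γ = 0.5 is a conventional midpoint for
p ≫ n expression data; it is exposed everywhere and results should be
checked for stability in γ. The sign convention makes case samples score
at least as high as controls on average. With p genes and n samples the
solve is routed through the Woodbury identity (an n × n system), so
permutation testing over thousands of genes is cheap; a dense solve is
used when p ≤ n, and the two paths agree to 1e-10 in tests.

**Significance.** The null distribution of |b_i| is obtained by refitting
the direction under random reassignments of the class labels (class sizes
preserved). The two-sided p-value is the inclusive exceedance fraction
with a +1 pseudocount in numerator and denominator, so p ∈ [1/(n_perm+1),
1]; inclusive ties make the p-values conservative. q-values are
Benjamini–Hochberg step-up. The permutation floor interacts with BH: with
m genes and k true discoveries, q < α at the floor requires roughly
n_perm ≳ m/(α k); the discovery recipes default to n_perm = 1000 and the
acceptance checks use 2000 at m = 1000, k = 20. A practical caveat
observed in testing: for a truly shifted gene the permutation null is
overdispersed when classes are small (random label splits of a bimodal
gene still produce large mean differences), so with fewer than ~15
samples per class even 3-SD effects may not reach the floor; the study
conditions (20 + 20) are comfortably past this regime.

**Projection.** score_s = Σ_i b_i (x_is − x̄_i·), with genes centered by
their means over the projected matrix's own samples. Centering makes
projections invariant to per-gene offsets and lets independently
normalized validation cohorts be projected without any parameter leaking
across datasets. When restricted to a regulon, the sub-vector of b is
*not* renormalized: the score keeps the regulon's relative weight within
the global direction, which is what "projecting the direction on a gene
set" means here.

## Regulon activities and their correlation

A transcription factor's per-sample activity is estimated as the
projection restricted to its regulon. Before correlating two factors,
shared targets can be removed from one regulon (`exclusive_regulon`), so
that a high correlation reflects co-varying activities rather than
common membership. Pearson p-values use the exact t transform; Spearman
uses midranks with the t approximation. The latent-regulon generator
shows the estimator recovers a planted coupling ρ = 0.95 within ±0.1 at
n = 60 and is unbiased under ρ = 0 (the null mean was verified against
500 independent draws; the fixed-seed null check uses 200 replicates so
that its Monte Carlo SE, ~0.009, is well below the 0.05 acceptance band).

## RNA-seq differential expression

Fold change is the ratio of group means on the linear RPKM scale with a
pseudocount (default 1) added to both means; testing is a Welch
(unequal-variance) t-test on log2(RPKM + pseudocount), which respects the
heavy-tailed, heteroskedastic nature of RPKM. Genes at zero in both
groups carry no information and an undefined fold change and are dropped
before testing; a gene with zero variance and equal means in both groups
gets p = 1. Calls use q < 0.05 and a 2-fold threshold by default; both
are configuration-exposed, as is the pseudocount and (through the module
surface) the test itself. Count-based negative-binomial models are out of
scope — inputs are normalized RPKM matrices, not read counts.

## Consensus and overlap statistics

Consensus genes are those called in the same direction on both platforms.
Overlap against a set of D annotated genes in a universe of N is
summarized by the expectation nD/N, fold-enrichment ratio k/(nD/N) and a
one-sided hypergeometric tail (Fisher exact): P[X ≥ k] for enrichment,
P[X ≤ k] for depletion. The gene universe defaults to the genes measured
on *both* platforms after alignment — the defensible implicit universe —
and is overridable. Venn partitions of up to three sets are exact region
counts by membership pattern.

## Flux fitting and ATP attribution

The metabolic model is a stoichiometric matrix S (metabolites ×
reactions) with flux bounds; exchange reactions carry one metabolite
across the boundary, and with the ``{met: −1}`` convention a positive
flux is secretion, matching the sign convention of measured rates
(uptake < 0). The fitted distribution solves

min Σ_r |v_r|  s.t.  S·v = 0,  lb ≤ v ≤ ub,  v_j fixed to measured rates,

the parsimonious reading of "minimizing the sum of all fluxes", which is
well-posed for reversible reactions. |v| is linearized by splitting each
flux into non-negative forward/backward parts; the LP is solved with
HiGHS at 1e-10 feasibility tolerances, and every accepted solution is
re-checked to satisfy ‖S·v‖∞ ≤ 1e-9. Infeasibility reports the fixed
exchanges so the offending measurements can be found.

Total ATP turnover is Σ_r max(0, s_ATP(r)·v_r) — production, which at
steady state equals consumption. ATP is modelled as a cycling species:
synthesis lumps produce it, a demand reaction consumes it.

Attribution follows the measured exchange rates: lactic fermentation is
credited at 1 ATP per lactate secreted (Embden–Meyerhof substrate-level
phosphorylation, 2 ATP per glucose → 2 lactate; the coefficient is a
parameter), and each branched-chain amino acid at uptake × its maximal
ATP yield per unit uptake. The yield LP maximizes ATP consumption with
the substrate's uptake fixed at 1 and all other *organic* uptakes closed
(oxygen and the model's declared inorganic exchanges stay open) —
"full degradation and oxidation". Yields are recomputed from whatever
model is loaded, never hard-coded. The remainder fraction ("other")
absorbs oxidative metabolism of other substrates; tiny negative
fractions (> −1e-6, LP round-off) are clamped to zero and anything
beyond that is an error.

## Synthetic data: what it does and does not emulate

* **Two-class matrices** — log-normal baseline intensities
  (log2 mean 7, SD 2), Gaussian log-scale noise (SD 1), planted genes
  shifted by ±effect·SD in the case class. Defaults (1000 genes, 20 + 20
  samples, 10 up + 10 down at 3 SD) mirror a well-powered two-cohort
  microarray comparison. Gene-level structure depends only on the seed,
  per-sample noise also on a stream index, so discovery and held-out
  cohorts share planted genes. RPKM mode exponentiates to a linear,
  non-negative scale.
* **Latent regulons** — disjoint consecutive gene blocks whose members
  load on per-sample latent activities correlated at a chosen coupling;
  ground-truth latents are returned. There is deliberately no class
  structure: a class shift shared by two regulons would correlate their
  activities even at zero coupling and mask estimator bias. The
  correlation-recovery checks therefore construct the projection
  direction from the known loadings; direction *estimation* is exercised
  by the two-class recoveries.
* **Toy metabolic network** — 14 reactions: glucose fermentation
  (2 ATP), a respiration lump (30 ATP/glucose), Leu/Ile/Val oxidation at
  authored yields 33/31/25 ATP per unit (distinct so that attribution
  errors are detectable; they are testing constants, not claims about
  human metabolism), O2/CO2/NH4 exchanges and an ATP demand.
* **Uptake profiles** — uniform draws over per-role magnitude ranges
  (glucose uptake 0.25–0.6, lactate secretion 0.05–0.5, each BCAA
  0.005–0.12, nominal mmol·gDW⁻¹·h⁻¹), feasible for the toy model by
  construction (max lactate ≤ 2 × min glucose). Across these ranges the
  BCAA share of ATP spans from a few percent to most of the budget.

What passing these tests shows is that the estimators and solvers behave
correctly on data with the assumed structure; real microarray/RNA-seq
data add probe effects, batch structure, library-size artifacts and
non-Gaussian noise that the generators do not model, and a real
genome-scale network has internal degrees of freedom the toy model lacks.

## Numerical and design choices

* Duplicate gene rows collapse by arithmetic mean on the stored scale;
  identifiers are opaque case-sensitive strings (no probe/symbol
  mapping).
* Expression tables round-trip through text at full float precision
  (`%.17g`); pipeline artifacts are written at 12 significant digits with
  a configuration-hash header, and the hash excludes the output
  directory so that reruns anywhere are byte-identical.
* Degenerate direction (identical class means) falls back to a fixed
  unit vector rather than 0/0.
* PCA signs are fixed by making each component's largest-magnitude gene
  loading positive.
* SBML import/export covers Level 3 core only — stoichiometry plus a
  reversibility flag; bounds beyond reversibility, the ATP species tag
  and role annotations live in the JSON dialect.
* The pipeline treats stages as isolated: a failing stage is recorded in
  the manifest and later stages still run; the manifest carries input
  paths, parameters, seeds and output checksums.

## Known limitations

* The permutation test refits the direction per permutation; at very
  large n_perm × genes this is the dominant cost (Woodbury keeps it to
  ~n × n solves).
* One-sided overlap tests only; two-sided Fisher is out of scope.
* ATP attribution assumes net lactate secretion; lines that consume
  lactate need a different crediting convention.
* The consensus recipe assumes both platforms were analyzed at the same
  α; it does not model between-platform dependence, so the Fisher p is a
  descriptive enrichment measure, not a calibrated joint test.
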