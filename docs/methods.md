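# Methods

## The Mendelian segregation model

Consider a pedigree of N_i individuals split into N_b *base* individuals
(both parents unknown) and N_d *descendants* (both parents known). With P
the parent-adjacency matrix (two 1's per descendant row, a single 2 under
self-mating, zero rows for base individuals), the matrix

    M = I − ½P

maps genetic values to within-family deviations: row i of M u is
u_i − ½(u_sire + u_dam). Under a base-first topological order M is unit
lower triangular with M_bb = I and M_bd = 0, so

    u = M⁻¹ [u_b; φ],   u_d = D u_b + M_dd⁻¹ φ,   D = −M_dd⁻¹ M_db.

D is the *transmission matrix*: row d gives the expected fraction of
descendant d's genome contributed by each base individual (rows sum to 1,
consanguinity accumulates multiple contributions). In classical pedigree
BLUP the Mendelian-sampling deviations φ are unobservable random terms; with
genome-wide genotypes W they have a *molecular* realization. Writing
W_b, W_d for the base/descendant dosage blocks, the accumulated deviation
design is

    S = W_d − D W_b,

each descendant's dosages minus its pedigree expectation from the base.
Replacing φ's contribution with S m (m the vector of marked effects) gives
the genetic-value decomposition u_d = D u_b + (W_d − DW_b) m, and, adding
the direct marker term W_d m carried over from the combined
individual+marker model, the phenotype model

    y = μ + Z_d D u_b + Z_d (2W_d − DW_b) m + e.

Assumptions: u_b ~ N(0, I σ²_u), m ~ N(0, I σ²_m), e ~ N(0, I σ²_e), all
mutually uncorrelated; complete genotypes on every individual; every
descendant has both parents in the pedigree (individuals with exactly one
known parent are rejected — no phantom-parent grouping); a single record per
phenotyped individual; variances known, not estimated.

Two details are deliberately configurable rather than resolved:

* **Marker coefficient for prediction.** The phenotype model uses
  2W_d − DW_b while the pure transmission decomposition uses W_d − DW_b.
  Fitting always uses the phenotype model; the composition of predicted
  genetic values defaults to the same 2W_d − DW_b coefficient (option
  `eq7`) for internal consistency, with `eq6` exposing the
  transmission-only alternative. Both are reported in study metadata.
* **Base predictions.** Base individuals are reported as û_b alone (their
  marker term W_b m̂ is part of the descendants' expectation through D, and
  adding it would double-count when comparing against descendants).

Only descendant phenotypes enter the MS likelihood; records on base
individuals are dropped with a warning (base individuals are the anchor of
the transmission term, not observations on it).

## Reference models

* `II` (pedigree BLUP): y = μ + Zu + e, Var(u) = A σ²_u with A from the
  recursive tabular method.
* `M` (SNP-BLUP): y = μ + ZWm + e, Var(m) = I σ²_m. The genomic
  relationship is taken as the raw cross-product G = WW′ — no allele
  frequency centering or heterozygosity scaling — because that is the form
  under which SNP-BLUP and GBLUP coincide exactly; a centered/scaled variant
  exists behind an explicit option and defaults off.
* `MI`: y = μ + Zu + ZWm + e; the reported genetic value is the total
  û + Wm̂ (u is a residual polygenic term), with both components exposed.

## Solving the mixed-model equations

With a mean-only fixed effect and random blocks (T_k, K_k, σ²_k), the MME
are assembled with ridge terms K_k⁻¹ σ²_e/σ²_k and solved by direct dense
factorization while the system dimension stays below 1,500. Above that —
dense SNP panels where the number of effects far exceeds the number of
records — the solver switches to the exact observation-space equivalent:
factorize V = Σ_k T_k K_k T_k′ σ²_k + I σ²_e (an n×n system, n = records),
estimate μ by GLS and back-map each block's BLUP as σ²_k K_k T_k′ V⁻¹
(y − μ̂). Both paths give identical solutions (tested); the closed-form GLS
oracle `gls_oracle` is retained in the package purely as a test reference.
A⁻¹ is built sparsely from the factorization A⁻¹ = M′ Θ⁻¹ M (Henderson's
rules with inbreeding), where Θ is diagonal with Θ_bb = 1 and
Θ_dd,i = ½ − ¼(F_sire + F_dam); dense inversion of the tabular A is used as
a cross-check below 500 individuals. Degenerate inputs: a monomorphic
marker column receives exactly zero effect (its design column is constant
and μ absorbs it); a fully confounded single record resolves to μ̂ = y,
û = 0.

## Known-variance assignment in the simulation study

The simulation scenarios fix total phenotypic variance V_p = 1 and
heritability h² = 0.4, split between QTL (fraction q) and an infinitesimal
polygenic component: σ²_qtl = q·h²·V_p, σ²_poly = (1−q)·h²·V_p,
σ²_e = (1−h²)·V_p. The fitted models receive the variances used to simulate,
mapped per model:

* `II`: σ²_u = h²·V_p (all genetic variance through the pedigree);
* `M`: σ²_m = h²·V_p / (2Σ_j p_j(1−p_j)) — markers must carry everything;
* `MI`/`MS`: σ²_u = σ²_poly and σ²_m = σ²_qtl / (2Σ_j p_j(1−p_j)) — the
  individual term carries the infinitesimal share, the markers the QTL
  share.

Allele frequencies p_j are computed on the training individuals (the
phenotyped cohorts); frequencies from the base cohort are available as an
option. The 2Σp(1−p) spread assumes Hardy–Weinberg/linkage-equilibrium
heterozygosity and is the standard device for converting an additive
variance into a per-marker effect variance.

## Simulator

The generator emulates a QMSim-style two-phase design at desk scale.

**Historical phase** (LD buildup): N_e = 100 diploid individuals random-mate
for 100 discrete generations; initial allele frequencies are Uniform(0.1,
0.9) with haplotypes in linkage equilibrium. These parameters produce
adjacent-marker r² around 0.5–0.8 at 2,000 SNP/Morgan density and realistic
decay with distance; loci fixed by drift stay in the panel as monomorphic
markers. **Study phase**: a base cohort of 25 draws founder haplotypes from
the final historical generation without replacement, then cohorts of 40/40/
40/40 are bred by random mating with family size 1 (distinct sire–dam pairs,
equal sex ratio), giving 185 individuals: 25 base, 120 phenotyped training
individuals (cohorts 1–3), 40 target individuals whose phenotypes are
simulated but masked from every fit. Genomes carry 2 chromosomes of 1
Morgan; 10 QTL per chromosome are placed uniformly among the SNP but never
enter the marker panel handed to the models.

Recombination uses the Haldane map function (no interference). Transmission
is simulated per inter-locus interval: the gamete's parental phase switches
between adjacent loci at map distance d with probability (1 − e^(−2d))/2,
and with probability ½ across chromosome boundaries. This is
distributionally identical at the loci to dropping Poisson(length)
crossovers at uniform positions, and vectorizes cleanly; the test suite
recovers both Mendel's 1:2:1 ratios and the Haldane recombination fraction
at 20 cM from simulated meioses.

QTL effects are standard normal, rescaled by one common factor so the
realized QTL variance (ddof = 1) in the base cohort equals σ²_qtl exactly;
QTL values are centred on the base-cohort mean. The polygenic component
follows the pedigree recursion u_i = ½(u_s + u_d) + φ_i with
Var(φ_i) = σ²_poly(½ − ¼(F_s + F_d)), so inbreeding shrinks within-family
variance exactly as in the Θ factorization above. Phenotypes are
y = u_qtl + u_poly + e with e ~ N(0, (1−h²)V_p). One RNG stream per
replicate, seeded as base_seed + replicate index; identical seeds give
byte-identical replicates.

**What the generator does not emulate:** selection, mutation, overlapping
generations, sex chromosomes, genotyping error or missingness, non-additive
gene action, and QMSim's exact historical-population settings (which the
replicated design does not pin down). Accuracies from this simulator
therefore validate the *relative* behaviour of the models under the stated
genetic architectures, not absolute accuracies in any real population; the
replicated-study tests use ±0.05 bands around the reported means
accordingly.

## Replicated accuracy study

`replicate_study` simulates n independent replicates, fits the requested
models on training phenotypes, and scores Pearson correlations between
predicted and true total genetic values separately for the training cohorts
and the target cohort (base individuals enter neither subset; their role
differs too much across models to compare). Summaries are plain means with
standard errors — Fisher-z averaging is available but off by default, since
plain means are what comparison tables in this literature report — plus the
MS/M relative accuracy 100·mean(acc_MS)/mean(acc_M) and two-sided paired
t-tests across replicates (the simplest valid paired design; degenerate
zero-variance differences report p = 1 for zero mean, else p = 0). A failed
replicate is dropped with a warning; more than 10% failures aborts. The
bundled study script and acceptance run use 100 replicates per scenario,
enough to hold the standard error of each mean accuracy near 0.01–0.02
while keeping a full two-scenario run within a few minutes on one CPU.

## Known limitations

* Variance components are required inputs; no REML/Bayesian estimation.
* Complete genotype data and two known parents per descendant are hard
  requirements — no imputation, phantom parents, or heterogeneous-variance
  handling of ungenotyped individuals.
* Marked effects are homogeneous-variance normal; no heavy-tailed priors,
  haplotype-based terms, or marker weighting.
* Base individuals are assumed independent (Var(u_b) = I σ²_u); a genomic
  covariance among base individuals would likely improve the MS model in
  marker-rich settings and is not implemented.
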