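# Methods

This note documents the models implemented in `epistasim`, the defaults
and their rationale, the numerical choices, and what the synthetic inputs
do and do not represent.

## The two-locus model

A fitness trait is controlled by two unlinked biallelic loci A and B. The
genotype–phenotype map (G-P map) is a 3×3 grid of genotype class means,
indexed by the number of copies of the alternative allele at each locus
(0 = AA/BB, 1 = heterozygote, 2 = aa/bb). Maps used in selection
simulations are min-max scaled to [0, 1] so that selection intensities
are comparable across patterns; a constant map cannot be scaled and is
returned unchanged with a warning.

Cis and trans double heterozygotes are assumed phenotypically equivalent
(the map is a function of genotype, not phase), which is what lets the
diploid fitness of an ordered gamete pair be read off the 3×3 grid.

### Deterministic dynamics

Selection acts on viability proportional to the map value. With gamete
frequencies x = (x_AB, x_Ab, x_aB, x_ab) and recombination fraction c,
one generation is

    x1' = (x1 w1 − c wH D)/w̄,   x2' = (x2 w2 + c wH D)/w̄,
    x3' = (x3 w3 + c wH D)/w̄,   x4' = (x4 w4 − c wH D)/w̄,

where wi = Σj w(i,j) xj, w̄ = Σ xi wi, wH is the double-heterozygote
fitness and D = x1x4 − x2x3. The recursion is verified against a
brute-force oracle that enumerates all 16 ordered gamete pairs, weights
them by frequency and fitness, and applies recombination explicitly;
agreement is required to 1e-12 and the oracle is the authoritative
definition.

Defaults: c = 0.5 (unlinked loci), 200 generations, initial linkage
equilibrium (D0 = 0), the 25-point initial-frequency grid
{0.1, 0.3, 0.5, 0.7, 0.9}². A locus is *fixed* when its minor-allele
frequency falls strictly below 1/(2N) with N = 1000; deterministic
frequencies never reach 0 exactly, so a cutoff is needed, and the strict
inequality makes the boundary value 1/(2N) itself count as segregating.
Frequencies are renormalised to the simplex each step to absorb
round-off.

A noteworthy property: the additive-by-additive pattern at
p = q = 0.5 holds its allele frequencies exactly (the symmetric point is
an allele-frequency equilibrium) while selection builds coupling
quasi-LD; gamete frequencies converge to D ≈ (√2 − 1)/4 and the loci
never fix. Away from the symmetric point the pattern collapses quickly.
Selection between *unlinked* loci generating D ≠ 0 ("quasi-LD") is why a
joint, LD-aware additive variance is needed.

## Catalogue of G-P maps

The study catalogue has 56 entries:

1. the neutral (constant) map;
2.–51. one representative of each of the 50 equivalence classes of
   non-constant binary (0/1) maps under the 16-element group generated by
   row reversal (allele swap at A), column reversal (allele swap at B),
   transposition (locus swap) and value inversion (trait polarity);
   representatives are the lexicographically smallest members and are
   listed in that order, which is reproducible but otherwise arbitrary;
52.–56. additive×additive, additive×dominance, dominance×dominance,
   overdominance (single-locus heterozygote advantage at A, neutral at
   B) and additive.

The class count (50 non-constant + 1 constant) is verified two ways:
explicit orbit enumeration over all 512 binary matrices, and Burnside's
lemma. A map is classified *epistatic* when the interaction sum of
squares of the equally-weighted saturated two-way decomposition exceeds
1e-9 (values are exact rationals after scaling, so the tolerance is
nominal). Exactly 51 of the 56 entries are epistatic; the five
non-epistatic entries are the neutral map, the additive map, the
overdominance map, and the two binary classes that are functions of one
locus only — which the canonical ordering happens to place at indices 6
and 29.

## Variance decomposition

Two decompositions are computed at every generation.

**Joint additive variance.** The average effects (αA, αB) solve the 2×2
normal equations of the weighted least-squares regression of genotypic
value on the two reference-allele dosages, with genotype frequencies
given by random union of gametes, Var(dosage) = 2pq per locus and
Cov(dosA, dosB) = 2D. Then

    VA_joint = 2 pA qA αA² + 4 D αA αB + 2 pB qB αB².

This equals the variance of fitted values of the regression (asserted to
1e-10 against an independent weighted-regression oracle). At complete
gametic coupling the dosages are collinear; the pseudo-inverse keeps the
fitted variance well defined. At linkage equilibrium the αs reduce to the
familiar marginal average effects α = p(m2−m1) + q(m1−m0).

**NOIA statistical decomposition.** Each locus contributes an orthogonal
basis (mean, centred dosage, heterozygosity indicator orthogonalised
against both) under its own genotype-frequency weights; the two-locus
design is the Kronecker product, solved exactly for the 9 effects. The
variance of each non-mean effect is its squared effect times the basis
norm. This construction is algebraically the NOIA statistical
formulation: orthogonal at arbitrary per-locus genotype frequencies
*under independence*, with components summing to VG (asserted to 1e-10).
Under linkage disequilibrium the loci are deliberately still treated as
independent — no two-locus decomposition is orthogonal under joint LD
and Hardy–Weinberg disequilibrium, and association-testing practice uses
exactly these incomplete marginal decompositions, whose behaviour is the
object of study. Orthogonality failure under LD (component sum ≠ VG) is
therefore expected and tolerated.

Components shifted by adding a constant to the map are unchanged;
multiplying the map by k scales every component by k². Negative
components within 1e-12 of zero are clipped; larger negatives raise.

## LD projection onto observed SNPs

Each causal locus has an observed SNP at the same allele frequency with
signed gametic correlation r (configured via r², taken positive /
coupling). The per-locus conditional matrix P(causal genotype | observed
genotype) comes from the gamete-pair model: gamete-level conditionals
P(C|M) = f(CM)/p etc. convolved over the two independently transmitted
gametes. The observed map is the double blur

    M_O(i,j) = Σk Σl P_A(k|i) P_B(l|j) M_C(k,l),

recomputed fresh each generation (only the causal variants are
inherited; the linked SNPs are recomposed every generation at the
configured LD). The observed pair carries D_obs = rA·rB·D_causal, so at
|r| = 1 the observed system is the causal system exactly. These choices
reproduce the classical decay laws at HWE/LE — observed VA = r²·VA,
observed VAA = rA²rB²·VAA, dominance components decay as r⁴ — which the
test suite asserts across the catalogue at 1e-10. The default r² grid is
{1.0, 0.8, 0.6, 0.4, 0.2}.

## Detection of additive variance (expected-F power)

The study design fixes a sample size n, broad-sense heritability H² at
generation 0, and Bonferroni thresholds α1D, α2D. The environmental
variance VE = VG0·(1−H²)/H² is set once per simulation from the causal
genetic variance at generation 0 and held fixed; selection then erodes
VG, so realised heritability declines along a trajectory.

Detection is deterministic: the expected F statistic
(V_model/k)/((V_phen−V_model)/(n−k−1)), with V_phen = VG + VE of the
observed system, is compared with the upper-α quantile of the central
F(k, n−k−1) distribution. Model variances per parameterisation:

| test          | k | V_model                      |
|---------------|---|------------------------------|
| A (1D)        | 1 | VA_l per locus               |
| A+D (1D)      | 2 | VA_l + VD_l per locus        |
| marginal (2D) | 4 | VA1+VD1+VA2+VD2              |
| epistatic (2D)| 4 | VAA+VAD+VDA+VDD              |
| full (2D)     | 8 | VG                           |

Accounting: a significant 2D test, or 1D significance at both loci,
credits the joint additive variance VA_joint; 1D significance at a single
locus credits that locus's additive component, clipped at VA_joint (under
repulsion quasi-LD a marginal component can exceed the joint additive
variance, and detected variance is never allowed to exceed what exists).
Variances below 1e-12 are treated as exactly zero so that round-off on
degenerate maps cannot reach significance. Sweep summaries report
Σ detected / Σ created VA_joint over all runs and generations as a
percentage.

Defaults: n = 5000, H² = 0.5, α1D = 5×10⁻⁸ (0.05/10⁶ SNPs),
α2D = 1×10⁻¹³ (≈ 0.05/C(10⁶,2) SNP pairs).

**Calibrated three-way comparison.** When asking *which* of the three
scan strategies (1D additive, 1D genotype, 2D full) is the most powerful
for each pattern, the default design is uninformative: with n = 5000 and
H² = 0.5 every strategy detects essentially everything and the
comparison degenerates into ties. The comparison is therefore run at
`CALIBRATED_COMPARISON_DESIGN` (n = 700, H² = 0.11, Bonferroni
thresholds unchanged), chosen so that the full 2D test is only marginally
significant at complete LD. In this regime the trade-off resolves
sharply: at r² = 1 the full 2D test is strictly the most powerful for 44
of the 56 patterns, while any reduction in LD (r² ≤ 0.8) collapses the
interaction components (which decay as r⁴) below the 2D threshold and
the 1D genotype (A+D) test dominates — the full test is then almost
never best. "Most powerful" means the strict unique argmax of summed
detected additive variance; exact ties (the separable patterns, for
which the A+D and full tests detect identically) credit no strategy.
The behaviour is stable to n within roughly ±2% at this heritability.

## Genetic algorithm over map space

Candidates are 3×3 maps scaled to [0, 1]. Scoring runs the deterministic
recursion from the 25-point frequency grid for G generations; a candidate
must keep at least a fraction `survival_frac` of those 25 runs unfixed to
be eligible, and its score is VA_joint summed over generations
g0+1..min(fixation, G) and over runs. Each round keeps the top s by score
(elitism: the best score provably never decreases), adds m Gaussian
mutants (sd `sigma_m` per cell, then min-max rescale) per survivor, and
refills the pool with fresh uniform-random maps. If nothing passes the
survival criterion the pool is reinitialised. Ties in selection break by
pool order then lexicographic map comparison, making selection
order-invariant.

Defaults: C = 100 candidates, s = 5, m = 10, G = 100, g0 = 10, R = 50
rounds, survival_frac = 0.8, sigma_m = 0.05, N = 1000, c = 0.5. The
Gaussian mutation kernel is a design choice; any symmetric perturbation
followed by rescaling preserves the invariants that matter (bounded,
scaled candidates; seeded reproducibility). Winning maps show
heterozygote advantage, and the variance they maintain is mostly
non-additive: averaged over the maintained phase VA_joint/VG < 0.5 —
purely additive deleterious maps cannot pass the survival criterion at
all, because selection fixes them from every start.

The acceptance test runs a reduced search (C = 40, m = 3, R = 20) to stay
within a few minutes of CPU; the elitism and survival properties it
asserts are size-independent.

## Stochastic population simulations

Diploid populations of N = 1000 individuals, initialised at allele
frequency 0.5 per locus (HWE, LE). Phenotype P = g + e with
e ~ Normal(0, VE), VE fixed at generation 0 from the *expected* genetic
variance at the initial frequencies (every replicate shares one VE) and
the configured H²0 (default 0.5). Each generation, 500 parent draws are
made with replacement with probability proportional to max(P, 0), paired
into 250 pairs, each producing 4 offspring; each offspring receives one
gamete per parent formed with recombination fraction c. A replicate stops
when an allele count reaches 0 or 2N (exact loss/fixation — the
stochastic engine does not need the deterministic 1/(2N) cutoff) or at
200 generations.

Two design details matter for consistency with the deterministic theory:

- *Replacement.* Sampling parent slots with replacement makes a
  genotype's expected gamete contribution exactly proportional to its
  expected selection weight. Without-replacement sampling of 500 of 1000
  saturates the weights of the fittest individuals and measurably damps
  the selection response.
- *Effective fitness.* Because negative phenotypes are clamped to zero
  before sampling, the expected selection weight of genotype value g is
  E[max(g+e, 0)] = g·Φ(g/s) + s·φ(g/s) (s = √VE), not g itself. The
  infinite-population mean of the engine is therefore the deterministic
  recursion run on this *effective* map, exposed as
  `effective_fitness_map` (identity at VE = 0). The consistency test
  compares 300-replicate mean trajectories against that exact mean-field
  limit and finds agreement within Monte-Carlo error; against the raw map
  the comparison would show the small systematic flattening that
  phenotypic (rather than genotypic) selection necessarily introduces.

Drift does real work here: A×A populations started at the deterministic
equilibrium (0.5, 0.5) fix within 200 generations in nearly all
replicates, because the symmetric point is unstable to perturbation of
the allele frequencies.

## What the synthetic inputs do and do not represent

All inputs are generated internally: the catalogue supplies the G-P maps
and the simulators supply the populations. The setup emulates a fitness
trait under sustained directional selection with exactly two interacting
causal loci, unlinked, with no mutation, migration, population structure,
or genotyping error, and observed SNPs that share the causal allele
frequency exactly. Passing tests therefore demonstrate the internal
consistency of the theory and its implementation — not that real complex
traits behave this way. In particular, the power results compare expected
test statistics on deterministic variance components; sampling noise in
real genotype data, multi-locus architectures and frequency mismatches
between SNPs and causal variants would all further erode the detection
percentages reported here.

## Problem sizes

The shipped analyses use the full 56-map catalogue, the 25-point
frequency grid and 200-generation horizons throughout. The stochastic
consistency analysis uses 300 replicates (the study's replicate count)
over the first 10 generations; the genetic-algorithm acceptance run uses
the reduced pool described above; stochastic power uses 50 replicate
populations per map.
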