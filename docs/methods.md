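# Methods

## Differential expression

Expression matrices are gene × sample tables on the log2 scale (microarray
intensities, or log2(count+1) for count data). For a two-group contrast the
per-gene fit is the ordinary two-sample model: effect = difference of group
means (log2 fold change), pooled within-group variance s² on
d = nₐ + n_b − 2 degrees of freedom, and unscaled variance v = 1/nₐ + 1/n_b.

Variances are moderated with an empirical-Bayes prior: the marginal
distribution of log s² under a scaled-χ² prior gives
e_g = log s²_g − ψ(d/2) + log(d/2), the prior degrees of freedom d₀ solve
ψ′(d₀/2) = var(e) − ψ′(d/2) (d₀ = ∞ when the excess is non-positive,
so all variances shrink fully to the prior), and the prior variance is
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). The moderated statistic uses
s̃² = (d₀s₀² + d·s²)/(d₀ + d) and is referred to a t distribution on
d₀ + d degrees of freedom (standard normal at d₀ = ∞). The trigamma
inverse is computed by monotone Newton iteration. A test run against
limma's `lmFit`/`eBayes` on an identical matrix agrees in the
hyperparameters, coefficients and p-values to ~1e-14.

DEG calling uses strict inequalities in both dimensions: stringent
(p < 0.005 and |log₂FC| > 1) for disease-versus-normal contrasts, relaxed
(p < 0.05 and |log₂FC| > 0.5) for disease-subtype and non-lesional-versus-
normal contrasts. No multiple-testing correction enters the calling path —
the calling regime is deliberately a raw-p rule — but a Benjamini–Hochberg
FDR column is emitted alongside for inspection. When an input table carries
duplicate gene symbols, the row with the largest interquartile range is
kept; the rule is deterministic and favors the most informative probe.

## Cross-dataset logic

DEG sets are intersected exactly after upper-casing symbols. Average
expression values that seed the pathway model pool samples across datasets
(one grand mean per gene over all disease-group samples) rather than
averaging per-dataset means; the shipped per-disease table of average
expressions is used verbatim by the model stage, so this choice does not
propagate into the dynamic model. miRNA hit lists are joined to target
genes through a local mapping table; miRNAs absent from the table are
reported, not fatal.

## Enrichment

Over-representation of a DEG set in a pathway is the upper-tail
hypergeometric probability of the observed overlap, with the universe equal
to the genes measured in that dataset (the test's null should condition on
what could have been called) and pathway sets intersected with the universe
first. Raw p ≤ 0.05 (inclusive) defines significance; only
over-representation is tested. The cross-dataset step intersects the
per-dataset significant sets. The implementation is verified against
exhaustive enumeration of all draws for universes up to 12 genes.

## The IL-17 pathway models

The two shipped models encode the figure-level sub-pathway of IL-17
signaling for psoriasis and cSCC. Species are genes, grouped gene families
(complexes), inhibitors, or terminal biological processes; grouped
memberships are fixed: in psoriasis MAPKs = {MAPK13, MAPK14}, chemokines =
{CXCL1, CXCL2, CXCL5, CXCL8, CXCL10, CCL2, CCL7, CCL20}, antimicrobial =
{S100A7, S100A8, S100A9, LCN2}, tissue remodeling = {MMP1, MMP9}, C1 =
{HSP90, ACT1}, C2 = {TAB2, TAB3, TAK1}, C3 = {ANAPC5, A20}, AP-1 = {FOSL1,
FOS}; the cSCC groups differ as published (five MAPKs, four chemokines, six
antimicrobial peptides, four MMPs, AP-1 = {FOSL1, JUN}).

Initial values: measured genes take their per-disease average expression;
grouped species take the mean over members with unmeasured members
contributing 0.5; unmeasured singletons take 0.5 (the midpoint of the
nominal 0–1 activity range); biological processes start at 0 so their
trajectories read out accumulated pathway output.

Kinetics. The underlying diagrams distinguish only activation and
inhibition reactions, so the kinetic law is a modeling choice here:

- activation S → T is mass-action conversion: flux k·[S] leaves S and
  enters T. With m > 1 outbound activation edges each edge carries
  k·[S]/m, so branching never inflates a species' total outflow.
- inhibition I ⊣ T is catalytic removal: flux k·[I]·[T] drains T, leaving
  I unchanged.

Conversion (rather than catalytic production) is what produces the
observed saturation: upstream pools drain into the terminal processes, so
every process trajectory is non-decreasing and plateaus, and an
activation-only network conserves total mass exactly — both properties are
tested numerically. Inhibition only removes mass, so with inhibitors the
total is non-increasing.

Wiring follows the canonical cascade: ligands (IL-17A/F, and IL-17D via its
receptor in psoriasis) → receptor/adaptor complex C1 → TRAF6 → TAK1 complex
C2 → the NF-κB arm and the MAPK → AP-1 arm → effector families → processes
(chemokines → neutrophil recruitment; antimicrobial peptides → immunity to
extracellular pathogens; MMPs and cytokines → autoimmune pathology). In
cSCC the TNF → TRADD → NF-κB arm, the JUND input into the AP-1 pool, and
the mRNA-stability regulators (ELAVL1 stabilizing chemokine transcripts,
SRSF1 acting on the MMP transcripts) are additional inputs. Inhibitors sit
on the nodes they adjoin: IKKε restrains the receptor-proximal complex
(psoriasis) or the NEMO/IKK node (cSCC), the A20/ANAPC5 complex terminates
IKKε activity, and TRAF2 restrains the receptor-proximal complex in cSCC.

Rate constants default to 1 per time unit; the exact diagram publishes no
rates, so individual constants were calibrated within [0.25, 4] — mostly
the NF-κB/AP-1 routing splits and the effector delivery rates — so that the
simulated process outputs reproduce the published dynamics: in psoriasis
the three processes plateau near 28 units around t ≈ 9.5 (the shipped model
gives 28.4 at 9.50 for autoimmune pathology), in cSCC they approach ≈ 21 by
t = 10 (shipped: 21.9). Every constant is recorded in the fixture JSON.
Integration uses LSODA with rtol 1e-8, atol 1e-10 on a 201-point uniform
grid over [0, 10] dimensionless time units.

## Sensitivity analysis

A gene enters the model only through its initial value, so "genes as
inputs" means initial-value sensitivities. For output Y and input X with
initial X₀ > 0, a central finite difference with relative step 1e-3
(absolute step 1e-3 at zero initials) gives s(t) = ∂Y(t)/∂X₀; the fully
normalized sensitivity n(t) = s(t)·X₀/Y(t) is summarized per (output,
input) pair by max |n(t)| over the grid, excluding early times where Y is
numerically zero (≤ atol). Classification flags entries strictly greater
than 1.5. Halving the step changes entries by far less than 1% (verified),
and on the X → M → Y conversion chain the finite differences match the
closed-form sensitivities to 1e-4.

A structural property of these kinetics is worth stating: in an
activation-only (hence linear, positive) network, Y(t) = Σ_Z c_Z(t)·Z₀ with
non-negative coefficients, so n_X(t) = c_X X₀ / Y ≤ 1 for every
non-inhibitor input at every time — a single conversion step realizes the
maximum, n ≡ 1. Values above 1 require the bilinear inhibition term, and
with the shipped models' modest inhibitor masses the summarized
sensitivities remain below the 1.5 bound: the > 1.5 classification flags no
inputs, and the analysis instead reports the sensitivity ranking, which
places the effector families (antimicrobial peptides, chemokines) first,
followed by tissue remodeling, IL1B, AP-1 and the MAPK pool. Reproducing
magnitudes above 1.5 for mid-cascade gene families would require either
rate constants outside the calibrated band, non-conversion kinetics, or
initial conditions far from the published expression values.

## Synthetic data

The microarray generator emulates post-normalization log2 intensities:
baseline + planted group shift + i.i.d. Gaussian noise, with a recorded
truth table (DEG flag, signed shift). The count generator draws
negative-binomial counts with group means 2^(baseline+shift) and
overdispersion α (variance μ + αμ²), returned on the log2(count+1) scale
used by the shared DE stage. Neither simulates probe-level structure,
batch effects, library-size variation, or gene–gene correlation; passing
tests therefore demonstrate correctness of the statistical machinery under
the generating model, not robustness to real-data artifacts. Default
condition: 2000 genes, 5 vs 5 samples, 5% DEGs at log2 shift 2, noise SD
0.5 — sized so a well-calibrated stringent regime recovers ≳ 90% of planted
DEGs while the null rejection rate stays at its nominal 0.005. All
generators derive per-stage substreams from one user seed by fixed offsets
and are bit-reproducible.

## Numerical and design notes

- Strict threshold inequalities keep DEG calling deterministic under ties.
- d₀ estimation clamps at ∞ for non-positive excess variance, avoiding
  negative trigamma arguments.
- The hypergeometric tail is computed by `scipy.stats.hypergeom.sf(x−1,…)`;
  x = 0 returns exactly 1.
- Enrichment emits a BH column but, as in the calling path, significance is
  decided on raw p.
- Sensitivity inputs default to gene-level species (roles gene/deg/complex);
  inhibitor species and the process outputs themselves are excluded.
- Problem sizes in tests and the analysis scripts (2000-gene cohorts,
  300-gene limma cross-check, 201-point grids) are chosen so the full suite
  runs in seconds while keeping every statistical check well-powered.

## Known limitations

- The dynamic model is a reconstruction: the published diagrams constrain
  species, groupings, roles and colors but not the full edge list or rates;
  alternative wirings consistent with those constraints exist, and the
  calibration (to the published peak values) does not identify them.
- Time units are dimensionless; concentrations are in arbitrary expression
  units, so only relative dynamics are meaningful.
- The DE stage covers two-group contrasts only (no paired designs or
  covariates), matching the study design it mirrors.
- Real-accession results (per-dataset DEG counts, specific biomarker
  lists, per-dataset enriched-pathway tables) require the original archives
  and are out of scope; the pipeline reproduces the procedure and artifact
  shapes on synthetic cohorts.
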