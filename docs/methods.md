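# Methods

## Electrophysiological models

**Cable analysis.** A perfused tubule is modelled as a finite leaky cable,
sealed at the collection end, with a constant current pulse *I₀* injected at
the perfusion end. The two-deflection variant is used: with deflections
ΔV₀ (injection end) and ΔV_L (far end), the length constant is
λ = L / acosh(ΔV₀/ΔV_L); the input resistance ΔV₀/I₀ together with λ gives
the core resistance per length r_c, the luminal resistivity ρ converts r_c
to a luminal diameter d = √(4ρ/(π r_c)), and the specific transepithelial
resistance is R_te = λ² r_c π d. The forward model (`forward_cable`) is the
exact algebraic inverse and doubles as the simulator's recording generator
and the round-trip oracle; the inversion is exact to floating-point
precision over the physiological grid (length 400–600 µm, diameter
15–30 µm, R_te 10–500 Ω·cm²). Deflections that do not decay along the
tubule (ΔV₀ ≤ ΔV_L) are rejected as non-invertible rather than fitted.

**Conventions.** All transepithelial voltages are lumen minus bath. The
luminal fluid resistivity defaults to ρ = 60 Ω·cm (physiological saline at
37 °C) and the temperature to 310.15 K; both are per-recording columns so a
rig can override them. The equivalent short-circuit current I′_sc =
V_te/R_te keeps the sign of V_te (lumen-negative voltage → negative
current); magnitudes can be taken downstream where a correlation should be
against transport strength. ΔV_te(amil) is reported signed
(basal − amiloride); the integration layer exposes a flag to correlate
against its magnitude, which is the default for the ENaC coupling analyses
because "more ENaC activity" means "more negative voltage".

**GHK dilution potentials.** The paracellular permeability ratio
β = P_Na/P_Cl is obtained from the NaCl dilution potential measured with
transcellular transport blocked (amiloride + hydrochlorothiazide) and the
bath switched to dilute NaCl. With the lumen at 145 mM and the bath at
30 mM, the bi-ionic GHK voltage equation is inverted in closed form:
a = exp(V_dp·F/RT), β = (Cl_lumen − a·Cl_bath)/(a·Na_lumen − Na_bath).
Potentials at exactly the pure-ion bounds ±(RT/F)·ln(145/30) ≈ ±42.1 mV
return the boundary solutions 0 and ∞; anything outside is an error, since
no permeability ratio can produce it. Activity coefficients are ignored
(concentrations enter the equation directly) and the liquid-junction
correction is assumed already applied upstream — both standard for this
solution pair.

## Targeted quantification

Transitions are kept only if (1) |mass error| < 10 ppm — strictly, so a
transition at exactly 10.0 ppm is rejected; (2) the chromatographic apex
falls inside the scheduled acquisition window; and (3) the transitions of a
peptide in a sample coelute. Coelution is made operational as: the maximum
apex-retention-time spread within a (peptide, sample) group must not exceed
a tolerance (default 0.2 min); while it does, the transition farthest from
the group's median apex is dropped (first in input order on ties). Groups
reduced below two transitions are dropped entirely, because coelution is
undefined for a singleton. Each rejected transition carries exactly one
primary reason code with precedence ppm > window > coelution > singleton.
Manual peak-shape validation of the original workflow has no automatic
equivalent; an optional signal-to-noise filter could stand in for it but is
deliberately not enabled by default.

Quantification is at MS2 level: peptide intensity is the sum of its
surviving transition areas, protein intensity the sum of its peptides. A
cell with no surviving transition is missing, never zero. Protein matrices
are normalized by log₂ transform followed by subtraction of column (sample)
means and then row (protein) means, each over observed entries; for a
complete matrix one pass of each leaves all row and column means at zero
exactly. No imputation is performed in targeted mode; downstream
correlations are pairwise-complete.

## Untargeted analysis

LFQ-style matrices are log₂ transformed and per-sample mean-centered.
Remaining missing values — treated as censoring at the detection limit —
are imputed per sample from Normal(mean − 1.8·SD, (0.3·SD)²), the standard
downshifted-normal model; a sample needs at least three observed values.
Differential testing uses the Student (equal-variance) two-sample two-tailed
t-test per protein (Welch by flag), log₂ fold change = mean(KO) − mean(WT),
Benjamini–Hochberg q-values, and a hit flag at the default cutoffs
|log₂FC| ≥ 1 and p < 0.05 (both configurable — published volcano plots vary
in their annotated cutoffs). Proteins with zero variance in both groups have
an undefined statistic and are flagged degenerate rather than dropped or
faked. iBAQ divides a protein's summed intensity by its count of
theoretically observable fully-tryptic peptides (cleave after K/R except
before P, zero missed cleavages, length 6–30); zero observable peptides
yields a missing iBAQ, not an error.

## Integration

Correlations are Pearson over pairwise-complete observations with a floor of
3 shared observations; zero-variance series give missing values. Proteins
observed in fewer than 70% of tubules are excluded from correlation, PCA
and clustering — under-sampled targets carry too little information, and
the same exclusion is applied in practice when low-abundance targets have
insufficient readings. Hierarchical clustering runs on Euclidean distances
between correlation-profile rows with average linkage (the distance metric
is the convention for these marker heatmaps; average linkage is the
package's choice) and deterministic tie-breaking by input order. PCA is a
mean-centered SVD with component signs fixed so the largest-magnitude
loading is positive; variance fractions sum to one.

Chord contributions summarize a protein × phenotype correlation grid per
cell class: for the positive diagram, mass(class, phenotype) = Σ max(r, 0)
over the class's proteins; widths normalize all masses of one sign to sum
to 1. Positive and negative masses are kept separate (paired diagrams)
rather than summed, and rows are sorted by decreasing mass for presentation
parity with circos-style plots.

The covariation-vs-regulation integration pairs each protein's wild-type
co-expression with an anchor (Pearson r across tubules, anchor itself
excluded) against its knockout log₂ fold change, returning the scatter
table, the overall Pearson r and quadrant counts. Significance is assessed
by permuting the pairing over protein labels (default 1000 permutations):
one-sided p-values for a negative overall r and for excess mass in the
coexpressed-and-decreased quadrant, where mass is Σ x·(−y) over points with
x > 0, y < 0. The mass statistic, not the raw quadrant count, is the
operational test because a count is bounded by an indicator: with a handful
of truly co-regulated proteins among dozens of nulls, the count's
permutation null absorbs nearly the whole signal into the margins and no
effect size can make it powerful, whereas the mass statistic weights each
point by how strongly it is co-expressed and how strongly it falls — the
quantity of interest.

## Synthetic cohorts

The simulator is the package's test bed: it generates data with known truth
under a generative model whose couplings mirror the physiology the pipeline
is meant to recover. Per tubule it draws length (uniform 400–600 µm),
diameter (18–28 µm), and an IC fraction from a bimodal distribution
(modes 0.14 and 0.52, within-mode SD 0.045, clipped to [0.05, 0.68]) —
superficial cortical CCDs are IC-rich, medullary-ray CCDs IC-poor — with the
IC fraction decreasing by 0.03 per +100 µm of length. Protein abundance is
baseline × composition weight (IC markers ∝ IC fraction, PC markers ∝ PC
fraction, housekeeping flat) × a length factor × log-normal noise. Three
latent programs are planted on top, all in log₂ units per latent SD:

* a PC transport program (+0.9 on β-ENaC, +0.3 on the other ENaC subunits,
  −1.1 on AQP2, −0.6 on AQP3/4, −0.7 on NEDD4L) — tubules adapted for Na⁺
  versus water transport;
* an IC-B program (+0.6 on pendrin and its partners CLCNKB, BSND,
  ATP6V1C2, INSRR) — the anchor co-expression the covariation analysis
  recovers;
* a housekeeping program (+0.7 on the glycolytic/cytoskeletal set) — the
  co-regulation that makes the housekeeping class a coherent cluster.

The 43-protein default panel spans 5.1 orders of magnitude of baseline
abundance (Na/K-ATPase and actin at the top, ENaC subunits and ROMK near
the detection limit). Biological noise is 0.3 log₂ units per tubule and
measurement noise 0.2 (0.3 for pooled knockout samples); missingness is
missing-not-at-random logistic dropout, P(observed) =
σ(2.5·(log₂ I − 7.5)), a sharp detection limit as in scheduled targeted
acquisition — the two lowest-abundance targets are mostly missing, the rest
nearly complete.

Phenotypes are forward-simulated through the same physics the analysis
inverts: a two-conductance equivalent circuit V_te = E·g_t/(g_t + g_p) with
E = −60 mV and g_t proportional to the realized β-ENaC abundance
(g_t/g_p = 0.5 at baseline; luminal amiloride sets g_t ≈ 0 leaving only
recording noise), deflections from the sealed-end cable model at 13 nA,
R_te ~ Normal(160, 25) Ω·cm² (matching equivalent short-circuit currents of
tens to ~200 µA/cm² at lumen-negative voltages of −5…−40 mV), and dilution
potentials from the GHK forward model at a log-normal planted β
(median 0.7). Recording noise: 0.8 mV on V_te, 0.5 mV on the amiloride
residual, 0.3 mV on V_dp.

Knockout cohorts use mouse-level samples, each pooling five CCDs dissected
at a consistent cortico-medullary position: tubule-level latents and noise
shrink by √5, and the composition is unimodal (tubule SD 0.08) because the
uniform dissection protocol removes the cortical/medullary split of the
perfusion cohort. The untargeted depth is filled to 3,630 proteins with
background entries of log-uniform baseline; the knockout module (default
CLCNKB, BSND, ATP6V1C2, INSRR) carries the planted log₂ fold change
(default −1.5), the anchor (pendrin) collapses to a noise-floor signal, and
every other protein is exchangeable between groups, so the false-positive
rate of the differential test is its nominal level by construction.

### What the simulator does and does not emulate

It reproduces the statistical structure that matters for validating the
analysis: composition as the dominant proteome axis (bimodality also makes
the recovered first principal component nearly linear in the IC fraction,
which a wide unimodal log-scale spread would not), a dynamic range over
five orders of magnitude, intensity-dependent dropout, physiological
voltage/resistance ranges, and co-regulation structure. It does not emulate
retention-time drift, isotope interference, peptide-level quantification
noise models, ionization differences between proteins (intensity is treated
as proportional to abundance), transcriptional kinetics, or any cell-type
change in the knockout beyond the planted module — so passing tests show
the analysis recovers what was planted under this model, not that the model
exhausts real single-tubule variability.

## Numerical and design choices

* Coelution tolerance 0.2 min; reason-code precedence as listed; filters are
  idempotent by construction.
* Correlation observation floor 3; completeness threshold 0.7 for
  PCA/clustering inputs.
* The cluster-display marker set excludes the transport-program proteins:
  the planted Na⁺-vs-water program makes ENaC subunits anticorrelate with
  aquaporins inside the PC class, so they separate cell states, not cell
  classes.
* Imputation defaults (downshift 1.8, width 0.3) are per-sample; the
  targeted branch never imputes.
* PCA sign convention: largest-|loading| element positive, making scores
  reproducible across row permutations up to that rule.
* Degenerate inputs: zero-variance t-tests are flagged, not dropped;
  all-zero chord masses give zero widths; non-invertible cables and
  out-of-range dilution potentials raise typed errors.
* All generators and the CLI are pure functions of (config, seed); reruns
  are byte-identical, which the test suite asserts on the full pipeline.

## Problem sizes

The validation suite uses the study-scale sizes throughout: 12-tubule
cohorts (200 replicates for coupling recovery), knockout cohorts of 5 vs 5
mice at 3,630-protein depth (100 replicates), 50 × 2,000 null proteins for
t-test calibration, and 1,000-permutation nulls for the covariation
integration.
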