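# Methods

This note records the modeling choices, parameter provenance, numerical
details and known limitations of the package. It is the reference for "why
is it built this way"; the README covers "what it does".

## Scope and substitutions

The package implements a desk-scale mechanistic pipeline: segmentation
ingestion (or phantoms) → perfusion fitting → coupled transport/growth/kill/
mechanics simulation over a dosing calendar → pCR decision rule → statistical
validation. Three components that exist in production-scale systems of this
kind are deliberately replaced:

- **Segmentation** is ingested as NIfTI label volumes (or generated as
  phantoms); no network is trained here.
- **Voxel metabolism** is a reduced two-nutrient Monod model with
  hypoxia-weighted lactate yield, not a genome-scale metabolic
  reconstruction. It preserves the causal chain the simulator needs —
  nutrient fields → per-voxel growth rates — with four interpretable
  parameters.
- **Cohorts** are synthetic. The generator is first-class, tested code; its
  defaults define the study conditions for every statistical result this
  package produces.

## Lattice and volumes

Cubic voxels, labels {0 background, 1 fat, 2 fibroglandular, 3 vessel,
4 tumor}, cell-centered fields, 0-based indices, physical placement via the
NIfTI affine. The desk-scale default voxel side is 2.0 mm; every algorithm
is resolution-parameterized and the native clinical resolution of 0.5 mm is
accepted (tests exercise it on small volumes — a full breast at 0.5 mm is
hundreds of millions of voxels and out of desk scope).

Imaging-equivalent volume counts voxels with ρ ≥ ρ_detect·ρ_max
(ρ_detect = 0.10 by default) times the voxel volume. Threshold counting was
chosen over total cell mass because predictions are compared against scan
segmentations, which see a detectability threshold, not a cell count; the
threshold is configurable and the choice matters mainly near the 0.01 cm³
decision boundary.

## Perfusion

Extended Tofts model with a population biexponential AIF (amplitudes
3.99/4.78 mM, rates 0.144/0.0111 min⁻¹ — classic population constants for a
standard gadolinium dose, used here as library defaults, not study-specific
measurements). The forward model uses the exact closed-form convolution for
biexponential input; fitting is bounded trust-region least squares
(init Ktrans 0.1 min⁻¹, v_e 0.3, v_p 0.02; bounds from the parameter
invariants). Degenerate fits return flagged results, never exceptions.

Two modeling decisions deserve emphasis:

- **Contrast-to-drug mapping.** The Ktrans/v_e map fitted from (synthetic)
  DCE data is reused as the delivery field for nutrients and drugs, with a
  per-species relative permeability scaling Ktrans. Small cytotoxics default
  to 0.03 and antibodies to 0.006 relative to the contrast agent. This is
  the knob that makes exposure delivery-limited: at contrast-agent
  permeability the tissue equilibrates to v_e·C_p within minutes and spatial
  perfusion heterogeneity becomes irrelevant to drug exposure, which would
  make response implausibly uniform.
- **Macrovascular voxels** (vessel label) are Dirichlet sources clamped to
  plasma concentration; the microvascular exchange elsewhere is
  `Ktrans·(C_p − C/v_e)`.

## Transport and the operator split

Chemical fields evolve by an explicit FTCS scheme (6-neighbor von Neumann
Laplacian, zero-flux boundaries by mirroring) with automatic substepping to
the 3D stability bound dt ≤ h²/(6D); with no sources the scheme conserves
mass to machine precision, and negative excursions from stiff sinks are
clipped with the clipped mass logged (a clean run logs nothing; the engine
aborts if clipping exceeds 5% of delivered mass).

The microvascular exchange term is much faster than the outer step
(Ktrans·60/v_e ≈ 16 h⁻¹ vs a 6 h step), so it is integrated exactly per
step (exponential relaxation toward v_e·C_p) rather than explicitly — an
operator split that keeps the outer step unconditionally stable.

Species whose plasma level is constant (oxygen, glucose, the non-limiting
amino-acid pool) sit near the steady balance of delivery, diffusion and
uptake. They are relaxed to quasi-steady state with a sparse symmetric
Helmholtz solve (β·I − D·L, Dirichlet rows on vessel voxels moved to the
right-hand side) using warm-started conjugate gradients, with Picard
iteration on the Monod sink. The refresh cadence is every 4 outer steps
(24 h), matching the slow evolution of the density that drives uptake; a
brute-force explicit fixed-point iteration reproduces the solve to < 0.5%
in tests. Drug fields, whose plasma levels vary within a dose interval,
update every outer step (exact exchange relaxation + explicit diffusion).
The quasi-steady and explicit paths are both implemented and switchable
(`oxygen_qss`, `nutrient_qss`).

Default diffusion coefficients (mm²/h): oxygen 6, glucose 1, amino pool 0.8,
lactate 1, small-molecule drugs 0.3–0.6, antibodies 0.05 — literature-order
values authored for this package, shipped in config, all overridable.

## Metabolism and growth

μ = μ_max·[G/(G+K_G)]·[O/(O+K_O)] with μ_max = 0.005 h⁻¹ (volume doubling
≈ 6 days at low density; crowding makes untreated tumors hold near carrying
capacity), K_G = 1 mM, K_O = 0.02 mM against plasma levels 5 and 0.1.
Lactate production is Y_L·(glucose uptake)·K_O/(O+K_O), Y_L = 2
(stoichiometric cap). Amino acids are tracked but non-limiting (no kinetics
are attached to them). Density updates are logistic with kill:
ρ' = ρ + dt·(μ(1−ρ/ρ_max) − δ)ρ, clamped to [0, ρ_max]; ρ = 0 is absorbing.

## Pharmacology

Plasma PK is linear superposition of bolus decays (1-compartment
exponential; doxorubicin uses a 2-compartment biexponential via the standard
hybrid rate constants). Dosing calendars are authored in days and converted
to hours. Dose reductions are per-administration multipliers; a
standard-dose flag ignores them to mirror a sensitivity analysis against
the as-documented regimen.

Kill is Hill-law in local tissue concentration, additive across concurrent
agents (a `max` rule is available; additivity was chosen as the simplest
defensible default for independent action). Antibody agents additionally
carry a growth multiplier < 1 applied smoothly with receptor-style occupancy
C/(C+IC50), so HER2-directed therapy acts as partial cytostasis plus a small
direct kill; both knobs are exposed because the mechanism split is genuinely
uncertain. HER2-directed agents have zero kill multiplier in HER2− cases.

**Parameter provenance.** The shipped drug library (doxorubicin,
cyclophosphamide, paclitaxel, docetaxel, carboplatin, trastuzumab,
pertuzumab) carries literature-order PK constants (half-lives of hours for
cytotoxics, weeks for antibodies) and kill/IC50 values expressed on the
tissue-concentration scale this simulator produces. They are package
defaults authored to give clinically plausible cohort behavior, not
measurements from any single study, and every field is overridable via a
user YAML or per-case multipliers.

## Mechanics

Springs on lattice edges (stiffness 1) and face diagonals (0.5, shear
resistance). Net growth over a mechanics window becomes a per-cell
volumetric factor g = e^{(μ−δ)dt}; rest lengths scale by g^(1/3) (isotropic
growth), and a damped explicit relaxation (step 0.1/k, halved whenever the
spring energy would rise, so the energy trace is monotone) finds the
deformed configuration. Density is remapped by depositing each cell's cell
number at its deformed centroid with trilinear weights — conservative by
construction — with over-capacity excess shed to neighbors over a bounded
number of passes and the remainder logged. The mesh resets to the regular
configuration after each remap, so deformation does not accumulate
numerically. Uniform g reproduces analytic scaling to well within 5% volume.

The engine applies mesh mechanics every 4 outer steps by default; a
bookkeeping mode skips deformation entirely and tracks volume through the
density field alone. Bookkeeping is used for cohort-scale sweeps, where the
per-case cost matters and the decision rule is driven by density collapse
rather than by morphology.

## Engine defaults and degenerate inputs

Outer step 6 h; mechanics every 4 steps; nutrient/oxygen refresh every
4 steps; surgery defaults to 21 days after the last administration when
unspecified. The decision rule is exactly: pCR iff V_final < 0.01 cm³
(strict) or percent reduction ≥ 99.9 (inclusive); a baseline already below
the absolute threshold classifies as pCR with a degenerate-input flag.
Clinical covariates ride through to outputs and the comparator model but do
not enter the mechanistic core except through subtype-linked sensitivity
multipliers. The forward model contains no randomness: identical config
gives bit-identical trajectories.

## Synthetic cohorts

Phantoms: ellipsoid / multifocal / rim-enhancing geometries; Gaussian-
filtered, rescaled white noise for Ktrans (default mean 0.08, sd 0.03
min⁻¹, 4 mm correlation length); necrotic cores are the exact innermost
fraction of tumor voxels by depth; a straight vessel track reaches the
tumor margin. Everything is a pure function of (spec, seed).

Cohorts mirror a neoadjuvant template: subtype mix TNBC 0.41 /
HR−/HER2+ 0.174 / HR+/HER2+ 0.167 / HR+/HER2− 0.25; HER2+ cases receive
HER2-directed regimens (35% anthracycline-containing), HER2− cases receive
chemotherapy (93% anthracycline-containing); four regimen templates (ddAC→T,
TC, TCHP, AC→THP) with 21- or 14-day cycles and surgery 21 days after the
last dose; 20% of cases carry 0.75× dose reductions on later cycles.

Per-case drug sensitivity is lognormal with subtype-specific log-means
(TNBC 0.19, HR−/HER2+ −0.20, HR+/HER2+ −0.96, HR+/HER2− −0.38; log-sd
0.55). These were calibrated once, by pilot simulation, so that the
simulated cohort pCR rate sits near 35% with the qualitative subtype
ordering of such populations (HER2-enriched most responsive, HR+/HER2−
least); at n = 200 the generator produces a 35% observed rate.

**Ground truth is not the predictor's output.** Observed outcomes come from
re-simulating each case with sensitivity perturbed by lognormal noise
(sd 0.25) and flipping the label with probability 0.05, so sensitivity and
specificity below 100% arise from the generator, and the evaluation layer
has a non-degenerate target. Follow-up scan volumes are the perturbed
trajectory at the scan days with 10% lognormal noise. Survival endpoints
are exponential with lower hazards for observed-pCR cases (events
concentrate in residual disease, qualitatively echoing the prognostic
separation such predictors show); no attempt is made to match any specific
hazard ratio.

**What passing tests do and do not show.** The synthetic cohort
demonstrates that the pipeline and the statistics are correct and that the
mechanistic model behaves sensibly (monotone in dose, kill and IC50;
threshold behavior near the decision rule). It does not validate the model
against real tumors: phantom geometry, the perfusion texture, the response
distribution and the outcome noise are all generator choices, and real
cohort metrics could differ arbitrarily.

## Statistics

Clopper–Pearson via Beta quantiles (lower 0 at x=0, upper 1 at x=n); AUROC
as the Mann–Whitney statistic with ties at ½; bootstrap CI is the
percentile interval over 1000 case resamples (fixed seed; single-class
resamples are redrawn); the clinical comparator is threefold stratified CV
logistic regression (one-hot, first-level reference; fold-internal
standardization; every case scored exactly once out-of-fold; a single-class
training fold scores with prevalence and is flagged). Survival uses the
log-rank test, Kaplan–Meier survival at a 5-year horizon, and a
single-covariate Cox fit for the hazard ratio — with the HR flagged, not
computed, when a group has no events. Pearson correlation is tested via the
Fisher transformation z = atanh(r)·√(n−3) against the standard normal
(implemented directly; the common beta-distribution p-value is a different
test). Percentages are rounded to one decimal in report rendering only; raw
proportions are retained in the CSVs. No multiple-testing correction is
applied. A power/sample-size calculator is deliberately not provided.

## Numerical choices and tie-breaks

- CFL safety factor 0.9 on the diffusion substep bound.
- CG tolerance 1e-8 (relative), Picard tolerance 1e-5 relative change,
  with a direct sparse solve as fallback on CG breakdown.
- Relaxation: force tolerance 1e-3 (engine) with max 200 iterations per
  mechanics call; unit tests use tighter settings.
- Necrotic-core selection breaks depth ties by stable sort order, making
  the core fraction exact and deterministic.
- Anisotropic NIfTI spacing is accepted with a warning; the voxel side is
  the geometric mean and the lattice is flagged.
- All seeds are consumed through `numpy.random.default_rng`; bootstrap, CV,
  cohort and phantom generation take independent seeds.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run phantoms of 12–26 mm at 2 mm voxels (12³–21³
lattices), full regimens of 84–126 days at 6 h steps, a 144-case end-to-end
cohort in the cheap-mechanics mode, and a 60-case cohort in the acceptance
script. These sizes were chosen as the package's desk-scale operating
point: large enough to exercise spatial heterogeneity and the full dosing
calendar, small enough to iterate on a laptop.

## Known limitations

- No lymph-node compartment: response is breast-volume only, so node-only
  residual disease is invisible to the decision rule.
- Isotropic growth, no contact with chest wall/skin, no stress-growth
  feedback; the mass-spring mesh is a far cry from finite-element
  hyperelasticity.
- The Monod surrogate has no explicit ATP/biomass accounting; CO₂/formate
  and pH effects of lactate are not modeled.
- Signal-intensity-to-concentration conversion is out of scope: synthetic
  DCE inputs are already concentrations.
- PK is population-level; no body-surface-area scaling, drug interactions,
  or intracellular prodrug conversion.
- The binary all-or-nothing character of simulated response is stronger
  than in real tumors; partial responders arise mainly from perfusion
  heterogeneity and necrotic cores.
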