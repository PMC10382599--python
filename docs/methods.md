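# Methods

`cns-screen` implements the computational selection procedure used to
triage benzoyl-phenoxy-acetamide (BPA) variants as CNS/glioblastoma drug
candidates, together with the arithmetic of the assays that validate the
survivors. This note records the models, the conventions chosen where the
design was open, and what the synthetic data do and do not establish.

## Scores

**CNS-MPO.** The central-nervous-system multiparameter optimization score
(Wager et al., ACS Chem. Neurosci. 2010) is the sum of six desirability
functions T0, each mapping one property to [0, 1]:

| property | ideal (T0 = 1) | unfavorable (T0 = 0) |
|---|---|---|
| ClogP | ≤ 3 | ≥ 5 |
| ClogD(7.4) | ≤ 2 | ≥ 4 |
| MW (g/mol) | ≤ 360 | ≥ 500 |
| TPSA (Å²) | 40–90 (hump) | ≤ 20 or ≥ 120 |
| HBD | ≤ 0.5 | ≥ 3.5 |
| pKa (most basic) | ≤ 8 | ≥ 10 |

Linear interpolation applies between breakpoints, so the score is
continuous and lies in [0, 6]. Conventional cut-offs: ≥ 4 (strict) and
> 3 (soft, ≈ 50% probability of CNS penetration); both are exposed as
presets because the screening literature uses both.

**BBB score.** The blood–brain-barrier score (Gupta et al., J. Med. Chem.
2019) is `P_aro + P_HA + 1.5·P_MWHBN + 2·P_TPSA + 0.5·P_pKa` with weights
summing to 6. `P_aro` is stepwise in the aromatic-ring count (maximum at
2 rings, zero above 4); `P_HA` and `P_MWHBN` are normalized cubics on
(5, 45] heavy atoms and (0.05, 0.45] MWHBN; `P_TPSA` is a normalized
linear ramp on (0, 120] Å²; `P_pKa` a normalized quartic on (3, 11],
peaking near pKa 9. Coefficients are stored in
`data/bbb_score_value_functions.json` with a citation header so the
transcription is auditable; raw polynomial values are clamped to [0, 1]
and values outside each domain score 0. MWHBN = (HBD + HBA)/√MW.

**Descriptor conventions.** Open estimators replace the commercial
calculators used in the original study: Crippen atomic contributions for
ClogP, Ertl's topological method for TPSA, Lipinski N–H/O–H counts for
HBD, typed acceptor counts (`CalcNumHBA`) for HBA, and the
Henderson–Hasselbalch monoprotic correction
`logD = logP − log10(1 + 10^(pKa_b − pH)) − log10(1 + 10^(pH − pKa_a))`
for ClogD(7.4), using only the most basic and most acidic center.
Fitted-model descriptors (ClogP, logS, pKa) differ between engines by a
few tenths of a log unit, so score comparisons against values computed
with other engines carry a tolerance of about ±0.6 CNS-MPO units.

pKa is deliberately *not* predicted: it is an override column. A
class-value heuristic (amide-deactivated pyridine 4.5, fused azine 4.9,
pyridine 5.2, aliphatic amine 9.5) exists only so the shipped fixtures
score end-to-end, and is flagged `heuristic` in the provenance map.
Water solubility uses Delaney's ESOL estimate when no measured value is
supplied; the screen filters on −logS ≤ 7.5.

Missing-value policies: with no basic pKa, CNS-MPO scores the pKa
component 1.0 (non-ionizable is ideal) and the BBB score evaluates its
pKa function at a neutral 7.0; both flag the decision in the result.

## Geometry

**Minimal projection area (MPA).** The silhouette area for a direction
is the union of the disks obtained by projecting every atomic van der
Waals sphere (Bondi radii, explicit hydrogens) onto the plane normal to
that direction, rasterized at a 0.05 Å pitch with bounding-box padding
equal to the largest radius. MPA minimizes this area over directions: a
1536-point Fibonacci hemisphere scan followed by Nelder–Mead refinement
in spherical coordinates (grid ties break by first index; a single atom
is returned in closed form as πr²). MPA is evaluated on the lowest-energy
conformer of 50 ETKDG embeddings (seed 17) minimized with MMFF94 (UFF
fallback). The conformer policy is fixed and documented rather than
matched to the original study, which does not state one; absolute
agreement with figure-embedded MPA values is therefore not asserted
anywhere — tests instead compare the search against a 50,000-direction
random brute force at half pitch (2% band) on small molecules (methane,
water, ethene), a problem size chosen so the full-resolution oracle runs
in about two minutes.

**Polarizability.** Miller's additive atomic hybrid polarizabilities
(ahp, J. Am. Chem. Soc. 1990): the molecular value is the sum of
element/hybridization terms, hence exactly additive over fragments.
The designed BPA-pyridines land in the 40–50 Å³ band.

## Screening

Guideline thresholds reproduce the printed criteria: hERG pIC50 ≤ 5.5,
−logS ≤ 7.5, CNS-MPO ≥ preset (3 default, 4 strict), BBB score ≥ 4,
MPA ≤ 60 Å². Boundaries are inclusive. Calibration against a reference
panel returns these guideline constants plus the panel's observed
min/max per property for audit — the cut-offs are conventions, not panel
statistics. hERG and frontier-orbital energies are ingest-only; absent
values yield "not evaluated" flags, never failures. High ClogD is a soft
warning (one candidate class reaches ClogD ≈ 7 yet remains reportable).
Ranking is the deterministic lexicographic order (n_pass desc, CNS-MPO
desc, BBB desc, −logS asc, id asc).

The shipped reference panel (`reference_panel_synthetic.sdf`) is a
representative reconstruction of CNS chemotherapy agents, labelled
synthetic because the original panel's identities sit in supplementary
material; nothing numeric depends on its membership.

## Assay mathematics

* **Viability**: absorbance as percent of the vehicle-control mean (the
  vehicle mean maps to exactly 100%).
* **4PL**: `R(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)`, fitted
  by Levenberg–Marquardt least squares in a log-IC50 parameterization
  with multi-start Hill slopes {0.5, 1, 2}; top/bottom seed from the
  response extremes and IC50 from the geometric-median dose. Noiseless
  curves are recovered to ~1e−6 relative error; a flat response raises
  (IC50 unidentifiable). `se_ic50` is a delta-method standard error.
* **Transwell permeability**: `P = V_A·C_A/(t·S·C_L)` in cm/s
  (concentration units cancel). Defaults mirror the 24-well design:
  3 h sampling, 0.33 cm² membrane, 0.5 cm³ acceptor volume, 25 µM donor
  load. TEER normalization multiplies P by TEER/batch-mean: leaky
  (low-TEER) inserts inflate apparent P, so the correction scales it
  down. The direction and reference are this package's documented
  convention — the underlying protocol literature states only that a
  TEER coefficient was applied.
* **HPLC**: linear peak-area calibration (≥ 3 standards) inverted as
  `(area − intercept)/slope`, clipped at zero with below-range and
  extrapolation flags.
* **Distribution**: `logBB = log10(C_brain/C_plasma)`; tissue ng/g
  converts to µM by dividing by the molar mass with the 1 g ≈ 1 mL
  tissue-density convention (flagged assumption).

## Synthetic data

Generators emulate the statistical structure of each input: triplicate
4PL dose–response with multiplicative Gaussian noise (default σ = 5%,
eight doses spanning three decades centered on the true IC50),
transwell acceptor concentrations back-computed from a chosen true P,
additive-noise linear HPLC series, and descriptor libraries that always
include vectors at, just inside and just outside every threshold.
Default seed 17 everywhere; zero noise reproduces the truth exactly.
They do not simulate cell biology, tumor growth or pharmacokinetics —
passing tests demonstrate that the estimators recover known truths under
the stated noise models, not that any cell-derived value (IC50s, brain
tissue levels) is predictable from structure.

## Known limitations

* Descriptor absolute values are engine-dependent; only banded
  comparisons against externally computed scores are meaningful.
* The pKa heuristic is a fixture convenience, not chemistry; real use
  requires measured or predicted pKa overrides.
* Regiochemistry of most HR structures is inferred from their class and
  marked provisional; mass-based guarantees apply only to the three
  compounds with printed names (HR67, HR80, HR89).
* Rasterized MPA carries O(pitch) discretization error (~0.3% at
  0.05 Å); the convergence test quantifies it.
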