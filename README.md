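# cns-screen

Physicochemical triage of CNS drug candidates, built around the
benzoyl-phenoxy-acetamide (BPA) scaffold family of glioblastoma leads.

Glioblastoma drugs fail mostly at the blood–brain barrier (BBB): a
cytotoxic compound is useless if it cannot reach the tumor at its IC50.
This package implements the integrated computational screen used to rank
BPA-pyridine candidates before synthesis — and the mathematics of the
assays used to validate the survivors — as one tested library:

* **CNS-MPO** — sum of six piecewise-linear desirabilities over ClogP,
  ClogD(7.4), MW, TPSA, HBD and the most basic pKa; range 0–6, with ≥ 4
  (strict) and > 3 (soft) cut-offs.
* **BBB score** — `P_aro + P_HA + 1.5·P_MWHBN + 2·P_TPSA + 0.5·P_pKa`,
  range 0–6, cut-off ≥ 4, where MWHBN = (HBD + HBA)/√MW.
* **MPA** — minimal projection area: the smallest van-der-Waals
  silhouette of the low-energy conformer over all directions (Å²);
  ≤ 60 Å² is taken as permissive for passive CNS entry. Plus Miller
  additive molecular polarizability (Å³).
* **Screening** — guideline thresholds (hERG pIC50 ≤ 5.5, −logS ≤ 7.5,
  CNS-MPO, BBB score, MPA), independent per-compound flags, and a
  deterministic rank.
* **Assay analysis** — MTT viability normalization and 4PL IC50 fitting
  `R(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)`; transwell
  permeability `P = V_A·C_A/(t·S·C_L)` with TEER normalization; linear
  HPLC quantification; `logBB = log10(C_brain/C_plasma)` and ng/g → µM
  tissue conversions.
* **Synthetic data** — seed-deterministic generators for every assay
  input, with recorded ground truth.

Fit-shaped pieces are scikit-learn estimators (`FourPLRegressor`,
`LinearCalibration`, `DescriptorCalculator`, `CompoundScreen`) and
compose with sklearn pipelines; everything is also reachable through
plain functions.

## Worked example

HR67 — `2-[4-(4-chlorobenzoyl)phenoxy]-2-methyl-N-(pyridin-3-yl)`
`propanamide`, one of the two lead candidates — from structure to verdict:

```python
from cns_screen import (BatchSpec, compute_descriptors, get_compound,
                        isolated_mass, cns_mpo, bbb_score, log_bb)

hr67 = get_compound("HR67")
print(hr67.formula)            # {'C': 22, 'O': 3, 'Cl': 1, 'N': 2, 'H': 19}
print(round(hr67.molar_mass, 2))   # 394.85 g/mol

d = compute_descriptors(hr67)
print(round(d.clogp, 2), d.tpsa, d.hbd, d.aro_rings)  # 4.76 68.29 1 3
print(round(cns_mpo(d).score, 2))           # 3.7   (> 3: CNS-favorable)
print(round(bbb_score(d).weighted_score, 2))  # 4.1  (>= 4: likely BBB+)

# a 0.15 mol preparation at 90% isolated yield
print(round(isolated_mass(BatchSpec("HR67", 0.15, 0.90), hr67), 1))  # 53.3 g

# temozolomide benchmark: 20% CNS penetration
print(round(log_bb(0.20, 1.0), 1))  # -0.7
```

The CNS-MPO of 3.7 sits above the soft cut-off but below the strict one,
and the BBB score of 4.1 clears its cut-off — exactly the profile that
makes HR67 a candidate worth carrying into transwell-permeability and
dose–response experiments:

```python
import numpy as np
from cns_screen import FourPLRegressor, PermeabilityRecord, four_pl, permeability

r = PermeabilityRecord(v_a=0.5, c_a=5.0, t=10800, s=0.33, c_l=25.0)
print(f"{permeability(r):.2e} cm/s")     # 2.81e-05 cm/s

doses = 1.17 * 10.0 ** np.linspace(-1.5, 1.5, 8)
fit = FourPLRegressor().fit(doses, four_pl(doses, 1.17, 1.5, 100, 5))
print(round(fit.ic50_, 2))               # 1.17 (µM)
```

A command-line front end wraps the library:

```bash
cns-screen run --thresholds default --out report/   # built-in HR library
cns-screen simulate dose-response --out sim/
```

## Layout

```
src/cns_screen/
  registry.py     compound identity, formula/mass arithmetic, fixtures
  descriptors.py  ClogP/ClogD/TPSA/HBD/HBA/MWHBN/logS engine + overrides
  scoring.py      CNS-MPO and BBB score value functions
  geometry.py     conformers, minimal projection area, polarizability
  screening.py    thresholds, flags, ranking (CompoundScreen)
  assays.py       4PL, permeability, HPLC calibration, logBB
  simulate.py     synthetic-data generators
  cli.py          cns-screen run | simulate
docs/methods.md   model assumptions, conventions, limitations
```
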