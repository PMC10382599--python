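"""Assay mathematics: MTT viability and IC50, transwell permeability,
HPLC quantification, and brain/plasma distribution.

The models are deliberately small and explicit:

* viability is absorbance expressed as percent of the vehicle-control
  mean;
* dose-response is the four-parameter logistic (4PL)
  ``R(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)``, fitted by
  least squares with multi-start initialization (the inflection
  concentration is the IC50);
* apparent transwell permeability is ``P = V_A * C_A / (t * S * C_L)``
  in cm/s, optionally rescaled by an insert's TEER relative to the batch
  mean (leaky, low-TEER inserts inflate apparent P, so multiplying by
  TEER/mean corrects downward);
* HPLC quantification inverts a linear peak-area calibration;
* ``logBB = log10(C_brain / C_plasma)``, and tissue amounts in ng/g
  convert to micromolar with the 1 g ~ 1 mL tissue-density convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .registry import Compound, molar_mass

__all__ = [
    "DoseResponseDataset",
    "FourPLFit",
    "FourPLRegressor",
    "PermeabilityRecord",
    "CalibrationCurve",
    "LinearCalibration",
    "normalize_viability",
    "fit_4pl",
    "four_pl",
    "permeability",
    "normalize_by_teer",
    "quantify",
    "log_bb",
    "tissue_concentration",
]


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------

def normalize_viability(raw: np.ndarray | pd.DataFrame,
                        vehicle_wells: Sequence[int]) -> np.ndarray | pd.DataFrame:
    """Express raw absorbances as percent of the vehicle-control mean."""
    arr = np.asarray(raw, dtype=float)
    flat = arr.reshape(-1) if arr.ndim > 1 else arr
    vehicle = np.asarray(flat)[list(vehicle_wells)]
    mean = float(vehicle.mean())
    if mean <= 0:
        raise ValueError(f"vehicle-control mean must be positive, got {mean}")
    out = 100.0 * arr / mean
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseDataset:
    """Doses in uM (strictly positive) with responses in % of control."""

    compound_id: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if len(np.unique(doses)) < 4:
            raise ValueError("need >= 4 distinct doses for a 4PL fit")
        if len(doses) != len(self.responses):
            raise ValueError("doses and responses differ in length")


@dataclass(frozen=True)
class FourPLFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    se_ic50: float | None = None


def four_pl(c: np.ndarray, ic50: float, hill: float,
            top: float, bottom: float) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


class FourPLRegressor(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response model.

    ``fit(doses, responses)`` minimizes the residual sum of squares on the
    percent scale in a log-IC50 parameterization, restarting from Hill
    slopes {0.5, 1, 2} with top/bottom seeded from the response extremes
    and IC50 from the geometric-median dose.  Fitted attributes:
    ``ic50_`` (uM), ``hill_``, ``top_``, ``bottom_``, ``rss_``,
    ``converged_``, ``se_ic50_`` (delta-method, may be None).

    Noiseless 4PL data are recovered to ~1e-6 relative error; a flat
    response raises because the IC50 is not identifiable.
    """

    def __init__(self, hill_starts: tuple[float, ...] = (0.5, 1.0, 2.0),
                 max_nfev: int = 2000):
        self.hill_starts = hill_starts
        self.max_nfev = max_nfev

    def fit(self, X, y, seed: int = 0) -> "FourPLRegressor":
        doses = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if len(np.unique(doses)) < 4:
            raise ValueError("need >= 4 distinct doses spanning the inflection")
        if float(np.var(resp)) < 1e-12:
            raise ValueError("flat response: IC50 is not identifiable")

        top0 = float(resp.max())
        bot0 = float(resp.min())
        log_ic50_0 = float(np.median(np.log(doses)))
        logc = np.log(doses)

        def residuals(p: np.ndarray) -> np.ndarray:
            log_ic50, hill, top, bottom = p
            pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_ic50)))
            return pred - resp

        best = None
        for h0 in self.hill_starts:
            try:
                res = least_squares(
                    residuals, x0=[log_ic50_0, h0, top0, bot0],
                    method="lm", max_nfev=self.max_nfev,
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            self.converged_ = False
            return self
        log_ic50, hill, top, bottom = best.x
        if hill < 0:  # equivalent curve with swapped asymptotes
            hill, top, bottom = -hill, bottom, top
        self.ic50_ = float(np.exp(log_ic50))
        self.hill_ = float(hill)
        self.top_ = float(max(top, bottom))
        self.bottom_ = float(min(top, bottom))
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.status > 0)
        self.se_ic50_ = self._se_ic50(best, len(resp))
        return self

    def _se_ic50(self, res, n: int) -> float | None:
        dof = n - 4
        if dof <= 0:
            return None
        try:
            jac = res.jac
            cov = np.linalg.inv(jac.T @ jac) * (2.0 * res.cost / dof)
            se_log = math.sqrt(max(cov[0, 0], 0.0))
            return float(self.ic50_ * se_log)  # delta method on exp
        except np.linalg.LinAlgError:
            return None

    def predict(self, X) -> np.ndarray:
        return four_pl(np.asarray(X, dtype=float).reshape(-1),
                       self.ic50_, self.hill_, self.top_, self.bottom_)

    def result_(self) -> FourPLFit:
        return FourPLFit(ic50=self.ic50_, hill=self.hill_, top=self.top_,
                         bottom=self.bottom_, rss=self.rss_,
                         converged=self.converged_, se_ic50=self.se_ic50_)


def fit_4pl(d: DoseResponseDataset, seed: int = 0) -> FourPLFit:
    """Fit the 4PL model to one dataset and return the parameter record."""
    reg = FourPLRegressor().fit(d.doses, d.responses, seed=seed)
    if not getattr(reg, "converged_", False) and not hasattr(reg, "ic50_"):
        return FourPLFit(ic50=float("nan"), hill=float("nan"),
                         top=float("nan"), bottom=float("nan"),
                         rss=float("inf"), converged=False)
    return reg.result_()


# ---------------------------------------------------------------------------
# Transwell permeability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeabilityRecord:
    """One transwell measurement.

    v_a: acceptor-compartment volume (cm^3); c_a: acceptor concentration
    at sampling time (uM); t: sampling time (s); s: membrane area (cm^2);
    c_l: initial donor (luminal) concentration (uM); teer: barrier
    integrity (Ohm*cm^2).
    """

    v_a: float
    c_a: float
    t: float
    s: float
    c_l: float
    teer: float | None = None

    def __post_init__(self) -> None:
        for name in ("v_a", "t", "s", "c_l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c_a < 0:
            raise ValueError("c_a must be non-negative")
        if self.teer is not None and self.teer <= 0:
            raise ValueError("teer must be strictly positive when given")


def permeability(r: PermeabilityRecord) -> float:
    """Apparent permeability P = V_A * C_A / (t * S * C_L), in cm/s."""
    return (r.v_a * r.c_a) / (r.t * r.s * r.c_l)


def normalize_by_teer(p: float, teer: float, teer_batch_mean: float) -> float:
    """Rescale P by the insert's TEER relative to the batch mean.

    Identity when the insert matches the batch mean; a leaky insert
    (TEER below the mean) is corrected downward.
    """
    if teer <= 0 or teer_batch_mean <= 0:
        raise ValueError("TEER values must be strictly positive")
    return p * (teer / teer_batch_mean)


# ---------------------------------------------------------------------------
# HPLC calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Linear peak-area calibration: area = slope * conc + intercept."""

    slope: float
    intercept: float
    r2: float
    conc_min: float
    conc_max: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


class LinearCalibration(BaseEstimator):
    """Least-squares line through standards; inverts areas to uM.

    ``fit(concentrations, areas)`` requires >= 3 standards; ``quantify``
    returns ``(area - intercept) / slope`` clipped at zero, together with
    below-range flags, and warns on extrapolation far above the calibrated
    range.
    """

    def __init__(self, extrapolation_factor: float = 1.5):
        self.extrapolation_factor = extrapolation_factor

    def fit(self, X, y) -> "LinearCalibration":
        conc = np.asarray(X, dtype=float).reshape(-1)
        area = np.asarray(y, dtype=float).reshape(-1)
        if len(conc) < 3:
            raise ValueError("need >= 3 calibration standards")
        slope, intercept = np.polyfit(conc, area, 1)
        pred = slope * conc + intercept
        ss_res = float(np.sum((area - pred) ** 2))
        ss_tot = float(np.sum((area - area.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        self.curve_ = CalibrationCurve(
            slope=float(slope), intercept=float(intercept), r2=float(r2),
            conc_min=float(conc.min()), conc_max=float(conc.max()),
        )
        return self

    def quantify(self, areas) -> pd.DataFrame:
        return quantify(areas, self.curve_,
                        extrapolation_factor=self.extrapolation_factor)


def quantify(areas, curve: CalibrationCurve,
             extrapolation_factor: float = 1.5) -> pd.DataFrame:
    """Invert peak areas through a calibration curve.

    Returns a frame with ``conc_uM`` (clipped at zero), ``below_range``
    (raw inversion negative or under the lowest standard) and
    ``extrapolated`` (above ``extrapolation_factor`` times the highest
    calibrated concentration).
    """
    areas = np.asarray(areas, dtype=float).reshape(-1)
    raw = (areas - curve.intercept) / curve.slope
    conc = np.clip(raw, 0.0, None)
    return pd.DataFrame({
        "conc_uM": conc,
        "below_range": raw < curve.conc_min,
        "extrapolated": raw > extrapolation_factor * curve.conc_max,
    })


# ---------------------------------------------------------------------------
# Distribution
# ---------------------------------------------------------------------------

def log_bb(c_brain: float, c_plasma: float) -> float:
    """Brain-blood distribution: log10(C_brain / C_plasma)."""
    if c_brain <= 0 or c_plasma <= 0:
        raise ValueError("concentrations must be strictly positive")
    return math.log10(c_brain / c_plasma)


def tissue_concentration(amount_per_gram: float, c: Compound) -> float:
    """Convert a tissue level in ng/g to uM.

    ng/g divided by molar mass (g/mol) gives nmol/g; with the 1 g ~ 1 mL
    tissue-density convention that is nmol/mL = umol/L.
    """
    if amount_per_gram < 0:
        raise ValueError("amount must be non-negative")
    return amount_per_gram / molar_mass(c)
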