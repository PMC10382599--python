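"""Synthetic inputs with the statistical structure each assay assumes.

Every generator is seed-deterministic and records its ground truth, so at
zero noise the downstream analysis recovers the truth in closed form.
Noise models follow the data types: multiplicative Gaussian for percent-
scale viability readouts (heteroscedastic like plate readers), additive
Gaussian for HPLC peak areas, multiplicative for transwell acceptor
concentrations.  The dose-response design emulates the wet protocol:
triplicate wells per dose, responses as percent of vehicle control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assays import four_pl
from .screening import DEFAULT_THRESHOLDS, ThresholdSet

__all__ = [
    "GeneratorConfig",
    "gen_dose_response",
    "gen_transwell",
    "gen_hplc",
    "gen_descriptor_library",
]

DEFAULT_SEED = 17


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings; ``truth`` holds per-generator parameters."""

    seed: int = DEFAULT_SEED
    n: int = 3
    noise_model: str = "multiplicative_gaussian"
    noise_sd: float = 0.05
    truth: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(0.0, cfg.noise_sd, size=values.shape)
    if cfg.noise_model == "multiplicative_gaussian":
        return values * (1.0 + eps)
    return values + eps


def gen_dose_response(cfg: GeneratorConfig) -> pd.DataFrame:
    """Triplicate 4PL dose-response table.

    Truth keys: ``ic50`` (uM), ``hill``, ``top``, ``bottom``; optional
    ``n_doses`` (default 8) and ``decades`` (default 3, centered on the
    true IC50 so the design spans the inflection).  Columns:
    compound_id, dose_uM, replicate, response_pct, plus the truth as
    frame attrs.
    """
    t = {"ic50": 1.0, "hill": 1.0, "top": 100.0, "bottom": 0.0,
         "n_doses": 8, "decades": 3.0, **cfg.truth}
    rng = cfg.rng()
    n_doses = int(t["n_doses"])
    half = t["decades"] / 2.0
    doses = t["ic50"] * 10.0 ** np.linspace(-half, half, n_doses)
    rows = []
    for dose in doses:
        clean = four_pl(np.array([dose]), t["ic50"], t["hill"],
                        t["top"], t["bottom"])[0]
        noisy = _apply_noise(np.full(cfg.n, clean), cfg, rng)
        for rep, resp in enumerate(noisy):
            rows.append({"compound_id": str(cfg.truth.get("compound_id", "SIM")),
                         "dose_uM": dose, "replicate": rep,
                         "response_pct": resp})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = t
    return df


def gen_transwell(cfg: GeneratorConfig) -> pd.DataFrame:
    """Transwell records whose noise-free permeability equals ``p_true``.

    Truth keys: ``p_true`` (cm/s), ``v_a`` (cm^3), ``t`` (s), ``s``
    (cm^2), ``c_l`` (uM), ``teer_mean`` and ``teer_sd`` (Ohm*cm^2).
    The acceptor concentration is back-computed from the permeability
    equation, then noised; TEER is drawn around the batch mean.
    Defaults emulate the 24-well transwell design: 3 h sampling, 0.33 cm^2
    insert, 0.5 mL acceptor volume, 25 uM donor load.
    """
    t = {"p_true": 2e-5, "v_a": 0.5, "t": 10800.0, "s": 0.33,
         "c_l": 25.0, "teer_mean": 150.0, "teer_sd": 0.0, **cfg.truth}
    rng = cfg.rng()
    c_a_clean = t["p_true"] * t["t"] * t["s"] * t["c_l"] / t["v_a"]
    c_a = _apply_noise(np.full(cfg.n, c_a_clean), cfg, rng)
    teer = rng.normal(t["teer_mean"], t["teer_sd"], size=cfg.n)
    df = pd.DataFrame({
        "replicate": np.arange(cfg.n),
        "v_a": t["v_a"], "c_a": np.clip(c_a, 0.0, None),
        "t": t["t"], "s": t["s"], "c_l": t["c_l"],
        "teer": np.clip(teer, 1e-9, None),
    })
    df.attrs["truth"] = t
    return df


def gen_hplc(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear HPLC calibration standards plus samples.

    Truth keys: ``slope`` (area per uM), ``intercept`` (area),
    ``standards`` (list of uM; default a 7-point doubling series) and
    ``sample_conc`` (list of true sample uM).  Standards and samples get
    additive area noise of ``noise_sd`` (area units).
    """
    t = {"slope": 1000.0, "intercept": 50.0, **cfg.truth}
    standards = np.asarray(t.get("standards",
                                 [0.0, 0.78125, 1.5625, 3.125, 6.25, 12.5, 25.0]),
                           dtype=float)
    samples = np.asarray(t.get("sample_conc", [5.0, 10.0]), dtype=float)
    rng = cfg.rng()
    noise_cfg = GeneratorConfig(seed=cfg.seed, n=cfg.n,
                                noise_model="additive_gaussian",
                                noise_sd=cfg.noise_sd)
    std_area = _apply_noise(t["slope"] * standards + t["intercept"],
                            noise_cfg, rng)
    sample_area = _apply_noise(t["slope"] * samples + t["intercept"],
                               noise_cfg, rng)
    std = pd.DataFrame({"conc_uM": standards, "area": std_area})
    smp = pd.DataFrame({"true_conc_uM": samples, "area": sample_area})
    std.attrs["truth"] = t
    smp.attrs["truth"] = t
    return std, smp


def gen_descriptor_library(
    cfg: GeneratorConfig,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score vectors stress-testing every screening threshold.

    Returns ``cfg.n`` random vectors uniform over wide bounds, plus, for
    each filter, one vector exactly on the boundary, one just passing and
    one just failing (so both sides of every cut-off are always
    represented in a non-empty library).  With ``n=0`` the table is empty.
    """
    rng = cfg.rng()
    bounds = {
        "herg": (3.0, 8.0), "neg_logs": (2.0, 10.0), "cns_mpo": (0.0, 6.0),
        "bbb_score": (0.0, 6.0), "mpa": (30.0, 90.0), "clogd_74": (-1.0, 8.0),
    }
    cuts = {
        "herg": (thresholds.herg_max, "le"),
        "neg_logs": (thresholds.neg_logs_max, "le"),
        "cns_mpo": (thresholds.cns_mpo_min, "ge"),
        "bbb_score": (thresholds.bbb_score_min, "ge"),
        "mpa": (thresholds.mpa_max, "le"),
    }
    rows = []
    for i in range(cfg.n):
        row = {k: rng.uniform(*b) for k, b in bounds.items()}
        row["compound_id"] = f"LIB{i:04d}"
        rows.append(row)
    if cfg.n > 0 and cfg.truth.get("include_boundaries", True):
        mid = {k: 0.5 * (b[0] + b[1]) for k, b in bounds.items()}
        for col, (cut, direction) in cuts.items():
            for tag, delta in (("at", 0.0), ("pass", -0.5), ("fail", 0.5)):
                sign = 1.0 if direction == "le" else -1.0
                row = dict(mid)
                row[col] = cut + sign * delta
                row["compound_id"] = f"EDGE_{col}_{tag}"
                rows.append(row)
    df = pd.DataFrame(rows, columns=["compound_id", *bounds])
    if len(df):
        df = df.set_index("compound_id")
    df.attrs["thresholds"] = thresholds
    return df
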