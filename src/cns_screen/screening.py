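"""Candidate selection: guideline thresholds, per-compound flags, ranking.

The procedure mirrors how a reference panel of clinically used CNS
chemotherapy agents is turned into guideline cut-offs — predicted hERG
pIC50 <= 5.5 (cardiac safety), -logS <= 7.5 (solubility), CNS-MPO above
a preset (the soft "over 3" screen or the strict >= 4 cut-off),
BBB score >= 4, and minimal projection area <= 60 A^2 — and then applied
uniformly to candidates.  hERG and frontier-orbital energies are never
computed here; they are ingest-only columns, and an absent value yields a
"not evaluated" flag rather than a failure.  High ClogD is reported as a
soft warning, not a hard filter.

:class:`CompoundScreen` is the scikit-learn-shaped front end: ``fit``
calibrates (records guideline thresholds plus the panel's observed
ranges for audit), ``transform`` screens a candidate table into flags,
pass counts and a deterministic rank.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .scoring import classify

__all__ = [
    "ThresholdSet",
    "DEFAULT_THRESHOLDS",
    "STRICT_THRESHOLDS",
    "calibrate_thresholds",
    "screen",
    "rank",
    "CompoundScreen",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Screening cut-offs; boundaries are inclusive (<= / >=)."""

    herg_max: float = 5.5
    neg_logs_max: float = 7.5
    cns_mpo_min: float = 3.0
    bbb_score_min: float = 4.0
    mpa_max: float = 60.0
    clogd_max: float | None = None  # soft warning only

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


DEFAULT_THRESHOLDS = ThresholdSet()  # CNS-MPO "over 3" preset
STRICT_THRESHOLDS = ThresholdSet(cns_mpo_min=4.0)  # >= 4 cut-off preset

# column -> (threshold attribute, pass direction)
_FILTERS: dict[str, tuple[str, str]] = {
    "herg": ("herg_max", "le"),
    "neg_logs": ("neg_logs_max", "le"),
    "cns_mpo": ("cns_mpo_min", "ge"),
    "bbb_score": ("bbb_score_min", "ge"),
    "mpa": ("mpa_max", "le"),
}


def calibrate_thresholds(
    panel: pd.DataFrame, preset: str = "default"
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Guideline thresholds plus an audit of the reference panel's ranges.

    The cut-offs themselves are the published guideline values (they are
    conventions, not panel statistics); the returned audit table holds the
    panel's observed min/max per property so a user can check the
    guideline against the panel that motivated it.
    """
    if panel is None or len(panel) == 0:
        raise ValueError("reference panel is empty; nothing to calibrate against")
    thresholds = {"default": DEFAULT_THRESHOLDS, "strict": STRICT_THRESHOLDS}[preset]
    cols = [c for c in _FILTERS if c in panel.columns]
    audit = pd.DataFrame({
        "min": panel[cols].min(),
        "max": panel[cols].max(),
    })
    return thresholds, audit


def screen(
    candidates: pd.DataFrame,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply every filter to every candidate row independently.

    ``candidates`` is indexed by compound id with columns among
    ``cns_mpo``, ``bbb_score``, ``neg_logs``, ``mpa``, ``clogd_74``;
    ``external`` (indexed by id) supplies ingest-only columns, notably
    ``herg``.  Output flags are ``True``/``False``/``pd.NA`` (not
    evaluated).  ``n_pass`` counts passes among evaluated filters; a
    ``clogd_warning`` column marks the soft lipophilicity alert.
    """
    df = candidates.copy()
    if external is not None and len(external):
        df = df.join(external, how="left", rsuffix="_ext")
    flags = pd.DataFrame(index=df.index)
    for col, (attr, direction) in _FILTERS.items():
        cutoff = getattr(thresholds, attr)
        if col not in df.columns:
            flags[f"pass_{col}"] = pd.NA
            continue
        values = df[col]
        flags[f"pass_{col}"] = pd.Series(
            [pd.NA if pd.isna(v) else classify(float(v), cutoff, direction)
             for v in values],
            index=df.index, dtype=object,
        )
    flag_cols = [c for c in flags.columns if c.startswith("pass_")]
    flags["n_pass"] = flags[flag_cols].apply(
        lambda r: int(sum(1 for v in r if v is True)), axis=1
    )
    if thresholds.clogd_max is not None and "clogd_74" in df.columns:
        flags["clogd_warning"] = df["clogd_74"] > thresholds.clogd_max
    else:
        flags["clogd_warning"] = False
    out = df.join(flags)
    out.index.name = "compound_id"
    return out


def rank(result: pd.DataFrame) -> pd.DataFrame:
    """Deterministic total order over a screening result.

    Lexicographic: n_pass desc, CNS-MPO desc, BBB score desc, -logS asc,
    then compound id asc.  Missing sort columns are treated as neutral.
    """
    df = result.copy()
    n = len(df)
    keys = pd.DataFrame(index=df.index)
    keys["k1"] = -df["n_pass"] if "n_pass" in df else 0.0
    keys["k2"] = -df["cns_mpo"] if "cns_mpo" in df else 0.0
    keys["k3"] = -df["bbb_score"] if "bbb_score" in df else 0.0
    keys["k4"] = df["neg_logs"] if "neg_logs" in df else 0.0
    keys["k5"] = df.index.astype(str)
    keys = keys.fillna(0.0)
    order = keys.sort_values(["k1", "k2", "k3", "k4", "k5"], kind="stable").index
    df = df.loc[order]
    df["rank"] = np.arange(1, n + 1)
    return df


class CompoundScreen(BaseEstimator, TransformerMixin):
    """Panel-calibrated physicochemical screen as a transformer.

    Parameters
    ----------
    preset : "default" or "strict"
        CNS-MPO cut-off preset: the soft "over 3" screen or the
        conventional >= 4 cut-off.
    thresholds : ThresholdSet, optional
        Explicit cut-offs; overrides the preset entirely.

    After ``fit`` (panel descriptor table, optional) the instance exposes
    ``thresholds_`` and ``panel_audit_``; ``transform`` maps a candidate
    score table to a ranked report.
    """

    def __init__(self, preset: str = "default",
                 thresholds: ThresholdSet | None = None):
        self.preset = preset
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "CompoundScreen":
        if self.thresholds is not None:
            self.thresholds_ = self.thresholds
            self.panel_audit_ = pd.DataFrame(columns=["min", "max"])
        elif X is not None and len(X):
            self.thresholds_, self.panel_audit_ = calibrate_thresholds(
                X, preset=self.preset)
        else:
            self.thresholds_ = {"default": DEFAULT_THRESHOLDS,
                                "strict": STRICT_THRESHOLDS}[self.preset]
            self.panel_audit_ = pd.DataFrame(columns=["min", "max"])
        return self

    def transform(self, X: pd.DataFrame,
                  external: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            self.fit(None)
        if len(X) == 0:
            empty = X.copy()
            empty["n_pass"] = pd.Series(dtype=int)
            empty["rank"] = pd.Series(dtype=int)
            return empty
        return rank(screen(X, self.thresholds_, external))
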