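"""CNS multiparameter optimization (CNS-MPO) and blood-brain-barrier scores.

Both are fixed, published scoring systems; this module evaluates them and
never refits their functional forms.

* CNS-MPO (Wager et al., ACS Chem. Neurosci. 2010, 1, 435-449): the sum
  of six piecewise-linear desirability functions T0 over ClogP, ClogD(7.4),
  MW, TPSA, HBD and the most basic pKa.  Each component lies in [0, 1], so
  the score lies in [0, 6]; >= 4 is the conventional cut-off for a
  CNS-favorable profile, with > 3 used as a softer screen.

* BBB score (Gupta et al., J. Med. Chem. 2019, 62, 9824-9836): a weighted
  sum of five value functions over aromatic-ring count (stepwise), heavy
  atoms (cubic), MWHBN (cubic), TPSA (linear) and pKa (quartic), with
  weights (1, 1, 1.5, 2, 0.5) summing to 6.  The polynomial coefficients
  are stored in ``data/bbb_score_value_functions.json`` with a citation
  header so the transcription is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

from .descriptors import DescriptorSet

__all__ = [
    "MPO_BREAKPOINTS",
    "MPOResult",
    "BBBScoreResult",
    "mpo_component",
    "cns_mpo",
    "bbb_score",
    "classify",
]

# CNS-MPO desirability breakpoints (x, T0) per property; linear in between,
# flat outside.  Monotone-decreasing properties hold T0 = 1 on the ideal
# side; TPSA is the one hump-shaped desirability.
MPO_BREAKPOINTS: dict[str, tuple[tuple[float, float], ...]] = {
    "clogp": ((3.0, 1.0), (5.0, 0.0)),
    "clogd": ((2.0, 1.0), (4.0, 0.0)),
    "mw": ((360.0, 1.0), (500.0, 0.0)),
    "tpsa": ((20.0, 0.0), (40.0, 1.0), (90.0, 1.0), (120.0, 0.0)),
    "hbd": ((0.5, 1.0), (3.5, 0.0)),
    "pka": ((8.0, 1.0), (10.0, 0.0)),
}


@dataclass(frozen=True)
class MPOResult:
    components: Mapping[str, float]
    score: float
    missing_policy_applied: tuple[str, ...] = ()


@dataclass(frozen=True)
class BBBScoreResult:
    components: Mapping[str, float]
    weighted_score: float
    missing_policy_applied: tuple[str, ...] = ()


def mpo_component(value: float, property_name: str) -> float:
    """One CNS-MPO desirability in [0, 1]; continuous piecewise-linear."""
    try:
        pts = MPO_BREAKPOINTS[property_name]
    except KeyError:
        raise KeyError(
            f"unknown CNS-MPO property {property_name!r}; "
            f"expected one of {sorted(MPO_BREAKPOINTS)}"
        ) from None
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(value, xs, ys))


def cns_mpo(d: DescriptorSet) -> MPOResult:
    """CNS-MPO score of a descriptor vector.

    An absent basic pKa is scored as non-ionizable (component = 1.0, the
    ideal plateau) and flagged in ``missing_policy_applied``.
    """
    flags = []
    if d.pka_basic is None:
        pka_component = 1.0
        flags.append("pka_basic_absent_scored_1.0")
    else:
        pka_component = mpo_component(d.pka_basic, "pka")
    components = {
        "clogp": mpo_component(d.clogp, "clogp"),
        "clogd": mpo_component(d.clogd_74, "clogd"),
        "mw": mpo_component(d.mw, "mw"),
        "tpsa": mpo_component(d.tpsa, "tpsa"),
        "hbd": mpo_component(d.hbd, "hbd"),
        "pka": pka_component,
    }
    return MPOResult(components=components,
                     score=float(sum(components.values())),
                     missing_policy_applied=tuple(flags))


def _load_bbb_params() -> dict:
    text = (resources.files("cns_screen") / "data" /
            "bbb_score_value_functions.json").read_text()
    return json.loads(text)


_BBB = _load_bbb_params()


def _poly_value(value: float, spec: Mapping) -> float:
    lo, hi = spec["domain"]
    if not (lo < value <= hi):
        return 0.0
    raw = float(np.polyval(spec["coefficients"], value)) / spec["normalizer"]
    return float(np.clip(raw, 0.0, 1.0))


def bbb_score(d: DescriptorSet, *, neutral_pka: float = 7.0) -> BBBScoreResult:
    """BBB score: aro + ha + 1.5*mwhbn + 2*tpsa + 0.5*pka, range [0, 6].

    An absent basic pKa is evaluated at a neutral default (``neutral_pka``)
    and flagged.  ``heavy_atoms`` must be positive.
    """
    if d.heavy_atoms <= 0:
        raise ValueError("heavy_atoms must be positive")
    flags = []
    pka = d.pka_basic
    if pka is None:
        pka = neutral_pka
        flags.append(f"pka_basic_absent_evaluated_at_{neutral_pka}")
    aro_step = _BBB["aro_step"]
    components = {
        "aro": float(aro_step.get(str(d.aro_rings), 0.0)),
        "ha": _poly_value(d.heavy_atoms, _BBB["ha"]),
        "mwhbn": _poly_value(d.mwhbn, _BBB["mwhbn"]),
        "tpsa": _poly_value(d.tpsa, _BBB["tpsa"]),
        "pka": _poly_value(pka, _BBB["pka"]),
    }
    weights = _BBB["weights"]
    score = float(sum(weights[k] * components[k] for k in components))
    return BBBScoreResult(components=components, weighted_score=score,
                          missing_policy_applied=tuple(flags))


def classify(score: float, cutoff: float, direction: str) -> bool:
    """Inclusive threshold test: ``ge`` means pass iff score >= cutoff."""
    if direction == "ge":
        return score >= cutoff
    if direction == "le":
        return score <= cutoff
    raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
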