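"""Habitat-preference indices with their published decision rules.

Five indices are computed from a use profile r and an availability vector p:

* Duncan forage-ratio index (configurable formula; default r/(k*p), parity 1/k)
* Ivlev electivity E = (r-p)/(r+p), preference when positive
* Bailey simultaneous binomial confidence intervals, compared with expected use
* Manly's alpha (constant resources) = (r/p)/sum(r/p), preference above 1/k
* Jacobs' D = (r-p)/(r+p-2rp), binned into avoidance/indifference/selection

A consensus call per habitat combines the per-index decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .availability_use import AvailabilityVector, expected_use
from .survey_model import SurveyDataError, UseProfile

__all__ = [
    "INDEX_NAMES",
    "IndexValue",
    "ConsensusCall",
    "ivlev",
    "jacobs_ii",
    "manly_alpha",
    "duncan",
    "bailey_intervals",
    "bailey_classification",
    "duncan_decision",
    "ivlev_decision",
    "alpha_decision",
    "jacobs_decision",
    "consensus",
    "preference_report",
]

INDEX_NAMES = ("duncan", "ivlev", "bailey", "alpha", "jacobs_ii")

#: decisions that count as a preference vote in the consensus
_PREFERENCE_SIGNALS = frozenset({"preference", "strong_selection"})
_AVOIDANCE_BINS = frozenset({"strong_avoidance", "moderate_avoidance"})


@dataclass(frozen=True)
class IndexValue:
    index: str
    habitat: str
    value: float
    decision: str
    interval: Optional[tuple[float, float]] = None  # bailey only, count scale


@dataclass(frozen=True)
class ConsensusCall:
    habitat: str
    votes: int
    label: str  # {"preferred", "used", "avoided"}


def _as_rp(r, p) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    p = p.p if isinstance(p, AvailabilityVector) else np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise SurveyDataError("use/availability dimension mismatch")
    if (p <= 0).any():
        raise SurveyDataError("availability proportions must be positive")
    return r, p


def ivlev(r, p) -> np.ndarray:
    """Electivity E_i = (r_i - p_i)/(r_i + p_i), in [-1, 1]."""
    r, p = _as_rp(r, p)
    return (r - p) / (r + p)


def jacobs_ii(r, p) -> np.ndarray:
    """Jacobs' D_i = (r_i - p_i)/(r_i + p_i - 2 r_i p_i), in [-1, 1]."""
    r, p = _as_rp(r, p)
    denom = r + p - 2 * r * p
    if (denom <= 0).any():
        raise SurveyDataError("degenerate cell in Jacobs denominator")
    return (r - p) / denom


def manly_alpha(r, p) -> np.ndarray:
    """Constant-resources selectivity alpha_i = (r_i/p_i)/sum_j(r_j/p_j)."""
    r, p = _as_rp(r, p)
    w = r / p
    total = w.sum()
    if total <= 0:
        raise SurveyDataError("all-zero use profile")
    return w / total


def duncan(
    r,
    p,
    k: Optional[int] = None,
    formula: Optional[Callable[[np.ndarray, np.ndarray, int], np.ndarray]] = None,
) -> np.ndarray:
    """Duncan preference index; default formula r_i/(k * p_i) with parity 1/k.

    The formula is a configuration point: pass ``formula(r, p, k)`` to
    substitute another variant.
    """
    r, p = _as_rp(r, p)
    k = k if k is not None else len(r)
    if formula is not None:
        return np.asarray(formula(r, p, k), dtype=float)
    return r / (k * p)


def ivlev_decision(value: float) -> str:
    return "preference" if value > 0 else "no_preference"


def duncan_decision(value: float, threshold: float = 0.3) -> str:
    return "preference" if value > threshold else "no_preference"


def alpha_decision(value: float, k: int) -> str:
    return "preference" if value > 1.0 / k else "no_preference"


def jacobs_decision(value: float) -> str:
    """Five-bin classification of Jacobs' D.

    The published bins leave (-0.26, -0.25) and (0.25, 0.26) uncovered; values
    in those gaps are assigned to the adjacent avoidance/selection bin
    (closed toward the stronger label).
    """
    if value >= 0.5:
        return "strong_selection"
    if value >= 0.25:
        return "neutral_selection"
    if value > -0.25:
        return "indifference"
    if value > -0.5:
        return "moderate_avoidance"
    return "strong_avoidance"


def bailey_intervals(
    O: np.ndarray, alpha_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted simultaneous binomial intervals, count scale.

    Normal approximation with a +-1/(2N) continuity correction on the
    proportion scale; z is taken at alpha_level/(2k) so the k intervals hold
    simultaneously.
    """
    O = np.asarray(O, dtype=float)
    N = O.sum()
    if N <= 0:
        raise SurveyDataError("empty profile")
    k = len(O)
    z = stats.norm.ppf(1 - alpha_level / (2 * k))
    phat = O / N
    half = z * np.sqrt(phat * (1 - phat) / N) + 1 / (2 * N)
    lower = np.clip(phat - half, 0.0, 1.0) * N
    upper = np.clip(phat + half, 0.0, 1.0) * N
    return lower, upper


def bailey_classification(
    O: np.ndarray, E: np.ndarray, alpha_level: float = 0.05
) -> list[tuple[float, float, str]]:
    """Per-habitat (lower, upper, decision) against expected counts.

    preference when the interval lies entirely above E_i; no_preference when
    entirely below; otherwise plain use.
    """
    E = np.asarray(E, dtype=float)
    lower, upper = bailey_intervals(O, alpha_level)
    out: list[tuple[float, float, str]] = []
    for lo, hi, e in zip(lower, upper, E):
        if lo > e:
            decision = "preference"
        elif hi < e:
            decision = "no_preference"
        else:
            decision = "use"
        out.append((float(lo), float(hi), decision))
    return out


def consensus(decisions: Mapping[str, str], habitat: str) -> ConsensusCall:
    """Combine per-index decisions for one habitat into a single call.

    preferred: at least 3 of the evaluated indices signal preference
    (counting Jacobs' strong-selection bin as a preference signal);
    avoided: the Jacobs bin is an avoidance bin and nothing signals
    preference; otherwise: used.
    """
    if len(decisions) < 3:
        raise SurveyDataError("consensus needs at least 3 indices")
    votes = sum(1 for d in decisions.values() if d in _PREFERENCE_SIGNALS)
    if votes >= 3:
        label = "preferred"
    elif decisions.get("jacobs_ii") in _AVOIDANCE_BINS and votes == 0:
        label = "avoided"
    else:
        label = "used"
    return ConsensusCall(habitat=habitat, votes=votes, label=label)


def preference_report(
    profile: UseProfile,
    p: AvailabilityVector,
    alpha_level: float = 0.05,
    duncan_formula: Optional[Callable] = None,
) -> tuple[list[IndexValue], list[ConsensusCall]]:
    """All five indices plus the consensus call for every habitat.

    Habitats with zero captures for this profile are reported with decision
    ``"absent"`` on every index; the consensus for such a habitat is still
    computed from the raw numeric rules (zero use reads as avoidance).
    """
    if profile.names != p.names:
        raise SurveyDataError("profile and availability habitats differ")
    r = profile.r
    k = len(r)
    E_exp = expected_use(profile, p).E

    values = {
        "duncan": duncan(r, p, k, formula=duncan_formula),
        "ivlev": ivlev(r, p),
        "alpha": manly_alpha(r, p),
        "jacobs_ii": jacobs_ii(r, p),
    }
    bailey = bailey_classification(profile.O, E_exp, alpha_level)

    raw_decisions: dict[str, dict[str, str]] = {h: {} for h in profile.names}
    for i, habitat in enumerate(profile.names):
        raw_decisions[habitat]["duncan"] = duncan_decision(values["duncan"][i])
        raw_decisions[habitat]["ivlev"] = ivlev_decision(values["ivlev"][i])
        raw_decisions[habitat]["bailey"] = bailey[i][2]
        raw_decisions[habitat]["alpha"] = alpha_decision(values["alpha"][i], k)
        raw_decisions[habitat]["jacobs_ii"] = jacobs_decision(values["jacobs_ii"][i])

    index_values: list[IndexValue] = []
    calls: list[ConsensusCall] = []
    for i, habitat in enumerate(profile.names):
        absent = profile.O[i] == 0
        for index in INDEX_NAMES:
            if index == "bailey":
                lo, hi, _ = bailey[i]
                value, interval = float(E_exp[i]), (lo, hi)
            else:
                value, interval = float(values[index][i]), None
            decision = "absent" if absent else raw_decisions[habitat][index]
            index_values.append(
                IndexValue(
                    index=index,
                    habitat=habitat,
                    value=value,
                    decision=decision,
                    interval=interval,
                )
            )
        calls.append(consensus(raw_decisions[habitat], habitat))
    return index_values, calls
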