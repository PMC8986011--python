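"""Sample-adequacy and goodness-of-fit of observed use against availability.

The log-likelihood-ratio (G) and Pearson chi-square statistics test whether a
multinomial use profile departs from proportional availability; the Cherry
criterion flags whether the sample is large enough for either test (every
N*p_i and N*(1-p_i) must exceed 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .availability_use import AvailabilityVector, ExpectedUse
from .survey_model import SurveyDataError, UseProfile

__all__ = [
    "AdequacyReport",
    "g_test",
    "chi_square_test",
    "cherry_flags",
    "adequacy_report",
]


@dataclass(frozen=True)
class AdequacyReport:
    group: str
    season: str
    G: float
    X2: float
    df: int
    p_G: float
    p_X2: float
    cherry_np: bool
    cherry_nq: bool


def _check(O: np.ndarray, E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    if O.shape != E.shape:
        raise SurveyDataError("observed/expected dimension mismatch")
    if O.sum() <= 0:
        raise SurveyDataError("empty profile")
    if ((E == 0) & (O > 0)).any():
        raise SurveyDataError("zero expectation with nonzero observation")
    return O, E


def g_test(O: np.ndarray, E: ExpectedUse | np.ndarray) -> tuple[float, int, float]:
    """Log-likelihood-ratio goodness-of-fit: G = 2 sum O ln(O/E), df = k-1.

    Zero cells contribute zero (the O ln O -> 0 limit).
    """
    Evals = E.E if isinstance(E, ExpectedUse) else E
    O, Evals = _check(O, Evals)
    mask = O > 0
    G = 2.0 * float(np.sum(O[mask] * np.log(O[mask] / Evals[mask])))
    G = max(G, 0.0)
    df = len(O) - 1
    return G, df, float(stats.chi2.sf(G, df))


def chi_square_test(
    O: np.ndarray, E: ExpectedUse | np.ndarray
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit: X2 = sum (O-E)^2/E, df = k-1."""
    Evals = E.E if isinstance(E, ExpectedUse) else E
    O, Evals = _check(O, Evals)
    X2 = float(np.sum((O - Evals) ** 2 / Evals))
    df = len(O) - 1
    return X2, df, float(stats.chi2.sf(X2, df))


def cherry_flags(N: int, p: AvailabilityVector | np.ndarray) -> tuple[bool, bool]:
    """Sample-adequacy flags: min N*p_i > 5 and min N*(1-p_i) > 5."""
    if N < 0:
        raise SurveyDataError("negative sample size")
    pvals = p.p if isinstance(p, AvailabilityVector) else np.asarray(p, float)
    return bool((N * pvals).min() > 5), bool((N * (1 - pvals)).min() > 5)


def adequacy_report(profile: UseProfile, p: AvailabilityVector) -> AdequacyReport:
    """Full adequacy panel for one group-season profile."""
    if profile.names != p.names:
        raise SurveyDataError("profile and availability habitats differ")
    E = profile.N * p.p
    G, df, p_G = g_test(profile.O, E)
    X2, _, p_X2 = chi_square_test(profile.O, E)
    c_np, c_nq = cherry_flags(profile.N, p)
    return AdequacyReport(
        group=profile.group,
        season=profile.season,
        G=G,
        X2=X2,
        df=df,
        p_G=p_G,
        p_X2=p_X2,
        cherry_np=c_np,
        cherry_nq=c_nq,
    )
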