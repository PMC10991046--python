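"""Score agreement, baseline accuracy, and session/test variance decomposition.

When a respondent is retested on a *different* parallel test in a
*different* session, their score change mixes two sources: test change and
session change.  Measuring the dispersion of score differences across both
a test and a session change, and separately across a test change alone
(same session), the session-only dispersion follows by subtraction on the
variance scale:

    var(session) = var(session+test) - var(test)

The printed dispersions practitioners exchange are usually standard
deviations, so the default convention squares the inputs, subtracts, and
reports the square root; the raw variance convention is also supported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .irt import AbilityEstimates, ResponseMatrix
from .subsets import SubsetPlan

__all__ = [
    "AgreementReport",
    "BaselineScores",
    "VarianceDecomposition",
    "ability_agreement",
    "baseline_scores",
    "variance_decomposition",
]


@dataclass
class AgreementReport:
    """Pearson agreement between two sets of ability estimates."""

    correlation: float
    n_shared: int
    mean_difference: float
    sd_difference: float


@dataclass
class BaselineScores:
    """Proportion-correct summaries per respondent and per item."""

    respondent_accuracy: pd.Series
    item_accuracy: pd.Series


@dataclass
class VarianceDecomposition:
    """Decomposition of score variability into test- and session-change parts.

    All ``sigma2_*`` fields live on the variance scale;
    ``session_dispersion`` is re-expressed in the requested convention.
    A negative solved session variance signals that the inputs violate the
    additive model; it is reported signed with ``negative_session_variance``
    set (and a NaN sd), never silently clipped.
    """

    sigma2_session_and_test: float
    sigma2_test: float
    sigma2_session: float
    convention: str
    session_dispersion: float
    negative_session_variance: bool


def ability_agreement(a: AbilityEstimates, b: AbilityEstimates) -> AgreementReport:
    """Correlate two ability estimates over their shared respondents."""
    shared = [r for r in a.respondent_ids if r in set(b.respondent_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared respondents to compute agreement, have {len(shared)}"
        )
    ta = a.frame.loc[shared, "theta"].to_numpy()
    tb = b.frame.loc[shared, "theta"].to_numpy()
    diff = ta - tb
    return AgreementReport(
        correlation=float(pearsonr(ta, tb)[0]),
        n_shared=len(shared),
        mean_difference=float(diff.mean()),
        sd_difference=float(diff.std(ddof=1)) if len(shared) > 1 else 0.0,
    )


def baseline_scores(
    responses: ResponseMatrix, subset: SubsetPlan | None = None
) -> BaselineScores:
    """Classical proportion-correct scoring, optionally within one subset.

    Respondent accuracy averages over the items the respondent actually
    answered; item accuracy averages over the respondents who saw the
    item.  Rows or columns with no observations are dropped with a
    warning rather than reported as NaN.
    """
    frame = responses.frame
    if subset is not None:
        frame = responses.subset_items(subset.item_ids).frame
    if frame.size == 0:
        raise ValueError("empty response matrix")
    obs = frame.notna()
    dead_r = list(frame.index[obs.sum(axis=1) == 0])
    dead_i = list(frame.columns[obs.sum(axis=0) == 0])
    if dead_r or dead_i:
        warnings.warn(
            f"excluded from baseline scoring - respondents with no responses: "
            f"{dead_r}; items with no responses: {dead_i}",
            RuntimeWarning,
            stacklevel=2,
        )
    resp_acc = frame.drop(index=dead_r).mean(axis=1, skipna=True)
    item_acc = frame.drop(columns=dead_i).mean(axis=0, skipna=True)
    resp_acc.name = "proportion_correct"
    item_acc.name = "proportion_correct"
    return BaselineScores(respondent_accuracy=resp_acc, item_accuracy=item_acc)


def _dispersion_to_variance(value, convention: str, label: str) -> float:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        v = float(arr)
        if v < 0:
            raise ValueError(f"{label}: a dispersion cannot be negative, got {v}")
        return v ** 2 if convention == "sd" else v
    if arr.size < 3:
        raise ValueError(f"{label}: need >= 3 score differences, have {arr.size}")
    return float(np.var(arr, ddof=1))


def variance_decomposition(
    delta_session_test, delta_test, convention: str = "sd"
) -> VarianceDecomposition:
    """Solve the session-change dispersion from two observed dispersions.

    Parameters
    ----------
    delta_session_test : scalar or array-like
        Dispersion of ability differences across both a session change and
        a test change — or the raw list of differences, whose sample SD
        (n-1 denominator) is taken first.
    delta_test : scalar or array-like
        Same, across a test change only (single session).
    convention : {"sd", "variance"}
        How scalar inputs are interpreted and how the solved session
        dispersion is reported.  The subtraction itself always happens on
        the variance scale.
    """
    if convention not in ("sd", "variance"):
        raise ValueError(f"convention must be 'sd' or 'variance', got {convention!r}")
    v_st = _dispersion_to_variance(delta_session_test, convention, "delta_session_test")
    v_t = _dispersion_to_variance(delta_test, convention, "delta_test")
    v_s = v_st - v_t
    negative = v_s < 0
    if convention == "sd":
        session = math.sqrt(v_s) if not negative else float("nan")
    else:
        session = v_s
    return VarianceDecomposition(
        sigma2_session_and_test=v_st,
        sigma2_test=v_t,
        sigma2_session=v_s,
        convention=convention,
        session_dispersion=session,
        negative_session_variance=negative,
    )
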