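"""Dichotomous item response theory for proficiency testing.

This module implements the measurement core of the toolkit: the logistic
item response function, marginal-maximum-likelihood (MML) calibration of
the Rasch (one-parameter logistic) model by expectation-maximization,
posterior-mean (EAP) ability scoring against a fixed item bank, test
information and standard-error curves, limited-information model-fit
statistics (AIC, BIC, M2-based RMSEA), and a scree-based dimensionality
check.

Model
-----
The probability that respondent *i* answers item *j* correctly is

    P(x_ij = 1 | theta_i) = c_j + (1 - c_j) * logistic(alpha_j * (theta_i - beta_j))

with ability ``theta``, difficulty ``beta``, slope ``alpha`` and guessing
asymptote ``c`` on a shared latent scale.  Calibration fits the Rasch
restriction (``alpha = 1``, ``c = 0``) under a standard-normal latent
prior, which anchors average ability at 0 and keeps every estimate finite,
including all-correct and all-incorrect response patterns.  The general
three-parameter form is evaluable everywhere (scoring, information), but
only ``beta`` is ever estimated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp
from scipy.stats import norm

__all__ = [
    "ResponseMatrix",
    "ItemParameters",
    "ItemBank",
    "AbilityEstimates",
    "FitStatistics",
    "InformationCurve",
    "ScreeResult",
    "CalibrationConfig",
    "probability_correct",
    "fit_rasch",
    "score_with_fixed_items",
    "test_information",
    "fit_statistics",
    "dimensionality_scree",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ResponseMatrix:
    """Respondents x items dichotomous outcomes with missing-value support.

    Wraps a float DataFrame whose rows are respondents, columns are items
    and cells are 1.0 (correct), 0.0 (incorrect) or NaN (not administered).

    Parameters
    ----------
    data : pandas.DataFrame
        Index holds respondent ids, columns hold item ids.  Cells must be
        in {0, 1, NaN}; ids must be unique.
    """

    def __init__(self, data: pd.DataFrame):
        frame = data.astype(float)
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate respondent ids: {dupes}")
        if frame.columns.has_duplicates:
            dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate item ids: {dupes}")
        vals = frame.to_numpy()
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "response cells must be 0, 1 or missing; found "
                f"{vals[i, j]!r} at respondent {frame.index[i]!r}, "
                f"item {frame.columns[j]!r}"
            )
        self.frame = frame

    @classmethod
    def from_arrays(cls, values, respondent_ids=None, item_ids=None) -> "ResponseMatrix":
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        if respondent_ids is None:
            respondent_ids = [f"r{i+1:04d}" for i in range(n)]
        if item_ids is None:
            item_ids = [f"i{j+1:04d}" for j in range(m)]
        return cls(pd.DataFrame(values, index=list(respondent_ids), columns=list(item_ids)))

    @property
    def respondent_ids(self) -> list:
        return list(self.frame.index)

    @property
    def item_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_respondents(self) -> int:
        return self.frame.shape[0]

    @property
    def n_items(self) -> int:
        return self.frame.shape[1]

    def subset_items(self, item_ids) -> "ResponseMatrix":
        missing = [i for i in item_ids if i not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown item ids: {missing}")
        return ResponseMatrix(self.frame.loc[:, list(item_ids)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ResponseMatrix({self.n_respondents} respondents x {self.n_items} items)"


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of one dichotomous item on the latent logit scale."""

    item_id: str
    beta: float
    alpha: float = 1.0
    c: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.beta):
            raise ValueError(f"item {self.item_id!r}: beta must be finite, got {self.beta}")
        if not (self.alpha > 0):
            raise ValueError(f"item {self.item_id!r}: alpha must be > 0, got {self.alpha}")
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"item {self.item_id!r}: c must lie in [0, 1), got {self.c}")


class ItemBank:
    """Ordered collection of calibrated item parameters.

    ``calibration_meta`` records how the bank was produced (latent prior,
    quadrature, convergence, degenerate items) so a bank serialized to disk
    is self-describing.
    """

    def __init__(self, items, calibration_meta: dict | None = None):
        items = list(items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            seen: set = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate item ids in bank: {dupes}")
        self.items = items
        self.calibration_meta = dict(calibration_meta or {})
        self._index = {it.item_id: it for it in items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        return self._index[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    @property
    def betas(self) -> np.ndarray:
        return np.array([it.beta for it in self.items])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([it.alpha for it in self.items])

    @property
    def cs(self) -> np.ndarray:
        return np.array([it.c for it in self.items])

    def subset(self, item_ids) -> "ItemBank":
        missing = [i for i in item_ids if i not in self._index]
        if missing:
            raise KeyError(f"item ids not in bank: {missing}")
        return ItemBank([self._index[i] for i in item_ids], self.calibration_meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "beta": self.betas,
                "alpha": self.alphas,
                "c": self.cs,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ItemBank({len(self)} items)"


class AbilityEstimates:
    """Per-respondent ability estimates (posterior mean and SD)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"theta", "se", "n_items_answered"}
        if not required.issubset(frame.columns):
            raise ValueError(f"ability frame needs columns {sorted(required)}")
        self.frame = frame

    @property
    def respondent_ids(self) -> list:
        return list(self.frame.index)

    @property
    def theta(self) -> np.ndarray:
        return self.frame["theta"].to_numpy()

    @property
    def se(self) -> np.ndarray:
        return self.frame["se"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AbilityEstimates({len(self)} respondents)"


@dataclass
class FitStatistics:
    """Marginal-likelihood model-fit summary."""

    log_likelihood: float
    n_parameters: int
    n_respondents: int
    aic: float
    bic: float
    converged: bool
    n_iterations: int
    rmsea: float | None = None
    rmsea_df: int | None = None
    m2_statistic: float | None = None
    rmsea_note: str | None = None

    @classmethod
    def from_loglik(cls, log_likelihood, n_parameters, n_respondents,
                    converged=True, n_iterations=0, **kw) -> "FitStatistics":
        aic = -2.0 * log_likelihood + 2.0 * n_parameters
        bic = -2.0 * log_likelihood + n_parameters * math.log(n_respondents)
        return cls(log_likelihood, n_parameters, n_respondents, aic, bic,
                   converged, n_iterations, **kw)


@dataclass
class InformationCurve:
    """Test information I(theta) and the matching SE(theta) = 1/sqrt(I)."""

    theta_grid: np.ndarray
    information: np.ndarray
    se: np.ndarray

    @property
    def peak_theta(self) -> float:
        return float(self.theta_grid[int(np.argmax(self.information))])

    @property
    def peak_information(self) -> float:
        return float(np.max(self.information))


@dataclass
class ScreeResult:
    """Eigenvalue spectrum of the inter-item correlation matrix."""

    eigenvalues: np.ndarray
    first_second_ratio: float
    unidimensional: bool
    excluded_items: list


@dataclass(frozen=True)
class CalibrationConfig:
    """Numerical settings for calibration and scoring.

    A fixed rectangular quadrature over the latent scale keeps every run
    deterministic; 61 points on [-6, 6] resolve the posterior comfortably
    for |theta| <= 4.
    """

    n_quadrature: int = 61
    quad_limit: float = 6.0
    tol: float = 1e-4
    max_iter: int = 500
    beta_clamp: float = 6.0

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        nodes = np.linspace(-self.quad_limit, self.quad_limit, self.n_quadrature)
        w = norm.pdf(nodes)
        return nodes, w / w.sum()

    def to_dict(self) -> dict:
        return {
            "n_quadrature": self.n_quadrature,
            "quad_limit": self.quad_limit,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "beta_clamp": self.beta_clamp,
        }


# ---------------------------------------------------------------------------
# Response function
# ---------------------------------------------------------------------------


def probability_correct(theta, item, *, alpha: float = 1.0, c: float = 0.0):
    """Probability of a correct response under the logistic response model.

    Parameters
    ----------
    theta : float or array-like
        Respondent ability; must be finite.
    item : ItemParameters or float
        Either a full parameter record or a bare difficulty ``beta`` (in
        which case ``alpha`` and ``c`` keywords apply).

    Returns
    -------
    float or ndarray
        ``c + (1 - c) * logistic(alpha * (theta - beta))``, strictly
        increasing in theta with lower asymptote ``c`` and upper asymptote 1.
    """
    if isinstance(item, ItemParameters):
        beta, alpha, c = item.beta, item.alpha, item.c
    else:
        beta = float(item)
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise ValueError("theta must be finite (got a non-finite ability value)")
    if not math.isfinite(beta):
        raise ValueError(f"beta must be finite, got {beta}")
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not (0.0 <= c < 1.0):
        raise ValueError(f"c must lie in [0, 1), got {c}")
    p = c + (1.0 - c) * expit(alpha * (theta_arr - beta))
    return float(p) if np.isscalar(theta) or theta_arr.ndim == 0 else p


def _node_probabilities(nodes: np.ndarray, betas, alphas, cs) -> np.ndarray:
    """P(correct) at each quadrature node (rows) for each item (columns)."""
    g = expit(np.asarray(alphas) * (nodes[:, None] - np.asarray(betas)[None, :]))
    return np.asarray(cs)[None, :] + (1.0 - np.asarray(cs))[None, :] * g


def _posterior(values, obs, P, log_w):
    """Posterior over quadrature nodes per respondent.

    Returns (posterior n x Q, marginal log-likelihood per respondent).
    """
    logP = np.log(P)
    log1mP = np.log1p(-P)
    X0 = np.where(obs, values, 0.0)
    O = obs.astype(float)
    ll_nodes = X0 @ logP.T + (O - X0) @ log1mP.T  # n x Q
    ll_nodes += log_w[None, :]
    marg = logsumexp(ll_nodes, axis=1)
    post = np.exp(ll_nodes - marg[:, None])
    return post, marg


def _eap_frame(post, marg, nodes, obs, respondent_ids) -> AbilityEstimates:
    theta = post @ nodes
    var = post @ (nodes ** 2) - theta ** 2
    se = np.sqrt(np.maximum(var, 1e-12))
    frame = pd.DataFrame(
        {
            "theta": theta,
            "se": se,
            "n_items_answered": obs.sum(axis=1).astype(int),
        },
        index=pd.Index(respondent_ids, name="respondent_id"),
    )
    return AbilityEstimates(frame)


# ---------------------------------------------------------------------------
# Rasch calibration (MML-EM)
# ---------------------------------------------------------------------------


def fit_rasch(responses: ResponseMatrix, config: CalibrationConfig | None = None):
    """Calibrate Rasch item difficulties by marginal-maximum-likelihood EM.

    The latent ability distribution is fixed at N(0, 1), which identifies
    the scale (average ability 0); slopes are constrained to 1 and guessing
    to 0.  The E-step computes each respondent's posterior over a fixed
    quadrature grid; the M-step solves, per item, the monotone score
    equation ``sum_q n_jq * P(theta_q; beta_j) = r_j`` by bracketing.
    Items answered identically by every respondent carry no information
    about a finite difficulty and are clamped to +/- ``beta_clamp`` with a
    warning.

    Returns
    -------
    (ItemBank, AbilityEstimates, FitStatistics)
        Bank of estimated difficulties with calibration metadata (including
        the per-iteration log-likelihood trace), EAP abilities with
        posterior-SD standard errors, and fit statistics (AIC/BIC; RMSEA is
        computed separately by :func:`fit_statistics`).
    """
    config = config or CalibrationConfig()
    X = responses.values
    obs = ~np.isnan(X)
    n, m = X.shape
    if m < 2 or n < 2:
        raise ValueError(f"need >= 2 items and >= 2 respondents, got {n} x {m}")
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        empty = [responses.item_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"items with no observed response: {empty}")
    if (obs.sum(axis=1) == 0).any():
        empty = [responses.respondent_ids[i] for i in np.flatnonzero(obs.sum(axis=1) == 0)]
        raise ValueError(f"respondents with no observed response: {empty}")

    r_tot = np.nansum(X, axis=0)
    all_wrong = r_tot == 0
    all_right = r_tot == n_obs
    degenerate = all_wrong | all_right
    if degenerate.any():
        names = [responses.item_ids[j] for j in np.flatnonzero(degenerate)]
        warnings.warn(
            f"items with no observed variation, difficulty clamped to +/-{config.beta_clamp}: {names}",
            RuntimeWarning,
            stacklevel=2,
        )

    nodes, w = config.quadrature()
    log_w = np.log(w)
    clamp = config.beta_clamp

    # moment start: sample logit of (smoothed) item accuracy
    p0 = (r_tot + 0.5) / (n_obs + 1.0)
    beta = np.clip(np.log((1.0 - p0) / p0), -clamp, clamp)
    beta[all_wrong] = clamp
    beta[all_right] = -clamp

    X0 = np.where(obs, X, 0.0)
    O = obs.astype(float)
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        P = expit(nodes[:, None] - beta[None, :])
        post, marg = _posterior(X, obs, P, log_w)
        ll_trace.append(float(marg.sum()))

        nq = post.T @ O   # Q x m expected exposure counts
        rq = post.T @ X0  # Q x m expected correct counts
        r_j = rq.sum(axis=0)

        new_beta = beta.copy()
        for j in range(m):
            if degenerate[j]:
                new_beta[j] = clamp if all_wrong[j] else -clamp
                continue
            nj = nq[:, j]
            target = r_j[j]

            def score(b, nj=nj, target=target):
                return float((nj * expit(nodes - b)).sum() - target)

            # score is strictly decreasing in beta
            if score(-clamp) <= 0.0:
                new_beta[j] = -clamp
            elif score(clamp) >= 0.0:
                new_beta[j] = clamp
            else:
                new_beta[j] = brentq(score, -clamp, clamp, xtol=1e-10)

        delta = float(np.max(np.abs(new_beta - beta)))
        beta = new_beta
        if delta < config.tol:
            converged = True
            break

    # final posterior at the converged difficulties
    P = expit(nodes[:, None] - beta[None, :])
    post, marg = _posterior(X, obs, P, log_w)
    ll = float(marg.sum())
    ll_trace.append(ll)

    meta = {
        "model": "rasch-1pl",
        "prior": {"distribution": "normal", "mean": 0.0, "sd": 1.0},
        "quadrature": config.to_dict(),
        "convergence": {
            "converged": converged,
            "n_iterations": n_iter,
            "final_max_delta_beta": delta,
            "log_likelihood": ll,
        },
        "log_likelihood_trace": ll_trace,
        "degenerate_items": [responses.item_ids[j] for j in np.flatnonzero(degenerate)],
        "n_respondents": n,
        "n_items": m,
    }
    bank = ItemBank(
        [ItemParameters(item_id=i, beta=float(b)) for i, b in zip(responses.item_ids, beta)],
        calibration_meta=meta,
    )
    abilities = _eap_frame(post, marg, nodes, obs, responses.respondent_ids)
    stats = FitStatistics.from_loglik(
        ll, n_parameters=m, n_respondents=n, converged=converged, n_iterations=n_iter
    )
    return bank, abilities, stats


def score_with_fixed_items(
    responses: ResponseMatrix,
    bank: ItemBank,
    config: CalibrationConfig | None = None,
) -> AbilityEstimates:
    """Score respondents against a fixed, previously calibrated item bank.

    Every item in ``responses`` must exist in the bank; bank items the
    respondent never saw are simply ignored, so a subset of the bank yields
    abilities on the same scale as full-bank scoring.  Estimates are
    posterior means (EAP) under the bank's N(0,1) latent prior, with the
    posterior SD as standard error.
    """
    config = config or CalibrationConfig()
    unknown = [i for i in responses.item_ids if i not in bank]
    if unknown:
        raise KeyError(f"items not present in the bank: {unknown}")
    sub = bank.subset(responses.item_ids)
    X = responses.values
    obs = ~np.isnan(X)
    empty = np.flatnonzero(obs.sum(axis=1) == 0)
    if empty.size:
        names = [responses.respondent_ids[i] for i in empty]
        raise ValueError(f"respondents with zero observed responses: {names}")
    nodes, w = config.quadrature()
    P = _node_probabilities(nodes, sub.betas, sub.alphas, sub.cs)
    post, marg = _posterior(X, obs, P, np.log(w))
    return _eap_frame(post, marg, nodes, obs, responses.respondent_ids)


# ---------------------------------------------------------------------------
# Information / SE curves
# ---------------------------------------------------------------------------


def test_information(bank: ItemBank, theta_grid) -> InformationCurve:
    """Fisher test information and SE over an ability grid.

    Item information for the three-parameter logistic form is
    ``alpha^2 * (1 - P) / P * ((P - c) / (1 - c))^2``, which reduces to
    ``P (1 - P)`` for a Rasch item.  Test information sums over items and
    ``SE = 1 / sqrt(I)`` wherever I > 0.
    """
    if len(bank) == 0:
        raise ValueError("empty item bank")
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("theta grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("theta grid must be strictly increasing")
    P = _node_probabilities(grid, bank.betas, bank.alphas, bank.cs)
    c = bank.cs[None, :]
    info_items = bank.alphas[None, :] ** 2 * (1.0 - P) / P * ((P - c) / (1.0 - c)) ** 2
    info = info_items.sum(axis=1)
    with np.errstate(divide="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
    return InformationCurve(theta_grid=grid, information=info, se=se)


# ---------------------------------------------------------------------------
# Fit statistics (marginal likelihood + M2-based RMSEA)
# ---------------------------------------------------------------------------


def _m2_rmsea(X: np.ndarray, P: np.ndarray, dP: np.ndarray, w: np.ndarray):
    """Limited-information fit statistic on univariate and bivariate margins.

    Quadratic-form statistic of Maydeu-Olivares & Joe type: with ``e`` the
    residual between sample and model-implied first- and second-order
    margins, ``Xi`` the model-implied covariance of the margin indicators
    and ``Delta`` the Jacobian of the margins with respect to the item
    difficulties,

        M2 = N * e' [Xi^-1 - Xi^-1 Delta (Delta' Xi^-1 Delta)^-1 Delta' Xi^-1] e

    on df = (#margins - #free parameters) degrees of freedom, and
    RMSEA = sqrt(max(M2 - df, 0) / (df * N)).
    """
    n, m = X.shape
    margins = [(j,) for j in range(m)] + [(j, k) for j in range(m) for k in range(j + 1, m)]
    s = len(margins)
    S = np.zeros((s, m), dtype=bool)
    for a, mem in enumerate(margins):
        S[a, list(mem)] = True

    logP = np.log(P)  # Q x m
    A = np.exp(S @ logP.T)  # s x Q: prod_{j in S} P_j at each node
    pi = A @ w

    p1 = X.mean(axis=0)
    cross = (X.T @ X) / n
    iu = np.triu_indices(m, k=1)
    p_obs = np.concatenate([p1, cross[iu]])
    e = p_obs - pi

    # Xi[a,b] = pi(S_a | S_b union) - pi_a pi_b, computed in row chunks
    Xi = np.empty((s, s))
    logPT = logP.T  # m x Q
    chunk = max(1, int(2_000_000 // max(s, 1)))
    for lo in range(0, s, chunk):
        hi = min(lo + chunk, s)
        U = S[lo:hi, None, :] | S[None, :, :]  # (hi-lo) x s x m
        block = np.exp(U.reshape(-1, m) @ logPT) @ w
        Xi[lo:hi] = block.reshape(hi - lo, s)
    Xi -= np.outer(pi, pi)

    Delta = np.zeros((s, m))
    for a, mem in enumerate(margins):
        for l in mem:
            Delta[a, l] = float(((A[a] / P[:, l]) * dP[:, l] * w).sum())

    try:
        t = np.linalg.solve(Xi, e)
        B = np.linalg.solve(Xi, Delta)
    except np.linalg.LinAlgError:
        from scipy.linalg import pinvh

        Xinv = pinvh(Xi)
        t = Xinv @ e
        B = Xinv @ Delta
    mid = Delta.T @ B
    u = Delta.T @ t
    m2 = float(n * (e @ t - u @ np.linalg.solve(mid, u)))
    df = s - m
    rmsea = math.sqrt(max(m2 - df, 0.0) / (df * n))
    return m2, df, rmsea


def fit_statistics(
    responses: ResponseMatrix,
    bank: ItemBank,
    config: CalibrationConfig | None = None,
    compute_rmsea: bool = True,
    rmsea_max_items: int = 40,
) -> FitStatistics:
    """Model-fit summary of a bank evaluated on a response matrix.

    AIC and BIC follow directly from the marginal log-likelihood by
    quadrature (free parameters = the bank's difficulties, N = number of
    respondents).  RMSEA comes from the M2 limited-information statistic on
    first- and second-order margins; it requires complete responses and is
    skipped (``rmsea=None`` with a note) beyond ``rmsea_max_items`` items,
    where the margin covariance matrix becomes quadratically large.
    """
    config = config or CalibrationConfig()
    unknown = [i for i in responses.item_ids if i not in bank]
    if unknown:
        raise KeyError(f"items not present in the bank: {unknown}")
    sub = bank.subset(responses.item_ids)
    X = responses.values
    obs = ~np.isnan(X)
    nodes, w = config.quadrature()
    P = _node_probabilities(nodes, sub.betas, sub.alphas, sub.cs)
    _, marg = _posterior(X, obs, P, np.log(w))
    ll = float(marg.sum())
    n, m = X.shape
    stats = FitStatistics.from_loglik(ll, n_parameters=m, n_respondents=n,
                                      converged=True, n_iterations=0)
    if not compute_rmsea:
        stats.rmsea_note = "rmsea not requested"
        return stats
    if not obs.all():
        stats.rmsea_note = "rmsea requires complete responses (missing values present)"
        return stats
    if m < 3:
        stats.rmsea_note = "rmsea requires >= 3 items"
        return stats
    if m > rmsea_max_items:
        stats.rmsea_note = (
            f"rmsea skipped: {m} items exceeds rmsea_max_items={rmsea_max_items}"
        )
        return stats
    g = expit(sub.alphas[None, :] * (nodes[:, None] - sub.betas[None, :]))
    dP = -(1.0 - sub.cs[None, :]) * sub.alphas[None, :] * g * (1.0 - g)
    m2, df, rmsea = _m2_rmsea(X, P, dP, w)
    stats.m2_statistic = m2
    stats.rmsea_df = df
    stats.rmsea = rmsea
    return stats


# ---------------------------------------------------------------------------
# Dimensionality
# ---------------------------------------------------------------------------


def dimensionality_scree(
    responses: ResponseMatrix, ratio_threshold: float = 3.0
) -> ScreeResult:
    """Scree check that a response matrix reflects a single latent trait.

    Eigen-decomposes the inter-item Pearson correlation matrix (pairwise
    complete observations) and declares the data unidimensional when the
    first-to-second eigenvalue ratio exceeds ``ratio_threshold``.
    Zero-variance items carry no correlation signal and are excluded with
    a warning.
    """
    frame = responses.frame
    stds = frame.std(axis=0, skipna=True)
    excluded = [c for c in frame.columns if not (stds[c] > 0)]
    if excluded:
        warnings.warn(
            f"excluding zero-variance items from scree: {excluded}",
            RuntimeWarning,
            stacklevel=2,
        )
        frame = frame.drop(columns=excluded)
    if frame.shape[1] < 3:
        raise ValueError(
            f"scree needs >= 3 items with response variation, have {frame.shape[1]}"
        )
    corr = frame.corr(min_periods=2).to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    ratio = float(eig[0] / eig[1]) if eig[1] > 0 else float("inf")
    return ScreeResult(
        eigenvalues=eig,
        first_second_ratio=ratio,
        unidimensional=ratio > ratio_threshold,
        excluded_items=excluded,
    )
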