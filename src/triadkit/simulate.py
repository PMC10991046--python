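"""Synthetic-respondent generation and simulation harnesses.

Every other module in the toolkit is testable without any proprietary
stimuli or human data because this module generates dichotomous response
matrices directly from the logistic response model: abilities are drawn
from a normal population, item difficulties from a uniform span (default
[-3.8, 1.7], the spread a well-built confusable-triad bank occupies), and
each cell is an independent Bernoulli draw.

Reproducibility: each experiment takes one integer seed, which is expanded
into independent child streams (abilities, difficulties, responses) via
``numpy.random.SeedSequence.spawn``.  Identical seeds therefore replay
bit-identical outputs regardless of how many draws each stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .irt import (
    CalibrationConfig,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    fit_rasch,
    score_with_fixed_items,
)

__all__ = [
    "SimulationDesign",
    "SimulatedResponses",
    "GuessingSummary",
    "RecoveryReport",
    "TransferReport",
    "make_uniform_bank",
    "simulate_responses",
    "simulate_guessing",
    "parameter_recovery_experiment",
    "cross_group_transfer_experiment",
]

DEFAULT_DIFFICULTY_SPAN = (-3.8, 1.7)


@dataclass(frozen=True)
class SimulationDesign:
    """Recipe for one synthetic respondent sample.

    Abilities come from N(ability_mean, ability_sd^2) unless an explicit
    list is given; difficulties come from the supplied bank or, failing
    that, from a uniform draw of ``n_items`` values on
    [difficulty_low, difficulty_high].
    """

    n_respondents: int
    n_items: int | None = None
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    abilities: Sequence[float] | None = None
    item_bank: ItemBank | None = None
    difficulty_low: float = DEFAULT_DIFFICULTY_SPAN[0]
    difficulty_high: float = DEFAULT_DIFFICULTY_SPAN[1]
    seed: int = 0

    def __post_init__(self):
        if self.abilities is None:
            if self.n_respondents < 1:
                raise ValueError(f"n_respondents must be >= 1, got {self.n_respondents}")
            if not self.ability_sd > 0:
                raise ValueError(f"ability_sd must be > 0, got {self.ability_sd}")
        if self.item_bank is None and self.n_items is None:
            raise ValueError("design needs either an item_bank or n_items")
        if self.item_bank is None and self.n_items is not None and self.n_items < 1:
            raise ValueError(f"n_items must be >= 1, got {self.n_items}")

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "n_items": self.n_items if self.item_bank is None else len(self.item_bank),
            "ability_mean": self.ability_mean,
            "ability_sd": self.ability_sd,
            "explicit_abilities": self.abilities is not None,
            "item_bank_supplied": self.item_bank is not None,
            "difficulty_span": [self.difficulty_low, self.difficulty_high],
            "seed": self.seed,
        }


class SimulatedResponses(NamedTuple):
    responses: ResponseMatrix
    abilities: pd.Series
    bank: ItemBank


class GuessingSummary(NamedTuple):
    per_respondent: pd.Series
    pooled: float
    chance_level: float


@dataclass
class RecoveryReport:
    """Truth-vs-estimate summary for one parameter-recovery run."""

    n_respondents: int
    n_items: int
    seed: int
    beta_bias: float
    beta_rmse: float
    beta_correlation: float
    theta_bias: float
    theta_rmse: float
    theta_correlation: float


@dataclass
class TransferReport:
    """Cross-ability-group calibration transfer summary."""

    transfer_correlation: float
    within_correlation: float
    n_calibration: int
    n_holdout: int


def make_uniform_bank(
    n_items: int,
    low: float = DEFAULT_DIFFICULTY_SPAN[0],
    high: float = DEFAULT_DIFFICULTY_SPAN[1],
    seed: int | np.random.Generator = 0,
) -> ItemBank:
    """Bank of ``n_items`` Rasch items with difficulties uniform on [low, high]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    betas = rng.uniform(low, high, size=n_items)
    items = [ItemParameters(item_id=f"i{j+1:04d}", beta=float(b)) for j, b in enumerate(betas)]
    return ItemBank(items, calibration_meta={"source": "synthetic-uniform",
                                             "span": [low, high]})


def _design_streams(design: SimulationDesign):
    ss = np.random.SeedSequence(design.seed)
    s_ability, s_bank, s_resp = ss.spawn(3)
    return (
        np.random.default_rng(s_ability),
        np.random.default_rng(s_bank),
        np.random.default_rng(s_resp),
    )


def simulate_responses(design: SimulationDesign) -> SimulatedResponses:
    """Draw a dichotomous response matrix from the logistic response model.

    Each cell is an independent Bernoulli draw with success probability
    ``c + (1 - c) * logistic(alpha * (theta_i - beta_j))``.  Truth tables
    (abilities and bank) are returned alongside for recovery checks.
    Identical designs (including seed) reproduce identical output.
    """
    rng_ability, rng_bank, rng_resp = _design_streams(design)
    if design.abilities is not None:
        theta = np.asarray(list(design.abilities), dtype=float)
        n = theta.size
        if n == 0:
            raise ValueError("explicit ability list is empty")
    else:
        n = design.n_respondents
        theta = rng_ability.normal(design.ability_mean, design.ability_sd, size=n)
    bank = design.item_bank
    if bank is None:
        bank = make_uniform_bank(
            design.n_items, design.difficulty_low, design.difficulty_high, rng_bank
        )
    g = 1.0 / (1.0 + np.exp(-bank.alphas[None, :] * (theta[:, None] - bank.betas[None, :])))
    prob = bank.cs[None, :] + (1.0 - bank.cs[None, :]) * g
    X = (rng_resp.random(prob.shape) < prob).astype(float)
    respondent_ids = [f"r{i+1:04d}" for i in range(n)]
    responses = ResponseMatrix(
        pd.DataFrame(X, index=respondent_ids, columns=bank.item_ids)
    )
    abilities = pd.Series(theta, index=pd.Index(respondent_ids, name="respondent_id"),
                          name="theta_true")
    return SimulatedResponses(responses, abilities, bank)


def simulate_guessing(
    n_items: int, n_alternatives: int, n_respondents: int, seed: int = 0
) -> GuessingSummary:
    """Pure-guessing baseline for an m-alternative forced-choice test.

    Each response is correct with probability ``1 / n_alternatives``
    (0.33 for the 3-AFC triad task).  Returns per-respondent and pooled
    proportion correct plus the analytic chance level.
    """
    if n_alternatives < 2:
        raise ValueError(f"n_alternatives must be >= 2, got {n_alternatives}")
    if n_items < 1 or n_respondents < 1:
        raise ValueError("n_items and n_respondents must be >= 1")
    chance = 1.0 / n_alternatives
    rng = np.random.default_rng(seed)
    X = rng.random((n_respondents, n_items)) < chance
    per = pd.Series(
        X.mean(axis=1),
        index=pd.Index([f"r{i+1:04d}" for i in range(n_respondents)], name="respondent_id"),
        name="proportion_correct",
    )
    return GuessingSummary(per_respondent=per, pooled=float(X.mean()), chance_level=chance)


def parameter_recovery_experiment(
    design: SimulationDesign, config: CalibrationConfig | None = None
) -> RecoveryReport:
    """Simulate, calibrate, and compare estimates with the generating truth.

    Reports bias, RMSE and Pearson correlation for both difficulties and
    abilities.  Deterministic given the design's seed.
    """
    responses, theta_true, bank_true = simulate_responses(design)
    bank_est, abilities, _ = fit_rasch(responses, config)
    beta_true = bank_true.betas
    beta_est = bank_est.betas
    theta_est = abilities.theta
    t_true = theta_true.to_numpy()
    return RecoveryReport(
        n_respondents=responses.n_respondents,
        n_items=responses.n_items,
        seed=design.seed,
        beta_bias=float(np.mean(beta_est - beta_true)),
        beta_rmse=float(np.sqrt(np.mean((beta_est - beta_true) ** 2))),
        beta_correlation=float(pearsonr(beta_true, beta_est)[0]),
        theta_bias=float(np.mean(theta_est - t_true)),
        theta_rmse=float(np.sqrt(np.mean((theta_est - t_true) ** 2))),
        theta_correlation=float(pearsonr(t_true, theta_est)[0]),
    )


def cross_group_transfer_experiment(
    calibration: SimulationDesign,
    holdout: SimulationDesign,
    config: CalibrationConfig | None = None,
) -> TransferReport:
    """Calibrate on one ability group, score another, check recovery.

    Both groups answer the same true item bank (if neither design carries
    one, a single bank is drawn from the calibration design's difficulty
    rule and shared).  The holdout group is scored with the calibrated
    bank held fixed and its scored abilities are correlated with its true
    abilities; the analogous within-group correlation is reported for
    comparison.
    """
    if calibration.item_bank is None and holdout.item_bank is None:
        shared = make_uniform_bank(
            calibration.n_items,
            calibration.difficulty_low,
            calibration.difficulty_high,
            np.random.default_rng(np.random.SeedSequence(calibration.seed).spawn(2)[1]),
        )
        calibration = replace(calibration, item_bank=shared)
        holdout = replace(holdout, item_bank=shared)
    elif calibration.item_bank is not None and holdout.item_bank is None:
        holdout = replace(holdout, item_bank=calibration.item_bank)
    if holdout.item_bank is not calibration.item_bank and (
        holdout.item_bank.item_ids != calibration.item_bank.item_ids
    ):
        raise ValueError("calibration and holdout groups must share one true item bank")

    calib_resp, calib_theta, _ = simulate_responses(calibration)
    hold_resp, hold_theta, _ = simulate_responses(holdout)
    bank_est, calib_abilities, _ = fit_rasch(calib_resp, config)
    hold_abilities = score_with_fixed_items(hold_resp, bank_est, config)
    r_transfer = float(pearsonr(hold_theta.to_numpy(), hold_abilities.theta)[0])
    r_within = float(pearsonr(calib_theta.to_numpy(), calib_abilities.theta)[0])
    return TransferReport(
        transfer_correlation=r_transfer,
        within_correlation=r_within,
        n_calibration=calib_resp.n_respondents,
        n_holdout=hold_resp.n_respondents,
    )
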