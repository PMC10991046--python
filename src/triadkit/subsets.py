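"""Assembly of graded-difficulty and parallel item subsets from a bank.

A calibrated bank supports two retest designs.  *Graded* subsets target a
specific ability range: items are ranked by difficulty, median-split into
an easy and a difficult half, and subsets are sampled without replacement
within each half.  *Parallel* subsets are engineered to equal difficulty,
either by excluding the easiest items and sampling uniformly from the
remainder ("exclude-then-sample") or by pairing one easy with one
difficult graded subset ("pair-graded").  Because subsets produced in one
call never share items, a respondent can sit them at different time
points without familiarity inflating their score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .irt import ItemBank, ResponseMatrix

__all__ = [
    "SubsetPlan",
    "make_graded_subsets",
    "make_parallel_subsets",
    "subset_summary",
]


@dataclass
class SubsetPlan:
    """A named, reproducible selection of items from a source bank."""

    name: str
    item_ids: list
    recipe: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError(f"subset {self.name!r} contains duplicate items")

    def __len__(self) -> int:
        return len(self.item_ids)


def _rank_items(bank: ItemBank) -> list:
    """Item ids from easiest to hardest (ties broken by item id)."""
    return [i for _, i in sorted(zip(bank.betas, bank.item_ids))]


def make_graded_subsets(
    bank: ItemBank,
    n_per_level: int = 3,
    subset_size: int = 36,
    seed: int = 0,
    median_to_easy: bool = True,
) -> list[SubsetPlan]:
    """Disjoint easy (E1..En) and difficult (D1..Dn) subsets via median split.

    Items are ranked by difficulty and median-split; with an odd item
    count the median item joins the easy half by default.  Within each
    half, subsets are sampled uniformly without replacement, so each easy
    subset's mean difficulty sits below each difficult subset's.  Leftover
    items stay unassigned and are recorded in every plan's recipe.
    """
    ranked = _rank_items(bank)
    m = len(ranked)
    half = (m + 1) // 2 if median_to_easy else m // 2
    easy_pool, hard_pool = ranked[:half], ranked[half:]
    need = n_per_level * subset_size
    if need > len(easy_pool) or need > len(hard_pool):
        raise ValueError(
            f"cannot draw {n_per_level} subsets of {subset_size} "
            f"({need} items) per level from halves of "
            f"{len(easy_pool)} easy / {len(hard_pool)} difficult items"
        )
    rng = np.random.default_rng(seed)
    plans: list[SubsetPlan] = []
    leftover = m - 2 * need
    for label, pool in (("E", easy_pool), ("D", hard_pool)):
        drawn = rng.choice(len(pool), size=need, replace=False)
        for k in range(n_per_level):
            members = sorted(pool[i] for i in drawn[k * subset_size:(k + 1) * subset_size])
            plans.append(
                SubsetPlan(
                    name=f"{label}{k+1}",
                    item_ids=members,
                    recipe={
                        "strategy": "graded-median-split",
                        "level": "easy" if label == "E" else "difficult",
                        "seed": seed,
                        "subset_size": subset_size,
                        "n_per_level": n_per_level,
                        "median_to_easy": median_to_easy,
                        "bank_size": m,
                        "n_leftover": leftover,
                    },
                )
            )
    return plans


def make_parallel_subsets(
    bank: ItemBank,
    n_subsets: int = 2,
    subset_size: int = 75,
    n_exclude_easiest: int = 4,
    seed: int = 0,
    strategy: str = "exclude-then-sample",
    graded_plans: list[SubsetPlan] | None = None,
) -> list[SubsetPlan]:
    """Disjoint equal-difficulty subsets for retesting across sessions.

    ``"exclude-then-sample"`` ranks items by difficulty, drops the
    ``n_exclude_easiest`` easiest, and samples each subset uniformly
    without replacement from the remainder.  ``"pair-graded"`` instead
    unions matched easy/difficult plans (E1+D1, E2+D2, ...) produced by
    :func:`make_graded_subsets` — pass them via ``graded_plans``.
    """
    if strategy == "pair-graded":
        if graded_plans is None:
            graded_plans = make_graded_subsets(bank, seed=seed)
        easy = sorted((p for p in graded_plans if p.recipe.get("level") == "easy"),
                      key=lambda p: p.name)
        hard = sorted((p for p in graded_plans if p.recipe.get("level") == "difficult"),
                      key=lambda p: p.name)
        if not easy or len(easy) != len(hard):
            raise ValueError(
                f"pair-graded needs matched easy/difficult plans, got "
                f"{len(easy)} easy and {len(hard)} difficult"
            )
        return [
            SubsetPlan(
                name=f"S{k+1}",
                item_ids=sorted(e.item_ids + d.item_ids),
                recipe={
                    "strategy": "pair-graded",
                    "paired": [e.name, d.name],
                    "seed": seed,
                },
            )
            for k, (e, d) in enumerate(zip(easy, hard))
        ]
    if strategy != "exclude-then-sample":
        raise ValueError(f"unknown strategy {strategy!r}")
    ranked = _rank_items(bank)
    m = len(ranked)
    pool = ranked[n_exclude_easiest:]
    need = n_subsets * subset_size
    if need > len(pool):
        raise ValueError(
            f"cannot draw {n_subsets} x {subset_size} = {need} items from "
            f"{m} - {n_exclude_easiest} = {len(pool)} eligible items"
        )
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(pool), size=need, replace=False)
    return [
        SubsetPlan(
            name=f"S{k+1}",
            item_ids=sorted(pool[i] for i in drawn[k * subset_size:(k + 1) * subset_size]),
            recipe={
                "strategy": "exclude-then-sample",
                "n_exclude_easiest": n_exclude_easiest,
                "subset_size": subset_size,
                "n_subsets": n_subsets,
                "seed": seed,
                "bank_size": m,
            },
        )
        for k in range(n_subsets)
    ]


def subset_summary(
    plan: SubsetPlan, bank: ItemBank, responses: ResponseMatrix | None = None
) -> dict:
    """Difficulty (and optionally accuracy) summary of one subset.

    Reports mean/SD/median of the members' difficulties (population SD, so
    a singleton subset has SD 0).  Given a response matrix, adds the
    per-respondent proportion correct restricted to the subset, summarized
    the same way; missing cells are excluded from the denominator.
    """
    sub = bank.subset(plan.item_ids)
    betas = sub.betas
    out = {
        "name": plan.name,
        "n_items": len(plan),
        "beta_mean": float(np.mean(betas)),
        "beta_sd": float(np.std(betas)),
        "beta_median": float(np.median(betas)),
    }
    if responses is not None:
        resp = responses.subset_items(plan.item_ids)
        acc = resp.frame.mean(axis=1, skipna=True)
        out.update(
            {
                "accuracy_mean": float(acc.mean()),
                "accuracy_sd": float(acc.std(ddof=0)),
                "accuracy_median": float(acc.median()),
                "respondent_accuracy": acc,
            }
        )
    return out
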