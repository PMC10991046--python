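"""Independent reference implementations used only by the tests.

These share no code with the package: the marginal likelihood is written
out from the model definition and maximized by exhaustive lattice search
with successive refinement, and the triad screen is re-derived by plain
nested-loop enumeration of the selection rules.
"""

from __future__ import annotations

import itertools

import numpy as np


def _quadrature(n_nodes: int = 61, limit: float = 6.0):
    nodes = np.linspace(-limit, limit, n_nodes)
    w = np.exp(-0.5 * nodes ** 2)
    return nodes, w / w.sum()


def rasch_marginal_loglik(X: np.ndarray, betas: np.ndarray) -> float:
    """Marginal log-likelihood of complete Rasch data under a N(0,1) prior.

    Written directly from the model: per respondent, integrate the product
    of Bernoulli terms over the latent ability with normalized rectangular
    quadrature (same 61-node grid definition the fitted model documents,
    so values are comparable at tight tolerance).
    """
    nodes, w = _quadrature()
    P = 1.0 / (1.0 + np.exp(-(nodes[:, None] - np.asarray(betas)[None, :])))
    ll = 0.0
    for row in X:
        like = np.prod(np.where(row[None, :] == 1, P, 1.0 - P), axis=1)
        ll += np.log((w * like).sum())
    return float(ll)


def grid_search_rasch_mml(X: np.ndarray, span=(-4.0, 4.0),
                          steps=(0.2, 0.02, 0.002, 0.0002)):
    """Maximize the 3-item Rasch marginal likelihood by lattice refinement.

    Starts from a coarse exhaustive lattice over ``span`` and zooms in by
    a factor of ten per round, ending on a 2e-4 spacing.  Returns the
    maximizing difficulties and the log-likelihood there.
    """
    assert X.shape[1] == 3, "oracle implemented for 3-item instances"
    nodes, w = _quadrature()
    patterns, counts = np.unique(X.astype(int), axis=0, return_counts=True)
    centers = np.full(3, (span[0] + span[1]) / 2.0)
    radius = (span[1] - span[0]) / 2.0
    best_ll = -np.inf
    for step in steps:
        grids = [np.arange(c - radius, c + radius + step / 2, step) for c in centers]
        tables = []
        for g in grids:
            P = 1.0 / (1.0 + np.exp(-(nodes[None, :] - g[:, None])))  # b x q
            tables.append(np.stack([1.0 - P, P]))  # response x b x q
        total = np.zeros((len(grids[0]), len(grids[1]), len(grids[2])))
        for pat, cnt in zip(patterns, counts):
            like = np.einsum(
                "aq,bq,cq,q->abc",
                tables[0][pat[0]], tables[1][pat[1]], tables[2][pat[2]], w,
            )
            total += cnt * np.log(like)
        idx = np.unravel_index(np.argmax(total), total.shape)
        centers = np.array([grids[j][idx[j]] for j in range(3)])
        best_ll = float(total[idx])
        radius = 1.5 * step
    return centers, best_ll


def enumerate_triads(sim: dict, identity_of: dict, race_of: dict, gender_of: dict,
                     yoke: bool = True):
    """Plain enumeration of the triad-screening rules.

    ``sim`` maps frozenset({a, b}) -> similarity.  Returns a set of
    (a0, ai, b0) tuples with a0 < ai the same pair, b0 the odd image.
    """
    images = sorted(identity_of)
    identities = sorted(set(identity_of.values()))
    members = {ident: sorted(i for i in images if identity_of[i] == ident)
               for ident in identities}

    def s(a, b):
        return sim[frozenset((a, b))]

    # best yoked cross pair per identity (ties: smallest sorted id pair)
    best = {}
    for x, y in itertools.combinations(images, 2):
        if identity_of[x] == identity_of[y]:
            continue
        if yoke and (race_of[x] != race_of[y] or gender_of[x] != gender_of[y]):
            continue
        key = tuple(sorted((x, y)))
        for ident in (identity_of[x], identity_of[y]):
            cur = best.get(ident)
            cand = (-s(x, y), key)
            if cur is None or cand < cur:
                best[ident] = cand
    retained = sorted({(negs, pair) for negs, pair in best.values()})

    triads = set()
    for _negs, (u, v) in retained:
        sides = []
        for anchor, other in ((u, v), (v, u)):
            partners = [p for p in members[identity_of[anchor]] if p != anchor]
            if not partners:
                continue
            lo = min(s(anchor, p) for p in partners)
            partner = min(p for p in partners if s(anchor, p) == lo)
            sides.append((lo, identity_of[anchor], anchor, partner, other))
        if not sides:
            continue
        sides.sort()
        _lo, _ident, a0, ai, b0 = sides[0]
        triads.add((min(a0, ai), max(a0, ai), b0))
    return triads


def observer_accuracy(triads, sim) -> float:
    """Fraction of triads whose least-similar-looking image is the true odd one."""
    correct = 0
    for a0, ai, b0 in triads:
        trio = (a0, ai, b0)
        pairs = [tuple(sorted(p)) for p in itertools.combinations(trio, 2)]
        top = max(sim[frozenset(p)] for p in pairs)
        winners = sorted(p for p in pairs if sim[frozenset(p)] == top)
        chosen = winners[0]
        pick = next(i for i in trio if i not in chosen)
        correct += pick == b0
    return correct / len(triads)
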