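"""Maximally confusable 3-AFC triad construction from image similarity.

A triad is a three-alternative forced-choice item: two images of one
identity (the "same pair") plus one image of a different identity (the
"odd one out").  Items are made hard by construction: the cross-identity
pair is the *most similar* pair available for an identity, and the same
pair is the *least similar* pair of images of the identity that looks the
least like itself.  Similarity comes from any embedding of the images
(e.g. a face-recognition network's top-level descriptors); this module
only consumes the resulting similarity matrix.

Screening algorithm (per identity, deterministic):

1. form all cross-identity image pairs; with demographic yoking only
   same-race, same-gender pairings survive;
2. keep, for each identity, the single cross pair with the highest
   similarity (ties: lexicographically smallest image-id pair);
3. for each side of a kept pair, find the partner image of the same
   identity with the *lowest* similarity to the paired image;
4. the side whose minimum same-identity similarity is lower contributes
   the same pair; the other side's image becomes the odd one out.

An "algorithm as observer" simulation answers each triad by calling the
two most similar images the same identity; on well-screened triads it
scores far below the 1/3 chance level, confirming the items cannot be
solved from the embedding that built them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "SimilarityMatrix",
    "Triad",
    "TriadSet",
    "ObserverResult",
    "compute_similarity",
    "build_triads",
    "simulate_algorithm_observer",
    "make_synthetic_embeddings",
]


@dataclass
class ImageRecord:
    """One image with its identity and (optional) demographic labels."""

    image_id: str
    identity_id: str
    race: str | None = None
    gender: str | None = None
    features: np.ndarray | None = None


class SimilarityMatrix:
    """Symmetric image-by-image similarity scores (higher = more similar)."""

    def __init__(self, frame: pd.DataFrame):
        if list(frame.index) != list(frame.columns):
            raise ValueError("similarity matrix must have identical row and column ids")
        if frame.index.has_duplicates:
            raise ValueError("duplicate image ids in similarity matrix")
        vals = frame.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-9, rtol=0.0):
            raise ValueError("similarity matrix must be symmetric within 1e-9")
        self.frame = frame.astype(float)
        self._pos = {img: k for k, img in enumerate(frame.index)}

    @classmethod
    def from_values(cls, values, image_ids) -> "SimilarityMatrix":
        ids = list(image_ids)
        return cls(pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=ids))

    @property
    def image_ids(self) -> list:
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def sim(self, a: str, b: str) -> float:
        return float(self.frame.iat[self._pos[a], self._pos[b]])

    def __contains__(self, image_id: str) -> bool:
        return image_id in self._pos


@dataclass
class Triad:
    """One 3-AFC item: same-identity pair (a0, ai) plus odd image b0."""

    a0: str
    ai: str
    b0: str
    identity_same: str
    identity_odd: str
    cross_similarity: float
    same_similarity: float

    def image_ids(self) -> tuple[str, str, str]:
        return (self.a0, self.ai, self.b0)


@dataclass
class TriadSet:
    triads: list[Triad]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triads)

    def __iter__(self):
        return iter(self.triads)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "triad_id": f"t{k+1:04d}",
                "a0": t.a0,
                "ai": t.ai,
                "b0": t.b0,
                "identity_same": t.identity_same,
                "identity_odd": t.identity_odd,
                "cross_similarity": t.cross_similarity,
                "same_similarity": t.same_similarity,
            }
            for k, t in enumerate(self.triads)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "triad_id", "a0", "ai", "b0", "identity_same", "identity_odd",
                "cross_similarity", "same_similarity",
            ],
        )


@dataclass
class ObserverResult:
    proportion_correct: float
    picks: pd.DataFrame
    n_ties: int


def compute_similarity(images, metric: str = "cosine") -> SimilarityMatrix:
    """Pairwise similarity of image feature vectors.

    ``metric`` is ``"cosine"`` (default) or ``"neg_euclidean"`` (negated
    Euclidean distance, so that higher still means more similar).
    """
    images = sorted(images, key=lambda im: im.image_id)
    for im in images:
        if im.features is None:
            raise ValueError(f"image {im.image_id!r} has no feature vector")
    F = np.asarray([np.asarray(im.features, dtype=float) for im in images])
    if F.ndim != 2:
        raise ValueError("feature vectors must all have the same length")
    ids = [im.image_id for im in images]
    if metric == "cosine":
        norms = np.linalg.norm(F, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(f"zero-norm feature vector for image {ids[zero[0]]!r}")
        Fn = F / norms[:, None]
        M = Fn @ Fn.T
    elif metric == "neg_euclidean":
        sq = (F ** 2).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (F @ F.T), 0.0)
        M = -np.sqrt(d2)
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    M = (M + M.T) / 2.0
    return SimilarityMatrix.from_values(M, ids)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_triads(
    similarity: SimilarityMatrix,
    images,
    yoke: bool = True,
    disjoint: bool = False,
) -> TriadSet:
    """Screen a labeled similarity matrix into confusable 3-AFC triads.

    Parameters
    ----------
    similarity : SimilarityMatrix
        Pairwise scores covering every image in ``images``.
    images : iterable of ImageRecord
        Identity and demographic labels; an identity needs at least two
        images to contribute a same pair (single-image identities can only
        serve as the odd image).
    yoke : bool
        Restrict cross-identity pairings to matching race and gender, so
        superficial demographic cues cannot solve the item.
    disjoint : bool
        When set, images and identities are consumed by at most one triad
        (off by default: a source pool may legitimately reuse identities).

    Output is deterministic and invariant to the input ordering of
    ``images``; ties on similarity resolve to the lexicographically
    smallest image-id pair.  Identities for which no eligible yoked pair
    or same-identity partner exists are skipped with a recorded reason.
    """
    images = sorted(images, key=lambda im: im.image_id)
    ids_seen = set()
    for im in images:
        if im.image_id in ids_seen:
            raise ValueError(f"duplicate image id {im.image_id!r}")
        ids_seen.add(im.image_id)
        if im.image_id not in similarity:
            raise ValueError(
                f"image {im.image_id!r} missing from the similarity matrix"
            )
        if yoke and (im.race is None or im.gender is None):
            raise ValueError(
                f"image {im.image_id!r} lacks demographic labels required for yoking"
            )
    by_identity: dict[str, list[ImageRecord]] = {}
    for im in images:
        by_identity.setdefault(im.identity_id, []).append(im)
    record = {im.image_id: im for im in images}
    identities = sorted(by_identity)

    # best cross-identity pair per identity
    best: dict[str, tuple[float, tuple[str, str]]] = {}
    for x in images:
        for y in images:
            if y.image_id <= x.image_id or y.identity_id == x.identity_id:
                continue
            if yoke and (x.race != y.race or x.gender != y.gender):
                continue
            s = similarity.sim(x.image_id, y.image_id)
            pair = _pair_key(x.image_id, y.image_id)
            for ident in (x.identity_id, y.identity_id):
                cur = best.get(ident)
                if cur is None or s > cur[0] or (s == cur[0] and pair < cur[1]):
                    best[ident] = (s, pair)

    skipped: list[tuple[str, str]] = []
    for ident in identities:
        if ident not in best:
            skipped.append((ident, "no eligible cross-identity pair"))

    # deduplicate retained pairs, order by similarity (desc) then pair id
    retained = sorted(
        {(s, pair) for s, pair in best.values()}, key=lambda t: (-t[0], t[1])
    )

    def min_same_partner(anchor: str, used: set[str]) -> tuple[float, str] | None:
        ident = record[anchor].identity_id
        cands = [
            im.image_id
            for im in by_identity[ident]
            if im.image_id != anchor and im.image_id not in used
        ]
        if not cands:
            return None
        scored = sorted((similarity.sim(anchor, c), c) for c in cands)
        lo = scored[0][0]
        partner = min(c for s, c in scored if s == lo)
        return lo, partner

    triads: list[Triad] = []
    used_images: set[str] = set()
    used_identities: set[str] = set()
    for s_cross, (u, v) in retained:
        ident_u, ident_v = record[u].identity_id, record[v].identity_id
        if disjoint and (
            {u, v} & used_images or {ident_u, ident_v} & used_identities
        ):
            skipped.append((f"{ident_u}|{ident_v}", "consumed by an earlier triad"))
            continue
        used = used_images if disjoint else set()
        options = []
        for anchor, other, ident_a, ident_b in (
            (u, v, ident_u, ident_v),
            (v, u, ident_v, ident_u),
        ):
            got = min_same_partner(anchor, used)
            if got is not None:
                options.append((got[0], ident_a, anchor, got[1], other, ident_b))
        if not options:
            skipped.append(
                (f"{ident_u}|{ident_v}", "neither identity has a same-identity partner")
            )
            continue
        options.sort(key=lambda o: (o[0], o[1]))  # lowest same-sim, tie -> identity id
        s_same, ident_same, a0, ai, b0, ident_odd = options[0]
        triads.append(
            Triad(
                a0=a0, ai=ai, b0=b0,
                identity_same=ident_same, identity_odd=ident_odd,
                cross_similarity=float(s_cross), same_similarity=float(s_same),
            )
        )
        if disjoint:
            used_images.update({a0, ai, b0})
            used_identities.update({ident_same, ident_odd})
    if skipped:
        warnings.warn(
            f"{len(skipped)} identity/pair candidates skipped during triad screening",
            RuntimeWarning,
            stacklevel=2,
        )
    return TriadSet(triads=triads, skipped=skipped)


def simulate_algorithm_observer(
    triads: TriadSet, similarity: SimilarityMatrix
) -> ObserverResult:
    """Answer each triad with the embedding's own decision rule.

    The two most similar images in the triad are declared the same
    identity; the remaining image is picked as the odd one out.  Ties on
    the maximal pair similarity resolve to the lexicographically smallest
    image-id pair and are counted in ``n_ties``.
    """
    rows = []
    n_ties = 0
    for k, t in enumerate(triads):
        for img in t.image_ids():
            if img not in similarity:
                raise ValueError(f"triad image {img!r} missing from similarity matrix")
        pairs = sorted(
            {_pair_key(a, b) for a, b in
             [(t.a0, t.ai), (t.a0, t.b0), (t.ai, t.b0)]}
        )
        sims = [similarity.sim(a, b) for a, b in pairs]
        top = max(sims)
        winners = [p for p, s in zip(pairs, sims) if s == top]
        if len(winners) > 1:
            n_ties += 1
        chosen = min(winners)
        pick = next(i for i in t.image_ids() if i not in chosen)
        rows.append(
            {
                "triad_id": f"t{k+1:04d}",
                "picked": pick,
                "truth": t.b0,
                "correct": pick == t.b0,
                "top_pair_similarity": top,
            }
        )
    picks = pd.DataFrame(rows, columns=["triad_id", "picked", "truth", "correct",
                                        "top_pair_similarity"])
    prop = float(picks["correct"].mean()) if len(picks) else float("nan")
    return ObserverResult(proportion_correct=prop, picks=picks, n_ties=n_ties)


def make_synthetic_embeddings(
    n_identities: int = 30,
    images_per_identity: int = 4,
    dim: int = 64,
    within_sd: float = 0.35,
    confusability: float = 0.85,
    races: tuple = ("r1", "r2"),
    genders: tuple = ("f", "m"),
    seed: int = 0,
) -> list[ImageRecord]:
    """Synthetic image embeddings with tunable identity confusability.

    Identities are Gaussian clusters on the unit sphere.  Identities are
    paired, each pair sharing demographic labels and a common base
    direction; ``confusability`` in [0, 1) pulls paired centroids together
    (0 = independent, ->1 = coincident), and ``within_sd`` controls how
    far images scatter around their identity centroid.  High
    confusability plus moderate scatter yields exactly the regime the
    triad screen exploits: cross-identity pairs that look more alike than
    the worst same-identity pairs.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    if images_per_identity < 1:
        raise ValueError("images_per_identity must be >= 1")
    if not (0.0 <= confusability < 1.0):
        raise ValueError(f"confusability must lie in [0, 1), got {confusability}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    demo_cycle = [(r, g) for r in races for g in genders]
    records: list[ImageRecord] = []
    n_pairs = (n_identities + 1) // 2
    for p in range(n_pairs):
        base = rng.normal(size=dim)
        base /= np.linalg.norm(base)
        race, gender = demo_cycle[p % len(demo_cycle)]
        members = [2 * p, 2 * p + 1]
        for ident_idx in members:
            if ident_idx >= n_identities:
                continue
            offset = rng.normal(size=dim) * (1.0 - confusability)
            centroid = base + offset
            centroid /= np.linalg.norm(centroid)
            ident = f"id{ident_idx+1:03d}"
            for k in range(images_per_identity):
                vec = centroid + rng.normal(size=dim) * within_sd
                vec /= np.linalg.norm(vec)
                records.append(
                    ImageRecord(
                        image_id=f"{ident}_{k+1:02d}",
                        identity_id=ident,
                        race=race,
                        gender=gender,
                        features=vec,
                    )
                )
    return records
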