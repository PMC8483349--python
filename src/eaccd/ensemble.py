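"""Dissimilarity learning by a deterministic PAM co-clustering ensemble.

The initial Mann-Whitney dissimilarities are refined by repeatedly
partitioning the combinations with the two-phase Partitioning Around
Medoids algorithm (greedy BUILD seeding followed by best-improvement SWAP)
and recording, for every pair, the fraction of partitions that separate
them.  The default ensemble is the deterministic sweep k = 2 ... M-1 with
equal weights; a bootstrap variant (resampling combinations with
replacement before each run) is available behind an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dissimilarity import DissimilarityMatrix

__all__ = ["PAMResult", "EnsembleSpec", "pam", "learned_matrix"]


@dataclass(frozen=True)
class PAMResult:
    k: int
    medoids: tuple
    labels: np.ndarray
    objective: float


@dataclass(frozen=True)
class EnsembleSpec:
    """Which PAM runs enter the ensemble.

    ``k_max=None`` means M-1 (capped by ``k_cap``); ``weights=None`` means
    equal weights.  ``bootstrap > 0`` replaces the deterministic sweep by
    that many resampled runs per k (requires ``seed``).
    """

    k_min: int = 2
    k_max: int | None = None
    k_cap: int = 50
    weights: tuple | None = None
    bootstrap: int = 0
    seed: int | None = None


def _assign(dist: np.ndarray, medoids) -> np.ndarray:
    """Each item to its nearest medoid; ties to the lowest medoid index."""
    med = np.asarray(sorted(medoids))
    sub = dist[:, med]
    return med[np.argmin(sub, axis=1)]  # argmin takes first minimum: lowest index


def _objective(dist: np.ndarray, medoids) -> float:
    med = np.asarray(sorted(medoids))
    return float(dist[:, med].min(axis=1).sum())


def pam(D: DissimilarityMatrix | np.ndarray, k: int) -> PAMResult:
    """Two-phase Partitioning Around Medoids, fully deterministic.

    BUILD greedily seeds medoids (first the item with minimal total
    dissimilarity, then the item giving the largest cost reduction, ties to
    the lowest index).  SWAP repeatedly applies the best-improvement
    (medoid-out, item-in) exchange, ties broken by the lowest index pair,
    until no swap lowers the objective.
    """
    dist = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)
    m = dist.shape[0]
    if not 2 <= k <= m:
        raise ValueError(f"k={k} out of range [2, {m}]")

    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))  # first maximum: lowest index
        medoids.append(cand)
        nearest = np.minimum(nearest, dist[:, cand])
    medoids = sorted(medoids)

    # SWAP (best improvement)
    obj = _objective(dist, medoids)
    max_iter = 10 * m
    for _ in range(max_iter):
        best = (obj, None)
        med_set = set(medoids)
        for m_out in medoids:
            rest = [x for x in medoids if x != m_out]
            for h_in in range(m):
                if h_in in med_set:
                    continue
                cand_obj = _objective(dist, rest + [h_in])
                if cand_obj < best[0]:  # strict: first (lowest index pair) wins ties
                    best = (cand_obj, (m_out, h_in))
        if best[1] is None:
            break
        m_out, h_in = best[1]
        medoids = sorted([x for x in medoids if x != m_out] + [h_in])
        obj = best[0]
    else:
        raise RuntimeError("PAM SWAP failed to converge")

    labels = _assign(dist, medoids)
    return PAMResult(k=k, medoids=tuple(medoids), labels=labels, objective=_objective(dist, medoids))


def learned_matrix(D: DissimilarityMatrix, spec: EnsembleSpec = EnsembleSpec()) -> DissimilarityMatrix:
    """Co-association learned dissimilarities from the PAM ensemble.

    ``learned[i, j]`` is the weighted fraction of ensemble runs in which i
    and j land in different clusters; 0 on the diagonal, symmetric, in
    [0, 1].
    """
    m = D.m
    if m < 3:
        raise ValueError("need at least 3 combinations for the ensemble")
    k_max = spec.k_max if spec.k_max is not None else m - 1
    k_max = min(k_max, m - 1, spec.k_cap)
    if not 2 <= spec.k_min <= k_max:
        raise ValueError(f"invalid k range [{spec.k_min}, {k_max}]")
    ks = list(range(spec.k_min, k_max + 1))

    if spec.bootstrap:
        if spec.seed is None:
            raise ValueError("bootstrap ensemble requires a seed")
        rng = np.random.default_rng(spec.seed)
        acc = np.zeros((m, m))
        wsum = 0.0
        for k in ks:
            for _ in range(spec.bootstrap):
                idx = np.sort(rng.choice(m, size=m, replace=True))
                idx = np.unique(idx)
                if len(idx) <= k:
                    continue
                sub = pam(D.values[np.ix_(idx, idx)], k)
                lab = np.full(m, -1)
                lab[idx] = sub.labels
                diff = (lab[:, None] != lab[None, :]) & (lab[:, None] >= 0) & (lab[None, :] >= 0)
                acc += diff
                wsum += 1.0
        learned = acc / wsum
    else:
        weights = spec.weights if spec.weights is not None else tuple(1.0 for _ in ks)
        if len(weights) != len(ks):
            raise ValueError("one weight per ensemble run required")
        acc = np.zeros((m, m))
        for k, w in zip(ks, weights):
            lab = pam(D, k).labels
            acc += w * (lab[:, None] != lab[None, :])
        learned = acc / float(sum(weights))

    np.fill_diagonal(learned, 0.0)
    learned = np.maximum(learned, learned.T)  # exact symmetry (co-association is symmetric)
    return DissimilarityMatrix(keys=D.keys, values=learned)
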