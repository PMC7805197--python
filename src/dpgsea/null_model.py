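"""Permutation null ensembles, score normalization, p-values and pooled FDR.

The null hypothesis is that a drug's score is no different from one obtained
by random gene-label permutation of the ranked list: the rank positions (and
hence the weight vector |T|^w) stay fixed while the gamma directional-hit
labels land uniformly at random among the p ranks. The same per-drug
ensemble (default 1000 permutations) serves three purposes:

* normalization — NES = ES / mean(null ES), and likewise NTCS;
* significance — the empirical p-value is the proportion of permuted scores
  strictly greater than the true score (so p = 0 is representable and is
  rendered ``< 1/n_perm`` in text output);
* error rate — a GSEA-style pooled-null FDR: for a drug with normalized
  score s, q(s) is the fraction of all drugs' pooled null normalized scores
  >= s divided by the fraction of observed normalized scores >= s, clipped
  to [0, 1] and made monotone non-increasing in s by a step-up pass.

Per-drug RNG streams are derived from (master seed, drug id) so results do
not depend on the order drugs are screened in.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .enrichment_core import HitVector, RankedList, running_sum
from .io_formats import logger

#: cap on elements per permutation block, keeps peak memory modest
_BLOCK_ELEMS = 4_000_000


@dataclass(frozen=True)
class DrugStatistics:
    """Normalized scores and empirical p-values for one drug."""

    nes: float
    ntcs: float
    es_p: float
    tcs_p: float


def drug_rng(master_seed: int, drug_id: str) -> np.random.Generator:
    """Independent, screening-order-invariant RNG stream for one drug."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(drug_id.encode("utf-8"))])
    )


def _null_scores_block(
    weights: np.ndarray, positions: np.ndarray, gamma: int, l_min: int
) -> tuple[np.ndarray, np.ndarray]:
    """ES and TCS for a block of permuted hit placements.

    ``positions`` is (n, gamma) ranks (0-based) of the permuted hits; the
    weight vector is fixed. Between consecutive hits the running sum falls
    linearly, so |v| is maximal only at a hit rank or at the rank just
    before one; evaluating v at those 2*gamma candidate points reproduces
    the full p-point scan of :func:`enrichment_scores` exactly (same float
    operations, same smallest-rank tie-break) at O(gamma) per permutation.
    """
    n, p = positions.shape[0], len(weights)
    pos = np.sort(positions, axis=1)  # 0-based hit ranks, ascending
    rows = np.arange(n)

    hit_w = weights[pos]
    cum_w = np.cumsum(hit_w, axis=1)
    denom = cum_w[:, -1].copy()  # sequential sum, matches running_sum bitwise
    zero_w = denom == 0
    if zero_w.any():  # all hit weights zero: fall back to hit-count fraction
        cum_w[zero_w] = np.arange(1, gamma + 1)
        denom[zero_w] = gamma
    hit_frac = cum_w / denom[:, None]  # v's hit term at l=h_i

    if gamma == p:
        # every gene a hit: v is the (non-decreasing) hit fraction alone
        abs_v = np.abs(hit_frac)
        idx = abs_v.argmax(axis=1)
        es = abs_v[rows, idx]
        l_max = idx + 1
        return es, np.abs(l_max - l_min) / (p - 1)

    i = np.arange(1, gamma + 1)
    miss_frac = (pos + 1 - i) / (p - gamma)  # miss term at both l=h_i and l=h_i-1
    at_hit = np.abs(hit_frac - miss_frac)
    before = np.empty_like(hit_frac)
    before[:, 0] = 0.0
    before[:, 1:] = hit_frac[:, :-1]
    before_hit = np.abs(before - miss_frac)
    before_hit[pos == 0] = -1.0  # no rank-0 point ahead of a hit at rank 1

    # candidate |v| values interleaved in increasing-rank order so argmax's
    # first occurrence implements the smallest-rank tie-break
    cand = np.empty((n, 2 * gamma))
    cand[:, 0::2] = before_hit
    cand[:, 1::2] = at_hit
    ranks = np.empty((n, 2 * gamma), dtype=np.int64)
    ranks[:, 0::2] = pos  # (h_i - 1) as a 1-based rank
    ranks[:, 1::2] = pos + 1
    idx = cand.argmax(axis=1)
    es = cand[rows, idx]
    l_max = ranks[rows, idx]
    return es, np.abs(l_max - l_min) / (p - 1)


def permute_null(
    rl: RankedList,
    hv: HitVector,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null ES and TCS from gene-label permutation.

    Hit labels are redrawn uniformly without replacement over the p fixed
    rank positions, ``n_perm`` times; scores are recomputed on the fixed
    weight vector. Fully determined by ``seed`` (or a supplied generator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if hv.gamma < 1:
        raise ValueError("permutation null undefined for gamma = 0")
    if n_perm < 100:
        logger.warning("n_perm=%d gives coarse p-value resolution (floor 1/%d)", n_perm, n_perm)
    if rng is None:
        rng = np.random.default_rng(seed)

    p, gamma, l_min = rl.p, hv.gamma, rl.l_min
    es_nulls = np.empty(n_perm)
    tcs_nulls = np.empty(n_perm)
    block = max(1, _BLOCK_ELEMS // p)
    for start in range(0, n_perm, block):
        n = min(block, n_perm - start)
        # uniform gamma-subset of ranks per permutation
        keys = rng.random((n, p))
        positions = np.argpartition(keys, gamma - 1, axis=1)[:, :gamma]
        es, tcs = _null_scores_block(rl.weights, positions, gamma, l_min)
        es_nulls[start : start + n] = es
        tcs_nulls[start : start + n] = tcs
    return es_nulls, tcs_nulls


def empirical_p(score: float, nulls: np.ndarray) -> float:
    """Proportion of null scores strictly greater than the true score."""
    return float(np.count_nonzero(nulls > score) / len(nulls))


def normalize_and_test(
    es: float, tcs: float, es_nulls: np.ndarray, tcs_nulls: np.ndarray
) -> DrugStatistics:
    """Normalized scores (true / null mean) and empirical p-values."""
    if len(es_nulls) == 0 or len(tcs_nulls) == 0:
        raise ValueError("null ensembles must be non-empty")

    def _norm(score: float, nulls: np.ndarray, name: str) -> float:
        m = float(nulls.mean())
        if m <= 0:
            logger.warning("null mean for %s is %g; normalized score undefined (NA)", name, m)
            return float("nan")
        return score / m

    return DrugStatistics(
        nes=_norm(es, es_nulls, "ES"),
        ntcs=_norm(tcs, tcs_nulls, "TCS"),
        es_p=empirical_p(es, es_nulls),
        tcs_p=empirical_p(tcs, tcs_nulls),
    )


def pooled_fdr(
    observed: np.ndarray,
    pooled_nulls: np.ndarray,
    numerator_only: bool = False,
    step_up: bool = True,
) -> np.ndarray:
    """GSEA-style FDR q-values from a pooled normalized-score null.

    For each observed normalized score s: numerator = fraction of pooled
    null scores >= s; denominator = fraction of observed scores >= s;
    q = numerator / denominator clipped to [0, 1]. ``numerator_only`` drops
    the denominator (a stricter variant). ``step_up`` enforces that q is
    non-increasing in score.

    NaN scores (drugs with undefined normalization) get NaN q-values.
    """
    observed = np.asarray(observed, dtype=float)
    pooled = np.asarray(pooled_nulls, dtype=float)
    pooled = pooled[~np.isnan(pooled)]
    q = np.full(len(observed), np.nan)
    ok = ~np.isnan(observed)
    if not ok.any():
        return q
    obs = observed[ok]
    if len(pooled) == 0:
        raise ValueError("pooled null is empty")

    pooled_sorted = np.sort(pooled)
    obs_sorted = np.sort(obs)
    # fraction >= s via searchsorted on ascending arrays
    num = 1.0 - np.searchsorted(pooled_sorted, obs, side="left") / len(pooled)
    den = 1.0 - np.searchsorted(obs_sorted, obs, side="left") / len(obs)
    ratio = num if numerator_only else num / den
    qv = np.clip(ratio, 0.0, 1.0)

    if step_up:
        # enforce q non-increasing in score: each drug takes the minimum ratio
        # over drugs with lower-or-equal score (BH-style accumulation)
        order = np.argsort(obs, kind="stable")
        qv[order] = np.minimum.accumulate(qv[order])
    q[ok] = qv
    return q
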