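"""Directional running-sum enrichment: ES, TCS and leading-edge genes.

The screen works on a ranked list L of the p genes shared between a DE
contrast and the analysis: genes are ordered by the absolute value of a
ranking statistic T (default T = -log10 of the DE significance, carrying the
sign of the effect), most significant first, so rank 1 is the top of the
list and the minimal |T| sits at rank p.

For one drug's signature S_k with per-gene regulation directions, a gene at
rank j is a *directional hit* when it belongs to S_k and the drug-induced
direction opposes (antagonist mode — the signature-reversion screen) or
matches (agonist mode) the sign of its disease effect. With gamma = number
of hits, the weighted running sum is

    v(l) = sum_{j<=l, hit} |T(j)|^w / sum_{j, hit} |T(j)|^w
         - sum_{j<=l, miss} 1 / (p - gamma)

and the enrichment score is ES = max_l |v(l)|. The target compatibility
score is the rank distance between the ES maximizer l_max and the position
l_min of minimal |T|, reported on the unit scale: TCS = |l_max - l_min| /
(p - 1), so a peak at the very top of the list scores near 1. Hit genes at
ranks <= l_max form the leading-edge (driver) set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DETable, ProtoMatrix, logger

ANTAGONIST = "antagonist"
AGONIST = "agonist"

RANK_STAT_KINDS = ("neglog10_significance", "signed_stat")


@dataclass(frozen=True)
class RankedList:
    """Merged rank-ordered gene vector with weights and disease directions.

    Attributes
    ----------
    genes : ndarray of str
        Gene ids, rank 1 first (most significant).
    rank_stat : ndarray of float
        Signed ranking statistic T(j); |T| is non-increasing along the list.
    weights : ndarray of float
        |T(j)|^omega, the running-sum hit weights.
    disease_dirs : ndarray of int
        sign(effect) in {-1, 0, +1}.
    omega : float
        Running-sum weight exponent.
    """

    genes: np.ndarray
    rank_stat: np.ndarray
    weights: np.ndarray
    disease_dirs: np.ndarray
    omega: float

    @property
    def p(self) -> int:
        return len(self.genes)

    @property
    def l_min(self) -> int:
        """1-based rank of minimal |T| (first occurrence on ties)."""
        return int(np.argmin(np.abs(self.rank_stat))) + 1


@dataclass(frozen=True)
class HitVector:
    """Directional membership of one drug's signature along a ranked list."""

    hit_flags: np.ndarray  # bool, length p
    gamma: int
    mode: str

    def __post_init__(self) -> None:
        assert self.gamma == int(self.hit_flags.sum())


@dataclass(frozen=True)
class EnrichmentScores:
    es: float
    l_max: int
    l_min: int
    tcs_raw: int
    tcs: float
    leading_edge: list[str]


def build_ranked_list(
    de: DETable,
    omega: float = 1.0,
    rank_stat_kind: str = "neglog10_significance",
) -> RankedList:
    """Rank a DE table by absolute significance and attach running-sum weights.

    ``rank_stat_kind`` selects T: ``neglog10_significance`` (default) uses
    T = -log10(significance) signed by the effect; ``signed_stat`` uses the
    effect column itself (a signed moderated statistic). Ranking always uses
    |T| descending; ties are broken lexicographically by gene id so output is
    deterministic.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if rank_stat_kind not in RANK_STAT_KINDS:
        raise ValueError(f"rank_stat_kind must be one of {RANK_STAT_KINDS}")

    genes = de.frame["gene"].to_numpy()
    effect = de.frame["effect"].to_numpy(float)
    sig = de.frame["significance"].to_numpy(float)
    dirs = np.sign(effect).astype(int)

    if rank_stat_kind == "neglog10_significance":
        t = -np.log10(sig) * np.where(dirs == 0, 1, dirs)
    else:
        t = effect

    abs_t = np.abs(t)
    if np.all(abs_t == abs_t[0]):
        logger.warning("ranking statistic is constant; ordering is tie-dominated")
    # lexsort: last key is primary; negative |T| -> descending, genes ascending
    order = np.lexsort((genes, -abs_t))
    abs_sorted = abs_t[order]
    return RankedList(
        genes=genes[order],
        rank_stat=t[order],
        weights=abs_sorted**omega,
        disease_dirs=dirs[order],
        omega=float(omega),
    )


def directional_hits(
    rl: RankedList, proto: ProtoMatrix, drug_id: str, mode: str = ANTAGONIST
) -> HitVector:
    """Mark the ranked-list positions where a drug's signature hits.

    A rank-j gene is a hit when it is in the drug's signature and the drug
    direction equals minus (antagonist) or plus (agonist) the disease
    direction. Signature genes absent from the list are ignored; present but
    direction-mismatched genes count as misses; disease direction 0 never
    matches.
    """
    if mode not in (ANTAGONIST, AGONIST):
        raise ValueError(f"mode must be {ANTAGONIST!r} or {AGONIST!r}")
    sig = proto.signature(drug_id)
    drug_dir = dict(zip(sig["gene"], sig["direction"]))
    sign = -1 if mode == ANTAGONIST else 1
    mapped = np.array([drug_dir.get(g, 0) for g in rl.genes], dtype=int)
    hit_flags = (mapped != 0) & (rl.disease_dirs != 0) & (mapped == sign * rl.disease_dirs)
    return HitVector(hit_flags=hit_flags, gamma=int(hit_flags.sum()), mode=mode)


def running_sum(rl: RankedList, hv: HitVector) -> np.ndarray:
    """The weighted running sum v(1..p); v(p) == 0 whenever gamma >= 1."""
    if hv.gamma < 1:
        raise ValueError("running sum undefined for gamma = 0")
    p = rl.p
    hits = hv.hit_flags
    hit_w = np.where(hits, rl.weights, 0.0)
    cum_w = np.cumsum(hit_w)
    total_w = cum_w[-1]  # sequential sum: bitwise-stable denominator
    if total_w > 0:
        hit_frac = cum_w / total_w
    else:
        logger.warning("all hit weights are zero; falling back to unweighted hit fraction")
        hit_frac = np.cumsum(hits) / hv.gamma
    if hv.gamma == p:
        logger.warning("every gene is a hit; miss fraction undefined, returning hit fraction")
        return hit_frac
    miss_frac = np.cumsum(~hits) / (p - hv.gamma)
    return hit_frac - miss_frac


def enrichment_scores(rl: RankedList, hv: HitVector) -> EnrichmentScores:
    """ES, TCS and the leading edge for one drug (gamma >= 1 required)."""
    v = running_sum(rl, hv)
    abs_v = np.abs(v)
    l_max = int(np.argmax(abs_v)) + 1  # first occurrence = smallest rank
    es = float(abs_v[l_max - 1])
    l_min = rl.l_min
    tcs_raw = abs(l_max - l_min)
    tcs = tcs_raw / (rl.p - 1)
    if v[l_max - 1] >= 0:
        leading = rl.genes[:l_max][hv.hit_flags[:l_max]].tolist()
    else:
        # peak is a depletion: the deviation is driven by the hits that all
        # sit below the minimum (there is always at least one, since v
        # climbs back to v(p)=0 only through hits)
        leading = rl.genes[l_max:][hv.hit_flags[l_max:]].tolist()
    return EnrichmentScores(
        es=es, l_max=l_max, l_min=l_min, tcs_raw=tcs_raw, tcs=float(tcs),
        leading_edge=leading,
    )
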