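"""End-to-end screen: ranked list -> per-drug scores -> nulls -> report.

For every drug in the proto-matrix: directional hits are located on the
significance-ranked list, ES/TCS and the leading edge are computed, a
permutation null normalizes the scores and yields empirical p-values, and a
pooled null across all screened drugs yields GSEA-style FDR q-values for
NES and NTCS separately. Drugs with no directional hit appear in the report
with NA statistics. Per-drug RNG streams make the per-drug numbers
independent of screening order, and a fixed seed makes the report
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment_core import (
    ANTAGONIST,
    AGONIST,
    build_ranked_list,
    directional_hits,
    enrichment_scores,
    running_sum,
)
from .io_formats import DETable, ProtoMatrix, ScreenReport, logger
from .null_model import drug_rng, normalize_and_test, permute_null, pooled_fdr

SORT_KEYS = ("es_p", "tcs_p", "nes", "ntcs")


class EmptyOverlapError(ValueError):
    """No gene shared between the DE table and the proto-matrix.

    Almost always an identifier-namespace mismatch (e.g. symbols vs Ensembl
    ids); the message shows examples from each side.
    """


@dataclass(frozen=True)
class ScreenConfig:
    """Screen settings; defaults follow the signature-reversion use case."""

    mode: str = ANTAGONIST
    omega: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    fdr_alpha: float = 0.05
    sort_key: str = "es_p"
    rank_stat_kind: str = "neglog10_significance"
    #: use only the null fraction as the FDR estimate (stricter variant)
    numerator_only_fdr: bool = False
    #: append Benjamini-Hochberg-adjusted empirical p-values as extra columns
    add_bh: bool = False

    def __post_init__(self) -> None:
        if self.mode not in (ANTAGONIST, AGONIST):
            raise ValueError(f"mode must be {ANTAGONIST!r} or {AGONIST!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.sort_key not in SORT_KEYS:
            raise ValueError(f"sort_key must be one of {SORT_KEYS}")


def _sort_report(frame: pd.DataFrame, sort_key: str) -> pd.DataFrame:
    if sort_key in ("es_p", "tcs_p"):
        tie = {"es_p": "nes", "tcs_p": "ntcs"}[sort_key]
        frame = frame.sort_values(
            [sort_key, tie, "drug_id"], ascending=[True, False, True], kind="stable",
            na_position="last",
        )
    else:
        frame = frame.sort_values(
            [sort_key, "drug_id"], ascending=[False, True], kind="stable",
            na_position="last",
        )
    return frame.reset_index(drop=True)


def screen(de: DETable, proto: ProtoMatrix, config: ScreenConfig = ScreenConfig()) -> ScreenReport:
    """Screen one DE contrast against every drug in a proto-matrix."""
    rl = build_ranked_list(de, omega=config.omega, rank_stat_kind=config.rank_stat_kind)
    drugs = proto.drug_ids()
    if not drugs:
        logger.warning("proto-matrix contains no drugs; emitting empty report")
        frame = pd.DataFrame(
            columns=[
                "drug_id", "es", "nes", "es_p", "es_fdr", "tcs", "ntcs", "tcs_p",
                "tcs_fdr", "n_hits", "es_pass_fdr", "tcs_pass_fdr", "leading_edge_genes",
            ]
        )
        return ScreenReport(frame, meta={"n_perm": config.n_perm})

    rl_genes = set(rl.genes.tolist())
    proto_genes = set(proto.frame["gene"].tolist())
    if not (rl_genes & proto_genes):
        raise EmptyOverlapError(
            "no gene shared between DE table and proto-matrix; "
            f"DE examples: {sorted(rl_genes)[:3]}, proto examples: {sorted(proto_genes)[:3]} "
            "(check the identifier namespace)"
        )

    rows = []
    nes_null_pool: list[np.ndarray] = []
    ntcs_null_pool: list[np.ndarray] = []
    for drug_id in drugs:
        hv = directional_hits(rl, proto, drug_id, mode=config.mode)
        if hv.gamma == 0:
            logger.info("%s: no directional hits (gamma=0); NA row emitted", drug_id)
            rows.append(
                dict(drug_id=drug_id, es=np.nan, nes=np.nan, es_p=np.nan, tcs=np.nan,
                     ntcs=np.nan, tcs_p=np.nan, n_hits=0, leading_edge_genes=[])
            )
            continue
        scores = enrichment_scores(rl, hv)
        es_nulls, tcs_nulls = permute_null(
            rl, hv, n_perm=config.n_perm, rng=drug_rng(config.seed, drug_id)
        )
        stats = normalize_and_test(scores.es, scores.tcs, es_nulls, tcs_nulls)
        es_mean, tcs_mean = es_nulls.mean(), tcs_nulls.mean()
        if es_mean > 0:
            nes_null_pool.append(es_nulls / es_mean)
        if tcs_mean > 0:
            ntcs_null_pool.append(tcs_nulls / tcs_mean)
        rows.append(
            dict(drug_id=drug_id, es=scores.es, nes=stats.nes, es_p=stats.es_p,
                 tcs=scores.tcs, ntcs=stats.ntcs, tcs_p=stats.tcs_p,
                 n_hits=hv.gamma, leading_edge_genes=scores.leading_edge)
        )

    frame = pd.DataFrame(rows)
    frame["es_fdr"] = pooled_fdr(
        frame["nes"].to_numpy(float),
        np.concatenate(nes_null_pool) if nes_null_pool else np.array([]),
        numerator_only=config.numerator_only_fdr,
    ) if nes_null_pool else np.nan
    frame["tcs_fdr"] = pooled_fdr(
        frame["ntcs"].to_numpy(float),
        np.concatenate(ntcs_null_pool) if ntcs_null_pool else np.array([]),
        numerator_only=config.numerator_only_fdr,
    ) if ntcs_null_pool else np.nan
    frame["es_pass_fdr"] = (frame["es_fdr"] <= config.fdr_alpha).fillna(False)
    frame["tcs_pass_fdr"] = (frame["tcs_fdr"] <= config.fdr_alpha).fillna(False)

    if config.add_bh:
        from statsmodels.stats.multitest import multipletests

        for col in ("es_p", "tcs_p"):
            pvals = frame[col].to_numpy(float)
            adj = np.full_like(pvals, np.nan)
            ok = ~np.isnan(pvals)
            if ok.any():
                adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            frame[col + "_bh"] = adj

    frame = _sort_report(frame, config.sort_key)
    return ScreenReport(frame, meta={"n_perm": config.n_perm, "mode": config.mode})


def plot_running_sum(de: DETable, proto: ProtoMatrix, drug_id: str,
                     config: ScreenConfig, path) -> None:
    """Save a running-sum profile for one drug (hit positions ticked)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rl = build_ranked_list(de, omega=config.omega, rank_stat_kind=config.rank_stat_kind)
    hv = directional_hits(rl, proto, drug_id, mode=config.mode)
    if hv.gamma == 0:
        logger.warning("%s: gamma=0, nothing to plot", drug_id)
        return
    v = running_sum(rl, hv)
    scores = enrichment_scores(rl, hv)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(np.arange(1, rl.p + 1), v, lw=1.2)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.axvline(scores.l_max, color="red", ls="--", lw=0.8,
               label=f"ES={scores.es:.3f} at rank {scores.l_max}")
    hits = np.flatnonzero(hv.hit_flags) + 1
    ax.plot(hits, np.full(hits.shape, v.min() - 0.02), "|", color="black", ms=8)
    ax.set_xlabel("rank in significance-ordered list")
    ax.set_ylabel("running sum v(l)")
    ax.set_title(f"{drug_id} ({hv.mode}, gamma={hv.gamma}, TCS={scores.tcs:.3f})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
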