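"""Build proto-matrices from per-drug DE tables.

Each drug's perturbation-versus-vehicle DE table is ranked either by
absolute fold change (``fc``) or by significance (``sig``); the top-N genes
are retained with direction = sign(effect) and their rank recorded. The
conventional label is ``"FC Rank 20"`` / ``"Sig Rank 10"`` etc. Upstream DE
fitting is out of scope: the builder consumes finished DE tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DETable, ProtoMatrix, ValidationError, logger

RANK_BY = ("fc", "sig")


@dataclass(frozen=True)
class BuilderConfig:
    rank_by: str = "sig"
    top_n: int = 20
    #: optional significance cutoff applied before taking the top-N
    max_p: float | None = None
    #: drop drugs with fewer than top_n genes instead of keeping them short
    strict: bool = False

    def __post_init__(self) -> None:
        if self.rank_by not in RANK_BY:
            raise ValueError(f"rank_by must be one of {RANK_BY}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    @property
    def label(self) -> str:
        prefix = "FC" if self.rank_by == "fc" else "Sig"
        return f"{prefix} Rank {self.top_n}"


def _rank_genes(de: DETable, rank_by: str) -> pd.DataFrame:
    """Total deterministic order: primary criterion, then the other, then gene id."""
    df = de.frame.copy()
    df["abs_effect"] = df["effect"].abs()
    # zero-effect genes carry no direction and cannot enter a signature
    n_zero = int((df["abs_effect"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-effect gene(s) with undefined direction", n_zero)
        df = df[df["abs_effect"] > 0]
    if rank_by == "fc":
        keys, ascending = ["abs_effect", "significance", "gene"], [False, True, True]
    else:
        keys, ascending = ["significance", "abs_effect", "gene"], [True, False, True]
    return df.sort_values(keys, ascending=ascending, kind="stable")


def build_proto_matrix(
    collection: dict[str, DETable], config: BuilderConfig = BuilderConfig()
) -> ProtoMatrix:
    """Top-N directional signatures for every drug in the collection.

    Signatures built at a smaller ``top_n`` are prefixes of those built at a
    larger one under the same ``rank_by`` (the ordering is total and does not
    depend on N).
    """
    rows = []
    for drug_id in sorted(collection):
        ranked = _rank_genes(collection[drug_id], config.rank_by)
        if config.max_p is not None:
            ranked = ranked[ranked["significance"] <= config.max_p]
        if len(ranked) < config.top_n:
            if config.strict:
                logger.warning(
                    "dropping %s: only %d usable gene(s), need %d",
                    drug_id, len(ranked), config.top_n,
                )
                continue
            logger.warning(
                "%s has only %d usable gene(s); keeping a short signature", drug_id, len(ranked)
            )
        top = ranked.head(config.top_n)
        for rank, rec in enumerate(top.itertuples(index=False), start=1):
            rows.append((drug_id, rec.gene, int(np.sign(rec.effect)), rank))

    frame = pd.DataFrame(rows, columns=["drug", "gene", "direction", "rank"])
    return ProtoMatrix(frame, label=config.label)
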