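"""Synthetic DE tables and proto-matrices with controlled, known signal.

The generator emulates the statistical structure the enrichment method
assumes, starting at the DE-table level the screen consumes (no read counts
or upstream model fitting):

* background genes have significance ~ Uniform(0, 1] and effect ~ N(0, 1);
* a *spiked* drug's signature genes are, with probability ``concordance``,
  given a disease effect whose sign opposes their drug direction (an
  antagonist-mode hit) and a significance of 10^(-Exp(mean=spike_strength)
  - 1), an exponential tail on the -log10 scale that concentrates them near
  the top of the ranked list at stochastic positions;
* *null* drugs get signatures drawn uniformly from all genes.

Ground-truth labels (spiked / null) are returned so power and type-I error
are measurable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DETable, ProtoMatrix


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen.

    ``concordance`` is the fraction of a spiked signature whose disease
    direction opposes the drug direction (so they are antagonist-mode hits);
    ``spike_strength`` is the mean of -log10(significance) above the floor of
    1 for those genes.
    """

    n_genes: int = 2000
    n_drugs: int = 10
    n_spiked: int = 1
    signature_size: int = 20
    concordance: float = 1.0
    spike_strength: float = 3.0
    disjoint: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.concordance <= 1):
            raise ValueError("concordance must lie in [0, 1]")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if not (0 <= self.n_spiked <= self.n_drugs):
            raise ValueError("need 0 <= n_spiked <= n_drugs")
        if self.spike_strength <= 0:
            raise ValueError("spike_strength must be positive")
        if self.disjoint and self.signature_size * self.n_drugs > self.n_genes:
            raise ValueError(
                "disjoint signatures need signature_size * n_drugs <= n_genes"
            )


def simulate_screen_inputs(
    config: SimConfig,
) -> tuple[DETable, ProtoMatrix, dict[str, str]]:
    """One simulated screen: disease DE table, proto-matrix, truth labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"g{i:05d}" for i in range(n)])
    significance = 1.0 - rng.random(n)  # in (0, 1]
    effect = rng.standard_normal(n)

    pool = np.arange(n)
    proto_rows: list[tuple[str, str, int, int]] = []
    truth: dict[str, str] = {}

    drug_ids = [f"spiked_{i + 1:02d}" for i in range(config.n_spiked)] + [
        f"null_{i + 1:02d}" for i in range(config.n_drugs - config.n_spiked)
    ]
    for drug_id in drug_ids:
        spiked = drug_id.startswith("spiked")
        idx = rng.choice(pool, size=config.signature_size, replace=False)
        if config.disjoint:
            pool = np.setdiff1d(pool, idx)
        directions = rng.choice([1, -1], size=config.signature_size)
        if spiked:
            n_conc = int(round(config.concordance * config.signature_size))
            conc = idx[:n_conc]
            # disease effect sign opposite the drug direction -> antagonist hit
            effect[conc] = -directions[:n_conc] * np.abs(rng.standard_normal(n_conc))
            significance[conc] = 10.0 ** (
                -rng.exponential(config.spike_strength, n_conc) - 1.0
            )
        truth[drug_id] = "spiked" if spiked else "null"
        for rank, (gi, d) in enumerate(zip(idx, directions), start=1):
            proto_rows.append((drug_id, genes[gi], int(d), rank))

    de = DETable(pd.DataFrame({"gene": genes, "effect": effect, "significance": significance}))
    proto = ProtoMatrix(
        pd.DataFrame(proto_rows, columns=["drug", "gene", "direction", "rank"]),
        label="simulated",
    )
    return de, proto, truth


def write_truth(truth: dict[str, str], path, sep: str = "\t") -> None:
    pd.DataFrame(
        sorted(truth.items()), columns=["drug", "truth"]
    ).to_csv(path, sep=sep, index=False)
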