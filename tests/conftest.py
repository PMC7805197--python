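import logging

import numpy as np
import pandas as pd
import pytest

from dpgsea import DETable, HitVector, ProtoMatrix, RankedList


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("dpgsea").setLevel(logging.ERROR)
    yield


def make_ranked_list(abs_t, signs=None, omega=1.0, genes=None) -> RankedList:
    """RankedList from a descending |T| vector, bypassing the DE-table path."""
    abs_t = np.asarray(abs_t, dtype=float)
    p = len(abs_t)
    signs = np.ones(p, dtype=int) if signs is None else np.asarray(signs, dtype=int)
    genes = np.array([f"g{i:03d}" for i in range(p)]) if genes is None else np.asarray(genes)
    return RankedList(
        genes=genes,
        rank_stat=abs_t * np.where(signs == 0, 1, signs),
        weights=abs_t**omega if omega > 0 else np.ones(p),
        disease_dirs=signs,
        omega=float(omega),
    )


def make_hits(p, positions) -> HitVector:
    """HitVector with hits at the given 1-based ranks."""
    flags = np.zeros(p, dtype=bool)
    flags[np.asarray(positions, dtype=int) - 1] = True
    return HitVector(hit_flags=flags, gamma=len(positions), mode="antagonist")


@pytest.fixture
def tiny_de() -> DETable:
    return DETable(
        pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "effect": [2.0, -1.0, 0.1],
                "significance": [0.001, 0.1, 0.9],
            }
        )
    )


@pytest.fixture
def tiny_proto() -> ProtoMatrix:
    frame = pd.DataFrame(
        {
            "drug": ["drugA", "drugA", "drugB"],
            "gene": ["g1", "g2", "g3"],
            "direction": [-1, 1, 1],
            "rank": [1, 2, 1],
        }
    )
    return ProtoMatrix(frame, label="toy")
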