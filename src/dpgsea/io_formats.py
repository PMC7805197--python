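"""Readers and writers for the three delimited-text artifacts.

The package moves data around as three typed records:

* :class:`DETable` — one differential-expression contrast (the disease
  signature): per gene a signed effect (log2 fold-change or moderated
  statistic) and a significance value (a p-value in ``(0, 1]``).
* :class:`ProtoMatrix` — drug-defined gene-set priors: per drug (drug name +
  cell line) the signature genes with the direction (+1 up / -1 down) the
  perturbation drives them and their rank within the signature.
* :class:`ScreenReport` — the per-drug output of a screen: enrichment score
  (ES), target compatibility score (TCS), their permutation-normalized
  versions, empirical p-values, pooled-null FDR q-values and the
  leading-edge driver genes.

All three are tab-separated text with a header by default; the delimiter is
configurable. Validation is strict so downstream modules can assume clean
typed input.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dpgsea")

#: Smallest positive significance substituted for 0/negative values so that
#: -log10 transforms stay finite.
SIG_FLOOR = 1e-300

#: Accepted spellings for drug-induced regulation direction (case-insensitive).
_DIRECTION_TOKENS = {
    "up": 1,
    "down": -1,
    "+1": 1,
    "-1": -1,
    "1": 1,
    "−1": -1,  # unicode minus
}

REPORT_COLUMNS = [
    "drug_id",
    "es",
    "nes",
    "es_p",
    "es_fdr",
    "tcs",
    "ntcs",
    "tcs_p",
    "tcs_fdr",
    "n_hits",
    "es_pass_fdr",
    "tcs_pass_fdr",
    "leading_edge_genes",
]


class FormatError(ValueError):
    """Malformed input file: missing columns, bad tokens, bad numbers."""


class ValidationError(ValueError):
    """Structurally well-formed input violating a domain invariant."""


def normalize_gene_id(gene: str) -> str:
    """Canonical gene identifier: whitespace-stripped and case-folded.

    Idempotent by construction: ``normalize_gene_id(normalize_gene_id(g))``
    equals ``normalize_gene_id(g)``.
    """
    return str(gene).strip().casefold()


# ---------------------------------------------------------------------------
# DETable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DETable:
    """A differential-expression contrast: gene, signed effect, significance.

    ``frame`` has columns ``gene`` (normalized, unique), ``effect`` (finite
    float) and ``significance`` (float in ``(0, 1]``).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"gene", "effect", "significance"} - set(f.columns)
        if missing:
            raise ValidationError(f"DETable missing columns: {sorted(missing)}")
        if len(f) < 2:
            raise ValidationError("DETable needs at least 2 records")
        if f["gene"].duplicated().any():
            dupes = f.loc[f["gene"].duplicated(), "gene"].unique()[:5].tolist()
            raise ValidationError(f"duplicate gene ids after normalization: {dupes}")
        if not np.isfinite(f["effect"].to_numpy(float)).all():
            raise ValidationError("non-finite effect values")
        sig = f["significance"].to_numpy(float)
        if not ((sig > 0) & (sig <= 1)).all():
            raise ValidationError("significance values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genes(self) -> np.ndarray:
        return self.frame["gene"].to_numpy()

    @property
    def records(self) -> list[tuple[str, float, float]]:
        return list(
            self.frame[["gene", "effect", "significance"]].itertuples(index=False, name=None)
        )


def read_de_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
    sig_floor: float = SIG_FLOOR,
) -> DETable:
    """Read a DE result table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Maps the logical names ``gene``, ``effect``, ``significance`` to the
        column names actually present; defaults to identity.
    sep
        Field delimiter (tab by default).
    sig_floor
        Replacement for zero/negative significance values (underflow from the
        upstream DE fit).

    Duplicate gene ids are collapsed to the most significant row (smallest
    significance) with a logged warning.
    """
    colmap = {"gene": "gene", "effect": "effect", "significance": "significance"}
    colmap.update(column_map or {})

    raw = pd.read_csv(path, sep=sep, dtype=str)
    for logical, actual in colmap.items():
        if actual not in raw.columns:
            raise FormatError(
                f"{path}: required column {actual!r} (mapped from {logical!r}) "
                f"not found; header has {list(raw.columns)}"
            )

    df = pd.DataFrame(
        {
            "gene": raw[colmap["gene"]].map(normalize_gene_id),
            "effect": pd.to_numeric(raw[colmap["effect"]], errors="coerce"),
            "significance": pd.to_numeric(raw[colmap["significance"]], errors="coerce"),
        }
    )
    bad = df["effect"].isna() | df["significance"].isna()
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()[:10]
        raise FormatError(f"{path}: non-numeric effect/significance on line(s) {lines}")

    clamped = df["significance"] <= 0
    if clamped.any():
        logger.warning(
            "%s: clamped %d non-positive significance value(s) to %g",
            path, int(clamped.sum()), sig_floor,
        )
        df.loc[clamped, "significance"] = sig_floor

    n_dup = int(df["gene"].duplicated().sum())
    if n_dup:
        logger.warning("%s: collapsed %d duplicate gene row(s), keeping most significant", path, n_dup)
        df = df.sort_values(["significance", "gene"], kind="stable").drop_duplicates("gene")
        df = df.sort_index()

    return DETable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# ProtoMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtoMatrix:
    """Drug-defined gene-set priors with per-gene regulation direction.

    ``frame`` has columns ``drug`` (drug + cell line, e.g.
    ``paclitaxel_HT29``), ``gene`` (normalized), ``direction`` (+1/-1) and
    ``rank`` (1-based position within the drug's signature).
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        f = self.frame
        missing = {"drug", "gene", "direction", "rank"} - set(f.columns)
        if missing:
            raise ValidationError(f"ProtoMatrix missing columns: {sorted(missing)}")
        if len(f):
            if not f["direction"].isin([1, -1]).all():
                raise ValidationError("direction values must be +1 or -1")
            dup = f.duplicated(["drug", "gene"])
            if dup.any():
                offenders = (
                    f.loc[dup, ["drug", "gene"]].apply(tuple, axis=1).unique()[:5].tolist()
                )
                raise ValidationError(f"duplicate (drug, gene) pairs: {offenders}")
            if (f["rank"].to_numpy(int) < 1).any():
                raise ValidationError("ranks must be positive integers")

    def drug_ids(self) -> list[str]:
        return sorted(self.frame["drug"].unique().tolist())

    def signature(self, drug_id: str) -> pd.DataFrame:
        """Rows for one drug, sorted by rank; LookupError if unknown."""
        sub = self.frame[self.frame["drug"] == drug_id]
        if sub.empty:
            raise LookupError(f"drug {drug_id!r} not in proto-matrix")
        return sub.sort_values("rank")

    def __len__(self) -> int:
        return len(self.frame)


def parse_direction(token) -> int:
    key = str(token).strip().casefold()
    try:
        return _DIRECTION_TOKENS[key]
    except KeyError:
        raise FormatError(
            f"unknown direction token {token!r}; expected one of "
            f"{sorted(set(_DIRECTION_TOKENS))}"
        ) from None


def read_proto_matrix(path, sep: str = "\t", label: str = "") -> ProtoMatrix:
    """Read a proto-matrix TSV with columns drug, gene, direction, rank."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"drug", "gene", "direction", "rank"} - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: proto-matrix missing column(s) {sorted(missing)}")
    if raw.empty:
        frame = pd.DataFrame(columns=["drug", "gene", "direction", "rank"])
        return ProtoMatrix(frame, label=label)

    rank = pd.to_numeric(raw["rank"], errors="coerce")
    if rank.isna().any():
        lines = (raw.index[rank.isna()] + 2).tolist()[:10]
        raise FormatError(f"{path}: non-numeric rank on line(s) {lines}")
    frame = pd.DataFrame(
        {
            "drug": raw["drug"].astype(str).str.strip(),
            "gene": raw["gene"].map(normalize_gene_id),
            "direction": raw["direction"].map(parse_direction).astype(int),
            "rank": rank.astype(int),
        }
    )
    return ProtoMatrix(frame, label=label)


def write_proto_matrix(proto: ProtoMatrix, path, sep: str = "\t") -> None:
    proto.frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ScreenReport
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Ranked per-drug screen output.

    ``frame`` has :data:`REPORT_COLUMNS`; ``leading_edge_genes`` holds an
    ordered list of gene ids per row. Drugs with no directional hits carry NA
    statistics and ``n_hits == 0``.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(REPORT_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValidationError(f"ScreenReport missing columns: {sorted(missing)}")
        extra = [c for c in self.frame.columns if c not in REPORT_COLUMNS]
        self.frame = self.frame[REPORT_COLUMNS + extra].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


def write_screen_report(
    report: ScreenReport, path, sep: str = "\t", gene_sep: str = ","
) -> None:
    """Write a report as delimited text, one row per drug.

    Leading-edge genes are joined by ``gene_sep``; floats are printed with 6
    significant digits so the file round-trips through
    :func:`read_screen_report` up to that precision.
    """
    out = report.frame.copy()
    out["leading_edge_genes"] = out["leading_edge_genes"].map(
        lambda genes: gene_sep.join(genes) if isinstance(genes, (list, tuple)) else ""
    )
    out.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_screen_report(path, sep: str = "\t", gene_sep: str = ",") -> ScreenReport:
    raw = pd.read_csv(path, sep=sep)
    if raw.empty and "drug_id" not in raw.columns:
        raise FormatError(f"{path}: not a screen report")
    raw["leading_edge_genes"] = raw["leading_edge_genes"].map(
        lambda s: s.split(gene_sep) if isinstance(s, str) and s else []
    )
    for col in ("es_pass_fdr", "tcs_pass_fdr"):
        raw[col] = raw[col].astype(bool)
    return ScreenReport(raw)


def format_p(p: float, n_perm: int) -> str:
    """Render an empirical p-value; 0 becomes ``< 1/n_perm``."""
    if np.isnan(p):
        return "NA"
    if p == 0:
        return f"<{1.0 / n_perm:g}"
    return f"{p:g}"


def configure_logging(verbose: int = 0, stream=sys.stderr) -> None:
    level = logging.DEBUG if verbose > 1 else logging.INFO if verbose else logging.WARNING
    handler = logging.StreamHandler(stream)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
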