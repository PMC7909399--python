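"""Data model, file I/O and preprocessing for sample x OTU community tables.

The central object is :class:`CommunityMatrix`: a samples-as-rows integer
count table with optional per-OTU taxonomy strings.  Per-sample metadata
(coordinates, environmental variables, habitat group) travels as a pandas
DataFrame indexed by sample id; :func:`validate_metadata` enforces its
contract and :func:`assign_groups` applies salinity/ecosystem habitat rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "HabitatRule",
    "DEFAULT_HABITAT_RULES",
    "load_community",
    "save_community",
    "load_metadata",
    "validate_metadata",
    "preprocess",
    "rarefy",
    "assign_groups",
]


@dataclass
class CommunityMatrix:
    """Sample x OTU count table with optional taxonomy.

    Parameters
    ----------
    data:
        DataFrame of non-negative integer counts, rows = samples,
        columns = OTUs.  Row order defines alignment with metadata.
    taxonomy:
        Optional Series mapping otu_id -> semicolon-delimited lineage
        string.  Every key must be a column of ``data``.
    """

    data: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.data = self.data.astype(np.int64)
        if (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.astype(str)
            unknown = self.taxonomy.index.difference(self.data.columns)
            if len(unknown):
                raise ValueError(
                    f"taxonomy refers to unknown OTU ids: {list(unknown[:5])}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_otus(self, otu_ids: Sequence[str]) -> "CommunityMatrix":
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(
                [o for o in otu_ids if o in self.taxonomy.index]
            ).dropna()
        return CommunityMatrix(self.data.loc[:, list(otu_ids)].copy(), tax)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total reads: {bad}")
        return self.data.div(totals, axis=0)


@dataclass(frozen=True)
class HabitatRule:
    """Half-open salinity interval [lo, hi) within one ecosystem type."""

    ecosystem: str
    salinity_min: float
    salinity_max: float  # exclusive; use inf for an unbounded bin
    label: str

    def matches(self, ecosystem: str, salinity: float) -> bool:
        return (
            ecosystem == self.ecosystem
            and self.salinity_min <= salinity < self.salinity_max
        )


#: Rivers are one group; lakes are binned at 1 and 8 permil salinity, so
#: freshwater lakes, low-brackish and high-brackish lakes separate.
DEFAULT_HABITAT_RULES: tuple[HabitatRule, ...] = (
    HabitatRule("river", 0.0, np.inf, "Group I"),
    HabitatRule("lake", 0.0, 1.0, "Group II"),
    HabitatRule("lake", 1.0, 8.0, "Group III"),
    HabitatRule("lake", 8.0, np.inf, "Group IV"),
)


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def load_community(
    counts_path: str | Path,
    taxonomy_path: str | Path | None = None,
    orientation: str = "auto",
) -> CommunityMatrix:
    """Read a TSV count table (and optional 2-column taxonomy TSV).

    ``orientation`` is one of ``"samples"`` (rows are samples), ``"otus"``
    (rows are OTUs; table is transposed) or ``"auto"``: if a taxonomy file
    is given its ids decide the orientation, otherwise the longer axis is
    assumed to be the OTU axis.
    """
    df = _read_table(counts_path)
    taxonomy = None
    if taxonomy_path is not None:
        tax_df = pd.read_csv(
            taxonomy_path, sep="\t", index_col=0, header=None,
            names=["otu_id", "lineage"], encoding="utf-8", skiprows=_tax_skip(taxonomy_path),
        )
        taxonomy = tax_df["lineage"].astype(str)
        taxonomy.index = taxonomy.index.astype(str)

    if orientation not in {"auto", "samples", "otus"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "auto":
        if taxonomy is not None:
            row_hits = df.index.isin(taxonomy.index).sum()
            col_hits = df.columns.isin(taxonomy.index).sum()
            orientation = "otus" if row_hits > col_hits else "samples"
        else:
            orientation = "otus" if df.shape[0] > df.shape[1] else "samples"
    if orientation == "otus":
        df = df.T

    values = df.to_numpy()
    try:
        numeric = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {counts_path}: {exc}") from exc
    if not np.allclose(numeric, np.round(numeric)):
        rows, cols = np.nonzero(~np.isclose(numeric, np.round(numeric)))
        raise ValueError(
            f"non-integer count at sample {df.index[rows[0]]!r}, "
            f"OTU {df.columns[cols[0]]!r}"
        )
    return CommunityMatrix(df.astype(np.int64), taxonomy)


def _tax_skip(path: str | Path) -> int:
    """Skip a header line if the taxonomy file has one."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return 1 if first.lower().startswith(("otu_id", "#")) else 0


def save_community(cm: CommunityMatrix, counts_path: str | Path,
                   taxonomy_path: str | Path | None = None) -> None:
    """Write counts as samples-as-rows TSV (and taxonomy as 2-column TSV)."""
    cm.data.to_csv(counts_path, sep="\t", encoding="utf-8")
    if taxonomy_path is not None and cm.taxonomy is not None:
        cm.taxonomy.to_csv(taxonomy_path, sep="\t", header=False, encoding="utf-8")


REQUIRED_METADATA_COLUMNS = ("ecosystem", "latitude", "longitude", "salinity")


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample metadata table (index = sample_id)."""
    if md.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if (md["salinity"] < 0).any():
        raise ValueError("salinity must be >= 0")
    if not md["latitude"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if not md["longitude"].between(-180, 180).all():
        raise ValueError("longitude outside [-180, 180]")
    return md


def load_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, index_col="sample_id", encoding="utf-8")
    md.index = md.index.astype(str)
    return validate_metadata(md)


def preprocess(
    cm: CommunityMatrix,
    min_total_reads: int = 10,
    exclude_patterns: Iterable[str] = ("Chloroplast",),
) -> CommunityMatrix:
    """Drop low-abundance OTUs and OTUs matching taxonomy exclusion patterns.

    An OTU is removed when its total reads across all samples fall below
    ``min_total_reads`` (default 10, the standard rare-noise filter), or
    when its lineage string contains any of ``exclude_patterns``
    (case-insensitive; chloroplast reads are non-bacterial signal).
    Sample order is unchanged; idempotent.
    """
    totals = cm.data.sum(axis=0)
    keep = totals >= min_total_reads
    patterns = [p.lower() for p in exclude_patterns]
    if patterns and cm.taxonomy is not None:
        lineages = cm.taxonomy.reindex(cm.data.columns).fillna("").str.lower()
        for pat in patterns:
            keep &= ~lineages.str.contains(pat, regex=False)
    kept = list(cm.data.columns[keep])
    if not kept:
        raise ValueError("empty community: all OTUs removed by preprocessing")
    return cm.subset_otus(kept)


def rarefy(cm: CommunityMatrix, depth: int, seed: int) -> CommunityMatrix:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; deterministic given
    ``seed``.  Samples whose total is below ``depth`` raise an error.
    """
    totals = cm.data.sum(axis=1)
    short = list(totals.index[totals < depth])
    if short:
        raise ValueError(
            f"samples with fewer than {depth} reads cannot be rarefied: {short}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(cm.counts)
    for i, row in enumerate(cm.counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    data = pd.DataFrame(out, index=cm.data.index, columns=cm.data.columns)
    return CommunityMatrix(data, cm.taxonomy)


def assign_groups(
    md: pd.DataFrame,
    rules: Sequence[HabitatRule] = DEFAULT_HABITAT_RULES,
) -> pd.DataFrame:
    """Fill ``habitat_group`` from ecosystem type and salinity bin."""
    validate_metadata(md)
    labels = []
    for sample_id, row in md.iterrows():
        for rule in rules:
            if rule.matches(row["ecosystem"], row["salinity"]):
                labels.append(rule.label)
                break
        else:
            raise ValueError(
                f"sample {sample_id!r} (ecosystem={row['ecosystem']!r}, "
                f"salinity={row['salinity']}) matches no habitat rule"
            )
    out = md.copy()
    out["habitat_group"] = labels
    return out
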