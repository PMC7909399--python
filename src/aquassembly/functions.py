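"""Taxon-to-function profiling of community tables.

A :class:`FunctionMapping` associates each ecological function with plain
substring match rules against semicolon-delimited lineage strings
(FAPROTAX-style semantics: an OTU contributes its reads to every function
it matches, without splitting).  The package ships a small synthetic
fixture mapping (`data/function_mapping.tsv`) covering the function names
that matter for inland-water communities — photoautotrophy,
chemoheterotrophy, methanotrophy, methylotrophy, fermentation, nitrogen
fixation, denitrification, nitrification, nitrogen respiration; real
analyses should supply their own rule file in the same 2-column format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CommunityMatrix
from .permtests import bh_adjust, whites_test

__all__ = [
    "FunctionMapping",
    "FunctionTable",
    "load_mapping",
    "bundled_mapping",
    "apply_mapping",
    "compare_profiles",
]


@dataclass
class FunctionMapping:
    """function name -> list of case-insensitive lineage substrings."""

    rules: dict

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("empty function mapping")
        for fn, pats in self.rules.items():
            if not pats:
                raise ValueError(f"function {fn!r} has no match rules")

    @property
    def functions(self) -> list[str]:
        return list(self.rules)


def load_mapping(path: str | Path) -> FunctionMapping:
    """Read a 2-column TSV (function, match rule); repeated function names
    accumulate rules."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    if df.shape[1] < 2:
        raise ValueError("mapping file needs two columns: function, match rule")
    fn_col, rule_col = df.columns[:2]
    rules: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        rules.setdefault(str(row[fn_col]), []).append(str(row[rule_col]))
    return FunctionMapping(rules)


def bundled_mapping() -> FunctionMapping:
    """The synthetic fixture mapping shipped with the package."""
    ref = resources.files("aquassembly.data") / "function_mapping.tsv"
    with resources.as_file(ref) as path:
        return load_mapping(path)


@dataclass
class FunctionTable:
    """Function x sample profile with counts and relative abundances."""

    counts: pd.DataFrame              # functions x samples
    relative: pd.DataFrame
    n_otus_assigned: int
    n_otus_total: int
    denominator: str                  # "annotated" or "sample_total"

    @property
    def fraction_assigned(self) -> float:
        return self.n_otus_assigned / self.n_otus_total


def apply_mapping(
    cm: CommunityMatrix,
    mapping: FunctionMapping,
    denominator: str = "annotated",
) -> FunctionTable:
    """Aggregate OTU reads into function counts by lineage matching.

    An OTU contributes its full read count to every matching function
    (multi-assignment, no splitting).  ``denominator`` chooses the
    relative-abundance convention: per-sample total annotated reads
    (default, so columns sum to 1 over functions counted once per match)
    or total sample reads.
    """
    if cm.taxonomy is None:
        raise ValueError("community has no taxonomy; cannot annotate")
    if denominator not in {"annotated", "sample_total"}:
        raise ValueError("denominator must be 'annotated' or 'sample_total'")
    lineages = cm.taxonomy.reindex(cm.data.columns).fillna("").str.lower()
    counts = {}
    assigned = np.zeros(cm.data.shape[1], dtype=bool)
    for fn, patterns in mapping.rules.items():
        mask = np.zeros(cm.data.shape[1], dtype=bool)
        for pat in patterns:
            mask |= lineages.str.contains(pat.lower(), regex=False).to_numpy()
        assigned |= mask
        counts[fn] = cm.data.loc[:, mask].sum(axis=1)
    table = pd.DataFrame(counts).T  # functions x samples
    if denominator == "annotated":
        denom = table.sum(axis=0)
    else:
        denom = cm.data.sum(axis=1)
    denom = denom.replace(0, np.nan)
    relative = table.div(denom, axis=1).fillna(0.0)
    return FunctionTable(table, relative, int(assigned.sum()),
                         cm.data.shape[1], denominator)


def compare_profiles(
    ft: FunctionTable,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison of every function's relative abundance with the
    non-parametric permutation test on mean proportions, BH-corrected
    across functions.  Returns a per-function table with the enriched
    group sign (positive difference = enriched in the first group)."""
    groups = pd.Series(groups).reindex(ft.relative.columns)
    labels = list(pd.unique(groups.dropna()))
    if len(labels) != 2:
        raise ValueError("compare_profiles expects exactly two groups")
    g1_cols = groups.index[groups == labels[0]]
    g2_cols = groups.index[groups == labels[1]]
    if len(g1_cols) < 2 or len(g2_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for i, fn in enumerate(ft.relative.index):
        res = whites_test(ft.relative.loc[fn, g1_cols],
                          ft.relative.loc[fn, g2_cols],
                          n_perm=n_perm, seed=seed + i)
        rows.append({"function": fn, "mean_difference": res.statistic,
                     "p": res.p_value,
                     "enriched_in": labels[0] if res.statistic > 0
                     else (labels[1] if res.statistic < 0 else "none")})
    out = pd.DataFrame(rows).set_index("function")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out
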