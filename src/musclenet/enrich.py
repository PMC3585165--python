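"""Gene-set over-representation analysis (Fisher exact / hypergeometric).

A methodological stand-in for database-backed annotation tools: each
user-supplied gene set is tested for over-representation in a query list
against a background universe with the one-sided hypergeometric tail,
optionally in the conservative EASE variant (overlap reduced by one
before testing), followed by Benjamini–Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .errors import ConfigurationError

__all__ = ["EnrichmentResult", "fisher_enrichment", "filter_enriched"]

MIN_TESTABLE_SET = 2


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set over-representation results.

    ``table`` has one row per tested set (overlap, sizes, one-sided p,
    BH FDR, overlapping genes), sorted by p ascending; ``untested``
    names the sets skipped for having fewer than two background members.
    """

    table: pd.DataFrame
    untested: tuple[str, ...]
    background_size: int
    list_size: int
    ease: bool

    def summary(self) -> str:
        n_sig = int((self.table["fdr"] <= 0.05).sum()) if len(self.table) else 0
        return (
            f"Over-representation of {len(self.table)} gene sets "
            f"({len(self.untested)} untested) against a background of "
            f"{self.background_size} genes; list size {self.list_size}; "
            f"{n_sig} sets at FDR ≤ 0.05"
            + (" [EASE variant]" if self.ease else "")
        )


def fisher_enrichment(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, frozenset[str] | set[str]],
    background: Iterable[str],
    *,
    ease: bool = False,
) -> EnrichmentResult:
    """One-sided over-representation test of each set in the list.

    ``gene_list`` must be a subset of ``background``; each set is
    intersected with the background before testing.  With ``ease=True``
    one is subtracted from the overlap before computing the tail
    (the conservative "modified Fisher" variant).
    """
    bg = set(background)
    if not bg:
        raise ConfigurationError("background must not be empty")
    query = set(gene_list)
    strays = sorted(query - bg)
    if strays:
        raise ConfigurationError(f"genes in list but not in background: {strays[:10]}")

    m_bg, n_list = len(bg), len(query)
    rows = []
    untested: list[str] = []
    for name in gene_sets:
        members = set(gene_sets[name]) & bg
        if len(members) < MIN_TESTABLE_SET:
            untested.append(name)
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        k_eff = k - 1 if ease else k
        if k_eff <= 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k_eff - 1, m_bg, len(members), n_list))
        rows.append((name, k, len(members), p, ",".join(overlap)))

    if rows:
        table = pd.DataFrame(
            rows, columns=["set_name", "overlap", "set_size", "p_value", "overlap_genes"]
        )
        table.insert(3, "list_size", n_list)
        table.insert(4, "background_size", m_bg)
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(
            ["p_value", "set_name"], kind="stable", ignore_index=True
        )
    else:
        table = pd.DataFrame(
            columns=[
                "set_name", "overlap", "set_size", "list_size",
                "background_size", "p_value", "overlap_genes", "fdr",
            ]
        )
    return EnrichmentResult(
        table=table,
        untested=tuple(untested),
        background_size=m_bg,
        list_size=n_list,
        ease=ease,
    )


def filter_enriched(result: EnrichmentResult, fdr_max: float = 0.05) -> EnrichmentResult:
    """Keep only sets at FDR ≤ ``fdr_max`` (FDR values are unchanged)."""
    if not 0 <= fdr_max <= 1:
        raise ConfigurationError("fdr_max must lie in [0, 1]")
    kept = result.table[result.table["fdr"] <= fdr_max].reset_index(drop=True)
    return EnrichmentResult(
        table=kept,
        untested=result.untested,
        background_size=result.background_size,
        list_size=result.list_size,
        ease=result.ease,
    )
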