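"""Gene-set over-representation testing and GO category prioritization.

Over-representation uses the one-sided hypergeometric upper tail, with
either Bonferroni-Holm step-down or Benjamini-Hochberg step-up correction.
A priority resolver collapses multiple functional category annotations per
gene into a single label following a fixed order (immunity first,
development last).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CATEGORY_PRIORITY = [
    "immunity",
    "metabolic",
    "transcription, translation",
    "migration",
    "mitochondria",
    "axon",
    "development",
]


@dataclass
class CategoryPriority:
    order: list[str] = field(default_factory=lambda: list(DEFAULT_CATEGORY_PRIORITY))

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("category priority list contains duplicates")
        self._rank = {c: i for i, c in enumerate(self.order)}


def adjust_holm(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values.

    Sorted ascending, padj_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)).
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = np.minimum(1.0, p[order] * (m - np.arange(m)))
    stepped = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = stepped
    return out


def hypergeom_enrich(
    query: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    padj_method: str = "holm",
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each term in the query.

    With universe size N, term size K, query size n and overlap k, the
    p-value is P(X >= k) for X ~ Hypergeom(N, K, n).  Terms with K = 0 are
    skipped.  The query must be a subset of the universe.
    """
    uni = set(universe)
    q = set(query)
    offenders = sorted(q - uni)
    if offenders:
        raise ValueError(f"query genes absent from universe: {offenders[:10]}")
    if padj_method not in ("holm", "bh"):
        raise ValueError("padj_method must be 'holm' or 'bh'")
    N, n = len(uni), len(q)
    rows = []
    for term_id, genes in terms.items():
        members = set(genes) & uni
        K = len(members)
        if K == 0:
            continue
        k = len(members & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": (term_names or {}).get(term_id, term_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if not df.empty:
        if padj_method == "holm":
            df["padj"] = adjust_holm(df["p"].to_numpy())
        else:
            from .differential import adjust_bh

            df["padj"] = adjust_bh(df["p"].to_numpy())
    else:
        df["padj"] = []
    df["padj_method"] = padj_method
    return df


def prioritize_category(
    gene_categories: Mapping[str, Iterable[str]],
    priority: CategoryPriority | None = None,
) -> dict[str, str]:
    """Collapse each gene's category set to the single highest-priority one.

    Genes with no category map to "unclassified"; genes whose only
    categories are outside the priority list map to "other".
    """
    priority = priority or CategoryPriority()
    out: dict[str, str] = {}
    for gene, cats in gene_categories.items():
        cats = set(cats)
        listed = [c for c in cats if c in priority._rank]
        if listed:
            out[gene] = min(listed, key=priority._rank.__getitem__)
        elif cats:
            out[gene] = "other"
        else:
            out[gene] = "unclassified"
    return out


def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Read a GMT term file -> (term_id -> genes, term_id -> description)."""
    terms: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            terms[f[0]] = [g for g in f[2:] if g]
            names[f[0]] = f[1]
    return terms, names
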