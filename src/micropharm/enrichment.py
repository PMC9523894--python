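"""Hypergeometric overrepresentation of categories in a study set.

Given a study set drawn from a background universe and item-to-category
annotations (flat category names, or hierarchical ATC codes expanded to all
ancestor levels), each category is tested with the upper-tail
hypergeometric probability of observing at least the seen number of
annotated study items.  Bonferroni, Benjamini-Hochberg and
Benjamini-Yekutieli corrections are computed over the full family of
tested categories.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CategoryAnnotation",
    "expand_atc",
    "hypergeom_upper_tail",
    "adjust_pvalues",
    "enrich",
    "report_significant",
]

ATC_LEVEL_LENGTHS = (1, 3, 4, 5, 7)

_METHOD_MAP = {"bonferroni": "bonferroni", "bh": "fdr_bh", "by": "fdr_by"}


def expand_atc(code: str) -> set[str]:
    """All ancestor prefixes of an ATC code at the five standard level lengths.

    ``A10BB -> {A, A10, A10B, A10BB}``; the code itself is included.
    """
    code = code.strip().upper()
    if len(code) not in ATC_LEVEL_LENGTHS:
        raise ValueError(
            f"invalid ATC code {code!r}: length must be one of {ATC_LEVEL_LENGTHS}"
        )
    return {code[:length] for length in ATC_LEVEL_LENGTHS if length <= len(code)}


@dataclass(frozen=True)
class CategoryAnnotation:
    """item_id -> category codes, under a flat or hierarchical (atc) scheme.

    For the atc scheme every stored code is expanded to all its ancestor
    levels at construction, so each hierarchy level is tested as its own
    category.
    """

    mapping: dict[str, frozenset[str]]
    scheme: str = "flat"

    def __post_init__(self) -> None:
        if self.scheme not in ("flat", "atc"):
            raise ValueError("scheme must be 'flat' or 'atc'")
        expanded: dict[str, frozenset[str]] = {}
        for item, codes in self.mapping.items():
            if self.scheme == "atc":
                full: set[str] = set()
                for code in codes:
                    full |= expand_atc(code)
                expanded[item] = frozenset(full)
            else:
                expanded[item] = frozenset(codes)
        object.__setattr__(self, "mapping", expanded)

    def categories_of(self, item: str) -> frozenset[str]:
        return self.mapping.get(item, frozenset())


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n): k or more annotated in the draw."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p_values: Sequence[float], method: str) -> list[float]:
    """Bonferroni / Benjamini-Hochberg / Benjamini-Yekutieli adjustment, order kept."""
    if method not in _METHOD_MAP:
        raise ValueError(f"method must be one of {sorted(_METHOD_MAP)}")
    p_values = list(p_values)
    if not p_values:
        return []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    _, adjusted, _, _ = multipletests(p_values, method=_METHOD_MAP[method])
    return [float(p) for p in adjusted]


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    annotations: CategoryAnnotation,
) -> pd.DataFrame:
    """Overrepresentation table for every category annotating the background.

    Columns: category, k (annotated in study), K (annotated in background),
    n (study size), N (background size), p_raw and the three corrections,
    sorted by ascending p_raw with ties broken by category code.  Items
    without annotations still count in n and N.
    """
    study = set(study)
    background = set(background)
    if not study or not background:
        raise ValueError("study and background must be nonempty")
    if not study <= background:
        raise ValueError("study set must be contained in the background")

    K_counts: dict[str, int] = {}
    k_counts: dict[str, int] = {}
    for item in background:
        for cat in annotations.categories_of(item):
            K_counts[cat] = K_counts.get(cat, 0) + 1
            if item in study:
                k_counts[cat] = k_counts.get(cat, 0) + 1

    n, N = len(study), len(background)
    categories = sorted(K_counts)
    rows = []
    for cat in categories:
        K = K_counts[cat]
        k = k_counts.get(cat, 0)
        rows.append(
            {
                "category": cat,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_upper_tail(k, K, n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p_raw"])
    if len(table):
        for method, col in (("bonferroni", "p_bonferroni"), ("bh", "p_bh"), ("by", "p_by")):
            table[col] = adjust_pvalues(table["p_raw"].tolist(), method)
    else:
        table["p_bonferroni"] = table["p_bh"] = table["p_by"] = []
    return (
        table.sort_values(["p_raw", "category"], kind="mergesort").reset_index(drop=True)
    )


def report_significant(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Rows where any of the three adjusted p-values is below ``alpha``."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    mask = (
        (table["p_bonferroni"] < alpha) | (table["p_bh"] < alpha) | (table["p_by"] < alpha)
    )
    return table.loc[mask].reset_index(drop=True)
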