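"""Druggable-space survey of microbe proteomes from homology-search tables.

A microbe protein counts as druggable at a threshold ``t`` when it has at
least one homolog among the target sequences of a drug-target (or
structure) database with e-value below ``t``.  Hits arrive as standard
BLAST tabular output (outfmt 6); per microbe, the fraction of distinct
proteins with such a homolog is computed against the microbe's total
protein inventory, and sweeping the threshold yields the
fraction-versus--log10(e-value) curve whose elbow locates the break
between close and distant homology.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "HomologyHit",
    "DruggabilityStat",
    "read_homology_table",
    "filter_hits",
    "druggability_fraction",
    "pooled_fraction",
    "threshold_curve",
    "elbow_point",
]

BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class HomologyHit:
    """One reported alignment of a microbe protein against a database target."""

    query_protein: str
    query_microbe: str
    subject_id: str
    database: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (self.e_value > 0.0):
            raise ValueError(f"e_value must be positive, got {self.e_value!r}")


@dataclass(frozen=True)
class DruggabilityStat:
    microbe_id: str
    database: str
    threshold: float
    n_proteins: int
    n_with_homolog: int

    @property
    def fraction(self) -> float:
        return self.n_with_homolog / self.n_proteins if self.n_proteins else 0.0


def read_homology_table(
    path: str | Path,
    database_tag: str,
    microbe_of_query: Mapping[str, str],
) -> list[HomologyHit]:
    """Parse a BLAST outfmt-6 file into hits, mapping each query to its microbe.

    Malformed rows and queries absent from ``microbe_of_query`` are rejected
    with their line number.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path} line {lineno}: expected {len(BLAST_COLUMNS)} columns, got {len(fields)}"
                )
            query, subject = fields[0], fields[1]
            try:
                e_value = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as err:
                raise ValueError(f"{path} line {lineno}: unparseable e-value/bitscore") from err
            if not math.isfinite(e_value) or e_value <= 0.0:
                raise ValueError(f"{path} line {lineno}: e-value must be a positive number")
            if query not in microbe_of_query:
                raise ValueError(f"{path} line {lineno}: unknown query microbe for {query!r}")
            hits.append(
                HomologyHit(
                    query_protein=query,
                    query_microbe=microbe_of_query[query],
                    subject_id=subject,
                    database=database_tag,
                    e_value=e_value,
                    bit_score=bit_score,
                )
            )
    return hits


def filter_hits(hits: Iterable[HomologyHit], e_max: float) -> list[HomologyHit]:
    """Keep hits with e-value strictly below ``e_max``."""
    if not (e_max > 0.0):
        raise ValueError("e_max must be positive")
    return [h for h in hits if h.e_value < e_max]


def druggability_fraction(
    hits: Iterable[HomologyHit],
    inventory: Mapping[str, int],
    threshold: float,
    database: str,
) -> list[DruggabilityStat]:
    """Per-microbe fraction of distinct proteins with a homolog below ``threshold``.

    Every microbe of the inventory yields a row (zero hits -> fraction 0);
    duplicated hit rows never change a fraction since counting is per
    distinct query protein.
    """
    if not (threshold > 0.0):
        raise ValueError("threshold must be positive")
    with_homolog: dict[str, set[str]] = {m: set() for m in inventory}
    for hit in hits:
        if hit.database != database or hit.e_value >= threshold:
            continue
        if hit.query_microbe not in inventory:
            raise KeyError(f"hit for microbe {hit.query_microbe!r} absent from inventory")
        with_homolog[hit.query_microbe].add(hit.query_protein)
    stats = []
    for microbe in sorted(inventory):
        n_hom = len(with_homolog[microbe])
        n_prot = int(inventory[microbe])
        if n_prot < n_hom:
            raise ValueError(
                f"inventory for {microbe!r} ({n_prot}) below its distinct hit queries ({n_hom})"
            )
        stats.append(DruggabilityStat(microbe, database, threshold, n_prot, n_hom))
    return stats


def pooled_fraction(
    hits: Iterable[HomologyHit],
    inventory: Mapping[str, int],
    threshold: float,
    database: str,
) -> float:
    """All-proteins-pooled alternative to the per-microbe mean."""
    stats = druggability_fraction(hits, inventory, threshold, database)
    total = sum(s.n_proteins for s in stats)
    return sum(s.n_with_homolog for s in stats) / total if total else 0.0


def threshold_curve(
    hits: Iterable[HomologyHit],
    inventory: Mapping[str, int],
    thresholds: Sequence[float],
    database: str,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean druggable fraction at each threshold, as (-log10 threshold, fraction).

    One output point per input threshold, in input order, duplicates kept.
    """
    hits = list(hits)
    rows = []
    for thr in thresholds:
        if pooled:
            frac = pooled_fraction(hits, inventory, thr, database)
        else:
            stats = druggability_fraction(hits, inventory, thr, database)
            frac = sum(s.fraction for s in stats) / len(stats) if stats else 0.0
        rows.append(
            {"threshold": thr, "neg_log10_evalue": -math.log10(thr), "mean_fraction": frac}
        )
    return pd.DataFrame(rows, columns=["threshold", "neg_log10_evalue", "mean_fraction"])


def elbow_point(curve: pd.DataFrame, rtol: float = 1e-6) -> float:
    """Threshold of the interior curve point with maximal discrete second difference.

    Requires at least three points equally spaced in -log10(threshold).
    Ties resolve to the most permissive (largest) threshold.  Advisory: the
    elbow never gates any pipeline stage.
    """
    neglog = curve["neg_log10_evalue"].to_numpy()
    frac = curve["mean_fraction"].to_numpy()
    if len(neglog) < 3:
        raise ValueError("elbow_point needs a curve with at least three points")
    steps = neglog[1:] - neglog[:-1]
    if not (abs(steps - steps[0]) <= rtol * max(1.0, abs(steps[0]))).all():
        raise ValueError("elbow_point requires equal spacing in -log10(threshold)")
    second = frac[:-2] - 2.0 * frac[1:-1] + frac[2:]
    top = second.max()
    # curvature ties (within rounding noise) resolve to the largest threshold
    tied = [i for i in range(1, len(frac) - 1) if second[i - 1] >= top - 1e-12]
    best = max(tied, key=lambda i: curve["threshold"].iloc[i])
    return float(curve["threshold"].iloc[best])
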