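"""Metabolite consumption/production profiles of gut microbes.

A microbe is described by the set of metabolites it consumes (its growth
resources, ``C``) and the set it produces (its secreted by-products, ``P``).
These binary profiles are the sole input of the interaction-network
inference: shared consumption implies competition, consumption of another's
products implies cross-feeding.

Profiles are exchanged as UTF-8 TSV files with a header row and columns
``microbe_id``, ``consumed``, ``produced``, the last two holding
semicolon-separated metabolite identifiers (empty string for an empty set).
Health labels (+1 commensal / -1 pathogenic) travel in a two-column TSV
``microbe_id``, ``label``; the words ``commensal`` / ``pathogenic`` are
accepted as case-insensitive aliases.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MetaboliteProfile",
    "read_profiles",
    "write_profiles",
    "read_labels",
    "write_labels",
    "profile_summary",
]

_LABEL_ALIASES = {
    "+1": 1,
    "1": 1,
    "commensal": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "pathogenic": -1,
}


@dataclass(frozen=True)
class MetaboliteProfile:
    """A microbe's consumed (``C``) and produced (``P``) metabolite sets."""

    microbe_id: str
    consumed: frozenset[str]
    produced: frozenset[str]

    def __post_init__(self) -> None:
        if not self.microbe_id or not str(self.microbe_id).strip():
            raise ValueError("microbe_id must be a non-empty token")
        object.__setattr__(self, "consumed", frozenset(self.consumed))
        object.__setattr__(self, "produced", frozenset(self.produced))


def _split_field(field: str) -> frozenset[str]:
    field = (field or "").strip()
    if not field:
        return frozenset()
    return frozenset(tok.strip() for tok in field.split(";") if tok.strip())


def read_profiles(path: str | Path) -> list[MetaboliteProfile]:
    """Read a profile TSV; duplicate microbe ids are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = {"microbe_id", "consumed", "produced"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table {path} lacks columns: {sorted(missing)}")
    profiles = [
        MetaboliteProfile(row.microbe_id, _split_field(row.consumed), _split_field(row.produced))
        for row in df.itertuples()
    ]
    seen: set[str] = set()
    for prof in profiles:
        if prof.microbe_id in seen:
            raise ValueError(f"duplicate microbe_id {prof.microbe_id!r} in {path}")
        seen.add(prof.microbe_id)
    return profiles


def write_profiles(profiles: Iterable[MetaboliteProfile], path: str | Path) -> None:
    rows = [
        {
            "microbe_id": p.microbe_id,
            "consumed": ";".join(sorted(p.consumed)),
            "produced": ";".join(sorted(p.produced)),
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["microbe_id", "consumed", "produced"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a health-label TSV mapping microbe_id -> +1 (commensal) / -1 (pathogenic)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if not {"microbe_id", "label"} <= set(df.columns):
        raise ValueError(f"label table {path} needs columns microbe_id, label")
    labels: dict[str, int] = {}
    for row in df.itertuples():
        key = row.label.strip().lower()
        if key not in _LABEL_ALIASES:
            raise ValueError(f"unrecognized label {row.label!r} for {row.microbe_id!r}")
        if row.microbe_id in labels:
            raise ValueError(f"duplicate label row for {row.microbe_id!r}")
        labels[row.microbe_id] = _LABEL_ALIASES[key]
    return labels


def write_labels(labels: Mapping[str, int], path: str | Path) -> None:
    rows = [{"microbe_id": m, "label": int(l)} for m, l in sorted(labels.items())]
    pd.DataFrame(rows, columns=["microbe_id", "label"]).to_csv(path, sep="\t", index=False)


def profile_summary(
    profiles: Iterable[MetaboliteProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-microbe consumption/production counts and per-metabolite microbe counts.

    Returns ``(per_microbe, per_metabolite)``.  The double-counting identity
    holds by construction: the per-microbe ``n_consumed`` column and the
    per-metabolite ``n_consumers`` column have equal totals (likewise for
    production).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("profile_summary requires a non-empty collection")
    per_microbe = pd.DataFrame(
        {
            "microbe_id": [p.microbe_id for p in profiles],
            "n_consumed": [len(p.consumed) for p in profiles],
            "n_produced": [len(p.produced) for p in profiles],
        }
    )
    counts: dict[str, list[int]] = {}
    for p in profiles:
        for met in p.consumed:
            counts.setdefault(met, [0, 0])[0] += 1
        for met in p.produced:
            counts.setdefault(met, [0, 0])[1] += 1
    per_metabolite = pd.DataFrame(
        {
            "metabolite_id": sorted(counts),
            "n_consumers": [counts[m][0] for m in sorted(counts)],
            "n_producers": [counts[m][1] for m in sorted(counts)],
        }
    )
    return per_microbe, per_metabolite
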