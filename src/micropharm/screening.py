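"""Pathogen-selective drug screening over drug-target interaction tables.

Two table dialects are screened.  Untyped tables (DrugBank-extract-like:
``drug_id``, ``inchikey``, ``target_id``) are joined to microbes through a
target-homology map; a drug passes the selective screen when it can hit at
least one pathogenic microbe's protein homolog and none of the commensal
microbes'.  Action-typed tables (STITCH-like: ``chemical_id``,
``inchikey``, ``microbe_id``, ``target_protein``, ``action``, ``is_drug``)
support four rules combining an activation/inhibition requirement on
pathogens with an exclusion on commensals.  Result sets from different
databases are intersected by normalized 27-character InChIKey.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "ScreenResult",
    "SCREEN_MODES",
    "read_drug_targets",
    "read_typed_interactions",
    "build_target_homology_map",
    "microbes_targeted_by_drug",
    "screen_selective",
    "screen_typed",
    "intersect_inchikey",
    "normalize_inchikey",
]

logger = logging.getLogger(__name__)

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: rule name -> (required action on pathogens, excluded action on commensals)
SCREEN_MODES: dict[str, tuple[str, str]] = {
    "act_not_act": ("activation", "activation"),
    "act_not_inh": ("activation", "inhibition"),
    "inh_not_inh": ("inhibition", "inhibition"),
    "inh_not_act": ("inhibition", "activation"),
}

_ACTIONS = ("inhibition", "activation", "other")


@dataclass(frozen=True)
class ScreenResult:
    """A screen rule's surviving identifier set plus the parameters used."""

    rule: str
    members: frozenset[str]
    params: dict = field(default_factory=dict)
    keys: dict[str, str | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def read_drug_targets(path: str | Path) -> pd.DataFrame:
    """Read an untyped drug-target TSV; (drug_id, target_id) pairs deduplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if not {"drug_id", "target_id"} <= set(df.columns):
        raise ValueError(f"{path} needs columns drug_id, target_id (inchikey optional)")
    if "inchikey" not in df.columns:
        df["inchikey"] = ""
    return df.drop_duplicates(subset=["drug_id", "target_id"]).reset_index(drop=True)


def read_typed_interactions(path: str | Path) -> pd.DataFrame:
    """Read an action-typed chemical-protein TSV; unknown actions map to 'other'."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = {"chemical_id", "microbe_id", "target_protein", "action", "is_drug"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    if "inchikey" not in df.columns:
        df["inchikey"] = ""
    df["action"] = df["action"].str.strip().str.lower()
    df.loc[~df["action"].isin(_ACTIONS), "action"] = "other"
    df["is_drug"] = df["is_drug"].str.strip().str.lower().isin(("true", "1", "yes"))
    return df


def build_target_homology_map(hits, e_max: float) -> dict[str, set[str]]:
    """target_id -> microbes whose proteins have a homolog to it below ``e_max``."""
    if not (e_max > 0.0):
        raise ValueError("e_max must be positive")
    mapping: dict[str, set[str]] = {}
    for hit in hits:
        if hit.e_value < e_max:
            mapping.setdefault(hit.subject_id, set()).add(hit.query_microbe)
    return mapping


def microbes_targeted_by_drug(
    drug_id: str,
    interactions: pd.DataFrame,
    homology_map: Mapping[str, Iterable[str]],
) -> set[str]:
    """Union of microbes reachable from the drug's targets through homology."""
    targets = interactions.loc[interactions["drug_id"] == drug_id, "target_id"]
    if targets.empty:
        raise KeyError(f"drug {drug_id!r} absent from interaction table")
    reached: set[str] = set()
    for target in targets:
        reached.update(homology_map.get(target, ()))
    return reached


def _check_disjoint(pathogenic: set[str], commensal: set[str]) -> None:
    overlap = pathogenic & commensal
    if overlap:
        raise ValueError(f"pathogenic and commensal sets overlap: {sorted(overlap)[:5]}")


def screen_selective(
    interactions: pd.DataFrame,
    homology_map: Mapping[str, Iterable[str]],
    pathogenic: Iterable[str],
    commensal: Iterable[str],
) -> ScreenResult:
    """Drugs that can hit >=1 pathogenic microbe and no commensal microbe."""
    pathogenic, commensal = set(pathogenic), set(commensal)
    _check_disjoint(pathogenic, commensal)
    keys: dict[str, str | None] = {}
    kept: set[str] = set()
    for drug_id, group in interactions.groupby("drug_id", sort=False):
        reached: set[str] = set()
        for target in group["target_id"]:
            reached.update(homology_map.get(target, ()))
        if reached & pathogenic and not reached & commensal:
            kept.add(str(drug_id))
            ik = next((k for k in group.get("inchikey", pd.Series(dtype=str)) if k), None)
            keys[str(drug_id)] = ik
    return ScreenResult(
        rule="selective",
        members=frozenset(kept),
        params={"n_pathogenic": len(pathogenic), "n_commensal": len(commensal)},
        keys=keys,
    )


def screen_typed(
    typed: pd.DataFrame,
    mode: str,
    pathogenic: Iterable[str],
    commensal: Iterable[str],
    drugs_only: bool = True,
) -> ScreenResult:
    """Apply one of the four action-typed rules.

    ``mode`` names the rule as <required>_not_<excluded>: the chemical must
    have at least one interaction of the required action type on a
    pathogenic microbe and none of the excluded type on commensal microbes.
    Actions outside inhibition/activation never satisfy either side.  With
    ``drugs_only`` non-drug chemicals are dropped from the result.
    """
    if mode not in SCREEN_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(SCREEN_MODES)}")
    pathogenic, commensal = set(pathogenic), set(commensal)
    _check_disjoint(pathogenic, commensal)
    required, excluded = SCREEN_MODES[mode]

    kept: set[str] = set()
    keys: dict[str, str | None] = {}
    for chem_id, group in typed.groupby("chemical_id", sort=False):
        if drugs_only and not group["is_drug"].any():
            continue
        hits_required = (
            (group["action"] == required) & group["microbe_id"].isin(pathogenic)
        ).any()
        hits_excluded = (
            (group["action"] == excluded) & group["microbe_id"].isin(commensal)
        ).any()
        if hits_required and not hits_excluded:
            kept.add(str(chem_id))
            ik = next((k for k in group.get("inchikey", pd.Series(dtype=str)) if k), None)
            keys[str(chem_id)] = ik
    return ScreenResult(
        rule=mode,
        members=frozenset(kept),
        params={
            "drugs_only": drugs_only,
            "n_pathogenic": len(pathogenic),
            "n_commensal": len(commensal),
        },
        keys=keys,
    )


def normalize_inchikey(key: str | None) -> str | None:
    """Trim and upper-case; return None for missing or malformed keys."""
    if key is None:
        return None
    key = key.strip().upper()
    if not key:
        return None
    if not INCHIKEY_RE.match(key):
        logger.warning("dropping malformed InChIKey %r", key)
        return None
    return key


def intersect_inchikey(result_a: ScreenResult, result_b: ScreenResult) -> ScreenResult:
    """Shared chemistry of two screens: the normalized InChIKeys present in both.

    Members lacking a valid key are dropped; the counts of dropped members
    are logged and recorded in the result parameters.
    """
    sets = []
    dropped = []
    for res in (result_a, result_b):
        valid = {
            norm
            for member in res.members
            if (norm := normalize_inchikey(res.keys.get(member))) is not None
        }
        n_dropped = len(res.members) - sum(
            1 for m in res.members if normalize_inchikey(res.keys.get(m)) is not None
        )
        if n_dropped:
            logger.warning("%s: dropped %d members without a valid InChIKey", res.rule, n_dropped)
        sets.append(valid)
        dropped.append(n_dropped)
    shared = frozenset(sets[0] & sets[1])
    return ScreenResult(
        rule=f"intersect({result_a.rule},{result_b.rule})",
        members=shared,
        params={"dropped_a": dropped[0], "dropped_b": dropped[1]},
        keys={k: k for k in shared},
    )
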