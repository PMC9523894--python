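"""Synthetic scenario generators with planted, recoverable structure.

Every downstream stage of the pipeline can be exercised without external
databases: the generators emit the exact table dialects the other modules
consume, alongside the planted ground truth and a JSON parameter sidecar.

The profile generator emulates a guild-structured gut community.  Each
guild is a set of metabolically identical species; guilds of the same
health class are chained by cross-feeding (each guild consumes the waste
block its in-class feeder secretes and re-exports a waste block of its
own), while guilds of opposite classes share a contested, diet-derived
metabolite block that nobody produces.  Under the difference aggregation
rule this plants clean positive edges along in-class trophic chains, clean
negative edges across classes, and the structurally unavoidable moderate
within-guild competition (identical consumption implies negative extent 1).
The recoverable signal is therefore exactly the balance-theoretic one:
friends-of-friends along cross-feeding chains share a label, enemies across
the contested diet do not.
"""

from __future__ import annotations

import json
import string
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import MetaboliteProfile, write_labels, write_profiles

__all__ = [
    "GuildSpec",
    "ProfileScenario",
    "ScreenScenario",
    "AnnotationScenario",
    "default_cross_feed",
    "gen_profiles",
    "gen_screen_scenario",
    "gen_annotation_scenario",
    "gen_homology_scenario",
]


@dataclass(frozen=True)
class GuildSpec:
    """One guild: its pools, size, health label and observed-label fraction."""

    guild_id: int
    size: int
    consumption_pool: frozenset[str]
    production_pool: frozenset[str]
    label: int
    labeled_fraction: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("guild size must be >= 1")
        if self.label not in (1, -1):
            raise ValueError("guild label must be +1 or -1")
        if not (0.0 <= self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must lie in [0, 1]")


@dataclass
class ProfileScenario:
    """Profiles plus planted truth for the network/annotation stages."""

    profiles: list[MetaboliteProfile]
    true_labels: dict[str, int]
    observed_labels: dict[str, int]
    guild_of: dict[str, int]
    universe: tuple[str, ...]
    params: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "profiles": out_dir / "profiles.tsv",
            "labels_true": out_dir / "labels_true.tsv",
            "labels_observed": out_dir / "labels_observed.tsv",
            "sidecar": out_dir / "profile_scenario.json",
        }
        write_profiles(self.profiles, paths["profiles"])
        write_labels(self.true_labels, paths["labels_true"])
        write_labels(self.observed_labels, paths["labels_observed"])
        paths["sidecar"].write_text(
            json.dumps({"params": self.params, "guild_of": self.guild_of}, indent=2)
        )
        return paths


def default_cross_feed(n_guilds: int) -> list[tuple[int, int]]:
    """Directed cross-feeding cycles within each half (label class) of the guilds."""
    half = (n_guilds + 1) // 2
    pairs: list[tuple[int, int]] = []
    for lo, hi in ((0, half), (half, n_guilds)):
        size = hi - lo
        if size >= 2:
            pairs.extend((lo + i, lo + (i + 1) % size) for i in range(size))
    return pairs


def gen_profiles(
    n_guilds: int = 6,
    guild_size: int = 15,
    pool_size: int = 12,
    cross_feed: Sequence[tuple[int, int]] | None = None,
    noise_rate: float = 0.05,
    labeled_fraction: float = 0.3,
    seed: int = 0,
    contested_size: int = 4,
) -> ProfileScenario:
    """Generate guild-structured metabolite profiles with planted labels.

    Guilds ``0 .. ceil(n/2)-1`` are commensal (+1), the rest pathogenic
    (-1).  ``pool_size`` is the per-guild waste-block size, and
    ``contested_size`` the size of the diet block each commensal guild
    shares with its paired pathogenic guild.  Each membership bit of every
    member's consumption and production set is flipped independently with
    probability ``noise_rate``; per guild, ``round(labeled_fraction *
    guild_size)`` members keep an observed label.
    """
    if not (0.0 <= noise_rate <= 1.0):
        raise ValueError("noise_rate must lie in [0, 1]")
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must lie in [0, 1]")
    if n_guilds < 1 or guild_size < 1 or pool_size < 1 or contested_size < 0:
        raise ValueError("inconsistent guild/pool sizes")
    rng = np.random.default_rng(seed)
    cross_feed = list(cross_feed) if cross_feed is not None else default_cross_feed(n_guilds)
    for producer, consumer in cross_feed:
        if not (0 <= producer < n_guilds and 0 <= consumer < n_guilds):
            raise ValueError(f"cross_feed pair {(producer, consumer)} out of range")

    half = (n_guilds + 1) // 2
    labels_per_guild = [1 if g < half else -1 for g in range(n_guilds)]

    waste = {g: frozenset(f"w{g}_{i}" for i in range(pool_size)) for g in range(n_guilds)}
    contested: dict[int, frozenset[str]] = {}
    n_pairs = min(half, n_guilds - half)
    for i in range(n_pairs):
        block = frozenset(f"s{i}_{j}" for j in range(contested_size))
        contested[i] = block
        contested[half + i] = block

    feeders: dict[int, set[int]] = {g: set() for g in range(n_guilds)}
    for producer, consumer in cross_feed:
        if producer != consumer:
            feeders[consumer].add(producer)

    guilds: list[GuildSpec] = []
    for g in range(n_guilds):
        imported: frozenset[str] = frozenset().union(*(waste[f] for f in feeders[g])) if feeders[g] else frozenset()
        diet = contested.get(g, frozenset())
        if feeders[g]:
            consumption = imported | diet
            production = imported | waste[g]
        else:
            # isolated guild: a closed, self-recycling community
            consumption = waste[g] | diet
            production = waste[g]
        guilds.append(
            GuildSpec(
                guild_id=g,
                size=guild_size,
                consumption_pool=consumption,
                production_pool=production,
                label=labels_per_guild[g],
                labeled_fraction=labeled_fraction,
            )
        )

    universe = tuple(sorted(frozenset().union(*(g.consumption_pool | g.production_pool for g in guilds))))
    met_index = {met: i for i, met in enumerate(universe)}

    profiles: list[MetaboliteProfile] = []
    true_labels: dict[str, int] = {}
    observed_labels: dict[str, int] = {}
    guild_of: dict[str, int] = {}
    for spec in guilds:
        base_c = np.zeros(len(universe), dtype=bool)
        base_p = np.zeros(len(universe), dtype=bool)
        base_c[[met_index[m] for m in spec.consumption_pool]] = True
        base_p[[met_index[m] for m in spec.production_pool]] = True
        member_ids = [f"g{spec.guild_id}_m{j}" for j in range(spec.size)]
        for member in member_ids:
            flips_c = rng.random(len(universe)) < noise_rate
            flips_p = rng.random(len(universe)) < noise_rate
            consumed = np.logical_xor(base_c, flips_c)
            produced = np.logical_xor(base_p, flips_p)
            profiles.append(
                MetaboliteProfile(
                    member,
                    frozenset(universe[i] for i in np.flatnonzero(consumed)),
                    frozenset(universe[i] for i in np.flatnonzero(produced)),
                )
            )
            true_labels[member] = spec.label
            guild_of[member] = spec.guild_id
        n_observed = int(round(spec.labeled_fraction * spec.size))
        for member in rng.choice(member_ids, size=n_observed, replace=False):
            observed_labels[str(member)] = spec.label

    params = {
        "generator": "gen_profiles",
        "n_guilds": n_guilds,
        "guild_size": guild_size,
        "pool_size": pool_size,
        "contested_size": contested_size,
        "cross_feed": [list(p) for p in cross_feed],
        "noise_rate": noise_rate,
        "labeled_fraction": labeled_fraction,
        "seed": int(seed),
    }
    return ProfileScenario(profiles, true_labels, observed_labels, guild_of, universe, params)


# ---------------------------------------------------------------------------
# drug screening scenario
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list(string.ascii_uppercase))


def _random_inchikey(rng: np.random.Generator) -> str:
    blocks = ["".join(rng.choice(_ALPHABET, 14)), "".join(rng.choice(_ALPHABET, 10)), "N"]
    return "-".join(blocks)


@dataclass
class ScreenScenario:
    """Typed and untyped drug-target tables with planted selective drugs."""

    typed_interactions: pd.DataFrame
    drug_targets: pd.DataFrame
    homology_map: dict[str, set[str]]
    pathogenic: set[str]
    commensal: set[str]
    inchikeys: dict[str, str]
    planted_inh_not_inh: set[str]
    planted_selective: set[str]
    params: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "typed": out_dir / "typed_interactions.tsv",
            "drug_targets": out_dir / "drug_targets.tsv",
            "homology_map": out_dir / "target_homology_map.tsv",
            "sidecar": out_dir / "screen_scenario.json",
        }
        self.typed_interactions.to_csv(paths["typed"], sep="\t", index=False)
        self.drug_targets.to_csv(paths["drug_targets"], sep="\t", index=False)
        rows = [
            {"target_id": t, "microbe_id": m}
            for t, ms in sorted(self.homology_map.items())
            for m in sorted(ms)
        ]
        pd.DataFrame(rows, columns=["target_id", "microbe_id"]).to_csv(
            paths["homology_map"], sep="\t", index=False
        )
        paths["sidecar"].write_text(
            json.dumps(
                {
                    "params": self.params,
                    "pathogenic": sorted(self.pathogenic),
                    "commensal": sorted(self.commensal),
                    "planted_inh_not_inh": sorted(self.planted_inh_not_inh),
                    "planted_selective": sorted(self.planted_selective),
                },
                indent=2,
            )
        )
        return paths


def gen_screen_scenario(
    n_pathogenic: int = 20,
    n_commensal: int = 10,
    n_drugs: int = 200,
    frac_pathogen_specific: float = 0.15,
    seed: int = 0,
) -> ScreenScenario:
    """Build drug-target tables in which a known drug subset is the right answer.

    The planted drugs inhibit only targets whose homologs live in pathogenic
    microbes; decoys inhibit commensal targets, merely activate pathogenic
    targets, hit nothing, or are non-drug chemicals.  By construction
    ``screen_typed(..., mode="inh_not_inh", drugs_only=True)`` returns
    exactly ``planted_inh_not_inh``, and the untyped selective screen
    returns exactly ``planted_selective``.
    """
    if not (0.0 <= frac_pathogen_specific <= 1.0):
        raise ValueError("frac_pathogen_specific must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pathogenic = {f"path{i}" for i in range(n_pathogenic)}
    commensal = {f"comm{i}" for i in range(n_commensal)}

    homology_map: dict[str, set[str]] = {}
    targets_of: dict[str, list[str]] = {}
    for microbe in sorted(pathogenic | commensal):
        targets_of[microbe] = []
        for t in range(3):
            target = f"t_{microbe}_{t}"
            homology_map[target] = {microbe}
            targets_of[microbe].append(target)
    # a few promiscuous targets with homologs in both classes
    for i in range(3):
        target = f"t_shared_{i}"
        homology_map[target] = {
            str(rng.choice(sorted(pathogenic))),
            str(rng.choice(sorted(commensal))),
        }

    n_planted = int(round(frac_pathogen_specific * n_drugs))
    chem_ids = [f"chem{i:04d}" for i in range(n_drugs)]
    inchikeys = {chem: _random_inchikey(rng) for chem in chem_ids}
    planted = set(chem_ids[:n_planted])

    path_targets = [t for m in sorted(pathogenic) for t in targets_of[m]]
    comm_targets = [t for m in sorted(commensal) for t in targets_of[m]]

    typed_rows: list[dict] = []
    planted_selective: set[str] = set()

    def add(chem: str, target: str, action: str, is_drug: bool) -> None:
        microbes = homology_map.get(target, set())
        for microbe in sorted(microbes) or ["unmapped"]:
            typed_rows.append(
                {
                    "chemical_id": chem,
                    "inchikey": inchikeys[chem],
                    "microbe_id": microbe,
                    "target_protein": target,
                    "action": action,
                    "is_drug": is_drug,
                }
            )

    for i, chem in enumerate(chem_ids):
        if chem in planted:
            for target in rng.choice(path_targets, size=rng.integers(1, 4), replace=False):
                add(chem, str(target), "inhibition", True)
            planted_selective.add(chem)
            continue
        pattern = i % 4
        if pattern == 0:  # inhibits both classes
            add(chem, str(rng.choice(path_targets)), "inhibition", True)
            add(chem, str(rng.choice(comm_targets)), "inhibition", True)
        elif pattern == 1:  # commensal-only inhibitor
            add(chem, str(rng.choice(comm_targets)), "inhibition", True)
        elif pattern == 2:  # pathogen-only activator (drug): fails inh screens,
            add(chem, str(rng.choice(path_targets)), "activation", True)
            planted_selective.add(chem)  # but survives the untyped selective screen
        else:  # non-drug pathogen-only inhibitor
            add(chem, str(rng.choice(path_targets)), "inhibition", False)
            planted_selective.add(chem)

    typed = pd.DataFrame(
        typed_rows,
        columns=["chemical_id", "inchikey", "microbe_id", "target_protein", "action", "is_drug"],
    )
    drug_targets = (
        typed[["chemical_id", "inchikey", "target_protein"]]
        .drop_duplicates()
        .rename(columns={"chemical_id": "drug_id", "target_protein": "target_id"})
        .reset_index(drop=True)
    )
    params = {
        "generator": "gen_screen_scenario",
        "n_pathogenic": n_pathogenic,
        "n_commensal": n_commensal,
        "n_drugs": n_drugs,
        "frac_pathogen_specific": frac_pathogen_specific,
        "seed": int(seed),
    }
    return ScreenScenario(
        typed_interactions=typed,
        drug_targets=drug_targets,
        homology_map=homology_map,
        pathogenic=pathogenic,
        commensal=commensal,
        inchikeys=inchikeys,
        planted_inh_not_inh=planted,
        planted_selective=planted_selective,
        params=params,
    )


# ---------------------------------------------------------------------------
# category-annotation scenario
# ---------------------------------------------------------------------------


@dataclass
class AnnotationScenario:
    """Item-category annotations with one planted enriched category."""

    annotations: dict[str, set[str]]
    study: set[str]
    background: set[str]
    planted_category: str | None
    params: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotations": out_dir / "annotations.tsv",
            "study": out_dir / "study_items.tsv",
            "sidecar": out_dir / "annotation_scenario.json",
        }
        rows = [
            {"item_id": item, "category_code": cat, "scheme": "flat"}
            for item, cats in sorted(self.annotations.items())
            for cat in sorted(cats)
        ]
        pd.DataFrame(rows, columns=["item_id", "category_code", "scheme"]).to_csv(
            paths["annotations"], sep="\t", index=False
        )
        pd.DataFrame({"item_id": sorted(self.study)}).to_csv(
            paths["study"], sep="\t", index=False
        )
        paths["sidecar"].write_text(
            json.dumps(
                {"params": self.params, "planted_category": self.planted_category},
                indent=2,
            )
        )
        return paths


def gen_annotation_scenario(
    n_items: int = 1000,
    n_categories: int = 40,
    enriched_category_odds: float = 50.0,
    study_size: int = 50,
    seed: int = 0,
    base_rate: float = 0.05,
) -> AnnotationScenario:
    """Annotate items at a base rate; boost one category's odds on study items.

    With ``enriched_category_odds == 1`` nothing is planted (null scenario).
    """
    if enriched_category_odds < 1.0:
        raise ValueError("enriched_category_odds must be >= 1")
    if study_size > n_items:
        raise ValueError("study_size cannot exceed n_items")
    rng = np.random.default_rng(seed)
    items = [f"item{i:04d}" for i in range(n_items)]
    categories = [f"CAT{j:03d}" for j in range(n_categories)]
    study = set(str(s) for s in rng.choice(items, size=study_size, replace=False))

    base_odds = base_rate / (1.0 - base_rate)
    boosted = base_odds * enriched_category_odds
    boosted_rate = boosted / (1.0 + boosted)
    planted = categories[0] if enriched_category_odds > 1.0 else None

    annotations: dict[str, set[str]] = {item: set() for item in items}
    for cat in categories:
        for item in items:
            rate = boosted_rate if (cat == planted and item in study) else base_rate
            if rng.random() < rate:
                annotations[item].add(cat)

    params = {
        "generator": "gen_annotation_scenario",
        "n_items": n_items,
        "n_categories": n_categories,
        "enriched_category_odds": enriched_category_odds,
        "study_size": study_size,
        "base_rate": base_rate,
        "seed": int(seed),
    }
    return AnnotationScenario(
        annotations=annotations,
        study=study,
        background=set(items),
        planted_category=planted,
        params=params,
    )


# ---------------------------------------------------------------------------
# homology-hit scenario (druggability survey input)
# ---------------------------------------------------------------------------


def gen_homology_scenario(
    n_microbes: int = 8,
    proteins_per_microbe: int = 60,
    frac_close: float = 0.15,
    frac_distant: float = 0.30,
    seed: int = 0,
    database: str = "target-db-A",
) -> tuple[pd.DataFrame, dict[str, str], dict[str, int]]:
    """Emit a BLAST-tabular hit table with a two-population e-value structure.

    A ``frac_close`` share of proteins get close homologs (e-value around
    1e-80) and a further ``frac_distant`` share distant ones (around 1e-15),
    so the fraction-versus-threshold curve bends near the close/distant
    boundary.  Returns ``(hits_table, query_to_microbe, inventory)`` where
    ``hits_table`` has the 12 standard BLAST outfmt-6 columns.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    query_to_microbe: dict[str, str] = {}
    inventory: dict[str, int] = {}
    for m in range(n_microbes):
        microbe = f"mic{m}"
        inventory[microbe] = proteins_per_microbe
        for p in range(proteins_per_microbe):
            query = f"{microbe}_p{p}"
            query_to_microbe[query] = microbe
            u = rng.random()
            if u < frac_close:
                log10_e = -rng.uniform(60.0, 120.0)
            elif u < frac_close + frac_distant:
                log10_e = -rng.uniform(5.0, 30.0)
            else:
                continue  # no homolog reported
            evalue = 10.0 ** log10_e
            rows.append(
                {
                    "qseqid": query,
                    "sseqid": f"target_{rng.integers(0, 500):04d}",
                    "pident": round(float(rng.uniform(30, 99)), 2),
                    "length": int(rng.integers(80, 400)),
                    "mismatch": int(rng.integers(0, 50)),
                    "gapopen": int(rng.integers(0, 5)),
                    "qstart": 1,
                    "qend": int(rng.integers(80, 400)),
                    "sstart": 1,
                    "send": int(rng.integers(80, 400)),
                    "evalue": evalue,
                    "bitscore": round(float(-log10_e * 2.0 + rng.uniform(40, 60)), 1),
                }
            )
    hits = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return hits, query_to_microbe, inventory
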