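"""Stage orchestration: validated configuration, manifests, reproducible runs.

Each stage is individually re-runnable and chainable: it reads the tables
earlier stages (or the user) produced, writes its outputs into
``<out_dir>/<stage>/`` together with a ``manifest.json`` recording the
parameters, the SHA-256 digests of its inputs, the package version and the
seed.  ``run_pipeline`` chains the simulate -> build-network -> annotate ->
loocv -> screen -> enrich path end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .druggability import read_homology_table, threshold_curve, elbow_point
from .enrichment import CategoryAnnotation, enrich, report_significant
from .network import SignedNetwork, build_network
from .profiles import read_labels, read_profiles
from .screening import (
    SCREEN_MODES,
    ScreenResult,
    intersect_inchikey,
    read_drug_targets,
    read_typed_interactions,
    screen_selective,
    screen_typed,
)
from .srwr import SRWRParams, annotate_all, loocv
from .synthetic import gen_annotation_scenario, gen_homology_scenario, gen_profiles, gen_screen_scenario

__all__ = ["PipelineConfig", "run_stage", "run_pipeline", "STAGES"]

STAGES = ("simulate", "build-network", "annotate", "loocv", "druggability", "screen", "enrich")


def _from_dict(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SrwrConfig:
    c: float = 0.15
    beta: float = 0.5
    gamma: float = 0.5
    tol: float = 1e-9
    max_iter: int = 1000
    tie_rule: str = "to_negative"
    reverse: bool = False

    def params(self) -> SRWRParams:
        return SRWRParams(
            c=self.c, beta=self.beta, gamma=self.gamma, tol=self.tol, max_iter=int(self.max_iter)
        )


@dataclass
class SimulateConfig:
    n_guilds: int = 6
    guild_size: int = 15
    pool_size: int = 12
    contested_size: int = 4
    noise_rate: float = 0.05
    labeled_fraction: float = 0.3
    n_pathogenic: int = 20
    n_commensal: int = 10
    n_drugs: int = 200
    frac_pathogen_specific: float = 0.15
    n_items: int = 1000
    n_categories: int = 40
    enriched_category_odds: float = 50.0
    study_size: int = 50


@dataclass
class ScreenConfig:
    modes: list[str] = field(default_factory=lambda: list(SCREEN_MODES))
    drugs_only: bool = True
    evalue_threshold: float = 1e-4
    intersect: bool = True


@dataclass
class EnrichConfig:
    alpha: float = 0.05
    scheme: str = "flat"


@dataclass
class DruggabilityConfig:
    database: str = "target-db-A"
    e_max: float = 1e-4
    neg_log10_min: int = 4
    neg_log10_max: int = 120
    neg_log10_step: int = 4


@dataclass
class PipelineConfig:
    """Validated configuration for all stages; unknown keys are rejected."""

    out_dir: str = "results/run"
    seed: int = 0
    srwr: SrwrConfig = field(default_factory=SrwrConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    druggability: DruggabilityConfig = field(default_factory=DruggabilityConfig)
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sub = {
            "srwr": SrwrConfig,
            "simulate": SimulateConfig,
            "screen": ScreenConfig,
            "enrich": EnrichConfig,
            "druggability": DruggabilityConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in sub:
                kwargs[key] = _from_dict(sub[key], value or {}, key)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def path(self, key: str, default: Path | None = None) -> Path:
        if key in self.paths:
            return Path(self.paths[key])
        if default is not None:
            return default
        raise FileNotFoundError(f"no input path configured for {key!r}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_manifest(stage_dir: Path, stage: str, config: PipelineConfig, inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "params": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(p) for p in outputs if Path(p).exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    d = Path(config.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} not found at {path}; run the producing stage first")
    return path


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "simulate")
    sim = config.simulate
    profile_sc = gen_profiles(
        n_guilds=sim.n_guilds,
        guild_size=sim.guild_size,
        pool_size=sim.pool_size,
        contested_size=sim.contested_size,
        noise_rate=sim.noise_rate,
        labeled_fraction=sim.labeled_fraction,
        seed=config.seed,
    )
    outputs = dict(profile_sc.write(stage_dir))
    screen_sc = gen_screen_scenario(
        n_pathogenic=sim.n_pathogenic,
        n_commensal=sim.n_commensal,
        n_drugs=sim.n_drugs,
        frac_pathogen_specific=sim.frac_pathogen_specific,
        seed=config.seed + 1,
    )
    outputs.update(screen_sc.write(stage_dir))
    ann_sc = gen_annotation_scenario(
        n_items=sim.n_items,
        n_categories=sim.n_categories,
        enriched_category_odds=sim.enriched_category_odds,
        study_size=sim.study_size,
        seed=config.seed + 2,
    )
    outputs.update(ann_sc.write(stage_dir))
    hits, query_map, inventory = gen_homology_scenario(seed=config.seed + 3)
    homology_path = stage_dir / "homology_hits.blast6.tsv"
    hits.to_csv(homology_path, sep="\t", index=False, header=False)
    pd.DataFrame(
        sorted(query_map.items()), columns=["query_protein", "microbe_id"]
    ).to_csv(stage_dir / "query_to_microbe.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(inventory.items()), columns=["microbe_id", "n_proteins"]
    ).to_csv(stage_dir / "protein_inventory.tsv", sep="\t", index=False)
    outputs["homology"] = homology_path
    outputs["query_map"] = stage_dir / "query_to_microbe.tsv"
    outputs["inventory"] = stage_dir / "protein_inventory.tsv"
    _write_manifest(stage_dir, "simulate", config, [], list(outputs.values()))
    return outputs


def _simulated(config: PipelineConfig, name: str) -> Path:
    return Path(config.out_dir) / "simulate" / name


def _stage_build_network(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "build-network")
    profiles_path = _require(
        config.path("profiles", _simulated(config, "profiles.tsv")), "profile table"
    )
    labels_path = config.path("labels", _simulated(config, "labels_observed.tsv"))
    profiles = read_profiles(profiles_path)
    labels = read_labels(labels_path) if labels_path.exists() else None
    network = build_network(profiles, labels)
    graphml = stage_dir / "network.graphml"
    edgelist = stage_dir / "network_edges.tsv"
    network.to_graphml(graphml)
    network.to_edgelist(edgelist)
    inputs = [profiles_path] + ([labels_path] if labels_path.exists() else [])
    _write_manifest(stage_dir, "build-network", config, inputs, [graphml, edgelist])
    return {"graphml": graphml, "edgelist": edgelist}


def _load_network(config: PipelineConfig) -> tuple[SignedNetwork, list[Path]]:
    graphml = _require(
        config.path("network", Path(config.out_dir) / "build-network" / "network.graphml"),
        "network GraphML",
    )
    return SignedNetwork.from_graphml(graphml), [graphml]


def _load_label_table(config: PipelineConfig) -> tuple[dict[str, int], Path]:
    labels_path = config.path("labels", _simulated(config, "labels_observed.tsv"))
    if not labels_path.exists():
        raise FileNotFoundError(
            f"label table not found at {labels_path}; provide paths.labels or run simulate"
        )
    return read_labels(labels_path), labels_path


def _stage_annotate(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "annotate")
    network, inputs = _load_network(config)
    labels, labels_path = _load_label_table(config)
    params = config.srwr.params()
    predictions = annotate_all(
        network, labels, params, tie_rule=config.srwr.tie_rule, reverse=config.srwr.reverse
    )
    out = stage_dir / "predictions.tsv"
    header = (
        f"# c={params.c} beta={params.beta} gamma={params.gamma} tol={params.tol}"
        f" tie_rule={config.srwr.tie_rule} labels_digest={_sha256(labels_path)}\n"
    )
    with open(out, "w", encoding="utf-8") as handle:
        handle.write(header)
        handle.write("microbe_id\ts_pos\ts_neg\tpredicted_label\n")
        for pred in predictions:
            handle.write(
                f"{pred.microbe_id}\t{pred.s_pos:.10g}\t{pred.s_neg:.10g}\t{pred.predicted}\n"
            )
    counts = {
        "n_predicted_commensal": sum(p.predicted == 1 for p in predictions),
        "n_predicted_pathogenic": sum(p.predicted == -1 for p in predictions),
    }
    summary = stage_dir / "prediction_summary.json"
    summary.write_text(json.dumps(counts, indent=2))
    _write_manifest(stage_dir, "annotate", config, inputs + [labels_path], [out, summary])
    return {"predictions": out, "summary": summary}


def _stage_loocv(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "loocv")
    network, inputs = _load_network(config)
    labels, labels_path = _load_label_table(config)
    summary = loocv(
        network,
        labels,
        config.srwr.params(),
        tie_rule=config.srwr.tie_rule,
        reverse=config.srwr.reverse,
    )
    out = stage_dir / "loocv.json"
    out.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    _write_manifest(stage_dir, "loocv", config, inputs + [labels_path], [out])
    return {"loocv": out}


def _stage_druggability(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "druggability")
    cfg = config.druggability
    hits_path = _require(
        config.path("homology", _simulated(config, "homology_hits.blast6.tsv")), "homology table"
    )
    query_map_path = _require(
        config.path("query_map", _simulated(config, "query_to_microbe.tsv")), "query map"
    )
    inventory_path = _require(
        config.path("inventory", _simulated(config, "protein_inventory.tsv")), "protein inventory"
    )
    query_map = dict(
        pd.read_csv(query_map_path, sep="\t", dtype=str).itertuples(index=False, name=None)
    )
    inv_df = pd.read_csv(inventory_path, sep="\t")
    inventory = dict(zip(inv_df["microbe_id"].astype(str), inv_df["n_proteins"].astype(int)))
    hits = read_homology_table(hits_path, cfg.database, query_map)
    thresholds = [
        10.0 ** (-x)
        for x in range(cfg.neg_log10_min, cfg.neg_log10_max + 1, cfg.neg_log10_step)
    ]
    curve = threshold_curve(hits, inventory, thresholds, cfg.database)
    curve_path = stage_dir / "threshold_curve.tsv"
    curve.to_csv(curve_path, sep="\t", index=False)
    from .druggability import druggability_fraction

    stats = druggability_fraction(hits, inventory, cfg.e_max, cfg.database)
    per_microbe = pd.DataFrame(
        [
            {
                "microbe_id": s.microbe_id,
                "database": s.database,
                "threshold": s.threshold,
                "n_proteins": s.n_proteins,
                "n_with_homolog": s.n_with_homolog,
                "fraction": s.fraction,
            }
            for s in stats
        ]
    )
    frac_path = stage_dir / "druggability_per_microbe.tsv"
    per_microbe.to_csv(frac_path, sep="\t", index=False)
    elbow_path = stage_dir / "elbow.json"
    elbow_path.write_text(json.dumps({"elbow_evalue": elbow_point(curve)}))
    _write_manifest(
        stage_dir,
        "druggability",
        config,
        [hits_path, query_map_path, inventory_path],
        [curve_path, frac_path, elbow_path],
    )
    return {"curve": curve_path, "per_microbe": frac_path, "elbow": elbow_path}


def _screen_labels(config: PipelineConfig) -> tuple[set[str], set[str], list[Path]]:
    sidecar = config.path("screen_sidecar", _simulated(config, "screen_scenario.json"))
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        return set(data["pathogenic"]), set(data["commensal"]), [sidecar]
    raise FileNotFoundError(
        f"screen label sets not found at {sidecar}; provide paths.screen_sidecar or run simulate"
    )


def _stage_screen(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "screen")
    typed_path = _require(
        config.path("typed", _simulated(config, "typed_interactions.tsv")), "typed interactions"
    )
    drug_targets_path = _require(
        config.path("drug_targets", _simulated(config, "drug_targets.tsv")), "drug-target table"
    )
    homology_map_path = _require(
        config.path("homology_map", _simulated(config, "target_homology_map.tsv")),
        "target homology map",
    )
    pathogenic, commensal, label_inputs = _screen_labels(config)
    typed = read_typed_interactions(typed_path)
    drug_targets = read_drug_targets(drug_targets_path)
    hom_df = pd.read_csv(homology_map_path, sep="\t", dtype=str)
    homology_map: dict[str, set[str]] = {}
    for row in hom_df.itertuples():
        homology_map.setdefault(row.target_id, set()).add(row.microbe_id)

    outputs: dict[str, Path] = {}
    results: dict[str, ScreenResult] = {}
    selective = screen_selective(drug_targets, homology_map, pathogenic, commensal)
    results["selective"] = selective
    for mode in config.screen.modes:
        results[mode] = screen_typed(
            typed, mode, pathogenic, commensal, drugs_only=config.screen.drugs_only
        )
    if config.screen.intersect and "inh_not_inh" in results:
        results["intersection"] = intersect_inchikey(selective, results["inh_not_inh"])
    for name, res in results.items():
        out = stage_dir / f"screen_{name}.tsv"
        with open(out, "w", encoding="utf-8") as handle:
            handle.write(f"# rule={res.rule} params={json.dumps(res.params, sort_keys=True)}\n")
            handle.write("member\tinchikey\n")
            for member in sorted(res.members):
                handle.write(f"{member}\t{res.keys.get(member) or ''}\n")
        outputs[name] = out
    counts = {name: len(res.members) for name, res in results.items()}
    summary = stage_dir / "screen_summary.json"
    summary.write_text(json.dumps(counts, indent=2, sort_keys=True))
    outputs["summary"] = summary
    _write_manifest(
        stage_dir,
        "screen",
        config,
        [typed_path, drug_targets_path, homology_map_path] + label_inputs,
        list(outputs.values()),
    )
    return outputs


def _stage_enrich(config: PipelineConfig) -> dict[str, Path]:
    stage_dir = _stage_dir(config, "enrich")
    ann_path = _require(
        config.path("annotations", _simulated(config, "annotations.tsv")), "annotation table"
    )
    study_path = _require(
        config.path("study", _simulated(config, "study_items.tsv")), "study item list"
    )
    ann_df = pd.read_csv(ann_path, sep="\t", dtype=str)
    mapping: dict[str, frozenset[str]] = {}
    grouped: dict[str, set[str]] = {}
    for row in ann_df.itertuples():
        grouped.setdefault(row.item_id, set()).add(row.category_code)
    mapping = {item: frozenset(cats) for item, cats in grouped.items()}
    annotations = CategoryAnnotation(mapping, scheme=config.enrich.scheme)
    study = set(pd.read_csv(study_path, sep="\t", dtype=str)["item_id"])
    background_path = config.path("background", Path("__missing__"))
    if background_path.exists():
        background = set(pd.read_csv(background_path, sep="\t", dtype=str)["item_id"])
        bg_inputs = [background_path]
    else:
        # default background: every annotated or study item in the scenario
        background = set(mapping) | study
        bg_inputs = []
    table = enrich(study, background, annotations)
    table_path = stage_dir / "enrichment.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    sig = report_significant(table, config.enrich.alpha)
    sig_path = stage_dir / "enrichment_significant.tsv"
    sig.to_csv(sig_path, sep="\t", index=False)
    _write_manifest(
        stage_dir, "enrich", config, [ann_path, study_path] + bg_inputs, [table_path, sig_path]
    )
    return {"table": table_path, "significant": sig_path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "build-network": _stage_build_network,
    "annotate": _stage_annotate,
    "loocv": _stage_loocv,
    "druggability": _stage_druggability,
    "screen": _stage_screen,
    "enrich": _stage_enrich,
}


def run_stage(name: str, config: PipelineConfig) -> dict[str, Path]:
    """Run one pipeline stage; outputs land in ``<out_dir>/<name>/``.

    On failure the stage directory's partial outputs are removed before the
    exception propagates.
    """
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    stage_dir = Path(config.out_dir) / name
    try:
        return _STAGE_FUNCS[name](config)
    except Exception:
        if stage_dir.exists():
            for child in stage_dir.iterdir():
                if child.is_file():
                    child.unlink()
        raise


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict[str, dict[str, Path]]:
    """Chain the requested stages in order under one configuration."""
    return {name: run_stage(name, config) for name in stages}
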