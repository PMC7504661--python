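"""End-to-end orchestration: upregulate -> TFs -> cluster -> cascades -> PF -> drugs.

``run_pipeline`` executes the full analysis from a single validated config
(YAML file or dict), writes every stage's output plus a manifest (seeds,
input checksums, per-stage row counts) into a run directory, and returns
the in-memory results.  Rerunning with the same config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from netsig import data_io, drug_mapping, impact_scoring, subgrouping, tf_activity
from netsig import upregulation as upreg
from netsig import upstream_signaling as upstream
from netsig.synthetic_data import SimulationConfig, SyntheticDataset, simulate_all, write_dataset

logger = logging.getLogger("netsig.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated run configuration with the pipeline's standard defaults."""

    seed: int = 0
    scale: str = "linear"
    alpha: float = 0.05
    fold_threshold: float = 2.0
    k: int = 3
    top_k: int = 3
    max_len: int = 12
    synergy_threshold: float = 8.0
    n_init: int = 10
    zero_variance: str = "error"
    mcmc: upreg.McmcSettings | None = None
    priors: upreg.PriorSpec = field(default_factory=upreg.PriorSpec)
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if self.k < 1 or self.top_k < 1 or self.max_len < 1 or self.n_init < 1:
            raise ValueError("k, top_k, max_len and n_init must be >= 1")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be linear or log2, got {self.scale!r}")
        if self.zero_variance not in ("error", "jitter"):
            raise ValueError("zero_variance must be 'error' or 'jitter'")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")
        if self.mcmc is None:
            self.mcmc = upreg.McmcSettings(seed=self.seed)


def load_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a YAML path or a plain mapping."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    raw = dict(raw or {})
    seed = int(raw.pop("seed", 0))
    kwargs: dict[str, Any] = {"seed": seed}
    for key in ("scale", "alpha", "fold_threshold", "k", "top_k", "max_len",
                "synergy_threshold", "n_init", "zero_variance"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "mcmc" in raw:
        m = dict(raw.pop("mcmc"))
        m.setdefault("seed", seed)
        kwargs["mcmc"] = upreg.McmcSettings(**m)
    if "priors" in raw:
        kwargs["priors"] = upreg.PriorSpec(**raw.pop("priors"))
    if "simulate" in raw:
        sim = dict(raw.pop("simulate") or {})
        sim.setdefault("seed", seed)
        tuple_fields = {f.name for f in fields(SimulationConfig)
                        if "tuple" in str(f.type)}
        for name in list(sim):
            if name in tuple_fields and isinstance(sim[name], list):
                sim[name] = tuple(sim[name])
        kwargs["simulate"] = SimulationConfig(**sim)
    if "inputs" in raw:
        kwargs["inputs"] = {k: str(v) for k, v in dict(raw.pop("inputs")).items()}
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    models: dict
    binary: pd.DataFrame
    pvalues: pd.DataFrame
    subgroups: subgrouping.SubgroupResult
    tf_report: dict
    cascades: dict[int, list]
    networks: dict[int, upstream.CoreSignalingNetwork]
    comparison: dict
    scores: dict[int, impact_scoring.PerturbationScores]
    ranked_genes: pd.DataFrame
    mapped_drugs: pd.DataFrame
    combinations: pd.DataFrame
    combination_targets: pd.DataFrame
    manifest: dict
    dataset: SyntheticDataset | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        dataset = simulate_all(config.simulate)
        input_paths = write_dataset(dataset, outdir / "inputs")
        return dataset, {k: Path(v) for k, v in input_paths.items() if Path(v).is_file()}
    paths = {k: Path(v) for k, v in (config.inputs or {}).items()}
    required = {"control", "tumor", "network", "pathways_dir", "drugs", "synergy"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"inputs config missing keys: {sorted(missing)}")
    dataset = SyntheticDataset(
        config=None,  # type: ignore[arg-type]
        control=data_io.read_expression_matrix(paths["control"], scale=config.scale, role="control"),
        tumor=data_io.read_expression_matrix(paths["tumor"], scale=config.scale, role="tumor"),
        network=data_io.read_regulatory_network(paths["network"]),
        pathways=data_io.read_pathway_dir(paths["pathways_dir"]),
        catalog=data_io.read_drug_catalog(paths["drugs"]),
        synergy=data_io.read_synergy_table(paths["synergy"]),
        truth=None,  # type: ignore[arg-type]
    )
    return dataset, {k: p for k, p in paths.items() if p.is_file()}


def run_pipeline(config: PipelineConfig | str | Path | Mapping[str, Any], outdir: str | Path) -> PipelineResult:
    """Execute every stage and write outputs + manifest under ``outdir``."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, input_files = _load_inputs(config, outdir)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "alpha": config.alpha,
        "fold_threshold": config.fold_threshold,
        "k": config.k,
        "top_k": config.top_k,
        "max_len": config.max_len,
        "synergy_threshold": config.synergy_threshold,
        "input_checksums": {k: _sha256(p) for k, p in sorted(input_files.items())},
        "stages": {},
    }

    def stage(name: str):
        logger.info("stage %s", name)
        return manifest["stages"].setdefault(name, {})

    # 1. up-regulation calls -------------------------------------------------
    st = stage("upregulate")
    calls, models = upreg.call_upregulated(
        dataset.control, dataset.tumor,
        priors=config.priors, settings=config.mcmc,
        fold_threshold=config.fold_threshold, alpha=config.alpha,
        zero_variance=config.zero_variance,
    )
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    st["rows"] = len(calls)
    st["genes_called_up"] = int(calls["up"].sum())
    st["nonconverged_models"] = sum(1 for m in models.values() if not m.converged)

    # 2. activated TFs -------------------------------------------------------
    st = stage("tf_activity")
    universe = set(dataset.control.genes)
    binary, pvalues = tf_activity.activation_matrix(calls, dataset.network, universe, alpha=config.alpha)
    binary.to_csv(outdir / "tf_binary.tsv", sep="\t", index_label="sample")
    pvalues.to_csv(outdir / "tf_pvalues.tsv", sep="\t", index_label="sample")
    st["activations"] = int(binary.values.sum())

    # 3. subgrouping ---------------------------------------------------------
    st = stage("subgrouping")
    result = subgrouping.kmodes_cluster(binary, k=config.k, n_init=config.n_init, seed=config.seed)
    report = subgrouping.subgroup_tf_report(result, binary)
    coords = subgrouping.project_profiles_2d(binary)
    coords.to_csv(outdir / "pca_coords.tsv", sep="\t", index_label="sample")
    groups_payload = {
        "k": result.k,
        "cost": result.cost,
        "labels": result.labels,
        "center_samples": {str(g): s for g, s in result.center_samples.items()},
        "group_tf_sets": {str(g): sorted(s) for g, s in result.group_tf_sets.items()},
        "shared_tfs": sorted(report["shared"]),
        "unique_tfs": {str(g): sorted(s) for g, s in report["unique"].items()},
    }
    (outdir / "groups.json").write_text(json.dumps(groups_payload, indent=1, sort_keys=True))
    st["group_sizes"] = {str(g): len(result.members(g)) for g in range(result.k)}

    # 4. upstream cascades ---------------------------------------------------
    st = stage("cascades")
    pathway_map = {pw.pathway_id: pw for pw in dataset.pathways}
    tumor_frame = dataset.tumor.to_frame()
    cascades: dict[int, list] = {}
    networks: dict[int, upstream.CoreSignalingNetwork] = {}
    probabilities: dict[int, dict[str, float]] = {}
    for g in range(result.k):
        center = result.center_samples[g]
        probs = {
            gene: float(upreg.gene_probability(models[gene], tumor_frame.at[gene, center]))
            for gene in dataset.tumor.genes
        }
        probabilities[g] = probs
        group_tfs = sorted(result.group_tf_sets[g])
        retained = upstream.extract_group_cascades(
            dataset.pathways, group_tfs, probs, top_k=config.top_k, max_len=config.max_len,
        )
        cascades[g] = retained
        if retained:
            networks[g] = upstream.build_core_network(retained, group_tfs, pathway_map)
    (outdir / "cascades.json").write_text(json.dumps(
        {str(g): [{"pathway": c.pathway_id, "nodes": list(c.nodes), "score": c.score}
                  for c in cs] for g, cs in cascades.items()},
        indent=1, sort_keys=True))
    st["retained_cascades"] = {str(g): len(cs) for g, cs in cascades.items()}

    # 5. perturbation factors ------------------------------------------------
    st = stage("impact")
    comparison = upstream.compare_groups(networks) if len(networks) >= 2 else {
        "shared": next(iter(networks.values())).genes if networks else set(),
        "unique_genes": {}, "unique_tfs": {},
    }
    scores: dict[int, impact_scoring.PerturbationScores] = {}
    for g, net in networks.items():
        deltaE = {n: probabilities[g].get(n, 0.0) for n in net.genes}
        scores[g] = impact_scoring.perturbation_factors(net.graph, deltaE)
        scores[g].as_series().rename("pf").to_csv(outdir / f"pf_group{g}.tsv", sep="\t", index_label="gene")
    ranked = impact_scoring.rank_genes(scores, set(comparison["shared"]))
    ranked.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
    st["shared_genes"] = len(comparison["shared"])

    # 6. drugs ---------------------------------------------------------------
    st = stage("drugs")
    merged = upstream.CoreSignalingNetwork()
    for g, net in networks.items():
        for node, data in net.graph.nodes(data=True):
            if node in merged.graph and merged.graph.nodes[node].get("role") == "tf":
                continue  # tf role wins on merge
            merged.graph.add_node(node, **data)
        for u, v, data in net.graph.edges(data=True):
            if not merged.graph.has_edge(u, v):
                merged.graph.add_edge(u, v, **data)
    mapped = drug_mapping.map_drugs(merged, dataset.catalog)
    combos = drug_mapping.filter_synergies(mapped, dataset.synergy, threshold=config.synergy_threshold)
    combo_targets = drug_mapping.rank_combination_targets(combos)
    mapped_out = mapped.copy()
    if len(mapped_out):
        mapped_out["targets"] = mapped_out["targets"].map(",".join)
        mapped_out["roles"] = mapped_out["roles"].map(",".join)
    mapped_out.to_csv(outdir / "mapped_drugs.tsv", sep="\t", index=False)
    combos_out = combos.copy()
    if len(combos_out):
        combos_out["targets1"] = combos_out["targets1"].map(",".join)
        combos_out["targets2"] = combos_out["targets2"].map(",".join)
    combos_out.to_csv(outdir / "combinations.tsv", sep="\t", index=False)
    combo_targets.to_csv(outdir / "combination_targets.tsv", sep="\t", index=False)
    drug_mapping.attach_drug_nodes(merged, mapped)
    data_io.write_core_network(merged.graph, outdir / "core_network.graphml",
                               outdir / "core_network_edges.tsv")
    for g, net in networks.items():
        data_io.write_core_network(net.graph, outdir / f"core_network_group{g}.graphml")
    st["mapped_drugs"] = len(mapped)
    st["validated_combinations"] = len(combos)

    manifest["output_checksums"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json"))
        if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        calls=calls, models=models, binary=binary, pvalues=pvalues,
        subgroups=result, tf_report=report, cascades=cascades, networks=networks,
        comparison=comparison, scores=scores, ranked_genes=ranked,
        mapped_drugs=mapped, combinations=combos, combination_targets=combo_targets,
        manifest=manifest, dataset=dataset if config.simulate is not None else dataset,
    )
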