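"""Synthetic pipeline inputs with planted ground truth.

The generator emulates, at desk scale, the statistical structure the
analysis assumes:

* per-gene approximately normal control expression (gene-level means and
  standard deviations drawn from configurable hyper-ranges),
* tumor samples organized into subgroups, each subgroup driven by its own
  set of "active" TFs whose target genes are shifted to ``planted_fold``
  times their control mean,
* a bipartite TF -> target regulatory network in which each planted active
  TF owns a disjoint target block (so planted enrichment is detectable) and
  decoy TFs draw targets from the remaining gene pool,
* directed signed pathway graphs, each containing exactly one planted
  start-node -> TF simple path plus decoy branches that never create a
  second start-to-TF route,
* a drug-target catalog partly aimed at pathway genes, and a combination
  screen in which a configurable fraction of pairs exceeds the synergy
  threshold of 8.

TF symbols appear as rows of the expression matrix (shifted in the groups
where the TF is active) so every cascade node carries an up-regulation
probability downstream.  All outputs are deterministic functions of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from netsig.data_io import (
    DrugTargetCatalog,
    ExpressionMatrix,
    PathwayGraph,
    RegulatoryNetwork,
    SynergyRecord,
    write_drug_catalog,
    write_expression_matrix,
    write_pathway_sif,
    write_regulatory_network,
    write_synergy_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_regulatory_network",
    "simulate_expression",
    "simulate_pathways",
    "simulate_drug_screen",
    "simulate_all",
    "write_dataset",
]

SYNERGY_CUTOFF = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator; defaults mirror the assumed
    data-generating process at reduced size (88 controls, 3 subgroups,
    >=2-fold planted shifts)."""

    n_normal: int = 88
    n_tumor: int = 60
    n_genes: int = 150
    n_tfs: int = 12
    targets_per_tf: tuple[int, int] = (8, 12)
    n_subgroups: int = 3
    active_tfs_per_group: int = 2
    # TFs active in EVERY subgroup (a common core, as real tumor cohorts
    # show); group-specific TFs come on top of these
    shared_active_tfs: int = 0
    planted_fold: float = 4.0
    noise_sd: float = 1.0
    tf_flip_noise: float = 0.0
    n_pathways: int | None = None
    cascade_length: tuple[int, int] = (3, 5)
    n_drugs: int = 20
    synergy_fraction: float = 0.2
    seed: int = 0
    mu_range: tuple[float, float] = (2.0, 10.0)
    sigma_range: tuple[float, float] = (0.5, 2.0)
    group_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        counts = dict(
            n_normal=self.n_normal, n_tumor=self.n_tumor, n_genes=self.n_genes,
            n_tfs=self.n_tfs, n_subgroups=self.n_subgroups,
            active_tfs_per_group=self.active_tfs_per_group, n_drugs=self.n_drugs,
        )
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not 0 <= self.tf_flip_noise <= 1:
            raise ValueError("tf_flip_noise must be a probability")
        if not 0 <= self.synergy_fraction <= 1:
            raise ValueError("synergy_fraction must be a probability")
        if self.planted_fold <= 2:
            raise ValueError("planted_fold must exceed 2 so planted genes clear the fold gate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.targets_per_tf
        if not (1 <= lo <= hi):
            raise ValueError("targets_per_tf must be a (lo, hi) range with 1 <= lo <= hi")
        lo, hi = self.cascade_length
        if not (2 <= lo <= hi):
            raise ValueError("cascade_length must be a (lo, hi) edge-count range with lo >= 2")
        if self.shared_active_tfs < 0:
            raise ValueError("shared_active_tfs must be >= 0")
        n_active = self.shared_active_tfs + self.n_subgroups * self.active_tfs_per_group
        if self.n_tfs < n_active:
            raise ValueError(
                f"n_tfs={self.n_tfs} < shared_active_tfs + n_subgroups x "
                f"active_tfs_per_group = {n_active}"
            )
        if self.group_proportions is not None:
            p = np.asarray(self.group_proportions, dtype=float)
            if len(p) != self.n_subgroups or np.any(p <= 0) or abs(p.sum() - 1) > 1e-9:
                raise ValueError("group_proportions must be n_subgroups positive values summing to 1")

    @property
    def pathway_count(self) -> int:
        base = self.n_subgroups * self.active_tfs_per_group
        return self.n_pathways if self.n_pathways is not None else base


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    upregulated: dict[str, set[str]] = field(default_factory=dict)
    subgroup_labels: dict[str, int] = field(default_factory=dict)
    active_tfs: dict[int, set[str]] = field(default_factory=dict)
    sample_active_tfs: dict[str, set[str]] = field(default_factory=dict)
    planted_cascades: list[tuple[str, ...]] = field(default_factory=list)
    synergy_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    mapped_drugs: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "upregulated": {s: sorted(g) for s, g in sorted(self.upregulated.items())},
            "subgroup_labels": dict(sorted(self.subgroup_labels.items())),
            "active_tfs": {str(g): sorted(t) for g, t in sorted(self.active_tfs.items())},
            "sample_active_tfs": {s: sorted(t) for s, t in sorted(self.sample_active_tfs.items())},
            "planted_cascades": [list(c) for c in self.planted_cascades],
            "synergy_pairs": sorted(list(p) for p in self.synergy_pairs),
            "mapped_drugs": sorted(self.mapped_drugs),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            upregulated={s: set(g) for s, g in raw["upregulated"].items()},
            subgroup_labels={s: int(g) for s, g in raw["subgroup_labels"].items()},
            active_tfs={int(g): set(t) for g, t in raw["active_tfs"].items()},
            sample_active_tfs={s: set(t) for s, t in raw["sample_active_tfs"].items()},
            planted_cascades=[tuple(c) for c in raw["planted_cascades"]],
            synergy_pairs={tuple(p) for p in raw["synergy_pairs"]},
            mapped_drugs=set(raw["mapped_drugs"]),
        )


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    control: ExpressionMatrix
    tumor: ExpressionMatrix
    network: RegulatoryNetwork
    pathways: list[PathwayGraph]
    catalog: DrugTargetCatalog
    synergy: list[SynergyRecord]
    truth: SyntheticTruth


def _gene_names(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _tf_names(config: SimulationConfig) -> list[str]:
    return [f"TF{i:02d}" for i in range(config.n_tfs)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------


def simulate_regulatory_network(config: SimulationConfig) -> tuple[RegulatoryNetwork, SyntheticTruth]:
    """Bipartite TF -> target network with disjoint planted target blocks.

    Group g's active TFs are TF[g*a : (g+1)*a].  Each active TF's target
    block is carved sequentially from the gene list (disjoint across active
    TFs); decoy TFs sample targets from the leftover pool so planted
    enrichment stays detectable.
    """
    rng = _rng(config, 11)
    genes = _gene_names(config)
    tfs = _tf_names(config)
    a = config.active_tfs_per_group
    shared = config.shared_active_tfs
    n_active = shared + config.n_subgroups * a
    lo, hi = config.targets_per_tf

    truth = SyntheticTruth()
    edges: list[tuple[str, str]] = []
    cursor = 0
    for g in range(config.n_subgroups):
        truth.active_tfs[g] = set(tfs[:shared])  # the common core
    for idx in range(n_active):
        tf = tfs[idx]
        if idx >= shared:
            group = (idx - shared) // a
            truth.active_tfs[group].add(tf)
        size = int(rng.integers(lo, hi + 1))
        block = genes[cursor : cursor + size]
        if len(block) < size:
            raise ValueError(
                f"infeasible target allocation: need {size} fresh targets for {tf} "
                f"but only {len(block)} genes remain; increase n_genes"
            )
        cursor += size
        edges.extend((tf, gene) for gene in block)
    pool = genes[cursor:]
    for tf in tfs[n_active:]:
        size = int(rng.integers(lo, hi + 1))
        if len(pool) < size:
            raise ValueError(
                f"infeasible target allocation: decoy TF {tf} needs {size} targets "
                f"but the non-planted pool has {len(pool)} genes; increase n_genes"
            )
        picks = rng.choice(len(pool), size=size, replace=False)
        edges.extend((tf, pool[i]) for i in sorted(picks))
    return RegulatoryNetwork(edges), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    network: RegulatoryNetwork | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Control and tumor matrices with planted up-regulation.

    Controls: gene-wise Normal(mu_g, sigma_g) with mu_g ~ U(mu_range) and
    sigma_g ~ U(sigma_range) * noise_sd.  Tumor samples: the targets of the
    sample's group's active TFs (and the TF genes themselves) are drawn
    around planted_fold * mu_g; everything else follows the control law.
    ``tf_flip_noise`` drops each planted TF independently per sample.
    """
    if network is None or truth is None:
        network, truth = simulate_regulatory_network(config)
    rng = _rng(config, 22)
    genes = _gene_names(config)
    tfs = _tf_names(config)
    all_rows = genes + tfs
    n_rows = len(all_rows)

    mu = rng.uniform(*config.mu_range, size=n_rows)
    sigma = rng.uniform(*config.sigma_range, size=n_rows) * config.noise_sd

    normals = [f"N{i:03d}" for i in range(config.n_normal)]
    tumors = [f"T{i:03d}" for i in range(config.n_tumor)]

    control_vals = mu[:, None] + sigma[:, None] * rng.standard_normal((n_rows, config.n_normal))
    control = ExpressionMatrix(all_rows, normals, control_vals, role="control")

    # multinomial group assignment; resample until every group is populated
    props = (
        np.asarray(config.group_proportions, dtype=float)
        if config.group_proportions is not None
        else np.full(config.n_subgroups, 1.0 / config.n_subgroups)
    )
    for _ in range(1000):
        labels = rng.choice(config.n_subgroups, size=config.n_tumor, p=props)
        if len(set(labels)) == config.n_subgroups:
            break
    else:
        raise ValueError("could not populate every subgroup; increase n_tumor")

    row_index = {name: i for i, name in enumerate(all_rows)}
    tumor_vals = mu[:, None] + sigma[:, None] * rng.standard_normal((n_rows, config.n_tumor))
    for j, sample in enumerate(tumors):
        group = int(labels[j])
        active = sorted(truth.active_tfs[group])
        kept = [tf for tf in active if rng.random() >= config.tf_flip_noise]
        planted: set[str] = set()
        for tf in kept:
            planted.update(network.targets_of(tf))
            planted.add(tf)  # the TF gene itself is shifted in its group
        for gene in planted:
            i = row_index[gene]
            tumor_vals[i, j] = config.planted_fold * mu[i] + sigma[i] * rng.standard_normal()
        truth.subgroup_labels[sample] = group
        truth.sample_active_tfs[sample] = set(kept)
        truth.upregulated[sample] = planted
    tumor = ExpressionMatrix(all_rows, tumors, tumor_vals, role="tumor")
    return control, tumor, truth


# ---------------------------------------------------------------------------
# Pathways
# ---------------------------------------------------------------------------


def simulate_pathways(
    config: SimulationConfig,
    network: RegulatoryNetwork,
    truth: SyntheticTruth,
) -> tuple[list[PathwayGraph], SyntheticTruth]:
    """One pathway per planted active TF, plus optional pure-decoy pathways.

    The planted cascade runs through the TF's own (planted up-regulated)
    target genes and terminates at the TF.  Decoy branches hang off the
    chain and a decoy start feeds a dead-end arm, so no second
    start-to-planted-TF path exists.
    """
    rng = _rng(config, 33)
    lo, hi = config.cascade_length
    pathways: list[PathwayGraph] = []
    active = sorted({tf for tf_set in truth.active_tfs.values() for tf in tf_set})
    for tf in active:
        targets = sorted(network.targets_of(tf))
        n_edges = int(rng.integers(lo, hi + 1))
        n_intermediate = n_edges - 1  # start + intermediates + tf
        if len(targets) < n_intermediate + 1:
            n_intermediate = max(1, len(targets) - 1)
        chain = targets[: n_intermediate + 1] + [tf]  # start, intermediates..., tf
        pw = PathwayGraph(f"pw_{tf}", f"planted pathway for {tf}")
        for u, v in zip(chain[:-1], chain[1:]):
            pw.add_edge(u, v, 1)
        # decoy leaves off each chain node (outgoing only: no new route to tf)
        for i, node in enumerate(chain[:-1]):
            leaf = f"D_{tf}_{i}"
            pw.add_edge(node, leaf, int(rng.choice([1, -1])))
        # decoy arm from its own start that dead-ends
        arm = [f"DS_{tf}", f"DA_{tf}_0", f"DA_{tf}_1"]
        for u, v in zip(arm[:-1], arm[1:]):
            pw.add_edge(u, v, int(rng.choice([1, -1])))
        pathways.append(pw)
        truth.planted_cascades.append(tuple(chain))
    for extra in range(config.pathway_count - len(active)):
        pw = PathwayGraph(f"pw_decoy{extra:02d}", f"decoy pathway {extra}")
        chain = [f"DX{extra}_{i}" for i in range(4)]
        for u, v in zip(chain[:-1], chain[1:]):
            pw.add_edge(u, v, int(rng.choice([1, -1])))
        pathways.append(pw)
    return pathways, truth


# ---------------------------------------------------------------------------
# Drug screen
# ---------------------------------------------------------------------------


def simulate_drug_screen(
    config: SimulationConfig,
    pathways: list[PathwayGraph],
    truth: SyntheticTruth,
    cell_lines: tuple[str, ...] = ("CL1",),
) -> tuple[DrugTargetCatalog, list[SynergyRecord], SyntheticTruth]:
    """Drug catalog plus a combination screen with planted synergistic pairs.

    ~70% of drugs target planted cascade genes (and therefore map onto the
    core network); the rest target off-pathway decoy genes.  All pairwise
    combinations of on-network drugs are screened; each is synergistic
    (score ~ U(9, 40)) with probability ``synergy_fraction``, otherwise
    score ~ U(0, 7).
    """
    if not pathways:
        raise ValueError("pathways must be nonempty")
    rng = _rng(config, 44)
    cascade_genes = sorted({g for casc in truth.planted_cascades for g in casc})
    if not cascade_genes:
        raise ValueError("no planted cascades; generate pathways first")
    off_genes = [f"OFF{i:03d}" for i in range(10)]
    n_on = max(2, int(np.ceil(0.7 * config.n_drugs)))
    records: list[tuple[str, str]] = []
    drugs = [f"drug{i:02d}" for i in range(config.n_drugs)]
    for i, drug in enumerate(drugs):
        n_targets = int(rng.integers(1, 3))
        pool = cascade_genes if i < n_on else off_genes
        picks = rng.choice(len(pool), size=min(n_targets, len(pool)), replace=False)
        for p in sorted(picks):
            records.append((drug, pool[p]))
        if i < n_on:
            truth.mapped_drugs.add(drug)
    catalog = DrugTargetCatalog(sorted(set(records)))

    synergy: list[SynergyRecord] = []
    on_drugs = drugs[:n_on]
    for cell_line in cell_lines:
        for i in range(len(on_drugs)):
            for j in range(i + 1, len(on_drugs)):
                hit = rng.random() < config.synergy_fraction
                score = float(rng.uniform(9.0, 40.0)) if hit else float(rng.uniform(0.0, 7.0))
                rec = SynergyRecord.normalized(on_drugs[i], on_drugs[j], cell_line, round(score, 2))
                synergy.append(rec)
                if rec.score > SYNERGY_CUTOFF:
                    truth.synergy_pairs.add((rec.drug1, rec.drug2, rec.cell_line))
    return catalog, synergy, truth


# ---------------------------------------------------------------------------
# Orchestration + serialization
# ---------------------------------------------------------------------------


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input plus ground truth from one config."""
    network, truth = simulate_regulatory_network(config)
    control, tumor, truth = simulate_expression(config, network, truth)
    pathways, truth = simulate_pathways(config, network, truth)
    catalog, synergy, truth = simulate_drug_screen(config, pathways, truth)
    return SyntheticDataset(config, control, tumor, network, pathways, catalog, synergy, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Serialize every input to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathway_dir = outdir / "pathways"
    pathway_dir.mkdir(exist_ok=True)
    paths = {
        "control": outdir / "control.tsv",
        "tumor": outdir / "tumor.tsv",
        "network": outdir / "tf_targets.tsv",
        "drugs": outdir / "drug_targets.tsv",
        "synergy": outdir / "synergy.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.json",
        "pathways_dir": pathway_dir,
    }
    write_expression_matrix(dataset.control, paths["control"])
    write_expression_matrix(dataset.tumor, paths["tumor"])
    write_regulatory_network(dataset.network, paths["network"])
    for pw in dataset.pathways:
        write_pathway_sif(pw, pathway_dir / f"{pw.pathway_id}.sif")
    write_drug_catalog(dataset.catalog, paths["drugs"])
    write_synergy_table(dataset.synergy, paths["synergy"])
    dataset.truth.to_json(paths["truth"])
    cfg = asdict(dataset.config)
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True, default=list))
    return paths
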