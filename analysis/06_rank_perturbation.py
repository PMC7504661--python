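#!/usr/bin/env python
"""Score genes by perturbation factor over each subgroup's core network.

PF(g_i) = dE(g_i) + sum_j beta_ij PF(g_j) / N_ds(g_j), with dE the gene's
up-regulation probability in the subgroup's center sample and beta the
edge sign.  Genes shared by all subgroup networks are ranked by mean PF.
"""

import json
from pathlib import Path

import pandas as pd

from netsig.data_io import read_core_network
from netsig.impact_scoring import perturbation_factors, rank_genes
from netsig.upstream_signaling import CoreSignalingNetwork, compare_groups

OUTDIR = Path("results/analysis")


def main() -> None:
    groups = json.loads((OUTDIR / "groups.json").read_text())
    probs = pd.read_csv(OUTDIR / "probabilities.tsv", sep="\t", index_col=0)

    networks, scores = {}, {}
    for g in sorted(groups["group_tf_sets"]):
        path = OUTDIR / f"core_network_group{g}.graphml"
        if not path.exists():
            continue
        graph = read_core_network(path)
        networks[g] = CoreSignalingNetwork(graph=graph)
        center = groups["center_samples"][g]
        deltaE = {n: float(probs[center].get(n, 0.0)) for n in graph.nodes}
        scores[g] = perturbation_factors(graph, deltaE)
        scores[g].as_series().rename("pf").to_csv(
            OUTDIR / f"pf_group{g}.tsv", sep="\t", index_label="gene")
        print(f"group {g}: PF solved by {scores[g].solver} over {graph.number_of_nodes()} genes")

    if len(networks) >= 2:
        comparison = compare_groups(networks)
        shared = set(comparison["shared"])
        for g, uniq in sorted(comparison["unique_genes"].items()):
            print(f"  group {g} unique genes: {sorted(uniq)}")
    else:
        shared = set(next(iter(networks.values())).genes) if networks else set()
    ranked = rank_genes(scores, shared)
    ranked.to_csv(OUTDIR / "ranked_genes.tsv", sep="\t", index=False)
    print(f"{len(shared)} genes shared by all subgroup networks")
    if not ranked.empty:
        top = ranked.head(5)
        print("top-5 shared genes by mean PF:")
        for row in top.itertuples():
            print(f"    {row.gene}: {row.mean_pf:.3f}")
    print(f"wrote {OUTDIR / 'ranked_genes.tsv'} and per-group pf tables")


if __name__ == "__main__":
    main()
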