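#!/usr/bin/env python
"""Cluster tumor samples on binary activated-TF profiles with k-modes (k=3).

Each subgroup is characterized by its center sample (the member nearest the
cluster mode); the center's activated TFs define the subgroup's TF set.
Also writes the 2-D PCA projection of the profiles and a cost-vs-k elbow
table, since k itself has no closed-form selection rule.
"""

import json
from pathlib import Path

import pandas as pd

from netsig.subgrouping import kmodes_cluster, project_profiles_2d, subgroup_tf_report

OUTDIR = Path("results/analysis")
SEED = 2026
K = 3


def main() -> None:
    binary = pd.read_csv(OUTDIR / "tf_binary.tsv", sep="\t", index_col=0)
    result = kmodes_cluster(binary, k=K, n_init=10, seed=SEED)
    report = subgroup_tf_report(result, binary)
    project_profiles_2d(binary).to_csv(OUTDIR / "pca_coords.tsv", sep="\t", index_label="sample")

    elbow = []
    for k in range(1, 7):
        try:
            elbow.append((k, kmodes_cluster(binary, k=k, n_init=5, seed=SEED).cost))
        except ValueError:
            break
    pd.DataFrame(elbow, columns=["k", "cost"]).to_csv(OUTDIR / "kmodes_elbow.tsv", sep="\t", index=False)

    payload = {
        "k": K,
        "cost": result.cost,
        "labels": result.labels,
        "center_samples": {str(g): s for g, s in result.center_samples.items()},
        "group_tf_sets": {str(g): sorted(s) for g, s in result.group_tf_sets.items()},
        "shared_tfs": sorted(report["shared"]),
        "unique_tfs": {str(g): sorted(s) for g, s in report["unique"].items()},
    }
    (OUTDIR / "groups.json").write_text(json.dumps(payload, indent=1, sort_keys=True))

    sizes = {g: len(result.members(g)) for g in range(K)}
    print(f"k-modes (k={K}, 10 restarts): group sizes {sizes}, total Hamming cost {result.cost:.0f}")
    for g in range(K):
        print(f"  group {g}: center {result.center_samples[g]}, "
              f"TFs {sorted(result.group_tf_sets[g])}")
    print(f"shared TFs: {sorted(report['shared'])}")
    print(f"wrote {OUTDIR / 'groups.json'}, pca_coords.tsv, kmodes_elbow.tsv")


if __name__ == "__main__":
    main()
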