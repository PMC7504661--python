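#!/usr/bin/env python
"""Map the drug catalog onto the merged core network; filter synergies.

A drug maps when >= 1 target is a core-network gene.  Combinations where
both members are mapped and the screen score is strictly above 8 are the
validated synergies; their targets are ranked by occurrence.
"""

import json
from pathlib import Path

from netsig.data_io import read_core_network, read_drug_catalog, read_synergy_table
from netsig.drug_mapping import filter_synergies, map_drugs, rank_combination_targets
from netsig.upstream_signaling import CoreSignalingNetwork

INDIR = Path("results/analysis/inputs")
OUTDIR = Path("results/analysis")


def main() -> None:
    groups = json.loads((OUTDIR / "groups.json").read_text())
    merged = CoreSignalingNetwork()
    for g in sorted(groups["group_tf_sets"]):
        path = OUTDIR / f"core_network_group{g}.graphml"
        if path.exists():
            merged.graph.update(read_core_network(path))
    catalog = read_drug_catalog(INDIR / "drug_targets.tsv")
    records = read_synergy_table(INDIR / "synergy.csv")

    mapped = map_drugs(merged, catalog)
    combos = filter_synergies(mapped, records, threshold=8)
    targets = rank_combination_targets(combos, top_n=10)

    out = mapped.copy()
    if len(out):
        out["targets"] = out["targets"].map(",".join)
        out["roles"] = out["roles"].map(",".join)
    out.to_csv(OUTDIR / "mapped_drugs.tsv", sep="\t", index=False)
    flat = combos.copy()
    if len(flat):
        flat["targets1"] = flat["targets1"].map(",".join)
        flat["targets2"] = flat["targets2"].map(",".join)
    flat.to_csv(OUTDIR / "combinations.tsv", sep="\t", index=False)
    targets.to_csv(OUTDIR / "combination_targets.tsv", sep="\t", index=False)

    print(f"core network: {merged.graph.number_of_nodes()} genes; "
          f"catalog: {len(catalog.drugs)} drugs")
    print(f"mapped drugs: {len(mapped)} ({sorted(mapped['drug'])})")
    print(f"validated synergistic combinations (score > 8): {len(combos)}")
    if not targets.empty:
        print("top combination targets: "
              + ", ".join(f"{r.target} ({r.count})" for r in targets.itertuples()))
    print(f"wrote mapped_drugs.tsv, combinations.tsv, combination_targets.tsv under {OUTDIR}/")


if __name__ == "__main__":
    main()
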