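#!/usr/bin/env python
"""Call activated TFs per tumor sample by hypergeometric target enrichment.

For each (sample, TF) pair, the TF's targets are tested for
over-representation among the sample's up-regulated genes against the
assayed-gene universe; TFs with p <= 0.05 are called active.
"""

from pathlib import Path

import pandas as pd

from netsig.data_io import read_expression_matrix, read_regulatory_network
from netsig.tf_activity import activation_matrix

INDIR = Path("results/analysis/inputs")
OUTDIR = Path("results/analysis")


def main() -> None:
    calls = pd.read_csv(OUTDIR / "calls.tsv", sep="\t")
    network = read_regulatory_network(INDIR / "tf_targets.tsv")
    universe = set(read_expression_matrix(INDIR / "control.tsv").genes)
    binary, pvalues = activation_matrix(calls, network, universe, alpha=0.05)
    binary.to_csv(OUTDIR / "tf_binary.tsv", sep="\t", index_label="sample")
    pvalues.to_csv(OUTDIR / "tf_pvalues.tsv", sep="\t", index_label="sample")
    per_sample = binary.sum(axis=1)
    print(f"tested {binary.shape[1]} TFs in {binary.shape[0]} samples "
          f"(universe: {len(universe)} genes)")
    print(f"activated TFs per sample: median {per_sample.median():.0f} "
          f"(range {per_sample.min()}-{per_sample.max()})")
    print(f"TFs never activated: {sorted(binary.columns[binary.sum(axis=0) == 0])}")
    print(f"wrote {OUTDIR / 'tf_binary.tsv'} and {OUTDIR / 'tf_pvalues.tsv'}")


if __name__ == "__main__":
    main()
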