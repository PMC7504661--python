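"""Activated-TF calling by hypergeometric target enrichment.

A TF is "activated" in a sample when its target genes are over-represented
among that sample's up-regulated genes.  With a universe of N assayed genes,
K targets of the TF inside the universe, m up-regulated genes and k
up-regulated targets, the one-sided Fisher / hypergeometric p-value is

    p = P(X >= k),  X ~ Hypergeometric(N, K, m)

and the TF is called active when p <= alpha (default 0.05).  The universe is
the set of genes tested in the expression matrix; network edges pointing
outside the universe are dropped before counting.  No multiple-testing
correction is applied by default.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from netsig.data_io import RegulatoryNetwork

__all__ = ["tf_enrichment", "activation_matrix"]


def tf_enrichment(
    upregulated: Iterable[str],
    universe: Iterable[str],
    network: RegulatoryNetwork,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-TF enrichment of ``upregulated`` within ``universe``.

    Returns a DataFrame indexed by TF with columns (k, K, m, N, p_value,
    active).  ``upregulated`` must be a subset of ``universe``.
    ``correction='bh'`` gates the active flag on Benjamini-Hochberg
    adjusted p-values instead of raw ones (off by default: the pipeline's
    standard rule is the raw 0.05 gate).
    """
    universe = frozenset(universe)
    upregulated = frozenset(upregulated)
    if not universe:
        raise ValueError("empty gene universe")
    if not upregulated <= universe:
        stray = sorted(upregulated - universe)[:5]
        raise ValueError(f"up-regulated genes outside the universe: {stray}")
    N = len(universe)
    m = len(upregulated)
    rows = []
    for tf in network.tfs:
        targets = network.targets_of(tf) & universe
        K = len(targets)
        k = len(targets & upregulated)
        # P(X >= k); k = 0 gives p = 1 exactly
        p = float(hypergeom.sf(k - 1, N, K, m)) if K > 0 else 1.0
        p = min(max(p, 0.0), 1.0)
        rows.append((tf, k, K, m, N, p))
    df = pd.DataFrame(rows, columns=["tf", "k", "K", "m", "N", "p_value"]).set_index("tf")
    if correction is None:
        df["active"] = df["p_value"] <= alpha
    elif correction == "bh":
        from scipy.stats import false_discovery_control

        df["active"] = false_discovery_control(df["p_value"].values, method="bh") <= alpha
    else:
        raise ValueError(f"correction must be None or 'bh', got {correction!r}")
    return df


def activation_matrix(
    calls: pd.DataFrame,
    network: RegulatoryNetwork,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x TF activation calls from an up-regulation call table.

    ``calls`` is the table produced by :func:`netsig.upregulation.call_upregulated`
    (columns sample, gene, up).  Returns (binary matrix, p-value matrix),
    both samples x TFs with TFs in network order and samples sorted.  A
    sample with zero called genes yields a zero row (every p-value 1).
    """
    universe = frozenset(universe)
    samples = sorted(calls["sample"].unique())
    if not samples:
        raise ValueError("no samples in call table")
    tfs = network.tfs
    up_by_sample: Mapping[str, frozenset] = {
        s: frozenset(g.gene for g in grp.itertuples() if g.up)
        for s, grp in calls.groupby("sample")
    }
    pmat = np.ones((len(samples), len(tfs)))
    for i, sample in enumerate(samples):
        enr = tf_enrichment(up_by_sample[sample] & universe, universe, network, alpha=alpha)
        pmat[i] = enr["p_value"].values
    pvals = pd.DataFrame(pmat, index=samples, columns=tfs)
    binary = (pvals <= alpha).astype(int)
    return binary, pvals
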