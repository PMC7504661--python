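"""Drug mapping, synergy filtering and combination-target ranking.

A drug maps onto the core signaling network when at least one of its
catalog targets is a network gene.  A combination from the synergy screen
is "validated" when both members are mapped drugs and its combination
score is strictly greater than the synergy threshold (default 8).  Drug
names are matched case-insensitively after trimming; no synonym
resolution is attempted.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from netsig.data_io import DrugTargetCatalog, SynergyRecord
from netsig.upstream_signaling import CoreSignalingNetwork

__all__ = ["map_drugs", "filter_synergies", "rank_combination_targets", "attach_drug_nodes"]

SYNERGY_THRESHOLD = 8.0


def map_drugs(network: CoreSignalingNetwork, catalog: DrugTargetCatalog) -> pd.DataFrame:
    """Drugs with >= 1 target on the network.

    Returns a DataFrame with columns (drug, targets, roles): ``targets`` is
    the sorted list of matched network genes, ``roles`` their node roles.
    """
    genes = network.genes
    roles = network.roles()
    rows = []
    for drug in catalog.drugs:
        matched = sorted(catalog.targets_of(drug) & genes)
        if matched:
            rows.append((drug, matched, [roles[t] for t in matched]))
    return pd.DataFrame(rows, columns=["drug", "targets", "roles"])


def _norm(name: str) -> str:
    return name.strip().lower()


def filter_synergies(
    mapped: pd.DataFrame,
    records: Sequence[SynergyRecord],
    threshold: float = SYNERGY_THRESHOLD,
) -> pd.DataFrame:
    """Validated combinations: both drugs mapped and score strictly > threshold.

    Output columns: drug1, drug2, targets1, targets2, cell_line, score;
    sorted by cell line then descending score.  Idempotent: re-filtering the
    output's records changes nothing.
    """
    targets_by_drug = {_norm(r.drug): r.targets for r in mapped.itertuples()} if len(mapped) else {}
    rows = []
    for rec in records:
        d1, d2 = _norm(rec.drug1), _norm(rec.drug2)
        if rec.score > threshold and d1 in targets_by_drug and d2 in targets_by_drug:
            rows.append(
                (rec.drug1, rec.drug2, targets_by_drug[d1], targets_by_drug[d2], rec.cell_line, rec.score)
            )
    df = pd.DataFrame(rows, columns=["drug1", "drug2", "targets1", "targets2", "cell_line", "score"])
    if df.empty:
        return df
    df = df.drop_duplicates(subset=["drug1", "drug2", "cell_line", "score"])
    return df.sort_values(["cell_line", "score"], ascending=[True, False], kind="stable").reset_index(drop=True)


def rank_combination_targets(validated: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Rank targets by occurrence across validated combination rows.

    Each row contributes every target it lists once (both drugs' target
    lists); ties are broken by target name.  Returns the top_n rows with
    columns (target, count).
    """
    counts: dict[str, int] = {}
    for row in validated.itertuples():
        for target in list(row.targets1) + list(row.targets2):
            counts[target] = counts.get(target, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(ranked[:top_n], columns=["target", "count"])


def attach_drug_nodes(network: CoreSignalingNetwork, mapped: pd.DataFrame) -> None:
    """Add mapped drugs as role='drug' nodes with edges to their targets (in place)."""
    g = network.graph
    for row in mapped.itertuples():
        g.add_node(row.drug, role="drug")
        for target in row.targets:
            g.add_edge(row.drug, target, sign=-1, provenance=[("drug_catalog", row.drug)], sign_conflict=False)
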