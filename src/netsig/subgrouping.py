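"""Patient subgrouping on binary activated-TF profiles with k-modes.

k-modes is the k-means analogue for categorical data: cluster dissimilarity
is the Hamming distance to the cluster "mode" (the per-column majority
vector), and modes are recomputed from assignments until the partition is
stable.  Initialization is Huang's density method for the first start plus
random distinct-row restarts; the best of ``n_init`` runs by total cost
wins.  Each subgroup is characterized by its center sample: the member
closest to the subgroup's mode (ties broken by lexicographic sample id).

Group ids are canonicalized by descending group size so reports are stable
across label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubgroupResult",
    "binarize_profiles",
    "kmodes_cluster",
    "center_sample",
    "subgroup_tf_report",
    "project_profiles_2d",
]


def binarize_profiles(pvalues: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Threshold a samples x TFs p-value matrix: entry 1 iff p <= alpha."""
    vals = pvalues.values
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return (pvalues <= alpha).astype(int)


@dataclass
class SubgroupResult:
    k: int
    labels: dict[str, int]            # sample id -> group id (0-based, by size)
    modes: np.ndarray                 # (k, n_tfs) binary
    center_samples: dict[int, str]
    group_tf_sets: dict[int, frozenset[str]]
    cost: float
    seed: int
    n_init: int
    cost_history: list[float]

    def members(self, group: int) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == group)


def _hamming_to_modes(X: np.ndarray, modes: np.ndarray) -> np.ndarray:
    # (n, k) matrix of Hamming distances
    return (X[:, None, :] != modes[None, :, :]).sum(axis=2)


def _majority_modes(X: np.ndarray, labels: np.ndarray, k: int, prev: np.ndarray) -> np.ndarray:
    modes = prev.copy()
    for g in range(k):
        members = X[labels == g]
        if len(members) == 0:
            continue
        ones = members.sum(axis=0)
        half = len(members) / 2.0
        modes[g] = np.where(ones > half, 1, np.where(ones < half, 0, prev[g]))
    return modes


def _huang_init(X: np.ndarray, k: int) -> np.ndarray:
    """Pick k distinct rows with the highest attribute-frequency density."""
    n, _ = X.shape
    col_freq_one = X.mean(axis=0)
    density = np.where(X == 1, col_freq_one, 1.0 - col_freq_one).sum(axis=1)
    order = np.argsort(-density, kind="stable")
    chosen: list[int] = []
    seen: set[bytes] = set()
    for i in order:
        key = X[i].tobytes()
        if key not in seen:
            seen.add(key)
            chosen.append(i)
        if len(chosen) == k:
            break
    return X[chosen].copy()


def _kmodes_once(X: np.ndarray, modes: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    k = modes.shape[0]
    labels = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        dist = _hamming_to_modes(X, modes)
        new_labels = dist.argmin(axis=1)
        # an emptied cluster grabs the worst-fit point
        for g in range(k):
            if not np.any(new_labels == g):
                worst = dist[np.arange(len(new_labels)), new_labels].argmax()
                new_labels[worst] = g
        cost = float(_hamming_to_modes(X, modes)[np.arange(len(new_labels)), new_labels].sum())
        history.append(cost)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        modes = _majority_modes(X, labels, k, modes)
    final_cost = float(_hamming_to_modes(X, modes)[np.arange(len(labels)), labels].sum())
    history.append(final_cost)
    return labels, modes, final_cost, history


def kmodes_cluster(
    binary: pd.DataFrame,
    k: int = 3,
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 100,
) -> SubgroupResult:
    """Cluster a samples x TFs binary matrix into k subgroups.

    Requires k <= number of distinct rows.  Deterministic given ``seed``.
    """
    X = binary.values.astype(np.int8)
    samples = list(binary.index)
    distinct = len({row.tobytes() for row in X})
    if k > distinct:
        raise ValueError(f"k={k} exceeds the number of distinct profiles ({distinct})")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for init in range(n_init):
        if init == 0:
            modes0 = _huang_init(X, k)
        else:
            # random distinct rows
            idx = rng.permutation(len(X))
            picked: list[int] = []
            seen: set[bytes] = set()
            for i in idx:
                key = X[i].tobytes()
                if key not in seen:
                    seen.add(key)
                    picked.append(int(i))
                if len(picked) == k:
                    break
            modes0 = X[picked].copy()
        labels, modes, cost, history = _kmodes_once(X, modes0, max_iter=max_iter)
        if best is None or cost < best[0]:
            best = (cost, labels, modes, history)
    assert best is not None
    cost, labels, modes, history = best

    # canonicalize: groups numbered by descending size, ties by mode bytes
    sizes = [(int((labels == g).sum()), modes[g].tobytes(), g) for g in range(k)]
    order = [g for _, _, g in sorted(sizes, key=lambda t: (-t[0], t[1]))]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[g] for g in labels])
    modes = modes[order]

    label_map = {s: int(g) for s, g in zip(samples, labels)}
    result = SubgroupResult(
        k=k,
        labels=label_map,
        modes=modes,
        center_samples={},
        group_tf_sets={},
        cost=cost,
        seed=seed,
        n_init=n_init,
        cost_history=history,
    )
    tfs = list(binary.columns)
    for g in range(k):
        center = center_sample(binary, result, g)
        result.center_samples[g] = center
        profile = binary.loc[center]
        result.group_tf_sets[g] = frozenset(t for t in tfs if profile[t] == 1)
    return result


def center_sample(binary: pd.DataFrame, result: SubgroupResult, group: int) -> str:
    """The group member nearest its mode; ties broken by sample id."""
    members = result.members(group)
    if not members:
        raise ValueError(f"group {group} is empty")
    mode = result.modes[group]
    dists = {s: int((binary.loc[s].values != mode).sum()) for s in members}
    return min(members, key=lambda s: (dists[s], s))


def subgroup_tf_report(result: SubgroupResult, binary: pd.DataFrame) -> dict:
    """Shared and per-group unique TF sets, from the center samples' profiles.

    ``shared`` is the intersection across groups; a group's ``unique`` TFs
    are those in no other group's set.
    """
    group_sets = {g: set(tf_set) for g, tf_set in result.group_tf_sets.items()}
    groups = sorted(group_sets)
    shared = set.intersection(*group_sets.values()) if group_sets else set()
    unique = {}
    for g in groups:
        others = set().union(*(group_sets[h] for h in groups if h != g)) if len(groups) > 1 else set()
        unique[g] = group_sets[g] - others
    return {"shared": shared, "group_sets": group_sets, "unique": unique}


def project_profiles_2d(binary: pd.DataFrame) -> pd.DataFrame:
    """First two principal-component coordinates of the centered binary matrix."""
    if binary.shape[0] < 2:
        raise ValueError("need >= 2 samples for a 2-D projection")
    X = binary.values.astype(float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 profile matrix: all samples identical")
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :2] * S[:2]
    if coords.shape[1] < 2:  # rank-1 matrix
        coords = np.column_stack([coords, np.zeros(len(coords))])
    return pd.DataFrame(coords, index=binary.index, columns=["PC1", "PC2"])
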