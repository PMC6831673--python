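"""Stage 1: weighted correlation network and module detection.

Features are connected by the soft-thresholded absolute Pearson correlation
a_ij = |cor(x_i, x_j)|^beta (an unsigned network).  The exponent is chosen so
the connectivity distribution approximates scale-free topology, the adjacency
is transformed to a topological-overlap dissimilarity, average-linkage
hierarchical clustering cuts the tree into modules, and modules whose
eigengenes (first principal components) correlate above a similarity
threshold are merged.  The whole stage is unsupervised and deterministic:
the outcome never enters, and no randomness is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

DEFAULT_POWER_GRID = tuple(range(1, 13))


@dataclass(frozen=True)
class NetworkParams:
    """Tuning parameters of the correlation-network stage.

    power
        Soft-threshold exponent (default 7, the standard unsigned-network
        choice for survey-scale data); used whenever ``candidate_powers``
        is None.
    candidate_powers
        Optional grid searched by the scale-free criterion; the smallest
        power whose fit index reaches ``rsq_target`` wins.  Off by default —
        pass e.g. ``DEFAULT_POWER_GRID`` to enable the search.
    rsq_target
        Scale-free topology R^2 threshold (default 0.8).
    min_module_size
        Clusters smaller than this are left unassigned (label 0).
    merge_similarity
        Eigengene correlation above which two modules are merged
        (default 0.5, i.e. "more than 50 percent similarity").
    n_bins
        Histogram bins for the scale-free fit index.
    cut_height_fraction
        The dendrogram is cut at this fraction of its merge-height *range*
        (min height + fraction * (max - min)).  TOM merge heights crowd
        toward 1, so the range-relative form is the scale that behaves
        sensibly across powers.
    reassign_threshold
        After clustering and merging, an unassigned feature joins the module
        whose eigengene it is most correlated with, provided |r| reaches
        this threshold (module-membership "kME" repair).  Set to None to
        disable.
    use_tom
        Cluster on topological-overlap dissimilarity (default) or directly
        on 1 - adjacency.
    """

    power: int = 7
    candidate_powers: tuple[int, ...] | None = None
    rsq_target: float = 0.8
    min_module_size: int = 5
    merge_similarity: float = 0.5
    n_bins: int = 10
    cut_height_fraction: float = 0.98
    reassign_threshold: float | None = 0.3
    use_tom: bool = True

    def __post_init__(self):
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_similarity < 1:
            raise ValueError("merge_similarity must lie in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 <= self.rsq_target <= 1:
            raise ValueError("rsq_target must lie in [0, 1]")
        if self.candidate_powers is not None:
            cand = tuple(self.candidate_powers)
            if not cand:
                raise ValueError("candidate_powers must be non-empty or None")
            if list(cand) != sorted(cand):
                raise ValueError("candidate_powers must be sorted ascending")
            object.__setattr__(self, "candidate_powers", cand)


@dataclass
class ModulePartition:
    """Feature -> module assignment plus module summaries.

    ``labels`` maps every feature to a module id (0 = unassigned).
    ``eigengenes`` holds one unit-norm column per non-zero module, sign-fixed
    so each correlates non-negatively with the mean of its module's
    standardized members.  ``variance_explained`` is the leading-eigenvalue
    share per module.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    variance_explained: dict[int, float]
    merge_history: list[tuple[tuple[int, int], float]]
    params: NetworkParams
    power: int | None = None
    rsq_path: list[tuple[int, float]] = field(default_factory=list)

    @property
    def module_ids(self) -> list[int]:
        return sorted(k for k in set(self.labels) if k != 0)

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def sizes(self) -> dict[int, int]:
        out = {k: int((self.labels == k).sum()) for k in set(self.labels)}
        return dict(sorted(out.items()))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def soft_adjacency(X, power: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor(x_i, x_j)|^power.

    Symmetric with unit diagonal; entries in [0, 1].  Zero-variance features
    are rejected by name, and at least three features are required for the
    network to be meaningful.
    """
    arr, names = _as_matrix(X)
    if int(power) < 1:
        raise ValueError("power must be >= 1")
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 features to build a network")
    sd = arr.std(axis=0)
    dead = [names[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    corr = np.corrcoef(arr, rowvar=False)
    A = np.abs(corr) ** int(power)
    A = np.clip(A, 0.0, 1.0)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=names, columns=names)


def scale_free_fit_index(A: pd.DataFrame, n_bins: int = 10) -> dict:
    """R^2 of the log-log binned connectivity regression.

    Connectivity k_i = sum_{j != i} a_ij is binned into ``n_bins`` equal-width
    bins; log10(bin frequency) is regressed on log10(mean bin connectivity)
    over non-empty bins.  Returns ``{"rsq", "mean_connectivity", "flag"}``;
    when the regression is undefined (all connectivities equal) ``rsq`` is 0
    and ``flag`` says why.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = A.to_numpy(dtype=float) if isinstance(A, pd.DataFrame) else np.asarray(A, float)
    k = arr.sum(axis=0) - np.diag(arr)
    mean_k = float(k.mean())
    if np.ptp(k) == 0:
        return {"rsq": 0.0, "mean_connectivity": mean_k, "flag": "degenerate"}
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    total = len(k)
    for b in range(n_bins):
        mask = which == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        kb = float(k[mask].mean())
        if kb <= 0:
            continue
        xs.append(np.log10(kb))
        ys.append(np.log10(cnt / total))
    if len(xs) < 2 or np.ptp(xs) == 0:
        return {"rsq": 0.0, "mean_connectivity": mean_k, "flag": "degenerate"}
    fit = linregress(xs, ys)
    return {"rsq": float(fit.rvalue**2), "mean_connectivity": mean_k, "flag": None}


def pick_soft_power(X, params: NetworkParams) -> dict:
    """Choose the smallest candidate power reaching the scale-free target.

    Returns ``{"power", "path", "reached_target"}`` where ``path`` is the
    full per-power R^2 trace.  If no candidate reaches ``rsq_target`` the
    argmax-R^2 power is returned with ``reached_target=False``.
    """
    cand = params.candidate_powers or (params.power,)
    path: list[tuple[int, float]] = []
    for b in cand:
        A = soft_adjacency(X, b)
        path.append((int(b), scale_free_fit_index(A, params.n_bins)["rsq"]))
    for b, rsq in path:
        if rsq >= params.rsq_target:
            return {"power": b, "path": path, "reached_target": True}
    best = max(path, key=lambda t: t[1])[0]
    return {"power": best, "path": path, "reached_target": False}


def tom_dissimilarity(A: pd.DataFrame) -> pd.DataFrame:
    """Topological-overlap dissimilarity 1 - TOM.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj.  Two features overlap fully when they are
    maximally connected and share all neighbors; the dissimilarity is then 0.
    """
    names = list(A.index) if isinstance(A, pd.DataFrame) else None
    arr = A.to_numpy(dtype=float) if isinstance(A, pd.DataFrame) else np.asarray(A, float)
    k = arr.sum(axis=0) - np.diag(arr)
    L = arr @ arr - 2.0 * arr  # removes u=i and u=j terms (diag is 1)
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + arr) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    D = np.clip(1.0 - tom, 0.0, 1.0)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    if names is not None:
        return pd.DataFrame(D, index=names, columns=names)
    return pd.DataFrame(D)


def detect_modules(D: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Average-linkage clustering of the dissimilarity, static tree cut.

    The tree is cut at ``cut_height_fraction`` of its merge-height range
    (``h_min + fraction * (h_max - h_min)``); clusters smaller than
    ``min_module_size`` are labeled 0 (unassigned), the rest 1..K by
    decreasing size (ties: smallest member name).  Features are clustered
    in lexicographic-name order so the result is independent of column
    order.
    """
    names = list(D.index)
    arr = D.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.diag(arr) != 0):
        raise ValueError("dissimilarity must have a zero diagonal")
    order = np.argsort(np.asarray(names, dtype=object))
    canon = arr[np.ix_(order, order)]
    Z = linkage(squareform(canon, checks=False), method="average")
    if len(Z):
        h_min, h_max = float(Z[:, 2].min()), float(Z[:, 2].max())
        cut = h_min + params.cut_height_fraction * (h_max - h_min)
    else:
        cut = 0.0
    raw = fcluster(Z, t=cut, criterion="distance")
    labels_canon = pd.Series(raw, index=[names[i] for i in order])

    groups: dict[int, list[str]] = {}
    for feat, lab in labels_canon.items():
        groups.setdefault(int(lab), []).append(feat)
    kept = [g for g in groups.values() if len(g) >= params.min_module_size]
    kept.sort(key=lambda g: (-len(g), min(g)))
    final = pd.Series(0, index=names, dtype=int)
    for new_id, members in enumerate(kept, start=1):
        final[members] = new_id
    return final


def _standardize(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    return (arr - mu) / sd


def module_eigengenes(X, labels: pd.Series) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component ("eigengene") of each module's block.

    Members are standardized, the leading left singular vector gives the
    respondent scores (unit norm), and the sign is fixed so the eigengene
    correlates non-negatively with the module's mean standardized feature.
    ``variance_explained`` is the leading eigenvalue share.  A singleton
    module's eigengene is its own standardized column.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    eig: dict[int, np.ndarray] = {}
    varex: dict[int, float] = {}
    for mod in sorted(k for k in set(labels) if k != 0):
        members = list(labels.index[labels == mod])
        block = _standardize(Xdf[members].to_numpy(dtype=float))
        if block.shape[1] == 1:
            e = block[:, 0]
            varex[mod] = 1.0
        else:
            U, s, _ = np.linalg.svd(block, full_matrices=False)
            e = U[:, 0]
            varex[mod] = float(s[0] ** 2 / np.sum(s**2))
        norm = np.linalg.norm(e)
        e = e / norm if norm > 0 else e
        ref = block.mean(axis=1)
        if np.dot(e, ref) < 0:
            e = -e
        eig[mod] = e
    E = pd.DataFrame({f"M{m}": v for m, v in eig.items()}, index=Xdf.index)
    return E, varex


def merge_modules(X, labels: pd.Series, params: NetworkParams) -> ModulePartition:
    """Iteratively merge the most-similar module pair until none exceed the
    similarity threshold.

    Similarity is the Pearson correlation of module eigengenes; pairs with
    correlation strictly above ``merge_similarity`` are merged most-similar
    first, eigengenes recomputed after every merge.  Terminates in at most
    K - 1 merges.
    """
    labels = labels.copy()
    history: list[tuple[tuple[int, int], float]] = []
    while True:
        E, varex = module_eigengenes(X, labels)
        mods = sorted(k for k in set(labels) if k != 0)
        if len(mods) < 2:
            break
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(mods):
            ea = E[f"M{a}"].to_numpy()
            for b in mods[i + 1 :]:
                r = float(np.corrcoef(ea, E[f"M{b}"].to_numpy())[0, 1])
                if best is None or r > best[0]:
                    best = (r, a, b)
        assert best is not None
        r, a, b = best
        if r <= params.merge_similarity:
            break
        labels[labels == b] = a
        history.append(((a, b), r))

    # relabel 1..K by decreasing size, ties by smallest member name
    groups = {
        k: list(labels.index[labels == k]) for k in set(labels) if k != 0
    }
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    final = pd.Series(0, index=labels.index, dtype=int)
    for new_id, members in enumerate(ordered, start=1):
        final[members] = new_id
    E, varex = module_eigengenes(X, final)
    return ModulePartition(
        labels=final,
        eigengenes=E,
        variance_explained=varex,
        merge_history=history,
        params=params,
    )


def _reassign_unassigned(
    X: pd.DataFrame, part: ModulePartition, threshold: float
) -> ModulePartition:
    """Attach unassigned features to the module whose eigengene they best
    correlate with (module membership, "kME"), when |r| >= threshold.

    One deterministic pass: all assignments are decided against the current
    eigengenes, then eigengenes are recomputed and modules relabeled by
    size.  Features below the threshold stay in pseudo-module 0.
    """
    labels = part.labels.copy()
    free = list(labels.index[labels == 0])
    mods = part.module_ids
    if not free or not mods:
        return part
    E = part.eigengenes
    moved = False
    arr = _standardize(X[free].to_numpy(dtype=float))
    n = arr.shape[0]
    for j, feat in enumerate(free):
        x = arr[:, j]
        best_mod, best_r = 0, 0.0
        for mod in mods:
            e = E[f"M{mod}"].to_numpy()
            r = abs(float(x @ (e - e.mean())) / (n * x.std() * e.std() + 1e-300) )
            if r > best_r:
                best_mod, best_r = mod, r
        if best_mod != 0 and best_r >= threshold:
            labels[feat] = best_mod
            moved = True
    if not moved:
        return part
    groups = {k: list(labels.index[labels == k]) for k in set(labels) if k != 0}
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    final = pd.Series(0, index=labels.index, dtype=int)
    for new_id, members in enumerate(ordered, start=1):
        final[members] = new_id
    E2, varex = module_eigengenes(X, final)
    return ModulePartition(
        labels=final,
        eigengenes=E2,
        variance_explained=varex,
        merge_history=part.merge_history,
        params=part.params,
        power=part.power,
        rsq_path=part.rsq_path,
    )


def build_network(
    X,
    params: NetworkParams | None = None,
    forbidden: list[str] | None = None,
) -> ModulePartition:
    """Full stage 1: power choice, adjacency, TOM, clustering, merging,
    membership repair.

    ``forbidden`` names columns that must not be present (outcome / weight /
    id) — stage 1 is unsupervised and their inclusion is an error, not a
    silent leak.  Deterministic: same input, same partition.
    """
    params = params or NetworkParams()
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if forbidden:
        leaked = [c for c in forbidden if c in Xdf.columns]
        if leaked:
            raise ValueError(
                f"non-feature column(s) {leaked} must be excluded from the network"
            )
    if params.candidate_powers is not None:
        picked = pick_soft_power(Xdf, params)
        power, path = picked["power"], picked["path"]
    else:
        power, path = params.power, []
    A = soft_adjacency(Xdf, power)
    D = tom_dissimilarity(A) if params.use_tom else _adjacency_dissimilarity(A)
    labels = detect_modules(D, params)
    part = merge_modules(Xdf, labels, params)
    part.power = int(power)
    part.rsq_path = path
    if params.reassign_threshold is not None:
        part = _reassign_unassigned(Xdf, part, params.reassign_threshold)
    return part


def _adjacency_dissimilarity(A: pd.DataFrame) -> pd.DataFrame:
    D = 1.0 - A.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(np.clip(D, 0, 1), index=A.index, columns=A.columns)


def write_partition(part: ModulePartition, outdir) -> None:
    """Write the partition artifacts: membership CSV, eigengene CSV, merge
    history JSON, and the soft-power R^2 path CSV (when a grid was run)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = part.sizes()
    membership = pd.DataFrame(
        {
            "feature": part.labels.index,
            "module_id": part.labels.to_numpy(),
            "module_size": [sizes[m] for m in part.labels],
        }
    )
    membership.to_csv(outdir / "module_membership.csv", index=False)
    part.eigengenes.to_csv(outdir / "eigengenes.csv", index_label="respondent")
    with open(outdir / "merge_history.json", "w") as fh:
        json.dump(
            [{"modules": list(pair), "similarity": sim}
             for pair, sim in part.merge_history],
            fh, indent=2,
        )
    if part.rsq_path:
        pd.DataFrame(part.rsq_path, columns=["power", "rsq"]).to_csv(
            outdir / "rsq_path.csv", index=False
        )


def partition_from_labels(
    X, labels: dict[str, int] | pd.Series, params: NetworkParams | None = None
) -> ModulePartition:
    """Build a :class:`ModulePartition` from analyst-specified module labels.

    The escape hatch for surveys whose sections already define correlation
    modules a priori; skips the network entirely.
    """
    params = params or NetworkParams()
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    ser = pd.Series(labels).reindex(Xdf.columns)
    if ser.isna().any():
        missing = list(ser.index[ser.isna()])
        raise ValueError(f"no module label for feature(s): {missing}")
    ser = ser.astype(int)
    E, varex = module_eigengenes(Xdf, ser)
    return ModulePartition(
        labels=ser, eigengenes=E, variance_explained=varex,
        merge_history=[], params=params,
    )
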