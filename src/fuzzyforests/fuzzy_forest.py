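"""Stage 2: module-wise recursive feature elimination with random forests.

Within every module (including the pseudo-module of unassigned features) a
recursive-feature-elimination forest keeps the top ``keep_fraction`` (default
35%) of members by OOB permutation importance; the survivors from all modules
are pooled into one final elimination forest and the top ``number_selected``
(default 20) features are selected.  Repeating stage 2 under different seeds
gives per-feature selection frequencies ("stability selection"); stage 1 is
deterministic and computed once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._forest import PermutationForest
from ._seeds import derive_seed
from .corr_network import ModulePartition, NetworkParams, build_network


@dataclass(frozen=True)
class FFParams:
    """Stage-2 tuning parameters.

    keep_fraction
        Fraction of each module kept by the per-module elimination (0.35,
        i.e. the top thirty-five percent best predictors per module).
    number_selected
        Size of the final selected set (20).
    drop_fraction
        Fraction of remaining features dropped per elimination round (0.25).
    ntree, mtry, sample_fraction, min_samples_leaf, max_oob_samples
        Forest sizing; ``mtry=None`` means ceil(sqrt(p)).  See
        docs/methods.md for the desk-scale sizing rationale.
    mtry_grid
        Optional candidate mtry values; the final selection forest picks the
        grid value with the best OOB accuracy on the pooled survivors.
    n_permutations
        Permutation repeats averaged per tree for the importance.
    weighted_bootstrap
        Draw tree bootstraps proportional to survey weights (off by default;
        the validation model, not the forest, carries the weights).
    seed
        Default master seed when an operation is not given one explicitly.
    """

    keep_fraction: float = 0.35
    number_selected: int = 20
    drop_fraction: float = 0.25
    ntree: int = 50
    mtry: int | None = None
    mtry_grid: tuple[int, ...] | None = None
    n_permutations: int = 1
    sample_fraction: float = 0.5
    min_samples_leaf: int = 5
    max_oob_samples: int | None = 500
    weighted_bootstrap: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.number_selected < 1:
            raise ValueError("number_selected must be >= 1")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


@dataclass
class FuzzyForestResult:
    """Outcome of a full two-stage fit.

    ``selected`` is ordered by final importance rank; ``survivors_by_module``
    records the per-module screening survivors; ``final_forest`` is the
    forest refit on the selected features (usable for prediction).
    """

    partition: ModulePartition
    survivors_by_module: dict[int, list[str]]
    selected: pd.DataFrame  # index: feature; columns: vim, rank, module_id
    params: FFParams
    seed: int
    final_forest: PermutationForest | None = None

    @property
    def selected_features(self) -> list[str]:
        return list(self.selected.index)

    def aggregate_to_parent(self, parent_map: dict[str, str]) -> pd.DataFrame:
        """Collapse indicator-level importances to their parent variable
        (max over indicators), for reporting nominal variables as one row."""
        df = self.selected.copy()
        df["parent"] = [parent_map.get(f, f) for f in df.index]
        agg = df.groupby("parent")["vim"].max().sort_values(ascending=False)
        return agg.to_frame("vim")


@dataclass
class StabilityResult:
    """Selection frequencies over repeated stage-2 runs."""

    frequencies: pd.Series  # feature -> fraction of runs selecting it
    selections: list[list[str]]  # per-run selected lists
    n_runs: int
    partition: ModulePartition

    def to_csv(self, path) -> None:
        out = self.frequencies.sort_values(ascending=False).rename("frequency")
        out.to_csv(path, index_label="feature")


def _forest(params: FFParams, seed: int, ntree: int | None = None) -> PermutationForest:
    return PermutationForest(
        ntree=ntree or params.ntree,
        mtry=params.mtry,
        sample_fraction=params.sample_fraction,
        min_samples_leaf=params.min_samples_leaf,
        n_permutations=params.n_permutations,
        max_oob_samples=params.max_oob_samples,
        seed=seed,
    )


def _rank_table(names, vims) -> pd.DataFrame:
    """Importance table with ranks 1..m; ties broken by feature name."""
    df = pd.DataFrame({"vim": vims}, index=pd.Index(names, name="feature"))
    order = sorted(df.index, key=lambda f: (-df.at[f, "vim"], f))
    df = df.loc[order]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def oob_permutation_importance(
    X, y, params: FFParams | None = None, seed: int | None = None,
    sample_weight=None,
) -> pd.DataFrame:
    """Fit one forest and return the OOB permutation importance table.

    VIM is the decrease in out-of-bag accuracy when the feature is permuted
    within each tree's OOB sample, averaged over trees (and over
    ``n_permutations`` permutations).  Deterministic given the seed; a
    constant feature gets VIM exactly 0 (no tree can split on it).
    """
    params = params or FFParams()
    seed = params.seed if seed is None else seed
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    yarr = np.asarray(y)
    if Xdf.shape[0] < 20:
        raise ValueError("need at least 20 observations for OOB importance")
    forest = _forest(params, seed).fit(
        Xdf.to_numpy(), yarr,
        sample_weight=sample_weight if params.weighted_bootstrap else None,
    )
    table = _rank_table(list(Xdf.columns), forest.importances_)
    table.attrs["oob_accuracy"] = forest.oob_accuracy_
    return table


def rfe_select(
    X, y, keep_n: int, params: FFParams | None = None, seed: int | None = None,
    sample_weight=None,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination down to exactly ``keep_n`` features.

    Each round drops the lowest-importance ``ceil(drop_fraction * current)``
    features, never dropping below ``keep_n``; the last round truncates to
    exactly ``keep_n`` by rank.  Returns the survivors (importance order) and
    their last-round importance table.
    """
    params = params or FFParams()
    seed = params.seed if seed is None else seed
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if keep_n < 1:
        raise ValueError("keep_n must be >= 1")
    if keep_n > Xdf.shape[1]:
        raise ValueError(f"keep_n={keep_n} exceeds feature count {Xdf.shape[1]}")
    current = list(Xdf.columns)
    iteration = 0
    table = None
    while True:
        table = oob_permutation_importance(
            Xdf[current], y, params, derive_seed(seed, "rfe", iteration),
            sample_weight=sample_weight,
        )
        if len(current) <= keep_n:
            break
        n_drop = min(
            math.ceil(params.drop_fraction * len(current)), len(current) - keep_n
        )
        current = list(table.index[: len(current) - n_drop])
        iteration += 1
    survivors = list(table.index[:keep_n])
    return survivors, table.loc[survivors]


def survivor_count(keep_fraction: float, module_size: int) -> int:
    """Per-module survivor count: max(1, ceil(keep_fraction * size))."""
    return max(1, math.ceil(keep_fraction * module_size))


def screen_modules(
    X, y, partition: ModulePartition, params: FFParams | None = None,
    seed: int | None = None, sample_weight=None,
) -> dict[int, list[str]]:
    """Per-module RFE screening (stage 2a).

    Every module — including pseudo-module 0 of unassigned features — keeps
    ``max(1, ceil(keep_fraction * size))`` members.  Module runs are
    independent, with per-module seeds derived from the master seed, so the
    screening order cannot change results.
    """
    params = params or FFParams()
    seed = params.seed if seed is None else seed
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    missing = [c for c in Xdf.columns if c not in partition.labels.index]
    if missing:
        raise ValueError(f"partition does not cover feature(s): {missing}")
    survivors: dict[int, list[str]] = {}
    for mod in sorted(set(partition.labels)):
        members = [f for f in partition.labels.index[partition.labels == mod]
                   if f in Xdf.columns]
        if not members:
            continue
        keep_n = survivor_count(params.keep_fraction, len(members))
        surv, _ = rfe_select(
            Xdf[members], y, keep_n, params,
            derive_seed(seed, "module", int(mod)),
            sample_weight=sample_weight,
        )
        survivors[int(mod)] = surv
    return survivors


def _tune_mtry(X, y, params: FFParams, seed: int) -> int:
    """Pick the mtry grid value with the best OOB accuracy (ties: smallest)."""
    best: tuple[float, int] | None = None
    for j, m in enumerate(params.mtry_grid):
        forest = _forest(replace(params, mtry=int(m)), derive_seed(seed, "mtry", j))
        forest.fit(np.asarray(X, float), np.asarray(y))
        score = forest.oob_accuracy_
        if best is None or score > best[0]:
            best = (score, int(m))
    return best[1]


def select_final(
    X_survivors, y, params: FFParams | None = None, seed: int | None = None,
    partition: ModulePartition | None = None,
    survivors_by_module: dict[int, list[str]] | None = None,
    sample_weight=None,
) -> FuzzyForestResult:
    """Final selection forest (stage 2b) over the pooled module survivors.

    RFE down to ``min(number_selected, #survivors)``; the result is ordered
    by final importance.  A forest refit on the selected set is attached for
    prediction and OOB accuracy reporting.
    """
    params = params or FFParams()
    seed = params.seed if seed is None else seed
    Xdf = (
        X_survivors
        if isinstance(X_survivors, pd.DataFrame)
        else pd.DataFrame(np.asarray(X_survivors, float))
    )
    if Xdf.shape[1] == 0:
        raise ValueError("no survivors to select from")
    if params.mtry_grid:
        params = replace(params, mtry=_tune_mtry(Xdf, y, params, derive_seed(seed, "tune")))
    keep_n = min(params.number_selected, Xdf.shape[1])
    selected, table = rfe_select(
        Xdf, y, keep_n, params, derive_seed(seed, "final"),
        sample_weight=sample_weight,
    )
    final_forest = _forest(params, derive_seed(seed, "final-forest")).fit(
        Xdf[selected].to_numpy(), np.asarray(y),
        sample_weight=sample_weight if params.weighted_bootstrap else None,
    )
    out = table.loc[selected].copy()
    if partition is not None:
        out["module_id"] = [
            int(partition.labels.get(f, 0)) for f in out.index
        ]
    return FuzzyForestResult(
        partition=partition,
        survivors_by_module=survivors_by_module or {},
        selected=out,
        params=params,
        seed=seed,
        final_forest=final_forest,
    )


def fuzzy_forest_fit(
    X, y, net_params: NetworkParams | None = None,
    ff_params: FFParams | None = None, seed: int | None = None,
    partition: ModulePartition | None = None,
    sample_weight=None, forbidden: list[str] | None = None,
) -> FuzzyForestResult:
    """Full two-stage Fuzzy Forests fit.

    Stage 1 (deterministic) builds the correlation network and module
    partition unless ``partition`` is supplied; stage 2 screens each module
    and selects the final set.  The master seed governs all stage-2
    randomness.
    """
    ff_params = ff_params or FFParams()
    seed = ff_params.seed if seed is None else seed
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if partition is None:
        partition = build_network(Xdf, net_params, forbidden=forbidden)
    survivors = screen_modules(
        Xdf, y, partition, ff_params, seed, sample_weight=sample_weight
    )
    pooled = [f for mod in sorted(survivors) for f in survivors[mod]]
    result = select_final(
        Xdf[pooled], y, ff_params, seed,
        partition=partition, survivors_by_module=survivors,
        sample_weight=sample_weight,
    )
    return result


def stability_selection(
    X, y, net_params: NetworkParams | None = None,
    ff_params: FFParams | None = None, n_runs: int = 50,
    master_seed: int = 0, sample_weight=None,
    partition: ModulePartition | None = None,
) -> StabilityResult:
    """Repeat stage 2 under ``n_runs`` derived seeds; report selection
    frequencies.

    Stage 1 is deterministic, so the network is computed once and shared.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if partition is None:
        partition = build_network(Xdf, net_params)
    counts = pd.Series(0.0, index=Xdf.columns)
    selections: list[list[str]] = []
    for run in range(n_runs):
        res = fuzzy_forest_fit(
            Xdf, y, net_params, ff_params,
            seed=derive_seed(master_seed, "stability", run),
            partition=partition, sample_weight=sample_weight,
        )
        sel = res.selected_features
        selections.append(sel)
        counts[sel] += 1.0
    return StabilityResult(
        frequencies=counts / n_runs,
        selections=selections,
        n_runs=n_runs,
        partition=partition,
    )


def module_importance_summary(result: FuzzyForestResult) -> pd.DataFrame:
    """Per-module selection summary (the "modplot" table).

    ``percent_important`` = 100 * n_selected / module_size; modules with no
    selections are included with 0.0.
    """
    labels = result.partition.labels
    selected = set(result.selected_features)
    rows = []
    for mod in sorted(set(labels)):
        members = set(labels.index[labels == mod])
        n_sel = len(members & selected)
        rows.append(
            {
                "module_id": int(mod),
                "module_size": len(members),
                "n_selected": n_sel,
                "percent_important": 100.0 * n_sel / len(members),
            }
        )
    return pd.DataFrame(rows).set_index("module_id")
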