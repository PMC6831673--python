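"""End-to-end screening workflow for CHIS-style survey waves.

Data preparation (outcome recode, chronic-condition indicator, rare-language
deletion), descriptive tables (language-of-interview summary, conditional
proportions), and the train-wave/test-wave orchestration: screen features
with Fuzzy Forests on the training wave, validate with a survey-weighted
logistic regression, and score the held-out wave.  Runs identically on
synthetic waves or a real CHIS-format extract described by a codebook.
"""

from __future__ import annotations

import decimal
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .corr_network import NetworkParams
from .data import Codebook, Variable, encode_features
from .fuzzy_forest import (
    FFParams,
    FuzzyForestResult,
    fuzzy_forest_fit,
    module_importance_summary,
)
from .survey_models import (
    SeparationError,
    WeightedGLMFit,
    add_intercept,
    evaluate_predictions,
    fit_weighted_logistic,
    odds_ratios,
    predict_prob,
)

GOOD_HEALTH_LEVELS = {"Excellent", "Very Good", "Good"}
BAD_HEALTH_LEVELS = {"Fair", "Poor"}
HEALTH_CODE_MAP = {1: "Excellent", 2: "Very Good", 3: "Good", 4: "Fair", 5: "Poor"}

# Published language-of-interview counts from the 2013/2014 CHIS adult
# surveys — the desk-check inputs for the summary-table arithmetic.
LANGUAGE_COUNTS_2013 = {
    "English": 18689,
    "Spanish": 1707,
    "Vietnamese": 54,
    "Korean": 147,
    "Cantonese": 68,
    "Mandarin": 58,
    "Filipino/Tagalog": 1,
}
LANGUAGE_COUNTS_2014 = {
    "English": 17032,
    "Spanish": 1619,
    "Vietnamese": 348,
    "Korean": 156,
    "Cantonese": 115,
    "Mandarin": 219,
    "Filipino/Tagalog": 27,
}
ASIAN_LANGUAGES = ("Vietnamese", "Korean", "Cantonese", "Mandarin", "Filipino/Tagalog")


def recode_good_health(values) -> np.ndarray:
    """Binary good-health recode of the 5-level self-rated health item.

    Excellent / Very Good / Good -> 1; Fair / Poor -> 0.  Accepts the level
    strings or their numeric codes 1-5; anything else is an error listing
    the offending values.
    """
    ser = pd.Series(values)
    as_num = pd.to_numeric(ser, errors="coerce")
    labels = ser.astype(object).copy()
    numeric = as_num.notna()
    bad_codes = sorted(
        {v for v in as_num[numeric] if v not in HEALTH_CODE_MAP}
    )
    if bad_codes:
        raise ValueError(f"health codes outside 1-5: {bad_codes}")
    labels[numeric] = [HEALTH_CODE_MAP[int(v)] for v in as_num[numeric]]
    bad = sorted(
        {str(v) for v in labels if v not in GOOD_HEALTH_LEVELS | BAD_HEALTH_LEVELS}
    )
    if bad:
        raise ValueError(f"unrecognized health response(s): {bad}")
    return np.asarray([1 if v in GOOD_HEALTH_LEVELS else 0 for v in labels], dtype=int)


def chronic_condition_indicator(diabetes, cvd, hbp) -> np.ndarray:
    """Any-of-three chronic-condition indicator (elementwise logical OR).

    Inputs must be binary 0/1 and complete; missing values are an error —
    no silent imputation of health conditions.
    """
    arrs = []
    for name, v in (("diabetes", diabetes), ("cvd", cvd), ("hbp", hbp)):
        ser = pd.Series(v)
        if ser.isna().any():
            raise ValueError(f"{name} contains missing values")
        arr = ser.to_numpy()
        if set(np.unique(arr)) - {0, 1, 0.0, 1.0, False, True}:
            raise ValueError(f"{name} must be binary 0/1")
        arrs.append(arr.astype(int))
    if not len(arrs[0]) == len(arrs[1]) == len(arrs[2]):
        raise ValueError("condition vectors differ in length")
    return (arrs[0] | arrs[1] | arrs[2]).astype(int)


def drop_rare_language(
    df: pd.DataFrame, codebook: Codebook, column: str, min_n: int = 2
) -> tuple[pd.DataFrame, Codebook, dict]:
    """Remove respondents whose language level has fewer than ``min_n``
    observations, and drop those levels from the factor.

    A single respondent in a level cannot support a level coefficient (the
    estimate is weakly identified at best), so such rows are deleted before
    modeling.  Returns the filtered table, the updated codebook, and a log
    of what was removed.
    """
    var = codebook[column]
    if var.kind != "nominal":
        raise ValueError(f"{column!r} is not a nominal variable")
    counts = df[column].value_counts()
    dropped_levels = [
        lv for lv in var.levels if int(counts.get(lv, 0)) < min_n
    ]
    keep = ~df[column].isin(dropped_levels)
    out = df.loc[keep].copy()
    new_levels = [lv for lv in var.levels if lv not in dropped_levels]
    new_vars = [
        Variable(v.name, v.role, v.kind, new_levels if v.name == column else v.levels)
        for v in codebook.variables
    ]
    log = {
        "column": column,
        "min_n": int(min_n),
        "dropped_levels": dropped_levels,
        "rows_removed": int((~keep).sum()),
        "level_counts": {lv: int(counts.get(lv, 0)) for lv in var.levels},
    }
    return out, Codebook(new_vars), log


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals, as published tables do."""
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
        )
    )


def language_summary(
    counts: dict[str, int] | pd.Series,
    aggregates: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Language-of-interview summary table: counts and two-decimal percents.

    ``aggregates`` adds roll-up rows (e.g. all Asian languages combined)
    computed from the same counts.  Percents are 100 * n / total, rounded
    half away from zero to 2 dp; the Total row closes the table.
    """
    ser = pd.Series(counts, dtype=float)
    if (ser < 0).any():
        raise ValueError("counts must be non-negative")
    total = ser.sum()
    if total <= 0:
        raise ValueError("all counts are zero")
    rows = {lang: (int(n), _round2(100.0 * n / total)) for lang, n in ser.items()}
    for name, levels in (aggregates or {}).items():
        n = int(ser.reindex(levels).fillna(0).sum())
        rows[name] = (n, _round2(100.0 * n / total))
    rows["Total"] = (int(total), _round2(100.0))
    return pd.DataFrame(
        [(k, n, p) for k, (n, p) in rows.items()],
        columns=["language", "n", "percent"],
    ).set_index("language")


def conditional_proportions(
    df: pd.DataFrame, attribute: str, group_by: str, where=None
) -> pd.DataFrame:
    """Within-group proportions of a binary attribute, after an optional
    row filter.

    ``where`` is a boolean mask or the name of a binary column; rows are
    restricted to it first (e.g. "not good health"), then within each level
    of ``group_by`` the proportion with ``attribute`` = 1 is computed.
    Empty cells yield NaN proportions flagged ``defined=False``, never 0.
    """
    if attribute not in df.columns or group_by not in df.columns:
        raise KeyError("attribute / group column missing from table")
    if where is None:
        sub = df
    elif isinstance(where, str):
        sub = df[df[where].astype(bool)]
    else:
        sub = df[np.asarray(where, dtype=bool)]
    rows = []
    for level, grp in sub.groupby(group_by, observed=False, sort=True):
        n = len(grp)
        if n == 0:
            rows.append({"group": level, "n": 0, "proportion": np.nan, "defined": False})
        else:
            rows.append(
                {
                    "group": level,
                    "n": n,
                    "proportion": float(grp[attribute].mean()),
                    "defined": True,
                }
            )
    # groups present in the full table but emptied by the filter
    all_levels = df[group_by].unique()
    seen = {r["group"] for r in rows}
    for level in all_levels:
        if level not in seen:
            rows.append({"group": level, "n": 0, "proportion": np.nan, "defined": False})
    out = pd.DataFrame(rows).sort_values("group").set_index("group")
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Workflow configuration: column roles and model settings.

    ``adjusters`` are always-included confounders in the validation model;
    names listed in ``sqrt_transform`` enter as square roots (the income
    convention).  ``language_column`` drives the rare-level deletion.
    """

    language_column: str = "language"
    min_language_n: int = 2
    adjusters: tuple[str, ...] = ()
    sqrt_transform: tuple[str, ...] = ()
    threshold: float = 0.5
    net_params: NetworkParams = field(default_factory=NetworkParams)
    ff_params: FFParams = field(default_factory=FFParams)


@dataclass
class RunReport:
    """Everything the train/test workflow produces."""

    selected: pd.DataFrame
    survivors_by_module: dict[int, list[str]]
    module_summary: pd.DataFrame
    or_table: pd.DataFrame
    metrics: dict
    glm: WeightedGLMFit
    ff_result: FuzzyForestResult
    manifest: dict
    language_log: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.selected.to_csv(outdir / "selected_features.csv")
        self.module_summary.to_csv(outdir / "modplot.csv")
        self.or_table.to_csv(outdir / "odds_ratios.csv")
        surv = pd.DataFrame(
            [
                (mod, feat)
                for mod, feats in sorted(self.survivors_by_module.items())
                for feat in feats
            ],
            columns=["module_id", "feature"],
        )
        surv.to_csv(outdir / "survivors.csv", index=False)
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(self.metrics, fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        from .corr_network import write_partition

        write_partition(self.ff_result.partition, outdir)


def _glm_design(
    df: pd.DataFrame,
    codebook: Codebook,
    selected: list[str],
    config: "PipelineConfig",
) -> pd.DataFrame:
    """Regression design: selected features plus forced adjusters.

    Nominal variables expand to reference-coded indicators; names listed in
    ``sqrt_transform`` enter as square roots; an intercept leads.
    """
    terms: list[str] = []
    for name in list(selected) + [a for a in config.adjusters if a not in selected]:
        if name not in terms:
            terms.append(name)
    cols: dict[str, np.ndarray] = {}
    for name in terms:
        if name in codebook and codebook[name].kind == "nominal":
            enc, _ = encode_features(df, codebook, include=[name])
            for c in enc.columns:
                cols[c] = enc[c].to_numpy()
        else:
            vals = df[name].to_numpy(dtype=float)
            if name in config.sqrt_transform:
                cols[f"sqrt_{name}"] = np.sqrt(np.clip(vals, 0, None))
            else:
                cols[name] = vals
    return add_intercept(pd.DataFrame(cols, index=df.index))


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes()
    ).hexdigest()


def run_pipeline(
    train: pd.DataFrame,
    test: pd.DataFrame,
    codebook: Codebook,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> RunReport:
    """Train-wave screening + validation, test-wave evaluation.

    Order of operations: recode the outcome to binary good health; delete
    rare language levels from the training wave (and the same levels from
    the test wave); run the two-stage Fuzzy Forests screen on the training
    features; fit the survey-weighted logistic on the selected features plus
    forced adjusters; score the held-out wave (accuracy at the configured
    threshold, Mann-Whitney AUC) and report odds ratios with Wald limits.
    Test rows are never touched before evaluation.
    """
    config = config or PipelineConfig()
    outcome = codebook.outcome
    weight_col = codebook.weight
    if outcome is None:
        raise ValueError("codebook declares no outcome column")
    for wave, name in ((train, "train"), (test, "test")):
        if outcome not in wave.columns:
            raise ValueError(f"{name} table lacks outcome column {outcome!r}")
        missing = [v.name for v in codebook.variables if v.name not in wave.columns]
        if missing:
            raise ValueError(f"{name} table does not match codebook; missing {missing}")

    # --- training wave preparation -------------------------------------
    y_train_full = recode_good_health(train[outcome])
    train = train.assign(_good_health=y_train_full)
    lang = config.language_column
    if lang and lang in codebook:
        train, codebook_fit, lang_log = drop_rare_language(
            train, codebook, lang, config.min_language_n
        )
    else:
        codebook_fit, lang_log = codebook, {"dropped_levels": [], "rows_removed": 0}
    y_train = train["_good_health"].to_numpy()
    w_train = (
        train[weight_col].to_numpy(dtype=float)
        if weight_col
        else np.ones(len(train))
    )
    if np.any(w_train <= 0):
        raise ValueError("survey weights must be strictly positive")

    # forest block: nominal factors as single coded columns, so a
    # multi-level variable competes for selection as one feature
    X_train, parent = encode_features(train, codebook_fit, nominal="codes")
    forbidden = [c for c in (outcome, weight_col, codebook.id, "_good_health") if c]

    ff_result = fuzzy_forest_fit(
        X_train,
        y_train,
        net_params=config.net_params,
        ff_params=config.ff_params,
        seed=derive_seed(seed, "fuzzy-forest"),
        sample_weight=w_train,
        forbidden=forbidden,
    )

    # --- validation model on the training wave -------------------------
    # A factor level with almost no respondents separates the logistic
    # (diverging coefficient).  The published survey workflow deletes those
    # respondents from the validation model; do the same, level by level,
    # and record it.
    selected = ff_result.selected_features
    codebook_glm = codebook_fit
    train_glm = train
    y_glm, w_glm = y_train, w_train
    separation_dropped: list[str] = []
    while True:
        design_train = _glm_design(train_glm, codebook_glm, selected, config)
        try:
            glm = fit_weighted_logistic(design_train, y_glm, w_glm)
            break
        except SeparationError as exc:
            if exc.term is None or "=" not in exc.term:
                raise
            var, level = exc.term.split("=", 1)
            if var not in codebook_glm or codebook_glm[var].kind != "nominal":
                raise
            keep = train_glm[var].astype(str) != level
            new_levels = [l for l in codebook_glm[var].levels if l != level]
            codebook_glm = Codebook(
                [
                    Variable(v.name, v.role, v.kind,
                             new_levels if v.name == var else v.levels)
                    for v in codebook_glm.variables
                ]
            )
            train_glm = train_glm.loc[keep]
            y_glm = train_glm["_good_health"].to_numpy()
            w_glm = (
                train_glm[weight_col].to_numpy(dtype=float)
                if weight_col
                else np.ones(len(train_glm))
            )
            separation_dropped.append(exc.term)
    or_labels = _or_labels(design_train.columns, parent, codebook_glm)
    or_table = odds_ratios(glm, labels=or_labels)

    # --- held-out evaluation -------------------------------------------
    y_test_full = recode_good_health(test[outcome])
    test = test.assign(_good_health=y_test_full)
    dropped = set(lang_log.get("dropped_levels", []))
    dropped |= {t.split("=", 1)[1] for t in separation_dropped
                if t.split("=", 1)[0] == lang}
    n_test_excluded = 0
    if dropped and lang in test.columns:
        keep = ~test[lang].astype(str).isin(dropped)
        n_test_excluded = int((~keep).sum())
        test = test.loc[keep]
    y_test = test["_good_health"].to_numpy()
    X_test, _ = encode_features(test, codebook_fit, nominal="codes")
    design_test = _glm_design(test, codebook_glm, selected, config)

    probs = predict_prob(glm, design_test)
    metrics = evaluate_predictions(probs, y_test, config.threshold)
    forest_pred = ff_result.final_forest.predict(X_test[selected].to_numpy())
    metrics = {
        "logistic_accuracy": metrics["accuracy"],
        "logistic_auc": metrics["auc"],
        "confusion": metrics["confusion"],
        "threshold": metrics["threshold"],
        "forest_accuracy": float(np.mean(forest_pred == y_test)),
        "forest_oob_accuracy_train": ff_result.final_forest.oob_accuracy_,
        "n_test": int(len(y_test)),
        "n_test_excluded_language": n_test_excluded,
        "n_train": int(len(y_train)),
        "n_train_glm": int(len(y_glm)),
        "separation_dropped_terms": separation_dropped,
    }

    manifest = {
        "seed": int(seed),
        "net_params": _params_dict(config.net_params),
        "ff_params": _params_dict(config.ff_params),
        "adjusters": list(config.adjusters),
        "language_column": lang,
        "min_language_n": config.min_language_n,
        "selected_features": selected,
        "chosen_power": ff_result.partition.power,
        "dropped_language_levels": sorted(dropped),
        "train_hash": _hash_frame(train.drop(columns=["_good_health"])),
    }
    return RunReport(
        selected=ff_result.selected,
        survivors_by_module=ff_result.survivors_by_module,
        module_summary=module_importance_summary(ff_result),
        or_table=or_table,
        metrics=metrics,
        glm=glm,
        ff_result=ff_result,
        manifest=manifest,
        language_log=lang_log,
    )


def _params_dict(params) -> dict:
    out = {}
    for k, v in vars(params).items():
        if isinstance(v, (NetworkParams, FFParams)):
            out[k] = _params_dict(v)
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def _or_labels(terms, parent, codebook) -> dict[str, str]:
    labels = {}
    for t in terms:
        if "=" in t:
            var, level = t.split("=", 1)
            if var in codebook and codebook[var].levels:
                labels[t] = f"{level} vs {codebook[var].levels[0]}"
    return labels
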