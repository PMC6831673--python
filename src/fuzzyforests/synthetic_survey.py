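"""Synthetic multilingual health-survey generator.

Emulates the structure of a CHIS-style adult survey at desk scale: blocks of
mutually correlated items (one latent factor per block, pairwise correlation
rho inside a block, ~0 across blocks), a handful of independent items, a
multi-level interview-language factor with one very rare level (the
Filipino/Tagalog analogue: expected count 1 at n=2000), a five-level
self-rated general-health item driven by a logistic model on a few planted
items plus language effects, and positive, right-skewed survey weights.

Effect sizes are fixed so the construction's Bayes accuracy is ~0.86 — the
held-out accuracy regime in which the screening method is meant to operate.
The ground truth (module labels, planted coefficients, realized Bayes
accuracy) is emitted separately and never read by any fitting stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .data import Codebook, Variable

GOOD_LEVELS = ("Excellent", "Very Good", "Good")
BAD_LEVELS = ("Fair", "Poor")

# share of each 5-level response within the good / not-good halves
_GOOD_SPLIT = (0.3, 0.4, 0.3)
_BAD_SPLIT = (0.7, 0.3)


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    within_correlation: float

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 < self.within_correlation < 1:
            raise ValueError("within_correlation must lie in (0, 1)")


@dataclass(frozen=True)
class LanguageSpec:
    levels: tuple[str, ...]
    probabilities: tuple[float, ...]
    effects: tuple[float, ...]  # additive log-odds shifts, reference first

    def __post_init__(self):
        if not (len(self.levels) == len(self.probabilities) == len(self.effects)):
            raise ValueError("levels, probabilities and effects must align")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValueError("language probabilities must sum to 1")


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec(40, 0.8),
        ModuleSpec(40, 0.7),
        ModuleSpec(40, 0.6),
        ModuleSpec(40, 0.7),
        ModuleSpec(40, 0.5),
    )


def _default_language() -> LanguageSpec:
    # CHIS-like interview-language mix (2014-wave non-English shares, which
    # are the larger ones); the last level is the Tagalog analogue with
    # expected count 1 at n=2000.  Log-odds effects sit in the upper part of
    # the odds-ratio range such surveys exhibit (ORs ~3 to ~90), making the
    # language factor a genuine top-20-strength predictor rather than a
    # token effect.
    return LanguageSpec(
        levels=("English", "Spanish", "Vietnamese", "Korean",
                "Cantonese", "Mandarin", "Tagalog"),
        probabilities=(0.8736, 0.0830, 0.0178, 0.0080, 0.0059, 0.0112, 0.0005),
        effects=(0.0, -3.0, -4.5, -1.1, -2.1, -2.9, -2.0),
    )


def _default_planted() -> tuple[tuple[str, float], ...]:
    # three in-module signals, two independent signals; magnitude 1.5 puts
    # the realized Bayes accuracy near 0.86
    return (
        ("mod1_f01", 1.5),
        ("mod2_f01", 1.5),
        ("mod3_f01", 1.5),
        ("ind_f01", 1.5),
        ("ind_f02", 1.5),
    )


@dataclass(frozen=True)
class SimConfig:
    n: int = 2000
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    n_independent: int = 30
    planted: tuple[tuple[str, float], ...] = field(default_factory=_default_planted)
    language: LanguageSpec = field(default_factory=_default_language)
    intercept: float = 1.0
    weight_mu: float = 0.0
    weight_sigma: float = 0.5
    discretize: bool = False  # quantile-cut features to 5 Likert-like levels

    def feature_names(self) -> list[str]:
        names = []
        for k, mod in enumerate(self.modules, start=1):
            names += [f"mod{k}_f{j:02d}" for j in range(1, mod.size + 1)]
        names += [f"ind_f{j:02d}" for j in range(1, self.n_independent + 1)]
        return names

    def module_labels(self) -> dict[str, int]:
        labels = {}
        for k, mod in enumerate(self.modules, start=1):
            for j in range(1, mod.size + 1):
                labels[f"mod{k}_f{j:02d}"] = k
        for j in range(1, self.n_independent + 1):
            labels[f"ind_f{j:02d}"] = 0
        return labels

    def __post_init__(self):
        missing = [f for f, _ in self.planted if f not in set(self.feature_names())]
        if missing:
            raise ValueError(f"planted feature(s) not generated: {missing}")


@dataclass
class SimTruth:
    module_labels: dict[str, int]
    planted: dict[str, float]
    language_effects: dict[str, float]
    intercept: float
    bayes_accuracy: float
    prevalence: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def simulate_modular_features(config: SimConfig, seed: int) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw the block-correlated feature matrix.

    Module k with correlation rho: x_j = sqrt(rho) f_k + sqrt(1-rho) eps_j,
    with f_k and eps_j i.i.d. standard normal, so every within-module pair
    has population correlation exactly rho and cross-module pairs 0.
    Independent features are pure standard normal.
    """
    rng = np.random.default_rng(seed)
    n = config.n
    cols: dict[str, np.ndarray] = {}
    for k, mod in enumerate(config.modules, start=1):
        rho = mod.within_correlation
        f = rng.standard_normal(n)
        eps = rng.standard_normal((n, mod.size))
        block = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * eps
        for j in range(mod.size):
            cols[f"mod{k}_f{j + 1:02d}"] = block[:, j]
    for j in range(1, config.n_independent + 1):
        cols[f"ind_f{j:02d}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols)
    if config.discretize:
        for c in X.columns:
            X[c] = pd.qcut(X[c], 5, labels=False).astype(float)
    return X, config.module_labels()


def simulate_outcome_and_language(
    X: pd.DataFrame, config: SimConfig, seed: int
) -> dict:
    """Draw language, binary outcome and weights on top of the features.

    Linear predictor: intercept + sum of planted beta_j x_j + language
    effect; y ~ Bernoulli(logistic(lp)); weights i.i.d. lognormal.  Also
    returns the per-respondent Bayes accuracy max(p, 1-p) realized on this
    sample.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    lang_idx = rng.choice(
        len(config.language.levels), size=n, p=config.language.probabilities
    )
    language = np.asarray(config.language.levels, dtype=object)[lang_idx]
    lp = np.full(n, config.intercept, dtype=float)
    for feat, beta in config.planted:
        lp += beta * X[feat].to_numpy()
    lp += np.asarray(config.language.effects)[lang_idx]
    p = 1.0 / (1.0 + np.exp(-lp))
    y = (rng.random(n) < p).astype(int)
    weights = rng.lognormal(config.weight_mu, config.weight_sigma, size=n)
    return {
        "y": y,
        "language": language,
        "weights": weights,
        "prob_good": p,
        "bayes_accuracy": float(np.maximum(p, 1 - p).mean()),
    }


def _health_item(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map the binary outcome to a 5-level self-rated health item that
    recodes back to y exactly (good -> Excellent/Very Good/Good)."""
    out = np.empty(len(y), dtype=object)
    good = y == 1
    out[good] = rng.choice(GOOD_LEVELS, size=int(good.sum()), p=_GOOD_SPLIT)
    out[~good] = rng.choice(BAD_LEVELS, size=int((~good).sum()), p=_BAD_SPLIT)
    return out


def build_codebook(config: SimConfig) -> Codebook:
    variables = [Variable("respondent_id", role="id")]
    variables += [Variable(name) for name in config.feature_names()]
    variables.append(
        Variable("language", kind="nominal", levels=list(config.language.levels))
    )
    variables.append(
        Variable(
            "general_health", role="outcome", kind="nominal",
            levels=list(GOOD_LEVELS + BAD_LEVELS),
        )
    )
    variables.append(Variable("survey_weight", role="weight"))
    return Codebook(variables=variables)


def generate_dataset(config: SimConfig, seed: int) -> tuple[pd.DataFrame, Codebook, SimTruth]:
    """One survey wave: respondent table + codebook + ground truth."""
    X, labels = simulate_modular_features(config, derive_seed(seed, "features"))
    drawn = simulate_outcome_and_language(X, config, derive_seed(seed, "outcome"))
    rng = np.random.default_rng(derive_seed(seed, "health-item"))
    table = X.copy()
    table.insert(0, "respondent_id", np.arange(1, len(X) + 1))
    table["language"] = drawn["language"]
    table["general_health"] = _health_item(drawn["y"], rng)
    table["survey_weight"] = drawn["weights"]
    truth = SimTruth(
        module_labels=labels,
        planted=dict(config.planted),
        language_effects=dict(zip(config.language.levels, config.language.effects)),
        intercept=config.intercept,
        bayes_accuracy=drawn["bayes_accuracy"],
        prevalence=float(np.mean(drawn["y"])),
        seed=int(seed),
    )
    return table, build_codebook(config), truth


def generate_train_test(
    config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, Codebook, SimTruth, SimTruth]:
    """Two independent waves from the same design: train and test."""
    train, codebook, truth_train = generate_dataset(config, derive_seed(seed, "train"))
    test, _, truth_test = generate_dataset(config, derive_seed(seed, "test"))
    return train, test, codebook, truth_train, truth_test
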