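"""Survey tables, codebooks and numeric feature encoding.

A survey table is a plain :class:`pandas.DataFrame`; the codebook declares
each column's role (feature / outcome / weight / id) and measurement kind
(ordinal-numeric or nominal with an explicit level list).  Nominal variables
are expanded into reference-coded indicator columns named
``"<variable>=<level>"``; the first listed level is the reference and gets no
indicator, matching the usual survey convention (White, Male, English ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VALID_ROLES = {"feature", "outcome", "weight", "id"}
VALID_KINDS = {"ordinal", "nominal"}


@dataclass
class Variable:
    name: str
    role: str = "feature"
    kind: str = "ordinal"
    levels: list[str] | None = None

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "nominal" and not self.levels:
            raise ValueError(f"nominal variable {self.name!r} needs a level list")


@dataclass
class Codebook:
    """Ordered collection of :class:`Variable` declarations."""

    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in codebook")

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def _unique_role(self, role: str) -> str | None:
        hits = [v.name for v in self.variables if v.role == role]
        if len(hits) > 1:
            raise ValueError(f"codebook declares {len(hits)} {role!r} columns")
        return hits[0] if hits else None

    @property
    def outcome(self) -> str | None:
        return self._unique_role("outcome")

    @property
    def weight(self) -> str | None:
        return self._unique_role("weight")

    @property
    def id(self) -> str | None:
        return self._unique_role("id")

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == "feature"]

    def replace(self, variables: list[Variable]) -> "Codebook":
        return Codebook(variables=variables)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d = {"name": v.name, "role": v.role, "kind": v.kind}
            if v.levels is not None:
                d["levels"] = list(v.levels)
            out.append(d)
        return {"variables": out}

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(variables=[Variable(**v) for v in d["variables"]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class UnseenLevelError(ValueError):
    """A nominal column contains a value outside its declared levels."""


def encode_features(
    df: pd.DataFrame,
    codebook: Codebook,
    include: list[str] | None = None,
    nominal: str = "indicator",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Turn survey features into an all-numeric design block.

    Ordinal variables pass through as floats.  Nominal variables are encoded
    according to ``nominal``:

    ``"indicator"``
        Reference-coded 0/1 indicators ``"<name>=<level>"`` (first level =
        reference, no column) — the regression design convention.
    ``"codes"``
        A single column of level indices in codebook order — how tree
        ensembles of the R lineage see a factor, keeping a multi-level
        variable's importance in one place.

    Returns the encoded frame and a map from each encoded column to its
    parent variable.  Raises :class:`UnseenLevelError` if a nominal column
    holds a value not in its declared levels — the guard against scoring
    respondents from a factor level the model never saw.
    """
    if nominal not in ("indicator", "codes"):
        raise ValueError("nominal must be 'indicator' or 'codes'")
    names = include if include is not None else codebook.feature_names
    cols: dict[str, np.ndarray] = {}
    parent: dict[str, str] = {}
    for name in names:
        var = codebook[name]
        if name not in df.columns:
            raise KeyError(f"column {name!r} missing from table")
        col = df[name]
        if var.kind == "nominal":
            observed = set(col.dropna().astype(str).unique())
            extra = observed - set(var.levels)
            if extra:
                raise UnseenLevelError(
                    f"variable {name!r} has undeclared level(s): {sorted(extra)}"
                )
            if nominal == "codes":
                index = {level: i for i, level in enumerate(var.levels)}
                cols[name] = col.astype(str).map(index).to_numpy(dtype=float)
                parent[name] = name
            else:
                for level in var.levels[1:]:
                    enc = f"{name}={level}"
                    cols[enc] = (col.astype(str) == level).to_numpy(dtype=float)
                    parent[enc] = name
        else:
            vals = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
            cols[name] = vals
            parent[name] = name
    X = pd.DataFrame(cols, index=df.index)
    return X, parent
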