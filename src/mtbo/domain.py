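"""Reaction condition spaces and their feature encodings.

A :class:`Domain` declares the searchable space of a reaction optimization
campaign: continuous variables (residence time, temperature, catalyst
loading, ...) with bounds in native units, and categorical variables
(solvent, ligand, catalyst, ...) with a fixed list of levels.  Surrogate
models consume encoded feature vectors: continuous variables are min-max
scaled to [0, 1] by their declared bounds and each categorical variable is
expanded to a one-hot block in declared level order.  Task identity is
metadata on observations, never an input feature; it enters the multitask
model through the task kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ContinuousVariable",
    "CategoricalVariable",
    "Domain",
    "Condition",
    "Observation",
    "ExperimentTable",
    "encode",
    "decode",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class ContinuousVariable:
    """A bounded continuous optimization variable in native units."""

    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("continuous variable needs a nonempty name")
        if not (self.lower < self.upper):
            raise ValueError(
                f"variable {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )


@dataclass(frozen=True)
class CategoricalVariable:
    """A categorical optimization variable with a fixed, ordered level list.

    The declared order is load-bearing: the one-hot encoding and the argmax
    tie-break for relaxed indicator vectors both follow it.
    """

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("categorical variable needs a nonempty name")
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValueError(f"variable {self.name!r}: needs >= 2 levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"variable {self.name!r}: levels must be distinct")


Variable = Union[ContinuousVariable, CategoricalVariable]


@dataclass(frozen=True)
class Domain:
    """An ordered collection of variables plus the optimization objective."""

    variables: tuple[Variable, ...]
    objective_name: str = "yield"
    maximize: bool = True

    def __post_init__(self) -> None:
        variables = tuple(self.variables)
        object.__setattr__(self, "variables", variables)
        if not variables:
            raise ValueError("domain needs at least one variable")
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique within a domain")
        if self.objective_name in names:
            raise ValueError("objective name collides with a variable name")

    # -- introspection -----------------------------------------------------
    @property
    def continuous(self) -> tuple[ContinuousVariable, ...]:
        return tuple(v for v in self.variables if isinstance(v, ContinuousVariable))

    @property
    def categorical(self) -> tuple[CategoricalVariable, ...]:
        return tuple(v for v in self.variables if isinstance(v, CategoricalVariable))

    @property
    def encoded_dim(self) -> int:
        return len(self.continuous) + sum(len(v.levels) for v in self.categorical)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {"variables": [], "objective": {"name": self.objective_name, "maximize": self.maximize}}
        for v in self.variables:
            if isinstance(v, ContinuousVariable):
                out["variables"].append(
                    {"name": v.name, "type": "continuous", "lower": v.lower, "upper": v.upper, "units": v.units}
                )
            else:
                out["variables"].append({"name": v.name, "type": "categorical", "levels": list(v.levels)})
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "Domain":
        variables: list[Variable] = []
        for spec in d["variables"]:
            if spec["type"] == "continuous":
                variables.append(
                    ContinuousVariable(spec["name"], float(spec["lower"]), float(spec["upper"]), spec.get("units", ""))
                )
            elif spec["type"] == "categorical":
                variables.append(CategoricalVariable(spec["name"], tuple(spec["levels"])))
            else:
                raise ValueError(f"unknown variable type {spec['type']!r}")
        obj = d.get("objective", {})
        return cls(tuple(variables), obj.get("name", "yield"), bool(obj.get("maximize", True)))

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "Domain":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Condition:
    """One assignment of a value to every domain variable.

    ``values`` maps variable name to a float (continuous) or level label
    (categorical).  Conditions are hashable and comparable, so they can key
    duplicate-suppression sets.
    """

    values: tuple[tuple[str, Union[float, str]], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Union[float, str]]) -> "Condition":
        return cls(tuple((k, v) for k, v in mapping.items()))

    def as_dict(self) -> dict[str, Union[float, str]]:
        return dict(self.values)

    def __getitem__(self, name: str) -> Union[float, str]:
        return self.as_dict()[name]


def _validate_condition(condition: Condition, domain: Domain) -> dict:
    values = condition.as_dict()
    missing = [v.name for v in domain.variables if v.name not in values]
    if missing:
        raise ValueError(f"condition missing variable(s) {missing}")
    extra = [k for k in values if k not in {v.name for v in domain.variables}]
    if extra:
        raise ValueError(f"condition has unknown variable(s) {extra}")
    for v in domain.variables:
        val = values[v.name]
        if isinstance(v, ContinuousVariable):
            x = float(val)
            if not np.isfinite(x) or not (v.lower <= x <= v.upper):
                raise ValueError(
                    f"variable {v.name!r}: value {val!r} outside bounds [{v.lower}, {v.upper}]"
                )
        else:
            if val not in v.levels:
                raise ValueError(f"variable {v.name!r}: unknown level {val!r}")
    return values


@dataclass(frozen=True)
class Observation:
    """A measured experiment: conditions, yield (%), and its task label."""

    condition: Condition
    yield_pct: float
    task: str = "main"

    def __post_init__(self) -> None:
        y = float(self.yield_pct)
        if not np.isfinite(y):
            raise ValueError("yield must be finite")
        object.__setattr__(self, "yield_pct", y)
        if self.task is None or str(self.task) == "":
            raise ValueError("task label must be present")
        object.__setattr__(self, "task", str(self.task))


@dataclass
class ExperimentTable:
    """An ordered set of observations, all valid under one domain."""

    domain: Domain
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for obs in self.observations:
            _validate_condition(obs.condition, self.domain)
            if not (0.0 <= obs.yield_pct <= 100.0):
                raise ValueError(f"yield {obs.yield_pct} outside [0, 100]")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def task_labels(self) -> list[str]:
        seen: list[str] = []
        for obs in self.observations:
            if obs.task not in seen:
                seen.append(obs.task)
        return seen

    def append(self, obs: Observation) -> None:
        _validate_condition(obs.condition, self.domain)
        if not (0.0 <= obs.yield_pct <= 100.0):
            raise ValueError(f"yield {obs.yield_pct} outside [0, 100]")
        self.observations.append(obs)

    def restrict(self, task: str) -> "ExperimentTable":
        return ExperimentTable(self.domain, [o for o in self.observations if o.task == task])

    def merged_with(self, others: Iterable["ExperimentTable"]) -> "ExperimentTable":
        obs = list(self.observations)
        for t in others:
            if t.domain.to_dict() != self.domain.to_dict():
                raise ValueError("cannot merge tables over different domains")
            obs.extend(t.observations)
        return ExperimentTable(self.domain, obs)

    # -- array views for the surrogates ------------------------------------
    def encoded(self) -> np.ndarray:
        """N x D matrix of encoded inputs (rows follow observation order)."""
        if not self.observations:
            return np.empty((0, self.domain.encoded_dim))
        return np.stack([encode(o.condition, self.domain) for o in self.observations])

    def yields(self) -> np.ndarray:
        return np.array([o.yield_pct for o in self.observations], dtype=float)

    def tasks(self) -> list[str]:
        return [o.task for o in self.observations]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for o in self.observations:
            row = dict(o.condition.values)
            row[self.domain.objective_name] = o.yield_pct
            row["task"] = o.task
            rows.append(row)
        cols = [v.name for v in self.domain.variables] + [self.domain.objective_name, "task"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# encoding


def encode(condition: Condition, domain: Domain) -> np.ndarray:
    """Encode a condition as a feature vector in [0, 1]^D.

    Continuous variables are min-max scaled by their bounds; categoricals
    become one-hot blocks in declared level order.  Continuous coordinates
    come first (in declaration order), then the categorical blocks.
    """
    values = _validate_condition(condition, domain)
    cont = [
        (float(values[v.name]) - v.lower) / (v.upper - v.lower) for v in domain.continuous
    ]
    blocks = []
    for v in domain.categorical:
        block = np.zeros(len(v.levels))
        block[v.levels.index(values[v.name])] = 1.0
        blocks.append(block)
    return np.concatenate([np.asarray(cont, dtype=float)] + blocks) if blocks else np.asarray(cont, dtype=float)


def decode(vector: np.ndarray, domain: Domain, categorical: str = "strict") -> Condition:
    """Invert :func:`encode`.

    ``categorical="strict"`` requires exact one-hot indicator blocks;
    ``categorical="argmax"`` resolves relaxed blocks (as produced by
    continuous acquisition optimization) by argmax, ties broken toward the
    lowest declared level index.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (domain.encoded_dim,):
        raise ValueError(
            f"expected vector of length {domain.encoded_dim}, got shape {vector.shape}"
        )
    values: dict[str, Union[float, str]] = {}
    ncont = len(domain.continuous)
    for i, v in enumerate(domain.continuous):
        z = float(np.clip(vector[i], 0.0, 1.0))
        values[v.name] = v.lower + z * (v.upper - v.lower)
    offset = ncont
    for v in domain.categorical:
        block = vector[offset : offset + len(v.levels)]
        offset += len(v.levels)
        if categorical == "strict":
            ones = np.flatnonzero(np.isclose(block, 1.0))
            if len(ones) != 1 or not np.allclose(np.delete(block, ones), 0.0):
                raise ValueError(f"variable {v.name!r}: block {block} is not a valid one-hot indicator")
            idx = int(ones[0])
        elif categorical == "argmax":
            idx = int(np.argmax(block))  # np.argmax takes the first maximum
        else:
            raise ValueError(f"unknown categorical policy {categorical!r}")
        values[v.name] = v.levels[idx]
    return Condition.from_mapping(values)


# ---------------------------------------------------------------------------
# CSV I/O  (UTF-8, header row, comma separator, objective column named by
# the domain's objective_name, plus a "task" column)


def read_table(path: Union[str, Path], domain: Domain) -> ExperimentTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [v.name for v in domain.variables] + [domain.objective_name]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    has_task = "task" in df.columns
    observations = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        values: dict[str, Union[float, str]] = {}
        for v in domain.variables:
            raw = row[v.name]
            if isinstance(v, ContinuousVariable):
                try:
                    values[v.name] = float(raw)
                except ValueError as err:
                    raise ValueError(f"row {rowno}: non-numeric value {raw!r} for {v.name!r}") from err
            else:
                values[v.name] = raw
        try:
            y = float(row[domain.objective_name])
        except ValueError as err:
            raise ValueError(
                f"row {rowno}: non-numeric {domain.objective_name!r} value {row[domain.objective_name]!r}"
            ) from err
        if not (0.0 <= y <= 100.0):
            raise ValueError(f"row {rowno}: {domain.objective_name} {y} outside [0, 100]")
        task = row["task"] if has_task else "main"
        try:
            obs = Observation(Condition.from_mapping(values), y, task)
            _validate_condition(obs.condition, domain)
        except ValueError as err:
            raise ValueError(f"row {rowno}: {err}") from err
        observations.append(obs)
    return ExperimentTable(domain, observations)


def write_table(table: ExperimentTable, path: Union[str, Path]) -> None:
    table.to_dataframe().to_csv(path, index=False)
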