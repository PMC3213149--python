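"""Data model, tabular I/O and log transforms shared by all analysis stages.

The central container is :class:`AllometryDataset`: per-individual body size
plus one column per organ, with group (genotype/driver), rearing temperature
and nutrition-treatment labels.  Sizes are unit-agnostic positive reals
(the measurements mix areas and lengths; no unit conversion is attempted).
All scaling analyses operate on log-transformed sizes; the log base is
recorded on the dataset and the allometric slope is base-invariant.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: canonical column names used internally
META_COLUMNS = ["individual_id", "group", "temperature", "treatment", "body"]


class ConfigurationError(ValueError):
    """A mapping, option or precondition supplied by the caller is invalid."""


class EmptyInputError(ValueError):
    """No usable rows remain after validation."""


class StateError(ValueError):
    """Operation applied to a dataset in the wrong size scale."""


@dataclass(frozen=True)
class IndividualRecord:
    """One fly: body size plus a mapping organ-name -> size.

    Body size is pupal-case area; organ sizes are areas or lengths in
    arbitrary units.  Missing organ measurements are allowed (dissection
    loss is routine) and are excluded pairwise by downstream analyses.
    """

    individual_id: str
    group: str
    body_size: float
    organ_sizes: Mapping[str, float] = field(default_factory=dict)
    temperature: float | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if not (self.body_size > 0):
            raise ValueError(f"body_size must be > 0, got {self.body_size}")
        for organ, size in self.organ_sizes.items():
            if not (size > 0) or not math.isfinite(size):
                raise ValueError(f"organ {organ!r} size must be a positive real, got {size}")


@dataclass
class AllometryDataset:
    """Ordered collection of individuals with a shared organ vocabulary.

    Internally backed by a DataFrame with columns
    ``individual_id, group, temperature, treatment, body, <organ...>``.
    ``size_scale`` is ``"raw"`` or ``"log"``; ``log_base`` is set only on
    log-scale data.
    """

    frame: pd.DataFrame
    organs: tuple[str, ...]
    size_scale: str = "raw"
    log_base: float | None = None

    def __post_init__(self) -> None:
        if self.size_scale not in ("raw", "log"):
            raise ValueError(f"size_scale must be 'raw' or 'log', got {self.size_scale!r}")
        if self.size_scale == "log" and self.log_base is None:
            raise ValueError("log-scale dataset must record its log_base")
        missing = [c for c in META_COLUMNS + list(self.organs) if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame is missing columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[IndividualRecord]:
        out = []
        for _, row in self.frame.iterrows():
            organs = {
                o: float(row[o]) for o in self.organs if pd.notna(row[o])
            }
            temp = None if pd.isna(row["temperature"]) else float(row["temperature"])
            treat = None if pd.isna(row["treatment"]) else str(row["treatment"])
            out.append(
                IndividualRecord(
                    individual_id=str(row["individual_id"]),
                    group=str(row["group"]),
                    body_size=float(row["body"]),
                    organ_sizes=organs,
                    temperature=temp,
                    treatment=treat,
                )
            )
        return out

    def size_columns(self) -> list[str]:
        return ["body", *self.organs]

    def pairs(self, y: str, x: str = "body") -> tuple[np.ndarray, np.ndarray]:
        """Complete (x, y) size pairs after pairwise missing-data exclusion."""
        for name in (y, x):
            if name not in self.size_columns():
                raise ConfigurationError(
                    f"unknown size column {name!r}; known: {self.size_columns()}"
                )
        sub = self.frame[[x, y]].dropna()
        return sub[x].to_numpy(float), sub[y].to_numpy(float)

    def subset(self, mask: pd.Series | np.ndarray) -> "AllometryDataset":
        return AllometryDataset(
            self.frame.loc[mask].reset_index(drop=True),
            self.organs,
            self.size_scale,
            self.log_base,
        )

    def copy(self) -> "AllometryDataset":
        return AllometryDataset(self.frame.copy(), self.organs, self.size_scale, self.log_base)


def dataset_from_arrays(
    body: Sequence[float],
    organ_sizes: Mapping[str, Sequence[float]],
    *,
    group: Sequence[str] | str = "pooled",
    temperature: Sequence[float] | float | None = None,
    treatment: Sequence[str] | str | None = None,
    individual_id: Sequence[str] | None = None,
    size_scale: str = "raw",
    log_base: float | None = None,
) -> AllometryDataset:
    """Convenience constructor from plain arrays (one entry per individual)."""
    n = len(body)
    frame = pd.DataFrame(
        {
            "individual_id": list(individual_id) if individual_id is not None else [f"ind{i}" for i in range(n)],
            "group": [group] * n if isinstance(group, str) else list(group),
            "temperature": [temperature] * n if np.isscalar(temperature) or temperature is None else list(temperature),
            "treatment": [treatment] * n if isinstance(treatment, str) or treatment is None else list(treatment),
            "body": np.asarray(body, float),
        }
    )
    for organ, sizes in organ_sizes.items():
        frame[organ] = np.asarray(sizes, float)
    return AllometryDataset(frame, tuple(organ_sizes), size_scale, log_base)


def read_individuals_csv(path: str | Path, column_map: Mapping[str, str]) -> AllometryDataset:
    """Read a per-individual morphometric CSV into a raw-scale dataset.

    ``column_map`` maps canonical names to CSV headers.  Required keys:
    ``individual_id``, ``group``, ``body``; optional: ``temperature``,
    ``treatment``; every remaining key is treated as an organ name mapped to
    its size column.  Rows whose body or organ sizes fail to parse as
    positive reals are rejected, and the rejections are reported by
    0-based data-row index in the raised error / returned diagnostics.

    The dialect is fixed: comma-separated, header row, UTF-8, "." decimal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", sep=",")

    required = ["individual_id", "group", "body"]
    for key in required:
        if key not in column_map:
            raise ConfigurationError(f"column_map must define {key!r}")
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mapped columns {missing} not present in {path.name}; found {list(raw.columns)}"
        )

    organ_keys = [k for k in column_map if k not in required + ["temperature", "treatment"]]

    frame = pd.DataFrame(
        {
            "individual_id": raw[column_map["individual_id"]].astype(str),
            "group": raw[column_map["group"]].astype(str),
        }
    )
    for opt in ("temperature", "treatment"):
        if opt in column_map:
            col = raw[column_map[opt]]
            frame[opt] = pd.to_numeric(col, errors="coerce") if opt == "temperature" else col
        else:
            frame[opt] = np.nan

    size_cols = {"body": column_map["body"], **{o: column_map[o] for o in organ_keys}}
    bad_rows: dict[int, list[str]] = {}
    for name, src in size_cols.items():
        parsed = pd.to_numeric(raw[src], errors="coerce")
        if name == "body":
            # body is mandatory: missing, unparseable or non-positive all reject
            bad = parsed.isna() | (parsed <= 0)
        else:
            # organs may be missing (blank cell) but must be positive when present
            bad = raw[src].notna() & (parsed.isna() | (parsed <= 0))
        for i in np.flatnonzero(bad.to_numpy()):
            bad_rows.setdefault(int(i), []).append(name)
        frame[name] = parsed.where(~bad)

    keep = ~frame["body"].isna()
    for o in organ_keys:
        # a bad organ value rejects the whole row (a silent NaN would hide a typo)
        keep &= ~frame.index.isin([i for i, cols in bad_rows.items() if o in cols])
    dataset = AllometryDataset(
        frame.loc[keep].reset_index(drop=True), tuple(organ_keys), "raw", None
    )
    dataset.rejected_rows = dict(sorted(bad_rows.items()))  # type: ignore[attr-defined]
    if len(dataset) == 0:
        raise EmptyInputError(
            f"no usable rows in {path.name}; rejected rows (0-based): {sorted(bad_rows)}"
        )
    return dataset


def write_dataset_csv(dataset: AllometryDataset, path: str | Path) -> None:
    """Write a dataset in the same fixed CSV dialect ``read_individuals_csv`` expects."""
    cols = META_COLUMNS + list(dataset.organs)
    dataset.frame[cols].rename(columns={"body": "body"}).to_csv(
        path, index=False, encoding="utf-8"
    )


def identity_column_map(dataset: AllometryDataset) -> dict[str, str]:
    m = {k: k for k in ("individual_id", "group", "temperature", "treatment", "body")}
    m.update({o: o for o in dataset.organs})
    return m


def log_transform(dataset: AllometryDataset, base: float = math.e) -> AllometryDataset:
    """Return a copy with all sizes replaced by log_base(size).

    The allometric slope downstream is invariant to the base; the intercept
    is not.  Applying this to an already-log dataset is a state error.
    """
    if dataset.size_scale != "raw":
        raise StateError("dataset is already on the log scale")
    if not (base > 0) or base == 1:
        raise ConfigurationError(f"log base must be positive and != 1, got {base}")
    frame = dataset.frame.copy()
    for col in dataset.size_columns():
        frame[col] = np.log(frame[col].to_numpy(float)) / math.log(base)
    return AllometryDataset(frame, dataset.organs, "log", float(base))


def exp_transform(dataset: AllometryDataset) -> AllometryDataset:
    """Inverse of :func:`log_transform`; recovers the raw scale."""
    if dataset.size_scale != "log":
        raise StateError("dataset is not on the log scale")
    frame = dataset.frame.copy()
    for col in dataset.size_columns():
        frame[col] = np.power(dataset.log_base, frame[col].to_numpy(float))
    return AllometryDataset(frame, dataset.organs, "raw", None)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"_type": type(obj).__name__, **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    raise TypeError(f"cannot serialize field of type {type(obj).__name__}")


def write_results_json(result: Any, path: str | Path, *, params: Mapping[str, Any] | None = None) -> None:
    """Serialize a result record (any of the package's dataclasses, or a dict).

    Output is schema-versioned and key-sorted so that identical inputs give
    byte-identical files; seeds and parameters used live inside the result
    objects themselves and in the optional ``params`` block.
    """
    doc = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
    if params is not None:
        doc["params"] = _jsonable(params)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n", encoding="utf-8")


def read_results_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
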