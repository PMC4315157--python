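"""Labelled sample x attribute tables and their on-disk formats.

The central container is :class:`Dataset`: a numeric matrix with named
attribute columns (genes, proteins, ...) and one nominal class label per
sample row.  Attributes are identified by *name* everywhere after load, so
subsets of attributes survive projection without index bookkeeping.

Supported formats are delimited text (CSV with a header row) and WEKA-style
ARFF with numeric feature attributes plus a single nominal class attribute.
"""

from __future__ import annotations

import csv
import json
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff

#: cell contents treated as missing values in delimited text input
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "?"})

#: numeric output format — 10 significant digits, so reruns are byte-identical
NUM_FMT = ".10g"


def format_number(x: float) -> str:
    """Render a float with 10 significant digits (fixed output format)."""
    return format(float(x), NUM_FMT)


class DatasetError(ValueError):
    """Raised for malformed input tables or invalid dataset operations."""


@dataclass
class Dataset:
    """A labelled numeric table: samples as rows, attributes as columns.

    Parameters
    ----------
    attribute_names :
        Unique, non-empty column names, in column order.
    sample_ids :
        One identifier per row.
    values :
        Float matrix of shape ``(n_samples, n_attributes)``; all entries
        finite (the missing-value policy is applied at load time).
    class_labels :
        One nominal label per sample.
    class_set :
        The distinct labels in order of first appearance.  Derived from
        ``class_labels`` when omitted.
    """

    attribute_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    class_labels: list[str]
    class_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.attribute_names = list(self.attribute_names)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        if not self.class_set:
            seen: dict[str, None] = {}
            for label in self.class_labels:
                seen.setdefault(label, None)
            self.class_set = list(seen)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`DatasetError`."""
        n_samples, n_attributes = self.values.shape
        if n_attributes < 1:
            raise DatasetError("a dataset needs at least one attribute")
        if len(self.attribute_names) != n_attributes:
            raise DatasetError(
                f"{len(self.attribute_names)} attribute names for "
                f"{n_attributes} columns"
            )
        if len(set(self.attribute_names)) != n_attributes:
            dupes = sorted(
                {a for a in self.attribute_names if self.attribute_names.count(a) > 1}
            )
            raise DatasetError(f"duplicate attribute names: {dupes}")
        if any(not a for a in self.attribute_names):
            raise DatasetError("attribute names must be non-empty")
        if len(self.sample_ids) != n_samples:
            raise DatasetError("sample_ids length must equal row count")
        if len(self.class_labels) != n_samples:
            raise DatasetError("class_labels length must equal row count")
        if not set(self.class_labels) <= set(self.class_set):
            raise DatasetError("every class label must be in class_set")
        if not np.isfinite(self.values).all():
            raise DatasetError("all matrix entries must be finite")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    def class_codes(self) -> np.ndarray:
        """Integer class codes in ``class_set`` (first-appearance) order."""
        index = {c: i for i, c in enumerate(self.class_set)}
        return np.fromiter(
            (index[c] for c in self.class_labels), dtype=np.intp, count=self.n_samples
        )

    def sample_mapping(self, row: int) -> dict[str, float]:
        """The ``attribute -> value`` view of one sample row."""
        return dict(zip(self.attribute_names, self.values[row]))

    def attribute_column(self, name: str) -> np.ndarray:
        try:
            j = self.attribute_names.index(name)
        except ValueError:
            raise DatasetError(f"unknown attribute: {name!r}") from None
        return self.values[:, j]

    def subset_rows(self, rows: Sequence[int] | np.ndarray) -> "Dataset":
        """A new dataset restricted to the given row indices (order kept)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return Dataset(
            attribute_names=list(self.attribute_names),
            sample_ids=[self.sample_ids[i] for i in rows],
            values=self.values[rows].copy(),
            class_labels=[self.class_labels[i] for i in rows],
        )


def project_attributes(dataset: Dataset, removed: Iterable[str]) -> Dataset:
    """Drop a set of attributes, keeping the survivors in original order.

    The input dataset is never modified.  Removing the empty set returns an
    equivalent copy; removing *all* attributes is an error (a dataset can
    never be emptied).
    """
    removed = set(removed)
    known = set(dataset.attribute_names)
    unknown = removed - known
    if unknown:
        raise DatasetError(f"unknown attribute(s): {sorted(unknown)}")
    if removed == known:
        raise DatasetError("cannot remove every attribute from a dataset")
    keep = [j for j, a in enumerate(dataset.attribute_names) if a not in removed]
    return Dataset(
        attribute_names=[dataset.attribute_names[j] for j in keep],
        sample_ids=list(dataset.sample_ids),
        values=dataset.values[:, keep].copy(),
        class_labels=list(dataset.class_labels),
    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_csv(
    path: str | os.PathLike,
    class_column: str = "class",
    id_column: str | None = None,
    missing_policy: str = "error",
) -> Dataset:
    """Read a delimited-text table into a :class:`Dataset`.

    Parameters
    ----------
    path :
        CSV file with a header row; "." decimal separator, UTF-8.
    class_column :
        Name of the nominal class column (default ``"class"``).
    id_column :
        Optional sample-identifier column; when absent, row numbers are used.
    missing_policy :
        ``"error"`` rejects empty/NA cells naming the offending row and
        column; ``"zero"`` loads them as 0.0 (absence-as-zero matches the
        abundance semantics of emPAI-like proteomics data).
    """
    if missing_policy not in ("error", "zero"):
        raise DatasetError(f"unknown missing_policy: {missing_policy!r}")
    with open(path, newline="", encoding="utf-8") as handle:
        header = next(csv.reader(handle), None)
    if not header:
        raise DatasetError(f"{path}: empty file or missing header row")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DatasetError(f"{path}: duplicate column names: {dupes}")
    if class_column not in header:
        raise DatasetError(f"{path}: class column {class_column!r} not in header")
    if id_column is not None and id_column not in header:
        raise DatasetError(f"{path}: id column {id_column!r} not in header")

    frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    labels = [str(v) for v in frame[class_column]]
    if id_column is not None:
        ids = [str(v) for v in frame[id_column]]
    else:
        ids = [str(i) for i in range(len(frame))]
    attr_names = [c for c in header if c != class_column and c != id_column]
    if not attr_names:
        raise DatasetError(f"{path}: no attribute columns")

    n = len(frame)
    matrix = np.empty((n, len(attr_names)), dtype=float)
    for j, name in enumerate(attr_names):
        raw = frame[name].astype(str).str.strip()
        missing = raw.isin(MISSING_TOKENS)
        parsed = pd.to_numeric(raw.mask(missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{name!r}, row {row + 2} (sample {ids[row]!r})"
            )
        if missing.any():
            if missing_policy == "error":
                row = int(np.flatnonzero(missing.to_numpy())[0])
                raise DatasetError(
                    f"{path}: missing value in column {name!r}, row {row + 2} "
                    f"(sample {ids[row]!r}); use missing_policy='zero' to "
                    "load absent entries as 0.0"
                )
            parsed = parsed.fillna(0.0)
        matrix[:, j] = parsed.to_numpy(dtype=float)

    dataset = Dataset(attr_names, ids, matrix, labels)
    if dataset.n_classes < 2:
        warnings.warn(
            f"{path}: fewer than 2 distinct classes — learning operations "
            "will refuse this dataset",
            stacklevel=2,
        )
    return dataset


def load_arff(
    path: str | os.PathLike,
    class_attribute: str | None = None,
    missing_policy: str = "error",
) -> Dataset:
    """Read a WEKA-dialect ARFF file into a :class:`Dataset`.

    All feature attributes must be numeric; exactly one nominal attribute —
    named by ``class_attribute``, or the last attribute by default — holds
    the class labels.
    """
    if missing_policy not in ("error", "zero"):
        raise DatasetError(f"unknown missing_policy: {missing_policy!r}")
    try:
        data, meta = _scipy_arff.loadarff(str(path))
    except Exception as exc:  # scipy raises several parse-error types
        raise DatasetError(f"{path}: malformed ARFF ({exc})") from exc
    names = list(meta.names())
    if not names:
        raise DatasetError(f"{path}: malformed ARFF (no attribute declarations)")
    types = dict(zip(names, meta.types()))
    if class_attribute is None:
        class_attribute = names[-1]
    if class_attribute not in names:
        raise DatasetError(f"{path}: class attribute {class_attribute!r} absent")
    if types[class_attribute] != "nominal":
        raise DatasetError(f"{path}: class attribute {class_attribute!r} not nominal")
    bad_nominal = [
        a for a in names if a != class_attribute and types[a] != "numeric"
    ]
    if bad_nominal:
        raise DatasetError(
            f"{path}: nominal non-class attributes unsupported: {bad_nominal}"
        )

    attr_names = [a for a in names if a != class_attribute]
    raw_labels = data[class_attribute]
    labels = [
        v.decode() if isinstance(v, bytes) else str(v) for v in raw_labels
    ]
    n = len(labels)
    matrix = np.empty((n, len(attr_names)), dtype=float)
    for j, name in enumerate(attr_names):
        col = np.asarray(data[name], dtype=float)
        if np.isnan(col).any():
            if missing_policy == "error":
                row = int(np.flatnonzero(np.isnan(col))[0])
                raise DatasetError(
                    f"{path}: missing value in attribute {name!r}, instance {row}"
                )
            col = np.nan_to_num(col, nan=0.0)
        matrix[:, j] = col
    ids = [str(i) for i in range(n)]
    dataset = Dataset(attr_names, ids, matrix, labels)
    if dataset.n_classes < 2:
        warnings.warn(f"{path}: fewer than 2 distinct classes", stacklevel=2)
    return dataset


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def save_csv(
    dataset: Dataset,
    path: str | os.PathLike,
    class_column: str = "class",
    id_column: str | None = None,
) -> None:
    """Write a dataset as CSV, numbers at 10 significant digits."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        header = list(dataset.attribute_names) + [class_column]
        if id_column is not None:
            header = [id_column] + header
        writer.writerow(header)
        for i in range(dataset.n_samples):
            row = [format_number(v) for v in dataset.values[i]]
            row.append(dataset.class_labels[i])
            if id_column is not None:
                row = [dataset.sample_ids[i]] + row
            writer.writerow(row)


def write_outputs(result, out_dir: str | os.PathLike) -> set[str]:
    """Write the five artefacts of a finished elimination run.

    Produces, inside ``out_dir``:

    * ``reduced_dataset.csv`` — the surviving attributes plus class column;
    * ``ranking.tsv`` — the final attribute relevance ranking;
    * ``trace.tsv`` — the per-trial audit log;
    * ``ruleset.txt`` — the final decision list trained on the reduced data;
    * ``summary.json`` — counts, metrics, seed and full configuration.

    Identical inputs, configuration and seed reproduce these files byte for
    byte.  Returns the set of paths written.
    """
    from .rules import render_ruleset  # local import avoids a cycle

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: set[str] = set()

    reduced_path = os.path.join(out_dir, "reduced_dataset.csv")
    save_csv(result.final_dataset, reduced_path)
    written.add(reduced_path)

    ranking_path = os.path.join(out_dir, "ranking.tsv")
    with open(ranking_path, "w", encoding="utf-8") as handle:
        handle.write("rank\tattribute\tusage_score\n")
        for rank, (attr, score) in enumerate(result.final_ranking.entries, start=1):
            handle.write(f"{rank}\t{attr}\t{format_number(score)}\n")
    written.add(ranking_path)

    trace_path = os.path.join(out_dir, "trace.tsv")
    with open(trace_path, "w", encoding="utf-8") as handle:
        handle.write(
            "iteration\tblock_size\ttrial_attributes\tref_correct\t"
            "trial_correct\tdecision\tconsecutive_failures\tn_attributes_after\n"
        )
        for rec in result.trials:
            handle.write(
                f"{rec.iteration}\t{rec.block_size}\t{';'.join(rec.block)}\t"
                f"{rec.ref_correct}\t{rec.trial_correct}\t{rec.decision}\t"
                f"{rec.consecutive_failures}\t{rec.n_attributes_after}\n"
            )
    written.add(trace_path)

    rules_path = os.path.join(out_dir, "ruleset.txt")
    with open(rules_path, "w", encoding="utf-8") as handle:
        handle.write(render_ruleset(result.final_model) + "\n")
    written.add(rules_path)

    summary_path = os.path.join(out_dir, "summary.json")
    summary = result.summary_dict()
    with open(summary_path, "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    written.add(summary_path)
    return written
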