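"""Core data model: person x item ordinal response matrices and instrument specs.

Persons are rows, items are columns. Category codes are 0-based integers
``0..m_i`` per item (``m_i + 1`` categories), mirroring the convention of
rating-scale questionnaires whose categories are printed ``c0, c1, ...``.
Missing entries are carried as a boolean mask alongside the value matrix; the
CSV representation uses a configurable sentinel (default ``"NA"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    EmptyDataError,
    MappingError,
    RangeError,
    SchemaError,
)

DEFAULT_MISSING_CODE = "NA"


@dataclass
class InstrumentSpec:
    """Structure of a rating-scale instrument.

    Parameters
    ----------
    name
        Instrument label, e.g. ``"AS-18-D"``.
    items
        Ordered ``(item_id, n_categories)`` pairs; ``n_categories`` is the
        number of ordered response categories (codes ``0..n_categories-1``).
    missing_code
        Sentinel string marking a missing cell in CSV files.
    """

    name: str
    items: list[tuple[str, int]]
    missing_code: str = DEFAULT_MISSING_CODE

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate item ids in spec {self.name!r}")
        for item_id, k in self.items:
            if int(k) < 2:
                raise SchemaError(
                    f"item {item_id!r}: n_categories must be >= 2, got {k}"
                )

    @property
    def item_ids(self) -> list[str]:
        return [i for i, _ in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([k for _, k in self.items], dtype=int)

    @classmethod
    def from_file(cls, path: str | Path) -> "InstrumentSpec":
        """Load a spec from JSON or YAML (by extension; YAML parses JSON too)."""
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        try:
            items = [(str(i["id"]), int(i["n_categories"])) for i in payload["items"]]
            return cls(
                name=str(payload.get("name", path.stem)),
                items=items,
                missing_code=str(payload.get("missing_code", DEFAULT_MISSING_CODE)),
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed instrument spec {path}: {exc}") from exc

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "name": self.name,
            "missing_code": self.missing_code,
            "items": [{"id": i, "n_categories": int(k)} for i, k in self.items],
        }
        with open(path, "w", encoding="utf-8") as fh:
            if path.suffix == ".json":
                json.dump(payload, fh, indent=2)
            else:
                yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with a missing mask.

    ``values[p, i]`` is the category code of person ``p`` on item ``i``
    (undefined where ``missing_mask`` is True). ``n_categories[i]`` gives the
    number of categories of item ``i``; every observed code must lie in
    ``[0, n_categories[i] - 1]``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    item_ids: list[str]
    n_categories: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D persons x items matrix")
        n, p = self.values.shape
        if self.missing_mask.shape != (n, p):
            raise SchemaError("missing_mask shape does not match values")
        if len(self.item_ids) != p or len(self.n_categories) != p:
            raise SchemaError("item_ids / n_categories length does not match columns")
        if len(set(self.item_ids)) != p:
            raise SchemaError("item_ids must be unique")
        if n < 1 or p < 1:
            raise EmptyDataError("response matrix must have at least 1 person and 1 item")
        if np.any(self.n_categories < 2):
            raise SchemaError("every item needs at least 2 categories")
        obs = ~self.missing_mask
        for j in range(p):
            col = self.values[obs[:, j], j]
            if col.size and (col.min() < 0 or col.max() >= self.n_categories[j]):
                bad = int(np.where(obs[:, j] & ((self.values[:, j] < 0) | (self.values[:, j] >= self.n_categories[j])))[0][0])
                raise RangeError(
                    f"item {self.item_ids[j]!r}, person {bad}: code "
                    f"{self.values[bad, j]} outside [0, {self.n_categories[j] - 1}]"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def max_codes(self) -> np.ndarray:
        """Per-item maximum code m_i (= n_categories - 1)."""
        return self.n_categories - 1

    def item_index(self, item: str | int) -> int:
        if isinstance(item, (int, np.integer)):
            if not 0 <= int(item) < self.n_items:
                raise SchemaError(f"item index {item} out of range")
            return int(item)
        try:
            return self.item_ids.index(item)
        except ValueError:
            raise SchemaError(f"unknown item id {item!r}") from None

    def select_items(self, items: Sequence[str | int]) -> "ResponseMatrix":
        idx = [self.item_index(i) for i in items]
        return ResponseMatrix(
            values=self.values[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            item_ids=[self.item_ids[i] for i in idx],
            n_categories=self.n_categories[idx].copy(),
        )

    def select_persons(self, rows: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(
            values=self.values[rows].copy(),
            missing_mask=self.missing_mask[rows].copy(),
            item_ids=list(self.item_ids),
            n_categories=self.n_categories.copy(),
        )

    def copy(self) -> "ResponseMatrix":
        return replace(
            self,
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            item_ids=list(self.item_ids),
            n_categories=self.n_categories.copy(),
        )


@dataclass
class MarginalTable:
    """Observed category counts (plus missing count) per item."""

    item_ids: list[str]
    counts: list[np.ndarray]  # per item: count per category
    missing: np.ndarray  # per item: missing count
    n_persons: int

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with columns c0..c{max}, missing (NaN where absent)."""
        kmax = max(len(c) for c in self.counts)
        rows = {}
        for item, cnt, miss in zip(self.item_ids, self.counts, self.missing):
            row = {f"c{k}": (int(cnt[k]) if k < len(cnt) else np.nan) for k in range(kmax)}
            row["missing"] = int(miss)
            rows[item] = row
        return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_responses(path: str | Path, spec: InstrumentSpec) -> ResponseMatrix:
    """Read a wide CSV of responses against an instrument spec.

    The header row must consist of the spec's item ids (any column order,
    preserved from the file); cells are integer category codes or the spec's
    missing sentinel.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyDataError(f"empty response file {path}") from exc
    if df.shape[0] == 0:
        raise EmptyDataError(f"no data rows in {path}")

    known = dict(spec.items)
    for col in df.columns:
        if col not in known:
            raise SchemaError(f"unknown item id {col!r} in {path}")
    missing_spec = [i for i in spec.item_ids if i not in df.columns]
    if missing_spec:
        raise SchemaError(f"items missing from {path}: {missing_spec}")

    item_ids = list(df.columns)
    n, p = df.shape
    values = np.zeros((n, p), dtype=int)
    mask = np.zeros((n, p), dtype=bool)
    n_cat = np.array([known[i] for i in item_ids], dtype=int)
    for j, col in enumerate(item_ids):
        raw = df[col].str.strip()
        is_missing = (raw == spec.missing_code) | (raw == "")
        mask[:, j] = is_missing.to_numpy()
        observed = ~mask[:, j]
        if observed.any():
            try:
                codes = raw[observed].astype(int).to_numpy()
            except ValueError as exc:
                raise SchemaError(
                    f"non-integer code in column {col!r} of {path}: {exc}"
                ) from exc
            bad = (codes < 0) | (codes >= n_cat[j])
            if bad.any():
                row = int(np.where(observed)[0][np.argmax(bad)])
                raise RangeError(
                    f"{path}: row {row}, item {col!r}: code {codes[np.argmax(bad)]} "
                    f"outside [0, {n_cat[j] - 1}]"
                )
            values[observed, j] = codes
    return ResponseMatrix(values=values, missing_mask=mask, item_ids=item_ids, n_categories=n_cat)


def save_responses(
    R: ResponseMatrix, path: str | Path, missing_code: str = DEFAULT_MISSING_CODE
) -> None:
    """Write a ResponseMatrix back to wide CSV (round-trips with load_responses)."""
    out = R.values.astype(object)
    out[R.missing_mask] = missing_code
    pd.DataFrame(out, columns=R.item_ids).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transformations and summaries
# ---------------------------------------------------------------------------

def merge_categories(
    R: ResponseMatrix, item: str | int, mapping: Sequence[int]
) -> ResponseMatrix:
    """Recode one item's categories with a monotone onto mapping.

    ``mapping[k]`` is the new code of old code ``k``; it must be
    non-decreasing, start at 0, and cover ``0..max(mapping)`` without gaps
    (e.g. ``(0, 0, 1, 1, 2, 2, 2)`` collapses 7 categories to 3).
    """
    j = R.item_index(item)
    mapping = np.asarray(mapping, dtype=int)
    m = int(R.n_categories[j])
    if mapping.shape != (m,):
        raise MappingError(
            f"mapping length {mapping.size} != {m} categories of item {R.item_ids[j]!r}"
        )
    if np.any(np.diff(mapping) < 0):
        raise MappingError(f"mapping {mapping.tolist()} is not non-decreasing")
    if mapping[0] != 0 or np.any(np.diff(mapping) > 1):
        raise MappingError(f"mapping {mapping.tolist()} must cover 0..max without gaps")
    if mapping[-1] < 1:
        raise MappingError("mapping collapses the item to a single category")
    out = R.copy()
    obs = ~out.missing_mask[:, j]
    out.values[obs, j] = mapping[out.values[obs, j]]
    out.values[~obs, j] = 0
    out.n_categories[j] = int(mapping[-1]) + 1
    return out


def marginal_frequencies(R: ResponseMatrix) -> MarginalTable:
    """Count responses per category per item, plus the missing count."""
    counts = []
    missing = np.zeros(R.n_items, dtype=int)
    for j in range(R.n_items):
        obs = ~R.missing_mask[:, j]
        counts.append(np.bincount(R.values[obs, j], minlength=R.n_categories[j]))
        missing[j] = int((~obs).sum())
    return MarginalTable(
        item_ids=list(R.item_ids), counts=counts, missing=missing, n_persons=R.n_persons
    )


def complete_cases(R: ResponseMatrix) -> tuple[ResponseMatrix, int]:
    """Listwise deletion: drop every person with any missing cell.

    Returns the reduced matrix and the number of removed persons.
    """
    keep = ~R.missing_mask.any(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyDataError("no complete cases remain after listwise deletion")
    return R.select_persons(np.where(keep)[0]), n_removed
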