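"""Core in-memory containers shared by every pipeline stage.

The common currency is :class:`OmicsMatrix`, a features x samples abundance
matrix (counts, RPKM/CPM, linear intensity, or log2 intensity) with a sample
metadata table carrying age group, animal id and condition labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_KINDS = ("counts", "intensity", "log2")


@dataclass
class OmicsMatrix:
    """Features x samples abundance matrix with sample metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by feature id, columns by sample id.
    kind : str
        One of ``counts`` (non-negative integers), ``intensity``
        (non-negative reals) or ``log2`` (reals).
    meta : pandas.DataFrame, optional
        Indexed by sample id; typical columns: ``group``, ``animal``,
        ``condition``. Restricted to the samples present in ``data``.
    """

    data: pd.DataFrame
    kind: str = "intensity"
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.kind in ("counts", "intensity"):
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"{self.kind} matrix must be non-negative")
        if self.meta is not None:
            missing = self.data.columns.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
            self.meta = self.meta.loc[self.data.columns]

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def groups(self) -> pd.Series:
        if self.meta is None or "group" not in self.meta.columns:
            raise ValueError("matrix has no 'group' metadata column")
        return self.meta["group"]

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups()
        return list(g.index[g == group])

    def to_log2(self, pseudo: float = 0.0) -> "OmicsMatrix":
        """Return a log2-scale copy; no-op if already log2."""
        if self.kind == "log2":
            return self
        return OmicsMatrix(np.log2(self.data + pseudo), kind="log2", meta=self.meta)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison, e.g. adult vs young ("12vs5")."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs >= 2 samples")

    @classmethod
    def from_groups(cls, matrix: OmicsMatrix, a: str, b: str, label: str | None = None) -> "Contrast":
        """Contrast of metadata group ``a`` vs group ``b`` (fold change a - b)."""
        return cls(
            tuple(matrix.samples_in_group(a)),
            tuple(matrix.samples_in_group(b)),
            label if label is not None else f"{a}vs{b}",
        )


class ComplexCatalog:
    """Named sets of feature identifiers (protein complexes or pathways).

    GMT-backed: each set has a name, a free-text description and a member
    list. Members are unique within a set; a feature may belong to several
    sets.
    """

    def __init__(self, sets: dict[str, set[str]], descriptions: dict[str, str] | None = None):
        self._sets: dict[str, set[str]] = {}
        self.descriptions = dict(descriptions or {})
        for name, members in sets.items():
            if name in self._sets:
                raise ValueError(f"duplicate set name: {name!r}")
            self._sets[name] = set(members)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self):
        return iter(self._sets)

    def members(self, name: str) -> set[str]:
        return set(self._sets[name])

    def items(self):
        return self._sets.items()

    def names(self) -> list[str]:
        return list(self._sets)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._sets.items()}

    def subset(self, names) -> "ComplexCatalog":
        return ComplexCatalog(
            {n: self._sets[n] for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )

    def restrict_to(self, universe: set[str], min_members: int = 1) -> "ComplexCatalog":
        """Intersect every set with ``universe``; drop sets falling below
        ``min_members``."""
        kept = {}
        for name, members in self._sets.items():
            inter = members & set(universe)
            if len(inter) >= min_members:
                kept[name] = inter
        return ComplexCatalog(kept, {n: self.descriptions.get(n, "") for n in kept})


@dataclass
class FishSurvival:
    """Per-fish lifespans with event indicators and delayed entry.

    Analysis is restricted to fish alive at the second sampling time, so
    risk sets honour left truncation at ``entry_time``.
    """

    table: pd.DataFrame  # index fish_id; columns lifespan, event, entry_time
    time_unit: str = "weeks"

    def __post_init__(self) -> None:
        required = {"lifespan", "event"}
        if not required <= set(self.table.columns):
            raise ValueError(f"survival table needs columns {required}")
        if "entry_time" not in self.table.columns:
            self.table = self.table.assign(entry_time=0.0)
        bad = self.table["lifespan"] <= self.table["entry_time"]
        if bad.any():
            raise ValueError(
                f"lifespan must exceed entry_time; offending fish: "
                f"{list(self.table.index[bad])[:5]}"
            )

    @property
    def fish_ids(self) -> pd.Index:
        return self.table.index

    @property
    def lifespan(self) -> np.ndarray:
        return self.table["lifespan"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def entry_time(self) -> np.ndarray:
        return self.table["entry_time"].to_numpy(dtype=float)

    def n_events(self) -> int:
        return int(self.table["event"].sum())


@dataclass
class SECMatrix:
    """Protein x elution-fraction intensity matrix for one SEC-MS run.

    Fractions are ordered by elution (columns ``1..n_fractions`` in reports,
    0-based internally when arrays are used).
    """

    data: pd.DataFrame  # proteins x fractions, non-negative
    condition: str = ""
    replicate: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("SEC intensities must be non-negative")

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    @property
    def proteins(self) -> pd.Index:
        return self.data.index
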