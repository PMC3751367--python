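"""Building quantitative transaction databases from time-course expression data.

Two-condition, replicated time-course log10-ratio measurements are turned
into one transaction database per condition in three steps:

1. **discretize** — each measured value becomes an up item (value strictly
   above the up threshold), a down item (strictly below the down threshold),
   or nothing.  Up and down items of the same probe are distinct items.
2. **integrate** — within a condition, the number of replicates in which an
   item occurs at a timepoint becomes the item's quantity in that
   timepoint's transaction.
3. **differentiate** — for each item and timepoint, the condition with the
   larger integrated quantity keeps the quantity *difference*; the other
   condition keeps nothing.  Equal quantities cancel on both sides.

Transactions are ordered by timepoint; the y-th transaction (1-based) holds
the items observed at the y-th timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
_ARROWS = {UP: "↑", DOWN: "↓"}

DEFAULT_UP_THRESHOLD = 0.2
DEFAULT_DOWN_THRESHOLD = -0.2

STAGE_INTEGRATED = "integrated"
STAGE_DIFFERENTIATED = "differentiated"


class InputError(ValueError):
    """Raised when an input file or dataset violates the expected structure."""


@dataclass(frozen=True)
class GeneItem:
    """A probe paired with a regulation direction.

    ``gene`` is the identifier used for impact-degree lookup; it defaults to
    the probe id when no probe-to-gene map is supplied.  Identity (equality
    and hashing) is carried by ``(probe, direction)`` together with ``gene``;
    a given probe always maps to one gene, so the pair remains unique.
    """

    probe: str
    direction: str
    gene: str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.gene is None:
            object.__setattr__(self, "gene", self.probe)

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``G5↓``."""
        return f"{self.probe}{_ARROWS[self.direction]}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def item_key(item: GeneItem) -> tuple[str, int]:
    """Canonical sort key: probe id, then up before down."""
    return (item.probe, 0 if item.direction == UP else 1)


def _timepoint_sort_key(values) -> list:
    try:
        return sorted(set(values), key=lambda v: (0, float(v)))
    except (TypeError, ValueError):
        return sorted(set(values), key=lambda v: (1, str(v)))


@dataclass
class ExpressionDataset:
    """Replicated two-condition time-course expression values.

    Parameters
    ----------
    values:
        Probes x samples matrix of log10 expression ratios.  NaN marks a
        missing measurement.
    samples:
        Sample sheet indexed by sample id with columns ``condition``,
        ``replicate`` and ``timepoint``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "replicate", "timepoint"}
        missing_cols = required - set(self.samples.columns)
        if missing_cols:
            raise InputError(f"sample sheet misses columns: {sorted(missing_cols)}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise InputError("expression matrix is empty")
        absent = [s for s in self.samples.index if s not in self.values.columns]
        if absent:
            raise InputError(f"samples in sheet but not in matrix: {absent}")
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise InputError(f"duplicate sample ids in sheet: {dupes}")
        # keep only sheeted samples, in sheet order
        self.values = self.values.loc[:, list(self.samples.index)]
        conds = list(dict.fromkeys(self.samples["condition"]))
        if len(conds) != 2:
            raise InputError(f"exactly 2 conditions required, got {conds}")
        key = self.samples[["condition", "replicate", "timepoint"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise InputError(
                "duplicate (condition, replicate, timepoint) samples: "
                f"{sorted(key[key.duplicated()].tolist())}"
            )
        self._conditions = conds
        self._timepoints = _timepoint_sort_key(self.samples["timepoint"])
        for cond in conds:
            sub = self.samples[self.samples["condition"] == cond]
            have = set(sub["timepoint"])
            lacking = [t for t in self._timepoints if t not in have]
            if lacking:
                raise InputError(f"condition {cond!r} has no sample at timepoints {lacking}")

    # -- structure ---------------------------------------------------------
    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self._conditions)

    @property
    def timepoints(self) -> list:
        return list(self._timepoints)

    @property
    def n_timepoints(self) -> int:
        return len(self._timepoints)

    def replicates(self, condition) -> list:
        sub = self.samples[self.samples["condition"] == condition]
        return sorted(set(sub["replicate"]), key=str)

    def n_replicates(self, condition) -> int:
        return len(self.replicates(condition))

    def sample_ids(self, condition=None, replicate=None, timepoint=None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if replicate is not None:
            mask &= self.samples["replicate"] == replicate
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        return list(self.samples.index[mask])

    def matrix(self, condition, timepoint) -> pd.DataFrame:
        """Probes x replicate-samples slice for one condition/timepoint."""
        return self.values[self.sample_ids(condition=condition, timepoint=timepoint)]


@dataclass
class Discretization:
    """Per-sample item sets, the output of :func:`discretize`."""

    dataset: ExpressionDataset
    up_threshold: float
    down_threshold: float
    items: dict  # (condition, replicate, timepoint) -> frozenset[GeneItem]


@dataclass
class TransactionDB:
    """Ordered per-timepoint transactions of items with integer quantities.

    ``transactions[y-1]`` is transaction T_y; items with quantity zero are
    never stored.
    """

    condition: str
    timepoints: list
    transactions: list[dict]
    n_replicates: int
    stage: str

    @property
    def n(self) -> int:
        return len(self.transactions)

    def quantity(self, item: GeneItem, y: int) -> int:
        """Quantity of *item* in transaction T_y (1-based), 0 if absent."""
        return self.transactions[y - 1].get(item, 0)

    def items(self) -> list[GeneItem]:
        """All items with positive quantity somewhere, in canonical order."""
        seen = set()
        for t in self.transactions:
            seen.update(t)
        return sorted(seen, key=item_key)

    def __iter__(self) -> Iterator[dict]:
        return iter(self.transactions)


def discretize(
    dataset: ExpressionDataset,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    probe_map: Mapping[str, str] | None = None,
) -> Discretization:
    """Turn each measured value into at most one gene item.

    A value strictly above ``up_threshold`` yields the probe's up item, a
    value strictly below ``down_threshold`` its down item; anything in
    between (including missing values) yields nothing.
    """
    if not up_threshold > down_threshold:
        raise InputError(
            f"up_threshold ({up_threshold}) must exceed down_threshold ({down_threshold})"
        )
    probe_map = probe_map or {}
    up_items = {
        p: GeneItem(p, UP, probe_map.get(p, p)) for p in dataset.probes
    }
    down_items = {
        p: GeneItem(p, DOWN, probe_map.get(p, p)) for p in dataset.probes
    }
    out: dict = {}
    for sample_id, row in dataset.samples.iterrows():
        col = dataset.values[sample_id]
        bad = col.index[np.isinf(col.to_numpy(dtype=float))]
        if len(bad):
            raise InputError(
                f"non-finite value for probe {bad[0]!r} in sample {sample_id!r}"
            )
        present = set()
        up_mask = col > up_threshold  # NaN compares False
        down_mask = col < down_threshold
        present.update(up_items[p] for p in col.index[up_mask])
        present.update(down_items[p] for p in col.index[down_mask])
        key = (row["condition"], row["replicate"], row["timepoint"])
        out[key] = frozenset(present)
    return Discretization(dataset, up_threshold, down_threshold, out)


def integrate(disc: Discretization, condition) -> TransactionDB:
    """Sum item occurrences over replicates into per-timepoint quantities."""
    ds = disc.dataset
    if condition not in ds.conditions:
        raise InputError(f"unknown condition {condition!r}; have {ds.conditions}")
    reps = ds.replicates(condition)
    transactions: list[dict] = []
    for tp in ds.timepoints:
        counts: dict = {}
        for rep in reps:
            for item in disc.items.get((condition, rep, tp), ()):
                counts[item] = counts.get(item, 0) + 1
        transactions.append(counts)
    return TransactionDB(
        condition=condition,
        timepoints=ds.timepoints,
        transactions=transactions,
        n_replicates=len(reps),
        stage=STAGE_INTEGRATED,
    )


def differentiate(db1: TransactionDB, db2: TransactionDB) -> tuple[TransactionDB, TransactionDB]:
    """Keep, per item and timepoint, only the cross-condition quantity excess.

    The condition with the larger integrated quantity receives the absolute
    difference, the other receives zero; equal quantities vanish from both.
    """
    if db1.n != db2.n:
        raise InputError(f"timepoint counts differ: {db1.n} vs {db2.n}")
    out1: list[dict] = []
    out2: list[dict] = []
    for t1, t2 in zip(db1.transactions, db2.transactions):
        d1: dict = {}
        d2: dict = {}
        for item in set(t1) | set(t2):
            q1 = t1.get(item, 0)
            q2 = t2.get(item, 0)
            if q1 > q2:
                d1[item] = q1 - q2
            elif q2 > q1:
                d2[item] = q2 - q1
        out1.append(d1)
        out2.append(d2)
    mk = lambda db, txs: TransactionDB(
        condition=db.condition,
        timepoints=list(db.timepoints),
        transactions=txs,
        n_replicates=db.n_replicates,
        stage=STAGE_DIFFERENTIATED,
    )
    return mk(db1, out1), mk(db2, out2)
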