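"""Top-k impactful itemset mining.

The *impactful value* of an itemset S in a transaction database D is an
average-utility score::

    i(S) = (1 / |S|) * sum over transactions T containing all of S
                       of sum over items x in S of d(x) * q(x, T)

where q is the item's quantity and d the gene's impact degree.  For a
single item this reduces to the plain weighted quantity sum.  The miner
returns the k itemsets of length >= 2 with the highest impactful values.

Search strategy: items are grouped into clusters with identical appearance
patterns (bit vectors over transactions).  All 2-itemsets are scored —
within a cluster the shared pattern is the support, across clusters the
AND of patterns is taken and all-zero intersections are skipped.  Longer
itemsets are grown level-wise: an l-itemset is only scored when one of its
(l-1)-subsets is still competitive, justified by the average-utility
upper bound (an itemset's value never exceeds the best value among its
one-smaller subsets, all quantities and degrees being nonnegative).  The
running threshold is the k-th best value seen (0 until k candidates are
found); search stops at the first level that adds nothing to the list.

Values are accumulated in exact integer arithmetic and divided once by the
itemset length (``fractions.Fraction``), so scores and hence rankings are
deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

from .impact import (
    ImpactDegreeTable,
    build_impact_table,
    constant_degree_table,
    significant_genes,
    uniform_degree_table,
)
from .transactions import (
    ExpressionDataset,
    GeneItem,
    TransactionDB,
    differentiate,
    discretize,
    integrate,
    item_key,
)

log = logging.getLogger(__name__)

MODE_TIIM = "tiim"
MODE_UNDIFFERENTIATION = "undifferentiation"
MODE_CONSTANT_DEGREE = "constant_degree"
MODES = (MODE_TIIM, MODE_UNDIFFERENTIATION, MODE_CONSTANT_DEGREE)

BRUTE_FORCE_ITEM_GUARD = 22


@dataclass(frozen=True)
class ScoredItemset:
    """An itemset with its impactful value and supporting transactions."""

    items: tuple[GeneItem, ...]  # canonically sorted
    value: Fraction
    support: tuple[int, ...]  # 1-based transaction indices containing all items

    @property
    def length(self) -> int:
        return len(self.items)


@dataclass
class TopKResult:
    """Ranked top-k list for one condition of one run mode."""

    itemsets: list[ScoredItemset]
    k: int
    mode: str = MODE_TIIM
    condition: str | None = None

    def __len__(self) -> int:
        return len(self.itemsets)

    def values(self) -> list[Fraction]:
        return [s.value for s in self.itemsets]


def rank_key(s: ScoredItemset):
    """Total order for ranking: higher value first, then shorter, then lexicographic."""
    return (-s.value, s.length, tuple(item_key(i) for i in s.items))


# ---------------------------------------------------------------------------
# appearance patterns

def _masks(db: TransactionDB) -> dict[GeneItem, int]:
    """Bitmask per item: bit (y-1) set iff q(item, T_y) > 0."""
    masks: dict[GeneItem, int] = {}
    for y0, t in enumerate(db.transactions):
        bit = 1 << y0
        for item in t:
            masks[item] = masks.get(item, 0) | bit
    return masks


def _support_from_mask(mask: int, n: int) -> tuple[int, ...]:
    return tuple(y for y in range(1, n + 1) if mask >> (y - 1) & 1)


def appearance_pattern(item: GeneItem, db: TransactionDB) -> tuple[int, ...]:
    """Presence/absence bit vector of *item* over the DB's transactions."""
    return tuple(1 if db.transactions[y].get(item, 0) > 0 else 0 for y in range(db.n))


def cluster_items(db: TransactionDB) -> list[list[GeneItem]]:
    """Partition items into clusters of bit-identical appearance patterns.

    Clusters are ordered by their smallest member's canonical key; members
    are canonically sorted within each cluster.
    """
    by_mask: dict[int, list[GeneItem]] = {}
    for item, mask in _masks(db).items():
        by_mask.setdefault(mask, []).append(item)
    clusters = [sorted(members, key=item_key) for members in by_mask.values()]
    clusters.sort(key=lambda c: item_key(c[0]))
    return clusters


# ---------------------------------------------------------------------------
# impactful values

def item_value(item: GeneItem, db: TransactionDB, degrees: ImpactDegreeTable) -> Fraction:
    """Impactful value of a single item: sum of degree x quantity over its transactions."""
    d = degrees.item_degree(item)
    total = sum(t.get(item, 0) for t in db.transactions)
    return Fraction(d * total)


def itemset_value(
    items: Iterable[GeneItem], db: TransactionDB, degrees: ImpactDegreeTable
) -> Fraction:
    """Impactful value of an itemset (average utility over containing transactions)."""
    s = list(items)
    if not s:
        raise ValueError("itemset must be nonempty")
    total = 0
    for t in db.transactions:
        if all(t.get(i, 0) > 0 for i in s):
            total += sum(degrees.item_degree(i) * t[i] for i in s)
    return Fraction(total, len(s))


def _score(
    items: tuple[GeneItem, ...],
    mask: int,
    db: TransactionDB,
    degrees: ImpactDegreeTable,
) -> ScoredItemset:
    """Score a candidate whose joint appearance mask is already known."""
    total = 0
    m = mask
    while m:
        y0 = (m & -m).bit_length() - 1
        t = db.transactions[y0]
        total += sum(degrees.item_degree(i) * t[i] for i in items)
        m &= m - 1
    return ScoredItemset(
        items=items,
        value=Fraction(total, len(items)),
        support=_support_from_mask(mask, db.n),
    )


# ---------------------------------------------------------------------------
# mining

def _eligible_items(
    db: TransactionDB, degrees: ImpactDegreeTable, keep_zero_degree: bool
) -> tuple[list[GeneItem], dict[GeneItem, int]]:
    masks = _masks(db)
    items = [i for i, m in masks.items() if m]
    if not keep_zero_degree:
        items = [i for i in items if degrees.item_degree(i) > 0]
    items.sort(key=item_key)
    return items, masks


def mine_top_k(
    db: TransactionDB,
    degrees: ImpactDegreeTable,
    k: int,
    max_len: int | None = None,
    keep_zero_degree: bool = False,
    mode: str = MODE_TIIM,
) -> TopKResult:
    """Mine the k itemsets (length >= 2) with the highest impactful values.

    Items whose gene has impact degree 0 are dropped before mining by
    default: a zero-weight item can never raise an itemset's average
    value.  Only itemsets with strictly positive value are reported; if
    fewer than k exist the list is shorter (logged).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items, masks = _eligible_items(db, degrees, keep_zero_degree)
    result: list[ScoredItemset] = []
    n_scored = 0
    if len(items) >= 2 and (max_len is None or max_len >= 2):
        clusters = cluster_items(db)
        keep = set(items)
        clusters = [[i for i in c if i in keep] for c in clusters]
        clusters = [c for c in clusters if c]

        scored_pairs: list[ScoredItemset] = []
        # (i) 2-itemsets within a cluster: the shared pattern is the support
        for c in clusters:
            mask = masks[c[0]]
            for a, b in itertools.combinations(c, 2):
                scored_pairs.append(_score((a, b), mask, db, degrees))
                n_scored += 1
        # (ii) 2-itemsets across clusters: intersect patterns, skip disjoint
        for ca, cb in itertools.combinations(clusters, 2):
            mask = masks[ca[0]] & masks[cb[0]]
            if mask == 0:
                continue
            for a in ca:
                for b in cb:
                    pair = (a, b) if item_key(a) <= item_key(b) else (b, a)
                    scored_pairs.append(_score(pair, mask, db, degrees))
                    n_scored += 1

        scored_pairs = [s for s in scored_pairs if s.value > 0]
        scored_pairs.sort(key=rank_key)
        result = scored_pairs[:k]
        threshold = result[-1].value if len(result) == k else Fraction(0)
        # (iii) grow level-wise; only competitive (l-1)-itemsets are extended
        frontier = [s for s in scored_pairs if s.value >= threshold]
        level = 3
        while frontier and (max_len is None or level <= max_len):
            candidates: dict[tuple[GeneItem, ...], int] = {}
            for s in frontier:
                smask = 0
                member = set(s.items)
                for it in items:
                    if it in member:
                        continue
                    mask = masks[it]
                    for i in s.items:
                        mask &= masks[i]
                    if mask == 0:
                        continue
                    cand = tuple(sorted(s.items + (it,), key=item_key))
                    candidates.setdefault(cand, mask)
            new_scored = [
                _score(cand, mask, db, degrees) for cand, mask in candidates.items()
            ]
            n_scored += len(new_scored)
            new_scored = [s for s in new_scored if s.value > 0]
            merged = sorted(result + new_scored, key=rank_key)
            new_result = merged[:k]
            added = {id(s) for s in new_result} - {id(s) for s in result}
            result = new_result
            threshold = result[-1].value if len(result) == k else Fraction(0)
            if not added:
                break
            frontier = [s for s in new_scored if s.value >= threshold]
            level += 1
    if len(result) < k:
        log.info(
            "top-%d requested but only %d itemsets with positive value exist "
            "(condition %r, %d candidates scored)",
            k, len(result), db.condition, n_scored,
        )
    log.debug(
        "mine_top_k: condition=%r items=%d scored=%d returned=%d",
        db.condition, len(items), n_scored, len(result),
    )
    return TopKResult(itemsets=result, k=k, mode=mode, condition=db.condition)


def brute_force_top_k(
    db: TransactionDB,
    degrees: ImpactDegreeTable,
    k: int,
    max_len: int | None = None,
    keep_zero_degree: bool = False,
    item_guard: int = BRUTE_FORCE_ITEM_GUARD,
) -> TopKResult:
    """Exhaustive-enumeration reference miner (testing oracle).

    Scores every itemset of length 2..max_len under the same ranking as
    :func:`mine_top_k`.  Refuses item counts above ``item_guard``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items, masks = _eligible_items(db, degrees, keep_zero_degree)
    if len(items) > item_guard:
        raise ValueError(
            f"brute force refused: {len(items)} items exceeds guard {item_guard}"
        )
    top = max_len if max_len is not None else len(items)
    scored: list[ScoredItemset] = []
    for l in range(2, top + 1):
        for combo in itertools.combinations(items, l):
            mask = masks[combo[0]]
            for it in combo[1:]:
                mask &= masks[it]
            if mask == 0:
                continue
            s = _score(combo, mask, db, degrees)
            if s.value > 0:
                scored.append(s)
    scored.sort(key=rank_key)
    return TopKResult(itemsets=scored[:k], k=k, mode=MODE_TIIM, condition=db.condition)


# ---------------------------------------------------------------------------
# end-to-end modes

def run_mode(
    dataset: ExpressionDataset,
    grn,
    k: int,
    mode: str = MODE_TIIM,
    alpha: float = 0.05,
    up_threshold: float = 0.2,
    down_threshold: float = -0.2,
    probe_map: Mapping[str, str] | None = None,
    max_len: int | None = None,
    keep_zero_degree: bool = False,
) -> dict[str, TopKResult]:
    """Run the full pipeline in one of three modes, returning per-condition top-k.

    ``tiim``
        differentiated transaction databases weighted by real impact degrees.
    ``undifferentiation``
        integrated databases (no cross-condition differencing), every gene
        weighted 1 — the classical frequent-pattern-style control.
    ``constant_degree``
        differentiated databases, weight 1 for every gene whose real impact
        degree is positive, 0 otherwise.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    disc = discretize(dataset, up_threshold, down_threshold, probe_map)
    c1, c2 = dataset.conditions
    int1 = integrate(disc, c1)
    int2 = integrate(disc, c2)

    if mode == MODE_UNDIFFERENTIATION:
        dbs = {c1: int1, c2: int2}
        degrees = uniform_degree_table()
    else:
        diff1, diff2 = differentiate(int1, int2)
        dbs = {c1: diff1, c2: diff2}
        sig = significant_genes(dataset, alpha, probe_map)
        table = build_impact_table(grn, sig, alpha)
        degrees = table if mode == MODE_TIIM else constant_degree_table(table)

    return {
        cond: mine_top_k(
            db, degrees, k,
            max_len=max_len,
            keep_zero_degree=keep_zero_degree,
            mode=mode,
        )
        for cond, db in dbs.items()
    }
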