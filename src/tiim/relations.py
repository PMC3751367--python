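"""Disassembling mined itemsets into pairwise gene relationships.

Each top-k itemset of length l contributes all C(l, 2) unordered item
pairs; pairs shared by several itemsets are merged with combined
provenance.  Pairs are the unit compared against curated regulatory
relationships: two genes appearing together in a high-value itemset are
candidate regulation/interaction partners.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

from .miner import ScoredItemset, TopKResult
from .transactions import GeneItem, item_key


@dataclass(frozen=True)
class Relation:
    """An unordered pair of items with the itemsets that produced it."""

    a: GeneItem
    b: GeneItem
    sources: tuple[tuple[int, ScoredItemset], ...]  # (rank, itemset), rank 1-based

    @property
    def best_rank(self) -> int:
        return min(r for r, _ in self.sources)

    @property
    def best_value(self) -> Fraction:
        return max(s.value for _, s in self.sources)

    @property
    def n_sources(self) -> int:
        return len(self.sources)


@dataclass
class RelationSet:
    """Deduplicated pairwise relations from one top-k list."""

    relations: list[Relation]
    gene_level: bool = False

    def pairs(self) -> set[frozenset]:
        """Pair identities, for set comparisons against a ground truth."""
        if self.gene_level:
            return {frozenset((r.a, r.b)) for r in self.relations}
        return {frozenset(((r.a.probe, r.a.direction), (r.b.probe, r.b.direction)))
                for r in self.relations}

    def __len__(self) -> int:
        return len(self.relations)


def disassemble(topk: TopKResult, gene_level: bool = False) -> RelationSet:
    """Break every itemset into its unordered pairs, merging duplicates.

    With ``gene_level=True`` items collapse to bare gene ids (direction
    dropped); pairs whose two items collapse to the same gene are skipped.
    """
    merged: dict = {}
    for rank, s in enumerate(topk.itemsets, start=1):
        for a, b in itertools.combinations(sorted(s.items, key=item_key), 2):
            if gene_level:
                ga, gb = sorted((a.gene, b.gene))
                if ga == gb:
                    continue
                key = (ga, gb)
                pair = (ga, gb)
            else:
                key = (item_key(a), item_key(b))
                pair = (a, b)
            merged.setdefault(key, (pair, []))[1].append((rank, s))
    relations = [
        Relation(a=pair[0], b=pair[1], sources=tuple(sources))
        for key, (pair, sources) in sorted(merged.items())
    ]
    return RelationSet(relations=relations, gene_level=gene_level)
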