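"""Merging DSO-DPs and their genes into gene groups (DSO-GGs).

One initial group is built per DSO-DP from its supporting genes in a
reference species. Two merge rules then run to transitive closure:

1. groups whose gene sets are exactly equal are merged (same genes, so the
   pairs plausibly descend from one shuffling event);
2. groups whose pairs are "nearly identical" — sharing one accession while
   the differing accessions are clan-mates in the Pfam clan table — are
   merged (clan-mate variation reflects model granularity, not independent
   events).

With an empty clan table rule 2 is the identity. Both rules are idempotent
and the result partitions the DSO-DP set; a gene may still belong to more
than one group. Ordering and serial-number assignment are fully
deterministic so group ids are stable across runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .classify import DsoCall
from .io_formats import same_clan
from .pairs import DomainPair


@dataclass(frozen=True)
class GeneGroup:
    """A merged set of DSO-DPs with the union of their supporting genes."""

    pairs: frozenset[DomainPair]
    genes: frozenset[str]
    represented_gene: str
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("a gene group needs at least one domain pair")


class _DSU:
    """Union-find over integer indices."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _merge_by(
    groups: Sequence[GeneGroup],
    should_merge,
) -> list[GeneGroup]:
    dsu = _DSU(len(groups))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if should_merge(groups[i], groups[j]):
                dsu.union(i, j)
    clusters: dict[int, list[GeneGroup]] = {}
    for i, g in enumerate(groups):
        clusters.setdefault(dsu.find(i), []).append(g)
    merged = [
        GeneGroup(
            pairs=frozenset().union(*(g.pairs for g in members)),
            genes=frozenset().union(*(g.genes for g in members)),
            represented_gene=min(g.represented_gene for g in members),
        )
        for _, members in sorted(clusters.items())
    ]
    return sorted(merged, key=lambda g: (g.represented_gene, sorted(map(str, g.pairs))))


def initial_groups(
    calls: Sequence[DsoCall], reference_species: str
) -> list[GeneGroup]:
    """One group per DSO-DP with that pair's reference-species genes.

    ``calls`` must be the ``is_dso`` calls of a single clade; calls without
    genes in the reference species are dropped (the pair is real but has no
    representative in the species the tables are written for).
    """
    clades = {c.clade for c in calls}
    if len(clades) > 1:
        raise ValueError(f"calls span multiple clades: {sorted(clades)}")
    records = [
        (c.pair, c.genes.get(reference_species, frozenset()))
        for c in calls
        if c.is_dso and c.genes.get(reference_species)
    ]
    return groups_from_pair_records(records)


def groups_from_pair_records(
    records: Iterable[tuple[DomainPair, frozenset[str]]],
) -> list[GeneGroup]:
    """Initial groups from bare (pair, supporting gene set) records."""
    return [
        GeneGroup(
            pairs=frozenset([pair]),
            genes=frozenset(genes),
            represented_gene=min(genes),
        )
        for pair, genes in sorted(records, key=lambda r: r[0])
    ]


def merge_equal_gene_sets(groups: Sequence[GeneGroup]) -> list[GeneGroup]:
    """Merge groups comprising exactly the same genes (transitively)."""
    return _merge_by(groups, lambda a, b: a.genes == b.genes)


def merge_near_identical_pairs(
    groups: Sequence[GeneGroup],
    clan_map: Mapping[str, str],
) -> list[GeneGroup]:
    """Merge groups whose pairs are nearly identical (transitively).

    Two pairs are nearly identical iff they share exactly one accession and
    the two differing accessions belong to one Pfam clan. With an empty clan
    map this is the identity.
    """
    def near_identical(p: DomainPair, q: DomainPair) -> bool:
        shared = p.accessions & q.accessions
        if len(shared) != 1:
            return False
        (a,) = p.accessions - shared
        (b,) = q.accessions - shared
        return same_clan(clan_map, a, b)

    def should_merge(g1: GeneGroup, g2: GeneGroup) -> bool:
        return any(
            near_identical(p, q) for p in g1.pairs for q in g2.pairs
        )

    return _merge_by(groups, should_merge)


def assign_group_ids(
    groups: Sequence[GeneGroup],
    prefix: str,
    descriptions: Optional[Mapping[str, str]] = None,
) -> list[GeneGroup]:
    """Sort deterministically and number ``prefix01``, ``prefix02``, ...

    Groups are ordered by the represented gene's description when a
    description table is supplied, falling back to the gene id; the
    represented gene is the lexicographically smallest member.
    """
    def sort_key(g: GeneGroup):
        desc = (descriptions or {}).get(g.represented_gene, "")
        return (desc, g.represented_gene)

    ordered = sorted(groups, key=sort_key)
    return [
        GeneGroup(
            pairs=g.pairs,
            genes=g.genes,
            represented_gene=g.represented_gene,
            group_id=f"{prefix}{i:02d}",
        )
        for i, g in enumerate(ordered, start=1)
    ]


def regroup(
    records: Iterable[tuple[DomainPair, frozenset[str]]],
    clan_map: Mapping[str, str],
    prefix: str = "GG",
    descriptions: Optional[Mapping[str, str]] = None,
) -> list[GeneGroup]:
    """The full two-stage merging pipeline from bare pair records."""
    groups = groups_from_pair_records(records)
    groups = merge_equal_gene_sets(groups)
    groups = merge_near_identical_pairs(groups, clan_map)
    return assign_group_ids(groups, prefix, descriptions)
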