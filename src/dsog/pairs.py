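"""Unordered within-gene domain pairs and the species x pair presence matrix.

A domain pair is an unordered pair of *distinct* Pfam accessions co-occurring
on one gene's protein product; domain order on the protein is not modelled.
The presence matrix records, for every pair and species, the set of genes
supporting the pair. Pairs whose two domains always lie one inside the other
("covered" pairs) in *every* carrier species are removed before lineage
analysis, since such nested hits describe one region, not a shuffled
combination.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import DomainHit


@dataclass(frozen=True, order=True)
class DomainPair:
    """Canonically ordered (acc_a < acc_b) pair of distinct Pfam accessions."""

    acc_a: str
    acc_b: str

    def __post_init__(self) -> None:
        if self.acc_a == self.acc_b:
            raise ValueError(f"self-pair {self.acc_a} is not a domain pair")
        if self.acc_a > self.acc_b:
            a, b = self.acc_b, self.acc_a
            object.__setattr__(self, "acc_a", a)
            object.__setattr__(self, "acc_b", b)

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset((self.acc_a, self.acc_b))

    def __str__(self) -> str:  # row label in the wide TSV serialisation
        return f"{self.acc_a}|{self.acc_b}"


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary domain-pair x species occurrence structure with gene support."""

    pairs: tuple[DomainPair, ...]
    species: tuple[str, ...]
    support: Mapping[DomainPair, Mapping[str, frozenset[str]]]

    def present(self, pair: DomainPair, species: str) -> bool:
        return bool(self.support.get(pair, {}).get(species))

    def genes(self, pair: DomainPair, species: str) -> frozenset[str]:
        return self.support.get(pair, {}).get(species, frozenset())

    def carriers(self, pair: DomainPair) -> frozenset[str]:
        return frozenset(
            s for s, genes in self.support.get(pair, {}).items() if genes
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide 0/1 matrix: rows ``PFxxxxx|PFyyyyy``, columns species."""
        data = {
            str(p): [int(self.present(p, s)) for s in self.species]
            for p in self.pairs
        }
        return pd.DataFrame(data, index=list(self.species)).T

    def support_table(self) -> pd.DataFrame:
        """Long-format (pair, species, gene_id) support table."""
        rows = [
            (str(p), s, g)
            for p in self.pairs
            for s in self.species
            for g in sorted(self.genes(p, s))
        ]
        return pd.DataFrame(rows, columns=["pair", "species", "gene_id"])

    def drop_pairs(self, pairs: Iterable[DomainPair]) -> "PresenceMatrix":
        doomed = set(pairs)
        return PresenceMatrix(
            pairs=tuple(p for p in self.pairs if p not in doomed),
            species=self.species,
            support={p: v for p, v in self.support.items() if p not in doomed},
        )


def enumerate_gene_pairs(hits_of_one_gene: Sequence[DomainHit]) -> set[DomainPair]:
    """All unordered pairs of distinct accessions present on one gene.

    Repeated instances of one accession contribute no self-pair; the result
    always has C(k, 2) members for k distinct accessions.
    """
    accs = sorted({h.pfam_acc for h in hits_of_one_gene})
    return {DomainPair(a, b) for a, b in combinations(accs, 2)}


def group_hits_by_gene(
    hits: Sequence[DomainHit],
) -> dict[str, list[DomainHit]]:
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    return by_gene


def build_presence_matrix(
    per_species_hits: Mapping[str, Sequence[DomainHit]],
) -> PresenceMatrix:
    """Compile the binary pair x species matrix with gene-level support."""
    support: dict[DomainPair, dict[str, set[str]]] = {}
    for species in per_species_hits:
        for gene, gene_hits in group_hits_by_gene(per_species_hits[species]).items():
            for pair in enumerate_gene_pairs(gene_hits):
                support.setdefault(pair, {}).setdefault(species, set()).add(gene)
    frozen = {
        p: {s: frozenset(genes) for s, genes in per_sp.items()}
        for p, per_sp in support.items()
    }
    return PresenceMatrix(
        pairs=tuple(sorted(frozen)),
        species=tuple(sorted(per_species_hits)),
        support=frozen,
    )


def species_domain_sets(
    per_species_hits: Mapping[str, Sequence[DomainHit]],
) -> dict[str, frozenset[str]]:
    """Per-species sets of single-domain accessions (for Class 1/2 calls)."""
    return {
        s: frozenset(h.pfam_acc for h in hits)
        for s, hits in per_species_hits.items()
    }


def _covers(outer: DomainHit, inner: DomainHit, cover_fraction: float) -> bool:
    overlap = min(outer.env_end, inner.env_end) - max(outer.env_start, inner.env_start) + 1
    shorter = min(
        outer.env_end - outer.env_start + 1,
        inner.env_end - inner.env_start + 1,
    )
    return overlap >= cover_fraction * shorter


def pair_covered_in_gene(
    gene_hits: Sequence[DomainHit],
    pair: DomainPair,
    cover_fraction: float = 1.0,
) -> bool:
    """True when EVERY (instance_a, instance_b) combination is nested.

    With the default ``cover_fraction=1.0`` a combination counts as nested
    when the shorter interval lies fully within the longer (equal intervals
    are mutual containment and count as covered).
    """
    hits_a = [h for h in gene_hits if h.pfam_acc == pair.acc_a]
    hits_b = [h for h in gene_hits if h.pfam_acc == pair.acc_b]
    if not hits_a or not hits_b:
        return False
    return all(
        _covers(ha, hb, cover_fraction) for ha, hb in product(hits_a, hits_b)
    )


def flag_covered_pairs(
    per_species_hits: Mapping[str, Sequence[DomainHit]],
    matrix: PresenceMatrix,
    cover_fraction: float = 1.0,
) -> dict[tuple[DomainPair, str], bool]:
    """Per (pair, species) flag: covered in every supporting gene."""
    by_species_gene = {
        s: group_hits_by_gene(per_species_hits.get(s, []))
        for s in matrix.species
    }
    flags: dict[tuple[DomainPair, str], bool] = {}
    for pair in matrix.pairs:
        for species in matrix.species:
            genes = matrix.genes(pair, species)
            if not genes:
                flags[(pair, species)] = False
                continue
            missing = [g for g in genes if g not in by_species_gene[species]]
            if missing:
                warnings.warn(
                    f"no coordinates for genes {missing} of {species}; "
                    f"pair {pair} treated as not covered",
                    stacklevel=2,
                )
                flags[(pair, species)] = False
                continue
            flags[(pair, species)] = all(
                pair_covered_in_gene(by_species_gene[species][g], pair, cover_fraction)
                for g in genes
            )
    return flags


def remove_conserved_covered_pairs(
    matrix: PresenceMatrix,
    covered_flags: Mapping[tuple[DomainPair, str], bool],
) -> PresenceMatrix:
    """Drop pairs covered in ALL carrier species; keep all others untouched."""
    doomed = [
        pair for pair in matrix.pairs
        if (carriers := matrix.carriers(pair))
        and all(covered_flags.get((pair, s), False) for s in carriers)
    ]
    return matrix.drop_pairs(doomed)
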