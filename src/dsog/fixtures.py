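"""Packaged fixtures: published gene-group tables, clan map, reference tree.

The three table fixtures transcribe the published lists of lineage-specific
shuffling-origin domain pairs and their supporting genes for vertebrates
(VGG), gnathostomes (GGG) and cyclostomes (CGG). For blind regrouping tests
the group labels can be separated from the bare pair -> gene-set records.

The clan fixture is a subset of the public Pfam clan-membership table
restricted to the accessions implicated in within-group pair variation.
The reference tree mirrors the 22-species metazoan topology used for the
clade definitions (four cyclostomes, eight gnathostomes, ten invertebrates).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .io_formats import SpeciesTree, read_clan_map, read_species_tree
from .pairs import DomainPair

CLADES = ("vertebrates", "gnathostomes", "cyclostomes")

_TABLE_FILES = {
    "vertebrates": "table1_vertebrate.tsv",
    "gnathostomes": "table2_gnathostome.tsv",
    "cyclostomes": "table3_cyclostome.tsv",
}

REFERENCE_CLADE_CONFIG = {
    "vertebrates": {"mrca": ["arctic_lamprey", "human"]},
    "gnathostomes": {"mrca": ["ghost_shark", "human"]},
    "cyclostomes": {"mrca": ["arctic_lamprey", "hagfish"]},
}


@dataclass(frozen=True)
class TableRecord:
    """One pair row of a published gene-group table."""

    clade: str
    group_id: str
    description: str
    represented_gene: str
    pair: DomainPair
    name_a: str
    name_b: str
    other_genes: tuple[str, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset((self.represented_gene, *self.other_genes))


def _data_path(filename: str):
    return resources.files("dsog.data").joinpath(filename)


def load_table_fixture(clade: str) -> list[TableRecord]:
    """Parse one packaged table into records (continuation rows expanded)."""
    records: list[TableRecord] = []
    with _data_path(_TABLE_FILES[clade]).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            group_id, desc, rep, acc_a, name_a, acc_b, name_b = fields[:7]
            others = tuple(
                g for g in (fields[7].split(",") if len(fields) > 7 else [])
                if g
            )
            records.append(TableRecord(
                clade=clade,
                group_id=group_id,
                description=desc,
                represented_gene=rep,
                pair=DomainPair(acc_a, acc_b),
                name_a=name_a,
                name_b=name_b,
                other_genes=others,
            ))
    return records


def make_table_fixtures() -> dict[str, list[TableRecord]]:
    """All three published tables as records, keyed by clade."""
    return {clade: load_table_fixture(clade) for clade in CLADES}


def pair_gene_records(
    records: list[TableRecord],
) -> list[tuple[DomainPair, frozenset[str]]]:
    """Strip group labels: bare (pair, supporting genes) for blind regrouping."""
    return [(r.pair, r.genes) for r in records]


def published_partition(records: list[TableRecord]) -> dict[str, frozenset[DomainPair]]:
    """The withheld grouping: group label -> set of pairs."""
    out: dict[str, set[DomainPair]] = {}
    for r in records:
        out.setdefault(r.group_id, set()).add(r.pair)
    return {g: frozenset(pairs) for g, pairs in out.items()}


def load_clan_fixture() -> dict[str, str]:
    """The packaged Pfam clan-membership subset."""
    return read_clan_map(_data_path("pfam_clans.tsv"))


def reference_tree() -> SpeciesTree:
    """The 22-species tree with the three named clades resolved."""
    return read_species_tree(
        _data_path("metazoa22.nwk"), REFERENCE_CLADE_CONFIG
    )
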