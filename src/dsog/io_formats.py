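"""Readers and writers for the external formats the pipeline touches.

Two hit formats are supported:

* HMMER3 per-domain tabular output ("domtblout", as written by ``hmmscan
  --domtblout``), from which the per-domain independent E-value (i-Evalue),
  envelope coordinates and the fraction of the profile model matched are
  taken;
* a documented 7-column TSV dialect
  ``protein_id  gene_id  pfam_acc  env_start  env_end  i_evalue  model_cov``
  used by the synthetic-data generator and for persisting retained hits.

All coordinates are 1-based inclusive envelope coordinates (the HMMER
convention). Pfam accession version suffixes (``PF00051.17`` -> ``PF00051``)
are stripped on input so that Pfam releases do not fragment pair identities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import yaml

#: Sentinel clan id for accessions absent from the clan membership table.
#: Two accessions mapping to this sentinel are *not* considered clan-mates.
NO_CLAN = "no-clan"


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ConfigError(ValueError):
    """A run-configuration value is inconsistent with the inputs."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One translated gene model of one species."""

    species_id: str
    gene_id: str
    protein_id: str
    length: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.length < 1:
            raise ValueError(f"protein length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class DomainHit:
    """One Pfam model match on one protein.

    ``model_cov`` is the fraction of the Pfam model length matched by the
    alignment; it drives the truncation filters.
    """

    protein: ProteinRecord
    pfam_acc: str
    pfam_name: str
    env_start: int
    env_end: int
    evalue: float
    model_cov: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end <= self.protein.length):
            raise ValueError(
                f"bad envelope [{self.env_start},{self.env_end}] on "
                f"{self.protein.protein_id} (length {self.protein.length})"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0.0 <= self.model_cov <= 1.0):
            raise ValueError("model_cov must be in [0, 1]")

    @property
    def species_id(self) -> str:
        return self.protein.species_id

    @property
    def gene_id(self) -> str:
        return self.protein.gene_id


def strip_version(acc: str) -> str:
    """``PF00051.17`` -> ``PF00051``."""
    return acc.split(".", 1)[0]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run.

    evalue_threshold
        Hits with i-Evalue >= this are discarded on input (strict ``<``).
    model_cov_min
        Minimum fraction of the Pfam model matched for a hit to count as a
        full-length domain instance (truncation Filters 4 and 5).
    relaxed_evalue
        Relaxed threshold used by the outgroup-architecture check (Filter 3)
        to guard against threshold-boundary false novelty.
    cover_fraction
        Fraction of the shorter interval that must be overlapped for a hit to
        count as "covered" by another; 1.0 (default) is strict containment.
    """

    evalue_threshold: float = 1e-3
    model_cov_min: float = 0.5
    relaxed_evalue: float = 1e-1
    cover_fraction: float = 1.0
    enable_filter3: bool = True
    enable_filter4: bool = True
    enable_filter5: bool = True
    clan_map_path: str | None = None
    seed: int = 0
    reference_species: dict = field(default_factory=lambda: {
        "vertebrates": "human",
        "gnathostomes": "human",
        "cyclostomes": "arctic_lamprey",
    })
    group_prefixes: dict = field(default_factory=lambda: {
        "vertebrates": "VGG",
        "gnathostomes": "GGG",
        "cyclostomes": "CGG",
    })

    def __post_init__(self) -> None:
        if not self.evalue_threshold > 0:
            raise ConfigError("evalue_threshold must be > 0")
        if not (0.0 <= self.model_cov_min <= 1.0):
            raise ConfigError("model_cov_min must be in [0, 1]")
        if not (0.0 < self.cover_fraction <= 1.0):
            raise ConfigError("cover_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

# domtblout column indices (hmmscan orientation: target = Pfam model,
# query = protein).
_DT_TNAME, _DT_TACC, _DT_TLEN = 0, 1, 2
_DT_QNAME, _DT_QLEN = 3, 5
_DT_IEVALUE = 12
_DT_HMM_FROM, _DT_HMM_TO = 15, 16
_DT_ENV_FROM, _DT_ENV_TO = 19, 20
_DT_MIN_COLS = 22


def read_domtblout(
    path: str | Path,
    config: RunConfig | None = None,
    *,
    species_id: str = "unknown",
    gene_map: Mapping[str, str] | None = None,
) -> list[DomainHit]:
    """Read a domtblout file or the 7-column TSV dialect.

    Only hits with i-Evalue strictly below ``config.evalue_threshold`` are
    returned. ``gene_map`` optionally maps protein ids to gene ids for
    domtblout input (the dialect carries gene ids explicitly); without it the
    protein id doubles as the gene id.

    Records with ``env_end < env_start`` are rejected with a warning and the
    run continues; any other malformed line raises :class:`ParseError` naming
    the line number.
    """
    threshold = (config or RunConfig()).evalue_threshold
    rows: list[tuple] = []  # (protein_id, gene_id, acc, name, s, e, ev, cov, qlen, lineno)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) >= _DT_MIN_COLS:
                    acc = fields[_DT_TACC]
                    if acc == "-":
                        acc = fields[_DT_TNAME]
                    tlen = int(fields[_DT_TLEN])
                    cov = (int(fields[_DT_HMM_TO]) - int(fields[_DT_HMM_FROM]) + 1) / tlen
                    protein_id = fields[_DT_QNAME]
                    rows.append((
                        protein_id,
                        (gene_map or {}).get(protein_id, protein_id),
                        strip_version(acc),
                        fields[_DT_TNAME],
                        int(fields[_DT_ENV_FROM]),
                        int(fields[_DT_ENV_TO]),
                        float(fields[_DT_IEVALUE]),
                        max(0.0, min(1.0, cov)),
                        int(fields[_DT_QLEN]),
                        lineno,
                    ))
                elif len(fields) == 7:
                    protein_id, gene_id, acc, s, e, ev, cov = fields
                    rows.append((
                        protein_id, gene_id, strip_version(acc), strip_version(acc),
                        int(s), int(e), float(ev), float(cov), None, lineno,
                    ))
                else:
                    raise ValueError(f"expected 7 or >= {_DT_MIN_COLS} columns")
            except ValueError as exc:
                raise ParseError(f"{path}: malformed line {lineno}: {exc}") from exc

    # Dialect rows carry no protein length; use the largest envelope end seen
    # on each protein as a lower bound.
    max_end: dict[str, int] = {}
    for r in rows:
        if r[8] is None:
            max_end[r[0]] = max(max_end.get(r[0], 1), max(r[4], r[5], 1))

    hits: list[DomainHit] = []
    proteins: dict[str, ProteinRecord] = {}
    for protein_id, gene_id, acc, name, s, e, ev, cov, qlen, lineno in rows:
        if e < s:
            warnings.warn(
                f"{path}: line {lineno}: env_end < env_start, record rejected",
                stacklevel=2,
            )
            continue
        if not ev < threshold:
            continue
        if protein_id not in proteins:
            proteins[protein_id] = ProteinRecord(
                species_id=species_id,
                gene_id=gene_id,
                protein_id=protein_id,
                length=qlen if qlen is not None else max_end[protein_id],
            )
        hits.append(DomainHit(
            protein=proteins[protein_id],
            pfam_acc=acc,
            pfam_name=name,
            env_start=s,
            env_end=e,
            evalue=ev,
            model_cov=cov,
        ))
    return hits


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the 7-column TSV dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("#protein_id\tgene_id\tpfam_acc\tenv_start\tenv_end\t"
                 "i_evalue\tmodel_cov\n")
        for h in hits:
            fh.write(
                f"{h.protein.protein_id}\t{h.gene_id}\t{h.pfam_acc}\t"
                f"{h.env_start}\t{h.env_end}\t{h.evalue!r}\t{h.model_cov!r}\n"
            )


def keep_longest_isoform(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Keep one translation per gene: the longest (ties: smallest protein id).

    The analysis works at gene-model level, so alternative translations of
    one gene must not inflate domain-pair support.
    """
    best: dict[tuple[str, str], ProteinRecord] = {}
    for h in hits:
        key = (h.species_id, h.gene_id)
        p = best.get(key)
        # longer wins; on equal length the lexicographically smaller id wins
        if p is None or h.protein.length > p.length or (
            h.protein.length == p.length and h.protein.protein_id < p.protein_id
        ):
            best[key] = h.protein
    return [
        h for h in hits
        if best[(h.species_id, h.gene_id)].protein_id == h.protein.protein_id
    ]


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """A rooted species tree with named internal clades."""

    tree: dendropy.Tree
    clades: dict[str, frozenset[str]]

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    def clade(self, name: str) -> frozenset[str]:
        try:
            return self.clades[name]
        except KeyError:
            raise ConfigError(f"clade {name!r} is not defined") from None

    def mrca_node(self, leaf_labels: Iterable[str]):
        return self.tree.mrca(taxon_labels=list(leaf_labels))


def read_species_tree(
    path: str | Path,
    clade_config: Mapping[str, object],
) -> SpeciesTree:
    """Read a Newick tree and resolve named clades to concrete species sets.

    ``clade_config`` maps each clade name either to an explicit leaf list or
    to ``{"mrca": [leaf_a, leaf_b]}``, in which case the clade is the full
    leaf set under the MRCA of the two leaves.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
    )
    tree.is_rooted = True
    leaves = frozenset(t.label for t in tree.taxon_namespace)
    clades: dict[str, frozenset[str]] = {}
    for name, spec in clade_config.items():
        if isinstance(spec, Mapping) and "mrca" in spec:
            anchors = list(spec["mrca"])
            missing = [a for a in anchors if a not in leaves]
            if missing:
                raise ConfigError(
                    f"clade {name!r}: species {missing} absent from tree"
                )
            node = tree.mrca(taxon_labels=anchors)
            members = frozenset(lf.taxon.label for lf in node.leaf_iter())
        else:
            members = frozenset(spec)  # type: ignore[arg-type]
            missing = sorted(members - leaves)
            if missing:
                raise ConfigError(
                    f"clade {name!r}: species {missing} absent from tree"
                )
        if not members:
            raise ConfigError(f"clade {name!r} is empty")
        clades[name] = members
    return SpeciesTree(tree=tree, clades=clades)


# ---------------------------------------------------------------------------
# Pfam clan membership
# ---------------------------------------------------------------------------

def read_clan_map(path: str | Path) -> dict[str, str]:
    """Read an accession -> clan TSV (columns: accession, clan[, clan name]).

    Accessions absent from the table map to :data:`NO_CLAN` via
    :func:`clan_of`. A duplicate accession with conflicting clans is an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"accession", "pfam_acc"}:
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}: malformed line {lineno}")
            acc, clan = strip_version(fields[0]), fields[1]
            if acc in mapping and mapping[acc] != clan:
                raise ConfigError(
                    f"{path}: accession {acc} assigned to conflicting clans "
                    f"{mapping[acc]} and {clan}"
                )
            mapping[acc] = clan
    return mapping


def clan_of(clan_map: Mapping[str, str], acc: str) -> str:
    return clan_map.get(acc, NO_CLAN)


def same_clan(clan_map: Mapping[str, str], acc_a: str, acc_b: str) -> bool:
    """True iff the accessions are identical or genuine clan-mates."""
    if acc_a == acc_b:
        return True
    ca, cb = clan_of(clan_map, acc_a), clan_of(clan_map, acc_b)
    return ca == cb and ca != NO_CLAN
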