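"""Forward simulator of domain-architecture evolution on a species tree.

Ancestral genes carrying synthetic Pfam accessions propagate from the root
to the leaves. On a branch with a planted shuffling event a new gene is
born combining one domain from each of two ancestral genes — creating a
domain pair absent ancestrally, the signature the pipeline is built to
detect. Genes are lost along branches with a per-branch retention-failure
probability, and hits can be emitted truncated (model coverage below the
truncation threshold). The output tables are valid pipeline input, and the
ground truth records which pairs should be called in which clade given the
losses that actually occurred.

No residue-level sequence is simulated: shuffling is modelled as
pair-creating gene birth, which is sufficient to exercise every pipeline
stage.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ConfigError, DomainHit, ProteinRecord, SpeciesTree
from .pairs import DomainPair

_TRUNCATED_COV = 0.3
_FULL_COV = 0.9


@dataclass
class SimConfig:
    """Study conditions for one simulated data set.

    ``n_shuffle_events`` maps branch labels (a leaf label, or the name of a
    clade for its stem branch) to the number of events planted there.
    ``loss_prob`` is the per-branch probability that a gene fails to be
    retained. ``convergent_events`` plants the pair of an earlier event
    (by index) again on another branch.
    """

    tree: SpeciesTree
    n_ancestral_genes: int = 30
    domains_per_gene: tuple[int, int] = (1, 3)
    n_shuffle_events: Mapping[str, int] = field(default_factory=dict)
    loss_prob: float = 0.0
    truncation_prob: float = 0.0
    convergent_events: Sequence[tuple[str, int]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_genes < 1:
            raise ConfigError("n_ancestral_genes must be >= 1")
        for p in (self.loss_prob, self.truncation_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimEvent:
    branch: str
    pair: DomainPair
    gene_id: str


@dataclass
class GroundTruth:
    """Planted events plus the per-clade call set they imply after losses."""

    events: list[SimEvent]
    expected_dso: dict[str, frozenset[DomainPair]]
    leaf_genes: dict[str, dict[str, tuple[str, ...]]]


def _branch_labels(tree: SpeciesTree) -> dict:
    """Map each addressable branch (child node) to a label."""
    by_leafset = {members: name for name, members in tree.clades.items()}
    labels = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            labels[node] = node.taxon.label
        else:
            leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if leafset in by_leafset:
                labels[node] = by_leafset[leafset]
    return labels


def simulate(config: SimConfig) -> tuple[dict[str, list[DomainHit]], GroundTruth]:
    """Run the forward simulation; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    labels = _branch_labels(tree)
    known_branches = set(labels.values())
    for branch in list(config.n_shuffle_events) + [b for b, _ in config.convergent_events]:
        if branch not in known_branches:
            raise ConfigError(
                f"event placed on unknown branch {branch!r}; known branches "
                f"are leaves and named clades"
            )

    # Ancestral genome: each synthetic accession belongs to exactly one gene,
    # so any cross-gene combination is novel by construction.
    lo, hi = config.domains_per_gene
    acc_counter = 0
    ancestral: dict[str, tuple[str, ...]] = {}
    for i in range(config.n_ancestral_genes):
        k = int(rng.integers(lo, hi + 1))
        accs = tuple(f"PF9{acc_counter + j:04d}" for j in range(k))
        acc_counter += k
        ancestral[f"anc{i:04d}"] = accs

    ancestral_pairs = {
        DomainPair(a, b)
        for accs in ancestral.values()
        for a in accs for b in accs if a < b
    }

    # Plan every event up-front so convergent copies can reference primary
    # events regardless of traversal order. Donor domains are drawn from
    # distinct ancestral genes, so the combined pair is novel by construction;
    # whether it is still Class 2 after losses is settled by the ground truth.
    events: list[SimEvent] = []
    planted_pairs: set[DomainPair] = set()
    gene_ids = sorted(ancestral)
    for branch in sorted(config.n_shuffle_events):
        for _ in range(config.n_shuffle_events[branch]):
            for _ in range(200):
                g1, g2 = rng.choice(gene_ids, size=2, replace=False)
                acc_a = str(rng.choice(ancestral[g1]))
                acc_b = str(rng.choice(ancestral[g2]))
                pair = DomainPair(acc_a, acc_b)
                if pair not in ancestral_pairs and pair not in planted_pairs:
                    break
            else:  # pragma: no cover — ample accession pool
                raise ConfigError("could not find a novel pair to plant")
            planted_pairs.add(pair)
            events.append(SimEvent(
                branch=branch, pair=pair,
                gene_id=f"dsog_{branch}_{len(events):02d}",
            ))
    n_primary = len(events)
    for branch, idx in config.convergent_events:
        if not 0 <= idx < n_primary:
            raise ConfigError(f"convergent event references unknown event {idx}")
        events.append(SimEvent(
            branch=branch, pair=events[idx].pair,
            gene_id=f"dsog_{branch}_{len(events):02d}",
        ))

    events_by_branch: dict[str, list[SimEvent]] = {}
    for e in events:
        events_by_branch.setdefault(e.branch, []).append(e)

    leaf_genes: dict[str, dict[str, tuple[str, ...]]] = {}

    def descend(node, genome: dict) -> None:
        for child in node.child_nodes():
            child_genome = dict(genome)
            if config.loss_prob > 0:
                for gene in sorted(child_genome):
                    if rng.random() < config.loss_prob:
                        del child_genome[gene]
            label = labels.get(child)
            if label is not None:
                for e in events_by_branch.get(label, []):
                    child_genome[e.gene_id] = (e.pair.acc_a, e.pair.acc_b)
            if child.is_leaf():
                leaf_genes[child.taxon.label] = child_genome
            else:
                descend(child, child_genome)

    descend(tree.tree.seed_node, ancestral)

    # Emit hit tables.
    per_species: dict[str, list[DomainHit]] = {}
    for species in sorted(leaf_genes):
        hits: list[DomainHit] = []
        for gene in sorted(leaf_genes[species]):
            accs = leaf_genes[species][gene]
            length = 10 + 200 * len(accs)
            protein = ProteinRecord(
                species_id=species, gene_id=gene,
                protein_id=f"{gene}.p1", length=length,
            )
            for j, acc in enumerate(accs):
                truncated = (
                    config.truncation_prob > 0
                    and rng.random() < config.truncation_prob
                )
                hits.append(DomainHit(
                    protein=protein,
                    pfam_acc=acc,
                    pfam_name=acc,
                    env_start=10 + 200 * j,
                    env_end=10 + 200 * j + 149,
                    evalue=float(10.0 ** -rng.uniform(5.0, 20.0)),
                    model_cov=_TRUNCATED_COV if truncated else _FULL_COV,
                ))
        per_species[species] = hits

    truth = GroundTruth(
        events=events,
        expected_dso=_expected_calls(tree, leaf_genes, events),
        leaf_genes=leaf_genes,
    )
    return per_species, truth


def _expected_calls(
    tree: SpeciesTree,
    leaf_genes: Mapping[str, Mapping[str, tuple[str, ...]]],
    events: Sequence[SimEvent],
) -> dict[str, frozenset[DomainPair]]:
    """Which planted pairs remain callable per clade, by direct bookkeeping.

    A pair is expected iff, after the losses that actually occurred, it is
    carried on both sides of the clade's basal split, absent from every
    outgroup species, meets the clade's high-conservation criterion, and
    both member domains still occur somewhere in the outgroup (Class 2).
    Computed with plain set arithmetic over the simulator state, independent
    of the detection pipeline.
    """
    from .lineage import reference_rules, derive_clade_rule

    try:
        rules = reference_rules(tree)
    except Exception:
        rules = {
            name: derive_clade_rule(tree, name)
            for name, members in tree.clades.items()
            if len(members) >= 2
        }

    pair_carriers: dict[DomainPair, set[str]] = {}
    acc_carriers: dict[str, set[str]] = {}
    for species, genome in leaf_genes.items():
        for accs in genome.values():
            for acc in accs:
                acc_carriers.setdefault(acc, set()).add(species)
            for a in accs:
                for b in accs:
                    if a < b:
                        pair_carriers.setdefault(DomainPair(a, b), set()).add(species)

    expected: dict[str, set[DomainPair]] = {name: set() for name in rules}
    for event in events:
        pair = event.pair
        carriers = pair_carriers.get(pair, set())
        for name, rule in rules.items():
            if carriers & rule.outgroup:
                continue
            if len(carriers & rule.split_a) < rule.min_a:
                continue
            if len(carriers & rule.split_b) < rule.min_b:
                continue
            if not rule.require_all <= carriers:
                continue
            class2 = all(
                acc_carriers.get(acc, set()) & rule.outgroup
                for acc in (pair.acc_a, pair.acc_b)
            )
            if class2:
                expected[name].add(pair)
    return {name: frozenset(pairs) for name, pairs in expected.items()}


def write_simulation(
    per_species: Mapping[str, Sequence[DomainHit]],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Emit per-species 7-column hit tables plus a ground-truth JSON."""
    from .io_formats import write_hits_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for species, hits in per_species.items():
        write_hits_tsv(hits, out / f"{species}.hits.tsv")
    payload = {
        "events": [
            {"branch": e.branch, "pair": str(e.pair), "gene_id": e.gene_id}
            for e in truth.events
        ],
        "expected_dso": {
            clade: sorted(str(p) for p in pairs)
            for clade, pairs in truth.expected_dso.items()
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
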