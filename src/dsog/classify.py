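"""The Filter 1-6 cascade turning lineage-specific pairs into DSO-DP calls.

Filter 1 keeps only highly conserved pairs (clade-specific criteria encoded
on :class:`~dsog.lineage.CladeRule`). Filter 2 splits pairs into Class 1
(either domain restricted to the lineage: origin ambiguous) and Class 2
(both domains present in outgroups: shuffling-favoured). Filters 3-5 are
named, independently switchable predicates guarding against threshold-
boundary false novelty and domain truncation. Filter 6 checks candidate
regions against cyclostome genomes through an injected similarity-search
port; no search backend is bundled.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

from .io_formats import DomainHit, RunConfig
from .lineage import CladeRule, lineage_specific_pairs
from .pairs import (
    DomainPair,
    PresenceMatrix,
    group_hits_by_gene,
    species_domain_sets,
)


class Klass(str, enum.Enum):
    CLASS1 = "CLASS1"
    CLASS2 = "CLASS2"


class Flag(str, enum.Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    SKIPPED = "SKIPPED"


FILTER_IDS = ("F1", "F2", "F3", "F4", "F5", "F6")


@dataclass
class DsoCall:
    """A lineage-specific pair with its full filter trajectory."""

    pair: DomainPair
    clade: str
    conserved: bool
    klass: Klass
    filter_flags: dict[str, Flag] = field(default_factory=dict)
    genes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def is_dso(self) -> bool:
        return (
            self.conserved
            and self.klass is Klass.CLASS2
            and not any(f is Flag.FAIL for f in self.filter_flags.values())
        )


class SequenceSearchPort(Protocol):
    """Similarity-search contract for the genomic-presence check (Filter 6).

    An adapter wrapping e.g. a BLAST installation implements this; the
    repository ships only mocks. ``find_region`` answers whether the region
    of ``gene_id`` spanning ``pair`` has a qualifying hit in the genome of
    ``target_species``.
    """

    def find_region(
        self, pair: DomainPair, gene_id: str, target_species: str
    ) -> bool: ...


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter1_conservation(
    matrix: PresenceMatrix, pair: DomainPair, rule: CladeRule
) -> bool:
    """High conservation within the clade (Filter 1)."""
    carriers = matrix.carriers(pair)
    return (
        rule.require_all <= carriers
        and len(carriers & rule.split_a) >= rule.min_a
        and len(carriers & rule.split_b) >= rule.min_b
    )


def filter2_classify(
    domain_sets: Mapping[str, frozenset[str]],
    pair: DomainPair,
    rule: CladeRule,
) -> Klass:
    """Class 2 iff BOTH member domains occur in >= 1 outgroup species."""
    def in_outgroup(acc: str) -> bool:
        return any(acc in domain_sets.get(s, frozenset()) for s in rule.outgroup)

    return (
        Klass.CLASS2
        if in_outgroup(pair.acc_a) and in_outgroup(pair.acc_b)
        else Klass.CLASS1
    )


def filters3to5(
    call: DsoCall,
    per_species_hits: Mapping[str, Sequence[DomainHit]],
    config: RunConfig,
    rule: CladeRule,
    raw_hits: Optional[Mapping[str, Sequence[DomainHit]]] = None,
) -> DsoCall:
    """Outgroup-conservation and truncation predicates (Filters 3-5).

    F3: fails when any outgroup gene carries both accessions once hits are
    re-thresholded at ``config.relaxed_evalue`` (needs ``raw_hits``, the
    unthresholded tables; without them the standard tables are re-used).
    F4: fails when every focal-lineage supporting instance of either domain
    is truncated (``model_cov < config.model_cov_min``).
    F5: discounts truncated outgroup hits; if the Class-2 status of either
    domain rested solely on truncated hits the pair reverts to Class 1.
    Disabled predicates are recorded as SKIPPED.
    """
    source = raw_hits if raw_hits is not None else per_species_hits

    # F3 — outgroup architecture at a relaxed threshold
    if not config.enable_filter3:
        call.filter_flags["F3"] = Flag.SKIPPED
    else:
        flag = Flag.PASS
        for species in rule.outgroup:
            for gene_hits in group_hits_by_gene(
                [h for h in source.get(species, [])
                 if h.evalue < config.relaxed_evalue]
            ).values():
                accs = {h.pfam_acc for h in gene_hits}
                if call.pair.acc_a in accs and call.pair.acc_b in accs:
                    flag = Flag.FAIL
                    break
            if flag is Flag.FAIL:
                break
        call.filter_flags["F3"] = flag

    # F4 — truncation of the focal-lineage instances
    if not config.enable_filter4:
        call.filter_flags["F4"] = Flag.SKIPPED
    else:
        flag = Flag.PASS
        for acc in (call.pair.acc_a, call.pair.acc_b):
            covs = [
                h.model_cov
                for species, genes in call.genes.items()
                for h in per_species_hits.get(species, [])
                if h.gene_id in genes and h.pfam_acc == acc
            ]
            if covs and all(c < config.model_cov_min for c in covs):
                flag = Flag.FAIL
                break
        call.filter_flags["F4"] = flag

    # F5 — truncation of the outgroup evidence behind Class 2
    if not config.enable_filter5:
        call.filter_flags["F5"] = Flag.SKIPPED
    else:
        flag = Flag.PASS
        if call.klass is Klass.CLASS2:
            for acc in (call.pair.acc_a, call.pair.acc_b):
                out_covs = [
                    h.model_cov
                    for species in rule.outgroup
                    for h in per_species_hits.get(species, [])
                    if h.pfam_acc == acc
                ]
                if out_covs and all(c < config.model_cov_min for c in out_covs):
                    call.klass = Klass.CLASS1
                    flag = Flag.FAIL
                    break
        call.filter_flags["F5"] = flag
    return call


def filter6_genomic_check(
    call: DsoCall,
    search: Optional[SequenceSearchPort],
    target_species: Sequence[str],
) -> DsoCall:
    """Genomic presence of the candidate region in target genomes (Filter 6).

    Fails when the pair-spanning region of any supporting gene has a
    qualifying hit in any target genome (the "novel" architecture already
    exists there un-annotated). Without a backend the check is SKIPPED; a
    raising backend also yields SKIPPED with a warning, never a silent PASS.
    """
    if search is None:
        call.filter_flags["F6"] = Flag.SKIPPED
        return call
    try:
        for target in target_species:
            for genes in call.genes.values():
                for gene in sorted(genes):
                    if search.find_region(call.pair, gene, target):
                        call.filter_flags["F6"] = Flag.FAIL
                        return call
    except Exception as exc:  # noqa: BLE001 — contract: never silently PASS
        warnings.warn(
            f"Filter 6 search backend failed ({exc}); call marked SKIPPED",
            stacklevel=2,
        )
        call.filter_flags["F6"] = Flag.SKIPPED
        return call
    call.filter_flags["F6"] = Flag.PASS
    return call


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def run_cascade(
    matrix: PresenceMatrix,
    clade_rules: Mapping[str, CladeRule],
    per_species_hits: Mapping[str, Sequence[DomainHit]],
    config: RunConfig,
    raw_hits: Optional[Mapping[str, Sequence[DomainHit]]] = None,
    search: Optional[SequenceSearchPort] = None,
) -> tuple[list[DsoCall], dict]:
    """Run Filters 1-6 over every lineage-specific pair of every clade.

    Returns the calls (ordered by clade then canonical pair order) and a
    manifest of per-stage surviving counts per clade. Filter 6 applies to
    the gnathostome clade, searching cyclostome genomes through ``search``.
    """
    domain_sets = species_domain_sets(per_species_hits)
    calls: list[DsoCall] = []
    manifest: dict = {"clades": {}}
    for clade in sorted(clade_rules):
        rule = clade_rules[clade]
        specific = sorted(lineage_specific_pairs(matrix, rule))
        stage_counts = {"lineage_specific": len(specific)}
        clade_calls: list[DsoCall] = []
        for pair in specific:
            conserved = filter1_conservation(matrix, pair, rule)
            klass = filter2_classify(domain_sets, pair, rule)
            call = DsoCall(
                pair=pair,
                clade=clade,
                conserved=conserved,
                klass=klass,
                filter_flags={
                    "F1": Flag.PASS if conserved else Flag.FAIL,
                    "F2": Flag.PASS if klass is Klass.CLASS2 else Flag.FAIL,
                },
                genes={
                    s: matrix.genes(pair, s)
                    for s in rule.clade_species
                    if matrix.genes(pair, s)
                },
            )
            if conserved and klass is Klass.CLASS2:
                call = filters3to5(call, per_species_hits, config, rule, raw_hits)
            else:
                call.filter_flags.update(
                    {"F3": Flag.SKIPPED, "F4": Flag.SKIPPED, "F5": Flag.SKIPPED}
                )
            if clade == "gnathostomes" and call.is_dso:
                cyclostomes = clade_rules.get("cyclostomes")
                targets = sorted(cyclostomes.clade_species) if cyclostomes else []
                call = filter6_genomic_check(call, search, targets)
            else:
                call.filter_flags["F6"] = Flag.SKIPPED
            clade_calls.append(call)
        stage_counts["conserved_f1"] = sum(1 for c in clade_calls if c.conserved)
        stage_counts["class2_f2"] = sum(
            1 for c in clade_calls if c.conserved and "F2" in c.filter_flags
            and c.filter_flags["F2"] is Flag.PASS
        )
        stage_counts["dso_dp"] = sum(1 for c in clade_calls if c.is_dso)
        manifest["clades"][clade] = stage_counts
        calls.extend(clade_calls)
    return calls, manifest


def calls_table(calls: Sequence[DsoCall]):
    """Flat table of calls (pair, clade, class, per-filter flag, genes)."""
    import pandas as pd

    rows = []
    for c in calls:
        row = {
            "pair": str(c.pair),
            "clade": c.clade,
            "class": c.klass.value,
            "is_dso": c.is_dso,
        }
        row.update({fid: c.filter_flags.get(fid, Flag.SKIPPED).value
                    for fid in FILTER_IDS})
        row["genes"] = ";".join(
            f"{s}:{','.join(sorted(g))}" for s, g in sorted(c.genes.items())
        )
        rows.append(row)
    return pd.DataFrame(rows)
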