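"""Lineage-specific domain-pair extraction under the basal-split sharing rule.

A pair is specific to a named clade when it is carried by at least one
species on each side of the clade's basal split and by no species outside
the clade. Convergent gain and secondary loss are not modelled; the rule
therefore under- or over-counts in their presence, a limitation carried
over from the underlying inference model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_formats import ConfigError, SpeciesTree
from .pairs import DomainPair, PresenceMatrix


@dataclass(frozen=True)
class CladeRule:
    """Declarative lineage-specificity / conservation criterion.

    ``split_a`` is the first-diverging sublineage of the clade, ``split_b``
    its sister; ``outgroup`` is every species outside the clade. ``min_a`` /
    ``min_b`` are minimum carrier counts on each side. ``require_all`` lists
    species that must ALL carry a pair for it to count as highly conserved
    (the Filter-1 criterion); it does not affect lineage specificity.
    """

    name: str
    split_a: frozenset[str]
    split_b: frozenset[str]
    outgroup: frozenset[str]
    min_a: int = 1
    min_b: int = 1
    require_all: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.split_a & self.split_b:
            raise ConfigError(f"clade {self.name!r}: splits overlap")
        if (self.split_a | self.split_b) & self.outgroup:
            raise ConfigError(f"clade {self.name!r}: outgroup overlaps clade")

    @property
    def clade_species(self) -> frozenset[str]:
        return self.split_a | self.split_b


def derive_clade_rule(tree: SpeciesTree, clade_name: str) -> CladeRule:
    """Build the rule for a named clade from the tree's basal split.

    The two children of the clade root provide ``split_a`` / ``split_b``; at
    a multifurcating root the first-listed child becomes ``split_a`` (with a
    loud warning) and the rest its sister.
    """
    members = tree.clade(clade_name)
    if len(members) < 2:
        raise ConfigError(
            f"clade {clade_name!r} has a single leaf: no basal split"
        )
    node = tree.mrca_node(members)
    node_leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
    if node_leaves != members:
        raise ConfigError(
            f"clade {clade_name!r} is not monophyletic on this tree"
        )
    children = node.child_nodes()
    child_sets = [
        frozenset(lf.taxon.label for lf in c.leaf_iter()) for c in children
    ]
    if len(child_sets) > 2:
        warnings.warn(
            f"clade {clade_name!r} root is multifurcating; using first child "
            "as the first-diverging sublineage",
            stacklevel=2,
        )
        child_sets = [child_sets[0], frozenset().union(*child_sets[1:])]
    split_a, split_b = child_sets
    return CladeRule(
        name=clade_name,
        split_a=split_a,
        split_b=split_b,
        outgroup=tree.leaves - members,
    )


def reference_rules(tree: SpeciesTree) -> dict[str, CladeRule]:
    """Rules for the three fully specified clades, with Filter-1 criteria.

    Highly conserved means: vertebrate pairs present in ALL gnathostomes and
    at least one cyclostome; gnathostome pairs in ALL gnathostomes;
    cyclostome pairs in at least one lamprey and one hagfish (which the
    basal-split minima already enforce).
    """
    rules = {}
    gnathostomes = tree.clade("gnathostomes")
    for name in ("vertebrates", "gnathostomes", "cyclostomes"):
        rule = derive_clade_rule(tree, name)
        if name in ("vertebrates", "gnathostomes"):
            rule = CladeRule(
                name=rule.name,
                split_a=rule.split_a,
                split_b=rule.split_b,
                outgroup=rule.outgroup,
                min_a=rule.min_a,
                min_b=rule.min_b,
                require_all=frozenset(gnathostomes),
            )
        rules[name] = rule
    return rules


def lineage_specific_pairs(
    matrix: PresenceMatrix, rule: CladeRule
) -> set[DomainPair]:
    """Pairs with enough carriers on both sides of the split and none outside."""
    known = set(matrix.species)
    missing = sorted((rule.clade_species | rule.outgroup) - known)
    if missing:
        raise ConfigError(
            f"clade {rule.name!r}: species {missing} absent from the matrix"
        )
    result: set[DomainPair] = set()
    for pair in matrix.pairs:
        carriers = matrix.carriers(pair)
        if (
            len(carriers & rule.split_a) >= rule.min_a
            and len(carriers & rule.split_b) >= rule.min_b
            and not carriers & rule.outgroup
        ):
            result.add(pair)
    return result
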