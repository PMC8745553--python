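"""Construction of up/down gene lists for connectivity-map queries.

Two kinds of signatures are built: (i) the six isoform proliferation-network
signatures — proliferation genes co-expressed with ZNF71, its KRAB or its
KRAB-less isoform, partitioned into up/down by the rule consequent under an
up- or down-regulated seed; and (ii) the mechanism-of-action signature
combining epithelial/mesenchymal EMT markers, drug-sensitive genes,
count-rule proliferation genes and the immune-checkpoint genes CD27/CD274.
Query submission to external services is out of scope; signatures export to
GRP/GMT.
"""

from __future__ import annotations

from collections.abc import Iterable, Set
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError, EmptySignature
from .implication import ImplicationRule, RuleType

#: 11 epithelial and 3 mesenchymal EMT markers of the 14-gene EMT classifier.
EPITHELIAL_MARKERS: tuple[str, ...] = (
    "CDH1", "EPCAM", "ESRP1", "ESRP2", "DDR1", "CTNNB1", "CD24",
    "CLDN7", "KRT8", "KRT19", "RAB25",
)
MESENCHYMAL_MARKERS: tuple[str, ...] = ("ZEB1", "VIM", "FN1")
ICI_GENES: tuple[str, ...] = ("CD27", "CD274")

#: Rule read off the seed's consequent: seed direction -> {rule type: list}.
_CONSEQUENT = {
    "up": {RuleType.UP_IMPLIES_NOTDOWN: "up", RuleType.UP_IMPLIES_NOTUP: "down"},
    "down": {RuleType.DOWN_IMPLIES_NOTDOWN: "up", RuleType.DOWN_IMPLIES_NOTUP: "down"},
}

#: Rule-type mirror when an edge's orientation is reversed (shared error cell).
_MIRROR = {
    RuleType.UP_IMPLIES_NOTDOWN: RuleType.DOWN_IMPLIES_NOTUP,
    RuleType.DOWN_IMPLIES_NOTUP: RuleType.UP_IMPLIES_NOTDOWN,
    RuleType.UP_IMPLIES_NOTUP: RuleType.UP_IMPLIES_NOTUP,
    RuleType.DOWN_IMPLIES_NOTDOWN: RuleType.DOWN_IMPLIES_NOTDOWN,
}


@dataclass(frozen=True)
class QuerySignature:
    """Named, ordered up/down gene lists with construction provenance."""

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ConsistencyError(overlap)

    def validate_for_export(self) -> None:
        if not self.up_genes or not self.down_genes:
            raise EmptySignature(f"signature {self.name!r} has an empty list")


def _oriented(rule: ImplicationRule, seed_gene: str) -> tuple[str, RuleType] | None:
    """Partner gene and the rule type as seen from the seed as premise."""
    if rule.source == seed_gene and rule.target != seed_gene:
        return rule.target, rule.rule_type
    if rule.target == seed_gene and rule.source != seed_gene:
        return rule.source, _MIRROR[rule.rule_type]
    return None


def build_isoform_signature(
    network_edges: Iterable[ImplicationRule],
    seed_gene: str,
    direction: str,
    proliferation_genes: Set[str],
) -> QuerySignature:
    """Up/down proliferation genes co-expressed with a seed isoform.

    ``direction`` ("up" or "down") is the regulation state of the seed; the
    partner gene lands in the up or down list according to the consequent of
    the significant rule whose premise matches that state.  Only partners in
    ``proliferation_genes`` are kept.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    consequent = _CONSEQUENT[direction]
    up: list[str] = []
    down: list[str] = []
    for rule in network_edges:
        if not rule.significant:
            continue
        oriented = _oriented(rule, seed_gene)
        if oriented is None:
            continue
        partner, rtype = oriented
        if partner not in proliferation_genes:
            continue
        side = consequent.get(rtype)
        if side == "up" and partner not in up:
            up.append(partner)
        elif side == "down" and partner not in down:
            down.append(partner)
    if not up and not down:
        raise EmptySignature(f"no proliferation genes co-expressed with {seed_gene}")
    return QuerySignature(
        name=f"{seed_gene}_{direction}",
        up_genes=tuple(up),
        down_genes=tuple(down),
        provenance={"rule": "isoform_proliferation", "seed": seed_gene,
                    "direction": direction},
    )


def build_mechanism_signature(
    epithelial: Iterable[str] = EPITHELIAL_MARKERS,
    mesenchymal: Iterable[str] = MESENCHYMAL_MARKERS,
    drug_sensitive_genes: Iterable[str] = (),
    proliferation_count_genes: Iterable[str] = (),
    ici_genes: Iterable[str] = ICI_GENES,
) -> QuerySignature:
    """The mechanism-of-action signature.

    UP = (epithelial ∪ drug-sensitive) minus proliferation genes;
    DOWN = mesenchymal ∪ (proliferation minus epithelial) ∪ immune-checkpoint
    genes.  Epithelial markers that are proliferation genes are excluded from
    both the up list and the proliferation term of the down list.  Any residual
    overlap between the final lists raises :class:`ConsistencyError` naming
    the offenders.
    """
    epi = list(dict.fromkeys(epithelial))
    mes = list(dict.fromkeys(mesenchymal))
    ds = list(dict.fromkeys(drug_sensitive_genes))
    prolif = set(proliferation_count_genes)
    ici = list(dict.fromkeys(ici_genes))

    up = [g for g in epi + [g for g in ds if g not in epi] if g not in prolif]
    down_prolif = sorted(prolif - set(epi))
    down = mes + [g for g in down_prolif if g not in mes]
    down += [g for g in ici if g not in down]
    return QuerySignature(
        name="mechanism_of_action",
        up_genes=tuple(up),
        down_genes=tuple(down),
        provenance={
            "rule": "mechanism_of_action",
            "n_epithelial": len(epi), "n_mesenchymal": len(mes),
            "n_drug_sensitive": len(ds), "n_proliferation": len(prolif),
            "ici": ici,
        },
    )


def drug_sensitive_genes(de_tables: Iterable[pd.DataFrame]) -> set[str]:
    """Genes sensitive to ≥ 1 regimen and resistant to none.

    Each table is a :func:`~implinet.drug_response.de_by_response` result for
    one (drug, dataset).  A gene qualifies when it is selected with direction
    higher-in-sensitive in at least one table and is never selected as
    higher-in-resistant in any table.
    """
    sensitive: set[str] = set()
    resistant: set[str] = set()
    for table in de_tables:
        sel = table[table["selected"]]
        sensitive |= set(sel.index[sel["direction"] == "higher-in-sensitive"])
        resistant |= set(sel.index[sel["direction"] == "higher-in-resistant"])
    return sensitive - resistant


def _canonical_key(rule: ImplicationRule) -> tuple:
    a = (rule.source, rule.source_layer)
    b = (rule.target, rule.target_layer)
    if a <= b:
        return (a, b, rule.rule_type)
    return (b, a, _MIRROR[rule.rule_type])


def confirm_knockdown_concordance(
    edges_patients: Iterable[ImplicationRule],
    edges_knockdown: Iterable[ImplicationRule],
) -> list[ImplicationRule]:
    """Patient-tumor edges whose pair and rule direction replicate in a
    perturbation-derived network.

    Orientation-insensitive: an edge and its mirrored reverse describe the
    same error cell and are treated as the same co-expression pattern.
    """
    knockdown_keys = {_canonical_key(r) for r in edges_knockdown if r.significant}
    return [r for r in edges_patients
            if r.significant and _canonical_key(r) in knockdown_keys]
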