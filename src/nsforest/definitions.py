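"""Assemble standardized cell type names, definitions, and logical axioms.

A cell type definition combines three components: the minimal necessary and
sufficient marker genes, a parent cell class, and a specimen source
description (anatomic structure + species).  The textual grammar is

    name:       "<first positive marker>-expressing <structure> <class>, <species>"
    definition: "A <species> <structure> <parent class> that selectively
                 expresses <positive markers> mRNAs, and lacks expression
                 of <negative markers> mRNA(s)"

and the structured counterpart is an equivalent-class axiom set: a genus
(the parent class) plus has-soma-location, capable-of, expresses, and
lacks-expression-of relations, renderable as an OWL-Manchester-like text
block.  No reasoner is invoked; the output is meant for curation.

Marker lists can be joined in two observed styles: ``all_and``
("KIT and NTNG1 and POU6F2") or ``oxfordless_comma``
("TESPA1, LINC00507 and SLC17A7").
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .datatypes import MarkerSet, ValidationError

__all__ = [
    "SpecimenContext",
    "CellTypeDefinition",
    "build_name",
    "build_definition_text",
    "build_axioms",
    "build_definition",
    "parse_definition_text",
    "render_owl",
    "summarize_marker_table",
    "load_table3_fixture",
]

LIST_STYLES = ("all_and", "oxfordless_comma")


@dataclass
class SpecimenContext:
    """Specimen metadata feeding a cell type definition.

    parent_class_short is the lineage term used in the name (e.g.
    "interneuron"); parent_class_full the one used in the definition text
    (e.g. "GABAergic interneuron").
    """

    species: str
    anatomic_structure: str
    parent_class_short: str
    parent_class_full: str | None = None
    soma_location_term: str | None = None
    functional_capacity_term: str | None = None

    def __post_init__(self) -> None:
        if not self.species or not self.anatomic_structure:
            raise ValidationError("species and anatomic_structure are required")
        if self.parent_class_full is None:
            self.parent_class_full = self.parent_class_short


@dataclass
class CellTypeDefinition:
    cluster_id: str
    name: str
    definition_text: str
    positive_markers: list[str]
    negative_markers: list[str]
    genus: str
    axioms: list[tuple[str, str]]
    colloquial_name: str | None = None

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "name": self.name,
            "colloquial_name": self.colloquial_name,
            "definition_text": self.definition_text,
            "positive_markers": list(self.positive_markers),
            "negative_markers": list(self.negative_markers),
            "genus": self.genus,
            "axioms": [list(a) for a in self.axioms],
        }


def _join(items: Sequence[str], style: str) -> str:
    if style not in LIST_STYLES:
        raise ValidationError(f"unknown list style {style!r}")
    if len(items) == 1:
        return items[0]
    if style == "all_and":
        return " and ".join(items)
    return ", ".join(items[:-1]) + " and " + items[-1]


def build_name(
    markers: MarkerSet, ctx: SpecimenContext, separator: str = "-expressing"
) -> str:
    """Standardized name led by the first positive marker gene."""
    if not markers.positive_markers:
        raise ValidationError(
            f"cluster {markers.target_cluster}: a name requires >= 1 positive marker"
        )
    first = markers.positive_markers[0]
    return (
        f"{first}{separator} {ctx.anatomic_structure} "
        f"{ctx.parent_class_short}, {ctx.species}"
    )


def build_definition_text(
    markers: MarkerSet, ctx: SpecimenContext, list_style: str = "all_and"
) -> str:
    """Textual definition; positive list always ends "mRNAs", the negative
    clause uses singular "mRNA" for a single gene."""
    if not markers.positive_markers:
        raise ValidationError(
            f"cluster {markers.target_cluster}: a definition requires >= 1 "
            "positive marker"
        )
    text = (
        f"A {ctx.species} {ctx.anatomic_structure} {ctx.parent_class_full} "
        f"that selectively expresses {_join(markers.positive_markers, list_style)} mRNAs"
    )
    if markers.negative_markers:
        unit = "mRNA" if len(markers.negative_markers) == 1 else "mRNAs"
        text += (
            f", and lacks expression of "
            f"{_join(markers.negative_markers, list_style)} {unit}"
        )
    return text


_DEF_RE = re.compile(
    r"^A (?P<species>\S+) (?P<rest>.+?) that selectively expresses "
    r"(?P<pos>.+?) mRNAs?"
    r"(?:, and lacks expression of (?P<neg>.+?) mRNAs?)?$"
)


def _split_list(text: str) -> list[str]:
    out: list[str] = []
    for chunk in text.split(", "):
        out.extend(chunk.split(" and "))
    return [x for x in out if x]


def parse_definition_text(text: str) -> tuple[list[str], list[str]]:
    """Inverse grammar: recover (positive, negative) marker lists."""
    m = _DEF_RE.match(text)
    if m is None:
        raise ValidationError(f"definition text does not match the grammar: {text!r}")
    pos = _split_list(m.group("pos"))
    neg = _split_list(m.group("neg")) if m.group("neg") else []
    return pos, neg


def build_axioms(
    markers: MarkerSet, ctx: SpecimenContext
) -> tuple[str, list[tuple[str, str]]]:
    """Equivalent-class content: genus plus relation/filler pairs."""
    if not markers.positive_markers:
        raise ValidationError("axioms require >= 1 positive marker")
    axioms: list[tuple[str, str]] = []
    if ctx.soma_location_term:
        axioms.append(("has soma location", ctx.soma_location_term))
    if ctx.functional_capacity_term:
        axioms.append(("capable of", ctx.functional_capacity_term))
    axioms += [("expresses", g) for g in markers.positive_markers]
    axioms += [("lacks expression of", g) for g in markers.negative_markers]
    return ctx.parent_class_short, axioms


def build_definition(
    markers: MarkerSet,
    ctx: SpecimenContext,
    list_style: str = "all_and",
    name_separator: str = "-expressing",
    colloquial_name: str | None = None,
) -> CellTypeDefinition:
    genus, axioms = build_axioms(markers, ctx)
    return CellTypeDefinition(
        cluster_id=markers.target_cluster,
        name=build_name(markers, ctx, name_separator),
        definition_text=build_definition_text(markers, ctx, list_style),
        positive_markers=list(markers.positive_markers),
        negative_markers=list(markers.negative_markers),
        genus=genus,
        axioms=axioms,
        colloquial_name=colloquial_name,
    )


def render_owl(definition: CellTypeDefinition) -> str:
    """OWL-Manchester-like plain-text equivalent-class block."""
    lines = [f"Class: '{definition.name}'", "  EquivalentTo:", f"    '{definition.genus}'"]
    for rel, filler in definition.axioms:
        lines.append(f"    and ('{rel}' some '{filler}')")
    return "\n".join(lines) + "\n"


def summarize_marker_table(
    definitions: Sequence[CellTypeDefinition],
) -> tuple[int, int, dict[str, int], dict[str, int]]:
    """Marker bookkeeping across a set of definitions.

    Returns (total marker mentions, distinct genes, per-cluster marker-set
    sizes, counts of cluster-id prefixes).  A gene used by two clusters
    counts twice in the mention total and once in the distinct count.
    """
    if not definitions:
        raise ValidationError("summarize_marker_table requires >= 1 definition")
    total = 0
    distinct: set[str] = set()
    sizes: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for d in definitions:
        genes = list(d.positive_markers) + list(d.negative_markers)
        total += len(genes)
        distinct.update(genes)
        sizes[d.cluster_id] = len(genes)
        prefix = re.match(r"^\D*", d.cluster_id).group(0) or d.cluster_id
        class_counts[prefix] = class_counts.get(prefix, 0) + 1
    return total, len(distinct), sizes, class_counts


def load_table3_fixture() -> list[dict]:
    """Packaged transcription of the published 16-cluster marker table."""
    text = resources.files("nsforest").joinpath("fixtures/table3.json").read_text()
    return json.loads(text)["rows"]
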