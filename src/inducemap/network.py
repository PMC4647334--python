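"""Genome-scale metabolic network as a reaction table.

A reaction is a set of reactants, a set of products, a reversibility flag,
an enzyme name and a gene association. Stoichiometry beyond species identity
is deliberately not modeled: the pipeline only needs metabolite membership
and the reaction -> gene mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

_COEF_RE = re.compile(r"^\d+(\.\d+)?\s+")


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    enzyme: str | None = None
    genes: frozenset[str] = frozenset()
    pathway: str | None = None

    @property
    def species(self) -> frozenset[str]:
        return self.reactants | self.products

    def equation(self) -> str:
        arrow = "<=>" if self.reversible else "=>"
        lhs = " + ".join(sorted(self.reactants))
        rhs = " + ".join(sorted(self.products))
        return f"{lhs} {arrow} {rhs}"


@dataclass
class MetabolicNetwork:
    reactions: list[Reaction]
    pathways: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions:
            if not rxn.reactants or not rxn.products:
                raise ValueError(
                    f"reaction {rxn.id!r} must have >=1 reactant and >=1 product"
                )
        if not self.pathways:
            self.pathways = self._pathways_from_reactions()

    def _pathways_from_reactions(self) -> dict[str, frozenset[str]]:
        acc: dict[str, set[str]] = {}
        for rxn in self.reactions:
            if rxn.pathway is None:
                continue
            acc.setdefault(rxn.pathway, set()).update(rxn.genes)
        return {p: frozenset(g) for p, g in acc.items() if g}

    @property
    def metabolites(self) -> set[str]:
        """Unique reactants/products over the whole network."""
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.species
        return out

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    def reactions_of(self, metabolite: str) -> list[Reaction]:
        """All reactions containing the metabolite as substrate or product."""
        hits = [r for r in self.reactions if metabolite in r.species]
        if not hits:
            logger.warning("metabolite %r not found in any reaction", metabolite)
        return hits


def parse_equation(eq: str) -> tuple[frozenset[str], frozenset[str], bool]:
    """Parse ``A + 2 B => C`` / ``A <=> B`` into (reactants, products, reversible).

    Integer/decimal coefficients are accepted and discarded — only species
    identity matters downstream.
    """
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        rev = True
    elif "=>" in eq:
        lhs, rhs = eq.split("=>")
        rev = False
    else:
        raise ValueError(f"no arrow ('=>' or '<=>') in equation {eq!r}")

    def side(s: str) -> frozenset[str]:
        names = []
        for tok in s.split(" + "):
            tok = _COEF_RE.sub("", tok.strip())
            if tok:
                names.append(tok)
        return frozenset(names)

    reactants, products = side(lhs), side(rhs)
    if not reactants or not products:
        raise ValueError(f"empty reaction side in equation {eq!r}")
    return reactants, products, rev


def read_reaction_table(
    path: str | Path, pathway_map: str | Path | None = None
) -> MetabolicNetwork:
    """Read a TSV reaction table.

    Required columns: reaction_id, equation, enzyme_name, gene_association
    (``;``-separated gene ids). Optional column: pathway. An external
    pathway -> gene map (GMT) may be supplied instead of the pathway column.
    """
    from .catalog import read_gmt

    reactions: list[Reaction] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            reactants, products, rev = parse_equation(row[idx["equation"]])
            genes = frozenset(
                g for g in row[idx["gene_association"]].split(";") if g
            )
            pathway = None
            if "pathway" in idx and row[idx["pathway"]]:
                pathway = row[idx["pathway"]]
            enzyme = row[idx["enzyme_name"]] or None
            reactions.append(
                Reaction(
                    id=row[idx["reaction_id"]],
                    reactants=reactants,
                    products=products,
                    reversible=rev,
                    enzyme=enzyme,
                    genes=genes,
                    pathway=pathway,
                )
            )
    pathways: dict[str, frozenset[str]] = {}
    if pathway_map is not None:
        pathways = read_gmt(pathway_map)
    return MetabolicNetwork(reactions=reactions, pathways=pathways)


def write_reaction_table(network: MetabolicNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tequation\tenzyme_name\tgene_association\tpathway\n")
        for rxn in network.reactions:
            fh.write(
                "\t".join(
                    [
                        rxn.id,
                        rxn.equation(),
                        rxn.enzyme or "",
                        ";".join(sorted(rxn.genes)),
                        rxn.pathway or "",
                    ]
                )
                + "\n"
            )


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read an SBML model into the reaction-table representation.

    Boolean gene–protein–reaction rules are flattened to the gene set (the
    pipeline never evaluates AND/OR logic); this is logged when it happens.
    """
    import cobra.io  # lazy: SBML support is optional

    model = cobra.io.read_sbml_model(str(path))
    reactions: list[Reaction] = []
    for rxn in model.reactions:
        reactants = frozenset(m.id for m in rxn.reactants)
        products = frozenset(m.id for m in rxn.products)
        if not reactants or not products:
            continue  # exchange/demand pseudo-reactions
        if rxn.gene_reaction_rule and (
            " and " in rxn.gene_reaction_rule or " or " in rxn.gene_reaction_rule
        ):
            logger.info(
                "flattening boolean gene rule for reaction %s: %r",
                rxn.id,
                rxn.gene_reaction_rule,
            )
        reactions.append(
            Reaction(
                id=rxn.id,
                reactants=reactants,
                products=products,
                reversible=rxn.reversibility,
                enzyme=rxn.name or None,
                genes=frozenset(g.id for g in rxn.genes),
                pathway=rxn.subsystem or None,
            )
        )
    return MetabolicNetwork(reactions=reactions)


def make_network(
    rows: Iterable[tuple[str, str, str | None, Iterable[str], str | None]],
) -> MetabolicNetwork:
    """Build a network from (id, equation, enzyme, genes, pathway) tuples."""
    reactions = []
    for rid, eq, enzyme, genes, pathway in rows:
        reactants, products, rev = parse_equation(eq)
        reactions.append(
            Reaction(
                id=rid,
                reactants=reactants,
                products=products,
                reversible=rev,
                enzyme=enzyme,
                genes=frozenset(genes),
                pathway=pathway,
            )
        )
    return MetabolicNetwork(reactions=reactions)
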