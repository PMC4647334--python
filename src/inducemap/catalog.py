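"""Gene annotation catalog: GO terms, pathway memberships, CAZy families,
extracellular flags and optional signal-peptide scores.

The catalog is the bridge between per-gene differential-expression calls and
the functional views (GO count matrices, pathway regulation fractions,
secretome/CAZy tables). Annotations are inputs here — GO assignment, CAZy
classification and signal-peptide prediction are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

ONTOLOGY_CLASSES = ("biological_process", "cellular_component", "molecular_function")

#: CAZy top-level classes: glycoside hydrolases, glycosyl transferases,
#: polysaccharide lyases, carbohydrate esterases, auxiliary activities.
CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA")


@dataclass
class AnnotationCatalog:
    """Per-gene functional annotations.

    Parameters
    ----------
    go
        Mapping gene -> list of ``(term, ontology_class)`` pairs. A gene may
        carry any number of terms; ontology classes are drawn from
        :data:`ONTOLOGY_CLASSES`.
    pathways
        Mapping pathway id -> set of member genes (metabolic pathway
        membership from the genome-scale model).
    cazy
        Mapping gene -> CAZy family label such as ``"GH-7"``.
    extracellular
        Genes predicted to encode extracellular (secreted) proteins.
    signal_peptide
        Optional gene -> SignalP-style D-score (input annotation, reported
        verbatim).
    function
        Optional gene -> free-text putative function label.
    """

    go: dict[str, list[tuple[str, str]]]
    pathways: dict[str, frozenset[str]]
    cazy: dict[str, str]
    extracellular: frozenset[str]
    signal_peptide: dict[str, float] = field(default_factory=dict)
    function: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.go.items():
            for _, klass in terms:
                if klass not in ONTOLOGY_CLASSES:
                    raise ValueError(
                        f"unknown ontology class {klass!r} for gene {gene!r}"
                    )

    @property
    def genes(self) -> set[str]:
        out = set(self.go)
        for members in self.pathways.values():
            out |= members
        out |= set(self.cazy)
        out |= set(self.extracellular)
        return out

    def go_terms(self) -> dict[str, str]:
        """All GO terms in the catalog mapped to their ontology class."""
        out: dict[str, str] = {}
        for terms in self.go.values():
            for term, klass in terms:
                out[term] = klass
        return out

    def cazy_class(self, gene: str) -> str | None:
        """Top-level CAZy class (``GH``/``GT``/``PL``/``CE``/``AA``) of a gene."""
        fam = self.cazy.get(gene)
        if fam is None:
            return None
        return fam.split("-", 1)[0]

    # ------------------------------------------------------------------ IO

    def write_tsv(self, path: str | Path) -> None:
        """Write the per-gene annotation table.

        Columns: gene, go_terms (``term|class`` joined by ``;``),
        cazy_family, extracellular (0/1), signal_peptide, function.
        """
        genes = sorted(self.genes)
        with open(path, "w") as fh:
            fh.write("gene\tgo_terms\tcazy_family\textracellular\tsignal_peptide\tfunction\n")
            for g in genes:
                terms = ";".join(f"{t}|{c}" for t, c in self.go.get(g, []))
                fam = self.cazy.get(g, "")
                ec = "1" if g in self.extracellular else "0"
                sp = f"{self.signal_peptide[g]:g}" if g in self.signal_peptide else ""
                fn = self.function.get(g, "")
                fh.write(f"{g}\t{terms}\t{fam}\t{ec}\t{sp}\t{fn}\n")

    def write_gmt(self, path: str | Path) -> None:
        """Write pathway gene sets in GMT format (one set per line)."""
        with open(path, "w") as fh:
            for pw in sorted(self.pathways):
                members = "\t".join(sorted(self.pathways[pw]))
                fh.write(f"{pw}\t{pw}\t{members}\n")

    @classmethod
    def read_tsv(
        cls, path: str | Path, gmt_path: str | Path | None = None
    ) -> "AnnotationCatalog":
        go: dict[str, list[tuple[str, str]]] = {}
        cazy: dict[str, str] = {}
        extracellular: set[str] = set()
        signal_peptide: dict[str, float] = {}
        function: dict[str, str] = {}
        seen: set[str] = set()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                row = line.rstrip("\n").split("\t")
                g = row[idx["gene"]]
                if g in seen:
                    raise ValueError(f"duplicate gene id in catalog: {g!r}")
                seen.add(g)
                terms = row[idx["go_terms"]]
                if terms:
                    go[g] = [
                        (t.split("|", 1)[0], t.split("|", 1)[1])
                        for t in terms.split(";")
                    ]
                else:
                    go[g] = []
                if row[idx["cazy_family"]]:
                    cazy[g] = row[idx["cazy_family"]]
                if row[idx["extracellular"]] == "1":
                    extracellular.add(g)
                if row[idx["signal_peptide"]]:
                    signal_peptide[g] = float(row[idx["signal_peptide"]])
                if row[idx["function"]]:
                    function[g] = row[idx["function"]]
        pathways: dict[str, frozenset[str]] = {}
        if gmt_path is not None:
            pathways = read_gmt(gmt_path)
        return cls(
            go=go,
            pathways=pathways,
            cazy=cazy,
            extracellular=frozenset(extracellular),
            signal_peptide=signal_peptide,
            function=function,
        )


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = frozenset(p for p in parts[2:] if p)
    return out


def make_catalog(
    go: Mapping[str, Iterable[tuple[str, str]]] | None = None,
    pathways: Mapping[str, Iterable[str]] | None = None,
    cazy: Mapping[str, str] | None = None,
    extracellular: Iterable[str] = (),
    **kw,
) -> AnnotationCatalog:
    """Convenience constructor accepting loose mappings/iterables."""
    return AnnotationCatalog(
        go={g: list(ts) for g, ts in (go or {}).items()},
        pathways={p: frozenset(m) for p, m in (pathways or {}).items()},
        cazy=dict(cazy or {}),
        extracellular=frozenset(extracellular),
        **kw,
    )
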