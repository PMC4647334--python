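"""Synthetic study generator with planted ground truth.

Emulates the design of the real experiment this pipeline targets: a glucose
reference plus ten di-/oligosaccharide enzyme inducers, three biological
replicates each, normalized log2 expression for a genome-scale gene set,
a functional annotation catalog (GO terms in three ontology classes,
metabolic pathway memberships, CAZy families, extracellular flags) and a
genome-scale reaction network. Every stochastic choice is driven by a single
seed so fixtures are bit-reproducible, and all planted structure (per-inducer
DE genes with signed log fold-changes, descriptor-space clusters, CAZy /
partner gene pairs sharing an expression profile, a fully down-regulated
pathway) is returned as an explicit :class:`GroundTruth` object.

The generator starts at normalized log2 intensities by fiat: probe-level
signal, normalization artifacts and dye bias are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import AnnotationCatalog, CAZY_CLASSES, ONTOLOGY_CLASSES
from .network import MetabolicNetwork, Reaction

#: The ten inducers of the study design, in the column order used throughout.
DEFAULT_INDUCERS = (
    "O-BGHEXA", "O-GMH", "O-XPE", "O-AHP", "O-GM3",
    "SOP", "TYR", "O-MHE", "O-CHE", "O-X3G4R",
)

DEFAULT_REFERENCE = "GLU"

# per-operation seed streams so each generator op is independently
# reproducible from the one config seed
_SEED_EXPR, _SEED_ANNOT, _SEED_NET, _SEED_DESC, _SEED_STUDY = range(5)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated experiment: a genome of 12,039 genes probed
    under 10 inducers plus a glucose reference with 3 replicates; 58 GO terms
    over the three ontology classes; 66 metabolic pathways; a reaction
    network of 2,360 reactions over 814 metabolites; a 10 item x 186
    chemical-descriptor matrix falling into 3 clusters.

    ``effect_size_logfc`` is the mean |logFC| of planted DE genes (per-gene
    magnitudes are uniform within +/-25% of it); ``noise_sd`` is the
    replicate noise standard deviation on the log2 scale.
    """

    n_genes: int = 12039
    inducers: tuple[str, ...] = DEFAULT_INDUCERS
    reference: str = DEFAULT_REFERENCE
    n_replicates: int = 3
    de_fraction_per_inducer: float = 0.1
    effect_size_logfc: float = 2.0
    noise_sd: float = 0.25
    n_go_terms: int = 58
    n_pathways: int = 66
    n_pathway_genes: int = 792  # 12 genes per pathway on average
    n_cazy_genes: int = 360
    n_cazy_families: int = 10
    extracellular_fraction: float = 0.1
    n_reactions: int = 2360
    n_metabolites: int = 814
    probe_metabolites: tuple[str, ...] = ()
    n_descriptor_items: int = 10
    n_descriptors: int = 186
    n_descriptor_clusters: int = 3
    descriptor_noise_sd: float = 1.0
    center_separation: float = 10.0  # in units of descriptor_noise_sd
    n_association_pairs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_go_terms, self.n_pathways,
               self.n_cazy_families, self.n_reactions, self.n_metabolites,
               self.n_descriptors) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.de_fraction_per_inducer <= 1.0:
            raise ValueError("de_fraction_per_inducer must be in [0, 1]")
        if not 0.0 <= self.extracellular_fraction <= 1.0:
            raise ValueError("extracellular_fraction must be in [0, 1]")
        if self.noise_sd <= 0 or self.descriptor_noise_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.reference in self.inducers:
            raise ValueError("reference condition must not appear in inducers")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset.

    ``planted_de`` maps inducer -> {gene: signed logFC} (signs are never 0);
    ``planted_clusters`` maps descriptor-matrix item -> cluster id;
    ``planted_associations`` lists (cazy_gene, partner_gene) pairs sharing an
    expression profile; ``planted_pathway`` names the (pathway, inducer) pair
    planted fully down-regulated, when one exists.
    """

    planted_de: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_clusters: dict[str, int] = field(default_factory=dict)
    planted_associations: list[tuple[str, str]] = field(default_factory=list)
    planted_pathway: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for inducer, genes in self.planted_de.items():
            for gene, lfc in genes.items():
                if lfc == 0:
                    raise ValueError(
                        f"planted logFC for {gene!r} in {inducer!r} is 0"
                    )

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_associations"] = [list(p) for p in self.planted_associations]
        payload["planted_pathway"] = (
            list(self.planted_pathway) if self.planted_pathway else None
        )
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_de=payload["planted_de"],
            planted_clusters=payload["planted_clusters"],
            planted_associations=[tuple(p) for p in payload["planted_associations"]],
            planted_pathway=tuple(payload["planted_pathway"])
            if payload["planted_pathway"] else None,
        )


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def sample_columns(config: SynthConfig) -> list[str]:
    """Sample ids encoding condition and replicate, reference first."""
    conds = (config.reference, *config.inducers)
    return [f"{c}_r{r + 1}" for c in conds for r in range(config.n_replicates)]


# --------------------------------------------------------------------------
# expression


def _plant_random(config: SynthConfig, genes: Sequence[str],
                  rng: np.random.Generator,
                  pool: Sequence[str] | None = None) -> dict[str, dict[str, float]]:
    """Independent per-inducer planting with overlap allowed across inducers."""
    pool = list(pool if pool is not None else genes)
    n_de = round(config.de_fraction_per_inducer * config.n_genes)
    n_de = min(n_de, len(pool))
    planted: dict[str, dict[str, float]] = {}
    for inducer in config.inducers:
        chosen = rng.choice(pool, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mags = config.effect_size_logfc * rng.uniform(0.75, 1.25, size=n_de)
        planted[inducer] = {g: float(s * m)
                            for g, s, m in zip(chosen, signs, mags)}
    return planted


def generate_expression(
    config: SynthConfig,
    planted: dict[str, dict[str, float]] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a replicated log2 expression matrix with planted effects.

    Non-planted genes share the same expected mean in every condition;
    a planted gene is shifted by its signed logFC in the named inducer only.
    If ``planted`` is not given, DE genes are drawn independently per inducer
    at ``de_fraction_per_inducer``.
    """
    rng = config.rng(_SEED_EXPR)
    genes = gene_ids(config.n_genes)
    cols = sample_columns(config)
    if planted is None:
        planted = (_plant_random(config, genes, rng)
                   if config.de_fraction_per_inducer > 0
                   else {i: {} for i in config.inducers})

    baseline = rng.normal(8.0, 1.5, size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(cols)))
    frame = pd.DataFrame(values, index=genes, columns=cols)
    frame.index.name = "gene"

    gene_pos = {g: i for i, g in enumerate(genes)}
    for inducer, effects in planted.items():
        cond_cols = [c for c in cols if c.rsplit("_r", 1)[0] == inducer]
        col_pos = [frame.columns.get_loc(c) for c in cond_cols]
        for g, lfc in effects.items():
            if g not in gene_pos:
                raise ValueError(f"planted gene {g!r} not in generated matrix")
            frame.iloc[gene_pos[g], col_pos] += lfc

    truth = GroundTruth(planted_de={i: dict(planted.get(i, {}))
                                   for i in config.inducers})
    return frame, truth


# --------------------------------------------------------------------------
# annotations


def _cazy_families(n: int) -> list[str]:
    # cycle the five CAZy classes; family numbers loosely evoke real ones
    numbers = (3, 7, 12, 28, 43, 61, 2, 5, 16, 9)
    return [f"{CAZY_CLASSES[i % len(CAZY_CLASSES)]}-{numbers[i % len(numbers)] + 10 * (i // len(numbers))}"
            for i in range(n)]


def generate_annotations(config: SynthConfig, genes: Sequence[str]) -> AnnotationCatalog:
    """Assign GO terms, pathway memberships, CAZy families and flags.

    GO terms are sampled per gene (Poisson mean 2, so a gene may carry
    several terms or none); pathway memberships partition a subset of
    ``n_pathway_genes`` genes into ``n_pathways`` disjoint sets; CAZy
    families go to ``n_cazy_genes`` genes; the extracellular flag is an
    independent Bernoulli(``extracellular_fraction``) per gene.
    """
    if len(genes) == 0:
        raise ValueError("genes must be nonempty")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    rng = config.rng(_SEED_ANNOT)

    # GO vocabulary split over the three ontology classes ~ 21:17:20
    n_bp = round(config.n_go_terms * 21 / 58)
    n_cc = round(config.n_go_terms * 17 / 58)
    n_mf = config.n_go_terms - n_bp - n_cc
    term_class = (
        [ONTOLOGY_CLASSES[0]] * n_bp
        + [ONTOLOGY_CLASSES[1]] * n_cc
        + [ONTOLOGY_CLASSES[2]] * n_mf
    )
    terms = [(f"GO:{i + 1:07d}", term_class[i]) for i in range(config.n_go_terms)]

    go: dict[str, list[tuple[str, str]]] = {}
    n_terms = rng.poisson(2.0, size=len(genes))
    for g, k in zip(genes, n_terms):
        k = min(int(k), len(terms))
        if k == 0:
            go[g] = []
        else:
            idx = rng.choice(len(terms), size=k, replace=False)
            go[g] = [terms[i] for i in sorted(idx)]

    # disjoint pathway partition of a gene subset
    n_pw_genes = min(config.n_pathway_genes, len(genes))
    pw_members = rng.choice(genes, size=n_pw_genes, replace=False)
    chunks = np.array_split(pw_members, config.n_pathways)
    pathways = {f"pw_{i + 1:03d}": frozenset(chunk.tolist())
                for i, chunk in enumerate(chunks) if len(chunk)}

    families = _cazy_families(config.n_cazy_families)
    n_cazy = min(config.n_cazy_genes, len(genes))
    cazy_genes = rng.choice(genes, size=n_cazy, replace=False)
    cazy = {g: families[i % len(families)]
            for i, g in enumerate(sorted(cazy_genes))}

    flags = rng.random(len(genes)) < config.extracellular_fraction
    extracellular = frozenset(g for g, f in zip(genes, flags) if f)

    function = {g: f"{fam} family protein" for g, fam in cazy.items()}
    signal_peptide = {g: float(np.round(rng.uniform(0.45, 0.95), 3))
                      for g in sorted(cazy) if g in extracellular}

    return AnnotationCatalog(
        go=go, pathways=pathways, cazy=cazy, extracellular=extracellular,
        signal_peptide=signal_peptide, function=function,
    )


# --------------------------------------------------------------------------
# metabolic network


def generate_metabolic_network(
    config: SynthConfig,
    genes: Sequence[str],
    pathways: dict[str, frozenset[str]] | None = None,
) -> MetabolicNetwork:
    """Generate a toy reaction network with guaranteed probe metabolites.

    Each reaction gets 1-3 reactants, 1-3 products, ~20% reversibility, a
    pathway label and a gene association drawn from that pathway's gene set
    (so the network's pathway map stays consistent with the catalog when one
    is passed in). Every ``probe_metabolites`` entry is guaranteed to occur
    in at least one gene-associated reaction.
    """
    if config.n_reactions < 1:
        raise ValueError("requested reaction count must be >= 1")
    rng = config.rng(_SEED_NET)

    if pathways is None:
        n_pw_genes = min(config.n_pathway_genes, len(genes))
        members = rng.choice(genes, size=n_pw_genes, replace=False)
        chunks = np.array_split(members, config.n_pathways)
        pathways = {f"pw_{i + 1:03d}": frozenset(c.tolist())
                    for i, c in enumerate(chunks) if len(c)}
    pw_names = sorted(pathways)

    n_plain = max(config.n_metabolites - len(config.probe_metabolites), 1)
    pool = np.array([f"M{i:04d}" for i in range(n_plain)]
                    + list(config.probe_metabolites))

    reactions: list[Reaction] = []
    for i in range(config.n_reactions):
        n_r = int(rng.integers(1, 4))
        n_p = int(rng.integers(1, 4))
        species = rng.choice(pool, size=n_r + n_p, replace=False)
        pw = pw_names[i % len(pw_names)]
        pw_genes = sorted(pathways[pw])
        n_g = int(rng.integers(0, 4)) if pw_genes else 0
        assoc = (frozenset(rng.choice(pw_genes, size=min(n_g, len(pw_genes)),
                                      replace=False).tolist())
                 if n_g else frozenset())
        reactions.append(Reaction(
            id=f"R{i + 1:04d}",
            reactants=frozenset(species[:n_r].tolist()),
            products=frozenset(species[n_r:].tolist()),
            reversible=bool(rng.random() < 0.2),
            enzyme=f"enzyme_{i + 1:04d}",
            genes=assoc,
            pathway=pw,
        ))

    # guarantee each probe metabolite a gene-associated reaction
    for j, probe in enumerate(config.probe_metabolites):
        if any(probe in r.species and r.genes for r in reactions):
            continue
        k = j % len(reactions)
        old = reactions[k]
        pw_genes = sorted(pathways.get(old.pathway, frozenset())) or sorted(
            pathways[pw_names[0]])
        assoc = old.genes or frozenset(
            rng.choice(pw_genes, size=1).tolist())
        reactions[k] = Reaction(
            id=old.id,
            reactants=frozenset({probe} | set(sorted(old.reactants)[1:])),
            products=old.products,
            reversible=old.reversible,
            enzyme=old.enzyme,
            genes=assoc,
            pathway=old.pathway,
        )

    return MetabolicNetwork(reactions=reactions, pathways=dict(pathways))


# --------------------------------------------------------------------------
# descriptor matrix


def generate_descriptor_table(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Item x chemical-descriptor matrix from well-separated Gaussian centers.

    Cluster centers are isotropic Gaussian draws rescaled so the minimum
    pairwise center distance equals ``center_separation * descriptor_noise_sd``;
    items are balanced over centers and perturbed by isotropic noise. The
    planted labels are recorded in ``GroundTruth.planted_clusters``.
    """
    n, d, k = (config.n_descriptor_items, config.n_descriptors,
               config.n_descriptor_clusters)
    if n < 2 or d < 1:
        raise ValueError("need >=2 items and >=1 descriptor")
    if k > n:
        raise ValueError(f"k={k} clusters exceed n={n} items")
    rng = config.rng(_SEED_DESC)

    if k == 1:
        centers = np.zeros((1, d))
    else:
        centers = rng.normal(size=(k, d))
        dists = [np.linalg.norm(centers[a] - centers[b])
                 for a in range(k) for b in range(a + 1, k)]
        target = config.center_separation * config.descriptor_noise_sd
        centers *= target / min(dists)

    labels = rng.permutation(np.arange(n) % k)
    X = centers[labels] + rng.normal(0.0, config.descriptor_noise_sd, size=(n, d))
    items = [f"item{i + 1:02d}" for i in range(n)]
    frame = pd.DataFrame(X, index=items,
                         columns=[f"D{j + 1}" for j in range(d)])
    frame.index.name = "item"
    truth = GroundTruth(planted_clusters={it: int(l)
                                          for it, l in zip(items, labels)})
    return frame, truth


# --------------------------------------------------------------------------
# coordinated study


@dataclass
class StudyData:
    """A coherent synthetic study: expression + annotations + network + truth."""

    config: SynthConfig
    expression: pd.DataFrame
    catalog: AnnotationCatalog
    network: MetabolicNetwork
    truth: GroundTruth


def generate_study(config: SynthConfig) -> StudyData:
    """Generate a full study with coordinated planted structure.

    Three kinds of structure are planted on top of the random per-inducer DE
    sets, using genes that are excluded from the random pool so the ground
    truth stays exact:

    * the lexicographically first metabolic pathway is planted fully
      down-regulated in one target inducer (O-CHE when present);
    * ``n_association_pairs`` (extracellular CAZy gene, extracellular
      non-CAZy gene) pairs are planted significant in every inducer with a
      shared per-pair sign vector, so the pair shares its signed expression
      profile end-to-end;
    * all metabolic-pathway genes receive planted effects only through the
      pathway planting above, keeping every other pathway's regulation
      fraction at the false-positive floor.
    """
    rng = config.rng(_SEED_STUDY)
    genes = gene_ids(config.n_genes)
    catalog = generate_annotations(config, genes)
    network = generate_metabolic_network(config, genes, pathways=catalog.pathways)

    pathway_genes = set().union(*catalog.pathways.values()) if catalog.pathways else set()
    target_pathway = sorted(catalog.pathways)[0] if catalog.pathways else None
    target_inducer = "O-CHE" if "O-CHE" in config.inducers else config.inducers[-1]

    planted: dict[str, dict[str, float]] = {i: {} for i in config.inducers}
    mag = config.effect_size_logfc

    if target_pathway is not None:
        for g in sorted(catalog.pathways[target_pathway]):
            planted[target_inducer][g] = float(-mag * rng.uniform(0.75, 1.25))

    cazy_ext = sorted((set(catalog.cazy) & set(catalog.extracellular))
                      - pathway_genes)
    partner_pool = sorted(set(catalog.extracellular) - set(catalog.cazy)
                          - pathway_genes)
    n_pairs = min(config.n_association_pairs, len(cazy_ext), len(partner_pool))
    pairs: list[tuple[str, str]] = []
    for p in range(n_pairs):
        c, g = cazy_ext[p], partner_pool[p]
        pairs.append((c, g))
        signs = rng.choice([-1.0, 1.0], size=len(config.inducers))
        for s, inducer in zip(signs, config.inducers):
            planted[inducer][c] = float(s * mag * rng.uniform(0.75, 1.25))
            planted[inducer][g] = float(s * mag * rng.uniform(0.75, 1.25))

    reserved = pathway_genes | {g for pr in pairs for g in pr}
    pool = [g for g in genes if g not in reserved]
    if config.de_fraction_per_inducer > 0:
        random_planted = _plant_random(config, genes, rng, pool=pool)
        for inducer in config.inducers:
            merged = dict(random_planted[inducer])
            merged.update(planted[inducer])  # coordinated planting wins
            planted[inducer] = merged

    expression, _ = generate_expression(config, planted=planted)
    truth = GroundTruth(
        planted_de=planted,
        planted_associations=pairs,
        planted_pathway=(target_pathway, target_inducer)
        if target_pathway else None,
    )
    return StudyData(config=config, expression=expression, catalog=catalog,
                     network=network, truth=truth)


# --------------------------------------------------------------------------
# serialization


def write_expression(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
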