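# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and the deliberate design decisions behind `inducemap`, in the
order the pipeline runs.

## Experimental design assumed

The pipeline assumes a *reference-vs-inducers* short-induction design: a
culture pre-grown on glucose is exposed to each of N chemically defined
inducer oligosaccharides, expression is measured on a log2 scale with
replicated samples per condition (≥ 2, typically 3), and every question is
phrased as "how does condition X differ from glucose". Sample columns are
named `<condition>_r<replicate>` (e.g. `O-CHE_r2`); exactly one condition
is the designated reference. Probe-level summarization, normalization and
background correction are upstream of the package: inputs are normalized
log2 intensities, one value per gene per sample.

## Differential expression

For each inducer and gene, `logFC = mean log2(inducer) − mean log2(glucose)`
and a two-sample t-test on the replicate values. Two statistics are
offered:

* **pooled (Student) t — default.** With tiny, equally sized replicate
  groups and a homoscedastic noise model, the pooled test is exactly
  calibrated: its null rejection rate at α equals α. This matters because
  downstream pathway fractions and secretome counts inherit the calibration
  of the gene-level calls.
* **Welch t — `statistic="welch"`.** The unequal-variance test is the safer
  choice when replicate variances genuinely differ, but at n = 3 per group
  its estimated degrees of freedom make it materially conservative
  (empirical size ≈ 0.035 at nominal 0.05 under equal variances), which
  biases every downstream count low. It is therefore an option, not the
  default.

Significance is raw *p* < α (default α = 0.05), matching the plain
significance rule this class of studies reports; Benjamini–Hochberg is
available behind `adjust="bh"`. Degenerate inputs are not errors: if both
groups have zero variance, *p* = 1 when the means agree and *p* → 0⁺ when
they differ. Genes with missing values in any used sample are dropped with
a logged warning. `direction` is `up`/`down` only for significant genes
with nonzero logFC.

## GO count matrix and descriptor importance

`cell(term, inducer)` counts significant genes annotated to the term; a
gene carrying *t* terms contributes once to each of the *t* rows (no
deduplication across terms — the alternative, counting a gene once in
total, would make row sums depend on an arbitrary term priority). Coverage
— the fraction of significant genes with ≥ 1 GO term — is reported per
inducer, since annotation completeness varies strongly between gene sets.
The term universe is whatever the catalog provides; no ancestor propagation
or enrichment testing is done (the matrix is a fingerprint, not a test).

Row standardization is the population z-score; zero-variance rows map to
all-zero and are flagged rather than dropped.

Descriptor importance uses the correlation-based feature-selection (CFS)
merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` evaluated for each descriptor as a
singleton (k = 1, where the merit reduces to the descriptor's absolute
label correlation, averaged over the label's class indicators), under
cross-validation over the items: folds default to 10 and degenerate to
leave-one-out when there are no more items than folds. Fold membership is
derived from *sorted column names* plus the seed, so the ranking is
invariant to column order. Ties break lexicographically by descriptor name.

## SOM-seeded k-means

The SOM is trained sequentially: per iteration one item is drawn uniformly
(seeded), its best-matching unit (BMU) found by Euclidean distance (ties →
lowest neuron index), and every codebook vector updated by
`w ← w + α(t)·exp(−d²(BMU, u)/2σ(t)²)·(x − w)` on the rectangular grid.
Defaults: 4000 iterations; α decays linearly 0.05 → 0.02; σ decays linearly
from half the grid diagonal to 0.1. The small σ floor is a deliberate
fine-tuning phase: with a wide final neighborhood (e.g. floor 0.5) each
neuron keeps being pulled toward neighboring clusters and the codebook ends
up interpolating *between* data clusters, which ruins it as a k-means seed;
with floor 0.1 each occupied neuron converges onto the centroid of its own
receptive field. The codebook is initialized by sampling items with
replacement plus a 10⁻⁴-scaled per-feature jitter, so a single-item dataset
is an exact fixed point and duplicate initial neurons separate
deterministically.

k-means then runs on the original items (`k` is an explicit parameter,
default 3 — no parameter-free rule can be promised for choosing it, so none
is pretended): k-means++ selects k centers among the *occupied* distinct
codebook vectors (BMU of ≥ 1 item; the full codebook is the fallback when
fewer than k are occupied), Lloyd iterations are capped at 4000, and the
best of `n_init = 20` seeded starts by final inertia is kept. The restarts
are cheap (item sets here are tens of rows) and close the gap between the
seeded local optimum and the global one: on planted three-cluster
descriptor matrices (10 items × 186 descriptors, center separation 10× the
per-descriptor noise), the planted partition is recovered with adjusted
Rand index 1.0 in ≈ 97/100 runs, and the residual failures are instances
whose *global* k-means optimum genuinely differs from the planted labels —
at this separation the noise volume of a 186-dimensional Gaussian
occasionally makes an alternative partition cheaper.

The 24-neuron grid used for GO matrices is realized as 4×6. Hierarchical
clustering is scipy's agglomerative linkage (default: average linkage,
Euclidean metric) with the dendrogram's leaf order exported for heatmaps
and a Newick rendering with merge heights as branch lengths.

## Pathway regulation

`f_up(p, i) = |pathway(p) ∩ up(i)| / |pathway(p)|`, analogously `f_down`;
denominators are the pathway's full gene-set size and constant across
inducers. Genes shared between pathways count toward each — per-pathway
fractions are only meaningful that way. "Highly affected" is the inclusive
rule `f_up + f_down ≥ 0.5`. Pathways with empty gene sets are excluded with
a warning. No flux analysis and no stoichiometry beyond species identity is
used anywhere. The two-block clustering matrix has inducers as rows and two
columns per pathway (`<pathway>|up`, `<pathway>|down`).

## Secretome and CAZy tables

The extracellular table keeps genes flagged extracellular with a
significant change in ≥ 1 inducer, carrying the *full* logFC row so the
matrix can be clustered directly. CAZy regulation counts are distinct-gene
and existential: a gene is "up" if up-regulated in at least one inducer;
genes up in one inducer and down in another increment both tallies and the
reported overlap. Signal-peptide scores are input annotations reported
verbatim — the package never predicts secretion or CAZy membership from
sequence. Induction tables render DE directions as `↑`/`↓`/`—` and raise on
unknown genes, listing the offenders.

## Guilt by association

Each gene's response collapses to a ternary signed profile (+1, −1, 0 per
inducer). A candidate (extracellular, non-CAZy) is associated with a CAZy
gene iff the profiles are *identical on the CAZy gene's nonzero support
set* and the support has ≥ `min_support` inducers (default 2 — a
one-inducer match carries no profile information). Direction is part of the
match: co-significance with opposite signs does not associate. A
correlation mode (Pearson on logFC over shared significant inducers) exists
behind the API for exploratory use but is not the default, because an exact
ternary rule has no free threshold and is reproducible by recount. Edges
are directed CAZy → candidate; the exported network types nodes as
`cazy_gene` / `associated_gene` / `inducer` and draws a gene–inducer edge
exactly when the gene is significant in that inducer.

## Metabolite–gene association

For each candidate metabolite, every reaction containing it as substrate or
product (reversible reactions match on either side) contributes one row per
associated gene; gene-less reactions keep an all-missing row so the
reaction context is preserved. Cells hold the gene's logFC where
significant and are missing ("-" in TSV) otherwise: missing means "not
significantly different from glucose" and is excluded from statistics and
consistency calls rather than treated as zero. A metabolite is
`down_consistent` iff every observed cell of every associated gene is
negative (`up_consistent` analogously), `mixed` otherwise, `no_data` with
no observed cells. Boolean gene–protein–reaction rules in SBML input are
flattened to their gene set (logged); the package never evaluates AND/OR
enzyme logic. An absent metabolite yields an empty reaction list with a
warning, not an error.

The packaged strong-binder table transcribes the six metabolites' printed
rows (ten inducer columns in the order O-BGHEXA, O-GMH, O-XPE, O-AHP,
O-GM3, SOP, TYR, O-MHE, O-CHE, O-X3G4R) and is SHA-256-checked on load. The
printed transketolase (T3P1) entry has eight filled cells against ten
columns with the two gaps not explicitly aligned; the fixture records them
under O-GM3 and O-X3G4R by column-count alignment — a transcription
assumption, flagged here. Its two additional cofactor-shuffling reactions
are kept as gene-less rows. The strong-binder list itself is an *input*:
docking, pocket detection and scoring are out of scope by design.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study geometry: 12,039 genes, ten inducers
(O-BGHEXA, O-GMH, O-XPE, O-AHP, O-GM3, SOP, TYR, O-MHE, O-CHE, O-X3G4R)
plus a glucose reference, three replicates; 58 GO terms split ≈ 21/17/20
over the three ontology classes; 66 metabolic pathways partitioning 792
genes (12 per pathway — typical for a genome-scale model); 2,360 reactions
over 814 metabolites; 360 CAZy genes over 10 families; 10% of genes flagged
extracellular; and a 10 × 186 chemical-descriptor matrix in 3 planted
clusters. Noise is independent Gaussian on the log2 scale per replicate
(default sd 0.25); planted DE genes are drawn independently per inducer
(default fraction 0.1, so inducers share regulated genes by overlap) with
signed logFC magnitudes uniform in ±25% of the configured mean effect
(default 2.0, i.e. 8× the noise sd — strong, clean microarray-scale
effects).

Coordinated structure is planted on genes *excluded from the random DE
pool*, so the ground truth is exact: the first pathway is planted fully
down-regulated in O-CHE, and five (extracellular CAZy, extracellular
non-CAZy) partner pairs are planted significant in **all** inducers with a
shared per-pair sign vector. The all-inducer support is deliberate: a
partial support set could be extended by a false-positive call on the CAZy
gene, which would change its observed support and make the planted partner
fail the exact-match rule through no fault of the association stage.

What the generator does **not** emulate: probe-level signal, normalization
artifacts, dye bias, heteroscedastic or heavy-tailed noise,
gene–gene expression correlation, annotation errors, or GO-term
correlation structure. Passing tests therefore demonstrate correctness of
the counting, testing and clustering machinery under the stated model —
not robustness to array artifacts.

## Verification problem sizes

The packaged checks run at these sizes, chosen to make every stochastic
bound comfortable: null calibration pools five independent effect-free
10,000-gene studies (the significant-call rate must sit in the 99% binomial
band around α); SOM→k-means recovery uses 100 seeded 10 × 186 descriptor
matrices (≥ 95 must reach ARI 1.0) plus exhaustive-partition inertia checks
at n ≤ 8; counting stages are compared with brute-force recounts on 100
randomized instances; and the end-to-end run uses the full default study
(12,039 genes), requiring ≥ 99.5% recall of planted effects with correct
sign, the planted pathway as the unique highly-affected pair, and all
planted association partners recovered.

## Known limitations

* The exact-ternary association rule is strict: one discordant support cell
  removes an edge. Real co-regulation is graded; the correlation mode
  exists for that, but has no default threshold for a reason.
* Significance-set-based pathway fractions ignore effect sizes; a pathway
  of barely significant genes and one of strongly regulated genes can score
  identically.
* The CFS ranking is evaluated per descriptor (k = 1); inter-descriptor
  redundancy affects the merit formula only for subsets, which the package
  does not search.
* With ten items, cluster counts and cross-validation folds are tiny;
  descriptor-importance ranks are stable only for clearly informative
  descriptors.
* The SOM is the sequential (online) variant; no batch SOM, no U-matrix.
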