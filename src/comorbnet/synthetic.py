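"""Planted-community fixtures for the cross-species network pipeline.

The generator emits the same five tables the real pipeline consumes —
disease-gene associations, mouse gene-phenotype associations, human-mouse
ortholog pairs, scored protein-protein links, and a protein-to-gene mapping
— plus a positive disease-pair list, all driven by a planted community
structure: diseases in the same community share genes (and, through
orthologs, mouse phenotypes), and the positive pairs are sampled within
communities.  A model that exploits the network should therefore rank
held-out within-community pairs above random pairs, and a label-shuffled
null should not.

Communities can be flagged *phenotype-only*: their diseases get disjoint
gene blocks (no shared genes, no cross-block protein interactions), so the
only within-community signal runs through the mouse layer — human gene ->
mouse ortholog -> shared phenotype -> mouse ortholog -> human gene.  This
isolates what the cross-species meta-paths contribute.

Protein-link scores are drawn uniform on [600, 999] within a community and
[1, 399] between communities, so a confidence-400 filter keeps exactly the
within-community interactions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import HeterogeneousGraph, build_graph
from .io import PPI_MIN_CONFIDENCE

Pair = tuple[str, str]


def _canon_pair(pair) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters (all probabilities in [0, 1], counts >= 1).

    The defaults describe the standard fixture: 4 communities of 8 diseases
    and 20 human genes, dense within-community disease-gene and
    protein-interaction structure, sparse cross-community noise, 60% of
    human genes with a mouse ortholog, and 5 phenotypes per community.
    Sized so a full repeated cross-validation finishes in minutes on one
    core.
    """

    n_communities: int = 4
    diseases_per_community: int = 8
    genes_per_community: int = 20
    dg_within: float = 0.35         # disease-gene attachment inside community
    dg_noise: float = 0.01          # cross-community disease-gene noise
    ppi_within: float = 0.15        # protein links inside community
    ppi_between: float = 0.01       # protein links across communities
    homolog_coverage: float = 0.6   # share of human genes with a mouse ortholog
    phenotypes_per_community: int = 5
    mp_attach: float = 0.4          # mouse gene - phenotype attachment
    phenotype_only_fraction: float = 0.0
    positive_rate: float = 0.5      # within-community pairs labelled positive
    seed: int = 0

    def __post_init__(self):
        for name in ("dg_within", "dg_noise", "ppi_within", "ppi_between",
                     "homolog_coverage", "mp_attach",
                     "phenotype_only_fraction", "positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_communities", "diseases_per_community",
                     "genes_per_community", "phenotypes_per_community"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def phenotype_only(cls, **overrides) -> "SyntheticSpec":
        """A fixture whose only within-community signal is cross-species.

        Every community is phenotype-only; gene blocks are small (2 genes
        per disease), ortholog coverage is high, and phenotypes attach
        densely enough that the mouse layer carries the community signal.
        """
        base = cls(genes_per_community=16, homolog_coverage=0.9,
                   mp_attach=0.5, phenotype_only_fraction=1.0)
        return replace(base, **overrides)


@dataclass
class SyntheticDataset:
    """Generated tables plus planted ground truth."""

    spec: SyntheticSpec
    disease_gene: pd.DataFrame      # disease_id, gene_id
    gene_pheno: pd.DataFrame        # mouse_gene_id, phenotype_id
    homologs: pd.DataFrame          # human_gene_id, mouse_gene_id
    ppi_links: pd.DataFrame         # protein_a, protein_b, combined_score
    protein_map: pd.DataFrame       # protein_id, gene_id
    positives: list[Pair]
    community: dict[str, int]       # disease -> community index

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.disease_gene.to_csv(out_dir / "disease_gene.tsv", sep="\t",
                                 index=False, header=False)
        self.gene_pheno.to_csv(out_dir / "gene_pheno.tsv", sep="\t",
                               index=False, header=False)
        self.homologs.to_csv(out_dir / "homologs.tsv", sep="\t",
                             index=False, header=False)
        self.ppi_links.to_csv(out_dir / "ppi_links.tsv", sep="\t",
                              index=False, header=False)
        self.protein_map.to_csv(out_dir / "protein_gene_map.tsv", sep="\t",
                                index=False, header=False)
        with open(out_dir / "positive_pairs.tsv", "w") as fh:
            for a, b in self.positives:
                fh.write(f"{a}\t{b}\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump({"spec": asdict(self.spec),
                       "community": self.community,
                       "positives": [list(p) for p in self.positives]},
                      fh, indent=2)

    def to_graph(self, min_confidence: int = PPI_MIN_CONFIDENCE,
                 ) -> HeterogeneousGraph:
        """Assemble the typed graph the way the file pipeline would."""
        prot2gene = dict(zip(self.protein_map.iloc[:, 0],
                             self.protein_map.iloc[:, 1]))
        kept = self.ppi_links[self.ppi_links.iloc[:, 2] >= min_confidence]
        gg = {}
        for pa, pb in zip(kept.iloc[:, 0], kept.iloc[:, 1]):
            ga, gb = prot2gene[pa], prot2gene[pb]
            if ga != gb:
                gg[(ga, gb) if ga <= gb else (gb, ga)] = None
        return build_graph(
            dg=list(self.disease_gene.itertuples(index=False, name=None)),
            gg=[(a, b, 1.0) for a, b in gg],
            gm=list(self.homologs.itertuples(index=False, name=None)),
            mp=list(self.gene_pheno.itertuples(index=False, name=None)))


def generate(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Draw one fixture; a pure function of (spec, seed).

    `seed` overrides ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_pheno_only = int(round(spec.phenotype_only_fraction * spec.n_communities))
    dg_rows: list[tuple[str, str]] = []
    ppi_rows: list[tuple[str, str, int]] = []
    gm_rows: list[tuple[str, str]] = []
    mp_rows: list[tuple[str, str]] = []
    positives: list[Pair] = []
    community: dict[str, int] = {}
    comm_diseases: list[list[str]] = []
    comm_genes: list[list[str]] = []
    gene_block: dict[str, int] = {}     # phenotype-only block index per gene

    for c in range(spec.n_communities):
        pheno_only = c < n_pheno_only
        diseases = [f"D{c:02d}_{j:02d}"
                    for j in range(spec.diseases_per_community)]
        genes = [f"G{c:02d}_{k:03d}" for k in range(spec.genes_per_community)]
        comm_diseases.append(diseases)
        comm_genes.append(genes)
        for d in diseases:
            community[d] = c
        if pheno_only:
            # disjoint gene blocks: disease j owns every gene k with
            # k % n_diseases == j, so no two diseases share a gene
            for k, g in enumerate(genes):
                j = k % len(diseases)
                gene_block[g] = j
                dg_rows.append((diseases[j], g))
        else:
            for d in diseases:
                attached = [g for g in genes if rng.random() < spec.dg_within]
                if not attached:
                    attached = [genes[rng.integers(len(genes))]]
                dg_rows.extend((d, g) for g in attached)
        # within-community protein links (confident scores)
        for ga, gb in itertools.combinations(genes, 2):
            if pheno_only and gene_block[ga] != gene_block[gb]:
                continue    # no cross-block interactions: gene layer is silent
            if rng.random() < spec.ppi_within:
                score = int(rng.integers(600, 1000))
                ppi_rows.append((f"PR_{ga}", f"PR_{gb}", score))
        # orthologs and phenotype attachments
        phenos = [f"P{c:02d}_{k:02d}"
                  for k in range(spec.phenotypes_per_community)]
        for g in genes:
            if rng.random() < spec.homolog_coverage:
                mg = f"M{g[1:]}"
                gm_rows.append((g, mg))
                for p in phenos:
                    if rng.random() < spec.mp_attach:
                        mp_rows.append((mg, p))
        # positive pairs live inside the community
        for da, db in itertools.combinations(diseases, 2):
            if rng.random() < spec.positive_rate:
                positives.append((da, db))

    # cross-community noise: disease-gene edges and low-confidence links
    all_genes = [g for genes in comm_genes for g in genes]
    for c, diseases in enumerate(comm_diseases):
        others = [g for cc, genes in enumerate(comm_genes) if cc != c
                  for g in genes]
        for d in diseases:
            n_noise = rng.binomial(len(others), spec.dg_noise)
            for g in rng.choice(len(others), size=n_noise, replace=False):
                dg_rows.append((d, others[g]))
    n_pairs_between = 0
    for ca, cb in itertools.combinations(range(spec.n_communities), 2):
        for ga in comm_genes[ca]:
            n_noise = rng.binomial(len(comm_genes[cb]), spec.ppi_between)
            for gi in rng.choice(len(comm_genes[cb]), size=n_noise,
                                 replace=False):
                gb = comm_genes[cb][gi]
                score = int(rng.integers(1, 400))
                ppi_rows.append((f"PR_{ga}", f"PR_{gb}", score))
                n_pairs_between += 1

    if not positives:
        raise ValueError("spec produced zero positive pairs; raise "
                         "positive_rate or community sizes")
    protein_map = pd.DataFrame(
        {"protein_id": [f"PR_{g}" for g in all_genes], "gene_id": all_genes})
    return SyntheticDataset(
        spec=spec,
        disease_gene=pd.DataFrame(dg_rows, columns=["disease_id", "gene_id"]),
        gene_pheno=pd.DataFrame(mp_rows,
                                columns=["mouse_gene_id", "phenotype_id"]),
        homologs=pd.DataFrame(gm_rows,
                              columns=["human_gene_id", "mouse_gene_id"]),
        ppi_links=pd.DataFrame(ppi_rows, columns=["protein_a", "protein_b",
                                                  "combined_score"]),
        protein_map=protein_map,
        positives=positives,
        community=community)


def shuffle_null(dataset: SyntheticDataset, seed: int = 0,
                 swaps_per_edge: int = 20) -> SyntheticDataset:
    """No-signal control: degree-preserving rewiring of the positive list.

    Seeded double-edge swaps on the positive pair graph preserve every
    disease's positive-degree while randomizing partners across
    communities, so the alignment between positives and the planted
    structure is destroyed; the five graph tables are untouched.  (A mere
    relabeling of disease identities would keep the positive pair graph
    isomorphic to the original and leave its cluster structure learnable;
    rewiring removes it.)
    """
    rng = np.random.default_rng(seed)
    edges = {_canon_pair(p) for p in dataset.positives}
    edge_list = sorted(edges)
    n_swaps = swaps_per_edge * len(edge_list)
    attempts = 0
    done = 0
    while done < n_swaps and attempts < 50 * n_swaps:
        attempts += 1
        i, j = rng.integers(len(edge_list)), rng.integers(len(edge_list))
        if i == j:
            continue
        (a, b), (c, d) = edge_list[i], edge_list[j]
        if rng.random() < 0.5:
            c, d = d, c
        new1, new2 = _canon_pair((a, c)), _canon_pair((b, d))
        if a == c or b == d or new1 in edges or new2 in edges:
            continue
        edges.discard(edge_list[i])
        edges.discard(edge_list[j])
        edges.add(new1)
        edges.add(new2)
        edge_list[i], edge_list[j] = new1, new2
        done += 1
    return SyntheticDataset(
        spec=dataset.spec, disease_gene=dataset.disease_gene,
        gene_pheno=dataset.gene_pheno, homologs=dataset.homologs,
        ppi_links=dataset.ppi_links, protein_map=dataset.protein_map,
        positives=sorted(edges), community=dataset.community)
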