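"""Self-contained synthetic datasets with controllable planted signal.

The generator plants pairwise similarity through shared generative
families rather than by writing feature values directly, so every planted
effect has to survive the real pipeline:

* structure — compounds draw SMILES from scaffold families (a large core
  plus a variable tail); within-family Tanimoto is high (> 0.8), across
  families it is near 0;
* target — protein sequences are point-mutated copies of per-family
  ancestor sequences, so sharing a sequence family yields high normalized
  Smith-Waterman scores;
* phenotype — genes are wired to per-block phenotype neighborhoods, so
  compounds whose targets share a block have correlated walk profiles.

``signal_shift`` maps to the probability that a planted positive pair is
matched on each feature: probability = min(1, shift / 3), i.e. a shift of
3 (nominal pooled standard deviations) plants the feature deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data_io import (
    AssociationNetwork,
    Compound,
    DataError,
    NodeKind,
    PairLabelSet,
    PhenotypeAnnotation,
    ProteinRecord,
    Role,
    read_annotations,
    read_compounds,
    read_network,
    read_pair_labels,
    read_proteome,
    write_annotations,
    write_network,
    write_pair_labels,
    write_proteome,
    write_structures,
    write_targets,
)
from .evaluation import (
    CoOccurrenceRecord,
    IndicationSet,
    read_cooccurrence,
    read_indications,
    write_cooccurrence,
    write_indications,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# large distinctive cores; appending an aliphatic tail keeps SMILES valid
_SCAFFOLD_CORES = [
    "c1ccc2ccccc2c1",            # naphthalene
    "c1ccc2[nH]ccc2c1",          # indole
    "c1ccc(-c2ccccc2)cc1",       # biphenyl
    "c1cc2oc3ccccc3c2cc1",       # dibenzofuran
    "c1ccc2ncccc2c1",            # quinoline
    "c1cc2sc3ccccc3c2cc1",       # dibenzothiophene
    "c1cnc2[nH]ccc2c1",          # azaindole
    "C1C2CC3CC1CC(C2)C3",        # adamantane
    "C1CCC2(CC1)CCCCC2",         # spiroundecane
    "C1CN2CCC1CC2",              # quinuclidine
]

# linear tails keep within-family fingerprints nearly identical
_SCAFFOLD_TAILS = [
    "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CCCCCO", "CCCCCCO", "CCCCCN", "CCCCCCN",
]


@dataclass(frozen=True)
class FixtureConfig:
    n_metabolites: int = 40
    n_natural_products: int = 20
    n_drugs: int = 100
    n_genes: int = 72
    n_phenotypes: int = 60
    edge_density: float = 0.03
    n_positives: int = 50
    signal_shift: tuple[float, float, float] = (3.0, 3.0, 3.0)  # structure, target, phenotype
    terms_per_metabolite: float = 5.0
    rng_seed: int = 0
    n_scaffold_families: int = 10
    n_gene_families: int = 6
    mutation_rate: float = 0.05
    decoy_structure_rate: float = 0.0
    frac_np_planted: float = 0.5
    n_cooccurrence: int = 30
    cooccurrence_total: int = 20000

    def __post_init__(self) -> None:
        counts = (
            self.n_metabolites,
            self.n_natural_products,
            self.n_drugs,
            self.n_genes,
            self.n_phenotypes,
            self.n_positives,
        )
        if min(counts) < 1:
            raise DataError("all counts must be >= 1")
        if self.n_positives > self.n_drugs * self.n_metabolites:
            raise DataError("more positives than drug-metabolite pairs")
        if self.n_positives > self.n_drugs:
            raise DataError("generator pairs each positive drug once: n_positives <= n_drugs")
        if not 0 <= self.edge_density <= 1:
            raise DataError("edge_density must be in [0, 1]")
        if any(s < 0 for s in self.signal_shift):
            raise DataError("signal shifts must be >= 0")
        if not 2 <= self.n_scaffold_families <= len(_SCAFFOLD_CORES):
            raise DataError(
                f"n_scaffold_families must be in [2, {len(_SCAFFOLD_CORES)}]"
            )


PRESETS = {
    "tiny": FixtureConfig(
        n_metabolites=8,
        n_natural_products=6,
        n_drugs=12,
        n_genes=16,
        n_phenotypes=16,
        n_positives=4,
        n_gene_families=4,
        n_scaffold_families=6,
        n_cooccurrence=10,
    ),
    "default": FixtureConfig(),
    "stress": FixtureConfig(
        n_metabolites=80,
        n_natural_products=60,
        n_drugs=200,
        n_genes=64,
        n_phenotypes=80,
        n_positives=100,
        n_cooccurrence=100,
    ),
}


@dataclass
class FixtureBundle:
    config: FixtureConfig
    metabolites: list[Compound]
    natural_products: list[Compound]
    drugs: list[Compound]
    proteome: dict[str, ProteinRecord]
    network: AssociationNetwork
    annotations: list[PhenotypeAnnotation]
    labels: PairLabelSet
    indications: list[IndicationSet]
    cooccurrence: list[CoOccurrenceRecord]
    cooccurrence_random: list[CoOccurrenceRecord]
    planted_np_pairs: list[tuple[str, str]]  # (natural_product_id, metabolite_id)


def _match_probability(shift: float) -> float:
    return min(1.0, shift / 3.0)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(chars)


def generate_fixture(cfg: FixtureConfig) -> FixtureBundle:
    """Build a full dataset bundle, reproducible from ``cfg.rng_seed``."""
    rng = np.random.default_rng(cfg.rng_seed)
    F = cfg.n_gene_families

    # scaffold families: cores x tails
    families = [
        [core + tail for tail in _SCAFFOLD_TAILS]
        for core in _SCAFFOLD_CORES[: cfg.n_scaffold_families]
    ]

    # proteome: per-family ancestors, genes carry (sequence family, phenotype block)
    ancestors = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=rng.integers(80, 200)))
        for _ in range(F)
    ]
    gene_ids = [f"G{i:03d}" for i in range(cfg.n_genes)]
    seq_fam = {g: i % F for i, g in enumerate(gene_ids)}
    phen_block = {g: (i // F) % F for i, g in enumerate(gene_ids)}
    proteome = {
        g: ProteinRecord(gene_id=g, sequence=_mutate(ancestors[seq_fam[g]], cfg.mutation_rate, rng))
        for g in gene_ids
    }
    genes_by_combo: dict[tuple[int, int], list[str]] = {}
    for g in gene_ids:
        genes_by_combo.setdefault((seq_fam[g], phen_block[g]), []).append(g)

    # network: genes wired to their block's phenotype neighborhood
    phen_ids = [f"P{i:03d}" for i in range(cfg.n_phenotypes)]
    block_of_phen = {p: i % F for i, p in enumerate(phen_ids)}
    nodes = {g: NodeKind.GENE for g in gene_ids}
    nodes.update({p: NodeKind.PHENOTYPE for p in phen_ids})
    edges: list[tuple[str, str, float]] = []
    for g in gene_ids:
        for p in phen_ids:
            if block_of_phen[p] == phen_block[g]:
                if rng.random() < 0.7:
                    edges.append((g, p, 1.0))
            elif rng.random() < cfg.edge_density:
                edges.append((g, p, 1.0))
        for g2 in gene_ids:
            if g2 != g and phen_block[g2] == phen_block[g] and rng.random() < 0.15:
                edges.append((g, g2, 1.0))
    network = AssociationNetwork(nodes=nodes, edges=edges)

    def sample_targets(sf: int, pb: int) -> frozenset[str]:
        pool = genes_by_combo.get((sf, pb)) or [g for g in gene_ids if seq_fam[g] == sf]
        k = min(len(pool), int(rng.integers(1, 3)))
        idx = rng.choice(len(pool), size=k, replace=False)
        return frozenset(pool[i] for i in sorted(idx))

    def sample_smiles(fam: int) -> str:
        variants = families[fam]
        return variants[rng.integers(len(variants))]

    # metabolites: one home (scaffold family, sequence family, phenotype block) each
    met_home: dict[str, tuple[int, int, int]] = {}
    metabolites = []
    for i in range(cfg.n_metabolites):
        mid = f"M{i:03d}"
        home = (
            int(rng.integers(cfg.n_scaffold_families)),
            int(rng.integers(F)),
            int(rng.integers(F)),
        )
        met_home[mid] = home
        metabolites.append(
            Compound(
                id=mid,
                role=Role.METABOLITE,
                smiles=sample_smiles(home[0]),
                targets=sample_targets(home[1], home[2]),
            )
        )

    p_struct, p_target, p_phen = (_match_probability(s) for s in cfg.signal_shift)

    def planted_partner(mid: str) -> tuple[str, frozenset[str]]:
        """SMILES and targets for a compound planted to resemble metabolite mid."""
        scaf_m, sf_m, pb_m = met_home[mid]
        scaf = scaf_m if rng.random() < p_struct else int(rng.integers(cfg.n_scaffold_families))
        sf = sf_m if rng.random() < p_target else int(rng.integers(F))
        pb = pb_m if rng.random() < p_phen else int(rng.integers(F))
        return sample_smiles(scaf), sample_targets(sf, pb)

    def background_partner() -> tuple[str, frozenset[str]]:
        if cfg.decoy_structure_rate > 0 and rng.random() < cfg.decoy_structure_rate:
            decoy = metabolites[rng.integers(len(metabolites))]
            scaf = met_home[decoy.id][0]
        else:
            scaf = int(rng.integers(cfg.n_scaffold_families))
        return sample_smiles(scaf), sample_targets(int(rng.integers(F)), int(rng.integers(F)))

    # drugs: the first n_positives are planted pairs, the rest are background
    drugs, positives = [], []
    for i in range(cfg.n_drugs):
        did = f"D{i:03d}"
        if i < cfg.n_positives:
            mate = metabolites[rng.integers(len(metabolites))].id
            smiles, targets = planted_partner(mate)
            positives.append((did, mate))
        else:
            smiles, targets = background_partner()
        drugs.append(Compound(id=did, role=Role.DRUG, smiles=smiles, targets=targets))
    labels = PairLabelSet(
        positives=frozenset(positives),
        universe=frozenset((d.id, m.id) for d in drugs for m in metabolites),
    )

    # natural products: a fraction planted against a partner metabolite
    natural_products, planted_np_pairs = [], []
    n_planted = int(round(cfg.frac_np_planted * cfg.n_natural_products))
    for i in range(cfg.n_natural_products):
        nid = f"N{i:03d}"
        if i < n_planted:
            mate = metabolites[rng.integers(len(metabolites))].id
            smiles, targets = planted_partner(mate)
            planted_np_pairs.append((nid, mate))
        else:
            smiles, targets = background_partner()
        natural_products.append(
            Compound(id=nid, role=Role.NATURAL_PRODUCT, smiles=smiles, targets=targets)
        )

    # annotations: phenotypes one hop from the metabolite's targets, plus noise
    out_phen: dict[str, list[str]] = {g: [] for g in gene_ids}
    for s, t, _ in edges:
        if t in block_of_phen:
            out_phen[s].append(t)
    annotations = []
    for m in metabolites:
        terms = sorted({p for g in sorted(m.targets) for p in out_phen[g]})
        n_noise = int(rng.poisson(max(0.0, cfg.terms_per_metabolite - len(terms))))
        for _ in range(n_noise):
            terms.append(phen_ids[rng.integers(len(phen_ids))])
        annotations.append(
            PhenotypeAnnotation(compound_id=m.id, phenotype_terms=frozenset(terms))
        )
    ann_by_id = {a.compound_id: a.phenotype_terms for a in annotations}

    # indications for planted natural products: partner terms thinned, plus noise
    indications = []
    for nid, mid in planted_np_pairs:
        terms = [t for t in sorted(ann_by_id[mid]) if rng.random() < 0.5]
        if not terms:
            terms = sorted(ann_by_id[mid])[:1]
        terms.append(phen_ids[rng.integers(len(phen_ids))])
        if terms:
            indications.append(IndicationSet(drug_id=nid, indications=frozenset(terms)))
    for npc in natural_products[n_planted : n_planted + 3]:
        noise = {phen_ids[rng.integers(len(phen_ids))] for _ in range(3)}
        indications.append(IndicationSet(drug_id=npc.id, indications=frozenset(noise)))

    # literature co-occurrence: associated vs independent regimes
    def _cooc(associated: bool, tag: str) -> list[CoOccurrenceRecord]:
        out = []
        for i in range(cfg.n_cooccurrence):
            n_a = int(rng.integers(100, 1000))
            n_b = int(rng.integers(100, 1000))
            if associated:
                n_c = int(rng.binomial(min(n_a, n_b), 0.3))
            else:
                n_c = int(rng.hypergeometric(n_a, cfg.cooccurrence_total - n_a, n_b))
            out.append(
                CoOccurrenceRecord(
                    term_a=f"{tag}A{i:03d}",
                    term_b=f"{tag}B{i:03d}",
                    n_c=n_c,
                    n_a=n_a,
                    n_b=n_b,
                    N=cfg.cooccurrence_total,
                )
            )
        return out

    return FixtureBundle(
        config=cfg,
        metabolites=metabolites,
        natural_products=natural_products,
        drugs=drugs,
        proteome=proteome,
        network=network,
        annotations=annotations,
        labels=labels,
        indications=indications,
        cooccurrence=_cooc(True, "assoc_"),
        cooccurrence_random=_cooc(False, "rand_"),
        planted_np_pairs=planted_np_pairs,
    )


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

_FILES = {
    "metabolites": "metabolites.smi",
    "metabolite_targets": "metabolite_targets.tsv",
    "natural_products": "natural_products.smi",
    "natural_product_targets": "natural_product_targets.tsv",
    "drugs": "drugs.smi",
    "drug_targets": "drug_targets.tsv",
    "proteome": "proteome.fasta",
    "network": "network.tsv",
    "annotations": "annotations.tsv",
    "positives": "positives.tsv",
    "indications": "indications.tsv",
    "cooccurrence": "cooccurrence.tsv",
    "cooccurrence_random": "cooccurrence_random.tsv",
}


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle in exactly the formats the readers consume."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in _FILES.items()}
    write_structures(bundle.metabolites, paths["metabolites"])
    write_targets(bundle.metabolites, paths["metabolite_targets"])
    write_structures(bundle.natural_products, paths["natural_products"])
    write_targets(bundle.natural_products, paths["natural_product_targets"])
    write_structures(bundle.drugs, paths["drugs"])
    write_targets(bundle.drugs, paths["drug_targets"])
    write_proteome(bundle.proteome, paths["proteome"])
    write_network(bundle.network, paths["network"])
    write_annotations(bundle.annotations, paths["annotations"])
    write_pair_labels(bundle.labels, paths["positives"])
    write_indications(bundle.indications, paths["indications"])
    write_cooccurrence(bundle.cooccurrence, paths["cooccurrence"])
    write_cooccurrence(bundle.cooccurrence_random, paths["cooccurrence_random"])
    return paths


def read_fixture(directory: str | Path, config: FixtureConfig | None = None) -> FixtureBundle:
    """Reload a written fixture through the standard readers."""
    d = Path(directory)
    p = {k: d / v for k, v in _FILES.items()}
    metabolites = read_compounds(p["metabolites"], p["metabolite_targets"], Role.METABOLITE)
    natural_products = read_compounds(
        p["natural_products"], p["natural_product_targets"], Role.NATURAL_PRODUCT
    )
    drugs = read_compounds(p["drugs"], p["drug_targets"], Role.DRUG)
    return FixtureBundle(
        config=config or FixtureConfig(),
        metabolites=metabolites,
        natural_products=natural_products,
        drugs=drugs,
        proteome=read_proteome(p["proteome"]),
        network=read_network(p["network"]),
        annotations=read_annotations(p["annotations"]),
        labels=read_pair_labels(p["positives"], drugs, metabolites),
        indications=read_indications(p["indications"]),
        cooccurrence=read_cooccurrence(p["cooccurrence"]),
        cooccurrence_random=read_cooccurrence(p["cooccurrence_random"]),
        planted_np_pairs=[],
    )


def null_config(cfg: FixtureConfig) -> FixtureConfig:
    """The same fixture with every planted signal removed."""
    return replace(cfg, signal_shift=(0.0, 0.0, 0.0))
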