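"""Domain types and readers/writers for every input format.

All tabular inputs are TSV: tab-separated, UTF-8, header row required,
``.`` denotes a missing value.  Identifiers are compared case-sensitively
after stripping surrounding whitespace.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "."

#: amino-acid alphabet accepted in protein sequences
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class DataError(ValueError):
    """Fatal problem in an input file or table."""


class Role(str, enum.Enum):
    METABOLITE = "metabolite"
    NATURAL_PRODUCT = "natural_product"
    DRUG = "drug"


@dataclass(frozen=True)
class Compound:
    """An identified molecule with a role, an optional structure and targets."""

    id: str
    role: Role
    smiles: str | None = None
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("compound id must be non-empty")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by its gene identifier."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise DataError(
                f"protein {self.gene_id!r}: illegal characters {sorted(bad)!r}"
            )


class NodeKind(str, enum.Enum):
    GENE = "gene"
    PHENOTYPE = "phenotype"


@dataclass
class AssociationNetwork:
    """Directed gene/phenotype association network.

    ``nodes`` maps node id to its kind; ``edges`` is a list of
    (source, target, weight) with weight >= 0.  Self-loops are dropped at
    load time and counted in ``n_self_loops_dropped``.
    """

    nodes: dict[str, NodeKind]
    edges: list[tuple[str, str, float]]
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        for src, dst, w in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise DataError(f"edge ({src!r}, {dst!r}) references unknown node")
            if src == dst:
                raise DataError(f"self-loop ({src!r}) must be dropped before construction")
            if w < 0:
                raise DataError(f"edge ({src!r}, {dst!r}) has negative weight {w}")

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, k in self.nodes.items() if k is NodeKind.GENE}

    @property
    def phenotype_nodes(self) -> set[str]:
        return {n for n, k in self.nodes.items() if k is NodeKind.PHENOTYPE}


@dataclass(frozen=True)
class PhenotypeAnnotation:
    """Normalized phenotype terms known for one compound."""

    compound_id: str
    phenotype_terms: frozenset[str]


@dataclass(frozen=True)
class PairLabelSet:
    """Positive (drug, metabolite) labels inside the full candidate universe."""

    positives: frozenset[tuple[str, str]]
    universe: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        extra = self.positives - self.universe
        if extra:
            raise DataError(f"positives outside the candidate universe: {sorted(extra)[:5]}")

    @property
    def unlabeled(self) -> frozenset[tuple[str, str]]:
        return self.universe - self.positives


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise DataError(f"input file not found: {p}")
    return p


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(_require(path), sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        df[col] = df[col].str.strip()
    return df


def _parse_smiles(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def read_structures(path: str | Path) -> dict[str, str | None]:
    """Read a structure file into ``{compound_id: smiles-or-None}``.

    ``.smi`` / other text: one molecule per line, ``SMILES<ws>id``.
    ``.sdf`` / ``.mol``: read with RDKit, id taken from the molecule name.
    Unparsable structures are kept with ``None`` and logged.
    """
    p = _require(path)
    out: dict[str, str | None] = {}

    def _add(cid: str, smiles: str | None) -> None:
        if cid in out and out[cid] != smiles and out[cid] is not None and smiles is not None:
            raise DataError(
                f"{p}: duplicate id {cid!r} with conflicting structures "
                f"{out[cid]!r} vs {smiles!r}"
            )
        if cid not in out or out[cid] is None:
            out[cid] = smiles

    if p.suffix.lower() in {".sdf", ".mol"}:
        from rdkit import Chem

        for i, mol in enumerate(Chem.SDMolSupplier(str(p), sanitize=True)):
            if mol is None:
                logger.warning("%s: record %d unparsable, structure dropped", p, i)
                continue
            cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else f"mol{i}"
            _add(cid, Chem.MolToSmiles(mol))
        return out

    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise DataError(f"{p}:{lineno}: expected 'SMILES id', got {line!r}")
        smiles, cid = parts[0], parts[1]
        if smiles == MISSING:
            _add(cid, None)
        elif _parse_smiles(smiles):
            _add(cid, smiles)
        else:
            logger.warning("%s:%d: unparsable SMILES %r for %r", p, lineno, smiles, cid)
            _add(cid, None)
    return out


def read_compounds(
    structures_path: str | Path, targets_path: str | Path, role: Role
) -> list[Compound]:
    """Load one :class:`Compound` per unique id in the structure file.

    Target rows (columns ``compound_id``, ``gene_id``) are aggregated with
    set semantics; ids in the target table that have no structure row are
    added as structureless compounds.
    """
    structures = read_structures(structures_path)
    targets: dict[str, set[str]] = {}
    df = _read_tsv(targets_path, ["compound_id", "gene_id"])
    for row in df.itertuples(index=False):
        targets.setdefault(row.compound_id, set()).add(row.gene_id)
    ids = sorted(set(structures) | set(targets))
    return [
        Compound(
            id=cid,
            role=role,
            smiles=structures.get(cid),
            targets=frozenset(targets.get(cid, set())),
        )
        for cid in ids
    ]


def read_proteome(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into ``{gene_id: ProteinRecord}``."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(_require(path)), "fasta"):
        gid = rec.id.strip()
        if gid in records:
            raise DataError(f"{path}: duplicate gene id {gid!r}")
        records[gid] = ProteinRecord(gene_id=gid, sequence=str(rec.seq).upper())
    return records


def read_network(edges_path: str | Path) -> AssociationNetwork:
    """Load the directed association network from a TSV edge list.

    Columns: ``source_id``, ``target_id``, ``source_kind``, ``target_kind``
    and optional ``weight`` (default 1.0).  Self-loops are dropped with a
    logged count; a negative weight or an unknown kind is fatal.
    """
    df = _read_tsv(edges_path, ["source_id", "target_id", "source_kind", "target_kind"])
    nodes: dict[str, NodeKind] = {}
    edges: list[tuple[str, str, float]] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            skind = NodeKind(row.source_kind)
            tkind = NodeKind(row.target_kind)
        except ValueError as exc:
            raise DataError(f"{edges_path}:{i}: unknown node kind ({exc})") from None
        for nid, kind in ((row.source_id, skind), (row.target_id, tkind)):
            if nodes.setdefault(nid, kind) is not kind:
                raise DataError(f"{edges_path}:{i}: node {nid!r} declared with two kinds")
        weight = 1.0
        if hasattr(row, "weight") and row.weight is not None and not pd.isna(row.weight):
            weight = float(row.weight)
            if weight < 0:
                raise DataError(f"{edges_path}:{i}: negative weight {weight}")
        if row.source_id == row.target_id:
            dropped += 1
            continue
        edges.append((row.source_id, row.target_id, weight))
    if dropped:
        logger.warning("%s: dropped %d self-loop(s)", edges_path, dropped)
    return AssociationNetwork(nodes=nodes, edges=edges, n_self_loops_dropped=dropped)


def read_annotations(path: str | Path) -> list[PhenotypeAnnotation]:
    """Read metabolite phenotype annotations (columns compound_id, phenotype_term)."""
    df = _read_tsv(path, ["compound_id", "phenotype_term"])
    terms: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if row.phenotype_term is None or pd.isna(row.phenotype_term):
            terms.setdefault(row.compound_id, set())
        else:
            terms.setdefault(row.compound_id, set()).add(row.phenotype_term)
    return [
        PhenotypeAnnotation(compound_id=cid, phenotype_terms=frozenset(t))
        for cid, t in sorted(terms.items())
    ]


def read_pair_labels(
    path: str | Path, drugs: list[Compound], metabolites: list[Compound]
) -> PairLabelSet:
    """Read positive pairs (columns drug_id, metabolite_id).

    The universe is the full Cartesian product of the supplied drugs and
    metabolites; a positive row naming an unknown compound is fatal.
    """
    drug_ids = {c.id for c in drugs}
    met_ids = {c.id for c in metabolites}
    universe = frozenset(itertools.product(sorted(drug_ids), sorted(met_ids)))
    df = _read_tsv(path, ["drug_id", "metabolite_id"])
    positives = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.drug_id not in drug_ids:
            raise DataError(f"{path}:{i}: unknown drug id {row.drug_id!r}")
        if row.metabolite_id not in met_ids:
            raise DataError(f"{path}:{i}: unknown metabolite id {row.metabolite_id!r}")
        positives.add((row.drug_id, row.metabolite_id))
    return PairLabelSet(positives=frozenset(positives), universe=universe)


# ---------------------------------------------------------------------------
# writers (used by the fixture generator and the CLI; round-trip with readers)
# ---------------------------------------------------------------------------


def write_structures(compounds: list[Compound], path: str | Path) -> None:
    lines = [f"{c.smiles if c.smiles is not None else MISSING}\t{c.id}" for c in compounds]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_targets(compounds: list[Compound], path: str | Path) -> None:
    rows = [
        {"compound_id": c.id, "gene_id": g}
        for c in compounds
        for g in sorted(c.targets)
    ]
    pd.DataFrame(rows, columns=["compound_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def write_proteome(proteome: dict[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(proteome):
            fh.write(f">{gid}\n{proteome[gid].sequence}\n")


def write_network(network: AssociationNetwork, path: str | Path) -> None:
    rows = [
        {
            "source_id": s,
            "target_id": t,
            "source_kind": network.nodes[s].value,
            "target_kind": network.nodes[t].value,
            "weight": w,
        }
        for s, t, w in network.edges
    ]
    pd.DataFrame(
        rows, columns=["source_id", "target_id", "source_kind", "target_kind", "weight"]
    ).to_csv(path, sep="\t", index=False)


def write_annotations(annotations: list[PhenotypeAnnotation], path: str | Path) -> None:
    rows = [
        {"compound_id": a.compound_id, "phenotype_term": t}
        for a in annotations
        for t in sorted(a.phenotype_terms)
    ]
    pd.DataFrame(rows, columns=["compound_id", "phenotype_term"]).to_csv(
        path, sep="\t", index=False
    )


def write_pair_labels(labels: PairLabelSet, path: str | Path) -> None:
    rows = [{"drug_id": d, "metabolite_id": m} for d, m in sorted(labels.positives)]
    pd.DataFrame(rows, columns=["drug_id", "metabolite_id"]).to_csv(path, sep="\t", index=False)
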