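"""The three pairwise similarity features and the final score matrix.

Structure similarity is the Tanimoto coefficient over hashed path
fingerprints; target similarity averages normalized Smith-Waterman scores
above a global top-fraction threshold; phenotype similarity is the absolute
Pearson correlation of random-walk-with-restart phenotype profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import AssociationNetwork, Compound, DataError, ProteinRecord

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["s_structure", "s_target", "s_phenotype"]


class ConvergenceError(RuntimeError):
    """Random walk failed to reach the requested tolerance."""


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: tuple[int, ...]  # sorted indices of set bits
    length: int

    @property
    def n_set(self) -> int:
        return len(self.bits)


def compute_fingerprint(compound: Compound, length: int = 1024) -> Fingerprint | None:
    """Hashed path fingerprint of a compound, or ``None`` when it has no structure.

    Deterministic and canonicalization-invariant: any two SMILES spellings
    of the same molecule hash to the same bits.  Hydrogens are stripped and
    bond orders are perceived before hashing.
    """
    if compound.smiles is None:
        return None
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        logger.warning("compound %s: unparsable SMILES, structure feature missing", compound.id)
        return None
    mol = Chem.RemoveHs(mol)
    bv = Chem.RDKFingerprint(mol, fpSize=length)
    return Fingerprint(bits=tuple(bv.GetOnBits()), length=length)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B|; two all-zero fingerprints give 0."""
    if fp_a.length != fp_b.length:
        raise DataError(f"fingerprint length mismatch: {fp_a.length} vs {fp_b.length}")
    a, b = set(fp_a.bits), set(fp_b.bits)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


# ---------------------------------------------------------------------------
# target
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentScoreConfig:
    """Smith-Waterman scoring parameters (BLOSUM-62 with affine gaps).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise DataError("gap penalties must be > 0")


@lru_cache(maxsize=8)
def _aligner(cfg: AlignmentScoreConfig):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(cfg.substitution_matrix)
    aligner.open_gap_score = -cfg.gap_open
    aligner.extend_gap_score = -cfg.gap_extend
    return aligner


def sw_score(seq_a: str, seq_b: str, cfg: AlignmentScoreConfig | None = None) -> float:
    """Raw Smith-Waterman local alignment score."""
    return float(_aligner(cfg or AlignmentScoreConfig()).score(seq_a, seq_b))


def normalized_sw(
    seq_a: ProteinRecord, seq_b: ProteinRecord, cfg: AlignmentScoreConfig | None = None
) -> float | None:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)); exactly 1 for self-comparison.

    Returns ``None`` if either self-alignment score is non-positive (cannot
    occur with BLOSUM-62's positive diagonal, guarded anyway).
    """
    cfg = cfg or AlignmentScoreConfig()
    if seq_a.sequence == seq_b.sequence:
        return 1.0
    saa = sw_score(seq_a.sequence, seq_a.sequence, cfg)
    sbb = sw_score(seq_b.sequence, seq_b.sequence, cfg)
    if saa <= 0 or sbb <= 0:
        logger.warning(
            "non-positive self-alignment score for %s/%s; target score missing",
            seq_a.gene_id,
            seq_b.gene_id,
        )
        return None
    sab = sw_score(seq_a.sequence, seq_b.sequence, cfg)
    return min(1.0, sab / math.sqrt(saa * sbb))


def target_pair_scores(
    compound_a: Compound,
    compound_b: Compound,
    proteome: dict[str, ProteinRecord],
    cfg: AlignmentScoreConfig | None = None,
    _cache: dict | None = None,
) -> list[float] | None:
    """Normalized SW score for every (target of A) x (target of B) pair.

    Targets without a sequence are skipped with a warning; if either side
    has no usable target the result is missing (``None``).  ``_cache`` maps
    unordered gene-id pairs to scores and is shared across calls when
    building a full matrix.
    """
    cfg = cfg or AlignmentScoreConfig()
    genes_a = sorted(g for g in compound_a.targets if g in proteome)
    genes_b = sorted(g for g in compound_b.targets if g in proteome)
    for comp, genes in ((compound_a, genes_a), (compound_b, genes_b)):
        skipped = comp.targets - set(genes)
        if skipped:
            logger.warning(
                "compound %s: %d target(s) without sequence skipped", comp.id, len(skipped)
            )
    if not genes_a or not genes_b:
        return None
    cache = _cache if _cache is not None else {}
    scores = []
    for ga in genes_a:
        for gb in genes_b:
            key = (ga, gb) if ga <= gb else (gb, ga)
            if key not in cache:
                cache[key] = normalized_sw(proteome[ga], proteome[gb], cfg)
            if cache[key] is not None:
                scores.append(cache[key])
    return scores if scores else None


def top_fraction_threshold(all_scores, fraction: float = 0.05) -> float:
    """The (1 - fraction) quantile of the pooled score distribution.

    Linear interpolation between order statistics; fatal on empty input.
    """
    arr = np.asarray(list(all_scores), dtype=float)
    if arr.size == 0:
        raise DataError("cannot compute a threshold from an empty score collection")
    if not 0 < fraction < 1:
        raise DataError(f"fraction must be in (0, 1), got {fraction}")
    return float(np.quantile(arr, 1.0 - fraction, method="linear"))


def target_similarity(pair_scores: list[float] | None, threshold: float) -> float | None:
    """Mean of scores at or above the threshold; 0 when none survive.

    Missing (``None``) input propagates: no target data at all is distinct
    from evidence of dissimilar target sets.
    """
    if pair_scores is None:
        return None
    surviving = [s for s in pair_scores if s >= threshold]
    if not surviving:
        return 0.0
    return float(np.mean(surviving))


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeProfile:
    """Steady-state RWR probabilities restricted to phenotype nodes."""

    compound_id: str
    scores: np.ndarray  # aligned with the propagator's phenotype node order

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise DataError(f"profile for {self.compound_id}: scores must be finite and >= 0")


class NetworkPropagator:
    """Random walk with restart on an association network.

    The transition matrix row-normalizes out-edge weights per node; nodes
    with no out-edges (dangling) redistribute their mass to the restart
    vector, which keeps total probability at 1.
    """

    def __init__(self, network: AssociationNetwork):
        self.node_ids: list[str] = sorted(network.nodes)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        n = len(self.node_ids)
        rows, cols, vals = [], [], []
        for src, dst, w in network.edges:
            rows.append(self._index[src])
            cols.append(self._index[dst])
            vals.append(w)
        adj = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        adj.sum_duplicates()
        out = np.asarray(adj.sum(axis=1)).ravel()
        self.dangling = out == 0
        inv = np.zeros(n)
        inv[~self.dangling] = 1.0 / out[~self.dangling]
        self._mt = (sp.diags(inv) @ adj).T.tocsr()  # M^T, column-stochastic off dangling
        self.phenotype_ids: list[str] = sorted(
            network.phenotype_nodes
        )
        self._phen_index = np.array(
            [self._index[p] for p in self.phenotype_ids], dtype=int
        )
        self.gene_ids = set(network.gene_nodes)

    def rwr(
        self,
        seeds: set[str],
        restart: float = 0.7,
        tol: float = 1e-5,
        max_iter: int = 1000,
    ) -> np.ndarray:
        """Iterate p_{s+1} = (1-r) M^T p_s + r p_0 to a steady state.

        p_0 is uniform over the seeds.  Convergence is max-norm of the step
        difference below ``tol``; exceeding ``max_iter`` is fatal.
        """
        seed_idx = [self._index[s] for s in seeds if s in self._index]
        if not seed_idx:
            raise DataError("no seed node present in the network")
        n = len(self.node_ids)
        p0 = np.zeros(n)
        p0[seed_idx] = 1.0 / len(seed_idx)
        p = p0.copy()
        for _ in range(max_iter):
            dangling_mass = p[self.dangling].sum()
            p_next = (1.0 - restart) * (self._mt @ p + dangling_mass * p0) + restart * p0
            residual = float(np.max(np.abs(p_next - p)))
            p = p_next
            if residual < tol:
                return p
        raise ConvergenceError(
            f"random walk did not converge in {max_iter} iterations "
            f"(final residual {residual:.3e})"
        )

    def phenotype_profile(
        self,
        compound: Compound,
        restart: float = 0.7,
        tol: float = 1e-5,
        max_iter: int = 1000,
    ) -> PhenotypeProfile | None:
        """RWR profile seeded at the compound's targets, restricted to phenotypes.

        Missing (``None``) when no target of the compound is a gene node.
        """
        seeds = {g for g in compound.targets if g in self.gene_ids}
        if not seeds:
            logger.warning("compound %s: no target in network, phenotype feature missing", compound.id)
            return None
        p = self.rwr(seeds, restart=restart, tol=tol, max_iter=max_iter)
        return PhenotypeProfile(compound_id=compound.id, scores=p[self._phen_index])


def rwr(
    network: AssociationNetwork,
    seeds: set[str],
    restart: float = 0.7,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> tuple[list[str], np.ndarray]:
    """Convenience wrapper: full node-score vector plus its node order."""
    prop = NetworkPropagator(network)
    return prop.node_ids, prop.rwr(seeds, restart=restart, tol=tol, max_iter=max_iter)


def phenotype_similarity(
    profile_a: PhenotypeProfile, profile_b: PhenotypeProfile
) -> float:
    """Absolute Pearson correlation of two phenotype profiles.

    A zero-variance profile on either side makes the correlation undefined;
    the similarity is then 0 (a flat profile is uninformative).
    """
    a, b = np.asarray(profile_a.scores), np.asarray(profile_b.scores)
    if a.shape != b.shape:
        raise DataError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning(
            "zero-variance phenotype profile (%s/%s): similarity set to 0",
            profile_a.compound_id,
            profile_b.compound_id,
        )
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(min(1.0, abs(r)))


# ---------------------------------------------------------------------------
# score matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for building the score matrix."""

    fp_length: int = 1024
    top_fraction: float = 0.05
    restart: float = 0.7
    tol: float = 1e-5
    max_iter: int = 1000
    alignment: AlignmentScoreConfig = field(default_factory=AlignmentScoreConfig)


@dataclass(frozen=True)
class FeatureVector:
    """The (structure, target, phenotype) triple for one compound pair."""

    pair: tuple[str, str]
    s_structure: float | None
    s_target: float | None
    s_phenotype: float | None

    def __post_init__(self) -> None:
        for name, v in (
            ("s_structure", self.s_structure),
            ("s_target", self.s_target),
            ("s_phenotype", self.s_phenotype),
        ):
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{self.pair}: {name}={v} outside [0, 1]")


def build_feature_matrix(
    metabolites: list[Compound],
    partners: list[Compound],
    proteome: dict[str, ProteinRecord],
    network: AssociationNetwork | None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Score matrix with one row per (partner, metabolite) pair.

    Columns: ``partner_id``, ``metabolite_id`` and the three feature
    columns (NaN marks missing).  The target-score threshold is the
    top-fraction quantile pooled over every target pair score in this
    matrix, computed before any per-pair averaging.
    """
    config = config or FeatureConfig()
    fps = {
        c.id: compute_fingerprint(c, config.fp_length) for c in metabolites + partners
    }

    sw_cache: dict = {}
    pair_scores: dict[tuple[str, str], list[float] | None] = {}
    pooled: list[float] = []
    for p in partners:
        for m in metabolites:
            scores = target_pair_scores(p, m, proteome, config.alignment, _cache=sw_cache)
            pair_scores[(p.id, m.id)] = scores
            if scores:
                pooled.extend(scores)
    threshold = top_fraction_threshold(pooled, config.top_fraction) if pooled else None
    if threshold is not None:
        logger.info(
            "target-score threshold (top %.1f%%): %.6f over %d pooled scores",
            100 * config.top_fraction,
            threshold,
            len(pooled),
        )

    profiles: dict[str, PhenotypeProfile | None] = {}
    if network is not None and network.phenotype_nodes:
        prop = NetworkPropagator(network)
        profile_by_seeds: dict[frozenset[str], PhenotypeProfile | None] = {}
        for c in metabolites + partners:
            seeds = frozenset(g for g in c.targets if g in prop.gene_ids)
            if seeds not in profile_by_seeds:
                profile_by_seeds[seeds] = prop.phenotype_profile(
                    c, restart=config.restart, tol=config.tol, max_iter=config.max_iter
                )
            profiles[c.id] = profile_by_seeds[seeds]
    else:
        profiles = {c.id: None for c in metabolites + partners}

    rows = []
    for p in partners:
        for m in metabolites:
            fa, fb = fps[p.id], fps[m.id]
            s_struct = tanimoto(fa, fb) if fa is not None and fb is not None else None
            s_target = (
                target_similarity(pair_scores[(p.id, m.id)], threshold)
                if threshold is not None
                else None
            )
            pa, pb = profiles[p.id], profiles[m.id]
            s_phen = phenotype_similarity(pa, pb) if pa is not None and pb is not None else None
            FeatureVector((p.id, m.id), s_struct, s_target, s_phen)  # range check
            rows.append(
                {
                    "partner_id": p.id,
                    "metabolite_id": m.id,
                    "s_structure": np.nan if s_struct is None else s_struct,
                    "s_target": np.nan if s_target is None else s_target,
                    "s_phenotype": np.nan if s_phen is None else s_phen,
                }
            )
    return pd.DataFrame(rows, columns=["partner_id", "metabolite_id", *FEATURE_COLUMNS])


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    """Write the score matrix as TSV, ``.`` for missing entries."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.10g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    expected = ["partner_id", "metabolite_id", *FEATURE_COLUMNS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing feature columns {missing}")
    return df
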