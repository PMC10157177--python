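"""Cross-species oriC geometry: gene migration and constellation analysis.

Two families of analyses live here.  Gene *migration* quantifies how much
single-copy orthologs drift in oriC proximity between species, per
regulatory-stringency subset.  *Constellation analysis* infers the oriC-ter
axis of two chromosomes jointly, exploiting the positional conservation of
genes relative to oriC: a candidate oriC is assigned to each chromosome,
the normalized oriC distances of all ortholog pairs are correlated
(Pearson), and the candidate pair maximizing the correlation is taken as
the superimposed origins.  The maximal correlation itself measures
oriC-distance conservation; a near-constant diagonal of high correlations
(stable under synchronous rotation of both candidates) flags a degenerate
optimum caused by conserved gene order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .chromosome import CircularChromosome, GeneRecord, circular_distance, ori_proximity
from .errors import InputError
from .io import OrthologTable, SpeciesMeta

__all__ = [
    "MigrationSummary",
    "ConstellationResult",
    "SpeciesGeometry",
    "migration_variation",
    "ori_distance_vector",
    "constellation_scan",
    "diagonal_ridge",
    "growth_class",
    "count_16S",
    "select_family_representatives",
    "class_symmetry_summary",
]


# ---------------------------------------------------------------------------
# gene migration between species
# ---------------------------------------------------------------------------

@dataclass
class MigrationSummary:
    """oriC-proximity drift of a gene set across species comparisons."""

    set_name: str
    per_gene: pd.Series      # averaged |proximity difference| per gene
    mean: float
    se: float                # standard error of the mean (sample sd / sqrt n)
    n_genes: int
    n_dropped: int


@dataclass
class SpeciesGeometry:
    """Positions of one species' genes on its (oriC-annotated) chromosome."""

    chrom: CircularChromosome
    positions: Mapping[str, int]   # gene id -> midpoint

    @classmethod
    def from_genes(cls, chrom: CircularChromosome,
                   genes: Sequence[GeneRecord]) -> "SpeciesGeometry":
        return cls(chrom, {g.gene_id: g.midpoint for g in genes})


def migration_variation(sets: Mapping[str, Iterable[str]],
                        ref: SpeciesGeometry,
                        others: Sequence[SpeciesGeometry],
                        orthologs: Sequence[Mapping[str, str]],
                        ) -> List[MigrationSummary]:
    """Mean oriC-proximity drift per gene set, averaged over comparisons.

    ``orthologs[i]`` maps reference gene ids to species ``others[i]`` gene
    ids (single-copy orthologs only).  Per gene, |Δ oriC proximity| is
    computed for each reference-vs-other comparison and averaged; per set,
    the mean and standard error of those per-gene averages are reported.
    Genes missing an ortholog in any species are dropped and counted.
    """
    if len(others) != len(orthologs):
        raise InputError("need one ortholog mapping per comparison species")
    out: List[MigrationSummary] = []
    for name, members in sets.items():
        members = list(members)
        diffs: Dict[str, List[float]] = {}
        dropped = 0
        for gid in members:
            if gid not in ref.positions:
                dropped += 1
                continue
            p_ref = ori_proximity(ref.positions[gid], ref.chrom)
            vals = []
            for geom, mapping in zip(others, orthologs):
                other_id = mapping.get(gid)
                if other_id is None or other_id not in geom.positions:
                    break
                vals.append(abs(p_ref - ori_proximity(geom.positions[other_id],
                                                      geom.chrom)))
            else:
                diffs[gid] = vals
                continue
            dropped += 1
        per_gene = pd.Series({g: float(np.mean(v)) for g, v in diffs.items()},
                             dtype=float)
        n = len(per_gene)
        mean = float(per_gene.mean()) if n else float("nan")
        se = float(per_gene.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(MigrationSummary(name, per_gene, mean, se, n, dropped))
    return out


# ---------------------------------------------------------------------------
# constellation analysis
# ---------------------------------------------------------------------------

def ori_distance_vector(positions, candidate_oriC: int,
                        chrom: CircularChromosome) -> np.ndarray:
    """Normalized oriC distances d/(L/2) in [0, 1] for gene positions."""
    d = np.asarray(circular_distance(positions, candidate_oriC, chrom),
                   dtype=float)
    return d / chrom.half_length


@dataclass
class ConstellationResult:
    """Grid scan of candidate oriC pairs for two chromosomes."""

    candidates_a: np.ndarray       # bp offsets scanned on chromosome A
    candidates_b: np.ndarray
    matrix: np.ndarray             # Pearson r, shape (len A, len B); NaN = masked
    best_a: float                  # bp
    best_b: float
    r_max: float
    n_orthologs: int
    ridge_score: float
    degenerate: bool

    @property
    def best_offset(self) -> float:
        """Circular offset (best_b - best_a) mod L_b, the inferred rotation."""
        return float((self.best_b - self.best_a))


def _distance_matrix(positions: np.ndarray, candidates: np.ndarray,
                     L: int) -> np.ndarray:
    """|genes| x |candidates| matrix of normalized oriC distances."""
    diff = np.abs(positions[:, None] - candidates[None, :]) % L
    return np.minimum(diff, L - diff) / (L / 2.0)


def constellation_scan(orthologs: OrthologTable,
                       geom_a: SpeciesGeometry, geom_b: SpeciesGeometry,
                       step: Optional[int] = None,
                       ridge_threshold: float = 0.9,
                       normalized: bool = True) -> ConstellationResult:
    """Scan all candidate oriC pairs and correlate ortholog oriC distances.

    ``step`` is the grid spacing per chromosome (default L/200).  Cells
    where a distance vector has zero variance are masked (NaN).  The
    arg-max tie-break is the first maximum in row-major scan order.
    """
    La, Lb = geom_a.chrom.length, geom_b.chrom.length
    pairs = [(a, b) for a, b in orthologs.pairs
             if a in geom_a.positions and b in geom_b.positions]
    if len(pairs) < 3:
        raise InputError("need >= 3 single-copy orthologs present in both species")
    pos_a = np.array([geom_a.positions[a] for a, _ in pairs], dtype=float)
    pos_b = np.array([geom_b.positions[b] for _, b in pairs], dtype=float)

    step_a = step or max(1, La // 200)
    step_b = step or max(1, Lb // 200)
    if La // step_a < 8 or Lb // step_b < 8:
        raise InputError("step too coarse: need >= 8 candidates per chromosome")
    cand_a = np.arange(0, La, step_a, dtype=float)
    cand_b = np.arange(0, Lb, step_b, dtype=float)

    A = _distance_matrix(pos_a, cand_a, La)
    B = _distance_matrix(pos_b, cand_b, Lb)
    if not normalized:
        A = A * (La / 2.0)
        B = B * (Lb / 2.0)

    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = np.sqrt((A ** 2).sum(axis=0))
    sb = np.sqrt((B ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = (A.T @ B) / np.outer(sa, sb)
    matrix[:, sb == 0] = np.nan
    matrix[sa == 0, :] = np.nan

    flat = np.where(np.isnan(matrix), -np.inf, matrix)
    i, j = np.unravel_index(int(np.argmax(flat)), matrix.shape)
    r_max = float(matrix[i, j])
    ridge, degenerate = diagonal_ridge(matrix, (int(i), int(j)),
                                       threshold=ridge_threshold)
    return ConstellationResult(cand_a, cand_b, matrix, float(cand_a[i]),
                               float(cand_b[j]), r_max, len(pairs),
                               ridge, degenerate)


def constellation_permutation_null(orthologs: OrthologTable,
                                   geom_a: SpeciesGeometry,
                                   geom_b: SpeciesGeometry,
                                   n_shuffles: int = 200,
                                   seed: Union[int, np.random.Generator] = 0,
                                   step: Optional[int] = None) -> np.ndarray:
    """Null distribution of r_max under shuffled ortholog pairing.

    Breaking the gene correspondence while keeping both position sets
    destroys any oriC-distance conservation; the returned r_max values
    (one per shuffle) calibrate how large a maximal correlation arises from
    the scan's own maximization over candidate pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    La, Lb = geom_a.chrom.length, geom_b.chrom.length
    pairs = [(a, b) for a, b in orthologs.pairs
             if a in geom_a.positions and b in geom_b.positions]
    if len(pairs) < 3:
        raise InputError("need >= 3 single-copy orthologs present in both species")
    pos_a = np.array([geom_a.positions[a] for a, _ in pairs], dtype=float)
    pos_b = np.array([geom_b.positions[b] for _, b in pairs], dtype=float)
    step_a = step or max(1, La // 200)
    step_b = step or max(1, Lb // 200)
    cand_a = np.arange(0, La, step_a, dtype=float)
    cand_b = np.arange(0, Lb, step_b, dtype=float)
    A = _distance_matrix(pos_a, cand_a, La)
    B = _distance_matrix(pos_b, cand_b, Lb)
    A = A - A.mean(axis=0)
    sa = np.sqrt((A ** 2).sum(axis=0))
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(len(pos_b))
        Bp = B[perm]
        Bp = Bp - Bp.mean(axis=0)
        sb = np.sqrt((Bp ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            m = (A.T @ Bp) / np.outer(sa, sb)
        out[i] = np.nanmax(m)
    return out


def diagonal_ridge(matrix: np.ndarray,
                   argmax: Optional[Tuple[int, int]] = None,
                   threshold: float = 0.9) -> Tuple[float, bool]:
    """Ridge score: mean r along the wrapped diagonal through the arg-max,
    divided by r_max.

    Synchronous rotation of both candidate origins moves along this
    diagonal; when gene order is conserved between the chromosomes the
    correlation barely changes, the score approaches 1, and the optimum is
    flagged degenerate (score >= ``threshold``).
    """
    flat = np.where(np.isnan(matrix), -np.inf, matrix)
    if argmax is None:
        argmax = tuple(np.unravel_index(int(np.argmax(flat)), matrix.shape))
    i0, j0 = argmax
    r_max = matrix[i0, j0]
    na, nb = matrix.shape
    steps = max(na, nb)
    diag = np.array([matrix[(i0 + k) % na, (j0 + k) % nb] for k in range(steps)])
    diag = diag[~np.isnan(diag)]
    if len(diag) == 0 or not np.isfinite(r_max) or r_max <= 0:
        return float("nan"), False
    score = float(diag.mean() / r_max)
    return score, score >= threshold


# ---------------------------------------------------------------------------
# growth classes and class-level symmetry
# ---------------------------------------------------------------------------

def growth_class(n_16S: int) -> str:
    """'slow' if n_16S <= 3, 'fast' if n_16S >= 6, 'excluded' in between."""
    if n_16S < 0:
        raise InputError("n_16S must be >= 0")
    if n_16S <= 3:
        return "slow"
    if n_16S >= 6:
        return "fast"
    return "excluded"


def count_16S(rrna_features: Sequence[Mapping]) -> int:
    """Count rRNA features whose product/name mentions 16S (case-insensitive)."""
    n = 0
    for f in rrna_features:
        text = f"{f.get('product', '')} {f.get('name', '')}".lower()
        if "16s" in text:
            n += 1
    return n


def select_family_representatives(meta: Sequence[SpeciesMeta],
                                  seed: Union[int, np.random.Generator] = 0,
                                  ) -> List[SpeciesMeta]:
    """One uniformly drawn representative species per family."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    by_family: Dict[str, List[SpeciesMeta]] = {}
    for m in meta:
        by_family.setdefault(m.family, []).append(m)
    out = []
    for family in sorted(by_family):
        members = sorted(by_family[family], key=lambda m: m.species)
        out.append(members[rng.integers(0, len(members))])
    return out


@dataclass
class GroupSymmetry:
    """Mean pairwise oriC-distance correlation within one growth group."""

    taxon_class: str
    group: str                  # 'slow' | 'fast'
    mean_r_max: float
    n_pairs: int
    r_values: List[float]


def class_symmetry_summary(
        members: Mapping[str, Sequence[str]],
        pair_data: Mapping[Tuple[str, str], Tuple[OrthologTable,
                                                  SpeciesGeometry,
                                                  SpeciesGeometry]],
        step: Optional[int] = None) -> List[GroupSymmetry]:
    """Constellation r_max for every within-group species pair, averaged.

    ``members`` maps '<class>/<group>' labels to species lists; ``pair_data``
    provides the ortholog table and geometries for each unordered species
    pair.  Groups with fewer than two species are skipped.
    """
    out: List[GroupSymmetry] = []
    for label, species in members.items():
        species = list(species)
        if len(species) < 2:
            continue
        rs: List[float] = []
        for sp1, sp2 in itertools.combinations(species, 2):
            key = (sp1, sp2) if (sp1, sp2) in pair_data else (sp2, sp1)
            table, ga, gb = pair_data[key]
            res = constellation_scan(table, ga, gb, step=step)
            rs.append(res.r_max)
        taxon_class, _, group = label.partition("/")
        out.append(GroupSymmetry(taxon_class, group or label,
                                 float(np.mean(rs)), len(rs), rs))
    return out
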