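"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analyses assume:

* exponential-phase DNA coverage with a log2-linear copy-number gradient
  from oriC (``gradient_ratio`` R copies) to ter (1 copy) on a circular
  chromosome, flat stationary-phase coverage, multiplicative lognormal
  noise per window;
* two-condition expression counts in which each gene's fold change is the
  product of its locus copy number and a planted promoter factor, with a
  configurable fraction of genes whose regulation is dominated by dosage;
* an "INV-like" rearranged genome with known inversion breakpoints;
* ortholog pairs between two circular chromosomes with tunable oriC-distance
  conservation and an unknown circular offset of the second chromosome.

Everything is reproducible bit-for-bit from ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chromosome import CircularChromosome, GeneRecord, circular_distance
from .errors import ConfigError
from .io import CountTable, CoverageTrack, OrthologTable

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genome",
    "planted_copy_number",
    "simulate_coverage",
    "simulate_expression",
    "simulate_ortholog_pair",
    "simulate_dataset",
    "invert_segment",
]

DEFAULT_CATEGORIES = ("C", "E", "F", "H", "J", "K", "L", "M", "P", "U")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults reflect the system the analyses target: an E. coli-sized
    chromosome (4.6 Mb), an oriC/ter copy ratio of 4 as seen for fast
    exponential growth with overlapping replication, lognormal coverage
    noise of 0.1 (log2 sd per 5 kb window), biological triplicates, and a
    dosage-dominant gene fraction of 0.4.
    """

    L: int = 4_600_000
    n_genes: int = 2000
    gradient_ratio: float = 4.0        # planted oriC/ter copy ratio R >= 1
    coverage_noise_sd: float = 0.1     # lognormal sd, log2 scale, per window
    coverage_window: int = 5000
    baseline_depth: float = 100.0
    promoter_log2fc_sd: float = 1.0
    fraction_dosage_dominant: float = 0.4
    replicate_noise_sd: float = 0.1    # lognormal sd, log2 scale, per replicate
    n_replicates: int = 3
    base_expression_log2_sd: float = 2.0
    inversion: Optional[Tuple[int, int]] = None
    ortholog_conservation: float = 0.8  # p_c
    oriC_offset: int = 0                # delta, bp
    seed: int = 0
    categories: Tuple[str, ...] = DEFAULT_CATEGORIES

    def validate(self) -> None:
        if self.L <= 0:
            raise ConfigError("L must be > 0")
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")
        if self.gradient_ratio < 1:
            raise ConfigError("gradient_ratio must be >= 1")
        for name in ("coverage_noise_sd", "promoter_log2fc_sd", "replicate_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.fraction_dosage_dominant <= 1:
            raise ConfigError("fraction_dosage_dominant must be in [0, 1]")
        if not 0 <= self.ortholog_conservation <= 1:
            raise ConfigError("ortholog_conservation must be in [0, 1]")
        if not 0 <= self.oriC_offset < self.L:
            raise ConfigError("oriC_offset must be in [0, L)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.inversion is not None:
            s, e = self.inversion
            if not (0 <= s < self.L and 0 < e <= self.L and s < e):
                raise ConfigError("inversion interval must satisfy 0 <= start < end <= L")


@dataclass
class SimulatedDataset:
    """A full synthetic study: genome, coverage, counts, and planted truth."""

    chrom: CircularChromosome
    genes: List[GeneRecord]
    coverage_exp: CoverageTrack
    coverage_stat: CoverageTrack
    counts: CountTable
    truth: pd.DataFrame            # per-gene f_copy, f_reg, dominant
    breakpoints: List[int] = field(default_factory=list)
    oriC_offset: int = 0


def simulate_genome(cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None,
                    ) -> Tuple[CircularChromosome, List[GeneRecord]]:
    """Place ``n_genes`` genes i.i.d. uniformly on the circle.

    Lengths are lognormal around ~900 bp; strands and functional categories
    are drawn uniformly from the configured label set.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    chrom = CircularChromosome("chrSim", cfg.L, oriC=0)
    mids = np.sort(rng.integers(0, cfg.L, size=cfg.n_genes))
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    lengths = np.clip(rng.lognormal(np.log(900), 0.5, size=cfg.n_genes), 90, 6000)
    cats = rng.choice(list(cfg.categories), size=cfg.n_genes)
    width = len(str(cfg.n_genes))
    genes = [
        GeneRecord(f"g{i:0{width}d}", int(mids[i]), str(strands[i]),
                   int(lengths[i]), str(cats[i]))
        for i in range(cfg.n_genes)
    ]
    return chrom, genes


def planted_copy_number(p, cfg: SimulationConfig, chrom: CircularChromosome):
    """Copy number R^(1 - d/(L/2)) at position(s) p: R at oriC, 1 at ter."""
    d = np.asarray(circular_distance(p, chrom.oriC, chrom), dtype=float)
    out = cfg.gradient_ratio ** (1.0 - d / chrom.half_length)
    return out.item() if out.ndim == 0 else out


def simulate_coverage(cfg: SimulationConfig, chrom: CircularChromosome,
                      rng: Optional[np.random.Generator] = None,
                      ) -> Tuple[CoverageTrack, CoverageTrack]:
    """Exponential- and stationary-phase coverage tracks.

    The chromosome is tiled in windows of ``coverage_window`` bp (last
    window may be short); stationary depth is baseline x noise, exponential
    depth additionally carries the planted copy number at the window
    midpoint.  Noise is lognormal with the configured log2 sd, drawn
    independently per window and phase (stationary first, then exponential).
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    w = cfg.coverage_window
    starts = np.arange(0, chrom.length, w, dtype=np.int64)
    ends = np.minimum(starts + w, chrom.length)
    mids = ((starts + ends) // 2) % chrom.length
    n = len(starts)
    noise_stat = 2.0 ** rng.normal(0.0, cfg.coverage_noise_sd, size=n)
    noise_exp = 2.0 ** rng.normal(0.0, cfg.coverage_noise_sd, size=n)
    cn = planted_copy_number(mids, cfg, chrom)
    stat = CoverageTrack(chrom.name, starts, ends, cfg.baseline_depth * noise_stat)
    exp = CoverageTrack(chrom.name, starts, ends,
                        cfg.baseline_depth * cn * noise_exp)
    return exp, stat


def _planted_promoter_log2fc(m: np.ndarray, dominant: np.ndarray,
                             cfg: SimulationConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Promoter log2 fold changes consistent with the planted dominance labels.

    Dominant genes draw from Normal(0, 0.1*sd) truncated to |lfc| < m (their
    copy effect wins); the rest draw from Normal(0, sd) truncated to
    |lfc| > m.  Truncation keeps the stated marginals near the per-gene
    dominance boundary m = |log2 f_copy|, so classification is exercised on
    near-boundary cases rather than trivially separated groups.
    """
    n = len(m)
    lfc = np.zeros(n)
    sd_dom = 0.1 * cfg.promoter_log2fc_sd

    dom = dominant & (m > 0)
    if sd_dom == 0:
        lfc[dom] = 0.0
    elif np.any(dom):
        a = -m[dom] / sd_dom
        b = m[dom] / sd_dom
        lfc[dom] = stats.truncnorm.rvs(a, b, scale=sd_dom, random_state=rng)

    non = ~dominant
    if np.any(non):
        sd = cfg.promoter_log2fc_sd
        if sd == 0:
            # degenerate config: no promoter variation available; place just
            # outside the boundary so labels stay consistent
            lfc[non] = np.where(m[non] > 0, 1.001 * m[non], 0.0)
        else:
            sign = rng.choice([-1.0, 1.0], size=int(non.sum()))
            a = m[non] / sd
            mag = stats.truncnorm.rvs(a, np.inf, scale=sd, random_state=rng)
            lfc[non] = sign * mag
    return lfc


def simulate_expression(cfg: SimulationConfig, chrom: CircularChromosome,
                        genes: Sequence[GeneRecord],
                        rng: Optional[np.random.Generator] = None,
                        ) -> Tuple[CountTable, pd.DataFrame]:
    """Two-condition (EXP/STAT) counts with planted per-gene factors.

    Expected stationary count is a lognormal per-gene baseline scaled by
    gene length; expected exponential count additionally carries the locus
    copy number and the planted promoter factor.  Replicates are drawn with
    multiplicative lognormal noise.  The returned truth table has one row
    per gene: f_copy, f_reg, dominant.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    n = len(genes)
    mids = np.array([g.midpoint for g in genes])
    lengths = np.array([g.length for g in genes], dtype=float)

    f_copy = np.asarray(planted_copy_number(mids, cfg, chrom), dtype=float)
    m = np.abs(np.log2(f_copy))

    n_dom = int(round(cfg.fraction_dosage_dominant * n))
    dominant = np.zeros(n, dtype=bool)
    dominant[rng.choice(n, size=n_dom, replace=False)] = True

    lfc = _planted_promoter_log2fc(m, dominant, cfg, rng)
    f_reg = 2.0 ** lfc

    base = 50.0 * (lengths / 1000.0) * 2.0 ** rng.normal(
        0.0, cfg.base_expression_log2_sd, size=n)
    mean_stat = base
    mean_exp = base * f_copy * f_reg

    cols = {}
    for r in range(1, cfg.n_replicates + 1):
        noise = 2.0 ** rng.normal(0.0, cfg.replicate_noise_sd, size=n)
        cols[f"EXP_{r}"] = mean_exp * noise
    for r in range(1, cfg.n_replicates + 1):
        noise = 2.0 ** rng.normal(0.0, cfg.replicate_noise_sd, size=n)
        cols[f"STAT_{r}"] = mean_stat * noise

    gene_ids = [g.gene_id for g in genes]
    counts = CountTable(pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")),
                        pd.Series(lengths.astype(np.int64), index=gene_ids))
    truth = pd.DataFrame(
        {"midpoint": mids, "f_copy": f_copy, "f_reg": f_reg,
         "f_total": f_copy * f_reg, "dominant": dominant},
        index=pd.Index(gene_ids, name="gene_id"))
    return counts, truth


def invert_segment(positions, start: int, end: int, L: int):
    """Mirror positions inside the half-open segment [start, end) of a circle.

    Positions outside the segment are unchanged; the segment must not wrap.
    Returns the rearranged coordinates (the "INV-like" genome map) — the
    breakpoints are ``start`` and ``end``.
    """
    p = np.asarray(positions)
    if not 0 <= start < end <= L:
        raise ConfigError("inversion interval must satisfy 0 <= start < end <= L")
    inside = (p >= start) & (p < end)
    out = p.copy()
    out[inside] = start + (end - 1) - p[inside]
    return out


def simulate_ortholog_pair(cfg: SimulationConfig, chrom: CircularChromosome,
                           genes: Sequence[GeneRecord],
                           rng: Optional[np.random.Generator] = None,
                           ) -> Tuple[CircularChromosome, List[GeneRecord],
                                      OrthologTable, dict]:
    """A second species with tunable oriC-distance conservation.

    Each gene keeps its oriC distance with probability ``p_c`` (replichore
    side re-randomized with probability 0.5 — the symmetric rearrangement
    mode), otherwise it moves to a uniform position.  All second-species
    coordinates are finally rotated by ``oriC_offset`` so its true oriC sits
    at (oriC_A + offset) mod L.  Orthologs pair gene i with gene i'.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    L = chrom.length
    mids = np.array([g.midpoint for g in genes])
    n = len(genes)

    conserved = rng.random(n) < cfg.ortholog_conservation
    side = np.where(rng.random(n) < 0.5, 1, -1)
    d = np.asarray(circular_distance(mids, chrom.oriC, chrom))
    pos_cons = (chrom.oriC + side * d) % L
    pos_rand = rng.integers(0, L, size=n)
    pos_b = np.where(conserved, pos_cons, pos_rand)
    pos_b = (pos_b + cfg.oriC_offset) % L

    oriC_b = int((chrom.oriC + cfg.oriC_offset) % L)
    chrom_b = CircularChromosome(chrom.name + "_B", L, oriC=oriC_b)
    genes_b = [
        GeneRecord(g.gene_id + "_b", int(pos_b[i]), g.strand, g.length, g.category)
        for i, g in enumerate(genes)
    ]
    table = OrthologTable("species_A", "species_B",
                          [(g.gene_id, g.gene_id + "_b") for g in genes])
    truth = {"oriC_offset": int(cfg.oriC_offset), "oriC_b": oriC_b,
             "conserved": conserved}
    return chrom_b, genes_b, table, truth


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset from one config and one seed.

    The RNG is consumed in a fixed order (genome, coverage, expression), so
    identical configs give byte-identical datasets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom, genes = simulate_genome(cfg, rng)
    cov_exp, cov_stat = simulate_coverage(cfg, chrom, rng)
    counts, truth = simulate_expression(cfg, chrom, genes, rng)
    breakpoints: List[int] = []
    if cfg.inversion is not None:
        s, e = cfg.inversion
        breakpoints = [s, e]
    return SimulatedDataset(chrom, genes, cov_exp, cov_stat, counts, truth,
                            breakpoints, cfg.oriC_offset)
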