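"""Expression normalization and sliding-window spatial statistics.

The chromosome-scale expression analyses work on windows of a fixed number
of genes (default 300) slid one gene at a time around the circle: the
up/down regulation bias, the average fold change (with correction for the
relative-frequency bias introduced by library-size normalization), regulon
window frequencies, and copy-number normalization of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chromosome import CircularChromosome, GeneRecord, replichore_of
from .errors import InputError
from .io import CountTable
from .mfa import CopyNumberModel, ZeroDifferenceResult

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedExpression",
    "WindowCurve",
    "normalize_expression",
    "gene_fold_changes",
    "FoldChanges",
    "updown_bias_curve",
    "fold_change_curve",
    "frequency_bias_correct",
    "exclude_breakpoint_windows",
    "copy_normalize_expression",
    "regulon_window_frequency",
    "select_up_genes",
    "spatial_log2_slope",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedExpression:
    """Length- and library-normalized (optionally quantile-normalized) values."""

    values: pd.DataFrame           # genes x samples
    conditions: Dict[str, str]     # sample -> condition
    quantile_normalized: bool = False

    def samples_of(self, condition: str) -> List[str]:
        return [s for s, c in self.conditions.items() if c == condition]

    def condition_mean(self, condition: str) -> pd.Series:
        cols = self.samples_of(condition)
        if not cols:
            raise InputError(f"no samples for condition {condition!r}")
        return self.values[cols].mean(axis=1)


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization; ties get the average of tied quantiles."""
    ranks = df.rank(method="average", axis=0)
    mean_sorted = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    n = len(df)
    grid = np.arange(1, n + 1, dtype=float)
    out = {
        col: np.interp(ranks[col].to_numpy(), grid, mean_sorted)
        for col in df.columns
    }
    return pd.DataFrame(out, index=df.index)


def normalize_expression(counts: CountTable, quantile: bool = True,
                         target_sum: float = 1e6) -> NormalizedExpression:
    """Normalize counts for gene length and library size, then (optionally)
    quantile-normalize all samples in one batch.

    Per sample: value = count / gene length, rescaled so each sample sums
    to ``target_sum``.  The quantile step forces every sample onto the
    common average distribution (appropriate for harmonizing technical
    variation; switch it off when the conditions are expected to differ
    globally in truth).
    """
    if (counts.lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    v = counts.counts.div(counts.lengths, axis=0)
    sums = v.sum(axis=0)
    if (sums <= 0).any():
        raise InputError("every sample needs positive total signal")
    v = v.div(sums, axis=1) * target_sum
    if quantile:
        v = _quantile_normalize(v)
    conditions = {s: counts.condition_of(s) for s in counts.samples}
    return NormalizedExpression(v, conditions, quantile_normalized=quantile)


@dataclass
class FoldChanges:
    """Per-gene expression fold changes between two conditions."""

    f_total: pd.Series             # genes with defined fold change
    excluded: List[str]            # genes with zero denominator
    cond_a: str
    cond_b: str


def gene_fold_changes(expr: NormalizedExpression, cond_a: str, cond_b: str,
                      ) -> FoldChanges:
    """f_total = mean(cond_a) / mean(cond_b) per gene.

    Genes whose denominator mean is zero are excluded and reported.
    """
    for c in (cond_a, cond_b):
        if not expr.samples_of(c):
            raise InputError(f"condition {c!r} absent from expression data")
    ma = expr.condition_mean(cond_a)
    mb = expr.condition_mean(cond_b)
    ok = mb > 0
    excluded = list(ma.index[~ok])
    if excluded:
        logger.warning("%d genes excluded (zero %s mean)", len(excluded), cond_b)
    return FoldChanges((ma[ok] / mb[ok]).rename("f_total"), excluded, cond_a, cond_b)


# ---------------------------------------------------------------------------
# sliding windows over gene order
# ---------------------------------------------------------------------------

@dataclass
class WindowCurve:
    """A sliding-window statistic along the chromosome.

    One window per gene (step 1, circular): window i contains the ``window``
    consecutive genes starting at position-rank i; its location is the mean
    coordinate of its members (unwrapped on the circle).
    """

    locations: np.ndarray          # bp, one per window
    values: np.ndarray
    window: int
    gene_order: List[str]          # gene ids sorted by coordinate
    positions: np.ndarray          # sorted midpoints, aligned with gene_order
    length: int                    # chromosome length
    excluded: np.ndarray = field(default=None)  # bool mask, True = dropped

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = np.zeros(len(self.values), dtype=bool)

    def kept(self) -> Tuple[np.ndarray, np.ndarray]:
        keep = ~self.excluded
        return self.locations[keep], self.values[keep]

    def span(self, i: int) -> Tuple[float, float]:
        """(first, last) member coordinate of window i along its arc."""
        n = len(self.gene_order)
        first = self.positions[i % n]
        last = self.positions[(i + self.window - 1) % n]
        return float(first), float(last)


def _sorted_genes(genes: Sequence[GeneRecord]):
    order = sorted(range(len(genes)), key=lambda i: genes[i].midpoint)
    ids = [genes[i].gene_id for i in order]
    pos = np.array([genes[i].midpoint for i in order], dtype=float)
    return ids, pos


def _rolling_circular(values: np.ndarray, window: int) -> np.ndarray:
    """Circular rolling sums of length ``window``, one window per start index."""
    ext = np.concatenate([values, values[: window - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return csum[window:] - csum[:-window]


def _window_locations(pos: np.ndarray, window: int, L: int) -> np.ndarray:
    # wrap-around members are unwrapped by +L before averaging
    ext = np.concatenate([pos, pos[: window - 1] + L])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    sums = csum[window:] - csum[: len(pos)]
    return (sums / window) % L


def _curve(genes, per_gene_values: pd.Series, window: int, L: int,
           reducer: str) -> WindowCurve:
    ids, pos = _sorted_genes(genes)
    if window > len(ids):
        raise InputError(f"window of {window} genes exceeds {len(ids)} genes")
    vals = per_gene_values.reindex(ids)
    if vals.isna().any():
        missing = int(vals.isna().sum())
        raise InputError(f"{missing} genes lack a value for the window statistic")
    v = vals.to_numpy(dtype=float)
    if reducer == "mean":
        out = _rolling_circular(v, window) / window
    elif reducer == "sum":
        out = _rolling_circular(v, window)
    else:  # pragma: no cover
        raise ValueError(reducer)
    locs = _window_locations(pos, window, L)
    return WindowCurve(locs, out, window, ids, pos, L)


def updown_bias_curve(fold: FoldChanges, genes: Sequence[GeneRecord],
                      chrom: CircularChromosome, window: int = 300) -> WindowCurve:
    """(up - down) / window per sliding window of ``window`` genes.

    A gene counts up if f_total > 1 and down if f_total < 1; genes with
    fold change exactly 1 count in neither direction.  Values lie in
    [-1, 1] by construction.
    """
    sign = pd.Series(np.sign(np.log(fold.f_total.to_numpy())),
                     index=fold.f_total.index)
    members = [g for g in genes if g.gene_id in sign.index]
    return _curve(members, sign, window, chrom.length, "mean")


def fold_change_curve(fold: FoldChanges, genes: Sequence[GeneRecord],
                      chrom: CircularChromosome, window: int = 300,
                      log_mean: bool = False) -> WindowCurve:
    """Average fold change per sliding window.

    The default is the arithmetic mean of the linear fold changes (directly
    comparable to a linear copy-number difference curve); ``log_mean``
    switches to the geometric mean.
    """
    members = [g for g in genes if g.gene_id in fold.f_total.index]
    if log_mean:
        lg = pd.Series(np.log2(fold.f_total.to_numpy()), index=fold.f_total.index)
        curve = _curve(members, lg, window, chrom.length, "mean")
        curve.values = 2.0 ** curve.values
        return curve
    return _curve(members, fold.f_total, window, chrom.length, "mean")


def regulon_window_frequency(target_genes: Iterable[str],
                             genes: Sequence[GeneRecord],
                             chrom: CircularChromosome,
                             window: int = 300) -> WindowCurve:
    """Fraction of window members belonging to a target gene set."""
    target = set(target_genes)
    universe = {g.gene_id for g in genes}
    stray = target - universe
    if stray:
        raise InputError(f"{len(stray)} target genes not in the gene universe")
    if not target:
        logger.warning("empty target set: regulon frequency curve is all zero")
    member = pd.Series({g.gene_id: 1.0 if g.gene_id in target else 0.0
                        for g in genes})
    return _curve(genes, member, window, chrom.length, "mean")


# ---------------------------------------------------------------------------
# frequency-bias correction and breakpoint exclusion
# ---------------------------------------------------------------------------

def _replichore_offsets(positions: np.ndarray, chrom: CircularChromosome):
    """Clockwise/counterclockwise offsets from oriC, split by replichore."""
    L = chrom.length
    t = (positions - chrom.oriC) % L
    arc_right = (chrom.ter - chrom.oriC) % L
    right = t < arc_right
    offs = np.where(right, t, L - t)
    return right, offs


def frequency_bias_correct(curve: WindowCurve, fold: FoldChanges,
                           genes: Sequence[GeneRecord],
                           chrom: CircularChromosome,
                           zero_loci: Sequence[ZeroDifferenceResult],
                           ) -> Tuple[WindowCurve, float]:
    """Anchor the average fold change to 1 where copy numbers do not differ.

    Library-size normalization makes fold changes relative: enriching
    oriC-proximal transcripts depletes the relative abundance of everything
    else, dragging terminus fold changes below 1.  Following the anchoring
    assumption — the true average fold change is 1 at the locus of zero
    copy-number difference — a log2-linear regression of the per-gene fold
    changes is fitted per replichore, its ordinate is evaluated at each
    replichore's zero-difference locus, and every window value is divided
    by the (geometric mean) ordinate.

    Returns the corrected curve and the linear correction factor c.
    """
    id_to_pos = {g.gene_id: g.midpoint for g in genes}
    ids = [i for i in fold.f_total.index if i in id_to_pos]
    pos = np.array([id_to_pos[i] for i in ids], dtype=float)
    y = np.log2(fold.f_total.reindex(ids).to_numpy(dtype=float))
    right, offs = _replichore_offsets(pos, chrom)

    ordinates = []
    for res in zero_loci:
        mask = right if res.replichore == "right" else ~right
        if mask.sum() < 3 or np.allclose(offs[mask].var(), 0):
            logger.warning("frequency-bias correction skipped on %s replichore",
                           res.replichore)
            continue
        fit = stats.linregress(offs[mask], y[mask])
        _, z_off = _replichore_offsets(np.array([res.locus]), chrom)
        ordinates.append(fit.intercept + fit.slope * z_off[0])
    if not ordinates:
        logger.warning("frequency-bias correction skipped: degenerate regression")
        return curve, 1.0
    c = float(2.0 ** np.mean(ordinates))
    corrected = WindowCurve(curve.locations, curve.values / c, curve.window,
                            curve.gene_order, curve.positions, curve.length,
                            curve.excluded.copy())
    return corrected, c


def exclude_breakpoint_windows(curve: WindowCurve,
                               breakpoints: Sequence[int]) -> WindowCurve:
    """Flag windows whose member-gene span contains a rearrangement breakpoint.

    A window is excluded when a breakpoint lies strictly between its first
    and last member coordinate along the window's arc; flagged windows are
    dropped from :meth:`WindowCurve.kept`.
    """
    if not len(breakpoints):
        return curve
    L = curve.length
    n = len(curve.values)
    excluded = curve.excluded.copy()
    for i in range(n):
        first, last = curve.span(i)
        arc = (last - first) % L
        for bp in breakpoints:
            rel = (bp - first) % L
            if 0 < rel < arc:
                excluded[i] = True
                break
    return WindowCurve(curve.locations, curve.values, curve.window,
                       curve.gene_order, curve.positions, L, excluded)


def copy_normalize_expression(expr: NormalizedExpression,
                              gene_copy_diff: pd.Series,
                              conditions: Sequence[str] = ("EXP",),
                              ) -> NormalizedExpression:
    """Divide expression by the per-gene copy-number difference.

    Removes the replication-induced dosage component from the listed
    conditions' samples (e.g. normalizing reference-strain exponential data
    by the reference/mutant copy-number difference before comparing
    expression), leaving promoter-driven variation.
    """
    diffs = gene_copy_diff.reindex(expr.values.index)
    if diffs.isna().any():
        raise InputError("copy-number difference missing for some genes")
    values = expr.values.copy()
    for s in values.columns:
        if expr.conditions[s] in conditions:
            values[s] = values[s] / diffs
    return NormalizedExpression(values, dict(expr.conditions),
                                expr.quantile_normalized)


# ---------------------------------------------------------------------------
# differential expression and spatial slope
# ---------------------------------------------------------------------------

def select_up_genes(expr: NormalizedExpression, cond_a: str, cond_b: str,
                    alpha: float = 0.05, bh: bool = False,
                    ) -> Tuple[Set[str], pd.Series]:
    """Genes significantly up in ``cond_a`` vs ``cond_b``.

    Welch two-sample t-test on log2 normalized values per gene; returns the
    set with mean_a > mean_b and p < alpha, plus all per-gene p-values.
    Benjamini-Hochberg adjustment is available but off by default (the
    selection rule is a raw p-value threshold).
    """
    sa = expr.samples_of(cond_a)
    sb = expr.samples_of(cond_b)
    if len(sa) < 2 or len(sb) < 2:
        raise InputError("need >= 2 replicates per condition for the t-test")
    eps = np.finfo(float).tiny
    la = np.log2(expr.values[sa].to_numpy(dtype=float) + eps)
    lb = np.log2(expr.values[sb].to_numpy(dtype=float) + eps)
    res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    pvals = pd.Series(res.pvalue, index=expr.values.index, name="pvalue")
    pvals = pvals.fillna(1.0)
    if bh:
        order = np.argsort(pvals.to_numpy())
        n = len(pvals)
        adj = np.empty(n)
        ranked = pvals.to_numpy()[order] * n / np.arange(1, n + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        pvals = pd.Series(np.minimum(adj, 1.0), index=pvals.index, name="pvalue")
    up = la.mean(axis=1) > lb.mean(axis=1)
    selected = set(pvals.index[(pvals < alpha) & up])
    return selected, pvals


def spatial_log2_slope(per_gene_values: pd.Series, genes: Sequence[GeneRecord],
                       chrom: CircularChromosome) -> float:
    """OLS slope of log2 value vs oriC distance (bp), both replichores pooled.

    A fitted copy-number gradient has negative slope (values fall toward
    ter); after successful copy normalization the slope magnitude should be
    near zero.
    """
    id_to_pos = {g.gene_id: g.midpoint for g in genes}
    ids = [i for i in per_gene_values.index if i in id_to_pos]
    pos = np.array([id_to_pos[i] for i in ids], dtype=float)
    _, offs = _replichore_offsets(pos, chrom)
    y = np.log2(per_gene_values.reindex(ids).to_numpy(dtype=float))
    fit = stats.linregress(offs, y)
    return float(fit.slope)
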