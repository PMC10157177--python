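"""Decompose expression fold changes into copy-number and promoter parts.

A gene's measured fold change f_total between two conditions is modelled as
the product of its replication-induced copy-number difference f_copy and
the remaining promoter regulation f_reg:

    f_reg = f_total / f_copy

Dominance and the copy share are computed on log2 magnitudes, so a 2-fold
copy effect and a 0.5-fold promoter effect carry equal weight; that keeps
the "proportion of each factor" well defined when the two act in opposite
directions (a linear-proportion alternative would not be symmetric under
f -> 1/f).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = [
    "FoldChangeRecord",
    "decompose",
    "classify_dominance",
    "copy_share",
    "quarter_criteria",
    "decompose_table",
    "stringency_subsets",
]

DEFAULT_STRINGENCY = (0.5, 0.65, 0.8)


@dataclass(frozen=True)
class FoldChangeRecord:
    """One gene's fold-change decomposition and derived classifications."""

    gene_id: str
    f_total: float
    f_copy: float
    f_reg: float
    copy_share_: float
    dominance: str                 # 'copy' | 'promoter'
    passes_quarter_total: bool     # copy share >= 1/4 of total
    passes_quarter_vs_reg: bool    # |log2 f_copy| >= 1/4 |log2 f_reg|
    share_defined: bool = True


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0) or not np.isfinite(v):
            raise DomainError(f"{name} must be a positive finite ratio, got {v}")


def decompose(f_total: float, f_copy: float) -> float:
    """Remaining promoter factor f_reg = f_total / f_copy."""
    _require_positive(f_total=f_total, f_copy=f_copy)
    return f_total / f_copy


def classify_dominance(f_copy: float, f_reg: float) -> str:
    """'copy' iff |log2 f_copy| > |log2 f_reg|; ties go to 'promoter'.

    The tie-break is conservative: it never inflates the copy-regulated
    class.
    """
    _require_positive(f_copy=f_copy, f_reg=f_reg)
    return "copy" if abs(np.log2(f_copy)) > abs(np.log2(f_reg)) else "promoter"


def copy_share(f_copy: float, f_reg: float) -> Tuple[float, bool]:
    """Fraction of the total log2 fold-change magnitude carried by copy number.

    Returns (share in [0,1], defined flag); if both factors are exactly 1
    the share is reported as 0 with defined=False.
    """
    _require_positive(f_copy=f_copy, f_reg=f_reg)
    a = abs(np.log2(f_copy))
    b = abs(np.log2(f_reg))
    if a + b == 0:
        return 0.0, False
    return a / (a + b), True


def quarter_criteria(f_copy: float, f_reg: float) -> Tuple[bool, bool]:
    """The two printed one-fourth criteria, evaluated side by side.

    * quarter_total: the copy effect covers at least one fourth of the
      total fold change (copy share >= 0.25);
    * quarter_vs_reg: the copy factor is at least one fourth of the other
      regulators' factor (|log2 f_copy| >= 0.25 |log2 f_reg|).
    """
    share, defined = copy_share(f_copy, f_reg)
    a = abs(np.log2(f_copy))
    b = abs(np.log2(f_reg))
    quarter_total = share >= 0.25 if defined else True
    quarter_vs_reg = a >= 0.25 * b
    return quarter_total, quarter_vs_reg


def decompose_table(f_total: pd.Series, f_copy: pd.Series) -> pd.DataFrame:
    """Vectorized decomposition for aligned per-gene series.

    Returns a DataFrame indexed by gene with columns f_total, f_copy,
    f_reg, copy_share, dominance, passes_quarter_total,
    passes_quarter_vs_reg, share_defined.
    """
    idx = f_total.index.intersection(f_copy.index)
    ft = f_total.reindex(idx).to_numpy(dtype=float)
    fc = f_copy.reindex(idx).to_numpy(dtype=float)
    if np.any(ft <= 0) or np.any(fc <= 0) or not np.all(np.isfinite(ft * fc)):
        raise DomainError("fold changes and copy numbers must be positive finite")
    fr = ft / fc
    a = np.abs(np.log2(fc))
    b = np.abs(np.log2(fr))
    denom = a + b
    defined = denom > 0
    share = np.where(defined, a / np.where(defined, denom, 1.0), 0.0)
    dominance = np.where(a > b, "copy", "promoter")
    q_total = np.where(defined, share >= 0.25, True)
    q_vs_reg = a >= 0.25 * b
    return pd.DataFrame(
        {"f_total": ft, "f_copy": fc, "f_reg": fr, "copy_share": share,
         "dominance": dominance, "passes_quarter_total": q_total,
         "passes_quarter_vs_reg": q_vs_reg, "share_defined": defined},
        index=idx)


def stringency_subsets(table: pd.DataFrame,
                       thresholds: Sequence[float] = DEFAULT_STRINGENCY,
                       ) -> Dict[str, List[Set[str]]]:
    """Nested copy- and promoter-dominated gene subsets.

    Copy subset k: genes with copy_share >= thresholds[k]; promoter subset
    k: copy_share <= 1 - thresholds[k].  Thresholds must be strictly
    increasing, so subsets are nested by construction.
    """
    thresholds = list(thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ConfigError("stringency thresholds must be strictly increasing")
    share = table["copy_share"]
    copy_sets = [set(share.index[share >= t]) for t in thresholds]
    promoter_sets = [set(share.index[share <= 1.0 - t]) for t in thresholds]
    return {"copy": copy_sets, "promoter": promoter_sets}
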