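"""Randomization z-score test for functional-category enrichment.

For a query gene set (e.g. the predominantly copy-number-regulated genes),
``n_random`` random sets of the same size are drawn uniformly without
replacement from the gene universe.  For every functional category the
observed member count x is compared against the mean m and standard
deviation s of the counts over the random sets:

    z = (x - m) / s

Unannotated genes stay in the universe and can be drawn (they dilute
counts); pass ``annotated_only=True`` to restrict sampling to annotated
genes.  s uses the population convention (no Bessel correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .chromosome import GeneRecord
from .errors import InputError

__all__ = ["EnrichmentResult", "functional_zscores"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs randomized category counts for one functional category."""

    category: str
    x: int          # observed count in the query set
    m: float        # mean count over random sets
    s: float        # population sd over random sets
    z: float
    degenerate: bool = False  # s == 0


def functional_zscores(query_set: Iterable[str],
                       universe: Sequence[GeneRecord],
                       n_random: int = 1000,
                       seed: Union[int, np.random.Generator, None] = 0,
                       annotated_only: bool = False,
                       ) -> List[EnrichmentResult]:
    """z-scores of category over/under-representation in a query gene set.

    Reproducible under ``seed`` (an int or a Generator).  Categories absent
    from the universe cannot occur and are not reported; genes in the query
    that lack a category simply contribute to no category count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    if annotated_only:
        universe = [g for g in universe if g.category is not None]
    ids = [g.gene_id for g in universe]
    id_set = set(ids)
    query = set(query_set)
    stray = query - id_set
    if stray:
        raise InputError(f"{len(stray)} query genes not in the universe")
    k = len(query)
    if k > len(ids):
        raise InputError("query set larger than the universe")
    if n_random < 2:
        raise InputError("n_random must be >= 2")

    cats = sorted({g.category for g in universe if g.category is not None})
    cat_index = {c: i for i, c in enumerate(cats)}
    codes = np.array([cat_index.get(g.category, -1) for g in universe])
    ncat = len(cats)
    if ncat == 0:
        raise InputError("universe carries no category annotations")

    in_query = np.array([g.gene_id in query for g in universe])
    x = np.bincount(codes[in_query & (codes >= 0)], minlength=ncat)

    counts = np.empty((n_random, ncat), dtype=np.int64)
    n = len(ids)
    for i in range(n_random):
        idx = rng.choice(n, size=k, replace=False)
        c = codes[idx]
        counts[i] = np.bincount(c[c >= 0], minlength=ncat)
    m = counts.mean(axis=0)
    s = counts.std(axis=0)  # population sd

    results: List[EnrichmentResult] = []
    for j, cat in enumerate(cats):
        if s[j] > 0:
            z = (x[j] - m[j]) / s[j]
            degenerate = False
        elif x[j] == m[j]:
            z, degenerate = 0.0, True
        else:
            z = float(np.inf if x[j] > m[j] else -np.inf)
            degenerate = True
        results.append(EnrichmentResult(cat, int(x[j]), float(m[j]),
                                        float(s[j]), float(z), degenerate))
    return results
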