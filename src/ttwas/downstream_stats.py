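"""Enrichment and essentiality statistics for identified gene sets.

* Hypergeometric enrichment of an identified gene set in an annotation set
  (upper-tail probability P(X >= x) over a background of N genes).
* Two-sided Fisher's exact test for TF enrichment in a 2x2 table.
* CRISPR essentiality flagging: genes whose median CERES dependency score
  across cell lines falls strictly below a cutoff (default -0.5; more
  negative = more essential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for a hypergeometric gene-set overlap test."""

    N: int  # background (e.g. 19,291 protein-coding genes)
    m: int  # genes in the annotation set
    k: int  # identified genes
    x: int  # overlap

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.N and 0 <= self.k <= self.N):
            raise ValueError("require m <= N and k <= N")
        if self.x < 0 or self.x > min(self.m, self.k):
            raise ValueError(f"overlap x={self.x} exceeds min(m, k)={min(self.m, self.k)}")


def hypergeom_enrichment(inp: EnrichmentInput) -> float:
    """Upper-tail hypergeometric probability P(X >= x)."""
    return float(stats.hypergeom.sf(inp.x - 1, inp.N, inp.m, inp.k))


def fisher_tf_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sidedness by summation of point probabilities at most that of the
    observed table (the conventional exact definition).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def ceres_essential(matrix: pd.DataFrame, cutoff: float = -0.5) -> list[str]:
    """Genes whose median CERES score across cell lines is strictly < cutoff.

    ``matrix`` is genes x cell lines; missing cells are excluded from each
    gene's median, and genes with no observed score are skipped with a
    warning.
    """
    flagged = []
    for gene, row in matrix.iterrows():
        vals = row.dropna()
        if vals.empty:
            logger.warning("gene %s has no CERES scores; excluded", gene)
            continue
        if float(np.median(vals)) < cutoff:
            flagged.append(str(gene))
    return flagged
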