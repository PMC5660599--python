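"""Expression-matrix cleaning and the pairwise correlation table.

The cleaning pipeline runs in a fixed, documented order:

1. :func:`log2_transform` (only for ratio-scale inputs),
2. :func:`collapse_isoforms` (average isoform rows into one gene-level row),
3. :func:`filter_missing` (drop genes absent in more than 40% of samples).

Collapsing before filtering lets isoform-level missingness be rescued by
averaging.  The missing filter is strict: a gene missing in exactly the
threshold fraction of samples is kept; only genes missing in *more* than the
threshold are dropped.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 10


def filter_missing(
    em: ExpressionMatrix, max_missing_frac: float = 0.4
) -> ExpressionMatrix:
    """Drop genes whose missing fraction exceeds ``max_missing_frac``.

    The boundary is inclusive for keeping: a gene missing in exactly
    ``max_missing_frac`` of samples survives.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be within [0, 1]")
    frac = em.missing_fraction()
    keep = frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_missing: dropped %d/%d genes missing in more than %.0f%% of samples",
            n_dropped,
            em.n_genes,
            100 * max_missing_frac,
        )
    return ExpressionMatrix(em.data.loc[keep.to_numpy()].copy(), dict(em.meta))


def collapse_isoforms(
    em: ExpressionMatrix, isoform_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Average isoform rows mapping to the same gene into one row per gene.

    Per-sample means ignore missing values; a sample where every isoform is
    missing stays missing.  Rows absent from the map are dropped with a
    warning.  Output gene order follows first appearance in the input.
    """
    if not isoform_to_gene:
        raise ValueError("isoform_to_gene map is empty")
    mapped = [rid for rid in em.gene_ids if rid in isoform_to_gene]
    unmapped = em.n_genes - len(mapped)
    if unmapped:
        logger.warning("collapse_isoforms: dropped %d unmapped row(s)", unmapped)
    sub = em.data.loc[mapped]
    genes = pd.Index([isoform_to_gene[rid] for rid in mapped], name="gene_id")
    collapsed = sub.groupby(genes, sort=False).mean()  # skips NaN per cell
    return ExpressionMatrix(collapsed, dict(em.meta))


def log2_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a ratio/intensity matrix; missing preserved."""
    values = em.values
    bad = np.argwhere((values <= 0) & ~np.isnan(values))
    if bad.size:
        cells = [
            f"({em.gene_ids[i]}, {em.sample_ids[j]})" for i, j in bad[:10]
        ]
        raise ValueError(
            f"log2_transform: {len(bad)} non-positive observed value(s), "
            f"e.g. {', '.join(cells)}"
        )
    return ExpressionMatrix(np.log2(em.data), dict(em.meta))


class CorrelationTable:
    """Pairwise-complete Pearson correlations between gene expression profiles.

    Internally a dense genes x genes matrix; entries with fewer than
    ``min_overlap`` jointly observed samples, or with a zero-variance profile
    over the overlap, are undefined (NaN) and omitted from iteration.
    """

    def __init__(
        self,
        genes: list[str],
        r: np.ndarray,
        n_overlap: np.ndarray,
        min_overlap: int,
    ):
        self.genes = list(genes)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.r = r
        self.n_overlap = n_overlap
        self.min_overlap = min_overlap

    def get(self, a: str, b: str) -> float | None:
        """Correlation of the unordered pair, or None if undefined."""
        ia, ib = self.index.get(a), self.index.get(b)
        if ia is None or ib is None:
            return None
        value = self.r[ia, ib]
        return None if math.isnan(value) else float(value)

    def get_pair(self, pair: Iterable[str]) -> float | None:
        a, b = tuple(pair)
        return self.get(a, b)

    def overlap(self, a: str, b: str) -> int:
        return int(self.n_overlap[self.index[a], self.index[b]])

    def n_defined(self) -> int:
        iu = np.triu_indices(len(self.genes), k=1)
        return int(np.isfinite(self.r[iu]).sum())

    def to_frame(self) -> pd.DataFrame:
        """4-column long form (gene_a, gene_b, r, n_overlap), defined pairs only."""
        ii, jj = np.triu_indices(len(self.genes), k=1)
        mask = np.isfinite(self.r[ii, jj])
        ii, jj = ii[mask], jj[mask]
        return pd.DataFrame(
            {
                "gene_a": [self.genes[i] for i in ii],
                "gene_b": [self.genes[j] for j in jj],
                "r": self.r[ii, jj],
                "n_overlap": self.n_overlap[ii, jj],
            }
        )


def pairwise_correlation(
    em: ExpressionMatrix,
    pairs: Iterable[tuple[str, str]] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationTable:
    """Pearson correlation on pairwise-complete samples for every gene pair.

    ``pairs`` restricts computation to the listed unordered pairs (entries
    outside the matrix are ignored); by default all pairs are computed.
    Pairs with fewer than ``min_overlap`` jointly observed samples, or with
    zero variance over the overlap, are left undefined.
    """
    if min_overlap < 3:
        raise ValueError("min_overlap must be at least 3")
    if em.data.index.has_duplicates:
        raise ValueError("correlation requires unique gene IDs (collapse first)")
    genes = em.gene_ids
    observed = em.data.notna().to_numpy()
    n_overlap = observed.astype(np.int32) @ observed.astype(np.int32).T
    if pairs is None:
        # pandas computes pairwise-complete Pearson in C and returns NaN for
        # zero-variance overlaps
        r = em.data.T.corr(min_periods=min_overlap).to_numpy()
    else:
        n = len(genes)
        r = np.full((n, n), np.nan)
        index = {g: i for i, g in enumerate(genes)}
        X = em.values
        for a, b in pairs:
            ia, ib = index.get(a), index.get(b)
            if ia is None or ib is None:
                continue
            mask = observed[ia] & observed[ib]
            if mask.sum() < min_overlap:
                continue
            x, y = X[ia, mask], X[ib, mask]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                logger.info("zero-variance overlap for pair (%s, %s)", a, b)
                continue
            value = float(np.corrcoef(x, y)[0, 1])
            r[ia, ib] = r[ib, ia] = value
        np.fill_diagonal(r, 1.0)
    np.fill_diagonal(n_overlap, observed.sum(axis=1))
    return CorrelationTable(genes, r, n_overlap, min_overlap)
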