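"""Single-sample gene-set scores and the cytolytic-activity (CYT) score.

Immune-cell abundance and the T cell-inflamed GEP are scored per sample with
a rank-weighted running-sum enrichment statistic (the ssGSEA form): genes
are ranked by expression within each sample and the score is the summed gap
between the weighted cumulative distribution of in-set genes (weights =
rank^alpha, normalized) and the uniform cumulative distribution of
out-of-set genes. Being rank-based, the scores are invariant to any strictly
monotone per-sample transform of expression. This is a deliberate,
documented stand-in for kernel-CDF GSVA: both capture relative per-sample
set enrichment, and the running sum has a desk-checkable closed form.

CYT is the geometric mean of GZMA and PRF1 expression, with a small additive
offset so that zero counts do not annihilate the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from icbsex.dataio import GeneSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_CYT_OFFSET = 0.01

CYT_GENES = ("GZMA", "PRF1")


class SignatureError(ValueError):
    pass


@dataclass
class SignatureScores:
    """Samples × signatures score matrix with the scoring parameters used."""

    values: pd.DataFrame
    alpha: float
    normalized: bool
    dropped_genes: dict[str, int]


def _normalize_gene_index(genes: Sequence[str]) -> pd.Index:
    return pd.Index([str(g).upper() for g in genes])


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Rank-weighted running-sum enrichment of one gene set, per sample.

    ``expr`` is genes × samples. Within each sample, genes get average ranks
    by expression (highest expression = rank N); walking the genes in
    descending expression order, the score accumulates the difference
    between the in-set weighted rank CDF and the uniform out-of-set CDF.
    Gene identifiers are matched exactly after uppercasing both sides;
    set genes absent from the matrix are dropped with a logged count.
    """
    if alpha < 0:
        raise SignatureError(f"alpha must be nonnegative, got {alpha}")
    if expr.shape[0] < 2:
        raise SignatureError("expression matrix needs >=2 genes")
    genes = _normalize_gene_index(expr.index)
    if genes.duplicated().any():
        raise SignatureError("duplicate gene identifiers after uppercasing")
    set_genes = set(_normalize_gene_index(gene_set.genes))
    present = [g in set_genes for g in genes]
    n_in = int(np.sum(present))
    n_dropped = len(set_genes) - n_in
    if n_in == 0:
        raise SignatureError(f"gene set {gene_set.name!r}: no genes found in the matrix")
    if n_dropped:
        logger.info("gene set %s: %d gene(s) absent from matrix", gene_set.name, n_dropped)
    in_set = np.asarray(present)
    n_genes = len(genes)
    n_out = n_genes - n_in
    if n_out == 0:
        logger.warning("gene set %s covers every gene; score defined as 0", gene_set.name)
        return pd.Series(0.0, index=expr.columns)

    values = expr.to_numpy(dtype=float)
    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        col = values[:, j]
        ranks = rankdata(col)  # average ranks, highest expression = N
        order = np.argsort(-ranks, kind="stable")  # descending expression
        in_ordered = in_set[order]
        w = np.where(in_ordered, ranks[order] ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_ordered) / n_out
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=expr.columns, name=gene_set.name)


def gep_score(
    expr: pd.DataFrame,
    gep_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """T cell-inflamed GEP score: the running-sum enrichment of the
    user-supplied GEP signature (the 18-gene IFN-γ-related list circulates
    as a GMT; it is not shipped)."""
    return ssgsea_score(expr, gep_set, alpha=alpha).rename("GEP")


def cyt_score(expr: pd.DataFrame, offset: float = DEFAULT_CYT_OFFSET) -> pd.Series:
    """Cytolytic activity: sqrt((GZMA + offset) · (PRF1 + offset)) per sample."""
    if offset < 0:
        raise SignatureError("offset must be nonnegative")
    genes = _normalize_gene_index(expr.index)
    rows = {}
    for g in CYT_GENES:
        hits = np.flatnonzero(genes == g)
        if hits.size == 0:
            raise SignatureError(f"CYT requires gene {g}, absent from the matrix")
        rows[g] = expr.iloc[hits[0]].to_numpy(dtype=float)
    vals = np.sqrt((rows["GZMA"] + offset) * (rows["PRF1"] + offset))
    return pd.Series(vals, index=expr.columns, name="CYT")


def immune_cell_scores(
    expr: pd.DataFrame,
    sets: Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> SignatureScores:
    """Score a panel of immune-cell signatures; per-set failures are
    isolated and logged, not fatal. Optional min–max normalization across
    samples (off by default; downstream tests are location-scale free)."""
    if not sets:
        raise SignatureError("no gene sets supplied")
    columns = {}
    dropped: dict[str, int] = {}
    genes = set(_normalize_gene_index(expr.index))
    for s in sets:
        try:
            columns[s.name] = ssgsea_score(expr, s, alpha=alpha)
            dropped[s.name] = len(set(_normalize_gene_index(s.genes)) - genes)
        except SignatureError as exc:
            logger.warning("gene set %s failed: %s", s.name, exc)
    if not columns:
        raise SignatureError("every gene set failed to score")
    values = pd.DataFrame(columns)
    if normalize:
        rng = values.max() - values.min()
        values = (values - values.min()) / rng.replace(0.0, 1.0)
    return SignatureScores(
        values=values, alpha=alpha, normalized=normalize, dropped_genes=dropped
    )
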