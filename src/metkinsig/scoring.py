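"""Per-gene z-normalization and whole-pathway expression scores.

The pathway/signature expression score of a sample is the arithmetic
mean of the per-gene z-scores of the member genes — computed within one
dataset at a time (no cross-cohort pooling). z-scores use the population
standard deviation (divide by n); the convention is pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet


def zscore_per_gene(values: pd.DataFrame, by: pd.Series | None = None) -> pd.DataFrame:
    """Normalize each gene row to mean 0, sd 1 (population sd).

    Parameters
    ----------
    values : pandas.DataFrame
        Genes x samples, log scale.
    by : pandas.Series, optional
        Sample -> group mapping (e.g. cell line). When given, each row is
        normalized within each group of columns separately — the per-gene,
        per-cell-line convention used for pathway coherency.

    Zero-variance rows (within a group) map to all zeros; their gene ids
    are recorded in ``result.attrs["zero_variance_genes"]``.
    """
    if values.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    if by is None:
        arr = values.to_numpy(dtype=float)
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=0, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0
        z = (arr - mean) / sd
        z[flat] = 0.0
        out = pd.DataFrame(z, index=values.index, columns=values.columns)
        out.attrs["zero_variance_genes"] = list(values.index[flat])
        return out

    by = by.loc[values.columns]
    pieces, flagged = [], set()
    for _, cols in values.T.groupby(by, sort=False):
        part = zscore_per_gene(cols.T)
        flagged.update(part.attrs["zero_variance_genes"])
        pieces.append(part)
    out = pd.concat(pieces, axis=1)[values.columns]
    out.attrs["zero_variance_genes"] = sorted(flagged)
    return out


@dataclass
class ExpressionScore:
    """Per-sample mean-z score of a gene set, with coverage bookkeeping."""

    scores: pd.Series
    coverage: float
    missing_genes: list


def set_expression_score(z_matrix: pd.DataFrame, gene_set: GeneSet) -> ExpressionScore:
    """Mean z-score over the member genes, per sample (column means).

    Genes absent from the matrix are excluded and reported via
    ``coverage = |present| / |gene_set|`` and ``missing_genes``.
    """
    members = sorted(gene_set.genes)
    present = z_matrix.index.intersection(members)
    missing = sorted(set(members) - set(present))
    if len(present) == 0:
        raise ValueError(
            f"no gene of set {gene_set.name!r} is present in the matrix "
            f"(missing: {missing[:10]}{'...' if len(missing) > 10 else ''})"
        )
    scores = z_matrix.loc[present].mean(axis=0)
    scores.name = gene_set.name
    return ExpressionScore(scores, len(present) / len(members), missing)


@dataclass
class HalfLifeComparison:
    mean_signature: float
    sd_signature: float
    mean_background: float
    sd_background: float
    p_value: float
    n_signature: int
    n_background: int
    n_dropped: int


def compare_half_lives(half_lives: pd.Series, signature: GeneSet) -> HalfLifeComparison:
    """Welch two-sample t-test of signature vs background mRNA half-lives.

    ``half_lives`` maps gene -> half-life in hours; signature genes absent
    from the table are dropped and counted in ``n_dropped``. The test asks
    whether signature transcripts turn over faster (shorter half-life)
    than the rest — two-sided.
    """
    half_lives = half_lives.dropna()
    in_sig = half_lives.index.isin(list(signature.genes))
    sig = half_lives[in_sig].to_numpy()
    bg = half_lives[~in_sig].to_numpy()
    if len(sig) < 2 or len(bg) < 2:
        raise ValueError("need at least 2 genes in each of signature and background")
    res = stats.ttest_ind(sig, bg, equal_var=False)
    return HalfLifeComparison(
        mean_signature=float(np.mean(sig)),
        sd_signature=float(np.std(sig, ddof=1)),
        mean_background=float(np.mean(bg)),
        sd_background=float(np.std(bg, ddof=1)),
        p_value=float(res.pvalue),
        n_signature=len(sig),
        n_background=len(bg),
        n_dropped=len(signature) - int(in_sig.sum()),
    )
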