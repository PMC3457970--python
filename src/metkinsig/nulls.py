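"""Randomized-signature nulls, the 95%-of-null rule, and enrichment.

Random signatures are size-matched gene sets sampled uniformly without
replacement from the measured universe. An observed statistic is called
significant when its -log10(p) exceeds the 95th percentile of the same
statistic over the randomized replicates; empirical quantiles use the
(r+1)/(n+1) convention so no replicate yields an exactly-zero p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet, NullDistribution
from .scoring import set_expression_score, zscore_per_gene
from .stratify import stratify_cohort
from .survival import logrank_test


def random_signatures(gene_universe, size: int, n: int = 100, seed: int = 0) -> list:
    """n size-matched gene sets sampled uniformly without replacement."""
    universe = sorted(set(gene_universe))
    if size > len(universe):
        raise ValueError(f"signature size {size} exceeds universe {len(universe)}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        picks = rng.choice(len(universe), size=size, replace=False)
        out.append(GeneSet(f"random_{i:03d}", {universe[j] for j in picks},
                           provenance=f"random size-{size} signature, seed {seed}"))
    return out


@dataclass
class NullCall:
    significant: bool
    empirical_quantile: float   # (r+1)/(n+1) of the observed among nulls
    threshold: float            # 95th percentile of null -log10(p)
    observed_neglog10: float


def null_significance_call(observed_p: float, null_ps, level: float = 0.95) -> NullCall:
    """The 95%-of-null rule on the -log10(p) scale.

    ``significant`` iff the observed -log10(p) exceeds the ``level``
    quantile of the null -log10(p) values; requires >= 20 null values.
    """
    null_ps = np.asarray(null_ps, dtype=float)
    null_ps = null_ps[~np.isnan(null_ps)]
    if len(null_ps) == 0:
        raise ValueError("empty null distribution")
    if len(null_ps) < 20:
        raise ValueError(f"need >= 20 null values, got {len(null_ps)}")
    obs = -np.log10(max(observed_p, np.finfo(float).tiny))
    null_scores = -np.log10(np.maximum(null_ps, np.finfo(float).tiny))
    threshold = float(np.quantile(null_scores, level))
    r = int((null_scores >= obs).sum())
    quantile = (r + 1) / (len(null_scores) + 1)
    return NullCall(bool(obs > threshold), quantile, threshold, float(obs))


@dataclass
class SignatureVsRandomResult:
    real_score: float                  # max log-rank p across cohorts (lower = better)
    null: NullDistribution | None
    rank: int | None                   # 1 = real signature beats every random one
    n_dropped: int


def _max_logrank_p(signature: GeneSet, cohorts, canonical: GeneSet) -> float:
    """Worst (max) High-vs-Low log-rank p for one signature across cohorts."""
    ps = []
    for cohort in cohorts:
        strat = stratify_cohort(cohort, signature, canonical)
        hi = strat.group("HighSig")
        lo = strat.group("LowSig")
        clin = cohort.clinical
        res = logrank_test(clin.loc[hi, "survival_time"], clin.loc[hi, "event"],
                           clin.loc[lo, "survival_time"], clin.loc[lo, "event"])
        if np.isnan(res.p_value):
            raise ValueError(f"log-rank undefined on cohort {cohort.name}")
        ps.append(res.p_value)
    return float(max(ps))


def signature_vs_random_survival(signature: GeneSet, cohorts, canonical: GeneSet,
                                 n: int = 100, seed: int = 0) -> SignatureVsRandomResult:
    """Rank the real signature's prognostic value among random signatures.

    Each signature (real and random, size-matched) stratifies every
    cohort; its score is the worst (maximum) High-vs-Low log-rank p
    across cohorts — a lower bound on performance. The real signature's
    rank is 1 + the number of random signatures scoring at least as well
    (smaller or equal max-p). Replicates whose stratification fails are
    dropped and counted.
    """
    real = _max_logrank_p(signature, cohorts, canonical)
    if n == 0:
        return SignatureVsRandomResult(real, None, None, 0)
    universe = set(cohorts[0].expression.index)
    for cohort in cohorts[1:]:
        universe &= set(cohort.expression.index)
    sigs = random_signatures(universe, len(signature), n=n, seed=seed)
    scores, dropped = [], 0
    for rs in sigs:
        try:
            scores.append(_max_logrank_p(rs, cohorts, canonical))
        except ValueError:
            dropped += 1
    null = NullDistribution("max_logrank_p", np.asarray(scores), seed, dropped)
    rank = 1 + int((null.values <= real).sum())
    return SignatureVsRandomResult(real, null, rank, dropped)


def hypergeometric_enrichment(query: GeneSet, annotation: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric annotation-term enrichment with BH.

    ``annotation`` maps term -> gene set. For each term, with N the
    universe size, K the in-universe term size, n the query size and k
    the overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n). Query genes
    outside the universe are an error.
    """
    from .kinetics import bh_fdr

    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set(query.genes) <= universe:
        raise ValueError("query genes outside the universe")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(annotation, key=str):
        term_genes = set(annotation[term]) & universe
        K = len(term_genes)
        k = len(term_genes & query.genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"]
                       ).set_index("term")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def null_differentiation_rate(score_tables, sample_groups: pd.Series,
                              alpha: float = 0.05) -> tuple:
    """Fraction of pathway-differentiation tests significant at ``alpha``.

    Convenience for null calibration: pools the t-tests of one or more
    pathway score tables (pathways x samples) against the high/low
    sample labels and returns (fraction, n_tests).
    """
    from .network import pathway_differentiation_test

    ps = []
    for table in score_tables:
        res = pathway_differentiation_test(table, sample_groups)
        ps.extend(res["p_value"].dropna().tolist())
    ps = np.asarray(ps)
    if len(ps) == 0:
        raise ValueError("no defined pathway tests")
    return float((ps < alpha).mean()), len(ps)
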