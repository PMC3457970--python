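"""Two-group hierarchical stratification and phenotype association.

Samples (or patients) are clustered on a gene set with the standard
expression-clustering choice — distance 1 - Pearson correlation between
sample profiles, average linkage — and the dendrogram is cut into two
clusters. The cluster with the higher mean canonical-pathway score is
labelled ``HighSig``. The same clustering contract backs the cell-line
separation test used during signature derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import GeneSet, PatientCohort, StratifiedCohort
from .scoring import set_expression_score, zscore_per_gene


@dataclass
class Bipartition:
    """Assignment of samples to clusters 1/2, with clustering diagnostics."""

    assignment: pd.Series           # sample id -> 1 | 2
    linkage_heights: np.ndarray
    flags: list = field(default_factory=list)

    def cluster(self, k: int) -> pd.Index:
        return self.assignment.index[self.assignment == k]


def _pearson_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows, clipped to [0, 2]."""
    corr = np.corrcoef(profiles)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def hcluster_two_groups(z_matrix: pd.DataFrame, gene_set: GeneSet,
                        method: str = "average") -> Bipartition:
    """Cluster samples on a gene set and cut into exactly two groups.

    Samples are sorted lexicographically before linkage so the result is
    invariant to input column (and gene) order. A sample with zero
    variance across the gene set has no defined correlation; it is left
    out of the linkage and assigned to the nearer cluster centroid
    (Euclidean), with a flag.
    """
    members = z_matrix.index.intersection(sorted(gene_set.genes))
    if len(members) == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    sub = z_matrix.loc[members, sorted(z_matrix.columns)]
    if sub.shape[1] < 4:
        raise ValueError("need at least 4 samples to stratify")

    profiles = sub.T.to_numpy(dtype=float)
    sample_ids = list(sub.columns)
    degenerate = profiles.std(axis=1) == 0
    flags = []
    usable = ~degenerate
    if degenerate.any():
        flags.append(f"zero-variance samples assigned by nearest centroid: "
                     f"{[s for s, d in zip(sample_ids, degenerate) if d]}")
    if usable.sum() < 4:
        raise ValueError("fewer than 4 samples with variance across the gene set")

    zlink = linkage(_pearson_distance(profiles[usable]), method=method)
    labels = fcluster(zlink, t=2, criterion="maxclust")
    if len(set(labels)) < 2:  # pathological flat dendrogram; split at the root
        labels = fcluster(zlink, t=zlink[-1, 2] - 1e-12, criterion="distance")
        labels = np.where(labels == labels[0], 1, 2)
        flags.append("flat dendrogram; split at root height")

    assignment = pd.Series(0, index=pd.Index(sample_ids, name="sample_id"), dtype=int)
    assignment.iloc[np.flatnonzero(usable)] = labels
    if degenerate.any():
        cents = np.stack([profiles[usable][labels == k].mean(axis=0) for k in (1, 2)])
        for i in np.flatnonzero(degenerate):
            d = np.linalg.norm(cents - profiles[i], axis=1)
            assignment.iloc[i] = int(np.argmin(d)) + 1

    # canonical cluster numbering: cluster containing the lexicographically
    # first sample is cluster 1 — stable under any input permutation
    if assignment.iloc[0] == 2:
        assignment = assignment.map({1: 2, 2: 1})
    return Bipartition(assignment, zlink[:, 2], flags)


def label_by_canonical(bipartition: Bipartition, canonical_scores: pd.Series) -> StratifiedCohort:
    """Label the cluster with the higher mean canonical score ``HighSig``.

    An exact tie is broken deterministically in favour of cluster 1, with
    a loud flag.
    """
    means = {k: float(canonical_scores.loc[bipartition.cluster(k)].mean()) for k in (1, 2)}
    tie = means[1] == means[2]
    high = 1 if (means[1] >= means[2]) else 2
    labels = bipartition.assignment.map(
        {high: "HighSig", (3 - high): "LowSig"}).rename("label")
    flags = list(bipartition.flags)
    if tie:
        flags.append("canonical score means exactly tied; cluster 1 labelled HighSig")
    return StratifiedCohort(
        labels=labels,
        canonical_means={"HighSig": means[high], "LowSig": means[3 - high]},
        linkage_heights=bipartition.linkage_heights,
        tie_broken=tie,
        flags=flags,
    )


def stratify_cohort(cohort: PatientCohort, signature: GeneSet,
                    canonical: GeneSet) -> StratifiedCohort:
    """Cluster patients on the signature, label High/Low by canonical score."""
    z = zscore_per_gene(cohort.expression)
    bipart = hcluster_two_groups(z, signature)
    canon = set_expression_score(z, canonical)
    return label_by_canonical(bipart, canon.scores)


def associate_phenotypes(strat: StratifiedCohort, cohort: PatientCohort,
                         discrete: list | None = None,
                         continuous: list | None = None) -> pd.DataFrame:
    """Association of the High/Low labels with clinical phenotypes.

    Discrete phenotypes: chi-square test of the label x category table,
    without continuity correction; a 2x2 table with any expected count
    below 5 falls back to Fisher's exact test (flagged). Continuous
    phenotypes: two-sided Welch t-test between the label groups.
    """
    discrete = discrete or []
    continuous = continuous or []
    labels = strat.labels.loc[cohort.patients.intersection(strat.labels.index)]
    rows = []
    for name in discrete:
        col = cohort.clinical.loc[labels.index, name]
        if col.nunique() < 2:
            rows.append((name, "NA", np.nan, np.nan, "constant phenotype"))
            continue
        table = pd.crosstab(labels, col)
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        note = ""
        if (expected < 5).any():
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table.to_numpy())
                chi2 = np.nan
                rows.append((name, "fisher_exact", chi2, p, "expected count < 5"))
                continue
            note = "expected count < 5 (no exact fallback for r x c)"
        rows.append((name, "chi_square", chi2, p, note))
    for name in continuous:
        col = cohort.clinical.loc[labels.index, name].astype(float)
        a = col[labels == "HighSig"].dropna()
        b = col[labels == "LowSig"].dropna()
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            rows.append((name, "NA", np.nan, np.nan, "constant phenotype"))
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append((name, "welch_t", float(res.statistic), float(res.pvalue), ""))
    return pd.DataFrame(rows, columns=["phenotype", "test", "statistic", "p_value", "note"])
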