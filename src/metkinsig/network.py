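"""Anchored pathway inference on a confidence-weighted PPI graph.

The receptor (anchor) is connected to each signature gene (terminal) by
the most confident path: edge weight is -ln(confidence), so a path's
weight is -ln of the product of its edge confidences, and the
minimum-weight path is the maximum-confidence chain. The union of these
paths is the anchored subnetwork. This is a documented shortest-path
stand-in for interactive anchored-network tools whose inference
internals (Steiner-style objectives, curated databases) are not public.

Determinism: ties in path weight are broken by fewer hops, then by
lexicographic node sequence, via an explicit Dijkstra whose priority is
the tuple (weight, hops, path).

Downstream pathway statistics: two-group differentiation and
good-vs-bad prognosis Welch t-tests on the whole-pathway expression
score; coherency (mean Pearson correlation of consecutive gene pairs on
per-gene, per-cell-line z-normalized cell-model data); prognosis
ranking (log10 of the worst p across cohorts); and their Spearman
correlation.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet, KineticExpressionMatrix, PPINetwork
from .scoring import set_expression_score, zscore_per_gene


@dataclass
class AnchoredPathway:
    """An ordered anchor -> terminal protein chain and its statistics."""

    nodes: tuple
    weight: float                       # sum of -ln(confidence) over edges
    coherency: float = np.nan
    coherency_pairs_used: int = 0
    diff_p: float = np.nan
    diff_direction: str = ""
    prognosis_p: dict = field(default_factory=dict)   # cohort -> p
    prognosis_rank: float = np.nan

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        if len(self.nodes) < 2:
            raise ValueError("a pathway needs at least anchor and terminal")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("pathway nodes must be distinct")
        if self.weight < 0:
            raise ValueError("pathway weight must be non-negative")

    @property
    def anchor(self):
        return self.nodes[0]

    @property
    def terminal(self):
        return self.nodes[-1]

    @property
    def pathway_id(self) -> str:
        return "-".join(str(n) for n in self.nodes)

    def gene_set(self) -> GeneSet:
        return GeneSet(self.pathway_id, set(self.nodes), "anchored pathway")


def _edge_weight(confidence: float) -> float:
    return -float(np.log(confidence))


def shortest_confidence_path(ppi: PPINetwork, anchor, terminal):
    """Minimum -ln(confidence) path anchor -> terminal, deterministic.

    Respects directionality overrides and removed nodes. Ties are broken
    by fewer hops, then lexicographically on the node sequence. Returns
    (path, weight) or None when the terminal is unreachable.
    """
    g = ppi.working_graph()
    if anchor not in g:
        raise ValueError(f"anchor {anchor!r} not in graph")
    if terminal not in g:
        return None
    # priority = (weight, hops, path-as-strings): heap order is total,
    # so the popped settlement for each node is its canonical best
    start = (0.0, 0, (str(anchor),), (anchor,))
    heap = [start]
    settled = set()
    while heap:
        w, hops, _, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == terminal:
            return list(path), w
        for nbr in g.neighbors(node):
            if nbr in settled or nbr in path:
                continue
            if not ppi.allows(node, nbr):
                continue
            ew = _edge_weight(g[node][nbr]["confidence"])
            new_path = path + (nbr,)
            heapq.heappush(heap, (w + ew, hops + 1,
                                  tuple(str(n) for n in new_path), new_path))
    return None


def build_anchored_network(ppi: PPINetwork, anchor, terminals):
    """Infer the anchored subnetwork: one best path per reachable terminal.

    Returns ``(pathways, subnetwork, left_out)`` where ``pathways`` is a
    list of :class:`AnchoredPathway` (sorted by terminal), ``subnetwork``
    the union graph of their edges, and ``left_out`` the terminals that
    are missing from the graph or unreachable (reported, not fatal).
    """
    g = ppi.working_graph()
    if anchor not in g:
        raise ValueError(f"anchor {anchor!r} not in the network")
    pathways, left_out = [], []
    for term in sorted(set(terminals), key=str):
        if term == anchor:
            left_out.append(term)
            continue
        hit = shortest_confidence_path(ppi, anchor, term)
        if hit is None:
            left_out.append(term)
            continue
        path, w = hit
        pathways.append(AnchoredPathway(tuple(path), w))
    sub = nx.Graph()
    for pw in pathways:
        for u, v in zip(pw.nodes[:-1], pw.nodes[1:]):
            sub.add_edge(u, v, confidence=g[u][v]["confidence"])
    return pathways, sub, left_out


def prune_contained(pathways) -> list:
    """Drop any pathway whose node chain contiguously contains another's.

    When one pathway's sequence occurs as a contiguous run inside a
    longer one's (in either orientation), the longer pathway is removed.
    Applied pairwise to exhaustion, so nested chains leave only the
    shortest.
    """
    def contains(long: tuple, short: tuple) -> bool:
        n, m = len(long), len(short)
        if m > n:
            return False
        for orient in (short, short[::-1]):
            for i in range(n - m + 1):
                if long[i:i + m] == orient:
                    return True
        return False

    keep = list(pathways)
    drop = set()
    for a, b in itertools.combinations(range(len(keep)), 2):
        pa, pb = keep[a], keep[b]
        if len(pa.nodes) == len(pb.nodes):
            continue
        long_i, short_i = (a, b) if len(pa.nodes) > len(pb.nodes) else (b, a)
        if contains(keep[long_i].nodes, keep[short_i].nodes):
            drop.add(long_i)
    return [p for i, p in enumerate(keep) if i not in drop]


def pathway_differentiation_test(score_table: pd.DataFrame,
                                 sample_groups: pd.Series) -> pd.DataFrame:
    """Welch t-test of each pathway's score between high and low samples.

    ``score_table`` is pathways x samples; ``sample_groups`` maps sample
    to "high"/"low". Returns per-pathway ``p_value`` and ``direction``
    ("higher_in_high"/"higher_in_low"); a group with fewer than two
    samples yields NaN.
    """
    groups = sample_groups.loc[score_table.columns]
    hi = score_table.loc[:, groups == "high"]
    lo = score_table.loc[:, groups == "low"]
    if hi.shape[1] == 0 or lo.shape[1] == 0:
        raise ValueError("both sample groups must be present")
    rows = []
    for pid in score_table.index:
        a, b = hi.loc[pid].to_numpy(), lo.loc[pid].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((pid, np.nan, ""))
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        direction = "higher_in_high" if a.mean() >= b.mean() else "higher_in_low"
        rows.append((pid, float(res.pvalue), direction))
    return pd.DataFrame(rows, columns=["pathway_id", "p_value", "direction"]
                        ).set_index("pathway_id")


def pathway_prognosis_test(score_tables: dict, prognosis_labels: dict) -> pd.DataFrame:
    """Good-vs-bad Welch t-test of pathway scores, per cohort.

    ``score_tables`` maps cohort name -> (pathways x patients) scores and
    ``prognosis_labels`` maps cohort name -> good/bad/excluded labels.
    Excluded patients are dropped; a cohort lacking either class yields
    NaN for every pathway. Result: pathways x cohorts p-value table.
    """
    cols = {}
    for cohort, table in score_tables.items():
        prog = prognosis_labels[cohort].loc[table.columns]
        good = table.loc[:, (prog == "good").to_numpy()]
        bad = table.loc[:, (prog == "bad").to_numpy()]
        if good.shape[1] < 2 or bad.shape[1] < 2:
            cols[cohort] = pd.Series(np.nan, index=table.index)
            continue
        res = stats.ttest_ind(good.to_numpy(), bad.to_numpy(), axis=1, equal_var=False)
        cols[cohort] = pd.Series(res.pvalue, index=table.index)
    return pd.DataFrame(cols)


def coherency_ranking(pathway: AnchoredPathway, cell_z: pd.DataFrame):
    """Mean Pearson correlation of consecutive gene pairs along the chain.

    ``cell_z`` must already be z-normalized per gene, per cell line.
    Pairs with a member lacking an expression row are skipped and
    counted; with no usable pair the coherency is NaN.
    """
    corrs = []
    skipped = 0
    for u, v in zip(pathway.nodes[:-1], pathway.nodes[1:]):
        if u not in cell_z.index or v not in cell_z.index:
            skipped += 1
            continue
        a, b = cell_z.loc[u].to_numpy(), cell_z.loc[v].to_numpy()
        if a.std() == 0 or b.std() == 0:
            skipped += 1
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        return np.nan, 0, skipped
    return float(np.mean(corrs)), len(corrs), skipped


def prognosis_ranking(p_values) -> float:
    """log10 of the worst (largest) good-vs-bad p across cohorts.

    NaN cohorts are dropped; all-NaN yields NaN. More negative means the
    pathway separates prognosis groups in every cohort.
    """
    p = np.asarray(pd.Series(p_values).dropna(), dtype=float)
    if len(p) == 0:
        return np.nan
    return float(np.log10(p.max()))


def coherency_prognosis_correlation(coherency, prognosis_rank):
    """Spearman rank correlation between coherency and prognosis ranking."""
    df = pd.DataFrame({"c": coherency, "r": prognosis_rank}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 pathways with both statistics")
    if df["c"].nunique() == 1 or df["r"].nunique() == 1:
        return np.nan, np.nan
    rho, p = stats.spearmanr(df["c"], df["r"])
    return float(rho), float(p)


@dataclass
class EdgeCorrelationResult:
    wmw_p_greater: float
    wmw_p_two_sided: float
    t_p_two_sided: float
    subnetwork_correlations: np.ndarray
    background_correlations: np.ndarray


def edge_correlation_test(subnetwork: nx.Graph, cell_z: pd.DataFrame,
                          background: PPINetwork) -> EdgeCorrelationResult:
    """Are subnetwork-adjacent gene pairs more co-expressed than background?

    Compares the distribution of Pearson correlations over the inferred
    subnetwork's edges with that over all expression-covered interacting
    pairs of the background PPI. Primary statistic: one-sided (greater)
    Wilcoxon-Mann-Whitney; a two-sided WMW and a two-sided Welch t-test
    are reported alongside.
    """
    def edge_corrs(edges) -> np.ndarray:
        vals = []
        for u, v in edges:
            if u in cell_z.index and v in cell_z.index:
                a, b = cell_z.loc[u].to_numpy(), cell_z.loc[v].to_numpy()
                if a.std() > 0 and b.std() > 0:
                    vals.append(np.corrcoef(a, b)[0, 1])
        return np.asarray(vals, dtype=float)

    sub = edge_corrs(subnetwork.edges())
    bg = edge_corrs(background.graph.edges())
    if len(sub) < 2 or len(bg) < 10:
        raise ValueError("insufficient expression-covered pairs "
                         f"(subnetwork {len(sub)}, background {len(bg)})")
    wmw_g = stats.mannwhitneyu(sub, bg, alternative="greater")
    wmw_2 = stats.mannwhitneyu(sub, bg, alternative="two-sided")
    t_2 = stats.ttest_ind(sub, bg, equal_var=False)
    return EdgeCorrelationResult(float(wmw_g.pvalue), float(wmw_2.pvalue),
                                 float(t_2.pvalue), sub, bg)


class AnchoredNetworkModel:
    """Anchored-pathway inference and evaluation, statsmodels-style.

    Parameters
    ----------
    ppi : PPINetwork
        Confidence-weighted interaction graph (with any manual
        directionality overrides / node removals already configured).
    anchor : node id
        The receptor.
    terminals : iterable of node ids
        The signature genes.
    prune : bool
        Apply the containment rule after inference (default True).
    """

    def __init__(self, ppi: PPINetwork, anchor, terminals, prune: bool = True):
        self.ppi = ppi
        self.anchor = anchor
        self.terminals = sorted(set(terminals), key=str)
        self.prune = prune

    def fit(self) -> "AnchoredNetworkResults":
        pathways, sub, left_out = build_anchored_network(
            self.ppi, self.anchor, self.terminals)
        if self.prune:
            pathways = prune_contained(pathways)
        return AnchoredNetworkResults(self, pathways, sub, left_out)


class AnchoredNetworkResults:
    """Inferred pathways plus lazily attached evaluation statistics."""

    def __init__(self, model, pathways, subnetwork, left_out):
        self.model = model
        self.pathways = pathways
        self.subnetwork = subnetwork
        self.left_out = left_out

    def score_pathways(self, z_matrix: pd.DataFrame) -> pd.DataFrame:
        """Whole-pathway expression score per sample (pathways x samples)."""
        rows = {}
        for pw in self.pathways:
            try:
                rows[pw.pathway_id] = set_expression_score(z_matrix, pw.gene_set()).scores
            except ValueError:
                rows[pw.pathway_id] = pd.Series(np.nan, index=z_matrix.columns)
        return pd.DataFrame(rows).T

    def attach_differentiation(self, matrix: KineticExpressionMatrix) -> pd.DataFrame:
        z = zscore_per_gene(matrix.values)
        table = self.score_pathways(z)
        res = pathway_differentiation_test(table, matrix.sample_meta["met_group"])
        for pw in self.pathways:
            pw.diff_p = float(res.loc[pw.pathway_id, "p_value"])
            pw.diff_direction = str(res.loc[pw.pathway_id, "direction"])
        return res

    def attach_coherency(self, matrix: KineticExpressionMatrix) -> pd.Series:
        cell_z = zscore_per_gene(matrix.values, by=matrix.sample_meta["cell_line"])
        out = {}
        for pw in self.pathways:
            coh, used, _ = coherency_ranking(pw, cell_z)
            pw.coherency = coh
            pw.coherency_pairs_used = used
            out[pw.pathway_id] = coh
        return pd.Series(out, name="coherency")

    def attach_prognosis(self, cohorts: list) -> pd.DataFrame:
        from .survival import label_prognosis
        tables, labels = {}, {}
        for cohort in cohorts:
            z = zscore_per_gene(cohort.expression)
            tables[cohort.name] = self.score_pathways(z)
            labels[cohort.name] = label_prognosis(cohort)
        per_cohort = pathway_prognosis_test(tables, labels)
        for pw in self.pathways:
            row = per_cohort.loc[pw.pathway_id]
            pw.prognosis_p = row.to_dict()
            pw.prognosis_rank = prognosis_ranking(row)
        return per_cohort

    def pathway_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [p.pathway_id for p in self.pathways],
                "terminal": [p.terminal for p in self.pathways],
                "n_nodes": [len(p.nodes) for p in self.pathways],
                "weight": [p.weight for p in self.pathways],
                "diff_p": [p.diff_p for p in self.pathways],
                "coherency": [p.coherency for p in self.pathways],
                "prognosis_rank": [p.prognosis_rank for p in self.pathways],
            }
        ).set_index("pathway_id")

    def coherency_prognosis_correlation(self):
        return coherency_prognosis_correlation(
            [p.coherency for p in self.pathways],
            [p.prognosis_rank for p in self.pathways],
        )

    def summary(self) -> str:
        t = self.pathway_table()
        lines = [
            "Anchored network inference",
            "=" * 60,
            f"anchor:              {self.model.anchor}",
            f"terminals requested: {len(self.model.terminals)}",
            f"pathways inferred:   {len(self.pathways)}"
            + (" (containment-pruned)" if self.model.prune else ""),
            f"terminals left out:  {len(self.left_out)}",
            f"subnetwork size:     {self.subnetwork.number_of_nodes()} nodes / "
            f"{self.subnetwork.number_of_edges()} edges",
        ]
        if t["diff_p"].notna().any():
            n_sig = int((t["diff_p"] < 0.05).sum())
            lines.append(f"differentiating pathways (p<0.05): {n_sig}/"
                         f"{int(t['diff_p'].notna().sum())}")
        if t["coherency"].notna().any() and t["prognosis_rank"].notna().any():
            rho, p = self.coherency_prognosis_correlation()
            lines.append(f"coherency vs prognosis ranking: Spearman rho = {rho:.3f}"
                         f" (p = {p:.3g})")
        return "\n".join(lines)
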