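"""Core containers shared across the pipeline.

The pipeline's objects are thin, validated wrappers around pandas
structures: a time-course expression matrix with sample metadata
(:class:`KineticExpressionMatrix`), a named gene set (:class:`GeneSet`),
a confidence-weighted protein-interaction network (:class:`PPINetwork`),
a patient cohort (:class:`PatientCohort`), and small result records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

REQUIRED_SAMPLE_META = ("cell_line", "met_group", "time_min", "replicate")
MET_GROUPS = ("high", "low")


@dataclass
class KineticExpressionMatrix:
    """Log-expression of a treated cell-line panel over a time course.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes (rows) by samples (columns), log scale.
    sample_meta : pandas.DataFrame
        Indexed by sample id, with columns ``cell_line``, ``met_group``
        (``"high"`` or ``"low"`` receptor activity), ``time_min`` (minutes
        since ligand stimulation; 0 is the untreated baseline) and
        ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        missing_cols = set(REQUIRED_SAMPLE_META) - set(self.sample_meta.columns)
        if missing_cols:
            raise ValueError(f"sample_meta missing columns: {sorted(missing_cols)}")
        if set(self.values.columns) != set(self.sample_meta.index):
            raise ValueError("sample ids of values and sample_meta differ")
        if self.sample_meta[list(REQUIRED_SAMPLE_META)].isna().any().any():
            raise ValueError("incomplete sample metadata")
        bad = set(self.sample_meta["met_group"]) - set(MET_GROUPS)
        if bad:
            raise ValueError(f"met_group values must be in {MET_GROUPS}, got {sorted(bad)}")
        # every cell line needs a time-0 baseline for response testing
        has_t0 = self.sample_meta.groupby("cell_line")["time_min"].apply(lambda t: (t == 0).any())
        if not has_t0.all():
            missing = list(has_t0.index[~has_t0])
            raise ValueError(f"cell lines without a time-0 baseline sample: {missing}")
        # keep metadata aligned with the column order
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def time_points(self) -> list[int]:
        return sorted(self.sample_meta["time_min"].unique())

    @property
    def post_baseline_times(self) -> list[int]:
        return [t for t in self.time_points if t != 0]

    def restrict_genes(self, genes) -> "KineticExpressionMatrix":
        keep = self.values.index.intersection(list(genes))
        return KineticExpressionMatrix(self.values.loc[keep], self.sample_meta.copy())


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids with free-text provenance (e.g. ``"down@10min"``)."""

    name: str
    genes: frozenset
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))

    def jaccard(self, other: "GeneSet") -> float:
        union = self.genes | other.genes
        if not union:
            return float("nan")
        return len(self.genes & other.genes) / len(union)


@dataclass
class PPINetwork:
    """Undirected PPI graph with per-edge confidence in (0, 1].

    ``directed_overrides`` lists ordered pairs that may only be traversed
    in the stated direction (manual curation, e.g. ligand->receptor);
    ``removed_nodes`` are excluded before any inference.
    """

    graph: nx.Graph
    directed_overrides: set = field(default_factory=set)
    removed_nodes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.directed_overrides = {tuple(p) for p in self.directed_overrides}
        self.removed_nodes = set(self.removed_nodes)
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            c = data.get("confidence")
            if c is None or not (0.0 < c <= 1.0):
                raise ValueError(f"edge ({u},{v}) confidence {c!r} not in (0,1]")
        for u, v in self.directed_overrides:
            if not self.graph.has_edge(u, v):
                raise ValueError(f"directed override ({u},{v}) is not an edge")

    @property
    def nodes(self):
        return self.graph.nodes

    def working_graph(self) -> nx.Graph:
        """Graph with removed_nodes excluded (a copy)."""
        if not self.removed_nodes:
            return self.graph
        keep = [n for n in self.graph.nodes if n not in self.removed_nodes]
        return self.graph.subgraph(keep)

    def allows(self, u, v) -> bool:
        """Whether traversal u -> v respects the directionality overrides."""
        if (v, u) in self.directed_overrides and (u, v) not in self.directed_overrides:
            return False
        return True


@dataclass
class PatientCohort:
    """Expression plus clinical follow-up for one patient cohort.

    ``clinical`` is indexed by patient id and carries ``survival_time``
    (months), ``event`` (1 = death from disease / metastasis per the
    configured endpoint), ``followup_time`` (months) and any number of
    phenotype columns.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        if set(self.expression.columns) != set(self.clinical.index):
            raise ValueError("expression and clinical patient ids differ")
        for col in ("survival_time", "event", "followup_time"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if (self.clinical["survival_time"] < 0).any() or (self.clinical["followup_time"] < 0).any():
            raise ValueError("negative survival/follow-up times")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.clinical = self.clinical.loc[self.expression.columns]

    @property
    def patients(self) -> pd.Index:
        return self.expression.columns


@dataclass
class StratifiedCohort:
    """Two-group stratification of samples/patients with High/Low labels."""

    labels: pd.Series          # sample id -> "HighSig" | "LowSig"
    canonical_means: dict      # label -> mean canonical score
    linkage_heights: np.ndarray
    tie_broken: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        groups = set(self.labels.unique())
        if groups != {"HighSig", "LowSig"}:
            raise ValueError(f"expected exactly the labels HighSig/LowSig, got {sorted(groups)}")

    def group(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


@dataclass
class NullDistribution:
    """Statistic values from randomized replicates (NA-free; failures counted)."""

    statistic: str
    values: np.ndarray
    seed: int
    n_failures: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("null distribution values must be NA-free")

    @property
    def n_replicates(self) -> int:
        return len(self.values)
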