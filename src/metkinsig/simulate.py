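"""Synthetic-data generators for every pipeline input.

The generators emit data with exactly the statistical structure the
downstream analysis assumes, plus ground-truth sidecar tables, so that
signature derivation, network inference, stratification and survival
analysis are all testable without external data:

* a cell-line time-course matrix with planted kinetic response groups
  and a planted baseline shift between high- and low-activity lines;
* a confidence-weighted PPI graph with planted high-confidence
  anchor-to-terminal paths over an Erdos-Renyi decoy background;
* patient cohorts whose survival follows a proportional-hazards law
  driven by the planted signature's expression score;
* an mRNA half-life table with a shifted mean for signature genes.

All randomness flows through a single integer seed; identical
(config, seed) reproduces every output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSet, KineticExpressionMatrix, PatientCohort, PPINetwork

DEFAULT_TIME_POINTS = (0, 10, 30, 1440)


def _default_group_sizes() -> dict:
    # one planted group per (direction, post-baseline time); the
    # down-at-10-minutes group is the designated signature (131 genes,
    # the size of the derived receptor kinetic signature)
    return {
        ("down", 10): 131,
        ("up", 10): 25,
        ("down", 30): 25,
        ("up", 30): 25,
        ("down", 1440): 25,
        ("up", 1440): 25,
    }


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Effects are on the log-expression scale; times in minutes; survival
    in months; half-lives in hours.
    """

    n_genes: int = 2000
    n_cell_lines_per_group: int = 3
    time_points_min: tuple = DEFAULT_TIME_POINTS
    n_replicates: int = 2
    planted_group_sizes: dict = field(default_factory=_default_group_sizes)
    signature_group: tuple = ("down", 10)
    response_effect: float = 1.0
    baseline_group_effect: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    n_patients: int = 300
    hazard_coefficient: float = 1.0
    baseline_median_survival: float = 60.0
    followup_window: float = 120.0
    censor_rate: float = 0.2
    ppi_n_nodes: int = 400
    ppi_n_edges: int = 1600
    confidence_range: tuple = (0.2, 0.99)
    half_life_mean_signature: float = 6.99
    half_life_mean_background: float = 8.9
    half_life_sd_signature: float = 3.3
    half_life_sd_background: float = 6.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines_per_group", "n_replicates",
                     "n_patients", "ppi_n_nodes", "ppi_n_edges"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.time_points_min = tuple(sorted(set(int(t) for t in self.time_points_min)))
        if 0 not in self.time_points_min:
            raise ValueError("time_points_min must include the baseline 0")

        def parse_key(key):
            # accept ("down", 10), ["down", 10] or the YAML-friendly "down@10"
            if isinstance(key, str):
                d, _, t = key.partition("@")
            else:
                d, t = key
            return (str(d), int(t))

        self.planted_group_sizes = {parse_key(k): int(v)
                                    for k, v in self.planted_group_sizes.items()}
        self.signature_group = parse_key(self.signature_group)
        lo, hi = self.confidence_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("confidence_range must be within (0, 1]")
        post = [t for t in self.time_points_min if t != 0]
        allowed = {(d, t) for d in ("up", "down") for t in post}
        extra = set(self.planted_group_sizes) - allowed
        if extra:
            raise ValueError(f"planted groups outside direction x time grid: {sorted(extra)}")
        if sum(self.planted_group_sizes.values()) > self.n_genes:
            raise ValueError("planted group sizes exceed n_genes")
        if self.signature_group not in allowed:
            raise ValueError(f"signature_group {self.signature_group} not on the time grid")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")
        if self.half_life_mean_signature <= 0 or self.half_life_mean_background <= 0:
            raise ValueError("half-life means must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def gene_ids(n: int) -> list:
    return [f"G{i:05d}" for i in range(n)]


def _assign_groups(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene -> planted-group assignment (first genes, in key order)."""
    genes = gene_ids(config.n_genes)
    group = pd.Series("none", index=pd.Index(genes, name="gene"), dtype=object)
    start = 0
    for (direction, t), size in sorted(config.planted_group_sizes.items()):
        group.iloc[start:start + size] = f"{direction}@{t}"
        start += size
    sig_key = "{}@{}".format(*config.signature_group)
    truth = pd.DataFrame({"group": group, "is_signature": group == sig_key})
    return truth


def simulate_cell_model(config: SimulationConfig):
    """Simulate the treated cell-line panel.

    Returns ``(matrix, truth)`` where ``matrix`` is a
    :class:`KineticExpressionMatrix` over ``2 * n_cell_lines_per_group``
    cell lines (labelled high/low receptor activity) and ``truth`` is the
    ground-truth gene table (columns ``group``, ``is_signature``).

    Each planted ``(direction, time)`` gene shifts by ``+-response_effect``
    from its onset time onward in every cell line; the designated
    signature group additionally carries a high-vs-low baseline contrast
    of magnitude ``baseline_group_effect`` whose sign varies across the
    signature genes (two-thirds higher in high-activity lines, one-third
    lower), so the groups differ in profile *shape* — a purely constant
    offset would be invisible to correlation-based clustering — while
    the signature's mean-z score keeps a net positive high-vs-low
    contrast. Residuals are
    iid Gaussian with sd ``noise_sd`` — no per-cell-line random effect,
    so group comparisons across samples stay exactly calibrated under
    the null.
    """
    rng = np.random.default_rng(config.seed)
    truth = _assign_groups(config)
    genes = truth.index

    cell_lines, groups = [], {}
    for grp in ("high", "low"):
        for i in range(config.n_cell_lines_per_group):
            cl = f"{grp}{i + 1}"
            cell_lines.append(cl)
            groups[cl] = grp

    sample_rows = []
    for cl in cell_lines:
        for t in config.time_points_min:
            for r in range(1, config.n_replicates + 1):
                sample_rows.append((f"{cl}_t{t}_r{r}", cl, groups[cl], t, r))
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "cell_line", "met_group", "time_min", "replicate"]
    ).set_index("sample_id")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.tile(baseline[:, None], (1, len(meta)))

    sign = {"up": 1.0, "down": -1.0}
    onset = np.full(config.n_genes, np.inf)
    direction = np.zeros(config.n_genes)
    for i, grp in enumerate(truth["group"]):
        if grp == "none":
            continue
        d, t = grp.split("@")
        onset[i] = float(t)
        direction[i] = sign[d]
    responding = (meta["time_min"].to_numpy()[None, :] >= onset[:, None])
    values = values + responding * (direction[:, None] * config.response_effect)

    is_sig = truth["is_signature"].to_numpy()
    # mixed per-gene contrast sign (2/3 up, 1/3 down): profiles differ in
    # shape between the groups and the set's mean score keeps a net shift
    gene_sign = np.where(np.arange(config.n_genes) % 3 != 2, 1.0, -1.0)
    grp_sign = np.where(meta["met_group"].to_numpy() == "high", 0.5, -0.5)
    values = values + np.outer(is_sig * gene_sign, grp_sign) * config.baseline_group_effect

    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    matrix = KineticExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=meta.index), meta
    )
    return matrix, truth


def simulate_ppi(config: SimulationConfig, anchor, terminals):
    """Simulate a confidence-weighted PPI graph with planted anchor paths.

    An Erdos-Renyi decoy background over ``ppi_n_nodes`` nodes (drawn
    from the gene universe, plus the anchor) is augmented, per terminal,
    with one planted anchor->terminal path of length 2-5 whose edges get
    confidences in the top decile of ``confidence_range``; decoy edges
    get confidences in the bottom 40%. With the default range that makes
    a single decoy edge heavier (-ln confidence) than any five-edge
    planted path, so each planted path is the unique optimum. Planted
    intermediates are sampled without replacement across paths while the
    pool lasts (reused afterwards), so planted skeletons do not offer
    shortcuts between each other. Disconnected components are tied to
    the giant component by decoy edges.

    Returns ``(ppi, planted)`` with ``planted`` a dict terminal -> node path.
    """
    terminals = list(terminals)
    universe = gene_ids(config.n_genes)
    if not set(terminals) <= set(universe) | {anchor}:
        raise ValueError("terminals must lie in the simulated gene universe")
    if config.ppi_n_edges < config.ppi_n_nodes - 1:
        raise ValueError("ppi_n_edges too small for a connected graph")

    rng = np.random.default_rng(config.seed + 1)
    nodes = [anchor] + [t for t in terminals if t != anchor]
    pool = [g for g in universe if g not in set(nodes)]
    n_extra = config.ppi_n_nodes - len(nodes)
    if n_extra < 0:
        raise ValueError("ppi_n_nodes smaller than anchor + terminals")
    if n_extra > len(pool):
        raise ValueError("gene universe too small for ppi_n_nodes")
    extra = [pool[i] for i in rng.choice(len(pool), size=n_extra, replace=False)]
    nodes = nodes + sorted(extra)
    intermediates = [n for n in nodes if n != anchor and n not in set(terminals)]
    if not intermediates:
        raise ValueError("no intermediate nodes available for planted paths")

    lo, hi = config.confidence_range
    span = hi - lo

    def decoy_conf() -> float:
        return float(rng.uniform(lo, lo + 0.4 * span)) if span > 0 else lo

    def planted_conf() -> float:
        return float(rng.uniform(lo + 0.9 * span, hi)) if span > 0 else hi

    g = nx.Graph()
    g.add_nodes_from(nodes)

    pool: list = []  # shuffled intermediate pool; refilled only when exhausted

    def take_intermediates(k: int) -> list:
        nonlocal pool
        out: list = []
        while len(out) < k:
            if not pool:
                pool = list(rng.permutation(intermediates))
            cand = pool.pop()
            if cand not in out:  # distinct within one path even after a refill
                out.append(cand)
        return out

    planted: dict = {}
    for term in terminals:
        n_inter = int(rng.integers(1, 5))  # path length 2..5 edges
        path = [anchor] + take_intermediates(min(n_inter, len(intermediates))) + [term]
        for u, v in zip(path[:-1], path[1:]):
            c = planted_conf()
            if not g.has_edge(u, v) or g[u][v]["confidence"] < c:
                g.add_edge(u, v, confidence=c)
        planted[term] = path

    n_nodes = len(nodes)
    while g.number_of_edges() < config.ppi_n_edges:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        u, v = nodes[i], nodes[j]
        if g.has_edge(u, v):
            continue
        g.add_edge(u, v, confidence=decoy_conf())

    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    for comp in comps[1:]:
        u = sorted(comp)[0]
        v = sorted(comps[0])[0]
        g.add_edge(u, v, confidence=decoy_conf())

    return PPINetwork(g), planted


def simulate_cohort(config: SimulationConfig, signature: GeneSet, name: str = "cohort",
                    seed_offset: int = 2, loading: str = "mixed") -> PatientCohort:
    """Simulate a patient cohort tied to the signature by proportional hazards.

    A latent per-patient risk ``r ~ N(0,1)`` loads on the signature genes
    with unit coefficients of mixed sign (two-thirds positive, one-third
    negative, the cell model's contrast pattern; noise sd 1): patient
    profiles over the signature then differ in shape with ``r`` — which
    correlation-based clustering can see — while the signature's mean-z
    expression score keeps a net positive track of ``r``
    (``loading="uniform"`` gives every gene coefficient +1 instead, for
    scenarios that score sets without clustering). Survival is
    exponential with hazard
    ``log(2)/baseline_median_survival * exp(hazard_coefficient * r)``.

    Censoring (when ``censor_rate > 0``): administrative end of study at
    ``followup_window`` months for everyone, plus independent dropout
    for a ``censor_rate`` fraction of patients at a uniform time over
    ``(0, followup_window)``. With ``censor_rate = 0`` censoring is
    disabled entirely (no administrative cap) and every event is
    observed — the exact null/ground-truth regime.

    Discrete (``grade``, ``node_status``) and continuous
    (``tumor_size``) phenotypes correlate with the latent risk;
    ``age`` is independent.
    """
    if len(signature) == 0:
        raise ValueError("empty signature")
    universe = gene_ids(config.n_genes)
    missing = set(signature.genes) - set(universe)
    if missing:
        raise ValueError(f"signature genes outside the simulated universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(config.seed + seed_offset)
    patients = [f"{name}_P{i:04d}" for i in range(config.n_patients)]
    risk = rng.normal(0.0, 1.0, size=config.n_patients)

    expr = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_patients))
    sig_mask = np.isin(universe, list(signature.genes))
    if loading == "mixed":
        coefs = np.where(np.arange(int(sig_mask.sum())) % 3 != 2, 1.0, -1.0)
    elif loading == "uniform":
        coefs = np.ones(int(sig_mask.sum()))
    else:
        raise ValueError(f"loading must be 'mixed' or 'uniform', got {loading!r}")
    expr[sig_mask, :] += np.outer(coefs, risk)
    expression = pd.DataFrame(expr, index=pd.Index(universe, name="gene"), columns=patients)

    lam = np.log(2.0) / config.baseline_median_survival * np.exp(
        config.hazard_coefficient * risk)
    event_time = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        dropout = rng.random(config.n_patients) < config.censor_rate
        censor_time = np.full(config.n_patients, config.followup_window)
        censor_time[dropout] = rng.uniform(0.0, config.followup_window,
                                           size=int(dropout.sum()))
    else:
        censor_time = np.full(config.n_patients, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    grade = np.clip(np.digitize(risk + rng.normal(0, 0.8, config.n_patients),
                                [-0.6, 0.6]) + 1, 1, 3)
    node_status = (risk + rng.normal(0, 1.0, config.n_patients) > 0).astype(int)
    clinical = pd.DataFrame(
        {
            "survival_time": observed,
            "event": event,
            "followup_time": observed,
            "grade": grade,
            "node_status": node_status,
            "age": rng.normal(55.0, 10.0, config.n_patients),
            "tumor_size": 20.0 + 4.0 * risk + rng.normal(0, 5.0, config.n_patients),
            "true_risk": risk,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return PatientCohort(expression, clinical, name=name)


def simulate_half_lives(config: SimulationConfig, signature: GeneSet) -> pd.Series:
    """mRNA half-lives (hours): signature genes drawn from a shorter-lived
    truncated normal than the background, both truncated at 0."""
    rng = np.random.default_rng(config.seed + 3)
    universe = gene_ids(config.n_genes)
    sig_mask = np.isin(universe, list(signature.genes))

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    values = np.empty(config.n_genes)
    values[sig_mask] = draw(int(sig_mask.sum()), config.half_life_mean_signature,
                            config.half_life_sd_signature)
    values[~sig_mask] = draw(int((~sig_mask).sum()), config.half_life_mean_background,
                             config.half_life_sd_background)
    return pd.Series(values, index=pd.Index(universe, name="gene"), name="half_life_hours")


def simulate_coherent_pathway_scenario(config: SimulationConfig, n_pathways: int = 40,
                                       n_coherent: int = 20, pathway_len: int = 4,
                                       n_cohorts: int = 3, coherent_loading: float = 1.0,
                                       pathway_noise_sd: float = 0.4):
    """End-to-end scenario: co-regulated anchored pathways that also drive hazard.

    Builds ``n_pathways`` disjoint anchor->terminal gene chains. Genes of
    the first ``n_coherent`` pathways share one latent per-sample profile
    in the cell model (pairwise co-expression, hence high coherency) and
    load on the latent patient risk in every cohort (hence small
    good-vs-bad p-values); the remaining pathways' genes are independent
    noise in both. This is the stated world in which more coherent
    pathways should earn more negative prognosis rankings.

    Returns ``(matrix, pathways, cohorts, coherent_flags)`` where
    ``pathways`` is a list of node chains starting at ``"ANCHOR"``.
    """
    if n_coherent > n_pathways:
        raise ValueError("n_coherent exceeds n_pathways")
    need = n_pathways * pathway_len
    if need > config.n_genes:
        raise ValueError("gene universe too small for the requested pathways")
    rng = np.random.default_rng(config.seed + 4)
    universe = gene_ids(config.n_genes)

    pathways, used = [], 0
    for _ in range(n_pathways):
        chain = ["ANCHOR"] + universe[used:used + pathway_len]
        pathways.append(chain)
        used += pathway_len
    coherent_flags = [i < n_coherent for i in range(n_pathways)]

    null_cfg = replace(config, planted_group_sizes={}, baseline_group_effect=0.0)
    matrix, _ = simulate_cell_model(null_cfg)
    # shared latent profile, constant within (cell line, time) condition
    meta = matrix.sample_meta
    conditions = meta[["cell_line", "time_min"]].apply(tuple, axis=1)
    levels = {c: rng.normal(0.0, 1.0) for c in sorted(set(conditions))}
    latent = conditions.map(levels).to_numpy(dtype=float)

    values = matrix.values.to_numpy()
    gene_pos = {g: i for i, g in enumerate(universe)}
    coherent_genes = [g for chain, coh in zip(pathways, coherent_flags) if coh
                      for g in chain[1:]]
    rows = [gene_pos[g] for g in coherent_genes]
    values[rows, :] += coherent_loading * latent[None, :]
    values[rows, :] += rng.normal(0.0, pathway_noise_sd, size=(len(rows), values.shape[1]))
    matrix = KineticExpressionMatrix(
        pd.DataFrame(values, index=matrix.genes, columns=matrix.samples),
        meta.copy(),
    )

    coherent_set = GeneSet("coherent_pathway_genes", coherent_genes, "scenario")
    # uniform loading: every coherent pathway's score tracks the risk
    # (this scenario evaluates prognosis ranking, not clustering)
    cohorts = [
        simulate_cohort(config, coherent_set, name=f"cohort{k + 1}",
                        seed_offset=10 + k, loading="uniform")
        for k in range(n_cohorts)
    ]
    return matrix, pathways, cohorts, coherent_flags
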