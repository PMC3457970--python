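"""End-to-end pipeline orchestration with a provenance manifest.

`run_pipeline` wires the stages — simulate, derive-signature, score,
stratify, survival, network, nulls — in dependency order from a single
config mapping (typically loaded from YAML), writes flat TSV
intermediates, and records a manifest (config echo, per-stage seeds,
parameters, output file SHA-256 hashes) so a rerun with the identical
config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import io
from .datatypes import GeneSet
from .kinetics import DEFAULT_ALPHA, derive_signature
from .network import AnchoredNetworkModel
from .nulls import null_significance_call, random_signatures
from .scoring import set_expression_score, zscore_per_gene
from .simulate import SimulationConfig, simulate_cell_model, simulate_cohort, \
    simulate_half_lives, simulate_ppi
from .stratify import associate_phenotypes, stratify_cohort
from .survival import label_prognosis, logrank_test, ppv_npv

STAGES = ("simulate", "derive_signature", "score", "stratify", "survival",
          "network", "nulls")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    cfg = dict(config or {})
    alpha = cfg.get("alpha", DEFAULT_ALPHA)
    if not (0.0 < float(alpha) < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    cfg["alpha"] = float(alpha)
    cfg["downstream_alpha"] = float(cfg.get("downstream_alpha", 0.05))
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    sim_kwargs = dict(cfg.get("simulation", {}))
    cfg["_sim_config"] = SimulationConfig(seed=int(cfg["seed"]), **sim_kwargs)
    cfg.setdefault("n_random_signatures", 50)
    cfg.setdefault("n_cohorts", 3)
    return cfg


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; return the manifest (also written as JSON)."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg: SimulationConfig = cfg["_sim_config"]
    stages = cfg["stages"]
    sim_dict = dataclasses.asdict(sim_cfg)
    # tuple keys are not JSON-representable; echo them as "dir@time"
    sim_dict["planted_group_sizes"] = {
        f"{d}@{t}": n for (d, t), n in sim_dict["planted_group_sizes"].items()}
    sim_dict["signature_group"] = "{}@{}".format(*sim_dict["signature_group"])
    manifest = {
        "config": {k: v for k, v in cfg.items() if not k.startswith("_")},
        "simulation_config": sim_dict,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, paths: dict, **params) -> None:
        manifest["stages"][stage] = {"parameters": params, "outputs": sorted(paths)}
        for name, p in paths.items():
            manifest["outputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    # --- simulate -----------------------------------------------------
    matrix, truth = simulate_cell_model(sim_cfg)
    planted_sig = GeneSet("planted_signature", set(truth.index[truth["is_signature"]]),
                          "ground truth")
    paths = {"expression": out / "cell_expression.tsv",
             "sample_meta": out / "cell_samples.tsv",
             "ground_truth": out / "ground_truth_genes.tsv"}
    io.write_expression(matrix, paths["expression"], paths["sample_meta"])
    truth.to_csv(paths["ground_truth"], sep="\t")
    anchor = "MET"
    ppi, planted_paths = simulate_ppi(sim_cfg, anchor, sorted(planted_sig.genes))
    paths["ppi"] = out / "ppi_edges.tsv"
    paths["ppi_sif"] = out / "ppi_edges.sif"
    io.write_ppi(ppi, paths["ppi"], paths["ppi_sif"])
    cohorts = [simulate_cohort(sim_cfg, planted_sig, name=f"cohort{k + 1}",
                               seed_offset=10 + k) for k in range(cfg["n_cohorts"])]
    for cohort in cohorts:
        paths[f"{cohort.name}_expr"] = out / f"{cohort.name}_expression.tsv"
        paths[f"{cohort.name}_clinical"] = out / f"{cohort.name}_clinical.tsv"
        io.write_cohort(cohort, paths[f"{cohort.name}_expr"],
                        paths[f"{cohort.name}_clinical"])
    half_lives = simulate_half_lives(sim_cfg, planted_sig)
    paths["half_lives"] = out / "half_lives.tsv"
    half_lives.to_csv(paths["half_lives"], sep="\t")
    record("simulate", paths, seed=sim_cfg.seed,
           n_planted_paths=len(planted_paths))

    if "derive_signature" not in stages:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- derive signature ---------------------------------------------
    results = derive_signature(matrix, alpha=cfg["alpha"])
    signature = results.signature
    paths = {"signature": out / "signature_genes.txt",
             "group_report": out / "group_report.tsv"}
    io.write_gene_list(signature.genes, paths["signature"])
    results.group_table.to_csv(paths["group_report"], sep="\t")
    record("derive_signature", paths, alpha=cfg["alpha"],
           selected_group=signature.name,
           jaccard_vs_planted=signature.jaccard(planted_sig))

    # canonical list: stand-in = the planted signature (configurable)
    canonical = GeneSet("canonical", set(signature.genes), "derived signature as canonical")

    # --- score ---------------------------------------------------------
    if "score" in stages:
        z = zscore_per_gene(matrix.values)
        score = set_expression_score(z, signature)
        paths = {"scores": out / "signature_scores.tsv"}
        score.scores.to_frame("score").to_csv(paths["scores"], sep="\t",
                                              index_label="sample_id")
        record("score", paths, coverage=score.coverage)

    # --- stratify + survival -------------------------------------------
    survival_rows = []
    strats = {}
    if "stratify" in stages:
        paths = {}
        for cohort in cohorts:
            strat = stratify_cohort(cohort, signature, canonical)
            strats[cohort.name] = strat
            lab_path = out / f"{cohort.name}_labels.tsv"
            strat.labels.to_frame().to_csv(lab_path, sep="\t", index_label="patient_id")
            paths[f"{cohort.name}_labels"] = lab_path
            assoc = associate_phenotypes(strat, cohort,
                                         discrete=["grade", "node_status"],
                                         continuous=["age", "tumor_size"])
            assoc_path = out / f"{cohort.name}_associations.tsv"
            assoc.to_csv(assoc_path, sep="\t", index=False)
            paths[f"{cohort.name}_associations"] = assoc_path
        record("stratify", paths)
    if "survival" in stages and strats:
        import pandas as pd
        paths = {}
        for cohort in cohorts:
            strat = strats[cohort.name]
            clin = cohort.clinical
            hi, lo = strat.group("HighSig"), strat.group("LowSig")
            lr = logrank_test(clin.loc[hi, "survival_time"], clin.loc[hi, "event"],
                              clin.loc[lo, "survival_time"], clin.loc[lo, "event"])
            prog = label_prognosis(cohort)
            pv = ppv_npv(strat.labels, prog)
            survival_rows.append((cohort.name, len(hi), len(lo), lr.statistic,
                                  lr.p_value, pv.ppv, pv.npv))
        stats_df = pd.DataFrame(survival_rows, columns=[
            "cohort", "n_high", "n_low", "logrank_chi2", "logrank_p", "ppv", "npv"])
        paths["survival_stats"] = out / "survival_stats.tsv"
        stats_df.to_csv(paths["survival_stats"], sep="\t", index=False)
        record("survival", paths, endpoint="os")

    # --- network --------------------------------------------------------
    net_results = None
    if "network" in stages:
        net_results = AnchoredNetworkModel(ppi, anchor, sorted(signature.genes)).fit()
        diff = net_results.attach_differentiation(matrix)
        net_results.attach_coherency(matrix)
        net_results.attach_prognosis(cohorts)
        paths = {"subnetwork": out / "subnetwork.sif",
                 "pathways": out / "pathways.tsv"}
        io.write_subnetwork_sif(net_results.subnetwork, paths["subnetwork"])
        net_results.pathway_table().to_csv(paths["pathways"], sep="\t")
        rho, rho_p = (np.nan, np.nan)
        try:
            rho, rho_p = net_results.coherency_prognosis_correlation()
        except ValueError:
            pass
        record("network", paths, n_pathways=len(net_results.pathways),
               n_left_out=len(net_results.left_out),
               n_differentiating=int((diff["p_value"] < cfg["downstream_alpha"]).sum()),
               coherency_prognosis_rho=rho, coherency_prognosis_p=rho_p)

    # --- nulls ----------------------------------------------------------
    if "nulls" in stages and net_results is not None:
        import pandas as pd
        rng_seed = sim_cfg.seed + 1000
        universe = sorted(matrix.genes)
        randoms = random_signatures(universe, len(signature),
                                    n=cfg["n_random_signatures"], seed=rng_seed)
        z = zscore_per_gene(matrix.values)
        null_ps = []
        for rs in randoms:
            rnet = AnchoredNetworkModel(ppi, anchor, sorted(rs.genes)).fit()
            rdiff = rnet.attach_differentiation(matrix)
            null_ps.extend(rdiff["p_value"].dropna().tolist())
        if len(null_ps) >= 20:
            calls = []
            for pw in net_results.pathways:
                if np.isnan(pw.diff_p):
                    continue
                call = null_significance_call(pw.diff_p, null_ps)
                calls.append((pw.pathway_id, pw.diff_p, call.significant,
                              call.empirical_quantile))
            calls_df = pd.DataFrame(calls, columns=["pathway_id", "diff_p",
                                                    "significant_vs_null",
                                                    "empirical_quantile"])
            paths = {"null_calls": out / "null_significance.tsv"}
            calls_df.to_csv(paths["null_calls"], sep="\t", index=False)
            record("nulls", paths, n_random_signatures=cfg["n_random_signatures"],
                   n_null_tests=len(null_ps),
                   n_significant=int(calls_df["significant_vs_null"].sum()))
        else:
            record("nulls", {}, n_random_signatures=cfg["n_random_signatures"],
                   n_null_tests=len(null_ps),
                   note="fewer than 20 null tests; significance calls skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
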