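"""Response testing, BH-FDR, six-group partition, signature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metkinsig.kinetics import test_kinetic_response as kinetic_response_records
from metkinsig import (
    GeneSet,
    KineticSignatureModel,
    SimulationConfig,
    bh_fdr,
    derive_signature,
    evaluate_separation,
    partition_six_groups,
    simulate_cell_model,
)
from tests.conftest import make_matrix


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """q_i = min over { p_j * m / rank_j : p_j >= p_i }, clipped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(ranked[j] * m / (j + 1) for j in range(m) if ranked[j] >= p[i]), 1.0)
    return q


class TestBHFDR:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagation(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # NaN excluded from ranking: remaining two behave as m=2
        assert np.allclose(q[[0, 2]], brute_force_bh(np.array([0.01, 0.04])))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.4])

    @settings(max_examples=200, deadline=None, derandomize=True, database=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_matches_brute_force_definition(self, ps):
        p = np.array(ps)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestKineticResponse:
    def test_noiseless_down_gene(self, tiny_timecourse):
        rec = kinetic_response_records(tiny_timecourse, alpha=0.05)
        row = rec.loc["g_down"]
        assert row["delta_t10"] == pytest.approx(-1.0)
        assert row["delta_t30"] == pytest.approx(-1.0)
        assert row["delta_t1440"] == pytest.approx(-1.0)

    def test_constant_gene_has_no_response(self, tiny_timecourse):
        rec = kinetic_response_records(tiny_timecourse, alpha=0.05)
        row = rec.loc["g_flat"]
        assert np.isnan(row["initial_time_min"])
        assert row["initial_direction"] is None
        # zero variance across ratios: p undefined, not 1
        assert np.isnan(row["p_t10"])

    def test_p_equals_hand_computed_t_test(self):
        # 6 cell lines, 1 replicate: the t=10 ratios are exactly the
        # treated-minus-baseline differences; check against a direct
        # one-sample t-test on those differences.
        rng = np.random.default_rng(42)
        diffs = rng.normal(0.8, 0.1, size=6)
        rows, cols = [], []
        for i in range(6):
            grp = "high" if i < 3 else "low"
            rows.append((f"c{i}_t0", f"c{i}", grp, 0, 1))
            rows.append((f"c{i}_t10", f"c{i}", grp, 10, 1))
        values = np.zeros((1, 12))
        for i in range(6):
            values[0, 2 * i] = 5.0
            values[0, 2 * i + 1] = 5.0 + diffs[i]
        # pad with two extra time points so the record structure is standard
        for t in (30, 1440):
            for i in range(6):
                rows.append((f"c{i}_t{t}", f"c{i}", "high" if i < 3 else "low", t, 1))
        values = np.hstack([values, np.full((1, 12), 5.0)])
        matrix = make_matrix(values, ["g"], rows)
        rec = kinetic_response_records(matrix, alpha=0.05)
        expected = stats.ttest_1samp(diffs, 0.0)
        assert rec.loc["g", "p_t10"] == pytest.approx(expected.pvalue, rel=1e-10)
        assert rec.loc["g", "delta_t10"] == pytest.approx(diffs.mean(), rel=1e-10)

    def test_alpha_validation(self, tiny_timecourse):
        with pytest.raises(ValueError):
            kinetic_response_records(tiny_timecourse, alpha=1.5)


class TestPartition:
    @pytest.fixture(scope="class")
    def all_six_world(self):
        sizes = {(d, t): 10 for d in ("up", "down") for t in (10, 30, 1440)}
        cfg = SimulationConfig(n_genes=300, planted_group_sizes=sizes,
                               noise_sd=0.05, signature_group=("down", 10), seed=19)
        matrix, truth = simulate_cell_model(cfg)
        return matrix, truth

    def test_recovers_all_planted_groups_at_low_noise(self, all_six_world):
        matrix, truth = all_six_world
        rec = kinetic_response_records(matrix, alpha=1e-4)
        groups = partition_six_groups(rec)
        for (d, t), gs in groups.items():
            planted = set(truth.index[truth["group"] == f"{d}@{t}"])
            assert planted <= gs.genes

    def test_partition_is_a_partition(self, all_six_world):
        matrix, _ = all_six_world
        rec = kinetic_response_records(matrix, alpha=1e-4)
        groups = partition_six_groups(rec)
        assert set(groups) == {(d, t) for d in ("up", "down") for t in (10, 30, 1440)}
        all_members = [g for gs in groups.values() for g in gs.genes]
        assert len(all_members) == len(set(all_members))
        responders = set(rec.index[rec["initial_time_min"].notna()])
        assert set(all_members) == responders

    def test_no_responders_gives_six_empty_groups(self, tiny_timecourse):
        rec = kinetic_response_records(tiny_timecourse, alpha=1e-12)
        groups = partition_six_groups(rec)
        assert len(groups) == 6
        assert all(len(gs) == 0 for gs in groups.values())

    def test_wrong_time_grid_errors(self, tiny_timecourse):
        rec = kinetic_response_records(tiny_timecourse, alpha=0.05)
        bad = rec.drop(columns=["delta_t1440"])
        with pytest.raises(ValueError, match="3 post-baseline"):
            partition_six_groups(bad)


class TestSeparation:
    def test_perfect_split_fisher_p(self, small_model, planted_signature):
        # 48 samples, 24 high / 24 low: perfect separation has the exact
        # two-sided Fisher p = 2 / C(48, 24)
        from math import comb

        matrix, _ = small_model
        res = evaluate_separation(matrix, planted_signature)
        assert res.perfect
        assert res.p_value == pytest.approx(2 / comb(48, 24), rel=1e-6)

    def test_24_sample_constant(self):
        # the spec-scale example: 12 high vs 12 low, perfect split
        from math import comb

        cfg = SimulationConfig(n_genes=200, n_cell_lines_per_group=3,
                               n_replicates=1, noise_sd=0.1,
                               planted_group_sizes={("down", 10): 20}, seed=23)
        matrix, truth = simulate_cell_model(cfg)
        sig = GeneSet("planted", set(truth.index[truth["is_signature"]]))
        res = evaluate_separation(matrix, sig)
        assert res.perfect
        assert res.p_value == pytest.approx(2 / comb(24, 12), rel=1e-6)
        assert res.p_value == pytest.approx(7.396e-7, rel=1e-3)

    def test_disjoint_gene_set_errors(self, small_model):
        matrix, _ = small_model
        with pytest.raises(ValueError):
            evaluate_separation(matrix, GeneSet("missing", {"NOPE1", "NOPE2"}))


class TestDeriveSignature:
    def test_recovers_planted_group(self, small_model, planted_signature):
        matrix, _ = small_model
        results = derive_signature(matrix)
        assert results.best_key == ("down", 10)
        assert results.signature.jaccard(planted_signature) >= 0.9
        assert "down@10" in results.summary()

    def test_no_group_effect_means_no_perfect_separation(self):
        cfg = SimulationConfig(n_genes=300, baseline_group_effect=0.0,
                               planted_group_sizes={("down", 10): 25}, seed=29)
        matrix, _ = simulate_cell_model(cfg)
        results = derive_signature(matrix)
        assert results.separation_p > 1e-4
        assert not results.separations[results.best_key].perfect

    def test_deterministic(self, small_model):
        matrix, _ = small_model
        r1 = KineticSignatureModel(matrix).fit()
        r2 = KineticSignatureModel(matrix).fit()
        assert r1.signature.genes == r2.signature.genes
        pd.testing.assert_frame_equal(r1.group_table, r2.group_table)

    def test_all_empty_groups_error(self, tiny_timecourse):
        with pytest.raises(ValueError, match="no gene responded"):
            KineticSignatureModel(tiny_timecourse, alpha=1e-12).fit()
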