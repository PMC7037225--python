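import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from upstreamx.diffexpr import (DegRecord, DegTable, _common_dispersion,
                                _exact_nb_pvalue, filter_degs, normalize)
from upstreamx.diffexpr import test_de as run_de_test
from upstreamx.io_formats import CountMatrix
from upstreamx.synthetic_data import simulate_counts


def _matrix(mat, n_a, n_b):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    cond = {s: ("control" if s.startswith("a") else "treatment")
            for s in samples}
    df = pd.DataFrame(np.asarray(mat, dtype=np.int64),
                      index=[f"g{i}" for i in range(len(mat))],
                      columns=samples)
    return CountMatrix(df, cond)


class TestNormalize:
    def test_matches_bruteforce_median_of_ratios(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 500, size=(60, 5))
        cm = _matrix(mat, 3, 2)
        got = normalize(cm).to_numpy()
        expected = oracles.median_of_ratios(mat.astype(float))
        assert np.allclose(got, expected, rtol=1e-12)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 300, size=(80, 6))
        mat[:10] = rng.integers(1, 300, size=(10, 6))  # some all-positive
        cm = _matrix(mat, 3, 3)
        f = normalize(cm).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_scaling_one_library_scales_its_factor(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(1, 200, size=(50, 4))
        scaled = mat.copy()
        scaled[:, 0] *= 3
        f0 = normalize(_matrix(mat, 2, 2)).to_numpy()
        f1 = normalize(_matrix(scaled, 2, 2)).to_numpy()
        # sample 0's factor grows ~3x relative to the rest
        assert f1[0] / f0[0] > 2.5 * (f1[1] / f0[1])

    def test_total_count_fallback_warns(self, caplog):
        mat = np.array([[5, 0], [0, 5]])
        cm = _matrix(mat, 1, 1)
        with caplog.at_level("WARNING", logger="upstreamx"):
            f = normalize(cm).to_numpy()
        assert any("total-count" in r.message for r in caplog.records)
        assert np.allclose(f, [1.0, 1.0])


class TestExactNbPvalue:
    def test_poisson_case_matches_binomial_min_likelihood(self):
        # alpha = 0: conditional law is Binomial(t, n_a/(n_a+n_b))
        for ka, kb, n_a, n_b in [(3, 9, 3, 3), (0, 7, 2, 3), (10, 10, 4, 4)]:
            t = ka + kb
            pmf = stats.binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
            expected = pmf[pmf <= pmf[ka] * (1 + 1e-9)].sum()
            got = _exact_nb_pvalue(ka, kb, n_a, n_b, 0.0)
            assert got == pytest.approx(min(expected, 1.0), rel=1e-9)

    def test_balanced_equal_counts_give_p_one(self):
        assert _exact_nb_pvalue(8, 8, 3, 3, 0.1) == pytest.approx(1.0)

    def test_zero_total_gives_p_one(self):
        assert _exact_nb_pvalue(0, 0, 3, 3, 0.1) == 1.0

    def test_symmetry_in_balanced_design(self):
        p1 = _exact_nb_pvalue(2, 14, 3, 3, 0.05)
        p2 = _exact_nb_pvalue(14, 2, 3, 3, 0.05)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_more_extreme_split_gives_smaller_p(self):
        ps = [_exact_nb_pvalue(k, 20 - k, 3, 3, 0.1) for k in (10, 6, 2)]
        assert ps[0] > ps[1] > ps[2]

    def test_dispersion_widens_the_null(self):
        # same split is less surprising under higher dispersion
        p_low = _exact_nb_pvalue(4, 16, 3, 3, 0.01)
        p_high = _exact_nb_pvalue(4, 16, 3, 3, 0.5)
        assert p_high > p_low


class TestCommonDispersion:
    def test_recovers_simulated_dispersion_roughly(self):
        rng = np.random.default_rng(5)
        alpha = 0.1
        mu = 100.0
        r = 1 / alpha
        mat = rng.negative_binomial(r, r / (r + mu), size=(3000, 6)).astype(
            float)
        est = _common_dispersion(mat, [np.arange(3), np.arange(3, 6)])
        assert est == pytest.approx(alpha, rel=0.3)

    def test_poisson_data_floored_at_zero(self):
        rng = np.random.default_rng(6)
        mat = rng.poisson(50.0, size=(2000, 6)).astype(float)
        est = _common_dispersion(mat, [np.arange(3), np.arange(3, 6)])
        assert 0.0 <= est < 0.02


class TestTestDe:
    def _sim(self, seed):
        counts, truth = simulate_counts(
            n_genes=300, n_reps_per_group=3, frac_de=0.1, planted_lfc=2.5,
            dispersion=0.05, seed=seed)
        return counts, truth

    def test_planted_genes_dominate_the_calls(self):
        counts, truth = self._sim(10)
        table = run_de_test(counts, "control", "treatment")
        up, down, _ = filter_degs(table)
        planted_up = {g for g, (d, _) in truth.de_genes.items() if d == "up"}
        planted_down = {g for g, (d, _) in truth.de_genes.items()
                        if d == "down"}
        # high power at lfc 2.5, low dispersion
        assert len(up & planted_up) / len(planted_up) > 0.8
        assert len(down & planted_down) / len(planted_down) > 0.8
        # called sets are mostly planted genes
        if up:
            assert len(up & planted_up) / len(up) > 0.8
        if down:
            assert len(down & planted_down) / len(down) > 0.8

    def test_logfc_sign_matches_planted_direction(self):
        counts, truth = self._sim(11)
        table = run_de_test(counts, "control", "treatment")
        by_gene = {r.gene_id: r for r in table.records}
        for g, (direction, mag) in truth.de_genes.items():
            expected = 1.0 if direction == "up" else -1.0
            assert np.sign(by_gene[g].logFC) == expected

    def test_label_swap_flips_logfc_and_keeps_p(self):
        counts, _ = self._sim(12)
        fwd = run_de_test(counts, "control", "treatment")
        rev = run_de_test(counts, "treatment", "control")
        f = {r.gene_id: r for r in fwd.records}
        r_ = {r.gene_id: r for r in rev.records}
        for g in f:
            assert f[g].logFC == pytest.approx(-r_[g].logFC, abs=1e-12)
            assert f[g].p_value == pytest.approx(r_[g].p_value, rel=1e-9)

    def test_all_zero_gene_retained_neutral(self):
        rng = np.random.default_rng(13)
        mat = rng.integers(10, 200, size=(20, 6))
        mat[7] = 0
        table = run_de_test(_matrix(mat, 3, 3), "control", "treatment")
        rec = next(r for r in table.records if r.gene_id == "g7")
        assert rec.logFC == 0.0 and rec.p_value == 1.0

    def test_requires_two_replicates(self):
        mat = np.array([[5, 6, 7], [8, 9, 10]])
        cm = _matrix(mat, 1, 2)
        with pytest.raises(ValueError, match="replicates"):
            run_de_test(cm, "control", "treatment")

    def test_deterministic(self):
        counts, _ = self._sim(14)
        a = run_de_test(counts, "control", "treatment")
        b = run_de_test(counts, "control", "treatment")
        assert [(r.logFC, r.p_value) for r in a.records] == \
               [(r.logFC, r.p_value) for r in b.records]


class TestFilterDegs:
    def _table(self, rows):
        return DegTable([DegRecord(g, fc, p, 10.0) for g, fc, p in rows])

    def test_strict_inequalities_at_boundaries(self):
        t = self._table([
            ("at_fc", 0.7, 0.001),       # logFC not strictly above
            ("at_p", 1.2, 0.05),         # p not strictly below
            ("in_up", 0.71, 0.049),
            ("in_down", -0.71, 0.049),
            ("at_fc_dn", -0.7, 0.001),
        ])
        up, down, no = filter_degs(t)
        assert up == {"in_up"}
        assert down == {"in_down"}
        assert no == {"at_fc", "at_p", "at_fc_dn"}

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(15)
        rows = [(f"g{i}", float(rng.normal(0, 1.5)),
                 float(rng.uniform(1e-6, 1))) for i in range(200)]
        t = self._table(rows)
        up, down, no = filter_degs(t)
        assert up | down | no == {f"g{i}" for i in range(200)}
        assert not (up & down) and not (up & no) and not (down & no)

    def test_bad_thresholds_rejected(self):
        t = self._table([("g0", 1.0, 0.01)])
        with pytest.raises(ValueError):
            filter_degs(t, theta_up=-0.1, theta_down=-0.7)


class TestDegTableRoundTrip:
    def test_frame_round_trip_preserves_records_and_calls(self):
        t = DegTable([DegRecord("g1", 1.2, 0.01, 55.0),
                      DegRecord("g2", -0.9, 0.02, 12.0),
                      DegRecord("g3", 0.1, 0.8, 5.0)])
        filter_degs(t)
        df = t.to_frame()
        again = DegTable.from_frame(df)
        filter_degs(again)
        assert again.up_set == t.up_set == {"g1"}
        assert again.down_set == t.down_set == {"g2"}
        assert [r.gene_id for r in again.records] == ["g1", "g2", "g3"]

    def test_invalid_p_value_rejected(self):
        with pytest.raises(ValueError):
            DegRecord("g1", 0.0, 0.0, 1.0)
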