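import numpy as np
import pytest

from helpers import brute_force_vifs, hwe_enumeration_pvalue, make_dataset, random_dataset
from prspredict.datamodel_io import MISSING
from prspredict.qc_filters import (
    QcConfig,
    filter_callrate,
    filter_hwe,
    filter_maf,
    filter_monomorphic,
    hwe_exact_test,
    ld_prune_vif,
    run_qc,
)


class TestCallRate:
    def test_rate_above_cutoff_removed(self):
        col = [1] * 8 + [-1, -1]  # missing rate 0.2
        ds = make_dataset(np.array([col, [1] * 10]).T)
        _, removed = filter_callrate(ds, 0.10)
        assert removed == ["V0"]

    def test_rate_exactly_at_cutoff_retained(self):
        col = [1] * 9 + [-1]  # rate exactly 0.10: "exceeding" is strict
        ds = make_dataset(np.array([col]).T)
        filtered, removed = filter_callrate(ds, 0.10)
        assert removed == [] and filtered.n_variants == 1

    def test_matches_brute_force_recount(self, rng):
        ds = random_dataset(rng, n=30, m=50, missing_rate=0.08)
        _, removed = filter_callrate(ds, 0.10)
        expected = [
            vid
            for j, vid in enumerate(ds.variant_ids)
            if sum(1 for g in ds.genotypes[:, j] if g == MISSING) / ds.n_samples > 0.10
        ]
        assert removed == expected


class TestMonomorphic:
    @pytest.mark.parametrize(
        "column,expect_removed",
        [([0, 0, 0], True), ([2, 2, 2], True), ([0, 0, 1], False), ([-1, -1, -1], True),
         ([0, -1, 0], True), ([1, 1, 1], True)],
    )
    def test_cases(self, column, expect_removed):
        ds = make_dataset(np.array([column]).T)
        _, removed = filter_monomorphic(ds)
        assert (removed == ["V0"]) == expect_removed


class TestHweExactTest:
    def test_perfect_hwe_is_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_small_triple_equals_enumeration(self):
        assert hwe_exact_test(3, 4, 3) == pytest.approx(
            hwe_enumeration_pvalue(3, 4, 3), abs=1e-12
        )

    def test_total_het_deficit_is_tiny(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_enumeration_oracle_all_triples_up_to_30(self):
        for total in range(1, 31):
            for n_AA in range(total + 1):
                for n_Aa in range(total - n_AA + 1):
                    n_aa = total - n_AA - n_Aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_enumeration_pvalue(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, abs=1e-12), (n_AA, n_Aa, n_aa)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestFilterHwe:
    def _case_violating_dataset(self):
        # controls in perfect HWE; cases het-free with common alleles
        n_ctrl, n_case = 100, 100
        ctrl_col = [0] * 25 + [1] * 50 + [2] * 25
        case_col = [0] * 50 + [2] * 50
        col = np.array(case_col + ctrl_col, dtype=np.int8)
        phenos = ["case"] * n_case + ["control"] * n_ctrl
        return make_dataset(col[:, None], phenotypes=phenos)

    def test_controls_only_rule(self):
        ds = self._case_violating_dataset()
        _, removed = filter_hwe(ds, alpha=1e-3)
        assert removed == []

    def test_planted_violation_removed(self):
        # 500 controls, zero heterozygotes, alleles 50/50: p << 1e-3
        col = np.array([0] * 250 + [2] * 250, dtype=np.int8)
        ds = make_dataset(col[:, None], phenotypes=["control"] * 500)
        assert hwe_enumeration_pvalue(250, 0, 250) < 1e-3  # oracle confirms
        _, removed = filter_hwe(ds, alpha=1e-3)
        assert removed == ["V0"]

    def test_alpha_zero_removes_nothing(self):
        ds = self._case_violating_dataset()
        _, removed = filter_hwe(ds, alpha=0.0)
        assert removed == []

    def test_no_controls_errors(self):
        ds = make_dataset([[0], [1]], phenotypes=["case", "case"])
        with pytest.raises(ValueError):
            filter_hwe(ds)


class TestMaf:
    def test_below_cutoff_removed(self):
        col = [1] + [0] * 99  # MAF 0.005
        ds = make_dataset(np.array([col]).T)
        _, removed = filter_maf(ds, 0.01)
        assert removed == ["V0"]

    def test_exactly_at_cutoff_retained(self):
        col = [1, 1] + [0] * 98  # MAF exactly 0.01: "less than" is strict
        ds = make_dataset(np.array([col]).T)
        _, removed = filter_maf(ds, 0.01)
        assert removed == []

    def test_matches_brute_force_counting(self, rng):
        ds = random_dataset(rng, n=40, m=30, missing_rate=0.1)
        _, removed = filter_maf(ds, 0.15)
        expected = []
        for j, vid in enumerate(ds.variant_ids):
            obs = [int(g) for g in ds.genotypes[:, j] if g != MISSING]
            freq = sum(obs) / (2 * len(obs)) if obs else 0.0
            if min(freq, 1 - freq) < 0.15:
                expected.append(vid)
        assert removed == expected


class TestLdPruneVif:
    def test_independent_variants_untouched(self, rng):
        maf = rng.uniform(0.3, 0.5, size=20)
        G = rng.binomial(2, maf, size=(300, 20)).astype(np.int8)
        ds = make_dataset(G)
        _, removed = ld_prune_vif(ds, window=10, step=5, vif_threshold=2.0)
        assert removed == []

    def test_exact_duplicate_one_copy_removed(self, rng):
        G = rng.binomial(2, 0.4, size=(100, 5)).astype(np.int8)
        G[:, 3] = G[:, 1]
        ds = make_dataset(G)
        filtered, removed = ld_prune_vif(ds, window=5, step=2, vif_threshold=2.0)
        # larger index removed on the VIF tie
        assert removed == ["V3"]
        assert "V1" in filtered.variant_ids

    def test_matches_brute_force_vif_oracle(self, rng):
        # one planted high-r2 pair inside a 10-variant window
        G = rng.binomial(2, 0.4, size=(400, 10)).astype(np.int8)
        noise = rng.random(400) < 0.05
        G[:, 7] = np.where(noise, rng.integers(0, 3, 400), G[:, 2]).astype(np.int8)
        ds = make_dataset(G)
        _, removed = ld_prune_vif(ds, window=10, step=10, vif_threshold=2.0)

        # brute-force greedy removal on the same single window
        X = G.astype(float)
        active = list(range(10))
        expected = []
        while True:
            vifs = brute_force_vifs(X[:, active])
            worst = vifs.max()
            if not worst > 2.0:
                break
            k = int(np.where(vifs >= worst)[0].max())
            expected.append(f"V{active[k]}")
            del active[k]
        assert removed == expected
        assert len(expected) >= 1  # the planted pair really fired

    def test_windows_never_span_chromosomes(self, rng):
        G = rng.binomial(2, 0.4, size=(100, 4)).astype(np.int8)
        G[:, 2] = G[:, 1]  # duplicate pair split across chromosomes
        ds = make_dataset(G, chroms=["1", "1", "2", "2"], bps=[1, 2, 1, 2])
        _, removed = ld_prune_vif(ds, window=4, step=2, vif_threshold=2.0)
        assert removed == []

    def test_missing_mean_imputed(self, rng):
        G = rng.binomial(2, 0.4, size=(200, 4)).astype(np.int8)
        G[:, 2] = G[:, 0]
        G[:5, 2] = MISSING
        ds = make_dataset(G)
        _, removed = ld_prune_vif(ds, window=4, step=2, vif_threshold=2.0)
        assert removed == ["V2"]

    def test_idempotent(self, rng):
        G = rng.binomial(2, 0.4, size=(150, 12)).astype(np.int8)
        G[:, 5] = G[:, 4]
        G[:, 9] = G[:, 7]
        pruned, removed = ld_prune_vif(make_dataset(G), window=6, step=3)
        assert len(removed) == 2
        _, removed_again = ld_prune_vif(pruned, window=6, step=3)
        assert removed_again == []

    def test_window_too_small_errors(self, tiny_dataset):
        with pytest.raises(ValueError):
            ld_prune_vif(tiny_dataset, window=1)


class TestRunQc:
    def test_clean_dataset_all_zero_counts(self, rng):
        maf = rng.uniform(0.2, 0.5, size=10)
        G = rng.binomial(2, maf, size=(200, 10)).astype(np.int8)
        phenos = ["case"] * 100 + ["control"] * 100
        ds = make_dataset(G, phenotypes=phenos)
        filtered, report = run_qc(ds)
        assert report.n_retained == 10 == filtered.n_variants
        assert all(report.count(s) == 0 for s in report.removed)

    def test_each_filter_attributed_first(self, rng):
        n = 500
        maf = rng.uniform(0.3, 0.5, size=8)
        G = rng.binomial(2, maf, size=(n, 8)).astype(np.int8)
        G[: int(0.2 * n), 0] = MISSING                      # callrate
        G[:, 1] = 0                                          # monomorphic
        G[:, 2] = np.where(np.arange(n) % 2 == 0, 0, 2)      # HWE het deficit
        G[:, 3] = 0
        G[:2, 3] = 1                                         # MAF 0.002
        G[:, 5] = G[:, 4]                                    # pruning duplicate
        phenos = ["case"] * 100 + ["control"] * 400
        ds = make_dataset(G, phenotypes=phenos)
        _, report = run_qc(ds)
        assert report.removed["callrate"] == ["V0"]
        assert report.removed["monomorphic"] == ["V1"]
        assert report.removed["hwe"] == ["V2"]
        assert report.removed["maf"] == ["V3"]
        assert report.removed["pruning"] == ["V5"]
        assert report.n_retained == 3

    def test_count_conservation(self, rng):
        for k in range(3):
            ds = random_dataset(rng, n=120, m=25, missing_rate=0.05)
            _, report = run_qc(ds, QcConfig(prune_window=5, prune_step=2))
            total_removed = sum(len(v) for v in report.removed.values())
            assert report.n_input - total_removed == report.n_retained

    def test_report_frames(self, rng):
        ds = random_dataset(rng, n=60, m=10)
        _, report = run_qc(ds)
        frame = report.to_frame()
        assert list(frame["stage"]) == [
            "input", "callrate", "monomorphic", "hwe", "maf", "pruning", "retained",
        ]
        log = report.removal_log()
        assert set(log.columns) == {"variant_id", "stage"}
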