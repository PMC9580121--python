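import itertools

import numpy as np
import pytest
from scipy import stats as sps

from spetpanel.io_formats import MISSING, GenotypeMatrix
from spetpanel.progeny_qc import (
    AAXBB,
    HKXHK,
    LMXLL,
    MISSING_PARENT,
    MONOMORPHIC,
    NNXNP,
    CrossDataset,
    classify_cp_marker,
    collapse_identical,
    detectable_fraction,
    distortion_scan,
    estimate_error_rate,
    export_joinmap_cp,
    mendelian_check,
    segregation_distortion,
)
from spetpanel.simdata import SimConfig, inject_errors_and_missing, simulate_f1, simulate_founders

from conftest import make_matrix


def oracle_gametes(g):
    """Brute-force oracle: alleles a genotype can transmit."""
    return {0: [0], 1: [0, 1], 2: [1]}[g]


def oracle_offspring(g1, g2):
    return {a + b for a in oracle_gametes(g1) for b in oracle_gametes(g2)}


class TestClassifyCpMarker:
    @pytest.mark.parametrize(
        "p1,p2,code",
        [
            (1, 0, LMXLL),
            (1, 2, LMXLL),
            (0, 1, NNXNP),
            (2, 1, NNXNP),
            (1, 1, HKXHK),
            (0, 0, MONOMORPHIC),
            (2, 2, MONOMORPHIC),
            (0, 2, AAXBB),
            (2, 0, AAXBB),
            (MISSING, 1, MISSING_PARENT),
            (1, MISSING, MISSING_PARENT),
        ],
    )
    def test_configuration_table(self, p1, p2, code):
        assert classify_cp_marker(p1, p2) == code

    def test_matches_gamete_enumeration_semantics(self):
        """Cross class determines the producible-offspring set; check the
        full 3x3 parental table against brute-force enumeration."""
        expected_sets = {
            MONOMORPHIC: {frozenset({0}), frozenset({2})},
            AAXBB: {frozenset({1})},
            LMXLL: {frozenset({0, 1}), frozenset({1, 2})},
            NNXNP: {frozenset({0, 1}), frozenset({1, 2})},
            HKXHK: {frozenset({0, 1, 2})},
        }
        for p1, p2 in itertools.product(range(3), repeat=2):
            code = classify_cp_marker(p1, p2)
            assert frozenset(oracle_offspring(p1, p2)) in expected_sets[code]


class TestMendelianCheck:
    def test_all_27_triples_against_enumeration(self):
        for p1, p2, off in itertools.product(range(3), repeat=3):
            expected = (
                "consistent" if off in oracle_offspring(p1, p2) else "inconsistent"
            )
            assert mendelian_check(p1, p2, off) == expected

    @pytest.mark.parametrize(
        "p1,p2,off",
        [(0, 0, 1), (0, 2, 0), (0, 2, 2), (2, 2, 1), (0, 0, 2)],
    )
    def test_known_inconsistent_cases(self, p1, p2, off):
        assert mendelian_check(p1, p2, off) == "inconsistent"

    def test_hkxhk_never_flags(self):
        for off in range(3):
            assert mendelian_check(1, 1, off) == "consistent"

    def test_missing_anything_unchecked(self):
        assert mendelian_check(MISSING, 0, 0) == "unchecked"
        assert mendelian_check(0, 0, MISSING) == "unchecked"


def oracle_detectable(p1, p2, model):
    """Independent enumeration of P(flagged | error hits a call)."""
    producible = oracle_offspring(p1, p2)
    gam1, gam2 = oracle_gametes(p1), oracle_gametes(p2)
    total = 0.0
    w = 1.0 / (len(gam1) * len(gam2))
    for a in gam1:
        for b in gam2:
            true_g = a + b
            if model == "uniform-swap":
                outcomes = [(g, 0.5) for g in (0, 1, 2) if g != true_g]
            else:  # allelic-dropout
                outcomes = (
                    [(0, 0.5), (2, 0.5)] if true_g == 1 else [(true_g, 1.0)]
                )
            for obs, p_obs in outcomes:
                if obs not in producible:
                    total += w * p_obs
    return total


class TestDetectableFraction:
    @pytest.mark.parametrize(
        "code,model,expected",
        [
            (MONOMORPHIC, "uniform-swap", 1.0),
            (AAXBB, "uniform-swap", 1.0),
            (LMXLL, "uniform-swap", 0.5),
            (NNXNP, "uniform-swap", 0.5),
            (HKXHK, "uniform-swap", 0.0),
            (HKXHK, "allelic-dropout", 0.0),
            (MONOMORPHIC, "allelic-dropout", 0.0),
            (LMXLL, "allelic-dropout", 0.25),
        ],
    )
    def test_enumeration_values(self, code, model, expected):
        assert detectable_fraction(code, model) == pytest.approx(expected)

    def test_matches_independent_enumeration_all_classes(self):
        reps = {MONOMORPHIC: (0, 0), AAXBB: (0, 2), LMXLL: (1, 0),
                NNXNP: (0, 1), HKXHK: (1, 1)}
        for code, (p1, p2) in reps.items():
            for model in ("uniform-swap", "allelic-dropout"):
                assert detectable_fraction(code, model) == pytest.approx(
                    oracle_detectable(p1, p2, model)
                )

    def test_unknown_model_raises(self):
        with pytest.raises(ValueError, match="unknown error model"):
            detectable_fraction(LMXLL, "telepathy")


def _make_cross(seed, n_sites=2_000, n_offspring=80, n_chrom=2):
    cfg = SimConfig(seed=seed, n_sites=n_sites, n_samples=4, n_chrom=n_chrom,
                    chrom_len_bp=1_000_000)
    founders, _ = simulate_founders(cfg)
    return simulate_f1(founders, "S001", "S002", n_offspring, cfg), cfg


class TestEstimateErrorRate:
    def test_error_free_cross_rate_zero(self):
        cross, _ = _make_cross(60)
        est = estimate_error_rate(cross)
        assert est.raw_rate == 0.0 and est.adjusted_rate == 0.0
        assert est.n_inconsistent == 0

    def test_recovery_across_injected_rates(self):
        """Adjusted rate is unbiased over a grid of injected rates."""
        cross, _ = _make_cross(61, n_sites=4_000, n_offspring=100)
        for i, rate in enumerate([0.005, 0.01, 0.02, 0.05]):
            pert, masks = inject_errors_and_missing(
                cross.offspring, rate, "uniform-swap", 0.0, seed=70 + i
            )
            est = estimate_error_rate(
                CrossDataset(cross.parent1, cross.parent2, pert)
            )
            n = est.n_calls_checked
            # 2 MC standard errors of the adjusted estimator
            se = 2 * np.sqrt(rate * (1 - rate) / (n * est.detectable_fraction))
            assert abs(est.adjusted_rate - rate) < max(se, 2e-4)

    def test_raw_rate_underestimates_with_hkxhk_markers(self):
        cross, _ = _make_cross(62, n_sites=4_000, n_offspring=100)
        assert (cross.codes == HKXHK).sum() > 100  # composition has hk x hk
        pert, _ = inject_errors_and_missing(
            cross.offspring, 0.02, "uniform-swap", 0.0, seed=63
        )
        est = estimate_error_rate(CrossDataset(cross.parent1, cross.parent2, pert))
        assert est.raw_rate < 0.8 * est.adjusted_rate
        assert est.detectable_fraction < 1.0

    def test_allelic_dropout_model_recovery(self):
        cross, _ = _make_cross(64, n_sites=4_000, n_offspring=100)
        pert, _ = inject_errors_and_missing(
            cross.offspring, 0.03, "allelic-dropout", 0.0, seed=65
        )
        est = estimate_error_rate(
            CrossDataset(cross.parent1, cross.parent2, pert),
            error_model="allelic-dropout",
        )
        assert est.adjusted_rate == pytest.approx(0.03, abs=0.006)

    def test_singleton_fraction_bounds(self):
        cross, _ = _make_cross(66, n_sites=1_000, n_offspring=50)
        pert, _ = inject_errors_and_missing(
            cross.offspring, 0.01, "uniform-swap", 0.0, seed=67
        )
        est = estimate_error_rate(CrossDataset(cross.parent1, cross.parent2, pert))
        assert 0.0 <= est.singleton_fraction <= 1.0
        assert est.singleton_fraction > 0.5  # low rate: most hits are singletons

    def test_all_missing_raises(self):
        cross, _ = _make_cross(68, n_sites=50, n_offspring=5)
        cross.offspring.codes[:] = MISSING
        with pytest.raises(ValueError, match="no checkable"):
            estimate_error_rate(cross)


class TestSegregationDistortion:
    def test_balanced_counts_not_distorted(self):
        chi2, df, p, flag = segregation_distortion(LMXLL, [45, 45])
        assert chi2 == 0.0 and p == 1.0 and not flag

    def test_60_30_distorted(self):
        chi2, df, p, flag = segregation_distortion(LMXLL, [60, 30])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.001565402258, rel=1e-6)
        assert flag

    def test_50_44_not_distorted(self):
        chi2, df, p, flag = segregation_distortion(NNXNP, [50, 44])
        assert chi2 == pytest.approx(0.3829787234, rel=1e-6)
        assert p == pytest.approx(0.5360133695, rel=1e-6)
        assert not flag

    def test_wrong_code_raises(self):
        with pytest.raises(ValueError, match="lmxll/nnxnp"):
            segregation_distortion(HKXHK, [10, 10])

    def test_zero_counts_raise(self):
        with pytest.raises(ValueError, match="no non-missing"):
            segregation_distortion(LMXLL, [0, 0])

    def test_pvalues_calibrated_under_null(self):
        """1:1 segregation in an error-free cross: scan p-values follow
        the exact discrete null distribution (markers on separate
        chromosomes, so meioses are independent)."""
        n_off = 100
        cfg = SimConfig(seed=69, n_sites=1_000, n_samples=4, n_chrom=1_000,
                        chrom_len_bp=10_000)
        founders, _ = simulate_founders(cfg)
        cross = simulate_f1(founders, "S001", "S002", n_off, cfg)
        scan = distortion_scan(cross)
        assert len(scan) >= 300
        p = scan["p"].to_numpy()
        # exact null CDF of the p-value lattice under Binomial(n_off, 1/2)
        ks = np.arange(n_off + 1)
        pmf = sps.binom.pmf(ks, n_off, 0.5)
        p_of_k = np.array(
            [segregation_distortion(LMXLL, [x, n_off - x])[2] for x in ks]
        )
        levels = np.unique(p_of_k)
        ecdf = np.array([(p <= t).mean() for t in levels])
        theo = np.array([pmf[p_of_k <= t].sum() for t in levels])
        # DKW bound at alpha = 1e-3
        assert np.abs(ecdf - theo).max() < np.sqrt(np.log(2 / 1e-3) / (2 * len(p)))


class TestCollapseIdentical:
    def test_exact_duplicates_collapse(self):
        rng = np.random.default_rng(80)
        col = rng.integers(0, 3, size=50)
        other = rng.integers(0, 3, size=50)
        kept, groups = collapse_identical(make_matrix(np.column_stack([col, col, other])))
        assert len(kept) == 2
        assert sorted(len(g) for g in groups) == [1, 2]

    def test_96_of_100_identical_grouped(self):
        col = np.zeros(100, dtype=int)
        col2 = col.copy()
        col2[:4] = 1  # identical in 96/100 samples: 0.96 > 0.95
        kept, groups = collapse_identical(
            make_matrix(np.column_stack([col, col2])), 0.95
        )
        assert len(kept) == 1

    def test_keeps_least_missing_member(self):
        col = np.tile([0, 1, 2, 1], 25)
        col_missing = col.copy()
        col_missing[:3] = MISSING
        m = make_matrix(np.column_stack([col_missing, col]))
        kept, _ = collapse_identical(m, 0.9)
        assert list(kept) == [1]

    def test_random_distinct_matrix_all_kept(self):
        rng = np.random.default_rng(81)
        codes = rng.integers(0, 3, size=(200, 30))
        kept, groups = collapse_identical(make_matrix(codes), 0.95)
        assert len(kept) == 30


class TestJoinmapExport:
    def test_export_counts_and_codes(self, tmp_path):
        cross, _ = _make_cross(82, n_sites=300, n_offspring=20)
        path = tmp_path / "cross.loc"
        n = export_joinmap_cp(cross, str(path))
        expected = int(((cross.codes == LMXLL) | (cross.codes == NNXNP)).sum())
        assert n == expected
        text = path.read_text()
        assert f"nloc = {n}" in text and "popt = CP" in text
        assert "<lmxll>" in text and "<nnxnp>" in text
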