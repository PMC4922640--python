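import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, nbinom, poisson

from conftest import nb_count_matrix
from ramscan import (
    PipelineConfig,
    bh_adjust,
    estimate_common_dispersion,
    estimate_tagwise_dispersion,
    nb_exact_pvalue,
    norm_factors,
    run_differential,
    tmm_norm_factors,
)
from ramscan.windows import CountMatrix

GROUPS_6V6 = ["A"] * 6 + ["B"] * 6


def enumeration_pvalue(sum_a, sum_b, n_a, n_b, phi, mu=3.7):
    """Independent oracle: conditional split probabilities from the joint NB
    (or Poisson) pmfs at an arbitrary mean, normalized by their sum."""
    t = sum_a + sum_b
    a = np.arange(t + 1)
    if phi == 0:
        pa, pb = poisson.pmf(a, n_a * mu), poisson.pmf(t - a, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        pa = nbinom.pmf(a, r_a, r_a / (r_a + n_a * mu))
        pb = nbinom.pmf(t - a, r_b, r_b / (r_b + n_b * mu))
    pmf = pa * pb
    pmf /= pmf.sum()
    return min(1.0, 2 * min(pmf[: sum_a + 1].sum(), pmf[sum_a:].sum()))


class TestNormalization:
    def test_identical_samples_tmm_unity(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=500).astype(float)
        f = tmm_norm_factors(np.stack([col, col], axis=1), np.array([col.sum()] * 2))
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # B = 2*A everywhere: all M-values equal the library-size ratio, so
        # TMM factors stay 1 and the 2x lives in the effective sizes.
        rng = np.random.default_rng(1)
        a = rng.poisson(rng.gamma(10, 5, size=800)).astype(float) + 1
        counts = np.stack([a, 2 * a], axis=1)
        f = tmm_norm_factors(counts, counts.sum(axis=0))
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-9)

    def test_libsize_method_all_ones(self):
        cm = nb_count_matrix(np.random.default_rng(2), 50, 4, 30, 0.1)
        np.testing.assert_array_equal(norm_factors(cm, "libsize"), np.ones(4))

    def test_all_zero_sample_rejected(self):
        counts = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(counts, np.array([3.0, 1.0]))


class TestDispersion:
    def test_identical_counts_hit_lower_bound(self):
        counts = np.tile(np.arange(10)[:, None] * 5 + 20, (1, 12))
        cm = CountMatrix(
            windows=pd.DataFrame({"chrom": "c", "start": np.arange(10), "end": np.arange(10) + 1}),
            samples=[f"s{i}" for i in range(12)],
            counts=counts,
            lib_sizes=np.full(12, 1000.0),
        )
        assert estimate_common_dispersion(cm, GROUPS_6V6) == pytest.approx(1e-6, rel=1e-3)

    def test_recovery_at_truth(self):
        cm = nb_count_matrix(np.random.default_rng(10), 2000, 12, 50, 0.2)
        assert 0.15 <= estimate_common_dispersion(cm, GROUPS_6V6) <= 0.25

    def test_huge_prior_collapses_tagwise_onto_common(self):
        cm = nb_count_matrix(np.random.default_rng(11), 300, 12, 50, 0.2)
        common = estimate_common_dispersion(cm, GROUPS_6V6)
        tag = estimate_tagwise_dispersion(cm, GROUPS_6V6, common, prior_df=1e9)
        assert np.abs(tag - common).max() < 1e-6

    def test_outlier_window_shrunk_between_mle_and_common(self):
        cm = nb_count_matrix(np.random.default_rng(12), 300, 12, 50, 0.05)
        # one wildly overdispersed window
        cm.counts[0] = np.array([5, 200, 10, 150, 2, 90, 180, 8, 120, 4, 160, 20])
        common = estimate_common_dispersion(cm, GROUPS_6V6)
        unshrunk = estimate_tagwise_dispersion(cm, GROUPS_6V6, common, prior_df=1e-9)[0]
        shrunk = estimate_tagwise_dispersion(cm, GROUPS_6V6, common, prior_df=10)[0]
        assert common < shrunk < unshrunk

    def test_variance_ordering_preserved(self):
        rng = np.random.default_rng(13)
        cm = nb_count_matrix(rng, 100, 12, 50, 0.1)
        quiet = np.full(12, 50)
        noisy = np.array([20, 90, 30, 75, 15, 100, 85, 25, 95, 18, 70, 40])
        cm.counts[0], cm.counts[1] = quiet, noisy
        tag = estimate_tagwise_dispersion(cm, GROUPS_6V6, prior_df=10)
        assert tag[0] < tag[1]

    def test_invariant_to_sample_rescaling(self):
        """Tripling one sample's counts and library size is undone by
        equalization.  Invariance is near-exact, not exact: the common
        (geometric-mean) pseudo-library shifts by 3^(1/12), a global scale
        the NB likelihood is mildly sensitive to."""
        cm = nb_count_matrix(np.random.default_rng(14), 400, 12, 40, 0.15)
        phi1 = estimate_common_dispersion(cm, GROUPS_6V6)
        scaled = CountMatrix(
            windows=cm.windows, samples=cm.samples,
            counts=np.concatenate([cm.counts[:, :1] * 3, cm.counts[:, 1:]], axis=1),
            lib_sizes=np.concatenate([cm.lib_sizes[:1] * 3, cm.lib_sizes[1:]]),
        )
        assert estimate_common_dispersion(scaled, GROUPS_6V6) == pytest.approx(phi1, rel=0.05)

    def test_no_replication_anywhere_raises(self):
        cm = nb_count_matrix(np.random.default_rng(15), 10, 2, 50, 0.1)
        with pytest.raises(ValueError, match="fixed dispersion"):
            estimate_common_dispersion(cm, ["A", "B"])


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert nb_exact_pvalue(5, 5, 6, 6, 0.1) == 1.0

    def test_all_zero_gives_p_one(self):
        assert nb_exact_pvalue(0, 0, 6, 6, 0.3) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_pvalue(-1, 5, 6, 6, 0.1)

    @pytest.mark.parametrize("phi", [0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n_a, n_b = rng.integers(2, 7, size=2)
            t = int(rng.integers(1, 61))
            sa = int(rng.integers(0, t + 1))
            p = nb_exact_pvalue(sa, t - sa, int(n_a), int(n_b), phi)
            assert p == pytest.approx(enumeration_pvalue(sa, t - sa, int(n_a), int(n_b), phi), abs=1e-8)

    def test_smallp_rule_also_valid(self):
        # both two-sided rules agree for a symmetric design and are p-values
        p1 = nb_exact_pvalue(40, 10, 6, 6, 0.1, rule="doubling")
        p2 = nb_exact_pvalue(40, 10, 6, 6, 0.1, rule="smallp")
        assert 0 < p1 <= 1 and 0 < p2 <= 1
        assert p1 == pytest.approx(p2, rel=0.5)


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_ties(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_permutation_stable(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1, size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.001, 1, size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestDifferential:
    def test_null_calibration_and_uniformity(self):
        """Under the null the p-value distribution is approximately uniform
        (no excess of small p beyond KS slack for NB discreteness)."""
        cm = nb_count_matrix(np.random.default_rng(30), 2000, 12, 50, 0.1)
        res = run_differential(cm, GROUPS_6V6, ("A", "B"))
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        grid = np.linspace(0.001, 0.5, 100)
        excess = max((res["p"].to_numpy()[:, None] <= grid).mean(axis=0) - grid)
        assert excess < 1.63 / np.sqrt(len(res))  # KS 1% critical value

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(31)
        med_p = []
        for fc in (1.0, 2.0, 4.0):
            lam_a = rng.gamma(10, 5, size=(300, 6))
            lam_b = lam_a[:, :6] * fc
            counts = rng.poisson(np.concatenate([lam_a, lam_b], axis=1))
            cm = CountMatrix(
                windows=pd.DataFrame(
                    {"chrom": "c", "start": np.arange(300) * 50, "end": np.arange(300) * 50 + 100}
                ),
                samples=[f"s{i}" for i in range(12)],
                counts=counts,
                lib_sizes=np.full(12, counts.sum() / 12),
            )
            res = run_differential(cm, GROUPS_6V6, ("A", "B"), phi=0.1)
            med_p.append(np.median(res["p"]))
        assert med_p[0] > med_p[1] > med_p[2]

    def test_direction_convention(self):
        """hyper iff elevated in the second (higher-dose) group."""
        counts = np.array([[10] * 6 + [80] * 6, [80] * 6 + [10] * 6])
        cm = CountMatrix(
            windows=pd.DataFrame({"chrom": "c", "start": [0, 50], "end": [100, 150]}),
            samples=[f"s{i}" for i in range(12)],
            counts=counts,
            lib_sizes=np.full(12, 540.0),
        )
        res = run_differential(cm, GROUPS_6V6, ("A", "B"), phi=0.1)
        assert list(res["direction"]) == ["hyper", "hypo"]
        assert res["log2FC"].iloc[0] > 0 > res["log2FC"].iloc[1]
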