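"""Genetic risk score computation and instrument diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heightmr import grs
from heightmr.grs import (WeakInstrumentError, compute_grs,
                          direction_concordance, effect_slope,
                          variance_explained, zprime)


def make_weights(betas, eff="A", oth="G"):
    m = len(betas)
    return pd.DataFrame({
        "rsid": [f"rs{j}" for j in range(m)],
        "chr": ["1"] * m, "pos": list(range(100, 100 + m)),
        "effect_allele": [eff] * m, "other_allele": [oth] * m,
        "beta": betas,
    })


def make_genotypes(dosage_rows, m, counted="A", other="G"):
    dosages = pd.DataFrame(dosage_rows, columns=[f"rs{j}" for j in range(m)],
                           index=[f"P{i}" for i in range(len(dosage_rows))])
    alleles = pd.DataFrame({"variant_id": [f"rs{j}" for j in range(m)],
                            "counted_allele": [counted] * m,
                            "other_allele": [other] * m})
    return dosages, alleles


class TestComputeGrs:
    def test_hand_sum(self):
        w = make_weights([0.1, -0.2, 0.05])
        d, a = make_genotypes([[2.0, 1.0, 0.0]], 3)
        score, log = compute_grs(d, a, w)
        assert score.iloc[0] == pytest.approx(0.2 - 0.2 + 0.0)
        assert (log["status"] == "matched").all()

    def test_zero_weights_zero_score(self):
        w = make_weights([0.0, 0.0])
        d, a = make_genotypes([[2.0, 1.0], [0.0, 1.0]], 2)
        score, _ = compute_grs(d, a, w)
        assert (score == 0.0).all()

    def test_allele_flip_rule(self):
        # genotype file counts the other allele: contribution beta * (2 - d)
        w = make_weights([0.1])
        d, a = make_genotypes([[0.5]], 1, counted="G", other="A")
        score, log = compute_grs(d, a, w)
        assert score.iloc[0] == pytest.approx(0.1 * (2 - 0.5))
        assert log.loc[0, "status"] == "flipped"

    def test_flip_involution(self, small_cohort):
        """Swapping stored orientation (d -> 2-d) leaves scores identical."""
        co = small_cohort
        s1, _ = compute_grs(co.dosages, co.variant_alleles, co.weights)
        flipped = 2.0 - co.dosages
        alleles = co.variant_alleles.copy()
        alleles[["counted_allele", "other_allele"]] = alleles[
            ["other_allele", "counted_allele"]].to_numpy()
        s2, _ = compute_grs(flipped, alleles, co.weights)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_linearity_and_permutation(self, small_cohort):
        co = small_cohort
        s1, _ = compute_grs(co.dosages, co.variant_alleles, co.weights)
        w3 = co.weights.copy()
        w3["beta"] *= 3.0
        s3, _ = compute_grs(co.dosages, co.variant_alleles, w3)
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-12)
        perm = co.weights.sample(frac=1.0, random_state=5)
        sp, _ = compute_grs(co.dosages, co.variant_alleles, perm)
        # permutation reorders the float summation; equality up to rounding
        np.testing.assert_allclose(sp, s1, atol=1e-10)

    def test_missing_dosage_mean_imputed(self):
        w = make_weights([1.0])
        d, a = make_genotypes([[2.0], [0.0], [np.nan]], 1)
        score, _ = compute_grs(d, a, w)
        assert score.iloc[2] == pytest.approx(1.0)  # mean of {2, 0}

    def test_mismatch_dropped_and_hard_error(self):
        w = make_weights([0.5, 0.5], eff="A", oth="G")
        d, a = make_genotypes([[1.0, 1.0]], 2, counted="C", other="T")
        with pytest.raises(ValueError, match="unmatched"):
            compute_grs(d, a, w)
        # one mismatch out of three is tolerated and logged
        w3 = make_weights([0.5, 0.5, 0.5])
        d3, a3 = make_genotypes([[1.0, 1.0, 1.0]], 3)
        a3.loc[2, ["counted_allele", "other_allele"]] = ["C", "T"]
        score, log = compute_grs(d3, a3, w3)
        assert log.loc[2, "status"] == "dropped_allele_mismatch"
        assert score.iloc[0] == pytest.approx(1.0)


class TestVarianceExplained:
    def test_perfect_and_null(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=2000)
        assert variance_explained(h, h).r2 == pytest.approx(1.0)
        s = rng.normal(size=2000)
        assert variance_explained(s, h).r2 < 0.01

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=500)
        h = 0.4 * s + rng.normal(size=500)
        r = np.corrcoef(s, h)[0, 1]
        assert variance_explained(s, h).r2 == pytest.approx(r * r)

    def test_zero_variance_score(self):
        with pytest.raises(WeakInstrumentError):
            variance_explained(np.ones(10), np.arange(10.0))


class TestDirectionConcordance:
    def test_null_expectation(self):
        a = np.r_[np.ones(50), -np.ones(50)]
        b = np.ones(100)
        prop, p = direction_concordance(a, b)
        assert prop == 0.5 and p == pytest.approx(1.0)

    def test_full_concordance_far_tail(self):
        a = np.ones(100)
        prop, p = direction_concordance(a, a)
        # chi-square = 100 on 1 df
        assert prop == 1.0
        assert p == pytest.approx(stats.chi2.sf(100, 1))
        assert p < 2e-16

    def test_zeros_excluded_and_degenerate(self):
        prop, _ = direction_concordance([1.0, 0.0, -1.0, 2.0],
                                        [1.0, 1.0, 1.0, 2.0])
        assert prop == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            direction_concordance([0.0, 0.0], [1.0, 1.0])


class TestZprime:
    @pytest.mark.parametrize("beta, se, n, expected", [
        (2.0, 1.0, 100, 0.2),
        (0.0, 0.5, 10, 0.0),
        (0.385, 0.0286, 134_534, 0.0367),
    ])
    def test_formula(self, beta, se, n, expected):
        assert zprime(beta, se, n) == pytest.approx(expected, abs=5e-5)

    def test_scale_invariance(self):
        # rescaling the phenotype rescales beta and se together
        assert zprime(0.3, 0.1, 50) == pytest.approx(zprime(3.0, 1.0, 50))

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            zprime(1.0, 0.0, 10)


class TestEffectSlope:
    def test_identity_line(self):
        x = np.arange(10.0)
        fit = effect_slope(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(scale=0.1, size=10)
        fit = effect_slope(y, x)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(expected)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(-2, 2), st.integers(0, 1000))
    def test_shrinking_noise_limit(self, true_slope, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(-1, 1, 20)
        y = true_slope * x + rng.normal(scale=1e-9, size=20)
        assert effect_slope(y, x).slope == pytest.approx(true_slope, abs=1e-6)

    def test_zero_variance_x(self):
        with pytest.raises(ValueError):
            effect_slope([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestVcfRoundTrip:
    def test_write_then_read(self, small_cohort, tmp_path):
        co = small_cohort
        sub = co.dosages.iloc[:20, :10]
        variants = co.variant_alleles.iloc[:10]
        path = tmp_path / "dos.vcf"
        grs.write_dosages_vcf(sub, variants, path)
        dosages, alleles = grs.read_dosages_vcf(path)
        np.testing.assert_allclose(dosages.to_numpy(), sub.to_numpy(), atol=1e-4)
        assert list(alleles["counted_allele"]) == list(variants["counted_allele"])
        # scores agree through either representation
        s1, _ = compute_grs(sub, co.variant_alleles.iloc[:10],
                            co.weights.iloc[:10])
        s2, _ = compute_grs(dosages, alleles, co.weights.iloc[:10])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-3)
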