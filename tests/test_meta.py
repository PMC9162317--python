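"""Meta-analysis, heterogeneity, summary-statistic reconstruction, concordance."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heightmr import meta
from heightmr.meta import (StratumSpec, heterogeneity_two_strata, ivw_meta,
                           log10_p_from_z, p_from_z, se_from_or_ci, se_from_p,
                           stratified_mr, z_from_p)


class TestSeFromP:
    def test_unit_normal(self):
        # 2 (1 - Phi(1)) = 0.31731...
        assert se_from_p(1.0, 0.3173105078629141) == pytest.approx(1.0, rel=1e-9)

    def test_far_tail(self):
        # z for p = 2e-41 is about 13.48
        se = se_from_p(math.log(1.47), 2.0e-41)
        assert se == pytest.approx(0.0286, abs=2e-4)

    @pytest.mark.parametrize("beta, p", [(0.0, 0.5), (1.0, 0.0), (1.0, 1.0),
                                         (1.0, 1.5)])
    def test_invalid_inputs(self, beta, p):
        with pytest.raises(ValueError):
            se_from_p(beta, p)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=-300.0, max_value=-0.01))
    def test_round_trip_identity_log_space(self, log10_p):
        """se_from_p inverts the p-value map to 1e-12 relative, incl. p < 1e-250."""
        beta = 0.7
        se = se_from_p(beta, log10_p=log10_p)
        back = log10_p_from_z(beta / se)
        assert back == pytest.approx(log10_p, rel=1e-12)

    def test_round_trip_plain_p(self):
        for p in (0.9, 0.05, 1e-8, 1e-100, 1e-300):
            se = se_from_p(0.4, p)
            assert p_from_z(0.4 / se) == pytest.approx(p, rel=1e-10)


class TestIvwMeta:
    def test_single_stratum_identity(self):
        m = ivw_meta([0.3], [0.1])
        assert (m.beta, m.se, m.k) == (0.3, 0.1, 1)
        assert m.q == 0.0

    def test_equal_weight_average(self):
        m = ivw_meta([0.2, 0.4], [0.1, 0.1])
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1 / math.sqrt(2))

    def test_identical_strata_halve_variance(self):
        m = ivw_meta([0.25, 0.25], [0.08, 0.08])
        assert m.se == pytest.approx(0.08 / math.sqrt(2))
        assert m.q == pytest.approx(0.0)

    def test_combined_se_bounded_by_min(self):
        m = ivw_meta([0.1, 0.5, -0.2], [0.05, 0.2, 0.4])
        assert m.se <= 0.05

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.01, 1)),
                    min_size=2, max_size=6),
           st.floats(0.1, 10))
    def test_order_and_scale_invariance(self, pairs, c):
        betas = [b for b, _ in pairs]
        ses = [s for _, s in pairs]
        m = ivw_meta(betas, ses)
        m_rev = ivw_meta(betas[::-1], ses[::-1])
        assert m_rev.beta == pytest.approx(m.beta, rel=1e-9, abs=1e-12)
        assert m_rev.q == pytest.approx(m.q, rel=1e-9, abs=1e-12)
        m_sc = ivw_meta([c * b for b in betas], [c * s for s in ses])
        assert m_sc.beta == pytest.approx(c * m.beta, rel=1e-9, abs=1e-9)
        assert m_sc.se == pytest.approx(c * m.se, rel=1e-9)
        assert m_sc.q == pytest.approx(m.q, rel=1e-6, abs=1e-9)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            ivw_meta([0.1, 0.2], [0.1, 0.0])


class TestHeterogeneity:
    def test_equal_betas_p_one(self):
        _, p = heterogeneity_two_strata(0.3, 0.1, 0.3, 0.2)
        assert p == pytest.approx(1.0)

    def test_unit_se_example(self):
        z, p = heterogeneity_two_strata(0.0, 1.0, 2.771, 1.0)
        assert abs(z) == pytest.approx(2.771 / math.sqrt(2), rel=1e-6)
        assert p == pytest.approx(0.050, abs=1e-3)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-1, 1), st.floats(0.01, 1), st.floats(-1, 1),
           st.floats(0.01, 1))
    def test_equals_cochran_q_df1(self, b1, s1, b2, s2):
        _, p = heterogeneity_two_strata(b1, s1, b2, s2)
        m = ivw_meta([b1, b2], [s1, s2])
        assert p == pytest.approx(m.het_p, rel=1e-9, abs=1e-12)

    def test_published_af_by_chd_strata(self):
        """ORs 1.51 [1.43, 1.59] vs 1.39 [1.32, 1.46] -> heterogeneity p 0.03."""
        b1, s1 = math.log(1.51), se_from_or_ci(1.43, 1.59)
        b2, s2 = math.log(1.39), se_from_or_ci(1.32, 1.46)
        _, p = heterogeneity_two_strata(b1, s1, b2, s2)
        assert round(p, 2) == 0.03


class TestTable2Reconstruction:
    @pytest.mark.parametrize("ea, aa, expected_or", [
        ((1.47, 2.0e-41), (1.66, 1.3e-4), 1.48),  # varicose veins of lower extremity
        ((1.53, 5.7e-53), (1.35, 4.9e-3), 1.52),  # chronic ulcer of leg or foot
        ((1.47, 2.2e-64), (1.21, 2.9e-3), 1.44),  # corns and callosities
    ])
    def test_meta_or_from_printed_or_and_p(self, ea, aa, expected_or):
        betas = [math.log(ea[0]), math.log(aa[0])]
        ses = [se_from_p(betas[0], ea[1]), se_from_p(betas[1], aa[1])]
        assert round(ivw_meta(betas, ses).or_, 2) == expected_or


def _mk_results(phecodes, betas, ps, n=1000):
    return pd.DataFrame({
        "phecode": phecodes, "beta": betas, "se": np.full(len(betas), 0.1),
        "p": ps, "n_case": n, "n_control": n, "converged": True,
    })


class TestConcordanceSummary:
    def test_identical_sets(self):
        res = _mk_results([f"p{i}" for i in range(10)],
                          np.linspace(-0.5, 0.5, 10),
                          np.geomspace(1e-8, 0.5, 10))
        out = meta.concordance_summary(res, res, 1e-4, 1e-4)
        assert out["venn"]["a_only"] == out["venn"]["b_only"] == 0
        assert out["concordant_proportion"] == 1.0
        assert out["slope"] == pytest.approx(1.0)

    def test_hand_chisquare_18_of_20(self):
        """18/20 concordant: chi-square (36-20)^2/20 = 12.8, p = 3.5e-4."""
        rng = np.random.default_rng(4)
        beta_a = rng.uniform(0.2, 0.6, size=20)
        beta_b = beta_a.copy()
        beta_b[:2] *= -1
        a = _mk_results([f"p{i}" for i in range(20)], beta_a, np.full(20, 1e-9))
        b = _mk_results([f"p{i}" for i in range(20)], beta_b, np.full(20, 1e-9))
        out = meta.concordance_summary(a, b, 1e-4, 1e-4)
        assert out["concordant_proportion"] == pytest.approx(0.9)
        assert out["concordance_p"] == pytest.approx(stats.chi2.sf(12.8, 1),
                                                     rel=1e-9)
        assert out["concordance_p"] == pytest.approx(3.5e-4, abs=5e-5)

    def test_empty_join_errors(self):
        a = _mk_results(["p1"], [0.1], [0.01])
        b = _mk_results(["q1"], [0.1], [0.01])
        with pytest.raises(ValueError):
            meta.concordance_summary(a, b, 0.05, 0.05)


@pytest.fixture(scope="module")
def modified_cohort():
    """Cohort with one defining condition modifying a causal height effect.

    Membership M is independent Bernoulli(0.3); the outcome log-odds per SD of
    height is 0.6 in members and 0.0 in non-members; a second outcome has the
    same effect (0.3) in both strata.
    """
    from heightmr.simulate import PopulationSpec, SimConfig, generate_cohort
    from heightmr import grs as grs_mod

    cfg = SimConfig(n_individuals=20_000, n_variants=80, n_phecodes=2,
                    populations=(PopulationSpec("EA", 1.0, 1.0),), seed=21)
    co = generate_cohort(cfg, emit_icd=False, emit_measurements=False)
    rng = np.random.default_rng(22)
    h = co.height_cm
    z = (h - h.mean()) / h.std(ddof=0)
    member = rng.random(len(h)) < 0.3
    gamma = np.where(member, 0.6, 0.0)
    p_mod = 1 / (1 + np.exp(-(-1.2 + gamma * z)))
    p_same = 1 / (1 + np.exp(-(-1.2 + 0.3 * z)))
    status = pd.DataFrame({
        "411": member.astype(float),
        "800": (rng.random(len(h)) < p_mod).astype(float),
        "801": (rng.random(len(h)) < p_same).astype(float),
    }, index=h.index)
    scores, _ = grs_mod.compute_grs(co.dosages, co.variant_alleles, co.weights)
    return {"height": h, "grs": scores, "status": status,
            "covars": co.covariates[["age", "sex"]]}


class TestStratifiedMr:
    def test_detects_constructed_effect_modification(self, modified_cohort):
        mc = modified_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stratified_mr(mc["height"], mc["grs"], mc["status"],
                                mc["covars"], StratumSpec("CHD", ("411",)))
        het = out["heterogeneity"].set_index("phecode")
        assert het.loc["800", "het_p"] < 0.05        # true modification
        assert het.loc["801", "het_p"] > 0.001       # homogeneous effect
        # defining phecode never appears among the outcomes
        for side in ("with", "without"):
            assert "411" not in set(out[side]["phecode"])

    def test_empty_stratum_named_in_error(self, modified_cohort):
        mc = modified_cohort
        status = mc["status"].copy()
        status["411"] = 0.0
        with pytest.raises(ValueError, match="CHD"):
            stratified_mr(mc["height"], mc["grs"], status, mc["covars"],
                          StratumSpec("CHD", ("411",)))
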