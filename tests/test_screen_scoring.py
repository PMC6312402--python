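"""Enrichment arithmetic, null fitting, effect likelihood, permutations, QC."""

import numpy as np
import pandas as pd
import pytest

from evscreen.deconvolution import CountMatrix
from evscreen.errors import EvscreenError
from evscreen.screen_scoring import (
    NullModel,
    ScoringConfig,
    call_hits,
    combine_replicates,
    compute_enrichment,
    element_curves,
    fit_null,
    gene_effect,
    gene_effect_from_curve,
    permutation_pvalues,
    qc_concordance,
    qc_growth_vs_ev,
)


@pytest.fixture(scope="module")
def cfg():
    return ScoringConfig(n_permutations=200, rng_seed=0)


def _counts(small_library, treated, reference):
    return CountMatrix(pd.DataFrame(
        {"T": treated, "R": reference}, index=small_library.element_ids))


class TestEnrichment:
    def test_identical_columns_give_all_zero_rho(self, small_library, cfg):
        col = np.full(len(small_library), 200)
        enr = compute_enrichment(_counts(small_library, col, col), "T", "R",
                                 small_library, cfg)
        assert np.allclose(enr.rho, 0.0)

    def test_median_is_zero_after_centering(self, small_library, cfg):
        rng = np.random.default_rng(0)
        t = rng.integers(20, 2000, len(small_library))
        r = rng.integers(20, 2000, len(small_library))
        enr = compute_enrichment(_counts(small_library, t, r), "T", "R",
                                 small_library, cfg)
        assert abs(np.median(enr.rho)) < 1e-12

    def test_doubling_one_treated_count_adds_one_log2_unit(self, small_library, cfg):
        n = len(small_library)
        t, r = np.full(n, 400), np.full(n, 100)
        enr0 = compute_enrichment(_counts(small_library, t, r), "T", "R",
                                  small_library, cfg)
        t2 = t.copy()
        t2[5] *= 2
        enr1 = compute_enrichment(_counts(small_library, t2, r), "T", "R",
                                  small_library, cfg)
        eid = small_library.element_ids[5]
        delta = enr1.rho[eid] - enr0.rho[eid]
        # exactly log2((800+ps)/(400+ps)); pseudocount makes it ~1
        expect = np.log2((800 + cfg.pseudocount) / (400 + cfg.pseudocount))
        assert delta == pytest.approx(expect, abs=1e-12)

    def test_low_reference_counts_are_filtered(self, small_library, cfg):
        n = len(small_library)
        t = np.full(n, 100)
        r = np.full(n, 100)
        r[:7] = 9  # below low_count_min
        enr = compute_enrichment(_counts(small_library, t, r), "T", "R",
                                 small_library, cfg)
        assert len(enr.data) == n - 7 and enr.n_filtered == 7
        assert not set(small_library.element_ids[:7]) & set(enr.data.index)

    def test_swapping_samples_negates_rho_up_to_recentering(self, small_library, cfg):
        rng = np.random.default_rng(1)
        t = rng.integers(50, 3000, len(small_library))
        r = rng.integers(50, 3000, len(small_library))
        cm = _counts(small_library, t, r)
        fwd = compute_enrichment(cm, "T", "R", small_library, cfg)
        rev = compute_enrichment(cm, "R", "T", small_library, cfg)
        recentred = -(fwd.rho - np.median(-fwd.rho))  # negate, re-centre
        assert np.allclose(rev.rho, -fwd.rho - np.median(-fwd.rho), atol=1e-12)


class TestFitNull:
    def test_standard_normal_density_at_zero(self):
        rng = np.random.default_rng(42)
        null = fit_null(rng.normal(0, 1, 5000))
        assert null.pdf(np.array(0.0)) == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.10)
        # integrates to one on its grid
        assert np.trapezoid(null.density, null.grid) == pytest.approx(1.0, abs=1e-6)

    def test_translation_equivariance_of_argmax(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 0.5, 2000)
        n0 = fit_null(base)
        n1 = fit_null(base + 1.5)
        m0 = n0.grid[np.argmax(n0.density)]
        m1 = n1.grid[np.argmax(n1.density)]
        assert m1 - m0 == pytest.approx(1.5, abs=0.05)

    def test_degenerate_controls_warn_and_floor_bandwidth(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            null = fit_null(np.zeros(100))
        assert null.bandwidth > 0

    def test_too_few_controls_raise_helpfully(self):
        with pytest.raises(EvscreenError, match="control"):
            fit_null(np.zeros(10))


@pytest.fixture(scope="module")
def tight_null():
    rng = np.random.default_rng(3)
    return fit_null(rng.normal(0, 0.1, 5000))


class TestGeneEffect:
    def test_null_elements_give_near_zero_effect_and_score(self, tight_null, cfg):
        rng = np.random.default_rng(4)
        e, score = gene_effect(rng.normal(0, 0.1, 50), tight_null, cfg)
        assert abs(e) <= 0.1 and score < 3.0

    def test_recovers_a_planted_shift_with_full_efficacy(self, tight_null, cfg):
        # the "maximum plausible phenotype" estimator sits at or slightly
        # above the elements' common enrichment
        e, score = gene_effect([3.0] * 10, tight_null, cfg)
        assert e == pytest.approx(3.0, abs=0.2) and score > 50

    def test_matches_direct_grid_search_oracle(self, tight_null, cfg):
        """Independent (e, t) grid evaluation of the marginal likelihood."""
        rho = np.array([2.0, 2.5, 3.0, 1.8, 2.9])
        E = cfg.effect_grid
        T = np.linspace(0, 1, cfg.efficacy_grid_size)
        ll = np.empty(E.size)
        for j, e in enumerate(E):  # deliberate slow loop
            tot = 0.0
            for r in rho:
                tot += np.log(np.mean([tight_null.pdf(np.array(r - t * e)) for t in T]))
            ll[j] = tot
        oracle_e = E[np.argmax(ll)]
        got_e, got_score = gene_effect(rho, tight_null, cfg)
        assert got_e == pytest.approx(oracle_e, abs=1e-9)
        assert got_score == pytest.approx(max(0, 2 * (ll.max() - ll[E == 0][0])), rel=1e-9)

    def test_score_invariant_under_element_ordering(self, tight_null, cfg):
        rho = [0.5, -1.0, 2.2, 0.1]
        e_f, s_f = gene_effect(rho, tight_null, cfg)
        e_r, s_r = gene_effect(rho[::-1], tight_null, cfg)
        assert e_f == e_r and s_f == pytest.approx(s_r, rel=1e-12)

    def test_empty_gene_raises(self, tight_null, cfg):
        with pytest.raises(EvscreenError):
            gene_effect([], tight_null, cfg)


class TestPermutations:
    def test_p_bounds_and_null_score_near_one(self, cfg):
        rng = np.random.default_rng(5)
        null = fit_null(rng.normal(0, 1, 2000))
        curves = element_curves(rng.normal(0, 1, 500), null, cfg)
        p = permutation_pvalues({"g": (0.0, 10)}, curves, cfg)
        assert p["g"] > 0.5
        assert p["g"] >= 1.0 / (cfg.n_permutations + 1)

    def test_huge_observed_score_hits_the_add_one_floor(self, cfg):
        rng = np.random.default_rng(6)
        null = fit_null(rng.normal(0, 1, 2000))
        curves = element_curves(rng.normal(0, 1, 500), null, cfg)
        p = permutation_pvalues({"g": (1e6, 10)}, curves, cfg)
        assert p["g"] == pytest.approx(1.0 / (cfg.n_permutations + 1))


class TestCombineReplicates:
    def test_two_identical_replicates_double_the_score(self, cfg):
        rng = np.random.default_rng(8)
        null = fit_null(rng.normal(0, 0.2, 3000))
        curve = element_curves(np.array([2.0, 2.2, 1.9]), null, cfg).sum(axis=0)
        e1, s1 = gene_effect_from_curve(curve, cfg)
        e2, s2, _ = combine_replicates([curve, curve], cfg)
        assert e2 == e1 and s2 == pytest.approx(2 * s1)

    def test_opposite_effects_yield_symmetric_attenuated_evidence(self, cfg):
        """Discordant replicates (+2 vs -2) leave the combined curve mirror
        symmetric, so the effect's sign is unidentifiable and the combined
        score collapses relative to two concordant replicates."""
        from scipy import stats
        grid = np.round(np.arange(-20.0, 20.0 + 1e-9, 0.01), 10)
        dens = np.maximum(stats.norm.pdf(grid, scale=0.2), 1e-12)
        null = NullModel(grid=grid, density=dens / np.trapezoid(dens, grid),
                         bandwidth=0.2, n_controls=0)
        plus = element_curves(np.full(8, 2.0), null, cfg).sum(axis=0)
        minus = element_curves(np.full(8, -2.0), null, cfg).sum(axis=0)
        combined = plus + minus
        assert np.allclose(combined, combined[::-1], atol=1e-6)
        _, s_discordant, _ = combine_replicates([plus, minus], cfg)
        _, s_concordant, _ = combine_replicates([plus, plus], cfg)
        assert s_discordant <= 0.5 * s_concordant + 1e-6

    def test_single_replicate_is_identity(self, cfg):
        rng = np.random.default_rng(10)
        null = fit_null(rng.normal(0, 0.2, 3000))
        curve = element_curves(np.array([1.0, 1.5]), null, cfg).sum(axis=0)
        assert combine_replicates([curve], cfg)[:2] == gene_effect_from_curve(curve, cfg)

    def test_grid_mismatch_raises(self, cfg):
        with pytest.raises(EvscreenError, match="grid"):
            combine_replicates([np.zeros(321), np.zeros(100)], cfg)


class TestHitCalling:
    def _frame(self, effect, neg_log_p):
        return pd.DataFrame({"effect": [effect], "neg_log_p": [neg_log_p]},
                            index=["g"])

    @pytest.mark.parametrize("effect, nlp, cutoffs, hit, direction", [
        (-3.0, 2.0, (2.0, 1.5), True, "activator"),
        (-1.5, 9.0, (2.0, 1.5), False, "activator"),
        (2.0, 3.0, (2.0, 2.5), True, "suppressor"),   # inclusive >= +2
        (-2.0, 3.0, (2.0, 2.5), True, "activator"),   # inclusive <= -2
        (2.5, 1.5, (2.0, 1.5), False, "suppressor"),  # -log p must exceed, not equal
        (0.0, 9.0, (2.0, 1.5), False, "none"),
    ])
    def test_threshold_semantics(self, effect, nlp, cutoffs, hit, direction):
        cfg = ScoringConfig(effect_cutoff=cutoffs[0], logp_cutoff=cutoffs[1])
        out = call_hits(self._frame(effect, nlp), cfg)
        assert bool(out.loc["g", "hit"]) is hit
        assert out.loc["g", "direction"] == direction


class TestQC:
    def test_sample_against_itself_r2_is_one(self, small_library):
        col = np.random.default_rng(0).integers(1, 1000, len(small_library))
        cm = _counts(small_library, col, col)
        assert qc_concordance(cm, "T", "R") == pytest.approx(1.0)

    def test_high_depth_poisson_resamples_concordant(self, small_library):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(4, 1, len(small_library)))
        a, b = rng.poisson(mu * 50), rng.poisson(mu * 50)
        assert qc_concordance(_counts(small_library, a, b), "T", "R") > 0.95

    def test_permuted_pairing_destroys_concordance(self, small_library):
        rng = np.random.default_rng(2)
        mu = np.exp(rng.normal(4, 1.5, len(small_library)))
        a = rng.poisson(mu * 50)
        b = rng.permutation(rng.poisson(mu * 50))
        assert qc_concordance(_counts(small_library, a, b), "T", "R") < 0.2

    def test_growth_vs_ev_pairs_genes_and_reports_r(self):
        g = pd.DataFrame({"effect": [1.0, -1.0, 0.0], "score": [1, 2, 3]},
                         index=["a", "b", "c"])
        e = pd.DataFrame({"effect": [0.5, 0.5, -0.5], "score": [1, 2, 3]},
                         index=["a", "b", "c"])
        paired = qc_growth_vs_ev(g, e)
        assert len(paired) == 3 and "pearson_r" in paired.attrs
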