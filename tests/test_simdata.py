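"""Generative designs: moments, coding conventions, and the evaluation harness."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from beidc import BeConfig, SimulationDesign, evaluate, gen_example1, gen_example2, gen_example3, generate
from beidc.simdata import EXAMPLE2_EFFECTS, EXAMPLE3_POSITIONS, GENOTYPE_CUT


def trichotomized_corr(rho):
    """Oracle: Pearson correlation of two genotype codes cut from a bivariate
    normal with latent correlation ``rho`` at +/- the third quartile."""
    c = GENOTYPE_CUT
    cuts = [-np.inf, -c, c, np.inf]
    probs = np.empty((3, 3))
    mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def rect(a0, a1, b0, b1):
        hi = np.clip([a1, b1], -37, 37)
        lo0 = np.clip([a0, b1], -37, 37)
        lo1 = np.clip([a1, b0], -37, 37)
        lo = np.clip([a0, b0], -37, 37)
        return mvn.cdf(hi) - mvn.cdf(lo0) - mvn.cdf(lo1) + mvn.cdf(lo)

    for a in range(3):
        for b in range(3):
            probs[a, b] = rect(cuts[a], cuts[a + 1], cuts[b], cuts[b + 1])
    codes = np.array([0.0, 1.0, 2.0])
    mean = (probs.sum(axis=1) * codes).sum()
    exy = (probs * np.outer(codes, codes)).sum()
    var = (probs.sum(axis=1) * codes**2).sum() - mean**2
    return (exy - mean**2) / var


class TestExample1:
    def test_deterministic_and_seed_sensitive(self):
        X1, y1 = gen_example1(50, 10, seed=3)
        X2, y2 = gen_example1(50, 10, seed=3)
        X3, _ = gen_example1(50, 10, seed=4)
        assert np.array_equal(X1.values, X2.values) and np.array_equal(y1, y2)
        assert not np.array_equal(X1.values, X3.values)

    def test_marginal_moments(self):
        X, _ = gen_example1(10000, 10, seed=0)
        assert np.abs(X.values.mean(axis=0)).max() < 0.05
        assert np.abs(X.values.var(axis=0) - 1.0).max() < 0.07

    def test_pairwise_correlation_is_rho(self):
        X, _ = gen_example1(5000, 6, seed=1)
        r = np.corrcoef(X.values[:, 0], X.values[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_fourth_feature_marginally_silent(self):
        X, y = gen_example1(20000, 8, seed=2)
        assert abs(np.corrcoef(X.values[:, 3], y)[0, 1]) < 0.05

    def test_phenotype_construction_noise_free(self):
        X, y = gen_example1(100, 6, seed=5, noise_sd=0.0)
        v = X.values
        expected = 5 * v[:, 0] + 5 * v[:, 1] + 5 * v[:, 2] - 15 * np.sqrt(0.5) * v[:, 3]
        assert np.allclose(y, expected, atol=1e-12)

    def test_requires_four_features(self):
        with pytest.raises(ValueError):
            gen_example1(10, 3, seed=0)


class TestExample2:
    def test_genotype_frequencies(self):
        X, _ = gen_example2(10000, 500, seed=0)
        v = X.values
        freqs = [(v == g).mean() for g in (0.0, 1.0, 2.0)]
        assert freqs[0] == pytest.approx(0.25, abs=0.02)
        assert freqs[1] == pytest.approx(0.50, abs=0.02)
        assert freqs[2] == pytest.approx(0.25, abs=0.02)

    def test_cut_point_is_normal_third_quartile(self):
        assert GENOTYPE_CUT == pytest.approx(norm.ppf(0.75), abs=1e-12)

    def test_effect_table(self):
        assert EXAMPLE2_EFFECTS[400] == (0.8, 1.2)
        assert sorted(EXAMPLE2_EFFECTS) == [100, 200, 300, 400, 500]

    def test_additive_dominant_recoding_noise_free(self):
        """With zero noise, y must reproduce the additive/dominant recodings:
        additive maps genotype (2,1,0) -> (1,0,-1), dominant maps Aa -> 1."""
        X, y = gen_example2(300, 500, seed=7, noise_sd=0.0)
        v = X.values
        expected = np.zeros(300)
        for pos, (ba, bd) in EXAMPLE2_EFFECTS.items():
            col = v[:, pos - 1]
            expected += ba * (col - 1.0) + bd * (col == 1.0)
        assert np.allclose(y, expected, atol=1e-12)

    def test_minimum_dimension(self):
        with pytest.raises(ValueError):
            gen_example2(100, 400, seed=0)


class TestExample3:
    def test_latent_autocorrelation_via_genotype_oracle(self):
        """Adjacent genotype columns inherit a Pearson correlation fixed by the
        latent AR parameter; compare with the trichotomized-normal oracle."""
        X, _ = gen_example3(20000, 1000, seed=1)
        v = X.values
        adj = np.mean([np.corrcoef(v[:, j], v[:, j + 1])[0, 1] for j in range(20)])
        assert adj == pytest.approx(trichotomized_corr(0.2), abs=0.03)
        far = np.corrcoef(v[:, 0], v[:, 500])[0, 1]
        assert abs(far) < 0.03

    def test_betas_within_uniform_bounds_noise_free(self):
        X, y = gen_example3(4000, 1000, seed=3, noise_sd=0.0)
        v = X.values
        # recover each class effect from the indicator model: the effect of
        # genotype 2 is exactly twice that of genotype 1
        cols = [v[:, pos - 1] for pos in EXAMPLE3_POSITIONS]
        design = np.column_stack([c for col in cols for c in ((col == 1.0), (col == 2.0))])
        coef = np.linalg.lstsq(design.astype(float), y, rcond=None)[0]
        b1 = coef[0::2]
        b2 = coef[1::2]
        assert np.allclose(b2, 2 * b1, atol=1e-8)
        assert np.all((b1 >= 2.0) & (b1 <= 3.0))

    def test_betas_redrawn_per_replicate(self):
        d = SimulationDesign("example3", n=50, p=1000, seed=9, noise_sd=0.0)
        _, y1 = generate(d, 0)
        _, y2 = generate(d, 1)
        assert not np.array_equal(y1, y2)


class TestEvaluate:
    def test_strict_power_bounded_by_individual(self):
        d = SimulationDesign("example1", n=60, p=20, seed=5)
        rep = evaluate("dcsis", d, 4, fixed_d=5, compute_mspe=False)
        assert rep.strict_power <= min(rep.individual_power.values())
        assert all(0.0 <= v <= 1.0 for v in rep.individual_power.values())

    def test_fixed_d_required_for_screening(self):
        d = SimulationDesign("example1", n=60, p=20, seed=5)
        with pytest.raises(ValueError):
            evaluate("dcsis", d, 2)
        with pytest.raises(ValueError):
            evaluate("nope", d, 2, fixed_d=3)
        with pytest.raises(ValueError):
            evaluate("dcsis", d, 0, fixed_d=3)

    def test_idcsis_truncated_cap_matches_full_run(self):
        """The fixed-d shortcut must reproduce the full-cap top-d exactly."""
        from beidc import IterationSchedule, idcsis_rank
        from beidc.simdata import _truncated_schedule
        d = SimulationDesign("example1", n=80, p=30, seed=2)
        X, y = generate(d, 0)
        full = idcsis_rank(X.values, y, IterationSchedule((3, 3), 27))
        short = idcsis_rank(X.values, y, _truncated_schedule(IterationSchedule((3, 3), 27), 7))
        assert np.array_equal(full.order[:7], short.order[:7])

    def test_beidc_end_to_end_small(self):
        d = SimulationDesign("example1", n=60, p=12, seed=6)
        cfg = BeConfig(n_bootstrap=10, seed=3)
        rep = evaluate("beidc", d, 2, config=cfg, compute_mspe=True)
        assert rep.n_replicates == 2
        assert np.isfinite(rep.cv_mspe)
        assert rep.average_threshold >= 1
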