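"""Per-protein mixed-model estimation and the P-value profile conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beepop as bp
from beepop.design import BlockDesign, SampleUnit
from beepop.lme import _design_arrays, _onehot

from conftest import make_matrix


def small_design():
    """4 populations x 1 colony, 4 blocks: every sample placed, valid."""
    roster = [bp.PopulationSpec(n, 1, 0.0) for n in "ABCD"]
    return bp.generate_design(bp.enumerate_samples(roster), seed=1)


class TestObservationFilter:
    def make(self, obs_blocks, n_blocks=58):
        vals = np.full((1, n_blocks * 3), np.nan)
        vals[0, : obs_blocks * 3] = 1.0
        return make_matrix(vals, block_ids=[f"b{i:02d}" for i in range(1, n_blocks + 1)])

    def test_14_of_58_blocks_retained(self):
        assert len(bp.filter_by_observation(self.make(14))) == 1

    def test_13_of_58_blocks_dropped(self):
        assert len(bp.filter_by_observation(self.make(13))) == 0

    def test_zero_fraction_is_identity(self):
        mat = self.make(1)
        assert len(bp.filter_by_observation(mat, min_fraction=0.0)) == 1


class TestPvalueConversions:
    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, 0.5), (1.959964, 0.975), (-1.959964, 0.025)],
    )
    def test_one_sided_p_is_normal_cdf(self, z, expected):
        p1 = bp.one_sided_pvalues(np.array([z]), np.array([1.0]))
        assert p1[0] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("p1,p2", [(0.5, 1.0), (0.975, 0.05), (0.025, 0.05)])
    def test_two_sided_examples(self, p1, p2):
        assert bp.two_sided_from_one_sided(np.array([p1]))[0] == pytest.approx(p2)

    def test_p2_identity_on_grid(self):
        grid = np.linspace(0.0, 1.0, 1001)
        p2 = bp.two_sided_from_one_sided(grid)
        np.testing.assert_allclose(p2, 1 - 2 * np.abs(grid - 0.5), atol=0)
        assert p2.min() >= 0.0 and p2.max() <= 1.0


class TestFitProteinLME:
    def test_degenerate_noise_free_data_gives_population_means_exactly(self):
        design = small_design()
        truth = bp.make_ground_truth(
            design, 1, seed=0, effect_sd=1.0, frac_differential=1.0,
            block_sd=0.0, label_sd=0.0, colony_sd=0.0, residual_sd=0.0,
            missing_prob=0.0,
        )
        mat = bp.simulate_ratio_matrix(design, truth, seed=0)
        fit = bp.fit_protein_lme(mat.iloc[0], design)
        assert fit.method == "ols"
        order = [truth.populations.index(p) for p in fit.populations]
        np.testing.assert_allclose(
            fit.effects, truth.population_effect[0][order], atol=1e-9
        )

    def test_effects_sum_to_zero_and_p2_identity(self, study_design):
        truth = bp.make_ground_truth(study_design, 5, seed=2, frac_differential=1.0)
        mat = bp.simulate_ratio_matrix(study_design, truth, seed=3)
        norm = bp.label_standardize(bp.block_center(mat))
        fits, failed = bp.fit_matrix(norm, study_design)
        assert not failed
        for f in fits:
            assert abs(np.nansum(f.effects)) < 1e-9
            np.testing.assert_allclose(
                f.p2, 1 - 2 * np.abs(f.p1 - 0.5), atol=1e-12
            )

    def test_gls_oracle_on_tiny_instance(self):
        """Fixed effects must equal direct GLS at the REML variance estimates."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        # 2 populations x 2 colonies, 2 blocks of 3 samples
        blocks = (
            (
                (SampleUnit("A-c1", "A", 1), "light"),
                (SampleUnit("A-c2", "A", 1), "medium"),
                (SampleUnit("B-c1", "B", 1), "heavy"),
            ),
            (
                (SampleUnit("A-c1", "A", 2), "medium"),
                (SampleUnit("B-c1", "B", 2), "light"),
                (SampleUnit("B-c2", "B", 1), "heavy"),
            ),
        )
        design = BlockDesign(blocks)
        rng = np.random.default_rng(8)
        cols = pd.MultiIndex.from_tuples(
            [(b, lab) for b, blk in zip(design.block_ids, blocks) for _, lab in blk],
            names=["block_id", "channel"],
        )
        y = pd.Series(rng.normal(size=6), index=cols, name="P0001")
        fit = bp.fit_protein_lme(y, design)

        colony, pop, block, label = _design_arrays(y.index, design)
        pops = sorted(set(pop))
        P = _onehot(np.array([pops.index(p) for p in pop]), 2)
        S = P[:, :1] - P[:, 1:]
        ub, binv = np.unique(block, return_inverse=True)
        ul, linv = np.unique(label, return_inverse=True)
        X = np.column_stack(
            [np.ones(6), _onehot(binv, len(ub))[:, 1:], _onehot(linv, len(ul))[:, 1:], S]
        )
        res = MixedLM(y.to_numpy(), X, groups=colony).fit(reml=True)
        Z = _onehot(np.unique(colony, return_inverse=True)[1], len(set(colony)))
        V = res.scale * np.eye(6) + float(np.asarray(res.cov_re)[0, 0]) * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy())
        coded = beta[-1]
        expected = np.array([coded, -coded])
        got = np.array([fit.effects[list(fit.populations).index(p)] for p in pops])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_too_few_blocks_raises_fit_error(self):
        design = small_design()
        vals = np.full((1, design.n_blocks * 3), np.nan)
        vals[0, :3] = [0.1, 0.2, 0.3]
        mat = make_matrix(vals, block_ids=design.block_ids)
        with pytest.raises(bp.FitError):
            bp.fit_protein_lme(mat.iloc[0], design)


class TestSignificanceTable:
    def fits(self, pvals, effects):
        pops = ("A", "B")
        return [
            bp.LMEFit(
                protein_id=f"P{i}", populations=pops,
                effects=np.array(e, float), ses=np.ones(2),
                factor_pvalue=p, p1=np.array([0.5, 0.5]), p2=np.array([1.0, 1.0]),
                n_blocks_observed=10,
            )
            for i, (p, e) in enumerate(zip(pvals, effects))
        ]

    def test_strict_threshold_excludes_exact_alpha(self):
        fits = self.fits([0.05, 0.049], [(1, -1), (1, -1)])
        table = bp.significance_table(fits, alpha=0.05)
        assert table.significant_ids() == {"P1"}

    def test_zero_effect_joins_neither_direction(self):
        fits = self.fits([0.01], [(0.0, 0.0)])
        table = bp.significance_table(fits)
        assert table.up["A"] == set() and table.down["A"] == set()

    def test_directions_partition(self):
        fits = self.fits([0.01, 0.02], [(1.0, -1.0), (-0.5, 0.5)])
        table = bp.significance_table(fits)
        assert table.up["A"] == {"P0"} and table.down["A"] == {"P1"}
        assert table.up["B"] == {"P1"} and table.down["B"] == {"P0"}
        for p in ("A", "B"):
            assert not (table.up[p] & table.down[p])
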