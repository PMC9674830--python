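"""Strip back-calculation, R-factor, decomposition, witnesses, greedy global."""

import numpy as np
import pytest

from qhelix.comand import (
    SelectionConfig,
    Strip,
    StripBackcalcParams,
    StripContext,
    _r_factor_rows,
    back_calculate_strip,
    decompose_strip,
    default_grid,
    greedy_global,
    r_factor,
    witness_strips,
)
from qhelix.gmm import select_k
from qhelix.synthetic import default_assignments, synth_strips


@pytest.fixture(scope="module")
def pool_profiles(planted_mixture, planted_strips):
    strip = planted_strips.strips[0]
    ctx = StripContext(
        planted_mixture.ensemble,
        (8, "HE21"),
        planted_strips.assignments,
        planted_strips.params,
        strip.ppm_grid,
    )
    return ctx.pool_profiles(planted_mixture.ensemble)


def minimal_ensemble(contributors):
    """Owner He21 at the origin plus ALA HA contributors at given offsets.

    contributors: list of (res_id, offset_vector).
    """
    import biotite.structure as struc
    from qhelix.ensemble import Ensemble

    atoms = [
        struc.Atom(np.zeros(3), chain_id="A", res_id=50, res_name="GLN",
                   atom_name="HE21", element="H", hetero=False)
    ]
    for rid, off in contributors:
        atoms.append(
            struc.Atom(np.asarray(off, float), chain_id="A", res_id=rid,
                       res_name="ALA", atom_name="HA", element="H", hetero=False)
        )
    return Ensemble.from_frames([struc.array(atoms)])


class TestBackCalculation:
    def test_r_minus_six_peak_ratio(self):
        """Two contributors at r and 2r give a 64-fold peak-intensity ratio."""
        ens = minimal_ensemble([(1, [2.0, 0, 0]), (2, [0, 4.0, 0])])
        asg = {(1, "HA"): 50.0, (2, "HA"): 40.0}
        strip = back_calculate_strip(ens, (50, "HE21"), asg)
        i40 = strip.intensity[np.argmin(np.abs(strip.ppm_grid - 40.0))]
        i50 = strip.intensity[np.argmin(np.abs(strip.ppm_grid - 50.0))]
        assert i50 / i40 == pytest.approx(64.0, rel=0.01)

    def test_lorentzian_halfwidth_on_grid(self):
        """A single contributor renders with FWHM 14 Hz = 0.070 ppm at 201.2 MHz."""
        ens = minimal_ensemble([(1, [3.0, 0, 0])])
        strip = back_calculate_strip(ens, (50, "HE21"), {(1, "HA"): 30.0})
        half = strip.intensity.max() / 2.0
        above = strip.ppm_grid[strip.intensity >= half]
        width = above.max() - above.min()
        assert width == pytest.approx(14.0 / 201.2, abs=0.012)

    def test_empty_contributor_set_gives_zero_strip(self):
        ens = minimal_ensemble([(1, [20.0, 0, 0])])  # beyond the 6 A cap
        strip = back_calculate_strip(
            ens, (50, "HE21"), {(1, "HA"): 30.0},
        )
        assert np.allclose(strip.intensity, 0.0)

    def test_unassigned_contributor_rejected(self, helix_llllq):
        asg = default_assignments(helix_llllq)
        asg.pop((8, "HB2"))
        with pytest.raises(ValueError, match="HB2"):
            back_calculate_strip(helix_llllq, (8, "HE21"), asg)

    def test_distant_contributors_ignored(self, helix_llllq):
        """Only protons within the 6 A cap contribute."""
        asg = default_assignments(helix_llllq)
        ctx = StripContext(
            helix_llllq, (8, "HE21"), asg, StripBackcalcParams()
        )
        coords = helix_llllq.stack.coord[0]
        owner = helix_llllq.atom_index(8, "HE21")
        d = np.linalg.norm(coords[ctx.contrib_idx] - coords[owner], axis=1)
        assert d.max() <= 6.0

    def test_grid_is_descending_and_covers_shifts(self):
        asg = {(1, "HA"): 50.0, (1, "HB2"): 30.0}
        grid = default_grid(asg)
        assert np.all(np.diff(grid) < 0)
        assert grid.max() >= 50.0 and grid.min() <= 30.0


class TestRFactor:
    def test_identity_and_scale_invariance(self, planted_strips):
        strip = planted_strips.strips[0]
        assert r_factor(strip, strip) == 0.0
        assert r_factor(strip.intensity, 2.0 * strip.intensity) == pytest.approx(0.0)

    def test_matches_scale_grid_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = np.abs(rng.normal(size=200))
            c = np.abs(rng.normal(size=200))
            mine = r_factor(y, c)
            scales = np.linspace(0.0, 10.0, 200001)
            brute = (
                np.abs(y[None, :] - scales[:, None] * c[None, :]).sum(axis=1).min()
                / np.abs(y).sum()
            )
            assert mine == pytest.approx(brute, abs=1e-6)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            r_factor(np.zeros(10), np.ones(10))

    def test_vectorized_rows_match_scalar(self):
        rng = np.random.default_rng(1)
        y = np.abs(rng.normal(size=150))
        calc = np.abs(rng.normal(size=(20, 150)))
        rows = _r_factor_rows(y, calc)
        for i in range(20):
            assert rows[i] == pytest.approx(r_factor(y, calc[i]), abs=1e-12)


class TestDecomposeStrip:
    def test_planted_conformer_recovered(self, diverse_pool):
        strips = synth_strips(diverse_pool.ensemble, owners=[(8, "HE21")], seed=3)
        ctx = StripContext(
            diverse_pool.ensemble, (8, "HE21"), strips.assignments,
            strips.params, strips.strips[0].ppm_grid,
        )
        profiles = ctx.pool_profiles(diverse_pool.ensemble)
        planted = 17
        obs = Strip((8, "HE21"), strips.strips[0].ppm_grid, profiles[planted])
        res = decompose_strip(obs, profiles, SelectionConfig(n_trials=60, seed=5))
        frac = np.mean(
            [planted in t for t, keep in zip(res.trials, res.retained) if keep]
        )
        assert frac >= 0.95
        assert res.r_min <= 1e-9

    def test_huge_threshold_gives_single_conformers(self, pool_profiles, planted_strips):
        cfg = SelectionConfig(improvement_threshold=10.0, n_trials=10, seed=1)
        res = decompose_strip(planted_strips.strips[0], pool_profiles, cfg)
        assert all(len(t) == 1 for t in res.trials)

    def test_mixture_fraction_recovery(self, planted_mixture, planted_strips,
                                       pool_profiles):
        res = decompose_strip(
            planted_strips.strips[0], pool_profiles,
            SelectionConfig(n_trials=60, seed=7),
        )
        labels = planted_mixture.labels
        lab8 = labels[labels.res_id == 8].set_index("frame")["label"] == "mt"
        mt = float(np.mean(lab8.loc[res.pooled].to_numpy()))
        assert mt == pytest.approx(0.8, abs=0.1)

    def test_deterministic_under_seed(self, pool_profiles, planted_strips):
        cfg = SelectionConfig(n_trials=5, seed=3)
        a = decompose_strip(planted_strips.strips[0], pool_profiles, cfg)
        b = decompose_strip(planted_strips.strips[0], pool_profiles, cfg)
        assert a.trials == b.trials
        assert np.array_equal(a.trial_r, b.trial_r)

    def test_small_pool_rejected(self, planted_strips):
        with pytest.raises(ValueError, match="seed pool"):
            decompose_strip(
                planted_strips.strips[0], np.ones((5, planted_strips.strips[0].ppm_grid.size)),
                SelectionConfig(),
            )


class TestWitnessStrips:
    def test_own_strip_included_far_residue_excluded(self, diverse_pool):
        strips = synth_strips(
            diverse_pool.ensemble, owners=[(8, "HE21"), (5, "HE21")], seed=3
        )
        w8 = witness_strips(8, diverse_pool.ensemble, strips.strips)
        assert 0 in w8  # strip owned by residue 8 itself
        # exhaustive distance scan oracle
        for k, strip in enumerate(strips.strips):
            owner = diverse_pool.ensemble.atom_index(*strip.owner)
            sc = [
                int(i)
                for i in np.flatnonzero(
                    (diverse_pool.ensemble.res_ids == 8)
                    & (diverse_pool.ensemble.stack.element == "H")
                    & (diverse_pool.ensemble.atom_names != "H")
                )
            ]
            dmin = min(
                np.linalg.norm(
                    diverse_pool.ensemble.stack.coord[f, sc]
                    - diverse_pool.ensemble.stack.coord[f, owner],
                    axis=1,
                ).min()
                for f in range(diverse_pool.ensemble.n_frames)
            )
            assert (k in w8) == (dmin <= 6.0)


class TestGreedyGlobal:
    def test_planted_single_conformer_and_monotone_trace(self, diverse_pool):
        ens = diverse_pool.ensemble
        strips = synth_strips(ens, owners=[(8, "HE21")], seed=3)
        ctx = StripContext(
            ens, (8, "HE21"), strips.assignments, strips.params,
            strips.strips[0].ppm_grid,
        )
        planted = 17
        prof = ctx.frame_profile(ens.frame(planted).coord)
        obs = [Strip((8, "HE21"), strips.strips[0].ppm_grid, prof)]
        pts = diverse_pool.labels[diverse_pool.labels.res_id == 8][
            ["chi1", "chi2"]
        ].to_numpy()
        model = select_k(pts, 5)
        res = greedy_global(
            ens, obs, {8: (model, 75.0)}, strips.assignments, strips.params,
            SelectionConfig(seed=3), n_repeats=3,
        )
        assert res.member_sources[0] == planted
        assert np.all(np.diff(res.r_trace) < 0) or len(res.r_trace) == 1
        assert res.repeat_r.size == 3
        assert res.repeat_r[res.best_repeat] == res.repeat_r.min()

    def test_sidechain_resampling_can_lower_r(self, diverse_pool):
        """An off-pool side-chain target is approached by GMM resampling."""
        ens = diverse_pool.ensemble
        strips = synth_strips(ens, owners=[(8, "HE21")], seed=3)
        ctx = StripContext(
            ens, (8, "HE21"), strips.assignments, strips.params,
            strips.strips[0].ppm_grid,
        )
        from qhelix.builder import set_chi

        target = ens.frame(17).copy()
        set_chi(target, 8, 1, -75.0)
        set_chi(target, 8, 2, 160.0)
        obs = [Strip((8, "HE21"), strips.strips[0].ppm_grid,
                     ctx.frame_profile(target.coord))]
        pts = diverse_pool.labels[diverse_pool.labels.res_id == 8][
            ["chi1", "chi2"]
        ].to_numpy()
        model = select_k(pts, 5)
        res = greedy_global(
            ens, obs, {8: (model, 75.0)}, strips.assignments, strips.params,
            SelectionConfig(seed=5), n_repeats=4,
        )
        base = _r_factor_rows(
            obs[0].intensity, ctx.pool_profiles(ens)
        ).min()
        assert res.repeat_r.min() <= base + 1e-12
        assert np.all(np.diff(res.r_trace) < 0) or len(res.r_trace) <= 1
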