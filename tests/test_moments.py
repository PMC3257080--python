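"""Second-order hydrophobic moment profiles, transitions, correlations."""

import numpy as np
import pytest

from hydromoment.moments import (
    MomentProfile,
    default_p_grid,
    moment_profile,
    profile_correlation,
    threshold_sweep,
    transition_point,
)
from hydromoment.sasa import AccessibilityProfile, atom_asa
from hydromoment.shape import center_of_mass
from hydromoment.structure import AtomSite, ResidueUnit, StructureModel
from hydromoment.synthetic import GlobuleSpec, make_globule, make_shell_case


def chain_at(coords, resnames=None):
    coords = np.asarray(coords, dtype=float)
    resnames = resnames or ["GLY"] * len(coords)
    residues = []
    for i, (c, name) in enumerate(zip(coords, resnames)):
        a = AtomSite("CA", "C", c)
        a.residue_index = i
        residues.append(ResidueUnit(name, i + 1, [a]))
    return StructureModel("points", residues)


def accessibility_of(structure, p_percent):
    """Profile with prescribed relative accessibilities (areas unused)."""
    n = structure.n_residues
    asa = np.zeros((n, 3))
    prof = AccessibilityProfile(structure.id, asa, 0.3)
    prof.p_percent = np.asarray(p_percent, dtype=float)
    return prof


def profile_on(grid, h2):
    grid = np.asarray(grid, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    return MomentProfile("x", "s", grid, np.ones(len(grid), dtype=int), h2)


def naive_H2(structure, p_percent, h_norm, p_grid):
    """Independent brute-force re-implementation: re-filters the residue
    set from scratch at every cutoff with explicit python loops."""
    com = structure.centroids().mean(axis=0)
    out = []
    for cutoff in p_grid:
        total, n = 0.0, 0
        for i, res in enumerate(structure.residues):
            if p_percent[i] <= cutoff or cutoff >= 100.0:
                d2 = float(np.sum((res.centroid - com) ** 2))
                total += h_norm[i] * d2
                n += 1
        out.append(total / n if n else np.nan)
    return np.array(out)


class TestMomentProfile:
    def test_two_residue_arithmetic(self):
        # residues at d = 2 and 1 from the centre of mass with
        # h' = (+1, -1): H2 = (1*2^2 - 1*1^2) / 2 = 1.5; a third
        # far-out residue with h' = 0 pins the centre of mass at the
        # origin without contributing to the collected sum
        chain = chain_at([(2.0, 0, 0), (1.0, 0, 0), (-3.0, 0, 0)])
        assert np.allclose(center_of_mass(chain), 0.0)
        acc = accessibility_of(chain, [0.0, 0.0, 200.0])
        prof = moment_profile(chain, acc, np.array([1.0, -1.0, 0.0]),
                              p_grid=[50.0, 100.0])
        # collected at 50%: residues with d = 2 and 1, h' = +1, -1
        assert prof.n_p[0] == 2
        assert prof.H2[0] == pytest.approx((4.0 - 1.0) / 2)

    def test_zero_scale(self, globule100):
        areas = atom_asa(globule100, 1.4, 480)
        from hydromoment.sasa import residue_asa_split, relative_accessibility
        prof = residue_asa_split(globule100, areas, 0.3)
        prof = relative_accessibility(
            globule100, prof, {r.resname: 243.0 for r in globule100.residues}
        )
        mp = moment_profile(globule100, prof,
                            np.zeros(globule100.n_residues))
        defined = ~np.isnan(mp.H2)
        np.testing.assert_allclose(mp.H2[defined], 0.0, atol=1e-12)

    def test_cumulative_collection_and_endpoint(self):
        rng = np.random.default_rng(2)
        chain = chain_at(rng.normal(size=(40, 3)) * 5)
        p = rng.uniform(0, 110, size=40)
        h = rng.normal(size=40)
        mp = moment_profile(chain, accessibility_of(chain, p), h)
        assert np.all(np.diff(mp.n_p) >= 0)
        assert mp.n_p[-1] == chain.n_residues  # everything at 100%
        com = center_of_mass(chain)
        d2 = np.sum((chain.centroids() - com) ** 2, axis=1)
        assert mp.H2[-1] == pytest.approx(np.mean(h * d2))

    def test_undefined_points_are_nan(self):
        chain = chain_at([(0, 0, 0), (4, 0, 0)])
        mp = moment_profile(chain, accessibility_of(chain, [90.0, 95.0]),
                            np.array([1.0, -1.0]), p_grid=[10.0, 100.0])
        assert np.isnan(mp.H2[0]) and mp.n_p[0] == 0
        assert np.isfinite(mp.H2[1])

    def test_coordinate_scaling_law(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(25, 3)) * 4
        p = rng.uniform(0, 100, size=25)
        h = rng.normal(size=25)
        base = moment_profile(chain_at(coords),
                              accessibility_of(chain_at(coords), p), h)
        c = 3.0
        scaled = moment_profile(chain_at(c * coords),
                                accessibility_of(chain_at(c * coords), p), h)
        defined = ~np.isnan(base.H2)
        np.testing.assert_allclose(
            scaled.H2[defined], c**2 * base.H2[defined], rtol=1e-9
        )
        assert profile_correlation(base, scaled) == pytest.approx(1.0)

    def test_against_naive_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 20
            chain = chain_at(rng.normal(size=(n, 3)) * 8)
            p = rng.uniform(0, 105, size=n)
            h = rng.normal(size=n)
            grid = default_p_grid()
            mp = moment_profile(chain, accessibility_of(chain, p), h, grid)
            expected = naive_H2(chain, p, h, grid)
            np.testing.assert_allclose(mp.H2, expected, atol=1e-10)


class TestTransitionPoint:
    def test_simple_crossing(self):
        prof = profile_on([0, 20, 40, 60], [5.0, 1.0, -2.0, -3.0])
        chain = chain_at([(1, 0, 0), (-1, 0, 0)])
        p_t, _ = transition_point(prof, accessibility_of(chain, [0, 0]),
                                  chain)
        assert p_t == 40.0

    def test_non_terminal_dip_ignored(self):
        prof = profile_on([0, 20, 40, 60, 80],
                          [5.0, -1.0, 1.0, -2.0, -4.0])
        chain = chain_at([(1, 0, 0), (-1, 0, 0)])
        p_t, _ = transition_point(prof, accessibility_of(chain, [0, 0]),
                                  chain)
        assert p_t == 60.0
        p_first, _ = transition_point(
            prof, accessibility_of(chain, [0, 0]), chain, rule="first"
        )
        assert p_first == 20.0

    def test_never_negative_flag(self):
        prof = profile_on([0, 50, 100], [5.0, 4.0, 3.0])
        chain = chain_at([(1, 0, 0), (-1, 0, 0)])
        p_t, d_t = transition_point(prof, accessibility_of(chain, [0, 0]),
                                    chain)
        assert p_t is None and d_t is None

    def test_d_bar_over_collected_set(self):
        chain = chain_at([(2.0, 0, 0), (-2.0, 0, 0), (0, 6.0, 0), (0, -6.0, 0)])
        acc = accessibility_of(chain, [10.0, 10.0, 80.0, 80.0])
        prof = profile_on([20.0, 90.0], [1.0, -1.0])
        p_t, d_t = transition_point(prof, acc, chain)
        assert p_t == 90.0
        assert d_t == pytest.approx(4.0)  # mean of (2, 2, 6, 6)


class TestProfileCorrelation:
    def test_identity_and_antisymmetry(self):
        x = profile_on([0, 25, 50, 75, 100], [5.0, 3.0, 0.5, -2.0, -4.0])
        y = profile_on([0, 25, 50, 75, 100],
                       -np.array([5.0, 3.0, 0.5, -2.0, -4.0]))
        assert profile_correlation(x, x) == pytest.approx(1.0)
        assert profile_correlation(x, y) == pytest.approx(-1.0)

    def test_normalisation_invariance(self):
        rng = np.random.default_rng(8)
        grid = np.linspace(0, 100, 12)
        a = rng.normal(size=12)
        b = 0.3 * a + rng.normal(size=12)
        x, y = profile_on(grid, a), profile_on(grid, b)
        raw = np.corrcoef(a, b)[0, 1]
        assert profile_correlation(x, y) == pytest.approx(raw, abs=1e-12)

    def test_nan_points_excluded_and_errors(self):
        grid = [0.0, 50.0, 100.0]
        x = profile_on(grid, [np.nan, 1.0, -1.0])
        y = profile_on(grid, [5.0, 2.0, -2.0])
        assert profile_correlation(x, y) == pytest.approx(1.0)
        z = profile_on(grid, [np.nan, np.nan, 1.0])
        with pytest.raises(ValueError):
            profile_correlation(x, z)
        w = profile_on([0.0, 40.0, 100.0], [1.0, 0.0, -1.0])
        with pytest.raises(ValueError):
            profile_correlation(x, w)


class TestThresholdSweep:
    def test_consistency_with_profile_correlation(self, globule100):
        areas = atom_asa(globule100, 1.4, 480)
        reference = {r: 243.0 for r in
                     {res.resname for res in globule100.residues}}
        sweep = threshold_sweep(globule100, areas, reference,
                                thresholds=(0.25, 0.3))
        assert set(sweep) == {0.25, 0.3}
        for r in sweep.values():
            assert -1.0 <= r <= 1.0
        # synthetic pseudo-charges are bimodal (0.05 / 0.55): both
        # thresholds classify identically, so R must agree exactly
        assert sweep[0.25] == pytest.approx(sweep[0.3], abs=1e-12)
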