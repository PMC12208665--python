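import numpy as np
import pytest

from mcligand.density import (DensityGrid, calc_density, footprint_mask,
                              grid_for_conformers, read_map,
                              scale_calc_to_obs, write_map)
from mcligand.ligand import Conformer
from mcligand.metrics import rscc


@pytest.fixture()
def carbon_pair():
    return Conformer(coords=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]],
                     b_factors=[15.0, 15.0])


def test_single_atom_peak_at_voxel_center():
    c = Conformer(coords=[[0.0, 0.0, 0.0]], b_factors=[15.0])
    grid = grid_for_conformers([c], 1.0)
    out = calc_density([c], [1.0], grid, 1.0)
    peak = np.unravel_index(np.argmax(out.values), out.shape)
    assert np.allclose(out.voxel_coords(np.array([peak]))[0], 0.0,
                       atol=out.voxel_spacing.max())


def test_linearity_in_weights(carbon_pair):
    grid = grid_for_conformers([carbon_pair], 1.2)
    full = calc_density([carbon_pair], [1.0], grid, 1.2)
    half = calc_density([carbon_pair], [0.5], grid, 1.2)
    assert np.allclose(half.values, 0.5 * full.values, atol=1e-12)


def test_mixture_is_weighted_sum(carbon_pair):
    other = carbon_pair.with_coords(carbon_pair.coords + 0.8)
    grid = grid_for_conformers([carbon_pair, other], 1.2)
    m1 = calc_density([carbon_pair], [1.0], grid, 1.2)
    m2 = calc_density([other], [1.0], grid, 1.2)
    mix = calc_density([carbon_pair, other], [0.3, 0.7], grid, 1.2)
    assert np.allclose(mix.values, 0.3 * m1.values + 0.7 * m2.values,
                       atol=1e-10)


def test_calc_density_errors(carbon_pair):
    grid = grid_for_conformers([carbon_pair], 1.2)
    with pytest.raises(ValueError):
        calc_density([], [1.0], grid, 1.2)
    bad = Conformer(coords=carbon_pair.coords, b_factors=[15.0, 15.0])
    bad.b_factors = np.array([15.0, -1.0])   # bypass constructor check
    with pytest.raises(ValueError):
        calc_density([bad], [1.0], grid, 1.2)


@pytest.mark.parametrize("resolution,b", [(0.8, 10.0), (1.5, 25.0)])
def test_electron_conservation(resolution, b):
    """Integrated density equals the total electron count within 1%."""
    c = Conformer(coords=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]],
                  b_factors=[b, b])
    grid = grid_for_conformers([c], resolution)
    out = calc_density([c], [1.0], grid, resolution,
                       atomic_numbers=[6.0, 8.0])
    total = out.values.sum() * out.voxel_volume
    assert total == pytest.approx(14.0, rel=0.01)


def test_self_rscc_exceeds_99_percent(carbon_pair):
    """A model correlates near-perfectly with its own noiseless map."""
    grid = grid_for_conformers([carbon_pair], 1.0)
    calc = calc_density([carbon_pair], [1.0], grid, 1.0)
    mask = footprint_mask([carbon_pair], grid, radius=1.5)
    assert rscc(calc, calc_density([carbon_pair], [1.0], grid, 1.0),
                mask) > 0.99


class TestFootprintMask:
    def test_empty_conformer_list(self):
        g = DensityGrid(np.zeros((8, 8, 8)), [0.5] * 3, [0.0] * 3, 1.0)
        assert footprint_mask([], g, radius=1.5).count == 0

    def test_count_matches_brute_force_lattice(self):
        # independent oracle: enumerate all lattice points within the radius
        g = DensityGrid(np.zeros((17, 17, 17)), [0.5] * 3, [-4.0] * 3, 1.0)
        atom = Conformer(coords=[[0.1, -0.2, 0.3]], b_factors=[15.0])
        radius = 1.5
        mask = footprint_mask([atom], g, radius=radius)
        count = 0
        for i in range(17):
            for j in range(17):
                for k in range(17):
                    p = np.array([-4.0, -4.0, -4.0]) + 0.5 * np.array([i, j, k])
                    if np.linalg.norm(p - atom.coords[0]) <= radius:
                        count += 1
        assert mask.count == count

    def test_monotone_in_radius(self, carbon_pair):
        g = grid_for_conformers([carbon_pair], 1.0)
        m1 = footprint_mask([carbon_pair], g, radius=1.0)
        m2 = footprint_mask([carbon_pair], g, radius=2.0)
        assert np.all(m2.mask[m1.mask])


class TestScaling:
    def _setup(self, factor, noise=0.0, rng=None):
        c = Conformer(coords=[[0.0, 0.0, 0.0]], b_factors=[15.0])
        g = grid_for_conformers([c], 1.0)
        calc = calc_density([c], [1.0], g, 1.0)
        obs = calc.empty_like()
        obs.values = factor * calc.values
        if noise:
            obs.values = obs.values + rng.normal(0, noise, obs.shape)
        return c, g, calc, obs

    def test_exact_factors(self):
        for f in (1.0, 2.0):
            c, g, calc, obs = self._setup(f)
            mask = footprint_mask([c], g, radius=1.5)
            assert scale_calc_to_obs(calc, obs, mask) == pytest.approx(f)

    def test_noisy_scale_matches_dot_product_oracle(self, rng):
        c, g, calc, obs = self._setup(3.0, noise=0.01, rng=rng)
        mask = footprint_mask([c], g, radius=1.5)
        s = scale_calc_to_obs(calc, obs, mask)
        cv, ov = mask.extract(calc), mask.extract(obs)
        assert s == pytest.approx(float(cv @ ov) / float(cv @ cv), abs=1e-12)
        assert s == pytest.approx(3.0, abs=0.05)

    def test_scaling_never_increases_residual(self, rng):
        c, g, calc, obs = self._setup(2.5, noise=0.05, rng=rng)
        mask = footprint_mask([c], g, radius=1.5)
        s = scale_calc_to_obs(calc, obs, mask)
        cv, ov = mask.extract(calc), mask.extract(obs)
        assert np.linalg.norm(s * cv - ov) <= np.linalg.norm(cv - ov) + 1e-12

    def test_zero_calc_raises(self):
        c, g, calc, obs = self._setup(1.0)
        calc.values[:] = 0.0
        mask = footprint_mask([c], g, radius=1.5)
        with pytest.raises(ValueError):
            scale_calc_to_obs(calc, obs, mask)


class TestMapIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        g = DensityGrid(rng.random((16, 16, 16)), [0.4, 0.5, 0.6],
                        [1.0, -2.0, 3.0], 1.3)
        path = tmp_path / "grid.ccp4"
        write_map(g, path)
        g2 = read_map(path, resolution=1.3)
        assert g2.shape == g.shape
        assert np.allclose(g2.values, g.values, atol=1e-6)
        assert np.allclose(g2.voxel_spacing, g.voxel_spacing, atol=1e-6)
        assert np.allclose(g2.origin, g.origin, atol=1e-5)

    def test_axis_permuted_file_reads_canonically(self, tmp_path, rng):
        import gemmi
        vals = rng.random((6, 8, 10))
        g = DensityGrid(vals, [0.5] * 3, [1.0, 2.0, 3.0], 1.5)
        # craft a file stored in (Y, Z, X) axis order
        arr = np.transpose(vals, (1, 2, 0))
        fg = gemmi.FloatGrid(*arr.shape)
        fg.set_unit_cell(gemmi.UnitCell(4.0, 5.0, 3.0, 90, 90, 90))
        np.asarray(fg.array)[:] = arr.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = fg
        m.update_ccp4_header()
        m.set_header_i32(17, 2)
        m.set_header_i32(18, 3)
        m.set_header_i32(19, 1)
        for w, v in zip((11, 12, 13), (3.0, 4.0, 5.0)):
            m.set_header_float(w, v)
        for w, v in zip((8, 9, 10), (6, 8, 10)):
            m.set_header_i32(w, v)
        for w, v in zip((50, 51, 52), g.origin):
            m.set_header_float(w, float(v))
        path = tmp_path / "perm.ccp4"
        m.write_ccp4_map(str(path))
        g2 = read_map(path, resolution=1.5)
        assert g2.shape == (6, 8, 10)
        assert np.allclose(g2.values, vals, atol=1e-6)
        assert np.allclose(g2.origin, g.origin, atol=1e-5)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.ccp4"
        path.write_bytes(b"MAP " * 20)
        with pytest.raises(ValueError):
            read_map(path)
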