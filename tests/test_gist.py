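"""Voxel solvation analysis: grid construction, binning, entropy estimators
against dense oracles, energy conservation, and regional sums."""

import numpy as np
import pytest

from xbsolv.gist import (
    COULOMB_K,
    KB_KJMOL,
    RHO_BULK_DEFAULT,
    RegionSpec,
    SolventTrajectory,
    VoxelOccupancy,
    WATER_CHARGES,
    WATER_LJ_EPS,
    WATER_LJ_SIGMA,
    build_grid,
    gist_fields,
    interaction_energies,
    region_block_series,
    region_sum,
    rot_entropy,
    trans_entropy,
    voxelize,
    water_site_positions,
)
from xbsolv.synth import (
    concentrated_quaternions,
    make_bulk_water_traj,
    make_ordered_site_traj,
    random_quaternions,
)


def single_frame_traj(positions, quats=None, box=(20.0, 20.0, 20.0), **kw):
    positions = np.asarray(positions, float)[None, :, :]
    if quats is None:
        n = positions.shape[1]
        quats = np.tile([1.0, 0, 0, 0], (1, n, 1))
    else:
        quats = np.asarray(quats, float)[None, :, :]
    return SolventTrajectory(water_positions=positions, water_quats=quats,
                             box=np.asarray(box, float), **kw)


class TestGrid:
    @pytest.mark.parametrize("extents, spacing, dims", [
        ((16, 17, 14), 0.5, (32, 34, 28)),
        ((6, 6, 6), 0.5, (12, 12, 12)),
        ((1, 1, 1), 1.0, (1, 1, 1)),
    ])
    def test_dims_from_extents(self, extents, spacing, dims):
        assert build_grid((0, 0, 0), extents, spacing).dims == dims

    def test_center_preserved(self):
        g = build_grid((3.0, -1.0, 2.5), (6, 6, 6), 0.5)
        center = np.asarray(g.origin) + g.extent / 2.0
        assert np.allclose(center, (3.0, -1.0, 2.5), atol=0.25)

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 0), (6, 6, 6), 0.0)


class TestVoxelize:
    def test_corner_water(self):
        g = build_grid((1.0, 1.0, 1.0), (2, 2, 2), 1.0)
        traj = single_frame_traj([np.asarray(g.origin) + 1e-9])
        occ = voxelize(traj, g)
        assert occ.counts[0, 0, 0] == 1 and occ.counts.sum() == 1

    def test_boundary_goes_to_higher_voxel(self):
        g = build_grid((1.0, 1.0, 1.0), (2, 2, 2), 1.0)
        boundary = np.asarray(g.origin) + np.array([1.0, 0.5, 0.5])
        occ = voxelize(single_frame_traj([boundary]), g)
        assert occ.counts[1, 0, 0] == 1

    def test_conservation_against_point_in_box_oracle(self, rng):
        g = build_grid((6, 6, 6), (7, 5, 6), 0.5)
        pts = rng.uniform(0, 12, size=(100, 3))
        occ = voxelize(single_frame_traj(pts, box=(12, 12, 12)), g)
        lo = np.asarray(g.origin)
        hi = lo + g.extent
        inside = np.sum(np.all((pts >= lo) & (pts < hi), axis=1))
        assert occ.counts.sum() == occ.n_observations == inside


class TestTransEntropy:
    def test_exact_bulk_is_zero(self):
        g = build_grid((0, 0, 0), (4, 4, 4), 1.0)
        n_frames = 100
        counts = np.full(g.dims, n_frames * g.voxel_volume * RHO_BULK_DEFAULT)
        ts = trans_entropy(counts, g, n_frames, bias_correction=False)
        assert np.allclose(ts, 0.0, atol=1e-15)

    def test_all_mass_in_one_voxel_closed_form(self):
        """N-voxel region with every observation in one voxel: that voxel's
        term equals -kB*T*(n/F)*ln(n/(F*V*rho0))."""
        g = build_grid((0, 0, 0), (2, 2, 2), 1.0)
        counts = np.zeros(g.dims)
        n_frames, n_obs = 50, 120
        counts[0, 1, 0] = n_obs
        ts = trans_entropy(counts, g, n_frames, temperature_K=300.0,
                           bias_correction=False)
        expected = -KB_KJMOL * 300.0 * (n_obs / n_frames) * np.log(
            n_obs / (n_frames * 1.0 * RHO_BULK_DEFAULT))
        assert ts[0, 1, 0] == pytest.approx(expected, rel=1e-12)
        assert ts.sum() == pytest.approx(expected, rel=1e-12)

    def test_density_normalisation(self):
        g = build_grid((0, 0, 0), (3, 3, 3), 1.0)
        counts = np.random.default_rng(0).poisson(5.0, size=g.dims).astype(float)
        a = trans_entropy(counts, g, 100, bias_correction=False)
        b = trans_entropy(2 * counts, g, 200, bias_correction=False)
        assert np.allclose(a, b)


class TestRotEntropy:
    @staticmethod
    def _occupancy_one_voxel(quats, n_frames):
        g = build_grid((0, 0, 0), (1, 1, 1), 1.0)
        occ = VoxelOccupancy(
            counts=np.array([[[len(quats)]]]), orientations={0: quats},
            n_frames=n_frames, n_observations=len(quats))
        return g, occ

    def test_isotropic_near_zero(self, rng):
        q = random_quaternions(rng, 3000)
        g, occ = self._occupancy_one_voxel(q, n_frames=3000)
        ts = rot_entropy(occ, g, temperature_K=300.0)
        # per-water dS in kB units should vanish for the uniform distribution
        per_water = ts[0, 0, 0] / (KB_KJMOL * 300.0 * 1.0)
        assert abs(per_water) < 0.1

    def test_identical_orientations_strongly_negative(self):
        q = np.tile([1.0, 0, 0, 0], (50, 1))
        g, occ = self._occupancy_one_voxel(q, n_frames=50)
        ts = rot_entropy(occ, g)
        assert ts[0, 0, 0] < -10.0

    def test_global_rotation_invariance(self, rng):
        from xbsolv.gist import quat_to_matrix
        q = concentrated_quaternions(rng, 400, 20.0)
        rot = random_quaternions(rng, 1)[0]
        w, x, y, z = rot

        def qmul(r, q):
            rw, rv = r[0], r[1:]
            qw, qv = q[:, 0], q[:, 1:]
            out = np.empty_like(q)
            out[:, 0] = rw * qw - qv @ rv
            out[:, 1:] = rw * qv + qw[:, None] * rv + np.cross(rv[None, :], qv)
            return out

        g, occ_a = self._occupancy_one_voxel(q, 400)
        _, occ_b = self._occupancy_one_voxel(qmul(rot, q), 400)
        assert rot_entropy(occ_a, g)[0, 0, 0] == pytest.approx(
            rot_entropy(occ_b, g)[0, 0, 0], rel=1e-9)

    def test_fewer_than_two_samples_contribute_zero(self):
        g, occ = self._occupancy_one_voxel(np.array([[1.0, 0, 0, 0]]), 10)
        assert rot_entropy(occ, g)[0, 0, 0] == 0.0

    def test_concentrated_matches_histogram_oracle(self, rng):
        """Nearest-neighbour estimate vs dense-histogram integration of
        -kB * sum p ln(p/p_iso) in rotation-vector space."""
        conc = 12.0
        n = 6000
        q = concentrated_quaternions(rng, n, conc)
        g, occ = self._occupancy_one_voxel(q, n_frames=n)
        ts = rot_entropy(occ, g, temperature_K=300.0)
        per_water_nn = ts[0, 0, 0] / (KB_KJMOL * 300.0)

        # oracle: histogram a large sample of rotation vectors w, convert the
        # Lebesgue density to a Haar density via j(w) = 2(1-cos|w|)/|w|^2
        big = concentrated_quaternions(rng, 200_000, conc)
        sign = np.sign(big[:, 0:1])
        sign[sign == 0] = 1.0
        big = big * sign  # w component >= 0 -> angle in [0, pi]
        theta = 2.0 * np.arccos(np.clip(big[:, 0], -1, 1))
        axis = big[:, 1:]
        norms = np.linalg.norm(axis, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        w = axis / norms * theta[:, None]
        lim = 4.0 / np.sqrt(conc)
        nbins = 40
        hist, edges = np.histogramdd(w, bins=nbins, range=[(-lim, lim)] * 3)
        widths = (2 * lim / nbins) ** 3
        centers = [0.5 * (e[1:] + e[:-1]) for e in edges]
        cx, cy, cz = np.meshgrid(*centers, indexing="ij")
        wn = np.sqrt(cx**2 + cy**2 + cz**2)
        wn[wn == 0] = 1e-12
        jac = 2.0 * (1.0 - np.cos(wn)) / wn**2
        p_bin = hist / hist.sum()
        occ_bins = p_bin > 0
        p_leb = p_bin[occ_bins] / widths
        p_haar = p_leb / jac[occ_bins]
        oracle = -np.sum(p_bin[occ_bins] * np.log(p_haar * 8.0 * np.pi**2))
        assert per_water_nn == pytest.approx(oracle, rel=0.10)


class TestInteractionEnergies:
    def test_no_solute_no_esw(self, rng):
        traj = make_bulk_water_traj((12, 12, 12), 10, 3, seed=0)
        g = build_grid((6, 6, 6), (6, 6, 6), 1.0)
        e_sw, _ = interaction_energies(traj, g, cutoff=5.0)
        assert np.all(e_sw == 0.0)

    def test_two_waters_half_pair_energy_each(self):
        g = build_grid((5, 5, 5), (8, 8, 8), 1.0)
        pos = np.array([[4.0, 5.0, 5.0], [7.0, 5.0, 5.0]])
        quats = np.tile([1.0, 0, 0, 0], (2, 1))
        traj = single_frame_traj(pos, quats, box=(20, 20, 20))
        e_sw, e_ww = interaction_energies(traj, g)
        # hand-evaluated oracle: all 9 site pairs Coulomb + O-O LJ
        sites = water_site_positions(pos, quats)
        e = 0.0
        for a in range(3):
            for b in range(3):
                r = np.linalg.norm(sites[0, a] - sites[1, b])
                e += COULOMB_K * WATER_CHARGES[a] * WATER_CHARGES[b] / r
        s6 = (WATER_LJ_SIGMA / 3.0) ** 6
        e += 4 * WATER_LJ_EPS * (s6 * s6 - s6)
        ijk, _ = g.voxel_indices(pos)
        assert e_ww[tuple(ijk[0])] == pytest.approx(e / 2.0, rel=1e-12)
        assert e_ww[tuple(ijk[1])] == pytest.approx(e / 2.0, rel=1e-12)
        assert e_ww.sum() == pytest.approx(e, rel=1e-12)

    def test_zero_charge_zero_eps_solute(self):
        g = build_grid((6, 6, 6), (6, 6, 6), 1.0)
        traj = make_bulk_water_traj((12, 12, 12), 8, 2, seed=1)
        traj.solute_positions = np.array([[6.0, 6.0, 6.0]])
        traj.solute_charges = np.zeros(1)
        traj.solute_lj_eps = np.zeros(1)
        e_sw, _ = interaction_energies(traj, g, cutoff=5.0)
        assert np.all(e_sw == 0.0)

    def test_totals_match_double_loop_oracle(self, rng):
        """Grid-assigned energies sum to an independent double-loop over all
        molecule pairs with the same in-grid crediting."""
        box = np.array([18.0, 18.0, 18.0])
        n_w, n_frames = 14, 3
        pos = rng.uniform(0, 18, size=(n_frames, n_w, 3))
        quats = random_quaternions(rng, n_frames * n_w).reshape(n_frames, n_w, 4)
        traj = SolventTrajectory(
            water_positions=pos, water_quats=quats, box=box,
            solute_positions=rng.uniform(6, 12, size=(4, 3)),
            solute_charges=rng.uniform(-0.5, 0.5, 4),
            solute_lj_eps=rng.uniform(0.1, 0.8, 4),
            solute_lj_sigma=rng.uniform(3.0, 3.6, 4),
        )
        g = build_grid((9, 9, 9), (10, 10, 10), 1.0)
        e_sw, e_ww = interaction_energies(traj, g, cutoff=8.0)

        def pair_ww(si, sj):
            d = si[:, None, :] - sj[None, :, :]
            r = np.linalg.norm(d, axis=-1)
            e = COULOMB_K * np.sum(np.outer(WATER_CHARGES, WATER_CHARGES) / r)
            s6 = (WATER_LJ_SIGMA / r[0, 0]) ** 6
            return e + 4 * WATER_LJ_EPS * (s6 * s6 - s6)

        tot_ww = tot_sw = 0.0
        lo = np.asarray(g.origin)
        hi = lo + g.extent
        for f in range(n_frames):
            sites = water_site_positions(pos[f], quats[f])
            ingrid = np.all((pos[f] >= lo) & (pos[f] < hi), axis=1)
            for i in range(n_w):
                for j in range(i + 1, n_w):
                    delta = pos[f, i] - pos[f, j]
                    shift = box * np.round(delta / box)
                    if np.linalg.norm(delta - shift) > 8.0:
                        continue
                    e = pair_ww(sites[i], sites[j] - shift)
                    tot_ww += e * (0.5 * ingrid[i] + 0.5 * ingrid[j])
                for s in range(4):
                    if not ingrid[i]:
                        continue
                    delta = pos[f, i] - traj.solute_positions[s]
                    shift = box * np.round(delta / box)
                    r_os = np.linalg.norm(delta - shift)
                    if r_os > 8.0:
                        continue
                    rs = np.linalg.norm(sites[i] - (traj.solute_positions[s] + shift),
                                        axis=1)
                    tot_sw += COULOMB_K * np.sum(
                        WATER_CHARGES * traj.solute_charges[s] / rs)
                    eps = np.sqrt(WATER_LJ_EPS * traj.solute_lj_eps[s])
                    sig = 0.5 * (WATER_LJ_SIGMA + traj.solute_lj_sigma[s])
                    s6 = (sig / r_os) ** 6
                    tot_sw += 4 * eps * (s6 * s6 - s6)
        assert e_ww.sum() * n_frames == pytest.approx(tot_ww, abs=1e-9)
        assert e_sw.sum() * n_frames == pytest.approx(tot_sw, abs=1e-9)

    def test_cutoff_beyond_half_box_rejected(self):
        traj = make_bulk_water_traj((12, 12, 12), 5, 1, seed=0)
        g = build_grid((6, 6, 6), (6, 6, 6), 1.0)
        with pytest.raises(ValueError):
            interaction_energies(traj, g, cutoff=7.0)


class TestRegions:
    def test_whole_grid_equals_total(self):
        traj = make_bulk_water_traj((12, 12, 12), 30, 50, seed=3)
        g = build_grid((6, 6, 6), (8, 8, 8), 1.0)
        f = gist_fields(traj, g, include_energies=False)
        whole = region_sum(f, RegionSpec(mask=np.ones(g.dims, bool)))
        assert whole["TS_trans"] == pytest.approx(f.TS_trans.sum())
        assert whole["minus_TdS_tot"] == pytest.approx(
            -(f.TS_trans.sum() + f.TS_rot.sum()))

    def test_disjoint_halves_additive(self):
        traj = make_bulk_water_traj((12, 12, 12), 30, 50, seed=4)
        g = build_grid((6, 6, 6), (8, 8, 8), 1.0)
        f = gist_fields(traj, g, include_energies=False)
        left = np.zeros(g.dims, bool)
        left[:4] = True
        a = region_sum(f, RegionSpec(mask=left))
        b = region_sum(f, RegionSpec(mask=~left))
        whole = region_sum(f, RegionSpec(mask=np.ones(g.dims, bool)))
        assert a["minus_TdS_tot"] + b["minus_TdS_tot"] == pytest.approx(
            whole["minus_TdS_tot"], abs=1e-12)

    def test_empty_region_rejected(self):
        g = build_grid((0, 0, 0), (4, 4, 4), 1.0)
        with pytest.raises(ValueError):
            RegionSpec(center=(50, 50, 50), extents=(1, 1, 1)).voxel_mask(g)


class TestNullAndOrdering:
    def test_bulk_null_within_three_se(self):
        box = (12.0, 12.0, 12.0)
        n_w = int(round(RHO_BULK_DEFAULT * 12**3))
        traj = make_bulk_water_traj(box, n_w, 800, seed=7)
        g = build_grid((6, 6, 6), (6, 6, 6), 1.0)
        region = RegionSpec(center=(6, 6, 6), extents=(6, 6, 6))
        est, se, _ = region_block_series(traj, g, region, n_blocks=5)
        assert abs(est) < 3.0 * se

    def test_confinement_ladder_monotone(self):
        """Tighter positional pinning of a planted water site never lowers
        the regional ordering penalty (median over seeds)."""
        g = build_grid((6, 6, 6), (6, 6, 6), 0.5)
        region = RegionSpec(center=(6, 6, 6), extents=(6, 6, 6))
        medians = []
        for sd in (0.1, 0.3, 0.6):
            vals = []
            for seed in range(10):
                traj = make_ordered_site_traj(
                    (6, 6, 6), sd, 40.0, (12, 12, 12), 20, 250, seed=seed)
                f = gist_fields(traj, g, include_energies=False)
                vals.append(region_sum(f, region)["minus_TdS_tot"])
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]
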