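"""Trajectory post-processing: averages, B-factors, catchbox, angles, RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bcri.simulate import simulate_trajectory
from bcri.structure import (
    CaChain,
    Catchbox,
    TrajectoryEnsemble,
    angle_density_map,
    average_structure,
    bfactors,
    catchbox_hits,
    ce_structure_correlation,
    construct_to_mature,
    kabsch,
    mature_to_construct,
    ring_orientation,
    sfe_site_statistics,
    superpose_and_rmsd,
)
from conftest import make_bcn_trajectory


def _random_structure(n=50, seed=0):
    return np.cumsum(np.random.default_rng(seed).normal(0, 2, (n, 3)), axis=0)


class TestAverageStructure:
    def test_single_frame_identity(self):
        base = _random_structure()
        traj = simulate_trajectory(base, 0.0, 1, seed=0)
        np.testing.assert_allclose(average_structure(traj), base, atol=1e-12)

    def test_symmetric_offsets_cancel(self):
        base = _random_structure()
        offset = np.random.default_rng(1).normal(0, 1, base.shape)
        traj = simulate_trajectory(base, 0.0, 2, seed=0)
        traj.coords[0] = base + offset
        traj.coords[1] = base - offset
        # superposition is onto frame 0; compare pairwise distances instead
        avg = average_structure(traj)
        d_avg = np.linalg.norm(avg[0] - avg[-1])
        d_base = np.linalg.norm(base[0] - base[-1])
        assert not np.isnan(avg).any()
        assert d_avg < max(np.linalg.norm((base + offset)[0] - (base + offset)[-1]),
                           np.linalg.norm((base - offset)[0] - (base - offset)[-1])) + 1e-9
        assert d_avg == pytest.approx(d_base, rel=0.2)

    def test_jitter_average_converges(self):
        base = _random_structure()
        sigma, n_frames = 0.3, 800
        traj = simulate_trajectory(base, sigma, n_frames, seed=2)
        avg = average_structure(traj)
        # the average lives in its own rigid frame; align it to the truth
        r, t, _ = kabsch(avg, base)
        per_atom = np.linalg.norm(avg @ r.T + t - base, axis=1)
        # per-coordinate SE is σ/√n; the 3D norm concentrates around √3·SE
        assert per_atom.mean() < 3 * sigma * np.sqrt(3) / np.sqrt(n_frames)
        assert per_atom.max() < 6 * sigma * np.sqrt(3) / np.sqrt(n_frames)

    def test_frame_order_invariance(self):
        base = _random_structure()
        traj = simulate_trajectory(base, 0.2, 50, seed=3)
        perm = np.random.default_rng(0).permutation(50)
        shuffled = TrajectoryEnsemble(
            traj.atom_names, traj.res_names, traj.res_ids, traj.chains,
            traj.coords[perm],
        )
        # compare in a frame-independent way: pairwise distance matrices
        a = average_structure(traj)
        b = average_structure(shuffled)
        da = np.linalg.norm(a[:, None] - a[None], axis=2)
        db = np.linalg.norm(b[:, None] - b[None], axis=2)
        np.testing.assert_allclose(da, db, atol=1e-9)

    def test_sub_ranges(self):
        base = _random_structure()
        traj = simulate_trajectory(base, 0.1, 100, seed=4)
        subs = average_structure(traj, sub_ranges=10)
        assert subs.shape == (10,) + base.shape

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            TrajectoryEnsemble(
                np.array(["CA"]), np.array(["ALA"]), np.array([1]),
                np.array(["A"]), np.empty((0, 1, 3)),
            ).coords.size or average_structure(
                TrajectoryEnsemble(
                    np.array(["CA"]), np.array(["ALA"]), np.array([1]),
                    np.array(["A"]), np.empty((0, 1, 3)),
                )
            )


class TestBfactors:
    def test_rigid_trajectory_is_zero(self):
        traj = simulate_trajectory(_random_structure(), 0.0, 20, seed=0)
        df = bfactors(traj, residues=[1, 5, 10], atom_names=("CA",))
        np.testing.assert_allclose(df["B"], 0.0, atol=1e-20)

    def test_isotropic_jitter_law(self):
        # B = 8π²σ² for isotropic per-axis jitter σ (here σ = 0.5 Å)
        sigma, n_frames = 0.5, 2000
        traj = simulate_trajectory(_random_structure(n=200, seed=1), sigma,
                                   n_frames, seed=5)
        df = bfactors(traj, residues=[100], atom_names=("CA",))
        expected = 8 * np.pi**2 * sigma**2
        se = expected * np.sqrt(2.0 / (3 * n_frames))
        assert abs(df["B"][0] - expected) < 3 * se

    def test_restrained_residues_fluctuate_less(self):
        base = _random_structure(n=30, seed=2)
        sig = np.full(30, 0.6)
        sig[:10] = 0.1  # "ligand-restrained" block
        traj = simulate_trajectory(base, sig, 400, seed=6)
        df = bfactors(traj, residues=list(range(1, 31)), atom_names=("CA",))
        assert df[df.res_id <= 10]["B"].mean() < 0.3 * df[df.res_id > 10]["B"].mean()

    def test_bcn_backbone_aliases(self):
        traj = make_bcn_trajectory(n_frames=50, jitter=0.2, seed=1)
        df = bfactors(traj, residues=[7])
        # BCN residue contributes through its renamed backbone atoms
        assert len(df) == 1 and df["n_atoms"][0] >= 1 and df["B"][0] > 0

    def test_missing_residue_warns(self):
        traj = simulate_trajectory(_random_structure(), 0.1, 10, seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            df = bfactors(traj, residues=[999], atom_names=("CA",))
        assert df.empty


class TestCatchbox:
    def test_midpoint_always_inside(self):
        traj = make_bcn_trajectory(n_frames=5, n_env_atoms=1)
        # place the env atom at the C14–C15 midpoint every frame
        mid = 0.5 * (traj.coords[:, 1] + traj.coords[:, 2])
        traj.coords[:, 5] = mid
        df = catchbox_hits(traj, 7)
        assert df["hit_frequency"].iloc[0] == 1.0

    def test_long_axis_boundary(self):
        traj = make_bcn_trajectory(n_frames=1, n_env_atoms=2)
        mid = 0.5 * (traj.coords[0, 1] + traj.coords[0, 2])
        traj.coords[0, 5] = mid + np.array([6.70, 0, 0])  # inside |x| ≤ 6.75
        traj.coords[0, 6] = mid + np.array([7.00, 0, 0])  # outside
        df = catchbox_hits(traj, 7)
        assert set(df["atom_index"]) == {5}

    def test_brute_force_half_space_oracle(self):
        rng = np.random.default_rng(9)
        traj = make_bcn_trajectory(n_frames=4, n_env_atoms=300, seed=3,
                                   jitter=0.05)
        box = Catchbox()
        df = catchbox_hits(traj, 7, box)
        counts = dict(zip(df["atom_index"], df["hit_count"]))
        # independent membership: explicit six half-space test per frame
        from bcri.structure import _bcn_frame

        brute = {}
        for f in range(traj.n_frames):
            axes, origin = _bcn_frame(traj, 7, f)
            for ai in range(5, traj.n_atoms):
                rel = traj.coords[f, ai] - origin
                proj = [abs(np.dot(rel, axes[k])) for k in range(3)]
                if all(p <= h for p, h in zip(proj, box.half)):
                    brute[ai] = brute.get(ai, 0) + 1
        assert counts == brute

    def test_empty_environment(self):
        traj = make_bcn_trajectory(n_frames=3)
        assert catchbox_hits(traj, 7).empty

    def test_missing_ring_atoms_rejected(self):
        traj = simulate_trajectory(_random_structure(), 0.0, 2, seed=0)
        with pytest.raises(KeyError):
            catchbox_hits(traj, 1)


class TestRingOrientation:
    def test_pole_convention(self):
        traj = make_bcn_trajectory(n_frames=1)
        # constructed geometry: v1 ∥ x with v2 tilted: compute directly
        o = ring_orientation(traj, 7, superpose=False)
        n = np.cross(
            traj.coords[0, 2] - traj.coords[0, 0],
            traj.coords[0, 1] - traj.coords[0, 3],
        )
        n = n / np.linalg.norm(n)
        assert o.polar[0] == pytest.approx(np.degrees(np.arccos(n[2])), abs=1e-9)

    def test_matches_symbolic_evaluation(self):
        rng = np.random.default_rng(4)
        traj = make_bcn_trajectory(n_frames=20, jitter=0.3, seed=5)
        o = ring_orientation(traj, 7, superpose=False)
        for f in range(20):
            v1 = traj.coords[f, 2] - traj.coords[f, 0]  # C15 − C11
            v2 = traj.coords[f, 1] - traj.coords[f, 3]  # C14 − C18
            n = np.cross(v1, v2)
            n = n / np.linalg.norm(n)
            assert o.polar[f] == pytest.approx(
                np.degrees(np.arccos(np.clip(n[2], -1, 1))), abs=1e-9
            )
            assert o.azimuth[f] == pytest.approx(
                np.degrees(np.arctan2(n[1], n[0])), abs=1e-9
            )

    def test_collinear_frame_excluded(self):
        traj = make_bcn_trajectory(n_frames=2)
        # make C15−C11 parallel to C14−C18 in frame 1
        traj.coords[1, 0] = [0.0, 0.0, 0.0]   # C11
        traj.coords[1, 2] = [1.0, 0.0, 0.0]   # C15
        traj.coords[1, 3] = [5.0, 0.0, 0.0]   # C18
        traj.coords[1, 1] = [6.0, 0.0, 0.0]   # C14
        o = ring_orientation(traj, 7, superpose=False)
        assert list(o.excluded_frames) == [1]
        assert o.polar.size == 1


class TestAngleDensity:
    def test_normalization(self):
        from bcri.structure import RingOrientation

        rng = np.random.default_rng(0)
        o = RingOrientation(polar=rng.uniform(40, 140, 60),
                            azimuth=rng.uniform(-120, 120, 60))
        out = angle_density_map(o, bandwidths=np.logspace(-1, 1, 10))
        integral = np.trapezoid(
            np.trapezoid(out["density"], out["azimuth_axis"], axis=1),
            out["polar_axis"],
        )
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_two_clusters_give_two_maxima(self):
        from bcri.structure import RingOrientation

        rng = np.random.default_rng(1)
        polar = np.concatenate([rng.normal(50, 2, 40), rng.normal(130, 2, 40)])
        az = np.concatenate([rng.normal(-90, 2, 40), rng.normal(90, 2, 40)])
        out = angle_density_map(RingOrientation(polar=polar, azimuth=az),
                                bandwidths=np.logspace(-1, 1, 10))
        d = out["density"]
        pk_pol = out["polar_axis"][np.unravel_index(d.argmax(), d.shape)[0]]
        # mask the first cluster and find the second maximum
        mask = np.ones_like(d)
        mask[np.abs(out["polar_axis"] - pk_pol) < 30, :] = 0
        d2 = d * mask
        pk2_pol = out["polar_axis"][np.unravel_index(d2.argmax(), d2.shape)[0]]
        assert {round(pk_pol, -1), round(pk2_pol, -1)} == {50.0, 130.0}

    def test_repeated_point_uses_minimum_bandwidth(self):
        from bcri.structure import RingOrientation

        o = RingOrientation(polar=np.full(12, 90.0), azimuth=np.full(12, 10.0))
        out = angle_density_map(o, bandwidths=np.logspace(-1, 1, 10))
        assert out["bandwidth"] == pytest.approx(0.1)

    def test_too_few_frames(self):
        from bcri.structure import RingOrientation

        o = RingOrientation(polar=np.arange(5.0), azimuth=np.arange(5.0))
        with pytest.raises(ValueError):
            angle_density_map(o)

    def test_levels_floor(self):
        from bcri.structure import RingOrientation

        rng = np.random.default_rng(2)
        o = RingOrientation(polar=rng.uniform(80, 100, 30),
                            azimuth=rng.uniform(-10, 10, 30))
        out = angle_density_map(o, bandwidths=np.array([2.0]))
        assert out["levels"].size == 8
        assert out["levels"][0] == pytest.approx(10**-6.5)


class TestSuperposeRmsd:
    def _chain(self, seed=11, n=80):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
        coords = np.cumsum(rng.normal(0, 2, (n, 3)), axis=0)
        return CaChain(res_ids=np.arange(2, n + 2), sequence=seq, coords=coords)

    def test_identical_structures_zero(self):
        ref = self._chain()
        prof = superpose_and_rmsd(ref, ref, region=(2, 81), anchors=[20, 60])
        for site in prof.sites.values():
            for v in site.values():
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_with_displaced_anchor(self):
        ref = self._chain()
        rot = Rotation.random(random_state=3).as_matrix()
        mob_coords = ref.coords @ rot.T + np.array([5.0, -3.0, 2.0])
        mob_coords[40 - 2] += rot @ np.array([0.5, 0.0, 0.0])
        mob = CaChain(ref.res_ids.copy(), ref.sequence, mob_coords)
        prof = superpose_and_rmsd(mob, ref, region=(2, 81), anchors=[40])
        assert prof.sites[40]["RMSD_0"] == pytest.approx(0.5, abs=0.02)
        # neighbours dilute the displacement: RMSD_1..3 strictly decreasing
        vals = [prof.sites[40][f"RMSD_{k}"] for k in range(4)]
        assert vals[0] > vals[1] > vals[2] > vals[3]

    def test_rigid_invariance_of_both_inputs(self):
        ref = self._chain()
        mob = self._chain(seed=12)
        base = superpose_and_rmsd(mob, ref, region=(2, 81), anchors=[30])
        rot = Rotation.random(random_state=5).as_matrix()
        mob2 = CaChain(mob.res_ids.copy(), mob.sequence,
                       mob.coords @ rot.T + 7.0)
        again = superpose_and_rmsd(mob2, ref, region=(2, 81), anchors=[30])
        assert again.sites[30]["RMSD_0"] == pytest.approx(
            base.sites[30]["RMSD_0"], abs=1e-9
        )

    def test_region_too_small_rejected(self):
        ref = self._chain()
        with pytest.raises(ValueError):
            superpose_and_rmsd(ref, ref, region=(2, 8), anchors=[4])

    def test_numbering_converter(self):
        assert mature_to_construct(97) == 103
        assert construct_to_mature(mature_to_construct(13)) == 13


class TestSfeAndCorrelation:
    def test_outlier_exclusion(self):
        # one gross outlier among 20 sub-trajectory values exceeds 3 SD
        # (with fewer than ~10 values the criterion cannot mathematically
        # trigger, since max |z| = (n−1)/√n)
        rng = np.random.default_rng(0)
        vals = {"K97": list(rng.normal(1.0, 0.05, 19)) + [50.0]}
        df = sfe_site_statistics(vals)
        assert df["n"][0] == 19
        assert df["dG_solv"][0] == pytest.approx(1.0, abs=0.05)

    def test_exact_linear_correlation(self):
        sites = list("ABCDE")
        ce = {s: i * 0.1 for i, s in enumerate(sites)}
        st = {s: 2.0 * ce[s] for s in sites}
        out = ce_structure_correlation(ce, st, seed=0, n_resamples=10)
        assert out["all"]["r"] == pytest.approx(1.0)

    def test_permutation_destroys_correlation(self):
        rng = np.random.default_rng(3)
        sites = [f"s{i}" for i in range(12)]
        x = rng.normal(0, 1, 12)
        ce = dict(zip(sites, x))
        st = dict(zip(sites, 2 * x + rng.normal(0, 0.1, 12)))
        out = ce_structure_correlation(ce, st, seed=0, n_resamples=10)
        r_true = out["all"]["r"]
        # permutation null: |r| of shuffled pairings rarely reaches r_true
        perm_rs = []
        for i in range(200):
            perm = rng.permutation(12)
            perm_st = dict(zip(sites, np.array([st[s] for s in sites])[perm]))
            perm_rs.append(abs(
                ce_structure_correlation(ce, perm_st, seed=0,
                                         n_resamples=2)["all"]["r"]
            ))
        assert r_true > np.quantile(perm_rs, 0.95)

    def test_mismatched_sites_rejected(self):
        with pytest.raises(ValueError):
            ce_structure_correlation({"A": 1.0, "B": 2.0}, {"C": 1.0}, seed=0)

    def test_domain_split(self):
        sites = list("ABCDEF")
        ce = {s: i * 0.1 for i, s in enumerate(sites)}
        st = {s: 1 - ce[s] for s in sites}
        domains = {s: ("D1" if i < 3 else "D2") for i, s in enumerate(sites)}
        out = ce_structure_correlation(ce, st, domains=domains, seed=0,
                                       n_resamples=5)
        assert set(out) == {"D1", "D2"}


class TestKabsch:
    def test_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(8)
        p = rng.normal(0, 3, (25, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        q = p @ rot.T + np.array([1.0, 2.0, 3.0])
        r, t, rmsd = kabsch(p, q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(r, rot, atol=1e-9)

    def test_no_reflection(self):
        rng = np.random.default_rng(9)
        p = rng.normal(0, 3, (25, 3))
        q = p.copy()
        q[:, 2] *= -1  # mirrored target
        r, _, _ = kabsch(p, q)
        assert np.linalg.det(r) == pytest.approx(1.0, rel=1e-9)
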