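import math

import numpy as np
import pytest

from ribodyn import traj_analysis as ta
from ribodyn.peakio import Atom, ResidueID, StructureModel, Trajectory
from ribodyn.synthetic_data import GeneratorSpec, gen_trajectory, make_helix


def _traj_from_frames(atoms, frames):
    return Trajectory(StructureModel(atoms=list(atoms)),
                      np.asarray(frames, dtype=float))


def _rot(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.cos(angle / 2.0)
    b, c, d = -axis * math.sin(angle / 2.0)
    return np.array([
        [a*a+b*b-c*c-d*d, 2*(b*c+a*d), 2*(b*d-a*c)],
        [2*(b*c-a*d), a*a+c*c-b*b-d*d, 2*(c*d+a*b)],
        [2*(b*d+a*c), 2*(c*d-a*b), a*a+d*d-b*b-c*c]])


BASE_ATOMS = [
    Atom("CA", ResidueID(1, "ALA"), "C", (0.0, 0.0, 0.0)),
    Atom("CA", ResidueID(2, "ALA"), "C", (3.8, 0.0, 0.0)),
    Atom("CA", ResidueID(3, "ALA"), "C", (3.8, 3.8, 0.0)),
    Atom("CA", ResidueID(4, "ALA"), "C", (0.0, 3.8, 2.0)),
    Atom("CA", ResidueID(5, "ALA"), "C", (1.9, 1.9, 4.0)),
]


class TestRmsf:
    def test_identical_frames_zero(self):
        coords = np.array([a.xyz for a in BASE_ATOMS])
        traj = _traj_from_frames(BASE_ATOMS, [coords] * 4)
        out = ta.rmsf(traj, np.arange(5))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_rigid_rotation_invisible(self):
        coords = np.array([a.xyz for a in BASE_ATOMS])
        frames = [coords,
                  coords @ _rot([0, 0, 1], 0.7),
                  coords @ _rot([1, 1, 0], -0.3) + [5.0, -2.0, 1.0]]
        traj = _traj_from_frames(BASE_ATOMS, frames)
        out = ta.rmsf(traj, np.arange(5))
        np.testing.assert_allclose(out, 0.0, atol=1e-8)

    def test_single_displaced_atom_hand_oracle(self):
        atoms = BASE_ATOMS + [Atom("CA", ResidueID(6, "ALA"), "C",
                                   (10.0, 0.0, 0.0))]
        coords = np.array([a.xyz for a in atoms])
        up = coords.copy()
        up[5, 2] += 1.0
        down = coords.copy()
        down[5, 2] -= 1.0
        traj = _traj_from_frames(atoms, [up, down])
        out = ta.rmsf(traj, np.arange(5))  # superpose on the rigid base
        np.testing.assert_allclose(out[:5], 0.0, atol=1e-10)
        assert out[5] == pytest.approx(1.0, rel=1e-10)

    def test_degenerate_selection_raises(self):
        coords = np.array([a.xyz for a in BASE_ATOMS])
        line = [Atom("CA", ResidueID(i + 1, "ALA"), "C", (float(i), 0.0, 0.0))
                for i in range(4)]
        traj = _traj_from_frames(line, [np.array([a.xyz for a in line])] * 2)
        with pytest.raises(ValueError, match="degenerate"):
            ta.rmsf(traj, np.arange(4))

    def test_needs_two_frames(self):
        coords = np.array([a.xyz for a in BASE_ATOMS])
        traj = _traj_from_frames(BASE_ATOMS, [coords])
        with pytest.raises(ValueError):
            ta.rmsf(traj, np.arange(5))

    def test_gaussian_jitter_closed_form(self):
        # rmsf of an atom with isotropic per-coordinate sigma tends to
        # sigma*sqrt(3)*sqrt(1-1/F); anchor atoms keep superposition exact
        sigma, frames = 0.4, 400
        helix = make_helix(6)
        jitter = np.zeros(len(helix.atoms))
        jitter[-1] = sigma
        spec = GeneratorSpec(seed=99)
        traj, truth = gen_trajectory(spec, protein_template=helix,
                                     n_waters=0, n_frames=frames,
                                     jitter_A=jitter)
        rigid = np.nonzero(jitter == 0)[0]
        out = ta.rmsf(traj, rigid)
        expect = sigma * math.sqrt(3.0) * math.sqrt(1.0 - 1.0 / frames)
        assert out[-1] == pytest.approx(expect, rel=0.10)


def _hbond_oracle(traj, donors, acceptors, criteria, convention):
    """Brute-force per-frame loop evaluation, independent of the
    vectorized implementation."""
    out = {}
    for d_idx, h_idx in donors:
        if h_idx is None:
            continue
        hits = 0
        for f in range(traj.n_frames):
            found = False
            for a_idx in acceptors:
                if a_idx == d_idx:
                    continue
                d = traj.frames[f, d_idx]
                h = traj.frames[f, h_idx]
                a = traj.frames[f, a_idx]
                if math.dist(d, a) > criteria.distance_cut:
                    continue
                if convention == "dha":
                    v1, v2 = d - h, a - h
                else:
                    v1, v2 = a - d, h - d
                cosang = float(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                ok = (ang >= 180.0 - criteria.angle_cut
                      if convention == "dha" else ang <= criteria.angle_cut)
                if ok:
                    found = True
                    break
            hits += found
        out[d_idx] = 100.0 * hits / traj.n_frames
    return out


class TestHbonds:
    def _static(self, acceptor_xyz):
        atoms = [Atom("N", ResidueID(1, "ALA"), "N", (0.0, 0.0, 0.0)),
                 Atom("H", ResidueID(1, "ALA"), "H", (1.0, 0.0, 0.0)),
                 Atom("O", ResidueID(2, "ALA"), "O", tuple(acceptor_xyz))]
        coords = np.array([a.xyz for a in atoms])
        return _traj_from_frames(atoms, [coords] * 3)

    def test_ideal_linear_bond_full_lifetime(self):
        traj = self._static((2.9, 0.0, 0.0))
        out = ta.hbond_lifetimes(traj, [(0, 1)], [2])
        assert out[0] == 100.0

    def test_beyond_distance_cut_zero(self):
        traj = self._static((3.6, 0.0, 0.0))
        out = ta.hbond_lifetimes(traj, [(0, 1)], [2])
        assert out[0] == 0.0

    def test_bent_geometry_rejected(self):
        # acceptor at right angle from the N-H direction, inside 3.5 A
        traj = self._static((0.0, 3.0, 0.0))
        out = ta.hbond_lifetimes(traj, [(0, 1)], [2])
        assert out[0] == 0.0

    def test_missing_hydrogen_skipped(self, caplog):
        traj = self._static((2.9, 0.0, 0.0))
        with caplog.at_level("WARNING"):
            out = ta.hbond_lifetimes(traj, [(0, None)], [2])
        assert out == {}
        assert "no attached hydrogen" in caplog.text

    @pytest.mark.parametrize("convention", ["dha", "adh"])
    def test_matches_brute_force_oracle_50_seeds(self, convention):
        crit = ta.HbondCriteria()
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_at, n_frames = 9, 25
            atoms = ([Atom("N", ResidueID(i + 1, "ALA"), "N", (0.0, 0.0, 0.0))
                      for i in range(3)]
                     + [Atom("H", ResidueID(i + 1, "ALA"), "H",
                             (0.0, 0.0, 0.0)) for i in range(3)]
                     + [Atom("O", ResidueID(i + 4, "ALA"), "O",
                             (0.0, 0.0, 0.0)) for i in range(3)])
            frames = rng.uniform(-3.0, 3.0, size=(n_frames, n_at, 3))
            traj = _traj_from_frames(atoms, frames)
            donors = [(0, 3), (1, 4), (2, 5)]
            acceptors = [6, 7, 8]
            got = ta.hbond_lifetimes(traj, donors, acceptors, crit,
                                     convention)
            want = _hbond_oracle(traj, donors, acceptors, crit, convention)
            assert got == want, f"seed {seed}"

    def test_planted_occupancy_recovered_exactly(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=0, n_frames=50,
                                     planted_hbonds=(0.9, 0.6, 0.25))
        donors = [(h["donor"], h["hydrogen"]) for h in truth["hbonds"]]
        acceptors = [h["acceptor"] for h in truth["hbonds"]]
        got = ta.hbond_lifetimes(traj, donors, acceptors)
        for h in truth["hbonds"]:
            assert got[h["donor"]] == h["occupancy_pct"]

    def test_freedom_complements_lifetime(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=0, n_frames=50,
                                     planted_hbonds=(0.9,))
        h = truth["hbonds"][0]
        freedom = ta.hbond_freedom(traj, [(h["donor"], h["hydrogen"])],
                                   [h["acceptor"]])
        (val,) = freedom.values()
        assert val == pytest.approx(1.0 - 0.9)


class TestHydrationGrid:
    def test_count_conservation(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=40, n_frames=30)
        grid = ta.hydration_grid(traj, truth["water_indices"],
                                 truth["protein_indices"])
        # oracle: recount in-shell observations frame by frame
        atoms = traj.topology.atoms
        heavy = [i for i in truth["protein_indices"]
                 if atoms[i].element != "H"]
        radii = np.array([ta.vdw_radius(atoms[i].element) for i in heavy])
        expected = 0
        for f in range(traj.n_frames):
            for w in truth["water_indices"]:
                dmin = min(np.linalg.norm(traj.frames[f, w]
                                          - traj.frames[f, h]) - r
                           for h, r in zip(heavy, radii))
                expected += dmin <= grid.shell2_max
        assert grid.total_count == expected

    def test_pinned_water_is_top_site(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=40, n_frames=50,
                                     planted_site=(5.0, 0.0, 5.0))
        grid = ta.hydration_grid(traj, truth["water_indices"],
                                 truth["protein_indices"])
        xyz, dens = grid.mdhs[0]
        assert np.linalg.norm(np.array(xyz) - (5.0, 0.0, 5.0)) < 0.9
        assert dens > 2.0

    def test_uniform_waters_no_sites_with_dense_statistics(self):
        spec = GeneratorSpec(seed=13)
        traj, truth = gen_trajectory(spec, protein_template=make_helix(3),
                                     n_waters=150, n_frames=400)
        grid = ta.hydration_grid(traj, truth["water_indices"],
                                 truth["protein_indices"], spacing=2.0)
        assert grid.mdhs == []
        shell = grid.normalized[(grid.counts > 0)]
        assert 0.2 < float(np.median(shell)) < 2.0

    def test_translation_equivariance(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=40, n_frames=20)
        grid_a = ta.hydration_grid(traj, truth["water_indices"],
                                   truth["protein_indices"])
        shift = np.array([3.1, -2.2, 5.7])
        moved = Trajectory(
            StructureModel(atoms=[
                Atom(a.name, a.residue, a.element,
                     tuple(np.array(a.xyz) + shift))
                for a in traj.topology.atoms]),
            traj.frames + shift)
        grid_b = ta.hydration_grid(moved, truth["water_indices"],
                                   truth["protein_indices"])
        np.testing.assert_array_equal(grid_a.counts, grid_b.counts)
        np.testing.assert_allclose(grid_b.origin - grid_a.origin, shift,
                                   atol=1e-9)

    def test_no_waters_raises_normalization_error(self):
        spec = GeneratorSpec(seed=6)
        traj, truth = gen_trajectory(spec, n_waters=0, n_frames=5,
                                     planted_hbonds=(1.0,))
        with pytest.raises(ta.NormalizationError):
            ta.hydration_grid(traj, [], truth["protein_indices"])


def _depth_mc_oracle(coords, radii, target, probe, n=10**6, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-probe, probe, size=(n, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= probe] + coords[target]
    outside_own = (np.linalg.norm(pts - coords[target], axis=1)
                   > radii[target])
    outside_all = outside_own.copy()
    for i, (c, r) in enumerate(zip(coords, radii)):
        if i == target:
            continue
        outside_all &= np.linalg.norm(pts - c, axis=1) > r
    return 2.0 * outside_all.sum() / outside_own.sum()


class TestAtomDepth:
    def _pair(self, sep):
        return StructureModel(atoms=[
            Atom("O", ResidueID(1, "UNK"), "O", (0.0, 0.0, 0.0)),
            Atom("C", ResidueID(2, "UNK"), "C", (sep, 0.0, 0.0))])

    def test_isolated_atom_exactly_two(self):
        s = StructureModel(atoms=[Atom("O", ResidueID(1, "UNK"), "O",
                                       (0.0, 0.0, 0.0))])
        prof = ta.atom_depth(s)
        assert prof.D[0] == pytest.approx(2.0, abs=1e-12)

    def test_buried_centre_of_cluster(self):
        atoms = [Atom("C", ResidueID(1, "UNK"), "C", (0.0, 0.0, 0.0))]
        n = 3
        k = 0
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                for l in range(-n, n + 1):
                    if (i, j, l) == (0, 0, 0):
                        continue
                    k += 1
                    atoms.append(Atom("C", ResidueID(k + 1, "UNK"), "C",
                                      (2.0 * i, 2.0 * j, 2.0 * l)))
        prof = ta.atom_depth(StructureModel(atoms=atoms),
                             atom_indices=[0])
        assert prof.D[0] < 0.3

    @pytest.mark.parametrize("sep", [1.5, 3.0, 6.0])
    def test_two_atom_monte_carlo_oracle(self, sep):
        s = self._pair(sep)
        prof = ta.atom_depth(s)
        radii = np.array([ta.vdw_radius("O"), ta.vdw_radius("C")])
        want = _depth_mc_oracle(s.coords, radii, 0, 8.0)
        assert prof.D[0] == pytest.approx(want, rel=0.01)

    def test_monotone_under_added_neighbours(self):
        d_alone = ta.atom_depth(StructureModel(atoms=[
            Atom("O", ResidueID(1, "UNK"), "O", (0.0, 0.0, 0.0))])).D[0]
        prev = d_alone
        atoms = [Atom("O", ResidueID(1, "UNK"), "O", (0.0, 0.0, 0.0))]
        for k, pos in enumerate([(2.0, 0, 0), (-2.0, 0, 0), (0, 2.0, 0)]):
            atoms.append(Atom("C", ResidueID(k + 2, "UNK"), "C",
                              tuple(float(x) for x in pos)))
            d = ta.atom_depth(StructureModel(atoms=list(atoms)),
                              atom_indices=[0]).D[0]
            assert d <= prev + 1e-12
            prev = d

    def test_probe_must_exceed_vdw(self):
        with pytest.raises(ValueError):
            ta.atom_depth(self._pair(3.0), probe_radius=1.0)
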