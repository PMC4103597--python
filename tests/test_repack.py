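import numpy as np
import pytest

from memqa._chem import CHI_ATOMS, HYDROPATHY, VDW_RADII
from memqa.features import MembraneSpec, membrane_depth
from memqa.geometry_eval import circular_difference, compute_chi_angles, tm_score
from memqa.model_io import Atom, Residue, StructureModel
from memqa.repack import (PackingParams, backbone_dihedrals, builtin_library,
                          generate_decoys, packing_energy, place_side_chain,
                          read_rotamer_library, repack, write_rotamer_library,
                          _MIN_ROT_PROB)

BB = {"N": np.array([0.0, 0.0, 0.0]),
      "CA": np.array([1.458, 0.0, 0.0]),
      "C": np.array([2.0, 1.42, 0.0])}


class TestBackboneDihedrals:
    def test_ideal_helix_values(self, single_helix):
        dih = backbone_dihedrals(single_helix)
        for phi, psi in dih[1:-1]:
            assert abs(phi - (-57.0)) < 1.0
            assert abs(psi - (-47.0)) < 1.0

    def test_termini_undefined(self, single_helix):
        dih = backbone_dihedrals(single_helix)
        assert dih[0][0] is None and dih[-1][1] is None

    def test_single_residue_chain(self):
        res = Residue(1, " ", "GLY", [
            Atom("N", "N", BB["N"]), Atom("CA", "C", BB["CA"]),
            Atom("C", "C", BB["C"]), Atom("O", "O", [2.0, 2.0, 1.0])])
        m = StructureModel("t", "m", [("A", [res])])
        assert backbone_dihedrals(m) == [(None, None)]

    def test_builder_round_trip(self):
        """Backbone rebuilt from stated phi/psi reproduces them."""
        from memqa.geometry_eval import place_atom, dihedral
        from memqa._chem import (ANG_CA_C_N, ANG_C_N_CA, ANG_N_CA_C,
                                 BB_CA_C, BB_C_N, BB_N_CA)
        phi, psi = -73.0, 140.0
        N = [np.zeros(3)]
        CA = [np.array([BB_N_CA, 0, 0])]
        ang = np.radians(ANG_N_CA_C)
        C = [CA[0] + BB_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
        for i in range(1, 4):
            N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], BB_C_N,
                                ANG_CA_C_N, psi))
            CA.append(place_atom(CA[i - 1], C[i - 1], N[i], BB_N_CA,
                                 ANG_C_N_CA, 180.0))
            C.append(place_atom(C[i - 1], N[i], CA[i], BB_CA_C,
                                ANG_N_CA_C, phi))
        assert dihedral(C[0], N[1], CA[1], C[1]) == pytest.approx(phi, abs=1e-3)
        assert dihedral(N[0], CA[0], C[0], N[1]) == pytest.approx(psi, abs=1e-3)


class TestPlaceSideChain:
    def test_ala_places_only_cb(self):
        side = place_side_chain("ALA", BB, [])
        assert list(side) == ["CB"]

    def test_leu_round_trip(self):
        side = place_side_chain("LEU", BB, [-60.0, 180.0])
        atoms = [Atom("N", "N", BB["N"]), Atom("CA", "C", BB["CA"]),
                 Atom("C", "C", BB["C"])]
        atoms += [Atom(nm, nm[0], c) for nm, c in side.items()]
        rec = compute_chi_angles(Residue(1, " ", "LEU", atoms))
        assert circular_difference(rec.chi[0], -60.0) < 1e-6
        assert circular_difference(rec.chi[1], 180.0) < 1e-6

    def test_deterministic_bitwise(self):
        a = place_side_chain("ARG", BB, [-60.0, 180.0, 180.0, 180.0])
        b = place_side_chain("ARG", BB, [-60.0, 180.0, 180.0, 180.0])
        for nm in a:
            assert np.array_equal(a[nm], b[nm])

    def test_wrong_chi_count_raises(self):
        with pytest.raises(ValueError, match="chi"):
            place_side_chain("LEU", BB, [-60.0])


class TestRotamerLibrary:
    def test_probabilities_normalized_everywhere(self):
        lib = builtin_library()
        for rots in list(lib.fallback.values()) + list(lib.entries.values()):
            assert sum(r.prob for r in rots) == pytest.approx(1.0, abs=1e-6)

    def test_every_chi_bearing_type_covered(self):
        lib = builtin_library()
        for aa, chis in CHI_ATOMS.items():
            if not chis:
                continue
            rots = lib.get(aa, None, None)
            assert rots
            assert all(len(r.chis) == len(chis) for r in rots)

    def test_backbone_dependence(self):
        lib = builtin_library()
        helix = lib.get("MET", -60.0, -45.0)
        fallback = lib.get("MET", None, None)
        assert max(r.prob for r in helix) != max(r.prob for r in fallback)

    def test_file_round_trip(self, tmp_path):
        lib = builtin_library()
        p = tmp_path / "rotlib.tsv"
        write_rotamer_library(lib, p)
        back = read_rotamer_library(p)
        assert set(back.fallback) == set(lib.fallback)
        for aa in lib.fallback:
            got = back.fallback[aa]
            want = lib.fallback[aa]
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.prob == pytest.approx(w.prob, abs=1e-6)
                assert np.allclose(g.chis, w.chis, atol=0.01)

    def test_nearest_picks_closest_rotamer(self):
        lib = builtin_library()
        rot = lib.nearest("SER", None, None, [179.0])
        assert rot.chis[0] == pytest.approx(180.0)


def _two_atom_model(d):
    # side-chain (CB) carbons on non-adjacent residues; a far-away spacer
    # residue sits between them
    res1 = Residue(1, " ", "ALA", [Atom("CB", "C", [0.0, 0, 0])])
    spacer = Residue(2, " ", "GLY", [Atom("CA", "C", [500.0, 0, 0])])
    res3 = Residue(3, " ", "ALA", [Atom("CB", "C", [d, 0.0, 0.0])])
    return StructureModel("t", "m", [("A", [res1, spacer, res3])])


class TestPackingEnergy:
    def test_distant_atoms_no_steric(self):
        params = PackingParams(rotamer_weight=0.0, membrane_weight=0.0)
        assert packing_energy(_two_atom_model(100.0), params) == 0.0

    def test_closed_form_clash_penalty(self):
        params = PackingParams(rotamer_weight=0.0, membrane_weight=0.0)
        r = VDW_RADII["C"]
        d = 0.5 * (2 * r)
        expected = (0.8 * 2 * r - d) ** 2
        got = packing_energy(_two_atom_model(d), params)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_bruteforce_term_oracle(self, scrambled_bundle):
        """Steric / rotamer / membrane terms recomputed independently."""
        params = PackingParams()
        spec = MembraneSpec()
        got = packing_energy(scrambled_bundle, params, spec)

        coords, owners = scrambled_bundle.heavy_coords()
        residues = scrambled_bundle.residues()
        bb = {"N", "CA", "C", "O"}
        steric = 0.0
        for a in range(len(owners)):
            for b in range(a + 1, len(owners)):
                ri, ai = owners[a]
                rj, aj = owners[b]
                if ri == rj:
                    continue
                both_bb = ai.name in bb and aj.name in bb
                both_bbcb = ai.name in (bb | {"CB"}) and aj.name in (bb | {"CB"})
                if both_bb or (abs(ri - rj) == 1 and both_bbcb):
                    continue
                d = np.linalg.norm(coords[a] - coords[b])
                rsum = VDW_RADII[ai.element] + VDW_RADII[aj.element]
                steric += max(0.0, 0.8 * rsum - d) ** 2

        lib = builtin_library()
        dih = backbone_dihedrals(scrambled_bundle)
        rot = 0.0
        for res, (phi, psi) in zip(residues, dih):
            if not CHI_ATOMS[res.aa_type]:
                continue
            chis = compute_chi_angles(res).chi
            best = None
            for cand in lib.get(res.aa_type, phi, psi):
                gaps = [circular_difference(c, m)
                        for c, m in zip(chis, cand.chis) if c is not None]
                key = (max(gaps) if gaps else 0.0, -cand.prob)
                if best is None or key < best[0]:
                    best = (key, cand.prob)
            rot += -np.log(max(best[1], _MIN_ROT_PROB))

        _, regions = membrane_depth(scrambled_bundle, spec)
        mem = 0.0
        for res, region in zip(residues, regions):
            hp = HYDROPATHY[res.aa_type] / 4.5
            if region == "core":
                mem += max(0.0, -hp)
            elif region == "water":
                mem += max(0.0, hp)

        expected = params.steric_weight * steric + \
            params.rotamer_weight * rot + params.membrane_weight * mem
        assert got == pytest.approx(expected, rel=1e-9)


class TestRepack:
    def test_backbone_bit_identical(self, scrambled_bundle):
        result = repack(scrambled_bundle, seed=3)
        for r0, r1 in zip(scrambled_bundle.residues(), result.model.residues()):
            for nm in ("N", "CA", "C", "O"):
                assert np.array_equal(r0.coord(nm), r1.coord(nm))

    def test_tm_score_unchanged(self, bundle, scrambled_bundle):
        result = repack(scrambled_bundle, seed=3)
        before = tm_score(scrambled_bundle, bundle).score
        after = tm_score(result.model, bundle).score
        assert after == pytest.approx(before, abs=1e-9)

    def test_energy_descends_on_clashed_input(self, scrambled_bundle):
        result = repack(scrambled_bundle, seed=3)
        assert result.final_energy < result.energy_trace[0]

    def test_trace_non_increasing_from_initialization(self, scrambled_bundle):
        trace = repack(scrambled_bundle, seed=5).energy_trace
        post_init = trace[1:]
        assert all(a >= b - 1e-9 for a, b in zip(post_init, post_init[1:]))

    def test_final_energy_matches_packing_energy(self, scrambled_bundle):
        result = repack(scrambled_bundle, seed=3)
        assert packing_energy(result.model) == pytest.approx(
            result.final_energy, rel=1e-9)

    def test_deterministic(self, scrambled_bundle):
        a = repack(scrambled_bundle, seed=11)
        b = repack(scrambled_bundle, seed=11)
        for r0, r1 in zip(a.model.residues(), b.model.residues()):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert np.array_equal(a0.coord, a1.coord)
        assert a.energy_trace == b.energy_trace

    def test_repack_is_fixed_point(self, scrambled_bundle):
        """Repacking a repacked model with the same seed reproduces it
        exactly: the greedy optimum is a fixed point and converges in one
        extra sweep."""
        first = repack(scrambled_bundle, seed=3)
        second = repack(first.model, seed=3)
        assert second.final_energy == pytest.approx(first.final_energy,
                                                    abs=1e-9)
        for r0, r1 in zip(first.model.residues(), second.model.residues()):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert np.array_equal(a0.coord, a1.coord)
        # input already at the optimum: its energy equals the final energy
        assert second.energy_trace[0] == pytest.approx(second.final_energy,
                                                       rel=1e-9)

    def test_native_chi_floor(self, bundle):
        """Repacking a well-packed native keeps side chains mostly right."""
        from memqa.geometry_eval import chi_correctness
        result = repack(bundle, seed=9)
        assert chi_correctness(result.model, bundle) >= 0.6


class TestStochasticVariants:
    def test_annealing_descends_and_keeps_backbone(self, scrambled_bundle):
        params = PackingParams(anneal=True, max_sweeps=6)
        result = repack(scrambled_bundle, params=params, seed=13)
        assert result.final_energy < result.energy_trace[0]
        assert packing_energy(result.model) == pytest.approx(
            result.final_energy, rel=1e-9)
        for r0, r1 in zip(scrambled_bundle.residues(), result.model.residues()):
            for nm in ("N", "CA", "C", "O"):
                assert np.array_equal(r0.coord(nm), r1.coord(nm))

    def test_annealing_deterministic_per_seed(self, scrambled_bundle):
        params = PackingParams(anneal=True, max_sweeps=6)
        a = repack(scrambled_bundle, params=params, seed=13)
        b = repack(scrambled_bundle, params=params, seed=13)
        assert a.energy_trace == b.energy_trace

    def test_chi_jitter_perturbs_rotamers(self, scrambled_bundle):
        params = PackingParams(jitter_sd_scale=1.0)
        jittered = repack(scrambled_bundle, params=params, seed=3)
        plain = repack(scrambled_bundle, seed=3)
        assert packing_energy(jittered.model) == pytest.approx(
            jittered.final_energy, rel=1e-6)
        # jittered chis deviate from the exact rotamer means
        diffs = []
        for r0, r1 in zip(plain.model.residues(), jittered.model.residues()):
            a0 = compute_chi_angles(r0)
            a1 = compute_chi_angles(r1)
            diffs += [circular_difference(x, y)
                      for x, y in zip(a0.chi, a1.chi)
                      if x is not None and y is not None]
        assert max(diffs) > 1.0
        for r0, r1 in zip(scrambled_bundle.residues(),
                          jittered.model.residues()):
            for nm in ("N", "CA", "C", "O"):
                assert np.array_equal(r0.coord(nm), r1.coord(nm))


class TestGenerateDecoys:
    def test_default_count(self, scrambled_bundle):
        assert len(generate_decoys(scrambled_bundle, base_seed=1)) == 10

    def test_bitwise_reproducible(self, scrambled_bundle):
        a = generate_decoys(scrambled_bundle, n=3, base_seed=5)
        b = generate_decoys(scrambled_bundle, n=3, base_seed=5)
        for da, db in zip(a, b):
            for r0, r1 in zip(da.model.residues(), db.model.residues()):
                for a0, a1 in zip(r0.atoms, r1.atoms):
                    assert np.array_equal(a0.coord, a1.coord)

    def test_single_decoy_reduces_to_repack(self, scrambled_bundle):
        decoy, = generate_decoys(scrambled_bundle, n=1, base_seed=20)
        direct = repack(scrambled_bundle, seed=21)
        for r0, r1 in zip(decoy.model.residues(), direct.model.residues()):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert np.array_equal(a0.coord, a1.coord)

    def test_shared_backbone(self, scrambled_bundle):
        for decoy in generate_decoys(scrambled_bundle, n=3, base_seed=2):
            for r0, r1 in zip(scrambled_bundle.residues(),
                              decoy.model.residues()):
                for nm in ("N", "CA", "C", "O"):
                    assert np.array_equal(r0.coord(nm), r1.coord(nm))

    def test_invalid_n(self, scrambled_bundle):
        with pytest.raises(ValueError):
            generate_decoys(scrambled_bundle, n=0, base_seed=1)
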