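import logging

import numpy as np
import pytest

from memqa._chem import ATOM_CLASSES, VDW_RADII, atom_class
from memqa.features import (MembraneSpec, SequenceProfile, _sphere_points,
                            assign_secondary_structure, atom_contact_counts,
                            build_feature_matrix, membrane_depth,
                            read_profile, residue_contact_counts,
                            shrake_rupley_sasa, write_profile,
                            base_feature_names)
from memqa.geometry_eval import place_atom
from memqa.model_io import Atom, Residue, StructureModel
from memqa.synthetic import make_helix_bundle, make_profile
from memqa._chem import (ANG_CA_C_N, ANG_CA_C_O, ANG_C_N_CA, ANG_N_CA_C,
                         BB_CA_C, BB_C_N, BB_C_O, BB_N_CA)


def _ca_only(positions, aa="GLY"):
    residues = [Residue(i + 1, " ", aa, [Atom("CA", "C", p)])
                for i, p in enumerate(positions)]
    return StructureModel("t", "m", [("A", residues)])


# ---------------------------------------------------------------------------
# SASA

class TestSASA:
    def test_isolated_carbon_matches_sphere_area(self):
        m = _ca_only([[0.0, 0.0, 0.0]])
        res = shrake_rupley_sasa(m)
        expected = 4.0 * np.pi * (1.87 + 1.4) ** 2
        assert res.atom_sasa[0] == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_are_additive(self):
        m = _ca_only([[0.0, 0, 0], [100.0, 0, 0]])
        res = shrake_rupley_sasa(m)
        iso = 4.0 * np.pi * (1.87 + 1.4) ** 2
        assert res.atom_sasa.sum() == pytest.approx(2 * iso, rel=0.01)

    def test_fully_caged_atom_is_zero(self):
        cage = 2.0 * _sphere_points(40)
        m = _ca_only(np.vstack([[0.0, 0.0, 0.0], cage]))
        res = shrake_rupley_sasa(m)
        assert res.atom_sasa[0] == 0.0

    def test_agrees_with_bruteforce_neighbour_oracle(self):
        """All-pairs naive recomputation on a ~50-residue bundle."""
        bundle = make_helix_bundle(4, 11, seed=13)
        res = shrake_rupley_sasa(bundle)
        coords, owners = bundle.heavy_coords()
        radii = np.array([VDW_RADII[a.element] for _, a in owners])
        pts = _sphere_points(960)
        inflated = radii + 1.4
        brute = np.empty(len(coords))
        for k in range(len(coords)):
            sample = coords[k] + inflated[k] * pts
            others = np.ones(len(coords), dtype=bool)
            others[k] = False
            d2 = ((sample[:, None, :] - coords[None, others, :]) ** 2).sum(axis=2)
            free = np.all(d2 > (inflated[others] ** 2)[None, :], axis=1)
            brute[k] = free.mean() * 4 * np.pi * inflated[k] ** 2
        np.testing.assert_allclose(res.atom_sasa, brute, atol=1e-9)

    def test_monotone_under_added_neighbours(self):
        lonely = shrake_rupley_sasa(_ca_only([[0.0, 0, 0]])).atom_sasa[0]
        crowded = shrake_rupley_sasa(
            _ca_only([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])).atom_sasa[0]
        assert crowded < lonely

    def test_sampling_convergence(self, bundle):
        a = shrake_rupley_sasa(bundle, n_points=960).residue_sasa.sum()
        b = shrake_rupley_sasa(bundle, n_points=1920).residue_sasa.sum()
        assert abs(a - b) / a < 0.005

    def test_unknown_element_raises(self):
        m = _ca_only([[0.0, 0, 0]])
        m.residues()[0].atoms[0].element = "XX"
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(m)

    def test_relative_accessibility_in_unit_range(self, bundle):
        res = shrake_rupley_sasa(bundle)
        assert np.all(res.relative >= 0.0) and np.all(res.relative <= 1.0)


# ---------------------------------------------------------------------------
# secondary structure

def _strand_arrays(n, phi=-179.0, psi=179.0):
    N = [np.zeros(3)]
    CA = [np.array([BB_N_CA, 0, 0])]
    ang = np.radians(ANG_N_CA_C)
    C = [CA[0] + BB_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    O = []
    for i in range(1, n):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], BB_C_N, ANG_CA_C_N, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], BB_N_CA, ANG_C_N_CA, 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i], BB_CA_C, ANG_N_CA_C, phi))
    for i in range(n):
        nn = place_atom(N[i], CA[i], C[i], BB_C_N, ANG_CA_C_N, psi)
        O.append(place_atom(nn, CA[i], C[i], BB_C_O, ANG_CA_C_O, 180.0))
    return [np.array(x) for x in (N, CA, C, O)]


def _backbone_model(chains):
    out = []
    for ci, (N, CA, C, O) in enumerate(chains):
        res = [Residue(i + 1, " ", "GLY",
                       [Atom("N", "N", N[i]), Atom("CA", "C", CA[i]),
                        Atom("C", "C", C[i]), Atom("O", "O", O[i])])
               for i in range(len(N))]
        out.append((chr(65 + ci), res))
    return StructureModel("s", "s", out)


class TestSecondaryStructure:
    def test_ideal_helix_mostly_H(self, single_helix):
        labels = assign_secondary_structure(single_helix)
        assert labels.count("H") >= 14

    def test_two_residue_peptide_all_coil(self):
        s = _strand_arrays(2)
        assert assign_secondary_structure(_backbone_model([s])) == ["C", "C"]

    def test_antiparallel_sheet_central_E(self):
        """Two flat extended strands paired by a two-fold rotation (the
        symmetry of an ideal antiparallel ladder) produce E labels."""
        s1 = _strand_arrays(8)
        px, py = 10.6, 3.9
        s2 = [np.column_stack([2 * px - a[:, 0], 2 * py - a[:, 1], a[:, 2]])
              for a in s1]
        labels = assign_secondary_structure(_backbone_model([s1, s2]))
        assert "".join(labels[:8]).count("E") >= 4
        assert "".join(labels[8:]).count("E") >= 4
        assert labels[2] == "E" and labels[10] == "E"

    def test_missing_backbone_is_coil(self, bundle):
        broken = bundle.copy()
        broken.residues()[20].atoms = [
            a for a in broken.residues()[20].atoms if a.name != "O"]
        labels = assign_secondary_structure(broken)
        assert labels[20] == "C"


# ---------------------------------------------------------------------------
# contacts

def _brute_atom_contacts(model, cutoff=4.5):
    coords, owners = model.heavy_coords()
    residues = model.residues()
    ch = model.chain_index()
    out = np.zeros((model.n_residues(), len(ATOM_CLASSES)))
    for i in range(model.n_residues()):
        mine = [a.coord for a in residues[i].heavy_atoms()]
        for j_atom, (rj, aj) in enumerate(owners):
            if rj == i or (ch[rj] == ch[i] and abs(rj - i) <= 1):
                continue
            if min(np.linalg.norm(coords[j_atom] - c) for c in mine) < cutoff:
                out[i, ATOM_CLASSES.index(atom_class(residues[rj].aa_type,
                                                     aj.name))] += 1
    return out


class TestContacts:
    def test_distant_residues_zero(self):
        m = _ca_only([[0.0, 0, 0], [100.0, 0, 0]])
        assert atom_contact_counts(m).sum() == 0
        assert residue_contact_counts(m).sum() == 0

    @pytest.mark.parametrize("d,expected", [(4.49, 1), (4.51, 0)])
    def test_atom_cutoff_half_open(self, d, expected):
        m = _ca_only([[0.0, 0, 0], [100.0, 0, 0], [d, 0, 0]])
        counts = atom_contact_counts(m)
        assert counts[0].sum() == expected
        assert counts[2].sum() == expected

    @pytest.mark.parametrize("d,expected", [(7.9, 1), (8.1, 0)])
    def test_residue_cutoff_boundary(self, d, expected):
        m = _ca_only([[0.0, 0, 0], [100.0, 0, 0], [d, 0, 0]])
        counts = residue_contact_counts(m)
        assert counts[0].sum() == expected

    @pytest.mark.parametrize("seed", [3, 17, 29])
    def test_bruteforce_recount_agreement(self, seed):
        bundle = make_helix_bundle(3, 10, seed=seed)
        fast = atom_contact_counts(bundle)
        assert np.array_equal(fast, _brute_atom_contacts(bundle))

    def test_residue_contacts_match_bruteforce(self, bundle):
        fast = residue_contact_counts(bundle)
        residues = bundle.residues()
        ch = bundle.chain_index()
        cb = [r.coord("CA") if r.aa_type == "GLY" else r.coord("CB")
              for r in residues]
        from memqa._chem import AA_ONE
        brute = np.zeros_like(fast)
        for i in range(len(residues)):
            for j in range(len(residues)):
                if i == j or (ch[i] == ch[j] and abs(i - j) <= 1):
                    continue
                if np.linalg.norm(cb[i] - cb[j]) < 8.0:
                    brute[i, AA_ONE.index(residues[j].one_letter)] += 1
        assert np.array_equal(fast, brute)

    def test_symmetry(self, bundle):
        counts = residue_contact_counts(bundle)
        # total contact events are symmetric: every contact is counted once
        # from each side, so the grand total is even
        assert counts.sum() % 2 == 0


# ---------------------------------------------------------------------------
# membrane depth

class TestMembraneDepth:
    @pytest.mark.parametrize("z,region", [(0.0, "core"), (15.1, "interface"),
                                          (25.0, "water")])
    def test_regions(self, z, region):
        m = _ca_only([[0.0, 0.0, z]])
        depths, labels = membrane_depth(m)
        assert depths[0] == pytest.approx(abs(z))
        assert labels[0] == region

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            MembraneSpec(half_thickness=0.0)


# ---------------------------------------------------------------------------
# profiles

class TestProfileIO:
    def test_round_trip(self, tmp_path, bundle, bundle_profile):
        p = tmp_path / "profile.tsv"
        write_profile(bundle_profile, p)
        back = read_profile(p, bundle_profile.sequence)
        np.testing.assert_allclose(back.pssm, bundle_profile.pssm, atol=1e-4)
        np.testing.assert_allclose(back.pred_ss, bundle_profile.pred_ss,
                                   atol=1e-6)
        assert back.pred_topology == bundle_profile.pred_topology

    def test_length_mismatch(self, tmp_path, bundle_profile):
        p = tmp_path / "profile.tsv"
        write_profile(bundle_profile, p)
        with pytest.raises(ValueError, match="rows"):
            read_profile(p, bundle_profile.sequence + "A")

    def test_offsimplex_row_renormalized_with_warning(self, tmp_path, caplog):
        prof = SequenceProfile("A", np.zeros((1, 20)),
                               np.array([[1 / 3, 1 / 3, 1 / 3]]),
                               np.array([0.5]), ["membrane"])
        p = tmp_path / "profile.tsv"
        write_profile(prof, p)
        text = p.read_text().splitlines()
        fields = text[2].split("\t")
        fields[22:25] = ["0.500000", "0.500000", "0.100000"]
        p.write_text("\n".join(text[:2] + ["\t".join(fields)]) + "\n")
        with caplog.at_level(logging.WARNING, logger="memqa.features"):
            back = read_profile(p, "A")
        assert back.pred_ss[0].sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(back.pred_ss[0],
                                   [0.5 / 1.1, 0.5 / 1.1, 0.1 / 1.1],
                                   atol=1e-6)
        assert any("renormalizing" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# feature matrix

class TestFeatureMatrix:
    def test_shape_contract(self, bundle, bundle_profile):
        fm = build_feature_matrix(bundle, bundle_profile, window=9)
        width = len(base_feature_names()) + 1
        assert fm.values.shape == (bundle.n_residues(), 9 * width)
        assert len(fm.columns) == 9 * width

    def test_terminus_padding(self, bundle, bundle_profile):
        fm = build_feature_matrix(bundle, bundle_profile, window=9)
        width = len(base_feature_names()) + 1
        first = fm.values[0]
        for w in range(4):  # offsets -4 .. -1 fall off the left end
            block = first[w * width:(w + 1) * width]
            assert block[-1] == 1.0  # pad indicator
            assert np.all(block[:-1] == 0.0)
        assert first[4 * width + width - 1] == 0.0  # own position not padded

    def test_chain_permutation_leaves_rows_unchanged(self, bundle_profile):
        m = make_helix_bundle(2, 12, seed=21)
        # split the single chain into two chains to make order permutable
        (cid, residues), = m.chains
        a, b = residues[:13], residues[13:]
        m1 = StructureModel("t", "m", [("A", a), ("B", b)])
        m2 = StructureModel("t", "m", [("B", b), ("A", a)])
        prof = make_profile(m1, 0.0, seed=3)
        seq_a = "".join(r.one_letter for r in a)
        seq_b = "".join(r.one_letter for r in b)
        prof2 = SequenceProfile(seq_b + seq_a,
                                np.vstack([prof.pssm[13:], prof.pssm[:13]]),
                                np.vstack([prof.pred_ss[13:], prof.pred_ss[:13]]),
                                np.concatenate([prof.pred_burial[13:],
                                                prof.pred_burial[:13]]),
                                prof.pred_topology[13:] + prof.pred_topology[:13])
        f1 = build_feature_matrix(m1, prof).values
        f2 = build_feature_matrix(m2, prof2).values
        n_a = len(a)
        np.testing.assert_allclose(f1[:n_a], f2[len(b):], atol=1e-9)
        np.testing.assert_allclose(f1[n_a:], f2[:len(b)], atol=1e-9)

    def test_rigid_invariance(self, bundle, bundle_profile, rng):
        moved = bundle.copy()
        theta = np.radians(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        for res in moved.residues():
            for a in res.atoms:
                a.coord = R @ a.coord  # rotation about the membrane normal
        f0 = build_feature_matrix(bundle, bundle_profile).values
        f1 = build_feature_matrix(moved, bundle_profile).values
        # SASA columns carry fixed-orientation sphere-sampling noise of
        # about 1%; everything else matches tightly
        np.testing.assert_allclose(f0, f1, atol=0.02)

    def test_profile_mismatch_raises(self, bundle, bundle_profile):
        other = make_helix_bundle(3, 12, seed=99)
        with pytest.raises(ValueError, match="match"):
            build_feature_matrix(other, bundle_profile)
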