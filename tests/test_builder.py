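import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dnaenm.builder import (
    build_structure,
    place_nucleotides,
    propagate_frames,
    write_pdb,
)
from dnaenm.params import HelicalParameterSet, PairParameters, StepParameters
from dnaenm.templates import load_templates


def _params_with_step(step: StepParameters) -> HelicalParameterSet:
    steps = {a + b: step for a in "ACGT" for b in "ACGT"}
    pairs = {b: PairParameters(0, 0, 0, 0, 0, 0) for b in "ACGT"}
    return HelicalParameterSet("test", steps, pairs)


def test_pure_rise_translation():
    p = _params_with_step(StepParameters(0, 0, 3.4, 0, 0, 0))
    fr = propagate_frames("AAAA", p)
    assert np.allclose(fr.origins[:, 2], [0, 3.4, 6.8, 10.2])
    assert np.allclose(fr.origins[:, :2], 0)
    for r in fr.orientations:
        assert np.allclose(r, np.eye(3), atol=1e-12)


def test_twist_closure_ten_steps():
    # 10 steps of 36° twist return the orientation to the start
    p = _params_with_step(StepParameters(0, 0, 3.4, 0, 0, 36.0))
    fr = propagate_frames("A" * 11, p)
    assert np.allclose(fr.orientations[10], fr.orientations[0], atol=1e-9)


def test_generic_step_matches_rotation_composition_oracle():
    # independent composition of the same convention via scipy rotations
    st = StepParameters(0.1, -0.2, 3.3, 2.0, 5.0, 34.0)
    fr = propagate_frames("AA", _params_with_step(st))
    tilt, roll, omega = np.deg2rad([st.tilt, st.roll, st.twist])
    gamma = np.hypot(tilt, roll)
    phi = np.arctan2(tilt, roll)
    rot = (
        Rotation.from_euler("z", omega / 2 - phi)
        * Rotation.from_euler("y", gamma)
        * Rotation.from_euler("z", omega / 2 + phi)
    ).as_matrix()
    mid = (
        Rotation.from_euler("z", omega / 2 - phi)
        * Rotation.from_euler("y", gamma / 2)
        * Rotation.from_euler("z", phi)
    ).as_matrix()
    assert np.allclose(fr.orientations[1], rot, atol=1e-12)
    assert np.allclose(fr.origins[1], mid @ [st.shift, st.slide, st.rise], atol=1e-12)


def test_frames_orthonormal_after_1000_steps(param_set_i):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=1001))
    fr = propagate_frames(seq, param_set_i)
    for r in (fr.orientations[0], fr.orientations[500], fr.orientations[1000]):
        assert np.max(np.abs(r @ r.T - np.eye(3))) < 1e-8
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)


def test_rigid_motion_equivariance(param_set_i):
    seq = "ACGTTGCA"
    base = build_structure(seq, param_set_i)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    shift = np.array([5.0, -2.0, 11.0])
    fr = propagate_frames(seq, param_set_i, origin=shift, orientation=rot)
    moved = place_nucleotides(fr, seq, param_set_i)
    assert np.allclose(moved.coords, base.coords @ rot.T + shift, atol=1e-9)


def test_homopolymer_helical_symmetry(param_set_i):
    s = build_structure("A" * 12, param_set_i, resolution="C1")
    c1 = s.c1_positions()
    n = 12
    # step-to-step C1' geometry identical for interior steps
    d1 = [np.linalg.norm(c1[i + 1] - c1[i]) for i in range(2, n - 3)]
    dpair = [np.linalg.norm(c1[i] - c1[n + i]) for i in range(2, n - 2)]
    assert np.ptp(d1) < 1e-9
    assert np.ptp(dpair) < 1e-9


def test_zero_pair_parameters_mirror_symmetry(flat_params):
    # with all intra-pair parameters zero, the two C1' nodes are mirror
    # images across the frame's short-axis/normal (x-z) plane
    s = build_structure("AGCT", flat_params, resolution="C1")
    c1 = s.c1_positions()
    x1, x2 = c1[0], c1[4]
    assert x1[0] == pytest.approx(x2[0], abs=1e-12)
    assert x1[1] == pytest.approx(-x2[1], abs=1e-12)
    assert x1[2] == pytest.approx(x2[2], abs=1e-12)


def test_intra_pair_c1_distance_single_pair_oracle(param_set_i):
    # direct one-pair evaluation: apply the half-split pair transform to the
    # template C1' positions with an independent rotation implementation
    from dnaenm.templates import C1_PRIME

    for base in "ACGT":
        s = build_structure(base * 4, param_set_i, resolution="C1")
        c1 = s.c1_positions()
        built = np.linalg.norm(c1[0] - c1[4])

        pp = param_set_i.pair(base)
        buck, prop, op = np.deg2rad([pp.buckle, pp.propeller, pp.opening])
        gamma = np.hypot(buck, prop)
        phi = np.arctan2(buck, prop)
        mid = (
            Rotation.from_euler("z", op / 2 - phi)
            * Rotation.from_euler("y", gamma / 2)
            * Rotation.from_euler("z", phi)
        ).as_matrix()
        full = (
            Rotation.from_euler("z", op / 2 - phi)
            * Rotation.from_euler("y", gamma)
            * Rotation.from_euler("z", op / 2 + phi)
        ).as_matrix()
        r2 = mid.T
        r1 = r2 @ full
        half = np.array([pp.shear, pp.stretch, pp.stagger]) / 2
        p1 = r1 @ C1_PRIME + half
        p2 = r2 @ (np.diag([1.0, -1, -1]) @ C1_PRIME) - half
        assert built == pytest.approx(np.linalg.norm(p1 - p2), abs=1e-9)


def test_all_atom_node_count_range(duplex_16):
    n = duplex_16.n_bp
    assert 2 * n * 19 <= duplex_16.n_atoms <= 2 * n * 22


def test_atom_counts_per_base(duplex_16):
    # heavy atoms per full nucleotide: C 19, T 20, A 21, G 22
    expected = {"C": 19, "T": 20, "A": 21, "G": 22}
    ids = duplex_16.nucleotide_id
    n = duplex_16.n_bp
    for k in range(2 * n):
        idx = np.flatnonzero(ids == k)
        base = duplex_16.base[idx[0]]
        count = len(idx)
        if k in (0, 2 * n - 1):  # the two 5'-terminal residues lack PO3
            assert count == expected[base] - 3
        else:
            assert count == expected[base]


def test_c1_resolution_one_node_per_nucleotide(param_set_i):
    s = build_structure("ACGTAC", param_set_i, resolution="C1")
    assert s.n_atoms == 12
    assert set(s.atom_names) == {"C1'"}


def test_backbone_connectivity(duplex_16):
    # successive residues place O3'(i) near P(i+1) on both strands
    s = duplex_16
    links = []
    for strand in (1, 2):
        for i in range(s.n_bp - 1):
            lo, hi = (i, i + 1) if strand == 1 else (i + 1, i)
            o3 = [a for a in np.flatnonzero((s.strand == strand) & (s.pair_index == lo))
                  if s.atom_names[a] == "O3'"]
            p = [a for a in np.flatnonzero((s.strand == strand) & (s.pair_index == hi))
                 if s.atom_names[a] == "P"]
            if o3 and p:
                links.append(np.linalg.norm(s.coords[o3[0]] - s.coords[p[0]]))
    links = np.array(links)
    assert links.size == 2 * (s.n_bp - 1)
    assert links.max() < 2.6 and links.min() > 1.0


def test_pdb_writer_roundtrips_through_reader(tmp_path, param_set_i):
    from dnaenm.pdbio import read_pdb

    s = build_structure("ACGTAG", param_set_i)
    path = tmp_path / "built.pdb"
    write_pdb(s, path)
    cs = read_pdb(path)
    assert cs.sequence == "ACGTAG"
    assert cs.n_atoms == s.n_atoms
    # same set of coordinates to PDB precision (order differs per strand 2)
    got = np.sort(cs.coords.round(3), axis=0)
    want = np.sort(s.coords.round(3), axis=0)
    assert np.allclose(got, want, atol=2e-3)


def test_templates_have_required_atoms():
    for base, tpl in load_templates().items():
        assert tpl.atom_names.count("C1'") == 1
        assert {"P", "OP1", "OP2", "O5'", "O3'"} <= set(tpl.atom_names)
        assert 19 <= len(tpl.atom_names) <= 22
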