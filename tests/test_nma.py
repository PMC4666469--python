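import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dnaenm import nma
from dnaenm.builder import build_structure
from dnaenm.constants import GAS_CONSTANT
from dnaenm.enm import ElasticNetwork, build_cgenm, hessian


def _modes(net, temperature=300.0):
    return nma.normal_modes(hessian(net), temperature=temperature)


def _mc_displacements(modes, n_draws, rng):
    """Independent sampling oracle: thermal displacements from mode amplitudes."""
    amp = np.sqrt(modes.mode_weights)
    out = []
    for start in range(0, n_draws, 200_000):
        m = min(200_000, n_draws - start)
        a = rng.normal(size=(m, amp.size)) * amp
        out.append(a @ modes.vectors.T)  # (m, 3N)
    return np.vstack(out)


def test_free_cgenm_has_exactly_six_zero_modes():
    net = build_cgenm(build_structure("ACGTACGT", resolution="C1"), cg=7.7)
    modes = _modes(net)
    assert modes.n_zero == 6
    assert modes.eigenvalues.min() > 0


def test_fully_restrained_network_has_no_zero_modes():
    from dnaenm.screening import synthetic_crystal
    from dnaenm.enm import build_aaenm

    cs = synthetic_crystal("ACGT", ca=2.0, bb=0.1, bw=0.05, n_waters=4, seed=0)
    net = build_aaenm(cs, ca=2.0, bb=0.1, bw=0.05)
    assert _modes(net).n_zero == 0


def test_two_mass_chain_closed_form():
    pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
    net = ElasticNetwork("AAENM", pos, np.array([[0, 1]]), np.array([1.5]),
                         4.0, np.zeros(2))
    modes = _modes(net)
    # single internal mode with λ = 2C, i.e. ω² = 2C/m
    assert modes.eigenvalues == pytest.approx([8.0])
    assert modes.n_zero == 5
    assert modes.omega_squared == pytest.approx([8.0 / modes.mass])


def test_single_restrained_node_equipartition():
    net = ElasticNetwork("AAENM", np.zeros((1, 3)), np.zeros((0, 2), int),
                         np.zeros(0), 2.0, np.array([0.5]))
    modes = _modes(net, temperature=300.0)
    af = nma.mean_square_fluctuation(modes)
    # isotropic harmonic well of stiffness B·C: AF = 3RT/(B·C)
    assert af[0] == pytest.approx(3 * GAS_CONSTANT * 300 / (0.5 * 2.0))


def test_af_mode_sum_identity(random_network):
    modes = _modes(random_network)
    af = nma.mean_square_fluctuation(modes)
    assert af.sum() == pytest.approx(modes.mode_weights.sum())


def test_af_matches_pseudoinverse_oracle(random_network):
    modes = _modes(random_network, temperature=290.0)
    af = nma.mean_square_fluctuation(modes)
    pinv = np.linalg.pinv(hessian(random_network), rcond=1e-10)
    per_node = GAS_CONSTANT * 290.0 * np.einsum("ii->i", pinv).reshape(-1, 3).sum(axis=1)
    assert np.allclose(af, per_node, rtol=1e-8, atol=1e-10)


def test_normal_modes_rejects_non_minimum():
    h = -np.eye(6)
    with pytest.raises(ValueError):
        nma.normal_modes(h)


def test_temperature_factor_scale():
    assert nma.temperature_factor([1.0])[0] == pytest.approx(8 * np.pi**2 / 3)
    assert nma.temperature_factor([1.0])[0] == pytest.approx(26.3189, abs=1e-4)


def test_motif_average_tf_toy():
    tf = [10.0, 20.0, 30.0]
    out = nma.motif_average_tf(tf, ["phosphate", "sugar", "base"], [0, 0, 0])
    assert list(out["matf"]) == [10.0, 20.0, 30.0]
    assert list(out["motif"]) == ["phosphate", "sugar", "base"]
    # empty motif (no phosphate atoms) is skipped, not NaN
    out2 = nma.motif_average_tf([5.0, 7.0], ["sugar", "base"], [0, 0])
    assert list(out2["matf"]) == [5.0, 7.0]


def test_nf_equals_af_for_single_atom_groups(random_network):
    modes = _modes(random_network)
    af = nma.mean_square_fluctuation(modes)
    nf = nma.group_fluctuations(modes, [[i] for i in range(random_network.n_nodes)])
    assert np.allclose(nf, af)


def test_nf_matches_monte_carlo_oracle(random_network):
    modes = _modes(random_network)
    groups = [[0, 1, 2], [3, 4, 5], [6, 7]]
    nf = nma.group_fluctuations(modes, groups)
    disp = _mc_displacements(modes, 600_000, np.random.default_rng(11))
    n = random_network.n_nodes
    disp = disp.reshape(-1, n, 3)
    mc = [np.mean(np.sum(disp[:, g].mean(axis=1) ** 2, axis=1)) for g in groups]
    assert np.allclose(nf, mc, rtol=0.01)


def test_axis_frames_properties(param_set_i):
    s = build_structure("ACGTACGTACGT", param_set_i, resolution="C1")
    axes = nma.axis_frames(s)
    for arr in (axes.b, axes.s, axes.t):
        assert np.allclose(np.linalg.norm(arr, axis=1), 1.0)
    assert np.allclose(np.einsum("ij,ij->i", axes.t, axes.b), 0, atol=1e-12)
    assert np.allclose(np.einsum("ij,ij->i", axes.t, axes.s), 0, atol=1e-12)
    # b and s stay well away from collinearity: the C1'-pair midpoints
    # precess ~2.5 Å off the helix axis, so the angle sits around 65–80°
    # rather than exactly π/2
    overlap = np.abs(np.einsum("ij,ij->i", axes.b, axes.s))
    assert overlap.max() < 0.7
    assert overlap.mean() < 0.5
    # terminal rule: s_N = s_{N-1}
    assert np.allclose(axes.s[-1], axes.s[-2])


def test_axis_frames_rejects_coincident_c1():
    pos = np.zeros((4, 3))
    with pytest.raises(ValueError, match="coincident"):
        nma.axis_frames(pos, 2)


def test_directional_parseval_with_orthonormal_axes():
    s = build_structure("ACGTACGT", resolution="C1")
    net = build_cgenm(s, cg=7.7)
    modes = _modes(net)
    axes = nma.axis_frames(s).orthonormalized()
    n = s.n_bp
    pair_of_node = np.concatenate([np.arange(n), np.arange(n)])
    total = nma.mean_square_fluctuation(modes)
    comp = sum(
        nma.node_direction_msf(modes, ax[pair_of_node])
        for ax in (axes.b, axes.s, axes.t)
    )
    assert np.allclose(comp, total, atol=1e-9)


def test_df_zero_for_common_motion():
    # a mode moving i and i' identically contributes nothing to DF
    vec = np.zeros((12, 1))
    vec[0:3, 0] = vec[6:9, 0] = [0.5, 0.5, 0.0]
    vec /= np.linalg.norm(vec)
    modes = nma.NormalModeSet(np.array([1.0]), vec, 5, 300.0, 1.0)
    df = nma.pair_difference_msf(modes, [[0, 2]], [[1.0, 0, 0]])
    assert df[0] == pytest.approx(0.0, abs=1e-15)


def test_df_matches_monte_carlo_oracle():
    s = build_structure("ACGTA", resolution="C1")
    net = build_cgenm(s, cg=7.7)
    modes = _modes(net)
    axes = nma.axis_frames(s)
    n = s.n_bp
    pairs = np.column_stack([np.arange(n), np.arange(n, 2 * n)])
    df = nma.pair_difference_msf(modes, pairs, axes.b)
    disp = _mc_displacements(modes, 600_000, np.random.default_rng(3))
    disp = disp.reshape(-1, 2 * n, 3)
    rel = disp[:, pairs[:, 0]] - disp[:, pairs[:, 1]]
    mc = np.mean(np.einsum("mnx,nx->mn", rel, axes.b) ** 2, axis=0)
    assert np.allclose(df, mc, rtol=0.01)


def test_rigid_motion_invariance_of_fluctuations():
    s = build_structure("ACGTACGTAC", resolution="C1")
    rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
    moved = s.transformed(rotation=rot, translation=[3.0, -8.0, 1.0])
    cf0 = nma.mean_square_fluctuation(_modes(build_cgenm(s, 7.7)))
    cf1 = nma.mean_square_fluctuation(_modes(build_cgenm(moved, 7.7)))
    assert np.allclose(cf0, cf1, rtol=1e-8)


def test_temperature_linearity_and_stiffness_scaling():
    s = build_structure("ACGTACGT", resolution="C1")
    cf_1 = nma.mean_square_fluctuation(_modes(build_cgenm(s, 7.7), 300.0))
    cf_2t = nma.mean_square_fluctuation(_modes(build_cgenm(s, 7.7), 600.0))
    cf_2c = nma.mean_square_fluctuation(_modes(build_cgenm(s, 15.4), 300.0))
    assert np.allclose(cf_2t, 2 * cf_1, rtol=1e-12)
    assert np.allclose(cf_2c, cf_1 / 2, rtol=1e-9)
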