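import numpy as np
import pytest

from dnaenm.builder import build_structure
from dnaenm.enm import (
    ElasticNetwork,
    build_aaenm,
    build_cgenm,
    cgenm_neighbor_pairs,
    hessian,
)


class _TwoCarbons:
    """Minimal structure stub: two carbon atoms at a chosen separation."""

    def __init__(self, d):
        self.coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        self.elements = ("C", "C")
        self.pair_index = np.array([0, 0])


@pytest.mark.parametrize("d,connected", [(5.40, True), (5.41, False)])
def test_aaenm_cutoff_boundary(d, connected):
    # R_C + R_C + R_c = 1.70 + 1.70 + 2.0 = 5.40 Å; the step function
    # includes the boundary case
    with pytest.warns(UserWarning) if not connected else _nullcontext():
        net = build_aaenm(_TwoCarbons(d), ca=1.0, bb=0.0)
    assert net.n_springs == (1 if connected else 0)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *a):
        return False


def test_aaenm_restraints_on_edges_and_waters_only():
    from dnaenm.screening import synthetic_crystal

    cs = synthetic_crystal("ACGTACGT", ca=2.0, bb=0.018, bw=0.002, n_waters=10, seed=1)
    net = build_aaenm(cs, ca=2.0, bb=0.018, bw=0.002)
    assert np.allclose(net.restraints[cs.is_edge], 0.018)
    assert np.allclose(net.restraints[cs.is_water], 0.002)
    other = ~(cs.is_edge | cs.is_water)
    assert np.allclose(net.restraints[other], 0.0)


def test_cgenm_interior_degree_and_terminal_degree():
    n = 10
    net = build_cgenm(build_structure("A" * n, resolution="C1"), cg=1.0)
    deg = net.degrees()
    interior = [i for i in range(n) if 3 <= i <= n - 4]
    assert all(deg[i] == 11 for i in interior)
    assert all(deg[n + i] == 11 for i in interior)
    assert deg[0] == 6  # terminal nucleotide


@pytest.mark.parametrize("n", [4, 5, 8, 17, 50])
def test_cgenm_spring_count_vs_enumeration_oracle(n):
    # brute-force application of the neighbor rule over all node pairs
    def neighbors(strand, i):
        other = 2 if strand == 1 else 1
        out = {(other, i)}
        for d in (1, 2):
            for s in (1, 2):
                out |= {(s, i + d), (s, i - d)}
        out |= {(other, i + 3), (other, i - 3)}
        return {(s, j) for s, j in out if 0 <= j < n}

    expected = set()
    for strand in (1, 2):
        for i in range(n):
            for s, j in neighbors(strand, i):
                a = i if strand == 1 else n + i
                b = j if s == 1 else n + j
                expected.add((min(a, b), max(a, b)))
    got = set(map(tuple, cgenm_neighbor_pairs(n)))
    assert got == expected
    # sum of degrees: interior 11, terminal deficits 5+3+1 per strand end,
    # so 22N − 36 half-springs, i.e. 11N − 18 springs
    assert len(got) == 11 * n - 18


def test_cgenm_rejects_short_duplex():
    with pytest.raises(ValueError, match="at least 4"):
        cgenm_neighbor_pairs(3)


def test_single_spring_hessian_closed_form():
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    net = ElasticNetwork(
        "AAENM", pos, np.array([[0, 1]]), np.array([2.0]), 3.0, np.zeros(2)
    )
    vals = np.linalg.eigvalsh(hessian(net))
    assert vals[-1] == pytest.approx(2 * 3.0)  # stretching mode: 2C
    assert np.allclose(vals[:-1], 0, atol=1e-12)


def test_restraint_free_row_block_sums_vanish(random_network):
    free = ElasticNetwork(
        random_network.model, random_network.positions, random_network.springs,
        random_network.rest_lengths, random_network.spring_constant,
        np.zeros(random_network.n_nodes),
    )
    h = hessian(free)
    n = free.n_nodes
    blocks = h.reshape(n, 3, n, 3)
    assert np.allclose(blocks.sum(axis=2), 0, atol=1e-12)


def test_hessian_matches_finite_differences(random_network):
    net = random_network
    h = hessian(net)
    q0 = net.positions.ravel()
    step = 1e-5
    m = q0.size
    fd = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            def v(da, db):
                q = q0.copy()
                q[a] += da
                q[b] += db
                return net.potential_energy(q)

            fd[a, b] = fd[b, a] = (
                v(step, step) - v(step, -step) - v(-step, step) + v(-step, -step)
            ) / (4 * step * step)
    assert np.allclose(h, fd, atol=1e-5)


def test_hessian_psd_and_minimum(random_network):
    h = hessian(random_network)
    vals = np.linalg.eigvalsh(h)
    assert vals[0] >= -1e-9 * vals[-1]
    # reference configuration is the exact potential minimum
    q0 = random_network.positions.ravel()
    grad = np.zeros_like(q0)
    eps = 1e-7
    for a in range(q0.size):
        qp, qm = q0.copy(), q0.copy()
        qp[a] += eps
        qm[a] -= eps
        grad[a] = (random_network.potential_energy(qp)
                   - random_network.potential_energy(qm)) / (2 * eps)
    assert np.max(np.abs(grad)) < 1e-8
    assert random_network.potential_energy(q0) == pytest.approx(0.0, abs=1e-12)


def test_rest_lengths_equal_reference_distances(duplex_16):
    net = build_aaenm(duplex_16, ca=1.29)
    d = np.linalg.norm(
        net.positions[net.springs[:, 0]] - net.positions[net.springs[:, 1]], axis=1
    )
    assert np.allclose(d, net.rest_lengths)


def test_edge_list_export(tmp_path, duplex_16):
    net = build_cgenm(build_structure("ACGTAC", resolution="C1"), cg=7.7)
    path = tmp_path / "net.txt"
    net.to_edge_list(path)
    lines = path.read_text().splitlines()
    assert sum(ln.startswith("e ") for ln in lines) == net.n_springs
    assert sum(ln.startswith("n ") for ln in lines) == net.n_nodes
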