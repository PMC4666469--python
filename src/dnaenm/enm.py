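"""Elastic network construction and Hessian assembly.

Two network flavors:

* **AAENM** — every heavy atom (plus, for crystals, each water oxygen) is a
  node; nodes i, j are joined by a spring of stiffness ``Ca`` whenever their
  reference distance is at most R_i + R_j + R_c (Van der Waals radii plus a
  cutoff, default R_c = 2 Å).  Isotropic restraints of strength ``B_j·Ca``
  anchor the atoms of the edge base pairs (B_j = B_B) and water oxygens
  (B_j = B_w) to their reference positions, modelling crystal packing.
* **CGENM** — one node per nucleotide at its C1' atom; node i is joined with
  stiffness ``Cg`` to its partner i', to neighbors i±1, i'±1, to next
  neighbors i±2, i'±2, and to the next-next neighbors on the other strand
  i'±3 — eleven springs per interior nucleotide, no restraints.

Every spring's natural length equals the reference inter-node distance, so
the reference configuration is the exact potential minimum and the Hessian
of the distance-spring potential reduces to ±C·û ûᵀ blocks (Tirion form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .builder import DnaStructure
from .constants import DEFAULT_CUTOFF, VDW_RADII


@dataclass(frozen=True)
class ElasticNetwork:
    """Nodes, springs and boundary restraints of one elastic network."""

    model: str  # "AAENM" or "CGENM"
    positions: np.ndarray  # (n, 3) reference coordinates, Å
    springs: np.ndarray  # (m, 2) int node pairs, i < j, unique
    rest_lengths: np.ndarray  # (m,) natural lengths = reference distances
    spring_constant: float  # kJ/(Å²·mol), identical for all springs
    restraints: np.ndarray = field(repr=False)  # (n,) dimensionless B_j >= 0

    def __post_init__(self):
        n = self.positions.shape[0]
        sp = self.springs
        if sp.size and (sp[:, 0] == sp[:, 1]).any():
            raise ValueError("self-springs are not allowed")
        if sp.size and len({(int(a), int(b)) for a, b in sp}) != sp.shape[0]:
            raise ValueError("duplicate spring pairs")
        if (self.restraints < 0).any():
            raise ValueError("restraint strengths must be non-negative")
        if self.restraints.shape[0] != n:
            raise ValueError("restraints length mismatch")
        deg = np.zeros(n)
        np.add.at(deg, sp.ravel(), 1.0)
        lonely = np.flatnonzero((deg == 0) & (self.restraints == 0))
        if lonely.size:
            warnings.warn(
                f"{lonely.size} isolated unrestrained node(s) (extra zero modes)",
                stacklevel=3,
            )

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_springs(self) -> int:
        return self.springs.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.springs.ravel(), 1)
        return deg

    def potential_energy(self, coords) -> float:
        """V(q) of the distance-spring + restraint potential at ``coords``."""
        q = np.asarray(coords, float).reshape(self.n_nodes, 3)
        i, j = self.springs.T
        d = np.linalg.norm(q[i] - q[j], axis=1)
        v = 0.5 * self.spring_constant * ((d - self.rest_lengths) ** 2).sum()
        dev = q - self.positions
        v += 0.5 * self.spring_constant * (
            self.restraints * (dev ** 2).sum(axis=1)
        ).sum()
        return float(v)

    def to_edge_list(self, path) -> None:
        """Dump nodes + springs as a plain-text edge list for cross-checks."""
        with open(path, "w") as fh:
            fh.write(f"# model {self.model}  C {self.spring_constant}\n")
            fh.write("# node x y z B\n")
            for k, (p, b) in enumerate(zip(self.positions, self.restraints)):
                fh.write(f"n {k} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {b:g}\n")
            fh.write("# edge i j rest_length\n")
            for (i, j), l0 in zip(self.springs, self.rest_lengths):
                fh.write(f"e {i} {j} {l0:.4f}\n")


def _make_network(model, positions, pairs, constant, restraints) -> ElasticNetwork:
    pairs = np.asarray(sorted({(min(a, b), max(a, b)) for a, b in pairs}), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    rest = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    return ElasticNetwork(
        model=model,
        positions=positions,
        springs=pairs,
        rest_lengths=rest,
        spring_constant=float(constant),
        restraints=np.asarray(restraints, float),
    )


def build_aaenm(
    structure,
    ca: float,
    rc: float = DEFAULT_CUTOFF,
    bb: float = 0.0,
    bw: float = 0.0,
    radii: dict[str, float] | None = None,
) -> ElasticNetwork:
    """All-atom network from a built or crystal structure.

    ``structure`` must expose ``coords``, ``elements`` and boolean masks for
    edge-base-pair atoms and water oxygens (crystal structures); built
    :class:`~dnaenm.builder.DnaStructure` objects have no waters and their
    edge pairs are the first and last base pair.  Atoms i, j are connected
    iff |r_i - r_j| <= R_i + R_j + rc.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    coords = np.asarray(structure.coords, float)
    elements = [e.strip().upper() for e in structure.elements]
    unknown = sorted(set(elements) - set(radii))
    if unknown:
        raise KeyError(f"no Van der Waals radius for element(s): {unknown}")
    r = np.array([radii[e] for e in elements])

    tree = cKDTree(coords)
    rmax = 2 * r.max() + rc
    pairs = []
    for i, j in tree.query_pairs(rmax):
        if np.linalg.norm(coords[i] - coords[j]) <= r[i] + r[j] + rc:
            pairs.append((i, j))

    restraints = np.zeros(coords.shape[0])
    restraints[_edge_pair_mask(structure)] = bb
    water = getattr(structure, "is_water", None)
    if water is not None:
        restraints[np.asarray(water, bool)] = bw
    return _make_network("AAENM", coords, pairs, ca, restraints)


def _edge_pair_mask(structure) -> np.ndarray:
    mask = getattr(structure, "is_edge", None)
    if mask is not None:
        return np.asarray(mask, bool)
    pi = np.asarray(structure.pair_index)
    return (pi == pi.min()) | (pi == pi.max())


def cgenm_neighbor_pairs(n_bp: int) -> list[tuple[int, int]]:
    """Spring pairs of the coarse-grained topology.

    Node ids: pair i strand 1 -> i; its partner i' -> n_bp + i.  For every
    nucleotide i the neighbor set is {i', i±1, i'±1, i±2, i'±2, i'+3, i'-3}
    (indices that exist); applying the rule from both strands and removing
    duplicates leaves 11·N − 16 springs for N ≥ 4.
    """
    if n_bp < 4:
        raise ValueError(f"CGENM topology needs at least 4 bp, got {n_bp}")
    pairs = set()

    def node(strand, i):
        return i if strand == 1 else n_bp + i

    for i in range(n_bp):
        for strand, other in ((1, 2), (2, 1)):
            me = node(strand, i)
            neigh = [(other, i)]  # partner in the same base pair
            for d in (1, 2):  # neighboring and next-neighboring pairs
                for s in (strand, other):
                    neigh += [(s, i + d), (s, i - d)]
            neigh += [(other, i + 3), (other, i - 3)]  # next-next, other strand
            for s, j in neigh:
                if 0 <= j < n_bp:
                    a, b = me, node(s, j)
                    pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def build_cgenm(structure: DnaStructure | np.ndarray, cg: float, n_bp: int | None = None) -> ElasticNetwork:
    """Coarse-grained network from a C1-resolution structure.

    Accepts a :class:`DnaStructure` (any resolution; C1' nodes are
    extracted) or a raw (2N, 3) array of C1' positions ordered strand 1
    pairs 0..N-1 then strand 2 pairs 0..N-1 (``n_bp`` required then).
    """
    if isinstance(structure, DnaStructure):
        positions = structure.c1_positions()
        n_bp = structure.n_bp
    else:
        positions = np.asarray(structure, float)
        if n_bp is None:
            if positions.shape[0] % 2:
                raise ValueError("need an even node count (two strands)")
            n_bp = positions.shape[0] // 2
    pairs = cgenm_neighbor_pairs(n_bp)
    return _make_network("CGENM", positions, pairs, cg, np.zeros(2 * n_bp))


def hessian(network: ElasticNetwork) -> np.ndarray:
    """3N×3N Hessian of the network potential at the reference configuration.

    Off-diagonal blocks are −C·û ûᵀ per spring (û the unit inter-node
    vector), diagonal blocks accumulate +C·û ûᵀ per incident spring plus
    B_j·C·I per restraint.  Eigenvalues of H/m are the squared
    eigenfrequencies ω_k².
    """
    n = network.n_nodes
    h = np.zeros((3 * n, 3 * n))
    c = network.spring_constant
    for (i, j), l0 in zip(network.springs, network.rest_lengths):
        u = (network.positions[j] - network.positions[i]) / l0
        block = c * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, si] += block
        h[sj, sj] += block
        h[si, sj] -= block
        h[sj, si] -= block
    for k in np.flatnonzero(network.restraints):
        sk = slice(3 * k, 3 * k + 3)
        h[sk, sk] += network.restraints[k] * c * np.eye(3)
    return h
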