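"""Normal-mode analysis and thermal fluctuation statistics.

Small harmonic deviations about the reference configuration decompose into
normal modes: eigenpairs (λ_k, v_k) of the 3N×3N Hessian, with squared
eigenfrequencies ω_k² = λ_k/m.  In thermal equilibrium each non-zero mode
carries mean-square amplitude k_B·T/(ω_k²·m) = R·T/λ_k (per-mole units), and
because modes are statistically independent every mean-square fluctuation is
a plain weighted sum over retained modes:

* per-node   AF_i  = Σ_k (RT/λ_k) |v_ik|²            (temperature factor
  TF_i = (8/3)π²·AF_i),
* per-group  NF_n  = Σ_k (RT/λ_k) |⟨v_jk⟩_{j∈n}|²     (atom-averaged
  nucleotide motion of the all-atom model),
* directional MSF along a unit axis a:  Σ_k (RT/λ_k) (v_ik·a)², and the
  inter-strand difference DF uses (v_ik − v_i'k)·a.

Rigid-body (zero) modes are identified by a relative eigenvalue threshold
and excluded from all sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .constants import (
    DEFAULT_TEMPERATURE,
    DEFAULT_ZERO_TOL,
    GAS_CONSTANT,
    NODE_MASS_KG,
)

TF_PER_AF = 8.0 * np.pi**2 / 3.0


@dataclass(frozen=True)
class NormalModeSet:
    """Retained (non-zero) normal modes of one elastic network."""

    eigenvalues: np.ndarray  # (K,) Hessian eigenvalues λ_k > 0, kJ/(mol·Å²)
    vectors: np.ndarray  # (3N, K) orthonormal mode vectors
    n_zero: int
    temperature: float  # K
    mass: float  # kg per node

    @property
    def n_nodes(self) -> int:
        return self.vectors.shape[0] // 3

    @property
    def omega_squared(self) -> np.ndarray:
        """ω_k² in (kJ/(mol·Å²))/kg — proportional to physical s⁻²."""
        return self.eigenvalues / self.mass

    @property
    def mode_weights(self) -> np.ndarray:
        """Thermal mean-square amplitude RT/λ_k of each retained mode, Å²."""
        return GAS_CONSTANT * self.temperature / self.eigenvalues

    def node_vectors(self) -> np.ndarray:
        """(N, 3, K) view of the mode vectors split per node."""
        return self.vectors.reshape(self.n_nodes, 3, -1)

    def with_temperature(self, temperature: float) -> "NormalModeSet":
        return NormalModeSet(
            self.eigenvalues, self.vectors, self.n_zero, temperature, self.mass
        )


def normal_modes(
    hess: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    mass: float = NODE_MASS_KG,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> NormalModeSet:
    """Full eigendecomposition of a symmetric Hessian with zero-mode removal.

    Eigenvalues below ``zero_tol`` × (largest eigenvalue) are classified as
    rigid-body modes and dropped; an eigenvalue below the negative of that
    threshold means the reference is not a potential minimum and raises.
    """
    hess = np.asarray(hess, float)
    if hess.ndim != 2 or hess.shape[0] != hess.shape[1] or hess.shape[0] % 3:
        raise ValueError("Hessian must be square with 3N rows")
    if not np.allclose(hess, hess.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    vals, vecs = eigh(hess, driver="evd")
    scale = float(vals[-1])
    if scale <= 0:
        raise ValueError("Hessian has no positive eigenvalue")
    thresh = zero_tol * scale
    if vals[0] < -thresh:
        raise ValueError(
            f"negative eigenvalue {vals[0]:.3e}: structure is not at a minimum"
        )
    keep = vals > thresh
    return NormalModeSet(
        eigenvalues=vals[keep],
        vectors=vecs[:, keep],
        n_zero=int((~keep).sum()),
        temperature=float(temperature),
        mass=float(mass),
    )


def mean_square_fluctuation(modes: NormalModeSet) -> np.ndarray:
    """Per-node mean-square fluctuation AF_i (Å²)."""
    v2 = (modes.node_vectors() ** 2).sum(axis=1)  # (N, K)
    return v2 @ modes.mode_weights


def temperature_factor(af) -> np.ndarray:
    """Crystallographic temperature factor TF = (8/3)π²·AF (Å²)."""
    return TF_PER_AF * np.asarray(af, float)


def motif_average_tf(tf, motifs, nucleotide_ids) -> pd.DataFrame:
    """Motif-averaged temperature factors.

    Averages TF over the atoms of each motif (phosphate, sugar, base) of
    each nucleotide and orders the result phosphate → sugar → base within
    each nucleotide, nucleotides in id order (strand 1 then strand 2).
    Motifs with no atoms (5'-terminal residues lack a phosphate) are
    skipped.
    """
    frame = pd.DataFrame(
        {
            "tf": np.asarray(tf, float),
            "motif": list(motifs),
            "nucleotide": np.asarray(nucleotide_ids),
        }
    )
    order = {"phosphate": 0, "sugar": 1, "base": 2}
    out = (
        frame.groupby(["nucleotide", "motif"], sort=False)["tf"]
        .mean()
        .reset_index()
        .rename(columns={"tf": "matf"})
    )
    out["rank"] = out["motif"].map(order)
    if out["rank"].isna().any():
        bad = out.loc[out["rank"].isna(), "motif"].unique()
        raise KeyError(f"unknown motif label(s): {list(bad)}")
    out = out.sort_values(["nucleotide", "rank"], kind="stable").drop(columns="rank")
    return out.reset_index(drop=True)


def group_fluctuations(modes: NormalModeSet, groups) -> np.ndarray:
    """Mean-square fluctuation of group-averaged displacements (NF).

    ``groups`` is a sequence of atom-index arrays (e.g. atoms per
    nucleotide); the displacement of a group is the unweighted mean of its
    atoms' displacements.
    """
    nv = modes.node_vectors()
    w = modes.mode_weights
    out = np.empty(len(groups))
    for g, idx in enumerate(groups):
        m = nv[np.asarray(idx)].mean(axis=0)  # (3, K)
        out[g] = (m**2).sum(axis=0) @ w
    return out


@dataclass(frozen=True)
class AxisFrames:
    """Per-base-pair unit axes: b (intra-pair C1'→C1'), s (local helix axis),
    t (torsional, normalized b×s)."""

    b: np.ndarray  # (N, 3)
    s: np.ndarray
    t: np.ndarray

    def __len__(self) -> int:
        return self.b.shape[0]

    def orthonormalized(self) -> "AxisFrames":
        """Gram-Schmidt per pair: exact orthonormal (b, s⊥, t) triads.

        b and s are nearly but not exactly perpendicular; this projects s
        into the plane normal to b so that component sums satisfy Parseval
        identities exactly.
        """
        b = self.b.copy()
        s = self.s - (self.s * b).sum(axis=1, keepdims=True) * b
        s /= np.linalg.norm(s, axis=1, keepdims=True)
        t = np.cross(b, s)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return AxisFrames(b, s, t)


def axis_frames(c1_positions, n_bp: int | None = None) -> AxisFrames:
    """Base-pair axis triads from C1' coordinates.

    ``c1_positions`` is (2N, 3) ordered strand 1 pairs 0..N-1 then strand 2
    pairs 0..N-1 (or a structure exposing ``c1_positions()``).  b_i points
    from the strand-2 C1' to the strand-1 C1'; s_i is the normalized
    displacement between consecutive pair midpoints (the last pair reuses
    s_{N-1}); t_i = b_i×s_i normalized.
    """
    if hasattr(c1_positions, "c1_positions"):
        c1_positions = c1_positions.c1_positions()
    pos = np.asarray(c1_positions, float)
    if n_bp is None:
        n_bp = pos.shape[0] // 2
    if pos.shape != (2 * n_bp, 3):
        raise ValueError("expected (2N, 3) C1' coordinates")
    if n_bp < 2:
        raise ValueError("need at least 2 base pairs for the helix axis")
    x1, x2 = pos[:n_bp], pos[n_bp:]
    diff = x1 - x2
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    if (norms < 1e-9).any():
        raise ValueError("coincident paired C1' positions")
    b = diff / norms
    mid = 0.5 * (x1 + x2)
    step = np.diff(mid, axis=0)
    step /= np.linalg.norm(step, axis=1, keepdims=True)
    s = np.vstack([step, step[-1]])  # terminal rule: s_N = s_{N-1}
    t = np.cross(b, s)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return AxisFrames(b, s, t)


def node_direction_msf(modes: NormalModeSet, directions) -> np.ndarray:
    """Per-node MSF of the displacement projected on a per-node unit axis."""
    d = np.asarray(directions, float)
    nv = modes.node_vectors()
    if d.shape != (nv.shape[0], 3):
        raise ValueError("directions must be (n_nodes, 3)")
    proj = np.einsum("nxk,nx->nk", nv, d)
    return (proj**2) @ modes.mode_weights


def group_direction_msf(modes: NormalModeSet, groups, directions) -> np.ndarray:
    """Directional MSF of group-averaged displacements (NF components)."""
    d = np.asarray(directions, float)
    nv = modes.node_vectors()
    w = modes.mode_weights
    out = np.empty(len(groups))
    for g, idx in enumerate(groups):
        m = nv[np.asarray(idx)].mean(axis=0)  # (3, K)
        out[g] = ((d[g] @ m) ** 2) @ w
    return out


def pair_difference_msf(
    modes: NormalModeSet, pairs, directions
) -> np.ndarray:
    """Inter-strand relative fluctuation DF per base pair.

    ``pairs`` is an (N, 2) array of node ids (i, i'); the projected
    relative displacement (v_i − v_i')·a_i is accumulated over modes.
    """
    pairs = np.asarray(pairs, int)
    d = np.asarray(directions, float)
    if pairs.shape[0] != d.shape[0]:
        raise ValueError("pair and direction counts differ")
    nv = modes.node_vectors()
    rel = nv[pairs[:, 0]] - nv[pairs[:, 1]]  # (N, 3, K)
    proj = np.einsum("nxk,nx->nk", rel, d)
    return (proj**2) @ modes.mode_weights
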