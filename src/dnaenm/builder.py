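"""Rebuild a 3-D double helix for an arbitrary sequence from helical parameters.

The rebuild follows the mid-step-triad (CEHS) convention of the standard
rebuild tools: consecutive base-pair frames are related by the rigid
transform encoded by the six base-step parameters, with the combined
roll-tilt rotation Γ = √(Tilt² + Roll²) applied about an axis phased by
φ = atan2(Tilt, Roll) and the (Shift, Slide, Rise) translation expressed in
the mid-step frame:

    R_{i+1} = R_i · Rz(Ω/2−φ) · Ry(Γ) · Rz(Ω/2+φ)
    o_{i+1} = o_i + R_mid · (Shift, Slide, Rise),
    R_mid   = R_i · Rz(Ω/2−φ) · Ry(Γ/2) · Rz(φ)

Within each pair frame the two nucleotide templates are placed symmetrically:
the six intra-pair parameters are split half-and-half between the two bases
with opposite sense (the same mid-frame construction applied to
Buckle/Propeller/Opening and Shear/Stretch/Stagger), and the strand-2
template is first rotated 180° about the frame's short axis (x), which is
what antiparallel Watson-Crick geometry requires of standard-frame templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import HelicalParameterSet, PairParameters, StepParameters, load_parameter_set
from .sequences import validate
from .templates import NucleotideTemplate, load_templates

_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: 180° rotation about the pair frame's short axis (strand-2 placement)
STRAND2_FLIP = np.diag([1.0, -1.0, -1.0])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _cehs_rotations(tilt_deg: float, roll_deg: float, twist_deg: float):
    """Full and mid-frame rotations for one six-parameter rigid step."""
    tilt, roll, omega = np.deg2rad([tilt_deg, roll_deg, twist_deg])
    gamma = float(np.hypot(tilt, roll))
    phi = float(np.arctan2(tilt, roll)) if gamma > 0 else 0.0
    full = _rz(omega / 2 - phi) @ _ry(gamma) @ _rz(omega / 2 + phi)
    mid = _rz(omega / 2 - phi) @ _ry(gamma / 2) @ _rz(phi)
    return full, mid


@dataclass(frozen=True)
class BasePairFrames:
    """Ordered base-pair frames: origins (N, 3) and orientation matrices (N, 3, 3).

    Orientation columns are the pair's short axis (x, toward the major
    groove), long axis (y, roughly along C1'--C1') and base-plane normal (z).
    """

    origins: np.ndarray
    orientations: np.ndarray

    def __len__(self) -> int:
        return self.origins.shape[0]


def propagate_frames(
    seq: str,
    params: HelicalParameterSet,
    origin=None,
    orientation=None,
) -> BasePairFrames:
    """Propagate base-pair frames along ``seq`` from the step parameters.

    Frame 1 is the identity at the origin unless ``origin``/``orientation``
    override it.  Orientations are re-orthonormalized after each step so
    numerical drift stays below 1e-12 even for thousands of steps.
    """
    seq = validate(seq)
    if len(seq) < 1:
        raise ValueError("need at least one base")
    n = len(seq)
    origins = np.zeros((n, 3))
    orients = np.zeros((n, 3, 3))
    origins[0] = np.zeros(3) if origin is None else np.asarray(origin, float)
    orients[0] = np.eye(3) if orientation is None else np.asarray(orientation, float)
    for i in range(n - 1):
        st = params.step(seq[i : i + 2])
        full, mid = _cehs_rotations(st.tilt, st.roll, st.twist)
        origins[i + 1] = origins[i] + orients[i] @ mid @ st.translation()
        nxt = orients[i] @ full
        # re-orthonormalize via polar decomposition (nearest rotation)
        u, _, vt = np.linalg.svd(nxt)
        orients[i + 1] = u @ vt
    return BasePairFrames(origins, orients)


def _pair_split(pair: PairParameters):
    """Frames of the two bases relative to the pair (mid) frame.

    Returns ``(R1, o1, R2, o2)``: orientation and origin offsets of the
    strand-1 base frame and the (flipped) strand-2 base frame, such that the
    pair frame is the symmetric mid-frame of the two.
    """
    full, mid = _cehs_rotations(pair.buckle, pair.propeller, pair.opening)
    r2 = mid.T  # A = M·R_mid⁻¹
    r1 = r2 @ full  # B = A·R_full
    half = pair.translation() / 2.0
    return r1, half, r2, -half


@dataclass(frozen=True)
class DnaStructure:
    """A built duplex: per-atom coordinates with nucleotide/motif labels.

    Nucleotides are indexed by base-pair index ``i`` (0-based, along strand
    1's 5'->3' direction); the strand-2 nucleotide paired with pair ``i`` has
    nucleotide id ``N + i`` (pairing-map order, not file order).  Atoms are
    stored strand 1 first (pairs 0..N-1), then strand 2 (pairs 0..N-1).
    """

    sequence: str
    resolution: str  # "C1" or "all-atom"
    coords: np.ndarray  # (n_atoms, 3)
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    motifs: tuple[str, ...]
    strand: np.ndarray  # (n_atoms,) in {1, 2}
    pair_index: np.ndarray  # (n_atoms,) 0-based
    base: tuple[str, ...] = field(repr=False)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def nucleotide_id(self) -> np.ndarray:
        """Per-atom nucleotide id in [0, 2N): pair index + N on strand 2."""
        return self.pair_index + (self.strand - 1) * self.n_bp

    def atoms_by_nucleotide(self) -> list[np.ndarray]:
        """Atom indices of each nucleotide, ordered by nucleotide id."""
        ids = self.nucleotide_id
        return [np.flatnonzero(ids == k) for k in range(2 * self.n_bp)]

    def c1_positions(self) -> np.ndarray:
        """(2N, 3) C1' coordinates ordered by nucleotide id."""
        mask = np.array([n == "C1'" for n in self.atom_names])
        idx = np.flatnonzero(mask)
        order = np.argsort(self.nucleotide_id[idx], kind="stable")
        pos = self.coords[idx[order]]
        if pos.shape[0] != 2 * self.n_bp:
            raise ValueError("structure does not have one C1' per nucleotide")
        return pos

    def transformed(self, rotation=None, translation=None) -> "DnaStructure":
        """Copy of the structure after a rigid motion (for invariance checks)."""
        r = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return DnaStructure(
            self.sequence, self.resolution, self.coords @ r.T + t,
            self.atom_names, self.elements, self.motifs,
            self.strand, self.pair_index, self.base,
        )


def place_nucleotides(
    frames: BasePairFrames,
    seq: str,
    params: HelicalParameterSet,
    resolution: str = "all-atom",
) -> DnaStructure:
    """Place nucleotide templates into base-pair frames.

    The intra-pair parameters of each pair are applied half to each base
    with opposite sense; the strand-2 template is rotated 180° about the
    frame's short axis first.  ``resolution="C1"`` keeps only the C1' node
    of each nucleotide; 5'-terminal residues lose their phosphate group
    (P, OP1, OP2) in all-atom resolution.
    """
    seq = validate(seq)
    if len(frames) != len(seq):
        raise ValueError("frame count does not match sequence length")
    if resolution not in ("C1", "all-atom"):
        raise ValueError(f"unknown resolution {resolution!r}")
    templates = load_templates()
    n = len(seq)

    placed: dict[int, list] = {1: [], 2: []}  # per strand: (pair, template, R, o)
    for i in range(n):
        base1 = seq[i]
        base2 = _COMPLEMENT_BASE[base1]
        o_i, r_i = frames.origins[i], frames.orientations[i]
        r1, d1, r2, d2 = _pair_split(params.pair(base1))
        t1 = templates[base1]
        t2 = templates[base2]
        if resolution == "all-atom":
            if i == 0:
                t1 = t1.without_5prime_phosphate()
            if i == n - 1:
                t2 = t2.without_5prime_phosphate()
        placed[1].append((i, t1, r_i @ r1, o_i + r_i @ d1, np.eye(3)))
        placed[2].append((i, t2, r_i @ r2, o_i + r_i @ d2, STRAND2_FLIP))

    coords, names, elements, motifs, strands, pairs, bases = [], [], [], [], [], [], []
    for strand in (1, 2):
        for i, tpl, rot, org, flip in placed[strand]:
            if resolution == "C1":
                sel = [tpl.c1_index]
            else:
                sel = range(len(tpl.atom_names))
            xyz = tpl.coords @ flip @ rot.T + org
            for a in sel:
                coords.append(xyz[a])
                names.append(tpl.atom_names[a])
                elements.append(tpl.elements[a])
                motifs.append(tpl.motifs[a])
                strands.append(strand)
                pairs.append(i)
                bases.append(tpl.base)
    return DnaStructure(
        sequence=seq,
        resolution=resolution,
        coords=np.array(coords),
        atom_names=tuple(names),
        elements=tuple(elements),
        motifs=tuple(motifs),
        strand=np.array(strands),
        pair_index=np.array(pairs),
        base=tuple(bases),
    )


def build_structure(
    seq: str,
    params: HelicalParameterSet | None = None,
    resolution: str = "all-atom",
) -> DnaStructure:
    """Build a duplex for ``seq``: frame propagation + template placement."""
    if params is None:
        params = load_parameter_set("i")
    return place_nucleotides(propagate_frames(seq, params), seq, params, resolution)


def write_pdb(structure: DnaStructure, path, bfactors=None) -> None:
    """Write a built structure in PDB format (chains A/B, 5'->3' file order).

    ``bfactors`` (per atom in structure order) fills the B-factor column,
    e.g. model temperature factors for visualization.
    """
    b = np.zeros(structure.n_atoms) if bfactors is None else np.asarray(bfactors, float)
    if b.shape[0] != structure.n_atoms:
        raise ValueError("bfactors length does not match atom count")
    n = structure.n_bp
    lines = []
    serial = 0
    for strand, chain in ((1, "A"), (2, "B")):
        # strand 2 is written in its own 5'->3' order: pair N-1 .. 0
        pair_order = range(n) if strand == 1 else range(n - 1, -1, -1)
        resseq = 0
        for i in pair_order:
            resseq += 1
            idx = np.flatnonzero(
                (structure.strand == strand) & (structure.pair_index == i)
            )
            for a in idx:
                serial += 1
                name = structure.atom_names[a]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = structure.coords[a]
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {'D' + structure.base[a]:>3s}"
                    f" {chain}{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[a]:6.2f}"
                    f"          {structure.elements[a]:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
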