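"""Crystal-structure input: naked-DNA PDB files with experimental B-factors.

Reads DNA duplex crystal structures (DNA heavy atoms plus crystallographic
waters, of which only the oxygen is kept as a node), classifies atoms into
the three nucleotide motifs (phosphate, sugar, base), flags the atoms of the
two edge base pairs, and exposes Van der Waals radii — everything the
all-atom elastic network needs.  Parsing is delegated to Bio.PDB; only the
first MODEL is used and the highest-occupancy altloc conformer is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .constants import VDW_RADII
from .templates import motif_of as classify_motif  # noqa: F401  (re-export)

_NUCLEIC_RESNAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}
_WATER_RESNAMES = {"HOH", "WAT", "H2O"}


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) of a nucleic-acid element (C, N, O, P)."""
    try:
        return VDW_RADII[element.strip().upper()]
    except KeyError:
        raise KeyError(
            f"no Van der Waals radius for element {element!r}; "
            f"known: {sorted(VDW_RADII)}"
        ) from None


@dataclass(frozen=True)
class CrystalStructure:
    """A parsed duplex crystal: DNA heavy atoms + water-oxygen nodes.

    Array fields are aligned per node.  DNA nucleotides are numbered by
    pairing-map id: strand-1 residues get ids 0..N-1 in chain order, the
    strand-2 residue paired with pair ``i`` gets id N+i (strand 2 runs
    antiparallel, so its chain order is reversed).  Water nodes carry
    ``pair_index`` −1 and motif ``water``.
    """

    source: str
    sequence: str  # strand-1 sequence, 5'->3'
    coords: np.ndarray  # (n, 3)
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    motifs: tuple[str, ...]
    bfactors: np.ndarray  # (n,) experimental temperature factors, Å²
    strand: np.ndarray  # (n,) 1/2 for DNA, 0 for water
    pair_index: np.ndarray  # (n,) 0-based, −1 for water
    is_water: np.ndarray  # (n,) bool
    is_edge: np.ndarray  # (n,) bool: atom of the first or last base pair
    warnings_: tuple[str, ...] = field(default=(), repr=False)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def nucleotide_id(self) -> np.ndarray:
        """Per-atom nucleotide id (−1 for water nodes)."""
        nid = self.pair_index + (self.strand - 1) * self.n_bp
        return np.where(self.is_water, -1, nid)

    def dna_mask(self) -> np.ndarray:
        return ~self.is_water

    def atoms_by_nucleotide(self) -> list[np.ndarray]:
        ids = self.nucleotide_id
        return [np.flatnonzero(ids == k) for k in range(2 * self.n_bp)]


def read_pdb(
    path,
    water_cutoff: float | None = None,
    motif_overrides: dict[str, str] | None = None,
) -> CrystalStructure:
    """Parse a naked-DNA crystal structure in PDB format.

    Keeps DNA heavy atoms and, for each water, the O atom only.  Hydrogens
    and non-water heteroatoms are dropped.  ``water_cutoff`` (Å) optionally
    restricts waters to a shell around the DNA; by default all deposited
    waters are kept.  ``motif_overrides`` reassigns atom names to motifs
    (e.g. ``{"O3'": "sugar"}`` to test the alternative bridging-oxygen
    convention).  Negative or missing B-factors trigger a recorded warning
    but the atom is kept.
    """
    overrides = motif_overrides or {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("x", path)[0]

    strands: list[list] = []
    waters: list = []
    for chain in model:
        residues = []
        for res in chain:
            name = res.get_resname().strip()
            if name in _NUCLEIC_RESNAMES:
                residues.append((res, _NUCLEIC_RESNAMES[name]))
            elif name in _WATER_RESNAMES:
                waters.append(res)
        if residues:
            strands.append(residues)
    if not strands:
        raise ValueError(f"{path}: no nucleic-acid residues found")
    if len(strands) == 1 and len(strands[0]) % 2 == 0:
        # single-chain duplex: split into two antiparallel halves
        half = len(strands[0]) // 2
        strands = [strands[0][:half], strands[0][half:]]
    if len(strands) != 2 or len(strands[0]) != len(strands[1]):
        raise ValueError(
            f"{path}: expected a two-strand duplex with equal strand lengths, "
            f"got {[len(s) for s in strands]}"
        )
    n_bp = len(strands[0])

    notes = []
    coords, names, elements, motifs, bf = [], [], [], [], []
    strand_arr, pair_arr = [], []
    for s_idx, residues in enumerate(strands):
        for r_idx, (res, base) in enumerate(residues):
            # strand 2 is antiparallel: its chain position r pairs with n-1-r
            pair = r_idx if s_idx == 0 else n_bp - 1 - r_idx
            for atom in res.get_atoms():
                if atom.element.strip().upper() == "H":
                    continue
                name = atom.get_name().strip().replace("*", "'")
                coords.append(atom.get_coord())
                names.append(name)
                elements.append(atom.element.strip().upper() or name[0])
                motifs.append(overrides.get(name, classify_motif(name)))
                b = atom.get_bfactor()
                if b is None or b <= 0:
                    notes.append(f"non-positive B-factor on {name} in {res}")
                    b = 0.0 if b is None else b
                bf.append(b)
                strand_arr.append(s_idx + 1)
                pair_arr.append(pair)

    sequence = "".join(base for _, base in strands[0])

    water_xyz, water_bf = [], []
    for res in waters:
        oxygens = [a for a in res.get_atoms() if a.element.strip().upper() == "O"]
        if not oxygens:
            notes.append(f"water {res} without an O atom, skipped")
            continue
        a = oxygens[0]
        water_xyz.append(a.get_coord())
        b = a.get_bfactor()
        if b is None or b <= 0:
            notes.append(f"non-positive B-factor on water {res}")
            b = 0.0 if b is None else b
        water_bf.append(b)

    coords = np.asarray(coords, float)
    if water_xyz:
        water_xyz = np.asarray(water_xyz, float)
        if water_cutoff is not None:
            tree = cKDTree(coords)
            d, _ = tree.query(water_xyz)
            keep = d <= water_cutoff
            water_xyz = water_xyz[keep]
            water_bf = [b for b, k in zip(water_bf, keep) if k]
        for xyz, b in zip(water_xyz, water_bf):
            names.append("O")
            elements.append("O")
            motifs.append("water")
            bf.append(b)
            strand_arr.append(0)
            pair_arr.append(-1)
        coords = np.vstack([coords, water_xyz])

    strand_arr = np.asarray(strand_arr)
    pair_arr = np.asarray(pair_arr)
    is_water = strand_arr == 0
    is_edge = (~is_water) & ((pair_arr == 0) | (pair_arr == n_bp - 1))
    return CrystalStructure(
        source=str(path),
        sequence=sequence,
        coords=coords,
        atom_names=tuple(names),
        elements=tuple(elements),
        motifs=tuple(motifs),
        bfactors=np.asarray(bf, float),
        strand=strand_arr,
        pair_index=pair_arr,
        is_water=is_water,
        is_edge=is_edge,
        warnings_=tuple(notes),
    )


def write_crystal_pdb(cs: CrystalStructure, path, bfactors=None) -> None:
    """Write a crystal structure back to PDB (DNA as ATOM, waters as HETATM).

    ``bfactors`` overrides the B-factor column (e.g. model temperature
    factors); parsing the output with :func:`read_pdb` reproduces
    coordinates and B-factors to format precision.
    """
    b = cs.bfactors if bfactors is None else np.asarray(bfactors, float)
    if b.shape[0] != cs.n_atoms:
        raise ValueError("bfactors length mismatch")
    lines = []
    serial = 0
    resname = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
    n = cs.n_bp
    for s_val, chain in ((1, "A"), (2, "B")):
        order = range(n) if s_val == 1 else range(n - 1, -1, -1)
        resseq = 0
        for pair in order:
            resseq += 1
            idx = np.flatnonzero((cs.strand == s_val) & (cs.pair_index == pair))
            base = cs.sequence[pair]
            if s_val == 2:
                base = {"A": "T", "T": "A", "C": "G", "G": "C"}[base]
            for a in idx:
                serial += 1
                name = cs.atom_names[a]
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = cs.coords[a]
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {resname[base]:>3s}"
                    f" {chain}{resseq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[a]:6.2f}"
                    f"          {cs.elements[a]:>2s}"
                )
        lines.append("TER")
    for k, a in enumerate(np.flatnonzero(cs.is_water), start=1):
        serial += 1
        x, y, z = cs.coords[a]
        lines.append(
            f"HETATM{serial:5d}  O   HOH W{k:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[a]:6.2f}           O"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
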