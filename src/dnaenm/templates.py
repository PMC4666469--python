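"""Idealized nucleotide geometry templates in the standard base reference frame.

Each template holds the heavy atoms (base + deoxyribose + phosphate; no
hydrogens) of one nucleotide type, expressed in the standard base reference
frame: origin in the base-pair plane, x toward the major groove (short
axis), y along the long (C1'--C1') axis, z normal to the base plane.  The
glycosidic nitrogen sits at (-1.289, 4.551, 0) and C1' at (-2.479, 5.346, 0),
so that a Watson-Crick pair is obtained by placing the complementary
template after a 180° rotation about x.

The packaged coordinates are synthetic: an idealized B-form geometry
constructed once by ``scripts/make_templates.py`` (planar base geometries
anchored at the standard-frame glycosidic positions, backbone torsions
optimized for inter-residue O3'-P closure under an average helical step) and
frozen as plain-text data.  Heavy-atom counts per nucleotide are C: 19,
T: 20, A: 21, G: 22 including the full 5'-phosphate group and O3'.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: standard-frame position of the glycosidic nitrogen (N9 purines, N1 pyrimidines)
GLYCOSIDIC_N = np.array([-1.289, 4.551, 0.0])
#: standard-frame position of the C1' atom
C1_PRIME = np.array([-2.479, 5.346, 0.0])

PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "O1P", "O2P", "O5'", "O3'"})
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'"})

#: atoms removed from a strand's 5'-terminal residue (no 5'-phosphate)
FIVE_PRIME_TRIM = ("P", "OP1", "OP2")


def motif_of(atom_name: str) -> str:
    """Classify a nucleic-acid heavy-atom name into phosphate/sugar/base."""
    name = atom_name.strip().replace("*", "'")
    if name in PHOSPHATE_ATOMS:
        return "phosphate"
    if name in SUGAR_ATOMS:
        return "sugar"
    if name in {
        "N1", "C2", "O2", "N2", "N3", "C4", "O4", "N4",
        "C5", "C6", "O6", "N6", "N7", "C8", "N9", "C7", "C5M",
    }:
        return "base"
    raise KeyError(f"unrecognized nucleic-acid atom name {atom_name!r}")


@dataclass(frozen=True)
class NucleotideTemplate:
    """Heavy atoms of one nucleotide type in the standard base frame."""

    base: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    motifs: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å

    def __post_init__(self):
        if self.atom_names.count("C1'") != 1:
            raise ValueError(f"template {self.base}: need exactly one C1' atom")

    @property
    def c1_index(self) -> int:
        return self.atom_names.index("C1'")

    def without_5prime_phosphate(self) -> "NucleotideTemplate":
        keep = [i for i, n in enumerate(self.atom_names) if n not in FIVE_PRIME_TRIM]
        return NucleotideTemplate(
            self.base,
            tuple(self.atom_names[i] for i in keep),
            tuple(self.elements[i] for i in keep),
            tuple(self.motifs[i] for i in keep),
            self.coords[keep],
        )


@lru_cache(maxsize=1)
def load_templates() -> dict[str, NucleotideTemplate]:
    """Load the packaged A/C/G/T templates, keyed by base letter."""
    ref = importlib.resources.files("dnaenm.data") / "nucleotide_templates.tsv"
    rows: dict[str, list[tuple[str, str, float, float, float]]] = {}
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("base\t"):
                continue
            base, name, element, x, y, z = line.split("\t")
            rows.setdefault(base, []).append(
                (name, element, float(x), float(y), float(z))
            )
    out = {}
    for base, atoms in rows.items():
        names = tuple(a[0] for a in atoms)
        out[base] = NucleotideTemplate(
            base=base,
            atom_names=names,
            elements=tuple(a[1] for a in atoms),
            motifs=tuple(motif_of(n) for n in names),
            coords=np.array([a[2:] for a in atoms]),
        )
    missing = set("ACGT") - set(out)
    if missing:
        raise RuntimeError(f"template data incomplete, missing bases: {missing}")
    return out
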