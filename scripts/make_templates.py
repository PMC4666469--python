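"""Generate the packaged nucleotide geometry templates (synthetic idealized B-form).

Constructs heavy-atom templates for the four deoxyribonucleotides in the
standard base reference frame and freezes them as
``src/dnaenm/data/nucleotide_templates.tsv``.  Procedure:

1. Planar base geometries from RDKit (MMFF-optimized N-methyl bases),
   flattened and anchored so the glycosidic nitrogen sits at the published
   standard-frame position (-1.289, 4.551, 0) with the N->C1' bond pointing
   at (-2.479, 5.346, 0).  The in-plane mirror ambiguity is resolved by a
   Watson-Crick hydrogen-bond distance fit between each template and its
   flipped complement.
2. A single sugar-phosphate backbone (shared by all four bases, as in fiber
   models) built by natural-extension (NeRF) placement from the anchored
   C1', with ten free torsions optimized so that (a) the deoxyribose ring
   closes, (b) O3'(i) meets P(i+1) at bond distance under an average
   helical step of parameter set (i), on both strands, and (c) no steric
   clashes occur, with weak priors pulling the solution into the B-form
   torsion ranges.

Run from the repository root:  python scripts/make_templates.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from dnaenm.builder import STRAND2_FLIP, _cehs_rotations  # noqa: E402
from dnaenm.templates import C1_PRIME, GLYCOSIDIC_N  # noqa: E402

RNG = np.random.default_rng(20150143)

# ---------------------------------------------------------------- geometry utils

def unit(v):
    return v / np.linalg.norm(v)


def dihedral(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    return np.degrees(np.arctan2(m1 @ n2, n1 @ n2))


def angle(p0, p1, p2):
    return np.degrees(np.arccos(np.clip(unit(p0 - p1) @ unit(p2 - p1), -1, 1)))


def nerf(a, b, c, r, theta_deg, phi_deg):
    """Place atom d bonded to c with |cd|=r, angle(b,c,d)=theta, torsion(a,b,c,d)=phi."""
    theta, phi = np.radians(theta_deg), np.radians(phi_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = r * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# self-check of NeRF torsion sign convention
_a, _b, _c = np.array([1.0, 1, 0]), np.array([0.0, 0, 0]), np.array([1.5, 0, 0])
_d = nerf(_a, _b, _c, 1.0, 109.0, 57.0)
assert abs(dihedral(_a, _b, _c, _d) - 57.0) < 1e-8, "NeRF convention broken"
assert abs(angle(_b, _c, _d) - 109.0) < 1e-8


# ---------------------------------------------------------------- base geometries

# Kekulé SMILES written atom-by-atom; atom order = name list below.
BASES = {
    "A": ("CN1C=NC2=C1N=CN=C2N",
          ["C1'", "N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"]),
    "G": ("CN1C=NC2=C1N=C(N)NC2=O",
          ["C1'", "N9", "C8", "N7", "C5", "C4", "N3", "C2", "N2", "N1", "C6", "O6"]),
    "C": ("CN1C=CC(N)=NC1=O",
          ["C1'", "N1", "C6", "C5", "C4", "N4", "N3", "C2", "O2"]),
    "T": ("CN1C=C(C)C(=O)NC1=O",
          ["C1'", "N1", "C6", "C5", "C7", "C4", "O4", "N3", "C2", "O2"]),
}

WC_TARGETS = {  # donor/acceptor heavy-atom distances, Å
    ("A", "T"): [(("N1", "A"), ("N3", "T"), 2.82), (("N6", "A"), ("O4", "T"), 2.95)],
    ("G", "C"): [(("N1", "G"), ("N3", "C"), 2.95), (("N2", "G"), ("O2", "C"), 2.86),
                 (("O6", "G"), ("N4", "C"), 2.91)],
}


def base_coords(base):
    """Planar heavy-atom coordinates of the N-methyl base, methyl first."""
    smiles, names = BASES[base]
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    conf = mol.GetConformer()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
    assert len(heavy) == len(names)
    # flatten onto the least-squares plane
    xyz -= xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(xyz)
    xyz = xyz @ vt.T
    xyz[:, 2] = 0.0
    return names, xyz


def anchor_base(names, xyz, mirror):
    """Rigidly place the flattened base at the standard-frame anchors."""
    n_idx, m_idx = 1, 0  # glycosidic N, methyl carbon (stand-in for C1')
    xyz = xyz - xyz[n_idx]
    if mirror:  # reflect across the N->methyl line (in-plane mirror)
        ax = unit(xyz[m_idx, :2])
        refl = 2 * np.outer(ax, ax) - np.eye(2)
        xyz[:, :2] = xyz[:, :2] @ refl.T
        xyz[:, 2] = 0.0
    target = unit((C1_PRIME - GLYCOSIDIC_N)[:2])
    cur = unit(xyz[m_idx, :2])
    ca = cur @ target
    sa = cur[0] * target[1] - cur[1] * target[0]
    rot = np.array([[ca, -sa], [sa, ca]])
    xyz[:, :2] = xyz[:, :2] @ rot.T
    return xyz + GLYCOSIDIC_N


def pick_wc_mirrors():
    """Choose the in-plane mirror of each base by Watson-Crick distance fit."""
    raw = {b: base_coords(b) for b in "AGCT"}
    placed = {(b, m): anchor_base(raw[b][0], raw[b][1].copy(), m)
              for b in "AGCT" for m in (False, True)}
    choice, report = {}, {}
    for (b1, b2), targets in WC_TARGETS.items():
        best = None
        for m1 in (False, True):
            for m2 in (False, True):
                x1 = placed[(b1, m1)]
                x2 = placed[(b2, m2)] @ STRAND2_FLIP  # complement on strand 2
                err = 0.0
                for (a1, _), (a2, _), d0 in targets:
                    i1 = raw[b1][0].index(a1)
                    i2 = raw[b2][0].index(a2)
                    err += (np.linalg.norm(x1[i1] - x2[i2]) - d0) ** 2
                if best is None or err < best[0]:
                    best = (err, m1, m2)
        choice[b1], choice[b2] = best[1], best[2]
        report[(b1, b2)] = best[0]
    bases = {}
    for b in "AGCT":
        names, _ = raw[b]
        xyz = placed[(b, choice[b])]
        bases[b] = (names[1:], xyz[1:])  # drop the methyl stand-in
    return bases, choice, report


# ---------------------------------------------------------------- backbone build

BACKBONE_ORDER = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]

# intra-residue bonds (backbone + glycosidic); base ring bonds added per base
BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("O4'", "C1'"), ("C3'", "O3'"),
    ("C3'", "C2'"), ("C2'", "C1'"),
]


def backbone_from_torsions(t):
    """NeRF chain from the fixed C1' anchor; returns {name: xyz}."""
    n = GLYCOSIDIC_N
    c1 = C1_PRIME
    v = n + np.array([0.0, 0.0, 1.0])  # fixed virtual reference
    at = {"C1'": c1}
    at["O4'"] = nerf(v, n, c1, 1.420, 108.2, t[0])
    at["C2'"] = nerf(v, n, c1, 1.521, 113.5, t[1])
    at["C3'"] = nerf(n, c1, at["C2'"], 1.525, 102.5, t[2])
    at["C4'"] = nerf(c1, at["C2'"], at["C3'"], 1.528, 102.5, t[3])
    at["O3'"] = nerf(c1, at["C2'"], at["C3'"], 1.423, 110.0, t[4])
    at["C5'"] = nerf(at["C2'"], at["C3'"], at["C4'"], 1.510, 114.7, t[5])
    at["O5'"] = nerf(at["C3'"], at["C4'"], at["C5'"], 1.440, 110.5, t[6])
    at["P"] = nerf(at["C4'"], at["C5'"], at["O5'"], 1.595, 120.5, t[7])
    at["OP1"] = nerf(at["C5'"], at["O5'"], at["P"], 1.485, 107.5, t[8])
    at["OP2"] = nerf(at["C5'"], at["O5'"], at["P"], 1.485, 107.5, t[9])
    return at


def average_step():
    from dnaenm.params import load_parameter_set
    ps = load_parameter_set("i")
    vals = np.array([[s.shift, s.slide, s.rise, s.tilt, s.roll, s.twist]
                     for s in ps.steps.values()])
    return vals.mean(axis=0)


def duplex_residues(atoms, step):
    """Backbone+anchor atoms of four residues: two pairs, two strands."""
    shift, slide, rise, tilt, roll, twist = step
    full, mid = _cehs_rotations(tilt, roll, twist)
    o1 = mid @ np.array([shift, slide, rise])
    frames = [(np.zeros(3), np.eye(3)), (o1, full)]
    out = {}
    for pair, (o, r) in enumerate(frames):
        for strand, flip in ((1, np.eye(3)), (2, STRAND2_FLIP)):
            out[(strand, pair)] = {
                name: (flip @ xyz) @ r.T + o for name, xyz in atoms.items()
            }
    return out


def wrap(a):
    return (a + 180.0) % 360.0 - 180.0


NAME_IDX = {n: i for i, n in enumerate(BACKBONE_ORDER)}


def _clash_masks(n_base):
    """Precomputed pair masks for the vectorized clash terms."""
    nb = len(BACKBONE_ORDER)
    # same-strand consecutive residues: exclude the O3'/C3' <-> P-shell pairs
    link_excl = np.zeros((nb, nb), dtype=bool)
    for a in ("O3'", "C3'"):
        for c in ("P", "O5'", "OP1", "OP2"):
            link_excl[NAME_IDX[a], NAME_IDX[c]] = True
            link_excl[NAME_IDX[c], NAME_IDX[a]] = True
    # base vs own backbone: exclude atoms bonded/1-3 to the glycosidic link
    base_near = np.zeros(nb, dtype=bool)
    for c in ("C1'", "O4'", "C2'"):
        base_near[NAME_IDX[c]] = True
    return link_excl, base_near


def all_steps():
    from dnaenm.params import load_parameter_set
    ps = load_parameter_set("i")
    return [np.array([s.shift, s.slide, s.rise, s.tilt, s.roll, s.twist])
            for s in ps.steps.values()]


def closure_objective(t, base_xyz, step, ref_chi_xyz, masks, steps_all=None):
    at = backbone_from_torsions(t)
    bb = np.array([at[n] for n in BACKBONE_ORDER])
    f = 0.0
    # deoxyribose ring closure
    f += 60.0 * (np.linalg.norm(at["C4'"] - at["O4'"]) - 1.446) ** 2
    f += 8.0 * ((angle(at["C3'"], at["C4'"], at["O4'"]) - 105.6) / 57.3) ** 2
    f += 8.0 * ((angle(at["C1'"], at["O4'"], at["C4'"]) - 109.9) / 57.3) ** 2
    f += 4.0 * ((angle(at["OP1"], at["P"], at["OP2"]) - 119.6) / 57.3) ** 2

    # four residues: (strand, pair) -> (11, 3) arrays
    shift, slide, rise, tilt, roll, twist = step
    full, mid = _cehs_rotations(tilt, roll, twist)
    o1 = mid @ np.array([shift, slide, rise])
    res = {
        (1, 0): bb,
        (1, 1): bb @ full.T + o1,
        (2, 0): bb @ STRAND2_FLIP,
        (2, 1): bb @ STRAND2_FLIP @ full.T + o1,
    }
    # backbone link geometry, summed over every dinucleotide step type so the
    # single shared backbone is a compromise that closes for all 16 steps
    step_list = [step] if steps_all is None else steps_all
    w = 1.0 / len(step_list)
    bb2 = bb @ STRAND2_FLIP
    for sp in step_list:
        full_s, mid_s = _cehs_rotations(sp[3], sp[4], sp[5])
        o1_s = mid_s @ sp[:3]
        res_s = {
            (1, 0): bb, (1, 1): bb @ full_s.T + o1_s,
            (2, 0): bb2, (2, 1): bb2 @ full_s.T + o1_s,
        }
        # strand 1: O3'(pair0) -> P(pair1); strand 2: O3'(pair1) -> P(pair0)
        for (s, po3, pp) in ((1, 0, 1), (2, 1, 0)):
            o3, c3 = res_s[(s, po3)][NAME_IDX["O3'"]], res_s[(s, po3)][NAME_IDX["C3'"]]
            p, o5 = res_s[(s, pp)][NAME_IDX["P"]], res_s[(s, pp)][NAME_IDX["O5'"]]
            f += w * 40.0 * (np.linalg.norm(o3 - p) - 1.605) ** 2
            f += w * 5.0 * ((angle(c3, o3, p) - 119.7) / 57.3) ** 2
            f += w * 5.0 * ((angle(o3, p, o5) - 104.0) / 57.3) ** 2
            for op in ("OP1", "OP2"):
                f += w * 1.0 * ((angle(o3, p, res_s[(s, pp)][NAME_IDX[op]]) - 107.7) / 57.3) ** 2

    link_excl, base_near = masks

    def hinge_sum(xa, xb, excl=None, floor=2.65):
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        pen = np.clip(floor - d, 0.0, None) ** 2
        if excl is not None:
            pen = np.where(excl, 0.0, pen)
        return pen.sum()

    keys = list(res)
    for ki in range(len(keys)):
        for kj in range(ki + 1, len(keys)):
            (si, _), (sj, _) = keys[ki], keys[kj]
            excl = link_excl if si == sj else None
            f += 0.5 * hinge_sum(res[keys[ki]], res[keys[kj]], excl)
    # base (residue (1,0), standard frame) vs own distal backbone
    f += 0.5 * hinge_sum(base_xyz, bb[~base_near])
    # base vs backbones of the other three residues
    for key in keys[1:]:
        f += 0.5 * hinge_sum(base_xyz, res[key])

    # weak B-form torsion priors: gamma-like and beta-like
    f += 0.02 * (wrap(t[6] - 54.0) / 100.0) ** 2
    f += 0.02 * (wrap(t[7] - 171.0) / 100.0) ** 2
    # anti glycosidic orientation prior
    chi = dihedral(at["O4'"], at["C1'"], GLYCOSIDIC_N, ref_chi_xyz)
    f += 0.3 * (wrap(chi - (-117.0)) / 100.0) ** 2
    return f


def optimize_backbone(base_xyz, ref_chi_xyz):
    from scipy.optimize import minimize

    step = average_step()
    masks = _clash_masks(base_xyz.shape[0])
    steps_all = all_steps()
    obj = lambda t: closure_objective(t, base_xyz, step, ref_chi_xyz, masks, steps_all)
    best = None
    starts = [np.array([20.0, 140.0, 35.0, -35.0, 90.0, 120.0, 54.0, 171.0, -60.0, 60.0])]
    for _ in range(14):
        starts.append(RNG.uniform(-180, 180, size=10))
    for t0 in starts:
        r = minimize(obj, t0, method="Powell",
                     options={"maxfev": 12000, "xtol": 1e-4, "ftol": 1e-9})
        if best is None or r.fun < best.fun:
            best = r
    r = minimize(obj, best.x, method="Powell",
                 options={"maxfev": 30000, "xtol": 1e-7, "ftol": 1e-12})
    return r if r.fun < best.fun else best


# ---------------------------------------------------------------- main

def main():
    out_path = Path(__file__).resolve().parents[1] / "src/dnaenm/data/nucleotide_templates.tsv"
    bases, mirrors, wc_err = pick_wc_mirrors()
    print("WC mirror choice:", mirrors, "fit errors:", wc_err)

    # shared backbone, optimized with the adenine base present for chi/clash terms
    a_names, a_xyz = bases["A"]
    ref_chi_xyz = a_xyz[a_names.index("C4")]
    result = optimize_backbone(a_xyz, ref_chi_xyz)
    print("backbone objective:", result.fun)
    at = backbone_from_torsions(result.x)

    # diagnostics
    step = average_step()
    res = duplex_residues(at, step)
    link = np.linalg.norm(res[(1, 0)]["O3'"] - res[(1, 1)]["P"])
    link2 = np.linalg.norm(res[(2, 1)]["O3'"] - res[(2, 0)]["P"])
    ring = np.linalg.norm(at["C4'"] - at["O4'"])
    chi_A = dihedral(at["O4'"], at["C1'"], GLYCOSIDIC_N, ref_chi_xyz)
    print(f"O3'-P link: strand1 {link:.3f} Å, strand2 {link2:.3f} Å; "
          f"ring C4'-O4' {ring:.3f} Å; chi(A) {chi_A:.1f}°")
    print("torsions:", np.round(result.x, 1))

    lines = ["# Idealized B-form nucleotide heavy-atom templates (synthetic),",
             "# standard base reference frame; generated by scripts/make_templates.py",
             "base\tname\telement\tx\ty\tz"]
    for b in "ACGT":
        names, xyz = bases[b]
        rows = [(n, at[n]) for n in BACKBONE_ORDER] + list(zip(names, xyz))
        for name, p in rows:
            lines.append(f"{b}\t{name}\t{name[0]}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}")
    out_path.write_text("\n".join(lines) + "\n")
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
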