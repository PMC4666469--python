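"""Batch pipelines: sequence profiling, GC sweeps, model comparison, crystal fits.

Four workflows built on the lower-level modules:

* :func:`profile_sequence` — sequence → coarse-grained fluctuation summary
  (⟨CF⟩ and directional components, inter-strand ⟨DF⟩ components, shape
  descriptors σ1/σ2).
* :func:`gc_sweep` — batches of random sequences across a GC-content grid,
  with pooled correlations between shape and fluctuation averages.
* :func:`compare_aaenm_cgenm` — per-nucleotide fluctuation profiles of the
  all-atom and coarse-grained models built from the same helical
  parameters, correlated sequence by sequence.
* :func:`fit_crystal` — grid search of the all-atom model's (Ca, B_B, B_w)
  against a crystal structure's experimental temperature factors, using the
  outlier-excluding correlation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nma
from .builder import DnaStructure, build_structure
from .constants import (
    DEFAULT_CA,
    DEFAULT_CG,
    DEFAULT_CUTOFF,
    DEFAULT_TEMPERATURE,
)
from .enm import build_aaenm, build_cgenm, hessian
from .geometry import shape_of
from .params import HelicalParameterSet, load_parameter_set
from .pdbio import CrystalStructure
from .sequences import gc_fraction, random_sequences, validate
from .stats import CorrelationResult, pearson, robust_pearson


@dataclass(frozen=True)
class SequenceSummary:
    """Averaged coarse-grained dynamics + shape of one sequence."""

    sequence_id: str
    length: int
    gc: float
    cf: float  # ⟨CF_i⟩ over all 2N nucleotides, Å²
    cf_b: float
    cf_s: float
    cf_t: float
    df: float  # ⟨DF_i⟩ over the N base pairs, Å²
    df_b: float
    df_s: float
    df_t: float
    lambda1: float
    lambda2: float
    lambda3: float
    sigma1: float
    sigma2: float

    def as_dict(self) -> dict:
        return asdict(self)


def cgenm_profiles(
    structure: DnaStructure,
    cg: float = DEFAULT_CG,
    temperature: float = DEFAULT_TEMPERATURE,
) -> dict[str, np.ndarray]:
    """Per-nucleotide CF (+ b/s/t components) and per-pair DF components."""
    n = structure.n_bp
    net = build_cgenm(structure, cg)
    modes = nma.normal_modes(hessian(net), temperature=temperature)
    axes = nma.axis_frames(net.positions, n)
    pair_of_node = np.concatenate([np.arange(n), np.arange(n)])
    pairs = np.column_stack([np.arange(n), np.arange(n, 2 * n)])

    out = {"cf": nma.mean_square_fluctuation(modes)}
    for name, ax in (("b", axes.b), ("s", axes.s), ("t", axes.t)):
        out[f"cf_{name}"] = nma.node_direction_msf(modes, ax[pair_of_node])
        out[f"df_{name}"] = nma.pair_difference_msf(modes, pairs, ax)
    # total inter-strand fluctuation |δx_i − δx_i'|²
    nv = modes.node_vectors()
    rel = nv[pairs[:, 0]] - nv[pairs[:, 1]]
    out["df"] = (rel**2).sum(axis=1) @ modes.mode_weights
    return out


def profile_sequence(
    seq: str,
    params: HelicalParameterSet | None = None,
    cg: float = DEFAULT_CG,
    temperature: float = DEFAULT_TEMPERATURE,
    sequence_id: str = "",
) -> SequenceSummary:
    """Coarse-grained fluctuation and shape summary of one duplex.

    Builds the C1-resolution structure, runs the CGENM normal-mode
    analysis, projects on the per-pair (b, s, t) axes and appends the
    covariance shape descriptors computed over the C1' nodes.
    """
    seq = validate(seq)
    if params is None:
        params = load_parameter_set("i")
    structure = build_structure(seq, params, resolution="C1")
    prof = cgenm_profiles(structure, cg, temperature)
    shape = shape_of(structure.c1_positions())
    return SequenceSummary(
        sequence_id=sequence_id or seq[:12],
        length=len(seq),
        gc=gc_fraction(seq),
        cf=float(prof["cf"].mean()),
        cf_b=float(prof["cf_b"].mean()),
        cf_s=float(prof["cf_s"].mean()),
        cf_t=float(prof["cf_t"].mean()),
        df=float(prof["df"].mean()),
        df_b=float(prof["df_b"].mean()),
        df_s=float(prof["df_s"].mean()),
        df_t=float(prof["df_t"].mean()),
        lambda1=shape.lambda1,
        lambda2=shape.lambda2,
        lambda3=shape.lambda3,
        sigma1=shape.sigma1,
        sigma2=shape.sigma2,
    )


def profile_batch(records, params=None, cg=DEFAULT_CG,
                  temperature=DEFAULT_TEMPERATURE) -> pd.DataFrame:
    """Profile ``[(id, sequence), ...]`` into a tidy summary table."""
    rows = [
        profile_sequence(s, params, cg, temperature, sequence_id=name).as_dict()
        for name, s in records
    ]
    return pd.DataFrame(rows)


def gc_sweep(
    gc_grid,
    n_per_gc: int,
    length: int = 150,
    seed: int = 0,
    params: HelicalParameterSet | None = None,
    cg: float = DEFAULT_CG,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[pd.DataFrame, dict]:
    """Random-sequence screening across a GC-content grid.

    Generates ``n_per_gc`` random sequences at every GC content of
    ``gc_grid``, profiles each, and reports pooled correlations between the
    shape descriptors and the fluctuation averages: (σ1, ⟨CF⟩),
    (⟨DF^b⟩, σ1) and (⟨DF^b⟩, σ2), both with and without the 2.5σ outlier
    rule.  Returns (summary table, correlation report).  Fully reproducible
    from ``seed``; per-sequence results are independent of the grid
    composition.
    """
    gc_grid = [float(g) for g in gc_grid]
    if any(not 0 <= g <= 1 for g in gc_grid):
        raise ValueError("GC grid values must lie in [0, 1]")
    if params is None:
        params = load_parameter_set("i")
    rows = []
    for gi, gc in enumerate(gc_grid):
        seqs = random_sequences(
            n_per_gc, length, gc, seed=np.random.SeedSequence((seed, gi))
        )
        for si, s in enumerate(seqs):
            summary = profile_sequence(
                s, params, cg, temperature, sequence_id=f"gc{gc:g}_{si}"
            )
            row = summary.as_dict()
            row["gc_target"] = gc
            rows.append(row)
    table = pd.DataFrame(rows)

    def both(x, y) -> dict:
        r = robust_pearson(table[x], table[y])
        return {
            "rho": r.rho, "n_used": r.n_used, "n_excluded": r.n_excluded,
            "rho_plain": pearson(table[x], table[y]),
        }

    report = {
        "sigma1_vs_cf": both("sigma1", "cf"),
        "dfb_vs_sigma1": both("df_b", "sigma1"),
        "dfb_vs_sigma2": both("df_b", "sigma2"),
        "per_gc_mean": table.groupby("gc_target")[
            ["cf", "df", "df_b", "df_s", "df_t", "sigma1", "sigma2"]
        ].mean().to_dict(orient="index"),
        "manifest": {
            "seed": seed, "length": length, "n_per_gc": n_per_gc,
            "gc_grid": gc_grid, "cg": cg, "temperature": temperature,
            "parameter_set": params.label,
        },
    }
    return table, report


def compare_aaenm_cgenm(
    n_sequences: int = 10,
    length: int = 50,
    params: HelicalParameterSet | None = None,
    ca: float = DEFAULT_CA,
    cg: float = DEFAULT_CG,
    seed: int = 0,
    gc: float = 0.5,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[pd.DataFrame, dict]:
    """Per-nucleotide fluctuation agreement between the two models.

    For each random sequence both models are built from the same helical
    parameters; the all-atom per-nucleotide profiles (NF and its b/s/t
    components, atom-averaged displacements) are correlated against the
    coarse-grained ones (CF and components) across all 2N nucleotides.
    Returns the per-sequence correlation table and a mean/SD report.
    """
    if params is None:
        params = load_parameter_set("i")
    seqs = random_sequences(n_sequences, length, gc, seed=seed)
    rows = []
    for si, seq in enumerate(seqs):
        structure = build_structure(seq, params, resolution="all-atom")
        n = structure.n_bp
        axes = nma.axis_frames(structure)
        pair_of_nuc = np.concatenate([np.arange(n), np.arange(n)])

        aa_net = build_aaenm(structure, ca)
        aa_modes = nma.normal_modes(hessian(aa_net), temperature=temperature)
        groups = structure.atoms_by_nucleotide()
        nf = nma.group_fluctuations(aa_modes, groups)

        cg_prof = cgenm_profiles(structure, cg, temperature)
        cf_by = {
            "": cg_prof["cf"],
            "b": cg_prof["cf_b"], "s": cg_prof["cf_s"], "t": cg_prof["cf_t"],
        }
        nf_by = {"": nf}
        for name, ax in (("b", axes.b), ("s", axes.s), ("t", axes.t)):
            nf_by[name] = nma.group_direction_msf(
                aa_modes, groups, ax[pair_of_nuc]
            )
        row = {"sequence": seq}
        for comp in ("", "b", "s", "t"):
            key = "nf_cf" if comp == "" else f"nf{comp}_cf{comp}"
            row[key] = pearson(nf_by[comp], cf_by[comp])
        rows.append(row)
    table = pd.DataFrame(rows)
    cols = ["nf_cf", "nfb_cfb", "nfs_cfs", "nft_cft"]
    report = {
        "mean": table[cols].mean().to_dict(),
        "std": table[cols].std(ddof=1).to_dict(),
        "grand_mean": float(table[cols].to_numpy().mean()),
        "manifest": {
            "seed": seed, "n_sequences": n_sequences, "length": length,
            "ca": ca, "cg": cg, "gc": gc, "temperature": temperature,
            "parameter_set": params.label,
        },
    }
    return table, report


def compare_groups(
    records_a,
    records_b,
    labels: tuple[str, str] = ("group_a", "group_b"),
    params: HelicalParameterSet | None = None,
    cg: float = DEFAULT_CG,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile two sequence groups (e.g. nucleosome-forming vs -inhibiting).

    ``records_*`` are ``[(id, sequence), ...]`` (e.g. from
    :func:`dnaenm.read_fasta`).  Returns the combined per-sequence table
    (with a ``group`` column, ready for histogramming) and a group
    mean/std summary of every fluctuation and shape field.
    """
    tables = []
    for label, records in zip(labels, (records_a, records_b)):
        t = profile_batch(records, params, cg, temperature)
        t.insert(0, "group", label)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    fields = ["cf", "cf_b", "cf_s", "cf_t", "df", "df_b", "df_s", "df_t",
              "sigma1", "sigma2"]
    summary = table.groupby("group")[fields].agg(["mean", "std"])
    return table, summary


@dataclass(frozen=True)
class CrystalFitResult:
    """Outcome of an all-atom parameter fit against experimental B-factors."""

    source: str
    ca: float
    bb: float
    bw: float
    rho_tf: CorrelationResult
    rho_matf: float
    grid: pd.DataFrame = field(repr=False)
    tf_model: np.ndarray = field(repr=False)
    tf_experiment: np.ndarray = field(repr=False)


def evaluate_crystal(
    cs: CrystalStructure,
    ca: float,
    bb: float,
    bw: float,
    temperature: float,
    rc: float = DEFAULT_CUTOFF,
    include_water: bool = False,
    s: float = 2.5,
    matf_robust: bool = False,
):
    """Model-vs-experiment TF and MATF correlations at one parameter point."""
    net = build_aaenm(cs, ca=ca, rc=rc, bb=bb, bw=bw)
    modes = nma.normal_modes(hessian(net), temperature=temperature)
    tf_model = nma.temperature_factor(nma.mean_square_fluctuation(modes))
    mask = np.ones(cs.n_atoms, bool) if include_water else cs.dna_mask()
    rho_tf = robust_pearson(tf_model[mask], cs.bfactors[mask], s=s)

    dna = cs.dna_mask()
    matf_model = nma.motif_average_tf(
        tf_model[dna], [cs.motifs[i] for i in np.flatnonzero(dna)],
        cs.nucleotide_id[dna],
    )["matf"].to_numpy()
    matf_exp = nma.motif_average_tf(
        cs.bfactors[dna], [cs.motifs[i] for i in np.flatnonzero(dna)],
        cs.nucleotide_id[dna],
    )["matf"].to_numpy()
    if matf_robust:
        rho_matf = robust_pearson(matf_model, matf_exp, s=s).rho
    else:
        rho_matf = pearson(matf_model, matf_exp)
    return rho_tf, rho_matf, tf_model


def fit_crystal(
    cs: CrystalStructure,
    ca_grid,
    bb_grid,
    bw_grid,
    temperature: float,
    rc: float = DEFAULT_CUTOFF,
    include_water: bool = False,
    s: float = 2.5,
    matf_robust: bool = False,
) -> CrystalFitResult:
    """Exhaustive (Ca, B_B, B_w) grid search maximizing the robust ρ(TF).

    ρ is scale-invariant, so Ca only sets the absolute TF scale; the shape
    of the fit is driven by the restraint strengths.  Returns the argmax
    point, the full ρ surface, and the MATF correlation at the optimum.
    """
    ca_grid, bb_grid, bw_grid = (
        [float(v) for v in g] for g in (ca_grid, bb_grid, bw_grid)
    )
    if not (ca_grid and bb_grid and bw_grid):
        raise ValueError("empty parameter grid")
    rows = []
    best = None
    for ca in ca_grid:
        for bb in bb_grid:
            for bw in bw_grid:
                rho_tf, rho_matf, tf_model = evaluate_crystal(
                    cs, ca, bb, bw, temperature, rc, include_water, s, matf_robust
                )
                rows.append(
                    {"ca": ca, "bb": bb, "bw": bw, "rho_tf": rho_tf.rho,
                     "rho_matf": rho_matf}
                )
                if best is None or rho_tf.rho > best[0].rho:
                    best = (rho_tf, rho_matf, tf_model, ca, bb, bw)
    rho_tf, rho_matf, tf_model, ca, bb, bw = best
    return CrystalFitResult(
        source=cs.source, ca=ca, bb=bb, bw=bw,
        rho_tf=rho_tf, rho_matf=rho_matf,
        grid=pd.DataFrame(rows),
        tf_model=tf_model, tf_experiment=cs.bfactors.copy(),
    )


def synthetic_crystal(
    seq: str,
    ca: float,
    bb: float,
    bw: float,
    temperature: float = DEFAULT_TEMPERATURE,
    n_waters: int = 20,
    seed: int = 0,
    noise: float = 0.0,
) -> CrystalStructure:
    """Model-generated stand-in for a crystal structure (synthetic).

    Builds an all-atom duplex, scatters ``n_waters`` water oxygens in a
    hydration shell around the backbone, computes the model's own
    temperature factors at (ca, bb, bw) and stores them in the B-factor
    field (optionally with multiplicative lognormal ``noise``).  Used to
    exercise crystal-fit workflows without experimental data.
    """
    rng = np.random.default_rng(seed)
    structure = build_structure(seq, resolution="all-atom")
    coords = structure.coords
    waters = []
    phosphate_like = [
        i for i, n in enumerate(structure.atom_names) if n in ("OP1", "OP2", "O3'")
    ]
    tries = 0
    while len(waters) < n_waters and tries < 200 * n_waters:
        tries += 1
        anchor = coords[rng.choice(phosphate_like)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        xyz = anchor + direction * rng.uniform(2.6, 3.2)
        all_pts = np.vstack([coords] + waters) if waters else coords
        if np.linalg.norm(all_pts - xyz, axis=1).min() > 2.4:
            waters.append(xyz[None, :])
    waters = np.vstack(waters) if waters else np.zeros((0, 3))

    n_dna = structure.n_atoms
    n_wat = waters.shape[0]
    cs = CrystalStructure(
        source=f"synthetic:{seq[:10]}",
        sequence=structure.sequence,
        coords=np.vstack([coords, waters]),
        atom_names=structure.atom_names + ("O",) * n_wat,
        elements=structure.elements + ("O",) * n_wat,
        motifs=structure.motifs + ("water",) * n_wat,
        bfactors=np.ones(n_dna + n_wat),
        strand=np.concatenate([structure.strand, np.zeros(n_wat, int)]),
        pair_index=np.concatenate([structure.pair_index, -np.ones(n_wat, int)]),
        is_water=np.concatenate([np.zeros(n_dna, bool), np.ones(n_wat, bool)]),
        is_edge=np.concatenate(
            [_edge_mask(structure), np.zeros(n_wat, bool)]
        ),
    )
    net = build_aaenm(cs, ca=ca, bb=bb, bw=bw)
    modes = nma.normal_modes(hessian(net), temperature=temperature)
    tf = nma.temperature_factor(nma.mean_square_fluctuation(modes))
    if noise > 0:
        tf = tf * np.exp(rng.normal(0.0, noise, size=tf.shape))
    return CrystalStructure(
        **{**{f: getattr(cs, f) for f in (
            "source", "sequence", "coords", "atom_names", "elements", "motifs",
            "strand", "pair_index", "is_water", "is_edge", "warnings_",
        )}, "bfactors": tf}
    )


def _edge_mask(structure: DnaStructure) -> np.ndarray:
    pi = structure.pair_index
    return (pi == 0) | (pi == structure.n_bp - 1)
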