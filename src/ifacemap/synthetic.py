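"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its arguments including the seed, so
identical calls give byte-identical output. Structures are deliberately
coarse — one backbone bead per residue plus a few pseudo side-chain atoms on
interface residues — because the downstream contracts (contact cutoffs,
clustering RMSD, salt-bridge geometry) are purely geometric. Real-PDB
ingestion lives in :mod:`ifacemap.structure_io`.

The emulated study conditions: rigid-body docking-pose ensembles around a
fixed receptor with a planted epitope (K54/K60 on the growth-factor side),
frame series in which designated residue pairs touch with planted Bernoulli
or Markov persistence, two-state HSQC peak tables where a planted residue set
loses intensity upon ligand addition, and 4-parameter-logistic competition
and thermal-melt curves with Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, ModelSet, SubstitutionList, write_models
from .binding_quant import DoseResponse, logistic_competition, logistic_melt

CONTACT_CUTOFF_A = 6.0  # heavy-atom contact rule, angstroms


# --------------------------------------------------------------------------
# truth records and plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseTruth:
    pose_id: int
    is_true_interface: bool
    planted_score: float
    epitope_contact: bool


@dataclass
class ContactPlan:
    """Planted residue-pair contact persistence for a synthetic frame series."""

    pairs: list[tuple[int, int, float]]  # (ligand resid, receptor resid, p)
    n_frames: int
    correlation_mode: str = "independent"  # or "markov"
    stay_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        keys = [(i, j) for i, j, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue pairs in plan")
        for _, _, p in self.pairs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"persistence probability {p} outside [0, 1]")
        if self.correlation_mode not in ("independent", "markov"):
            raise ValueError(f"unknown correlation mode {self.correlation_mode!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Rigid-body perturbation bounds: translation in angstrom, rotation in degrees."""

    max_translation: float = 3.0
    max_rotation: float = 8.0
    seed: int = 0
    exact_magnitude: bool = False

    def __post_init__(self) -> None:
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")
        if not 0.0 <= self.max_rotation <= 180.0:
            raise ValueError("max_rotation must be in [0, 180] degrees")


# --------------------------------------------------------------------------
# coarse bead templates
# --------------------------------------------------------------------------

def _spiral_points(n: int, radius: float) -> np.ndarray:
    """Deterministic quasi-uniform points on a sphere (Fibonacci spiral)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])

LIGAND_RESIDUES = [26, 27, 30, 54, 60, 74, 127, 128, 133, 150]
_LIGAND_NAMES = {26: "ALA", 27: "ASP", 30: "ARG", 54: "LYS", 60: "LYS",
                 74: "LYS", 127: "LYS", 128: "ARG", 133: "LYS", 150: "MET"}
RECEPTOR_RESIDUES = [382, 397, 420, 440, 460, 480, 498, 500, 524, 525,
                     529, 533, 542, 548, 560, 575, 590, 599]
_RECEPTOR_NAMES = {397: "GLU", 498: "GLU", 524: "LYS", 525: "GLU", 529: "ASP",
                   533: "LYS", 542: "GLU", 548: "GLU", 560: "ASP"}


def ligand_template() -> tuple[list[AtomRecord], np.ndarray]:
    """Coarse growth-factor model: one CA bead per residue, NZ pseudo-atoms on
    the epitope lysines (radius ~4 A, compact by construction)."""
    beads = _spiral_points(len(LIGAND_RESIDUES), 4.0)
    atoms, xyz, serial = [], [], 1
    for rid, pos in zip(LIGAND_RESIDUES, beads):
        name = _LIGAND_NAMES.get(rid, "ALA")
        atoms.append(AtomRecord(serial, "CA", "C", name, "L", rid))
        xyz.append(pos)
        serial += 1
        if name == "LYS":
            atoms.append(AtomRecord(serial, "NZ", "N", name, "L", rid))
            xyz.append(pos * (5.5 / np.linalg.norm(pos)))
            serial += 1
    return atoms, np.asarray(xyz)


def receptor_template() -> tuple[list[AtomRecord], np.ndarray]:
    """Coarse nucleotide-binding-domain model: CA beads on a 9 A shell."""
    beads = _spiral_points(len(RECEPTOR_RESIDUES), 9.0)
    atoms = [AtomRecord(1000 + i, "CA", "C", _RECEPTOR_NAMES.get(rid, "ALA"),
                        "R", rid)
             for i, rid in enumerate(RECEPTOR_RESIDUES)]
    return atoms, beads


# --------------------------------------------------------------------------
# pose ensembles
# --------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


def gen_complex_poses(n_true: int, n_decoy: int,
                      epitope: tuple[int, ...] = (54, 60),
                      seed: int = 0,
                      contact_cutoff: float = CONTACT_CUTOFF_A,
                      true_score_mean: float = -20.0,
                      decoy_score_mean: float = -5.0,
                      score_sd: float = 2.0,
                      decoy_shell_offset: float = 15.0,
                      ) -> tuple[ModelSet, list[PoseTruth]]:
    """Rigid ligand placements around a fixed receptor with planted truth.

    True poses put one epitope pseudo-atom at a distance drawn uniformly in
    [3 A, cutoff) from a receptor atom; decoys sit on a shell at the receptor
    bounding radius + ``decoy_shell_offset``, guaranteeing no epitope contact.
    Planted scores for true poses are stochastically lower (more favorable)
    than for decoys. Truth labels are recomputed geometrically before return.
    """
    if n_true + n_decoy < 1:
        raise ValueError("at least one pose must be requested")
    lig_atoms, lig_xyz = ligand_template()
    rec_atoms, rec_xyz = receptor_template()
    lig_resids = {a.residue_id for a in lig_atoms}
    missing = [r for r in epitope if r not in lig_resids]
    if missing:
        raise ValueError(f"epitope residues absent from ligand template: {missing}")

    rng = np.random.default_rng(seed)
    lig_xyz = lig_xyz - lig_xyz.mean(axis=0)
    rec_radius = float(np.linalg.norm(rec_xyz, axis=1).max())
    epi_idx = [i for i, a in enumerate(lig_atoms) if a.residue_id in epitope]

    labels = np.array([True] * n_true + [False] * n_decoy)
    rng.shuffle(labels)
    models, truths = [], []
    for pose_id, is_true in enumerate(labels):
        rot = _random_rotation(rng)
        placed = lig_xyz @ rot.T
        if is_true:
            anchor = int(rng.integers(len(epi_idx)))
            target_atom = int(rng.integers(len(rec_xyz)))
            u = rec_xyz[target_atom]
            u = u / np.linalg.norm(u)
            d = rng.uniform(3.0, contact_cutoff)
            shift = rec_xyz[target_atom] + d * u - placed[epi_idx[anchor]]
            score = rng.normal(true_score_mean, score_sd)
        else:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            shift = (rec_radius + decoy_shell_offset) * v
            score = rng.normal(decoy_score_mean, score_sd)
        placed = placed + shift
        models.append(np.vstack([placed, rec_xyz]))
        dmin = np.min(np.linalg.norm(
            placed[epi_idx][:, None, :] - rec_xyz[None, :, :], axis=-1))
        truths.append(PoseTruth(pose_id=pose_id,
                                is_true_interface=bool(is_true),
                                planted_score=float(score),
                                epitope_contact=bool(dmin < contact_cutoff)))
    ensemble = ModelSet(atoms=lig_atoms + rec_atoms,
                        coords=np.stack(models), metadata="synthetic poses")
    return ensemble, truths


# --------------------------------------------------------------------------
# contact-trajectory frame series
# --------------------------------------------------------------------------

def _sample_contact_series(p: float, plan: ContactPlan,
                           rng: np.random.Generator) -> np.ndarray:
    n = plan.n_frames
    if plan.correlation_mode == "independent" or p in (0.0, 1.0):
        return rng.random(n) < p
    s = plan.stay_prob
    p01 = (1.0 - s) * p / (1.0 - p)  # keeps Bernoulli(p) stationary
    if p01 > 1.0:
        raise ValueError("stay_prob incompatible with stationary probability p")
    out = np.empty(n, dtype=bool)
    out[0] = rng.random() < p
    for t in range(1, n):
        out[t] = rng.random() < (s if out[t - 1] else p01)
    return out


def gen_contact_trajectory(plan: ContactPlan,
                           cutoff: float = CONTACT_CUTOFF_A,
                           seed: int = 0,
                           contact_distance: float = 3.0,
                           ) -> tuple[ModelSet, dict[tuple[int, int], np.ndarray]]:
    """Frame series in which each planned pair touches with its planted
    probability; unplanned pairs are never within the cutoff.

    Ligand residues are modelled as LYS (CA + NZ) strung far apart; each
    planned receptor residue is a GLU whose carboxylate oxygen approaches the
    partner's NZ to ``contact_distance`` (default 3 A, inside the 4 A
    salt-bridge rule) on contact frames and retreats to cutoff + 8 A
    otherwise. Returns the frames plus the realized per-pair contact series.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_ids = sorted({i for i, _, _ in plan.pairs})
    rec_ids = sorted({j for _, j, _ in plan.pairs})
    spacing = 10.0 * (cutoff + contact_distance)

    lig_pos = {r: np.array([0.0, spacing * k, 0.0])
               for k, r in enumerate(lig_ids)}
    atoms, base = [], []
    serial = 1
    for r in lig_ids:
        atoms.append(AtomRecord(serial, "CA", "C", "LYS", "L", r)); serial += 1
        base.append(lig_pos[r])
        atoms.append(AtomRecord(serial, "NZ", "N", "LYS", "L", r)); serial += 1
        base.append(lig_pos[r] + np.array([1.5, 0.0, 0.0]))
    rec_ca = {r: np.array([6.0 * spacing, spacing * k, 0.0])
              for k, r in enumerate(rec_ids)}
    for r in rec_ids:
        atoms.append(AtomRecord(serial, "CA", "C", "GLU", "R", r)); serial += 1
        base.append(rec_ca[r])
    oxy_names = ["OE1", "OE2", "OE3", "OE4"]
    moving: list[tuple[int, tuple[int, int]]] = []  # (atom index, pair key)
    per_res_count: dict[int, int] = {}
    for i, j, _ in plan.pairs:
        k = per_res_count.get(j, 0)
        if k >= len(oxy_names):
            raise ValueError(f"receptor residue {j} appears in too many pairs")
        per_res_count[j] = k + 1
        atoms.append(AtomRecord(serial, oxy_names[k], "O", "GLU", "R", j))
        serial += 1
        moving.append((len(base), (i, j)))
        base.append(rec_ca[j].copy())

    rng = np.random.default_rng(seed)
    realized = {(i, j): _sample_contact_series(p, plan, rng)
                for i, j, p in plan.pairs}
    nz_pos = {r: lig_pos[r] + np.array([1.5, 0.0, 0.0]) for r in lig_ids}
    frames = np.repeat(np.asarray(base)[None, :, :], plan.n_frames, axis=0)
    for atom_idx, (i, j) in moving:
        near = nz_pos[i] + np.array([contact_distance, 0.0, 0.0])
        far = nz_pos[i] + np.array([cutoff + 8.0, 0.0, 0.0])
        series = realized[(i, j)]
        frames[:, atom_idx, :] = np.where(series[:, None], near, far)
    ms = ModelSet(atoms=atoms, coords=frames, metadata="synthetic trajectory")
    return ms, realized


# --------------------------------------------------------------------------
# HSQC peak tables
# --------------------------------------------------------------------------

PEAK_COLUMNS = ["residue", "assigned", "dH_ppm", "dN_ppm", "intensity",
                "noise", "overlapped", "proline"]


def gen_peak_tables(n_residues: int, affected: tuple[int, ...],
                    attenuation: float, shift_noise: float = 0.0,
                    seed: int = 0, broadening: float = 0.9,
                    proline: tuple[int, ...] = (),
                    overlapped: tuple[int, ...] = (),
                    intensity_noise: float = 0.0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apo/holo peak-table pair with a planted intensity-loss residue set.

    Holo intensities of ``affected`` residues are apo x ``attenuation``;
    all other residues get the mild global line-broadening factor
    ``broadening`` (complex formation slows tumbling for every peak). Peak
    positions jitter by ``shift_noise`` ppm; noise levels are identical
    between conditions so SN ratios equal intensity ratios.
    """
    if not 0.0 <= attenuation < 1.0:
        raise ValueError("attenuation must be in [0, 1)")
    bad = [r for r in affected if not 1 <= r <= n_residues]
    if bad:
        raise ValueError(f"affected residues out of range: {bad}")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    dh = rng.uniform(6.5, 10.5, n_residues)
    dn = rng.uniform(102.0, 133.0, n_residues)
    inten = rng.uniform(0.8e6, 1.2e6, n_residues)
    noise = np.full(n_residues, 2.0e4)
    aff = np.isin(residues, affected)
    pro = np.isin(residues, proline)
    ovl = np.isin(residues, overlapped)

    apo = pd.DataFrame({
        "residue": residues, "assigned": True, "dH_ppm": dh, "dN_ppm": dn,
        "intensity": inten, "noise": noise, "overlapped": ovl, "proline": pro})
    factor = np.where(aff, attenuation, broadening)
    holo_int = inten * factor
    if intensity_noise > 0:
        holo_int = np.clip(
            holo_int + rng.normal(0.0, intensity_noise * inten), 0.0, None)
    holo = pd.DataFrame({
        "residue": residues, "assigned": True,
        "dH_ppm": dh + rng.normal(0.0, shift_noise, n_residues),
        "dN_ppm": dn + rng.normal(0.0, shift_noise, n_residues),
        "intensity": holo_int, "noise": noise,
        "overlapped": ovl, "proline": pro})
    return apo, holo


# --------------------------------------------------------------------------
# sigmoid curves
# --------------------------------------------------------------------------

def gen_sigmoid_curve(kind: str, midpoint: float, slope: float = 1.0,
                      plateaus: tuple[float, float] = (1.0, 0.0),
                      n_points: int = 12, noise_sd: float = 0.0,
                      seed: int = 0,
                      x_range: tuple[float, float] | None = None,
                      n_replicates: int = 1,
                      ) -> DoseResponse:
    """4-parameter-logistic curve with Gaussian noise.

    ``kind="competition"``: log-spaced concentrations (default 1.4e-3 to
    22.5 uM, the competitor range used for apparent-KD fits); signal falls
    from the top plateau to the bottom with increasing competitor.
    ``kind="melt"``: linear temperatures (default 20-95 C); the A330/A350
    ratio steps between plateaus at the unfolding midpoint.

    ``noise_sd`` is the per-measurement noise; with ``n_replicates`` > 1 each
    reported point is the mean of that many independent measurements,
    emulating assays whose plotted series averages technical/biological
    replicates before fitting.
    """
    if n_points < 5:
        raise ValueError("need at least 5 points")
    top, bottom = plateaus
    if top == bottom:
        raise ValueError("plateaus must be distinct")
    rng = np.random.default_rng(seed)
    if kind == "competition":
        lo, hi = x_range if x_range else (1.4e-3, 22.5)
        if lo <= 0 or hi <= 0:
            raise ValueError("competition concentrations must be positive")
        if midpoint <= 0:
            raise ValueError("competition midpoint must be positive")
        x = np.logspace(np.log10(lo), np.log10(hi), n_points)
        y = logistic_competition(x, top, bottom, midpoint, slope)
        kind_label = "competition"
    elif kind == "melt":
        lo, hi = x_range if x_range else (20.0, 95.0)
        x = np.linspace(lo, hi, n_points)
        y = logistic_melt(x, top, bottom, midpoint, slope)
        kind_label = "melt"
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    y = y + rng.normal(0.0, noise_sd, (n_replicates, n_points)).mean(axis=0)
    return DoseResponse(x=x, y=y, kind=kind_label)


# --------------------------------------------------------------------------
# synthetic accession stand-in: alpha1 subCD3 sequence pair
# --------------------------------------------------------------------------

SUBCD3_SUBSTITUTIONS = ["S391F", "S473A", "A497S", "R500Q", "I521L", "L578I"]
HUMAN_SUBCD3_RANGE = (382, 599)  # T382-V599, human alpha1 numbering
PIG_SUBCD3_RANGE = (380, 597)    # T380-V597, Sus scrofa numbering

def gen_subcd3_sequence_pair(seed: int = 2020
                             ) -> tuple[str, int, str, int, SubstitutionList]:
    """Synthetic stand-in for the human/pig alpha1 subCD3 sequence pair.

    Constructs a random 218-residue sequence pair (synthetic — not the real
    UniProt/PDB sequences) that reproduces the documented relationship: the
    human nucleotide-binding domain (T382-V599) differs from the pig one
    (T380-V597) at exactly six positions, the S391F, S473A, A497S, R500Q,
    I521L and L578I substitutions (positions in the human numbering frame).
    Returns ``(human_seq, 382, pig_seq, 380, substitutions)`` where applying
    the substitutions to the pig sequence (renumbered into the human frame)
    yields the human sequence.
    """
    h0, h1 = HUMAN_SUBCD3_RANGE
    length = h1 - h0 + 1
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = rng.choice(alphabet, size=length)
    seq[0], seq[-1] = "T", "V"
    subs = SubstitutionList.parse(SUBCD3_SUBSTITUTIONS)
    pig = seq.copy()
    human = seq.copy()
    for e in subs.entries:
        i = e.position - h0
        pig[i] = e.wild_type
        human[i] = e.new_residue
    return ("".join(human), h0, "".join(pig), PIG_SUBCD3_RANGE[0], subs)


# --------------------------------------------------------------------------
# file emitters
# --------------------------------------------------------------------------

def write_truth_json(truths: list[PoseTruth], path) -> str:
    with open(path, "w") as fh:
        json.dump([t.__dict__ for t in truths], fh, indent=1)
    return str(path)


def write_peak_table(table: pd.DataFrame, path) -> str:
    """TSV with the documented header (residue, assigned, dH_ppm, dN_ppm,
    intensity, noise, overlapped, proline)."""
    table.to_csv(path, sep="\t", index=False, columns=PEAK_COLUMNS)
    return str(path)


def read_peak_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ensemble(ms: ModelSet, path) -> str:
    return write_models(ms, path)
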