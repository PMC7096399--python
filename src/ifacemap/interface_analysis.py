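"""Residue-level interface statistics over trajectory frame series.

From a stack of frames this module computes ligand x receptor
contact-probability maps (fraction of frames with any heavy-atom pair inside
the cutoff), persistence-thresholded contact lists (probability strictly
above 50% by default), per-residue contributions (row/column sums of the
map), truncated Coulomb + Lennard-Jones pairwise interaction-energy maps,
salt-bridge (ion-pair) occupancies, and wild-type-vs-mutant map comparisons.

The energy terms are a plain cutoff Coulomb + LJ evaluation with a
configurable combination rule — a transparent approximation that reproduces
the structure of a force-field short-range decomposition without claiming
force-field accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import ModelSet

COULOMB_KJ_NM = 138.935  # kJ mol^-1 nm e^-2

# side-chain atoms carrying formal charge, by residue type
CHARGED_GROUPS: dict[str, tuple[int, tuple[str, ...]]] = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2", "OE3", "OE4")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NH1", "NH2", "NE")),
}


@dataclass
class ContactMap:
    ligand_residues: list[int]
    receptor_residues: list[int]
    probability: np.ndarray  # entries in [0, 1]
    n_frames_analyzed: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        if self.probability.shape != (len(self.ligand_residues),
                                      len(self.receptor_residues)):
            raise ValueError("probability matrix does not match residue lists")
        if self.probability.min() < 0 or self.probability.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probability, index=self.ligand_residues,
                            columns=self.receptor_residues)


@dataclass
class EnergyMap:
    ligand_residues: list[int]
    receptor_residues: list[int]
    mean_electrostatic: np.ndarray  # kJ/mol
    mean_vdw: np.ndarray
    n_frames_analyzed: int
    window: tuple[int, int]

    @property
    def mean_total(self) -> np.ndarray:
        return self.mean_electrostatic + self.mean_vdw


@dataclass
class NonbondedParams:
    """Per-atom charge (e), LJ sigma (nm) and epsilon (kJ/mol), keyed by
    (chain_id, residue_id, atom_name)."""

    charge: dict[tuple[str, int, str], float]
    sigma: dict[tuple[str, int, str], float]
    epsilon: dict[tuple[str, int, str], float]
    combination_rule: str = "lorentz_berthelot"  # or "geometric"
    cutoff_nm: float = 1.2

    def __post_init__(self) -> None:
        if self.combination_rule not in ("lorentz_berthelot", "geometric"):
            raise ValueError(f"unknown combination rule {self.combination_rule!r}")
        if any(e < 0 for e in self.epsilon.values()):
            raise ValueError("epsilon must be >= 0")
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("sigma must be positive")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "NonbondedParams":
        """TSV columns: chain, residue, atom, q_e, sigma_nm, epsilon_kJmol."""
        df = pd.read_csv(path, sep="\t")
        key = lambda r: (str(r["chain"]), int(r["residue"]), str(r["atom"]))
        return cls(
            charge={key(r): float(r["q_e"]) for _, r in df.iterrows()},
            sigma={key(r): float(r["sigma_nm"]) for _, r in df.iterrows()},
            epsilon={key(r): float(r["epsilon_kJmol"]) for _, r in df.iterrows()},
            **kwargs)


# --------------------------------------------------------------------------
# windows and residue bookkeeping
# --------------------------------------------------------------------------

def resolve_window(n_frames: int, window: tuple[int, int] | str | None
                   ) -> tuple[int, int]:
    """Default analysis window is the last half of the frames."""
    if window is None or window == "last-half":
        return n_frames // 2, n_frames
    if window == "all":
        return 0, n_frames
    lo, hi = window
    if not 0 <= lo < hi <= n_frames:
        raise ValueError(f"window {window} outside frame range 0..{n_frames}")
    return lo, hi


def _residue_atom_indices(frames: ModelSet, chain: str) -> dict[int, np.ndarray]:
    out: dict[int, list[int]] = {}
    for i, a in enumerate(frames.atoms):
        if a.chain_id == chain and a.element.upper() != "H":
            out.setdefault(a.residue_id, []).append(i)
    return {r: np.asarray(ix) for r, ix in out.items()}


# --------------------------------------------------------------------------
# contact maps
# --------------------------------------------------------------------------

def contact_probability_map(frames: ModelSet, cutoff: float = 6.0,
                            window: tuple[int, int] | str | None = None,
                            ligand_chain: str = "L",
                            receptor_chain: str = "R") -> ContactMap:
    """Per residue pair, the fraction of window frames in which any
    heavy-atom pair is strictly within ``cutoff`` (angstrom)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lo, hi = resolve_window(frames.n_models, window)
    if hi <= lo:
        raise ValueError("empty analysis window")
    lig = _residue_atom_indices(frames, ligand_chain)
    rec = _residue_atom_indices(frames, receptor_chain)
    lig_ids, rec_ids = sorted(lig), sorted(rec)
    counts = np.zeros((len(lig_ids), len(rec_ids)))
    for m in range(lo, hi):
        xyz = frames.coords[m]
        for i, lr in enumerate(lig_ids):
            dl = xyz[lig[lr]]
            for j, rr in enumerate(rec_ids):
                if cdist(dl, xyz[rec[rr]]).min() < cutoff:
                    counts[i, j] += 1
    return ContactMap(ligand_residues=lig_ids, receptor_residues=rec_ids,
                      probability=counts / (hi - lo),
                      n_frames_analyzed=hi - lo, window=(lo, hi))


def persistent_contacts(cmap: ContactMap, threshold: float = 0.5
                        ) -> list[tuple[int, int, float]]:
    """Pairs with probability strictly above ``threshold``, by descending
    probability (ties by residue ids)."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    out = []
    for i, lr in enumerate(cmap.ligand_residues):
        for j, rr in enumerate(cmap.receptor_residues):
            p = cmap.probability[i, j]
            if p > threshold:
                out.append((lr, rr, float(p)))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def residue_contribution(cmap: ContactMap, side: str = "ligand"
                         ) -> pd.Series:
    """Per-residue interface contribution: the sum of that residue's contact
    probabilities over all partners. Summed over either side it equals the
    total of all map entries."""
    if side == "ligand":
        vals = cmap.probability.sum(axis=1)
        return pd.Series(vals, index=cmap.ligand_residues, name="contribution")
    if side == "receptor":
        vals = cmap.probability.sum(axis=0)
        return pd.Series(vals, index=cmap.receptor_residues, name="contribution")
    raise ValueError(f"unknown side {side!r}")


# --------------------------------------------------------------------------
# interaction energies
# --------------------------------------------------------------------------

def pair_interaction_energy(frames: ModelSet, params: NonbondedParams,
                            window: tuple[int, int] | str | None = None,
                            ligand_chain: str = "L",
                            receptor_chain: str = "R") -> EnergyMap:
    """Window-mean residue-pair interaction energies (kJ/mol).

    Per frame and residue pair: electrostatic = sum over atom pairs of
    f q_i q_j / r and LJ = sum of 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6],
    both truncated at the cutoff; r in nm with f = 138.935 kJ mol^-1 nm e^-2.
    """
    lo, hi = resolve_window(frames.n_models, window)
    lig = _residue_atom_indices(frames, ligand_chain)
    rec = _residue_atom_indices(frames, receptor_chain)
    lig_ids, rec_ids = sorted(lig), sorted(rec)

    def atom_params(idx: np.ndarray):
        q = np.empty(len(idx)); s = np.empty(len(idx)); e = np.empty(len(idx))
        for k, i in enumerate(idx):
            a = frames.atoms[i]
            key = (a.chain_id, a.residue_id, a.name)
            if key not in params.charge:
                raise KeyError(f"missing nonbonded parameters for atom {key}")
            q[k], s[k], e[k] = (params.charge[key], params.sigma[key],
                                params.epsilon[key])
        return q, s, e

    lig_p = {r: atom_params(ix) for r, ix in lig.items()}
    rec_p = {r: atom_params(ix) for r, ix in rec.items()}
    elec = np.zeros((len(lig_ids), len(rec_ids)))
    vdw = np.zeros_like(elec)
    for m in range(lo, hi):
        xyz = frames.coords[m]
        for i, lr in enumerate(lig_ids):
            qi, si, ei = lig_p[lr]
            xi = xyz[lig[lr]]
            for j, rr in enumerate(rec_ids):
                qj, sj, ej = rec_p[rr]
                r_nm = cdist(xi, xyz[rec[rr]]) / 10.0
                if np.any(r_nm == 0):
                    raise ValueError(
                        f"zero interatomic distance between residues {lr} and {rr}")
                mask = r_nm < params.cutoff_nm
                if not mask.any():
                    continue
                qq = np.outer(qi, qj)[mask]
                r = r_nm[mask]
                elec[i, j] += np.sum(COULOMB_KJ_NM * qq / r)
                if params.combination_rule == "lorentz_berthelot":
                    sij = (si[:, None] + sj[None, :]) / 2.0
                else:
                    sij = np.sqrt(np.outer(si, sj))
                eij = np.sqrt(np.outer(ei, ej))[mask]
                sr6 = (sij[mask] / r) ** 6
                vdw[i, j] += np.sum(4.0 * eij * (sr6 ** 2 - sr6))
    n = hi - lo
    return EnergyMap(ligand_residues=lig_ids, receptor_residues=rec_ids,
                     mean_electrostatic=elec / n, mean_vdw=vdw / n,
                     n_frames_analyzed=n, window=(lo, hi))


# --------------------------------------------------------------------------
# ion pairs
# --------------------------------------------------------------------------

def detect_ion_pairs(frames: ModelSet, distance_cutoff: float = 4.0,
                     min_occupancy: float = 0.5,
                     window: tuple[int, int] | str | None = "all",
                     ligand_chain: str = "L", receptor_chain: str = "R",
                     groups: dict[str, tuple[int, tuple[str, ...]]] | None = None,
                     ) -> list[tuple[tuple[int, int], float]]:
    """Salt bridges across the interface: oppositely charged residue pairs
    whose minimal side-chain N-O distance is within ``distance_cutoff`` in at
    least ``min_occupancy`` of the window frames. Returns
    ``[((ligand_resid, receptor_resid), occupancy), ...]`` by descending
    occupancy."""
    groups = CHARGED_GROUPS if groups is None else groups
    lo, hi = resolve_window(frames.n_models, window)

    def charged_atoms(chain: str):
        out: dict[int, tuple[int, list[int]]] = {}
        for i, a in enumerate(frames.atoms):
            if a.chain_id != chain:
                continue
            if a.residue_name not in groups:
                continue
            sign, names = groups[a.residue_name]
            if a.name in names:
                out.setdefault(a.residue_id, (sign, []))[1].append(i)
        return {r: (sign, np.asarray(ix)) for r, (sign, ix) in out.items()}

    lig = charged_atoms(ligand_chain)
    rec = charged_atoms(receptor_chain)
    results = []
    for lr, (ls, lix) in sorted(lig.items()):
        for rr, (rs, rix) in sorted(rec.items()):
            if ls * rs >= 0:
                continue  # like charges never form a salt bridge
            formed = 0
            for m in range(lo, hi):
                xyz = frames.coords[m]
                if cdist(xyz[lix], xyz[rix]).min() < distance_cutoff:
                    formed += 1
            occ = formed / (hi - lo)
            if occ >= min_occupancy:
                results.append(((lr, rr), occ))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results


# --------------------------------------------------------------------------
# map comparison
# --------------------------------------------------------------------------

def compare_contact_maps(map_a: ContactMap, map_b: ContactMap,
                         threshold: float = 0.5) -> tuple[int, int, float]:
    """Count persistent contacts in two maps sharing axes and report the
    percent change 100 (n_a - n_b) / n_a (e.g. 10 -> 3 pairs is a 70%
    reduction)."""
    if (map_a.ligand_residues != map_b.ligand_residues
            or map_a.receptor_residues != map_b.receptor_residues):
        raise ValueError("maps do not share residue axes")
    n_a = len(persistent_contacts(map_a, threshold))
    n_b = len(persistent_contacts(map_b, threshold))
    if n_a == 0:
        raise ValueError("percent change undefined: no persistent contacts in map_a")
    return n_a, n_b, 100.0 * (n_a - n_b) / n_a


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def write_map_tsv(matrix: np.ndarray, row_ids: list[int], col_ids: list[int],
                  path) -> str:
    pd.DataFrame(matrix, index=row_ids, columns=col_ids).to_csv(path, sep="\t")
    return str(path)
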