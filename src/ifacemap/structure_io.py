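"""Multi-model coordinate I/O, superposition, RMSD and sequence bookkeeping.

Coordinates are held in angstroms throughout the package; RMSD values that feed
the clustering layer are reported in nanometres, with explicit ``*_nm`` names
wherever they cross an interface. Residues keep their author (PDB/UniProt)
numbering verbatim: FGF2 positions use 18-kDa-isoform numbering (K54, K60),
Na,K-ATPase alpha1 positions use human alpha1 numbering (T382-V599, D560).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices


class TopologyError(ValueError):
    """Models in one file do not share an identical atom sequence."""


class SubstitutionError(ValueError):
    """A substitution's wild-type letter does not match the sequence."""


# --------------------------------------------------------------------------
# atom / model containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology (coordinates live in ModelSet.coords)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_id: int


@dataclass
class ModelSet:
    """An ordered stack of models sharing one topology.

    ``atoms`` is the per-atom metadata common to every model; ``coords`` is an
    ``(n_models, n_atoms, 3)`` float array in angstroms.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms) \
                or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with "
                f"{len(self.atoms)} atoms")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, chain_id: str | None = None,
               residue_ids: Iterable[int] | None = None,
               atom_names: Iterable[str] | None = None,
               heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms matching all given filters, in file order."""
        rid = set(residue_ids) if residue_ids is not None else None
        names = set(atom_names) if atom_names is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if rid is not None and a.residue_id not in rid:
                continue
            if names is not None and a.name not in names:
                continue
            if heavy_only and a.element.upper() == "H":
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def residue_ids(self, chain_id: str) -> list[int]:
        """Distinct author residue ids of a chain, in order of appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_id, None)
        return list(seen)


def read_models(path, dialect: str = "pdb") -> ModelSet:
    """Read a (multi-model) PDB file into a ModelSet.

    The first altloc of each atom is kept; insertion codes are rejected.
    Raises TopologyError if models disagree in atom count or identity.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    st.remove_alternative_conformations()

    def model_atoms(model):
        recs, xyz = [], []
        for chain in model:
            for res in chain:
                if res.seqid.icode not in ("", " "):
                    raise ValueError(
                        f"insertion code {res.seqid.icode!r} at "
                        f"{chain.name}{res.seqid.num} is not supported")
                for at in res:
                    recs.append(AtomRecord(
                        serial=at.serial, name=at.name,
                        element=at.element.name,
                        residue_name=res.name, chain_id=chain.name,
                        residue_id=res.seqid.num))
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
        return recs, np.asarray(xyz, dtype=float)

    atoms0, xyz0 = model_atoms(st[0])
    key0 = [(a.name, a.residue_name, a.chain_id, a.residue_id) for a in atoms0]
    frames = [xyz0]
    for model in list(st)[1:]:
        recs, xyz = model_atoms(model)
        key = [(a.name, a.residue_name, a.chain_id, a.residue_id) for a in recs]
        if key != key0:
            raise TopologyError(
                f"model {len(frames)} topology differs from model 0 "
                f"({len(recs)} vs {len(atoms0)} atoms)")
        frames.append(xyz)
    return ModelSet(atoms=atoms0, coords=np.stack(frames), metadata=str(path))


def write_models(ms: ModelSet, path) -> str:
    """Write a ModelSet as a multi-model PDB with MODEL/ENDMDL framing."""
    if ms.n_models == 0:
        raise ValueError("empty model list")
    if np.abs(ms.coords).max() >= 10000:
        raise ValueError("coordinates exceed PDB fixed-width field")
    st = gemmi.Structure()
    st.name = "ifacemap"
    for m in range(ms.n_models):
        model = gemmi.Model(m + 1)
        chain = None
        res = None
        last = (None, None)
        for a, pos in zip(ms.atoms, ms.coords[m]):
            if chain is None or chain.name != a.chain_id:
                chain = gemmi.Chain(a.chain_id)
                model.add_chain(chain)
                chain = model[-1]
                last = (None, None)
            if last != (a.residue_id, a.residue_name):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_id, " ")
                res.het_flag = "A"
                chain.add_residue(res)
                res = chain[-1]
                last = (a.residue_id, a.residue_name)
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
    return str(path)


# --------------------------------------------------------------------------
# superposition and RMSD
# --------------------------------------------------------------------------

def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det +1) and the rmsd (angstrom) is the post-fit value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - cm, reference - cr
    u, s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def compute_rmsd(a: np.ndarray, b: np.ndarray, prefit: bool = False,
                 fit_a: np.ndarray | None = None,
                 fit_b: np.ndarray | None = None,
                 unit: str = "nm") -> float:
    """RMSD between two equal-length coordinate sets.

    With ``prefit`` the Kabsch transform is computed on the caller-supplied
    fit selections (``fit_a`` onto ``fit_b``; defaulting to the measured
    atoms) and applied to ``a`` before measuring — e.g. fit on the receptor,
    measure on the ligand. ``unit`` is ``"nm"`` (default, matching how
    clustering reports it) or ``"angstrom"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape} vs {b.shape}")
    if prefit:
        rot, trans, _ = superpose_kabsch(
            fit_a if fit_a is not None else a,
            fit_b if fit_b is not None else b)
        a = a @ rot.T + trans
    val = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    if unit == "nm":
        return val / 10.0
    if unit in ("angstrom", "A"):
        return val
    raise ValueError(f"unknown unit {unit!r}")


# --------------------------------------------------------------------------
# sequence bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    wild_type: str
    position: int  # author numbering
    new_residue: str


@dataclass
class SubstitutionList:
    """Point substitutions in author numbering, e.g. S391F."""

    entries: list[Substitution] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [e.position for e in self.entries]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("substitution positions must be strictly increasing")

    @classmethod
    def parse(cls, tokens: Sequence[str]) -> "SubstitutionList":
        """Build from tokens like ["S391F", "S473A"]."""
        entries = [Substitution(t[0], int(t[1:-1]), t[-1]) for t in tokens]
        return cls(sorted(entries, key=lambda e: e.position))

    def inverse(self) -> "SubstitutionList":
        return SubstitutionList(
            [Substitution(e.new_residue, e.position, e.wild_type)
             for e in self.entries])


def apply_substitutions(seq: str, offset: int, subs: SubstitutionList) -> str:
    """Apply point substitutions to ``seq`` whose first residue is ``offset``.

    Each entry's wild-type letter must match the sequence at its author
    position; the result differs from the input exactly there.
    """
    chars = list(seq)
    for e in subs.entries:
        i = e.position - offset
        if not 0 <= i < len(chars):
            raise SubstitutionError(
                f"position {e.position} outside sequence range "
                f"{offset}-{offset + len(chars) - 1}")
        if chars[i] != e.wild_type:
            raise SubstitutionError(
                f"wild-type mismatch at {e.position}: expected "
                f"{e.wild_type}, sequence has {chars[i]}")
        chars[i] = e.new_residue
    return "".join(chars)


def count_sequence_differences(seq_a: str, offset_a: int,
                               seq_b: str, offset_b: int
                               ) -> tuple[int, list[int], float]:
    """Hamming comparison of two sequences in their author frames.

    Equal-length sequences are paired column-by-column; unequal lengths fall
    back to a deterministic global alignment (BLOSUM62, gap open 10,
    extend 0.5). Returns ``(n_diff, positions_in_a_numbering, fraction)``.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if len(seq_a) == len(seq_b):
        cols = zip(seq_a, seq_b)
        aligned_len = len(seq_a)
        positions = [offset_a + i for i, (x, y) in enumerate(cols) if x != y]
        return len(positions), positions, len(positions) / aligned_len
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    n_diff, positions, ia = 0, [], 0
    for x, y in zip(a_row, b_row):
        if x != "-" and y != "-" and x != y:
            n_diff += 1
            positions.append(offset_a + ia)
        if x != "-":
            ia += 1
    return n_diff, positions, n_diff / len(a_row)


def unique_positions(alignment: dict[str, str], query: str,
                     min_absent_fraction: float,
                     query_offset: int = 1) -> list[int]:
    """Query positions whose residue is rare among the other sequences.

    ``alignment`` maps sequence id to an aligned (gapped) row of equal
    length. A query column is reported when the query's residue is absent
    from at least ``min_absent_fraction`` of the other sequences at that
    column (gaps count as absent). Positions are returned in the query's
    ungapped numbering starting at ``query_offset``.
    """
    if query not in alignment:
        raise KeyError(f"query id {query!r} not found in alignment")
    qrow = alignment[query]
    others = [row for sid, row in alignment.items() if sid != query]
    if any(len(r) != len(qrow) for r in others):
        raise ValueError("alignment rows have inconsistent lengths")
    out, qpos = [], query_offset - 1
    for col, q in enumerate(qrow):
        if q == "-":
            continue
        qpos += 1
        if not others:
            continue
        absent = sum(1 for r in others if r[col] != q)
        if absent / len(others) >= min_absent_fraction:
            out.append(qpos)
    return out


def read_fasta(path) -> dict[str, str]:
    """Read sequences (plain or aligned FASTA) keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
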