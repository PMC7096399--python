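"""Docking-pose post-processing: score retention, epitope-contact and clash
filters, rigid-body perturbation, GROMOS clustering and representative
selection.

The cascade mirrors standard rigid-body docking triage: keep the small
fraction of poses with the most favorable interface scores, keep only poses
where the planted epitope (any atom of the designated ligand residues) lies
strictly within the contact cutoff of the receptor, align each survivor onto
a reference frame through its receptor and drop poses whose ligand overlaps
the surrounding reference context, then cluster the survivors on ligand RMSD
with the GROMOS neighbor-counting algorithm and report per-cluster size,
mean pairwise RMSD (nm), center and centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ModelSet, compute_rmsd, superpose_kabsch
from .synthetic import PerturbationSpec


@dataclass(frozen=True)
class ScoredPose:
    pose_id: int
    model_index: int
    interface_score: float  # lower = more favorable by default


@dataclass
class TriageConfig:
    """Cascade parameters; defaults follow the documented filter cascade."""

    score_keep_fraction: float = 0.06
    contact_cutoff: float = 6.0          # angstrom, strict <
    epitope: tuple[int, ...] = (54, 60)  # ligand residues
    clash_cutoff: float = 2.0            # angstrom, heavy atoms
    cluster_cutoff_nm: float = 0.6
    rmsd_selection: str = "CA"           # or "heavy"
    ligand_chain: str = "L"
    receptor_chain: str = "R"
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.score_keep_fraction <= 1:
            raise ValueError("score_keep_fraction must be in (0, 1]")
        for name in ("contact_cutoff", "clash_cutoff", "cluster_cutoff_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ClusterResult:
    assignments: dict[int, int]      # pose_id -> cluster label
    centers: list[int]               # max-neighbor pose per cluster
    centroids: list[int]             # min mean-RMSD pose per cluster
    sizes: list[int]
    mean_pairwise_rmsd_nm: list[float]


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------

def filter_by_score(poses: list[ScoredPose], keep_fraction: float,
                    lower_is_better: bool = True) -> list[ScoredPose]:
    """Retain the best ceil(n * keep_fraction) poses; ties at the boundary
    score keep the lower pose_id."""
    if not poses:
        raise ValueError("empty pose list")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n_keep = int(np.ceil(len(poses) * keep_fraction))
    sign = 1.0 if lower_is_better else -1.0
    ranked = sorted(poses, key=lambda p: (sign * p.interface_score, p.pose_id))
    return ranked[:n_keep]


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(cdist(a, b).min())


def filter_by_contact(ensemble: ModelSet, poses: list[ScoredPose],
                      epitope: tuple[int, ...], cutoff: float,
                      ligand_chain: str = "L", receptor_chain: str = "R"
                      ) -> list[ScoredPose]:
    """Keep poses with any epitope atom strictly within ``cutoff`` of any
    receptor atom (boundary equality discards)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    epi_idx = ensemble.select(chain_id=ligand_chain, residue_ids=epitope)
    if len(epi_idx) == 0:
        raise ValueError(f"epitope residues {epitope} missing from chain "
                         f"{ligand_chain!r}")
    present = {ensemble.atoms[i].residue_id for i in epi_idx}
    missing = [r for r in epitope if r not in present]
    if missing:
        raise ValueError(f"epitope residues missing from ligand chain: {missing}")
    rec_idx = ensemble.select(chain_id=receptor_chain)
    kept = []
    for p in poses:
        xyz = ensemble.coords[p.model_index]
        if _min_dist(xyz[epi_idx], xyz[rec_idx]) < cutoff:
            kept.append(p)
    return kept


def filter_by_clash(ensemble: ModelSet, poses: list[ScoredPose],
                    reference_context: np.ndarray,
                    reference_fit: np.ndarray,
                    clash_cutoff: float = 2.0,
                    ligand_chain: str = "L", receptor_chain: str = "R",
                    fit_atom_names: tuple[str, ...] = ("CA",)
                    ) -> list[ScoredPose]:
    """Discard poses whose ligand overlaps the reference context.

    Each pose is superposed onto ``reference_fit`` (coordinates matching the
    pose's receptor fit atoms, in order) and discarded when any ligand heavy
    atom lies within ``clash_cutoff`` of any ``reference_context`` heavy
    atom. An empty context retains everything.
    """
    reference_context = np.asarray(reference_context, dtype=float).reshape(-1, 3)
    if len(reference_context) == 0:
        return list(poses)
    fit_idx = ensemble.select(chain_id=receptor_chain,
                              atom_names=fit_atom_names)
    reference_fit = np.asarray(reference_fit, dtype=float)
    if reference_fit.shape != (len(fit_idx), 3):
        raise ValueError(
            f"fit selection mismatch: pose has {len(fit_idx)} fit atoms, "
            f"reference has {reference_fit.shape[0]}")
    lig_idx = ensemble.select(chain_id=ligand_chain, heavy_only=True)
    kept = []
    for p in poses:
        xyz = ensemble.coords[p.model_index]
        rot, trans, _ = superpose_kabsch(xyz[fit_idx], reference_fit)
        lig = xyz[lig_idx] @ rot.T + trans
        if _min_dist(lig, reference_context) >= clash_cutoff:
            kept.append(p)
    return kept


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

def perturb_pose(ligand_xyz: np.ndarray, spec: PerturbationSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Rigid-body perturbation of a ligand: rotation about a uniform random
    axis through the ligand centroid by an angle up to ``max_rotation``
    degrees, then a translation of magnitude up to ``max_translation``
    angstrom (uniform in the ball). ``exact_magnitude`` uses the maxima as
    exact displacement/rotation magnitudes. Internal geometry is preserved.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xyz = np.asarray(ligand_xyz, dtype=float)
    center = xyz.mean(axis=0)

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    max_rad = np.deg2rad(spec.max_rotation)
    angle = max_rad if spec.exact_magnitude else rng.uniform(0.0, max_rad)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    if spec.exact_magnitude:
        radius = spec.max_translation
    else:
        radius = spec.max_translation * rng.random() ** (1.0 / 3.0)
    return (xyz - center) @ rot.T + center + radius * direction


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def ligand_rmsd_matrix(ensemble: ModelSet, poses: list[ScoredPose],
                       rmsd_selection: str = "CA",
                       ligand_chain: str = "L",
                       receptor_chain: str = "R",
                       fit_atom_names: tuple[str, ...] = ("CA",)
                       ) -> np.ndarray:
    """Pairwise ligand RMSD (nm) after superposing every model's receptor
    onto the first pose's receptor."""
    fit_idx = ensemble.select(chain_id=receptor_chain,
                              atom_names=fit_atom_names)
    if rmsd_selection == "CA":
        lig_idx = ensemble.select(chain_id=ligand_chain, atom_names=("CA",))
    elif rmsd_selection == "heavy":
        lig_idx = ensemble.select(chain_id=ligand_chain, heavy_only=True)
    else:
        raise ValueError(f"unknown rmsd selection {rmsd_selection!r}")
    ref = ensemble.coords[poses[0].model_index]
    aligned = []
    for p in poses:
        xyz = ensemble.coords[p.model_index]
        rot, trans, _ = superpose_kabsch(xyz[fit_idx], ref[fit_idx])
        aligned.append(xyz[lig_idx] @ rot.T + trans)
    n = len(poses)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = aligned[i] - aligned[j]
            mat[i, j] = mat[j, i] = np.sqrt(np.mean(np.sum(d * d, axis=1))) / 10.0
    return mat


def gromos_cluster_from_matrix(rmsd_nm: np.ndarray, pose_ids: list[int],
                               cutoff_nm: float) -> ClusterResult:
    """GROMOS neighbor-counting clustering on a precomputed RMSD matrix.

    Iteratively take the pose with the most neighbors (RMSD < cutoff) as a
    cluster center, remove it with its neighbors as one cluster, repeat.
    Neighbor-count ties break to the lower pose_id; final labels are ordered
    by decreasing size (ties again by lower center pose_id).
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    n = len(pose_ids)
    if n == 0:
        raise ValueError("empty input")
    remaining = list(range(n))
    raw: list[tuple[int, list[int]]] = []  # (center local idx, member idxs)
    while remaining:
        counts = [(-sum(1 for j in remaining
                        if j != i and rmsd_nm[i, j] < cutoff_nm),
                   pose_ids[i], i) for i in remaining]
        counts.sort()
        center = counts[0][2]
        members = [center] + [j for j in remaining
                              if j != center and rmsd_nm[center, j] < cutoff_nm]
        raw.append((center, members))
        remaining = [i for i in remaining if i not in set(members)]
    raw.sort(key=lambda cm: (-len(cm[1]), pose_ids[cm[0]]))

    assignments, centers, centroids, sizes, mean_rmsd = {}, [], [], [], []
    for label, (center, members) in enumerate(raw):
        for i in members:
            assignments[pose_ids[i]] = label
        centers.append(pose_ids[center])
        sizes.append(len(members))
        if len(members) == 1:
            centroids.append(pose_ids[members[0]])
            mean_rmsd.append(0.0)
        else:
            sub = rmsd_nm[np.ix_(members, members)]
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            order = sorted(range(len(members)),
                           key=lambda k: (mean_to_others[k], pose_ids[members[k]]))
            centroids.append(pose_ids[members[order[0]]])
            iu = np.triu_indices(len(members), k=1)
            mean_rmsd.append(float(sub[iu].mean()))
    return ClusterResult(assignments=assignments, centers=centers,
                         centroids=centroids, sizes=sizes,
                         mean_pairwise_rmsd_nm=mean_rmsd)


def cluster_gromos(ensemble: ModelSet, poses: list[ScoredPose],
                   cutoff_nm: float = 0.6, rmsd_selection: str = "CA",
                   ligand_chain: str = "L", receptor_chain: str = "R"
                   ) -> ClusterResult:
    """GROMOS clustering of poses on ligand RMSD after receptor superposition."""
    if not poses:
        raise ValueError("empty pose list")
    mat = ligand_rmsd_matrix(ensemble, poses, rmsd_selection,
                             ligand_chain, receptor_chain)
    return gromos_cluster_from_matrix(mat, [p.pose_id for p in poses], cutoff_nm)


def select_centroid(ensemble: ModelSet, member_ids: list[int],
                    poses: list[ScoredPose], rmsd_selection: str = "CA",
                    ligand_chain: str = "L", receptor_chain: str = "R") -> int:
    """Member with the smallest mean RMSD to all other members (the cluster's
    representative structure); ties break to the lower pose_id."""
    if not member_ids:
        raise ValueError("empty cluster")
    if len(member_ids) == 1:
        return member_ids[0]
    sub = [p for p in poses if p.pose_id in set(member_ids)]
    sub.sort(key=lambda p: member_ids.index(p.pose_id))
    mat = ligand_rmsd_matrix(ensemble, sub, rmsd_selection,
                             ligand_chain, receptor_chain)
    mean_to_others = mat.sum(axis=1) / (len(sub) - 1)
    order = sorted(range(len(sub)),
                   key=lambda k: (mean_to_others[k], sub[k].pose_id))
    return sub[order[0]].pose_id


# --------------------------------------------------------------------------
# cascade
# --------------------------------------------------------------------------

def run_triage(ensemble: ModelSet, poses: list[ScoredPose],
               config: TriageConfig,
               reference_context: np.ndarray | None = None,
               reference_fit: np.ndarray | None = None) -> dict:
    """Score -> contact -> clash filters followed by GROMOS clustering.

    Returns a report with per-stage retained pose ids and counts, the
    ClusterResult, and per-cluster size / mean pairwise RMSD (nm) /
    center / centroid. Deterministic for fixed inputs.
    """
    s1 = filter_by_score(poses, config.score_keep_fraction,
                         config.lower_is_better)
    s2 = filter_by_contact(ensemble, s1, config.epitope,
                           config.contact_cutoff, config.ligand_chain,
                           config.receptor_chain)
    if reference_context is not None and len(reference_context) > 0:
        s3 = filter_by_clash(ensemble, s2, reference_context,
                             reference_fit, config.clash_cutoff,
                             config.ligand_chain, config.receptor_chain)
    else:
        s3 = s2
    report = {
        "n_input": len(poses),
        "stage_counts": {"score": len(s1), "contact": len(s2), "clash": len(s3)},
        "retained_ids": {
            "score": [p.pose_id for p in s1],
            "contact": [p.pose_id for p in s2],
            "clash": [p.pose_id for p in s3]},
    }
    if s3:
        cr = cluster_gromos(ensemble, s3, config.cluster_cutoff_nm,
                            config.rmsd_selection, config.ligand_chain,
                            config.receptor_chain)
        report["clusters"] = {
            "sizes": cr.sizes,
            "centers": cr.centers,
            "centroids": cr.centroids,
            "mean_pairwise_rmsd_nm": cr.mean_pairwise_rmsd_nm,
            "assignments": {str(k): v for k, v in cr.assignments.items()},
        }
        report["cluster_result"] = cr
    else:
        report["clusters"] = None
        report["cluster_result"] = None
    return report
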