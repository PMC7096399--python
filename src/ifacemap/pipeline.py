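"""End-to-end orchestration of the synthetic interface-mapping pipeline.

A run generates synthetic inputs with planted ground truth (pose ensemble
with a K54/K60 epitope, wild-type and mutant contact trajectories, HSQC peak
tables, competition and melt curves), then pushes them through pose triage,
interface analysis, the NMR screen and the binding-assay fits, writing
per-stage artifacts and one machine-readable summary. Reruns with the same
config are bit-identical because every stage draws from seeds derived
deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import binding_quant, interface_analysis, nmr_csp, pose_triage, synthetic

log = logging.getLogger("ifacemap")

ALL_STAGES = ("synthetic", "triage", "interface", "nmr", "quant")

# planted wild-type interface: ligand residue, receptor residue, persistence
WT_CONTACT_PLAN = [
    (54, 560, 0.95), (54, 498, 0.90), (54, 524, 0.85),
    (60, 525, 0.95), (60, 529, 0.90), (60, 542, 0.80),
    (30, 498, 0.70), (74, 529, 0.70), (27, 524, 0.65), (26, 533, 0.60),
]
# D560N-like mutant: the same pair axes, 3 of 10 contacts persist
MUTANT_CONTACT_PLAN = [
    (54, 560, 0.10), (54, 498, 0.90), (54, 524, 0.25),
    (60, 525, 0.95), (60, 529, 0.90), (60, 542, 0.30),
    (30, 498, 0.25), (74, 529, 0.20), (27, 524, 0.15), (26, 533, 0.10),
]


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "ifacemap_run"
    seed: int = 0
    # synthetic pose ensemble
    n_true: int = 20
    n_decoy: int = 80
    epitope: tuple[int, ...] = (54, 60)
    # trajectories
    n_frames: int = 1000
    contact_cutoff: float = 6.0
    window: str = "last-half"
    # NMR tables (three of the six affected residues span K54-K60)
    n_residues: int = 90
    affected: tuple[int, ...] = (30, 54, 58, 60, 74, 83)
    attenuation: float = 0.3
    broadening: float = 0.9
    shift_noise: float = 0.005
    # binding quantification
    ic50_uM: float = 0.8
    tm_C: float = 52.0
    curve_noise_sd: float = 0.02
    # keep fraction matches the planted true fraction (20 of 100)
    triage: pose_triage.TriageConfig = field(
        default_factory=lambda: pose_triage.TriageConfig(
            score_keep_fraction=0.2))

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tri = raw.pop("triage", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if tri:
            cfg.triage = pose_triage.TriageConfig(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in tri.items()})
        return cfg

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("outdir")  # where results land does not change what they are
        return json.loads(json.dumps(d, sort_keys=True, default=list))

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order and return the summary
    (also written to ``<outdir>/summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages_run": []}
    log.info("run start: seed=%d config=%s", config.seed, config.config_hash())
    try:
        stages = [s for s in ALL_STAGES if s in config.stages]
        artifacts: dict = {}
        for stage in stages:
            log.info("stage %s (seed %d)", stage, _stage_seed(config.seed, stage))
            _STAGE_FUNCS[stage](config, outdir, artifacts, summary)
            summary["stages_run"].append(stage)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
        log.info("run complete")
    finally:
        log.removeHandler(handler)
        handler.close()
    return summary


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_synthetic(config: RunConfig, outdir: Path, art: dict,
                     summary: dict) -> None:
    seed = _stage_seed(config.seed, "synthetic")
    ensemble, truths = synthetic.gen_complex_poses(
        config.n_true, config.n_decoy, epitope=config.epitope,
        seed=seed, contact_cutoff=config.contact_cutoff)
    synthetic.write_ensemble(ensemble, outdir / "poses.pdb")
    synthetic.write_truth_json(truths, outdir / "pose_truth.json")

    def traj(plan_pairs, tag, offset):
        plan = synthetic.ContactPlan(pairs=list(plan_pairs),
                                     n_frames=config.n_frames)
        frames, realized = synthetic.gen_contact_trajectory(
            plan, cutoff=config.contact_cutoff, seed=seed + offset)
        return frames, realized

    art["ensemble"], art["truths"] = ensemble, truths
    art["wt_frames"], art["wt_realized"] = traj(WT_CONTACT_PLAN, "wt", 1)
    art["mut_frames"], art["mut_realized"] = traj(MUTANT_CONTACT_PLAN, "mut", 2)
    apo, holo = synthetic.gen_peak_tables(
        config.n_residues, config.affected, config.attenuation,
        shift_noise=config.shift_noise, seed=seed + 3,
        broadening=config.broadening)
    synthetic.write_peak_table(apo, outdir / "peaks_apo.tsv")
    synthetic.write_peak_table(holo, outdir / "peaks_holo.tsv")
    art["apo"], art["holo"] = apo, holo
    art["competition"] = synthetic.gen_sigmoid_curve(
        "competition", config.ic50_uM, slope=1.0, plateaus=(1.0, 0.0),
        n_points=12, noise_sd=config.curve_noise_sd, seed=seed + 4,
        n_replicates=3)  # assay points are replicate averages
    art["melt"] = synthetic.gen_sigmoid_curve(
        "melt", config.tm_C, slope=2.0, plateaus=(0.9, 0.6),
        n_points=60, noise_sd=0.003, seed=seed + 5)
    binding_quant.write_dose_response(art["competition"],
                                      outdir / "competition.csv")
    binding_quant.write_dose_response(art["melt"], outdir / "melt.csv")
    summary["synthetic"] = {
        "n_poses": ensemble.n_models,
        "n_true": int(sum(t.is_true_interface for t in truths)),
        "n_frames": config.n_frames,
        "planted_persistent_wt": sum(p > 0.5 for *_, p in WT_CONTACT_PLAN),
        "planted_persistent_mut": sum(p > 0.5 for *_, p in MUTANT_CONTACT_PLAN),
    }


def _stage_triage(config: RunConfig, outdir: Path, art: dict,
                  summary: dict) -> None:
    if "ensemble" not in art:
        raise RuntimeError("triage stage requires the synthetic stage")
    poses = [pose_triage.ScoredPose(t.pose_id, t.pose_id, t.planted_score)
             for t in art["truths"]]
    report = pose_triage.run_triage(art["ensemble"], poses, config.triage)
    truth = {t.pose_id: t.is_true_interface for t in art["truths"]}
    survivors = report["retained_ids"]["clash"]
    n_true = sum(truth.values())
    tp = sum(truth[i] for i in survivors)
    summary["triage"] = {
        "stage_counts": report["stage_counts"],
        "cluster_sizes": report["clusters"]["sizes"] if report["clusters"] else [],
        "cluster_mean_rmsd_nm": (report["clusters"]["mean_pairwise_rmsd_nm"]
                                 if report["clusters"] else []),
        "sensitivity": tp / n_true if n_true else None,
        "specificity": (1.0 - (len(survivors) - tp)
                        / max(1, len(truth) - n_true)),
    }
    with open(outdir / "triage_report.json", "w") as fh:
        rep = {k: v for k, v in report.items() if k != "cluster_result"}
        json.dump(rep, fh, indent=1, default=float)
    art["triage_report"] = report


def _stage_interface(config: RunConfig, outdir: Path, art: dict,
                     summary: dict) -> None:
    if "wt_frames" not in art:
        raise RuntimeError("interface stage requires the synthetic stage")
    maps = {}
    for tag in ("wt", "mut"):
        cmap = interface_analysis.contact_probability_map(
            art[f"{tag}_frames"], cutoff=config.contact_cutoff,
            window=config.window)
        maps[tag] = cmap
        interface_analysis.write_map_tsv(
            cmap.probability, cmap.ligand_residues, cmap.receptor_residues,
            outdir / f"contact_map_{tag}.tsv")
    contrib = interface_analysis.residue_contribution(maps["wt"], "ligand")
    top2 = list(contrib.sort_values(ascending=False).index[:2])
    n_wt, n_mut, pct = interface_analysis.compare_contact_maps(
        maps["wt"], maps["mut"])
    ion = interface_analysis.detect_ion_pairs(art["wt_frames"],
                                              window=config.window)
    summary["interface"] = {
        "top2_ligand_residues": sorted(int(r) for r in top2),
        "ligand_contributions": {int(k): float(v) for k, v in contrib.items()},
        "persistent_contacts_wt": n_wt,
        "persistent_contacts_mut": n_mut,
        "contact_reduction_percent": pct,
        "ion_pairs": [[list(pair), occ] for pair, occ in ion],
    }
    art["maps"] = maps


def _stage_nmr(config: RunConfig, outdir: Path, art: dict,
               summary: dict) -> None:
    if "apo" not in art:
        raise RuntimeError("nmr stage requires the synthetic stage")
    results, windows = nmr_csp.intensity_ratio_analysis(
        art["apo"], [art["holo"]])
    flagged = sorted(r.residue_id for r in results
                     if r.flagged_strong_reduction)
    nmr_csp.results_to_frame(results).to_csv(
        outdir / "nmr_screen.tsv", sep="\t", index=False)
    summary["nmr"] = {
        "flagged_residues": flagged,
        "flagged_windows": [list(w) for w in windows],
        "planted_affected": sorted(config.affected),
    }


def _stage_quant(config: RunConfig, outdir: Path, art: dict,
                 summary: dict) -> None:
    if "competition" not in art:
        raise RuntimeError("quant stage requires the synthetic stage")
    ic50 = binding_quant.fit_competition_ic50(art["competition"])
    melt = binding_quant.melting_midpoint(art["melt"])
    summary["quant"] = {
        "ic50_uM": ic50.midpoint,
        "apparent_kd_uM": ic50.apparent_kd,
        "ic50_stderr": ic50.midpoint_stderr,
        "tm_C": melt.midpoint,
        "planted_ic50_uM": config.ic50_uM,
        "planted_tm_C": config.tm_C,
    }
    with open(outdir / "fits.json", "w") as fh:
        json.dump({"ic50": dataclasses.asdict(ic50),
                   "melt": dataclasses.asdict(melt)}, fh, indent=1,
                  default=float)


_STAGE_FUNCS = {
    "synthetic": _stage_synthetic,
    "triage": _stage_triage,
    "interface": _stage_interface,
    "nmr": _stage_nmr,
    "quant": _stage_quant,
}
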