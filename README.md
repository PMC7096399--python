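# ifacemap

Tools for mapping a protein–protein interaction interface from four
complementary computational readouts, built around the FGF2 / Na,K-ATPase α1
nucleotide-binding-domain (subCD3) system:

- **Docking-pose triage** — filter a rigid-body docking ensemble by interface
  score, by an epitope contact rule (any atom of the candidate epitope
  residues, K54/K60 of FGF2, strictly within 6 Å of the receptor), and by
  steric overlap with the surrounding reference structure; then cluster the
  survivors with the GROMOS neighbor-counting algorithm (RMSD cutoff 0.6 nm
  on ligand coordinates after receptor superposition) and pick each cluster's
  representative (smallest mean RMSD to the other members).
- **Interface statistics over trajectory frames** — residue-pair contact
  probability maps (fraction of frames with any heavy-atom pair within the
  cutoff), persistent contacts (probability > 50%), per-residue contributions
  (Σ of a residue's contact probabilities), truncated Coulomb + Lennard-Jones
  pair interaction-energy maps, salt-bridge occupancies, and wild-type vs
  mutant (e.g. D560N) contact-site comparisons.
- **HSQC screening** — assignment transfer by mutual-nearest peak matching,
  combined chemical-shift perturbation
  Δδ(¹H,¹⁵N) = ((ΔδH)² + (0.15·ΔδN)²)^½, and an intensity-ratio screen on
  per-peak signal-to-noise (SN_holo/SN_apo) that flags residues with a strong
  ligand-induced intensity loss.
- **Binding-assay quantification** — cross-titration grid normalization and
  percent heat maps, competition IC₅₀ by four-parameter-logistic regression
  (the apparent IC₅₀ equals the dissociation constant K_D under the assay
  conditions), loading-fraction-corrected bound/total ratios, and thermal
  unfolding midpoints (Tm) from A330/A350 melt curves.

Every pipeline input can be generated synthetically with planted ground
truth (`ifacemap.synthetic`), so the whole analysis chain is testable end to
end without external data: pose ensembles with a planted epitope and score
gap, frame series with planted Bernoulli/Markov contact persistence,
two-state peak tables with a planted attenuated residue set, and noisy
logistic curves.

## Worked example

```python
from ifacemap import RunConfig, run_pipeline

cfg = RunConfig(outdir="run", seed=42)
s = run_pipeline(cfg)
print("triage stage counts :", s["triage"]["stage_counts"])
print("top-2 ligand residues by contribution:",
      s["interface"]["top2_ligand_residues"])
print("persistent contacts wt/mut:",
      s["interface"]["persistent_contacts_wt"], "/",
      s["interface"]["persistent_contacts_mut"],
      f"({s['interface']['contact_reduction_percent']:.0f}% reduction)")
print("flagged NMR residues:", s["nmr"]["flagged_residues"])
print(f"apparent KD         : {s['quant']['apparent_kd_uM']:.2f} uM (planted 0.8)")
print(f"melting midpoint    : {s['quant']['tm_C']:.2f} C (planted 52.0)")
```

prints

```
triage stage counts : {'score': 20, 'contact': 20, 'clash': 20}
top-2 ligand residues by contribution: [54, 60]
persistent contacts wt/mut: 10 / 3 (70% reduction)
flagged NMR residues: [30, 54, 58, 60, 74, 83]
apparent KD         : 0.91 uM (planted 0.8)
melting midpoint    : 51.96 C (planted 52.0)
```

The triage cascade keeps exactly the 20 poses planted at the epitope (none
of the 80 decoys survive the contact filter); the contribution ranking
recovers the planted epitope K54/K60; the wild-type map carries 10 persistent
contacts against 3 in the mutant map (a 70% loss of contact sites); the NMR
screen flags exactly the six residues whose peaks were attenuated; and the
binding fits recover the planted affinity and melting temperature within
their noise.

The same runs are available from a shell:

```sh
ifacemap run --seed 42 --outdir run          # full chain
ifacemap simulate --seed 1 --outdir fixtures # synthetic inputs only
```

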