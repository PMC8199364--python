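# helixmd

Trajectory analysis for **4-α-helical bundle proteins**: the wild-type Rop
hairpin dimer (two chains of 63 residues, each a helix–loop–helix hairpin)
and its "loopless" RM6-style tetramer (four 58-residue chains, one long helix
each). The package quantifies how such bundles respond to thermal
perturbation through the standard structural battery:

- **rmsd(t)** over Cα after Kabsch superposition, with the tail-exclusion
  conventions of bundle studies (last 7 residues per chain; plus the first 4
  for the tetramer), and the relative thermal contrast
  **%D(t) = |rmsd_T − rmsd_ref| / rmsd_ref**;
- per-residue **rmsf** with chain averaging;
- geometric **hydrogen-bond** detection (D–A ≤ 0.35 nm, H–D–A ≤ 30°) with the
  full classification: ⟨P-P⟩ inter-/intrachain, ⟨P-W⟩, ⟨W-W⟩ per water,
  intrachain bonds per residue, the α-helical **O(i)→N(i+4)** count per
  helix, and the hairpin **loop-bridge table**;
- **hydrophobic contacts**: Cβ–Cβ radial distribution functions between
  chains/chain-pairs and hydrophobic centre-of-mass distances;
- **Ramachandran** analysis: φ/ψ, region percentages, per-residue (φ,ψ) time
  maps with footprint areas, per-helix mean torsions (circular statistics);
- **helix geometry**: rise d, length L = d·n, radius r, twist θ and
  end-to-end distance Ree from a principal-axis fit;
- **block averaging** (std across block means over a trailing window) for
  every trajectory-level number.

Since MD trajectories of these systems are rarely deposited, a synthetic
generator builds ideal bundles from internal coordinates and emits noisy
trajectories with known per-residue amplitudes, providing ground truth for
every analysis. Trajectories are plain multi-model PDB files.

## Worked example

```python
from helixmd.builder import build_bundle, generate_trajectory, NoiseModel, default_sigma_profile
from helixmd.core import select_atoms
from helixmd.superpose import rmsd_series, rmsf_per_residue
from helixmd.hbonds import helix_i_to_i4

system, ann = build_bundle("wtrop_like")          # 2 chains x 63 residues
noise = NoiseModel(sigma=default_sigma_profile(ann), seed=1)
traj = generate_trajectory(system, 80, noise, dt=0.5)

sel = select_atoms(system, ann, atoms=("CA",), exclude=("tail7",))
print(rmsd_series(traj, system, sel).values[:3])
print(rmsf_per_residue(traj, sel, chain_average=True).head(3))
print(helix_i_to_i4(traj, system, ann)[("A", "HELIX1")]["block"].mean)
```

```
[0.03138331 0.03144865 0.03667388]
res_index
1    0.082233
2    0.085917
3    0.020799
Name: rmsf, dtype: float64
16.675
```

The rmsd sits near 0.032 nm (pure positional noise at the helix amplitude
0.012 nm), tail residues fluctuate ~4x more than helix residues, and
helix-1 (22 residues, 18 possible i->i+4 bonds) keeps ~16.7 of them on
average under the noise.

The same battery runs end-to-end from a YAML config:

```bash
helixmd run -c config.yaml -o out --seed 1 --stages rmsd,rmsf,hbonds,rdf,rama,helix
helixmd fixture -c config.yaml -o fixtures   # multi-model PDBs + ground truth
```

writing one CSV per table (`rmsd_summary.csv`, `pd_summary.csv`,
`hbond_census.csv`, `helix_hb.csv`, `loop_bridge.csv`, `rdf.csv`,
`rama_percent.csv`, `helix_metrics.csv`, ...) and a `manifest.json` with the
config hash and per-stage status. The numbered scripts under `analysis/`
drive the full three-tier study (noise scales 1/2/3 labelled
300K/350K/368K) for both topologies and write their tables under `results/`:

```bash
python analysis/01_build_systems.py
python analysis/02_deviation_analysis.py
...
python analysis/06_helix_geometry.py
```

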