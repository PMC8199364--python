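# Methods

`helixmd` analyses the structure and thermal response of 4-α-helical bundle
proteins — the wild-type Rop hairpin dimer (2 chains × 63 residues, two
antiparallel helices joined by a short loop) and its loopless RM6-style
tetramer (4 chains × 58 residues, one long helix each) — from trajectories
given as multi-model PDB files. Because production MD trajectories of these
systems are large and rarely deposited, the package ships a synthetic
structure/trajectory generator with known ground truth; every analysis is
validated against that ground truth or against closed-form oracles.

## Units, conventions, degenerate inputs

All internal coordinates are in nm; the only Å↔nm conversion happens at PDB
I/O. Times are in ns. Residue indexing is 1-based per chain and contiguous,
so backbone connectivity follows from residue order. Torsions use the IUPAC
sign convention, wrapped to (−180°, 180°]; a dihedral over collinear atoms is
NaN and flagged undefined rather than silently zeroed. Alternate locations
other than blank/'A' are dropped; insertion codes are rejected — the
trajectory topology must be deterministic.

## Synthetic generator

Chains are grown residue-by-residue from internal coordinates (the NeRF
construction) with bond lengths N–Cα 0.1458, Cα–C 0.1525, C–N 0.1329 nm,
angles Cα–C–N 116.2°, C–N–Cα 121.7° and ω = 180°. The N–Cα–C angle τ
defaults to 110.0°: the helix rise per residue is strongly τ-sensitive, and
110° is the value for which a chain built at the canonical helix torsions
(−57°, −47°) reproduces the textbook α-helix dimensions (rise 0.152 nm,
radius 0.227 nm, twist 100.1°/residue, 3.6 residues/turn) within ~1.5%; the
common tabulated alternative 111.2° yields a rise of 0.156 nm, ~4% high.
All geometry values are configurable. Only backbone atoms plus Cβ are built
(every analysis in scope uses backbone, Cβ or water atoms); Cβ is placed with
the L-amino-acid hand (improper N–Cα–C–Cβ ≈ −123°). Amide hydrogens are not
built — hydrogen-bond detection reconstructs them, which also exercises the
code path needed for crystal-structure input.

Bundles place chains on a square lattice (default spacing 1.2 nm, a typical
inter-helix packing distance), antiparallel alternation, each chain aligned
to its principal axis. Sequences follow an amphipathic heptad pattern with
hydrophobic a/d positions (Leu/Ala); the hairpin's 9-residue loop carries
Leu-Asp-Ala-Asp at positions 29–32, echoing the wild-type loop. The default
hairpin annotation partitions 63 residues as N-tail 1–2, helix-1 3–24, loop
25–33, helix-2 34–56, C-tail 57–63 (the region between helix-2's crystallo-
graphic end at 52 and the 7-residue tail is folded into helix-2 so labels
partition the chain); the tetramer chain is N-tail 1–4, helix 5–51, C-tail
52–58. Loop and tail torsions default to an extended (−80°, 80°) coil — the
synthetic hairpin is topological, not spatially folded back, which is
irrelevant to the analyses but means the default geometry puts the two
helices of a chain side by side only through lattice placement.

Trajectories add i.i.d. per-frame Gaussian displacements with per-residue
amplitude σᵢ (tails 0.050, loop 0.030, helices 0.012 nm by default, scaled by
a per-tier factor), optionally with a linear drift toward a target
conformation. Noise tiers are labelled "300K"/"350K"/"368K" after the
temperatures of the bundle thermal-stability studies; the labels carry no
thermodynamics — they select scale factors 1/2/3, chosen to reproduce the
qualitative ordering of fluctuations with temperature. What the generator
does NOT emulate: time-correlated dynamics, cooperative unfolding, solvent
structure (waters are placed uniformly, so protein–water coordination is
sparse), or side chains beyond Cβ. Passing tests therefore demonstrate
correctness of the measurement machinery on known ground truth, not fidelity
of any physical model of real proteins.

## Deviation metrics

rmsd(t) = √(1/N Σᵢ ‖rᵢ(t) − rᵢʳᵉᶠ‖²) over a Cα selection; the analysis
convention excludes the 7 C-tail residues of every chain, plus the first 4
residues per chain for the tetramer (its crystal structure lacks them).
Frames are superposed onto the reference by least-squares (Kabsch) fit on the
same selection before the metric is taken; the fit is an explicit flag since
the identity mean_t rmsd² = mean_i rmsf_i² holds exactly only without it.
The thermal contrast %D(tᵢ) = |rmsd_T(tᵢ) − rmsd_ref(tᵢ)| / rmsd_ref(tᵢ)
is reported per time point and time-averaged; points with zero reference
rmsd are undefined and excluded (clamping would bias the average).

rmsf_i = √(1/T Σⱼ ‖rᵢ(tⱼ) − rᵢʳᵉᶠ‖²) per Cα, with the reference either the
first frame or (default) the time mean. On generator output, where no rigid-
body motion exists, the unbiased estimator disables the superposition: the
fit against a noisy frame injects a common-mode jitter of order σ̄·√(6/3N)
which is material for the least-mobile residues. For isotropic noise,
rmsf = σ√3 (E‖ΔX‖² = 3σ²), the recovery contract the tests check to 5%.

## Hydrogen bonds

Geometric criterion: donor–acceptor distance ≤ 0.35 nm and H–donor–acceptor
angle ≤ 30° (the GROMACS convention; configurable). Donors are backbone
amide N–H and water O–H; acceptors backbone carbonyl O and water O. Missing
amide H is reconstructed 0.10 nm from N in the C(i−1)–N–Cα plane opposite
the bisector; chain-first residues and prolines are skipped. Donor–acceptor
pairs ≤ 2 covalent bonds apart (same-residue N···O, N(i+1)···O(i)) are
excluded, as any geometric criterion requires. Each donor–acceptor pair
counts at most once per frame (best hydrogen kept).

The census partitions counts exactly into protein–protein (inter-/intra-
chain), protein–water, and water–water; W-W is reported per water molecule
with each bond attributed to both partners (⟨W-W⟩/W = 2·N_WW/N_w). The
intrachain rate divides by all protein residues, with no exclusions. The
α-helical i→i+4 count admits only O(i)→N(i+4) pairs inside one annotated
helix. The loop-bridge table counts protein–protein bonds between each loop
residue (either role) and each helix; a residue bridges a chain when its mean
count to both helices of that chain exceeds 0.05 (the smallest reportable
mean at the table's precision; configurable).

## Hydrophobic contacts

g(r) between Cβ atoms of hydrophobic residues (default set Ala, Val, Leu,
Ile, Met, Phe, Trp; configurable) across chains (dimer) or chain pairs
{A,B}–{C,D} (tetramer), normalised by the ideal-gas expectation
N_A·N_B·V_shell/V with exact shell volumes, minimum-image distances for
orthorhombic boxes, default bin width 0.01–0.02 nm and r_max = min(2 nm,
half box edge). The hydrophobic-core extension is the distance between the
(geometric, since all atoms are Cβ) centres of the two sets.

## Ramachandran analysis

φ = C(i−1)–N–Cα–C, ψ = N–Cα–C–N(i+1). Region classification uses explicit
disjoint rectangles standing in for density-derived regions: ALPHA φ∈[−180,0),
ψ∈[−120,50); BETA φ∈[−180,−20), ψ∈[50,180]∪[−180,−150); LEFT_ALPHA φ∈[0,180],
ψ∈[−20,90); OTHER elsewhere. Rectangles are verified disjoint at load time
and are configurable; absolute region percentages are definition-dependent
and only their trends should be compared across conditions. Per-residue
(φ,ψ) time maps report the occupied-cell footprint on a 5°×5° grid (the
granularity of typical published maps). All torsion means are circular
(wrap-aware), mapped back to (−180°, 180°]; helix mean torsions average
spatially over the helix per frame first, then block-average over time.

## Helix geometry

The axis is the principal component of the helix's Cα cloud, oriented
N→C — adequate for short straight bundle helices and consistent with a
single-axis radius formula; a local spline axis is a possible extension, not
implemented. In the axis frame: rise d = mean |Δz| of consecutive Cα; radius
r = √(mean(x²+y²)); twist θ = |mean signed rotation about the axis between
consecutive Cα| (the rotation-per-residue reading, ~100°/residue for an ideal
helix — not the inclination of the Cα–Cα vector to the axis); length
L = d·n with n the residue count, deliberately n not n−1, so L slightly
exceeds the geometric Cα span. Ree is the distance from the first atom of
the first helix residue to the last atom of the last. A straight line of Cα
(r → 0) is rejected as degenerate since θ is undefined there.

## Block averaging

Every trajectory-level summary reports mean ± error from contiguous,
equal-duration blocks over a trailing analysis window; the error is the
population standard deviation across block means. Defaults: 5 blocks over
the trailing half of the series (the analogue of averaging "over the last
100 ns" of a 200–270 ns run); both are configurable, and n_blocks ≥ 2 is
required for an error bar. Angular series use the circular variant.

## Problem sizes

The shipped study conditions — chosen to keep any run in seconds while
leaving every statistical contract comfortably resolved — are 80 frames ×
0.5 ns per tier for the tiered studies, 2000 frames for the fluctuation-
recovery check, 150–200 point-pairs × 25–30 frames for the rdf ideal-gas
limit, and 10⁴ rotation samples × 20 instances for the superposition
brute-force comparison.

## Reference structures

The native states of the real proteins are PDB entries 1RPR (NMR; the first
model is taken as the reference conformation) and 1QX8. The pipeline can
analyse them, or any multi-model PDB trajectory over them, via the `input`
config block; they are not required by any test, and no PDB download happens
anywhere in the package.
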