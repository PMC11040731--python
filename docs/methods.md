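# Methods

This note records the models implemented in `qewald`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Units and conventions

Angstrom, kcal/mol and elementary charges throughout; time in fs,
temperature in K. The Coulomb constant is 332.0637 kcal·Å/(mol·e²) and
k_B = 1.9872041×10⁻³ kcal/(mol·K). Structures carry atomic numbers,
Cartesian coordinates, an integer total charge Q (default 0 when an
extended-XYZ frame has no `charge` key, matching data sets of neutral
closed-shell complexes), and optionally a labeled total energy.

## Short-range baseline

A continuous-filter message-passing network. Defaults: F = 64 features,
T = 3 interaction blocks, K = 32 Gaussian radial basis functions on
[0, cutoff], cutoff 5.0 Å with a cosine envelope (value 1 at d = 0,
value and slope 0 at the cutoff), shifted-softplus activation
ssp(x) = ln(½eˣ + ½) everywhere. Desk-scale experiments shrink this to
F = 16, T = 2, K = 8, cutoff 3.0 Å (`qewald.protocols`); the small cutoff
is deliberate, so that the synthetic clusters (spanning up to ~8–13 Å)
have substantial interactions outside the local model's horizon.

Two structural conventions are exact by construction rather than
approximate: the filter network's final layer and the update network
carry no bias, and ssp(0) = 0, so an atom with an empty neighborhood is
bit-exactly unchanged by an interaction block; and per-element energy
offsets are trainable and initialized by least-squares regression of the
training energies on element counts, which absorbs the large
composition-dependent part of the label so the network trains on
relative energetics only.

## Charge head and total-charge constraint

Raw charges are predicted from the *initial* nuclear embeddings x⁰ (not
the message-refined ones): the constraint machinery should see the same
per-element representation regardless of conformation, leaving
conformation dependence to the long-range geometry kernel. The
constraint is enforced by uniform redistribution of the deficit,
q_i = q̃_i + (Q − Σq̃)/N. Among the maps that guarantee ΣQ exactly, the
uniform shift is the simplest differentiable one and is exact to
floating-point roundoff (measured residuals ~1e-14 e). Alternatives
(proportional rescaling, softmax-weighted redistribution) behave badly
when Σq̃ crosses zero.

The scalar charge is lifted to F dimensions as q·u with a learned
direction u, then passed through a two-layer residual block
(c = P + MLP₂(P)); zeroing the block's parameters makes the lift exact,
which is the tested identity.

## Long-range (Fourier-space) messages

For isolated, aperiodic molecules the package defines two realizations
linked by an oracle test:

- `direct_radial` (reference semantics): m_i = Σ_j K(d_ij) ⊙ c_j with
  the band-limited kernel K(d) = Σ_m w_m sinc(k_m d), K(0) = Σ w_m.
  Depending only on distances, it is exactly rotation invariant. The
  self term is added analytically (sinc → 1) to avoid differentiating
  √· at zero.
- `plane_wave` (factorized): structure factors S_cos/S_sin per frequency
  and direction give the same quantity as a direction average at
  O(N·M·K) cost. Direction sets are inversion-symmetric: octahedron
  (M = 6), the {−1,0,1}³ shell (M = 26), antipodally symmetrized
  Fibonacci lattices otherwise. The spherical average of cos(k u·δ) is
  sinc(k|δ|), so the plane-wave kernel converges to `direct_radial` as M
  grows; the suite asserts the max error over d ∈ [0.5, 10] Å falls
  monotonically for M ∈ {6, 26, 98}.

Frequencies are k_m = m·k_c/K for m = 1..K with defaults K = 8,
k_c = 2.0 Å⁻¹ (desk scale: K = 4). The per-frequency filters w_m are
F-vectors, learned. Messages are injected once, after the last baseline
block, through a learned projection initialized to zero — so at
initialization (and whenever w_m = 0) the full model is bit-identical to
the baseline, which makes the ablation a controlled experiment.

The `ewald` variant feeds x⁰ itself to the long-range block; it can
distinguish element types at long range but is blind to Q and to the
charge bottleneck, which is exactly the contrast the ablation probes.

## Synthetic ground truth and sampling

The generator emulates labeled conformer ensembles of small
metal-centered clusters. Ground truth is Morse pair wells (geometric-mean
depths, summed radii, width 1.8 Å⁻¹, cutoff 8 Å) plus full-range Coulomb
over fixed per-element charges (Zn +0.8, O −0.4, N −0.3, C +0.05,
H +0.1, shifted uniformly so they sum to Q). Clusters have a Zn core, an
inner shell near equilibrium distances and an outer shell at 3.5–6.5 Å,
so the 1/r tail reaches well past the model cutoff. This surface is
smooth, cheap, and has a genuinely long-range component — the three
properties the experiments need — but it is *not* chemistry: no
directionality, no polarization, no charge transfer. Passing tests show
the architecture can exploit charge-aware long-range structure when it
exists; they say nothing about accuracy against quantum-chemical labels.

Sampling is Langevin dynamics (BAOAB splitting; 300 K, 0.5 fs timestep,
friction 10⁻³ fs⁻¹) on the ground truth plus the metadynamics bias
V = Σ k_i exp(−α_i Δ_i²), with Δ_i the Kabsch-aligned RMSD to each
deposited reference. The bias gradient holds the optimal rotation fixed
(valid by stationarity of the Kabsch optimum) giving
∇Δ² = (2/N)(p_c − R q_c); it matches central differences to ~1e-9
relative. With zero friction and zero bias the integrator reduces to
velocity Verlet and conserves energy to <0.01% over 1000 steps on a
dimer. Each run deposits on a fixed interval with fixed (k, α); runs
with different (k, α) are pooled per configuration, deduplicated at
0.1 Å RMSD and labeled.

Deduplication is a greedy keep-first scan: a conformer is kept iff its
RMSD to every already-kept member exceeds the cutoff. This is
deterministic and order-preserving; the final kept set is only
guaranteed separated from each survivor at its insertion time. The
superposition uses proper rotations only (SVD determinant correction) so
enantiomers are not aliased to RMSD 0, and index correspondence (no
permutation search), appropriate for conformers from dynamics.

### Double-well toy

The rare-event demonstration uses a 1-atom-mobile O···H···O system: two
frozen oxygen anchors 4.4 Å apart, a deep sharp Morse well (20 kcal/mol,
width 3 Å⁻¹, r_eq 1.6 Å) to each. The inter-basin barrier is
~9 kcal/mol (≫ k_BT, so unbiased 10⁴-step runs essentially never cross)
while escape to vacuum costs ~20 kcal/mol, leaving the bias a wide
window to drive crossings before it ejects the walker. The frozen bias
protocol (k = 0.5 kcal/mol, α = 8 Å⁻², deposit every 50 steps) was
chosen to fill the narrow basins — the two basins are only ~0.57 Å apart
in RMSD space, so wide Gaussians lift both at once and push nothing.
Under it roughly half to three quarters of seeds visit both basins
within 10⁴ steps versus none without bias.

## Training and evaluation

Adam on total-energy MSE (MAE reported), batch training with a
milestone-warmup schedule: lr starts at warmup_factor × base, ramps
linearly to base over the warmup steps, then multiplies by the decay
factor at each milestone. Full-scale defaults mirror the standard recipe
for this model family (base 5e-4, batch 64, 30k warmup at factor 0.2,
decays at 60k/90k/120k by 0.1); a plateau schedule (patience 10, factor
0.5, applied at validation checks) is available. Desk-scale runs use
2500 steps, batch 16, base 1e-3, warmup over the first fifth, decays at
60%/84% by 0.3. The best-on-validation checkpoint is returned; training
is bit-deterministic for a given seed. MSE was preferred over MAE as the
default loss for its smooth gradients; the reported metric is MAE either
way.

Evaluation follows the conformer-benchmark protocol: MAE of total
energies; Pearson r between reference and predicted relative
conformational energies (ΔE to each ensemble's reference minimum),
pooled over test ensembles with ≥2 members; and the misranking count —
per ensemble, the conformer with the lowest *reference* energy is the
most stable, and every other conformer whose *test* energy is strictly
below the test energy of that conformer counts (ties do not count;
singleton ensembles are skipped).

## Desk-scale study sizes

The frozen protocols run on one CPU in minutes: 50 configurations with
two metadynamics runs each (~550 conformers after dedup), the tiny model
above, 2500 training steps per variant, three seeds for the ablation
medians, 20 seeds per arm for the double-well fractions, 1000 random
structures (N ≤ 60, Q ∈ −2..+2) for charge conservation, 100 rigid
motions for the symmetry bound and 100 random cases for the plane-wave
oracle. The observed ablation ordering — charge-fed long-range < nuclear-
embedding long-range < baseline in median test MAE — is the qualitative
claim these sizes support.

## Known limitations

- The ground truth is a toy; absolute MAEs (kcal/mol, on ~50 kcal/mol
  label spread) are not comparable to quantum-chemistry benchmarks.
- The plane-wave mode is only approximately rotation invariant at finite
  M; `direct_radial` is the reference semantics and the default.
- No force training, no periodic boundary conditions, no explicit
  physics-based electrostatic energy terms: long range is modeled
  implicitly, by design.
- The pure-NumPy autodiff engine favors clarity over speed; it is
  adequate for desk-scale models (milliseconds per training step) but
  not a GPU replacement.
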