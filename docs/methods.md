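# Methods

## Gaussian accelerated sampling on toy potentials

The boost potential follows the standard GaMD construction. For a
boosted energy term with instantaneous value V,

    ΔV = ½ k (E − V)²  if V < E,   else 0,

with k = k₀/(V_max − V_min), 0 < k₀ ≤ 1, and the threshold constrained
to V_max ≤ E ≤ V_min + 1/k. Two threshold modes are supported:

* **lower bound** (default): E = V_max and
  k₀ = min(1, (σ₀/σ_V)·(V_max − V_min)/(V_max − V_avg));
* **upper bound**: k₀″ = (1 − σ₀/σ_V)·(V_max − V_min)/(V_avg − V_min)
  and E = V_min + 1/k when 0 < k₀″ ≤ 1, otherwise the lower-bound
  formula is used.

σ₀ is the user ceiling on the boost standard deviation that keeps
second-order reweighting accurate; the default is 6.0 kcal/mol per
boosted term. Dual boost applies independent boosts to the full
potential energy and to the dihedral-like term; the modified energy is
V* = V + ΔV_total + ΔV_dihedral and the modified force follows from the
chain rule, F* = F_full·(1 − k_P(E_P − V)) − F_dih·k_D(E_D − V_dih),
which vanishes smoothly at the thresholds.

The staged protocol mirrors production GaMD engines at toy scale:
a conventional-MD stage collects running V_max/V_min/V_avg/σ_V
statistics (Welford updates; max/min exact), an equilibration stage
applies the boost and refreshes parameters every `update_interval`
steps, and production runs under frozen final parameters with per-frame
ΔV recorded. Defaults — 10,400 cMD steps, 32,000 equilibration steps,
refresh every 400 steps — preserve the stage ratios of a typical
membrane-protein protocol (10.4 ns / 32 ns / 800 ps updates at 2 fs)
scaled to desk-size systems. Statistics are always accumulated from the
*unmodified* term energies, because E and k are functions of the
unbiased landscape. Equilibration frames, generated under non-final
parameters, are excluded from all downstream analyses; the parameter
history is persisted so this is auditable. On a flat (zero-variance)
potential the statistics are degenerate and boosting is refused with a
`NoVariabilityError` rather than silently producing k = ∞.

A 1D double well boosted on its total energy is the ground-truth
workhorse; a genuinely dual-boost exercise needs two nonzero energy
channels and uses the 2D double-well × cosine-dihedral surface. On the
1D well the dihedral term is identically zero, so dual boost is
impossible there by construction (σ_V = 0 is refused).

## Langevin integrator

Sampling uses BAOAB splitting, chosen for its small configurational
bias at moderate time steps: half-kick, half-drift,
Ornstein–Uhlenbeck velocity refresh with c₁ = exp(−γΔt), half-drift,
half-kick. Units are kcal/mol, Å, ps, amu and kelvin with
k_B = 0.0019872041 kcal/(mol·K) and 1 kcal/mol = 418.4 amu·Å²/ps².
Defaults for the double-well studies: T = 300 K, γ = 1 ps⁻¹,
Δt = 0.005 ps, m = 12 amu. At the well curvature (ω ≈ 19 ps⁻¹) this
gives ωΔt ≈ 0.09, i.e. a configurational bias orders of magnitude below
the 0.5 kcal/mol recovery tolerance. The integrator is seeded
explicitly and bit-reproducible; coordinates or energies exceeding
sanity bounds raise an integration failure naming the step.

## Reweighting

Frames are binned on an origin-aligned half-open grid (default width
1.0 Å, matching common practice for distance coordinates; the
double-well studies use 0.5 Å to resolve the barrier). Each bin's
canonical probability is p*(A_j)·⟨e^{βΔV}⟩_j, normalized over included
bins. The ensemble average is evaluated two ways:

* **cumulant expansion** (default order 2, order 1–3 available) with
  cumulants computed from the bin's own ΔV sample — local reweighting,
  matching the per-bin ensemble average; a trajectory-global cumulant
  variant exists purely as a diagnostic;
* **exact exponential average** with max-shift stabilisation, used as
  the oracle for the cumulant route.

Implementation detail: bin weights are computed as
counts·exp(log f − max log f), which keeps the zero-boost and
constant-boost identities exact bin-for-bin rather than merely close.
Bins with fewer frames than the occupancy cutoff (default 500 frames)
are reported as excluded, never interpolated — the cutoff is a validity
filter, not a smoothing rule. Degenerate bins where all ΔV coincide take
the C₂ = 0 branch exactly. Multi-replica PMFs pool frames from all
replicas before binning. The reweighting temperature is the simulation
temperature. A Gaussianity report (C₁, C₂, standardized third cumulant)
quantifies whether second-order truncation is justified and checks
σ_ΔV ≤ σ₀ when σ₀ is supplied.

For validating histogram PMFs against ground truth the package provides
a *binned* analytic reference, F_j = −k_BT·ln ∫_bin e^{−V/k_BT}: a
histogram estimates the bin-integrated Boltzmann weight, so comparing
against the potential evaluated at bin centers would conflate estimator
error with discretisation error (up to ~1 kcal/mol on steep walls at
0.5 Å bins).

## Structure analysis

Residues are addressed by Ballesteros–Weinstein labels supplied as a
JSON map next to the PDB file, since PDB files do not carry generic
GPCR numbering. Inter-selection distances use the unweighted geometric
center of the pooled backbone (Cα, C, N) atoms; with near-equal masses
this differs from a mass-weighted center by <0.2% and is held as a
documented constant choice. The TM3–TM6 coordinate defaults to
R3.50 ↔ E/A6.30 but the TM3 label is a parameter (conventions differ
between R3.50 and D3.50). "α5 hook" means the five C-terminal residues
of the mini-G chain. The D3.32–ligand coordinate is a single-atom pair
(Cγ to the ligand's amine nitrogen).

RMSF superposes each replica's frames onto an iteratively refined mean
structure over the receptor backbone (Kabsch fits, 3 iterations), takes
the per-residue Cα fluctuation (heavy-atom average for the ligand) and
averages profiles arithmetically across replicas. For isotropic
per-axis jitter σ the expected RMSF is σ√3; superposition absorbs a
small share of the jitter and adds lever-arm noise for atoms far from
the alignment centroid, so the closed form holds tightly for the
profile mean (<1%) and within a few percent per residue.

Contacts: a residue pair is in contact when any inter-group heavy-atom
pair is within the cutoff (5 Å for receptor–mG contact counting, 4 Å
for the classified interface network, both configurable); edge weights
are atom-pair counts. Interaction classes use common structural-biology
geometric criteria, configurable because published figures rarely state
them: salt bridge when an anionic side-chain oxygen (Asp/Glu or a
C-terminal carboxylate) lies within 4.0 Å of a cationic side-chain
nitrogen (Arg/Lys/protonated His); otherwise hydrogen bond when any
N/O–N/O pair is within 3.5 Å; otherwise van der Waals. The precedence
makes the classification a partition. Binding energies are consumed,
not computed: the module aggregates per-complex per-frame MM/GBSA
tables (population SD over frames) or reported means and forms all
pairwise mean differences.

## Assay analysis

Traces are divided pointwise by the mean wild-type control trace — the
time-resolved form is the default; a scalar grand-mean mode sits behind
a flag because the verbal protocol is ambiguous — then the corrected
mean L-15 (vehicle) trace is subtracted. AUC is trapezoidal over the
post-addition window on the recorded timestamps, with no resampling.
Normalization maps L-15 to 0% and the canonical system's 100 µM
response to 100%. The 4PL fit is least squares on per-concentration
replicate means with initial guesses bottom = min, Emax = max, logEC50
at the half-range crossing, Hill slope 1 bounded to [0.2, 5]; standard
errors are asymptotic from the Jacobian. A fit is reported "n.d." when
the fitted span is below 3× the residual SD or the optimizer sticks at
a bound — flat plates therefore come back not-determined rather than
with a spurious potency.

## Synthetic data: what it emulates, and what it does not

* `make_double_well` / `make_dual_term_surface` provide potentials with
  closed-form (or quadrature) PMFs; answer keys store the reference
  curve on an exactly symmetric grid.
* `synth_complex_trajectory` builds a geometric receptor–mini-G
  scaffold: helices are straight segments whose backbone triplets
  average exactly to designed centers, so planted values (19.0 Å
  TM3–TM6; 3 Å bound / 8 Å free ligand distances; α5–TM2 of 14 Å in
  the Gs-like and 8 Å in the Gi-like orientation) are reproduced to
  machine precision at zero jitter. The ligand–D3.32 distance follows a
  two-state Markov chain (default unbind/rebind probabilities 0.05/0.15
  per frame, stationary bound fraction 0.75); per-residue isotropic
  jitter plants RMSF amplitudes; seven designed side-chain pairs plant
  the interface contact network (two salt bridges, two hydrogen bonds,
  three van der Waals, one of them at 4.5 Å so 4 Å and 5 Å cutoffs
  genuinely differ). The mini-G helix sits 5.6 Å below the receptor
  floor so no backbone pair can enter a 5 Å cutoff accidentally.
  The scaffold is *not* physical: no membrane, no solvent, no energy
  realism — the analyses under test are geometric and statistical, and
  passing them says nothing about force-field accuracy on real
  receptors.
* `synth_lumi_plate` emulates substrate autooxidation as a
  multiplicative exponential drift (τ = 45 min) on
  baseline + response·activation, with saturating activation after
  agonist addition at 15 min, triplicate wells over 8 concentrations,
  wild-type and L-15 controls, and optional multiplicative Gaussian
  noise. Default planted parameters (pEC50 6.86, Emax 100%, Hill 1)
  sit in the physiological range of histamine acting on a Gs-coupled
  receptor. Real plates have well-position effects and non-Gaussian
  outliers the generator does not model.

Generators are byte-deterministic in (parameters, seed) and every
downstream test consumes only the spec and the answer key.

## Problem sizes and numerical choices

Ground-truth PMF recovery uses three replicas of 5×10⁵ production steps
(plus 10,400 cMD and 32,000 equilibration steps each) on the 5 kcal/mol
double well at 300 K, pooled before binning at 0.5 Å with the 500-frame
cutoff — enough sampling that the maximum deviation from the binned
analytic reference is ≈0.1 kcal/mol, comfortably inside the 0.5
kcal/mol validation band, while the unreweighted modified-ensemble
profile underestimates the barrier by >2 kcal/mol. Noise studies use
100 seeds. The threshold-bound check E ≤ V_min + 1/k is asserted with
1e-12 relative slack: k is stored as k₀/(V_max − V_min), and the
reciprocal round-trip can violate exact float equality by one ulp even
though the bound holds in real arithmetic.

## Known limitations

* The integrator is serial and pure Python — adequate for 1–2 degrees
  of freedom, not a molecular engine.
* Only histogram PMF estimators are provided (no WHAM/MBAR, no kernel
  densities); 2D PMFs marginalize by probability summation.
* Interaction classification is geometric only; no angular hydrogen-
  bond criteria.
* MM/GBSA energies and conformational cluster membership are inputs;
  the package only aggregates them.
* The representative-conformation selector for network extraction
  (frame nearest the PMF global-minimum bin) is one defensible choice
  among several; published analyses rarely state theirs.
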