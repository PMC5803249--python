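# Methods

## Model overview

`torsionnet` treats a molecule as rigid fragments connected by rotatable
bonds, so a conformation is fully described by its vector of n_d dihedral
angles α ∈ [0, 360)^{n_d}. Three energy models over that space are
implemented:

1. **Uncorrelated force field** — a sum of independent one-angle terms,
   either the standard four-term Fourier series
   E(φ) = Σ_m V_m/2 (1 + s_m cos(mφ − φ_m)) with alternating signs
   s = (+, −, +, −), or tabulated profiles with periodic interpolation.
   Parameterized by 1-D scans (n_s points per dihedral, all others held at
   a reference configuration: exactly n_s·n_d oracle calls).
2. **Correlated network ensemble** — five feed-forward networks with
   logistic hidden units h(x) = 1/(1+e^{−x}) and a linear output, averaged
   arithmetically. Hidden-layer sizes: (30,10), (100,10), (110,7),
   (60,30,10), (50,20,8). The classifier twin uses (30), (40), (50), (5,5),
   (10,3) with a logistic output.
3. **Synthetic correlated PES** — the ground-truth stand-in for an external
   quantum-chemistry oracle (see below).

## Feature encoding

Per dihedral, the network input is the raw angle (degrees) followed by
(sin kα, cos kα) for k ∈ {0.5} ∪ {1, …, 10} — 23 features per dihedral.
The half-integer periodicity is not 360°-periodic; it is made well defined
by always encoding the canonical representative in [0, 360). Consequently
α → 0⁺ and α → 360⁻ agree on every integer-k feature but flip the sign of
the k = 0.5 cosine; downstream networks see this as an ordinary feature and
the convention is serialized with every trained model. Raw angles are fed
in degrees; feature standardization (below) removes the scale.

## Training protocol

Indices are shuffled once per run and split 72% / 13% / 15%
(train/validation/test), validation and test sizes floor-rounded with the
remainder going to training (150 000 → 108 000 / 19 500 / 22 500). All five
members share the split; they differ by architecture and initialization
seed (base_seed + member index). Features and targets are standardized with
training-split statistics only — logistic units saturate on degree-scaled
inputs otherwise. Each member is fit with Adam (learning rate 10⁻³,
β₁ = 0.9, β₂ = 0.999), minibatch 200, L2 penalty 10⁻⁴, and early stopping
with patience 10 epochs at relative tolerance 10⁻⁴, retaining the
best-validation-epoch weights. Optimizer, batch size, split fractions and
the architectures are fixed by the protocol; the remaining hyperparameter
defaults are this package's own choices and are exposed in
`TrainingConfig`.

Fitting is delegated to scikit-learn's `MLPRegressor`/`MLPClassifier`; the
weights are then extracted into plain arrays and **prediction always runs
through this package's own explicit matrix-vector forward pass**, so a
saved model is a self-contained JSON archive (weights, scalers, encoding,
metadata) with no pickle dependency. scikit-learn's early stopping holds
out a fraction of the data passed to `fit`; we pass train ∪ validation with
`validation_fraction = 13/85`, which reproduces the 72/13 proportions but
cedes index-level control of the validation set to scikit-learn. For a
constant-target dataset (allowed only behind an explicit flag) early
stopping is disabled, because the validation R² score is undefined there.

The classifier labels a conformation "low" (the positive class) when its
energy is below the threshold (default 46 kcal/mol = 2 eV). Each member
votes with a 0.5 cutoff on its logistic output before averaging, so
ensemble probabilities lie exactly on {0, 0.2, 0.4, 0.6, 0.8, 1.0} and the
five voters can never tie. Positive-is-low matches the gating application:
the class we must not miss is the low-energy one.

## Scan parameterization details

Per-dihedral scan profiles have their own minimum subtracted before fitting
— any per-term constant is degenerate with the model's single global
offset, which is finally set so the model's minimum over the scan grid is
zero. The Fourier fit is linear least squares over {1, cos mφ, sin mφ}
(m = 1..4), re-expressed to (V_m, φ_m) form; a vanishing amplitude leaves
its phase at 0. When no reference configuration is given, a coarse
sequential pre-scan (12 points per dihedral, taking the running argmin)
chooses one at the cost of 12·n_d extra oracle calls; with an explicit
reference the call count is exactly n_s·n_d.

Tabulated profiles are interpolated with a periodic cubic spline by
default. Linear interpolation (`kind="linear"`) is available, but on a 5°
grid it leaves ~10⁻² kcal/mol residuals for kcal/mol-scale barriers, which
would mask the separable-regime agreement the benchmark is designed to
show; the spline reduces the interpolation residual to ~10⁻⁴ so that any
remaining error is attributable to missing correlation terms.

## Synthetic PES and what it does (not) emulate

The synthetic surface is E(α) = Σ_d Fourier_d(α_d) + Σ_{(i,j)} c_ij
cos(m_i α_i − ψ_i) cos(m_j α_j − ψ_j) + offset. Per-dihedral amplitudes
decay as 1/m² with random scale ~`amplitude_scale` (default 1 kcal/mol,
the order of a conjugated-biaryl torsion barrier); coupling coefficients
have magnitude ~`coupling_strength` with random signs, phases and small
integer orders. Coupling graph presets: `hub` (all pairs through dihedral
0 plus an adjacent ring — the branched, correlation-dominated topology)
and `chain` (adjacent pairs only). With coupling 0 the surface is exactly
separable by construction. The offset is calibrated so the minimum is ≈ 0:
10⁴ uniform random samples followed by Nelder-Mead refinement from the
best eight, leaving the minimum within ~10⁻⁶ of zero rather than at the
~10⁻² sampling error.

The `strained_branched_pes` preset (amplitude scale 7, coupling strength
5 kcal/mol, hub graph, 5 torsions) emulates the energy landscape of a
bulky branched aromatic: conformer energies span roughly 0–80 kcal/mol,
with ~three quarters of random conformers below the 46 kcal/mol (2 eV)
classification threshold — the class balance reported for such systems —
and a few percent below 23 kcal/mol (1 eV). The scales were fixed once
from that class-balance requirement by sampling energy distributions
before any model training.

What the synthetic surface does **not** capture: real electronic-structure
energies (no quantum-chemical realism is attempted), hard steric walls
(couplings are smooth bounded cosines, with clash rejection handled
geometrically and separately), bond-length/angle relaxation, and
higher-than-pairwise correlations. Passing benchmarks on it therefore
demonstrate that the estimator recovers smooth pairwise-correlated
surfaces from random samples — not that it reproduces any particular
molecule's quantum-chemistry energies, which requires plugging a real
oracle into the file-exchange seam.

Dataset generation samples angles i.i.d. uniform on [0, 360); with clash
filtering enabled, conformers with any eligible atom pair below the
threshold (default 2.1 Å) are rejected and replaced by fresh draws
(uniform-proposal rejection, so the retained sample is uniform on the
clash-free region), aborting if the rejection rate exceeds 99.9% over a
2000-proposal window.

## Geometry conventions

Torsions follow the IUPAC convention (atan2 of cross products, mapped to
[0, 360) — the canonical range the k = 0.5 features require). Setting a
torsion applies a Rodrigues rotation about the j→k bond axis to the moving
set (the connected component of k once the j–k bond is removed, minus k),
leaving all intra-fragment distances bitwise-stable to ~10⁻⁹ Å. Rotatable
bonds must be bridges of the bond graph (no torsions on rings).

"Non-bonded" for the clash test is defined as: different rigid fragments
AND at least 4 bonds apart in the bond graph. Intra-fragment and
1-2/1-3/1-4 distances are fixed or governed directly by a single torsion,
so flagging them would veto legitimate rotations. A single distance
threshold is used for all elements; element-specific radii are out of
scope. Fixture molecules (rhombus-fragment chains and hub-branched stars)
have invented geometries — they exercise the rotation/clash machinery and
make the branched-coupling topology concrete, nothing more.

## Monte Carlo sampler

Single-molecule, single-temperature Metropolis: each step perturbs one
uniformly chosen dihedral by a uniform offset within ±proposal_width
(default 30°) and accepts with min(1, e^{−ΔE/k_BT}),
k_B = 0.0019872041 kcal/(mol·K). Detailed balance holds for the ungated
chain; with a classifier gate, proposals voted high-energy are rejected
before the energy model is called, so the gated chain targets the model's
Boltzmann distribution restricted to the gate's low region (gate-skips plus
energy-model calls always equal the proposal count). Annealing schedules
and intermolecular terms are out of scope: the sampler demonstrates the
energy models' intended use, it is not a morphology engine.

## Verification sizes and numerical choices

The test suite and the acceptance script size their computations for a
single-CPU desk run: the coupled benchmark uses 20 000 conformers of a
5-torsion surface (training ≈ 1.5 min), unit-scale checks use 5 000
conformers of 3-torsion surfaces, the Boltzmann validation uses a 10⁶-step
single-torsion chain thinned by 10 (72 bins, chi-square at the 1% level,
with a wide ±180° proposal so the thinned samples are nearly independent),
and the acceptance-rate check uses 10⁵ fixed-ΔE trials compared with e⁻¹
to within three binomial standard errors. Statistical assertions are run
at committed seeds. Pilot-derived regression bounds are frozen in the
tests: e.g. the small 5 000-sample classifier check asserts ≥ 0.75
test accuracy (measured 0.78 at its seed; the 20 000-sample benchmark
reaches ≈ 0.93, asserted ≥ 0.9 in the acceptance suite).

Degenerate inputs are handled explicitly rather than silently: undefined
torsions (collinear atoms) raise; Pearson r on a zero-variance series is
reported as undefined, as are confusion metrics with zero denominators;
single-class classification datasets abort with their class counts;
non-finite proposal energies are rejected moves, and non-finite training
losses abort naming the member. Energies are kcal/mol throughout, with
meV (1 eV = 23.0605 kcal/mol) computed only at reporting boundaries.
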