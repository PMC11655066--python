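# Methods

`idpdissect` implements an integrated analysis chain for dissecting the
conformational ensemble of an intrinsically disordered protein (IDP) with
and without a bound small molecule: a β-weighted variational autoencoder
(β-VAE) over inter-residue distances, a Markov state model (MSM) on the
learned latent space, contact-map fingerprinting with a denoising
convolutional VAE (DCVAE), torsion-angle conformational entropy with a
maximum-information-spanning-tree (MIST) correction, and two-phase
thermodynamics (2PT) water entropy. A ground-truth-labelled synthetic
ensemble generator makes every stage testable at desk scale.

## Synthetic ensemble generator

The generator emulates the statistical structure the downstream analysis
assumes, not force-field physics:

* **Conformations.** K macrostates, each a self-avoiding random Cα chain
  template (virtual bond 0.38 nm — the trans-peptide Cα–Cα convention —
  with a 0.4 nm hard core, rejection-sampled with a bounded retry budget).
  Templates are accepted only if every pairwise 8 Å contact-map Hamming
  fraction is ≥ 0.10, which is the separability floor the latent-space
  analyses rely on. Frames are template coordinates plus isotropic
  Gaussian jitter (default 0.05 nm — well below the 0.38 nm template
  geometry, so states stay distinguishable while microstate structure is
  non-trivial).
* **Kinetics.** An explicit first-order Markov chain over the K states,
  one step per saved frame; time is therefore counted in frames and
  attaches to physical units only when a trajectory carries a frame
  interval. The benchmark chain is Metropolis-type over target weights
  (top state ≈ 2× the rest) with per-state escape rates coupled to each
  state's torsion concentration κ: more ordered states (higher κ, lower
  conformational entropy) escape toward the top state faster, so the MFPT
  to the top state increases with state entropy. This builds the
  entropy/transition-time correlation into the ground truth so the
  analysis chain can be checked for recovering it.
* **Ligand contacts.** Per-state, per-residue Bernoulli hotspot profiles.
* **Velocities.** Harmonic traces v(t) = A cos(2πνt + φ) with amplitude
  fixed by equipartition and uniform random phase, giving an analytic
  single-line density of states; Nyquist violations are rejected.
* **Torsions.** Uniform, von Mises(κ) (analytic differential entropy
  H = ln(2π I₀(κ)) − κ I₁(κ)/I₀(κ)), or a Gaussian-copula correlated pair
  for mutual-information tests. Benchmark ensembles attach a per-frame
  torsion vector drawn von Mises with the current state's κ.

What the generator deliberately does **not** emulate: continuous
intra-state diffusion, non-Markovian dwell-time distributions (except in
the constructed Chapman–Kolmogorov counterexample), solvent degrees of
freedom, and real side-chain chemistry. Tests passing on this generator
therefore demonstrate that the estimators recover a known
discrete-kinetics ground truth, not that real MD data satisfies the
estimators' assumptions.

## Featurization

Distance features are Cα–Cα Euclidean distances for all residue pairs
(i, j) with j − i ≥ 3 (the short-range pairs carry almost no
conformational information), ordered lexicographically; a 140-residue
chain yields C(140,2) − 277 = 9453 features. Intra-chain contacts use a
strict 8 Å Cα cutoff averaged over frames (diagonal fixed at 1 by
convention); ligand contacts use a strict 0.6 nm minimum distance between
any ligand *heavy* atom and the residue's atoms (all residue atoms by
default; a heavy-atoms-only protein side is a flag, since Cα-only would
undercount side-chain contacts). Min–max scaling maps each feature to
[0, 1] with the (min, max) recorded for exact inversion; constant features
map to 0. Radius of gyration is uniform-weight in Cα-only synthetic mode
and mass-weighted with a full topology. Coordinates are assumed
pre-wrapped/whole; no minimum-image handling is applied.

## β-VAE

A symmetric dense VAE with tanh hidden layers, Glorot-uniform
initialisation, sigmoid output, diagonal-Gaussian posterior and standard
normal prior. Loss = MSE reconstruction + β·KL with
KL = ½ Σ (σ² + μ² − 1 − ln σ²); sampling uses z = μ + σ⊙ε. The reference
architecture is [9453, 4096, 512, 128, 16] → 2 latent, lr 1e-4, 300
epochs, batch 64, 80/20 split, β default 1e-12 (selected in a log-grid
scan over [5, 1e-15] by minimum test-set reconstruction RMSE). MSE was
chosen as the reconstruction form because model selection is by RMSE;
binary cross-entropy is exposed nowhere since distances are not Bernoulli.
Downstream projection uses the posterior mean μ, for reproducibility;
sampled z is retained as an option. Scaling statistics come from the
training split only. Networks are implemented on an in-repo numpy core
(dense/conv layers, Adam, manual backprop) that is gradient-checked by
finite differences in the test suite; training is bit-reproducible under a
seed. For small synthetic feature counts the hidden stack shrinks to the
reference widths that fit under the input dimension (e.g. [P, 32, 16]).

The free-energy landscape is the latent 2-D histogram mapped through
−kBT ln(p/p_max), empty bins masked, minimum exactly 0.

## Markov state model

k-means (k-means++ seeding, seeded, duplicate guard) discretises the
latent space; transitions are counted sliding-window within each
trajectory (never across boundaries); the largest strongly connected set
is retained (discarded frame fraction logged); detailed balance is
enforced by the standard self-consistent reversible maximum-likelihood
iteration (required for the real spectrum PCCA+ needs). Implied
timescales are t_i = −τ/ln λ_i with complex or out-of-range eigenvalues
flagged unresolved. The "levels off" lag rule is made quantitative: the
smallest lag whose slowest timescale changes < 10 % over a lag doubling.
The macrostate count is the largest gap ratio t_i/t_{i+1} among resolved
processes (K−1 slow processes ⇒ K states). VAMP-2 is the sum of squared
singular values of the half-weighted Koopman operator on indicator
features (≥ 1; → n for an n-block metastable chain). PCCA+ uses the
inner-simplex algorithm on the dominant right eigenvectors
(π-orthonormal, symmetrised solve), memberships clipped and
row-normalised. The Chapman–Kolmogorov test compares macrostate
self-transition probabilities of T(τ)^m against re-estimated T(mτ),
projected with stationary-weighted memberships. MFPTs solve the linear
first-passage system (h = 1 + Th off-target, h = 0 on target) with
π-weighted source averaging, scaled by the lag.

**Bootstrap.** Ten iterations, each rebuilding the model after removing
one randomly chosen trajectory, with macrostates aligned across iterations
by maximum stationary-weighted overlap (Hungarian assignment). Delete-one
replicates share ~90 % of their data, so their raw spread understates the
sampling error; the jackknife standard error (raw std × √(n_traj − 1)) is
reported alongside and used for ground-truth recovery z-scores.

## DCVAE contact-map fingerprint

Per-macrostate contact maps get 200 noisy replicas each (noise =
0.035 × N(0,1) per pixel, then per-replica min–max rescale to [0, 1]); the
DCVAE is trained to reconstruct the *clean* map from the noisy replica
(this is what prevents the identity-function overfitting a plain
convolutional VAE exhibits on so few distinct inputs). Reference
architecture: five 3×3 conv layers with filters (16, 32, 64, 96, 128) and
strides (1, 2, 2, 2, 2) — a published six-entry stride list is one entry
longer than the layer list; the trailing entry is taken as the
flatten/dense transition — then dense (4096, 2048, 1024, 256, 64, 16) → 2
latent, mirrored decoder, lr 5e-4, batch 32, 90/10 split, β = 1e-12.
Small maps use a scaled stack ((8, 16, 16) filters, (128, 32) dense).
Fidelity is scored with **global single-window SSIM** (luminance ×
contrast × structure with k1 = 0.01, k2 = 0.03, C3 = C2/2, exponents 1;
one scalar per map pair — a windowed mean variant exists behind a flag)
and **PSNR** = 10 log₁₀(R²/MSE) with R = 255 (maps rescaled to 8-bit range
for PSNR only; the MSE uses squared differences — a sign-free "MSE" is not
defined — and identical maps report an `inf` sentinel).

## Torsion entropy (nearest-neighbor + MIST)

Marginal and pairwise torsion entropies use the Kozachenko–Leonenko
k-nearest-neighbor estimator (k = 3 by default; bias is checked against
analytic von Mises cases in the tests) with wrapped circular distances:
Chebyshev (ℓ∞) metric on the torus via a periodic KD-tree, ball volume
(2ε)^d, H = ψ(n) − ψ(k) + d ln 2 + d⟨ln ε⟩. Entropies are reported
relative to a fully flexible chain (subtract ln 2π per torsion), so values
are ≤ 0 up to estimator noise, in J mol⁻¹ K⁻¹ (R × nats; nats retained).
The order-2 MIST total subtracts pairwise mutual informations
(MI = H_i + H_j − H_ij, clipped at 0) along the maximum spanning tree of
the MI graph, so S₂ ≤ S₁ always. Backbone (φ/ψ) and side-chain (χ) totals
restrict the torsion set; per-residue values take each residue's own
marginal terms with tree-edge MI assigned to the pair's lower residue
index (the attribution rule is a convention; no canonical choice exists).
Exact duplicate torsions have divergent continuous joint entropy; the
estimator returns a large finite MI for them, so adding a copy never
raises the total and the copy pair carries the maximum-MI edge — this is
the meaningful cancellation property, and the one the tests assert. A
jitter guard (with warning) keeps log-distances finite on duplicate-heavy
samples. Totals are *not* expected to match any particular published
magnitude for a real protein: the normalisation of such numbers is
underdetermined, so raw totals and per-torsion values are both available.

## 2PT water entropy

The density of states I(ν) is the mass-weighted one-sided power spectral
density of atomic velocities divided by kBT (the Wiener–Khinchin
equivalent of Fourier-transforming the velocity autocorrelation). All
bins, including DC, carry the doubled one-sided density, so
I(0) = 4mD/kBT per degree of freedom in the diffusive limit, and the
trapezoid rule's endpoint half-weights make ∫I dν count degrees of freedom
exactly (Parseval). For rigid multi-site molecules the translational
component uses centre-of-mass velocities (weight: molecular mass) and the
rotational component uses angular velocities about instantaneous principal
axes (weight: principal moments; axis sign continuity enforced along the
trajectory); the vibrational component is identically zero for rigid
models and reported as the clipped remainder, with a warning, if
intramolecular bonds fluctuate.

The fluidicity f solves the standard 2PT universal equation
2Δ^{-9/2}f^{15/2} − 6Δ^{-3}f^5 − Δ^{-3/2}f^{7/2} + 6Δ^{-3/2}f^{5/2} + 2f − 2 = 0
in the dimensionless diffusivity
Δ = (2 s₀ / 9N) √(πkBT/m) ρ^{1/3} (6/π)^{2/3}, where s₀ = I(0); a root
always exists in (0, 1) since g(0) = −2 and g(1) > 0, and f below 1e-10 is
snapped to the pure-solid limit. The gas-like DoS is the hard-sphere
memory-function form s₀ / (1 + (π s₀ ν / 6fN)²), which integrates exactly
to 3Nf; the solid part is the clipped remainder. Entropy integrates
I_s against the quantum harmonic-oscillator weight
W^s = βhν/(e^{βhν} − 1) − ln(1 − e^{−βhν}) (log-divergent at ν → 0, which
is integrable only when I_s(0) → 0 — a finite solid DoS at zero frequency
raises, signalling a bad partition) and I_g against constant weights
S_HS/3kB (Enskog hard sphere: ideal gas + Carnahan–Starling excess at
packing fraction y = f^{5/2}Δ^{-3/2}) and S_RR/3kB (classical rigid rotor,
symmetry number 2 for water, configurable). These gas-reference forms
follow the established 2PT literature; units are amu, nm, ps, K
internally, J mol⁻¹ K⁻¹ in reports. The machinery is validated on
analytic traces (harmonic lines reproduce the quantum HO entropy; the
Green–Kubo diffusion constant fixes I(0)); reproducing an absolute bulk
water number would require external MD with fast velocity output and is
out of scope.

## Benchmark study conditions (desk scale)

Fixed conditions: K = 3 ("apo-like") vs K = 6 ("ligand-like"), 20
residues, 100 000 frames per condition split into 10 independent
trajectories, jitter 0.05 nm, base escape rate 0.01/frame, 200 replicas
and noise factor 0.035 for the fingerprint stage, 10 bootstrap
iterations. Desk-scale choices (sized so the full chain runs comfortably
on one CPU): β-VAE trained on a 4000-frame subsample for 60 epochs at lr
1e-3 with the auto-scaled architecture and used to encode all frames;
k = 40 microstates; lag grid 1–64 frames; DCVAE 150 epochs at lr 1e-3
with the scaled conv stack; entropy estimated on at most 15 000 frames
per macrostate with 8 torsions. The per-frame Markov construction makes
the synthetic ITS flat from lag 1, so the lag-selection rule picks lag 1
there — on real data the same rule lands on the knee of the ITS curve.

## Numerical conventions and degenerate inputs

Contact cutoffs use strict `<`. Residue indexing is 1-based everywhere.
Constant features scale to 0 with the degenerate range recorded. k-means
reduces k to the number of distinct points. Transition estimation errors
out on an empty connected set or zero transition pairs; unreachable MFPT
targets report `inf`; identical bootstrap trajectories give exactly zero
spread. Eigenvalue ties and signs in PCCA+ are fixed by the symmetrised
solve and a sign convention on the constant eigenvector. All randomness
flows through explicit seeds; every generator, trainer and stage is
bit-reproducible given (config, seed).

## Known limitations

* Latent separability (and hence clean state recovery) needs the
  inter-template contact divergence and jitter regime above; heavily
  overlapping states would need more latent dimensions, as would real
  IDP data.
* The MSM stage assumes the generator's per-frame Markov kinetics;
  semi-Markov dynamics are detected by the CK test but not modelled.
* MIST order is 2; higher-order mutual-information terms are not
  implemented.
* The 2PT gas references (hard sphere, rigid rotor) are classical; the
  vibrational channel is only meaningful for flexible models, which the
  rigid-water path treats as a flagged remainder.
* The DCVAE ingests numeric matrices only; there is no image-file path.
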