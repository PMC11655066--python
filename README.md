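# idpdissect

Dissecting the conformational ensemble of an intrinsically disordered
protein (IDP), with and without a bound small molecule, from molecular
dynamics trajectories — for computational biophysicists who want a
states-and-rates plus thermodynamics view of a fuzzy ensemble.

IDPs such as α-synuclein have no single folded structure: they live as an
ensemble of interconverting conformations, and a small molecule can
reshape that ensemble without producing any obvious structural signature.
`idpdissect` makes the reshaping measurable:

1. **Featurization** — exclusion-filtered Cα–Cα distances d(i,j), j ≥ i+3
   (a 140-residue chain gives 9453 features), intra-chain contact maps
   (8 Å Cα rule), ligand-contact profiles (0.6 nm heavy-atom rule).
2. **β-VAE** — a variational autoencoder with loss
   `L = MSE(x, x̂) + β · KL(q(z|x) ‖ N(0, I))`, β ≈ 1e-12, compressing the
   distance features into a 2-D probabilistic latent space
   (z = μ + σ⊙ε), plus free-energy landscapes −kBT ln(p/p_max).
3. **Markov state model** — k-means microstates on the latent space,
   reversible maximum-likelihood transition matrix T(τ), implied
   timescales t_i = −τ/ln λ_i(τ) with automatic lag and state-count
   selection, PCCA+ macrostates, Chapman–Kolmogorov validation,
   leave-one-out bootstrap, and mean first passage times from the linear
   first-passage system.
4. **DCVAE fingerprinting** — a denoising convolutional VAE embeds each
   macrostate's contact map in 2-D; fidelity is scored with SSIM
   (luminance·contrast·structure, k1=0.01, k2=0.03, C3=C2/2) and
   PSNR = 10 log₁₀(R²/MSE), R = 255.
5. **Entropy** — torsion conformational entropy relative to a fully
   flexible chain via nearest-neighbor estimation on the torus with a
   maximum-information-spanning-tree (MIST) pairwise correction
   (S₂ = Σᵢhᵢ − Σ_tree MI), split into backbone/side-chain and
   per-residue terms; and 2PT water entropy from the velocity density of
   states split into solid-like (quantum harmonic weight) and gas-like
   (hard-sphere / rigid-rotor weight) parts through the fluidicity.

A ground-truth-labelled synthetic ensemble generator (discrete Markov
kinetics over self-avoiding Cα chain templates, Bernoulli ligand
hotspots, harmonic velocity traces, von Mises torsions) makes the whole
chain testable without external trajectory data; real trajectories
(PDB topology + XTC/DCD frames) enter through the same interfaces.

See `docs/methods.md` for the models, assumptions, parameter defaults and
limitations.

## Worked example

The built-in benchmark generates an "apo-like" 3-state and a
"ligand-like" 6-state synthetic ensemble (100 000 frames each, 10
trajectories, known kinetics and per-state torsion concentration) and
runs the full chain on both:

```bash
idpdissect benchmark --seed 1 --out benchmark_report.json
```

prints (abridged):

```
apo: 3 macrostates, populations ['0.174', '0.205', '0.622'], entropy/MFPT rho=1.00
ligand: 6 macrostates, populations ['0.121', '0.124', '0.124', '0.131', '0.136', '0.364'], entropy/MFPT rho=1.00
```

Reading the apo line: the implied-timescale gap criterion recovered the 3
planted states; the bootstrap-mean populations (0.174, 0.205, 0.622)
match the generator's exact stationary vector (0.169, 0.201, 0.630)
within the jackknife standard errors; and the per-state torsion entropies
(−48.9, −27.2, −4.7 J mol⁻¹ K⁻¹ relative to a fully flexible chain) rise
with the MFPT to the top state with Spearman ρ = 1.0 — the more ordered a
state, the faster it drains into the dominant one, exactly as
constructed. The JSON report adds the MFPT matrices, SSIM/PSNR tables
(denoised replicas beat noisy ones, mean SSIM gain ≈ +0.02) and the DCVAE
latent silhouette (≈ 0.999: each state's replica cloud occupies its own
territory).

The same stages run individually on a persistent run directory with
manifests:

```bash
idpdissect pipeline --seed 1 --out run/        # simulate ... report
idpdissect msm --seed 1 --out run/             # re-run one stage
```

Library use follows the same shape:

```python
from idpdissect import featurize, bvae, msm

traj = featurize.EnsembleTrajectory.from_ca_coordinates(coords)  # (F, R, 3) nm
feats = featurize.compute_distance_features(traj)
x, rec = featurize.minmax_scale(feats.values)
model, hist = bvae.train(x, bvae.BetaVaeArchitecture.scaled(x.shape[1]),
                         bvae.TrainingConfig(seed=0))
z = model.encode(x).coordinates
assign = msm.cluster_microstates(z, k=40, seed=0)
its = msm.implied_timescales(assign, lag_grid=[1, 2, 4, 8, 16])
```

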