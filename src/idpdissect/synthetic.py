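"""Ground-truth-labelled synthetic ensembles for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
conformational ensemble drawn from K discrete macrostates (distinct
self-avoiding Cα chain templates plus isotropic Gaussian jitter) whose
inter-state kinetics are an explicit first-order Markov chain; per-state
ligand-contact hotspot profiles; harmonic-oscillator velocity traces with an
analytically known density of states; and torsion-angle samples with known
differential entropy.  Every stage of the analysis can therefore be tested
against an exact ground truth.

Units: coordinates nm, velocities nm/ps, masses amu, time ps; one Markov
step per saved frame (time is abstract "frames" in synthetic mode).
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Boltzmann constant in amu nm^2 ps^-2 K^-1 (numerically kJ mol^-1 K^-1).
KB = 0.008314462618

#: Virtual Ca-Ca bond length, nm (trans-peptide convention).
BOND_LENGTH = 0.38

#: Hard-core diameter for self-avoidance between non-bonded beads, nm.
HARD_CORE = 0.40

#: Ca-Ca contact cutoff used for template distinguishability, nm (8 A).
CONTACT_CUTOFF = 0.8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroundTruthEnsembleSpec:
    """Full description of a synthetic K-state ensemble.

    ``templates`` holds one (n_residues, 3) Ca coordinate set per state;
    ``transition_matrix`` is the row-stochastic per-frame-step kinetics;
    ``hotspots`` (K, n_residues) are per-state ligand-contact probabilities;
    ``state_torsion_kappa`` optionally attaches a per-state von Mises
    concentration used to draw per-frame torsion samples (the synthetic
    stand-in for state-dependent conformational order).
    """

    n_states: int
    n_residues: int
    templates: np.ndarray
    jitter_sigma: float
    transition_matrix: np.ndarray
    hotspots: np.ndarray | None = None
    seed: int = 0
    state_torsion_kappa: np.ndarray | None = None
    n_torsions: int = 8

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix shape mismatch")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1 (1e-12)")
        self.transition_matrix = t
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.shape != (self.n_states, self.n_residues, 3):
            raise ValueError("templates shape mismatch")
        if self.hotspots is not None:
            h = np.asarray(self.hotspots, dtype=float)
            if h.shape != (self.n_states, self.n_residues):
                raise ValueError("hotspot matrix shape mismatch")
            if np.any(h < 0) or np.any(h > 1):
                raise ValueError("hotspot probabilities must lie in [0, 1]")
            self.hotspots = h


@dataclasses.dataclass
class SyntheticEnsemble:
    """Frames drawn from a GroundTruthEnsembleSpec, with labels retained."""

    coordinates: np.ndarray            # (frames, n_residues, 3) nm
    state_labels: np.ndarray           # (frames,) int in [0, K)
    ligand_contact_indicators: np.ndarray | None = None  # (frames, n_residues)
    torsions: np.ndarray | None = None  # (frames, n_torsions) radians


@dataclasses.dataclass
class VelocityTrace:
    masses: np.ndarray        # (particles,) amu
    velocities: np.ndarray    # (frames, particles, 3) nm/ps
    dt: float                 # ps
    temperature: float        # K

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")


@dataclasses.dataclass
class TorsionSample:
    angles: np.ndarray                 # (frames, n_torsions), wrapped (-pi, pi]
    generator: str
    analytic_entropy: float | None     # differential entropy per torsion, nats


# ---------------------------------------------------------------------------
# Chain templates
# ---------------------------------------------------------------------------

def _grow_chain(n_residues: int, rng: np.random.Generator,
                max_retries: int = 10_000) -> np.ndarray:
    """Self-avoiding random walk with fixed bond length and hard core."""
    coords = np.zeros((n_residues, 3))
    i = 1
    retries = 0
    while i < n_residues:
        step = rng.normal(size=3)
        step *= BOND_LENGTH / np.linalg.norm(step)
        cand = coords[i - 1] + step
        # hard core against all non-bonded predecessors
        if i >= 2:
            d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
            if np.any(d < HARD_CORE):
                retries += 1
                if retries > max_retries:
                    raise RuntimeError(
                        "self-avoiding chain growth failed after "
                        f"{max_retries} retries (n_residues={n_residues})")
                continue
        coords[i] = cand
        i += 1
    return coords


def template_contact_map(template: np.ndarray,
                         cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Boolean Ca-Ca contact map of a single template (strict <)."""
    d = np.linalg.norm(template[:, None] - template[None, :], axis=-1)
    return d < cutoff


def _contact_hamming(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of off-diagonal i<j pairs whose contact state differs."""
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(a[iu] != b[iu]))


def generate_state_templates(n_states: int, n_residues: int, seed: int,
                             min_hamming: float = 0.10,
                             max_retries: int = 10_000) -> np.ndarray:
    """Generate mutually distinguishable self-avoiding Ca chain templates.

    Each template is a random chain with 0.38 nm bonds and a 0.4 nm hard
    core; templates are accepted only if every pairwise contact-map Hamming
    fraction is at least ``min_hamming``.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4 (chain too short)")
    rng = np.random.default_rng(seed)
    templates: list[np.ndarray] = []
    maps: list[np.ndarray] = []
    attempts = 0
    while len(templates) < n_states:
        attempts += 1
        if attempts > max_retries:
            raise RuntimeError("could not generate distinguishable templates")
        cand = _grow_chain(n_residues, rng, max_retries=max_retries)
        cmap = template_contact_map(cand)
        if all(_contact_hamming(cmap, m) >= min_hamming for m in maps):
            templates.append(cand)
            maps.append(cmap)
    return np.stack(templates)


# ---------------------------------------------------------------------------
# Markov ensemble
# ---------------------------------------------------------------------------

def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Exact stationary vector (left eigenvector of eigenvalue 1)."""
    t = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(t.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_markov_chain(transition_matrix: np.ndarray, n_frames: int,
                        rng: np.random.Generator,
                        initial: int | None = None) -> np.ndarray:
    t = np.asarray(transition_matrix, dtype=float)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must sum to 1")
    k = t.shape[0]
    cum = np.cumsum(t, axis=1)
    labels = np.empty(n_frames, dtype=np.int64)
    if initial is None:
        pi = stationary_distribution(t)
        state = int(rng.choice(k, p=pi))
    else:
        state = int(initial)
    u = rng.random(n_frames)
    for i in range(n_frames):
        labels[i] = state
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, k - 1)
    return labels


def simulate_markov_ensemble(spec: GroundTruthEnsembleSpec, n_frames: int,
                             seed: int | None = None,
                             with_ligand: bool = False,
                             with_torsions: bool = False) -> SyntheticEnsemble:
    """Draw a labelled ensemble: Markov state sequence + jittered templates."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = sample_markov_chain(spec.transition_matrix, n_frames, rng)
    coords = spec.templates[labels] + rng.normal(
        scale=spec.jitter_sigma, size=(n_frames, spec.n_residues, 3))
    ens = SyntheticEnsemble(coordinates=coords, state_labels=labels)
    if with_ligand:
        ens.ligand_contact_indicators = simulate_ligand_contacts(
            ens, spec, seed=int(rng.integers(2**31)))
    if with_torsions:
        ens.torsions = _state_torsions(labels, spec, rng)
    return ens


def _state_torsions(labels: np.ndarray, spec: GroundTruthEnsembleSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-frame torsion vectors with state-dependent von Mises concentration."""
    if spec.state_torsion_kappa is None:
        raise ValueError("spec.state_torsion_kappa not set")
    kappa = np.asarray(spec.state_torsion_kappa, dtype=float)
    out = np.empty((labels.size, spec.n_torsions))
    for s in range(spec.n_states):
        mask = labels == s
        out[mask] = rng.vonmises(0.0, kappa[s],
                                 size=(int(mask.sum()), spec.n_torsions))
    return out


def simulate_ligand_contacts(ensemble: SyntheticEnsemble,
                             spec: GroundTruthEnsembleSpec,
                             seed: int) -> np.ndarray:
    """Bernoulli per-frame, per-residue contact indicators from the hotspots."""
    if ensemble.state_labels is None:
        raise ValueError("ensemble labels required")
    if spec.hotspots is None:
        raise ValueError("spec.hotspots not set")
    if spec.hotspots.shape != (spec.n_states, spec.n_residues):
        raise ValueError("hotspot matrix shape mismatch")
    rng = np.random.default_rng(seed)
    p = spec.hotspots[ensemble.state_labels]          # (frames, residues)
    return (rng.random(p.shape) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# Velocity traces and torsion samples
# ---------------------------------------------------------------------------

def generate_ho_velocities(frequencies, temperature: float, n_steps: int,
                           dt: float, seed: int,
                           mass: float = 18.0) -> VelocityTrace:
    """Harmonic-oscillator velocity traces with an analytically known DoS.

    Each particle gets an independent 1-D cosine velocity per Cartesian
    direction, ``v(t) = A cos(2 pi nu t + phi)``, with the amplitude fixed by
    equipartition (<m v^2>/2 = kB T / 2 per degree of freedom, so
    A = sqrt(2 kB T / m)) and a uniform random phase.  The exact density of
    states is a spectral line at ``nu``; ``nu = 0`` degenerates to free
    streaming at constant speed.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    nyquist = 1.0 / (2.0 * dt)
    if np.any(freqs >= nyquist):
        raise ValueError(
            f"aliasing: frequency >= Nyquist {nyquist:.4g} 1/ps for dt={dt}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt
    amp = np.sqrt(2.0 * KB * temperature / mass)
    vel = np.empty((n_steps, freqs.size, 3))
    for p, nu in enumerate(freqs):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        vel[:, p, :] = amp * np.cos(2.0 * np.pi * nu * t[:, None]
                                    + phases[None, :])
    masses = np.full(freqs.size, mass)
    return VelocityTrace(masses=masses, velocities=vel, dt=dt,
                         temperature=temperature)


def vonmises_entropy(kappa: float) -> float:
    """Differential entropy of the von Mises distribution, in nats:
    H = ln(2 pi I0(kappa)) - kappa I1(kappa)/I0(kappa)."""
    from scipy.special import ive

    if kappa == 0.0:
        return float(np.log(2.0 * np.pi))
    # scaled Bessel functions avoid overflow for large kappa
    i0, i1 = ive(0, kappa), ive(1, kappa)
    return float(np.log(2.0 * np.pi * i0) + kappa - kappa * i1 / i0)


def sample_torsions(descriptor, n: int, seed: int) -> TorsionSample:
    """Draw circular samples from a named distribution.

    ``descriptor`` is ``"uniform"``, ``("von_mises", kappa)`` or
    ``("correlated_pair", rho)`` (Gaussian-copula pair wrapped to the circle;
    no closed-form entropy, used for mutual-information tests).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if descriptor == "uniform":
        angles = rng.uniform(-np.pi, np.pi, size=(n, 1))
        return TorsionSample(_wrap(angles), "uniform",
                             float(np.log(2 * np.pi)))
    if isinstance(descriptor, (tuple, list)) and len(descriptor) == 2:
        kind, param = descriptor
        if kind == "von_mises":
            angles = rng.vonmises(0.0, float(param), size=(n, 1))
            return TorsionSample(_wrap(angles), f"von_mises(kappa={param})",
                                 vonmises_entropy(float(param)))
        if kind == "correlated_pair":
            rho = float(param)
            cov = np.array([[1.0, rho], [rho, 1.0]])
            z = rng.multivariate_normal(np.zeros(2), cov, size=n)
            return TorsionSample(_wrap(z), f"correlated_pair(rho={rho})", None)
    raise ValueError(f"unknown torsion descriptor: {descriptor!r}")


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    wrapped = np.mod(angles + np.pi, 2.0 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


# ---------------------------------------------------------------------------
# Benchmark study specs (apo-like K=3 / ligand-like K=6)
# ---------------------------------------------------------------------------

def benchmark_spec(n_states: int, n_residues: int = 20, seed: int = 0,
                   jitter_sigma: float = 0.05,
                   base_escape: float = 0.01) -> GroundTruthEnsembleSpec:
    """Study-condition generator spec for the end-to-end benchmark.

    State 0 is the "major" state (largest stationary weight and least
    concentrated torsions, hence highest conformational entropy).  Kinetics
    are a Metropolis-type chain over state weights with per-state escape
    rates coupled to the per-state torsion concentration: more ordered
    (higher kappa, lower entropy) states escape toward the major state
    faster, so MFPT to the top state increases with state entropy -- the
    synthetic analogue of the entropy/transition-time correlation the
    analysis is designed to expose.
    """
    k = n_states
    # stationary weights: top state ~2x the rest, mild spread below
    w = np.array([2.0] + [1.0 + 0.15 * s for s in range(k - 1)])
    w /= w.sum()
    # torsion concentration: state 0 broadest; kappa grows with state index
    kappa = np.array([0.5 + 1.0 * s for s in range(k)])
    # escape-rate multiplier grows with kappa (ordered states leave sooner)
    rate = 0.5 + kappa / kappa.max()
    t = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            accept = min(1.0, w[j] / w[i])
            t[i, j] = base_escape * rate[i] * accept
        t[i, i] = 1.0 - t[i].sum()
    if np.any(np.diag(t) <= 0):
        raise ValueError("base_escape too large for a valid chain")
    templates = generate_state_templates(k, n_residues, seed)
    rng = np.random.default_rng(seed + 1)
    hotspots = np.clip(rng.beta(0.4, 1.2, size=(k, n_residues)), 0.0, 1.0)
    return GroundTruthEnsembleSpec(
        n_states=k, n_residues=n_residues, templates=templates,
        jitter_sigma=jitter_sigma, transition_matrix=t, hotspots=hotspots,
        seed=seed, state_torsion_kappa=kappa, n_torsions=8)


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def write_ensemble(ensemble: SyntheticEnsemble, prefix: str,
                   coord_format: str = "xtc") -> None:
    """Write PDB topology (one CA per residue) + coordinate frames + a CSV
    sidecar mapping frame -> ground-truth state."""
    import mdtraj as md
    import pandas as pd

    n_res = ensemble.coordinates.shape[1]
    top = md.Topology()
    chain = top.add_chain()
    for r in range(n_res):
        res = top.add_residue("ALA", chain, resSeq=r + 1)
        top.add_atom("CA", md.element.carbon, res)
    traj = md.Trajectory(ensemble.coordinates, top)
    traj[0].save_pdb(prefix + ".pdb")
    if coord_format == "xtc":
        traj.save_xtc(prefix + ".xtc")
    elif coord_format == "dcd":
        traj.save_dcd(prefix + ".dcd")
    else:
        raise ValueError(f"unknown coordinate format {coord_format!r}")
    pd.DataFrame({"frame": np.arange(len(ensemble.state_labels)),
                  "state": ensemble.state_labels}
                 ).to_csv(prefix + "_states.csv", index=False)


def write_velocity_trace(trace: VelocityTrace, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("masses", data=trace.masses)
        f.create_dataset("velocities", data=trace.velocities)
        f.create_dataset("dt", data=trace.dt)
        f.create_dataset("temperature", data=trace.temperature)


def read_velocity_trace(path: str) -> VelocityTrace:
    import h5py

    with h5py.File(path, "r") as f:
        return VelocityTrace(masses=f["masses"][...],
                             velocities=f["velocities"][...],
                             dt=float(f["dt"][()]),
                             temperature=float(f["temperature"][()]))
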