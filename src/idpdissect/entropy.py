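"""Conformational and solvent entropy estimators.

Two independent estimators:

1. **Torsion entropy** -- differential entropy of torsion-angle
   distributions relative to a fully flexible chain (uniform torsions),
   estimated with a Kozachenko-Leonenko nearest-neighbor scheme using
   wrapped (circular) distances, and assembled over many torsions with the
   Maximum Information Spanning Tree (MIST) pairwise correction:
   ``S_2 = sum_i h_i - sum_{(i,j) in MST} MI_ij``.  Backbone (phi/psi) and
   sidechain (chi) splits and per-residue attributions are reported.
   Relative entropies are <= 0 up to estimator noise; they are reported in
   J mol^-1 K^-1 (R x nats) with nats retained.

2. **2PT water entropy** -- the density of states I(nu) (mass-weighted
   power spectrum of velocities, normalised so its integral counts degrees
   of freedom) is split into a gas-like part (hard-sphere/rigid-rotor
   weighted) and a solid-like part (quantum harmonic-oscillator weighted)
   through the fluidicity f, solved from the standard 2PT universal
   equation in the dimensionless diffusivity Delta.

Internal units: nm, ps, amu, K; kB = 0.008314 amu nm^2 ps^-2 K^-1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from scipy.special import digamma

KB = 0.008314462618          # amu nm^2 ps^-2 K^-1  (= kJ mol^-1 K^-1)
PLANCK_H = 0.399031          # amu nm^2 ps^-1
R_GAS = 8.314462618          # J mol^-1 K^-1
TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Torsion computation
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle in (-pi, pi] for four points (vectorised over
    leading axes).  Zero is cis, pi is trans."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    u = p0 - p1
    w = p3 - p2
    v = u - np.sum(u * b1, axis=-1, keepdims=True) * b1
    w = w - np.sum(w * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.arctan2(y, x)


def virtual_ca_torsions(coords: np.ndarray) -> np.ndarray:
    """Pseudo-dihedrals over four consecutive Ca beads: (frames, n_res-3)."""
    c = np.asarray(coords, dtype=float)
    return dihedral(c[:, :-3], c[:, 1:-2], c[:, 2:-1], c[:, 3:])


@dataclasses.dataclass
class TorsionDataset:
    angles: np.ndarray          # (frames, n_torsions), wrapped (-pi, pi]
    labels: list                # [(residue_index 1-based, kind), ...]
    temperature: float = 300.0

    def __post_init__(self):
        if len(self.labels) != self.angles.shape[1]:
            raise ValueError("labels/angles width mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("torsion labels must be unique")

    def subset(self, columns) -> "TorsionDataset":
        cols = list(columns)
        return TorsionDataset(self.angles[:, cols],
                              [self.labels[c] for c in cols],
                              self.temperature)


def compute_torsions(traj, temperature: float = 300.0) -> TorsionDataset:
    """Extract phi/psi and chi torsions from an mdtraj Trajectory.

    Chain-end residues lacking a dihedral are skipped; missing sidechain
    atoms simply contribute no chi entry.
    """
    import mdtraj as md

    angles, labels = [], []
    idx_phi, phi = md.compute_phi(traj)
    for col, quad in enumerate(idx_phi):
        res = traj.topology.atom(int(quad[-1])).residue.index + 1
        angles.append(phi[:, col])
        labels.append((res, "phi"))
    idx_psi, psi = md.compute_psi(traj)
    for col, quad in enumerate(idx_psi):
        res = traj.topology.atom(int(quad[0])).residue.index + 1
        angles.append(psi[:, col])
        labels.append((res, "psi"))
    for n_chi, fn in enumerate((md.compute_chi1, md.compute_chi2,
                                md.compute_chi3, md.compute_chi4), start=1):
        idx, chi = fn(traj)
        for col, quad in enumerate(idx):
            res = traj.topology.atom(int(quad[0])).residue.index + 1
            angles.append(chi[:, col])
            labels.append((res, f"chi{n_chi}"))
    arr = _wrap(np.column_stack(angles)) if angles else np.empty((traj.n_frames, 0))
    return TorsionDataset(arr, labels, temperature)


def _wrap(a: np.ndarray) -> np.ndarray:
    w = np.mod(a + np.pi, TWO_PI) - np.pi
    w[w == -np.pi] = np.pi
    return w


# ---------------------------------------------------------------------------
# Nearest-neighbor circular entropy
# ---------------------------------------------------------------------------

def _knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Chebyshev (l-inf) distance to the k-th nearest neighbor on the
    d-torus of circumference 2 pi."""
    x = np.mod(points + np.pi, TWO_PI)  # -> [0, 2pi)
    tree = cKDTree(x, boxsize=TWO_PI)
    dist, _ = tree.query(x, k=k + 1, p=np.inf)
    return dist[:, -1]


def nn_entropy(samples: np.ndarray, k_neighbors: int = 3) -> float:
    """Kozachenko-Leonenko differential entropy (nats) with circular
    wrapped distances and l-inf product-ball volumes.

    H = psi(n) - psi(k) + d ln 2 + d <ln eps_k>.
    Duplicate-heavy samples trigger a jitter guard (warning) so that log
    distances stay finite.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 samples")
    eps = _knn_distances(x, k_neighbors)
    if np.any(eps == 0):
        warnings.warn("duplicate-heavy samples: applying jitter guard")
        rng = np.random.default_rng(0)
        x = _wrap(x + 1e-9 * rng.standard_normal(x.shape))
        eps = _knn_distances(x, k_neighbors)
        eps = np.maximum(eps, 1e-12)
    return float(digamma(n) - digamma(k_neighbors)
                 + d * np.log(2.0) + d * np.mean(np.log(eps)))


def nn_relative_entropy(samples: np.ndarray, k_neighbors: int = 3,
                        in_joules: bool = False) -> float:
    """Entropy relative to the uniform (fully flexible) reference:
    H_rel = H - d ln(2 pi), in nats (or J mol^-1 K^-1 with ``in_joules``).
    Always <= 0 up to estimator noise."""
    x = np.asarray(samples, dtype=float)
    d = 1 if x.ndim == 1 else x.shape[1]
    h = nn_entropy(x, k_neighbors) - d * np.log(TWO_PI)
    return float(h * R_GAS) if in_joules else float(h)


def mutual_information(a: np.ndarray, b: np.ndarray,
                       k_neighbors: int = 3) -> float:
    """MI(a, b) = H(a) + H(b) - H(a, b), clipped at 0 (nats)."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    mi = (nn_entropy(a, k_neighbors) + nn_entropy(b, k_neighbors)
          - nn_entropy(np.column_stack([a, b]), k_neighbors))
    return max(0.0, float(mi))


# ---------------------------------------------------------------------------
# MIST assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EntropyDecomposition:
    total: float                       # J mol^-1 K^-1, relative (<= 0)
    total_nats: float
    backbone_total: float
    sidechain_total: float
    per_residue: dict                  # residue -> {"backbone": x, "sidechain": y}
    order: int
    marginal_sum_nats: float           # order-1 total for the same torsions
    tree_edges: list                   # [(i, j, MI_nats), ...] torsion columns


MIN_FRAMES_PAIRWISE = 50


def _mist_core(angles: np.ndarray, order: int, k_neighbors: int):
    """Marginal relative entropies, maximum-MI spanning-tree edges and the
    MIST total (nats) for one torsion set.  Marginal absolute entropies are
    computed once and reused inside every pairwise MI."""
    n, t = angles.shape
    h_abs = np.array([nn_entropy(angles[:, i], k_neighbors)
                      for i in range(t)])
    marg = h_abs - np.log(TWO_PI)
    edges = []
    if order == 2 and t >= 2:
        mi = np.zeros((t, t))
        for i in range(t):
            for j in range(i + 1, t):
                h_joint = nn_entropy(angles[:, (i, j)], k_neighbors)
                mi[i, j] = max(0.0, h_abs[i] + h_abs[j] - h_joint)
        # maximum spanning tree == minimum spanning tree of negated weights
        tree = minimum_spanning_tree(coo_matrix(-mi)).tocoo()
        edges = [(int(i), int(j), float(-w))
                 for i, j, w in zip(tree.row, tree.col, tree.data) if w < 0]
    total = float(marg.sum() - sum(w for _, _, w in edges))
    return marg, edges, total


def mist_total_entropy(dataset: TorsionDataset, order: int = 2,
                       k_neighbors: int = 3) -> EntropyDecomposition:
    """Torsion entropy relative to a fully flexible chain via MIST.

    Order 1 sums the marginal relative entropies; order 2 subtracts the
    pairwise mutual informations along the maximum-information spanning
    tree, so ``S_2 <= S_1`` always.  Backbone/sidechain totals restrict the
    torsion set; per-residue values collect each residue's own marginal
    terms, with tree-edge MI assigned to the lower residue index.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n, t = dataset.angles.shape
    if t == 0:
        raise ValueError("dataset has no torsions")
    if order == 2 and t >= 2 and n < MIN_FRAMES_PAIRWISE:
        raise ValueError(
            f"pairwise MI estimation needs >= {MIN_FRAMES_PAIRWISE} frames "
            f"(got {n})")
    marg, edges, total_nats = _mist_core(dataset.angles, order, k_neighbors)

    kinds = [kind for _, kind in dataset.labels]
    backbone_cols = [i for i, k in enumerate(kinds) if k in ("phi", "psi")]
    sidechain_cols = [i for i, k in enumerate(kinds) if k.startswith("chi")]

    def sub_total(cols):
        if not cols:
            return 0.0
        if len(cols) == t:
            return total_nats
        if len(cols) == 1 or order == 1:
            return float(marg[cols].sum())
        return _mist_core(dataset.angles[:, cols], order, k_neighbors)[2]

    bb_nats = sub_total(backbone_cols)
    sc_nats = sub_total(sidechain_cols)

    per_res: dict = {}
    for col, (res, kind) in enumerate(dataset.labels):
        slot = per_res.setdefault(res, {"backbone": 0.0, "sidechain": 0.0})
        key = "backbone" if kind in ("phi", "psi") else "sidechain"
        slot[key] += float(marg[col]) * R_GAS
    for i, j, w in edges:
        res_i, kind_i = dataset.labels[min(i, j)]
        key = "backbone" if kind_i in ("phi", "psi") else "sidechain"
        per_res.setdefault(res_i, {"backbone": 0.0, "sidechain": 0.0})
        per_res[res_i][key] -= w * R_GAS

    return EntropyDecomposition(
        total=total_nats * R_GAS, total_nats=total_nats,
        backbone_total=bb_nats * R_GAS, sidechain_total=sc_nats * R_GAS,
        per_residue=per_res, order=order,
        marginal_sum_nats=float(marg.sum()), tree_edges=edges)


# ---------------------------------------------------------------------------
# Density of states (2PT)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DoSSpectrum:
    frequencies: np.ndarray     # (F,) 1/ps, starting at 0
    intensity: np.ndarray       # (F,) ps; integral = degrees of freedom
    components: dict = dataclasses.field(default_factory=dict)
    temperature: float = 300.0

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.frequencies))


def _velocity_psd(vel: np.ndarray, weights: np.ndarray, dt: float,
                  kbt: float) -> tuple[np.ndarray, np.ndarray]:
    """Weight-summed one-sided power spectral density of velocity columns.

    ``vel`` is (frames, channels); ``weights`` (channels,) carries the mass
    (or moment of inertia) of each channel.  Every bin (including DC and
    Nyquist) carries the doubled one-sided density, so the zero-frequency
    value matches the diffusive limit I(0) = 4 m D / kB T per degree of
    freedom; the trapezoid rule's half-weight at the interval endpoints
    then makes the integral equal sum_c w_c <v_c^2> / kbt (Parseval).
    """
    n = vel.shape[0]
    spec = np.fft.rfft(vel, axis=0)
    psd = 2.0 * (dt / n) * np.abs(spec) ** 2
    intensity = (psd * weights[None, :]).sum(axis=1) / kbt
    freqs = np.fft.rfftfreq(n, dt)
    return freqs, intensity


def compute_dos(trace) -> DoSSpectrum:
    """Mass-weighted density of states from a velocity trace.

    The spectral density of each atomic velocity component is taken per the
    Wiener-Khinchin equivalence as the squared magnitude of its Fourier
    transform; weighting by mass/(kB T) and summing makes the integral
    count degrees of freedom (= 1 per Cartesian component at
    equipartition).
    """
    v = np.asarray(trace.velocities, dtype=float)
    if v.ndim != 3:
        raise ValueError("velocities must be (frames, particles, 3)")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    kbt = KB * trace.temperature
    n, p, _ = v.shape
    flat = v.reshape(n, p * 3)
    w = np.repeat(np.asarray(trace.masses, dtype=float), 3)
    freqs, intensity = _velocity_psd(flat, w, trace.dt, kbt)
    return DoSSpectrum(frequencies=freqs, intensity=intensity,
                       temperature=trace.temperature)


def decompose_rigid_water_dos(coords: np.ndarray, velocities: np.ndarray,
                              site_masses: np.ndarray, dt: float,
                              temperature: float,
                              flex_tol: float = 1e-6) -> DoSSpectrum:
    """Translational/rotational DoS decomposition for rigid multi-site
    molecules (e.g. 3-site water).

    ``coords``/``velocities`` are (frames, molecules, sites, 3).  The
    translational part uses center-of-mass velocities weighted by the
    molecular mass; the rotational part uses angular velocities about the
    instantaneous principal axes weighted by the principal moments of
    inertia.  For rigid molecules the vibrational component is identically
    zero; if intramolecular bond lengths fluctuate beyond ``flex_tol`` the
    remainder is reported as ``vib`` with a warning.
    """
    x = np.asarray(coords, dtype=float)
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(site_masses, dtype=float)
    n_f, n_mol, n_sites, _ = x.shape
    mtot = m.sum()
    kbt = KB * temperature

    com_v = np.einsum("s,fmsx->fmx", m, v) / mtot
    freqs, i_trn = _velocity_psd(com_v.reshape(n_f, n_mol * 3),
                                 np.full(n_mol * 3, mtot), dt, kbt)

    com_x = np.einsum("s,fmsx->fmx", m, x) / mtot
    rel = x - com_x[:, :, None, :]
    rel_v = v - com_v[:, :, None, :]
    # angular momentum and inertia tensor per frame/molecule
    ang_l = np.einsum("s,fmsx->fmx", m, np.cross(rel, rel_v))
    r2 = np.sum(rel**2, axis=-1)
    eye = np.eye(3)
    inertia = (np.einsum("s,fms,xy->fmxy", m, r2, eye)
               - np.einsum("s,fmsx,fmsy->fmxy", m, rel, rel))
    evals, evecs = np.linalg.eigh(inertia)   # ascending moments
    # keep axis orientation continuous along the trajectory
    for f in range(1, n_f):
        flip = np.einsum("mxa,mxa->ma", evecs[f], evecs[f - 1]) < 0
        evecs[f][:, :, :] *= np.where(flip[:, None, :], -1.0, 1.0)
    omega = np.linalg.solve(inertia, ang_l[..., None])[..., 0]
    omega_p = np.einsum("fmxa,fmx->fma", evecs, omega)
    # a 3-site linear check: smallest moment ~ 0 -> drop that axis
    axis_ok = evals.mean(axis=(0, 1)) > 1e-12
    chans, weights = [], []
    for a in range(3):
        if axis_ok[a]:
            chans.append(omega_p[:, :, a])
            weights.append(evals[:, :, a].mean(axis=0))
    omega_mat = np.concatenate(chans, axis=1)
    w_rot = np.concatenate(weights)
    _, i_rot = _velocity_psd(omega_mat, w_rot, dt, kbt)

    bond0 = np.linalg.norm(x[:, :, 1] - x[:, :, 0], axis=-1)
    flexible = float(bond0.var()) > flex_tol
    total_freqs, i_tot = _velocity_psd(
        v.reshape(n_f, n_mol * n_sites * 3),
        np.repeat(np.tile(m, n_mol), 3), dt, kbt)
    components = {"trn": i_trn, "rot": i_rot}
    if flexible:
        warnings.warn("flexible molecules detected; vib = remainder")
        components["vib"] = np.clip(i_tot - i_trn - i_rot, 0.0, None)
    else:
        components["vib"] = np.zeros_like(i_trn)
    return DoSSpectrum(frequencies=freqs,
                       intensity=i_trn + i_rot + components["vib"],
                       components=components, temperature=temperature)


# ---------------------------------------------------------------------------
# Two-phase partition
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TwoPhasePartition:
    fluidicity: float
    gas_dos: np.ndarray
    solid_dos: np.ndarray
    frequencies: np.ndarray
    delta: float
    n_dof: float
    n_particles: int
    component: str = "trn"


def normalized_diffusivity(s0: float, temperature: float, mass: float,
                           number_density: float, n_particles: int) -> float:
    """Dimensionless diffusivity Delta from the zero-frequency DoS:
    Delta = (2 s0 / 9 N) sqrt(pi kB T / m) rho^{1/3} (6/pi)^{2/3}."""
    return (2.0 * s0 / (9.0 * n_particles)
            * np.sqrt(np.pi * KB * temperature / mass)
            * number_density ** (1.0 / 3.0)
            * (6.0 / np.pi) ** (2.0 / 3.0))


def solve_fluidicity(delta: float) -> float:
    """Root in [0, 1] of the 2PT universal fluidicity equation
    2 D^-9/2 f^15/2 - 6 D^-3 f^5 - D^-3/2 f^7/2 + 6 D^-3/2 f^5/2 + 2f - 2 = 0."""
    if delta <= 0:
        return 0.0

    def g(f):
        return (2.0 * delta**-4.5 * f**7.5 - 6.0 * delta**-3 * f**5
                - delta**-1.5 * f**3.5 + 6.0 * delta**-1.5 * f**2.5
                + 2.0 * f - 2.0)

    # g(0) = -2 and g(1) = u(2u^2 - 6u + 5) > 0 with u = Delta^-3/2,
    # so a root always exists in (0, 1)
    if g(1.0) < 0:
        raise RuntimeError(
            f"no fluidicity root in [0,1] for Delta={delta:.4g}")
    f = float(brentq(g, 0.0, 1.0, xtol=1e-14))
    return 0.0 if f < 1e-10 else f


def two_phase_partition(dos: DoSSpectrum, number_density: float,
                        temperature: float, mass: float,
                        n_particles: int,
                        component: str = "trn") -> TwoPhasePartition:
    """Split a DoS component into gas-like and solid-like parts.

    The gas part is the hard-sphere memory-function form
    I_g(nu) = s0 / (1 + (pi s0 nu / (6 f N))^2), which integrates exactly to
    3 N f; the solid part is the remainder floored at 0.  I(0) = 0 yields a
    pure solid (f = 0, gas identically zero).
    """
    freqs = dos.frequencies
    intensity = (dos.components.get(component, dos.intensity)
                 if dos.components else dos.intensity)
    s0 = float(intensity[0])
    if s0 < 0:
        raise ValueError("I(0) must be >= 0")
    n_dof = float(np.trapezoid(intensity, freqs))
    if s0 == 0.0:
        return TwoPhasePartition(0.0, np.zeros_like(intensity),
                                 intensity.copy(), freqs, 0.0, n_dof,
                                 n_particles, component)
    delta = normalized_diffusivity(s0, temperature, mass, number_density,
                                   n_particles)
    f = solve_fluidicity(delta)
    if f == 0.0:
        gas = np.zeros_like(intensity)
    else:
        gas = s0 / (1.0 + (np.pi * s0 * freqs / (6.0 * f * n_particles)) ** 2)
        gas = np.minimum(gas, intensity)
    solid = np.clip(intensity - gas, 0.0, None)
    return TwoPhasePartition(f, gas, solid, freqs, float(delta), n_dof,
                             n_particles, component)


# ---------------------------------------------------------------------------
# Entropy integration
# ---------------------------------------------------------------------------

def solid_weight(nu: np.ndarray, temperature: float) -> np.ndarray:
    """Quantum harmonic-oscillator entropy weight
    W_s = bhv/(e^bhv - 1) - ln(1 - e^-bhv), with bhv = h nu / (kB T).
    Diverges logarithmically at nu -> 0; frozen modes (bhv -> inf) weigh 0.
    """
    bhv = PLANCK_H * np.asarray(nu, dtype=float) / (KB * temperature)
    out = np.zeros_like(bhv)
    pos = bhv > 0
    b = bhv[pos]
    with np.errstate(over="ignore"):
        out[pos] = b / np.expm1(b) - np.log1p(-np.exp(-b))
    return out


def hard_sphere_entropy(temperature: float, mass: float,
                        number_density: float, fluidicity: float,
                        delta: float) -> float:
    """Enskog hard-sphere entropy per molecule in kB units: ideal gas plus
    the Carnahan-Starling excess at packing fraction y = f^{5/2}/Delta^{3/2}."""
    y = fluidicity**2.5 / delta**1.5 if delta > 0 else 0.0
    y = min(y, 0.74)  # keep below close packing for numerical sanity
    therm = (TWO_PI * mass * KB * temperature / PLANCK_H**2) ** 1.5
    v_per = fluidicity / number_density if number_density > 0 else 1.0
    s_ig = 2.5 + np.log(max(therm * v_per, 1e-300))
    excess = y * (3.0 * y - 4.0) / (1.0 - y) ** 2
    return float(s_ig + excess)


def rigid_rotor_entropy(temperature: float, principal_moments,
                        symmetry_number: float = 2.0) -> float:
    """Classical rigid-rotor entropy per molecule in kB units.
    Theta_X = h^2 / (8 pi^2 I_X kB) are the rotational temperatures."""
    moments = np.asarray(principal_moments, dtype=float)
    theta = PLANCK_H**2 / (8.0 * np.pi**2 * moments * KB)
    arg = (np.sqrt(np.pi) * np.e**1.5 / symmetry_number
           * np.sqrt(temperature**3 / np.prod(theta)))
    return float(np.log(arg))


@dataclasses.dataclass
class WaterEntropyReport:
    molar_entropy: float        # J mol^-1 K^-1
    translational: float
    rotational: float
    vibrational: float


def integrate_entropy(partition: TwoPhasePartition, temperature: float,
                      gas_weight: float | None = None,
                      solid_zero_tol: float = 0.05) -> float:
    """Entropy of one component, in kB units for the whole system:
    S/kB = int I_s W_s dnu + W_g int I_g dnu.

    ``gas_weight`` is the constant W^g (S_HS/3kB for translation,
    S_RR/3kB for rotation); unused when f = 0.  The W_s weight diverges at
    nu -> 0, which is integrable only where I_s(0) -> 0; a solid DoS that
    stays finite at zero frequency signals a bad partition and raises.
    """
    freqs = partition.frequencies
    i_s, i_g = partition.solid_dos, partition.gas_dos
    if i_s[0] > solid_zero_tol * max(partition.n_dof, 1e-12):
        raise ValueError(
            "solid DoS does not vanish at zero frequency "
            f"(I_s(0)={i_s[0]:.4g}); partition looks invalid")
    w_s = solid_weight(freqs, temperature)
    # exclude the nu=0 bin (I_s(0) ~ 0; W_s log-divergence is integrable)
    s_solid = float(np.trapezoid(i_s[1:] * w_s[1:], freqs[1:]))
    s_gas = 0.0
    if partition.fluidicity > 0:
        if gas_weight is None:
            raise ValueError("gas_weight required when fluidicity > 0")
        s_gas = float(gas_weight * np.trapezoid(i_g, freqs))
    return s_solid + s_gas


def water_entropy_report(dos: DoSSpectrum, number_density: float,
                         temperature: float, molecular_mass: float,
                         n_molecules: int, principal_moments,
                         symmetry_number: float = 2.0) -> WaterEntropyReport:
    """End-to-end 2PT: decompose, partition, and integrate each component,
    reporting molar entropies (J mol^-1 K^-1 per mole of molecules)."""
    part_t = two_phase_partition(dos, number_density, temperature,
                                 molecular_mass, n_molecules, "trn")
    whs = hard_sphere_entropy(temperature, molecular_mass, number_density,
                              part_t.fluidicity, max(part_t.delta, 1e-300)
                              ) / 3.0 if part_t.fluidicity > 0 else 0.0
    s_trn = integrate_entropy(part_t, temperature, gas_weight=whs)
    part_r = two_phase_partition(dos, number_density, temperature,
                                 molecular_mass, n_molecules, "rot")
    wrr = rigid_rotor_entropy(temperature, principal_moments,
                              symmetry_number) / 3.0 \
        if part_r.fluidicity > 0 else 0.0
    s_rot = integrate_entropy(part_r, temperature, gas_weight=wrr)
    s_vib = 0.0
    if dos.components.get("vib") is not None and \
            float(np.trapezoid(dos.components["vib"], dos.frequencies)) > 1e-9:
        part_v = TwoPhasePartition(
            0.0, np.zeros_like(dos.components["vib"]),
            dos.components["vib"], dos.frequencies, 0.0,
            float(np.trapezoid(dos.components["vib"], dos.frequencies)),
            n_molecules, "vib")
        s_vib = integrate_entropy(part_v, temperature)
    to_molar = R_GAS / n_molecules
    return WaterEntropyReport(
        molar_entropy=(s_trn + s_rot + s_vib) * to_molar,
        translational=s_trn * to_molar, rotational=s_rot * to_molar,
        vibrational=s_vib * to_molar)
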