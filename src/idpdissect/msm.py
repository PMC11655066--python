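"""Markov state modelling of the latent space.

Pipeline: k-means microstate discretisation -> sliding-window transition
counts at a lag -> (reversible) maximum-likelihood transition matrix on the
largest strongly connected set -> implied timescales / lag selection ->
PCCA+ macrostates -> Chapman-Kolmogorov validation, mean first passage
times, and leave-one-out bootstrap uncertainty.

Transitions are never counted across trajectory boundaries.  Time is
expressed in frames; multiply by a frame interval to attach physical units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix


@dataclasses.dataclass
class MicrostateAssignment:
    labels: np.ndarray               # (frames,) int in [0, k)
    centers: np.ndarray              # (k, dim)
    k: int
    seed: int
    trajectory_boundaries: np.ndarray  # start indices of independent trajs
    inertia: float = np.nan

    def split_labels(self) -> list:
        bounds = list(self.trajectory_boundaries) + [len(self.labels)]
        return [self.labels[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


@dataclasses.dataclass
class TransitionModel:
    lag: int
    counts: np.ndarray               # (k, k) on the full microstate set
    transition_matrix: np.ndarray    # (m, m) on the active (connected) set
    active_set: np.ndarray           # microstate ids of the active set
    eigenvalues: np.ndarray          # sorted descending (real for reversible)
    stationary: np.ndarray           # pi on the active set
    reversible: bool
    discarded_frame_fraction: float = 0.0


@dataclasses.dataclass
class MacrostateModel:
    n_macrostates: int
    memberships: np.ndarray          # (m, M) fuzzy PCCA+ memberships
    crisp_map: np.ndarray            # (m,) microstate -> macrostate argmax
    populations: np.ndarray          # (M,) from chi^T pi
    population_std: np.ndarray | None = None   # raw spread across iterations
    population_se: np.ndarray | None = None    # jackknife standard error
    mfpt: np.ndarray | None = None   # (M, M) frames
    mfpt_std: np.ndarray | None = None
    mfpt_se: np.ndarray | None = None


@dataclasses.dataclass
class ImpliedTimescalesTable:
    lags: np.ndarray
    timescales: np.ndarray           # (n_lags, n_processes); NaN unresolved
    resolved: np.ndarray             # bool, t_i > lag and eigenvalue in (0,1)


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------

def cluster_microstates(coords: np.ndarray, k: int, seed: int,
                        trajectory_boundaries=None) -> MicrostateAssignment:
    """k-means with plus-plus seeding; deterministic under ``seed``.

    Duplicate-heavy data is guarded: k is reduced to the number of distinct
    points when necessary.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of frames {x.shape[0]}")
    n_unique = np.unique(x, axis=0).shape[0]
    k_eff = min(k, n_unique)
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=3,
                random_state=seed).fit(x)
    bounds = (np.array([0]) if trajectory_boundaries is None
              else np.asarray(trajectory_boundaries, dtype=int))
    return MicrostateAssignment(labels=km.labels_.astype(np.int64),
                                centers=km.cluster_centers_, k=k_eff,
                                seed=seed, trajectory_boundaries=bounds,
                                inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Transition counting and estimation
# ---------------------------------------------------------------------------

def count_transitions(labels_list, n_states: int, lag: int,
                      sliding: bool = True) -> np.ndarray:
    """Sliding-window (or strided) transition counts within each trajectory."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    counts = np.zeros((n_states, n_states))
    for labels in labels_list:
        labels = np.asarray(labels)
        if labels.size <= lag:
            continue
        step = 1 if sliding else lag
        a = labels[:-lag:step]
        b = labels[lag::step]
        np.add.at(counts, (a, b), 1.0)
    return counts


def largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Microstates of the largest strongly connected component of the count
    graph (edges where counts > 0)."""
    n_comp, assign = connected_components(csr_matrix(counts > 0),
                                          directed=True, connection="strong")
    sizes = np.bincount(assign, weights=counts.sum(axis=1) + counts.sum(axis=0))
    return np.nonzero(assign == np.argmax(sizes))[0]


def _reversible_mle(counts: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 10_000) -> np.ndarray:
    """Detailed-balance maximum-likelihood transition matrix via the
    standard self-consistent iteration on the symmetrised count variables."""
    c = np.asarray(counts, dtype=float)
    c_sym = c + c.T
    row = c.sum(axis=1)
    x = c_sym.copy()
    x /= x.sum()
    for _ in range(max_iter):
        xs = x.sum(axis=1)
        denom = row[:, None] / xs[:, None] + row[None, :] / xs[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    t = x / x.sum(axis=1)[:, None]
    return t


def estimate_transition_matrix(assignment: MicrostateAssignment, lag: int,
                               mode: str = "reversible",
                               sliding: bool = True) -> TransitionModel:
    """Estimate the row-stochastic transition matrix on the largest
    connected set.  ``mode='reversible'`` (default) enforces detailed
    balance by iterative maximum likelihood; ``mode='counts'`` row-normalizes
    the raw counts."""
    if mode not in ("counts", "reversible"):
        raise ValueError("mode must be 'counts' or 'reversible'")
    labels_list = assignment.split_labels()
    counts = count_transitions(labels_list, assignment.k, lag, sliding)
    if counts.sum() == 0:
        raise ValueError(f"no transition pairs at lag {lag}")
    active = largest_connected_set(counts)
    if active.size == 0:
        raise ValueError("empty connected set")
    sub = counts[np.ix_(active, active)]
    if mode == "reversible":
        t = _reversible_mle(sub)
    else:
        rows = sub.sum(axis=1)
        rows[rows == 0] = 1.0
        t = sub / rows[:, None]
    evals = np.linalg.eigvals(t)
    order = np.argsort(-np.real(evals))
    evals = evals[order]
    if np.allclose(np.imag(evals), 0, atol=1e-10):
        evals = np.real(evals)
    pi = _stationary(t)
    in_active = np.isin(assignment.labels, active)
    return TransitionModel(
        lag=lag, counts=counts, transition_matrix=t, active_set=active,
        eigenvalues=evals, stationary=pi, reversible=(mode == "reversible"),
        discarded_frame_fraction=float(1.0 - in_active.mean()))


def _stationary(t: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(t.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(np.real(v[:, idx]))
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Implied timescales, lag and macrostate-count selection
# ---------------------------------------------------------------------------

def implied_timescales(assignment: MicrostateAssignment, lag_grid,
                       n_processes: int = 5,
                       mode: str = "reversible") -> ImpliedTimescalesTable:
    """t_i(tau) = -tau / ln lambda_i(tau) for the non-stationary processes.

    Complex, negative or >=1 eigenvalues are flagged unresolved (NaN)."""
    lags = np.asarray(list(lag_grid), dtype=int)
    if np.any(lags < 1):
        raise ValueError("all lags must be >= 1")
    ts = np.full((lags.size, n_processes), np.nan)
    resolved = np.zeros((lags.size, n_processes), dtype=bool)
    for li, lag in enumerate(lags):
        model = estimate_transition_matrix(assignment, int(lag), mode=mode)
        evs = model.eigenvalues[1:n_processes + 1]
        for pi_, lam in enumerate(np.atleast_1d(evs)):
            if np.iscomplexobj(lam) and abs(np.imag(lam)) > 1e-12:
                continue
            lam = float(np.real(lam))
            if 0.0 < lam < 1.0:
                t = -lag / np.log(lam)
                ts[li, pi_] = t
                resolved[li, pi_] = t > lag
            elif lam >= 1.0:
                ts[li, pi_] = np.inf
    return ImpliedTimescalesTable(lags=lags, timescales=ts, resolved=resolved)


def timescales_from_eigenvalues(eigenvalues: np.ndarray, lag: int) -> np.ndarray:
    """-tau/ln(lambda) for real lambda in (0,1); inf for lambda >= 1, NaN else."""
    evs = np.atleast_1d(eigenvalues)
    out = np.full(evs.shape, np.nan)
    for i, lam in enumerate(evs):
        if np.iscomplexobj(lam) and abs(np.imag(lam)) > 1e-12:
            continue
        lam = float(np.real(lam))
        if lam >= 1.0:
            out[i] = np.inf
        elif lam > 0.0:
            out[i] = -lag / np.log(lam)
    return out


def select_lag(table: ImpliedTimescalesTable,
               rel_change: float = 0.10) -> int:
    """Smallest lag at which the slowest implied timescale changes by less
    than ``rel_change`` over a doubling of the lag (quantitative form of the
    'levels off' criterion); falls back to the largest lag in the grid."""
    lags, ts = table.lags, table.timescales[:, 0]
    for i, lag in enumerate(lags):
        target = 2 * lag
        j = np.searchsorted(lags, target)
        if j >= lags.size:
            break
        if not (np.isfinite(ts[i]) and np.isfinite(ts[j])) or ts[i] == 0:
            continue
        if abs(ts[j] - ts[i]) / ts[i] < rel_change:
            return int(lag)
    return int(lags[-1])


def select_n_macrostates(timescales: np.ndarray, max_states: int = 10) -> int:
    """Macrostate count from the largest gap ratio t_i / t_{i+1} among the
    resolved processes: a gap after the (K-1)-th slow process yields K."""
    ts = np.asarray(timescales, dtype=float)
    ts = ts[np.isfinite(ts)]
    if ts.size < 2:
        return 2
    ratios = ts[:-1] / ts[1:]
    limit = min(ratios.size, max_states - 1)
    best = int(np.argmax(ratios[:limit]))
    return best + 2


# ---------------------------------------------------------------------------
# VAMP-2 score
# ---------------------------------------------------------------------------

def vamp2_score(labels_or_assignment, lag: int, n_processes: int = 10,
                epsilon: float = 1e-10) -> float:
    """Sum of squared singular values of the half-weighted Koopman operator
    estimated from microstate indicator features.

    >= 1 always (the constant singular function); -> n for an n-block
    perfectly metastable process; -> 1 for i.i.d. labels."""
    if isinstance(labels_or_assignment, MicrostateAssignment):
        labels_list = labels_or_assignment.split_labels()
        n = labels_or_assignment.k
    else:
        labels_list = [np.asarray(labels_or_assignment)]
        n = int(max(l.max() for l in labels_list)) + 1
    if lag < 1:
        raise ValueError("lag must be >= 1")
    pairs_a, pairs_b = [], []
    for labels in labels_list:
        if labels.size > lag:
            pairs_a.append(labels[:-lag])
            pairs_b.append(labels[lag:])
    if not pairs_a:
        raise ValueError("too few transition pairs for VAMP-2 at this lag")
    a = np.concatenate(pairs_a)
    b = np.concatenate(pairs_b)
    m = a.size
    # covariance matrices of indicator features (diagonal C00/C11)
    c00 = np.bincount(a, minlength=n) / m
    c11 = np.bincount(b, minlength=n) / m
    c01 = np.zeros((n, n))
    np.add.at(c01, (a, b), 1.0 / m)
    s0 = np.where(c00 > epsilon, 1.0 / np.sqrt(c00), 0.0)
    s1 = np.where(c11 > epsilon, 1.0 / np.sqrt(c11), 0.0)
    koop = s0[:, None] * c01 * s1[None, :]
    sv = np.linalg.svd(koop, compute_uv=False)
    sv = np.clip(sv, 0.0, 1.0)
    return float(np.sum(sv[:n_processes] ** 2))


# ---------------------------------------------------------------------------
# PCCA+ coarse graining
# ---------------------------------------------------------------------------

def pcca_coarse_grain(model: TransitionModel,
                      n_macrostates: int) -> MacrostateModel:
    """Fuzzy macrostate memberships by the PCCA+ spectral simplex
    transformation of the dominant eigenvectors of a reversible transition
    matrix."""
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible transition matrix; "
                         "estimate with mode='reversible'")
    t = model.transition_matrix
    m_states = t.shape[0]
    mm = int(n_macrostates)
    if mm < 1 or mm > m_states:
        raise ValueError("n_macrostates out of range")
    if mm == m_states:
        chi = np.eye(m_states)
    else:
        chi = _pcca_memberships(t, model.stationary, mm)
    crisp = np.argmax(chi, axis=1)
    pops = chi.T @ model.stationary
    pops = pops / pops.sum()
    return MacrostateModel(n_macrostates=mm, memberships=chi,
                           crisp_map=crisp, populations=pops)


def _pcca_memberships(t: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    """Inner-simplex PCCA+ algorithm on the dominant right eigenvectors."""
    # symmetrised spectral problem for a numerically real spectrum
    sp = np.sqrt(pi)
    sym = (sp[:, None] * t) / sp[None, :]
    sym = 0.5 * (sym + sym.T)
    w, v = np.linalg.eigh(sym)
    order = np.argsort(-w)
    # right eigenvectors of T, pi-orthonormal
    x = v[:, order[:m]] / sp[:, None]
    x /= np.sign(x[0, 0]) if x[0, 0] != 0 else 1.0
    x[:, 0] = 1.0  # constant eigenvector, fixed sign
    # inner simplex: find m rows spanning the simplex
    idx = np.zeros(m, dtype=int)
    ortho = x.copy()
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - x[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        vj = ortho[idx[j]].copy()
        nj = vj @ vj
        if nj > 0:
            ortho = ortho - np.outer(ortho @ vj, vj) / nj
    a = np.linalg.inv(x[idx])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1)[:, None]
    return chi


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

def ck_test(assignment: MicrostateAssignment, lag: int, multiples,
            n_macrostates: int) -> dict:
    """Compare macrostate self-transition probabilities predicted by
    T(tau)^m against those re-estimated at lag m*tau.

    Returns {'multiples', 'predicted', 'estimated', 'deviation', 'flags'};
    predicted/estimated are (n_multiples, M) self-transition curves.  m=1
    deviates by exactly 0 by construction."""
    multiples = np.asarray(list(multiples), dtype=int)
    if multiples.size < 1:
        raise ValueError("at least one multiple required")
    base = estimate_transition_matrix(assignment, lag, mode="reversible")
    macro = pcca_coarse_grain(base, n_macrostates)
    chi, pi = macro.memberships, base.stationary
    weights = chi * pi[:, None]                      # (m, M)

    def project(tmat, active):
        # restrict chi/pi to the states of this model's active set
        sel = np.searchsorted(base.active_set, active)
        ok = np.isin(active, base.active_set)
        w = weights[sel[ok]][:, :]
        tm = tmat[np.ix_(ok, ok)]
        col = chi[sel[ok]]
        num = w.T @ tm @ col                         # (M, M)
        den = w.sum(axis=0)[:, None]
        return num / den

    n_m = macro.n_macrostates
    predicted = np.full((multiples.size, n_m), np.nan)
    estimated = np.full((multiples.size, n_m), np.nan)
    flags = []
    t_base = base.transition_matrix
    for i, m in enumerate(multiples):
        t_pred = np.linalg.matrix_power(t_base, int(m))
        predicted[i] = np.diag(project(t_pred, base.active_set))
        try:
            re = estimate_transition_matrix(assignment, int(m) * lag,
                                            mode="reversible")
            estimated[i] = np.diag(project(re.transition_matrix, re.active_set))
            flags.append(True)
        except ValueError:
            flags.append(False)  # insufficient data at m * lag
    deviation = np.abs(predicted - estimated)
    return {"multiples": multiples, "predicted": predicted,
            "estimated": estimated, "deviation": deviation,
            "resolved": np.array(flags)}


# ---------------------------------------------------------------------------
# Mean first passage times
# ---------------------------------------------------------------------------

def mfpt(model: TransitionModel, source, target) -> float:
    """Mean first passage time (frames) from the source set to the target
    set, solved from the linear first-passage system
    h = 1 + T h on non-target states, h = 0 on the target.

    The source average is stationary-weighted.  Source == target gives 0;
    an unreachable target gives inf."""
    t = model.transition_matrix
    n = t.shape[0]
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if target.size == 0:
        raise ValueError("target set must be non-empty")
    h = np.zeros(n)
    rest = np.setdiff1d(np.arange(n), target)
    if rest.size:
        a = np.eye(rest.size) - t[np.ix_(rest, rest)]
        try:
            h[rest] = np.linalg.solve(a, np.ones(rest.size))
        except np.linalg.LinAlgError:
            return np.inf
        if np.any(h[rest] < -1e-8):
            return np.inf
    pi = model.stationary[source]
    if pi.sum() == 0:
        return float(np.mean(h[source]) * model.lag)
    return float((pi @ h[source]) / pi.sum() * model.lag)


def mfpt_matrix(model: TransitionModel, crisp_map: np.ndarray,
                n_macrostates: int) -> np.ndarray:
    """M x M matrix of macrostate MFPTs (frames), crisp state sets."""
    out = np.zeros((n_macrostates, n_macrostates))
    sets = [np.nonzero(crisp_map == s)[0] for s in range(n_macrostates)]
    for a in range(n_macrostates):
        for b in range(n_macrostates):
            if a == b or sets[a].size == 0 or sets[b].size == 0:
                continue
            out[a, b] = mfpt(model, sets[a], sets[b])
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _align_macrostates(ref_crisp: np.ndarray, crisp: np.ndarray,
                       pi: np.ndarray, n_macro: int) -> np.ndarray:
    """Permutation mapping bootstrap macrostate ids onto the reference ids
    by maximum stationary-weighted microstate overlap."""
    overlap = np.zeros((n_macro, n_macro))
    for s in range(n_macro):
        for r in range(n_macro):
            overlap[s, r] = pi[(crisp == s) & (ref_crisp == r)].sum()
    row, col = linear_sum_assignment(-overlap)
    perm = np.empty(n_macro, dtype=int)
    perm[row] = col
    return perm


def bootstrap_populations(label_trajectories, k: int, lag: int,
                          n_macrostates: int, n_iter: int = 10,
                          seed: int = 0) -> MacrostateModel:
    """Leave-one-out bootstrap: in each of ``n_iter`` iterations the model
    is rebuilt after eliminating one randomly selected trajectory; mean and
    std of macrostate populations and MFPTs are reported.

    Delete-one replicates scatter far less than independent samples would,
    so alongside the raw across-iteration std the jackknife standard error
    (std scaled by sqrt(n_trajectories - 1)) is reported; the latter is the
    statistically calibrated uncertainty."""
    trajs = [np.asarray(t) for t in label_trajectories]
    if len(trajs) < 2:
        raise ValueError("bootstrap requires at least 2 trajectories")
    rng = np.random.default_rng(seed)

    def build(traj_subset):
        labels = np.concatenate(traj_subset)
        bounds = np.cumsum([0] + [len(t) for t in traj_subset[:-1]])
        assign = MicrostateAssignment(
            labels=labels, centers=np.empty((k, 0)), k=k, seed=seed,
            trajectory_boundaries=np.asarray(bounds))
        model = estimate_transition_matrix(assign, lag, mode="reversible")
        macro = pcca_coarse_grain(model, n_macrostates)
        return model, macro

    ref_model, ref_macro = build(trajs)
    # crisp map on the full microstate space (inactive -> -1)
    def full_crisp(model, macro):
        out = np.full(k, -1, dtype=int)
        out[model.active_set] = macro.crisp_map
        return out

    ref_crisp = full_crisp(ref_model, ref_macro)
    pops, mfpts = [], []
    for _ in range(n_iter):
        drop = int(rng.integers(len(trajs)))
        subset = [t for i, t in enumerate(trajs) if i != drop]
        model, macro = build(subset)
        crisp = full_crisp(model, macro)
        pi_full = np.zeros(k)
        pi_full[model.active_set] = model.stationary
        perm = _align_macrostates(ref_crisp, crisp, pi_full, n_macrostates)
        p = np.zeros(n_macrostates)
        p[perm] = macro.populations
        pops.append(p)
        mm = mfpt_matrix(model, macro.crisp_map, n_macrostates)
        aligned = np.zeros_like(mm)
        aligned[np.ix_(perm, perm)] = mm
        mfpts.append(aligned)
    pops = np.array(pops)
    mfpts = np.array(mfpts)
    mean_pops = pops.mean(axis=0)
    mean_pops = mean_pops / mean_pops.sum()
    jack = np.sqrt(len(trajs) - 1.0)
    return MacrostateModel(
        n_macrostates=n_macrostates, memberships=ref_macro.memberships,
        crisp_map=ref_macro.crisp_map, populations=mean_pops,
        population_std=pops.std(axis=0),
        population_se=pops.std(axis=0) * jack,
        mfpt=mfpts.mean(axis=0), mfpt_std=mfpts.std(axis=0),
        mfpt_se=mfpts.std(axis=0) * jack)
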