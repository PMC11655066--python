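"""Beta-weighted variational autoencoder over the Ca-Ca distance features.

A symmetric dense VAE compresses the exclusion-filtered pairwise-distance
matrix into a low-dimensional (default 2-D) probabilistic latent space.  The
loss is

    L = reconstruction + beta * KL(q(z|x) || N(0, I)),

with mean-squared-error reconstruction on min-max-scaled inputs (sigmoid
output layer), tanh hidden activations, Glorot-uniform initialisation and
Adam.  The encoder parameterises a diagonal Gaussian posterior (mu, sigma);
training samples z = mu + sigma * eps, downstream projection uses the
posterior mean mu for reproducibility.

The reference architecture for a 140-residue chain is
[9453, 4096, 512, 128, 16] -> 2; for small synthetic feature counts the
hidden widths scale down (``BetaVaeArchitecture.scaled``).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import Adam, Dense, Sigmoid, Tanh, params_hash

KB_KJ_MOL_K = 0.008314462618  # kJ mol^-1 K^-1


@dataclasses.dataclass
class BetaVaeArchitecture:
    input_dim: int
    hidden_widths: tuple = (4096, 512, 128, 16)
    latent_dim: int = 2

    @classmethod
    def scaled(cls, input_dim: int, latent_dim: int = 2) -> "BetaVaeArchitecture":
        """Shrink the reference widths for small feature counts."""
        widths = [w for w in (4096, 512, 128, 16) if w < input_dim]
        if not widths:
            widths = [max(4, input_dim // 2)]
        if len(widths) < 2:
            widths = [max(widths[0], 32), 16]
        return cls(input_dim=input_dim, hidden_widths=tuple(widths),
                   latent_dim=latent_dim)


@dataclasses.dataclass
class TrainingConfig:
    beta: float = 1e-12
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 64
    split: float = 0.8          # train fraction
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 < self.split < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")


@dataclasses.dataclass
class LatentEmbedding:
    coordinates: np.ndarray     # (frames, latent_dim)
    mu: np.ndarray
    sigma: np.ndarray
    source: str                 # "posterior_mean" | "sampled"


@dataclasses.dataclass
class LossBreakdown:
    """Per-epoch loss history; total = reconstruction + beta * kl."""

    reconstruction: list
    kl: list
    total: list
    val_reconstruction: list
    val_kl: list
    val_total: list


# ---------------------------------------------------------------------------
# Elementary operations (exposed for direct testing)
# ---------------------------------------------------------------------------

def kl_divergence_diag_gaussian(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """KL(N(mu, diag sigma^2) || N(0, I)) per sample:
    0.5 * sum_d (sigma_d^2 + mu_d^2 - 1 - ln sigma_d^2).  Always >= 0."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    s2 = sigma**2
    return 0.5 * np.sum(s2 + mu**2 - 1.0 - np.log(s2), axis=-1)


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   epsilon: np.ndarray) -> np.ndarray:
    """z = mu + sigma * epsilon (elementwise)."""
    mu, sigma, epsilon = (np.asarray(a, dtype=float)
                          for a in (mu, sigma, epsilon))
    if not (mu.shape == sigma.shape == epsilon.shape):
        raise ValueError("mu, sigma, epsilon shapes must agree")
    return mu + sigma * epsilon


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error over all elements."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class BetaVae:
    def __init__(self, arch: BetaVaeArchitecture, config: TrainingConfig):
        self.arch = arch
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = [arch.input_dim, *arch.hidden_widths]
        self.enc = []
        for a, b in zip(widths[:-1], widths[1:]):
            self.enc.append(Dense(a, b, rng))
            self.enc.append(Tanh())
        self.mu_head = Dense(widths[-1], arch.latent_dim, rng)
        self.logvar_head = Dense(widths[-1], arch.latent_dim, rng)
        self.dec = []
        rev = [arch.latent_dim, *widths[:0:-1]]
        for a, b in zip(rev[:-1], rev[1:]):
            self.dec.append(Dense(a, b, rng))
            self.dec.append(Tanh())
        self.dec.append(Dense(widths[1], arch.input_dim, rng))
        self.dec.append(Sigmoid())
        # replace the last hidden->input transition properly: decoder layers
        # above already mirror encoder (latent -> 16 -> ... -> 4096 -> input)
        self._layers = [*self.enc, self.mu_head, self.logvar_head, *self.dec]
        self._rng = rng
        self.trained = False

    # -- forward passes -----------------------------------------------------
    def _encode_hidden(self, x):
        h = x
        for layer in self.enc:
            h = layer.forward(h)
        return h

    def encode_params(self, x):
        h = self._encode_hidden(x)
        mu = self.mu_head.forward(h)
        logvar = self.logvar_head.forward(h)
        return mu, logvar

    def decode(self, z):
        h = z
        for layer in self.dec:
            h = layer.forward(h)
        return h

    # -- training -----------------------------------------------------------
    def _step(self, x, opt):
        n, beta = x.shape[0], self.config.beta
        mu, logvar = self.encode_params(x)
        sigma = np.exp(0.5 * logvar)
        eps = self._rng.standard_normal(mu.shape)
        z = reparameterize(mu, sigma, eps)
        xhat = self.decode(z)

        recon = float(np.mean((xhat - x) ** 2))
        kl = float(np.mean(kl_divergence_diag_gaussian(mu, sigma)))

        # backward
        g = 2.0 * (xhat - x) / (x.size)
        for layer in reversed(self.dec):
            g = layer.backward(g)
        # g is now dL/dz; route through the reparameterisation
        dmu = g.copy()
        dlogvar = g * sigma * eps * 0.5
        # KL gradients (mean over batch)
        dmu += beta * mu / n
        dlogvar += beta * 0.5 * (np.exp(logvar) - 1.0) / n
        gh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        for layer in reversed(self.enc):
            gh = layer.backward(gh)
        opt.step([g for layer in self._layers for g in layer.grads])
        return recon, kl

    def _eval(self, x):
        mu, logvar = self.encode_params(x)
        sigma = np.exp(0.5 * logvar)
        xhat = self.decode(mu)
        recon = float(np.mean((xhat - x) ** 2))
        kl = float(np.mean(kl_divergence_diag_gaussian(mu, sigma)))
        return recon, kl

    def fit(self, features: np.ndarray) -> LossBreakdown:
        """Train on min-max-scaled features; records per-epoch train and
        validation losses.  Aborts with a diagnostic on NaN loss."""
        x = np.asarray(features, dtype=float)
        if x.min() < -1e-9 or x.max() > 1.0 + 1e-9:
            raise ValueError("features must be scaled to [0, 1] "
                             "(sigmoid output range)")
        cfg = self.config
        split_rng = np.random.default_rng(cfg.seed + 1)
        order = split_rng.permutation(x.shape[0])
        n_train = max(1, int(round(cfg.split * x.shape[0])))
        train, val = x[order[:n_train]], x[order[n_train:]]
        if val.shape[0] == 0:
            val = train
        params = [p for layer in self._layers for p in layer.params]
        opt = Adam(params, lr=cfg.learning_rate)
        hist = LossBreakdown([], [], [], [], [], [])
        for _ in range(cfg.epochs):
            perm = self._rng.permutation(train.shape[0])
            recs, kls = [], []
            for start in range(0, train.shape[0], cfg.batch_size):
                batch = train[perm[start:start + cfg.batch_size]]
                r, k = self._step(batch, opt)
                recs.append(r)
                kls.append(k)
            er, ek = float(np.mean(recs)), float(np.mean(kls))
            if not np.isfinite(er):
                raise FloatingPointError(
                    "NaN/inf training loss: lower the learning rate "
                    f"(lr={cfg.learning_rate}) or beta ({cfg.beta})")
            vr, vk = self._eval(val)
            hist.reconstruction.append(er)
            hist.kl.append(ek)
            hist.total.append(er + cfg.beta * ek)
            hist.val_reconstruction.append(vr)
            hist.val_kl.append(vk)
            hist.val_total.append(vr + cfg.beta * vk)
        self.trained = True
        self.history = hist
        return hist

    # -- inference ----------------------------------------------------------
    def encode(self, features: np.ndarray,
               sampled: bool = False, seed: int = 0) -> LatentEmbedding:
        x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.arch.input_dim:
            raise ValueError(
                f"feature dimension {x.shape} does not match architecture "
                f"input {self.arch.input_dim}")
        mu, logvar = self.encode_params(x)
        sigma = np.exp(0.5 * logvar)
        if sampled:
            eps = np.random.default_rng(seed).standard_normal(mu.shape)
            coords, source = reparameterize(mu, sigma, eps), "sampled"
        else:
            coords, source = mu, "posterior_mean"
        return LatentEmbedding(coordinates=coords, mu=mu, sigma=sigma,
                               source=source)

    def reconstruct(self, features: np.ndarray) -> np.ndarray:
        emb = self.encode(features)
        return self.decode(emb.mu)

    def weights_hash(self) -> str:
        return params_hash(self._layers)


def train(features: np.ndarray, arch: BetaVaeArchitecture,
          config: TrainingConfig) -> tuple[BetaVae, LossBreakdown]:
    model = BetaVae(arch, config)
    hist = model.fit(features)
    return model, hist


def scan_beta(features: np.ndarray, arch: BetaVaeArchitecture,
              beta_values, config: TrainingConfig):
    """Train one model per beta on the same split/seed; select the beta with
    minimum test-set RMSE between original and reconstructed data.

    Returns (table, selected_beta, best_model) where table is a list of
    (beta, rmse-or-None) rows; per-beta training failures are recorded and
    the scan continues.
    """
    betas = list(beta_values)
    if len(betas) < 1:
        raise ValueError("at least one beta value required")
    x = np.asarray(features, dtype=float)
    split_rng = np.random.default_rng(config.seed + 1)
    order = split_rng.permutation(x.shape[0])
    n_train = max(1, int(round(config.split * x.shape[0])))
    test = x[order[n_train:]]
    if test.shape[0] == 0:
        test = x
    table = []
    best = (None, np.inf, None)
    for beta in betas:
        cfg = dataclasses.replace(config, beta=beta)
        try:
            model, _ = train(x, arch, cfg)
            err = rmse(test, model.reconstruct(test))
            table.append((beta, err))
            if err < best[1]:
                best = (beta, err, model)
        except FloatingPointError:  # record the failure, continue the scan
            table.append((beta, None))
    if best[0] is None:
        raise RuntimeError("every beta in the scan failed to train")
    return table, best[0], best[2]


def default_beta_grid(n: int = 6) -> np.ndarray:
    """Log grid spanning the scan range endpoints 5 .. 1e-15."""
    return np.geomspace(5.0, 1e-15, n)


def free_energy_landscape(embedding: LatentEmbedding, bins: int = 50,
                          temperature: float = 300.0):
    """2-D free-energy surface -kB T ln(p / p_max) from latent histograms.

    Returns (surface, x_edges, y_edges); empty bins are masked (NaN); the
    minimum of the populated surface is exactly 0.  Energy unit kJ/mol.
    """
    coords = embedding.coordinates
    if coords.shape[1] != 2:
        raise ValueError("free-energy landscape requires a 2-D latent space")
    n_bins = bins if np.ndim(bins) == 0 else max(np.shape(bins))
    if coords.shape[0] < n_bins:
        import warnings

        warnings.warn("fewer frames than bins; landscape will be sparse")
    h, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins)
    p = h / h.sum()
    surface = np.full_like(p, np.nan)
    occ = p > 0
    surface[occ] = -KB_KJ_MOL_K * temperature * np.log(p[occ] / p[occ].max())
    return surface, xe, ye
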