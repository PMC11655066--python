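"""Contact-map fingerprinting with a denoising convolutional VAE.

Macrostate contact maps are corrupted with Gaussian noise (standard-normal
draws scaled by a noise factor, default 0.035, then min-max rescaled to
[0, 1]), and a convolutional VAE is trained to reconstruct the *clean* map
from the noisy replica.  Denoising fidelity is scored with SSIM (global,
single-window, luminance x contrast x structure with the conventional
stabilising constants k1=0.01, k2=0.03, C3=C2/2) and PSNR
(10 log10(R^2/MSE) with R=255, maps rescaled to 8-bit range for PSNR only).
The trained model's 2-D latent space assigns each macrostate's replica
cloud a distinct location, fingerprinting the state.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import (Adam, Conv2D, ConvTranspose2D, Dense, Sigmoid, Tanh,
                  params_hash)
from .featurize import minmax_scale
from .bvae import kl_divergence_diag_gaussian, reparameterize

SSIM_K1 = 0.01
SSIM_K2 = 0.03
PSNR_R = 255.0
DEFAULT_NOISE_FACTOR = 0.035
DEFAULT_REPLICAS = 200


# ---------------------------------------------------------------------------
# Similarity metrics
# ---------------------------------------------------------------------------

def ssim(x: np.ndarray, y: np.ndarray, dynamic_range: float = 1.0,
         alpha: float = 1.0, beta: float = 1.0, gamma: float = 1.0) -> float:
    """Global (single-window) structural similarity index.

    SSIM = l^alpha * c^beta * s^gamma with
    l = (2 mx my + C1)/(mx^2 + my^2 + C1),
    c = (2 sx sy + C2)/(sx^2 + sy^2 + C2),
    s = (sxy + C3)/(sx sy + C3),
    C1 = (k1 L)^2, C2 = (k2 L)^2, C3 = C2/2.  Result in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ssim: shape mismatch")
    c1 = (SSIM_K1 * dynamic_range) ** 2
    c2 = (SSIM_K2 * dynamic_range) ** 2
    c3 = c2 / 2.0
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    sxy = ((x - mx) * (y - my)).mean()
    lum = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
    con = (2 * sx * sy + c2) / (sx**2 + sy**2 + c2)
    stru = (sxy + c3) / (sx * sy + c3)
    return float(lum**alpha * con**beta * stru**gamma)


def ssim_windowed(x: np.ndarray, y: np.ndarray, window: int = 7,
                  dynamic_range: float = 1.0) -> float:
    """Mean of global SSIM over sliding square windows (variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ssim: shape mismatch")
    h, w = x.shape
    vals = []
    for i in range(0, max(1, h - window + 1)):
        for j in range(0, max(1, w - window + 1)):
            vals.append(ssim(x[i:i + window, j:j + window],
                             y[i:i + window, j:j + window],
                             dynamic_range=dynamic_range))
    return float(np.mean(vals))


def psnr(original: np.ndarray, denoised: np.ndarray,
         r: float = PSNR_R, assume_unit_range: bool = True) -> float:
    """Peak signal-to-noise ratio, 10 log10(R^2 / MSE), in decibels.

    Maps living in [0, 1] are rescaled to the 8-bit range [0, R] before the
    MSE (``assume_unit_range``); identical inputs return +inf.
    """
    o = np.asarray(original, dtype=float)
    d = np.asarray(denoised, dtype=float)
    if o.shape != d.shape:
        raise ValueError("psnr: shape mismatch")
    if assume_unit_range:
        o, d = o * r, d * r
    mse = float(np.mean((o - d) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(r**2 / mse))


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NoisyMapSet:
    originals: np.ndarray    # (S, H, W) clean maps in [0, 1]
    replicas: np.ndarray     # (S, n_replicas, H, W) noisy, rescaled to [0, 1]
    state_of: np.ndarray     # (S * n_replicas,) state index per flat replica
    noise_factor: float
    seed: int


def add_noise(maps: np.ndarray, noise_factor: float = DEFAULT_NOISE_FACTOR,
              n_replicas: int = DEFAULT_REPLICAS, seed: int = 0) -> NoisyMapSet:
    """replica = map + noise_factor * N(0,1) elementwise, then min-max
    rescaled to [0, 1] (per replica)."""
    if noise_factor < 0:
        raise ValueError("noise_factor must be >= 0")
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.min() < -1e-12 or maps.max() > 1 + 1e-12:
        raise ValueError("maps must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s, h, w = maps.shape
    reps = maps[:, None] + noise_factor * rng.standard_normal(
        (s, n_replicas, h, w))
    flat = reps.reshape(s * n_replicas, h * w)
    scaled, _ = minmax_scale(flat.T, per_feature=True)  # per-replica min-max
    reps = scaled.T.reshape(s, n_replicas, h, w)
    state_of = np.repeat(np.arange(s), n_replicas)
    return NoisyMapSet(originals=maps, replicas=reps, state_of=state_of,
                       noise_factor=noise_factor, seed=seed)


# ---------------------------------------------------------------------------
# Denoising convolutional VAE
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DcvaeArchitecture:
    """Reference: conv filters (16, 32, 64, 96, 128) with 3x3 kernels and
    strides (1, 2, 2, 2, 2), dense widths (4096, 2048, 1024, 256, 64, 16),
    2-D latent.  ``scaled`` shrinks both stacks for small synthetic maps."""

    conv_filters: tuple = (16, 32, 64, 96, 128)
    conv_strides: tuple = (1, 2, 2, 2, 2)
    dense_widths: tuple = (4096, 2048, 1024, 256, 64, 16)
    latent_dim: int = 2

    @classmethod
    def scaled(cls, map_size: int, latent_dim: int = 2) -> "DcvaeArchitecture":
        if map_size >= 64:
            return cls(latent_dim=latent_dim)
        return cls(conv_filters=(8, 16, 16), conv_strides=(1, 2, 2),
                   dense_widths=(128, 32), latent_dim=latent_dim)


@dataclasses.dataclass
class DcvaeTrainingConfig:
    beta: float = 1e-12
    learning_rate: float = 5e-4
    epochs: int = 300
    batch_size: int = 32
    split: float = 0.9
    seed: int = 0


class _Flatten:
    """(N,C,H,W) <-> (N, C*H*W) bridge with a symmetric backward."""

    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class _Unflatten:
    params: list = []
    grads: list = []

    def __init__(self, chw):
        self._chw = chw

    def forward(self, x):
        return x.reshape(x.shape[0], *self._chw)

    def backward(self, g):
        return g.reshape(g.shape[0], -1)


class Dcvae:
    """Convolutional VAE trained on (noisy -> clean) contact-map pairs."""

    def __init__(self, map_size: int, arch: DcvaeArchitecture,
                 config: DcvaeTrainingConfig):
        self.arch, self.config, self.map_size = arch, config, map_size
        rng = np.random.default_rng(config.seed)
        # encoder convs, recording the shape chain for the mirrored decoder
        self.enc_layers = []
        shapes = [(map_size, map_size)]
        c_prev = 1
        h = w = map_size
        for f, s in zip(arch.conv_filters, arch.conv_strides):
            conv = Conv2D(c_prev, f, 3, s, rng)
            h, w = conv.out_shape(h, w)
            shapes.append((h, w))
            self.enc_layers += [conv, Tanh()]
            c_prev = f
        self._conv_out = (c_prev, h, w)
        flat = c_prev * h * w
        self.enc_layers.append(_Flatten())
        widths = [flat] + [d for d in arch.dense_widths if d < flat]
        if len(widths) == 1:
            widths.append(max(8, flat // 4))
        for a, b in zip(widths[:-1], widths[1:]):
            self.enc_layers += [Dense(a, b, rng), Tanh()]
        self.mu_head = Dense(widths[-1], arch.latent_dim, rng)
        self.logvar_head = Dense(widths[-1], arch.latent_dim, rng)
        # decoder: mirrored dense stack then mirrored conv-transpose stack
        self.dec_layers = []
        rev = [arch.latent_dim] + widths[::-1]
        for a, b in zip(rev[:-1], rev[1:]):
            self.dec_layers += [Dense(a, b, rng), Tanh()]
        self.dec_layers.append(_Unflatten(self._conv_out))
        filters_rev = (1,) + tuple(arch.conv_filters[:-1])
        for i in range(len(arch.conv_filters) - 1, -1, -1):
            convt = ConvTranspose2D(arch.conv_filters[i], filters_rev[i], 3,
                                    arch.conv_strides[i], shapes[i], rng)
            self.dec_layers.append(convt)
            self.dec_layers.append(Tanh() if i > 0 else Sigmoid())
        self._layers = [l for l in
                        [*self.enc_layers, self.mu_head, self.logvar_head,
                         *self.dec_layers] if l.params]
        self._rng = rng
        self.trained = False
        self.history = None

    # -- forward ------------------------------------------------------------
    def _enc(self, x_img):
        h = x_img[:, None, :, :]
        for layer in self.enc_layers:
            h = layer.forward(h)
        return self.mu_head.forward(h), self.logvar_head.forward(h)

    def _dec(self, z):
        h = z
        for layer in self.dec_layers:
            h = layer.forward(h)
        return h[:, 0, :, :]

    def _backward(self, g_img, dmu_extra, dlogvar_extra, sigma, eps):
        g = g_img[:, None, :, :]
        for layer in reversed(self.dec_layers):
            g = layer.backward(g)
        # g is dL/dz
        dmu = g + dmu_extra
        dlogvar = g * sigma * eps * 0.5 + dlogvar_extra
        gh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        for layer in reversed(self.enc_layers):
            gh = layer.backward(gh)

    # -- training -----------------------------------------------------------
    def fit(self, noisy: np.ndarray, clean: np.ndarray):
        """Train on noisy inputs against clean targets.  Returns the loss
        history dict with train/test reconstruction, KL and totals."""
        noisy = np.asarray(noisy, dtype=float)
        clean = np.asarray(clean, dtype=float)
        cfg = self.config
        rng_split = np.random.default_rng(cfg.seed + 1)
        order = rng_split.permutation(noisy.shape[0])
        n_train = max(1, int(round(cfg.split * noisy.shape[0])))
        tr, te = order[:n_train], order[n_train:]
        if te.size == 0:
            te = tr
        params = [p for layer in self._layers for p in layer.params]
        opt = Adam(params, lr=cfg.learning_rate)
        hist = {"reconstruction": [], "kl": [], "total": [],
                "test_reconstruction": [], "test_kl": [], "test_total": []}
        for _ in range(cfg.epochs):
            perm = self._rng.permutation(tr.size)
            recs, kls = [], []
            for start in range(0, tr.size, cfg.batch_size):
                sel = tr[perm[start:start + cfg.batch_size]]
                x, target = noisy[sel], clean[sel]
                mu, logvar = self._enc(x)
                sigma = np.exp(0.5 * logvar)
                eps = self._rng.standard_normal(mu.shape)
                z = reparameterize(mu, sigma, eps)
                out = self._dec(z)
                recon = float(np.mean((out - target) ** 2))
                kl = float(np.mean(kl_divergence_diag_gaussian(mu, sigma)))
                if not np.isfinite(recon):
                    raise FloatingPointError(
                        "NaN/inf DCVAE loss: reduce learning rate "
                        f"(lr={cfg.learning_rate}) or beta ({cfg.beta})")
                g = 2.0 * (out - target) / out.size
                n_b = x.shape[0]
                self._backward(g, cfg.beta * mu / n_b,
                               cfg.beta * 0.5 * (np.exp(logvar) - 1.0) / n_b,
                               sigma, eps)
                opt.step([gr for layer in self._layers for gr in layer.grads])
                recs.append(recon)
                kls.append(kl)
            er, ek = float(np.mean(recs)), float(np.mean(kls))
            tr_r, tr_k = er, ek
            te_r, te_k = self._eval(noisy[te], clean[te])
            hist["reconstruction"].append(tr_r)
            hist["kl"].append(tr_k)
            hist["total"].append(tr_r + cfg.beta * tr_k)
            hist["test_reconstruction"].append(te_r)
            hist["test_kl"].append(te_k)
            hist["test_total"].append(te_r + cfg.beta * te_k)
        self.trained = True
        self.history = hist
        return hist

    def _eval(self, noisy, clean):
        mu, logvar = self._enc(noisy)
        sigma = np.exp(0.5 * logvar)
        out = self._dec(mu)
        return (float(np.mean((out - clean) ** 2)),
                float(np.mean(kl_divergence_diag_gaussian(mu, sigma))))

    # -- inference ----------------------------------------------------------
    def denoise(self, maps: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model is not trained")
        mu, _ = self._enc(np.asarray(maps, dtype=float))
        return self._dec(mu)

    def project_latent(self, maps: np.ndarray) -> np.ndarray:
        """Posterior-mean 2-D coordinates for each map."""
        if not self.trained:
            raise RuntimeError("model is not trained")
        mu, _ = self._enc(np.asarray(maps, dtype=float))
        return mu

    def weights_hash(self) -> str:
        return params_hash(self._layers)


def train_dcvae(noisy_set: NoisyMapSet,
                arch: DcvaeArchitecture | None = None,
                config: DcvaeTrainingConfig | None = None):
    """Train a DCVAE on a NoisyMapSet (noisy replicas -> clean originals).

    Returns (model, history, heldout) where ``heldout`` carries the held-out
    replica indices of the split for downstream scoring.
    """
    config = config or DcvaeTrainingConfig()
    s, n_rep, h, w = noisy_set.replicas.shape
    arch = arch or DcvaeArchitecture.scaled(h)
    noisy = noisy_set.replicas.reshape(s * n_rep, h, w)
    clean = noisy_set.originals[noisy_set.state_of]
    model = Dcvae(h, arch, config)
    rng_split = np.random.default_rng(config.seed + 1)
    order = rng_split.permutation(noisy.shape[0])
    n_train = max(1, int(round(config.split * noisy.shape[0])))
    heldout = order[n_train:]
    hist = model.fit(noisy, clean)
    return model, hist, heldout


def fingerprint_report(model: Dcvae, noisy_set: NoisyMapSet,
                       heldout: np.ndarray) -> dict:
    """Score denoising on the held-out split and fingerprint the states.

    Returns per-state SSIM/PSNR for noisy and denoised replicas, the mean
    SSIM gain, the 2-D latent embedding of all replicas and the silhouette
    score of the ground-truth state labels in that space.
    """
    from sklearn.metrics import silhouette_score

    s, n_rep, h, w = noisy_set.replicas.shape
    noisy = noisy_set.replicas.reshape(s * n_rep, h, w)
    states = noisy_set.state_of
    if heldout.size == 0:
        heldout = np.arange(noisy.shape[0])
    den = model.denoise(noisy[heldout])
    rows = []
    for st in range(s):
        mask = states[heldout] == st
        if not np.any(mask):
            continue
        orig = noisy_set.originals[st]
        ssim_noisy = np.mean([ssim(orig, m) for m in noisy[heldout][mask]])
        ssim_den = np.mean([ssim(orig, m) for m in den[mask]])
        psnr_noisy = np.mean([psnr(orig, m) for m in noisy[heldout][mask]])
        psnr_den = np.mean([psnr(orig, m) for m in den[mask]])
        rows.append({"state": st, "ssim_noisy": float(ssim_noisy),
                     "ssim_denoised": float(ssim_den),
                     "psnr_noisy": float(psnr_noisy),
                     "psnr_denoised": float(psnr_den)})
    emb = model.project_latent(noisy)
    sil = float(silhouette_score(emb, states)) if s > 1 else np.nan
    gain = float(np.mean([r["ssim_denoised"] - r["ssim_noisy"] for r in rows]))
    return {"per_state": rows, "ssim_gain": gain,
            "latent": emb, "silhouette": sil}
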