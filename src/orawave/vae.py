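"""A compact variational autoencoder for 400-sample applanation waveforms.

Architecture (mirrored encoder/decoder multilayer perceptrons):

    encoder: 400 -> 40 -> 20 -> (mu, logvar) in R^2
    decoder:   2 -> 20 -> 40 -> 400

The posterior is a diagonal 2-D Gaussian (2 means + 2 log-variances); hidden
layers are rectified-linear, outputs linear.  Traces are normalised by a
single constant (the maximum over the training set) so relative peak heights
are preserved.  The loss is the negative evidence lower bound with a
Gaussian decoder of fixed observation sd ``recon_sigma``:

    loss = mean_batch[ ||x - xhat||^2 / (2 sigma^2) ] + beta * mean_batch[KL],
    KL   = 1/2 sum_d (exp(logvar_d) + mu_d^2 - 1 - logvar_d).

``recon_sigma`` defaults to 0.01 — the order of the instrument's
high-frequency jitter on the normalised scale — which keeps the KL term a
regulariser rather than letting it collapse the posterior.  Optimisation is
adaptive-moment estimation (Adam) with the reparameterisation trick; all
randomness flows from one seed, so training is bit-reproducible.

Latent traversal: after fitting a least-squares axis PRAA ~ intercept +
w . mu over the cohort's posterior means, decoding points along that axis
animates how the waveform deforms as the retinal-artery angle changes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigError, DegenerateFitError, TrainingError

__all__ = [
    "VAEArch", "LatentCode", "VAEModel", "PraaAxis",
    "init_vae", "kl_standard_normal", "elbo_loss", "train_vae",
    "reconstruct", "fit_praa_axis", "traverse", "export_animation",
    "save_model", "load_model",
]

DEFAULT_RECON_SIGMA = 0.01


@dataclass(frozen=True)
class VAEArch:
    """Layer sizes; the decoder mirrors the encoder."""

    input_dim: int = 400
    encoder_hidden: Tuple[int, int] = (40, 20)
    latent_dim: int = 2

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        if self.input_dim < 1 or any(h < 1 for h in self.encoder_hidden):
            raise ConfigError("layer sizes must be positive")

    @property
    def decoder_hidden(self) -> Tuple[int, int]:
        return tuple(reversed(self.encoder_hidden))

    @property
    def n_parameters(self) -> int:
        h1, h2 = self.encoder_hidden
        d, z = self.input_dim, self.latent_dim
        enc = (d * h1 + h1) + (h1 * h2 + h2) + 2 * (h2 * z + z)  # mu and logvar heads
        dec = (z * h2 + h2) + (h2 * h1 + h1) + (h1 * d + d)
        return enc + dec


@dataclass
class LatentCode:
    """Diagonal-Gaussian posterior parameters for one trace."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.logvar = np.asarray(self.logvar, dtype=float)
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("LatentCode entries must be finite")


@dataclass(eq=False)
class VAEModel:
    arch: VAEArch
    params: Dict[str, np.ndarray]
    seed: int
    norm_const: Optional[float] = None
    trained: bool = False
    history: List[Dict[str, float]] = field(default_factory=list)
    latent_center: Optional[np.ndarray] = None
    latent_sd: Optional[np.ndarray] = None

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def init_vae(arch: VAEArch, seed: int) -> VAEModel:
    """Reproducible He/Xavier-style initialisation."""
    rng = np.random.default_rng(seed)
    h1, h2 = arch.encoder_hidden
    d, z = arch.input_dim, arch.latent_dim

    def layer(n_in: int, n_out: int, relu: bool) -> Tuple[np.ndarray, np.ndarray]:
        scale = np.sqrt((2.0 if relu else 1.0) / n_in)
        return rng.normal(0.0, scale, (n_in, n_out)), np.zeros(n_out)

    params: Dict[str, np.ndarray] = {}
    for name, (n_in, n_out, relu) in {
        "W1": (d, h1, True), "W2": (h1, h2, True),
        "Wm": (h2, z, False), "Wv": (h2, z, False),
        "U1": (z, h2, True), "U2": (h2, h1, True), "U3": (h1, d, False),
    }.items():
        W, b = layer(n_in, n_out, relu)
        params[name] = W
        params["b" + name[1:].lower() if name[0] == "W" else "c" + name[1:]] = b
    return VAEModel(arch=arch, params=params, seed=seed)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _encode(params: Dict[str, np.ndarray], x: np.ndarray):
    a1 = x @ params["W1"] + params["b1"]
    h1 = _relu(a1)
    a2 = h1 @ params["W2"] + params["b2"]
    h2 = _relu(a2)
    mu = h2 @ params["Wm"] + params["bm"]
    logvar = h2 @ params["Wv"] + params["bv"]
    return mu, logvar, (a1, h1, a2, h2)


def _decode(params: Dict[str, np.ndarray], z: np.ndarray):
    g1 = z @ params["U1"] + params["c1"]
    r1 = _relu(g1)
    g2 = r1 @ params["U2"] + params["c2"]
    r2 = _relu(g2)
    out = r2 @ params["U3"] + params["c3"]
    return out, (g1, r1, g2, r2)


def forward(model: VAEModel, x: np.ndarray) -> np.ndarray:
    """Deterministic pass: decode the posterior mean.  ``x`` is normalised."""
    mu, _, _ = _encode(model.params, np.atleast_2d(x))
    out, _ = _decode(model.params, mu)
    return out


def kl_standard_normal(code: Union[LatentCode, Tuple[np.ndarray, np.ndarray]]) -> float:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), in closed form.

    Equals ``1/2 sum_d (exp(logvar_d) + mu_d^2 - 1 - logvar_d)``; always
    >= 0 and 0 iff mu = 0, logvar = 0.
    """
    if not isinstance(code, LatentCode):
        code = LatentCode(*code)
    lv = code.logvar
    return float(0.5 * np.sum(np.exp(lv) + code.mu ** 2 - 1.0 - lv))


def elbo_loss(batch: np.ndarray, model: VAEModel, beta: float = 1.0,
              recon_sigma: float = DEFAULT_RECON_SIGMA) -> Tuple[float, float, float]:
    """(reconstruction, KL, total) for a batch of *normalised* traces.

    Deterministic evaluation: the decoder sees the posterior mean.  The
    reconstruction term is the Gaussian negative log-likelihood (constant
    dropped), ``||x - xhat||^2 / (2 sigma^2)`` averaged over the batch; the
    KL term is the batch mean of :func:`kl_standard_normal`; total =
    reconstruction + beta * KL.
    """
    x = np.atleast_2d(np.asarray(batch, dtype=float))
    if np.max(np.abs(x)) > 10.0:
        warnings.warn("input looks unnormalised (|value| > 10 after scaling)",
                      stacklevel=2)
    mu, logvar, _ = _encode(model.params, x)
    xhat, _ = _decode(model.params, mu)
    recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)) / (2.0 * recon_sigma ** 2))
    kl = float(np.mean(0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar,
                                    axis=1)))
    return recon, kl, recon + beta * kl


def train_vae(model: VAEModel, traces: np.ndarray, epochs: int = 500,
              batch_size: int = 16, learning_rate: float = 1e-3,
              seed: int = 0, beta: float = 1.0,
              recon_sigma: float = DEFAULT_RECON_SIGMA) -> VAEModel:
    """Train in place with Adam + the reparameterisation trick; returns the model.

    ``traces`` are raw (unnormalised); the model's normalisation constant is
    set to their maximum on first training.  ``epochs = 0`` is a no-op.
    Identical data + seed give bit-identical weights.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] != model.arch.input_dim:
        raise ConfigError(
            f"traces must have shape (n, {model.arch.input_dim}), "
            f"got {traces.shape}")
    if traces.shape[0] < 10:
        raise ValueError("need at least 10 traces to train")
    if epochs == 0:
        return model
    if model.norm_const is None:
        peak = float(np.max(np.abs(traces)))
        model.norm_const = peak if peak > 0 else 1.0
    X = traces / model.norm_const
    n = X.shape[0]
    p = model.params
    rng = np.random.default_rng(seed)
    inv_s2 = 1.0 / recon_sigma ** 2

    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v_) for k, v_ in p.items()}
    b1m, b2m, eps_adam = 0.9, 0.999, 1e-8
    step = 0

    for epoch in range(epochs):
        perm = rng.permutation(n)
        ep = {"recon": 0.0, "kl": 0.0}
        n_batches = 0
        for start in range(0, n, batch_size):
            xb = X[perm[start:start + batch_size]]
            B = xb.shape[0]
            mu, logvar, (a1, h1, a2, h2) = _encode(p, xb)
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + std * eps
            xhat, (g1, r1, g2, r2) = _decode(p, z)

            recon = np.sum((xb - xhat) ** 2) * inv_s2 / (2.0 * B)
            kl = 0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar) / B
            if not np.isfinite(recon + kl):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            ep["recon"] += recon
            ep["kl"] += kl
            n_batches += 1

            # ---- backward ----
            grads: Dict[str, np.ndarray] = {}
            dout = (xhat - xb) * inv_s2 / B                    # dL/dxhat
            grads["U3"] = r2.T @ dout
            grads["c3"] = dout.sum(0)
            dr2 = (dout @ p["U3"].T) * (g2 > 0)
            grads["U2"] = r1.T @ dr2
            grads["c2"] = dr2.sum(0)
            dr1 = (dr2 @ p["U2"].T) * (g1 > 0)
            grads["U1"] = z.T @ dr1
            grads["c1"] = dr1.sum(0)
            dz = dr1 @ p["U1"].T

            dmu = dz + beta * mu / B
            dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(logvar) - 1.0) / B
            grads["Wm"] = h2.T @ dmu
            grads["bm"] = dmu.sum(0)
            grads["Wv"] = h2.T @ dlv
            grads["bv"] = dlv.sum(0)
            dh2 = (dmu @ p["Wm"].T + dlv @ p["Wv"].T) * (a2 > 0)
            grads["W2"] = h1.T @ dh2
            grads["b2"] = dh2.sum(0)
            dh1 = (dh2 @ p["W2"].T) * (a1 > 0)
            grads["W1"] = xb.T @ dh1
            grads["b1"] = dh1.sum(0)

            step += 1
            corr1 = 1.0 - b1m ** step
            corr2 = 1.0 - b2m ** step
            for k, g in grads.items():
                m[k] = b1m * m[k] + (1 - b1m) * g
                v[k] = b2m * v[k] + (1 - b2m) * g * g
                p[k] = p[k] - learning_rate * (m[k] / corr1) / (
                    np.sqrt(v[k] / corr2) + eps_adam)

        rec, klm = ep["recon"] / n_batches, ep["kl"] / n_batches
        model.history.append({"epoch": epoch, "recon": rec, "kl": klm,
                              "total": rec + beta * klm})

    mu_all, _, _ = _encode(p, X)
    model.latent_center = mu_all.mean(axis=0)
    model.latent_sd = mu_all.std(axis=0)
    model.trained = True
    return model


def encode_traces(model: VAEModel, traces: np.ndarray) -> List[LatentCode]:
    """Posterior codes for raw traces (normalised internally)."""
    norm = model.norm_const or 1.0
    mu, logvar, _ = _encode(model.params, np.atleast_2d(traces) / norm)
    return [LatentCode(mu[i], logvar[i]) for i in range(mu.shape[0])]


def reconstruct(model: VAEModel, trace: np.ndarray) -> np.ndarray:
    """Denoised trace: decode the posterior mean, back on the raw scale."""
    if not model.trained:
        warnings.warn("reconstructing with an untrained model", stacklevel=2)
    norm = model.norm_const or 1.0
    single = np.asarray(trace).ndim == 1
    out = forward(model, np.atleast_2d(trace) / norm) * norm
    return out[0] if single else out


@dataclass(frozen=True)
class PraaAxis:
    """Latent direction along which predicted PRAA changes fastest."""

    direction: np.ndarray      # unit vector in latent space
    slope: float               # degrees per latent unit (>= 0)
    intercept: float           # degrees

    def predict(self, z: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * (np.atleast_2d(z) @ self.direction)


def fit_praa_axis(codes: Sequence[LatentCode], praa: Sequence[float]) -> PraaAxis:
    """Least squares PRAA ~ intercept + w . mu; direction = w/|w|, slope = |w|."""
    if len(codes) < 3:
        raise ValueError("need at least 3 eyes to fit the PRAA axis")
    M = np.vstack([c.mu for c in codes])
    y = np.asarray(praa, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("praa values must be finite")
    if np.max(np.ptp(M, axis=0)) == 0.0:
        raise DegenerateFitError("all latent means identical; axis undefined")
    A = np.column_stack([np.ones(len(y)), M])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    w = coef[1:]
    slope = float(np.linalg.norm(w))
    direction = w / slope if slope > 0 else np.eye(M.shape[1])[0]
    return PraaAxis(direction=direction, slope=slope, intercept=float(coef[0]))


def traverse(model: VAEModel, axis: PraaAxis, span: float, n_frames: int,
             center: Optional[np.ndarray] = None) -> List[np.ndarray]:
    """Decode along ``z(s) = center + s * direction``, s in [-span, span].

    Frames are returned ordered by decreasing predicted PRAA, so the
    animation plays from the largest to the smallest retinal-artery angle.
    The middle frame (odd ``n_frames``) decodes the latent center itself.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if center is None:
        center = model.latent_center if model.latent_center is not None \
            else np.zeros(model.arch.latent_dim)
    # Predicted PRAA is intercept + slope * (direction . z) and slope >= 0,
    # so decreasing predicted PRAA means descending s.
    svals = np.linspace(span, -span, n_frames)
    Z = center[None, :] + svals[:, None] * axis.direction[None, :]
    norm = model.norm_const or 1.0
    out, _ = _decode(model.params, Z)
    return [out[i] * norm for i in range(n_frames)]


def export_animation(frames: Sequence[np.ndarray], path, fps: float = 4.0):
    """Write the traversal as an animated GIF plus a per-frame CSV.

    The CSV (``<path>.frames.csv``) holds one frame per row and round-trips
    the decoded traces; the GIF renders each frame as a line plot with a
    common vertical scale.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    import imageio.v2 as imageio
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.vstack([np.asarray(f, dtype=float) for f in frames])
    lo, hi = arr.min(), arr.max()
    pad = 0.05 * (hi - lo + 1e-9)
    images = []
    for i, f in enumerate(arr):
        fig, ax = plt.subplots(figsize=(5, 3), dpi=80)
        ax.plot(f, lw=1.2)
        ax.set_ylim(lo - pad, hi + pad)
        ax.set_xlabel("sample")
        ax.set_ylabel("signal")
        ax.set_title(f"frame {i + 1}/{len(arr)} (decreasing PRAA)")
        fig.tight_layout()
        fig.canvas.draw()
        img = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
        images.append(img)
        plt.close(fig)
    imageio.mimsave(path, images, duration=1000.0 / fps, loop=0)
    csv_path = str(path) + ".frames.csv"
    np.savetxt(csv_path, arr, delimiter=",", fmt="%.8e")
    return path


def save_model(model: VAEModel, path) -> None:
    """Weight archive (.npz) + JSON sidecar with arch/normalisation/seed."""
    np.savez(path, **model.params)
    sidecar = {
        "input_dim": model.arch.input_dim,
        "encoder_hidden": list(model.arch.encoder_hidden),
        "latent_dim": model.arch.latent_dim,
        "norm_const": model.norm_const,
        "seed": model.seed,
        "trained": model.trained,
        "latent_center": None if model.latent_center is None
        else list(map(float, model.latent_center)),
        "latent_sd": None if model.latent_sd is None
        else list(map(float, model.latent_sd)),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path) -> VAEModel:
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    arch = VAEArch(input_dim=side["input_dim"],
                   encoder_hidden=tuple(side["encoder_hidden"]),
                   latent_dim=side["latent_dim"])
    with np.load(path) as npz:
        params = {k: npz[k] for k in npz.files}
    model = VAEModel(arch=arch, params=params, seed=side["seed"],
                     norm_const=side["norm_const"], trained=side["trained"])
    if side["latent_center"] is not None:
        model.latent_center = np.asarray(side["latent_center"])
        model.latent_sd = np.asarray(side["latent_sd"])
    return model
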