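"""Representation models: variational autoencoder, plain autoencoder, PCA.

The multimodal ("M-style") configuration trains one model on the fused
waveform tensor; the unimodal ("U-style") configuration trains one model per
modality and concatenates the per-modality embeddings, matching the total
latent budget.  The autoencoder is a dense encoder/decoder pair trained with
Adam on the beta-VAE objective (mean squared reconstruction error plus a
rescaled KL divergence toward the standard-normal prior); with ``beta = 0``
and latent sampling disabled it reduces exactly to a plain (non-variational)
autoencoder.  Embeddings are always the posterior means, so downstream
association phenotypes are deterministic.

Everything is a pure function of (data, config, seed): two runs with the
same seed produce bit-identical losses and weights.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .waveforms import FusedTensor

__all__ = [
    "VAEConfig",
    "EmbeddingMatrix",
    "ModelCandidate",
    "PCAModel",
    "train_vae",
    "encode",
    "decode",
    "max_offdiag_corr",
    "overall_mse",
    "reconstruction_compare",
    "select_model",
    "pca_embed",
    "fit_pca",
    "perturb_and_interpolate",
]


@dataclass
class VAEConfig:
    """Hyper-parameters of the dense beta-VAE.

    ``beta`` rescales the KL term (0 disables it); ``stochastic`` toggles
    latent sampling during training (``False`` with ``beta = 0`` gives the
    plain autoencoder baseline).  The decoder mirrors the encoder's hidden
    widths in reverse.
    """

    latent_dim: int = 12
    hidden: tuple[int, ...] = (128, 32)
    activation: str = "tanh"  # "tanh" | "relu" | "identity"
    beta: float = 1e-3
    learning_rate: float = 3e-3
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0
    stochastic: bool = True

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.activation not in ("tanh", "relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class EmbeddingMatrix:
    """n x d posterior-mean embeddings with provenance."""

    sample_ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids and values row count disagree")

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    return x


def _act_grad(name: str, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return 1.0 - post**2
    if name == "relu":
        return (pre > 0).astype(pre.dtype)
    return np.ones_like(pre)


class _DenseVAE:
    """Dense encoder/decoder with manual backprop and Adam."""

    def __init__(self, n_features: int, config: VAEConfig, rng: np.random.Generator):
        self.cfg = config
        self.n_features = n_features
        enc_dims = [n_features, *config.hidden]
        dec_dims = [config.latent_dim, *config.hidden[::-1], n_features]

        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        self.enc = [(glorot(a, b), np.zeros(b)) for a, b in zip(enc_dims[:-1], enc_dims[1:])]
        h = enc_dims[-1]
        self.W_mu, self.b_mu = glorot(h, config.latent_dim), np.zeros(config.latent_dim)
        self.W_lv, self.b_lv = glorot(h, config.latent_dim), np.zeros(config.latent_dim)
        self.dec = [(glorot(a, b), np.zeros(b)) for a, b in zip(dec_dims[:-1], dec_dims[1:])]

    # -- parameter flattening for Adam / checkpoints ------------------------
    def params(self) -> list[np.ndarray]:
        out = []
        for W, b in self.enc:
            out += [W, b]
        out += [self.W_mu, self.b_mu, self.W_lv, self.b_lv]
        for W, b in self.dec:
            out += [W, b]
        return out

    def set_params(self, flat: list[np.ndarray]) -> None:
        it = iter(flat)
        self.enc = [(next(it), next(it)) for _ in self.enc]
        self.W_mu, self.b_mu, self.W_lv, self.b_lv = next(it), next(it), next(it), next(it)
        self.dec = [(next(it), next(it)) for _ in self.dec]

    # -- forward passes -----------------------------------------------------
    def encode_mu(self, x: np.ndarray) -> np.ndarray:
        h = x
        for W, b in self.enc:
            h = _act(self.cfg.activation, h @ W + b)
        return h @ self.W_mu + self.b_mu

    def decode_z(self, z: np.ndarray) -> np.ndarray:
        h = z
        for i, (W, b) in enumerate(self.dec):
            h = h @ W + b
            if i < len(self.dec) - 1:  # linear output layer
                h = _act(self.cfg.activation, h)
        return h

    def loss(self, x: np.ndarray) -> tuple[float, float, float]:
        """(total, recon, kl) at posterior means — the deterministic
        validation objective used for checkpoint selection."""
        h = x
        for W, b in self.enc:
            h = _act(self.cfg.activation, h @ W + b)
        mu = h @ self.W_mu + self.b_mu
        lv = h @ self.W_lv + self.b_lv
        xhat = self.decode_z(mu)
        recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)))
        kl = float(np.mean(0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)))
        return recon + self.cfg.beta * kl, recon, kl

    # -- training step ------------------------------------------------------
    def grads(self, x: np.ndarray, rng: np.random.Generator) -> tuple[float, list[np.ndarray]]:
        cfg = self.cfg
        B = x.shape[0]
        acts = [x]
        pres = []
        h = x
        for W, b in self.enc:
            pre = h @ W + b
            h = _act(cfg.activation, pre)
            pres.append(pre)
            acts.append(h)
        mu = h @ self.W_mu + self.b_mu
        lv = h @ self.W_lv + self.b_lv
        lv = np.clip(lv, -10.0, 10.0)
        if cfg.stochastic:
            eps = rng.standard_normal(mu.shape)
            z = mu + eps * np.exp(0.5 * lv)
        else:
            eps = np.zeros_like(mu)
            z = mu

        d_acts = [z]
        d_pres = []
        hz = z
        for i, (W, b) in enumerate(self.dec):
            pre = hz @ W + b
            hz = pre if i == len(self.dec) - 1 else _act(cfg.activation, pre)
            d_pres.append(pre)
            d_acts.append(hz)
        xhat = hz

        recon = float(np.mean(np.sum((x - xhat) ** 2, axis=1)))
        kl = float(np.mean(0.5 * np.sum(np.exp(lv) + mu**2 - 1.0 - lv, axis=1)))
        total = recon + cfg.beta * kl
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite training loss (recon={recon}, kl={kl}); "
                "reduce the learning rate or beta"
            )

        # backward through decoder
        g = 2.0 * (xhat - x) / B
        dec_grads: list[np.ndarray] = []
        for i in range(len(self.dec) - 1, -1, -1):
            W, b = self.dec[i]
            if i < len(self.dec) - 1:
                g = g * _act_grad(cfg.activation, d_pres[i], d_acts[i + 1])
            dec_grads.append(g.sum(axis=0))
            dec_grads.append(d_acts[i].T @ g)
            g = g @ W.T
        dec_grads.reverse()

        dz = g
        dmu = dz + cfg.beta * mu / B
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + cfg.beta * 0.5 * (np.exp(lv) - 1.0) / B

        henc = acts[-1]
        gW_mu, gb_mu = henc.T @ dmu, dmu.sum(axis=0)
        gW_lv, gb_lv = henc.T @ dlv, dlv.sum(axis=0)
        g = dmu @ self.W_mu.T + dlv @ self.W_lv.T
        enc_grads: list[np.ndarray] = []
        for i in range(len(self.enc) - 1, -1, -1):
            W, b = self.enc[i]
            g = g * _act_grad(cfg.activation, pres[i], acts[i + 1])
            enc_grads.append(g.sum(axis=0))
            enc_grads.append(acts[i].T @ g)
            g = g @ W.T
        enc_grads.reverse()

        return total, enc_grads + [gW_mu, gb_mu, gW_lv, gb_lv] + dec_grads


@dataclass
class ModelCandidate:
    """A trained model plus its selection metrics."""

    config: VAEConfig
    net: _DenseVAE
    val_recon_loss: float  # per-feature mean squared error on validation
    max_abs_corr: float
    n_features: int
    template: dict  # fusion spec / lengths captured at training time

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim


def save_candidate(candidate: ModelCandidate, path: str) -> None:
    """Single-file checkpoint: weights plus a JSON config digest."""
    import json

    cfg = candidate.config
    arrays = {f"p{i}": p for i, p in enumerate(candidate.net.params())}
    meta = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
        "val_recon_loss": candidate.val_recon_loss,
        "max_abs_corr": candidate.max_abs_corr,
        "n_features": candidate.n_features,
        "shape": list(candidate.template["shape"]),
        "modality_order": list(candidate.template["spec"].modality_order),
        "strategy": candidate.template["spec"].strategy,
        "scale_factors": candidate.template["spec"].scale_factors,
        "lengths": candidate.template["lengths"],
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_candidate(path: str) -> ModelCandidate:
    import json

    from .waveforms import FusionSpec

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
    cfg_d = dict(meta["config"])
    cfg_d["hidden"] = tuple(cfg_d["hidden"])
    cfg = VAEConfig(**cfg_d)
    net = _DenseVAE(meta["n_features"], cfg, np.random.default_rng(0))
    net.set_params(arrays)
    spec = FusionSpec(meta["strategy"], tuple(meta["modality_order"]),
                      dict(meta["scale_factors"]))
    return ModelCandidate(cfg, net, meta["val_recon_loss"], meta["max_abs_corr"],
                          meta["n_features"],
                          {"spec": spec, "lengths": dict(meta["lengths"]),
                           "shape": tuple(meta["shape"])})


def max_offdiag_corr(values: np.ndarray) -> float:
    """Maximum |off-diagonal| entry of the sample correlation matrix."""
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    c = np.corrcoef(v[:, keep], rowvar=False)
    np.fill_diagonal(c, 0.0)
    return float(np.abs(c).max())


def train_vae(fused: FusedTensor, val: FusedTensor, config: VAEConfig) -> ModelCandidate:
    """Train the dense beta-VAE, keeping the best-validation checkpoint.

    Validation loss is evaluated at the posterior means each epoch; the
    parameters with the lowest validation total loss are returned, which
    makes over-training benign.
    """
    if set(fused.sample_ids) & set(val.sample_ids):
        raise ValueError("train and validation sets must be disjoint by sample id")
    X, Xv = fused.matrix, val.matrix
    if config.latent_dim >= X.shape[1]:
        raise ValueError("latent_dim must be smaller than the input length")

    rng = np.random.default_rng(config.seed)
    net = _DenseVAE(X.shape[1], config, rng)

    params = net.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    t = 0
    best = (np.inf, copy.deepcopy(params))

    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            if batch.shape[0] < 2:
                continue
            _, grads = net.grads(batch, rng)
            t += 1
            lr_t = config.learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
            for i, g in enumerate(grads):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g**2
                params[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps_adam)
            net.set_params(params)
        val_total, _, _ = net.loss(Xv)
        if val_total < best[0]:
            best = (val_total, copy.deepcopy(params))

    net.set_params(best[1])
    mu_val = net.encode_mu(Xv)
    xhat_val = net.decode_z(mu_val)
    val_mse = float(np.mean((Xv - xhat_val) ** 2))
    return ModelCandidate(
        config=config,
        net=net,
        val_recon_loss=val_mse,
        max_abs_corr=max_offdiag_corr(mu_val),
        n_features=X.shape[1],
        template={"spec": fused.spec, "lengths": fused.lengths,
                  "shape": fused.data.shape[1:]},
    )


# ---------------------------------------------------------------------------
# PCA baseline


@dataclass
class PCAModel:
    """Rank-k PCA with a deterministic sign convention (largest-|loading|
    element of each component positive)."""

    mean_: np.ndarray
    components_: np.ndarray  # (k, features)
    explained_variance_ratio_: np.ndarray
    template: dict

    @property
    def latent_dim(self) -> int:
        return self.components_.shape[0]


def fit_pca(fused: FusedTensor, k: int) -> PCAModel:
    X = fused.matrix
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n, features)={min(X.shape)}")
    mean = X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
    comp = Vt[:k]
    flip = np.sign(comp[np.arange(k), np.abs(comp).argmax(axis=1)])
    comp = comp * flip[:, None]
    var = S**2 / max(X.shape[0] - 1, 1)
    ratio = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return PCAModel(mean, comp, ratio,
                    {"spec": fused.spec, "lengths": fused.lengths, "shape": fused.data.shape[1:]})


def pca_embed(fused: FusedTensor, k: int) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Mean-centered projection on the top-k principal components."""
    model = fit_pca(fused, k)
    emb = encode(model, fused)
    return emb, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# shared encode/decode surface


def encode(candidate, fused: FusedTensor) -> EmbeddingMatrix:
    """Posterior-mean (or PC-score) embeddings; deterministic, no sampling."""
    X = fused.matrix
    if isinstance(candidate, PCAModel):
        vals = (X - candidate.mean_) @ candidate.components_.T
        prov = {"model": "pca", "d": candidate.latent_dim}
    else:
        if X.shape[1] != candidate.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects {candidate.n_features}")
        vals = candidate.net.encode_mu(X)
        prov = {"model": "vae" if candidate.config.stochastic else "cae",
                "d": candidate.latent_dim, "seed": candidate.config.seed,
                "beta": candidate.config.beta}
    return EmbeddingMatrix(list(fused.sample_ids), vals, prov)


def decode(candidate, embedding: np.ndarray | EmbeddingMatrix) -> np.ndarray:
    """Decode embeddings back to the fused-input shape (n, ...)."""
    Z = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    if Z.ndim == 1:
        Z = Z[None, :]
    if isinstance(candidate, PCAModel):
        flat = Z @ candidate.components_ + candidate.mean_
    else:
        flat = candidate.net.decode_z(Z)
    return flat.reshape(Z.shape[0], *candidate.template["shape"])


def encode_concat(candidates: Mapping[str, object], fused_by_modality: Mapping[str, FusedTensor],
                  order: Sequence[str]) -> EmbeddingMatrix:
    """U-style embeddings: per-modality encoders concatenated in order."""
    parts, ids = [], None
    for m in order:
        emb = encode(candidates[m], fused_by_modality[m])
        if ids is None:
            ids = emb.sample_ids
        elif ids != emb.sample_ids:
            raise ValueError("modalities carry different sample orderings")
        parts.append(emb.values)
    return EmbeddingMatrix(ids, np.concatenate(parts, axis=1), {"model": "u-concat"})


# ---------------------------------------------------------------------------
# comparison, selection, interpretation


def overall_mse(per_modality: Mapping[str, float], lengths: Mapping[str, int],
                strategy: str) -> float:
    """Combine per-modality MSEs into one comparable number.

    Length-weighted average for concatenation fusion; plain mean across
    leads for channel-stack fusion (all leads share one length there).
    """
    if strategy == "concatenate":
        return sum(lengths[m] * per_modality[m] for m in per_modality) / \
            sum(lengths[m] for m in per_modality)
    return float(np.mean(list(per_modality.values())))


def _per_modality_mse(candidate, fused: FusedTensor) -> dict[str, float]:
    emb = encode(candidate, fused)
    recon = decode(candidate, emb)
    out = {}
    for m, idx in fused.modality_slices().items():
        out[m] = float(np.mean((fused.data[idx] - recon[idx]) ** 2))
    return out


def reconstruction_compare(m_candidate, u_candidates: Mapping[str, object],
                           m_fused: FusedTensor,
                           u_fused: Mapping[str, FusedTensor]) -> dict:
    """Overall + per-modality reconstruction MSE for M- and U-style models.

    The U-style overall loss is the length-weighted average of per-modality
    MSEs for concatenation fusion, and the plain mean across leads for
    channel-stack fusion; the M-style overall loss is computed the same way
    from the joint model's per-modality reconstructions, which makes the two
    comparable.
    """
    m_total = m_candidate.latent_dim
    u_total = sum(c.latent_dim for c in u_candidates.values())
    if m_total != u_total:
        warnings.warn(f"total latent dims differ (M={m_total}, U={u_total}); "
                      "comparison computed anyway", stacklevel=2)

    m_per = _per_modality_mse(m_candidate, m_fused)
    u_per = {m: _per_modality_mse(c, u_fused[m])[m] for m, c in u_candidates.items()}

    lengths = m_fused.lengths
    strategy = m_fused.spec.strategy
    m_overall = overall_mse(m_per, lengths, strategy)
    u_overall = overall_mse(u_per, lengths, strategy)
    return {
        "m_overall": m_overall,
        "u_overall": u_overall,
        "m_per_modality": m_per,
        "u_per_modality": u_per,
        "ratio": m_overall / u_overall if u_overall > 0 else np.nan,
        "reduction_pct": 100.0 * (1.0 - m_overall / u_overall) if u_overall > 0 else np.nan,
    }


def select_model(candidates: Sequence[ModelCandidate],
                 corr_threshold: float = 0.1) -> ModelCandidate:
    """Pick the candidate with the lowest validation reconstruction loss
    among those whose validation embeddings have max |off-diagonal|
    correlation <= ``corr_threshold``; ties broken by smaller correlation,
    then by candidate order.  If none pass, fall back to the globally
    least-correlated candidate with a warning."""
    if not candidates:
        raise ValueError("empty candidate list")
    passing = [c for c in candidates if c.max_abs_corr <= corr_threshold]
    if not passing:
        warnings.warn(
            f"no candidate has max |corr| <= {corr_threshold}; "
            "falling back to the least-correlated candidate", stacklevel=2)
        return min(candidates, key=lambda c: (c.max_abs_corr,))
    return min(passing, key=lambda c: (c.val_recon_loss, c.max_abs_corr))


def perturb_and_interpolate(candidate, e_start: np.ndarray, dim: int,
                            e_end: np.ndarray | None = None, steps: int = 20,
                            range_sd: tuple[float, float] = (-2.0, 2.0)) -> np.ndarray:
    """Decode a sweep of one latent coordinate.

    Interpolation mode (``e_end`` given): vary coordinate ``dim`` linearly
    from e_start[dim] to e_end[dim] in ``steps`` evenly spaced values with
    all other coordinates held at e_start.  Perturbation mode (``e_end``
    None): start from ``e_start`` (canonically the all-zero embedding — the
    mean of the VAE prior) and sweep coordinate ``dim`` over ``range_sd``
    (default two prior standard deviations either side).
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    e_start = np.asarray(e_start, dtype=float)
    if not (0 <= dim < e_start.size):
        raise ValueError(f"dim {dim} outside latent dimension {e_start.size}")
    if e_end is not None:
        lo, hi = float(e_start[dim]), float(np.asarray(e_end)[dim])
    else:
        lo, hi = range_sd
    grid = np.linspace(lo, hi, steps)
    Z = np.tile(e_start, (steps, 1))
    Z[:, dim] = grid
    return decode(candidate, Z)
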