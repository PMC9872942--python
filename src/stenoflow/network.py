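"""Dual input-sampling-channel point-cloud network, in pure NumPy.

Architecture (per-point fully connected stacks, PointNet-style):

* shared stem FC1 -> FC2 applied identically to both input clouds — the two
  channels literally reference the same weight arrays, so preliminary
  feature extraction is shared by construction;
* cavity channel: FC3 stack ending at 512 features per surface point,
  followed by a max pool over points (a symmetric function, making the
  output invariant to cavity point order) — one 512-d global geometry code;
* fluid channel: FC4 stack ending at 128 features per fluid point;
* stitching: the global code is tiled to every fluid point and concatenated,
  giving 512 + 128 = 640 features per fluid point;
* decoder FC5 -> FC6 -> linear head to 1 (pressure) or 3 (velocity) values
  per fluid point.

Training uses per-sample (batch size 1) Adam steps on an MSE loss over the
normalized field, mirroring the reference schedule of learning rate 0.001,
beta1 0.9, beta2 0.999, epsilon 1e-8 and 1,000 epochs; the weights with the
best held-out loss are retained.  All arithmetic is float32 and every source
of randomness is seeded, so runs are reproducible on fixed hardware.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError
from . import datasets as _ds

__all__ = ["NetworkConfig", "SurrogateModel", "TrainingHistory",
           "build_network", "train", "predict_bundle"]


@dataclass(frozen=True)
class NetworkConfig:
    """Widths, optimizer settings and training schedule.

    The reference configuration fixes the cavity global feature at 512, the
    fluid per-point feature at 128 (stitched: 640); hidden widths elsewhere
    follow PointNet-style conventions.
    """

    output_dim: int = 1
    shared_widths: tuple[int, ...] = (64, 64)        # FC1, FC2
    cavity_head_widths: tuple[int, ...] = (128, 512)  # FC3 stack -> 512
    fluid_head_widths: tuple[int, ...] = (128, 128)   # FC4 stack -> 128
    decoder_widths: tuple[int, ...] = (256, 128)      # FC5, FC6
    activation: str = "relu"
    loss: str = "mse"
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 1
    epochs: int = 1000
    seed: int = 0
    cavity_subsample: int | None = None   # per-step random subset sizes
    fluid_subsample: int | None = None
    eval_subsample: int | None = 1024     # held-out loss subset (fixed draw)
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.output_dim not in (1, 3):
            raise ConfigurationError("output_dim must be 1 (pressure) or 3 (velocity)")
        if self.activation != "relu":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")
        if self.loss not in ("mse", "mae"):
            raise ConfigurationError(f"unsupported loss {self.loss!r}")
        if self.batch_size != 1:
            raise ConfigurationError("training is defined per sample (batch size 1)")

    @property
    def cavity_feature_dim(self) -> int:
        return self.cavity_head_widths[-1]

    @property
    def fluid_feature_dim(self) -> int:
        return self.fluid_head_widths[-1]

    @property
    def stitched_dim(self) -> int:
        return self.cavity_feature_dim + self.fluid_feature_dim


@dataclass
class TrainingHistory:
    """Per-epoch training loss and the retained-best bookkeeping."""

    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)   # (epoch, loss) pairs
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def _layer_names(config: NetworkConfig) -> list[tuple[str, int, int]]:
    names = []
    prev = 3
    for i, w in enumerate(config.shared_widths):
        names.append((f"shared{i}", prev, w))
        prev = w
    stem_out = prev
    for i, w in enumerate(config.cavity_head_widths):
        names.append((f"cavity{i}", prev, w))
        prev = w
    prev = stem_out
    for i, w in enumerate(config.fluid_head_widths):
        names.append((f"fluid{i}", prev, w))
        prev = w
    prev = config.stitched_dim
    for i, w in enumerate(config.decoder_widths):
        names.append((f"decoder{i}", prev, w))
        prev = w
    names.append(("out", prev, config.output_dim))
    return names


class SurrogateModel:
    """Weights + configuration of the dual-channel field-regression network.

    FC1/FC2 are single arrays used by both channels; there is no per-channel
    copy anywhere, so the weight-sharing invariant holds by construction and
    survives any number of optimizer updates.
    """

    def __init__(self, config: NetworkConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # -- forward ----------------------------------------------------------

    def _stack(self, x: np.ndarray, prefix: str, n_layers: int,
               cache: list | None) -> np.ndarray:
        for i in range(n_layers):
            w, b = self.params[f"{prefix}{i}.W"], self.params[f"{prefix}{i}.b"]
            z = x @ w + b
            a = np.maximum(z, 0.0)
            if cache is not None:
                cache.append((prefix + str(i), x, z))
            x = a
        return x

    def forward(self, cavity: np.ndarray, fluid: np.ndarray,
                cache: dict | None = None) -> np.ndarray:
        """Predict the (N2, output_dim) normalized field from normalized clouds."""
        cavity = np.ascontiguousarray(cavity, dtype=np.float32)
        fluid = np.ascontiguousarray(fluid, dtype=np.float32)
        if cavity.ndim != 2 or cavity.shape[1] != 3 or len(cavity) == 0:
            raise ValueError("cavity input must be a non-empty (N1, 3) array")
        if fluid.ndim != 2 or fluid.shape[1] != 3 or len(fluid) == 0:
            raise ValueError("fluid input must be a non-empty (N2, 3) array")
        cfg = self.config
        cav_cache: list | None = [] if cache is not None else None
        flu_cache: list | None = [] if cache is not None else None
        h_cav = self._stack(cavity, "shared", len(cfg.shared_widths), cav_cache)
        h_cav = self._stack(h_cav, "cavity", len(cfg.cavity_head_widths), cav_cache)
        pool_idx = np.argmax(h_cav, axis=0)
        g = h_cav[pool_idx, np.arange(h_cav.shape[1])]
        h_flu = self._stack(fluid, "shared", len(cfg.shared_widths), flu_cache)
        h_flu = self._stack(h_flu, "fluid", len(cfg.fluid_head_widths), flu_cache)
        stitched = np.concatenate(
            [np.broadcast_to(g, (len(fluid), cfg.cavity_feature_dim)), h_flu], axis=1)
        dec_cache: list | None = [] if cache is not None else None
        h = self._stack(stitched, "decoder", len(cfg.decoder_widths), dec_cache)
        y = h @ self.params["out.W"] + self.params["out.b"]
        if cache is not None:
            cache.update(cav=cav_cache, flu=flu_cache, dec=dec_cache,
                         pool_idx=pool_idx, h_dec_in=stitched, h_out_in=h,
                         n_fluid=len(fluid))
        return y

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        arrays = dict(self.params)
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with np.load(path) as data:
            cfg_d = json.loads(bytes(data["__config__"]).decode())
            for key in ("shared_widths", "cavity_head_widths",
                        "fluid_head_widths", "decoder_widths"):
                cfg_d[key] = tuple(cfg_d[key])
            config = NetworkConfig(**cfg_d)
            params = {k: data[k].copy() for k in data.files if k != "__config__"}
        return cls(config, params)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_network(config: NetworkConfig) -> SurrogateModel:
    """He-initialised model; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    for name, fan_in, fan_out in _layer_names(config):
        std = np.sqrt(2.0 / fan_in)
        params[f"{name}.W"] = rng.normal(0.0, std, (fan_in, fan_out)).astype(np.float32)
        params[f"{name}.b"] = np.zeros(fan_out, dtype=np.float32)
    return SurrogateModel(config, params)


# ---------------------------------------------------------------------------
# Backpropagation


def _backward(model: SurrogateModel, cache: dict, d_y: np.ndarray
              ) -> dict[str, np.ndarray]:
    cfg = model.config
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}

    def back_stack(cache_list: list, d_out: np.ndarray) -> np.ndarray:
        d = d_out
        for name, x, z in reversed(cache_list):
            d = d * (z > 0.0)
            grads[f"{name}.W"] += x.T @ d
            grads[f"{name}.b"] += d.sum(axis=0)
            d = d @ model.params[f"{name}.W"].T
        return d

    h = cache["h_out_in"]
    grads["out.W"] += h.T @ d_y
    grads["out.b"] += d_y.sum(axis=0)
    d = d_y @ model.params["out.W"].T
    d_stitched = back_stack(cache["dec"], d)

    d_g = d_stitched[:, :cfg.cavity_feature_dim].sum(axis=0)
    d_flu = d_stitched[:, cfg.cavity_feature_dim:]
    back_stack(cache["flu"], d_flu)

    # route the pooled gradient to the argmax cavity points
    last_cav = cache["cav"][-1]
    n1 = len(last_cav[1])
    d_cav = np.zeros((n1, cfg.cavity_feature_dim), dtype=np.float32)
    d_cav[cache["pool_idx"], np.arange(cfg.cavity_feature_dim)] = d_g
    back_stack(cache["cav"], d_cav)
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: NetworkConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        self.t += 1
        b1t = 1.0 - cfg.beta1 ** self.t
        b2t = 1.0 - cfg.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = cfg.beta1 * self.m[k] + (1.0 - cfg.beta1) * g
            v = self.v[k] = cfg.beta2 * self.v[k] + (1.0 - cfg.beta2) * g * g
            params[k] -= (cfg.learning_rate * (m / b1t)
                          / (np.sqrt(v / b2t) + cfg.epsilon)).astype(np.float32)


def _loss_and_grad(y_hat: np.ndarray, y: np.ndarray, kind: str
                   ) -> tuple[float, np.ndarray]:
    resid = y_hat - y
    n = resid.size
    if kind == "mse":
        return float(np.mean(resid ** 2)), (2.0 / n) * resid
    return float(np.mean(np.abs(resid))), np.sign(resid) / n


# ---------------------------------------------------------------------------
# Training / prediction


def _normalized_cache(bundle: _ds.DatasetBundle, indices: np.ndarray
                      ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = []
    for i in indices:
        cav, flu, y = _ds.normalized_arrays(bundle, int(i))
        out.append((cav.astype(np.float32), flu.astype(np.float32),
                    y.astype(np.float32)))
    return out


def train(model: SurrogateModel, bundle: _ds.DatasetBundle,
          config: NetworkConfig | None = None
          ) -> tuple[SurrogateModel, TrainingHistory]:
    """Per-sample Adam training with best-held-out-weight retention."""
    cfg = config or model.config
    expect = 3 if bundle.target == "velocity" else 1
    if cfg.output_dim != expect:
        raise ConfigurationError(
            f"output_dim {cfg.output_dim} does not match target {bundle.target!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    train_data = _normalized_cache(bundle, bundle.train_indices)
    val_data = _normalized_cache(bundle, bundle.test_indices)
    if cfg.eval_subsample is not None:
        val_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
        sub = []
        for cav, flu, y in val_data:
            k = min(cfg.eval_subsample, len(flu))
            idx = val_rng.choice(len(flu), size=k, replace=False)
            kc = min(cfg.eval_subsample, len(cav))
            idxc = val_rng.choice(len(cav), size=kc, replace=False)
            sub.append((cav[idxc], flu[idx], y[idx]))
        val_data = sub

    opt = _Adam(model.params, cfg)
    history = TrainingHistory()
    best_params = model.copy_params()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        epoch_loss = 0.0
        for j in order:
            cav, flu, y = train_data[j]
            if cfg.cavity_subsample is not None and len(cav) > cfg.cavity_subsample:
                cav = cav[rng.choice(len(cav), cfg.cavity_subsample, replace=False)]
            if cfg.fluid_subsample is not None and len(flu) > cfg.fluid_subsample:
                keep = rng.choice(len(flu), cfg.fluid_subsample, replace=False)
                flu, y = flu[keep], y[keep]
            cache: dict = {}
            y_hat = model.forward(cav, flu, cache=cache)
            loss, d_y = _loss_and_grad(y_hat, y, cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {int(j)}")
            grads = _backward(model, cache, d_y.astype(np.float32))
            opt.step(model.params, grads)
            epoch_loss += loss
        history.train_losses.append(epoch_loss / max(1, len(train_data)))
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
            val = _held_out_loss(model, val_data, cfg.loss)
            history.val_losses.append((epoch, val))
            if val < history.best_val_loss:
                history.best_val_loss = val
                history.best_epoch = epoch
                best_params = model.copy_params()
    model.params = best_params
    return model, history


def _held_out_loss(model: SurrogateModel, data: list, kind: str) -> float:
    total = 0.0
    for cav, flu, y in data:
        y_hat = model.forward(cav, flu)
        total += _loss_and_grad(y_hat, y, kind)[0]
    return total / max(1, len(data))


def predict_bundle(model: SurrogateModel, bundle: _ds.DatasetBundle,
                   split: str = "test") -> list[np.ndarray]:
    """Denormalized per-sample field predictions on full clouds."""
    out = []
    norm = bundle.normalization
    for i in bundle.split(split):
        cav, flu, _ = _ds.normalized_arrays(bundle, int(i))
        y_hat = model.forward(cav.astype(np.float32), flu.astype(np.float32))
        out.append(_ds.denormalize_field(y_hat.astype(float), norm.field_scale,
                                         norm.field_offset))
    return out
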