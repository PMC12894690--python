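"""Deep variational perfusion-deficit model.

A variational autoencoder over joint (perfusion map, deficit score) data
whose deficit decoder is constrained, by construction, to the dot product
between the perfusion map and an inferred voxel-wise substrate map.  The
encoder maps a five-channel volume — perfusion map, X/Y/Z coordinate
meshes, and the broadcast deficit score — to a Gaussian posterior over a
latent code; the first half of the code decodes to the substrate, the
second half to a reconstruction of the perfusion map; the score is
reconstructed as ``<substrate, perfusion map>``.  Training minimises the
negative evidence lower bound: KL to the unit Gaussian prior plus squared
reconstruction errors of map and score.

The inductive bias is the point: any voxel pattern that predicts the score
must do so through a linear readout of the perfusion map, so the learned
substrate is interpretable as a map of neural dependence rather than an
arbitrary nonlinear feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "ModelConfig",
    "CohortSplit",
    "PerfusionDLM",
    "TrainResult",
    "assemble_input",
    "pad_to_shape",
    "crop_to_shape",
    "predict_score",
    "elbo_loss",
    "kl_divergence",
    "split_cohort",
    "train",
    "infer_substrate",
    "calibrate_threshold",
    "select_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture and optimisation hyper-parameters.

    The defaults are the full clinical-scale model: 128-cube input, six
    halving blocks with output channels (5, 16, 32, 64, 128, 256) applied to
    the 5-channel input volume (so the flattened encoder output is
    256 * 2^3 = 2048), a 50-dimensional latent split 25/25 between substrate
    and reconstruction branches, Adam at lr 1e-4 with weight decay 1e-5,
    batches of ten, up to 4000 epochs.  ``channel_schedule[k]`` is block k's
    output channel count; its length is the number of halvings.
    """

    input_shape: tuple[int, int, int] = (128, 128, 128)
    channel_schedule: tuple[int, ...] = (5, 16, 32, 64, 128, 256)
    input_channels: int = 5
    latent_dim: int = 50
    substrate_latent: int = 25
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 4000
    batch_size: int = 10
    rng_seed: int = 0
    score_scale: float = 4.0  # maximum ordinal level; scores divided by it
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # kl, cpm, score
    # internal normalisation of the deficit dot product: the decoded weights
    # are divided by sqrt(n_voxels) inside the model so the decoder works at
    # its natural O(1) output scale; the substrate map is relative either
    # way (calibration binarises it by percentile of its own weights)
    dot_scale: float | None = None
    # trainable intercept in the deficit readout during training: absorbs
    # the cohort-mean score within a few steps so the substrate head learns
    # the covariance-driven map instead of first building and then
    # sculpting away a mean-perfusion-shaped component.  The inferred
    # substrate and predict_score remain a pure dot product.
    score_intercept: bool = True

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        if self.input_channels != 5:
            raise ValueError("input must have 5 channels (cpm, x, y, z, score)")
        if not 0 < self.substrate_latent < self.latent_dim:
            raise ValueError("substrate_latent must split latent_dim")
        depth = self.depth
        for s in self.input_shape:
            if s % (2**depth) != 0:
                raise ValueError(
                    f"input shape {self.input_shape} not divisible by 2^{depth}"
                )
        if self.max_epochs > 4000:
            raise ValueError("max_epochs capped at 4000")

    @property
    def depth(self) -> int:
        return len(self.channel_schedule)

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        f = 2**self.depth
        return tuple(s // f for s in self.input_shape)

    @property
    def flat_dim(self) -> int:
        """Flattened encoder output size (2048 for the full-scale model)."""
        return self.channel_schedule[-1] * int(np.prod(self.bottleneck_shape))

    @property
    def recon_latent(self) -> int:
        return self.latent_dim - self.substrate_latent

    @property
    def effective_dot_scale(self) -> float:
        if self.dot_scale is not None:
            return self.dot_scale
        return 1.0 / float(np.sqrt(np.prod(self.input_shape)))


@dataclass
class CohortSplit:
    train_ids: list
    validation_ids: list
    calibration_ids: list


def split_cohort(ids: list, rng_seed: int = 0) -> CohortSplit:
    """Deterministic shuffled 90/5/5 split into train/validation/calibration.

    Calibration and validation sizes are each ``round(0.05 * n)`` (banker's
    rounding as implemented by numpy), the remainder trains.  For a cohort
    of 1393 this yields 70 calibration patients.
    """
    ids = list(ids)
    n = len(ids)
    if n < 20:
        raise ValueError("cohort too small to split (need >= 20 patients)")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 10]))
    order = rng.permutation(n)
    n_cal = int(np.round(0.05 * n))
    n_val = int(np.round(0.05 * n))
    shuffled = [ids[i] for i in order]
    return CohortSplit(
        train_ids=shuffled[n_cal + n_val :],
        validation_ids=shuffled[n_cal : n_cal + n_val],
        calibration_ids=shuffled[:n_cal],
    )


def pad_to_shape(volume: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Symmetrically zero-pad (or centre-crop) a volume to ``shape``."""
    out = volume
    for ax in range(3):
        diff = shape[ax] - out.shape[ax]
        if diff > 0:
            pad = [(0, 0)] * 3
            pad[ax] = (diff // 2, diff - diff // 2)
            out = np.pad(out, pad)
        elif diff < 0:
            cut = -diff
            lo = cut // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + shape[ax])
            out = out[tuple(sl)]
    return out


def crop_to_shape(volume: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`pad_to_shape` for a volume that was padded up."""
    return pad_to_shape(volume, shape)


def coordinate_channels(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalised meshgrid channels in [-1, 1], shape (D, H, W, 3)."""
    axes = [
        np.linspace(-1.0, 1.0, s) if s > 1 else np.zeros(1) for s in shape
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=-1).astype(np.float32)


def assemble_input(
    cpm: np.ndarray,
    score: float,
    score_scale: float,
    input_shape: tuple[int, int, int],
    cpm_scale: float = 1.0,
) -> np.ndarray:
    """Build the five-channel model input (D, H, W, 5), channels-last.

    Channel 0 is the perfusion map (divided by ``cpm_scale``, zero-padded to
    ``input_shape``); channels 1-3 are X/Y/Z coordinate meshes normalised to
    [-1, 1]; channel 4 broadcasts the scaled score over the whole grid.
    """
    if not 0 <= score <= score_scale:
        raise ValueError(f"score {score} outside ordinal range [0, {score_scale}]")
    vol = pad_to_shape(np.asarray(cpm, dtype=np.float32) / cpm_scale, input_shape)
    out = np.empty(tuple(input_shape) + (5,), dtype=np.float32)
    out[..., 0] = vol
    out[..., 1:4] = coordinate_channels(input_shape)
    out[..., 4] = score / score_scale
    return out


def predict_score(substrate: np.ndarray, cpm: np.ndarray) -> float:
    """Deficit prediction: the substrate-perfusion dot product."""
    if substrate.shape != cpm.shape:
        raise ValueError(
            f"grid mismatch: {substrate.shape} vs {cpm.shape}"
        )
    return float(np.sum(np.asarray(substrate, np.float64) * np.asarray(cpm, np.float64)))


def kl_divergence(mean: np.ndarray, sd: np.ndarray) -> float:
    """KL( N(mean, diag sd^2) || N(0, I) ), closed form."""
    mean = np.asarray(mean, dtype=np.float64)
    sd = np.asarray(sd, dtype=np.float64)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    return float(0.5 * np.sum(mean**2 + sd**2 - 1.0 - 2.0 * np.log(sd)))


def elbo_loss(
    mean: np.ndarray,
    sd: np.ndarray,
    cpm: np.ndarray,
    recon_cpm: np.ndarray,
    score: float,
    pred_score: float,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> dict[str, float]:
    """Negative ELBO for one sample, with named components.

    ``total = w_kl * KL + w_cpm * ||recon - cpm||^2 + w_score * (pred - score)^2``.
    """
    for arr in (mean, sd, cpm, recon_cpm):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input to loss")
    kl = kl_divergence(mean, sd)
    l2_cpm = float(np.sum((np.asarray(recon_cpm, np.float64) - np.asarray(cpm, np.float64)) ** 2))
    l2_score = float((pred_score - score) ** 2)
    total = weights[0] * kl + weights[1] * l2_cpm + weights[2] * l2_score
    return {"kl": kl, "l2_cpm": l2_cpm, "l2_score": l2_score, "total": total}


class _Decoder:
    """One decoder branch: FC to the bottleneck volume, then mirrored blocks.

    With ``zero_init_head=True`` the final convolution starts at exactly
    zero, so the branch's output map is built entirely by training
    gradients instead of riding on a frozen random initial pattern — the
    substrate head uses this: under the squared score loss, gradient flow
    only ever adds components lying in the span of the training perfusion
    maps, so a nonzero initial output would persist as structured noise in
    the inferred substrate.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 out_channels: int = 1, zero_init_head: bool = False):
        ch = config.channel_schedule
        self.bottleneck = config.bottleneck_shape
        self.c_last = ch[-1]
        self.fc = nn.Linear(config.substrate_latent, config.flat_dim, rng)
        layers: list[nn.Module] = []
        for k in range(config.depth - 1, -1, -1):
            cout = ch[k - 1] if k > 0 else out_channels
            layers += [
                nn.ConvUp2(ch[k], ch[k], rng),
                nn.BatchNorm(ch[k]),
                nn.GELU(),
                nn.Conv3x3(ch[k], cout, rng),
            ]
        self.blocks = nn.Sequential(*layers)
        if zero_init_head:
            # near-zero: suppresses the frozen random initial output
            # pattern while keeping interior-layer gradients alive
            head = layers[-1]
            head.weight.value *= 1e-2
            head.bias.value[...] = 0.0

    def params(self) -> list[nn.Param]:
        return self.fc.params() + self.blocks.params()

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.fc.forward(z.astype(np.float32), train)
        n = h.shape[0]
        h = h.reshape((n,) + self.bottleneck + (self.c_last,))
        return self.blocks.forward(h, train)

    def backward(self, dvol: np.ndarray) -> np.ndarray:
        dh = self.blocks.backward(dvol)
        return self.fc.backward(dh.reshape(dh.shape[0], -1))


class _Encoder:
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        ch = config.channel_schedule
        layers: list[nn.Module] = []
        prev = config.input_channels
        for k in range(config.depth):
            layers += [
                nn.Conv3x3(prev, ch[k], rng),
                nn.BatchNorm(ch[k]),
                nn.GELU(),
                nn.ConvDown2(ch[k], ch[k], rng),
            ]
            prev = ch[k]
        self.blocks = nn.Sequential(*layers)
        self.fc = nn.Linear(config.flat_dim, 2 * config.latent_dim, rng)
        self.latent_dim = config.latent_dim
        self.flat_dim = config.flat_dim
        self.last_flat: int | None = None  # observed pre-FC dimensionality

    def params(self) -> list[nn.Param]:
        return self.blocks.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = True):
        h = self.blocks.forward(x.astype(np.float32), train)
        flat = h.reshape(h.shape[0], -1)
        self.last_flat = flat.shape[1]
        out = self.fc.forward(flat, train)
        self._hshape = h.shape
        mu = out[:, : self.latent_dim]
        logvar = out[:, self.latent_dim :]
        return mu, logvar

    def backward(self, dmu: np.ndarray, dlogvar: np.ndarray) -> np.ndarray:
        dout = np.concatenate([dmu, dlogvar], axis=1).astype(np.float32)
        dflat = self.fc.backward(dout)
        return self.blocks.backward(dflat.reshape(self._hshape))


class PerfusionDLM:
    """Encoder + split-latent dual decoder, with explicit numpy backprop."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 20]))
        self.encoder = _Encoder(config, rng)
        self.dec_substrate = _Decoder(config, rng, out_channels=1,
                                      zero_init_head=True)
        self.dec_recon = _Decoder(config, rng, out_channels=1)
        self.score_bias = nn.Param(np.zeros(1), "score.bias")
        # voxel-wise output bias of the substrate head: the population-shared
        # component of the substrate, learned directly in map space.  Its
        # gradient is the cohort covariance between perfusion maps and score
        # residuals, free of reparameterisation noise, so per-voxel Adam on
        # it performs the (implicitly ridge-regularised) gradient descent
        # the deficit readout calls for; the latent pathway models
        # per-patient deviations around it.
        self.substrate_map_bias = nn.Param(
            np.zeros(config.input_shape), "substrate.map_bias"
        )
        # reconstruction branch decodes the *second* half of the latent
        self.dec_recon.fc = nn.Linear(config.recon_latent, config.flat_dim, rng)

    def params(self) -> list[nn.Param]:
        out = (
            self.encoder.params()
            + self.dec_substrate.params()
            + self.dec_recon.params()
        )
        out.append(self.substrate_map_bias)
        if self.config.score_intercept:
            out.append(self.score_bias)
        return out

    # -- inference ---------------------------------------------------------
    def encode(self, x: np.ndarray, train: bool = True):
        """Posterior (mean, sd) for a batch of 5-channel inputs."""
        mu, logvar = self.encoder.forward(x, train)
        sd = np.exp(0.5 * logvar)
        return mu, sd, logvar

    def reparameterize(self, mu, sd, rng: np.random.Generator):
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        return mu + sd * eps, eps

    def decode_substrate(self, z_first: np.ndarray, train: bool = True) -> np.ndarray:
        """Substrate maps (N, D, H, W) from the first latent half."""
        return self.dec_substrate.forward(z_first, train)[..., 0]

    def decode_perfusion(self, z_last: np.ndarray, train: bool = True) -> np.ndarray:
        """Reconstructed perfusion maps (N, D, H, W) from the second half."""
        return self.dec_recon.forward(z_last, train)[..., 0]

    def substrate_for(self, x: np.ndarray) -> np.ndarray:
        """Posterior-mean substrate (latent decode + shared map bias)."""
        mu, _, _ = self.encode(x, train=False)
        k = self.config.substrate_latent
        return (
            self.decode_substrate(mu[:, :k], train=False)
            + self.substrate_map_bias.value[None]
        )

    # -- training step -----------------------------------------------------
    def train_step(self, x: np.ndarray, scores: np.ndarray, optim: nn.Adam,
                   rng: np.random.Generator) -> dict[str, float]:
        """One forward/backward/update on a batch; returns loss components.

        ``x`` is (N, D, H, W, 5) with channel 0 the (scaled, padded) CPM and
        ``scores`` the scaled observed scores.  The score is reconstructed
        as the dot product of the decoded substrate with channel 0.
        """
        n = x.shape[0]
        k = self.config.substrate_latent
        w_kl, w_cpm, w_score = self.config.loss_weights
        ds = self.config.effective_dot_scale
        cpm = x[..., 0]

        mu, logvar = self.encoder.forward(x, train=True)
        sd = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape).astype(np.float32)
        z = mu + sd * eps
        sub = (
            self.dec_substrate.forward(z[:, :k], train=True)[..., 0]
            + self.substrate_map_bias.value[None]
        )
        rec = self.dec_recon.forward(z[:, k:], train=True)[..., 0]
        pred = ds * np.sum(sub * cpm, axis=(1, 2, 3))
        if self.config.score_intercept:
            pred = pred + self.score_bias.value[0]

        kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
        l2_cpm = np.sum((rec - cpm) ** 2, axis=(1, 2, 3))
        l2_score = (pred - scores) ** 2
        loss = float(np.mean(w_kl * kl + w_cpm * l2_cpm + w_score * l2_score))

        # backward (mean over batch)
        optim.zero_grad()
        dpred = w_score * 2.0 * (pred - scores) / n
        if self.config.score_intercept:
            self.score_bias.grad += dpred.sum()
        dsub = (ds * dpred)[:, None, None, None] * cpm
        self.substrate_map_bias.grad += dsub.sum(axis=0)
        drec = w_cpm * 2.0 * (rec - cpm) / n
        dz_sub = self.dec_substrate.backward(dsub[..., None].astype(np.float32))
        dz_rec = self.dec_recon.backward(drec[..., None].astype(np.float32))
        dz = np.concatenate([dz_sub, dz_rec], axis=1)
        dmu = dz + w_kl * mu / n
        dlogvar = dz * eps * 0.5 * sd + w_kl * 0.5 * (np.exp(logvar) - 1.0) / n
        self.encoder.backward(dmu.astype(np.float32), dlogvar.astype(np.float32))
        optim.step()
        return {
            "loss": loss,
            "kl": float(kl.mean()),
            "l2_cpm": float(l2_cpm.mean()),
            "l2_score": float(l2_score.mean()),
        }

    # -- checkpointing -----------------------------------------------------
    def state(self) -> list[np.ndarray]:
        vals = [p.value.copy() for p in self.params()]
        for m in self._bn_modules():
            vals += [m.running_mean.copy(), m.running_var.copy()]
        return vals

    def load_state(self, vals: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, vals[: len(ps)]):
            p.value[...] = v
        rest = vals[len(ps) :]
        for i, m in enumerate(self._bn_modules()):
            m.running_mean[...] = rest[2 * i]
            m.running_var[...] = rest[2 * i + 1]

    def _bn_modules(self) -> list[nn.BatchNorm]:
        mods = []
        for seq in (
            self.encoder.blocks,
            self.dec_substrate.blocks,
            self.dec_recon.blocks,
        ):
            mods += [m for m in seq.layers if isinstance(m, nn.BatchNorm)]
        return mods

    def save(self, path: str) -> None:
        arrays = {f"arr{i}": v for i, v in enumerate(self.state())}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path: str) -> "PerfusionDLM":
        data = np.load(path, allow_pickle=False)
        config = ModelConfig(**json.loads(str(data["config"])))
        model = cls(config)
        n = len([k for k in data.files if k.startswith("arr")])
        model.load_state([data[f"arr{i}"] for i in range(n)])
        return model


def select_checkpoint(errors: list[float]) -> int:
    """Index of the checkpoint with minimal validation error; ties -> earliest."""
    return int(np.argmin(errors))


@dataclass
class TrainResult:
    model: PerfusionDLM           # loaded with the best-validation checkpoint
    log: pd.DataFrame
    best_epoch: int
    cpm_scale: float
    score_scale: float
    final_state: list | None = None  # last-epoch weights, for diagnostics


def _validation_mse(model, val_inputs, val_scores) -> float:
    ds = model.config.effective_dot_scale
    bias = (
        float(model.score_bias.value[0]) if model.config.score_intercept else 0.0
    )
    preds = []
    for x in val_inputs:
        sub = model.substrate_for(x[None])[0]
        preds.append(bias + ds * float(np.sum(sub * x[..., 0])))
    return float(np.mean((np.asarray(preds) - np.asarray(val_scores)) ** 2))


def train(
    cpms: dict,
    scores: dict,
    split: CohortSplit,
    config: ModelConfig,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Fit one perfusion-deficit model for one sub-score.

    ``cpms`` and ``scores`` map patient id -> native-grid CPM / ordinal
    score.  CPMs are normalised by the training cohort's 99th-percentile
    intensity before entering the network (recorded as ``cpm_scale``), and
    scores by ``config.score_scale``.  After every epoch the validation
    score-reconstruction MSE (at the posterior mean) is logged; the returned
    model is the checkpoint minimising it, ties resolved to the earliest
    epoch.  Raises on divergence (non-finite loss).
    """
    if epochs is None:
        epochs = config.max_epochs
    epochs = min(epochs, config.max_epochs)
    model = PerfusionDLM(config)
    if config.score_intercept:
        # start the readout intercept at the cohort-mean score so training
        # gradients are centred from the first step
        mean_score = float(
            np.mean([scores[i] for i in split.train_ids])
        ) / config.score_scale
        model.score_bias.value[0] = mean_score
    optim = nn.Adam(
        model.params(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 21]))

    all_train = [c for c in split.train_ids]
    cpm_scale = float(
        np.percentile(np.concatenate([cpms[i].ravel() for i in all_train]), 99)
    )
    if cpm_scale <= 0:
        cpm_scale = 1.0

    def make_input(i):
        return assemble_input(
            cpms[i], scores[i], config.score_scale, config.input_shape, cpm_scale
        )

    train_inputs = {i: make_input(i) for i in all_train}
    val_inputs = [make_input(i) for i in split.validation_ids]
    val_scores = [scores[i] / config.score_scale for i in split.validation_ids]

    rows = []
    best: tuple[float, int, list] | None = None
    for epoch in range(epochs):
        order = rng.permutation(len(all_train))
        comps = {"loss": 0.0, "kl": 0.0, "l2_cpm": 0.0, "l2_score": 0.0}
        nb = 0
        for start in range(0, len(order), config.batch_size):
            ids = [all_train[j] for j in order[start : start + config.batch_size]]
            x = np.stack([train_inputs[i] for i in ids])
            s = np.asarray(
                [scores[i] / config.score_scale for i in ids], dtype=np.float64
            )
            out = model.train_step(x, s, optim, rng)
            if not np.isfinite(out["loss"]):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            for key in comps:
                comps[key] += out[key]
            nb += 1
        for key in comps:
            comps[key] /= max(nb, 1)
        val_mse = _validation_mse(model, val_inputs, val_scores)
        rows.append({"epoch": epoch, **comps, "val_mse": val_mse})
        if best is None or val_mse < best[0]:
            best = (val_mse, epoch, model.state())
        if verbose:
            print(
                f"epoch {epoch:4d}  loss {comps['loss']:.4g}  "
                f"val_mse {val_mse:.4g}"
            )
    final_state = model.state()
    model.load_state(best[2])
    return TrainResult(
        model=model,
        log=pd.DataFrame(rows),
        best_epoch=best[1],
        cpm_scale=cpm_scale,
        score_scale=config.score_scale,
        final_state=final_state,
    )


def infer_substrate(
    result: TrainResult,
    cpms: dict,
    scores: dict,
    ids: list,
    native_shape: tuple[int, int, int] | None = None,
    reduce: str = "mean",
) -> np.ndarray:
    """Population substrate: per-patient posterior-mean decodes, averaged.

    Each patient's substrate is decoded from the posterior mean of their
    latent code; the population map is the voxel-wise mean (or median) over
    ``ids``, cropped back to the native CPM grid.
    """
    if not ids:
        raise ValueError("empty patient subset")
    model = result.model
    maps = []
    for i in ids:
        x = assemble_input(
            cpms[i],
            scores[i],
            result.score_scale,
            model.config.input_shape,
            result.cpm_scale,
        )
        maps.append(model.substrate_for(x[None])[0])
    stack = np.stack(maps)
    if reduce == "mean":
        pop = stack.mean(axis=0)
    elif reduce == "median":
        pop = np.median(stack, axis=0)
    else:
        raise ValueError("reduce must be 'mean' or 'median'")
    if native_shape is not None:
        pop = crop_to_shape(pop, native_shape)
    return np.asarray(pop, dtype=np.float64)


def calibrate_threshold(
    substrate: np.ndarray,
    cal_cpms: list[np.ndarray],
    cal_scores: list[float],
    grid_lo: float = 90.5,
    grid_hi: float = 99.5,
    step: float = 0.5,
    metric: str = "mae",
) -> tuple[float, np.ndarray, pd.DataFrame]:
    """Percentile calibration of the population substrate.

    For each candidate percentile in [grid_lo, grid_hi] (step 0.5 by
    default, 19 candidates over 90.5-99.5) the substrate is binarised at
    that percentile of its own weights; each calibration patient's score is
    predicted as the dot product of the binary map with their perfusion map
    after a least-squares scale fit, and the candidate is scored by the
    chosen accuracy metric (negative MAE by default; 'mse' and 'spearman'
    also available).  Returns (best percentile, binary map, per-candidate
    table); ties resolve to the lowest percentile.
    """
    substrate = np.asarray(substrate, dtype=np.float64)
    if np.ptp(substrate) == 0:
        raise ValueError("constant substrate: calibration degenerate")
    if len(cal_cpms) == 0:
        raise ValueError("need at least one calibration patient")
    if len(cal_cpms) != len(cal_scores):
        raise ValueError("cpms and scores length mismatch")
    candidates = np.arange(grid_lo, grid_hi + step / 2, step)
    scores_arr = np.asarray(cal_scores, dtype=np.float64)
    rows = []
    best = None
    for p in candidates:
        thr = np.percentile(substrate, p)
        binary = (substrate > thr).astype(np.float64)
        if binary.sum() == 0:
            acc = -np.inf
            rows.append({"percentile": p, "accuracy": acc, "n_voxels": 0})
            continue
        raw = np.array([predict_score(binary, c) for c in cal_cpms])
        denom = float(raw @ raw)
        a = float(raw @ scores_arr) / denom if denom > 0 else 0.0
        pred = a * raw
        if metric == "mae":
            acc = -float(np.mean(np.abs(pred - scores_arr)))
        elif metric == "mse":
            acc = -float(np.mean((pred - scores_arr) ** 2))
        elif metric == "spearman":
            from scipy.stats import spearmanr

            rho = spearmanr(pred, scores_arr).statistic
            acc = float(rho) if np.isfinite(rho) else -np.inf
        else:
            raise ValueError("metric must be 'mae', 'mse' or 'spearman'")
        rows.append({"percentile": p, "accuracy": acc, "n_voxels": int(binary.sum())})
        if best is None or acc > best[0]:
            best = (acc, p, binary)
    if best is None or not np.isfinite(best[0]):
        raise ValueError("calibration failed: no candidate produced voxels")
    table = pd.DataFrame(rows)
    return float(best[1]), best[2], table
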