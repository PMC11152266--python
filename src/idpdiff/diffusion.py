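"""Sequence-conditioned latent denoising diffusion over Cα encodings.

The generative model lives in the autoencoder's latent space: a forward
process gradually replaces an encoding ``z_0 ∈ R^{L×c}`` with Gaussian
noise according to a sigmoid signal schedule (``T = 1000`` steps), and a
transformer noise-prediction network ``ε_θ(z_t, t, a)`` — conditioned on
the amino-acid sequence ``a`` and the timestep through adaLN-Zero
modulation, with the noisy input re-injected at every block — is trained
with the simple noise-matching objective ``‖ε − ε_θ‖²``.

Sampling runs the deterministic accelerated (implicit, η = 0) reverse
recursion over a strided subsequence of timesteps (default 100 of 1000) and
decodes the final latent with the autoencoder's decoder.  Full ancestral
sampling over all ``T`` steps is available for cross-checks.

Encodings are standardized per channel before diffusion (``LatentScaler``)
so the terminal distribution matches the unit Gaussian the reverse process
starts from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autodiff import Tensor, embedding_lookup, no_grad
from .autoencoder import AEParams
from .geometry import Ensemble, InvalidInputError, Sequence


# ------------------------------------------------------------------ schedule
@dataclass
class NoiseSchedule:
    """Signal-retention curve ᾱ_t, t = 0…T with ᾱ_0 = 1."""

    T: int
    alpha_bar: np.ndarray  # shape (T+1,), strictly decreasing, ᾱ_0 = 1

    def __post_init__(self):
        if len(self.alpha_bar) != self.T + 1:
            raise InvalidInputError("alpha_bar must have T+1 entries")
        if (np.diff(self.alpha_bar) >= 0).any():
            raise InvalidInputError("alpha_bar must be strictly decreasing")


def build_schedule(T: int, kind: str = "sigmoid", lambda_min: float = -3.0,
                   lambda_max: float = 3.0, alpha_final: float = 1e-4
                   ) -> NoiseSchedule:
    """Construct the noise schedule.

    ``sigmoid``: ᾱ(t) follows σ(−λ(t)) with λ linear in t, rescaled so that
    ᾱ(0) = 1 exactly and ᾱ(T) = ``alpha_final``.  ``linear`` (for
    cross-checks) interpolates ᾱ linearly between the same endpoints.
    """
    if T < 2:
        raise InvalidInputError("schedule needs T >= 2")
    t = np.arange(T + 1) / T
    if kind == "sigmoid":
        lam = lambda_min + (lambda_max - lambda_min) * t
        v = 1.0 / (1.0 + np.exp(lam))  # σ(−λ)
        ab = alpha_final + (1.0 - alpha_final) * (v - v[-1]) / (v[0] - v[-1])
    elif kind == "linear":
        ab = 1.0 + (alpha_final - 1.0) * t
    else:
        raise InvalidInputError(f"unknown schedule kind: {kind!r}")
    return NoiseSchedule(T, ab)


def perturb(z0: np.ndarray, t, eps: np.ndarray, sched: NoiseSchedule
            ) -> np.ndarray:
    """Closed-form forward noising: z_t = √ᾱ_t z_0 + √(1−ᾱ_t) ε."""
    t = np.asarray(t)
    if ((t < 1) | (t > sched.T)).any():
        raise InvalidInputError(f"t must be in [1, {sched.T}]")
    ab = sched.alpha_bar[t]
    shape = (-1,) + (1,) * (np.asarray(z0).ndim - 1) if t.ndim else ()
    ab = ab.reshape(shape) if t.ndim else ab
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


# ------------------------------------------------------------- latent scaling
class LatentScaler:
    """Per-channel affine standardization of encodings before diffusion."""

    def __init__(self, mean: np.ndarray, std: np.ndarray, floor: float = 1e-6):
        self.mean = np.asarray(mean, dtype=np.float64)
        self.std = np.maximum(np.asarray(std, dtype=np.float64), floor)

    @classmethod
    def fit(cls, encodings: list[np.ndarray]) -> "LatentScaler":
        flat = np.concatenate([np.asarray(z).reshape(-1, z.shape[-1])
                               for z in encodings], axis=0)
        return cls(flat.mean(axis=0), flat.std(axis=0))

    def forward(self, z: np.ndarray) -> np.ndarray:
        return (z - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LatentScaler":
        return cls(np.array(d["mean"]), np.array(d["std"]))


# -------------------------------------------------------------------- network
@dataclass
class NoiseNetConfig:
    c: int = 16
    width: int = 64
    blocks: int = 2        # production-scale models use 16+; desk-scale toy is 2
    heads: int = 4
    relpos_clip: int = 32
    n_aa: int = 20
    t_embed_dim: int = 64


class NoiseNet(nn.Module):
    """Transformer ε_θ with adaLN-Zero conditioning and input re-injection.

    The conditioning vector combines a sinusoidal timestep embedding
    (shared across residues) with a learned per-residue amino-acid
    embedding; each block receives it through zero-initialized
    scale/shift/gate modulation, so at initialization every block is the
    identity and the output is the (zero-initialized) final projection of
    the unmodulated stream.
    """

    def __init__(self, cfg: NoiseNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.width
        self.inp = self._adopt("inp", nn.Linear(rng, cfg.c, w))
        self.aa_embed = self._register(
            "aa_embed", Tensor(rng.normal(0, 0.3, (cfg.n_aa, w)), requires_grad=True))
        self.cond_mlp1 = self._adopt("cond_mlp1", nn.Linear(rng, w, w))
        self.cond_mlp2 = self._adopt("cond_mlp2", nn.Linear(rng, w, w))
        self.t_proj = self._adopt("t_proj", nn.Linear(rng, cfg.t_embed_dim, w))
        n_rel = 2 * cfg.relpos_clip + 1
        self.relpos = self._register(
            "relpos", Tensor(rng.normal(0, 0.02, (n_rel, cfg.heads)), requires_grad=True))
        self.blocks = [
            self._adopt(f"block{i}", nn.AdaLNZeroBlock(rng, w, cfg.heads))
            for i in range(cfg.blocks)
        ]
        self.inject = [
            self._adopt(f"inject{i}", nn.Linear(rng, cfg.c, w))
            for i in range(cfg.blocks)
        ]
        self.final_ln = self._adopt("final_ln", nn.LayerNorm(w, affine=False))
        self.final_mod = self._adopt("final_mod", nn.Linear(rng, w, 2 * w, zero_init=True))
        self.out = self._adopt("out", nn.Linear(rng, w, cfg.c, zero_init=True))

    def __call__(self, z_t, t, aa_idx: np.ndarray) -> Tensor:
        if not isinstance(z_t, Tensor):
            z_t = Tensor(np.asarray(z_t, dtype=np.float64))
        if z_t.ndim == 2:
            z_t = z_t.reshape(1, *z_t.shape)
        B, L, c = z_t.shape
        aa_idx = np.asarray(aa_idx)
        if c != self.cfg.c or len(aa_idx) != L:
            raise InvalidInputError(
                f"shape mismatch: z_t {z_t.shape}, sequence length {len(aa_idx)}")
        temb = nn.sinusoidal_embedding(np.broadcast_to(np.asarray(t), (B,)),
                                       self.cfg.t_embed_dim)
        cond = self.t_proj(Tensor(temb)).reshape(B, 1, self.cfg.width) \
            + embedding_lookup(self.aa_embed, aa_idx)
        cond = self.cond_mlp2(nn.gelu(self.cond_mlp1(cond)))
        rel = nn.relative_positions(L, self.cfg.relpos_clip)
        bias = embedding_lookup(self.relpos, rel)
        bias = bias.transpose(2, 0, 1).reshape(1, self.cfg.heads, L, L)
        x = self.inp(z_t)
        for blk, inj in zip(self.blocks, self.inject):
            x = blk(x + inj(z_t), cond, bias)
        w = self.cfg.width
        m = self.final_mod(nn.gelu(cond))
        x = self.final_ln(x) * (m[..., w:] + 1.0) + m[..., :w]
        return self.out(x)

    # ------------------------------------------------------ fast inference
    def apply_np(self, z_t: np.ndarray, t, aa_idx: np.ndarray,
                 dtype=np.float64) -> np.ndarray:
        """Graph-free numpy forward pass (inference only).

        Numerically identical to ``__call__`` at float64; used in the inner
        sampling loop where building the autodiff graph would dominate
        runtime.  A parity test pins the two paths together.  ``dtype`` may
        be ``np.float32`` for long sampling chains where single precision
        is ample.
        """
        P = {k: v.data.astype(dtype) for k, v in self.params.items()}

        def lin(name, x):
            return x @ P[f"{name}.w"] + P[f"{name}.b"]

        def ln(x, name=None):
            mu = x.mean(-1, keepdims=True)
            xc = x - mu
            y = xc / np.sqrt((xc * xc).mean(-1, keepdims=True) + 1e-5)
            if name is not None:
                y = y * P[f"{name}.g"] + P[f"{name}.b"]
            return y

        def gelu_np(x):
            return x * 0.5 * (np.tanh((x + 0.044715 * (x * x * x)) * np.sqrt(2 / np.pi)) + 1.0)

        z_t = np.asarray(z_t, dtype=dtype)
        if z_t.ndim == 2:
            z_t = z_t[None]
        B, L, _ = z_t.shape
        wdt, H = self.cfg.width, self.cfg.heads
        dk = wdt // H
        # at a scalar timestep the conditioning is shared by the whole batch
        t_arr = np.asarray(t)
        Bc = 1 if t_arr.ndim == 0 else B
        temb = nn.sinusoidal_embedding(np.broadcast_to(t_arr, (Bc,)),
                                       self.cfg.t_embed_dim).astype(dtype)
        cond = lin("t_proj", temb)[:, None, :] + P["aa_embed"][np.asarray(aa_idx)]
        cond = lin("cond_mlp2", gelu_np(lin("cond_mlp1", cond)))
        gcond = gelu_np(cond)
        rel = nn.relative_positions(L, self.cfg.relpos_clip)
        bias = P["relpos"][rel].transpose(2, 0, 1)[None]  # (1, H, L, L)

        def attn(prefix, x):
            def split(y):
                return y.reshape(B, L, H, dk).transpose(0, 2, 1, 3)
            q = split(lin(f"{prefix}.wq", x))
            k = split(lin(f"{prefix}.wk", x))
            v = split(lin(f"{prefix}.wv", x))
            logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(dk) + bias
            logits -= logits.max(-1, keepdims=True)
            e = np.exp(logits)
            a = e / e.sum(-1, keepdims=True)
            o = (a @ v).transpose(0, 2, 1, 3).reshape(B, L, wdt)
            return lin(f"{prefix}.wo", o)

        x = lin("inp", z_t)
        for i in range(self.cfg.blocks):
            x = x + lin(f"inject{i}", z_t)
            m = lin(f"block{i}.mod", gcond)
            sh1, sc1, g1 = m[..., :wdt], m[..., wdt:2*wdt], m[..., 2*wdt:3*wdt]
            sh2, sc2, g2 = m[..., 3*wdt:4*wdt], m[..., 4*wdt:5*wdt], m[..., 5*wdt:]
            h = ln(x) * (sc1 + 1.0) + sh1
            x = x + g1 * attn(f"block{i}.attn", h)
            h = ln(x) * (sc2 + 1.0) + sh2
            h = lin(f"block{i}.ff.l2", gelu_np(lin(f"block{i}.ff.l1", h)))
            x = x + g2 * h
        m = lin("final_mod", gcond)
        x = ln(x) * (m[..., wdt:] + 1.0) + m[..., :wdt]
        return lin("out", x)


# ------------------------------------------------------------------- training
def ddpm_loss(z0_batch: np.ndarray, aa_idx: np.ndarray, sched: NoiseSchedule,
              net: NoiseNet, rng: np.random.Generator) -> Tensor:
    """L_simple: per-item uniform t, fresh Gaussian ε, mean squared error."""
    B = z0_batch.shape[0]
    if B == 0:
        raise InvalidInputError("empty batch")
    t = rng.integers(1, sched.T + 1, size=B)
    eps = rng.normal(size=z0_batch.shape)
    z_t = perturb(z0_batch, t, eps, sched)
    pred = net(z_t, t, aa_idx)
    return ((pred - Tensor(eps)) ** 2).mean()


@dataclass
class DDPMTrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    warmup_frac: float = 0.05
    seed: int = 0
    replicas: int = 1
    n_frames: int = 200
    val_frames: int = 200


@dataclass
class EncodedSystem:
    """Encodings of one system's ensemble, tied to its sequence."""

    sequence: Sequence
    z: np.ndarray  # (N, L, c), standardized latents


def encode_dataset(systems: list[Ensemble], ae: AEParams
                   ) -> tuple[list[EncodedSystem], LatentScaler]:
    """Encode ensembles with a trained (frozen) encoder and fit the latent scaler."""
    raw = [ae.encode(e.coords) for e in systems]
    scaler = LatentScaler.fit(raw)
    return (
        [EncodedSystem(e.sequence, scaler.forward(z))
         for e, z in zip(systems, raw)],
        scaler,
    )


def _validation_ddpm(net: NoiseNet, systems: list[EncodedSystem],
                     sched: NoiseSchedule, n_frames: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    total, count = 0.0, 0
    with no_grad():
        for s in systems:
            take = min(n_frames, len(s.z))
            idx = rng.choice(len(s.z), size=take, replace=False)
            loss = ddpm_loss(s.z[idx], s.sequence.indices, sched, net, rng)
            total += float(loss.data) * take
            count += take
    return total / count


def train_ddpm(train_systems: list[EncodedSystem],
               val_systems: list[EncodedSystem],
               cfg: DDPMTrainConfig, sched: NoiseSchedule,
               arch: NoiseNetConfig | None = None,
               verbose: bool = False) -> tuple[NoiseNet, dict]:
    """Train ε_θ on encoded conformations; replica with best validation wins."""
    if not train_systems:
        raise InvalidInputError("empty training set")
    if not val_systems:
        raise InvalidInputError("validation set must not be empty")
    arch = arch or NoiseNetConfig(c=train_systems[0].z.shape[-1])
    best_net, best_val = None, np.inf
    log: dict = {"replicas": [], "config": asdict(cfg)}
    for rep in range(cfg.replicas):
        seed = cfg.seed + rep
        rng = np.random.default_rng(seed)
        net = NoiseNet(arch, np.random.default_rng(seed))
        opt = nn.Adam(net.params, lr=cfg.lr)
        steps_per_epoch = max(
            1, sum(min(cfg.n_frames, len(s.z)) for s in train_systems)
            // cfg.batch_size)
        total = cfg.epochs * steps_per_epoch
        lr_at = nn.warmup_cosine_schedule(cfg.lr, int(cfg.warmup_frac * total), total)
        rep_log = {"seed": seed, "train": [], "val": []}
        rep_best, rep_state = np.inf, None
        step = 0
        for epoch in range(cfg.epochs):
            batches = []
            for s in train_systems:
                take = min(cfg.n_frames, len(s.z))
                idx = rng.choice(len(s.z), size=take, replace=False)
                for i in range(0, take, cfg.batch_size):
                    batches.append((s, idx[i:i + cfg.batch_size]))
            order = rng.permutation(len(batches))
            ep_loss, ep_n = 0.0, 0
            for bi in order:
                s, idx = batches[bi]
                loss = ddpm_loss(s.z[idx], s.sequence.indices, sched, net, rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite DDPM loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step(lr=lr_at(step))
                step += 1
                ep_loss += float(loss.data) * len(idx)
                ep_n += len(idx)
            val = _validation_ddpm(net, val_systems, sched, cfg.val_frames,
                                   seed + 20_000)
            rep_log["train"].append(ep_loss / max(ep_n, 1))
            rep_log["val"].append(val)
            if val < rep_best:
                rep_best = val
                rep_state = net.state_arrays()
            if verbose:
                print(f"[DDPM rep {rep}] epoch {epoch}: "
                      f"train {rep_log['train'][-1]:.4f} val {val:.4f}")
        net.load_state_arrays(rep_state)
        rep_log["best_val"] = rep_best
        log["replicas"].append(rep_log)
        if rep_best < best_val:
            best_val = rep_best
            best_net = net
    log["selected_replica"] = int(np.argmin([r["best_val"] for r in log["replicas"]]))
    log["best_val"] = best_val
    return best_net, log


# ------------------------------------------------------------------- sampling
@dataclass
class SampleConfig:
    n_samples: int = 100
    steps: int = 100
    eta: float = 0.0       # 0 = deterministic implicit sampling
    seed: int = 0
    batch_size: int = 2000
    precision: str = "double"  # "double" | "single" network inference

    @property
    def dtype(self):
        return np.float32 if self.precision == "single" else np.float64


def timestep_subsequence(T: int, steps: int) -> np.ndarray:
    """Uniformly strided decreasing timesteps including T and 1."""
    if not 1 <= steps <= T:
        raise InvalidInputError(f"steps must be in [1, {T}]")
    ts = np.unique(np.round(np.linspace(1, T, steps)).astype(int))[::-1]
    return ts


def _reverse_ddim(z: np.ndarray, ts: np.ndarray, aa_idx: np.ndarray,
                  sched: NoiseSchedule, net: NoiseNet, eta: float,
                  rng: np.random.Generator, dtype=np.float64) -> np.ndarray:
    """Implicit (DDIM-style) reverse recursion over the subsequence ``ts``."""
    ab = sched.alpha_bar
    with no_grad():
        for i, t in enumerate(ts):
            t_prev = ts[i + 1] if i + 1 < len(ts) else 0
            eps_hat = net.apply_np(z, t, aa_idx, dtype=dtype)
            ab_t, ab_p = ab[t], ab[t_prev]
            z0_hat = (z - np.sqrt(1.0 - ab_t) * eps_hat) / np.sqrt(ab_t)
            sigma = 0.0
            if eta > 0 and t_prev > 0:
                sigma = (eta * np.sqrt((1 - ab_p) / (1 - ab_t))
                         * np.sqrt(1 - ab_t / ab_p))
            dir_coef = np.sqrt(max(1.0 - ab_p - sigma**2, 0.0))
            z = np.sqrt(ab_p) * z0_hat + dir_coef * eps_hat
            if sigma > 0:
                z = z + sigma * rng.normal(size=z.shape)
    return z


def sample_latents(seq: Sequence, cfg: SampleConfig, sched: NoiseSchedule,
                   net: NoiseNet) -> np.ndarray:
    """Generate standardized latents (N, L, c) via accelerated reverse diffusion."""
    rng = np.random.default_rng(cfg.seed)
    ts = timestep_subsequence(sched.T, cfg.steps)
    aa_idx = seq.indices
    out = []
    for start in range(0, cfg.n_samples, cfg.batch_size):
        nb = min(cfg.batch_size, cfg.n_samples - start)
        z = rng.normal(size=(nb, len(seq), net.cfg.c))
        out.append(_reverse_ddim(z, ts, aa_idx, sched, net, cfg.eta, rng,
                                 dtype=cfg.dtype))
    return np.concatenate(out, axis=0)


def sample(seq: Sequence, cfg: SampleConfig, sched: NoiseSchedule,
           net: NoiseNet, ae: AEParams, latent_scaler: LatentScaler
           ) -> Ensemble:
    """Full generative path: noise → latents → decoded Cα ensemble."""
    z = sample_latents(seq, cfg, sched, net)
    coords = ae.decode(latent_scaler.inverse(z))
    return Ensemble(seq, coords)


def ancestral_sample(seq: Sequence, n_samples: int, sched: NoiseSchedule,
                     net: NoiseNet, ae: AEParams, latent_scaler: LatentScaler,
                     seed: int = 0, batch_size: int = 2000,
                     dtype=np.float64) -> Ensemble:
    """Stochastic ancestral reverse diffusion over all T steps (reference path)."""
    rng = np.random.default_rng(seed)
    aa_idx = seq.indices
    ab = sched.alpha_bar
    out = []
    with no_grad():
        for start in range(0, n_samples, batch_size):
            nb = min(batch_size, n_samples - start)
            z = rng.normal(size=(nb, len(seq), net.cfg.c))
            for t in range(sched.T, 0, -1):
                eps_hat = net.apply_np(z, t, aa_idx, dtype=dtype)
                alpha_t = ab[t] / ab[t - 1]
                beta_t = 1.0 - alpha_t
                z = (z - beta_t / np.sqrt(1.0 - ab[t]) * eps_hat) / np.sqrt(alpha_t)
                if t > 1:
                    var = beta_t * (1.0 - ab[t - 1]) / (1.0 - ab[t])
                    z = z + np.sqrt(var) * rng.normal(size=z.shape)
            out.append(z)
    z = np.concatenate(out, axis=0)
    coords = ae.decode(latent_scaler.inverse(z))
    return Ensemble(seq, coords)


# ---------------------------------------------------------------- checkpoints
def save_ddpm_checkpoint(path, net: NoiseNet, sched: NoiseSchedule,
                         latent_scaler: LatentScaler) -> None:
    header = {"kind": "idpdiff-ddpm", "version": 1,
              "config": asdict(net.cfg), "T": sched.T,
              "latent_scaler": latent_scaler.to_dict()}
    np.savez(path,
             __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             __alpha_bar__=sched.alpha_bar,
             **net.state_arrays())


def load_ddpm_checkpoint(path) -> tuple[NoiseNet, NoiseSchedule, LatentScaler]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("kind") != "idpdiff-ddpm":
            raise InvalidInputError(f"{path} is not a diffusion checkpoint")
        cfg = NoiseNetConfig(**header["config"])
        net = NoiseNet(cfg, np.random.default_rng(0))
        net.load_state_arrays(
            {k: data[k] for k in data.files if not k.startswith("__")})
        sched = NoiseSchedule(header["T"], data["__alpha_bar__"])
        scaler = LatentScaler.from_dict(header["latent_scaler"])
    return net, sched, scaler
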