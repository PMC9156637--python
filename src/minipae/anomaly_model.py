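"""Adversarial auto-encoder for unsupervised emphysema detection.

The generator is a skip-connected encoder-decoder (U-Net style): strided
4x4 convolutions halve the image down to a 2x2 latent representation and
transposed convolutions mirror the path back up, with encoder feature maps
forwarded to the decoder through dropout-regularised skip connections.
Every layer is followed by batch normalisation and a leaky ReLU; the output
layer is a tanh so reconstructions live in the same [-1, 1] range as the
windowed input. The discriminator mirrors the encoder and ends in a single
logit; its last-convolution feature maps are exposed — they define the
latent representation used for scoring.

Training uses only slices from participants without emphysema, minimising
three losses: contextual (L1 between input X and reconstruction X'),
latent (L2 between discriminator feature maps of X and X'), and
adversarial (binary cross-entropy against the discriminator). Because the
model only ever sees normal parenchyma, low-attenuation lesions at
inference time reconstruct poorly and score high.

Layer counts scale with image size (log2(size) - 1 down-sampling steps),
so a 512-pixel configuration has 8 encoder + 8 decoder generator layers
and 8 discriminator layers, while 64-pixel models stay CPU-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn as _nn
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    LeakyReLU,
    Tanh,
    bce_with_logits,
    bce_with_logits_grad,
    sigmoid,
)
from .phantom import LABEL_NORMAL


def nn_dtype():
    return _nn.DTYPE


@dataclass
class ModelConfig:
    """Hyper-parameters of the adversarial auto-encoder.

    ``image_size`` 512 reproduces the full-scale architecture (8+8
    generator layers, 8 discriminator layers); 64 is the CPU test scale.
    Loss weights follow the convention of reconstruction-based adversarial
    anomaly detectors: the contextual term dominates (50), latent and
    adversarial terms weigh 1. The optimiser is Adam at lr 2e-4.
    """

    image_size: int = 64
    base_channels: int = 8
    kernel: int = 4
    stride: int = 2
    dropout_p: float = 0.25
    #: number of decoder levels (coarsest first) that receive skip
    #: connections; None means every level (the full-scale U-Net layout).
    #: The test-scale default is 0: at 64 px any informative skip lets the
    #: decoder copy small anomalies into the reconstruction, erasing the
    #: residual signal the scorer depends on.
    skip_levels: int | None = 0
    loss_weights: tuple[float, float, float] = (50.0, 1.0, 1.0)  # contextual, latent, adversarial
    score_weight: float = 0.9  # w_r: share of contextual loss in the raw anomaly score
    lr: float = 2e-4
    #: discriminator learning-rate factor (< 1 slows the discriminator
    #: relative to the generator)
    d_lr_factor: float = 1.0
    #: global-norm clip on generator gradients per step (None disables)
    grad_clip: float | None = None
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0
    disc_augment: tuple[str, ...] = ("flip", "translate", "cutout")
    augment_prob: float = 0.3

    @property
    def n_down(self) -> int:
        n = int(np.log2(self.image_size)) - 1
        if 2**int(np.log2(self.image_size)) != self.image_size or n < 2:
            raise ValueError("image_size must be a power of 2, at least 8")
        return n


@dataclass
class LossTerms:
    contextual: float
    latent: float
    adversarial: float
    weights: tuple[float, float, float] = (50.0, 1.0, 1.0)

    @property
    def total(self) -> float:
        wc, wl, wa = self.weights
        return wc * self.contextual + wl * self.latent + wa * self.adversarial


@dataclass
class AnomalyResult:
    score: float
    raw_score: float
    reconstruction: np.ndarray
    slice_index: int = 0
    participant_id: str = ""


def _enc_channels(cfg: ModelConfig) -> list[int]:
    return [cfg.base_channels * min(2**i, 8) for i in range(cfg.n_down)]


class Generator:
    """Skip-connected encoder-decoder with explicit backward pass."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ch = _enc_channels(cfg)
        k, s = cfg.kernel, cfg.stride
        self.enc = []
        cin = 1
        for i, c in enumerate(ch):
            conv = Conv2d(cin, c, k, s, 1, rng)
            bn = BatchNorm2d(c) if i > 0 else None
            self.enc.append((conv, bn, LeakyReLU()))
            cin = c
        self.dec = []
        n = len(ch)
        n_skip = n - 1 if cfg.skip_levels is None else min(cfg.skip_levels, n - 1)
        self.has_skip = [i < n_skip for i in range(n)]  # coarsest levels first
        dec_in = ch[-1]
        for i in range(n):
            last = i == n - 1
            cout = 1 if last else ch[n - 2 - i]
            convt = ConvTranspose2d(dec_in, cout, k, s, 1, rng)
            bn = None if last else BatchNorm2d(cout)
            act = Tanh() if last else LeakyReLU()
            self.dec.append((convt, bn, act))
            dec_in = cout + (ch[n - 2 - i] if not last and self.has_skip[i] else 0)
        self.skip_dropout = Dropout(cfg.dropout_p)

    def params(self):
        ps = []
        for conv, bn, _ in self.enc + self.dec:
            ps += conv.params()
            if bn is not None:
                ps += bn.params()
        return ps

    def forward(self, x, train=True, rng=None):
        feats, ecaches = [], []
        h = x
        for conv, bn, act in self.enc:
            h, cc = conv.forward(h, train, rng)
            bc = None
            if bn is not None:
                h, bc = bn.forward(h, train, rng)
            h, ac = act.forward(h, train, rng)
            ecaches.append((cc, bc, ac))
            feats.append(h)
        skips = feats[:-1][::-1]
        h = feats[-1]
        dcaches = []
        for i, (convt, bn, act) in enumerate(self.dec):
            h, cc = convt.forward(h, train, rng)
            bc = None
            if bn is not None:
                h, bc = bn.forward(h, train, rng)
            h, ac = act.forward(h, train, rng)
            dc = None
            if i < len(self.dec) - 1 and self.has_skip[i]:
                skip, dc = self.skip_dropout.forward(skips[i], train, rng)
                h = np.concatenate([h, skip], axis=1)
            dcaches.append((cc, bc, ac, dc))
        return h, (ecaches, dcaches)

    def backward(self, dxp, cache):
        ecaches, dcaches = cache
        n_enc = len(self.enc)
        dskip_into_enc = [None] * n_enc  # gradient entering encoder feature i via skip
        dh = dxp
        for i in range(len(self.dec) - 1, -1, -1):
            convt, bn, act = self.dec[i]
            cc, bc, ac, dc = dcaches[i]
            if i < len(self.dec) - 1 and self.has_skip[i]:
                # split the concat: decoder channels first, then the skip
                skip_ch = dc.shape[1] if dc is not None else self.enc[n_enc - 2 - i][0].cout
                d_dec, d_skip = dh[:, :-skip_ch], dh[:, -skip_ch:]
                d_skip = self.skip_dropout.backward(d_skip, dc)
                dskip_into_enc[n_enc - 2 - i] = d_skip
                dh = d_dec
            dh = act.backward(dh, ac)
            if bn is not None:
                dh = bn.backward(dh, bc)
            dh = convt.backward(dh, cc)
        # dh now flows into the last encoder feature (the latent)
        for i in range(n_enc - 1, -1, -1):
            conv, bn, act = self.enc[i]
            cc, bc, ac = ecaches[i]
            if dskip_into_enc[i] is not None:
                dh = dh + dskip_into_enc[i]
            dh = act.backward(dh, ac)
            if bn is not None:
                dh = bn.backward(dh, bc)
            dh = conv.backward(dh, cc)
        return dh


class Discriminator:
    """Mirror of the generator's encoder plus a single-logit head.

    The feature maps after the last body convolution are the latent
    representation used for the latent loss and anomaly scoring.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        ch = _enc_channels(cfg)
        k, s = cfg.kernel, cfg.stride
        self.body = []
        cin = 1
        for i, c in enumerate(ch):
            conv = Conv2d(cin, c, k, s, 1, rng)
            bn = BatchNorm2d(c) if i > 0 else None
            self.body.append((conv, bn, LeakyReLU()))
            cin = c
        self.head = Conv2d(cin, 1, k, s, 1, rng)  # 2x2 -> 1x1 logit

    def params(self):
        ps = []
        for conv, bn, _ in self.body:
            ps += conv.params()
            if bn is not None:
                ps += bn.params()
        return ps + self.head.params()

    def forward(self, x, train=True, rng=None):
        caches = []
        h = x
        for conv, bn, act in self.body:
            h, cc = conv.forward(h, train, rng)
            bc = None
            if bn is not None:
                h, bc = bn.forward(h, train, rng)
            h, ac = act.forward(h, train, rng)
            caches.append((cc, bc, ac))
        feats = h
        logits, hc = self.head.forward(h, train, rng)
        return feats, logits.reshape(x.shape[0]), (caches, hc, feats.shape)

    def backward(self, dfeats, dlogits, cache):
        caches, hc, fshape = cache
        dh = np.zeros(fshape)
        if dlogits is not None:
            dh += self.head.backward(dlogits.reshape(-1, 1, 1, 1), hc)
        if dfeats is not None:
            dh += dfeats
        for i in range(len(self.body) - 1, -1, -1):
            conv, bn, act = self.body[i]
            cc, bc, ac = caches[i]
            dh = act.backward(dh, ac)
            if bn is not None:
                dh = bn.backward(dh, bc)
            dh = conv.backward(dh, cc)
        return dh


@dataclass
class AnomalyModel:
    config: ModelConfig
    generator: Generator
    discriminator: Discriminator
    history: dict = field(default_factory=dict)
    calibration: tuple[float, float] | None = None  # (min, max) raw score

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        xp, _ = self.generator.forward(x, train=False)
        return xp

    def discriminator_prob(self, x: np.ndarray) -> np.ndarray:
        """Per-image probability of being a real (normal) slice, in (0,1)."""
        _, logits, _ = self.discriminator.forward(x, train=False)
        return sigmoid(logits)


def build_model(config: ModelConfig) -> AnomalyModel:
    """Construct generator and discriminator with seed-deterministic weights."""
    config.n_down  # validates image_size
    rng = np.random.default_rng(config.seed)
    return AnomalyModel(config, Generator(config, rng), Discriminator(config, rng))


def compute_losses(x, xp, z, zp, d_real, d_fake, weights=(50.0, 1.0, 1.0)) -> LossTerms:
    """The three training losses.

    contextual: mean |X - X'| (L1); latent: mean squared difference of the
    latent feature maps; adversarial: binary cross-entropy of the
    discriminator's fake logits against the 'real' target (generator side).
    """
    if x.shape != xp.shape or z.shape != zp.shape:
        raise ValueError("shape mismatch between inputs and reconstructions")
    contextual = float(np.abs(x - xp).mean())
    latent = float(((z - zp) ** 2).mean())
    adversarial = bce_with_logits(d_fake, 1.0)
    return LossTerms(contextual, latent, adversarial, weights)


def _augment_pair(x, xp, cfg: ModelConfig, rng: np.random.Generator):
    """Apply one discriminator-heuristics augmentation identically to both
    images; returns the pair plus the (linear) adjoint for the gradient."""
    if not cfg.disc_augment or rng.random() >= cfg.augment_prob:
        return x, xp, lambda g: g
    kind = cfg.disc_augment[rng.integers(len(cfg.disc_augment))]
    size = x.shape[-1]
    if kind == "flip":
        return x[..., ::-1], xp[..., ::-1], lambda g: g[..., ::-1]
    if kind == "translate":
        dy, dx = rng.integers(-size // 8, size // 8 + 1, size=2)
        fwd = lambda a: np.roll(a, (dy, dx), axis=(-2, -1))
        return fwd(x), fwd(xp), lambda g: np.roll(g, (-dy, -dx), axis=(-2, -1))
    if kind == "cutout":
        c = size // 4
        y0, x0 = rng.integers(0, size - c + 1, size=2)
        mask = np.ones(x.shape[-2:])
        mask[y0 : y0 + c, x0 : x0 + c] = 0.0
        return x * mask, xp * mask, lambda g: g * mask
    return x, xp, lambda g: g


def train(model: AnomalyModel, slices: np.ndarray, labels=None, config: ModelConfig | None = None):
    """Train the adversarial auto-encoder on normal slices only.

    Parameters
    ----------
    slices : ndarray (n, size, size) in [-1, 1]
        Windowed minIP slices from non-emphysema participants.
    labels : optional sequence of per-slice participant labels; if given,
        any label other than "normal" raises — emphysema must never leak
        into training.

    Returns the model with ``history`` holding per-epoch means of the
    three generator losses and the discriminator loss.
    """
    cfg = config or model.config
    if labels is not None:
        bad = [l for l in labels if l != LABEL_NORMAL]
        if bad:
            raise ValueError(f"training set contains non-normal labels: {set(bad)}")
    x_all = np.asarray(slices, dtype=nn_dtype())[:, None]  # (n,1,H,W)
    n = x_all.shape[0]
    rng = np.random.default_rng(cfg.seed + 1)
    opt_g = Adam(model.generator.params(), lr=cfg.lr)
    opt_d = Adam(model.discriminator.params(), lr=cfg.lr * cfg.d_lr_factor)
    wc, wl, wa = cfg.loss_weights
    hist = {"contextual": [], "latent": [], "adversarial": [], "discriminator": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {k: [] for k in hist}
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs at least 2 samples
            x = x_all[idx]
            xp, gcache = model.generator.forward(x, train=True, rng=rng)
            xa, xpa, adjoint = _augment_pair(x, xp, cfg, rng)
            f_real, l_real, dcache_r = model.discriminator.forward(xa, train=True, rng=rng)
            f_fake, l_fake, dcache_f = model.discriminator.forward(xpa, train=True, rng=rng)

            terms = compute_losses(x, xp, f_real, f_fake, l_real, l_fake, cfg.loss_weights)
            d_loss = 0.5 * (bce_with_logits(l_real, 1.0) + bce_with_logits(l_fake, 0.0))

            # --- generator update: gradients flow through the discriminator
            # into X', but discriminator parameter grads from this pass are
            # discarded afterwards
            opt_g.zero_grad()
            opt_d.zero_grad()
            dxp = wc * np.sign(xp - x) / x.size
            dfeat_fake = wl * 2.0 * (f_fake - f_real) / f_fake.size
            dlogit_fake = wa * bce_with_logits_grad(l_fake, 1.0)
            dxpa = model.discriminator.backward(dfeat_fake, dlogit_fake, dcache_f)
            dxp = dxp + adjoint(dxpa)
            model.generator.backward(dxp, gcache)
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(sum(float((p.grad**2).sum()) for p in opt_g.params))
                if gnorm > cfg.grad_clip:
                    scale = cfg.grad_clip / gnorm
                    for p in opt_g.params:
                        p.grad *= scale
            opt_g.step()

            # --- discriminator update: X' treated as a constant
            opt_d.zero_grad()
            model.discriminator.backward(None, 0.5 * bce_with_logits_grad(l_real, 1.0), dcache_r)
            model.discriminator.backward(None, 0.5 * bce_with_logits_grad(l_fake, 0.0), dcache_f)
            opt_d.step()

            ep["contextual"].append(terms.contextual)
            ep["latent"].append(terms.latent)
            ep["adversarial"].append(terms.adversarial)
            ep["discriminator"].append(d_loss)
        for k in hist:
            hist[k].append(float(np.mean(ep[k])) if ep[k] else float("nan"))
    model.history = hist
    return model


class ScoreCalibration:
    """Statistics learned on normal (training) slices that anchor scoring.

    tau is the 95th-percentile signed residual inside normal lungs: the
    level of reconstruction excess that plain parenchyma reaches by chance.
    The mean/sd pairs standardise the contextual and latent terms so the
    weighted combination is scale-free.
    """

    __slots__ = ("tau", "c_mean", "c_sd", "l_mean", "l_sd")

    def __init__(self, tau, c_mean, c_sd, l_mean, l_sd):
        self.tau = float(tau)
        self.c_mean, self.c_sd = float(c_mean), float(max(c_sd, 1e-12))
        self.l_mean, self.l_sd = float(l_mean), float(max(l_sd, 1e-12))


def _erode2d(mask: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Erode a lung slice mask to its interior.

    May be empty (extreme apex/base slabs): such slices contain no
    reliable parenchyma and contribute a contextual score of 0 — scoring
    their boundary pixels instead would swamp the score with segmentation-
    edge residuals.
    """
    from scipy import ndimage

    return ndimage.binary_erosion(mask, iterations=iterations)


def score_terms(model: AnomalyModel, slices: np.ndarray, lung_masks=None,
                tau: float = 0.0, batch_size: int = 64):
    """Per-slice contextual and latent score terms plus reconstructions.

    With lung masks the contextual term is the mean positive part of the
    signed residual (X' - X) above ``tau`` inside the eroded lung — large
    when the input is darker than the model can explain, i.e. emphysema-
    like. Without masks it falls back to the plain mean absolute residual
    over the whole slice. The latent term is the mean squared difference
    of discriminator feature maps of X and X'.
    """
    x_all = np.asarray(slices, dtype=nn_dtype())
    if x_all.ndim == 2:
        x_all = x_all[None]
    x_all = x_all[:, None]
    n = x_all.shape[0]
    ctx = np.empty(n)
    lat = np.empty(n)
    recons = []
    eroded = None
    if lung_masks is not None:
        eroded = [_erode2d(m) for m in np.asarray(lung_masks, dtype=bool)]
    for start in range(0, n, batch_size):
        x = x_all[start : start + batch_size]
        xp, _ = model.generator.forward(x, train=False)
        f_real, _, _ = model.discriminator.forward(x, train=False)
        f_fake, _, _ = model.discriminator.forward(xp, train=False)
        diff = (xp - x)[:, 0].astype(np.float64)
        for j in range(diff.shape[0]):
            i = start + j
            if eroded is not None:
                m = eroded[i]
                ctx[i] = np.clip(diff[j][m] - tau, 0, None).mean() if m.any() else 0.0
            else:
                ctx[i] = np.abs(diff[j]).mean()
        lat[start : start + batch_size] = ((f_real - f_fake) ** 2).mean(axis=(1, 2, 3))
        recons.append(xp[:, 0])
    return ctx, lat, np.concatenate(recons)


def calibrate_scores(model: AnomalyModel, normal_slices: np.ndarray, lung_masks,
                     quantile: float = 95.0) -> ScoreCalibration:
    """Fit the scoring calibration on held-in normal slices.

    Pools signed residuals inside eroded normal lungs to set tau at the
    given percentile, then records mean/sd of both score terms at that
    tau. Stored on the model and used by subsequent scoring calls.
    """
    x_all = np.asarray(normal_slices, dtype=nn_dtype())[:, None]
    masks = [_erode2d(m) for m in np.asarray(lung_masks, dtype=bool)]
    pooled = []
    for start in range(0, x_all.shape[0], 64):
        x = x_all[start : start + 64]
        xp, _ = model.generator.forward(x, train=False)
        diff = (xp - x)[:, 0].astype(np.float64)
        for j in range(diff.shape[0]):
            if masks[start + j].any():
                pooled.append(diff[j][masks[start + j]])
    tau = float(np.percentile(np.concatenate(pooled), quantile))
    ctx, lat, _ = score_terms(model, normal_slices, lung_masks, tau=tau)
    cal = ScoreCalibration(tau, ctx.mean(), ctx.std(), lat.mean(), lat.std())
    model.score_calibration = cal
    return cal


def raw_anomaly_scores(model: AnomalyModel, slices: np.ndarray, lung_masks=None,
                       batch_size: int = 64):
    """Unnormalised anomaly scores and reconstructions for a set of slices.

    raw = w_r * contextual + (1 - w_r) * latent, with both terms
    standardised by the stored calibration when one exists (otherwise
    combined on their native scales).
    """
    wr = model.config.score_weight
    cal = getattr(model, "score_calibration", None)
    tau = cal.tau if (cal is not None and lung_masks is not None) else 0.0
    ctx, lat, recons = score_terms(model, slices, lung_masks, tau=tau, batch_size=batch_size)
    if cal is not None:
        raws = wr * (ctx - cal.c_mean) / cal.c_sd + (1 - wr) * (lat - cal.l_mean) / cal.l_sd
    else:
        raws = wr * ctx + (1 - wr) * lat
    return raws, recons


def score_slices(model: AnomalyModel, slices: np.ndarray, slice_indices=None,
                 lung_masks=None) -> list[AnomalyResult]:
    """Score a set of slices, min-max normalising raw scores into [0, 1].

    The minimum of the scored set maps to 0 and the maximum to 1; the
    (min, max) pair is stored on the model as calibration for later
    single-slice scoring.
    """
    raws, recons = raw_anomaly_scores(model, slices, lung_masks=lung_masks)
    lo, hi = float(raws.min()), float(raws.max())
    model.calibration = (lo, hi)
    if hi > lo:
        scores = (raws - lo) / (hi - lo)
    else:
        scores = np.full_like(raws, 0.5)
    idx = slice_indices if slice_indices is not None else range(len(raws))
    return [
        AnomalyResult(score=float(s), raw_score=float(r), reconstruction=rec, slice_index=int(i))
        for s, r, rec, i in zip(scores, raws, recons, idx)
    ]


def anomaly_score(model: AnomalyModel, slice_2d: np.ndarray, slice_index: int = 0,
                  lung_mask=None) -> AnomalyResult:
    """Score one slice.

    Uses the stored min-max calibration when available (clipped to [0, 1]);
    without calibration the raw score is squashed by a sigmoid — a
    documented fallback that preserves ordering but not the [min, max]
    anchoring.
    """
    masks = None if lung_mask is None else [lung_mask]
    raws, recons = raw_anomaly_scores(model, slice_2d[None], lung_masks=masks)
    raw = float(raws[0])
    if model.calibration is not None:
        lo, hi = model.calibration
        score = 0.5 if hi <= lo else float(np.clip((raw - lo) / (hi - lo), 0.0, 1.0))
    else:
        score = float(sigmoid(np.array(raw)))
    return AnomalyResult(score=score, raw_score=raw, reconstruction=recons[0], slice_index=slice_index)
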