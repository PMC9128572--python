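"""Multi-task CNN observers: the hybrid approximated IO and the sub-ideal NO.

One network serves two sub-tasks.  A block of shared 5x5 convolutional
layers (leaky rectifier, 64 filters at full scale) feeds (i) a detection head
(max-pool, dense, sigmoid) trained with binary cross entropy, whose output
approximates p(H1 | g) and hence a monotonic transform of the likelihood
ratio, and (ii) an estimation branch of additional convolutional layers plus
a linear head trained with the negative utility as its loss.  Training
alternates one estimation step and one detection step per iteration; both
update the shared block.  Semi-online noise draws fresh measurement noise on
the stored noiseless images each iteration.

From the trained network two observers are assembled:

* hybrid:   T = Lambda_hat(g) * U_hat(g), with Lambda_hat = p/(1-p) from the
  detection head and U_hat the Monte-Carlo utility-weighted posterior mean
  over MCMC samples, evaluated at the estimation head's theta_hat;
* sub-ideal: T = Lambda_hat(g) alone (no MCMC).

With a constant utility the two test statistics coincide exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ..eroc import UtilityFunction, evaluate_utility
from ..nn import Adam, Conv2D, Dense, Flatten, LeakyReLU, MaxPool2D, Sequential, sigmoid
from .reference import utility_weighted_posterior_mean


@dataclass(frozen=True)
class MultiTaskNetSpec:
    """Architecture of the multi-task CNN."""

    n_shared_conv: int = 1
    n_estimation_conv: int = 1
    filters: int = 64
    kernel: int = 5
    leaky_slope: float = 0.2
    image_shape: tuple[int, int] = (64, 64)
    theta_dim: int = 1
    # fixed multiplicative input normalization (e.g. 1/sigma_n); part of the
    # architecture, applied before the first convolution
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_shared_conv < 1 or self.n_estimation_conv < 1:
            raise ValueError("both conv blocks need at least one layer")


@dataclass(frozen=True)
class TrainConfig:
    """Alternating-training settings (full-scale defaults)."""

    batch_present: int = 200
    batch_absent: int = 200
    lr: float = 1e-5
    n_minibatches: int = 200_000
    semi_online_noise: bool = True
    seed: int = 0
    val_every: int = 200

    def __post_init__(self) -> None:
        if min(self.batch_present, self.batch_absent, self.n_minibatches + 1) < 0:
            raise ValueError("counts must be nonnegative")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


class MultiTaskCNN:
    """Shared conv trunk with detection and estimation branches."""

    def __init__(self, spec: MultiTaskNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, k = spec.filters, spec.kernel
        H, W = spec.image_shape
        if H % 2 or W % 2:
            raise ValueError("image dimensions must be even (2x2 max-pool)")

        def conv_block(n_layers, in_ch):
            layers = []
            for i in range(n_layers):
                layers.append(Conv2D(in_ch if i == 0 else f, f, kernel=k, rng=rng))
                layers.append(LeakyReLU(spec.leaky_slope))
            return layers

        self.shared = Sequential(conv_block(spec.n_shared_conv, 1))
        n_flat = f * (H // 2) * (W // 2)
        self.det_head = Sequential([MaxPool2D(), Flatten(), Dense(n_flat, 1, rng=rng)])
        self.est_branch = Sequential(
            conv_block(spec.n_estimation_conv, f)
            + [MaxPool2D(), Flatten(), Dense(n_flat, spec.theta_dim, rng=rng)]
        )

    # -- forward passes ---------------------------------------------------
    def _to_maps(self, g: np.ndarray) -> np.ndarray:
        H, W = self.spec.image_shape
        G = np.atleast_2d(np.asarray(g, dtype=float)) * self.spec.input_scale
        return G.reshape(-1, 1, H, W)

    def detection_logits(self, g: np.ndarray) -> np.ndarray:
        z = self.det_head.forward(self.shared.forward(self._to_maps(g)))
        return z[:, 0]

    def detection_prob(self, g: np.ndarray) -> np.ndarray:
        return sigmoid(self.detection_logits(g))

    def estimate(self, g: np.ndarray) -> np.ndarray:
        return self.est_branch.forward(self.shared.forward(self._to_maps(g)))

    # -- training steps ---------------------------------------------------
    def _detection_step(self, x: np.ndarray, y: np.ndarray, opt: Adam) -> float:
        logits = self.detection_logits(x)
        p = sigmoid(logits)
        loss = detection_loss(p, y)
        dlogit = (p - y) / y.size  # d(mean BCE)/dlogit
        dshared = self.det_head.backward(dlogit[:, None])
        self.shared.backward(dshared)
        opt.step()
        return loss

    def _estimation_step(self, x: np.ndarray, theta: np.ndarray,
                         u: UtilityFunction, opt: Adam) -> float:
        theta_hat = self.est_branch.forward(self.shared.forward(self._to_maps(x)))
        loss = estimation_loss(theta_hat, theta, u)
        dth = -utility_gradient(u, theta_hat, theta) / theta.shape[0]
        dshared = self.est_branch.backward(dth)
        self.shared.backward(dshared)
        opt.step()
        return loss

    def trainable_layers(self, branch: str) -> list:
        trunk = self.shared.parameterized()
        if branch == "detection":
            return trunk + self.det_head.parameterized()
        return trunk + self.est_branch.parameterized()


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------


def detection_loss(posterior_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross entropy; probabilities are clamped away from {0, 1}."""
    p = np.asarray(posterior_probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn("probabilities outside (0,1) clamped for the cross entropy")
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def estimation_loss(theta_hats: np.ndarray, thetas: np.ndarray, u: UtilityFunction) -> float:
    """Negative mean utility over signal-present cases."""
    th = np.atleast_2d(np.asarray(theta_hats, dtype=float))
    t = np.atleast_2d(np.asarray(thetas, dtype=float))
    if th.shape[0] == 0:
        raise ValueError("estimation loss needs a non-empty signal-present batch")
    return float(-np.mean(evaluate_utility(u, th, t)))


def utility_gradient(u: UtilityFunction, theta_hat: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """d u(theta_hat, theta) / d theta_hat, case-wise, shape (n, d)."""
    e = np.atleast_2d(theta_hat) - np.atleast_2d(theta)
    if u.kind == "gaussian":
        vals = np.exp(-np.sum(e**2, axis=-1, keepdims=True) / (2.0 * u.param**2))
        return -vals * e / u.param**2
    if u.kind == "quadratic":
        return -2.0 * e / u.param
    return -np.sign(e) / u.param  # l1 (subgradient)


# --------------------------------------------------------------------------
# Training and architecture search
# --------------------------------------------------------------------------


def _val_losses(net: MultiTaskCNN, val_ds, u: UtilityFunction, counter: int) -> tuple[float, float]:
    imgs = val_ds.render_noisy(counter=counter)
    p = net.detection_prob(imgs)
    det = detection_loss(p, val_ds.labels)
    pres = val_ds.labels == 1
    est = estimation_loss(net.estimate(imgs[pres]), val_ds.theta, u)
    return det, est


def train_multitask(
    dataset,
    spec: MultiTaskNetSpec,
    cfg: TrainConfig,
    val_dataset=None,
    net: MultiTaskCNN | None = None,
) -> tuple[MultiTaskCNN, dict]:
    """Alternating detection/estimation training with semi-online noise.

    Per iteration one estimation gradient step (shared + estimation weights)
    is taken first, then one detection step (shared + detection weights), as
    separate Adam updates.  Noise is redrawn per iteration from the dataset's
    counter-based stream when semi-online noise is enabled.  Returns the
    trained net and a history dict with per-iteration training losses and
    periodic validation losses.
    """
    u = dataset.config.utility_fn()
    net = net or MultiTaskCNN(spec, seed=cfg.seed)
    opt_est = Adam(net.trainable_layers("estimation"), lr=cfg.lr)
    opt_det = Adam(net.trainable_layers("detection"), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    nm = dataset.noise_model()

    pres_idx = np.flatnonzero(dataset.labels == 1)
    abs_idx = np.flatnonzero(dataset.labels == 0)
    hist = {"det_loss": [], "est_loss": [], "val_det": [], "val_est": [], "val_iter": []}

    for it in range(cfg.n_minibatches):
        i1 = rng.choice(pres_idx, size=min(cfg.batch_present, pres_idx.size), replace=False)
        i0 = rng.choice(abs_idx, size=min(cfg.batch_absent, abs_idx.size), replace=False)
        x1 = dataset.noiseless[i1]
        x0 = dataset.noiseless[i0]
        if cfg.semi_online_noise:
            x1 = x1 + nm.sample(x1.shape, counter=2 * it)
            x0 = x0 + nm.sample(x0.shape, counter=2 * it + 1)
        elif dataset.images is not None:
            x1, x0 = dataset.images[i1], dataset.images[i0]
        theta1 = dataset.theta[np.searchsorted(pres_idx, i1)]

        hist["est_loss"].append(net._estimation_step(x1, theta1, u, opt_est))
        x = np.vstack([x1, x0])
        y = np.concatenate([np.ones(len(i1)), np.zeros(len(i0))])
        hist["det_loss"].append(net._detection_step(x, y, opt_det))

        if val_dataset is not None and (it + 1) % cfg.val_every == 0:
            vd, ve = _val_losses(net, val_dataset, u, counter=it)
            hist["val_det"].append(vd)
            hist["val_est"].append(ve)
            hist["val_iter"].append(it + 1)
    return net, hist


def _smoothed_final_val(values: list[float]) -> float:
    """Average over the final 10% of recorded validation losses."""
    if not values:
        raise ValueError("no validation losses recorded (increase iterations)")
    k = max(1, len(values) // 10)
    return float(np.mean(values[-k:]))


def select_depth(losses: list[float], rel_tol: float = 0.01) -> int:
    """Depth-growth stopping rule.

    ``losses[i]`` is the validation loss of the model with depth i+1.  Layers
    are added while each addition decreases the loss by at least ``rel_tol``
    of the previous depth's loss; the selected depth is the last one whose
    addition still helped significantly (depth 1 if none did).
    """
    depth = 1
    for i in range(1, len(losses)):
        if losses[i - 1] - losses[i] >= rel_tol * abs(losses[i - 1]):
            depth = i + 1
        else:
            break
    return depth


def architecture_search(
    dataset,
    cfg: TrainConfig,
    val_dataset,
    base_spec: MultiTaskNetSpec,
    max_shared: int = 8,
    max_estimation: int = 4,
    rel_tol: float = 0.01,
) -> tuple[MultiTaskNetSpec, dict]:
    """Grow the shared block, then the estimation block, with the 1% rule.

    Each candidate depth is trained from scratch; its score is the validation
    loss averaged over the final 10% of recorded evaluations (detection cross
    entropy for the shared block, estimation loss for the estimation block).
    Growth stops when the improvement over the one-layer-shallower model
    falls below ``rel_tol`` of the latter's loss.  Returns the selected spec
    and the search trace.
    """
    trace = {"shared_losses": [], "estimation_losses": []}
    for depth in range(1, max_shared + 1):
        spec = replace(base_spec, n_shared_conv=depth)
        _, hist = train_multitask(dataset, spec, cfg, val_dataset=val_dataset)
        trace["shared_losses"].append(_smoothed_final_val(hist["val_det"]))
        if select_depth(trace["shared_losses"], rel_tol) < depth:
            break
    n_shared = select_depth(trace["shared_losses"], rel_tol)

    for depth in range(1, max_estimation + 1):
        spec = replace(base_spec, n_shared_conv=n_shared, n_estimation_conv=depth)
        _, hist = train_multitask(dataset, spec, cfg, val_dataset=val_dataset)
        trace["estimation_losses"].append(_smoothed_final_val(hist["val_est"]))
        if select_depth(trace["estimation_losses"], rel_tol) < depth:
            break
    n_est = select_depth(trace["estimation_losses"], rel_tol)
    return replace(base_spec, n_shared_conv=n_shared, n_estimation_conv=n_est), trace


# --------------------------------------------------------------------------
# Observers assembled from the trained network
# --------------------------------------------------------------------------


def posterior_to_likelihood_ratio(p):
    """Lambda_hat = p/(1-p) under balanced-class training prevalence."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("posterior probability must lie in [0, 1]")
    if np.any(p == 1.0):
        warnings.warn("posterior probability of exactly 1; likelihood ratio is +inf")
    with np.errstate(divide="ignore"):
        out = p / (1.0 - p)
    return float(out) if out.ndim == 0 else out


def subideal_apply(net: MultiTaskCNN, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sub-ideal NO: T = Lambda_hat(g) from the detection head, no MCMC."""
    G = np.atleast_2d(np.asarray(g, dtype=float))
    t = posterior_to_likelihood_ratio(net.detection_prob(G))
    theta_hat = net.estimate(G)
    if np.asarray(g).ndim == 1:
        return float(t[0]), theta_hat[0]
    return t, theta_hat


def hybrid_io_apply(
    net: MultiTaskCNN,
    sampler,
    u: UtilityFunction,
    g: np.ndarray,
) -> tuple[float, np.ndarray, float, float]:
    """Hybrid approximated IO on one image: T = Lambda_hat(g) * U_hat(g).

    ``sampler`` maps an image to posterior samples of theta under H1 (one of
    the RWMH samplers, configured for the task).  Returns
    (T, theta_hat, Lambda_hat, U_hat).
    """
    g = np.asarray(g, dtype=float).ravel()
    lam, theta_hat = subideal_apply(net, g)
    samples = sampler(g)
    u_hat = utility_weighted_posterior_mean(theta_hat, samples, u)
    return lam * u_hat, theta_hat, lam, u_hat
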