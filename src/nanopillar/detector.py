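"""From-scratch MLP pillar-tip detector: 12×12-patch classifier plus scanning.

A fully connected three-layer backpropagation network classifies 12×12-pixel
patches as pillar tip (class P) or empty space (class E).  Each pixel feeds
three input neurons (the colour channels; identical values for grayscale
sources), giving the fixed production architecture 432–24–2 with logistic
sigmoid activations throughout and squared-error loss against the targets
[1, 0] (E) and [0, 1] (P).  Training is online stochastic gradient descent:
one weight update per pattern, patterns shuffled each epoch.

Detection slides the 12×12 window over a calibrated micrograph, records the
activation of the P output neuron per window, and reports tip positions as
local response maxima above a threshold, greedily pruned to a minimum
separation (the tip width, so that leaning pillar bundles collapse to one
detection, as they do for the real surfaces).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .containers import Micrograph, TipSet

__all__ = [
    "PATCH_SIZE",
    "NetworkWeights",
    "ResponseMap",
    "TrainingSet",
    "augment_patch",
    "augment_training_set",
    "patch_to_input",
    "forward",
    "forward_batch",
    "train",
    "loss_and_gradient",
    "scan",
    "detect_tips",
    "normalize_image",
    "extract_patch",
    "sample_training_patches",
]

PATCH_SIZE = 12
_CHANNELS = 3
N_INPUT = PATCH_SIZE * PATCH_SIZE * _CHANNELS  # 432
N_HIDDEN = 24
N_OUTPUT = 2
TARGET_E = np.array([1.0, 0.0])
TARGET_P = np.array([0.0, 1.0])
#: 24 equidistant rotation angles and three rescales used for augmentation.
AUGMENT_ANGLES = tuple(np.arange(24) * 15.0)
AUGMENT_SCALES = (0.90, 1.00, 1.10)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class NetworkWeights:
    """Weights and biases of the three-layer network (logistic activations).

    The production architecture is 432–24–2; smaller shapes are accepted so
    the arithmetic can be verified on hand-computable instances.
    """

    w1: np.ndarray  # (n_in, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden, n_out)
    b2: np.ndarray  # (n_out,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, float)
        self.b1 = np.asarray(self.b1, float)
        self.w2 = np.asarray(self.w2, float)
        self.b2 = np.asarray(self.b2, float)
        if self.w1.shape[1] != self.w2.shape[0] or self.b1.shape != (self.w1.shape[1],) \
                or self.b2.shape != (self.w2.shape[1],):
            raise ValueError("inconsistent layer shapes")
        for a in (self.w1, self.b1, self.w2, self.b2):
            if not np.isfinite(a).all():
                raise ValueError("non-finite weights")

    @classmethod
    def initialize(cls, seed: int = 0, n_in: int = N_INPUT, n_hidden: int = N_HIDDEN,
                   n_out: int = N_OUTPUT) -> "NetworkWeights":
        """Uniform(−0.5, 0.5) initialisation from a seed."""
        rng = np.random.default_rng(seed)
        return cls(
            rng.uniform(-0.5, 0.5, (n_in, n_hidden)),
            rng.uniform(-0.5, 0.5, n_hidden),
            rng.uniform(-0.5, 0.5, (n_hidden, n_out)),
            rng.uniform(-0.5, 0.5, n_out),
            meta={"seed": seed},
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "architecture": [self.w1.shape[0], self.w1.shape[1], self.w2.shape[1]],
            "activation": "logistic",
            "w1": self.w1.ravel().tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.ravel().tolist(),
            "b2": self.b2.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkWeights":
        d = json.loads(Path(path).read_text())
        n_in, n_hid, n_out = d["architecture"]
        return cls(
            np.array(d["w1"]).reshape(n_in, n_hid),
            np.array(d["b1"]),
            np.array(d["w2"]).reshape(n_hid, n_out),
            np.array(d["b2"]),
            meta=d.get("meta", {}),
        )


def patch_to_input(patch: np.ndarray) -> np.ndarray:
    """Flatten a 12×12 grayscale patch (values in [0,1]) to the 432-vector.

    Each pixel is replicated into its three colour-channel input neurons
    (channel-fastest ordering).  A 12×12×3 patch is flattened as-is.
    """
    patch = np.asarray(patch, float)
    if patch.shape == (PATCH_SIZE, PATCH_SIZE):
        return np.repeat(patch.ravel(), _CHANNELS)
    if patch.shape == (PATCH_SIZE, PATCH_SIZE, _CHANNELS):
        return patch.ravel()
    raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}[x{_CHANNELS}]")


def forward(net: NetworkWeights, x: np.ndarray) -> tuple[float, float]:
    """Feed-forward pass; returns (out_E, out_P), each in (0, 1)."""
    x = np.asarray(x, float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite input")
    hidden = _sigmoid(x @ net.w1 + net.b1)
    out = _sigmoid(hidden @ net.w2 + net.b2)
    return float(out[0]), float(out[1])


def forward_batch(net: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Vectorised feed-forward over rows of ``X``; returns (n, 2) activations."""
    hidden = _sigmoid(X @ net.w1 + net.b1)
    return _sigmoid(hidden @ net.w2 + net.b2)


def loss_and_gradient(net: NetworkWeights, X: np.ndarray, T: np.ndarray):
    """Mean squared-error loss over a batch and its analytic gradient.

    Loss = mean over patterns of 0.5·Σ(out − target)².  Returns
    ``(loss, (gw1, gb1, gw2, gb2))``; used for the finite-difference check
    and full-batch evaluation.
    """
    n = X.shape[0]
    hidden = _sigmoid(X @ net.w1 + net.b1)
    out = _sigmoid(hidden @ net.w2 + net.b2)
    err = out - T
    loss = float(0.5 * (err**2).sum() / n)
    delta2 = err * out * (1 - out) / n
    gw2 = hidden.T @ delta2
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ net.w2.T) * hidden * (1 - hidden)
    gw1 = X.T @ delta1
    gb1 = delta1.sum(axis=0)
    return loss, (gw1, gb1, gw2, gb2)


class DivergenceError(RuntimeError):
    """Training loss became non-finite; use a smaller learning rate."""


def train(
    net: NetworkWeights,
    X: np.ndarray,
    labels: np.ndarray,
    passes_per_pattern: int = 2000,
    learning_rate: float = 0.1,
    seed: int = 0,
    record_loss: bool = True,
) -> NetworkWeights:
    """Online backpropagation training.

    ``passes_per_pattern`` forward passes per training picture are realised as
    that many epochs over the set with one full error backpropagation (weight
    update) per pattern; patterns are reshuffled each epoch.  ``labels`` holds
    'E'/'P' (or 0/1) per row of ``X``.  Raises :class:`DivergenceError` if the
    loss becomes non-finite.
    """
    X = np.asarray(X, float)
    lab = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty training set")
    y = np.where((lab == "P") | (lab == 1), 1, 0)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes (E and P) must be present")
    T = np.where(y[:, None] == 1, TARGET_P, TARGET_E)
    w1, b1 = net.w1.copy(), net.b1.copy()
    w2, b2 = net.w2.copy(), net.b2.copy()
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    history: list[float] = []
    tmp = NetworkWeights(w1, b1, w2, b2)
    for _ in range(passes_per_pattern):
        order = rng.permutation(n)
        for k in order:
            x = X[k]
            hidden = _sigmoid(x @ w1 + b1)
            out = _sigmoid(hidden @ w2 + b2)
            err = out - T[k]
            delta2 = err * out * (1 - out)
            delta1 = (w2 @ delta2) * hidden * (1 - hidden)
            w2 -= learning_rate * np.outer(hidden, delta2)
            b2 -= learning_rate * delta2
            w1 -= learning_rate * np.outer(x, delta1)
            b1 -= learning_rate * delta1
        if record_loss:
            tmp.w1, tmp.b1, tmp.w2, tmp.b2 = w1, b1, w2, b2
            loss, _ = loss_and_gradient(tmp, X, T)
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training diverged (non-finite loss); reduce the learning rate"
                )
            history.append(loss)
    meta = dict(net.meta)
    meta.update(
        {
            "passes_per_pattern": passes_per_pattern,
            "learning_rate": learning_rate,
            "train_seed": seed,
            "loss_curve": history,
        }
    )
    return NetworkWeights(w1, b1, w2, b2, meta=meta)


# ---------------------------------------------------------------------------
# Training-set augmentation

def _resample_to_patch(img: np.ndarray) -> np.ndarray:
    """Centre-crop or reflect-pad an array back to 12×12."""
    out = img
    for axis in (0, 1):
        size = out.shape[axis]
        if size > PATCH_SIZE:
            lo = (size - PATCH_SIZE) // 2
            out = out.take(range(lo, lo + PATCH_SIZE), axis=axis)
        elif size < PATCH_SIZE:
            pad = PATCH_SIZE - size
            widths = [(0, 0), (0, 0)]
            widths[axis] = (pad // 2, pad - pad // 2)
            out = np.pad(out, widths, mode="reflect")
    return out


def augment_patch(patch: np.ndarray) -> np.ndarray:
    """All 72 rotation × scale variants of one 12×12 patch.

    24 equidistant rotation angles × rescales to 90, 100, 110 % of the
    original size, each resampled back to 12×12 with bilinear interpolation
    and reflective border padding.  Angle 0 at scale 100 % reproduces the
    patch exactly.
    """
    patch = np.asarray(patch, float)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError("base patch must be 12x12 grayscale")
    variants = np.empty((len(AUGMENT_ANGLES) * len(AUGMENT_SCALES), PATCH_SIZE, PATCH_SIZE))
    k = 0
    for scale in AUGMENT_SCALES:
        if scale == 1.0:
            scaled = patch
        else:
            scaled = ndimage.zoom(patch, scale, order=1, mode="reflect", grid_mode=True)
            if min(scaled.shape) < 1:
                raise ValueError("patch vanished after rescale")
            scaled = _resample_to_patch(scaled)
        for angle in AUGMENT_ANGLES:
            if angle == 0.0:
                rot = scaled
            else:
                rot = ndimage.rotate(
                    scaled, angle, reshape=False, order=1, mode="reflect"
                )
            variants[k] = rot
            k += 1
    return variants


@dataclass(frozen=True)
class TrainingSet:
    """Augmented 12×12 patches ready for training.

    ``X`` holds one 432-vector per row, ``labels`` the matching 'E'/'P'.
    """

    X: np.ndarray
    labels: np.ndarray

    @property
    def per_class(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))


def augment_training_set(patches: np.ndarray, labels) -> TrainingSet:
    """Expand base patches 72-fold (24 angles × 3 scales) into a TrainingSet.

    Seven base patches per class give the canonical 504 pictures per class.
    """
    patches = np.asarray(patches, float)
    labels = np.asarray(labels)
    if patches.ndim != 3 or patches.shape[1:] != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError("patches must be (n, 12, 12)")
    if not (set(np.unique(labels)) <= {"E", "P"}):
        raise ValueError("labels must be 'E' or 'P'")
    for cls in ("E", "P"):
        if not (labels == cls).any():
            raise ValueError(f"no base patches for class {cls}")
    xs, ys = [], []
    for patch, lab in zip(patches, labels):
        var = augment_patch(patch)
        xs.append(np.repeat(var.reshape(var.shape[0], -1), _CHANNELS, axis=1))
        ys.extend([lab] * var.shape[0])
    return TrainingSet(np.vstack(xs), np.array(ys))


# ---------------------------------------------------------------------------
# Scanning and detection

def normalize_image(image: np.ndarray) -> np.ndarray:
    """Global min–max normalisation of intensities to [0, 1]."""
    image = np.asarray(image, float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def extract_patch(normalized: np.ndarray, row: int, col: int) -> np.ndarray:
    """The 12×12 patch whose top-left anchor is (row, col)."""
    return normalized[row : row + PATCH_SIZE, col : col + PATCH_SIZE]


@dataclass(frozen=True)
class ResponseMap:
    """Per-window activation of the P output neuron over a micrograph.

    ``values[i, j]`` is the response of the window anchored at pixel
    ``(i*stride, j*stride)``; the window centre sits ``(PATCH_SIZE-1)/2``
    pixels further in each axis.
    """

    values: np.ndarray
    stride: int
    pixel_size_nm: float

    @property
    def center_offset_px(self) -> float:
        return (PATCH_SIZE - 1) / 2.0


def scan(net: NetworkWeights, image: Micrograph, stride: int = 1) -> ResponseMap:
    """Forward-pass every stride-th 12×12 window; collect P responses.

    Exploits that grayscale patches feed identical values to the three colour
    channels: the input weights are summed per pixel, reducing each window to
    a 144-vector product.  Processed in row blocks to bound memory.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape
    if h < PATCH_SIZE or w < PATCH_SIZE:
        raise ValueError("image smaller than one 12x12 window")
    norm = normalize_image(image.data)
    # sum the three channel weights per pixel (channel-fastest layout)
    w1_px = net.w1.reshape(PATCH_SIZE * PATCH_SIZE, _CHANNELS, -1).sum(axis=1)
    windows = sliding_window_view(norm, (PATCH_SIZE, PATCH_SIZE))[::stride, ::stride]
    n_rows, n_cols = windows.shape[:2]
    out = np.empty((n_rows, n_cols))
    block = max(1, 2_000_000 // max(n_cols, 1) // (PATCH_SIZE * PATCH_SIZE))
    for r0 in range(0, n_rows, block):
        blk = windows[r0 : r0 + block].reshape(-1, PATCH_SIZE * PATCH_SIZE)
        hid = _sigmoid(blk @ w1_px + net.b1)
        out[r0 : r0 + block] = _sigmoid(hid @ net.w2 + net.b2)[:, 1].reshape(-1, n_cols)
    return ResponseMap(out, stride, image.pixel_size_nm)


def detect_tips(
    response: ResponseMap, threshold: float = 0.5, min_separation_nm: float = 110.0
) -> TipSet:
    """Tip positions from local response maxima above ``threshold``.

    Local maxima of the P-response (8-neighbourhood) above the threshold are
    greedily accepted in order of decreasing response; a candidate closer
    than ``min_separation_nm`` to an accepted tip is suppressed (the higher
    response wins), mirroring how leaning pillar bundles are counted once.
    Coordinates are window centres in nm; the extent is the scanned region.
    """
    v = response.values
    px = response.pixel_size_nm
    stride_nm = response.stride * px
    local_max = v == ndimage.maximum_filter(v, size=3, mode="nearest")
    cand = np.argwhere(local_max & (v >= threshold))
    off = response.center_offset_px * px
    x0 = off
    y0 = off
    x1 = off + (v.shape[1] - 1) * stride_nm
    y1 = off + (v.shape[0] - 1) * stride_nm
    extent = (x0, y0, max(x1, x0 + 1e-9), max(y1, y0 + 1e-9))
    if cand.size == 0:
        return TipSet(np.empty((0, 2)), extent)
    resp = v[cand[:, 0], cand[:, 1]]
    order = np.argsort(-resp)
    accepted: list[np.ndarray] = []
    min_sep2 = min_separation_nm**2
    for k in order:
        i, j = cand[k]
        p = np.array([off + j * stride_nm, off + i * stride_nm])
        ok = True
        for q in accepted:
            dv = p - q
            if dv @ dv < min_sep2:
                ok = False
                break
        if ok:
            accepted.append(p)
    return TipSet(np.array(accepted), extent)


def sample_training_patches(
    image: Micrograph,
    tips: TipSet,
    n_per_class: int = 7,
    seed: int = 0,
    empty_margin_nm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick tip-centred (P) and between-pillar (E) base patches from a render.

    Emulates the manual training-set picking on a reference micrograph:
    ``n_per_class`` patches centred on known tips and the same number at
    positions at least ``empty_margin_nm`` (default 1.2× the detector's
    min-separation scale, 130 nm) from every tip.  Patches come from the
    min–max normalised image.  Returns ``(patches, labels)``.
    """
    from scipy.spatial import cKDTree

    if tips.n < n_per_class:
        raise ValueError("not enough tips for the requested training patches")
    if empty_margin_nm is None:
        empty_margin_nm = 130.0
    rng = np.random.default_rng(seed)
    norm = normalize_image(image.data)
    h, w = norm.shape
    px = image.pixel_size_nm
    half = PATCH_SIZE // 2
    ex0, ey0 = tips.extent[0], tips.extent[1]

    def grab(x_nm: float, y_nm: float) -> np.ndarray | None:
        col = int(round((x_nm - ex0) / px)) - half
        row = int(round((y_nm - ey0) / px)) - half
        if row < 0 or col < 0 or row + PATCH_SIZE > h or col + PATCH_SIZE > w:
            return None
        return norm[row : row + PATCH_SIZE, col : col + PATCH_SIZE]

    patches, labels = [], []
    for idx in rng.permutation(tips.n):
        p = grab(*tips.xy[idx])
        if p is not None:
            patches.append(p)
            labels.append("P")
        if labels.count("P") == n_per_class:
            break
    tree = cKDTree(tips.xy)
    x0, y0, x1, y1 = tips.extent
    attempts = 0
    while labels.count("E") < n_per_class and attempts < 20_000:
        attempts += 1
        q = rng.uniform([x0, y0], [x1, y1])
        if tree.query(q)[0] < empty_margin_nm:
            continue
        p = grab(*q)
        if p is not None:
            patches.append(p)
            labels.append("E")
    if labels.count("P") < n_per_class or labels.count("E") < n_per_class:
        raise RuntimeError("could not collect the requested training patches")
    return np.array(patches), np.array(labels)
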