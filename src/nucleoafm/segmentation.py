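"""Patch-based pixel classification into background / NCP / DNA.

Each pixel is classified from its 11x11 median-subtracted neighbourhood by a
small fully connected network (121 inputs -> 121 ReLU units -> 3 class
logits) trained by backpropagation on hand-labeled (here: ground-truth
synthetic) frames.  Component rules then isolate the main particle (largest
connected NCP component) and discard small spurious DNA components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.measure import label
from sklearn.neural_network import MLPClassifier

BACKGROUND, NCP, DNA = 0, 1, 2
CLASS_NAMES = ("background", "NCP", "DNA")
PATCH = 11
HALF = PATCH // 2

__all__ = ["BACKGROUND", "NCP", "DNA", "CLASS_NAMES", "PatchClassifier",
           "ConfusionTable", "extract_patch", "frame_patches",
           "train_classifier", "predict_mask", "main_particle",
           "filter_dna_components", "confusion_rates", "NoParticleError"]


class NoParticleError(ValueError):
    """Raised when a mask contains no NCP pixels."""


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def _padded(frame):
    return np.pad(np.asarray(frame, float), HALF, mode="symmetric")


def extract_patch(frame, pixel_coord):
    """11x11 median-subtracted patch around one pixel (symmetric padding)."""
    i, j = pixel_coord
    frame = np.asarray(frame)
    if not (0 <= i < frame.shape[0] and 0 <= j < frame.shape[1]):
        raise ValueError("pixel outside frame")
    padded = _padded(frame)
    win = padded[i:i + PATCH, j:j + PATCH].ravel()
    return win - np.median(win)


def frame_patches(frame, coords=None):
    """Median-subtracted patches for selected (or all) pixels of a frame.

    Returns an (n, 121) float32 array; with ``coords=None`` rows follow
    C-order over all pixels.
    """
    frame = np.asarray(frame, float)
    windows = sliding_window_view(_padded(frame), (PATCH, PATCH))
    if coords is None:
        pats = windows.reshape(frame.shape[0] * frame.shape[1], PATCH * PATCH)
    else:
        coords = np.asarray(coords)
        pats = windows[coords[:, 0], coords[:, 1]].reshape(len(coords), PATCH * PATCH)
    pats = np.ascontiguousarray(pats, dtype=np.float32)
    pats -= np.median(pats, axis=1, keepdims=True).astype(np.float32)
    return pats


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass
class ConfusionTable:
    """3x3 (actual, predicted) pixel fractions plus per-class rates.

    ``rates[c]`` is the class-conditional correct-labeling rate: the joint
    fraction of pixels that are class c and predicted c, divided by the
    actual fraction of class c (e.g. 81.3% / 89.2% = 91.1%).  Classes absent
    from the truth get NaN.
    """

    fractions: np.ndarray
    rates: dict = field(default_factory=dict)

    @property
    def counts_to_fractions(self):
        return self.fractions


@dataclass
class PatchClassifier:
    """121 -> 121 (ReLU) -> 3 patch classifier with training metadata."""

    mlp: MLPClassifier
    seed: int
    epochs: int
    learning_rate: float

    @property
    def layer_sizes(self):
        sizes = [c.shape[0] for c in self.mlp.coefs_]
        sizes.append(self.mlp.coefs_[-1].shape[1])
        return tuple(sizes)

    def predict(self, patches):
        return self.mlp.predict(patches)


def _balanced_coords(masks, n_per_class, rng):
    """Sample (frame, row, col) coordinates, balanced across classes."""
    out = {c: [] for c in (BACKGROUND, NCP, DNA)}
    for f, m in enumerate(masks):
        for c in out:
            ij = np.argwhere(m == c)
            if len(ij):
                out[c].append(np.column_stack([np.full(len(ij), f), ij]))
    samples = []
    for c, lst in out.items():
        if not lst:
            continue
        all_c = np.vstack(lst)
        take = min(n_per_class, len(all_c))
        sel = rng.choice(len(all_c), size=take, replace=False)
        samples.append(all_c[sel])
    return np.vstack(samples)


def train_classifier(
    frames,
    masks,
    split: float = 0.8,
    seed: int = 0,
    n_per_class: int = 6000,
    epochs: int = 50,
    learning_rate: float = 1e-3,
    batch_size: int = 256,
    eval_subsample: int | None = None,
):
    """Train the patch classifier and score it on held-out frames.

    Frames are split ``split`` / ``1 - split`` into train / held-out sets
    (in order).  Training patches are sampled class-balanced to counter the
    ~89/3/7 background/NCP/DNA prior.  Deterministic for a fixed seed.

    Returns ``(PatchClassifier, ConfusionTable)`` where the confusion table
    is computed over every pixel of the held-out frames.
    """
    frames = [np.asarray(f, float) for f in frames]
    masks = [np.asarray(m) for m in masks]
    if len(frames) != len(masks) or not frames:
        raise ValueError("frames and masks must be non-empty and aligned")
    present = np.unique(np.concatenate([m.ravel() for m in masks]))
    if len(present) < 2:
        raise ValueError("training labels must contain at least 2 classes")

    n_train = max(1, int(round(split * len(frames))))
    if n_train == len(frames):
        n_train = len(frames) - 1
    rng = np.random.default_rng(seed)

    coords = _balanced_coords(masks[:n_train], n_per_class, rng)
    X = np.vstack([
        frame_patches(frames[f], coords[coords[:, 0] == f][:, 1:])
        for f in np.unique(coords[:, 0])
    ])
    y = np.concatenate([
        masks[f][tuple(coords[coords[:, 0] == f][:, 1:].T)]
        for f in np.unique(coords[:, 0])
    ])

    mlp = MLPClassifier(
        hidden_layer_sizes=(121,), activation="relu", solver="adam",
        learning_rate_init=learning_rate, batch_size=batch_size,
        max_iter=epochs, n_iter_no_change=epochs, tol=0.0,
        random_state=int(seed))
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # convergence warning at fixed epoch budget
        mlp.fit(X, y)
    model = PatchClassifier(mlp, int(seed), epochs, learning_rate)

    preds, truths = [], []
    for f in range(n_train, len(frames)):
        m = predict_mask(model, frames[f])
        preds.append(m.ravel())
        truths.append(masks[f].ravel())
    pred = np.concatenate(preds)
    truth = np.concatenate(truths)
    if eval_subsample and eval_subsample < len(pred):
        sel = rng.choice(len(pred), eval_subsample, replace=False)
        pred, truth = pred[sel], truth[sel]
    table = confusion_rates(pred, truth)
    return model, table


def predict_mask(model: PatchClassifier, frame):
    """Per-pixel argmax class labels for one frame."""
    frame = np.asarray(frame, float)
    pats = frame_patches(frame)
    if pats.shape[1] != model.mlp.coefs_[0].shape[0]:
        raise ValueError("frame patches do not match the trained patch size")
    labels = model.predict(pats)
    return labels.reshape(frame.shape).astype(np.uint8)


# ---------------------------------------------------------------------------
# component rules
# ---------------------------------------------------------------------------

def main_particle(mask):
    """Largest 8-connected NCP component as a boolean pixel set.

    Size ties break deterministically toward the component whose
    lexicographically smallest (row, col) pixel sorts first.
    """
    mask = np.asarray(mask)
    lab = label(mask == NCP, connectivity=2)
    n = lab.max()
    if n == 0:
        raise NoParticleError("mask contains no NCP pixels")
    best = None
    for c in range(1, n + 1):
        pix = np.argwhere(lab == c)
        key = (-len(pix), tuple(pix[np.lexsort((pix[:, 1], pix[:, 0]))][0]))
        if best is None or key < best[0]:
            best = (key, c)
    return lab == best[1]


def filter_dna_components(mask, min_fraction: float = 0.5):
    """Drop DNA components smaller than ``min_fraction`` of the largest.

    The default fraction implements the half-the-largest rule used to
    discard small spurious DNA specks; components of exactly the cutoff
    size are kept ("smaller than" is strict).  Returns a new mask with
    dropped pixels set to background.
    """
    mask = np.asarray(mask).copy()
    lab = label(mask == DNA, connectivity=2)
    n = lab.max()
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    cutoff = sizes.max() * min_fraction
    for c in np.nonzero(sizes < cutoff)[0] + 1:
        mask[lab == c] = BACKGROUND
    return mask


def confusion_rates(pred_mask, truth_mask) -> ConfusionTable:
    """Confusion fractions and class-conditional correct-labeling rates."""
    pred = np.asarray(pred_mask).ravel()
    truth = np.asarray(truth_mask).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal shapes")
    n = len(truth)
    frac = np.zeros((3, 3))
    for a in (BACKGROUND, NCP, DNA):
        for p in (BACKGROUND, NCP, DNA):
            frac[a, p] = np.count_nonzero((truth == a) & (pred == p)) / n
    rates = {}
    for c, name in enumerate(CLASS_NAMES):
        actual = frac[c].sum()
        rates[name] = float(frac[c, c] / actual) if actual > 0 else float("nan")
    return ConfusionTable(frac, rates)
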