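"""Facial keyframe selection from frame sequences.

Per frame: a pluggable detector finds face boxes and the frame is cropped to
the largest one. Within each sliding window of 2i+1 = 11 usable frames
(stride 8), every frame gets a difference score — the chi-square distance
between its color histogram and those of its in-window temporal neighbors —
and the frame with the smallest score (the locally most stable one) becomes
the window's keyframe. Keyframes are resized to 227x227x3 for the
recognition model.

The face detector is a contract, not a fixed implementation: anything
callable as ``detector(frame) -> [(x, y, w, h, confidence), ...]`` plugs in.
An LBP/Haar cascade adapter from any external library satisfies it; this
module ships a color-threshold detector for the procedural faces of the
synthetic generator and an oracle detector for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from PIL import Image

KEYFRAME_SIZE = 227
WINDOW_HALF = 5          # i; window is 2i + 1 = 11 frames
WINDOW_STRIDE = 8

Box = tuple[int, int, int, int, float]   # x, y, w, h, confidence


class FaceDetector(Protocol):
    def __call__(self, frame: np.ndarray) -> Sequence[Box]: ...


@dataclass
class FrameSequence:
    """Ordered RGB frames at a nominal frame rate."""

    frames: np.ndarray      # (n, H, W, 3) uint8
    frame_rate: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (n, H, W, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class KeyframeSet:
    """Selected keyframes (227x227x3) and their source frame indices."""

    images: np.ndarray          # (m, 227, 227, 3) uint8
    source_indices: np.ndarray  # (m,), one source frame per keyframe

    def __post_init__(self) -> None:
        if self.images.ndim != 4 or self.images.shape[1:] != (
                KEYFRAME_SIZE, KEYFRAME_SIZE, 3):
            raise ValueError("keyframes must be 227x227x3")
        idx = np.asarray(self.source_indices)
        # windows overlap by 2i+1-stride frames, so neighboring windows may
        # legally pick the same or out-of-order source frames
        if len(idx) != self.images.shape[0] or np.any(idx < 0):
            raise ValueError("need one non-negative source index per image")

    def __len__(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def synthetic_face_detector(frame: np.ndarray,
                            bg_tolerance: int = 30) -> list[Box]:
    """Detector for the procedural renderer's faces.

    Finds the bounding box of pixels that differ from the (dark, uniform)
    background by more than ``bg_tolerance`` in any channel; the background
    color is estimated from the frame corners. Returns one box, or none for
    a blank frame.
    """
    f = np.asarray(frame, dtype=np.int16)
    corners = np.concatenate([f[:4, :4].reshape(-1, 3), f[:4, -4:].reshape(-1, 3),
                              f[-4:, :4].reshape(-1, 3), f[-4:, -4:].reshape(-1, 3)])
    bg = np.median(corners, axis=0)
    mask = np.any(np.abs(f - bg) > bg_tolerance, axis=-1)
    if not mask.any():
        return []
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    x, y = int(cols[0]), int(rows[0])
    w, h = int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1)
    return [(x, y, w, h, 1.0)]


def oracle_detector(boxes_by_frame: dict[int, Sequence[Box]]) -> Callable:
    """Build a detector that replays known ground-truth boxes (for tests)."""
    counter = {"i": -1}

    def detect(frame: np.ndarray) -> Sequence[Box]:
        counter["i"] += 1
        return boxes_by_frame.get(counter["i"], [])

    return detect


# ---------------------------------------------------------------------------
# per-frame operations
# ---------------------------------------------------------------------------

def detect_and_crop_face(frame: np.ndarray,
                         detector: FaceDetector) -> np.ndarray | None:
    """Crop the frame to the largest detected face box; None when no face."""
    boxes = detector(frame)
    if not boxes:
        return None
    x, y, w, h, _ = max(boxes, key=lambda b: b[2] * b[3])
    hgt, wid = frame.shape[:2]
    x0, y0 = max(0, int(x)), max(0, int(y))
    x1, y1 = min(wid, int(x + w)), min(hgt, int(y + h))
    if x1 <= x0 or y1 <= y0:
        return None
    return frame[y0:y1, x0:x1]


def frame_histogram(image: np.ndarray, bins_per_channel: int = 32) -> np.ndarray:
    """Concatenated per-channel histograms, normalized to sum 1."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an RGB image")
    hists = [np.histogram(img[..., c].ravel(), bins=bins_per_channel,
                          range=(0, 256))[0] for c in range(3)]
    h = np.concatenate(hists).astype(float)
    total = h.sum()
    return h / total if total > 0 else h


def chi_square_distance(h1: np.ndarray, h2: np.ndarray) -> float:
    """Chi-square histogram distance: sum (h1-h2)^2 / (h1+h2), zero-denominator
    terms skipped. Symmetric and non-negative."""
    a = np.asarray(h1, dtype=float)
    b = np.asarray(h2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must have the same shape")
    denom = a + b
    mask = denom > 0
    return float((((a - b) ** 2)[mask] / denom[mask]).sum())


def resize_frame(image: np.ndarray, width: int = KEYFRAME_SIZE,
                 height: int = KEYFRAME_SIZE) -> np.ndarray:
    """Bilinear resize preserving the 3 channels."""
    img = np.asarray(image)
    if img.shape[0] == height and img.shape[1] == width:
        return img.copy()
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((width, height), Image.BILINEAR))


# ---------------------------------------------------------------------------
# keyframe selection
# ---------------------------------------------------------------------------

def select_keyframes(seq: FrameSequence, i: int = WINDOW_HALF,
                     stride: int = WINDOW_STRIDE,
                     detector: FaceDetector | None = None,
                     bins_per_channel: int = 32) -> KeyframeSet:
    """Windowed minimum-difference keyframe selection.

    Windows of 2i+1 usable (face-detected) frames start at 0, stride,
    2*stride, ... while a full window fits. Within a window, frame j's score
    is the chi-square distance to its previous in-window neighbor plus that
    to its next; the frame with the smallest score wins (ties -> earliest).
    When a detector is given, undetected frames are excluded before
    windowing and histograms are computed on the cropped faces.
    """
    win = 2 * i + 1
    if detector is not None:
        crops, usable_idx = [], []
        for j in range(len(seq)):
            crop = detect_and_crop_face(seq.frames[j], detector)
            if crop is not None:
                crops.append(crop)
                usable_idx.append(j)
    else:
        crops = [seq.frames[j] for j in range(len(seq))]
        usable_idx = list(range(len(seq)))

    n = len(crops)
    if n < win:
        raise ValueError(f"need at least {win} usable frames, got {n}")

    hists = [frame_histogram(c, bins_per_channel) for c in crops]
    picked: list[int] = []   # indices into the usable list
    start = 0
    while start + win <= n:
        scores = []
        for j in range(start, start + win):
            score = 0.0
            if j > start:
                score += chi_square_distance(hists[j], hists[j - 1])
            if j < start + win - 1:
                score += chi_square_distance(hists[j], hists[j + 1])
            scores.append(score)
        picked.append(start + int(np.argmin(scores)))  # argmin ties -> earliest
        start += stride

    images = np.stack([resize_frame(crops[j]) for j in picked])
    indices = np.asarray([usable_idx[j] for j in picked])
    return KeyframeSet(images=images, source_indices=indices)


def expected_keyframe_count(n_frames: int, i: int = WINDOW_HALF,
                            stride: int = WINDOW_STRIDE) -> int:
    """floor((n - (2i+1)) / stride) + 1 for a fully usable sequence."""
    win = 2 * i + 1
    if n_frames < win:
        return 0
    return (n_frames - win) // stride + 1


# ---------------------------------------------------------------------------
# directory I/O
# ---------------------------------------------------------------------------

def load_frames(frames_dir, pattern: str = "*.png",
                frame_rate: float = 30.0) -> FrameSequence:
    """Read a directory of image frames (sorted by filename)."""
    paths = sorted(Path(frames_dir).glob(pattern))
    if not paths:
        raise ValueError(f"no frames matching {pattern!r} in {frames_dir}")
    frames = np.stack([np.asarray(Image.open(p).convert("RGB")) for p in paths])
    return FrameSequence(frames=frames, frame_rate=frame_rate,
                         source_id=str(frames_dir))


def save_keyframes(ks: KeyframeSet, out_dir) -> None:
    """Write keyframe PNGs plus an index CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in range(len(ks)):
        name = f"keyframe_{m:04d}.png"
        Image.fromarray(ks.images[m]).save(out / name)
        rows.append(dict(keyframe=name, source_index=int(ks.source_indices[m])))
    pd.DataFrame(rows).to_csv(out / "keyframes.csv", index=False)
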