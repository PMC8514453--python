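"""Image-sequence construction and pixel-domain curvature.

Generates synthetic grayscale clips, the two scale manipulations used in the
experimental design (spatial zoom by upsampling the central square, and
temporal subsampling that keeps endpoints), and the "unnatural" fade
sequences obtained by linear interpolation between a clip's first and last
frames.  Fades are exactly straight in pixel-intensity space by
construction; 8-bit quantization can re-introduce a small positive
curvature, which the 8-bit mode of :func:`pixel_curvature` exposes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import geometry

__all__ = ["FrameSequence", "synthesize_clip", "zoom2", "subsample_time",
           "make_fade", "pixel_curvature", "build_stimulus_set"]

CLIP_KINDS = ("drifting-texture", "translating-object", "filtered-noise-morph")


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with design metadata.

    Attributes
    ----------
    frames : (T+1, H, W) float array with intensities in [0, 1].
    label : "natural" or "fade".
    zoom : spatial-scale tag (1 or 2).
    framerate : temporal-scale tag (1 or 2).
    name : free-form clip identifier.
    """

    frames: np.ndarray
    label: str = "natural"
    zoom: int = 1
    framerate: int = 1
    name: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if self.frames.shape[0] < 3:
            raise ValueError("a sequence needs at least 3 frames")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self):
        return self.frames.shape[0]

    @property
    def frame_shape(self):
        return self.frames.shape[1:]

    def as_uint8(self) -> np.ndarray:
        return np.round(self.frames * 255).astype(np.uint8)

    # ---------------------------------------------------------------- I/O
    def save_png(self, directory):
        """Write one 8-bit PNG per frame plus a JSON metadata sidecar."""
        import pathlib

        import imageio.v3 as iio
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for t, frame in enumerate(self.as_uint8()):
            iio.imwrite(directory / f"frame_{t:03d}.png", frame)
        meta = {"label": self.label, "zoom": self.zoom,
                "framerate": self.framerate, "name": self.name,
                "n_frames": int(self.n_frames)}
        (directory / "sequence.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load_png(cls, directory) -> "FrameSequence":
        import pathlib

        import imageio.v3 as iio
        directory = pathlib.Path(directory)
        meta = json.loads((directory / "sequence.json").read_text())
        frames = [iio.imread(p).astype(float) / 255.0
                  for p in sorted(directory.glob("frame_*.png"))]
        return cls(frames=np.stack(frames), label=meta["label"],
                   zoom=meta["zoom"], framerate=meta["framerate"],
                   name=meta["name"])

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=self.frames)
            d.attrs.update({"label": self.label, "zoom": self.zoom,
                            "framerate": self.framerate, "name": self.name})

    @classmethod
    def from_hdf5(cls, path) -> "FrameSequence":
        import h5py
        with h5py.File(path, "r") as f:
            d = f["frames"]
            return cls(frames=d[...], label=str(d.attrs["label"]),
                       zoom=int(d.attrs["zoom"]),
                       framerate=int(d.attrs["framerate"]),
                       name=str(d.attrs["name"]))


def _smooth_noise(rng, shape, scale: float) -> np.ndarray:
    """Low-pass filtered Gaussian noise field, zero mean, unit-ish range."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), scale,
                                     mode="wrap")
    return field_ / (np.abs(field_).max() + 1e-12)


def _normalize(frames: np.ndarray) -> np.ndarray:
    lo, hi = frames.min(), frames.max()
    return (frames - lo) / (hi - lo + 1e-12)


def synthesize_clip(seed: int, n_frames: int = 11, kind: str = "drifting-texture",
                    shape=(32, 32)) -> FrameSequence:
    """Deterministically generate a synthetic grayscale clip.

    Three families span low to high pixel curvature: a band-limited texture
    drifting with subpixel shifts, a Gaussian object translating on a
    textured background, and a morph through a chain of filtered noise
    fields.
    """
    if n_frames < 3:
        raise ValueError("a clip needs at least 3 frames")
    if kind not in CLIP_KINDS:
        raise ValueError(f"kind must be one of {CLIP_KINDS}")
    rng = np.random.default_rng(seed)
    H, W = shape
    if kind == "drifting-texture":
        texture = _smooth_noise(rng, (H, W), scale=2.0)
        fy, fx = np.meshgrid(np.fft.fftfreq(H), np.fft.fftfreq(W),
                             indexing="ij")
        spec = np.fft.fft2(texture)
        vel = rng.uniform(0.5, 1.5, size=2) * rng.choice([-1, 1], size=2)
        frames = [np.real(np.fft.ifft2(
            spec * np.exp(-2j * np.pi * t * (fy * vel[0] + fx * vel[1]))))
            for t in range(n_frames)]
        frames = np.stack(frames)
    elif kind == "translating-object":
        background = 0.25 * _smooth_noise(rng, (H, W), scale=4.0)
        yy, xx = np.mgrid[0:H, 0:W]
        y0 = rng.uniform(0.3, 0.7) * H
        x_start, x_step = 0.15 * W, 0.7 * W / (n_frames - 1)
        frames = np.stack([
            background + np.exp(-(((yy - y0) ** 2 + (xx - (x_start + t * x_step)) ** 2)
                                  / (2 * (0.08 * W) ** 2)))
            for t in range(n_frames)])
    else:  # filtered-noise-morph
        keys = [_smooth_noise(rng, (H, W), scale=3.0) for _ in range(3)]
        ts = np.linspace(0, 1, n_frames)
        frames = np.stack([
            (1 - u) ** 2 * keys[0] + 2 * u * (1 - u) * keys[1] + u ** 2 * keys[2]
            for u in ts])
    return FrameSequence(frames=_normalize(frames), label="natural",
                         name=f"{kind}-{seed}")


def zoom2(seq: FrameSequence) -> FrameSequence:
    """Spatial rescaling: crop the central square of half side length and
    upsample it by a factor of two (bilinear), restoring the original shape."""
    H, W = seq.frame_shape
    if H < 4 or W < 4:
        raise ValueError("frames must be at least 4x4 to zoom")
    if H % 2 or W % 2:
        raise ValueError("frame side lengths must be even")
    h, w = H // 2, W // 2
    top, left = (H - h) // 2, (W - w) // 2
    crops = seq.frames[:, top:top + h, left:left + w]
    frames = np.stack([ndimage.zoom(c, 2.0, order=1, grid_mode=True,
                                    mode="nearest") for c in crops])
    return FrameSequence(frames=np.clip(frames, 0.0, 1.0), label=seq.label,
                         zoom=2, framerate=seq.framerate, name=seq.name)


def subsample_time(seq: FrameSequence, factor: int = 2) -> FrameSequence:
    """Temporal rescaling: keep every `factor`-th frame including both
    endpoints.  An 11-frame sequence at factor 2 becomes the 6-frame version."""
    n = seq.n_frames
    if (n - 1) % factor:
        raise ValueError(
            f"cannot keep both endpoints of {n} frames with factor {factor}")
    return FrameSequence(frames=seq.frames[::factor], label=seq.label,
                         zoom=seq.zoom, framerate=seq.framerate * factor,
                         name=seq.name)


def make_fade(seq: FrameSequence) -> FrameSequence:
    """Unnatural control sequence: frame t is the linear interpolation
    ``(1 - t/T) frame_0 + (t/T) frame_T``; the middle frame is the average of
    the first and last frames (a "double exposure")."""
    T = seq.n_frames - 1
    first, last = seq.frames[0], seq.frames[-1]
    if np.array_equal(first, last):
        warnings.warn("first and last frames are identical: the fade is "
                      "degenerate for curvature", RuntimeWarning, stacklevel=2)
    w = np.arange(seq.n_frames) / T
    frames = (1 - w)[:, None, None] * first + w[:, None, None] * last
    return FrameSequence(frames=frames, label="fade", zoom=seq.zoom,
                         framerate=seq.framerate, name=seq.name)


def pixel_curvature(seq: FrameSequence, bit8: bool = False):
    """Discrete curvature of the sequence in pixel-intensity space.

    Each frame is vectorized to a point; the global value is the mean of the
    local turning angles.  Returns ``(global_deg, locals_deg)``.  With
    ``bit8=True`` the frames are first quantized to 8 bits, exposing the
    small curvature that quantization induces in nominally straight fades.
    """
    frames = seq.as_uint8().astype(float) if bit8 else seq.frames
    points = frames.reshape(seq.n_frames, -1)
    locals_deg = geometry.local_curvatures(points)
    return float(np.mean(locals_deg)), locals_deg


def build_stimulus_set(base_clips) -> list:
    """Expand base clips into the full experimental design.

    Each 11-frame base clip yields a natural sequence at zoom x1 and one at
    zoom x2, plus a fade counterpart of each: 10 clips produce 20 natural
    and 20 fade sequences.  Coarser temporal-scale variants are derivable
    from any returned sequence via :func:`subsample_time`.
    """
    base_clips = list(base_clips)
    if not base_clips:
        raise ValueError("need at least one base clip")
    out = []
    for clip in base_clips:
        if clip.n_frames != 11:
            raise ValueError("base clips must have 11 frames")
        for nat in (clip, zoom2(clip)):
            out.append(nat)
            out.append(make_fade(nat))
    return out
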