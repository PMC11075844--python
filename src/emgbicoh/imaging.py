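"""Render bicoherence maps as fixed-size RGB images for classification.

The classifier consumes 224x224x3 images. A map is rendered as a dense
heatmap: bins are clipped to a fixed value range ([0, 1] by default — the
bicoherence scale — so that absolute coupling strength survives rendering),
passed through a pinned colormap, and resampled to the output size with
nearest-neighbor interpolation so no inter-bin values are invented. The
frequency axes are centered (-fs/2, fs/2) via FFT shift so the map's
symmetric structure is displayed the way higher-order spectra are usually
plotted. Class labels ride in a manifest, never in pixel content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .hosa import BicoherenceMap

__all__ = [
    "RenderConfig",
    "LabeledImage",
    "render_map",
    "write_image",
    "read_image",
    "BicoherenceImager",
]


@dataclass(frozen=True)
class RenderConfig:
    out_height: int = 224
    out_width: int = 224
    colormap: str = "viridis"
    value_min: float = 0.0
    value_max: float = 1.0
    axes: bool = False

    def validate(self) -> None:
        if self.out_height <= 0 or self.out_width <= 0:
            raise ValueError("output dimensions must be positive")
        if not self.value_min < self.value_max:
            raise ValueError("value_min must be below value_max")


@dataclass
class LabeledImage:
    """H x W x 3 uint8 image with provenance labels."""

    pixels: np.ndarray
    class_label: str = ""
    subject_id: str = ""
    muscle: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")

    def manifest_row(self, path: str = "") -> dict:
        return {
            "path": path,
            "class_label": self.class_label,
            "subject_id": self.subject_id,
            "muscle": self.muscle,
            "source_id": self.source_id,
        }


def _nearest_resample(a: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    src_h, src_w = a.shape[:2]
    rows = np.minimum((np.arange(out_h) + 0.5) * src_h / out_h, src_h - 1).astype(int)
    cols = np.minimum((np.arange(out_w) + 0.5) * src_w / out_w, src_w - 1).astype(int)
    return a[np.ix_(rows, cols)]


def render_array(values: np.ndarray, mask: np.ndarray | None,
                 config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Heatmap pixels (uint8 H x W x 3) from a raw value matrix."""
    config.validate()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty map")
    vals = np.clip(values, config.value_min, config.value_max)
    if mask is not None:
        vals = np.where(mask, vals, config.value_min)
    norm = (vals - config.value_min) / (config.value_max - config.value_min)
    cmap = colormaps[config.colormap]
    rgba = cmap(norm)  # float in [0, 1]
    rgb = (rgba[..., :3] * 255.0 + 0.5).astype(np.uint8)
    return _nearest_resample(rgb, config.out_height, config.out_width)


def render_map(
    bic_map: BicoherenceMap,
    config: RenderConfig = RenderConfig(),
    **labels,
) -> LabeledImage:
    """Render a bicoherence map; frequency axes centered via FFT shift.

    With ``config.axes`` a decorated matplotlib plot (ticks, colorbar) is
    rasterized instead of the plain heatmap; the output size contract holds
    either way.
    """
    values = np.fft.fftshift(bic_map.values)
    mask = np.fft.fftshift(bic_map.mask)
    if config.axes:
        pixels = _render_decorated(values, mask, bic_map, config)
    else:
        pixels = render_array(values, mask, config)
    return LabeledImage(pixels=pixels, **labels)


def _render_decorated(values, mask, bic_map, config: RenderConfig) -> np.ndarray:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dpi = 100
    fig = plt.figure(
        figsize=(config.out_width / dpi, config.out_height / dpi), dpi=dpi
    )
    ax = fig.add_subplot(111)
    freqs = np.fft.fftshift(bic_map.freqs)
    shown = np.where(mask, values, config.value_min)
    im = ax.imshow(
        shown,
        origin="lower",
        extent=[freqs[0], freqs[-1], freqs[0], freqs[-1]],
        cmap=config.colormap,
        vmin=config.value_min,
        vmax=config.value_max,
        aspect="auto",
    )
    ax.set_xlabel("f1 (Hz)")
    ax.set_ylabel("f2 (Hz)")
    fig.colorbar(im, ax=ax)
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())[..., :3].copy()
    plt.close(fig)
    return _nearest_resample(buf, config.out_height, config.out_width)


def write_image(image: LabeledImage, path: str | Path) -> Path:
    """Lossless PNG write."""
    path = Path(path)
    if path.suffix.lower() != ".png":
        path = path.with_suffix(".png")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.pixels, mode="RGB").save(path, format="PNG")
    return path


def read_image(path: str | Path, **labels) -> LabeledImage:
    """Read a PNG back into a LabeledImage; labels come from the manifest."""
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return LabeledImage(pixels=pixels, **labels)


class BicoherenceImager(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: map value arrays -> uint8 RGB images.

    ``transform`` maps (n, nfft, nfft) value arrays (as produced by
    ``BicoherenceEstimator.transform``) to (n, H, W, 3) uint8 images.
    """

    def __init__(
        self,
        out_height: int = 224,
        out_width: int = 224,
        colormap: str = "viridis",
        value_min: float = 0.0,
        value_max: float = 1.0,
    ):
        self.out_height = out_height
        self.out_width = out_width
        self.colormap = colormap
        self.value_min = value_min
        self.value_max = value_max

    def _config(self) -> RenderConfig:
        return RenderConfig(
            out_height=self.out_height,
            out_width=self.out_width,
            colormap=self.colormap,
            value_min=self.value_min,
            value_max=self.value_max,
        )

    def fit(self, X, y=None):
        self._config().validate()
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        config = self._config()
        return np.stack(
            [render_array(np.fft.fftshift(v), None, config) for v in X]
        )
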