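"""Ion images and three-color prediction maps.

Prediction maps follow the standard convention: cancer red, normal glands
green, normal stroma blue, background white.  Ion images show per-pixel
summed intensity in a narrow m/z window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CLASSES, MSISample
from .model import PixelPrediction

#: RGB colors per class; background is white.
CLASS_COLORS = {
    "cancer": (220, 30, 30),
    "glands": (30, 180, 60),
    "stroma": (40, 70, 220),
}
BACKGROUND_COLOR = (255, 255, 255)


@dataclass
class PredictionImage:
    """RGB raster of per-pixel class calls at the sample's grid shape."""

    rgb: np.ndarray  # (rows, cols, 3) uint8

    def save(self, path, rescale: tuple[int, int] | None = None) -> None:
        """Write as PNG; ``rescale`` optionally resizes to (width, height)."""
        from PIL import Image

        img = Image.fromarray(self.rgb, mode="RGB")
        if rescale is not None:
            img = img.resize(rescale, Image.NEAREST)
        img.save(path)


def render_prediction_map(
    prediction: PixelPrediction, grid_shape: tuple[int, int]
) -> PredictionImage:
    """Paint each predicted pixel its class color; all others white.

    The prediction must carry a pixel index (row, col); pixels absent from
    it (background / excluded) stay white.
    """
    rgb = np.full(tuple(grid_shape) + (3,), 255, dtype=np.uint8)
    if prediction.n_pixels:
        if prediction.pixels is None:
            raise ValueError("prediction carries no (row, col) pixel index")
        rows = prediction.pixels["row"].to_numpy()
        cols = prediction.pixels["col"].to_numpy()
        if rows.max() >= grid_shape[0] or cols.max() >= grid_shape[1]:
            raise ValueError("prediction pixel index exceeds grid shape")
        colors = np.array([CLASS_COLORS[c] for c in CLASSES], dtype=np.uint8)
        class_idx = {c: i for i, c in enumerate(CLASSES)}
        idx = np.array([class_idx[lab] for lab in prediction.labels])
        rgb[rows, cols] = colors[idx]
    return PredictionImage(rgb)


@dataclass
class IonImage:
    """Single-channel intensity raster for one m/z window."""

    values: np.ndarray  # (rows, cols)
    mz_center: float
    window_halfwidth: float
    colormap: str = "viridis"

    def save(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        im = ax.imshow(self.values, cmap=self.colormap, interpolation="nearest")
        ax.set_title(f"m/z {self.mz_center:g} +/- {self.window_halfwidth:g}")
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)


def render_ion_image(
    sample: MSISample, mz_center: float, window_halfwidth: float = 0.25
) -> IonImage:
    """Per-pixel summed intensity in [mz_center - w, mz_center + w].

    The window must intersect the mass axis.  A window covering the whole
    axis yields the TIC image.
    """
    mz = sample.axis.mz_values
    lo, hi = mz_center - window_halfwidth, mz_center + window_halfwidth
    sel = (mz >= lo) & (mz <= hi)
    if not sel.any():
        raise ValueError(
            f"window [{lo:g}, {hi:g}] does not intersect the mass axis "
            f"[{mz[0]:g}, {mz[-1]:g}]"
        )
    values = sample.spectra[:, :, sel].sum(axis=2)
    values[~sample.tissue] = 0.0
    return IonImage(values, mz_center, window_halfwidth)
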