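"""Spectral binning and pixel selection.

Raw spectra carry 13,320 m/z channels; averaging non-overlapping bins of six
channels reduces each spectrum to 2,220 features and absorbs small
registration differences between spectra.  With the default axis each bin is
~0.5 m/z wide, so bin-center labels land on the half-unit grid used to label
selected features (e.g. 233.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BACKGROUND, CANCER, EXCLUDED, GLANDS, STROMA, AnnotationMask, MSISample

DEFAULT_BIN_SIZE = 6

_CLASS_OF_CODE = {CANCER: "cancer", GLANDS: "glands", STROMA: "stroma"}


@dataclass
class FeatureMatrix:
    """Pixels x binned-intensity features.

    ``values`` is ``(n_pixels, n_features)``; ``mz`` holds bin-center m/z
    labels (strictly increasing); ``pixels`` is a DataFrame with columns
    ``sample_id, row, col`` indexing each matrix row back to its pixel.
    ``tic_flagged`` marks pixels whose feature sum was zero at TIC
    normalization time (left unnormalized).
    """

    values: np.ndarray
    mz: np.ndarray
    pixels: pd.DataFrame
    tic_flagged: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (pixels x features)")
        if self.mz.size != self.values.shape[1]:
            raise ValueError("one m/z label per feature required")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("feature m/z labels must be strictly increasing")
        if len(self.pixels) != self.values.shape[0]:
            raise ValueError("pixel index length must match number of rows")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def mz_labels(self, decimals: int = 1) -> np.ndarray:
        """Bin-center labels rounded for display (one decimal by default)."""
        return np.round(self.mz, decimals)

    def subset(self, index: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[index],
            self.mz,
            self.pixels.iloc[np.atleast_1d(index)].reset_index(drop=True),
            None if self.tic_flagged is None else self.tic_flagged[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{m:.4f}" for m in self.mz])
        return pd.concat([self.pixels.reset_index(drop=True), df], axis=1)

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        mz = parts[0].mz
        for p in parts[1:]:
            if not np.array_equal(p.mz, mz):
                raise ValueError("feature axes differ")
        return FeatureMatrix(
            np.vstack([p.values for p in parts]),
            mz,
            pd.concat([p.pixels for p in parts], ignore_index=True),
        )


def bin_features(sample: MSISample, bin_size: int = DEFAULT_BIN_SIZE) -> FeatureMatrix:
    """Average non-overlapping channel bins to build the feature matrix.

    Feature ``j`` is the arithmetic mean of channels
    ``[j*bin_size, (j+1)*bin_size)``; a trailing partial bin is averaged over
    its actual members.  Labels are the mean m/z of the member channels.
    Only tissue pixels (those carrying a spectrum) enter the matrix.

    With the default 13,320-channel axis and ``bin_size=6`` this yields
    2,220 features.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    nchan = sample.axis.channel_count
    if bin_size > nchan:
        raise ValueError(f"bin_size {bin_size} exceeds channel count {nchan}")
    rows, cols = sample.grid_shape
    r_idx, c_idx = np.nonzero(sample.tissue)
    flat = sample.spectra[r_idx, c_idx, :]

    n_full = nchan // bin_size
    full = flat[:, : n_full * bin_size].reshape(len(flat), n_full, bin_size).mean(axis=2)
    mz_full = (
        sample.axis.mz_values[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1)
    )
    rem = nchan - n_full * bin_size
    if rem:
        tail = flat[:, n_full * bin_size :].mean(axis=1, keepdims=True)
        full = np.hstack([full, tail])
        mz_full = np.append(mz_full, sample.axis.mz_values[n_full * bin_size :].mean())

    pixels = pd.DataFrame(
        {"sample_id": sample.sample_id, "row": r_idx, "col": c_idx}
    )
    return FeatureMatrix(full, mz_full, pixels)


def normalize_tic(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each pixel's features by their sum (optional, off by default).

    Pixels whose feature sum is zero are left unchanged and flagged in
    ``tic_flagged``.
    """
    sums = fm.values.sum(axis=1)
    flagged = sums == 0
    safe = np.where(flagged, 1.0, sums)
    return FeatureMatrix(fm.values / safe[:, None], fm.mz, fm.pixels.copy(), flagged)


def select_pixels(
    fm: FeatureMatrix, mask: AnnotationMask
) -> tuple[FeatureMatrix, np.ndarray]:
    """Keep only pixels annotated cancer / glands / stroma.

    Background pixels and excluded histologies (lymphocytes, inflammation,
    necrosis) are dropped.  Returns the reduced matrix and a parallel array
    of class-name labels.
    """
    rows = fm.pixels["row"].to_numpy()
    cols = fm.pixels["col"].to_numpy()
    if rows.size and (
        rows.max() >= mask.grid_shape[0] or cols.max() >= mask.grid_shape[1]
    ):
        raise ValueError(
            f"mask grid {mask.grid_shape} does not cover pixel index "
            f"({rows.max()}, {cols.max()})"
        )
    codes = mask.labels[rows, cols]
    keep = (codes != BACKGROUND) & (codes != EXCLUDED)
    labels = np.array([_CLASS_OF_CODE[c] for c in codes[keep]], dtype=object)
    return fm.subset(np.nonzero(keep)[0]), labels


def infer_background(
    sample: MSISample, tic_fraction: float = 0.05
) -> np.ndarray:
    """Fallback background detection when no annotation mask exists.

    Flags pixels whose TIC is below ``tic_fraction`` of the sample's median
    tissue TIC (glass-slide pixels carry little signal).  Returns a boolean
    grid, True = background.
    """
    tic = sample.tic()
    med = np.median(tic[sample.tissue]) if sample.tissue.any() else 0.0
    bg = ~sample.tissue | (tic < tic_fraction * med)
    if bg.all():
        warnings.warn("all pixels flagged background by TIC threshold")
    return bg
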