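"""Data model and text I/O for pixel-resolved mass-spectrometry-imaging samples.

A sample is a rectangular grid of pixels, each holding one negative-ion-mode
mass spectrum over a shared mass axis (default: 13,320 channels spanning
m/z 90-1,200 at 200 um pixel spacing).  Samples travel in a simple
self-describing text dialect::

    #desilasso-msi v1
    #sample PC0001
    #patient P01
    #grid 12 10
    #spacing 200.0
    #mz 90.0 90.0833 ...
    0 0 12.5 0.0 3.25 ...
    0 1 ...

Header lines carry the grid shape and mass axis; each remaining line is one
pixel keyed by 0-based ``row col`` (row-major).  Pixels with no spectrum line
are background (glass slide imaged but carrying no tissue).

Annotation masks assign each pixel one of five labels -- ``cancer``,
``glands``, ``stroma``, ``excluded`` (lymphocytes / inflammation / necrosis)
or ``background`` -- and may carry a region table giving a pathologist-style
percent composition per region.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Tissue classes, in fixed prediction order.
CLASSES = ("cancer", "glands", "stroma")

#: All mask labels.  Integer codes are the index into this tuple.
MASK_LABELS = ("background", "cancer", "glands", "stroma", "excluded")

BACKGROUND, CANCER, GLANDS, STROMA, EXCLUDED = range(5)

_LABEL_CODE = {name: i for i, name in enumerate(MASK_LABELS)}

DEFAULT_CHANNELS = 13320
DEFAULT_MZ_MIN = 90.0
DEFAULT_MZ_MAX = 1200.0
DEFAULT_PIXEL_SPACING_UM = 200.0


class MSIParseError(ValueError):
    """Malformed sample file (names the offending line)."""


class DimensionError(ValueError):
    """A spectrum's length does not match the mass axis."""


@dataclass(frozen=True)
class MassAxis:
    """Ordered m/z channel centers shared by every pixel of a sample."""

    mz_values: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz_values, dtype=float)
        if mz.ndim != 1 or mz.size < 1:
            raise ValueError("mass axis must be a non-empty 1-D array")
        if not np.all(np.diff(mz) > 0):
            raise ValueError("mass axis must be strictly increasing")
        object.__setattr__(self, "mz_values", mz)

    @property
    def channel_count(self) -> int:
        return int(self.mz_values.size)

    @classmethod
    def default(cls) -> "MassAxis":
        """13,320 channels spanning m/z 90-1,200 (~0.0833 m/z per channel)."""
        return cls(np.linspace(DEFAULT_MZ_MIN, DEFAULT_MZ_MAX, DEFAULT_CHANNELS))


@dataclass
class MSISample:
    """One imaged tissue section: a grid of spectra plus identity metadata.

    ``spectra`` has shape ``(rows, cols, channel_count)`` with non-negative
    intensities in arbitrary ion-count units.  ``tissue`` flags pixels that
    carried a spectrum; the rest are background.
    """

    sample_id: str
    patient_id: str
    axis: MassAxis
    spectra: np.ndarray
    tissue: np.ndarray = None
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_UM

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 3:
            raise ValueError("spectra must have shape (rows, cols, channels)")
        if self.spectra.shape[2] != self.axis.channel_count:
            raise DimensionError(
                f"spectra have {self.spectra.shape[2]} channels, "
                f"mass axis has {self.axis.channel_count}"
            )
        if np.any(self.spectra < 0):
            raise ValueError("intensities must be non-negative")
        if self.tissue is None:
            self.tissue = np.ones(self.spectra.shape[:2], dtype=bool)
        else:
            self.tissue = np.asarray(self.tissue, dtype=bool)
            if self.tissue.shape != self.spectra.shape[:2]:
                raise ValueError("tissue mask shape must equal grid shape")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.spectra.shape[:2]

    def tic(self) -> np.ndarray:
        """Total ion current per pixel (summed spectrum intensity)."""
        return self.spectra.sum(axis=2)


@dataclass
class AnnotationMask:
    """Per-pixel ground truth plus optional region-level percent composition.

    ``labels`` is an integer grid with codes indexing :data:`MASK_LABELS`.
    ``region_map`` (optional) assigns each pixel a region id; ``regions``
    maps region id -> composition 3-vector ``(cancer, glands, stroma)``
    summing to 1.
    """

    labels: np.ndarray
    region_map: np.ndarray | None = None
    regions: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind == "O" and self.labels.size and isinstance(
            self.labels.ravel()[0], str
        ):
            self.labels = self.labels.astype(str)
        if self.labels.dtype.kind in "US":
            codes = np.empty(self.labels.shape, dtype=np.int8)
            for name, code in _LABEL_CODE.items():
                codes[self.labels == name] = code
            unknown = ~np.isin(self.labels, MASK_LABELS)
            if unknown.any():
                bad = self.labels[unknown].ravel()[0]
                raise ValueError(f"unknown mask label {bad!r}")
            self.labels = codes
        else:
            self.labels = self.labels.astype(np.int8)
            if self.labels.min() < 0 or self.labels.max() >= len(MASK_LABELS):
                raise ValueError("mask codes out of range")
        for rid, comp in list(self.regions.items()):
            comp = np.asarray(comp, dtype=float)
            if comp.shape != (3,) or np.any(comp < 0) or np.any(comp > 1):
                raise ValueError(f"region {rid}: composition must be 3 fractions in [0,1]")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"region {rid}: composition must sum to 1")
            self.regions[rid] = comp

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_names(self) -> np.ndarray:
        """Grid of label strings."""
        return np.array(MASK_LABELS, dtype=object)[self.labels]

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for name, code in _LABEL_CODE.items()}


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

_MAGIC = "#desilasso-msi v1"


def write_msi_text(sample: MSISample, path) -> None:
    """Write a sample in the project text dialect (readable by read_msi_text).

    Intensities are printed with 17 significant digits so that float64 values
    round-trip bit-identically.  Background pixels are omitted.
    """
    rows, cols = sample.grid_shape
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"#sample {sample.sample_id}\n")
        fh.write(f"#patient {sample.patient_id}\n")
        fh.write(f"#grid {rows} {cols}\n")
        fh.write(f"#spacing {float(sample.pixel_spacing)!r}\n")
        fh.write("#mz " + " ".join(repr(float(v)) for v in sample.axis.mz_values) + "\n")
        for r in range(rows):
            for c in range(cols):
                if not sample.tissue[r, c]:
                    continue
                vals = " ".join(f"{v:.17g}" for v in sample.spectra[r, c])
                fh.write(f"{r} {c} {vals}\n")


def read_msi_text(path) -> MSISample:
    """Read a sample from the project text dialect.

    Missing pixels are marked background (zero spectrum, ``tissue`` False).

    Raises
    ------
    MSIParseError
        Malformed header or pixel line (message names the line number).
    DimensionError
        A spectrum whose intensity count differs from the mass axis
        (message names the pixel).
    """
    header = {}
    mz = None
    pixels = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise MSIParseError(f"line 1: expected {_MAGIC!r}, got {first!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, _, rest = line[1:].partition(" ")
                    if key == "grid":
                        r, c = rest.split()
                        header["grid"] = (int(r), int(c))
                    elif key == "mz":
                        mz = np.array([float(v) for v in rest.split()])
                    elif key in ("sample", "patient", "spacing"):
                        header[key] = rest
                    else:
                        raise ValueError(f"unknown header key {key!r}")
                except (ValueError, TypeError) as exc:
                    raise MSIParseError(f"line {lineno}: bad header ({exc})") from exc
            else:
                pixels.append((lineno, line))
    if "grid" not in header:
        raise MSIParseError("missing '#grid R C' header line")
    if mz is None:
        raise MSIParseError("missing '#mz ...' header line")
    axis = MassAxis(mz)
    rows, cols = header["grid"]
    spectra = np.zeros((rows, cols, axis.channel_count))
    tissue = np.zeros((rows, cols), dtype=bool)
    for lineno, line in pixels:
        parts = line.split()
        try:
            r, c = int(parts[0]), int(parts[1])
        except (ValueError, IndexError) as exc:
            raise MSIParseError(f"line {lineno}: bad pixel key") from exc
        if not (0 <= r < rows and 0 <= c < cols):
            raise MSIParseError(f"line {lineno}: pixel ({r}, {c}) outside grid {rows}x{cols}")
        vals = np.array([float(v) for v in parts[2:]])
        if vals.size != axis.channel_count:
            raise DimensionError(
                f"pixel ({r}, {c}): {vals.size} intensities, expected {axis.channel_count}"
            )
        spectra[r, c] = vals
        tissue[r, c] = True
    return MSISample(
        sample_id=header.get("sample", ""),
        patient_id=header.get("patient", ""),
        axis=axis,
        spectra=spectra,
        tissue=tissue,
        pixel_spacing=float(header.get("spacing", DEFAULT_PIXEL_SPACING_UM)),
    )


def write_mask_csv(mask: AnnotationMask, path) -> None:
    """Write an annotation mask as a CSV grid of label names."""
    pd.DataFrame(mask.label_names()).to_csv(path, index=False, header=False)


def read_mask_csv(path) -> AnnotationMask:
    """Read an annotation mask from a CSV grid of label names."""
    df = pd.read_csv(path, header=None, dtype=str)
    return AnnotationMask(df.to_numpy())


def read_imzml(path) -> MSISample:  # pragma: no cover - optional dependency
    """Read a continuous-mode imzML file into an :class:`MSISample`.

    Requires the optional ``pyimzml`` dependency.  Coordinates are mapped to
    0-based (row, col) = (y-1, x-1); pixels absent from the file are
    background.
    """
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:
        raise ImportError("reading imzML requires the 'pyimzml' extra") from exc
    parser = ImzMLParser(str(path))
    coords = np.array([(y, x) for x, y, *_ in parser.coordinates])
    rows = int(coords[:, 0].max())
    cols = int(coords[:, 1].max())
    mzs, _ = parser.getspectrum(0)
    axis = MassAxis(np.asarray(mzs, dtype=float))
    spectra = np.zeros((rows, cols, axis.channel_count))
    tissue = np.zeros((rows, cols), dtype=bool)
    for i, (y, x) in enumerate(coords):
        mz_i, ints = parser.getspectrum(i)
        if len(ints) != axis.channel_count:
            raise DimensionError(
                f"pixel ({y - 1}, {x - 1}): {len(ints)} intensities, "
                f"expected {axis.channel_count} (processed-mode imzML is unsupported)"
            )
        spectra[y - 1, x - 1] = ints
        tissue[y - 1, x - 1] = True
    return MSISample("", "", axis, spectra, tissue)


# ---------------------------------------------------------------------------
# digitized reference weight table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceWeightTable:
    """Signed lasso weights per m/z bin and class (reference table).

    ``table`` has columns ``mz, cancer, glands, stroma`` (absent cells = 0);
    ``selected`` has boolean columns marking which cells the classifier
    selected.  The distinction matters because a selected weight may round to
    0.000 in print while an unselected cell is genuinely absent.
    """

    table: pd.DataFrame
    selected: pd.DataFrame

    def __post_init__(self):
        if self.table["mz"].duplicated().any():
            dup = self.table["mz"][self.table["mz"].duplicated()].iloc[0]
            raise ValueError(f"duplicate m/z row {dup}")
        if not (self.selected[list(CLASSES)].any(axis=1)).all():
            raise ValueError("every row must have at least one selected class weight")

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def n_selected(self, cls: str) -> int:
        """Number of m/z values selected as informative for one class."""
        return int(self.selected[cls].sum())

    def weight(self, mz: float, cls: str) -> float:
        row = self.table[np.isclose(self.table["mz"], mz)]
        if row.empty:
            return 0.0
        return float(row[cls].iloc[0])


def load_reference_weight_table(path=None) -> ReferenceWeightTable:
    """Load the packaged digitized feature-weight table (or one like it).

    The packaged fixture digitizes the reference table of m/z values selected
    by the lasso for the three pancreatic tissue classes with their signed
    statistical weights.
    """
    if path is None:
        path = importlib.resources.files("desilasso") / "data" / "table1_weights.csv"
    df = pd.read_csv(path)
    selected = df[list(CLASSES)].notna()
    selected.insert(0, "mz", df["mz"])
    table = df.fillna(0.0)
    return ReferenceWeightTable(table=table, selected=selected)
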