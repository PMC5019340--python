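"""Synthetic multi-patient MSI cohorts with the structure the analysis assumes.

The generator emulates negative-ion-mode spectra of pancreatic tissue over
m/z 90-1,200: each tissue class has a lipid-peak profile (Gaussian peaks on
the mass axis), stroma carries an overall lower total ion abundance, mixed
regions blend class templates convexly, and patients differ through a
per-patient log-normal shift of peak intensities.  None of it models
desorption/ionization physics, isotope patterns, or adducts -- it exists so
that every downstream stage (binning, lasso fitting, patient-grouped CV,
customized training, margin calls) is testable end to end with known truth.

Pixel truth labels are sampled per pixel from the region composition,
mimicking cell-level mixing at 200-um pixels; each pixel's expected spectrum
is its label's template, optionally blended toward the region's composition
mixture (partial-volume effect, weight ``beta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationMask, MassAxis, MSISample, CLASSES

#: Documented default seed for packaged fixtures and examples.
DEFAULT_SEED = 20130227

#: Default peak height (ion counts) for a relative intensity of 1 at
#: total_abundance_scale 1.  Sets the Poisson signal-to-noise regime.
DEFAULT_AMPLITUDE = 60.0

#: Default Gaussian peak sigma in m/z units; each peak spans ~2 channels of
#: the 0.0833-m/z default axis so it lands in a predictable 0.5-m/z bin.
DEFAULT_PEAK_WIDTH = 0.15


@dataclass(frozen=True)
class Peak:
    mz: float
    rel_intensity: float
    width: float = DEFAULT_PEAK_WIDTH


@dataclass(frozen=True)
class ClassProfile:
    """Lipid-peak profile of one tissue class.

    ``total_abundance_scale`` multiplies every peak height; stroma's default
    is well below the glandular and cancer scales, reproducing its overall
    lower total ion count.
    """

    label: str
    peaks: tuple[Peak, ...]
    total_abundance_scale: float = 1.0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("profile needs at least one peak")
        if any(p.rel_intensity > 1 or p.rel_intensity <= 0 for p in self.peaks):
            raise ValueError("relative intensities must lie in (0, 1]")
        if self.total_abundance_scale <= 0:
            raise ValueError("total_abundance_scale must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Instrument/biological variation not otherwise modeled.

    shot_noise: Poisson resampling of expected counts (on by default).
    multiplicative_cv: per-pixel log-normal intensity factor (mean 1).
    baseline_level: additive expected background counts per channel.
    patient_effect_sd: sd of the per-patient log-normal multiplier applied
        independently to each profile peak.
    """

    shot_noise: bool = True
    multiplicative_cv: float = 0.6
    baseline_level: float = 2.0
    patient_effect_sd: float = 0.35

    def __post_init__(self):
        if self.multiplicative_cv < 0 or self.baseline_level < 0 or self.patient_effect_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(shot_noise=False, multiplicative_cv=0.0, baseline_level=0.0,
                   patient_effect_sd=0.0)


def default_class_profiles() -> dict[str, ClassProfile]:
    """Default lipid profiles for the three pancreatic tissue classes.

    Glands: abundant free fatty acids -- oleic (281.2), palmitic (255.3),
    arachidonic (303.3) -- and their dimers at 537.0 and 563.0, plus modest
    glycerophospholipids.  Cancer: polyunsaturated FAs (303.3, adrenic 331.2)
    and PC/PG/PI species (792.4, 794.4, 773.6, 885.6).  Stroma: oleic and
    palmitic acid, PS 788.8 and 816.5, PI 885.6, at a reduced overall
    abundance scale.
    """
    P = Peak
    glands = ClassProfile(
        "glands",
        (
            P(255.3, 0.95), P(281.2, 1.00), P(303.3, 0.60),
            P(537.0, 0.50), P(563.0, 0.45),
            P(750.5, 0.12), P(771.5, 0.10), P(833.5, 0.10),
            P(861.5, 0.14), P(885.6, 0.18),
        ),
        total_abundance_scale=1.0,
    )
    cancer = ClassProfile(
        "cancer",
        (
            P(255.3, 0.45), P(281.2, 0.55), P(303.3, 0.90), P(331.2, 0.70),
            P(773.6, 0.35), P(792.4, 0.40), P(794.4, 0.45), P(885.6, 0.55),
        ),
        total_abundance_scale=0.9,
    )
    # stroma shares the free-FA ions with glands (plus traces of the glands
    # dimers, as fibrous stroma interdigitates glandular tissue) and is
    # distinguished mainly by PS species and its low overall abundance --
    # which is what makes it the hardest class to call per pixel.
    stroma = ClassProfile(
        "stroma",
        (
            P(255.3, 0.85), P(281.2, 1.00), P(303.3, 0.45),
            P(537.0, 0.30), P(563.0, 0.27),
            P(788.8, 0.08), P(816.5, 0.07), P(885.6, 0.50),
        ),
        total_abundance_scale=0.35,
    )
    return {"cancer": cancer, "glands": glands, "stroma": stroma}


def class_template(
    profile: ClassProfile,
    axis: MassAxis,
    amplitude: float = DEFAULT_AMPLITUDE,
    peak_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free expected spectrum of a pure-class pixel.

    Each peak contributes a Gaussian of height
    ``amplitude * rel_intensity * total_abundance_scale`` (optionally times a
    per-peak multiplier, e.g. a patient effect).
    """
    mz = axis.mz_values
    out = np.zeros_like(mz)
    mults = np.ones(len(profile.peaks)) if peak_multipliers is None else peak_multipliers
    for peak, m in zip(profile.peaks, mults):
        h = amplitude * peak.rel_intensity * profile.total_abundance_scale * m
        lo, hi = np.searchsorted(mz, [peak.mz - 6 * peak.width, peak.mz + 6 * peak.width])
        out[lo:hi] += h * np.exp(-0.5 * ((mz[lo:hi] - peak.mz) / peak.width) ** 2)
    return out


def sample_patient_effect(
    profiles: dict[str, ClassProfile], sd: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-patient log-normal multipliers, one per peak per class profile."""
    return {
        label: np.exp(rng.normal(-0.5 * sd**2, sd, size=len(prof.peaks)))
        for label, prof in profiles.items()
    }


def _check_composition(composition) -> np.ndarray:
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (3,) or np.any(comp < 0):
        raise ValueError("composition must be 3 non-negative fractions")
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition must sum to 1 (got {comp.sum()!r})")
    return comp


def generate_pixel_spectrum(
    composition,
    profiles: dict[str, ClassProfile],
    noise: NoiseModel,
    patient_effect: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    axis: MassAxis | None = None,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> np.ndarray:
    """Draw one pixel spectrum for a composition ``(cancer, glands, stroma)``.

    The expected spectrum is the composition-weighted sum of the class
    templates (scaled by the patient effect) plus the noise baseline; the
    log-normal factor has mean 1 and Poisson resampling preserves the mean,
    so averaging many draws recovers template + baseline.
    """
    comp = _check_composition(composition)
    axis = axis or MassAxis.default()
    rng = rng or np.random.default_rng()
    templates = {
        label: class_template(
            profiles[label], axis, amplitude,
            None if patient_effect is None else patient_effect[label],
        )
        for label in CLASSES
    }
    mean = sum(c * templates[label] for c, label in zip(comp, CLASSES))
    if noise.multiplicative_cv > 0:
        s = noise.multiplicative_cv
        mean = mean * np.exp(rng.normal(-0.5 * s**2, s))
    mean = mean + noise.baseline_level
    if noise.shot_noise:
        return rng.poisson(mean).astype(float)
    return mean


@dataclass(frozen=True)
class Region:
    """A connected pixel set with a fixed cell-type composition."""

    name: str
    pixel_mask: np.ndarray
    composition: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pixel_mask", np.asarray(self.pixel_mask, dtype=bool))
        object.__setattr__(self, "composition", _check_composition(self.composition))
        if not self.pixel_mask.any():
            raise ValueError(f"region {self.name!r} has zero area")


@dataclass(frozen=True)
class TissueLayout:
    """Regions partitioning the non-background pixels of one grid."""

    grid_shape: tuple[int, int]
    regions: tuple[Region, ...]

    def __post_init__(self):
        cover = np.zeros(self.grid_shape, dtype=int)
        for reg in self.regions:
            if reg.pixel_mask.shape != tuple(self.grid_shape):
                raise ValueError(f"region {reg.name!r} mask shape mismatch")
            cover += reg.pixel_mask
        if cover.max() > 1:
            raise ValueError("regions overlap")


def banded_layout(
    grid_shape: tuple[int, int],
    fractions: dict[str, float],
    border: int = 0,
) -> TissueLayout:
    """Horizontal pure-class bands occupying the given row fractions.

    ``fractions`` maps class name -> fraction of the (non-border) rows;
    fractions must sum to 1.  ``border`` rows/cols around the edge stay
    background.
    """
    rows, cols = grid_shape
    inner_rows = rows - 2 * border
    if inner_rows <= 0 or cols - 2 * border <= 0:
        raise ValueError("border too large for grid")
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("band fractions must sum to 1")
    edges = [border]
    names = list(fractions)
    for i, name in enumerate(names):
        if i == len(names) - 1:
            edges.append(rows - border)
        else:
            edges.append(edges[-1] + max(1, round(fractions[name] * inner_rows)))
    regions = []
    for name, lo, hi in zip(names, edges[:-1], edges[1:]):
        m = np.zeros(grid_shape, dtype=bool)
        m[lo:hi, border : cols - border] = True
        comp = np.array([float(name == c) for c in CLASSES])
        regions.append(Region(name, m, comp))
    return TissueLayout(grid_shape, tuple(regions))


def mixed_layout(
    grid_shape: tuple[int, int], composition, name: str = "mixed", border: int = 0
) -> TissueLayout:
    """A single region of mixed histology covering the whole (inner) grid.

    Example: ``composition=(0.20, 0, 0.80)`` emulates a sample of 20% tumor
    cells infiltrating 80% stroma.
    """
    rows, cols = grid_shape
    m = np.zeros(grid_shape, dtype=bool)
    m[border : rows - border, border : cols - border] = True
    return TissueLayout(grid_shape, (Region(name, m, np.asarray(composition, float)),))


@dataclass
class SyntheticCohortConfig:
    """Recipe for a reproducible multi-patient cohort.

    One sample per (patient, layout); layouts cycle if fewer than
    ``samples_per_patient``.  ``batch_peaks`` optionally adds spurious peaks
    ``(mz, amplitude, width)`` to every spectrum of every sample (an
    instrument batch shift).  The seed is recorded in the output manifest.
    """

    n_patients: int
    layouts: list[TissueLayout]
    samples_per_patient: int = 1
    profiles: dict[str, ClassProfile] = field(default_factory=default_class_profiles)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = DEFAULT_SEED
    beta: float = 0.3
    amplitude: float = DEFAULT_AMPLITUDE
    axis: MassAxis | None = None
    batch_peaks: list[tuple[float, float, float]] | None = None
    patient_prefix: str = "P"

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")


def generate_sample(
    layout: TissueLayout,
    profiles: dict[str, ClassProfile],
    noise: NoiseModel,
    rng: np.random.Generator,
    sample_id: str = "S",
    patient_id: str = "P",
    axis: MassAxis | None = None,
    beta: float = 0.3,
    amplitude: float = DEFAULT_AMPLITUDE,
    patient_effect: dict[str, np.ndarray] | None = None,
    batch_peaks: list[tuple[float, float, float]] | None = None,
) -> tuple[MSISample, AnnotationMask]:
    """Generate one sample: truth labels sampled per pixel, then spectra.

    For a region of composition ``c`` each pixel's label is drawn from ``c``
    (cell-level mixing at 200-um pixels).  The pixel's expected spectrum is
    ``(1-beta) * T_label + beta * T_mix(c)`` where ``T_mix`` is the convex
    template mixture -- the partial-volume blend.
    """
    axis = axis or MassAxis.default()
    templates = np.stack(
        [
            class_template(
                profiles[label], axis, amplitude,
                None if patient_effect is None else patient_effect[label],
            )
            for label in CLASSES
        ]
    )  # (3, nchan)
    batch = np.zeros(axis.channel_count)
    if batch_peaks:
        mz = axis.mz_values
        for center, amp, width in batch_peaks:
            batch += amp * np.exp(-0.5 * ((mz - center) / width) ** 2)

    grid = tuple(layout.grid_shape)
    labels = np.zeros(grid, dtype=np.int8)  # background
    spectra = np.zeros(grid + (axis.channel_count,))
    tissue = np.zeros(grid, dtype=bool)
    region_map = np.full(grid, -1, dtype=int)
    regions = {}
    for rid, reg in enumerate(layout.regions):
        r_idx, c_idx = np.nonzero(reg.pixel_mask)
        n = r_idx.size
        drawn = rng.choice(3, size=n, p=reg.composition)
        labels[r_idx, c_idx] = drawn + 1  # class codes are 1..3
        tissue[r_idx, c_idx] = True
        region_map[r_idx, c_idx] = rid
        regions[rid] = reg.composition
        t_mix = reg.composition @ templates
        mean = (1 - beta) * templates[drawn] + beta * t_mix + batch
        if noise.multiplicative_cv > 0:
            s = noise.multiplicative_cv
            mean = mean * np.exp(rng.normal(-0.5 * s**2, s, size=(n, 1)))
        mean = mean + noise.baseline_level
        spectra[r_idx, c_idx] = rng.poisson(mean) if noise.shot_noise else mean
    sample = MSISample(sample_id, patient_id, axis, spectra, tissue)
    mask = AnnotationMask(labels, region_map, regions)
    return sample, mask


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[tuple[MSISample, AnnotationMask]], pd.DataFrame]:
    """Generate a cohort grouped by patient plus its manifest.

    Deterministic given ``config.seed``: per-sample random streams are
    spawned from a single seed sequence, so the same seed reproduces the
    cohort bit for bit.  The manifest records sample_id, patient_id, layout
    index and seed.
    """
    ss = np.random.SeedSequence(config.seed)
    patient_seeds = ss.spawn(config.n_patients)
    out = []
    manifest = []
    for p in range(config.n_patients):
        p_ss = patient_seeds[p]
        eff_rng = np.random.default_rng(p_ss.spawn(1)[0])
        effect = sample_patient_effect(
            config.profiles, config.noise.patient_effect_sd, eff_rng
        )
        patient_id = f"{config.patient_prefix}{p:03d}"
        for s in range(config.samples_per_patient):
            layout = config.layouts[(p * config.samples_per_patient + s) % len(config.layouts)]
            rng = np.random.default_rng(p_ss.spawn(1)[0])
            sample_id = f"{patient_id}S{s}"
            pair = generate_sample(
                layout, config.profiles, config.noise, rng,
                sample_id=sample_id, patient_id=patient_id,
                axis=config.axis, beta=config.beta, amplitude=config.amplitude,
                patient_effect=effect, batch_peaks=config.batch_peaks,
            )
            out.append(pair)
            manifest.append(
                {"sample_id": sample_id, "patient_id": patient_id,
                 "layout": (p * config.samples_per_patient + s) % len(config.layouts),
                 "seed": config.seed}
            )
    return out, pd.DataFrame(manifest)
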