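"""Synthetic fossil phantoms and forward-simulated XRF count cubes.

Real specimens of interest are flattened fossils whose tissues —
phosphatized bone, finely mineralized muscle, other soft tissue, cuticle —
differ from each other and from the sedimentary matrix in major elements
(Ca, P vs Si, K, Fe) and in trace rare-earth content (ppm to ~0.2 wt%).
The phantom generator draws a labeled tissue-region image with that
compositional structure and forward-simulates the raster-scan cube:
Gaussian detector line shapes on tabulated emission energies, a smooth
continuum plus a small elastic-scatter peak, and Poisson counting noise.

The per-element sensitivity is a deliberately simplified fixture —
photoabsorption of the beam by the element times shell fraction and
fluorescence yield, with no self-absorption or secondary enhancement —
adequate to emulate relative count budgets, not to quantify.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse

from .core import EnergyCalibration, SpectralMap
from .decomposition import LineModel, _group_profile
from .depth import elemental_mu_rho
from . import lines as _lines

__all__ = [
    "TissueClass",
    "Phantom",
    "default_compositions",
    "shrimp_compositions",
    "make_phantom",
    "forward_spectra",
    "expected_class_spectra",
    "element_sensitivity",
    "default_calibration",
    "classify_by_reference",
    "save_phantom",
    "load_phantom",
]

BEAM_ENERGY_KEV = 17.2   # excitation used for all default simulations
DEFAULT_DWELL_S = 0.5
DEFAULT_FLUX_SCALE = 20000.0   # counts per (sensitivity * wt fraction * s)
BACKGROUND_FRACTION = 0.05     # continuum counts relative to line counts
ELASTIC_FRACTION = 0.01        # elastic-scatter peak relative to line counts

_SHELL_FRACTION = {"K": 0.87, "L": 0.60}


def default_calibration() -> EnergyCalibration:
    """1024 channels x 20 eV: 0-20.48 keV, covering Si Ka to the elastic peak."""
    return EnergyCalibration(offset=0.0, gain=0.02, n_channels=1024)


@dataclass(frozen=True)
class TissueClass:
    """A tissue (or matrix) with its elemental composition.

    ``composition`` maps element symbols to concentrations in weight
    fraction; the remainder is an undetected light matrix.
    ``relative_brightness`` scales the expected total count rate of the
    class (thickness/density proxy).
    """

    name: str
    composition: dict[str, float]
    relative_brightness: float = 1.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.composition.values()):
            raise ValueError("concentrations must be non-negative")
        if sum(self.composition.values()) > 1.0:
            raise ValueError("concentrations sum above 1")


def default_compositions() -> list[TissueClass]:
    """Tissue compositions of the default (teleost fish) phantom.

    Bone carries the trace inventory reported for fossil bone — Sr 150 ppm,
    Y 550 ppm, La 750 ppm, Nd 0.18 wt%, Gd 550 ppm, Yb 10 ppm — on a Ca/P
    apatite major composition; mineralized muscle keeps Ca/P with Nd
    900 ppm and reduced Y but retains a clay/organic admixture (Si, K,
    extra Fe) reflecting its finer, incomplete mineralization; other soft
    tissue carries more admixture still; the clayey matrix is Si/K/Fe-rich
    and REE-poor.  The admixture gradient is what makes the tissues'
    *relative* compositions — hence their spectral densities — mutually
    distinct, as in real specimens.
    """
    return [
        TissueClass("matrix", {
            "Si": 0.25, "K": 0.022, "Ca": 0.012, "Ti": 0.003, "Fe": 0.050,
            "Sr": 3e-5, "Y": 1e-5, "Nd": 2e-5, "Gd": 5e-6,
        }, relative_brightness=1.0),
        TissueClass("bone", {
            "Ca": 0.36, "P": 0.167, "Fe": 0.010,
            "Sr": 1.5e-4, "Y": 5.5e-4, "La": 7.5e-4, "Nd": 1.8e-3,
            "Gd": 5.5e-4, "Yb": 1.0e-5,
        }, relative_brightness=1.1),
        TissueClass("muscle", {
            "Ca": 0.15, "P": 0.070, "Si": 0.07, "K": 0.007, "Fe": 0.020,
            "Sr": 8e-5, "Y": 1.5e-4, "La": 3e-4, "Nd": 9.0e-4,
            "Gd": 2.75e-4, "Yb": 5e-6,
        }, relative_brightness=1.0),
        TissueClass("soft_tissue", {
            "Ca": 0.05, "P": 0.028, "Si": 0.13, "K": 0.013, "Fe": 0.036,
            "Sr": 2e-5, "Y": 5e-5, "La": 8e-5, "Nd": 2.0e-4, "Gd": 8e-5,
        }, relative_brightness=0.9),
    ]


def shrimp_compositions() -> list[TissueClass]:
    """Alternate preset for a phosphatized shrimp cross-section.

    Cuticle and soft tissues are apatitic with Sr ~100 ppm, Y ~200 ppm and
    Nd 0.12 wt% concentrated in the cuticle.
    """
    return [
        TissueClass("matrix", {
            "Si": 0.25, "K": 0.022, "Ca": 0.012, "Ti": 0.003, "Fe": 0.050,
            "Sr": 3e-5, "Y": 1e-5, "Nd": 2e-5,
        }),
        TissueClass("cuticle", {
            "Ca": 0.30, "P": 0.14, "Fe": 0.015,
            "Sr": 1.0e-4, "Y": 2.0e-4, "Nd": 1.2e-3, "La": 5e-4, "Gd": 3e-4,
        }, relative_brightness=1.05),
        TissueClass("muscle", {
            "Ca": 0.16, "P": 0.075, "Si": 0.05, "K": 0.005, "Fe": 0.012,
            "Sr": 7e-5, "Y": 2.0e-4, "Nd": 7e-4, "Gd": 2e-4,
        }),
        TissueClass("soft_tissue", {
            "Ca": 0.07, "P": 0.040, "Si": 0.10, "K": 0.010, "Fe": 0.028,
            "Sr": 3e-5, "Y": 1.1e-4, "Nd": 3e-4, "Gd": 9e-5,
        }, relative_brightness=0.9),
    ]


@dataclass
class Phantom:
    """Labeled tissue image with per-class compositions and truth maps."""

    labels: np.ndarray
    classes: list[TissueClass]
    pixel_pitch: tuple[float, float] = (100.0, 100.0)

    def __post_init__(self) -> None:
        if self.labels.max() >= len(self.classes) or self.labels.min() < 0:
            raise ValueError("labels index undefined classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def elements(self) -> list[str]:
        out: set[str] = set()
        for cls in self.classes:
            out.update(cls.composition)
        return sorted(out)

    def class_index(self, name: str) -> int:
        for i, cls in enumerate(self.classes):
            if cls.name == name:
                return i
        raise KeyError(f"no class named {name!r}")

    def truth_map(self, element: str) -> np.ndarray:
        """Ground-truth concentration image (wt fraction) of an element."""
        levels = np.array(
            [cls.composition.get(element, 0.0) for cls in self.classes]
        )
        return levels[self.labels]

    def truth_maps(self) -> dict[str, np.ndarray]:
        return {el: self.truth_map(el) for el in self.elements}

    def class_fractions(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(),
                           minlength=len(self.classes)) / self.labels.size

    def reference_pixels(self) -> dict[str, tuple[int, int]]:
        """One deterministic interior pixel per class (maximally inside)."""
        refs = {}
        for i, cls in enumerate(self.classes):
            mask = self.labels == i
            dist = ndimage.distance_transform_edt(mask)
            r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
            refs[cls.name] = (int(r), int(c))
        return refs


# ---------------------------------------------------------------------------
# Layout drawing
# ---------------------------------------------------------------------------

def _fish_labels(shape: tuple[int, int], rng: np.random.Generator,
                 idx: dict[str, int]) -> np.ndarray:
    rows, cols = shape
    labels = np.full(shape, idx["matrix"], dtype=np.int32)
    cr, cc = rows / 2.0, cols / 2.0
    body_r = 0.44 * rows * rng.uniform(0.95, 1.05)
    body_c = 0.30 * cols * rng.uniform(0.95, 1.05)
    rr, cc_ = ellipse(cr, cc, body_r, body_c, shape=shape)
    labels[rr, cc_] = idx["soft_tissue"]
    body = labels == idx["soft_tissue"]

    # muscle bands flanking the spine
    spine_col = int(cc + rng.integers(-2, 3))
    half_w = max(3, int(0.10 * cols))
    gap = max(2, int(0.025 * cols))
    band = np.zeros(shape, bool)
    band[:, max(0, spine_col - half_w - gap):spine_col - gap] = True
    band[:, spine_col + 1 + gap:min(cols, spine_col + half_w + gap + 1)] = True
    labels[band & body] = idx["muscle"]

    # spine plus rib rods and a skull blob: bone
    spine = np.zeros(shape, bool)
    r0, r1 = int(cr - body_r * 0.92), int(cr + body_r * 0.80)
    spine[max(0, r0):min(rows, r1), spine_col - 1:spine_col + 2] = True
    rib_len = max(4, int(0.16 * cols))
    for r in range(max(2, r0 + 4), r1, 7):
        rib_r = r + int(rng.integers(-1, 2))
        if 0 <= rib_r < rows:
            spine[rib_r, max(0, spine_col - rib_len):spine_col] = True
            spine[rib_r, spine_col:min(cols, spine_col + rib_len)] = True
    rr, cc_ = ellipse(max(4, r0), spine_col, 0.06 * rows, 0.14 * cols,
                      shape=shape)
    skull = np.zeros(shape, bool)
    skull[rr, cc_] = True
    labels[(spine | skull) & (labels != idx["matrix"])] = idx["bone"]
    labels[skull] = idx["bone"]
    return labels


def _shrimp_labels(shape: tuple[int, int], rng: np.random.Generator,
                   idx: dict[str, int]) -> np.ndarray:
    rows, cols = shape
    labels = np.full(shape, idx["matrix"], dtype=np.int32)
    cr, cc = rows / 2.0, cols / 2.0
    outer_r = 0.42 * rows * rng.uniform(0.95, 1.05)
    outer_c = 0.40 * cols * rng.uniform(0.95, 1.05)
    rr, cc_ = ellipse(cr, cc, outer_r, outer_c, shape=shape)
    labels[rr, cc_] = idx["cuticle"]
    rr, cc_ = ellipse(cr, cc, 0.82 * outer_r, 0.82 * outer_c, shape=shape)
    labels[rr, cc_] = idx["soft_tissue"]
    rr, cc_ = ellipse(cr - 0.3 * outer_r, cc, 0.28 * outer_r, 0.5 * outer_c,
                      shape=shape)
    sub = labels[rr, cc_]
    sub[sub == idx["soft_tissue"]] = idx["muscle"]
    labels[rr, cc_] = sub
    return labels


def _blob_labels(shape: tuple[int, int], rng: np.random.Generator,
                 n_classes: int) -> np.ndarray:
    rows, cols = shape
    labels = np.zeros(shape, dtype=np.int32)
    for k in range(1, n_classes):
        target = 0.08 * rows * cols
        placed = 0
        while placed < target:
            r = rng.uniform(0.1, 0.9) * rows
            c = rng.uniform(0.1, 0.9) * cols
            rad = rng.uniform(0.05, 0.14) * min(rows, cols)
            rr, cc_ = disk((r, c), rad, shape=shape)
            labels[rr, cc_] = k
            placed += rr.size
    return labels


def make_phantom(
    shape: tuple[int, int] = (128, 96),
    layout: str = "fish",
    seed: int = 0,
    classes: list[TissueClass] | None = None,
    pixel_pitch: tuple[float, float] = (100.0, 100.0),
) -> Phantom:
    """Draw a labeled phantom; deterministic for a fixed seed.

    Layouts: ``fish`` (elongated soft-tissue body, spine + ribs + skull in
    bone, muscle bands flanking the spine, matrix elsewhere),
    ``shrimp_section`` (cuticle ring, soft interior, muscle region) and
    ``blobs`` (random discs per class).  Every class covers >= 2 % of the
    pixels.
    """
    if min(shape) < 16:
        raise ValueError("shape must be at least 16 x 16")
    rng = np.random.default_rng(seed)
    if layout == "fish":
        classes = classes or default_compositions()
        idx = {cls.name: i for i, cls in enumerate(classes)}
        labels = _fish_labels(shape, rng, idx)
    elif layout == "shrimp_section":
        classes = classes or shrimp_compositions()
        idx = {cls.name: i for i, cls in enumerate(classes)}
        labels = _shrimp_labels(shape, rng, idx)
    elif layout == "blobs":
        classes = classes or default_compositions()
        labels = _blob_labels(shape, rng, len(classes))
    else:
        raise ValueError(
            f"unknown layout {layout!r}; expected fish, shrimp_section or blobs"
        )
    phantom = Phantom(labels, classes, pixel_pitch)
    fractions = phantom.class_fractions()
    if fractions.min() < 0.02:
        # deterministically pad the rarest class with a corner block
        k = int(np.argmin(fractions))
        need = int(np.ceil((0.02 - fractions[k]) * labels.size))
        side = int(np.ceil(np.sqrt(need)))
        labels[:side, :side] = k
    return Phantom(labels, classes, pixel_pitch)


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=256)
def element_sensitivity(element: str, series: str,
                        beam_energy: float = BEAM_ENERGY_KEV) -> float:
    """Synthetic detection sensitivity per unit weight fraction.

    Photoabsorption of the beam by the element (cm²/g) times the emitting
    shell's share and fluorescence yield.  A fixture constant, not a
    fundamental-parameters quantity: self-absorption, detector efficiency
    and enhancement are deliberately omitted.
    """
    edge = _lines.edge_energy(element, series)
    if edge >= beam_energy:
        raise ValueError(
            f"{element} {series} edge at {edge} keV not excitable at "
            f"{beam_energy} keV"
        )
    mu = elemental_mu_rho(element, beam_energy)
    return mu * _SHELL_FRACTION[series.upper()[0]] * \
        _lines.fluorescence_yield(element, series)


def _continuum_shape(energies: np.ndarray, beam_energy: float) -> np.ndarray:
    """Unit-sum smooth continuum: rises from zero, decays, cut at the beam."""
    shape = np.clip(energies, 0, None) * np.exp(-energies / 4.0)
    shape[energies < 0.8] = 0.0
    shape[energies > beam_energy + 0.3] = 0.0
    return shape / shape.sum()


def expected_class_spectra(
    phantom: Phantom,
    model: LineModel | None = None,
    cal: EnergyCalibration | None = None,
    dwell: float = DEFAULT_DWELL_S,
    flux_scale: float = DEFAULT_FLUX_SCALE,
) -> tuple[np.ndarray, LineModel, EnergyCalibration]:
    """Noise-free expected spectrum per tissue class.

    Returns ``(expected, model, cal)`` with ``expected`` of shape
    ``(n_classes, n_channels)``.  These are the ground-truth class spectra
    the Poisson simulation draws from; normalized, they are the true class
    spectral densities used to validate denoising.
    """
    cal = cal or default_calibration()
    model = model or LineModel.for_elements(
        phantom.elements, beam_energy=BEAM_ENERGY_KEV
    )
    energies = cal.energies
    profiles: dict[str, np.ndarray] = {}
    series_of: dict[str, str] = {}
    for label, group in model.groups.items():
        element, series = label.split("_")
        profiles[element] = _group_profile(group, model, energies)
        series_of[element] = series
    for el in phantom.elements:
        if el not in profiles:
            raise ValueError(f"line model lacks a group for element {el}")
    continuum = _continuum_shape(energies, model.beam_energy)
    if energies[0] < model.beam_energy < energies[-1]:
        sigma = model.fwhm(model.beam_energy) / 2.3548
        elastic = np.exp(-0.5 * ((energies - model.beam_energy) / sigma) ** 2)
        elastic = elastic / elastic.sum()
    else:
        elastic = np.zeros_like(energies)

    expected = np.zeros((len(phantom.classes), cal.n_channels))
    for i, cls in enumerate(phantom.classes):
        line_part = np.zeros(cal.n_channels)
        for el, conc in cls.composition.items():
            sens = element_sensitivity(el, series_of[el], model.beam_energy)
            line_part += conc * sens * profiles[el]
        line_total = line_part.sum()
        spectrum = (
            line_part
            + BACKGROUND_FRACTION * line_total * continuum
            + ELASTIC_FRACTION * line_total * elastic
        )
        expected[i] = dwell * flux_scale * cls.relative_brightness * spectrum
    return expected, model, cal


def forward_spectra(
    phantom: Phantom,
    model: LineModel | None = None,
    cal: EnergyCalibration | None = None,
    dwell: float = DEFAULT_DWELL_S,
    flux_scale: float = DEFAULT_FLUX_SCALE,
    seed: int = 0,
) -> SpectralMap:
    """Poisson-sample the raster-scan count cube of a phantom.

    Deterministic for a fixed seed (one RNG stream per cube); a zero
    ``flux_scale`` yields an all-zero cube.
    """
    expected, model, cal = expected_class_spectra(
        phantom, model, cal, dwell, flux_scale
    )
    rng = np.random.default_rng(seed)
    lam = expected[phantom.labels]           # rows x cols x channels
    cube = rng.poisson(lam).astype(np.uint32)
    return SpectralMap(
        cube, cal, phantom.pixel_pitch,
        metadata={
            "beam_energy_keV": model.beam_energy,
            "dwell_s": dwell,
            "flux_scale": flux_scale,
            "seed": seed,
        },
    )


def classify_by_reference(
    spectral_map: SpectralMap,
    reference_pixels: dict[str, tuple[int, int]],
    pseudocount: int = 1,
) -> tuple[np.ndarray, list[str]]:
    """Assign every pixel to the reference with the highest likelihood weight.

    Returns ``(assignment, names)`` where ``assignment[r, c]`` indexes
    ``names`` (argmin of the KL divergence across the reference set).
    """
    from .kl import divergence_map

    names = list(reference_pixels)
    stack = np.stack([
        divergence_map(spectral_map, reference_pixels[name], pseudocount).values
        for name in names
    ])
    return np.argmin(stack, axis=0), names


# ---------------------------------------------------------------------------
# Phantom I/O (ground truth rides along in /truth)
# ---------------------------------------------------------------------------

def save_phantom(phantom: Phantom, spectral_map: SpectralMap, path) -> None:
    """Write cube plus ground truth (labels, truth maps) to one HDF5 file."""
    import h5py
    from .core import save_map

    save_map(spectral_map, path)
    with h5py.File(path, "a") as f:
        truth = f.create_group("truth")
        truth.create_dataset("labels", data=phantom.labels.astype(np.int32))
        truth.attrs["class_names"] = [cls.name for cls in phantom.classes]
        maps = truth.create_group("element_maps")
        for el, img in phantom.truth_maps().items():
            maps.create_dataset(el, data=img.astype(np.float32))


def load_phantom(path) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Read back ground truth: (labels, class names, element truth maps)."""
    import h5py

    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise KeyError(f"{path}: no '/truth' group")
        truth = f["truth"]
        labels = truth["labels"][()]
        names = [n if isinstance(n, str) else n.decode()
                 for n in truth.attrs["class_names"]]
        maps = {k: v[()] for k, v in truth["element_maps"].items()}
    return labels, names, maps
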