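"""Statistical discrimination of tissues from full XRF spectra.

Each pixel's spectrum, normalized to unit sum, estimates the probability
that a detected photon has a given energy — the *spectral density*.  Two
pixels of identical composition (and stratigraphy) share a spectral
density regardless of dwell time or flux, so comparing densities compares
materials.  The comparison uses the Kullback-Leibler divergence

.. math:: KL(t, s) = \\sum_i \\hat t_i \\ln(\\hat t_i / \\hat s_i),

between a preselected *reference* pixel ``t`` and every *evaluated* pixel
``s``.  Because the densities are empirical, a channel can be zero in
``s`` while nonzero in ``t``, making the divergence blow up on counting
noise alone; one photon is therefore added to every channel of the
evaluated spectrum (the pseudocount), never to the reference.  The
likelihood transform ``w = exp(-KL)`` of the divergence is the expected
likelihood ratio of ``s`` under ``t``; pixels with ``w`` above a
threshold λ form the set ``P_λ`` whose weighted mean density is the
denoised density of the reference tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EnergyCalibration, SpectralMap, Spectrum

__all__ = [
    "SpectralDensity",
    "DivergenceImage",
    "WeightImage",
    "spectral_density",
    "kl_divergence",
    "divergence_map",
    "likelihood_weights",
    "denoised_density",
    "weight_histogram",
    "log_ratio",
    "KLTissueModel",
    "KLTissueResults",
]


@dataclass(frozen=True)
class SpectralDensity:
    """Per-channel probability distribution of photon energy.

    ``probabilities`` are non-negative and sum to 1 (within 1e-12).
    """

    probabilities: np.ndarray
    calibration: EnergyCalibration | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12 * max(1.0, p.size):
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return self.probabilities.size


@dataclass(frozen=True)
class DivergenceImage:
    """Per-pixel KL divergence from a reference pixel.

    Pixels with zero total counts have no defined density; their
    divergence is +inf and ``valid`` is False there.
    """

    values: np.ndarray
    reference_pixel: tuple[int, int]
    pseudocount: int = 1

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class WeightImage:
    """exp(-divergence) likelihood weights with a retention threshold λ.

    ``retained`` marks pixels entering the denoised average: valid pixels
    with weight >= λ (the boundary is inclusive).
    """

    weights: np.ndarray
    threshold: float
    valid: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        return self.valid & (self.weights >= self.threshold)


def spectral_density(spectrum: Spectrum | np.ndarray) -> SpectralDensity:
    """Normalize a count spectrum to a unit-sum spectral density."""
    if isinstance(spectrum, Spectrum):
        counts, cal = spectrum.counts, spectrum.calibration
    else:
        counts, cal = np.asarray(spectrum, float), None
    total = counts.sum()
    if total <= 0:
        raise ValueError("spectral density undefined for an all-zero spectrum")
    return SpectralDensity(counts / total, cal)


def kl_divergence(
    t_counts: np.ndarray | Spectrum,
    s_counts: np.ndarray | Spectrum,
    pseudocount: int = 1,
) -> float:
    """KL divergence of the evaluated spectrum ``s`` from the reference ``t``.

    The pseudocount is added to every channel of ``s`` only (``t`` is taken
    as the true distribution and receives no regularization); channels with
    zero reference density contribute 0 (the ``0·ln 0`` convention).
    """
    t = t_counts.counts if isinstance(t_counts, Spectrum) else np.asarray(t_counts, float)
    s = s_counts.counts if isinstance(s_counts, Spectrum) else np.asarray(s_counts, float)
    if t.shape != s.shape:
        raise ValueError(f"spectra have different lengths: {t.shape} vs {s.shape}")
    if t.sum() <= 0:
        raise ValueError("reference spectrum has no counts")
    t_hat = t / t.sum()
    s_reg = s + pseudocount
    s_total = s_reg.sum()
    if s_total <= 0:
        return float("inf")
    s_hat = s_reg / s_total
    mask = t_hat > 0
    if np.any(s_hat[mask] == 0):
        return float("inf")
    return float(np.sum(t_hat[mask] * np.log(t_hat[mask] / s_hat[mask])))


def divergence_map(
    spectral_map: SpectralMap,
    reference_pixel: tuple[int, int],
    pseudocount: int = 1,
) -> DivergenceImage:
    """KL divergence of every pixel's density from the reference pixel's.

    Vectorized over the raster; pixels with zero total counts are flagged
    invalid (+inf), not zero.
    """
    cube = spectral_map.counts_cube.astype(np.float64)
    rows, cols, n_ch = cube.shape
    r0, c0 = reference_pixel
    t = cube[r0, c0]
    if t.sum() <= 0:
        raise ValueError(f"reference pixel {reference_pixel} has no counts")
    t_hat = t / t.sum()
    mask = t_hat > 0
    t_m = t_hat[mask]
    t_entropy = float(np.sum(t_m * np.log(t_m)))

    flat = cube.reshape(-1, n_ch)
    totals = flat.sum(axis=1)
    s_reg = flat[:, mask] + pseudocount
    s_tot = totals + pseudocount * n_ch
    with np.errstate(divide="ignore", invalid="ignore"):
        log_s = np.log(s_reg) - np.log(s_tot)[:, None]
        kl = t_entropy - log_s @ t_m
    kl = np.asarray(kl, float)
    if pseudocount == 0:
        kl[np.any(s_reg == 0, axis=1)] = np.inf
    kl[totals <= 0] = np.inf
    kl = np.maximum(kl, 0.0)  # clip float round-off at the KL(t,t)=0 point
    return DivergenceImage(kl.reshape(rows, cols), (r0, c0), pseudocount)


def likelihood_weights(div: DivergenceImage, threshold: float = 0.8) -> WeightImage:
    """Transform divergences to weights ``w = exp(-KL)`` and threshold at λ.

    Valid pixels always satisfy ``0 < w <= 1``; invalid pixels get weight 0.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    valid = np.isfinite(div.values)
    weights = np.where(valid, np.exp(-np.where(valid, div.values, 0.0)), 0.0)
    return WeightImage(weights, threshold, valid)


def denoised_density(
    spectral_map: SpectralMap,
    weights: WeightImage,
) -> SpectralDensity:
    """Likelihood-weighted mean density over the retained pixel set P_λ.

    ``Σ_{p∈P_λ} w_p ŝ_p / Σ_{p∈P_λ} w_p`` — a convex combination of the
    retained pixels' densities, so it sums to 1.
    """
    retained = weights.retained
    if not retained.any():
        raise ValueError(
            "no pixels retained at this threshold; lower the threshold"
        )
    cube = spectral_map.counts_cube.astype(np.float64)
    sel = cube[retained]
    totals = sel.sum(axis=1, keepdims=True)
    densities = sel / totals
    w = weights.weights[retained][:, None]
    avg = (w * densities).sum(axis=0) / w.sum()
    return SpectralDensity(avg / avg.sum(), spectral_map.calibration)


def weight_histogram(
    weights: WeightImage, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of valid pixels' weights over [0, 1].

    Returns (bin_edges, counts, threshold); counts sum to the number of
    valid pixels.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = weights.weights[weights.valid]
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return edges, counts, weights.threshold


def log_ratio(d1: SpectralDensity, d2: SpectralDensity) -> np.ndarray:
    """Per-channel signed log-ratio ``ln(d1_i / d2_i)`` of two densities.

    The sign marks which density is higher at that energy.  Channels where
    both densities are 0 give 0; channels where exactly one is 0 give ±inf
    (flagged, not clipped).  Antisymmetric by construction.
    """
    p1, p2 = d1.probabilities, d2.probabilities
    if p1.shape != p2.shape:
        raise ValueError("densities have different lengths")
    out = np.zeros_like(p1)
    both = (p1 > 0) & (p2 > 0)
    out[both] = np.log(p1[both] / p2[both])
    out[(p1 > 0) & (p2 == 0)] = np.inf
    out[(p1 == 0) & (p2 > 0)] = -np.inf
    return out


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------

class KLTissueModel:
    """Divergence-based tissue discrimination against one reference pixel.

    Parameters
    ----------
    spectral_map : SpectralMap
    reference_pixel : (row, col)
        A pixel judged characteristic of the tissue of interest.
    pseudocount : int
        Photons added per channel of each evaluated spectrum (default 1).

    ``fit(threshold)`` computes the divergence image, likelihood weights,
    and the denoised density of the reference tissue.
    """

    def __init__(
        self,
        spectral_map: SpectralMap,
        reference_pixel: tuple[int, int],
        pseudocount: int = 1,
    ) -> None:
        self.spectral_map = spectral_map
        self.reference_pixel = tuple(reference_pixel)
        self.pseudocount = pseudocount

    def fit(self, threshold: float = 0.8) -> "KLTissueResults":
        div = divergence_map(self.spectral_map, self.reference_pixel,
                             self.pseudocount)
        weights = likelihood_weights(div, threshold)
        denoised = denoised_density(self.spectral_map, weights)
        return KLTissueResults(self, div, weights, denoised)


@dataclass
class KLTissueResults:
    """Fitted divergence/weight maps and the denoised reference density."""

    model: KLTissueModel
    divergence: DivergenceImage
    weights: WeightImage
    denoised: SpectralDensity

    @property
    def n_retained(self) -> int:
        return int(self.weights.retained.sum())

    def reference_density(self) -> SpectralDensity:
        spec = self.model.spectral_map.spectrum_at(*self.model.reference_pixel)
        return spectral_density(spec)

    def summary(self) -> str:
        d = self.divergence.values[self.divergence.valid]
        lines = [
            "KL tissue discrimination",
            "=" * 40,
            f"reference pixel      : {self.model.reference_pixel}",
            f"pseudocount          : {self.model.pseudocount}",
            f"threshold λ          : {self.weights.threshold}",
            f"valid pixels         : {int(self.divergence.valid.sum())}",
            f"retained pixels |P_λ|: {self.n_retained}",
            f"divergence min/median: {d.min():.4g} / {np.median(d):.4g}",
            f"weight of reference  : "
            f"{self.weights.weights[self.model.reference_pixel]:.4f}",
        ]
        return "\n".join(lines)

    def plot_denoised(self, ax=None):
        """Overlay the raw reference density and its denoised estimate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cal = self.model.spectral_map.calibration
        ax.plot(cal.energies, self.reference_density().probabilities,
                color="0.6", lw=0.7, label="measured")
        ax.plot(cal.energies, self.denoised.probabilities,
                color="crimson", lw=1.0, label="denoised")
        ax.set_xlabel("energy (keV)")
        ax.set_ylabel("spectral density")
        ax.set_yscale("log")
        ax.legend()
        return ax
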