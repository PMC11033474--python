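"""Seeded generator of synthetic labelled Ramanomes.

Emulates a single-cell Raman study of nine closely related lactic acid
bacteria (LAB) species/subspecies: three biological replicates per species,
60 cells per replicate, spectra on the 600–1800 cm⁻¹ fingerprint region.
Each species is a :class:`SpeciesProfile` — Gaussian bands at the nine
characteristic peak positions (805, 851, 1000, 1095, 1240, 1328, 1450,
1570, 1653 cm⁻¹) with a species-specific amplitude pattern.  A generated
cell spectrum is

    sum_k  A_k · jitter_k(cell) · shift(replicate) · exp(-(x - mu_k)²/2σ_k²)
        + polynomial baseline drift(cell) + N(0, noise_sd)

The default amplitude patterns are constructed, not measured: they encode
the qualitative class structure the classifier bank has to cope with — one
five-member cluster of nearly collinear profiles and one nearly collinear
pair (the "hard" groups, standing in for subspecies that overlap in a 2-D
embedding), plus two well-separated species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import SpectrumSet

__all__ = [
    "CHARACTERISTIC_PEAKS",
    "PEAK_ASSIGNMENTS",
    "SpeciesProfile",
    "SyntheticConfig",
    "default_profiles",
    "hard_groups",
    "generate_ramanome",
]

#: The nine characteristic Raman peak positions (cm⁻¹) of the LAB
#: fingerprint region that the species amplitude patterns live on.
CHARACTERISTIC_PEAKS = (805.0, 851.0, 1000.0, 1095.0, 1240.0,
                        1328.0, 1450.0, 1570.0, 1653.0)

#: Literature band assignments carried as annotation strings.
PEAK_ASSIGNMENTS = {
    805.0: "backbone geometry and phosphate ion interactions",
    851.0: "proline, hydroxyproline, tyrosine",
    1000.0: "phenylalanine",
    1095.0: "lipid / PO2- symmetric stretching",
    1240.0: "asymmetric phosphate stretching",
    1328.0: "CH3CH2 wagging, purine bases of nucleic acids",
    1450.0: "CH2 bending",
    1570.0: "guanine, adenine, tryptophan",
    1653.0: "amide I",
}


@dataclass(frozen=True)
class SpeciesProfile:
    """Noise-free spectral signature of one species/subspecies."""

    name: str
    peak_positions: tuple = CHARACTERISTIC_PEAKS
    peak_amplitudes: tuple = ()
    peak_widths: tuple = ()  # Gaussian sigmas, cm⁻¹

    def __post_init__(self) -> None:
        if len(self.peak_positions) != len(self.peak_amplitudes):
            raise ValueError("positions and amplitudes must have equal length")
        widths = self.peak_widths or tuple(8.0 for _ in self.peak_positions)
        object.__setattr__(self, "peak_widths", widths)
        if len(self.peak_widths) != len(self.peak_positions):
            raise ValueError("positions and widths must have equal length")
        if not any(a > 0 for a in self.peak_amplitudes):
            raise ValueError("profile needs at least one positive amplitude")
        if any(a < 0 for a in self.peak_amplitudes):
            raise ValueError("amplitudes must be nonnegative")

    def curve(self, axis: np.ndarray) -> np.ndarray:
        """Noise-free profile spectrum on the given axis."""
        axis = np.asarray(axis, dtype=float)
        y = np.zeros_like(axis)
        for mu, a, sig in zip(self.peak_positions, self.peak_amplitudes,
                              self.peak_widths):
            y += a * np.exp(-0.5 * ((axis - mu) / sig) ** 2)
        return y


# Amplitude patterns: a five-member near-collinear cluster (strains that
# overlap in the 2-D embedding), a near-collinear pair, and two separated
# species.  Perturbations of ±0.05–0.10 on a few bands keep within-group
# cosine similarity above 0.98 (hard groups still overlap in an embedding)
# while leaving per-class accuracy high, as in the emulated study.
_CLUSTER_BASE = np.array([0.55, 0.40, 1.00, 0.45, 0.35, 0.60, 0.80, 0.30, 0.90])
_PAIR_BASE = np.array([0.90, 0.25, 0.70, 0.80, 0.55, 0.35, 0.60, 0.70, 0.40])

_AMPLITUDES: dict[str, np.ndarray] = {
    "001_Lc_paracasei_subsp_paracasei":
        _CLUSTER_BASE + [0.080, -0.048, 0.000, 0.064, 0.000, -0.064, 0.000, 0.048, 0.000],
    "016_Lc_paracasei":
        _CLUSTER_BASE + [-0.064, 0.064, 0.000, 0.000, 0.064, 0.000, -0.080, 0.000, 0.048],
    "036_Lb_gallinarum":
        _CLUSTER_BASE + [0.000, 0.000, -0.096, 0.080, -0.048, 0.064, 0.000, -0.048, 0.000],
    "138_P_pentosaceus":
        _CLUSTER_BASE + [0.048, 0.000, 0.080, -0.064, 0.000, 0.000, 0.064, 0.000, -0.080],
    "143_Lc_rhamnosus":
        _CLUSTER_BASE + [-0.048, -0.064, 0.000, 0.000, -0.064, 0.080, 0.000, 0.064, 0.064],
    "063_Lp_plantarum":
        _PAIR_BASE + [0.064, 0.048, -0.080, 0.000, 0.064, 0.000, -0.048, 0.000, 0.048],
    "067_Lp_plantarum_subsp_plantarum":
        _PAIR_BASE + [-0.064, 0.000, 0.064, 0.064, -0.064, 0.048, 0.000, -0.064, 0.000],
    "114_Lp_argentoratensis":
        np.array([0.30, 0.85, 0.50, 0.25, 0.90, 0.75, 0.40, 0.55, 0.65]),
    "146_Lp_pentosus":
        np.array([0.70, 0.60, 0.35, 0.95, 0.25, 0.85, 0.55, 0.40, 0.30]),
}


def default_profiles() -> list[SpeciesProfile]:
    """Nine species profiles sharing the nine characteristic peak positions."""
    return [SpeciesProfile(name=name, peak_amplitudes=tuple(np.round(amp, 4)))
            for name, amp in _AMPLITUDES.items()]


def hard_groups() -> list[frozenset[str]]:
    """Species groups whose profiles are nearly collinear (hence confusable)."""
    return [
        frozenset({"001_Lc_paracasei_subsp_paracasei", "016_Lc_paracasei",
                   "036_Lb_gallinarum", "138_P_pentosaceus", "143_Lc_rhamnosus"}),
        frozenset({"063_Lp_plantarum", "067_Lp_plantarum_subsp_plantarum"}),
    ]


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Defaults emulate the sampling design of the emulated study: 9 species ×
    3 biological replicates × 60 cells on a 600–1800 cm⁻¹ axis at 1 cm⁻¹
    steps.  Noise parameters (all dimensionless or in normalized intensity
    units, peak amplitudes being O(1)):

    amplitude_jitter_cv : lognormal coefficient of variation of each band
        amplitude, drawn independently per cell and per band — cell-to-cell
        metabolic variability.
    replicate_shift : sd of a lognormal multiplicative effect shared by all
        cells of one (species, replicate) culture — batch effects between
        biological replicates.
    baseline_coeffs : mean polynomial coefficients (constant term first, on
        x scaled to [0, 1]) of the fluorescence drift; each cell draws its
        own coefficients around these.
    baseline_jitter : relative sd of the per-cell coefficient draw.
    noise_sd : additive white-noise sd per axis point (shot/detector noise).
    """

    profiles: list[SpeciesProfile] = field(default_factory=default_profiles)
    n_replicates: int = 3
    cells_per_replicate: int = 60
    axis_low: float = 600.0
    axis_high: float = 1800.0
    axis_step: float = 1.0
    amplitude_jitter_cv: float = 0.08
    replicate_shift: float = 0.03
    baseline_coeffs: tuple = (0.8, 0.4, -0.3, 0.2)
    baseline_jitter: float = 0.25
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates <= 0 or self.cells_per_replicate <= 0:
            raise ValueError("replicate and cell counts must be positive")
        if self.noise_sd < 0 or self.amplitude_jitter_cv < 0:
            raise ValueError("noise_sd and amplitude_jitter_cv must be >= 0")
        if self.axis_step <= 0 or self.axis_low >= self.axis_high:
            raise ValueError("invalid axis specification")
        if not self.profiles:
            raise ValueError("at least one species profile required")

    def axis(self) -> np.ndarray:
        return np.arange(self.axis_low, self.axis_high + 0.5 * self.axis_step,
                         self.axis_step)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative factor with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_ramanome(cfg: SyntheticConfig | None = None) -> SpectrumSet:
    """Generate a labelled synthetic SpectrumSet, fully determined by cfg.seed."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    x01 = (axis - axis[0]) / (axis[-1] - axis[0])
    basis = np.vstack([x01 ** k for k in range(len(cfg.baseline_coeffs))])

    rows, labels = [], []
    for prof in cfg.profiles:
        mus = np.asarray(prof.peak_positions)
        amps = np.asarray(prof.peak_amplitudes)
        sigs = np.asarray(prof.peak_widths)
        # (n_peaks, n_points) Gaussian band shapes, unit amplitude
        bands = np.exp(-0.5 * ((axis[None, :] - mus[:, None]) / sigs[:, None]) ** 2)
        for rep in range(1, cfg.n_replicates + 1):
            rep_factor = _lognormal_factor(rng, cfg.replicate_shift, None)
            for cell in range(1, cfg.cells_per_replicate + 1):
                jitter = _lognormal_factor(rng, cfg.amplitude_jitter_cv, mus.size)
                signal = (amps * jitter * rep_factor) @ bands
                coeffs = np.asarray(cfg.baseline_coeffs) * (
                    1.0 + (cfg.baseline_jitter
                           * rng.standard_normal(len(cfg.baseline_coeffs))
                           if cfg.baseline_jitter > 0 else 0.0))
                baseline = coeffs @ basis
                noise = (rng.normal(0.0, cfg.noise_sd, axis.size)
                         if cfg.noise_sd > 0 else 0.0)
                rows.append(signal + baseline + noise)
                labels.append({"cell_id": f"{prof.name}_r{rep}_c{cell:03d}",
                               "species": prof.name, "replicate": f"r{rep}"})
    meta = {"generator": "ramanid.synthetic",
            "config": {k: v for k, v in asdict(cfg).items() if k != "profiles"},
            "species": [p.name for p in cfg.profiles]}
    return SpectrumSet(axis, np.vstack(rows), pd.DataFrame(labels), meta)
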