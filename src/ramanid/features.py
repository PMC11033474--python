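"""Characteristic-peak analysis and 2-D embedding of spectrum sets.

The species-discriminating information of a bacterial Raman fingerprint is
concentrated in a handful of characteristic bands (phenylalanine at
1000 cm⁻¹, amide I at 1653 cm⁻¹, CH₂ bending at 1450 cm⁻¹, ...).  This
module detects those bands in mean spectra, tabulates per-cell band
intensities by species, tests each band for between-species differences
(Kruskal–Wallis by default) and encodes each p-value as a significance tier:

    tier 0: p > 0.05          tier 1: 0.01 < p ≤ 0.05
    tier 2: 0.001 < p ≤ 0.01  tier 3: 0.0001 < p ≤ 0.001
    tier 4: p ≤ 0.0001

For visual cluster structure, cells can be embedded in 2-D with t-SNE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import kruskal, f_oneway
from sklearn.manifold import TSNE
from statsmodels.stats.multitest import multipletests

from .io import SpectrumSet
from .preprocess import MeanSpectrum

__all__ = [
    "PeakTable",
    "tier_from_p",
    "detect_characteristic_peaks",
    "merge_peak_positions",
    "peak_intensity_table",
    "peak_significance",
    "embed_2d",
]

_TIER_EDGES = (0.05, 0.01, 0.001, 0.0001)


def tier_from_p(p: float) -> int:
    """Map a p-value to its significance tier (0–4, monotone in -log p).

    Boundaries are inclusive on the more significant side: p = 0.05 is
    tier 1, p = 0.0001 is tier 4.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    tier = 0
    for edge in _TIER_EDGES:
        if p <= edge:
            tier += 1
    return tier


@dataclass(eq=False)
class PeakTable:
    """Per-peak positions, assignments, species mean intensities and tiers.

    ``table`` columns: ``position``, ``assignment``, one column per species
    (mean peak intensity), and after :func:`peak_significance` also
    ``p_value`` and ``tier``.  ``cell_intensities`` holds the per-cell
    windowed peak intensities the species means were aggregated from
    (cells × peaks), which the significance test reuses.
    """

    table: pd.DataFrame
    cell_intensities: pd.DataFrame
    species_columns: list[str]

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = ["position", "assignment"]
        for extra in ("p_value", "tier"):
            if extra in self.table.columns:
                cols.append(extra)
        self.table[cols + self.species_columns].to_csv(path, index=False)
        return path


def detect_characteristic_peaks(m: MeanSpectrum,
                                min_prominence: float = 0.05) -> np.ndarray:
    """Positions of local maxima with prominence ≥ min_prominence·max(mean).

    Returns wavenumbers in ascending order; an empty array when the mean
    spectrum has no sufficiently prominent local maximum.
    """
    if not 0 <= min_prominence:
        raise ValueError("min_prominence must be nonnegative")
    scale = float(np.max(m.mean)) if m.mean.size else 0.0
    if scale <= 0:
        return np.array([])
    idx, _ = find_peaks(m.mean, prominence=min_prominence * scale)
    return m.axis[idx]


def merge_peak_positions(positions, tol: float = 4.0) -> np.ndarray:
    """Collapse positions closer than ``tol`` cm⁻¹ to their mean.

    Peak detection run per species can report the same band at grid-adjacent
    positions; merging yields one entry per physical band.
    """
    positions = np.sort(np.asarray(list(positions), dtype=float))
    if positions.size == 0:
        return positions
    groups = [[positions[0]]]
    for p in positions[1:]:
        if p - groups[-1][-1] <= tol:
            groups[-1].append(p)
        else:
            groups.append([p])
    return np.array([float(np.mean(g)) for g in groups])


def peak_intensity_table(s: SpectrumSet, positions, half_width: float = 5.0,
                         assignments: dict[float, str] | None = None) -> PeakTable:
    """Windowed peak intensities per cell, aggregated to species means.

    Per cell, the intensity of a peak at position w is the maximum intensity
    within w ± half_width (half_width 0 → the nearest grid point).
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    if positions.size and (positions[0] < s.axis[0] or positions[-1] > s.axis[-1]):
        raise ValueError("peak position outside the wavenumber axis span")
    cols = {}
    for pos in positions:
        lo = np.searchsorted(s.axis, pos - half_width, side="left")
        hi = np.searchsorted(s.axis, pos + half_width, side="right")
        if hi <= lo:  # empty window: fall back to the nearest grid point
            lo = int(np.argmin(np.abs(s.axis - pos)))
            hi = lo + 1
        cols[pos] = s.intensities[:, lo:hi].max(axis=1)
    cells = pd.DataFrame(cols, index=s.labels["cell_id"])
    cells.insert(0, "species", s.species)
    means = cells.groupby("species", sort=True).mean()
    species = list(means.index)
    def _assign(p: float) -> str:
        # nearest annotated band within 3 cm^-1 (detection is grid-quantised)
        if not assignments:
            return ""
        key = min(assignments, key=lambda k: abs(k - p))
        return assignments[key] if abs(key - p) <= 3.0 else ""

    table = pd.DataFrame({
        "position": positions,
        "assignment": [_assign(p) for p in positions],
    })
    for sp in species:
        table[sp] = means.loc[sp].to_numpy()
    return PeakTable(table=table, cell_intensities=cells, species_columns=species)


def peak_significance(t: PeakTable, test: str = "kruskal",
                      correct: bool = False) -> PeakTable:
    """Test each peak for between-species intensity differences.

    Kruskal–Wallis by default (no normality assumption); ``test="anova"``
    switches to one-way ANOVA.  ``correct=True`` applies Benjamini–Hochberg
    across peaks before tier assignment (off by default: tiers are
    conventionally reported on raw p-values).
    """
    cells = t.cell_intensities
    groups = cells.groupby("species")
    if groups.ngroups < 2:
        raise ValueError("significance test needs at least 2 species")
    small = [sp for sp, g in groups if len(g) < 2]
    if small:
        raise ValueError(f"species with fewer than 2 cells: {small}")
    stat = {"kruskal": kruskal, "anova": f_oneway}[test]
    pvals = []
    for pos in t.positions:
        samples = [g[pos].to_numpy() for _, g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            pvals.append(1.0)  # identical constant intensities: no evidence
            continue
        pvals.append(float(stat(*samples).pvalue))
    pvals = np.asarray(pvals)
    if correct and pvals.size:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    table = t.table.copy()
    table["p_value"] = pvals
    table["tier"] = [tier_from_p(p) for p in pvals]
    return PeakTable(table=table, cell_intensities=t.cell_intensities,
                     species_columns=list(t.species_columns))


def embed_2d(s: SpectrumSet, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """t-SNE embedding of the cells into 2-D (deterministic given seed)."""
    if s.n_cells <= 3 * perplexity:
        raise ValueError(
            f"{s.n_cells} cells is too few for perplexity {perplexity} "
            "(need n_cells > 3*perplexity)")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(s.intensities)
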