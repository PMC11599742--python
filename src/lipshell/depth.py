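"""Bilayer-depth profiles of lipid and noble-gas atoms.

Depth is the signed projection of an atom onto the membrane normal relative
to the bilayer median. Profiles are plain binned counts over the slab
between the hydrophobic-hydrophilic boundaries (atoms outside the boundaries
are excluded by design), and modes are the local maxima of the
moving-average-smoothed counts. Deliberately no kernel density estimation:
the analysed quantity is the histogram itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .components import LipidComponentEntry
from .frame import MembraneFrame
from .model import AtomSet, Partition, Structure, partition

DEFAULT_BIN_WIDTH = 2.0  # Å
DEFAULT_PROXIMITY_CUTOFF = 5.0  # Å, reuses the annular-shell cutoff
DEFAULT_SMOOTHING_WINDOW = 3  # bins


def depths_of(atoms: AtomSet | np.ndarray, frame: MembraneFrame) -> np.ndarray:
    """Signed depths (Å) of atoms relative to the bilayer median."""
    coords = atoms.coords if isinstance(atoms, AtomSet) else np.asarray(atoms, dtype=float)
    if coords.size == 0:
        return np.empty(0)
    return frame.depth(coords)


def proximal_lipid_atoms(structure: Structure, frame: MembraneFrame,
                         proximity_cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
                         dictionary: dict[str, LipidComponentEntry] | None = None,
                         part: Partition | None = None) -> AtomSet:
    """Lipid *carbon* atoms proximal to the protein and inside the boundaries.

    An atom qualifies when its nearest protein heavy atom is within
    ``proximity_cutoff`` and its depth lies within [z_lower, z_upper]; polar
    headgroup atoms and out-of-slab atoms are excluded.
    """
    if part is None:
        part = partition(structure, dictionary)
    carbons = part.lipid.heavy().filter(lambda a: a.element.upper() == "C")
    protein = part.protein.heavy()
    if len(carbons) == 0 or len(protein) == 0:
        return AtomSet()
    tree = cKDTree(protein.coords)
    dist, _ = tree.query(carbons.coords, k=1)
    depths = frame.depth(carbons.coords)
    keep = (dist <= proximity_cutoff) & frame.contains(depths)
    return AtomSet(a for a, ok in zip(carbons, keep) if ok)


@dataclass(frozen=True)
class DepthHistogram:
    """Binned atom depths between the membrane boundaries, with detected modes."""

    bin_edges: np.ndarray  # (n_bins + 1,), uniform
    counts: np.ndarray  # (n_bins,), non-negative ints
    n_total: int
    boundaries_applied: bool
    modes: tuple[float, ...]  # bin-center depths, ascending

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_dict(self) -> dict:
        return {"bin_edges": self.bin_edges.tolist(), "counts": self.counts.tolist(),
                "n_total": self.n_total, "boundaries_applied": self.boundaries_applied,
                "modes": list(self.modes)}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_center\tcount\n")
            for c, n in zip(self.bin_centers, self.counts):
                fh.write(f"{c:.3f}\t{int(n)}\n")


def make_histogram(depths: np.ndarray, frame: MembraneFrame,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   apply_boundaries: bool = True,
                   smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> DepthHistogram:
    """Uniform-bin depth histogram spanning [z_lower, z_upper].

    Depths outside the boundaries are dropped when ``apply_boundaries`` is
    set (the default). An empty depth list yields an all-zero histogram, not
    an error.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    depths = np.asarray(depths, dtype=float)
    n_bins = max(1, int(np.ceil((frame.z_upper - frame.z_lower) / bin_width - 1e-12)))
    edges = frame.z_lower + bin_width * np.arange(n_bins + 1)
    if apply_boundaries:
        depths = depths[frame.contains(depths)]
    # np.histogram is right-open except the final bin; clip anything the edge
    # extension admitted beyond z_upper into the final covered bin
    counts, _ = np.histogram(np.clip(depths, edges[0], edges[-1] - 1e-12), bins=edges)
    counts = counts.astype(int)
    centers = 0.5 * (edges[:-1] + edges[1:])
    modes = detect_modes(counts, centers, smoothing_window=smoothing_window)
    return DepthHistogram(edges, counts, int(counts.sum()), apply_boundaries, tuple(modes))


def moving_average(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with zero padding beyond the ends (window odd)."""
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window == 1:
        return np.asarray(counts, dtype=float)
    return np.convolve(np.asarray(counts, dtype=float), np.ones(window) / window, mode="same")


def detect_modes(counts: np.ndarray, bin_centers: np.ndarray,
                 smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> list[float]:
    """Local maxima of the smoothed counts, as bin-center depths (ascending).

    Plateaus count once, attributed to their lowest-depth bin; an all-zero
    histogram has no modes.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(bin_centers, dtype=float)
    if counts.size == 0 or not np.any(counts > 0):
        return []
    smoothed = moving_average(counts, smoothing_window)
    # collapse equal-value runs, then compare each run against its neighbours
    runs: list[tuple[int, float]] = []  # (start index, value)
    for i, v in enumerate(smoothed):
        if not runs or runs[-1][1] != v:
            runs.append((i, v))
    modes = []
    for r, (start, value) in enumerate(runs):
        if value <= 0:
            continue
        left = runs[r - 1][1] if r > 0 else -np.inf
        right = runs[r + 1][1] if r + 1 < len(runs) else -np.inf
        if value > left and value > right:
            modes.append(float(centers[start]))
    return sorted(modes)


def plot_histogram(histogram: DepthHistogram, path: str | Path,
                   title: str = "depth profile") -> None:
    """Optional bar plot of a depth profile (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(histogram.bin_centers, histogram.counts, width=histogram.bin_width * 0.9)
    for m in histogram.modes:
        ax.axvline(m, color="crimson", ls="--", lw=0.8)
    ax.axvline(histogram.bin_edges[0], color="k", lw=1.5)
    ax.axvline(histogram.bin_edges[-1], color="k", lw=1.5)
    ax.set_xlabel("depth along membrane normal (Å)")
    ax.set_ylabel("atom count")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
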