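"""Worm-like-chain end-to-end statistics for disordered linkers.

A disordered peptide linker of ``n`` residues is modelled as a worm-like
chain with persistence length ``l_p`` and contour length ``L_c = n b``,
where ``b`` is the virtual Calpha-Calpha bond length per residue.  In
the long-chain limit (``L_c >> l_p``) the end-to-end vector is Gaussian
with mean-square end-to-end distance ``<r^2> = 2 l_p L_c``, giving the
isotropic per-volume density

    p(r) = (3 / (4 pi l_p L_c))^{3/2} exp(-3 r^2 / (4 l_p L_c)).

Two density conventions appear in effective-concentration work and are
a classic source of factor-of-4*pi*r^2 errors:

* the *vector* density above (per Angstrom^3), which enters overlap
  integrals directly, and
* the *radial* density ``4 pi r^2 p(r)`` (per Angstrom), which is what a
  histogram of scalar distances estimates.

Every public function states which convention it returns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WLCParams",
    "DistanceDistribution",
    "contour_length",
    "wlc_vector_density",
    "wlc_radial_density",
    "radial_density_from_samples",
    "read_distance_trace",
    "write_distance_trace",
]

#: Persistence length of an unfolded polypeptide, Angstrom.
DEFAULT_PERSISTENCE_LENGTH = 3.0
#: Calpha-Calpha virtual bond length, Angstrom per residue.
DEFAULT_RESIDUE_CONTOUR = 3.8
#: Histogram bin count for empirical radial densities.
DEFAULT_N_BINS = 100


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters: persistence length and per-residue contour.

    Both lengths are in Angstrom.  The persistence length of natively
    unstructured proteins increases weakly with chain length, so a
    per-call override is supported everywhere these parameters are used.
    """

    persistence_length: float = DEFAULT_PERSISTENCE_LENGTH
    residue_contour: float = DEFAULT_RESIDUE_CONTOUR

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.residue_contour <= 0:
            raise ValueError("residue_contour must be > 0")


@dataclass(frozen=True)
class DistanceDistribution:
    """Bound-state inter-site distance model: samples, histogram or delta.

    Exactly one representation is populated:

    * ``samples`` — raw scalar distances in Angstrom (e.g. Calpha-Calpha
      distances measured frame by frame along a trajectory);
    * ``bin_edges``/``density`` — a normalised histogram estimate of the
      radial (per-Angstrom) density, H(r) such that sum(H * dr) = 1;
    * ``delta`` — a single fixed separation d0 in Angstrom.
    """

    samples: tuple[float, ...] | None = None
    bin_edges: tuple[float, ...] | None = None
    density: tuple[float, ...] | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        kinds = [
            self.samples is not None,
            self.bin_edges is not None or self.density is not None,
            self.delta is not None,
        ]
        if sum(kinds) != 1:
            raise ValueError("provide exactly one of samples, histogram, or delta")
        if self.samples is not None:
            if len(self.samples) == 0:
                raise ValueError("empty sample list")
            if min(self.samples) <= 0:
                raise ValueError("all distances must be positive")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta distance must be positive")
        if self.density is not None:
            edges = np.asarray(self.bin_edges, dtype=float)
            dens = np.asarray(self.density, dtype=float)
            if edges.size != dens.size + 1:
                raise ValueError("bin_edges must have one more entry than density")
            if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
                raise ValueError("bin edges must be positive and increasing")
            total = float(np.sum(dens * np.diff(edges)))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"histogram density integrates to {total}, not 1")

    @property
    def kind(self) -> str:
        if self.samples is not None:
            return "samples"
        if self.delta is not None:
            return "delta"
        return "histogram"


def contour_length(n_linker: int, params: WLCParams | None = None) -> float:
    """Contour length in Angstrom of an ``n_linker``-residue peptide."""
    if n_linker < 1:
        raise ValueError(f"n_linker must be >= 1, got {n_linker}")
    params = params or WLCParams()
    return n_linker * params.residue_contour


def wlc_vector_density(
    r: float | np.ndarray, n_linker: int, params: WLCParams | None = None
) -> float | np.ndarray:
    """Gaussian-limit WLC density of the end-to-end *vector*, per Angstrom^3.

    Valid when the contour length greatly exceeds the persistence
    length; the mean-square end-to-end distance is ``2 l_p L_c``.
    Accepts scalar or array separations ``r >= 0``.
    """
    params = params or WLCParams()
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("separation r must be >= 0")
    lc = contour_length(n_linker, params)
    lp = params.persistence_length
    prefactor = (3.0 / (4.0 * math.pi * lp * lc)) ** 1.5
    out = prefactor * np.exp(-3.0 * r_arr**2 / (4.0 * lp * lc))
    return float(out) if np.isscalar(r) else out


def wlc_radial_density(
    r: float | np.ndarray, n_linker: int, params: WLCParams | None = None
) -> float | np.ndarray:
    """Radial (per-Angstrom) WLC density, ``4 pi r^2`` times the vector density."""
    r_arr = np.asarray(r, dtype=float)
    out = 4.0 * math.pi * r_arr**2 * wlc_vector_density(r_arr, n_linker, params)
    return float(out) if np.isscalar(r) else out


def radial_density_from_samples(
    samples: Sequence[float], n_bins: int = DEFAULT_N_BINS
) -> DistanceDistribution:
    """Histogram estimate of the radial density from scalar distance samples.

    The returned density H(r) is per Angstrom and integrates to 1 over
    the histogram support.

    Parameters
    ----------
    samples:
        At least two positive distances in Angstrom.
    n_bins:
        Number of equal-width bins (default 100).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to build a histogram")
    if np.any(arr <= 0):
        raise ValueError("all distances must be positive")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        # Degenerate trace: one bin of unit width centred on the point.
        lo, hi = lo - 0.5, hi + 0.5
    dens, edges = np.histogram(arr, bins=n_bins, range=(lo, hi), density=True)
    return DistanceDistribution(bin_edges=tuple(edges), density=tuple(dens))


# ---------------------------------------------------------------------------
# Trace I/O: CSV with header "frame,distance_A"


def read_distance_trace(path: str | Path) -> np.ndarray:
    """Read a distance trace CSV (columns ``frame,distance_A``) into Angstrom."""
    df = pd.read_csv(path)
    if "distance_A" not in df.columns:
        raise ValueError(f"{path}: expected a 'distance_A' column")
    dist = df["distance_A"].to_numpy(dtype=float)
    if dist.size == 0:
        raise ValueError(f"{path}: empty trace")
    if np.any(dist <= 0):
        bad = int(np.argmax(dist <= 0))
        raise ValueError(f"{path}: non-positive distance at row {bad}")
    return dist


def write_distance_trace(path: str | Path, distances: Sequence[float]) -> None:
    """Write distances (Angstrom) as a ``frame,distance_A`` CSV."""
    df = pd.DataFrame(
        {"frame": np.arange(len(distances)), "distance_A": np.asarray(distances, dtype=float)}
    )
    df.to_csv(path, index=False)
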