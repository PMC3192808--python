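"""Effective local concentration of a tethered motif at a free SH3 site.

When one motif of a multivalent scaffold is bound to one domain of a
two-domain adaptor, the remaining free domain experiences the second
motif at an *effective* concentration set by the overlap of two spatial
densities: the worm-like-chain density ``p(r)`` of the linker
end-to-end vector and the bound-state density ``q(r)`` of the vector
between the two binding sites on the adaptor,

    C_eff = integral p(r) q(r) d^3 r .

Treating q as isotropic (only scalar inter-site distances are
measured), the overlap reduces to the expectation of the vector density
over the sampled radii:  C_eff = < p(|r_k|) >_k.  Three back-ends are
provided: *hybrid* (empirical distance samples, e.g. from a simulation
trace), *delta* (a single fixed separation), and the implicit
histogram form used when a :class:`~multibind.wlc.DistanceDistribution`
histogram is supplied.

Densities are molecules per Angstrom^3 internally; results are
converted to molar via 1 A^-3 = 1e27 / N_A mol/L (so one molecule per
cubic micrometre is ~1.66 nM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .motifs import MotifLayout
from .wlc import DistanceDistribution, WLCParams, wlc_vector_density

__all__ = [
    "CeffResult",
    "CeffTable",
    "ceff_hybrid",
    "ceff_delta",
    "ceff_from_distribution",
    "ceff_table",
    "density_to_molar",
]

logger = logging.getLogger(__name__)

#: Angstrom^-3 -> mol/L conversion factor (1e27 A^3 per litre / N_A).
_A3_TO_MOLAR = 1e27 / Avogadro

#: Below this many frames the Monte-Carlo error of the overlap is large.
MIN_RECOMMENDED_SAMPLES = 100


def density_to_molar(density_per_A3: float | np.ndarray) -> float | np.ndarray:
    """Convert a number density in molecules/Angstrom^3 to mol/L."""
    return density_per_A3 * _A3_TO_MOLAR


@dataclass(frozen=True)
class CeffResult:
    """An effective concentration with provenance.

    ``value_M`` is molar; ``back_end`` records which representation of
    the bound-state separation distribution produced it.
    """

    value_M: float
    back_end: str
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if not self.value_M > 0:
            raise ValueError(f"effective concentration must be positive, got {self.value_M}")

    @property
    def value_mM(self) -> float:
        return self.value_M * 1e3


def ceff_hybrid(
    samples: np.ndarray | list[float],
    linker_n: int,
    wlc: WLCParams | None = None,
) -> CeffResult:
    """Overlap C_eff from empirical scalar separation samples (molar).

    Averages the WLC vector density over the sampled bound-state radii:
    ``(1/N) sum_k p(r_k)``, then converts to mol/L.  Fewer than
    :data:`MIN_RECOMMENDED_SAMPLES` frames triggers a warning but the
    value is still computed.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample list")
    if np.any(arr <= 0):
        raise ValueError("all separation samples must be positive")
    if arr.size < MIN_RECOMMENDED_SAMPLES:
        logger.warning(
            "only %d separation samples; Monte-Carlo error of C_eff may be large", arr.size
        )
    if arr.min() == arr.max():
        # Degenerate trace: evaluate once so the result is bit-identical
        # to the delta back-end (averaging would round).
        mean_density = float(wlc_vector_density(float(arr[0]), linker_n, wlc))
    else:
        mean_density = float(np.mean(wlc_vector_density(arr, linker_n, wlc)))
    return CeffResult(
        value_M=density_to_molar(mean_density), back_end="hybrid", n_samples=int(arr.size)
    )


def ceff_delta(d0: float, linker_n: int, wlc: WLCParams | None = None) -> CeffResult:
    """Delta-function C_eff: the WLC vector density at a fixed separation (molar)."""
    if d0 <= 0:
        raise ValueError(f"d0 must be positive, got {d0}")
    dens = wlc_vector_density(d0, linker_n, wlc)
    return CeffResult(value_M=density_to_molar(float(dens)), back_end="delta")


def ceff_from_distribution(
    separation: DistanceDistribution,
    linker_n: int,
    wlc: WLCParams | None = None,
) -> CeffResult:
    """C_eff for any separation representation (samples, histogram or delta).

    The histogram form evaluates the overlap at bin midpoints weighted
    by the bin probability mass.
    """
    if separation.kind == "samples":
        return ceff_hybrid(np.asarray(separation.samples), linker_n, wlc)
    if separation.kind == "delta":
        return ceff_delta(float(separation.delta), linker_n, wlc)
    edges = np.asarray(separation.bin_edges, dtype=float)
    dens = np.asarray(separation.density, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    weights = dens * np.diff(edges)
    mean_density = float(np.sum(weights * wlc_vector_density(mids, linker_n, wlc)))
    return CeffResult(value_M=density_to_molar(mean_density), back_end="histogram")


@dataclass
class CeffTable:
    """Effective concentrations over ordered (N-bound motif, C-bound motif) pairs.

    Values are millimolar.  The diagonal is undefined: one motif cannot
    occupy both domains at once.
    """

    values_mM: dict[tuple[str, str], float]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        try:
            return self.values_mM[pair]
        except KeyError:
            raise KeyError(f"no effective concentration for motif pair {pair}") from None

    def __len__(self) -> int:
        return len(self.values_mM)

    @property
    def motifs(self) -> list[str]:
        seen: dict[str, None] = {}
        for n, c in self.values_mM:
            seen.setdefault(n, None)
            seen.setdefault(c, None)
        return list(seen)


def ceff_table(
    layout: MotifLayout,
    separations: dict[tuple[str, str], DistanceDistribution] | DistanceDistribution,
    wlc: WLCParams | None = None,
    include_motif_flanks: bool = False,
) -> CeffTable:
    """Compute C_eff (mM) for every ordered pair of motifs in a layout.

    The linker for pair ``(i, j)`` is the residue count strictly between
    the two motif spans; with ``include_motif_flanks`` the intervening
    motif residues of both partners are counted into the contour as
    well.  ``separations`` maps ordered (N-motif, C-motif) id pairs to
    their bound-state distance distributions, or a single shared
    distribution may be given.

    Raises
    ------
    KeyError
        If a required ordered pair is missing from ``separations``.
    """
    sites = layout.sites
    if len(sites) < 2:
        raise ValueError("need at least two motif sites")
    shared = isinstance(separations, DistanceDistribution)
    out: dict[tuple[str, str], float] = {}
    for a in sites:
        for b in sites:
            if a.motif_id == b.motif_id:
                continue
            first, second = (a, b) if a.start <= b.start else (b, a)
            n_between = second.start - first.end - 1
            if include_motif_flanks:
                n_between += (first.end - first.start) + (second.end - second.start)
            n_between = max(n_between, 1)
            sep = separations if shared else separations[(a.motif_id, b.motif_id)]
            res = ceff_from_distribution(sep, n_between, wlc)
            out[(a.motif_id, b.motif_id)] = res.value_mM
    return CeffTable(values_mM=out)
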