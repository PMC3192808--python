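"""Mass-action speciation of adaptor (G) and scaffold (S) complexes.

Closed solution system with two coupled equilibria,

    G + S  <->  GS      [GS]  = K_GS  [G][S]
    G + GS <->  GSG     [GSG] = K_GSG [G][GS]

under conservation of mass

    G_tot = [G] + [GS] + 2 [GSG]
    S_tot = [S] + [GS] + [GSG].

Only 1:1 and 2:1 adaptor-scaffold complexes are considered; scaffold
cross-linking by a single adaptor is neglected (valid at low scaffold
concentration).  The solver reduces the system to a single bracketed
root-find on free [G], which is monotone and therefore has a unique
non-negative solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["SpeciationInput", "SpeciationResult", "solve_equilibrium", "stoichiometry_sweep"]


@dataclass(frozen=True)
class SpeciationInput:
    """Total concentrations (molar) and association constants (1/molar)."""

    total_G: float
    total_S: float
    K_GS: float
    K_GSG: float

    def __post_init__(self) -> None:
        vals = (self.total_G, self.total_S, self.K_GS, self.K_GSG)
        if not all(np.isfinite(vals)):
            raise ValueError("speciation inputs must be finite")
        if self.total_G < 0 or self.total_S < 0:
            raise ValueError("total concentrations must be >= 0")
        if self.K_GS < 0 or self.K_GSG < 0:
            raise ValueError("association constants must be >= 0")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium concentrations (molar) and derived composition measures."""

    free_G: float
    free_S: float
    conc_GS: float
    conc_GSG: float

    @property
    def f_GSG(self) -> float:
        """Fraction of scaffold complexes that carry two adaptors."""
        total = self.conc_GS + self.conc_GSG
        return 0.0 if total == 0 else self.conc_GSG / total

    @property
    def effective_stoichiometry(self) -> float:
        """Bound adaptor per bound scaffold, in (0, 2]."""
        bound_s = self.conc_GS + self.conc_GSG
        return 0.0 if bound_s == 0 else (self.conc_GS + 2 * self.conc_GSG) / bound_s

    @property
    def bound_fraction_G(self) -> float:
        total = self.free_G + self.conc_GS + 2 * self.conc_GSG
        return 0.0 if total == 0 else (self.conc_GS + 2 * self.conc_GSG) / total

    @property
    def bound_fraction_S(self) -> float:
        total = self.free_S + self.conc_GS + self.conc_GSG
        return 0.0 if total == 0 else (self.conc_GS + self.conc_GSG) / total


def _species_at(g: float, inp: SpeciationInput) -> tuple[float, float, float]:
    """Free S and complex concentrations for a trial free G (exact in S)."""
    denom = 1.0 + inp.K_GS * g + inp.K_GS * inp.K_GSG * g * g
    s = inp.total_S / denom
    gs = inp.K_GS * g * s
    gsg = inp.K_GSG * g * gs
    return s, gs, gsg


def solve_equilibrium(inp: SpeciationInput) -> SpeciationResult:
    """Unique non-negative equilibrium of the three-species system.

    Scaffold conservation is satisfied exactly by construction; adaptor
    conservation is solved by bracketed root-finding on free [G] over
    [0, G_tot] followed by Newton polishing, to better than 1e-12
    relative.
    """
    if inp.total_G == 0.0 or inp.total_S == 0.0 or inp.K_GS == 0.0:
        # No complexes can form (K_GS = 0 implies K_GSG path is closed too).
        return SpeciationResult(
            free_G=inp.total_G, free_S=inp.total_S, conc_GS=0.0, conc_GSG=0.0
        )

    def residual(g: float) -> float:
        s, gs, gsg = _species_at(g, inp)
        return g + gs + 2.0 * gsg - inp.total_G

    lo, hi = 0.0, inp.total_G
    # residual(0) = -G_tot < 0, residual(G_tot) >= 0: a bracket always exists.
    g = brentq(residual, lo, hi, xtol=1e-300, rtol=4 * np.finfo(float).eps)
    # One Newton step against the analytic derivative tightens the root
    # to machine precision.
    s, gs, gsg = _species_at(g, inp)
    denom = 1.0 + inp.K_GS * g + inp.K_GS * inp.K_GSG * g * g
    ddenom = inp.K_GS + 2.0 * inp.K_GS * inp.K_GSG * g
    ds = -inp.total_S * ddenom / denom**2
    dgs = inp.K_GS * (s + g * ds)
    dgsg = inp.K_GSG * (gs + g * dgs)
    slope = 1.0 + dgs + 2.0 * dgsg
    if slope > 0:
        g = min(max(g - residual(g) / slope, 0.0), inp.total_G)
    s, gs, gsg = _species_at(g, inp)
    return SpeciationResult(free_G=g, free_S=s, conc_GS=gs, conc_GSG=gsg)


def stoichiometry_sweep(
    base: SpeciationInput,
    vary: Literal["G", "S"],
    ratios: Iterable[float],
) -> pd.DataFrame:
    """Titration sweep: scale one total concentration across ``ratios``.

    For each ratio the varied species' total is ``ratio`` times its
    base value while the other is held fixed.  Returns one row per
    ratio with the solved concentrations, the 2:1 complex fraction
    ``f_GSG``, the effective (bound G per bound S) stoichiometry, and
    the bound fractions of both species.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty ratio list")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rows = []
    for r in ratios:
        inp = SpeciationInput(
            total_G=base.total_G * r if vary == "G" else base.total_G,
            total_S=base.total_S * r if vary == "S" else base.total_S,
            K_GS=base.K_GS,
            K_GSG=base.K_GSG,
        )
        res = solve_equilibrium(inp)
        rows.append(
            {
                "ratio": r,
                "total_G": inp.total_G,
                "total_S": inp.total_S,
                "free_G": res.free_G,
                "free_S": res.free_S,
                "conc_GS": res.conc_GS,
                "conc_GSG": res.conc_GSG,
                "f_GSG": res.f_GSG,
                "effective_stoichiometry": res.effective_stoichiometry,
                "bound_fraction_G": res.bound_fraction_G,
                "bound_fraction_S": res.bound_fraction_S,
            }
        )
    return pd.DataFrame(rows)
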