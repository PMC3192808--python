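"""Equilibrium-constant algebra for a bivalent adaptor on a multivalent scaffold.

An adaptor (Grb2) carries two peptide-binding domains, N-SH3 and C-SH3;
the scaffold (Sos1) carries several polyproline motifs on a disordered
tail.  Given single-site dissociation constants ``Kd_N(i)`` and
``Kd_C(j)`` for each motif and effective local concentrations
``C_eff(i, j)`` for the intramolecular second binding step, this module
derives:

* the effective bivalent dissociation constant for simultaneous
  engagement of motifs i (N-domain) and j (C-domain),

      Kd_eff(i, j) = Kd_N(i) * Kd_C(j) / C_eff(i, j) ;

* ``K_GS``, the overall association constant for a 1:1
  adaptor-scaffold complex, summed over all singly bound modes
  (2 domains x m motifs) and doubly bound modes (m(m-1) ordered motif
  pairs), together with the singly/doubly composition of that complex;

* ``K_GSG``, the conditional association constant for a second adaptor
  binding an existing 1:1 complex, from the enumeration of mode pairs
  occupying disjoint motif sets, with an indistinguishability
  convention for the two identical adaptors (see :func:`k_gsg`);

* ΔG <-> Kd conversion (``Kd = exp(ΔG / RT)``, ΔG in kcal/mol).

Associations are handled internally in inverse micromolar; effective
concentrations enter in millimolar and are converted on use.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "AffinityModel",
    "BindingMode",
    "EquilibriumSummary",
    "kd_from_dg",
    "dg_from_kd",
    "kd_eff_bivalent",
    "enumerate_1to1",
    "k_gs",
    "k_gsg",
    "load_packaged_model",
    "load_affinity_csv",
    "load_ceff_csv",
]

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3
#: Temperature of the reference binding measurements, K.
DEFAULT_TEMPERATURE_K = 298.0

Convention = Literal["paper", "strict"]


def kd_from_dg(
    dg_kcal: float, temperature_K: float = DEFAULT_TEMPERATURE_K, gas_constant: float = GAS_CONSTANT_KCAL
) -> float:
    """Dissociation constant in molar from a binding free energy in kcal/mol.

    ``Kd = exp(ΔG / RT)`` with the convention that favourable binding
    has ΔG < 0 (so ΔG = 0 gives the 1 M standard state).
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(dg_kcal / (gas_constant * temperature_K))


def dg_from_kd(
    kd_molar: float, temperature_K: float = DEFAULT_TEMPERATURE_K, gas_constant: float = GAS_CONSTANT_KCAL
) -> float:
    """Binding free energy in kcal/mol from a molar dissociation constant."""
    if kd_molar <= 0:
        raise ValueError("Kd must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return gas_constant * temperature_K * math.log(kd_molar)


def kd_eff_bivalent(kd_N_uM: float, kd_C_uM: float, ceff_mM: float) -> float:
    """Effective bivalent Kd in µM from two single-site Kds and C_eff.

    ``Kd_eff = Kd_N * Kd_C / C_eff`` with C_eff converted mM -> µM, so
    µM * µM / µM = µM.  Symmetric in binding order by construction
    (detailed balance).  C_eff -> 0 gives no avidity (Kd_eff -> inf).
    """
    if kd_N_uM <= 0 or kd_C_uM <= 0 or ceff_mM <= 0:
        raise ValueError("single-site Kds and C_eff must be positive")
    return kd_N_uM * kd_C_uM / (ceff_mM * 1e3)


@dataclass(frozen=True)
class BindingMode:
    """One way a single adaptor can attach to the scaffold.

    ``kind`` is ``"singly"`` (one domain, one motif) or ``"doubly"``
    (N-domain on ``n_motif`` and C-domain on a distinct ``c_motif``).
    ``association`` is 1/Kd in inverse µM.
    """

    kind: Literal["singly", "doubly"]
    association: float
    domain: Literal["N", "C"] | None = None
    motif: str | None = None
    n_motif: str | None = None
    c_motif: str | None = None

    def __post_init__(self) -> None:
        if self.association <= 0:
            raise ValueError("association must be positive")
        if self.kind == "singly":
            if self.domain not in ("N", "C") or self.motif is None:
                raise ValueError("singly mode needs a domain and a motif")
        else:
            if self.n_motif is None or self.c_motif is None:
                raise ValueError("doubly mode needs both motifs")
            if self.n_motif == self.c_motif:
                raise ValueError("doubly mode must use two distinct motifs")

    @property
    def motifs_used(self) -> frozenset[str]:
        if self.kind == "singly":
            return frozenset({self.motif})
        return frozenset({self.n_motif, self.c_motif})

    @property
    def label(self) -> str:
        if self.kind == "singly":
            return f"{self.domain}:{self.motif}"
        return f"N:{self.n_motif}+C:{self.c_motif}"


@dataclass
class AffinityModel:
    """Single-site Kd tables, C_eff table and substitution rules.

    ``kd_N_uM``/``kd_C_uM`` map motif ids to single-site dissociation
    constants in µM for the two adaptor domains.  Motifs without a
    measured affinity can borrow a proxy's values through
    ``substitutions`` (by default the predicted RP motif borrows P3,
    the weakest measured binder).  ``ceff_mM`` maps ordered
    (N-motif, C-motif) pairs to effective concentrations in mM.
    """

    kd_N_uM: dict[str, float]
    kd_C_uM: dict[str, float]
    ceff_mM: dict[tuple[str, str], float]
    substitutions: dict[str, str] = field(default_factory=lambda: {"RP": "P3"})
    temperature_K: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    @property
    def motifs(self) -> list[str]:
        """All motif ids known to the model (affinity tables and C_eff pairs)."""
        ids = set(self.kd_N_uM) | set(self.kd_C_uM)
        for n, c in self.ceff_mM:
            ids.add(n)
            ids.add(c)
        return sorted(ids)

    def _resolve(self, table: dict[str, float], motif: str, domain: str) -> float:
        if motif in table and table[motif] > 0:
            return table[motif]
        proxy = self.substitutions.get(motif)
        if proxy is not None and proxy in table:
            logger.info("substituting %s affinity of %s with %s", domain, motif, proxy)
            return table[proxy]
        raise KeyError(f"no {domain}-domain affinity for motif {motif!r} (after substitutions)")

    def kd_N(self, motif: str) -> float:
        """Single-site Kd (µM) of a motif at the N-domain, after substitutions."""
        return self._resolve(self.kd_N_uM, motif, "N")

    def kd_C(self, motif: str) -> float:
        """Single-site Kd (µM) of a motif at the C-domain, after substitutions."""
        return self._resolve(self.kd_C_uM, motif, "C")

    def ceff(self, n_motif: str, c_motif: str) -> float:
        """Effective concentration (mM) for the ordered (N, C) motif pair."""
        try:
            return self.ceff_mM[(n_motif, c_motif)]
        except KeyError:
            raise KeyError(f"no C_eff for ordered pair ({n_motif}, {c_motif})") from None

    def kd_eff(self, n_motif: str, c_motif: str) -> float:
        """Effective bivalent Kd (µM) for the ordered (N, C) motif pair."""
        return kd_eff_bivalent(self.kd_N(n_motif), self.kd_C(c_motif), self.ceff(n_motif, c_motif))


@dataclass
class EquilibriumSummary:
    """Derived effective constants and bound-state composition.

    ``K_GS`` (µM^-1) is the overall 1:1 association constant and
    ``Kd_GS`` its inverse; ``fraction_singly``/``fraction_doubly``
    partition the 1:1 complex.  When a second-adaptor enumeration was
    run, ``K_GSG`` (µM^-1) is the conditional association constant for
    adding it and ``gsg_fractions`` partitions the 2:1 complex into
    (both-doubly, mixed, both-singly) shares.
    """

    K_GS: float
    fraction_singly: float
    fraction_doubly: float
    n_modes: int
    K_GSG: float | None = None
    gsg_fractions: tuple[float, float, float] | None = None
    n_pairs: int | None = None
    convention: Convention | None = None

    @property
    def Kd_GS_uM(self) -> float:
        return 1.0 / self.K_GS

    @property
    def Kd_GSG_uM(self) -> float | None:
        return None if self.K_GSG is None else 1.0 / self.K_GSG


def enumerate_1to1(model: AffinityModel, motifs: Sequence[str]) -> list[BindingMode]:
    """All distinct 1:1 binding modes of one adaptor on the scaffold.

    With ``m`` motifs there are ``2 m`` singly bound modes (either
    domain on any motif) and ``m (m - 1)`` doubly bound modes (ordered
    pairs of distinct motifs on the N- and C-domains): 30 modes for the
    five-motif scaffold.
    """
    if len(motifs) == 0:
        raise ValueError("need at least one motif")
    if len(set(motifs)) != len(motifs):
        raise ValueError("duplicate motif labels")
    modes: list[BindingMode] = []
    for m in motifs:
        modes.append(
            BindingMode(kind="singly", domain="N", motif=m, association=1.0 / model.kd_N(m))
        )
    for m in motifs:
        modes.append(
            BindingMode(kind="singly", domain="C", motif=m, association=1.0 / model.kd_C(m))
        )
    for i, j in itertools.permutations(motifs, 2):
        modes.append(
            BindingMode(
                kind="doubly", n_motif=i, c_motif=j, association=1.0 / model.kd_eff(i, j)
            )
        )
    return modes


def k_gs(model: AffinityModel, motifs: Sequence[str]) -> EquilibriumSummary:
    """Overall 1:1 association constant and its singly/doubly split.

    ``K_GS`` is the sum of the associations of every 1:1 binding mode;
    the singly bound fraction is the share contributed by the
    single-domain modes.
    """
    modes = enumerate_1to1(model, motifs)
    singly = sum(m.association for m in modes if m.kind == "singly")
    doubly = sum(m.association for m in modes if m.kind == "doubly")
    total = singly + doubly
    return EquilibriumSummary(
        K_GS=total,
        fraction_singly=singly / total,
        fraction_doubly=doubly / total,
        n_modes=len(modes),
    )


def _pair_weight(a: BindingMode, b: BindingMode, convention: Convention) -> float:
    """Statistical weight of an unordered pair of modes on one scaffold.

    Under ``strict`` every unordered pair of distinct modes carries the
    plain product of associations (the global 1/2 for identical
    adaptors cancelling the ordered double count).  Under ``paper`` the
    mixed doubly-singly cross terms enter the double sum once before
    the global factor of 1/2, so they carry half the product.
    """
    w = a.association * b.association
    if convention == "paper" and a.kind != b.kind:
        w *= 0.5
    return w


def k_gsg(
    model: AffinityModel,
    motifs: Sequence[str],
    convention: Convention = "paper",
) -> EquilibriumSummary:
    """Second-adaptor association constant and 2:1 complex composition.

    Enumerates all unordered pairs of 1:1 binding modes whose motif
    sets are disjoint (two adaptors cannot share a motif), weights each
    pair by the product of associations with the chosen
    indistinguishability convention, and reports

    * ``K_GSG = total weight / K_GS`` — the conditional association
      constant (µM^-1) for one more adaptor binding an existing 1:1
      complex, and
    * ``gsg_fractions`` — the weight shares of (both-doubly, mixed,
      both-singly) configurations.

    Conventions
    -----------
    ``strict``
        Each unordered pair of distinct modes carries ``K1 * K2``.
    ``paper`` (default)
        Mixed doubly-singly pairs carry ``K1 * K2 / 2``; this is the
        counting that reproduces the published 68/27/5 composition for
        the five-motif scaffold, and differs measurably from
        ``strict`` (~52/44/4 on the same inputs).
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motifs for a 2:1 complex")
    one_to_one = k_gs(model, motifs)
    modes = enumerate_1to1(model, motifs)
    w_dd = w_ds = w_ss = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(modes, 2):
        if a.motifs_used & b.motifs_used:
            continue
        n_pairs += 1
        w = _pair_weight(a, b, convention)
        kinds = {a.kind, b.kind}
        if kinds == {"doubly"}:
            w_dd += w
        elif kinds == {"singly"}:
            w_ss += w
        else:
            w_ds += w
    total = w_dd + w_ds + w_ss
    if total <= 0:
        raise ValueError("no feasible 2:1 configurations for the given motifs")
    return EquilibriumSummary(
        K_GS=one_to_one.K_GS,
        fraction_singly=one_to_one.fraction_singly,
        fraction_doubly=one_to_one.fraction_doubly,
        n_modes=one_to_one.n_modes,
        K_GSG=total / one_to_one.K_GS,
        gsg_fractions=(w_dd / total, w_ds / total, w_ss / total),
        n_pairs=n_pairs,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# Affinity table I/O


def load_affinity_csv(path: str | Path) -> dict[str, float]:
    """Read ``motif,kd_uM`` (or a table with a kd_expt_uM column) into a dict."""
    df = pd.read_csv(path)
    col = "kd_uM" if "kd_uM" in df.columns else "kd_expt_uM"
    if col not in df.columns:
        raise ValueError(f"{path}: expected a 'kd_uM' or 'kd_expt_uM' column")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        if pd.notna(row[col]):
            out[str(row["motif"])] = float(row[col])
    return out


def load_ceff_csv(path: str | Path) -> dict[tuple[str, str], float]:
    """Read ``n_motif,c_motif,ceff_mM`` into an ordered-pair dict."""
    df = pd.read_csv(path)
    for col in ("n_motif", "c_motif", "ceff_mM"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        (str(r["n_motif"]), str(r["c_motif"])): float(r["ceff_mM"]) for _, r in df.iterrows()
    }


def load_packaged_model(use_measured_kd_eff: bool = False) -> AffinityModel:
    """The packaged Grb2-Sos1 reference model (experimental single-site
    Kds for P1-P4, C_eff per ordered motif pair, RP borrowing P3).

    With ``use_measured_kd_eff`` the effective concentrations are
    replaced by values back-computed from the published effective Kds,
    which carry the rounding of the printed two-significant-figure
    C_eff but match the published downstream composition exactly.
    """
    pkg = resources.files("multibind.data")
    with resources.as_file(pkg / "single_site_nsh3.csv") as p:
        kd_n = load_affinity_csv(p)
    with resources.as_file(pkg / "single_site_csh3.csv") as p:
        kd_c = load_affinity_csv(p)
    with resources.as_file(pkg / "ceff_pairs.csv") as p:
        df = pd.read_csv(p)
    subs = {"RP": "P3"}
    if use_measured_kd_eff:
        # Invert Kd_eff = KdN*KdC/C_eff to recover the C_eff each
        # printed Kd_eff implies, so model.kd_eff reproduces it exactly.
        model_tmp = AffinityModel(kd_N_uM=kd_n, kd_C_uM=kd_c, ceff_mM={}, substitutions=subs)
        ceff = {
            (str(r["n_motif"]), str(r["c_motif"])): model_tmp.kd_N(str(r["n_motif"]))
            * model_tmp.kd_C(str(r["c_motif"]))
            / (float(r["kd_eff_uM"]) * 1e3)
            for _, r in df.iterrows()
        }
    else:
        ceff = {
            (str(r["n_motif"]), str(r["c_motif"])): float(r["ceff_mM"]) for _, r in df.iterrows()
        }
    return AffinityModel(kd_N_uM=kd_n, kd_C_uM=kd_c, ceff_mM=ceff, substitutions=subs)
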