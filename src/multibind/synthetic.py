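"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators:

* :func:`gen_distance_trace` — frame-by-frame scalar separations that
  emulate the inter-site distance measurement from a simulation of the
  bound adaptor: each frame is ``|mu + eps|`` with isotropic Gaussian
  noise ``eps``, so the scalar distances follow a (scaled) non-central
  chi distribution with 3 degrees of freedom and every moment has a
  closed form to test against.

* :func:`gen_sequence` — a disordered sequence carrying requested
  class I/II motifs at requested linker spacings, built so that motif
  scanning plus layout construction recovers the ground truth exactly.
  The background (linker) alphabet excludes P, R and K by default, which
  makes accidental motif creation impossible.

* :func:`gen_msa` — a gapless multiple sequence alignment whose
  per-column majority-identity conservation targets a given profile.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import MotifClass, MotifLayout, build_layout, scan_motifs
from .wlc import write_distance_trace

__all__ = [
    "TraceSpec",
    "SequenceSpec",
    "gen_distance_trace",
    "gen_sequence",
    "gen_msa",
    "DEFAULT_TEMPLATES",
]

#: Default motif templates per class; both are minimal consensus windows
#: taken from the reference scaffold's motif repertoire.
DEFAULT_TEMPLATES: dict[MotifClass, str] = {
    MotifClass.II: "PPVPPR",   # PxxPx[RK]
    MotifClass.I: "RHLPSPP",   # [RK]xxPxxP
}

#: Linker alphabet: the standard residues minus P, R, K (and C, routinely
#: excluded from designed disordered sequences).
DEFAULT_BACKGROUND = "ADEFGHILMNQSTVWY"


@dataclass(frozen=True)
class TraceSpec:
    """Specification of a synthetic bound-state separation trace.

    ``mean_offset`` is the mean 3-D displacement between the two
    binding-site anchors in Angstrom (a scalar is placed on the x-axis);
    ``per_axis_sd`` the isotropic per-axis spread; ``n_frames`` the
    number of frames.
    """

    mean_offset: tuple[float, float, float] | float
    per_axis_sd: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_axis_sd < 0:
            raise ValueError("per_axis_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def mu(self) -> np.ndarray:
        if np.isscalar(self.mean_offset):
            return np.array([float(self.mean_offset), 0.0, 0.0])
        return np.asarray(self.mean_offset, dtype=float)


def gen_distance_trace(spec: TraceSpec, out_path: str | Path | None = None) -> np.ndarray:
    """Draw scalar separations ``|mu + eps|``, optionally writing a CSV trace.

    ``eps`` is isotropic Gaussian with the spec's per-axis standard
    deviation; with ``per_axis_sd = 0`` every frame equals ``|mu|``.
    """
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.per_axis_sd, size=(spec.n_frames, 3))
    distances = np.linalg.norm(spec.mu[None, :] + eps, axis=1)
    if out_path is not None:
        write_distance_trace(out_path, distances)
    return distances


@dataclass(frozen=True)
class SequenceSpec:
    """Specification of a motif-bearing disordered sequence.

    ``motif_classes`` lists the requested classes N-to-C; ``linkers``
    the residue counts strictly between consecutive motifs (length one
    less than the motif count).  ``n_before``/``n_after`` pad the ends.
    """

    motif_classes: tuple[MotifClass | str, ...]
    linkers: tuple[int, ...]
    n_before: int = 10
    n_after: int = 10
    templates: dict[MotifClass, str] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    background: str = DEFAULT_BACKGROUND
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif_classes) > 0 and len(self.linkers) != len(self.motif_classes) - 1:
            raise ValueError("need exactly one linker length per adjacent motif pair")
        if any(n < 0 for n in self.linkers):
            raise ValueError("linker lengths must be >= 0")
        if self.n_before < 0 or self.n_after < 0:
            raise ValueError("padding lengths must be >= 0")
        forbidden = set("PRK") & set(self.background)
        if forbidden:
            raise ValueError(
                f"background alphabet contains motif-forming residues {sorted(forbidden)}; "
                "accidental motif matches would break ground-truth recovery"
            )


def gen_sequence(spec: SequenceSpec) -> tuple[str, MotifLayout]:
    """Build a sequence realizing the spec and its ground-truth layout.

    The returned layout is what motif scanning of the sequence must
    recover: classes and linker lengths match the spec exactly.

    Raises
    ------
    ValueError
        If a zero-length linker would fuse two motifs into an
        overlapping or adjacent arrangement that the templates cannot
        realise without creating a spurious match (not possible with
        the default templates, which never combine across a junction).
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.array(list(spec.background))

    def linker(n: int) -> str:
        return "".join(rng.choice(bg, size=n)) if n > 0 else ""

    parts = [linker(spec.n_before)]
    classes = [MotifClass(c) for c in spec.motif_classes]
    for k, mclass in enumerate(classes):
        parts.append(spec.templates[mclass])
        if k < len(spec.linkers):
            parts.append(linker(spec.linkers[k]))
    parts.append(linker(spec.n_after))
    sequence = "".join(parts)

    sites = scan_motifs(sequence, classes=set(classes) or {MotifClass.I, MotifClass.II})
    layout = build_layout("synthetic", sites)
    if layout.classes != classes or layout.linker_lengths != list(spec.linkers):
        raise ValueError(
            "spec is not realizable: scanning the generated sequence does not "
            f"recover the requested layout (got classes {layout.classes}, "
            f"linkers {layout.linker_lengths})"
        )
    return sequence, layout


def gen_msa(
    profile: Sequence[float],
    n_sequences: int,
    seed: int = 0,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> list[str]:
    """Alignment whose per-column conservation targets ``profile``.

    Column ``j`` carries a designated consensus residue with
    probability ``profile[j]`` and a uniformly random *other* residue
    otherwise, so the expected majority-identity fraction equals the
    profile value (for profile values above chance).

    Profile values must lie in [1/len(alphabet), 1].
    """
    p = np.asarray(profile, dtype=float)
    lo = 1.0 / len(alphabet)
    if np.any(p < lo - 1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError(f"profile values must lie in [{lo:.3g}, 1]")
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    consensus = rng.choice(letters, size=p.size)
    rows = []
    for _ in range(n_sequences):
        take = rng.random(p.size) < p
        others = rng.integers(0, len(alphabet) - 1, size=p.size)
        chars = []
        for j in range(p.size):
            if take[j]:
                chars.append(consensus[j])
            else:
                # Uniform over the 19 non-consensus letters.
                pool = [c for c in alphabet if c != consensus[j]]
                chars.append(pool[others[j]])
        rows.append("".join(chars))
    return rows
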