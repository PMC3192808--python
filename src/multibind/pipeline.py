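"""End-to-end pipeline: motif scan -> effective constants -> speciation.

The pipeline is deliberately thin: each stage is a call into the
corresponding library module, and a run is fully determined by its
:class:`~multibind.config.RunConfig` (identical config and inputs give
identical outputs; every report embeds the config hash).
"""

from __future__ import annotations

import json
from importlib.metadata import version
from pathlib import Path

from .config import RunConfig
from .equilibria import (
    AffinityModel,
    k_gs,
    k_gsg,
    load_affinity_csv,
    load_ceff_csv,
    load_packaged_model,
)
from .motifs import build_layout, read_fasta, scan_motifs, write_motif_report
from .speciation import SpeciationInput, solve_equilibrium, stoichiometry_sweep

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage of the pipeline could not run on the given configuration."""


def _build_model(config: RunConfig) -> AffinityModel:
    inp = config.inputs
    if inp.affinities_nsh3_csv or inp.affinities_csh3_csv or inp.ceff_csv:
        if not (inp.affinities_nsh3_csv and inp.affinities_csh3_csv and inp.ceff_csv):
            raise PipelineError(
                "either all of affinities_nsh3_csv, affinities_csh3_csv and "
                "ceff_csv must be given, or none (to use the packaged model)"
            )
        model = AffinityModel(
            kd_N_uM=load_affinity_csv(inp.affinities_nsh3_csv),
            kd_C_uM=load_affinity_csv(inp.affinities_csh3_csv),
            ceff_mM=load_ceff_csv(inp.ceff_csv),
            substitutions=dict(config.substitutions),
            temperature_K=config.thermo.temperature_K,
            gas_constant=config.thermo.gas_constant_kcal,
        )
    else:
        model = load_packaged_model(use_measured_kd_eff=True)
        model.substitutions = dict(config.substitutions)
    return model


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write JSON/TSV/CSV reports.

    Returns the result bundle that was written to ``results.json`` in
    the configured output directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "config_digest": config.digest(),
        "multibind_version": version("multibind"),
    }

    # Stage 1: motif scanning (optional; needs a FASTA input).
    if config.inputs.fasta:
        fasta_path = Path(config.inputs.fasta)
        if not fasta_path.exists():
            raise PipelineError(f"FASTA input not found: {fasta_path}")
        layouts = []
        for seq_id, seq in read_fasta(fasta_path).items():
            sites = scan_motifs(seq)
            layouts.append(build_layout(seq_id, sites))
        write_motif_report(
            layouts, out_dir / "motif_sites.tsv", out_dir / "motif_linkers.tsv"
        )
        bundle["motifs"] = {
            layout.sequence_id: {
                "classes": [c.value for c in layout.classes],
                "linker_lengths": layout.linker_lengths,
            }
            for layout in layouts
        }

    # Stage 2: effective equilibrium constants.
    model = _build_model(config)
    motifs = config.inputs.motifs if config.inputs.motifs is not None else model.motifs
    if not motifs:
        raise PipelineError("empty motif list")
    summary = k_gsg(model, motifs, convention=config.convention) if len(motifs) >= 2 else k_gs(
        model, motifs
    )
    bundle["equilibria"] = {
        "motifs": motifs,
        "n_modes": summary.n_modes,
        "K_GS_per_uM": summary.K_GS,
        "Kd_GS_uM": summary.Kd_GS_uM,
        "fraction_singly": summary.fraction_singly,
        "fraction_doubly": summary.fraction_doubly,
    }
    if summary.K_GSG is not None:
        bundle["equilibria"].update(
            {
                "K_GSG_per_uM": summary.K_GSG,
                "Kd_GSG_uM": summary.Kd_GSG_uM,
                "convention": summary.convention,
                "gsg_fractions": {
                    "both_doubly": summary.gsg_fractions[0],
                    "mixed": summary.gsg_fractions[1],
                    "both_singly": summary.gsg_fractions[2],
                },
            }
        )

    # Stage 3: speciation at cellular concentrations (optional).
    spc = config.speciation
    if spc.total_G_M is not None and spc.total_S_M is not None:
        if summary.K_GSG is None:
            raise PipelineError("speciation needs at least two motifs (for K_GSG)")
        inp = SpeciationInput(
            total_G=spc.total_G_M,
            total_S=spc.total_S_M,
            K_GS=summary.K_GS * 1e6,   # per-uM -> per-M
            K_GSG=summary.K_GSG * 1e6,
        )
        res = solve_equilibrium(inp)
        bundle["speciation"] = {
            "free_G_M": res.free_G,
            "free_S_M": res.free_S,
            "conc_GS_M": res.conc_GS,
            "conc_GSG_M": res.conc_GSG,
            "f_GSG": res.f_GSG,
            "effective_stoichiometry": res.effective_stoichiometry,
        }
        if spc.sweep_ratios:
            sweep = stoichiometry_sweep(inp, spc.sweep_species, spc.sweep_ratios)
            sweep.insert(0, "config_digest", config.digest())
            sweep.to_csv(out_dir / "speciation_sweep.csv", index=False)
            bundle["speciation"]["sweep_csv"] = str(out_dir / "speciation_sweep.csv")

    with open(out_dir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
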