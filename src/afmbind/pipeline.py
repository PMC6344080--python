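"""Command-line orchestration, configuration, and sequence utilities.

Subcommands wrap the library stages (simulate -> fit, simulate -> trace ->
classify); every command takes an explicit seed and produces deterministic
JSON/TSV output. ``protein-calc`` computes average molecular mass and the
280 nm molar extinction coefficient for a protein sequence, used as a
desk check of protein concentration determination.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import click
import numpy as np
from pydantic import BaseModel, Field

from . import afm_particles, afm_trace, binding, synthetic

__all__ = [
    "RunConfig",
    "protein_mass_and_extinction",
    "load_uniprot_sequence",
    "construct_sequence",
    "run_pipeline",
    "main",
]

log = logging.getLogger("afmbind")

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def protein_mass_and_extinction(
    sequence: str, reduced: bool = True
) -> tuple[float, float, float]:
    """Average mass (monomer and tetramer, Da) and 280 nm extinction (M^-1 cm^-1).

    Mass is the average-isotopic sum of residue masses minus (n-1) waters.
    Extinction follows the Trp/Tyr(/cystine) additivity rule: 5500 per Trp,
    1490 per Tyr, plus 125 per cystine when ``reduced`` is False (cysteines
    are assumed reduced by default, contributing nothing).
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise ValueError(f"unknown residue(s): {sorted(bad)}")
    pa = ProteinAnalysis(seq)
    mono = float(pa.molecular_weight())
    ext_reduced, ext_oxidized = pa.molar_extinction_coefficient()
    ext = float(ext_reduced if reduced else ext_oxidized)
    return mono, 4.0 * mono, ext


def construct_sequence(core: str, n_term: str = "", c_term: str = "") -> str:
    """Expression-construct sequence: core flanked by vector-derived extensions."""
    return (n_term + core + c_term).upper()


def load_uniprot_sequence(accession: str, cache_dir=None) -> str:
    """Load a protein sequence for a UniProt accession from a local FASTA.

    Looks for ``<accession>.fasta`` in ``cache_dir``. No network access is
    attempted; download the entry once and point ``cache_dir`` at it.
    """
    if cache_dir is not None:
        path = Path(cache_dir) / f"{accession}.fasta"
        if path.exists():
            lines = path.read_text().splitlines()
            return "".join(l.strip() for l in lines if not l.startswith(">"))
    raise LookupError(
        f"sequence for {accession} not found locally; download the FASTA from "
        f"UniProt and pass cache_dir"
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

class StageConfig(BaseModel):
    command: str
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Schema-validated multi-stage run description."""

    seed: int = 0
    stages: list[StageConfig] = Field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)


def _hash_file(path) -> str:
    p = Path(path)
    if not p.exists():
        return "missing"
    return hashlib.sha256(p.read_bytes()).hexdigest()[:12]


def _log_stage(command: str, seed: int, params: dict) -> None:
    echo = {k: (_hash_file(v) if isinstance(v, str) and Path(str(v)).is_file() else v) for k, v in params.items()}
    log.info("stage=%s seed=%d params=%s", command, seed, json.dumps(echo, sort_keys=True, default=str))


# --------------------------------------------------------------------------
# Stage implementations (shared by run_pipeline and the CLI)
# --------------------------------------------------------------------------

def _stage_simulate_binding(seed: int, params: dict) -> None:
    model = params["model"]
    out = params["out"]
    conc = np.asarray(params["conc_grid"], dtype=float)
    noise = float(params.get("noise_sd", 0.0))
    reps = int(params.get("replicates", 1))
    probe = float(params.get("probe_conc", 5.0))
    mp = params.get("params", {})
    if model == "hyperbolic":
        mobj = binding.HyperbolicParams(**mp)
    elif model == "ic50":
        mobj = binding.Ic50Params(**mp)
    elif model == "tight_binding":
        mobj = binding.TightBindingParams(**mp)
    elif model == "mechanistic":
        mobj = mp
    else:
        raise ValueError(f"unknown model {model!r}")
    tits = synthetic.generate_titration(model, mobj, conc, noise, reps, seed, probe)
    binding.write_titration_csv(out, tits)


def _stage_fit_binding(seed: int, params: dict) -> None:
    mode = params["mode"]
    tits = binding.read_titration_csv(params["in"], float(params.get("probe_conc", 5.0)), mode)
    if mode == "direct":
        res = binding.fit_hyperbolic(tits[0], seed=seed)
    elif mode == "competition":
        res = binding.fit_ic50(tits[0], seed=seed)
    elif mode == "tight_binding":
        res = binding.fit_stoichiometry_global(tits, float(params["fixed_kd"]), seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res.to_json(params["out"])


_PRESETS = {
    # control field of bare 587 bp substrate molecules
    "fig6": dict(n_molecules=30, multimer_fractions={}, circle_fraction=0.0),
    "fig6_bridged": dict(n_molecules=30, multimer_fractions={2: 0.07, 3: 0.02}, circle_fraction=0.0),
}


def _stage_simulate_afm(seed: int, params: dict) -> None:
    outdir = Path(params["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    scene_kw = dict(_PRESETS[params["preset"]]) if "preset" in params else {}
    for key in ("n_molecules", "multimer_fractions", "circle_fraction", "n_bp", "persistence_nm"):
        if key in params:
            scene_kw[key] = params[key]
    scene_kw["multimer_fractions"] = {
        int(k): v for k, v in dict(scene_kw.get("multimer_fractions", {})).items()
    }
    chains, gt = synthetic.build_bridged_scene(seed=seed, **scene_kw)
    topos = synthetic.render_scene(
        chains,
        gt,
        tip_radius_nm=float(params.get("tip_radius_nm", 5.0)),
        noise_rms_nm=float(params.get("noise_rms_nm", 0.05)),
        line_offset_rms_nm=float(params.get("line_offset_rms_nm", 0.0)),
        seed=seed,
    )
    for i, topo in enumerate(topos):
        topo.write(outdir / f"field_{i:03d}.tif")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "molecules": gt.molecules,
                "scale_nm_per_px": gt.scale_nm_per_px,
                "image_size_px": gt.image_size_px,
                "n_fields": gt.n_fields,
                "seed": seed,
            },
            fh,
            sort_keys=True,
            indent=2,
        )
        fh.write("\n")


def _stage_flatten(seed: int, params: dict) -> None:
    topo = synthetic.Topograph.read(params["in"])
    afm_trace.flatten(topo, int(params.get("order", 1))).write(params["out"])


def _stage_trace(seed: int, params: dict) -> None:
    topo = synthetic.Topograph.read(params["in"])
    if params.get("flatten", True):
        topo = afm_trace.flatten(topo, int(params.get("order", 1)))
    mols = afm_trace.trace_dna(
        topo,
        height_threshold_nm=float(params.get("height_threshold_nm", 0.25)),
        min_length_nm=float(params.get("min_length_nm", 20.0)),
    )
    afm_trace.write_molecule_table(params["out"], mols)


def _stage_bridge_report(seed: int, params: dict) -> None:
    control = [
        m.contour_nm
        for m in afm_trace.read_molecule_table(params["control"])
        if m.valid and not m.is_closed
    ]
    sample = [
        m.contour_nm
        for m in afm_trace.read_molecule_table(params["in"])
        if m.valid and not m.is_closed
    ]
    dist = afm_trace.fit_length_histogram(control)
    report = afm_trace.classify_bridging(sample, dist)
    report.to_json(params["out"])


def _stage_particle_report(seed: int, params: dict) -> None:
    topo = synthetic.Topograph.read(params["in"])
    if params.get("flatten", True):
        topo = afm_trace.flatten(topo, int(params.get("order", 1)))
    fid = params.get("fiducial")
    records = afm_particles.analyze_particles(
        topo,
        fiducial_center=tuple(fid) if fid else None,
        threshold_nm=float(params.get("threshold_nm", 1.0)),
    )
    afm_particles.write_particle_table(params["out"], records)
    if params.get("summary_out"):
        with open(params["summary_out"], "w") as fh:
            json.dump(afm_particles.class_summary(records), fh, sort_keys=True, indent=2)
            fh.write("\n")


def _stage_protein_calc(seed: int, params: dict) -> None:
    fasta = Path(params["in"]).read_text().splitlines()
    seq = "".join(l.strip() for l in fasta if not l.startswith(">"))
    mono, tetra, ext = protein_mass_and_extinction(seq, reduced=params.get("reduced", True))
    payload = {
        "monomer_da": round(mono, 2),
        "tetramer_da": round(tetra, 2),
        "extinction_m1cm1": ext,
        "n_residues": len(seq.strip()),
    }
    text = json.dumps(payload, sort_keys=True, indent=2)
    if params.get("out"):
        Path(params["out"]).write_text(text + "\n")
    else:
        click.echo(text)


_STAGES = {
    "simulate-binding": _stage_simulate_binding,
    "fit-binding": _stage_fit_binding,
    "simulate-afm": _stage_simulate_afm,
    "flatten": _stage_flatten,
    "trace": _stage_trace,
    "bridge-report": _stage_bridge_report,
    "particle-report": _stage_particle_report,
    "protein-calc": _stage_protein_calc,
}


def run_pipeline(config: RunConfig) -> None:
    """Execute the configured stages in order; identical config + seed gives
    identical outputs."""
    for stage in config.stages:
        if stage.command not in _STAGES:
            raise ValueError(f"unknown stage {stage.command!r}")
        _log_stage(stage.command, config.seed, stage.params)
        _STAGES[stage.command](config.seed, stage.params)


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

@click.group()
def main() -> None:
    """Binding-isotherm fitting and AFM topograph quantification."""
    logging.basicConfig(level=logging.INFO, format="%(message)s")


@main.command("run")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def _cli_run(config_path):
    """Run a multi-stage pipeline from a JSON config."""
    run_pipeline(RunConfig.from_json(config_path))


def _json_opt(s):
    return json.loads(s) if isinstance(s, str) else s


@main.command("simulate-binding")
@click.option("--model", required=True, type=click.Choice(["hyperbolic", "ic50", "tight_binding", "mechanistic"]))
@click.option("--params", "params_json", required=True, help="model parameters as JSON")
@click.option("--conc-grid", required=True, help="JSON list of concentrations (nM)")
@click.option("--noise-sd", default=0.0, type=float)
@click.option("--replicates", default=1, type=int)
@click.option("--probe-conc", default=5.0, type=float)
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def _cli_simulate_binding(model, params_json, conc_grid, noise_sd, replicates, probe_conc, seed, out):
    """Simulate a titration CSV from a binding model."""
    params = dict(
        model=model, params=_json_opt(params_json), conc_grid=_json_opt(conc_grid),
        noise_sd=noise_sd, replicates=replicates, probe_conc=probe_conc, out=out,
    )
    _log_stage("simulate-binding", seed, params)
    _stage_simulate_binding(seed, params)


@main.command("fit-binding")
@click.option("--mode", required=True, type=click.Choice(["direct", "competition", "tight_binding"]))
@click.option("--in", "infile", required=True, type=click.Path(exists=True))
@click.option("--probe-conc", default=5.0, type=float)
@click.option("--fixed-kd", default=None, type=float)
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def _cli_fit_binding(mode, infile, probe_conc, fixed_kd, seed, out):
    """Fit a titration CSV and write a JSON fit report."""
    params = {"mode": mode, "in": infile, "probe_conc": probe_conc, "out": out}
    if fixed_kd is not None:
        params["fixed_kd"] = fixed_kd
    _log_stage("fit-binding", seed, params)
    _stage_fit_binding(seed, params)


@main.command("simulate-afm")
@click.option("--preset", default=None, type=click.Choice(sorted(_PRESETS)))
@click.option("--n-molecules", default=None, type=int)
@click.option("--multimer-fractions", default=None, help='JSON, e.g. {"2": 0.07}')
@click.option("--circle-fraction", default=None, type=float)
@click.option("--tip-radius-nm", default=5.0, type=float)
@click.option("--noise-rms-nm", default=0.05, type=float)
@click.option("--line-offset-rms-nm", default=0.0, type=float)
@click.option("--seed", default=0, type=int)
@click.option("--outdir", required=True, type=click.Path())
def _cli_simulate_afm(preset, n_molecules, multimer_fractions, circle_fraction,
                      tip_radius_nm, noise_rms_nm, line_offset_rms_nm, seed, outdir):
    """Render synthetic topographs (float TIFF + JSON sidecars + ground truth)."""
    params = {"outdir": outdir, "tip_radius_nm": tip_radius_nm,
              "noise_rms_nm": noise_rms_nm, "line_offset_rms_nm": line_offset_rms_nm}
    if preset:
        params["preset"] = preset
    if n_molecules is not None:
        params["n_molecules"] = n_molecules
    if multimer_fractions is not None:
        params["multimer_fractions"] = _json_opt(multimer_fractions)
    if circle_fraction is not None:
        params["circle_fraction"] = circle_fraction
    _log_stage("simulate-afm", seed, params)
    _stage_simulate_afm(seed, params)


@main.command("flatten")
@click.option("--in", "infile", required=True, type=click.Path(exists=True))
@click.option("--order", default=1, type=int)
@click.option("--out", required=True, type=click.Path())
def _cli_flatten(infile, order, out):
    """Flatten a topograph (per-line background + global plane removal)."""
    _log_stage("flatten", 0, {"in": infile, "order": order, "out": out})
    _stage_flatten(0, {"in": infile, "order": order, "out": out})


@main.command("trace")
@click.option("--in", "infile", required=True, type=click.Path(exists=True))
@click.option("--height-threshold-nm", default=0.25, type=float)
@click.option("--min-length-nm", default=20.0, type=float)
@click.option("--no-flatten", is_flag=True, default=False)
@click.option("--out", required=True, type=click.Path())
def _cli_trace(infile, height_threshold_nm, min_length_nm, no_flatten, out):
    """Trace DNA molecules and write the per-molecule TSV table."""
    params = {"in": infile, "height_threshold_nm": height_threshold_nm,
              "min_length_nm": min_length_nm, "flatten": not no_flatten, "out": out}
    _log_stage("trace", 0, params)
    _stage_trace(0, params)


@main.command("bridge-report")
@click.option("--in", "infile", required=True, type=click.Path(exists=True))
@click.option("--control", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def _cli_bridge_report(infile, control, out):
    """Classify contour-length multimers against a control molecule table."""
    params = {"in": infile, "control": control, "out": out}
    _log_stage("bridge-report", 0, params)
    _stage_bridge_report(0, params)


@main.command("particle-report")
@click.option("--in", "infile", required=True, type=click.Path(exists=True))
@click.option("--fiducial", default=None, help="x,y (nm) of a DNA ridge point")
@click.option("--threshold-nm", default=1.0, type=float)
@click.option("--out", required=True, type=click.Path())
@click.option("--summary-out", default=None, type=click.Path())
def _cli_particle_report(infile, fiducial, threshold_nm, out, summary_out):
    """Detect, classify and volume-measure particles."""
    params = {"in": infile, "threshold_nm": threshold_nm, "out": out}
    if fiducial:
        params["fiducial"] = [float(v) for v in fiducial.split(",")]
    if summary_out:
        params["summary_out"] = summary_out
    _log_stage("particle-report", 0, params)
    _stage_particle_report(0, params)


@main.command("protein-calc")
@click.argument("fasta", type=click.Path(exists=True))
@click.option("--oxidized", is_flag=True, default=False, help="count cystine pairs")
@click.option("--out", default=None, type=click.Path())
def _cli_protein_calc(fasta, oxidized, out):
    """Average mass and 280 nm extinction coefficient from a FASTA."""
    params = {"in": fasta, "reduced": not oxidized}
    if out:
        params["out"] = out
    _log_stage("protein-calc", 0, params)
    _stage_protein_calc(0, params)


if __name__ == "__main__":
    main()
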