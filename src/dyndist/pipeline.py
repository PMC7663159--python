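"""Reproducible pipeline driver: build → zip-up → anneal → TI → analyze.

One seed in the run configuration feeds a ``numpy.random.SeedSequence``
that is split into independent per-stage streams, so every stage is
individually reproducible and re-running the same configuration
regenerates all outputs bit-identically.  Every output file is listed
in ``manifest.json`` with a SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import pattern_timeseries
from .cv import dynamic_distance
from .free_energy import WindowSchedule, run_ti
from .geometry import (
    build_antiparallel_duplex,
    guanine_to_isoguanine,
    insert_modified_pair,
    neutralize,
    parallelize,
    select_constraint_pairs,
)
from .io import RunConfig, write_md_traces, write_pdb, write_xyz
from .md import NoseHooverChain, anneal, initialize_velocities, zip_up
from .toymodel import make_toy_duplex

logger = logging.getLogger(__name__)

_STAGES = ("build", "zip", "anneal", "ti", "analyze")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def build_from_config(config: RunConfig):
    """Construct the duplex model a configuration describes."""
    duplex = build_antiparallel_duplex(config.sequence)
    if config.parallel:
        duplex = parallelize(duplex)
    if config.isoguanine:
        duplex = guanine_to_isoguanine(duplex)
    if config.modify_at:
        duplex = insert_modified_pair(
            duplex, config.modify_at, hg=config.hg, protonated=not config.hg
        )
    if config.neutralize:
        duplex = neutralize(duplex, seed=_stage_seeds(config.seed)["build"])
    return duplex


def pipeline_run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage failures are recorded in the manifest with the stages that
    completed; outputs of finished stages are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "completed": [],
        "files": {},
        "summary": {},
    }
    config.to_yaml(outdir / "config.yml")

    try:
        # validate the schedule string before any MD is spent
        WindowSchedule.from_string(config.schedule)
        duplex = build_from_config(config)
        write_pdb(duplex, outdir / "model.pdb")
        manifest["completed"].append("build")
        manifest["summary"]["build"] = {
            "n_pairs": duplex.n_pairs,
            "n_counter_ions": len(duplex.counter_ions),
            "net_charge": duplex.total_charge,
        }

        topo, conf, smap = make_toy_duplex(duplex)
        equi = select_constraint_pairs(duplex, "EQUI")
        zres = zip_up(
            topo, conf, equi,
            D_start=config.zip_d_start, D_end=config.zip_d_end,
            steps=config.zip_steps, dt=config.dt,
            thermostat=NoseHooverChain(config.temperature),
            seed=seeds["zip"],
        )
        write_md_traces(zres, outdir / "zip_trace.csv")
        d_final = dynamic_distance(equi, conf.positions)
        manifest["completed"].append("zip")
        manifest["summary"]["zip"] = {"D_final": d_final}
        logger.info("zip-up finished at D_EQUI = %.4f", d_final)

        if config.anneal_steps > 0:
            anneal(
                topo, conf, config.temperature, config.anneal_factor,
                config.anneal_steps, config.anneal_interval, config.dt,
                spec=equi,
            )
        write_pdb(duplex.with_coordinates(conf.positions), outdir / "relaxed.pdb")
        manifest["completed"].append("anneal")

        spec = select_constraint_pairs(duplex, config.variant)
        schedule = WindowSchedule.from_string(
            config.schedule,
            min_steps_per_window=config.ti_steps_per_window,
            equilibration_fraction=config.ti_equilibration_fraction,
        )
        conf.velocities[:] = 0.0
        initialize_velocities(
            conf, config.temperature, np.random.default_rng(seeds["ti"]), spec
        )
        ti = run_ti(
            topo, conf, spec, schedule, dt=config.dt,
            temperature=config.temperature,
            pre_equilibration_steps=config.ti_pre_equilibration_steps,
            seed=seeds["ti"],
        )
        ti.profile.to_dataframe().to_csv(outdir / "profile.csv", index=False)
        for w, tr in enumerate(ti.lambda_traces):
            pd.DataFrame({"lambda": tr}).to_csv(
                outdir / f"window_{w:03d}_lambda.csv", index=False
            )
        if ti.pair_mean_distances is not None:
            pd.DataFrame(
                ti.pair_mean_distances, columns=ti.pair_labels
            ).to_csv(outdir / "pair_distances.csv", index=False)
        manifest["completed"].append("ti")
        manifest["summary"]["ti"] = {
            "n_windows": len(ti.profile.D),
            "delta_A_total": float(ti.profile.delta_A[-1]),
            "failures": ti.failures,
        }

        if duplex.hg_ions:
            frame = conf.positions
            write_xyz(
                outdir / "final.xyz", [frame],
                labels=[l for l, _, _ in duplex.atom_table()],
                comments=[f"final frame D={dynamic_distance(spec, frame):.4f}"],
            )
            ts = pattern_timeseries(
                [frame], smap, cutoff=config.pattern_cutoff,
                debounce=config.pattern_debounce,
            )
            manifest["summary"]["analyze"] = {
                "final_pattern": ts.labels[-1],
                "transitions": ts.transitions,
            }
        manifest["completed"].append("analyze")
    except Exception as exc:  # record partial completion, then re-raise
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(outdir, manifest)
        raise
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
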