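"""End-to-end orchestration of the synthetic design/analysis pipeline.

A run is described by a TOML/dict config with a global seed and a list of
stages; per-stage RNG streams are derived from the root seed with
``numpy.random.SeedSequence.spawn`` so every stage is independently
reproducible.  Each run directory receives a ``provenance.json`` recording
the config hash, the root seed, per-stage seeds and the artifacts written;
re-running an identical config reproduces identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import comand, gmm, helixcoil, motifs, synthetic

logger = logging.getLogger("qhelix.pipeline")

KNOWN_STAGES = ("design", "helicity", "plant", "strips", "decompose", "gmm")

REQUIRED_PARAMS: dict[str, list[str]] = {
    "design": ["n_units"],
    "helicity": ["dg_side"],
    "plant": ["mixture", "n_frames"],
    "strips": ["noise_sd"],
    "decompose": [],
    "gmm": [],
}


def validate_config(config: dict) -> None:
    """Schema check; raises ValueError naming the offending field path."""
    if "seed" not in config:
        raise ValueError("missing field: seed")
    stages = config.get("stages")
    if not stages:
        raise ValueError("missing field: stages")
    for i, stage in enumerate(stages):
        name = stage.get("name")
        if name not in KNOWN_STAGES:
            raise ValueError(f"stages[{i}].name: unknown stage {name!r}")
        params = stage.get("params", {})
        for key in REQUIRED_PARAMS[name]:
            if key not in params:
                raise ValueError(f"stages[{i}].params.{key}: missing")
        for key in ("input", "pool"):
            if key in params and not Path(params[key]).exists():
                raise ValueError(f"stages[{i}].params.{key}: path not found")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    root = int(config["seed"])
    streams = np.random.SeedSequence(root).spawn(len(config["stages"]))
    stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in streams]
    chash = config_hash(config)
    provenance = {"config_hash": chash, "seed": root, "stages": []}
    ctx: dict = {}
    try:
        for i, stage in enumerate(config["stages"]):
            name = stage["name"]
            params = dict(stage.get("params", {}))
            t0 = time.time()
            logger.info("stage %s starting (seed %d)", name, stage_seeds[i])
            artifacts = _STAGE_FUNCS[name](params, ctx, stage_seeds[i], out)
            artifacts = [str(Path(a).relative_to(out)) for a in artifacts]
            provenance["stages"].append(
                {
                    "name": name,
                    "seed": stage_seeds[i],
                    "params": params,
                    "artifacts": artifacts,
                }
            )
            logger.info("stage %s done in %.2f s", name, time.time() - t0)
    finally:
        # partial provenance is still written on stage failure
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
        logger.removeHandler(handler)
        handler.close()
    return out


def _stage_design(params, ctx, seed, out: Path):
    design = motifs.design_scaffold(
        params["n_units"],
        ncap=params.get("ncap"),
        guest=tuple(params["guest"]) if "guest" in params else None,
        control=params.get("control", False),
    )
    ctx["design"] = design
    path = out / "scaffold.json"
    with open(path, "w") as fh:
        json.dump(
            {
                "sequence": design.sequence,
                "pairs": design.pairs,
                "tail_donors": design.tail_donors,
                "free_positions": design.free_positions,
            },
            fh,
            indent=2,
        )
    return [str(path)]


def _stage_helicity(params, ctx, seed, out: Path):
    design = ctx.get("design")
    sequence = params.get("sequence") or design.sequence
    pairs = []
    if design is not None and params.get("interactions", "auto") == "auto":
        pairs = design.pairs + design.tail_donors
    interactions = [helixcoil.Interaction(a, d, params["dg_side"]) for a, d in pairs]
    model = helixcoil.HelixCoilModel.from_scale(sequence, interactions=interactions)
    profile = helixcoil.predict_profile(model)
    path = out / "helicity.csv"
    profile.to_csv(path)
    ctx["profile"] = profile
    return [str(path)]


def _stage_plant(params, ctx, seed, out: Path):
    design = ctx.get("design")
    sequence = params.get("sequence") or design.sequence
    planted = synthetic.plant_rotamer_ensemble(
        sequence,
        dict(params["mixture"]),
        int(params["n_frames"]),
        seed=seed,
        residues=params.get("residues"),
    )
    ctx["planted"] = planted
    pdb = out / "ensemble.pdb"
    planted.ensemble.to_pdb(pdb)
    labels = out / "labels.csv"
    planted.labels.to_csv(labels, index=False)
    return [str(pdb), str(labels)]


def _stage_strips(params, ctx, seed, out: Path):
    planted = ctx["planted"]
    stripset = synthetic.synth_strips(
        planted.ensemble,
        noise_sd=float(params["noise_sd"]),
        seed=seed,
        owners=[tuple(o) for o in params["owners"]] if "owners" in params else None,
    )
    ctx["strips"] = stripset
    paths = []
    for strip in stripset.strips:
        p = out / f"strip_{strip.owner[0]}_{strip.owner[1]}.csv"
        strip.to_csv(p)
        paths.append(str(p))
    ap = out / "assignments.csv"
    comand.write_assignments(ap, stripset.assignments)
    paths.append(str(ap))
    return paths


def _stage_decompose(params, ctx, seed, out: Path):
    stripset = ctx["strips"]
    planted = ctx["planted"]
    config = comand.SelectionConfig(
        n_trials=int(params.get("n_trials", 100)),
        max_ensemble=int(params.get("max_ensemble", 20)),
        seed_pool_size=int(params.get("seed_pool_size", 20)),
        seed=seed,
    )
    results = {}
    pooled_all = {}
    for strip in stripset.strips:
        res = comand.decompose_strip(
            strip, planted.ensemble, config, stripset.assignments, stripset.params
        )
        pooled_all[strip.owner[0]] = res.pooled
        results[f"{strip.owner[0]}:{strip.owner[1]}"] = {
            "r_min": res.r_min,
            "n_retained": int(res.retained.sum()),
            "mean_retained_r": float(res.trial_r[res.retained].mean()),
            "pooled_size": int(res.pooled.size),
        }
    ctx["pooled"] = pooled_all
    path = out / "decomposition.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2)
    return [str(path)]


def _stage_gmm(params, ctx, seed, out: Path):
    planted = ctx["planted"]
    pooled = ctx["pooled"]
    labels = planted.labels
    paths = []
    fractions = {}
    for res_id, frames in pooled.items():
        sub = labels[labels.res_id == res_id].set_index("frame")
        pts = sub.loc[frames, ["chi1", "chi2"]].to_numpy()
        model = gmm.select_k(pts, int(params.get("k_max", 9)))
        fractions[str(res_id)] = gmm.rotamer_fractions(model)
        p = out / f"gmm_res{res_id}.json"
        model.to_json(p)
        paths.append(str(p))
    fp = out / "rotamer_fractions.json"
    with open(fp, "w") as fh:
        json.dump(fractions, fh, indent=2)
    paths.append(str(fp))
    ctx["fractions"] = fractions
    return paths


_STAGE_FUNCS = {
    "design": _stage_design,
    "helicity": _stage_helicity,
    "plant": _stage_plant,
    "strips": _stage_strips,
    "decompose": _stage_decompose,
    "gmm": _stage_gmm,
}


DEMO_CONFIG = {
    "seed": 0,
    "stages": [
        {"name": "design", "params": {"n_units": 4}},
        {"name": "helicity", "params": {"dg_side": -0.6}},
        {
            "name": "plant",
            "params": {"mixture": {"mt": 0.8, "tp": 0.2}, "n_frames": 150},
        },
        {"name": "strips", "params": {"noise_sd": 0.02, "owners": [[13, "HE21"]]}},
        {"name": "decompose", "params": {"n_trials": 50}},
        {"name": "gmm", "params": {}},
    ],
}
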