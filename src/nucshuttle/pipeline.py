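"""End-to-end pipeline: phantom generation and all measurement stages from one config.

A single YAML configuration declares either an input stack or a phantom
specification plus per-stage parameters; stages run in a fixed order
(phantom → preprocess → partition / granules / axon / bleach) and every output
CSV carries the seed and a hash of the configuration, so a rerun with the same
config is identical for deterministic stages and for seeded stochastic ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import axon as axon_mod
from . import bleach as bleach_mod
from . import compartment, granules, phantom, preprocess
from .io import VolumeStack, write_stack

__all__ = ["load_config", "validate_config", "run_pipeline"]

log = logging.getLogger("nucshuttle")

_STAGE_CHANNEL_KEYS = {
    "partition": ("reporter", "nuclear", "soma"),
    "granules": ("channel", "within"),
    "axon": ("channel",),
    "bleach": ("channel",),
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_config(cfg: dict, channel_names: tuple[str, ...]) -> None:
    """Check every channel referenced by a stage exists in the inputs."""
    for stage, keys in _STAGE_CHANNEL_KEYS.items():
        section = cfg.get(stage)
        if not section:
            continue
        for key in keys:
            ch = section.get(key)
            if ch is not None and ch not in channel_names:
                raise ValueError(
                    f"stage {stage!r} references missing channel {ch!r}; "
                    f"available: {list(channel_names)}"
                )


def _build_phantom(cfg: dict, seed: int) -> tuple[VolumeStack, phantom.PhantomScene]:
    p = dict(cfg)
    optics = phantom.OpticsParams(**p.pop("optics", {}))
    voxel_size = tuple(p.pop("voxel_size", (0.4, 0.2, 0.2)))
    supersample = int(p.pop("supersample", 3))
    with_axon = bool(p.pop("with_axon", False))
    n_granules = int(p.pop("n_granules", 0))
    rng = np.random.default_rng(seed)
    if n_granules:
        vols = phantom.sample_granule_volumes(n_granules, rng)
        p.setdefault("granule_radii", phantom.radius_from_volume(vols).tolist())
    scene = phantom.build_scene(seed=seed, **p)
    if with_axon:
        scene.axon = phantom.default_axon(scene.soma)
    shape = phantom.grid_for_scene(scene, voxel_size)
    stack = phantom.render(
        scene, optics, shape, voxel_size, seed=seed, supersample=supersample
    )
    return stack, scene


def _write_csv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {seed}\n# config_sha256: {cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the declared stages; returns a bundle of result tables and paths.

    Stage failures abort with the stage name; outputs written before the
    failure are renamed with a ``partial.`` prefix by the caller's inspection
    of the returned bundle.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    outdir = Path(output_dir or cfg.get("output_dir", "nucshuttle_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(cfg)
    bundle: dict[str, Any] = {"seed": seed, "config_hash": cfg_hash, "outputs": []}

    # --- inputs -----------------------------------------------------------
    stage = "input"
    try:
        if "phantom" in cfg:
            stack, scene = _build_phantom(cfg["phantom"], seed)
            bundle["scene"] = scene
            stack_path = outdir / "phantom.ome.tif"
            write_stack(stack, stack_path)
            bundle["outputs"].append(stack_path)
        elif "stack" in cfg:
            from .io import read_stack

            stack = read_stack(cfg["stack"], cfg.get("voxel_size_override"))
        else:
            raise ValueError("config needs either a 'phantom' or a 'stack' entry")
        validate_config(cfg, stack.channel_names)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    bundle["stack"] = stack

    # --- preprocess -------------------------------------------------------
    pp = cfg.get("preprocess", {})
    background = None
    try:
        stage = "preprocess"
        if pp.get("background_lines"):
            background = preprocess.estimate_background_lines(
                stack, n_lines=int(pp["background_lines"]), seed=seed
            )
            bundle["background"] = background
        if pp.get("mean_filter_radius"):
            stack = preprocess.mean_filter(stack, int(pp["mean_filter_radius"]))
            bundle["stack"] = stack
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- measurement stages ----------------------------------------------
    if "partition" in cfg:
        stage = "partition"
        try:
            s = cfg["partition"]
            masks = compartment.compute_masks(
                stack,
                nuclear_channel=s.get("nuclear", "nuclear"),
                soma_channel=s.get("soma", "cytoplasm"),
                method=s.get("method", "otsu"),
            )
            res = compartment.partition(
                stack,
                s.get("reporter", "reporter"),
                masks,
                background if s.get("subtract_background") else None,
            )
            df = pd.DataFrame(
                [
                    {
                        "frame": 0,
                        "nuclear_sum": res.nuclear_sum,
                        "cytoplasmic_sum": res.cytoplasmic_sum,
                        "nuclear_fraction": res.nuclear_fraction,
                        "voxels_nuc": res.voxels_nuclear,
                        "voxels_cyt": res.voxels_cytoplasm,
                        "thresholds": json.dumps(res.thresholds),
                    }
                ]
            )
            path = outdir / "partition.csv"
            _write_csv(df, path, seed, cfg_hash)
            bundle["partition"] = res
            bundle["outputs"].append(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "granules" in cfg:
        stage = "granules"
        try:
            s = cfg["granules"]
            mask = None
            if s.get("within"):
                mask = compartment.segment_channel(
                    stack, s["within"], s.get("within_method", "otsu")
                )
            gs = granules.detect_objects(
                stack,
                s.get("channel", "reporter"),
                mask=mask,
                threshold=s.get("threshold", "otsu"),
                min_voxels=int(s.get("min_voxels", 2)),
                connectivity=int(s.get("connectivity", 26)),
            )
            path = outdir / "granules.csv"
            _write_csv(gs.table, path, seed, cfg_hash)
            bundle["granules"] = gs
            bundle["outputs"].append(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "axon" in cfg:
        stage = "axon"
        try:
            s = cfg["axon"]
            if "path" in s:
                apath = axon_mod.read_path(s["path"], step=float(s.get("step", 1.0)))
            elif bundle.get("scene") is not None and bundle["scene"].axon is not None:
                apath = axon_mod.AxonPath(bundle["scene"].axon, step=float(s.get("step", 1.0)))
            else:
                raise ValueError("axon stage needs a 'path' file or a phantom axon")
            bg = background or preprocess.estimate_background_lines(
                stack, n_lines=int(s.get("background_lines", 2)), seed=seed
            )
            prof = axon_mod.sample_path(
                stack, apath, radius=float(s.get("radius", 0.0)), background=bg
            )
            rows = []
            for ch, means in prof.segment_means.items():
                for pos, m in zip(prof.arc_positions, means):
                    rows.append(
                        {
                            "channel": ch,
                            "arc_um": pos,
                            "mean": m,
                            "mean_bg_subtracted": m - bg.mean[ch],
                        }
                    )
            path = outdir / "axon.csv"
            _write_csv(pd.DataFrame(rows), path, seed, cfg_hash)
            bundle["axon"] = prof
            bundle["outputs"].append(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "bleach" in cfg:
        stage = "bleach"
        try:
            s = cfg["bleach"]
            center = tuple(s.get("column_center", (0.0, 0.0)))
            post = phantom.apply_uv_bleach(
                stack,
                center,
                float(s.get("half_attenuation_radius", 10.0)),
                float(s.get("floor", 0.05)),
            )
            prof = bleach_mod.radial_attenuation(
                stack,
                post,
                s.get("channel", stack.channel_names[0]),
                center,
                bin_width=float(s.get("bin_width", 2.0)),
                max_radius=s.get("max_radius"),
            )
            df = pd.DataFrame(
                {
                    "radius_um": prof.radii,
                    "attenuation": prof.attenuation,
                    "voxels": prof.counts,
                }
            )
            path = outdir / "bleach.csv"
            _write_csv(df, path, seed, cfg_hash)
            bundle["bleach"] = prof
            bundle["outputs"].append(path)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log.info("pipeline complete: %d outputs in %s", len(bundle["outputs"]), outdir)
    return bundle
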