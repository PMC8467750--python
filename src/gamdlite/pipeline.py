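"""End-to-end orchestration: simulate → reweight → analyze, with a
provenance manifest (config hash, seeds, file checksums, timings)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .constants import KB
from .gamd_engine import BoostSpec, run_gamd_protocol
from .model_systems import LangevinSpec, surface_from_config
from .reweighting import reweight_pmf


class ConfigError(ValueError):
    """Schema-invalid pipeline configuration; message carries a JSON path."""


@dataclass
class RunManifest:
    config_hash: str
    seeds: list
    version: str
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    frame_counts: dict = field(default_factory=dict)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: dict, key: str, where: str):
    if key not in cfg:
        raise ConfigError(f"missing key at /{where}/{key}")
    return cfg[key]


def run_pipeline(config: dict, outdir, seed: int = 0) -> RunManifest:
    """Run the simulate → reweight chain described by ``config``.

    Config blocks: "surface" (potential definition), "langevin"
    (temperature, friction, timestep, production steps), "gamd"
    (BoostSpec fields), "reweight" (bin_width, cutoff, order),
    "replicas" (number of independent seeds).  Frames from all replicas
    are pooled before binning, so the combined PMF uses every replica.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
        seeds=[], version=__version__,
    )

    surface = surface_from_config(_require(config, "surface", ""))
    lv = dict(_require(config, "langevin", ""))
    rw = dict(config.get("reweight", {}))
    gcfg = dict(config.get("gamd", {}))
    n_replicas = int(config.get("replicas", 1))
    try:
        boost_spec = BoostSpec(**gcfg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value at /gamd: {exc}") from exc

    coords, dvs = [], []
    total_frames = 0
    for r in range(n_replicas):
        rep_seed = (seed + 7919 * r) % (2 ** 31)
        manifest.seeds.append(rep_seed)
        spec = LangevinSpec(
            temperature=float(_require(lv, "temperature", "langevin")),
            friction=float(lv.get("friction", 1.0)),
            timestep=float(_require(lv, "timestep", "langevin")),
            n_steps=int(_require(lv, "n_steps", "langevin")),
            seed=rep_seed,
            mass=float(lv.get("mass", 12.0)),
            x0=tuple(lv.get("x0", [0.0] * surface.dimension)),
            stride=int(lv.get("stride", 1)),
        )
        t0 = time.perf_counter()
        run = run_gamd_protocol(surface, spec, boost_spec)
        manifest.timings[f"simulate_rep{r}"] = time.perf_counter() - t0
        prod = run.production
        traj_path = out / f"production_rep{r}.csv"
        prod.to_csv(traj_path)
        manifest.checksums[traj_path.name] = _sha256(traj_path)
        manifest.frame_counts[f"rep{r}"] = len(prod)
        total_frames += len(prod)
        coords.append(prod.frames[:, 0])
        dvs.append(prod.dv_sum)
        with open(out / f"params_rep{r}.json", "w") as fh:
            json.dump(
                [
                    {"step": step,
                     "params": {t: vars(p) for t, p in prm.items()},
                     "stats": {t: {"v_max": s.v_max, "v_min": s.v_min,
                                   "v_avg": s.v_avg, "sigma_v": s.sigma_v,
                                   "n": s.n_samples}
                               for t, s in snap.items()}}
                    for step, prm, snap in run.params_history
                ],
                fh, indent=1,
            )
        manifest.checksums[f"params_rep{r}.json"] = _sha256(
            out / f"params_rep{r}.json")

    t0 = time.perf_counter()
    pmf = reweight_pmf(
        np.concatenate(coords), np.concatenate(dvs),
        temperature=float(lv["temperature"]),
        bin_width=float(rw.get("bin_width", 0.5)),
        cutoff=int(rw.get("cutoff", 500)),
        order=int(rw.get("order", 2)),
    )
    manifest.timings["reweight"] = time.perf_counter() - t0
    manifest.frame_counts["combined"] = total_frames

    import pandas as pd

    pmf_path = out / "pmf.csv"
    pd.DataFrame({
        "bin_center": pmf.bin_centers[0],
        "free_energy": pmf.free_energy,
        "occupancy": pmf.occupancy,
    }).to_csv(pmf_path, index=False, float_format="%.9f")
    manifest.checksums[pmf_path.name] = _sha256(pmf_path)
    manifest.write(out / "manifest.json")
    return manifest
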