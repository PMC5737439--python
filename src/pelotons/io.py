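"""Serialization of trajectories, profiles, and kymographs.

Formats are deliberately plain: events and snapshots as TSV, kymographs
as an integer CSV matrix with a JSON sidecar of bin metadata, profiles
as TSV or (optionally) bedGraph-style 4-column text for genome-browser
visualization.  Every trajectory directory carries a ``meta.json`` with
the seed and the full parameter set, enough to replay the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .model import LatticeState, ModelParams
from .observables import ProfileEstimate
from .simulate import KIND_NAMES, Kymograph, Trajectory

__all__ = ["save_trajectory", "load_trajectory", "save_kymograph",
           "save_profiles", "profiles_to_bedgraph"]

_KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


def save_trajectory(traj: Trajectory, outdir: str | Path) -> Path:
    """Write events.tsv, snapshots.tsv and meta.json under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ev = pd.DataFrame({
        "time_s": traj.times,
        "kind": [KIND_NAMES[k] for k in traj.kinds],
        "position": traj.positions,
    })
    ev.to_csv(outdir / "events.tsv", sep="\t", index=False,
              float_format="%.9g")
    rows = []
    for s in traj.snapshots:
        for p in s.motors:
            rows.append((s.time, "motor", p))
        for q in s.roadblocks:
            rows.append((s.time, "roadblock", q))
    pd.DataFrame(rows, columns=["time_s", "kind", "position"]).to_csv(
        outdir / "snapshots.tsv", sep="\t", index=False, float_format="%.9g")
    meta = {
        "params": dataclasses.asdict(traj.params),
        "t_max": traj.t_max,
        "burn_in": traj.burn_in,
        "dt_sample": traj.dt_sample,
        "seed": traj.seed,
        "n_events": traj.n_events(),
        "initial_state": {
            "motors": list(traj.initial_state.motors),
            "roadblocks": list(traj.initial_state.roadblocks),
        },
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return outdir


def load_trajectory(outdir: str | Path) -> Trajectory:
    """Inverse of :func:`save_trajectory`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    params = ModelParams(**meta["params"])
    ev = pd.read_csv(outdir / "events.tsv", sep="\t")
    snaps_df = pd.read_csv(outdir / "snapshots.tsv", sep="\t")
    snapshots: list[LatticeState] = []
    for t, grp in snaps_df.groupby("time_s", sort=True):
        motors = tuple(int(p) for p in grp.loc[grp.kind == "motor", "position"])
        rbs = tuple(sorted(int(q) for q in
                           grp.loc[grp.kind == "roadblock", "position"]))
        snapshots.append(LatticeState(time=float(t), motors=motors,
                                      roadblocks=rbs))
    init = meta["initial_state"]
    return Trajectory(
        params=params,
        t_max=meta["t_max"],
        burn_in=meta["burn_in"],
        dt_sample=meta["dt_sample"],
        seed=meta["seed"],
        times=ev["time_s"].to_numpy(dtype=float),
        kinds=np.asarray([_KIND_CODES[k] for k in ev["kind"]], dtype=np.int8),
        positions=ev["position"].to_numpy(dtype=np.int64),
        snapshots=snapshots,
        initial_state=LatticeState(time=0.0, motors=tuple(init["motors"]),
                                   roadblocks=tuple(init["roadblocks"])),
    )


def save_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Integer CSV matrix plus a ``.json`` sidecar with bin metadata."""
    path = Path(path)
    np.savetxt(path, kymo.matrix, fmt="%d", delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "t0_s": kymo.t0, "dt_bin_s": kymo.dt_bin,
        "n_bins": int(kymo.matrix.shape[0]), "L": int(kymo.matrix.shape[1]),
        "codes": {"empty": 0, "motor": 1, "roadblock": 2},
    }))


def save_profiles(profile: ProfileEstimate, path: str | Path) -> None:
    pd.DataFrame({
        "x": profile.x,
        "rho_m": profile.rho_m,
        "rho_rb": profile.rho_rb,
        "v_m": profile.v_m,
        "step_count": profile.step_counts,
        "front_time_s": profile.front_time,
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")


def profiles_to_bedgraph(
    profile: ProfileEstimate, path: str | Path,
    track: str = "rho_m", chrom: str = "gene",
) -> None:
    """Write one profile track as bedGraph-style 4-column text
    (0-based, half-open intervals)."""
    y = getattr(profile, track)
    step = profile.bin_size
    with open(path, "w") as fh:
        for i, v in enumerate(y):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{i * step}\t{(i + 1) * step}\t{v:.6g}\n")
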