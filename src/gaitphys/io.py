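"""On-disk formats: long-format sensor CSV, JSON-lines labels, HDF5 cycle
stores, wide feature CSV, metrics logs.

Cohort layout (one directory per subject):

    cohort/
      manifest.json                  # profiles, seeds, parameters, config hash
      subject_<seed>/
        sensors_L<level>.csv         # time_s,sensor_id,channel,value
        grf_L<level>.csv             # time_s,foot,component,value
        labels.jsonl                 # {"cycle_id", "fatigue_level", ...}
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import synthetic
from .biomech import JOINTS
from .features import MANIFEST, MANIFEST_NAMES, FeatureSet
from .segment import NormalizedCycle, RejectionLog


# ------------------------------------------------------------------- cohort
def write_cohort(recordings: list[synthetic.Recording], outdir: str | Path,
                 config_hash: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash, "rate_hz": synthetic.RATE_HZ, "subjects": {}}
    for rec in recordings:
        sid = f"subject_{rec.profile.seed}"
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        manifest["subjects"].setdefault(sid, {
            "height": rec.profile.height, "mass": rec.profile.mass,
            "base_cadence": rec.profile.base_cadence,
            "asymmetry_gain": rec.profile.asymmetry_gain,
            "variability_gain": rec.profile.variability_gain,
            "seed": rec.profile.seed, "levels": [],
        })["levels"].append(rec.fatigue_level)
        t_len, n, c = rec.sensors.shape
        frame = pd.DataFrame({
            "time_s": np.repeat(rec.time, n * c),
            "sensor_id": np.tile(np.repeat(synthetic.SENSOR_NAMES, c), t_len),
            "channel": np.tile(synthetic.CHANNEL_NAMES, t_len * n),
            "value": rec.sensors.ravel(),
        })
        frame.to_csv(sdir / f"sensors_L{rec.fatigue_level}.csv", index=False)
        comp = ("ap", "vertical")
        grf = pd.DataFrame({
            "time_s": np.repeat(rec.time, 4),
            "foot": np.tile(["left", "left", "right", "right"], t_len),
            "component": np.tile(comp + comp, t_len),
            "value": np.concatenate([rec.grf_left, rec.grf_right], axis=1).ravel(),
        })
        grf.to_csv(sdir / f"grf_L{rec.fatigue_level}.csv", index=False)
        theta = pd.DataFrame(rec.theta, columns=list(JOINTS))
        theta.insert(0, "time_s", rec.time)
        theta.to_csv(sdir / f"joint_angles_L{rec.fatigue_level}.csv", index=False)
        with open(sdir / "labels.jsonl", "a") as fh:
            for k, start in enumerate(rec.cycle_starts_left):
                fh.write(json.dumps({
                    "cycle_id": f"{sid}_L{rec.fatigue_level}_c{k}",
                    "fatigue_level": rec.fatigue_level,
                    "start_sample": int(start),
                }) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(cohort_dir: str | Path) -> list[synthetic.Recording]:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    recs = []
    n, c = len(synthetic.SENSOR_NAMES), len(synthetic.CHANNEL_NAMES)
    for sid, meta in manifest["subjects"].items():
        profile = synthetic.SubjectProfile(
            height=meta["height"], mass=meta["mass"], base_cadence=meta["base_cadence"],
            asymmetry_gain=meta["asymmetry_gain"], variability_gain=meta["variability_gain"],
            seed=meta["seed"],
        )
        for lvl in meta["levels"]:
            sdf = pd.read_csv(cohort_dir / sid / f"sensors_L{lvl}.csv")
            time = sdf["time_s"].to_numpy()[:: n * c]
            sensors = sdf["value"].to_numpy().reshape(-1, n, c)
            gdf = pd.read_csv(cohort_dir / sid / f"grf_L{lvl}.csv")
            gv = gdf["value"].to_numpy().reshape(-1, 4)
            tdf = pd.read_csv(cohort_dir / sid / f"joint_angles_L{lvl}.csv")
            theta = tdf[list(JOINTS)].to_numpy()
            starts = [
                json.loads(line)["start_sample"]
                for line in (cohort_dir / sid / "labels.jsonl").read_text().splitlines()
                if json.loads(line)["fatigue_level"] == lvl
            ]
            recs.append(synthetic.Recording(
                profile=profile, fatigue_level=lvl, time=time, sensors=sensors,
                theta=theta,
                grf_left=gv[:, :2], grf_right=gv[:, 2:],
                cycle_starts_left=np.asarray(starts, int),
                cycle_starts_right=np.asarray(starts, int),
            ))
    return recs


# ------------------------------------------------------------------- cycles
def write_cycles_h5(cycles: list[NormalizedCycle], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for i, c in enumerate(cycles):
            g = f.create_group(f"cycle_{i:05d}")
            g.create_dataset("channels", data=c.channels)
            if c.grf is not None:
                g.create_dataset("grf", data=c.grf)
            if c.joint_angles is not None:
                g.create_dataset("joint_angles", data=c.joint_angles)
            g.attrs.update({
                "duration": c.duration, "side": c.side,
                "subject_id": c.subject_id,
                "fatigue_level": -1 if c.fatigue_level is None else c.fatigue_level,
            })


def read_cycles_h5(path: str | Path) -> list[NormalizedCycle]:
    out = []
    grid = np.linspace(0.0, 100.0, 101)
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            lvl = int(g.attrs["fatigue_level"])
            out.append(NormalizedCycle(
                grid=grid,
                channels=g["channels"][()],
                grf=g["grf"][()] if "grf" in g else None,
                joint_angles=g["joint_angles"][()] if "joint_angles" in g else None,
                duration=float(g.attrs["duration"]),
                side=str(g.attrs["side"]),
                subject_id=str(g.attrs["subject_id"]),
                fatigue_level=None if lvl < 0 else lvl,
            ))
    return out


def write_rejection_log(log: RejectionLog, path: str | Path) -> None:
    pd.DataFrame(log.entries, columns=["cycle_index", "reason"]).to_csv(path, index=False)


# ------------------------------------------------------------------ features
def write_features_csv(
    feature_sets: list[FeatureSet], meta: list[dict], path: str | Path
) -> None:
    """Wide CSV (metadata columns + 127 named descriptor columns) plus a JSON
    manifest with units and domain tags alongside."""
    rows = []
    for fs, m in zip(feature_sets, meta):
        rows.append({**m, **fs.as_dict()})
    pd.DataFrame(rows).to_csv(path, index=False)
    manifest = [{"name": n, "domain": d, "unit": u} for n, d, u in MANIFEST]
    Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=1))


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [n for n in MANIFEST_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"feature file lacks {len(missing)} manifest columns")
    return df


# ------------------------------------------------------------------- metrics
def append_metrics_jsonl(record: dict, path: str | Path) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
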