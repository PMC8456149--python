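"""File formats: record CSVs, per-fly vector CSVs, frame directories.

Angle records travel as long-format CSV (one row per frame) with columns

    fly_id, species, sex, treatment, datetime_local, lat, lon,
    utc_offset, frame_index, time_s, angle_deg

and frame stacks as numbered 8-bit grayscale PNGs plus a ``stack.json``
sidecar carrying rate, timestamps and the compass calibration offset.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .circstats import MeanVector
from .records import FlightRecord
from .solar import Site
from .track import FrameStack

__all__ = [
    "write_records_csv",
    "read_records_csv",
    "write_vectors_csv",
    "read_vectors_csv",
    "write_frame_stack",
    "read_frame_stack",
    "write_tracked_csv",
]

_SIDECAR = "stack.json"


def write_records_csv(records, path) -> None:
    rows = []
    for rec in records:
        times = rec.times_s
        for k, angle in enumerate(rec.angles_deg):
            rows.append(
                {
                    "fly_id": rec.fly_id,
                    "species": rec.species,
                    "sex": rec.sex,
                    "treatment": rec.treatment,
                    "datetime_local": rec.start_time.isoformat()
                    if rec.start_time
                    else "",
                    "lat": rec.site.latitude,
                    "lon": rec.site.longitude,
                    "utc_offset": rec.site.utc_offset,
                    "frame_index": k,
                    "time_s": times[k],
                    "angle_deg": angle,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records_csv(path) -> list[FlightRecord]:
    df = pd.read_csv(path)
    records = []
    for fly_id, grp in df.groupby("fly_id", sort=False):
        grp = grp.sort_values("frame_index")
        first = grp.iloc[0]
        times = grp["time_s"].to_numpy()
        rate = 1.0 / np.median(np.diff(times)) if len(times) > 1 else 5.0
        start = (
            datetime.fromisoformat(str(first["datetime_local"]))
            if str(first["datetime_local"]) not in ("", "nan")
            else None
        )
        records.append(
            FlightRecord(
                fly_id=str(fly_id),
                treatment=str(first["treatment"]),
                angles_deg=grp["angle_deg"].to_numpy(),
                rate_hz=float(round(rate, 6)),
                species=str(first["species"]),
                sex=str(first["sex"]),
                start_time=start,
                site=Site(
                    latitude=float(first["lat"]),
                    longitude=float(first["lon"]),
                    utc_offset=float(first["utc_offset"]),
                ),
            )
        )
    return records


def write_vectors_csv(vectors: dict[str, MeanVector], path) -> None:
    """Write per-fly mean vectors as (fly_id, theta_deg, r, n_obs)."""
    pd.DataFrame(
        [
            {"fly_id": fid, "theta_deg": v.theta, "r": v.r, "n_obs": v.n_obs}
            for fid, v in vectors.items()
        ]
    ).to_csv(path, index=False)


def read_vectors_csv(path) -> dict[str, MeanVector]:
    df = pd.read_csv(path)
    return {
        str(row.fly_id): MeanVector(
            theta=float(row.theta_deg), r=float(row.r), n_obs=int(row.n_obs)
        )
        for row in df.itertuples()
    }


def write_frame_stack(stack: FrameStack, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(stack.frames):
        iio.imwrite(d / f"frame_{k:05d}.png", frame)
    sidecar = {
        "rate_hz": stack.rate_hz,
        "timestamps": list(map(float, stack.timestamps)),
        "calibration_offset_deg": stack.calibration_offset_deg,
    }
    (d / _SIDECAR).write_text(json.dumps(sidecar))


def read_frame_stack(directory) -> FrameStack:
    d = Path(directory)
    paths = sorted(p for p in d.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg"))
    if not paths:
        raise FileNotFoundError(f"no frames found in {d}")
    frames = np.stack([iio.imread(p) for p in paths])
    if frames.ndim == 4:  # RGB(A) -> grayscale
        frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
    meta = {}
    if (d / _SIDECAR).exists():
        meta = json.loads((d / _SIDECAR).read_text())
    return FrameStack(
        frames=frames,
        rate_hz=float(meta.get("rate_hz", 5.0)),
        timestamps=np.asarray(meta["timestamps"]) if "timestamps" in meta else None,
        calibration_offset_deg=float(meta.get("calibration_offset_deg", 0.0)),
    )


def write_tracked_csv(tracked, path, fly_id: str = "fly") -> None:
    pd.DataFrame(
        {
            "fly_id": fly_id,
            "frame_index": tracked.frame_index,
            "time_s": tracked.times_s,
            "angle_deg": tracked.angles_deg,
            "score": tracked.scores,
            "flag": tracked.flags.astype(int),
        }
    ).to_csv(path, index=False)
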