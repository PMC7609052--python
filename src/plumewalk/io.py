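"""File formats: HDF5 plume movies, delimited tables, YAML configs.

Movies are stored as an HDF5 container with layout:

    /frames        uint8 dataset, shape (frame, y, x)
    attributes: frame_rate (Hz), pixel_size (mm),
                source_position (mm, length-2)

Trajectories are delimited text with columns (trajectory_id, t, x_mm, y_mm,
theta_deg); encounter/filter traces with columns (t, w, d, W_freq, W_dur,
W_conc); event tables with (type, onset_s, offset_s, dtheta_deg).  All
delimited outputs carry a header naming the units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .synthetic_world import PlumeMovie

TRAJECTORY_COLUMNS = ["trajectory_id", "t", "x_mm", "y_mm", "theta_deg"]


def save_movie(path, movie: PlumeMovie) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=movie.frames.astype(np.uint8),
                              compression="gzip", compression_opts=4)
        f.attrs["frame_rate"] = movie.frame_rate
        f.attrs["pixel_size"] = movie.pixel_size
        f.attrs["source_position"] = np.asarray(movie.source_position, dtype=float)


def load_movie(path) -> PlumeMovie:
    import h5py
    with h5py.File(path, "r") as f:
        return PlumeMovie(frames=f["frames"][...],
                          frame_rate=float(f.attrs["frame_rate"]),
                          pixel_size=float(f.attrs["pixel_size"]),
                          source_position=tuple(f.attrs["source_position"]))


def write_trajectories(path, trajectories) -> None:
    """``trajectories``: iterable of (t, x, y, theta) arrays (n, 4)."""
    frames = []
    for i, tr in enumerate(trajectories):
        tr = np.asarray(tr, dtype=float)
        frames.append(pd.DataFrame(
            dict(zip(TRAJECTORY_COLUMNS, [i, *tr.T]))))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trajectories(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    return [g[TRAJECTORY_COLUMNS[1:]].to_numpy()
            for _, g in df.groupby("trajectory_id", sort=True)]


def write_encounter_table(path, enc, filt=None) -> None:
    """Encounter train and filtered signals as a delimited table.

    Columns: t (s), w (onset impulse), d (exposure), and -- when ``filt``
    is given -- W_freq (Hz), W_dur (s), W_conc (intensity).
    """
    n = enc.w.size
    data = dict(t=np.arange(n) * enc.time_step, w=enc.w, d=enc.d)
    if filt is not None:
        data.update(W_freq=filt.W_freq, W_dur=filt.W_dur, W_conc=filt.W_conc)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_events(path, events) -> None:
    rows = [dict(type="turn", onset_s=t.onset, offset_s=t.offset,
                 dtheta_deg=t.dtheta) for t in events.turns]
    rows += [dict(type="stop", onset_s=a, offset_s=b, dtheta_deg=np.nan)
             for a, b in events.stops]
    rows += [dict(type="walk", onset_s=a, offset_s=b, dtheta_deg=np.nan)
             for a, b in events.walks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_table(path, fit_result) -> None:
    fit_result.table.to_csv(path, sep="\t", index=False)


def write_yaml(path, obj: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
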