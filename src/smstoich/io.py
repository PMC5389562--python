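"""Delimited-text readers/writers for spots, traces and calibration tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from smstoich.spotfind import Spot
from smstoich.stoichfit import LabelingParams

__all__ = [
    "write_spots", "read_spots", "write_traces", "read_traces",
    "read_calibration", "write_calibration",
]


def write_spots(spots: list[Spot], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"spot_id": i, "x": s.x, "y": s.y, "amplitude": s.amplitude,
             "sigma": s.sigma, "background": s.background, "fit_rss": s.fit_rss,
             "channel": s.channel}
            for i, s in enumerate(spots)
        ]
    )
    df.to_csv(path, index=False)


def read_spots(path: str | Path) -> list[Spot]:
    df = pd.read_csv(path)
    return [
        Spot(x=r.x, y=r.y, amplitude=r.amplitude, sigma=r.sigma,
             background=r.background, fit_rss=r.fit_rss,
             channel="" if pd.isna(r.channel) else str(r.channel))
        for r in df.itertuples()
    ]


def write_traces(
    traces: list[np.ndarray],
    path: str | Path,
    spot_ids: list[int] | None = None,
    meta: dict | None = None,
) -> None:
    """One row per trace, one ``frame_N`` column per frame; JSON header sidecar."""
    if spot_ids is None:
        spot_ids = list(range(len(traces)))
    n = max((len(t) for t in traces), default=0)
    rows = []
    for sid, t in zip(spot_ids, traces):
        row = {"spot_id": sid}
        row.update({f"frame_{i}": float(v) for i, v in enumerate(t)})
        rows.append(row)
    cols = ["spot_id"] + [f"frame_{i}" for i in range(n)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def read_traces(path: str | Path) -> tuple[list[np.ndarray], list[int]]:
    df = pd.read_csv(path)
    frame_cols = [c for c in df.columns if c.startswith("frame_")]
    frame_cols.sort(key=lambda c: int(c.split("_")[1]))
    traces = [np.asarray(row, dtype=float) for row in df[frame_cols].to_numpy()]
    ids = df["spot_id"].astype(int).tolist() if "spot_id" in df else list(range(len(df)))
    return traces, ids


def write_calibration(params: dict[str, LabelingParams], path: str | Path) -> None:
    rows = [
        {"protein": name, "f_labeled": p.f_labeled,
         "free_1step": p.dimer_1step, "free_2step": p.dimer_2step}
        for name, p in params.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration(path: str | Path) -> dict[str, LabelingParams]:
    """Read a calibration table: protein, f_labeled, free 1-/2-step counts."""
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples():
        out[str(r.protein)] = LabelingParams(
            f_labeled=float(r.f_labeled),
            dimer_1step=int(r.free_1step),
            dimer_2step=int(r.free_2step),
        )
    return out
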