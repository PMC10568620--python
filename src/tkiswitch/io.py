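"""CSV readers/writers for trajectories and experiment results.

Numbers are serialised with 12 significant digits so re-reading a file
stays below the package's test tolerances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .therapy import Trajectory

__all__ = [
    "FLOAT_FORMAT",
    "write_frame_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

FLOAT_FORMAT = "%.12g"


def write_frame_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    write_frame_csv(traj.to_frame(), path)


def read_trajectory_csv(path) -> Trajectory:
    frame = pd.read_csv(path)
    counts = frame[["w", "x", "y", "z"]].to_numpy(dtype=float)
    return Trajectory(times=frame["time_day"].to_numpy(dtype=float), counts=counts)
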