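"""Growth trajectories: (N_L, N_M) recorded after each pathway acquisition."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "write_trajectory", "read_trajectory"]


@dataclass
class Trajectory:
    """Ordered (N_L, N_M) pairs, one per pathway addition.

    N_L counts acquired pathways (equal to dedicated transcriptional
    regulators); N_M counts metabolites in the organism-specific network.
    N_L increases strictly by one per step, N_M is non-decreasing.
    """

    n_l: np.ndarray
    n_m: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_l = np.asarray(self.n_l, dtype=np.int64)
        self.n_m = np.asarray(self.n_m, dtype=np.int64)
        if self.n_l.shape != self.n_m.shape:
            raise ValueError("N_L and N_M must have equal length")

    def __len__(self) -> int:
        return self.n_l.size

    def validate(self) -> None:
        if len(self) and not np.all(np.diff(self.n_l) == 1):
            raise ValueError("N_L must increase by exactly 1 per step")
        if len(self) and np.any(np.diff(self.n_m) < 0):
            raise ValueError("N_M must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": np.arange(1, len(self) + 1), "N_L": self.n_l, "N_M": self.n_m}
        )


def write_trajectory(traj: Trajectory, path_or_buf) -> None:
    """TSV with columns step, N_L, N_M and a JSON metadata header line."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# meta: {json.dumps(traj.meta, sort_keys=True)}\n")
        fh.write("step\tN_L\tN_M\n")
        for step, (nl, nm) in enumerate(zip(traj.n_l, traj.n_m), start=1):
            fh.write(f"{step}\t{nl}\t{nm}\n")
    finally:
        if own:
            fh.close()


def read_trajectory(path_or_buf) -> Trajectory:
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        meta = {}
        n_l, n_m = [], []
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# meta:"):
                    meta = json.loads(line[len("# meta:"):])
                continue
            if not header_seen:
                header_seen = True
                continue
            _, nl, nm = line.split("\t")
            n_l.append(int(nl))
            n_m.append(int(nm))
    finally:
        if own:
            fh.close()
    return Trajectory(np.array(n_l), np.array(n_m), meta=meta)
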