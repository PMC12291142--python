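"""Run archives: time-indexed records of spawning / adiabatic runs.

One :class:`RunArchive` holds the full record of a single run: per-frame
TBF centroids, states, Mulliken weights, dipoles and energies (dense arrays
padded with NaN before spawn / after death), per-state populations, and the
event log (spawns, rejections, stochastic selections).  Archives round-trip
through HDF5 (one file per run, groups ``/meta``, ``/tbf``, ``/populations``,
``/events``) and export to a flat table (one row per TBF per frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RunArchive", "load_archive"]


@dataclass
class RunArchive:
    times: np.ndarray              # (T,) fs
    populations: np.ndarray        # (T, S)
    norm: np.ndarray               # (T,)
    tbf_q: np.ndarray              # (T, N, d)
    tbf_p: np.ndarray              # (T, N, d)
    tbf_state: np.ndarray          # (T, N) int, -1 = not live
    tbf_weight: np.ndarray         # (T, N) Mulliken weight per TBF
    tbf_dipole: np.ndarray         # (T, N) Debye
    tbf_donor: np.ndarray          # (T, N)
    tbf_gap: np.ndarray            # (T, N) S1-S0 gap at the centroid
    tbf_energy: np.ndarray         # (T, N) classical total energy
    tbf_parent: np.ndarray         # (N,) parent id, -1 for the root
    tbf_spawn_time: np.ndarray     # (N,) fs
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    truncated: bool = False

    @property
    def n_tbfs(self):
        return self.tbf_state.shape[1]

    @property
    def n_frames(self):
        return len(self.times)

    def survivors(self, frame=-1):
        """Indices of TBFs alive at the given frame."""
        return np.flatnonzero(self.tbf_state[frame] >= 0)

    def to_frame(self):
        import pandas as pd

        T, N, d = self.tbf_q.shape
        rows = []
        for t in range(T):
            for n in range(N):
                if self.tbf_state[t, n] < 0:
                    continue
                row = {"time_fs": self.times[t], "tbf": n,
                       "state": int(self.tbf_state[t, n]),
                       "weight": self.tbf_weight[t, n],
                       "dipole_D": self.tbf_dipole[t, n],
                       "donor_charge": self.tbf_donor[t, n],
                       "gap_eV": self.tbf_gap[t, n],
                       "energy_eV": self.tbf_energy[t, n]}
                row.update({f"q{k}": self.tbf_q[t, n, k] for k in range(d)})
                rows.append(row)
        return pd.DataFrame(rows)

    _ARRAYS = ("times", "populations", "norm", "tbf_q", "tbf_p", "tbf_state",
               "tbf_weight", "tbf_dipole", "tbf_donor", "tbf_gap",
               "tbf_energy", "tbf_parent", "tbf_spawn_time")

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            g = fh.create_group("meta")
            g.attrs["json"] = json.dumps(self.meta, default=str)
            g.attrs["truncated"] = self.truncated
            tg = fh.create_group("tbf")
            for name in self._ARRAYS:
                grp = fh if name in ("times", "populations", "norm") else tg
                grp.create_dataset(name, data=getattr(self, name))
            fh.create_group("events").attrs["json"] = json.dumps(
                self.events, default=str)

    @classmethod
    def from_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as fh:
            kw = {}
            for name in cls._ARRAYS:
                grp = fh if name in ("times", "populations", "norm") else fh["tbf"]
                kw[name] = grp[name][...]
            return cls(meta=json.loads(fh["meta"].attrs["json"]),
                       truncated=bool(fh["meta"].attrs["truncated"]),
                       events=json.loads(fh["events"].attrs["json"]), **kw)


def load_archive(path) -> RunArchive:
    return RunArchive.from_hdf5(path)
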