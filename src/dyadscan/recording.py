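"""In-memory containers for single-subject recordings and dyad sessions,
plus columnar (CSV) serialization.

A Recording holds a channels x time voltage matrix in microvolts together
with its montage, sampling rate, a per-sample validity mask on the shared
session timeline, and free-form metadata (subject role, dyad, day,
condition).  A DyadSession pairs the two simultaneously recorded partners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from dyadscan.montage import Montage


@dataclass
class Recording:
    samples: np.ndarray  # (n_channels, n_times), microvolts
    fs: float  # Hz
    montage: Montage
    valid_mask: np.ndarray | None = None  # (n_times,) bool, shared timeline
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.shape[1], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.samples.shape[1],):
                raise ValueError("valid_mask length must equal the time axis")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            valid_mask=self.valid_mask.copy(),
            meta=dict(self.meta),
        )

    # ----------------------------- I/O -------------------------------- #

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_times) / self.fs
        df = pd.DataFrame({"time": t})
        for i, name in enumerate(self.montage.channel_names):
            df[name] = self.samples[i]
        return df

    def write_csv(self, path: str | Path) -> None:
        """Write a columnar trace (time, ch1..chN) plus a JSON sidecar with
        fs, montage and metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6g")
        sidecar = {
            "fs": self.fs,
            "channel_names": list(self.montage.channel_names),
            "region_of": dict(self.montage.region_of),
            "excluded": sorted(self.montage.excluded),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sc = json.loads(sidecar_path.read_text())
            montage = Montage(
                tuple(sc["channel_names"]), sc["region_of"], frozenset(sc["excluded"])
            )
            fs = float(sc["fs"])
            meta = sc.get("meta", {})
        else:
            # infer from the time column; all non-time columns are channels
            chans = [c for c in df.columns if c != "time"]
            fs = 1.0 / float(np.median(np.diff(df["time"].to_numpy())))
            montage = Montage(tuple(chans), {c: "frontal" for c in chans})
            meta = {}
        samples = df[list(montage.channel_names)].to_numpy().T
        return cls(samples=samples, fs=fs, montage=montage, meta=meta)

    @classmethod
    def read_edf(cls, path: str | Path, montage: Montage, meta: dict | None = None) -> "Recording":
        """Read a European Data Format file (requires :mod:`mne`)."""
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data(picks=list(montage.channel_names)) * 1e6  # V -> uV
        return cls(samples=data, fs=float(raw.info["sfreq"]), montage=montage, meta=meta or {})


@dataclass
class DyadSession:
    """One session: the two partners recorded simultaneously."""

    human: Recording
    dog: Recording
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.human.n_times != self.dog.n_times:
            raise ValueError("paired recordings must share the session timeline")
        if self.human.fs != self.dog.fs:
            raise ValueError("paired recordings must share the sampling rate")

    @property
    def fs(self) -> float:
        return self.human.fs

    def subjects(self) -> dict[str, Recording]:
        return {"human": self.human, "dog": self.dog}
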