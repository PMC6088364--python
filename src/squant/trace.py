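"""Voltage-clamp trace container and HDF5/NPZ I/O.

A :class:`Trace` is a uniformly sampled whole-cell current record (pA) with
its sampling rate, holding voltage and any seal-test exclusion windows.
On disk a trace is an HDF5 file with a single ``current_pA`` dataset and
``fs_hz`` / ``v_hold_mV`` / ``seal_test_windows_s`` attributes (an NPZ
variant with the same keys is also supported).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """Sampled current record with acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Membrane current in pA at uniform spacing ``1/fs``.
    fs : float
        Sampling rate in Hz.
    v_hold : float
        Holding voltage in mV (−60 mV for sEPSC, 0 mV for sIPSC recordings).
    exclusion_windows : list of (float, float)
        Seal-test (or other artifact) windows in seconds; excluded from
        event counting and segment sampling.
    """

    samples: np.ndarray
    fs: float
    v_hold: float = 0.0
    exclusion_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.duration
        for lo, hi in self.exclusion_windows:
            if not (0 <= lo < hi <= dur + 1e-9):
                raise ValueError(
                    f"exclusion window ({lo}, {hi}) outside [0, {dur:.3f}] s"
                )

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.samples)) / self.fs

    @property
    def analyzed_duration(self) -> float:
        """Duration in seconds with exclusion windows subtracted."""
        excl = sum(hi - lo for lo, hi in self.exclusion_windows)
        return self.duration - excl

    def in_exclusion(self, t: float | np.ndarray) -> np.ndarray:
        """Boolean mask: does time ``t`` (s) fall inside an exclusion window?"""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.exclusion_windows:
            mask |= (t >= lo) & (t < hi)
        return mask

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | os.PathLike) -> None:
        """Write to HDF5 (``.h5``/``.hdf5``) or NPZ (``.npz``)."""
        path = os.fspath(path)
        windows = np.asarray(self.exclusion_windows, dtype=float).reshape(-1, 2)
        if path.endswith(".npz"):
            np.savez(
                path,
                current_pA=self.samples,
                fs_hz=self.fs,
                v_hold_mV=self.v_hold,
                seal_test_windows_s=windows,
            )
            return
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("current_pA", data=self.samples)
            ds.attrs["fs_hz"] = self.fs
            ds.attrs["v_hold_mV"] = self.v_hold
            ds.attrs["seal_test_windows_s"] = windows

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Trace":
        """Read a trace written by :meth:`save`."""
        path = os.fspath(path)
        if path.endswith(".npz"):
            with np.load(path) as z:
                windows = z["seal_test_windows_s"].reshape(-1, 2)
                return cls(
                    samples=z["current_pA"],
                    fs=float(z["fs_hz"]),
                    v_hold=float(z["v_hold_mV"]),
                    exclusion_windows=[tuple(w) for w in windows],
                )
        with h5py.File(path, "r") as f:
            ds = f["current_pA"]
            windows = np.asarray(ds.attrs.get("seal_test_windows_s", [])).reshape(-1, 2)
            return cls(
                samples=ds[()],
                fs=float(ds.attrs["fs_hz"]),
                v_hold=float(ds.attrs.get("v_hold_mV", 0.0)),
                exclusion_windows=[tuple(w) for w in windows],
            )
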