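"""Band-limited lagged phase synchronization and adjacency construction.

Resting-state source signals are epoched (2-s epochs at 256 Hz by
default), tapered with a Hann window and Fourier-transformed per epoch.
For a channel pair the spectral coefficients are normalized to unit
modulus (phase only) and averaged over epochs into a complex phase
coherency rho(f); the lagged synchronization at frequency f is

    Im(rho)^2 / (1 - Re(rho)^2),

which discards the instantaneous (zero-lag) component and is therefore
robust to volume-conduction-like common signals.  The band value is the
arithmetic mean over the DFT bins inside the band, clipped to [0, 1].
Frequency bands default to delta (1-4 Hz) and theta (4-8 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "BandDefinition",
    "DELTA",
    "THETA",
    "SourceEpochs",
    "ConnectivityMatrix",
    "lagged_phase_synchronization",
    "build_subject_adjacency",
    "group_average_adjacency",
    "write_connectivity_matrix",
    "read_connectivity_matrix",
    "write_source_epochs",
    "read_source_epochs",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError("band must satisfy 0 < f_low < f_high")

    def validate_against(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.f_high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )

    def bins(self, n_samples: int, fs: float) -> np.ndarray:
        """Indices of rFFT bins inside [f_low, f_high]."""
        freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
        idx = np.flatnonzero((freqs >= self.f_low) & (freqs <= self.f_high))
        if idx.size == 0:
            raise ValueError(f"no DFT bins fall inside band {self.name}")
        return idx


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)


@dataclass
class SourceEpochs:
    """Epoched ROI source signals for one subject.

    ``epochs`` has shape (n_rois, n_samples, n_epochs); ``roi_order``
    matches the atlas.
    """

    subject_id: str
    roi_order: list[str]
    epochs: np.ndarray
    fs: float = 256.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D ROI x samples x epoch array")
        if self.epochs.shape[0] != len(self.roi_order):
            raise ValueError("first axis must match roi_order")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal weighted adjacency for one band."""

    band: str
    values: np.ndarray
    roi_order: list[str]
    level: str = "subject"  # "subject" | "group-average"
    subject_id: str | None = None
    n_epochs: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if v.shape[0] != len(self.roi_order):
            raise ValueError("adjacency size must match roi_order")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("adjacency weights must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


# ----------------------------------------------------------------------
# spectral machinery


def _unit_phasors(epochs: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Phase-only rFFT coefficients, shape (..., n_epochs, n_bins).

    Input shape (..., n_samples, n_epochs): samples on the second-to-last
    axis.  A Hann taper is applied per epoch.
    """
    x = np.moveaxis(np.asarray(epochs, float), -1, -2)  # (..., n_epochs, n_samples)
    n_samples = x.shape[-1]
    taper = np.hanning(n_samples)
    spec = np.fft.rfft(x * taper, axis=-1)
    idx = band.bins(n_samples, fs)
    spec = spec[..., idx]
    mag = np.abs(spec)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    return out


def _lps_from_rho(rho: np.ndarray) -> np.ndarray:
    """Im(rho)^2 / (1 - Re(rho)^2) with the degenerate Re = +-1 case -> 0."""
    re = rho.real
    im = rho.imag
    denom = 1.0 - re**2
    out = np.zeros_like(denom)
    ok = denom > 1e-15
    out[ok] = im[ok] ** 2 / denom[ok]
    return out


def lagged_phase_synchronization(
    x: np.ndarray,
    y: np.ndarray,
    band: BandDefinition,
    fs: float = 256.0,
) -> float:
    """Band-mean lagged phase synchronization between two epoched signals.

    ``x`` and ``y`` have shape (n_samples, n_epochs); at least 2 epochs
    are required.  Returns a value in [0, 1].
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("x and y must be 2-D (n_samples, n_epochs) and equal-shaped")
    if x.shape[1] < 2:
        raise ValueError("at least 2 epochs are required")
    band.validate_against(fs)
    ux = _unit_phasors(x, band, fs)
    uy = _unit_phasors(y, band, fs)
    rho = np.mean(ux * np.conj(uy), axis=0)  # per-bin epoch mean
    return float(np.clip(np.mean(_lps_from_rho(rho)), 0.0, 1.0))


def build_subject_adjacency(
    epochs: SourceEpochs, band: BandDefinition
) -> ConnectivityMatrix:
    """All-pairs lagged-phase-synchronization adjacency for one subject."""
    if epochs.n_epochs < 2:
        raise ValueError("at least 2 epochs are required")
    band.validate_against(epochs.fs)
    u = _unit_phasors(epochs.epochs, band, epochs.fs)  # (roi, epoch, bin)
    n_ep = u.shape[1]
    rho = np.einsum("aeb,ceb->acb", u, np.conj(u)) / n_ep
    lps = _lps_from_rho(rho).mean(axis=-1)
    lps = (lps + lps.T) / 2.0
    np.fill_diagonal(lps, 0.0)
    return ConnectivityMatrix(
        band=band.name,
        values=np.clip(lps, 0.0, 1.0),
        roi_order=list(epochs.roi_order),
        level="subject",
        subject_id=epochs.subject_id,
        n_epochs=epochs.n_epochs,
    )


def group_average_adjacency(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean adjacency across subjects of one group."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.band != first.band:
            raise ValueError("mixed bands cannot be averaged")
        if m.roi_order != first.roi_order:
            raise ValueError("mixed ROI orders cannot be averaged")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        band=first.band,
        values=mean,
        roi_order=list(first.roi_order),
        level="group-average",
    )


# ----------------------------------------------------------------------
# plain-text / HDF5 I/O


def write_connectivity_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Write an adjacency as plain text with an ROI-order header + JSON sidecar."""
    path = Path(path)
    header = "roi_order: " + " ".join(matrix.roi_order)
    np.savetxt(path, matrix.values, fmt="%.8f", header=header)
    sidecar = {
        "band": matrix.band,
        "level": matrix.level,
        "subject_id": matrix.subject_id,
        "n_epochs": matrix.n_epochs,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_connectivity_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    roi_order = first.lstrip("# ").strip().removeprefix("roi_order: ").split()
    values = np.loadtxt(path)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(
        band=meta.get("band", "unknown"),
        values=values,
        roi_order=roi_order,
        level=meta.get("level", "subject"),
        subject_id=meta.get("subject_id"),
        n_epochs=meta.get("n_epochs"),
    )


def write_source_epochs(
    path: str | Path, subjects: list[SourceEpochs], band: str = ""
) -> None:
    """HDF5 container: /subjects/<id>/epochs with fs and band attributes."""
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("subjects")
        for s in subjects:
            g = grp.create_group(str(s.subject_id))
            d = g.create_dataset("epochs", data=s.epochs)
            d.attrs["fs"] = s.fs
            d.attrs["band"] = band
            g.create_dataset(
                "roi_order", data=np.array(s.roi_order, dtype=h5py.string_dtype())
            )


def read_source_epochs(path: str | Path) -> list[SourceEpochs]:
    out = []
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh["subjects"]):
            g = fh["subjects"][sid]
            out.append(
                SourceEpochs(
                    subject_id=sid,
                    roi_order=[r.decode() for r in g["roi_order"][()]],
                    epochs=g["epochs"][()],
                    fs=float(g["epochs"].attrs["fs"]),
                )
            )
    return out
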