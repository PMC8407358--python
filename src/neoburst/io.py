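"""EEG input/output and amplitude-based artifact masking.

Recordings are held in memory as an :class:`EEGRecording`: a channels x
samples matrix in microvolts with a shared per-sample artifact mask.
Artifactual sections are *masked*, never excised, so hour-scale periodicity
analysis downstream keeps true timestamps.

EDF (European Data Format) files are read through :func:`mne.io.read_raw_edf`.
Writing uses a minimal EDF writer (16-bit samples, 1-second data records)
implemented here.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical 9-channel neonatal montage (modified 10/20 placement).
DEFAULT_CHANNELS = ["F3", "F4", "C3", "C4", "Cz", "T3", "T4", "O1", "O2"]

#: Amplitude criterion for artifactual EEG, in microvolts.
DEFAULT_ARTIFACT_THRESHOLD_UV = 500.0


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts with a per-sample artifact mask.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in µV.
    channel_labels : list of str
        10/20-system electrode names, one per row of ``signal``.
    sampling_rate : float
        Sampling rate in Hz.
    artifact_mask : ndarray of bool, shape (n_samples,)
        True marks samples excluded from analysis (artifact). Shared across
        channels: an exceedance on any channel masks the sample everywhere.
    start_time : float
        Offset of the first sample in seconds (default 0).
    """

    signal: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows for "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.signal.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.signal.shape[1],):
            raise ValueError("artifact_mask length must equal the sample count")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Total recording span in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def clean_duration(self) -> float:
        """Unmasked (artifact-free) duration in seconds."""
        return float((~self.artifact_mask).sum()) / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording "
                f"(have {self.channel_labels})"
            ) from None

    def copy(self) -> "EEGRecording":
        return replace(
            self,
            signal=self.signal.copy(),
            channel_labels=list(self.channel_labels),
            artifact_mask=self.artifact_mask.copy(),
        )


# ---------------------------------------------------------------------------
# EDF writing (16-bit, 1-second records)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} chars")
    return text.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording to an EDF file.

    Samples are quantised to 16 bits over a symmetric physical range covering
    the data; data records are 1 s long. A trailing partial second is dropped
    with a warning (EDF stores whole records only).
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    if rec.n_samples % fs:
        warnings.warn(
            "dropping trailing partial second when writing EDF", stacklevel=2
        )
    data = rec.signal[:, : n_records * fs]

    # symmetric physical range, integer-rounded so it fits an 8-char field
    phys_max = max(1.0, float(np.ceil(np.abs(data).max()))) if data.size else 1.0
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.clip(np.rint(data * scale), -dig_max, dig_max).astype("<i2")

    ns = rec.n_channels
    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field(now.strftime("%d.%m.%y"), 8),
            _edf_field(now.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    header += b"".join(_edf_field(lab, 16) for lab in rec.channel_labels)
    header += b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_edf_field("uV", 8) for _ in range(ns))
    header += b"".join(_edf_field(int(-phys_max), 8) for _ in range(ns))
    header += b"".join(_edf_field(int(phys_max), 8) for _ in range(ns))
    header += b"".join(_edf_field(-dig_max, 8) for _ in range(ns))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))
    header += b"".join(_edf_field(fs, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 32) for _ in range(ns))

    # records: for each second, all channels back to back
    chunks = digital.reshape(ns, n_records, fs)  # (ch, rec, samp)
    body = np.ascontiguousarray(chunks.transpose(1, 0, 2)).tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)


def read_recording(path, drop_channels: list[str] | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV).

    Parameters
    ----------
    path : path-like
        EDF file with µV-scaled EEG channels.
    drop_channels : list of str, optional
        Channel labels to remove (e.g. ``["Cz"]`` for a channel deleted due
        to poor recording quality). Unknown labels raise ``KeyError``.

    The artifact mask is initialised all-false; apply
    :func:`mask_artifacts` afterwards.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if drop_channels:
        unknown = [c for c in drop_channels if c not in labels]
        if unknown:
            raise KeyError(f"drop_channels not present in file: {unknown}")
        raw.drop_channels(drop_channels)
        labels = list(raw.ch_names)
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("mixed sampling rates are not supported")
    signal_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    return EEGRecording(
        signal=signal_uv,
        channel_labels=labels,
        sampling_rate=float(raw.info["sfreq"]),
    )


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------

def mask_artifacts(
    rec: EEGRecording,
    amplitude_threshold: float = DEFAULT_ARTIFACT_THRESHOLD_UV,
    pad: float = 0.5,
) -> tuple[EEGRecording, float]:
    """Mask samples whose absolute amplitude exceeds the threshold.

    Samples where any channel's absolute value exceeds ``amplitude_threshold``
    (µV), expanded by ``pad`` seconds on each side, are marked in the artifact
    mask. Signal values are untouched: masking, not excision, so the time
    axis is preserved for periodicity analysis.

    Returns
    -------
    (recording, masked_seconds)
        A new recording with the union of the old and new mask, and the total
        masked duration of that recording in seconds.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    if pad < 0:
        raise ValueError("pad must be non-negative")
    exceed = np.any(np.abs(rec.signal) > amplitude_threshold, axis=0)
    if exceed.any() and pad > 0:
        from scipy.ndimage import binary_dilation

        pad_samples = int(round(pad * rec.sampling_rate))
        if pad_samples:
            exceed = binary_dilation(exceed, iterations=pad_samples)
    out = rec.copy()
    out.artifact_mask = rec.artifact_mask | exceed
    masked_seconds = float(out.artifact_mask.sum()) / rec.sampling_rate
    return out, masked_seconds


def mask_to_intervals(rec: EEGRecording) -> pd.DataFrame:
    """Masked stretches as a table with ``onset_s`` / ``offset_s`` columns."""
    mask = rec.artifact_mask
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    fs = rec.sampling_rate
    return pd.DataFrame(
        {
            "onset_s": np.asarray(starts) / fs + rec.start_time,
            "offset_s": np.asarray(stops) / fs + rec.start_time,
        }
    )


def write_mask_intervals(rec: EEGRecording, path) -> None:
    mask_to_intervals(rec).to_csv(path, sep="\t", index=False)
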