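"""Morlet time–frequency characterisation of detected bursts.

Each burst is characterised by convolving the EEG with Morlet wavelets on a
log-spaced 0.2–40 Hz grid, using a cycle count increasing from 3 at 0.2 Hz
to 135 at 40 Hz (linear in log-frequency, matching the log-spaced grid).
Power is expressed in decibels relative to the mean power in the 11 s
preceding burst onset, then averaged over bursts into a grand-average map.

The dB normalisation subtracts the baseline mean of 10*log10(power) per
frequency, so each burst's baseline rows average to exactly 0 dB and any
static gain cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import EEGRecording

FREQ_MIN = 0.2
FREQ_MAX = 40.0
CYCLES_MIN = 3.0
CYCLES_MAX = 135.0


def default_frequencies(n: int = 60) -> np.ndarray:
    """Log-spaced analysis grid over [0.2, 40] Hz."""
    return np.logspace(np.log10(FREQ_MIN), np.log10(FREQ_MAX), n)


def cycles_for(frequencies: np.ndarray) -> np.ndarray:
    """Cycle schedule: linear in log-frequency from 3 to 135 cycles."""
    f = np.asarray(frequencies, dtype=float)
    frac = (np.log(f) - np.log(FREQ_MIN)) / (np.log(FREQ_MAX) - np.log(FREQ_MIN))
    return CYCLES_MIN + (CYCLES_MAX - CYCLES_MIN) * np.clip(frac, 0.0, 1.0)


@dataclass
class TimeFrequencyMap:
    """Grand-average burst-locked power map.

    ``power_db`` is (n_frequencies, n_times) in dB relative to each burst's
    pre-onset baseline; ``times`` are seconds relative to burst onset.
    """

    frequencies: np.ndarray
    times: np.ndarray
    power_db: np.ndarray
    n_bursts_averaged: int
    channel: str
    n_skipped: int = 0


def morlet_power(rec: EEGRecording, channel: str,
                 frequencies: np.ndarray | None = None,
                 cycles: np.ndarray | None = None,
                 decim: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous Morlet power (µV²) of one channel.

    Returns ``(power, times)`` with power of shape (n_frequencies,
    n_times). The wavelet support at the lowest frequencies can reach tens
    of seconds; values within half a wavelet of the recording edges are
    edge-contaminated.
    """
    from mne.time_frequency import tfr_array_morlet

    frequencies = default_frequencies() if frequencies is None else np.asarray(frequencies, float)
    if np.any(np.diff(frequencies) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    nyq = rec.sampling_rate / 2.0
    if frequencies.max() >= nyq:
        raise ValueError(f"frequencies must stay below Nyquist ({nyq} Hz)")
    cycles = cycles_for(frequencies) if cycles is None else np.asarray(cycles, float)
    if np.any(cycles <= 0) or np.any(np.diff(cycles) < 0):
        raise ValueError("cycles must be positive and non-decreasing")
    data = rec.signal[rec.channel_index(channel)][None, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(
            data, sfreq=rec.sampling_rate, freqs=frequencies, n_cycles=cycles,
            output="power", decim=decim, verbose="error",
        )[0, 0]
    times = np.arange(rec.n_samples)[::decim] / rec.sampling_rate + rec.start_time
    return power, times


def max_wavelet_duration(frequencies: np.ndarray, cycles: np.ndarray,
                         sampling_rate: float) -> float:
    """Two-sided (5 sigma) Morlet support in seconds, max over the grid."""
    sigma_t = np.asarray(cycles, float) / (2.0 * np.pi * np.asarray(frequencies, float))
    return float(np.max(10.0 * sigma_t)) + 2.0 / sampling_rate


def burst_tfr(rec: EEGRecording, events, channel: str,
              baseline: float = 11.0, post: float = 4.0,
              frequencies: np.ndarray | None = None,
              decim: int = 4) -> TimeFrequencyMap:
    """Grand-average baseline-relative dB map of bursts at one channel.

    Eligible bursts have the full ``baseline`` seconds of unmasked pre-onset
    data and enough surrounding recording to hold the longest wavelet (the
    epoch is cut symmetrically wider than [-baseline, post] for that reason);
    other bursts are skipped and counted. Per burst, power is converted to
    dB relative to that burst's per-frequency baseline mean (mean of log
    power over [-baseline, 0)), then averaged across bursts.
    """
    from mne.time_frequency import tfr_array_morlet

    frequencies = default_frequencies() if frequencies is None else np.asarray(frequencies, float)
    cycles = cycles_for(frequencies)
    nyq = rec.sampling_rate / 2.0
    if frequencies.max() >= nyq:
        raise ValueError(f"frequencies must stay below Nyquist ({nyq} Hz)")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    fs = rec.sampling_rate
    ci = rec.channel_index(channel)

    # widen the epoch so the longest wavelet fits inside it
    need = max_wavelet_duration(frequencies, cycles, fs)
    margin = max(0.0, (need - (baseline + post)) / 2.0) + 1.0
    pre_span = baseline + margin
    post_span = post + margin

    sub = events[events["channel"] == channel]
    epochs = []
    n_skipped = 0
    for row in sub.itertuples(index=False):
        t_on = row.onset_s - rec.start_time
        i_on = int(round(t_on * fs))
        i0 = i_on - int(round(pre_span * fs))
        i1 = i_on + int(round(post_span * fs))
        ib0 = i_on - int(round(baseline * fs))
        if i0 < 0 or i1 > rec.n_samples:
            n_skipped += 1
            continue
        if rec.artifact_mask[ib0:i_on].any():
            n_skipped += 1
            continue
        epochs.append(rec.signal[ci, i0:i1])
    if not epochs:
        raise ValueError(
            "no eligible bursts: all events lack the required pre-onset "
            "baseline or surrounding data"
        )
    data = np.asarray(epochs)[:, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(
            data, sfreq=fs, freqs=frequencies, n_cycles=cycles,
            output="power", decim=decim, verbose="error",
        )[:, 0]  # (n_bursts, n_freqs, n_times)
    ep_times = (np.arange(data.shape[-1])[::decim] / fs) - pre_span
    keep = (ep_times >= -baseline - 1e-9) & (ep_times <= post + 1e-9)
    base = (ep_times >= -baseline - 1e-9) & (ep_times < 0)
    logp = 10.0 * np.log10(np.maximum(power, np.finfo(float).tiny))
    db = logp - logp[:, :, base].mean(axis=2, keepdims=True)
    grand = db[:, :, keep].mean(axis=0)
    return TimeFrequencyMap(
        frequencies=frequencies,
        times=ep_times[keep],
        power_db=grand,
        n_bursts_averaged=data.shape[0],
        channel=channel,
        n_skipped=n_skipped,
    )


def write_tfr(tfmap: TimeFrequencyMap, matrix_path, header_path=None) -> None:
    """Export the map as a TSV matrix plus a frequency/time header file."""
    import pandas as pd

    df = pd.DataFrame(tfmap.power_db,
                      index=np.round(tfmap.frequencies, 4),
                      columns=np.round(tfmap.times, 4))
    df.index.name = "freq_hz"
    df.to_csv(matrix_path, sep="\t")
    if header_path is not None:
        meta = pd.DataFrame({
            "field": ["channel", "n_bursts_averaged", "n_skipped"],
            "value": [tfmap.channel, tfmap.n_bursts_averaged, tfmap.n_skipped],
        })
        meta.to_csv(header_path, sep="\t", index=False)


def plot_tfr(tfmap: TimeFrequencyMap, path=None, vmax: float | None = None):
    """Quick-look image of the grand-average map (optional PNG export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    vmax = vmax or float(np.abs(tfmap.power_db).max()) or 1.0
    mesh = ax.pcolormesh(tfmap.times, tfmap.frequencies, tfmap.power_db,
                         cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto")
    ax.set_yscale("log")
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("time from burst onset (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"{tfmap.channel}: {tfmap.n_bursts_averaged} bursts")
    fig.colorbar(mesh, ax=ax, label="power (dB re baseline)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
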