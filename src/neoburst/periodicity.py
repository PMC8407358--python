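"""Sleep-cycle periodicity of cortical burst power.

Burst power in the neonatal EEG waxes and wanes with the ultradian sleep
cycle (tracé alternant / rapid-eye-movement alternation). This module bins
detected bursts' normalised power onto a regular time grid, estimates the
dominant spectral period below 3.5 h by discrete Fourier transform of the
mean-removed series, flags estimates from recordings with under 4.5 h of
clean data as unreliable, and computes the per-channel correlation between
each burst's power and the time elapsed since the previous burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_SECONDS_PER_HOUR = 3600.0

#: Upper bound on a plausible sleep-cycle period, hours.
MAX_PERIOD_HOURS = 3.5
#: Minimum clean recording duration for a reliable spectral peak, hours.
MIN_RELIABLE_HOURS = 4.5
#: Parasagittal channel used for the headline series.
DEFAULT_CYCLE_CHANNEL = "C4"


@dataclass
class BurstPowerSeries:
    """Binned mean burst power on a regular grid.

    ``times`` are bin centres in hours; ``values`` are mean normalised burst
    power (µV²) of bursts whose onset falls in the bin, with empty interior
    bins linearly interpolated (``interpolated`` marks them).
    ``clean_duration`` is the artifact-free recording span in hours.
    """

    times: np.ndarray
    values: np.ndarray
    interpolated: np.ndarray
    bin_width: float  # seconds
    channel: str
    clean_duration: float  # hours


@dataclass
class SleepCycleEstimate:
    """Dominant sub-3.5-h period of the burst-power series.

    ``period`` is in hours (None when the spectrum is flat, e.g. a constant
    series); ``amplitude`` is the DFT magnitude at the peak (arbitrary
    units). ``reliable`` is False whenever the clean recording duration is
    below 4.5 h, regardless of the peak.
    """

    period: float | None
    amplitude: float
    reliable: bool
    channel: str


@dataclass
class IntervalPowerCorrelation:
    """Correlation between burst power and time since the previous burst."""

    per_channel_r: dict[str, float]
    mean_r: float
    n_bursts: int


def build_power_series(events: pd.DataFrame, bin_width: float = 60.0,
                       channel: str = DEFAULT_CYCLE_CHANNEL,
                       duration: float | None = None,
                       masked_seconds: float = 0.0) -> BurstPowerSeries:
    """Bin one channel's burst powers onto a regular grid.

    Parameters
    ----------
    events : DataFrame
        Burst table with ``channel, onset_s, normalised_power_uV2``.
    bin_width : float
        Grid step in seconds (default 60 s, resolving periods >= 0.25 h).
    duration : float, optional
        Recording span in seconds; defaults to the last offset on the
        channel.
    masked_seconds : float
        Artifact-masked time, subtracted from the clean duration.
    """
    sub = events[events["channel"] == channel].sort_values("onset_s")
    if len(sub) < 2:
        raise ValueError(f"need >=2 bursts on channel {channel!r}")
    if duration is None:
        duration = float(sub["offset_s"].max())
    n_bins = max(2, int(np.ceil(duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.clip(np.digitize(sub["onset_s"].to_numpy(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=sub["normalised_power_uV2"].to_numpy(),
                       minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=values, where=counts > 0)
    filled = counts > 0
    interpolated = ~filled
    # linear interpolation over empty bins (edges held at nearest value)
    centres = (edges[:-1] + edges[1:]) / 2.0
    values = np.interp(centres, centres[filled], values[filled])
    return BurstPowerSeries(
        times=centres / _SECONDS_PER_HOUR,
        values=values,
        interpolated=interpolated,
        bin_width=bin_width,
        channel=channel,
        clean_duration=max(duration - masked_seconds, 0.0) / _SECONDS_PER_HOUR,
    )


def estimate_cycle(series: BurstPowerSeries,
                   max_period: float = MAX_PERIOD_HOURS,
                   min_reliable_duration: float = MIN_RELIABLE_HOURS) -> SleepCycleEstimate:
    """Dominant spectral period of the burst-power series.

    The mean-removed series is Fourier-transformed (no taper); the
    highest-magnitude bin with period below ``max_period`` hours (and above
    two bin widths, the Nyquist limit of the grid) is the estimate. The
    ``reliable`` flag is False when the clean duration is below
    ``min_reliable_duration`` hours: for such short recordings the identified
    peak is determined almost entirely by recording length.
    """
    x = np.asarray(series.values, float)
    if x.size < 2:
        raise ValueError("series must have at least 2 bins")
    x = x - x.mean()
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=series.bin_width / _SECONDS_PER_HOUR)  # 1/h
    with np.errstate(divide="ignore"):
        periods = 1.0 / freqs
    min_period = 2.0 * series.bin_width / _SECONDS_PER_HOUR
    candidate = (periods < max_period) & (periods > min_period)
    reliable = series.clean_duration >= min_reliable_duration
    if not candidate.any() or np.allclose(mags[candidate], 0.0):
        return SleepCycleEstimate(period=None, amplitude=0.0, reliable=False,
                                  channel=series.channel)
    k = np.flatnonzero(candidate)[np.argmax(mags[candidate])]
    return SleepCycleEstimate(
        period=float(periods[k]),
        amplitude=float(mags[k]),
        reliable=bool(reliable),
        channel=series.channel,
    )


def cycle_reliability_check(estimates: list[SleepCycleEstimate],
                            durations: list[float],
                            masked_fractions: list[float],
                            alpha: float = 0.05) -> pd.DataFrame:
    """Test whether cycle estimates depend on duration or artifact load.

    For a set of recordings, correlates estimated period and amplitude
    against recording duration (hours) and masked fraction; a dependence is
    flagged at p < alpha. A trustworthy estimator shows no dependence when
    the planted period is common across recordings.
    """
    if len(estimates) < 3:
        raise ValueError("need at least 3 recordings")
    if not len(estimates) == len(durations) == len(masked_fractions):
        raise ValueError("inputs must have equal length")
    period = np.array([np.nan if e.period is None else e.period for e in estimates])
    amplitude = np.array([e.amplitude for e in estimates])
    rows = []
    for qname, q in [("period", period), ("amplitude", amplitude)]:
        for cname, c in [("duration", np.asarray(durations, float)),
                         ("masked_fraction", np.asarray(masked_fractions, float))]:
            ok = np.isfinite(q) & np.isfinite(c)

            def _flat(a):  # numerically constant input
                return a.std() <= 1e-12 * max(1.0, np.abs(a).max())

            if ok.sum() < 3 or _flat(q[ok]) or _flat(c[ok]):
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(q[ok], c[ok])
            rows.append((qname, cname, r, p, bool(np.isfinite(p) and p < alpha)))
    return pd.DataFrame(rows, columns=["quantity", "against", "r", "p", "dependent"])


def interval_power_correlation(events: pd.DataFrame,
                               mask_intervals: pd.DataFrame | None = None,
                               gap: str = "onset_to_previous_offset",
                               min_events: int = 3) -> IntervalPowerCorrelation:
    """Correlate each burst's power with the time since the previous burst.

    Per channel, the Pearson correlation between normalised power and the
    preceding inter-burst gap (onset minus previous offset by default;
    ``gap="onset_to_onset"`` for onset-to-onset intervals). The first burst
    of each channel, and pairs whose gap spans a masked interval, are
    excluded. The headline number is the mean of the per-channel
    coefficients.
    """
    if gap not in ("onset_to_previous_offset", "onset_to_onset"):
        raise ValueError(f"unknown gap definition {gap!r}")
    per_channel: dict[str, float] = {}
    n_used = 0
    for ch, sub in events.groupby("channel"):
        sub = sub.sort_values("onset_s")
        if len(sub) < min_events:
            continue
        onsets = sub["onset_s"].to_numpy()
        offsets = sub["offset_s"].to_numpy()
        power = sub["normalised_power_uV2"].to_numpy()
        if gap == "onset_to_previous_offset":
            gaps = onsets[1:] - offsets[:-1]
        else:
            gaps = np.diff(onsets)
        p = power[1:]
        keep = np.ones(gaps.size, dtype=bool)
        if mask_intervals is not None and len(mask_intervals):
            for m in mask_intervals.itertuples(index=False):
                keep &= ~((offsets[:-1] < m.offset_s) & (onsets[1:] > m.onset_s))
        if keep.sum() < min_events or gaps[keep].std() == 0 or p[keep].std() == 0:
            continue
        r, _ = stats.pearsonr(gaps[keep], p[keep])
        per_channel[ch] = float(r)
        n_used += int(keep.sum())
    if not per_channel:
        raise ValueError("no channel with enough bursts for a correlation")
    return IntervalPowerCorrelation(
        per_channel_r=per_channel,
        mean_r=float(np.mean(list(per_channel.values()))),
        n_bursts=n_used,
    )
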