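"""Up-state detection and ISI-shuffled surrogates for spike-time data.

Cultured-slice recordings alternate between active (up) and silent (down)
epochs at ~0.1 Hz.  Up-states are detected from the population firing
rate binned at 10 ms and smoothed with a 100-ms square kernel: maximal
runs above 30% of the maximum of the filtered series lasting at least 1 s.
Surrogate rasters shuffle each neuron's ISIs within each up-state, which
destroys the temporal correlation structure of avalanches while
preserving per-neuron spike counts and ISI multisets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster
from .spikestats import spike_count_series, square_filter

__all__ = ["UpStateSegments", "detect_up_states", "shuffle_isi"]


@dataclass
class UpStateSegments:
    intervals: list             # [(start_ms, end_ms), ...], disjoint, sorted
    dt: float = 10.0
    kernel_T: float = 100.0
    threshold_fraction: float = 0.3
    min_duration: float = 1000.0

    def __len__(self) -> int:
        return len(self.intervals)

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def contains(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.intervals)


def detect_up_states(raster: SpikeRaster, dt: float = 10.0,
                     kernel_T: float = 100.0,
                     threshold_fraction: float = 0.3,
                     min_duration: float = 1000.0,
                     threshold_on: str = "filtered") -> UpStateSegments:
    """Detect up-states as supra-threshold runs of the smoothed population
    rate.  The threshold is ``threshold_fraction`` times the maximum of
    the filtered series (``threshold_on="raw"`` switches to the unfiltered
    maximum).  Returned intervals are in ms, each >= ``min_duration``."""
    if raster.n_spikes == 0:
        raise ValueError("empty raster")
    series = spike_count_series(raster, dt, exclude_discard=False)
    filt = square_filter(series, kernel_T)
    ref = filt.counts if threshold_on == "filtered" else series.counts
    thresh = threshold_fraction * ref.max()
    above = filt.counts > thresh
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above.size and above[0]:
        starts = np.r_[0, starts]
    if above.size and above[-1]:
        ends = np.r_[ends, above.size]
    t0 = raster.t_start
    intervals = []
    for s, e in zip(starts, ends):
        dur = (e - s) * dt
        if dur >= min_duration:
            intervals.append((t0 + s * dt, t0 + e * dt))
    return UpStateSegments(intervals, dt=dt, kernel_T=kernel_T,
                           threshold_fraction=threshold_fraction,
                           min_duration=min_duration)


def shuffle_isi(raster: SpikeRaster, segments: UpStateSegments,
                seed: int = 0) -> SpikeRaster:
    """Per neuron and per up-state segment, permute the ISIs uniformly at
    random with the first spike anchored: spike counts and the
    segment-local first/last spike times are preserved.  Neurons with <= 2
    spikes in a segment are left unchanged."""
    rng = np.random.default_rng(seed)
    times = raster.times.copy()
    ids = raster.ids
    for (s, e) in segments.intervals:
        in_seg = (times >= s) & (times < e)
        seg_ids = ids[in_seg]
        seg_times = times[in_seg]
        new_times = seg_times.copy()
        for nid in np.unique(seg_ids):
            sel = seg_ids == nid
            tt = np.sort(seg_times[sel])
            if tt.size <= 2:
                continue
            isis = np.diff(tt)
            rng.shuffle(isis)
            new_times[sel] = tt[0] + np.r_[0.0, np.cumsum(isis)]
        times[in_seg] = new_times
    return SpikeRaster(times, ids.copy(), raster.population,
                       t_start=raster.t_start, t_end=raster.t_end,
                       discard=raster.discard,
                       meta={**raster.meta, "surrogate": "isi-shuffled"})
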