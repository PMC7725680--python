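"""Spike-train and voltage statistics.

Count series, CV of ISI, Fano factors, pairwise Pearson correlation,
voltage coherence, population-rate CV, Welch power spectra with power-law
decay fits, and pooled voltage-distribution moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .raster import SpikeRaster, VoltageTrace

__all__ = [
    "CountSeries", "PSDResult",
    "spike_count_series", "square_filter",
    "cv_isi", "population_mean_cv_isi", "fano_factor",
    "mean_pairwise_pcc", "voltage_coherence", "population_rate_cv",
    "rate_psd", "voltage_moments",
]


@dataclass
class CountSeries:
    counts: np.ndarray          # per-window counts (ints raw, reals filtered)
    dt: float                   # window, ms
    scope: str = "population"   # "population" or "neuron"
    n_units: int = 1            # neurons contributing (for the rate view)
    kernel_T: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)

    @property
    def rate_per_ms(self) -> np.ndarray:
        """q(t) = N(t) / (n_units * dt), the population-averaged rate."""
        return self.counts / (self.n_units * self.dt)

    @property
    def rate_hz(self) -> np.ndarray:
        return self.rate_per_ms * 1000.0

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass
class PSDResult:
    freq_hz: np.ndarray
    power: np.ndarray
    peak_freq_hz: float
    beta: float | None
    fit_range_hz: tuple | None


def spike_count_series(raster: SpikeRaster, dt: float,
                       scope: str = "population",
                       population: str | None = None,
                       neuron: int | None = None,
                       exclude_discard: bool = True) -> CountSeries:
    """Bin spikes into consecutive half-open windows [k dt, (k+1) dt).

    ``scope="population"`` sums spikes of all (or one population's)
    neurons; ``scope="neuron"`` requires ``neuron`` and counts its spikes.
    An empty raster yields an all-zero series.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sub = raster.select(population, exclude_discard)
    span = sub.t_end - sub.t_start
    n_bins = int(np.floor(span / dt))
    if scope == "neuron":
        if neuron is None:
            raise ValueError("scope='neuron' requires a neuron id")
        times = sub.spike_times_of(neuron)
        n_units = 1
    elif scope == "population":
        times = sub.times
        n_units = sub.neuron_ids(population).size
    else:
        raise ValueError("scope must be 'population' or 'neuron'")
    idx = np.floor((times - sub.t_start) / dt).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return CountSeries(counts, dt=dt, scope=scope, n_units=max(n_units, 1))


def square_filter(series: CountSeries, T: float) -> CountSeries:
    """Trailing moving average with a square kernel of length T (support
    [-T, 0]): the filtered value at bin t averages bins t-T/dt+1 .. t."""
    if T < series.dt:
        raise ValueError("kernel length T must be >= the bin width")
    w = int(round(T / series.dt))
    if abs(w * series.dt - T) > 1e-9 * T:
        raise ValueError("T must be a multiple of the bin width")
    # trailing alignment: y[t] = mean(x[t-w+1 .. t])
    kernel = np.full(w, 1.0 / w)
    filt = np.convolve(series.counts.astype(float), kernel)[:len(series)]
    return CountSeries(filt, dt=series.dt, scope=series.scope,
                       n_units=series.n_units, kernel_T=T)


def _isis(raster: SpikeRaster, neuron: int) -> np.ndarray:
    return np.diff(raster.spike_times_of(neuron))


def cv_isi(raster: SpikeRaster, neuron: int,
           exclude_discard: bool = True) -> float | None:
    """SD/mean of the neuron's inter-spike intervals; ``None`` (flagged,
    excluded from population averages) when it has fewer than 3 spikes."""
    sub = raster.select(None, exclude_discard)
    isis = _isis(sub, neuron)
    if isis.size < 2:
        return None
    m = isis.mean()
    return float(isis.std() / m)


def population_mean_cv_isi(raster: SpikeRaster, population: str = "E",
                           exclude_discard: bool = True) -> float:
    """CV of ISI averaged over the population's neurons with >= 3 spikes."""
    sub = raster.select(population, exclude_discard)
    order = np.argsort(sub.ids, kind="stable")
    ids = sub.ids[order]
    times = sub.times[order]
    cvs = []
    for nid, lo, count in zip(*_runs(ids)):
        if count < 3:
            continue
        tt = np.sort(times[lo:lo + count])
        isis = np.diff(tt)
        m = isis.mean()
        if m > 0:
            cvs.append(isis.std() / m)
    if not cvs:
        raise ValueError("no neuron has >= 3 spikes")
    return float(np.mean(cvs))


def _runs(sorted_ids: np.ndarray):
    """(unique ids, start offsets, run lengths) of a sorted id array."""
    uniq, start, count = np.unique(sorted_ids, return_index=True,
                                   return_counts=True)
    return uniq, start, count


def fano_factor(series: CountSeries) -> float:
    """var/mean of the count series (windowed, default window 50 ms at the
    call sites that follow the reference analysis)."""
    m = series.counts.mean()
    if m <= 0:
        raise ValueError("zero mean count: Fano factor undefined")
    return float(series.counts.var() / m)


def mean_pairwise_pcc(raster: SpikeRaster, dt: float = 1.0, T: float = 50.0,
                      population: str = "E", max_pair_neurons: int = 150,
                      seed: int = 0, exclude_discard: bool = True) -> float:
    """Mean Pearson correlation of square-filtered 1-ms count series over
    excitatory neuron pairs.

    All pairs are used when the population has <= ``max_pair_neurons``
    neurons; otherwise a seed-controlled random subset of
    ``max_pair_neurons`` neurons is sampled and all of their ~10^4 pairs
    are averaged.  Zero-variance neurons are excluded.
    """
    sub = raster.select(population, exclude_discard)
    ids_all = sub.neuron_ids(population)
    if ids_all.size > max_pair_neurons:
        rng = np.random.default_rng(seed)
        ids_all = np.sort(rng.choice(ids_all, size=max_pair_neurons,
                                     replace=False))
    span = sub.t_end - sub.t_start
    n_bins = int(np.floor(span / dt))
    w = int(round(T / dt))
    kernel = np.full(w, 1.0 / w)
    rows = []
    for nid in ids_all:
        tt = sub.spike_times_of(int(nid))
        idx = np.floor((tt - sub.t_start) / dt).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        c = np.bincount(idx, minlength=n_bins).astype(float)
        rows.append(np.convolve(c, kernel)[:n_bins])
    X = np.array(rows)
    var = X.var(axis=1)
    X = X[var > 0]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 neurons with nonzero variance")
    C = np.corrcoef(X)
    iu = np.triu_indices(C.shape[0], k=1)
    return float(C[iu].mean())


def voltage_coherence(trace: VoltageTrace, population: str = "E",
                      exclude_discard: bool = True) -> float:
    """Temporal variance of the population-mean voltage divided by the mean
    over neurons of the individual temporal variances — in (0, 1], 1 for
    identical traces, ~1/N for independent ones."""
    sub = trace.select(population, exclude_discard)
    if sub.values.shape[0] < 2:
        raise ValueError("need >= 2 recorded neurons")
    indiv = sub.values.var(axis=1)
    if np.any(indiv == 0):
        sub_vals = sub.values[indiv > 0]
        if sub_vals.shape[0] < 2:
            raise ValueError("zero-variance traces")
        indiv = indiv[indiv > 0]
        mean_trace = sub_vals.mean(axis=0)
    else:
        mean_trace = sub.values.mean(axis=0)
    denom = indiv.mean()
    if denom == 0:
        raise ValueError("zero variance")
    return float(mean_trace.var() / denom)


def population_rate_cv(raster: SpikeRaster, dt: float = 1.0,
                       population: str = "E",
                       exclude_discard: bool = True) -> float:
    """CV of the 1-ms population firing-rate series — short-timescale
    population variability; ~1/sqrt(n r dt) for asynchronous Poisson."""
    series = spike_count_series(raster, dt, population=population,
                                exclude_discard=exclude_discard)
    q = series.rate_per_ms
    m = q.mean()
    if m <= 0:
        raise ValueError("zero mean rate")
    return float(q.std() / m)


def rate_psd(series: CountSeries, segment_ms: float = 1000.0,
             peak_min_hz: float = 10.0,
             beta_range_hz: tuple | None = None,
             beta_range_factor: float = 1.5,
             beta_max_hz: float = 1000.0) -> PSDResult:
    """Welch PSD of a rate series (Hann segments of ``segment_ms``, 50%
    overlap, mean detrended).  Peak frequency is the argmax above
    ``peak_min_hz``; the decay exponent beta is a least-squares slope of
    log P vs log f over [beta_range_factor * peak, beta_max_hz] (or an
    explicit ``beta_range_hz``)."""
    fs = 1000.0 / series.dt  # Hz
    x = series.rate_per_ms * 1000.0
    nperseg = int(round(segment_ms / series.dt))
    if x.size < 2 * nperseg:
        raise ValueError("series too short for Welch segmentation "
                         f"(need >= {2 * nperseg} bins, got {x.size})")
    f, p = signal.welch(x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend="constant")
    above = f >= peak_min_hz
    peak = float(f[above][np.argmax(p[above])])
    if beta_range_hz is None:
        beta_range_hz = (beta_range_factor * peak, min(beta_max_hz, f[-1]))
    lo, hi = beta_range_hz
    sel = (f >= lo) & (f <= hi) & (p > 0)
    beta = None
    if sel.sum() >= 4:
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]
        beta = float(-slope)
    return PSDResult(f, p, peak, beta, (float(lo), float(hi)))


def voltage_moments(trace: VoltageTrace, population: str | None = None,
                    exclude_discard: bool = True) -> tuple[float, float]:
    """(skewness, kurtosis) of the pooled (neurons x 1-ms samples) membrane
    potential distribution; (0, 3) for Gaussian samples."""
    sub = trace.select(population, exclude_discard)
    x = sub.values.ravel()
    if x.size < 1000:
        raise ValueError("need >= 1000 pooled samples")
    if x.std() == 0:
        raise ValueError("zero variance")
    return (float(stats.skew(x)), float(stats.kurtosis(x, fisher=False)))
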