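"""Detection of synaptic transmission events and input barrages.

Two signal streams are analysed:

* per-ROI ΔF fluorescence traces (5–15 Hz), in which a synaptic calcium
  transient appears as a multi-frame fluorescence increase.  An event must
  exceed twice the trace's noise level for at least two consecutive frames.
* the somatic current trace (10 kHz, voltage clamp, inward negative), in
  which a barrage of synaptic inputs appears as a compound inward current of
  at least 10 pA; barrages closer than 3 s are merged into one episode.

Charges are reported in pC (pA · s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RoiTrace",
    "CurrentTrace",
    "TransmissionEvent",
    "Barrage",
    "BarrageConfig",
    "estimate_noise",
    "detect_events",
    "detect_barrages",
    "barrage_charge",
    "associate_events",
    "zscore_amplitudes",
    "geometric_bins",
]


@dataclass
class RoiTrace:
    roi_id: str
    times: np.ndarray  # frame times, s, strictly increasing
    values: np.ndarray  # ΔF, arbitrary fluorescence units
    recording_id: str = "r0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")


@dataclass
class CurrentTrace:
    times: np.ndarray  # s, uniform sampling (nominally 10 kHz)
    values: np.ndarray  # pA, inward negative
    recording_id: str = "r0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class TransmissionEvent:
    synapse_id: str
    recording_id: str
    onset: float  # s, time of first supra-threshold frame
    duration_frames: int
    amplitude: float  # peak ΔF above baseline
    z_amplitude: float | None = None  # per-synapse z-score, filled later
    barrage_id: str | None = None


@dataclass
class Barrage:
    barrage_id: str
    recording_id: str
    onset: float
    offset: float
    charge_pC: float
    peak_pA: float
    n_events: int = 0

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BarrageConfig:
    """Detection thresholds for somatic barrages.

    min_peak_pA: minimum peak inward deflection for a barrage (10 pA).
    min_gap_s: deflections separated by less than this merge into one (3 s).
    edge_fraction: onset/offset taken at this fraction of the peak deflection.
    baseline_window_s / baseline_percentile: running-percentile baseline.
    """

    min_peak_pA: float = 10.0
    min_gap_s: float = 3.0
    edge_fraction: float = 0.10
    baseline_window_s: float = 10.0
    baseline_percentile: float = 20.0
    smooth_s: float = 0.05  # envelope smoothing; a barrage is a compound
    # current, so single EPSC-scale blips must not trigger detection
    dip_tolerance_s: float = 0.6  # envelope may dip below the edge level
    # this long inside one barrage without ending its window


def estimate_noise(trace: RoiTrace) -> float:
    """Noise σ of a ΔF trace, robust to sparse transients.

    Uses 1.4826 × MAD of the first differences, scaled by 1/√2 (differencing
    white noise inflates σ by √2).  Differencing removes slow baseline drift
    and transients contribute to only a small fraction of the differences, so
    the median absolute deviation is unaffected by them.
    """
    x = np.asarray(trace.values, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 frames to estimate noise")
    d = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    if sigma == 0:
        warnings.warn(
            f"ROI {trace.roi_id}: degenerate (constant) trace, noise σ = 0",
            stacklevel=2,
        )
    return float(sigma)


def detect_events(
    trace: RoiTrace,
    noise: float,
    synapse_id: str | None = None,
    accept_mask: np.ndarray | None = None,
    threshold_sigma: float = 2.0,
    min_frames: int = 2,
) -> list[TransmissionEvent]:
    """Detect calcium transients: runs of ≥ ``min_frames`` consecutive frames
    with ΔF at least ``threshold_sigma`` × σ above the trace baseline
    (median ΔF).

    ``accept_mask``, if given, is a per-frame boolean curation hook: frames
    marked False cannot belong to an event (emulates manual review, e.g.
    movement rejection).
    """
    if noise <= 0:
        raise ValueError("noise σ must be positive")
    x = trace.values
    baseline = float(np.median(x))
    supra = x >= baseline + threshold_sigma * noise
    if accept_mask is not None:
        supra = supra & np.asarray(accept_mask, dtype=bool)
    events: list[TransmissionEvent] = []
    sid = synapse_id if synapse_id is not None else trace.roi_id
    n = len(x)
    i = 0
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1]:
            j += 1
        if j - i + 1 >= min_frames:  # reject too-short excursions
            peak = float(np.max(x[i : j + 1]) - baseline)
            events.append(
                TransmissionEvent(
                    synapse_id=sid,
                    recording_id=trace.recording_id,
                    onset=float(trace.times[i]),
                    duration_frames=j - i + 1,
                    amplitude=peak,
                )
            )
        i = j + 1
    return events


def _running_percentile(x: np.ndarray, fs: float, window_s: float, q: float) -> np.ndarray:
    """Blockwise running percentile, linearly interpolated back to full
    resolution.  Adequate as a slow baseline for 10 kHz current traces."""
    block = max(1, int(round(window_s * fs)))
    nblocks = max(1, len(x) // block)
    centers = []
    vals = []
    for b in range(nblocks):
        seg = x[b * block : (b + 1) * block if b < nblocks - 1 else len(x)]
        centers.append(b * block + len(seg) / 2.0)
        vals.append(np.percentile(seg, q))
    if len(vals) == 1:
        return np.full_like(x, vals[0])
    return np.interp(np.arange(len(x)), centers, vals)


def detect_barrages(
    trace: CurrentTrace, config: BarrageConfig | None = None
) -> list[Barrage]:
    """Detect barrages of synaptic currents in the somatic trace.

    A barrage is a compound inward deflection whose peak exceeds 10 pA below
    baseline; its window extends to the crossings at ``edge_fraction`` of the
    peak, and windows separated by less than 3 s are merged (then re-tested
    against the peak criterion).  Returned barrages are time-ordered.
    """
    cfg = config or BarrageConfig()
    fs = trace.fs
    baseline = _running_percentile(
        -np.asarray(trace.values, float), fs, cfg.baseline_window_s,
        100.0 - cfg.baseline_percentile,
    )
    # work with the inward deflection as a positive signal; threshold and
    # window edges operate on a smoothed envelope
    raw_deflection = -np.asarray(trace.values, float) - baseline
    if cfg.smooth_s > 0:
        from scipy.ndimage import uniform_filter1d

        deflection = uniform_filter1d(
            raw_deflection, max(1, int(round(cfg.smooth_s * fs)))
        )
    else:
        deflection = raw_deflection
    supra = deflection >= cfg.min_peak_pA
    if not supra.any():
        return []
    # candidate regions: contiguous supra-threshold runs
    d = np.flatnonzero(np.diff(np.r_[0, supra.astype(np.int8), 0]))
    starts, stops = list(d[::2]), list(d[1::2] - 1)
    # expand each region to the edge_fraction crossings of its peak,
    # tolerating brief dips of the envelope inside the barrage
    dip_n = max(1, int(round(cfg.dip_tolerance_s * fs)))
    regions = []
    for s, e in zip(starts, stops):
        peak = deflection[s : e + 1].max()
        lo = cfg.edge_fraction * peak
        i, k, gap = s, s, 0
        while k > 0 and gap <= dip_n:
            k -= 1
            if deflection[k] >= lo:
                i, gap = k, 0
            else:
                gap += 1
        j, k, gap = e, e, 0
        while k + 1 < len(deflection) and gap <= dip_n:
            k += 1
            if deflection[k] >= lo:
                j, gap = k, 0
            else:
                gap += 1
        regions.append([i, j])
    # merge overlapping or near (< min_gap_s) regions
    merged: list[list[int]] = []
    gap_n = cfg.min_gap_s * fs
    for r in sorted(regions):
        if merged and r[0] - merged[-1][1] < gap_n:
            merged[-1][1] = max(merged[-1][1], r[1])
        else:
            merged.append(list(r))
    out = []
    t = trace.times
    for k, (i, j) in enumerate(merged):
        peak = float(deflection[i : j + 1].max())
        if peak < cfg.min_peak_pA:
            continue
        b = Barrage(
            barrage_id=f"{trace.recording_id}_b{k}",
            recording_id=trace.recording_id,
            onset=float(t[i]),
            offset=float(t[j]),
            charge_pC=0.0,
            peak_pA=peak,
        )
        b.charge_pC = barrage_charge(trace, b, baseline=-baseline)
        out.append(b)
    return out


def barrage_charge(
    trace: CurrentTrace, barrage: Barrage, baseline: np.ndarray | float | None = None
) -> float:
    """Charge transferred during a barrage window: Q = ∫ (baseline − I) dt,
    in pC.  Positive for net-inward windows."""
    t = trace.times
    if barrage.onset < t[0] - 1e-9 or barrage.offset > t[-1] + 1e-9:
        raise ValueError("barrage window outside trace")
    sel = (t >= barrage.onset) & (t <= barrage.offset)
    if baseline is None:
        base = np.median(trace.values)
    elif np.isscalar(baseline):
        base = baseline
    else:
        base = np.asarray(baseline)[sel]
    q = np.trapezoid(base - trace.values[sel], t[sel])
    return float(q)


def associate_events(
    events: list[TransmissionEvent],
    barrages: list[Barrage],
    tolerance: float = 0.2,
) -> list[TransmissionEvent]:
    """Assign each event to at most one barrage of the same recording.

    An event belongs to a barrage if its onset lies within
    [barrage onset − tolerance, barrage offset + tolerance].  If several
    windows qualify, the barrage with the nearest onset wins; exact ties go
    to the earlier barrage.  Barrage ``n_events`` counters are updated.
    """
    for b in barrages:
        b.n_events = 0
    by_rec: dict[str, list[Barrage]] = {}
    for b in barrages:
        by_rec.setdefault(b.recording_id, []).append(b)
    out = []
    for ev in events:
        candidates = [
            b
            for b in by_rec.get(ev.recording_id, [])
            if b.onset - tolerance <= ev.onset <= b.offset + tolerance
        ]
        if candidates:
            best = min(candidates, key=lambda b: (abs(b.onset - ev.onset), b.onset))
            best.n_events += 1
            out.append(replace(ev, barrage_id=best.barrage_id))
        else:
            out.append(replace(ev, barrage_id=None))
    return out


def zscore_amplitudes(events: list[TransmissionEvent]) -> list[TransmissionEvent]:
    """Fill z_amplitude: each synapse's event amplitudes z-scored across all
    of that synapse's events (sample SD).  Synapses with a single event, or
    with zero amplitude spread, get z = 0."""
    by_syn: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_syn.setdefault(ev.synapse_id, []).append(i)
    out = list(events)
    for idxs in by_syn.values():
        amps = np.array([events[i].amplitude for i in idxs], dtype=float)
        if len(amps) >= 2 and np.std(amps, ddof=1) > 0:
            z = (amps - amps.mean()) / np.std(amps, ddof=1)
        else:
            z = np.zeros_like(amps)
        for i, zi in zip(idxs, z):
            out[i] = replace(out[i], z_amplitude=float(zi))
    return out


def geometric_bins(
    values, factor: float = 2.0, origin: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Geometric binning: half-open bins [origin·factor^k, origin·factor^(k+1)).

    Returns (edges, per-bin means); empty bins hold NaN.  Used to summarise
    right-skewed quantities such as barrage charges.
    """
    v = np.asarray(values, dtype=float)
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    if origin is None:
        origin = v.min()
    nbins = max(1, int(np.ceil(np.log(v.max() / origin) / np.log(factor))))
    edges = origin * factor ** np.arange(nbins + 1)
    if edges[-1] <= v.max():  # top value must fall inside the last bin
        edges = np.append(edges, edges[-1] * factor)
    idx = np.digitize(v, edges) - 1
    means = np.array(
        [v[idx == k].mean() if np.any(idx == k) else np.nan
         for k in range(len(edges) - 1)]
    )
    return edges, means
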