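"""ERP analysis chain: filter, re-reference, epoch, baseline, reject,
average, motor-correct, collapsed-localizer windows, windowed means.

The chain order is fixed — filter → rereference → extract_epochs →
baseline_correct → reject_epochs → drop_initial → average_erp →
motor_correct → collapsed_localizer → mean_amplitude — because the
rejection criterion operates on baseline-corrected voltages and the
localizer must see the cleaned averages. Time windows are half-open
[start, end) on the sampling grid; all voltages are μV.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as spsig

from .containers import ComponentMeasure, ComponentWindow, EpochSet, Waveform

N1_POOL = ["Fz", "FCz", "Cz"]
P2_POOL = ["FCz", "Cz", "CPz"]
# localizer search ranges are analysis choices (defaults, not reported values)
DEFAULT_SEARCH_MS = {"N1": (50.0, 150.0), "P2": (120.0, 220.0)}


def filter_continuous(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.1, 30.0),
    notch_hz: float | None = 50.0,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Zero-phase band-pass plus mains notch on channels × samples data.

    Band-pass: order-1 Butterworth per edge (6 dB/octave one-pass) run
    forward and backward (sosfiltfilt), giving a 12 dB/octave asymptotic
    roll-off and zero phase distortion. Notch: second-order IIR at
    ``notch_hz``, also bidirectional. The contract is attenuation:
    in-band sinusoids pass essentially unchanged, DC and mains are
    removed.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    lo, hi = band
    if fs <= 2.0 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for a {hi} Hz band edge")
    sos = spsig.butter(1, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = spsig.sosfiltfilt(sos, x, axis=-1)
    if notch_hz is not None:
        b, a = spsig.iirnotch(notch_hz, notch_q, fs=fs)
        y = spsig.filtfilt(b, a, y, axis=-1)
    return y


def rereference(data: np.ndarray, channel_labels: list[str],
                reference_labels: list[str]) -> np.ndarray:
    """Subtract the per-sample mean of the reference channels (e.g. mastoids)."""
    missing = [r for r in reference_labels if r not in channel_labels]
    if missing:
        raise ValueError(f"reference channels not found: {missing}")
    x = np.asarray(data, dtype=float)
    idx = [channel_labels.index(r) for r in reference_labels]
    ref = x[idx].mean(axis=0)
    return x - ref[None, :]


def extract_epochs(
    data: np.ndarray,
    fs: float,
    event_times_s,
    channel_labels: list[str],
    window_ms: tuple[float, float] = (-200.0, 400.0),
    production: str = "AV",
    soa: float = 0.8,
    participant_id: str = "rec",
) -> EpochSet:
    """Cut [start, end) ms epochs around each event from a continuous record.

    The epoch length is round(span · fs) samples. Events whose window
    falls outside the recording are dropped; the number of dropped events
    is logged in ``meta['n_dropped_events']``. MA/MO epochs carry the
    keypress marker at −100 ms (the tone follows the keypress by 100 ms).
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n_samples_total = x.shape[1]
    t0, t1 = window_ms
    n_samp = int(round((t1 - t0) / 1000.0 * fs))
    kept, dropped = [], 0
    for ev in event_times_s:
        start = int(round((ev + t0 / 1000.0) * fs))
        if start < 0 or start + n_samp > n_samples_total:
            dropped += 1
            continue
        kept.append(x[:, start : start + n_samp])
    if not kept:
        raise ValueError("no events yielded a complete epoch")
    meta: dict = {"n_dropped_events": dropped}
    if production in ("MA", "MO"):
        meta["keypress_ms"] = -100.0
    return EpochSet(
        data=np.stack(kept), fs=fs, t0_offset_ms=t0,
        channel_labels=list(channel_labels),
        production=production, soa=soa, participant_id=participant_id,
        meta=meta,
    )


def preprocess_continuous(
    data: np.ndarray,
    fs: float,
    event_times_s,
    channel_labels: list[str],
    reference_labels: list[str] | None = None,
    band: tuple[float, float] = (0.1, 30.0),
    notch_hz: float | None = 50.0,
    **epoch_kwargs,
) -> EpochSet:
    """Continuous-record front end: filter → rereference → extract_epochs."""
    y = filter_continuous(data, fs, band=band, notch_hz=notch_hz)
    if reference_labels:
        y = rereference(y, channel_labels, reference_labels)
    return extract_epochs(y, fs, event_times_s, channel_labels, **epoch_kwargs)


def _window_slice(times_ms: np.ndarray, start_ms: float, end_ms: float) -> np.ndarray:
    return (times_ms >= start_ms) & (times_ms < end_ms)


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = _window_slice(epochs.times_ms, *window_ms)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - base, baseline_ms=window_ms)


def reject_epochs(epochs: EpochSet,
                  threshold_uv: float = 200.0) -> tuple[EpochSet, int]:
    """Drop epochs whose peak-to-peak range on any channel exceeds threshold.

    "Exceeds" is strict: an epoch with a range of exactly the threshold
    is retained.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be > 0")
    ptp = np.ptp(epochs.data, axis=2)  # epochs × channels
    bad = np.any(ptp > threshold_uv, axis=1)
    n_rejected = int(bad.sum())
    if n_rejected == epochs.n_epochs:
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed {threshold_uv} μV peak-to-peak "
            f"(max range {ptp.max():.1f} μV)"
        )
    kept = epochs.copy_with(epochs.data[~bad], n_rejected=n_rejected,
                            rejection_threshold_uv=threshold_uv)
    return kept, n_rejected


def drop_initial(epochs: EpochSet, k: int = 13) -> EpochSet:
    """Remove the first k epochs (startup transients; matches the IKI
    discard so 525 recorded epochs leave 512 analyzable)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if epochs.n_epochs <= k:
        raise ValueError(f"cannot drop {k} of {epochs.n_epochs} epochs")
    if k == 0:
        return epochs
    return epochs.copy_with(epochs.data[k:], n_dropped_initial=k)


def average_erp(epochs: EpochSet) -> Waveform:
    """Trial-average ERP (channels × samples)."""
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return Waveform(
        data=epochs.data.mean(axis=0), fs=epochs.fs,
        t0_offset_ms=epochs.t0_offset_ms,
        channel_labels=list(epochs.channel_labels),
        production=epochs.production, soa=epochs.soa,
        participant_id=epochs.participant_id,
    )


def motor_correct(ma_erp: Waveform, mo_erp: Waveform) -> Waveform:
    """C-MA waveform: pointwise MA − MO, removing motor activity from the
    motor-auditory average."""
    if ma_erp.production != "MA" or mo_erp.production != "MO":
        raise ValueError("motor_correct expects an MA and an MO waveform")
    if (ma_erp.data.shape != mo_erp.data.shape
            or ma_erp.channel_labels != mo_erp.channel_labels
            or ma_erp.soa != mo_erp.soa
            or ma_erp.fs != mo_erp.fs
            or ma_erp.t0_offset_ms != mo_erp.t0_offset_ms):
        raise ValueError("MA and MO waveforms do not match in shape/labels/SOA")
    return Waveform(
        data=ma_erp.data - mo_erp.data, fs=ma_erp.fs,
        t0_offset_ms=ma_erp.t0_offset_ms,
        channel_labels=list(ma_erp.channel_labels),
        production="C-MA", soa=ma_erp.soa, participant_id=ma_erp.participant_id,
    )


def _pool_trace(wf: Waveform, pool: list[str]) -> np.ndarray:
    missing = [c for c in pool if c not in wf.channel_labels]
    if missing:
        raise ValueError(f"pool channels not present: {missing}")
    idx = [wf.channel_labels.index(c) for c in pool]
    return wf.data[idx].mean(axis=0)


def collapsed_localizer(
    all_condition_erps: list[Waveform],
    component: str,
    pool: list[str],
    search_range_ms: tuple[float, float] | None = None,
    width_ms: float = 30.0,
) -> ComponentWindow:
    """Place the component window from the grand average over all conditions.

    All supplied condition ERPs are averaged with equal weight, the trace
    is pooled over the electrode pool, and the extremum (minimum for N1,
    maximum for P2) inside the search range becomes the window center.
    Ties break to the earliest latency; a peak on the range boundary
    emits a truncation warning.
    """
    import warnings

    if component not in ("N1", "P2"):
        raise ValueError("component must be 'N1' or 'P2'")
    if not all_condition_erps:
        raise ValueError("need at least one condition ERP")
    if search_range_ms is None:
        search_range_ms = DEFAULT_SEARCH_MS[component]
    ref = all_condition_erps[0]
    grand = np.mean([_pool_trace(w, pool) for w in all_condition_erps], axis=0)
    times = ref.times_ms
    mask = (times >= search_range_ms[0]) & (times <= search_range_ms[1])
    if not mask.any():
        raise ValueError(f"search range {search_range_ms} outside epoch span")
    seg = grand[mask]
    seg_times = times[mask]
    idx = int(np.argmin(seg)) if component == "N1" else int(np.argmax(seg))
    peak_ms = float(seg_times[idx])
    if idx in (0, len(seg) - 1):
        warnings.warn(
            f"{component} peak at the search-range boundary ({peak_ms:.1f} ms); "
            "the window may be truncated", stacklevel=2,
        )
    return ComponentWindow(name=component, center_ms=peak_ms, width_ms=width_ms,
                           electrode_pool=list(pool))


def mean_amplitude(erp: Waveform, window: ComponentWindow) -> ComponentMeasure:
    """Windowed mean amplitude over the pooled electrodes (μV).

    The trace is pooled across electrodes first and then averaged over
    the in-window samples; on a fixed grid the order is irrelevant.
    """
    trace = _pool_trace(erp, window.electrode_pool)
    mask = _window_slice(erp.times_ms, window.start_ms, window.end_ms)
    if not mask.any():
        raise ValueError(
            f"window [{window.start_ms}, {window.end_ms}) ms contains no samples"
        )
    return ComponentMeasure(
        participant_id=erp.participant_id,
        production=erp.production,
        soa=erp.soa,
        component=window.name,
        mean_amplitude_uv=float(trace[mask].mean()),
    )


def process_epochs(
    epochs: EpochSet,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    reject_threshold_uv: float = 200.0,
    drop_first: int = 13,
) -> Waveform:
    """Epoch-stage chain for one condition cell:
    baseline → reject → drop_initial → average."""
    e = baseline_correct(epochs, baseline_ms)
    e, _ = reject_epochs(e, reject_threshold_uv)
    e = drop_initial(e, drop_first)
    return average_erp(e)
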