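"""Synthetic IKI series and ERP epochs with known ground truth.

The behavioral generator draws fractional Gaussian noise (fGn) by exact
circulant embedding, so the Hurst parameter H of the generated series is
known exactly and can serve as the oracle for the DFA α estimator (for
stationary fGn, α = H on (0, 1)).

The ERP generator builds epochs as a sum of Gaussian-in-time component
bumps (N1 ≈ 90 ms negative, P2 ≈ 160 ms positive by default) scaled by a
per-channel topography and per-condition amplitude offsets, over 1/f-type
noise. Condition metadata carries the ground-truth amplitudes so every
downstream stage can be checked against a closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .containers import IKISeries, EpochSet, SOA_LEVELS

IKI_CLIP_FLOOR_S = 0.001  # physical positivity floor for clipped intervals


class EmbeddingError(RuntimeError):
    """Circulant embedding produced materially negative eigenvalues."""


def fgn_autocovariance(hurst: float, max_lag: int) -> np.ndarray:
    """Theoretical unit-variance fGn autocovariance γ(0..max_lag).

    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).
    """
    k = np.arange(max_lag + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def simulate_fgn(hurst: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n samples of unit-variance fractional Gaussian noise.

    Exact circulant (Davies–Harte) embedding: the circulant extension of
    the covariance is diagonalized by the DFT, and the sample is synthesized
    from complex Gaussian spectral weights, so the theoretical
    autocovariance holds in expectation at every lag.

    Parameters
    ----------
    hurst : float in (0, 1)
        Hurst parameter; H = 0.5 is white noise.
    n : int >= 16
        Series length.
    seed : int or numpy Generator
        Same seed, same output, bit for bit.

    Raises
    ------
    ValueError
        If ``hurst`` is outside (0, 1) or ``n`` < 16.
    EmbeddingError
        If the circulant embedding is not positive semi-definite (can
        happen at extreme H with short n); never silently truncated.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 16:
        raise ValueError(f"need n >= 16, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m = 2 * n
    gamma = fgn_autocovariance(hurst, n)
    # first row of the circulant extension: γ(0..n), γ(n−1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    tol = 1e-10 * lam.max()
    if lam.min() < -tol:
        raise EmbeddingError(
            f"circulant embedding not PSD (min eigenvalue {lam.min():.3e}) "
            f"for H={hurst}, n={n}"
        )
    lam = np.clip(lam, 0.0, None)  # only round-off negatives survive the check

    # complex spectral weights with Hermitian symmetry
    w = np.zeros(m, dtype=complex)
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[0] = math.sqrt(lam[0] / m) * rng.standard_normal()
    w[1:n] = np.sqrt(lam[1:n] / (2 * m)) * (u + 1j * v)
    w[n] = math.sqrt(lam[n] / m) * rng.standard_normal()
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    return np.fft.fft(w).real[:n]


def simulate_iki_series(
    target_alpha: float,
    mean_iki: float,
    sd_iki: float,
    n: int,
    seed: int,
    participant_id: str = "sim",
    production: str = "MA",
    soa: float = 0.8,
) -> IKISeries:
    """Generate an IKI series with a known fractal exponent.

    Affine-scaled fGn with H = ``target_alpha`` (valid on (0, 1); the
    series is stationary, so the DFA α of the generating process equals
    H). Values falling at or below zero after scaling are clipped to a
    1 ms floor and the clip count is recorded in ``meta`` — with
    paper-typical parameters (mean 0.85 s, SD 0.16 s) no clipping occurs.

    ``sd_iki = 0`` degenerates to a constant series at ``mean_iki``.
    """
    if not (0.0 < target_alpha < 1.0):
        raise ValueError(
            f"target_alpha must lie in (0, 1); got {target_alpha}. "
            "Exponents >= 1 correspond to fBm-type nonstationary series, "
            "which this generator does not produce."
        )
    if mean_iki <= 0:
        raise ValueError("mean_iki must be > 0")
    if sd_iki < 0:
        raise ValueError("sd_iki must be >= 0")
    if n < 16:
        raise ValueError("need n >= 16")

    if sd_iki == 0.0:
        intervals = np.full(n, mean_iki)
        n_clipped = 0
    else:
        x = simulate_fgn(target_alpha, n, seed)
        intervals = mean_iki + sd_iki * x
        n_clipped = int(np.sum(intervals < IKI_CLIP_FLOOR_S))
        intervals = np.clip(intervals, IKI_CLIP_FLOOR_S, None)

    return IKISeries(
        participant_id=participant_id,
        production=production,
        soa=soa,
        intervals=intervals,
        meta={
            "seed": seed,
            "target_alpha": target_alpha,
            "mean_iki": mean_iki,
            "sd_iki": sd_iki,
            "n_clipped": n_clipped,
        },
    )


@dataclass
class ErpComponentSpec:
    """One simulated ERP component: a Gaussian bump in time.

    ``width_ms`` is the Gaussian σ. Windowed means are shape-insensitive
    near the bump center: for σ comparable to the window width the mean
    over a centered 30 ms window stays within ~5% of the peak amplitude
    (closed form in :func:`windowed_mean_closed_form`).
    """

    name: str
    polarity: int  # −1 for N1-type, +1 for P2-type
    peak_latency_ms: float
    width_ms: float  # Gaussian sigma
    base_amplitude_uv: float  # unsigned magnitude; sign comes from polarity
    topography: dict[str, float]  # per-channel weights

    def amplitude(self, offset_uv: float = 0.0) -> float:
        """Signed peak amplitude including a condition offset (μV)."""
        return self.polarity * (self.base_amplitude_uv + offset_uv)


@dataclass
class ErpSimSpec:
    """Full specification for one simulated recording session."""

    n_epochs_per_cell: int
    channels: list[str]
    fs: float  # Hz
    epoch_window_ms: tuple[float, float]  # (start, end) relative to sound onset
    components: list[ErpComponentSpec]
    condition_effects: dict[tuple[str, str, float], float] = field(default_factory=dict)
    # keys (component name, production, soa) -> additive amplitude offset, μV
    noise_exponent: float = 1.0  # 1/f^exponent spectral shape
    noise_rms_uv: float = 10.0
    seed: int = 0
    cells: list[tuple[str, float]] = field(
        default_factory=lambda: [
            (p, s) for p in ("MA", "MO", "AV") for s in SOA_LEVELS
        ]
    )
    participant_id: str = "sim"

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window_ms
        if not t0 < 0 < t1:
            raise ValueError("epoch window must straddle sound onset (start < 0 < end)")
        for c in self.components:
            if not (t0 <= c.peak_latency_ms <= t1):
                raise ValueError(
                    f"component {c.name} latency {c.peak_latency_ms} ms "
                    f"outside epoch window {self.epoch_window_ms}"
                )
            for ch, w in c.topography.items():
                if not np.isfinite(w):
                    raise ValueError(f"non-finite topography weight for {c.name}/{ch}")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], exponent: float,
                rms: float) -> np.ndarray:
    """Noise with a 1/f^exponent amplitude spectrum along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    cur = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return shaped / cur * rms


def component_amplitude(spec: ErpSimSpec, component: str, production: str,
                        soa: float) -> float:
    """Signed ground-truth peak amplitude of a component in one cell (μV)."""
    for c in spec.components:
        if c.name == component:
            off = spec.condition_effects.get((component, production, soa), 0.0)
            return c.amplitude(off)
    raise KeyError(f"no component named {component!r}")


def windowed_mean_closed_form(peak_uv: float, latency_ms: float, sigma_ms: float,
                              win_start_ms: float, win_end_ms: float) -> float:
    """Exact mean of a Gaussian bump over a continuous time window (μV)."""
    a = (win_start_ms - latency_ms) / sigma_ms
    b = (win_end_ms - latency_ms) / sigma_ms
    mass = norm.cdf(b) - norm.cdf(a)
    return peak_uv * sigma_ms * math.sqrt(2.0 * math.pi) * mass / (win_end_ms - win_start_ms)


def simulate_epochs(spec: ErpSimSpec) -> dict[tuple[str, float], EpochSet]:
    """Simulate one EpochSet per condition cell listed in ``spec.cells``.

    Each epoch is Σ components (Gaussian bump × topography × signed
    amplitude) + 1/f noise. The keypress event is marked at −100 ms for
    MA/MO cells (the tone follows the keypress by 100 ms). Ground-truth
    amplitudes go into each EpochSet's ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.epoch_window_ms
    n_samples = int(round((t1 - t0) / 1000.0 * spec.fs))
    times = t0 + np.arange(n_samples) * 1000.0 / spec.fs
    n_ch = len(spec.channels)

    out: dict[tuple[str, float], EpochSet] = {}
    for production, soa in spec.cells:
        signal = np.zeros((n_ch, n_samples))
        truth: dict[str, float] = {}
        for c in spec.components:
            off = spec.condition_effects.get((c.name, production, soa), 0.0)
            amp = c.amplitude(off)
            truth[c.name] = amp
            bump = np.exp(-0.5 * ((times - c.peak_latency_ms) / c.width_ms) ** 2)
            topo = np.array([c.topography.get(ch, 0.0) for ch in spec.channels])
            signal += amp * topo[:, None] * bump[None, :]

        if spec.noise_rms_uv > 0:
            noise = _pink_noise(
                rng,
                (spec.n_epochs_per_cell, n_ch, n_samples),
                spec.noise_exponent,
                spec.noise_rms_uv,
            )
        else:
            noise = np.zeros((spec.n_epochs_per_cell, n_ch, n_samples))
        data = signal[None, :, :] + noise

        meta = {
            "ground_truth_amplitudes_uv": truth,
            "seed": spec.seed,
            "noise_rms_uv": spec.noise_rms_uv,
            "noise_exponent": spec.noise_exponent,
        }
        if production in ("MA", "MO"):
            meta["keypress_ms"] = -100.0  # tone follows the keypress by 100 ms
        out[(production, soa)] = EpochSet(
            data=data,
            fs=spec.fs,
            t0_offset_ms=t0,
            channel_labels=list(spec.channels),
            production=production,
            soa=soa,
            participant_id=spec.participant_id,
            meta=meta,
        )
    return out


def default_erp_spec(
    n_epochs_per_cell: int = 64,
    seed: int = 0,
    p2_attenuation_uv: dict[float, float] | None = None,
    n1_enhancement_uv: dict[float, float] | None = None,
    noise_rms_uv: float = 10.0,
    participant_id: str = "sim",
    fs: float = 1024.0,
) -> ErpSimSpec:
    """Paper-flavored default session: N1/P2 auditory bumps, a motor bump,
    and per-SOA P2 attenuation (C-MA minus AV) of 1 μV at the longer SOAs.

    MO cells carry no auditory components (offset −base switches them off);
    AV cells carry no motor component. Attenuation dictionaries map SOA to
    the μV reduction of the MA auditory component relative to AV, so the
    motor-corrected contrast recovers them by construction.
    """
    if p2_attenuation_uv is None:
        p2_attenuation_uv = {0.8: 0.0, 1.6: 1.0, 3.2: 1.0}
    if n1_enhancement_uv is None:
        n1_enhancement_uv = {0.8: 0.0, 1.6: 0.5, 3.2: 0.5}

    channels = ["Fz", "FCz", "Cz", "CPz", "Pz"]
    n1 = ErpComponentSpec(
        name="N1", polarity=-1, peak_latency_ms=90.0, width_ms=14.0,
        base_amplitude_uv=4.0,
        topography={"Fz": 1.0, "FCz": 1.0, "Cz": 1.0, "CPz": 0.7, "Pz": 0.4},
    )
    p2 = ErpComponentSpec(
        name="P2", polarity=+1, peak_latency_ms=160.0, width_ms=22.0,
        base_amplitude_uv=5.0,
        topography={"Fz": 0.7, "FCz": 1.0, "Cz": 1.0, "CPz": 1.0, "Pz": 0.7},
    )
    motor = ErpComponentSpec(
        name="motor", polarity=-1, peak_latency_ms=-100.0, width_ms=60.0,
        base_amplitude_uv=2.0,
        topography={"Fz": 0.5, "FCz": 0.8, "Cz": 1.0, "CPz": 0.8, "Pz": 0.5},
    )

    effects: dict[tuple[str, str, float], float] = {}
    for soa in SOA_LEVELS:
        # auditory components absent in MO; motor absent in AV
        effects[("N1", "MO", soa)] = -n1.base_amplitude_uv
        effects[("P2", "MO", soa)] = -p2.base_amplitude_uv
        effects[("motor", "AV", soa)] = -motor.base_amplitude_uv
        # attenuation: MA auditory response reduced relative to AV
        effects[("P2", "MA", soa)] = -p2_attenuation_uv[soa]
        # enhancement: N1 is negative-going, so a LARGER (more negative)
        # C-MA response means a more negative windowed mean; increase base
        effects[("N1", "MA", soa)] = n1_enhancement_uv[soa]

    return ErpSimSpec(
        n_epochs_per_cell=n_epochs_per_cell,
        channels=channels,
        fs=fs,
        epoch_window_ms=(-200.0, 400.0),
        components=[n1, p2, motor],
        condition_effects=effects,
        noise_rms_uv=noise_rms_uv,
        seed=seed,
        participant_id=participant_id,
    )


def simulate_study_ikis(
    n_participants: int,
    n: int = 512,
    seed: int = 0,
    alpha_targets: dict[tuple[str, float], float] | None = None,
    iki_params: dict[tuple[str, float], tuple[float, float]] | None = None,
    alpha_subject_sd: float = 0.08,
) -> list[IKISeries]:
    """Full balanced behavioral design: participants × {MA, MO} × 3 SOAs.

    Defaults mirror the study's observed cell statistics: group-mean α
    targets rise with SOA (0.68/0.75/0.82) with MA slightly above MO
    (±0.02), and per-cell IKI mean/SD follow the reported table (e.g. MA-0.8:
    0.85 s ± 0.16). Per-subject α is jittered by ``alpha_subject_sd``
    (clipped to (0.1, 0.95)) to give realistic between-subject spread.
    """
    if alpha_targets is None:
        soa_alpha = {0.8: 0.68, 1.6: 0.75, 3.2: 0.82}
        alpha_targets = {}
        for soa, a in soa_alpha.items():
            alpha_targets[("MA", soa)] = a + 0.02
            alpha_targets[("MO", soa)] = a - 0.02
    if iki_params is None:
        iki_params = {
            ("MA", 0.8): (0.85, 0.16), ("MA", 1.6): (1.71, 0.28),
            ("MA", 3.2): (3.18, 0.48), ("MO", 0.8): (0.75, 0.14),
            ("MO", 1.6): (1.45, 0.25), ("MO", 3.2): (3.06, 0.67),
        }
    ss = np.random.SeedSequence(seed)
    series: list[IKISeries] = []
    for p_idx, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        pid = f"P{p_idx + 1:02d}"
        for (production, soa), target in sorted(alpha_targets.items()):
            mean_iki, sd_iki = iki_params[(production, soa)]
            a = float(np.clip(target + alpha_subject_sd * rng.standard_normal(),
                              0.1, 0.95))
            cell_seed = int(rng.integers(0, 2**31 - 1))
            s = simulate_iki_series(
                a, mean_iki, sd_iki, n, cell_seed,
                participant_id=pid, production=production, soa=soa,
            )
            s.meta["group_target_alpha"] = target
            series.append(s)
    return series
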