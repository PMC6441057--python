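"""Synthetic multichannel LFP/EEG/EMG generator with exact ground truth.

Emulates a freely-moving mouse session as the analysis chain assumes it:
alternating movement / waking-immobility / NREM / REM bouts; NREM carries a
frontal delta oscillation, a continuous low-amplitude spindle-band (sigma)
background, Poisson spindle bursts on cortical/thalamic channels and Poisson
CA1 ripples (also, at a lower rate, during WI); REM carries theta on
hippocampal and frontal channels plus a theta-phase-modulated 60-90 Hz gamma
on hippocampal channels (modulation depth kappa); movement shows large EMG
bursts. A shared 1/f background across channels gives nonzero, band-
structured interregional coherence.

Ripple packets are sinusoids under a plateau-with-cosine-ramps (Tukey-like)
envelope, calibrated *per event* against the actual local background: the
packet amplitude is solved so the detector's power-envelope z-score at the
peak hits the ``amp_sd`` target, and the plateau length is solved so the
contiguous span above the detector's 2-SD boundary threshold equals
``dur_ms``. In-band 1/f background noise is comparable to a 3-SD packet, so
a single global amplitude would scatter detected peak heights and durations
far outside their targets; solving per event against the realized background
makes detector recall, duration and amplitude fidelity well-defined.

The ripple-to-cortex coupling knob ``coupling.gain`` places a spindle burst
on mFC at each NREM ripple peak (+ ``lag_ms``) with amplitude scaled by the
gain; gain 0 means no coupling (the transgenic-like condition).

Every injected event and the true hypnogram are recorded in
``Recording.ground_truth``. Generation is bit-reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._filters import bandpass
from .errors import ConfigurationError
from .io import ChannelInfo, EventTable, GroundTruth, Hypnogram, Recording
from .ripples import power_envelope

#: Channel layout of a synthetic session (one channel per region).
CHANNEL_LAYOUT = (
    ChannelInfo("sFC", region="sFC", kind="screw"),
    ChannelInfo("mFC", region="mFC", kind="wire"),
    ChannelInfo("CA1", region="CA1", kind="wire"),
    ChannelInfo("DG", region="DG", kind="wire"),
    ChannelInfo("RS", region="RS", kind="wire"),
    ChannelInfo("Th-RT", region="Th-RT", kind="wire"),
    ChannelInfo("EMG", region="EMG", kind="emg"),
)

CORTICAL = ("sFC", "mFC", "RS", "Th-RT")  # delta / spindle / sigma carriers
HIPPOCAMPAL = ("CA1", "DG")  # theta / gamma carriers
THETA_CHANNELS = ("sFC", "mFC", "RS", "CA1", "DG")


def default_schedule(total_s: float = 600.0) -> list[tuple[str, float]]:
    """MOVE/WI/NREM/REM cycle (60/60/240/120 s) trimmed to ``total_s``."""
    cycle = [("MOVE", 60.0), ("WI", 60.0), ("NREM", 240.0), ("REM", 120.0)]
    schedule: list[tuple[str, float]] = []
    t = 0.0
    i = 0
    while t < total_s:
        state, dur = cycle[i % len(cycle)]
        dur = min(dur, total_s - t)
        if dur < 20.0 and schedule:  # avoid trailing slivers
            schedule[-1] = (schedule[-1][0], schedule[-1][1] + dur)
        else:
            schedule.append((state, dur))
        t += dur
        i += 1
    return schedule


@dataclass
class NoiseParams:
    # LFP spectra fall off roughly as 1/f^2 in the 10-250 Hz range; a flatter
    # slope leaves an unrealistically strong 150-250 Hz Gaussian floor whose
    # interference (cross term) with ripple packets fragments the detector's
    # above-threshold runs.
    one_over_f_exponent: float = 2.0
    colored_sd_uv: float = 20.0
    white_sd_uv: float = 5.0
    shared_gain: float = 0.6  # fraction of colored noise shared across channels


@dataclass
class NremParams:
    delta_hz: float = 2.0
    delta_amp_uv: float = 40.0
    sigma_amp_uv: float = 10.0  # continuous 10-15 Hz background on cortex
    spindle_hz: float = 13.0
    spindle_rate_per_min: float = 6.0
    spindle_dur_s: float = 0.7
    spindle_amp_uv: float = 30.0


@dataclass
class RemParams:
    theta_hz: float = 7.5
    theta_amp_uv: float = 50.0
    gamma_lo_hz: float = 60.0
    gamma_hi_hz: float = 90.0
    gamma_amp_uv: float = 10.0
    pac_strength: float = 0.8  # kappa in [0, 1]
    hf_amp_uv: float = 8.0  # desynchronized 30-90 Hz boost on the screw channel


@dataclass
class EmgParams:
    move_burst_amp_uv: float = 100.0
    rest_amp_uv: float = 10.0


@dataclass
class RippleParams:
    rate_per_min: float = 9.0
    wi_rate_factor: float = 0.4  # WI rate = rate_per_min * factor
    freq_hz: float = 160.0
    dur_ms: float = 60.0  # span above the detector's 2-SD boundary threshold
    amp_sd: float = 3.0  # detector z-score target at the peak


@dataclass
class ArtifactParams:
    """Sharp broadband CA1 transients (population spikes, twitches).

    Real pyramidal-layer LFP contains millisecond-scale spikes far larger
    than the ripple-band noise floor; they dominate the session SD of the
    ripple-band power envelope, which is what puts genuine ripples at a
    modest 2-5 SD above baseline (and artifacts far above 5 SD). Without
    them a Gaussian background gives envelope SD ~ mean and no packet can
    sustain 50-100 ms above 2 SD with a peak below 5 SD.
    """

    rate_per_min: float = 20.0
    amp_uv: float = 150.0
    width_ms: float = 2.0


@dataclass
class CouplingParams:
    gain: float = 1.0  # mFC burst amplitude = gain * burst_amp_uv
    lag_ms: float = 0.0
    #: Base amplitude of the ripple-locked mFC spindle burst; comparable to
    #: the continuous sigma background so the peri-ripple power increase is a
    #: modest fraction, as in real ripple-spindle coupling.
    burst_amp_uv: float = 10.0


@dataclass
class SynthParams:
    seed: int = 0
    fs: float = 2000.0
    #: Global multiplicative gain (electrode position/impedance surrogate);
    #: drawn per animal by two_group_experiment. Ratio- and z-score-based
    #: measures are invariant to it; absolute powers are not.
    animal_gain: float = 1.0
    bout_schedule: list[tuple[str, float]] = field(default_factory=default_schedule)
    noise: NoiseParams = field(default_factory=NoiseParams)
    nrem: NremParams = field(default_factory=NremParams)
    rem: RemParams = field(default_factory=RemParams)
    emg: EmgParams = field(default_factory=EmgParams)
    ripples: RippleParams = field(default_factory=RippleParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)

    def __post_init__(self) -> None:
        if not self.bout_schedule:
            raise ConfigurationError("bout schedule must be non-empty")
        if not 0 <= self.rem.pac_strength <= 1:
            raise ConfigurationError("pac_strength must lie in [0, 1]")
        if self.coupling.gain < 0:
            raise ConfigurationError("coupling gain must be >= 0")
        for state, dur in self.bout_schedule:
            if state not in ("MOVE", "WI", "NREM", "REM") or dur <= 0:
                raise ConfigurationError(f"bad schedule entry ({state}, {dur})")
        if self.ripples.rate_per_min > 0 and self.fs <= 500.0:
            raise ConfigurationError(
                "fs must exceed 500 Hz for 150-250 Hz ripple injection; "
                "set ripples.rate_per_min=0 for low-rate recordings"
            )


def _colored_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bout_intervals(schedule: list[tuple[str, float]], fs: float) -> list[tuple[str, int, int]]:
    out = []
    t = 0.0
    for state, dur in schedule:
        i0 = int(round(t * fs))
        t += dur
        out.append((state, i0, int(round(t * fs))))
    return out


def _ramped_envelope(n: int, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps (no clicks at bout edges)."""
    env = np.ones(n)
    r = min(int(round(ramp_s * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _poisson_times(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    rate_per_min: float,
    margin_s: float,
    min_sep_s: float,
) -> np.ndarray:
    """Poisson event times within (t0+margin, t1-margin), thinned to a minimum
    separation (overlapping packets would distort amplitude calibration)."""
    dur = t1 - t0
    n = rng.poisson(rate_per_min * dur / 60.0)
    lo, hi = t0 + margin_s, t1 - margin_s
    if n == 0 or hi <= lo:
        return np.empty(0)
    times = np.sort(rng.uniform(lo, hi, size=n))
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_sep_s:
            kept.append(t)
    return np.asarray(kept)


def _add_packet(x: np.ndarray, fs: float, center_s: float, dur_s: float, freq_hz: float, amp: float, phase: float) -> None:
    """Add ``amp * hann * sin`` centered at ``center_s`` in place."""
    half = dur_s / 2.0
    i0 = max(0, int(round((center_s - half) * fs)))
    i1 = min(len(x), int(round((center_s + half) * fs)))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    rel = (t - (center_s - half)) / dur_s
    env = np.sin(np.pi * np.clip(rel, 0, 1)) ** 2
    x[i0:i1] += amp * env * np.sin(2 * np.pi * freq_hz * t + phase)


#: Cosine ramp length of a ripple packet (s) on each side of the plateau.
RIPPLE_RAMP_S = 0.020


def _ripple_template(fs: float, center_s: float, plateau_s: float, freq_hz: float, i0: int, i1: int) -> np.ndarray:
    """Unit-amplitude ripple packet on the sample grid [i0, i1)."""
    t = np.arange(i0, i1) / fs
    rel = np.abs(t - center_s)
    env = np.zeros_like(t)
    env[rel <= plateau_s / 2] = 1.0
    on_ramp = (rel > plateau_s / 2) & (rel <= plateau_s / 2 + RIPPLE_RAMP_S)
    x = (rel[on_ramp] - plateau_s / 2) / RIPPLE_RAMP_S
    env[on_ramp] = 0.5 * (1 + np.cos(np.pi * x))
    return env * np.sin(2 * np.pi * freq_hz * t)


def _merged_run_span(above: np.ndarray, peak_idx: int, merge_gap: int) -> tuple[int, int] | None:
    """Span of the above-threshold run containing ``peak_idx`` after merging
    runs separated by less than ``merge_gap`` samples (detector convention)."""
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    for a, b in merged:
        if a <= peak_idx < b:
            return a, b
    return None


class _RippleInjector:
    """Per-event calibrated ripple injection against a fixed z baseline.

    Given detector-side mean/SD (mu, sigma) of the smoothed ripple-band power
    envelope, solves each packet's amplitude so its envelope peak reaches
    ``mu + amp_sd*sigma`` and its plateau so the contiguous span above
    ``mu + 2*sigma`` equals ``dur_ms``, on the realized local background.
    """

    def __init__(self, bg: np.ndarray, fs: float, band=(150.0, 250.0), smooth_ms=10.0, merge_gap_ms=20.0):
        from scipy.signal import firwin

        self.bg = bg
        self.fs = fs
        self.smooth_n = max(1, int(round(smooth_ms * 1e-3 * fs)))
        self.merge_gap = int(round(merge_gap_ms * 1e-3 * fs))
        taps = int(round(3 * fs / band[0])) | 1
        self.taps = firwin(taps, [band[0], band[1]], pass_zero=False, fs=fs)
        self.bgf = np.convolve(bg, self.taps, mode="same")
        self.kernel = np.full(self.smooth_n, 1.0 / self.smooth_n)

    def _smooth(self, x: np.ndarray) -> np.ndarray:
        return np.convolve(x, self.kernel, mode="same")

    def calibrate(self, center_s: float, dur_s: float, freq_hz: float, amp_sd: float, mu: float, sigma: float):
        """Returns (waveform, i0, realized_span_s) or None if uncalibratable."""
        target = mu + amp_sd * sigma
        boundary = mu + 2.0 * sigma
        wc = math.sqrt(min(2.0 / max(amp_sd, 2.01), 0.999))
        t_cross = (RIPPLE_RAMP_S / math.pi) * math.acos(1 - 2 * wc)
        plateau = max(0.005, dur_s - 2 * (RIPPLE_RAMP_S - t_cross))
        amp = span = None
        for _ in range(4):
            half_win = plateau / 2 + RIPPLE_RAMP_S + 0.08
            i0 = max(0, int((center_s - half_win) * self.fs))
            i1 = min(len(self.bg), int((center_s + half_win) * self.fs))
            ci = int(center_s * self.fs) - i0
            tmpl = _ripple_template(self.fs, center_s, plateau, freq_hz, i0, i1)
            tf = np.convolve(tmpl, self.taps, mode="same")
            bgf = self.bgf[i0:i1]
            a = self._smooth(bgf**2)
            b = self._smooth(2 * bgf * tf)
            c = self._smooth(tf**2)
            half_p = max(1, int(plateau / 2 * self.fs))
            support = slice(max(0, ci - half_p), min(len(a), ci + half_p + 1))

            def plateau_max(A: float) -> float:
                env = a + b * A + c * A * A
                return float(env[support].max())

            # amplitude: the envelope max on the packet plateau hits the target
            amp_hi = 1.0
            for _ in range(60):
                if plateau_max(amp_hi) >= target:
                    break
                amp_hi *= 2.0
            else:
                return None
            amp_lo = 0.0
            for _ in range(40):
                mid = (amp_lo + amp_hi) / 2
                if plateau_max(mid) >= target:
                    amp_hi = mid
                else:
                    amp_lo = mid
            amp = amp_hi
            env = a + b * amp + c * amp * amp
            run = _merged_run_span(env >= boundary, ci, self.merge_gap)
            if run is None:
                return None
            # a nearby background spike above the detector's acceptance band
            # (or far above the target) would corrupt the event; skip it
            run_peak = float(env[run[0] : run[1]].max())
            if run_peak > max(target + 0.5 * sigma, mu + 4.8 * sigma):
                return None
            span = (run[1] - run[0]) / self.fs
            if abs(span - dur_s) <= 0.002:
                break
            plateau = max(0.005, plateau + (dur_s - span))
        if span is None or abs(span - dur_s) > 0.005:
            return None
        return amp * tmpl, i0, span


def generate_recording(params: SynthParams | None = None, meta: dict | None = None) -> Recording:
    """Generate one synthetic session; see module docstring for the model."""
    p = params or SynthParams()
    fs = p.fs
    bouts = _bout_intervals(p.bout_schedule, fs)
    n = bouts[-1][2]
    names = [c.name for c in CHANNEL_LAYOUT]

    ss = np.random.SeedSequence(p.seed)
    streams = ss.spawn(13)
    rng_shared = np.random.default_rng(streams[0])
    rng_ch = {name: np.random.default_rng(streams[1 + i]) for i, name in enumerate(names)}
    rng_ripple = np.random.default_rng(streams[8])
    rng_spindle = np.random.default_rng(streams[9])
    rng_gamma = np.random.default_rng(streams[10])
    rng_phase = np.random.default_rng(streams[11])
    rng_artifact = np.random.default_rng(streams[12])

    alpha = p.noise.one_over_f_exponent
    g = p.noise.shared_gain
    shared = _colored_noise(rng_shared, n, alpha)
    data = np.empty((len(names), n))
    for i, name in enumerate(names):
        if name == "EMG":
            data[i] = 0.0
            continue
        own = _colored_noise(rng_ch[name], n, alpha)
        colored = g * shared + math.sqrt(max(0.0, 1 - g * g)) * own
        data[i] = p.noise.colored_sd_uv * colored + p.noise.white_sd_uv * rng_ch[name].standard_normal(n)
    sig = {name: data[i] for i, name in enumerate(names)}

    # EMG: low-amplitude tone at rest, large bursts during movement
    emg = p.emg.rest_amp_uv * rng_ch["EMG"].standard_normal(n)
    for state, i0, i1 in bouts:
        if state == "MOVE":
            env = _ramped_envelope(i1 - i0, fs)
            emg[i0:i1] += p.emg.move_burst_amp_uv * env * rng_ch["EMG"].standard_normal(i1 - i0)
    sig["EMG"][:] = emg

    delta_phase = rng_phase.uniform(0, 2 * np.pi)
    theta_phase0 = rng_phase.uniform(0, 2 * np.pi)
    t_full = np.arange(n) / fs

    events: list[dict] = []
    ripple_times: list[tuple[str, float]] = []  # (state, center_s), injected later

    for state, i0, i1 in bouts:
        nb = i1 - i0
        t0, t1 = i0 / fs, i1 / fs
        env = _ramped_envelope(nb, fs)
        t = t_full[i0:i1]

        if state == "NREM":
            delta = p.nrem.delta_amp_uv * np.sin(2 * np.pi * p.nrem.delta_hz * t + delta_phase)
            for name in CORTICAL:
                sig[name][i0:i1] += env * delta
                sigma = bandpass(rng_ch[name].standard_normal(nb), fs, 10.0, 15.0)
                sd_sigma = sigma.std()
                if sd_sigma > 0:
                    sig[name][i0:i1] += env * p.nrem.sigma_amp_uv * sigma / sd_sigma
            spindle_times = _poisson_times(
                rng_spindle, t0, t1, p.nrem.spindle_rate_per_min,
                margin_s=p.nrem.spindle_dur_s, min_sep_s=2 * p.nrem.spindle_dur_s,
            )
            for ts in spindle_times:
                phase = rng_spindle.uniform(0, 2 * np.pi)
                for name in CORTICAL:
                    _add_packet(sig[name], fs, ts, p.nrem.spindle_dur_s, p.nrem.spindle_hz, p.nrem.spindle_amp_uv, phase)
                events.append(
                    {
                        "start_s": ts - p.nrem.spindle_dur_s / 2,
                        "peak_s": ts,
                        "end_s": ts + p.nrem.spindle_dur_s / 2,
                        "channel": "mFC",
                        "kind": "spindle",
                        "state": state,
                    }
                )

        if state == "REM":
            theta = p.rem.theta_amp_uv * np.sin(2 * np.pi * p.rem.theta_hz * t + theta_phase0)
            for name in THETA_CHANNELS:
                sig[name][i0:i1] += env * theta
            kappa = p.rem.pac_strength
            mod = (1.0 + kappa * np.cos(2 * np.pi * p.rem.theta_hz * t + theta_phase0)) / math.sqrt(1 + kappa**2 / 2)
            for name in HIPPOCAMPAL:
                carrier = bandpass(rng_gamma.standard_normal(nb), fs, p.rem.gamma_lo_hz, p.rem.gamma_hi_hz)
                sd_c = carrier.std()
                if sd_c > 0:
                    sig[name][i0:i1] += env * p.rem.gamma_amp_uv * (carrier / sd_c) * mod
            hf = bandpass(rng_ch["sFC"].standard_normal(nb), fs, 30.0, min(90.0, fs / 2 - 1))
            sd_hf = hf.std()
            if sd_hf > 0:
                sig["sFC"][i0:i1] += env * p.rem.hf_amp_uv * hf / sd_hf

        if state == "MOVE":
            hf = bandpass(rng_ch["sFC"].standard_normal(nb), fs, 30.0, min(90.0, fs / 2 - 1))
            sd_hf = hf.std()
            if sd_hf > 0:
                sig["sFC"][i0:i1] += env * p.rem.hf_amp_uv * hf / sd_hf

        if p.artifacts.rate_per_min > 0:
            tau = p.artifacts.width_ms * 1e-3 / 2
            for ts in _poisson_times(
                rng_artifact, t0, t1, p.artifacts.rate_per_min,
                margin_s=4 * tau, min_sep_s=0.05,
            ):
                i_a = int(round((ts - 4 * tau) * fs))
                i_b = int(round((ts + 4 * tau) * fs))
                tt = np.arange(i_a, i_b) / fs - ts
                # biphasic derivative-of-Gaussian spike, unit peak amplitude
                wave = -(tt / tau) * np.exp(0.5 - tt**2 / (2 * tau**2))
                sig["CA1"][i_a:i_b] += p.artifacts.amp_uv * wave
                events.append(
                    {
                        "start_s": ts - 4 * tau, "peak_s": ts, "end_s": ts + 4 * tau,
                        "channel": "CA1", "kind": "artifact", "state": state,
                    }
                )

        if state in ("NREM", "WI") and p.ripples.rate_per_min > 0:
            rate = p.ripples.rate_per_min * (1.0 if state == "NREM" else p.ripples.wi_rate_factor)
            packet_s = p.ripples.dur_ms * 1e-3 + 2 * RIPPLE_RAMP_S
            for ts in _poisson_times(
                rng_ripple, t0, t1, rate,
                margin_s=packet_s / 2 + 0.1, min_sep_s=2.0 * packet_s,
            ):
                ripple_times.append((state, float(ts)))

    # --- per-event calibrated ripple injection on CA1 ----------------------
    rp = p.ripples
    if ripple_times:
        nrem_wi = np.zeros(n, dtype=bool)
        for state, i0, i1 in bouts:
            if state in ("NREM", "WI"):
                nrem_wi[i0:i1] = True
        ca1_bg = sig["CA1"].copy()
        injector = _RippleInjector(ca1_bg, fs)
        dur_s = rp.dur_ms * 1e-3

        def _baseline(x: np.ndarray) -> tuple[float, float]:
            env = power_envelope(x, fs, (150.0, 250.0), 10.0)
            sel = env[nrem_wi] if nrem_wi.any() else env
            return float(sel.mean()), float(sel.std())

        mu, sd = _baseline(ca1_bg)
        kept: list[tuple[str, float]] = []
        # two passes: the second recalibrates against the envelope statistics
        # of the injected signal (which the detector will actually see)
        for _pass in range(2):
            ca1 = ca1_bg.copy()
            kept = []
            for state, ts in ripple_times:
                result = injector.calibrate(ts, dur_s, rp.freq_hz, rp.amp_sd, mu, sd)
                if result is None:
                    continue
                waveform, i0, _span = result
                ca1[i0 : i0 + len(waveform)] += waveform
                kept.append((state, ts))
            if _pass == 0:
                mu, sd = _baseline(ca1)
        sig["CA1"][:] = ca1
        for state, ts in kept:
            events.append(
                {
                    "start_s": ts - dur_s / 2,
                    "peak_s": ts,
                    "end_s": ts + dur_s / 2,
                    "channel": "CA1",
                    "kind": "ripple",
                    "state": state,
                }
            )
            if state == "NREM" and p.coupling.gain > 0:
                tc = ts + p.coupling.lag_ms * 1e-3
                _add_packet(
                    sig["mFC"], fs, tc, p.nrem.spindle_dur_s, p.nrem.spindle_hz,
                    p.coupling.gain * p.coupling.burst_amp_uv, rng_ripple.uniform(0, 2 * np.pi),
                )
                events.append(
                    {
                        "start_s": tc - p.nrem.spindle_dur_s / 2,
                        "peak_s": tc,
                        "end_s": tc + p.nrem.spindle_dur_s / 2,
                        "channel": "mFC",
                        "kind": "coupled_spindle",
                        "state": state,
                    }
                )

    # true hypnogram at 2-s bins
    bin_s = 2.0
    n_bins = int(n / fs // bin_s)
    labels = np.empty(n_bins, dtype="U4")
    for state, i0, i1 in bouts:
        b0 = int(round(i0 / fs / bin_s))
        b1 = int(round(i1 / fs / bin_s))
        labels[b0:min(b1, n_bins)] = state
    if p.animal_gain != 1.0:
        data *= p.animal_gain
    truth = GroundTruth(
        hypnogram=Hypnogram(labels, bin_s=bin_s),
        events=EventTable.from_records(events),
        params={"seed": p.seed, "fs": p.fs, "schedule": list(p.bout_schedule)},
    )
    return Recording(
        data=data,
        fs=fs,
        channels=list(CHANNEL_LAYOUT),
        meta={"animal": f"synthetic-{p.seed}", "genotype": "NA", **(meta or {})},
        ground_truth=truth,
    )


def two_group_experiment(
    p_wt: SynthParams,
    p_tg: SynthParams,
    n_per_group: tuple[int, int] = (6, 8),
    seed: int = 0,
    gain_sigma: float = 0.2,
) -> list[Recording]:
    """Cohort of n_wt + n_tg synthetic animals with per-animal derived seeds.

    Group sizes default to the study design (6 wild-type, 8 transgenic).
    Each animal gets a lognormal global gain (sd ``gain_sigma`` on the log
    scale) emulating electrode-to-electrode differences in absolute signal
    amplitude.
    """
    n_wt, n_tg = n_per_group
    if min(n_wt, n_tg) < 2:
        raise ConfigurationError("need at least 2 animals per group")
    children = np.random.SeedSequence(seed).spawn(n_wt + n_tg)
    recs = []
    for i, child in enumerate(children):
        genotype = "WT" if i < n_wt else "TG"
        base = p_wt if genotype == "WT" else p_tg
        rng = np.random.default_rng(child)
        animal_seed = int(rng.integers(0, 2**31 - 1))
        gain = float(np.exp(rng.normal(0.0, gain_sigma))) if gain_sigma > 0 else 1.0
        p = replace(base, seed=animal_seed, animal_gain=gain)
        idx = i + 1 if genotype == "WT" else i - n_wt + 1
        recs.append(generate_recording(p, meta={"animal": f"{genotype}{idx:02d}", "genotype": genotype}))
    return recs
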