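"""Synthetic emulator of the mock circulatory loop (MCL).

The physical rig this module stands in for is a bench-top hydraulic
circulation: a servo motor squeezes a silicone right ventricle, mechanical
heart valves open and close, and a throttle valve sets the distal
pulmonary artery resistance.  Five channels are recorded synchronously:
right-ventricular pressure, pulmonary-artery pressure, the servo motor
pulse (high = systole, low = diastole) and the closure vibration sounds of
the tricuspid and pulmonary valves.

The emulator is phenomenological: waveform templates plus monotone
response maps.  A dimensionless *resistance setting* ``s`` (0 = lowest
discrete resistance state, 1 = highest) drives affine maps for the
pressure parameters and for the valve-burst amplitude, timing and carrier
frequency.  The maps are calibrated once (``data/mcl_calibration.yaml``)
so that

* the six discrete states reproduce the rig's mean PASP ladder
  (28.5 … 86.5 mmHg) and rising/falling-rate ranges,
* burst amplitude and energy increase, closure timing (measured from the
  servo falling edge) decreases, and the spectral main peak frequency
  decreases as distal resistance rises — for both valves,
* continuous sweep runs span PASP ≈ 38–94 mmHg over ~582 cycles in 10 min.

Valve closures are modelled as exponentially damped sinusoid bursts,
s(t) = A·e^(−λt)·sin(2πf_c t); white Gaussian noise is added to every
channel.  All randomness is derived from the explicit seed, so outputs
are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy.io import wavfile

__all__ = [
    "MCLConfig",
    "BurstModel",
    "Recording",
    "load_calibration",
    "default_burst_models",
    "generate_servo",
    "generate_pressures",
    "generate_valve_sounds",
    "generate_recording",
    "generate_six_state_dataset",
    "generate_continuous_dataset",
    "setting_for_pasp",
]

_BURST_LEN_S = 0.15  # damped burst support; e^(-2*60*0.15) ~ 1e-8 of energy left


def load_calibration() -> dict:
    """The packaged generator calibration (affine response-map coefficients)."""
    text = (
        resources.files("pulmovib").joinpath("data/mcl_calibration.yaml")
    ).read_text()
    return yaml.safe_load(text)


_CAL = load_calibration()


def setting_for_pasp(pasp: float, cal: dict | None = None) -> float:
    """Invert the PASP response map: the setting s whose design PASP is
    ``pasp`` mmHg."""
    p = (cal or _CAL)["pressure"]
    return (pasp - p["pasp_base"]) / p["pasp_span"]


@dataclass
class MCLConfig:
    """Operating point of the emulated rig.

    ``resistance_setting`` is either a scalar (held fixed) or a per-cycle
    schedule (array; resampled by linear interpolation if its length
    differs from the number of cycles generated).
    """

    fs: float = 2000.0
    cycle_period: float = 1.03
    duty: float = 0.45
    stroke_volume: float = 67.0
    resistance_setting: float | np.ndarray = 0.0
    noise_sd_pressure: float = 0.3
    noise_sd_sound: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValueError("fs must be at least 1000 Hz")
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        if self.stroke_volume <= 0:
            raise ValueError("stroke_volume must be positive")

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_period * self.fs))


@dataclass
class BurstModel:
    """Response maps of one valve's closure burst."""

    valve: str
    carrier_freq_fn: Callable[[float], float]  # setting -> Hz, decreasing
    amp_fn: Callable[[float], float]  # transvalvular dP proxy -> a.u., increasing
    timing_fn: Callable[[float], float]  # setting -> ms after governing edge, decr.
    damping: float = 60.0  # s^-1


def default_burst_models(cal: dict | None = None) -> tuple[BurstModel, BurstModel]:
    """(tricuspid, pulmonary) burst models from the packaged calibration."""
    cal = cal or _CAL

    def make(key: str) -> BurstModel:
        c = cal[key]
        return BurstModel(
            valve=key,
            carrier_freq_fn=lambda s, c=c: c["freq_base_hz"] + c["freq_span_hz"] * s,
            amp_fn=lambda dp, c=c: c["amp_base"] + c["amp_per_mmhg"] * dp,
            timing_fn=lambda s, c=c: c["delay_base_ms"] + c["delay_span_ms"] * s,
            damping=c["damping"],
        )

    return make("tricuspid"), make("pulmonary")


@dataclass
class Recording:
    """One synchronous multichannel recording of the emulated rig."""

    t: np.ndarray
    p_rv: np.ndarray
    p_pa: np.ndarray
    servo: np.ndarray
    snd_tricuspid: np.ndarray
    snd_pulmonary: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("p_rv", "p_pa", "servo", "snd_tricuspid", "snd_pulmonary"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs

    def save(self, outdir: str | Path) -> None:
        """Write the recording: WAV (sounds), CSV (pressures + servo),
        JSON sidecar (config and provenance)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("snd_tricuspid", "snd_pulmonary"):
            wavfile.write(
                outdir / f"{name}.wav", int(self.fs),
                getattr(self, name).astype(np.float32),
            )
        arr = np.column_stack([self.t, self.p_rv, self.p_pa, self.servo])
        np.savetxt(
            outdir / "pressures.csv", arr, delimiter=",",
            header="t,p_rv,p_pa,servo", comments="", fmt="%.6f",
        )
        (outdir / "meta.json").write_text(json.dumps(self.meta, indent=1))

    @classmethod
    def load(cls, outdir: str | Path) -> "Recording":
        outdir = Path(outdir)
        arr = np.loadtxt(outdir / "pressures.csv", delimiter=",", skiprows=1)
        fs_t, snd_t = wavfile.read(outdir / "snd_tricuspid.wav")
        fs_p, snd_p = wavfile.read(outdir / "snd_pulmonary.wav")
        meta = json.loads((outdir / "meta.json").read_text())
        return cls(
            t=arr[:, 0], p_rv=arr[:, 1], p_pa=arr[:, 2], servo=arr[:, 3],
            snd_tricuspid=snd_t.astype(float), snd_pulmonary=snd_p.astype(float),
            fs=float(fs_t), meta=meta,
        )


# ---------------------------------------------------------------------------
# per-cycle design state
# ---------------------------------------------------------------------------


def _cycle_settings(config: MCLConfig, n_cycles: int, rng: np.random.Generator,
                    cal: dict) -> np.ndarray:
    """Per-cycle resistance settings: schedule plus small per-cycle jitter
    (the rig's cycle-to-cycle variability)."""
    s = config.resistance_setting
    if np.isscalar(s):
        sched = np.full(n_cycles, float(s))
    else:
        s = np.asarray(s, dtype=float)
        if len(s) == n_cycles:
            sched = s.copy()
        else:
            sched = np.interp(
                np.linspace(0.0, 1.0, n_cycles),
                np.linspace(0.0, 1.0, len(s)), s,
            )
    p = cal["pressure"]
    jitter_sd = (
        p["setting_jitter_base"]
        + p["setting_jitter_span"] * np.clip(sched, 0.0, None)
    )
    return sched + rng.normal(0.0, 1.0, n_cycles) * jitter_sd


def _design(config: MCLConfig, n_cycles: int, rng: np.random.Generator,
            cal: dict | None = None) -> dict[str, np.ndarray]:
    """Noise-free per-cycle design state derived from the setting schedule."""
    cal = cal or _CAL
    p = cal["pressure"]
    s = _cycle_settings(config, n_cycles, rng, cal)
    pasp = p["pasp_base"] + p["pasp_span"] * s
    dia = p["dia_base"] + p["dia_span"] * s
    return {
        "setting": s,
        "pasp": pasp,
        "dia": dia,
        "rvsp": pasp + p["rv_offset"],
        "mrr": p["mrr_base"] + p["mrr_span"] * s,  # mmHg/s
        "mfr": p["mfr_base"] + p["mfr_span"] * s,  # magnitude, mmHg/s
    }


# ---------------------------------------------------------------------------
# channel generators
# ---------------------------------------------------------------------------


def generate_servo(duration: float, config: MCLConfig) -> np.ndarray:
    """Square servo pulse: high (1) during systole, low (0) during diastole."""
    if duration < config.cycle_period:
        raise ValueError("duration must cover at least one cycle")
    spc = config.samples_per_cycle
    n_cycles = int(duration / config.cycle_period)
    high = int(round(config.duty * spc))
    one_cycle = np.zeros(spc)
    one_cycle[:high] = 1.0
    return np.tile(one_cycle, n_cycles)


def _half_cos_rise(tau: np.ndarray, t0: float, T: float) -> np.ndarray:
    """0 -> 1 half-cosine ramp on [t0, t0+T]; max slope pi/(2T) at midpoint."""
    x = np.clip((tau - t0) / T, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _pressure_cycle(tau: np.ndarray, pasp: float, dia0: float, dia1: float,
                    mrr: float, mfr: float, t0: float) -> np.ndarray:
    """One cycle of PA pressure: half-cosine rise dia0 -> pasp with peak
    slope ``mrr``, half-cosine fall to dia1 with peak slope ``mfr``, then
    hold until the cycle ends."""
    amp_up = pasp - dia0
    T_r = np.pi * amp_up / (2.0 * mrr)
    amp_dn = pasp - dia1
    T_f = np.pi * amp_dn / (2.0 * mfr)
    up = dia0 + amp_up * _half_cos_rise(tau, t0, T_r)
    down = 1.0 - _half_cos_rise(tau, t0 + T_r, T_f)
    return np.where(tau < t0 + T_r, up, dia1 + amp_dn * down)


def generate_pressures(
    config: MCLConfig, duration: float, *, cal: dict | None = None,
    _design_state: dict | None = None, _rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-ventricular and pulmonary-artery pressure channels [mmHg].

    Smooth periodic templates whose per-cycle systolic peak, baseline and
    rising/falling rates follow the resistance-setting schedule, plus
    additive white measurement noise.
    """
    cal = cal or _CAL
    p = cal["pressure"]
    spc = config.samples_per_cycle
    n_cycles = int(duration / config.cycle_period)
    rng = _rng if _rng is not None else np.random.default_rng(config.seed)
    d = (
        _design_state
        if _design_state is not None
        else _design(config, n_cycles, rng, cal)
    )

    tau = np.arange(spc) / config.fs
    t0 = p["transmission_delay_s"]
    sysT = config.duty * config.cycle_period
    p_pa = np.empty(n_cycles * spc)
    p_rv = np.empty(n_cycles * spc)
    rv_dia = p["rv_dia"]
    bump = np.sin(np.pi * np.clip((tau - 0.01) / (sysT + 0.1), 0.0, 1.0)) ** 2
    for k in range(n_cycles):
        dia1 = d["dia"][k + 1] if k + 1 < n_cycles else d["dia"][k]
        p_pa[k * spc:(k + 1) * spc] = _pressure_cycle(
            tau, d["pasp"][k], d["dia"][k], dia1, d["mrr"][k], d["mfr"][k], t0
        )
        p_rv[k * spc:(k + 1) * spc] = rv_dia + (d["rvsp"][k] - rv_dia) * bump
    if config.noise_sd_pressure > 0:
        p_rv = p_rv + rng.normal(0.0, config.noise_sd_pressure, len(p_rv))
        p_pa = p_pa + rng.normal(0.0, config.noise_sd_pressure, len(p_pa))
    return p_rv, p_pa


def generate_valve_sounds(
    p_rv: np.ndarray, p_pa: np.ndarray, servo: np.ndarray, config: MCLConfig,
    bursts: tuple[BurstModel, BurstModel] | None = None, *,
    cal: dict | None = None, _design_state: dict | None = None,
    _rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricuspid and pulmonary valve vibration-sound channels [a.u.].

    Each cycle carries exactly one damped-sinusoid burst per valve: the
    tricuspid burst follows the servo rising edge (closure at systole
    onset), the pulmonary burst follows the falling edge (closure at
    diastole onset).  Burst amplitude grows with the transvalvular
    pressure proxy, the carrier frequency falls and the delay shortens as
    the resistance setting rises.
    """
    if not (len(p_rv) == len(p_pa) == len(servo)):
        raise ValueError("channels must be aligned")
    cal = cal or _CAL
    tri, pul = bursts if bursts is not None else default_burst_models(cal)
    spc = config.samples_per_cycle
    n_cycles = len(servo) // spc
    rng = _rng if _rng is not None else np.random.default_rng(config.seed + 1)
    d = (
        _design_state
        if _design_state is not None
        else _design(config, n_cycles, rng, cal)
    )

    fs = config.fs
    n = len(servo)
    snd_t = np.zeros(n)
    snd_p = np.zeros(n)
    nb = int(_BURST_LEN_S * fs)
    tau_b = np.arange(nb) / fs
    high = int(round(config.duty * spc))

    def add_burst(target: np.ndarray, i0: int, A: float, f_c: float, lam: float):
        wave = A * np.exp(-lam * tau_b) * np.sin(2.0 * np.pi * f_c * tau_b)
        j1 = min(i0 + nb, n)
        if i0 < n:
            target[i0:j1] += wave[: j1 - i0]

    for k in range(n_cycles):
        s = d["setting"][k]
        rise_i = k * spc
        fall_i = k * spc + high
        i_t = rise_i + int(round(tri.timing_fn(s) / 1000.0 * fs))
        i_p = fall_i + int(round(pul.timing_fn(s) / 1000.0 * fs))
        add_burst(snd_t, i_t, tri.amp_fn(d["rvsp"][k]),
                  tri.carrier_freq_fn(s), tri.damping)
        add_burst(snd_p, i_p, pul.amp_fn(d["pasp"][k]),
                  pul.carrier_freq_fn(s), pul.damping)
    if config.noise_sd_sound > 0:
        snd_t = snd_t + rng.normal(0.0, config.noise_sd_sound, n)
        snd_p = snd_p + rng.normal(0.0, config.noise_sd_sound, n)
    return snd_t, snd_p


def generate_recording(
    config: MCLConfig, duration: float, *, cal: dict | None = None,
    meta_extra: dict | None = None,
) -> Recording:
    """One complete synchronous recording of all five channels."""
    cal = cal or _CAL
    n_cycles = int(duration / config.cycle_period)
    if n_cycles < 1:
        raise ValueError("duration must cover at least one cycle")
    rng = np.random.default_rng(config.seed)
    d = _design(config, n_cycles, rng, cal)
    servo = generate_servo(duration, config)
    p_rv, p_pa = generate_pressures(
        config, duration, cal=cal, _design_state=d, _rng=rng
    )
    snd_t, snd_p = generate_valve_sounds(
        p_rv, p_pa, servo, config, cal=cal, _design_state=d, _rng=rng
    )
    t = np.arange(len(servo)) / config.fs
    sched = config.resistance_setting
    meta = {
        "fs": config.fs,
        "cycle_period": config.cycle_period,
        "duty": config.duty,
        "seed": config.seed,
        "noise_sd_pressure": config.noise_sd_pressure,
        "noise_sd_sound": config.noise_sd_sound,
        "n_cycles": n_cycles,
        "resistance_setting": (
            float(sched) if np.isscalar(sched) else np.asarray(sched).tolist()
        ),
        "design_pasp": d["pasp"].tolist(),
        "design_setting": d["setting"].tolist(),
        "design_mrr": d["mrr"].tolist(),
        "design_mfr": d["mfr"].tolist(),
    }
    if meta_extra:
        meta.update(meta_extra)
    return Recording(
        t=t, p_rv=p_rv, p_pa=p_pa, servo=servo,
        snd_tricuspid=snd_t, snd_pulmonary=snd_p, fs=config.fs, meta=meta,
    )


# ---------------------------------------------------------------------------
# study datasets
# ---------------------------------------------------------------------------


def generate_six_state_dataset(
    seed: int = 0, duration: float = 300.0, config: MCLConfig | None = None,
) -> list[Recording]:
    """Six discrete resistance states, 5 min each, increasing PASP ladder."""
    cal = _CAL
    base = config or MCLConfig()
    recs = []
    for i, pasp in enumerate(cal["six_state_pasp"]):
        cfg = replace(
            base,
            resistance_setting=setting_for_pasp(pasp, cal),
            seed=(seed * 1009 + i) % 2**31,
        )
        recs.append(generate_recording(cfg, duration, meta_extra={"state": i + 1}))
    return recs


def _triangular_schedule(n_cycles: int, s_lo: float, s_hi: float) -> np.ndarray:
    """Up-then-down sweep of the resistance setting over the run."""
    half = n_cycles // 2
    up = np.linspace(s_lo, s_hi, half)
    down = np.linspace(s_hi, s_lo, n_cycles - half)
    return np.concatenate([up, down])


def generate_continuous_dataset(
    seed: int = 0, duration: float = 600.0, n_runs: int = 5,
    config: MCLConfig | None = None,
) -> list[Recording]:
    """Continuous resistance sweeps: ``n_runs`` recordings of ``duration``
    seconds whose per-cycle PASP sweeps up and back down across each run's
    design range (~38–94 mmHg overall)."""
    cal = _CAL
    base = config or MCLConfig()
    n_cycles = int(duration / base.cycle_period)
    ranges = cal["continuous_pasp_ranges"]
    recs = []
    for i in range(n_runs):
        lo, hi = ranges[i % len(ranges)]
        sched = _triangular_schedule(
            n_cycles, setting_for_pasp(lo, cal), setting_for_pasp(hi, cal)
        )
        cfg = replace(
            base, resistance_setting=sched, seed=(seed * 1013 + i) % 2**31
        )
        recs.append(generate_recording(cfg, duration, meta_extra={"run": i + 1}))
    return recs
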