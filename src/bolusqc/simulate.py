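"""Synthetic injector bench: generates photometric TC-recordings.

No bench recordings ship with this package, so a physically motivated
simulator stands in for the sensor.  It reproduces the structural
features the analysis assumes:

* a >= 10 s saline baseline before the contrast reaches the sensor,
* piston-syringe (PS) pumps with near-constant flow vs roller pumps (RP)
  with pulsatile flow, both with a pressure- and viscosity-limited ramp,
* tube-line dilution modelled as a tanks-in-series cascade whose
  effective mixing grows with line filling volume and shrinks with
  contrast-medium viscosity (more viscous boluses resist dissolution
  into the saline propellant),
* Beer-Lambert photometric readout sampled at 12.2 Hz with additive
  Gaussian sensor noise, seeded and fully reproducible.

The dispersion and pulsatility coefficients are interpretable knobs, not
vendor calibrations; they are chosen so the simulated bench shows the
qualitative contrasts a real one does (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import (
    DEFAULT_SAMPLING_HZ,
    WATER_VISCOSITY_MPA_S,
    CMType,
    InjectionProtocol,
    InjectorConfig,
    PumpType,
    StudyDesign,
    TCRecording,
    stable_seed,
)

__all__ = [
    "SimulationConfig",
    "FlowProfile",
    "TransportResult",
    "SimulationError",
    "make_flow_profile",
    "simulate_transport",
    "sensor_readout",
    "simulate_recording",
    "generate_study",
]

MAX_TANKS = 400
MAX_STEPS_PER_S = 10_000


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic bench; defaults define the study conditions."""

    n_tanks_base: int = 120         # mixing discretization scale
    dispersion_scale: float = 1.0   # multiplies line-volume-driven mixing
    pulsatility_amp: float = 0.3    # RP flow modulation, fraction of set flow
    pulsatility_hz: float = 1.5     # roller passage rate
    ramp_viscosity_coeff: float = 0.05  # s * pressure / (mPa*s * ml/s)
    noise_sd: float = 2.0           # sensor-intensity units
    epsilon_path: float = 1.0       # absorbance at full contrast concentration
    baseline_intensity: float = 1000.0
    day_jitter_frac: float = 0.01   # day-to-day baseline intensity drift
    washout_threshold: float = 1e-3  # outlet concentration treated as clear
    tail_s: float = 2.0             # recorded tail after washout
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tanks_base < 1:
            raise SimulationError("n_tanks_base must be >= 1")
        if self.dispersion_scale < 0:
            raise SimulationError("dispersion_scale must be >= 0")
        if not 0 <= self.pulsatility_amp < 1:
            raise SimulationError("pulsatility_amp must be in [0, 1)")
        if self.pulsatility_hz <= 0 or self.sampling_hz <= 0:
            raise SimulationError("rates must be positive")
        if (
            self.noise_sd < 0
            or self.epsilon_path <= 0
            or self.baseline_intensity <= 0
        ):
            raise SimulationError("bad sensor parameters")


@dataclass(frozen=True)
class FlowProfile:
    """Pump-side flow and inlet contrast concentration on a fine grid."""

    time_s: np.ndarray   # left edges of integration steps
    q_ml_s: np.ndarray   # volumetric flow per step
    c_in: np.ndarray     # inlet CM concentration per step (0..1)
    dt: float
    set_flow_ml_s: float

    @property
    def delivered_cm_ml(self) -> float:
        return float(np.sum(self.q_ml_s * self.c_in) * self.dt)


@dataclass(frozen=True)
class TransportResult:
    """Outlet concentration of the tube-line cascade."""

    time_s: np.ndarray
    c_out: np.ndarray
    q_ml_s: np.ndarray
    n_tanks: int
    delivered_cm_ml: float  # in-scheme cumulative CM volume past the outlet


def viscosity_ratio(cm_type: CMType) -> float:
    return cm_type.viscosity_mpa_s / WATER_VISCOSITY_MPA_S


def ramp_time_s(
    injector: InjectorConfig, protocol: InjectionProtocol, cfg: SimulationConfig
) -> float:
    """Pressure-limited flow ramp: slower for viscous media, fast pumps."""
    return (
        cfg.ramp_viscosity_coeff
        * protocol.cm_type.viscosity_mpa_s
        * protocol.flow_rate_ml_s
        / injector.max_pressure
    )


def make_flow_profile(
    injector: InjectorConfig,
    protocol: InjectionProtocol,
    cfg: SimulationConfig,
) -> FlowProfile:
    """Commanded pump output: delay, ramp, plateau, saline chaser.

    The pump is idle for the injection delay, ramps to the set flow over
    the viscosity/pressure-limited ramp time, and keeps pumping until it
    has delivered the contrast volume plus the saline flush (tube-line
    volume + per-protocol flush, the bench's washout rule).  Roller
    pumps additionally modulate the flow sinusoidally.  Inlet
    concentration is 1 exactly while the commanded contrast volume
    passes the pump, with fractional edge steps so the delivered
    contrast volume is exact.
    """
    flow = protocol.flow_rate_ml_s
    t_inj = protocol.cm_volume_ml / flow
    ramp = ramp_time_s(injector, protocol, cfg)
    if ramp >= t_inj / 2.0:
        raise SimulationError(
            f"underpowered configuration: ramp {ramp:.3f} s >= half the "
            f"{t_inj:.3f} s injection of {protocol.protocol_id} on "
            f"{injector.injector_id}"
        )
    flush_ml = injector.line_volume_ml + protocol.saline_flush_ml
    target_ml = protocol.cm_volume_ml + flush_ml
    delay = protocol.injection_delay_s
    dt = 1.0 / (10.0 * cfg.sampling_hz)
    est = delay + ramp + target_ml / flow + 2.0
    t = np.arange(0.0, est, dt)
    tp = t - delay  # time since pump start
    q = np.clip(tp / ramp, 0.0, 1.0) * flow if ramp > 0 else np.where(
        tp >= 0, flow, 0.0
    )
    q = np.where(tp >= 0, q, 0.0)
    if injector.pump_type is PumpType.RP and cfg.pulsatility_amp > 0:
        q = q * (
            1.0
            + cfg.pulsatility_amp
            * np.sin(2.0 * math.pi * cfg.pulsatility_hz * np.maximum(tp, 0.0))
        )
    cum = np.concatenate([[0.0], np.cumsum(q) * dt])
    q = np.where(cum[:-1] < target_ml, q, 0.0)
    # fractional overlap of each step's pumped volume with [0, cm_volume]
    v0, v1 = cum[:-1], cum[1:]
    dv = v1 - v0
    overlap = np.clip(np.minimum(v1, protocol.cm_volume_ml) - v0, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_in = np.where(dv > 0, np.clip(overlap / np.where(dv > 0, dv, 1.0), 0.0, 1.0), 0.0)
    return FlowProfile(
        time_s=t, q_ml_s=q, c_in=c_in, dt=dt, set_flow_ml_s=flow
    )


def n_tanks(line_volume_ml: float, cm_type: CMType, cfg: SimulationConfig) -> int:
    """Cascade length: fewer tanks = stronger mixing.

    Mixing strength scales with line volume (longer residence, more
    intermixture with the saline propellant) and inversely with
    contrast-medium viscosity (Stokes-Einstein direction: viscous boluses
    diffuse less).
    """
    if cfg.dispersion_scale == 0:
        return MAX_TANKS
    raw = cfg.n_tanks_base * viscosity_ratio(cm_type) / (
        cfg.dispersion_scale * line_volume_ml
    )
    return int(min(MAX_TANKS, max(1, round(raw))))


def _march(
    c: np.ndarray,
    q: np.ndarray,
    c_in: np.ndarray,
    dt: float,
    tank_volume_ml: float,
    n_sub: int,
) -> tuple[np.ndarray, float]:
    """Explicit conservative update of the cascade; returns the outlet
    series (one value per coarse step) and the CM volume carried out."""
    out = np.empty(q.size)
    delivered = 0.0
    dt_sub = dt / n_sub
    single = c.size == 1
    for k in range(q.size):
        qk = float(q[k])
        alpha = qk * dt_sub / tank_volume_ml
        cin = float(c_in[k])
        for _ in range(n_sub):
            delivered += qk * dt_sub * c[-1]
            if single:
                c[0] += alpha * (cin - c[0])
            else:
                # RHS evaluated before assignment: synchronous update
                c[1:] += alpha * (c[:-1] - c[1:])
                c[0] += alpha * (cin - c[0])
        out[k] = c[-1]
    return out, float(delivered)


def simulate_transport(
    profile: FlowProfile,
    line_volume_ml: float,
    cm_type: CMType,
    cfg: SimulationConfig,
    extend_until_clear: bool = True,
) -> TransportResult:
    """Push the commanded profile through the tube-line cascade.

    The line is a chain of equal well-mixed tanks summing to the line
    filling volume, advanced by explicit volume-balance updates
    (sub-stepped so no tank turns over more than half its volume per
    step) — exactly mass conserving by construction.  With
    ``extend_until_clear`` the pump keeps pushing saline at the set flow
    beyond the commanded flush until the outlet concentration falls
    below the washout threshold, so every recording ends on baseline.
    """
    if line_volume_ml <= 0:
        raise SimulationError("line_volume_ml must be > 0")
    n = n_tanks(line_volume_ml, cm_type, cfg)
    v_tank = line_volume_ml / n
    q_max = float(np.max(profile.q_ml_s))
    if q_max <= 0:
        raise SimulationError("profile has no flow")
    n_sub = max(1, math.ceil(q_max * profile.dt / (0.5 * v_tank)))
    if n_sub / profile.dt > MAX_STEPS_PER_S:
        raise SimulationError(
            f"stability needs {n_sub / profile.dt:.0f} steps/s "
            f"(> {MAX_STEPS_PER_S}); line too finely divided for this flow"
        )
    c = np.zeros(n)
    out, delivered = _march(
        c, profile.q_ml_s, profile.c_in, profile.dt, v_tank, n_sub
    )
    times = [profile.time_s]
    outs = [out]
    qs = [profile.q_ml_s]
    if extend_until_clear and out[-1] >= cfg.washout_threshold:
        q_ext = profile.set_flow_ml_s
        chunk_s = max(2.0, 2.0 * line_volume_ml / q_ext)
        m = int(round(chunk_s / profile.dt))
        t_end = profile.time_s[-1] + profile.dt
        max_extra_ml = 60.0 * line_volume_ml
        pumped = 0.0
        while outs[-1][-1] >= cfg.washout_threshold and pumped < max_extra_ml:
            q_chunk = np.full(m, q_ext)
            c_chunk = np.zeros(m)
            out_ext, d_ext = _march(
                c, q_chunk, c_chunk, profile.dt, v_tank, n_sub
            )
            delivered += d_ext
            times.append(t_end + profile.dt * np.arange(m))
            outs.append(out_ext)
            qs.append(q_chunk)
            t_end += profile.dt * m
            pumped += q_ext * profile.dt * m
    return TransportResult(
        time_s=np.concatenate(times),
        c_out=np.concatenate(outs),
        q_ml_s=np.concatenate(qs),
        n_tanks=n,
        delivered_cm_ml=float(delivered),
    )


def sensor_readout(
    time_s: np.ndarray,
    c_out: np.ndarray,
    cfg: SimulationConfig,
    seed: int,
    intensity_scale: float = 1.0,
    recording_id: str = "sim",
    **metadata,
) -> TCRecording:
    """Beer-Lambert photometric sampling of an outlet concentration trace.

    Intensity = baseline * exp(-epsilon_path * c) plus seeded Gaussian
    noise, resampled to the nominal acquisition rate.  The recording
    runs from t = 0 (pre-injection baseline included) until the
    concentration has stayed below the washout threshold for the
    configured tail.
    """
    c_out = np.asarray(c_out, dtype=float)
    if np.any(c_out < -1e-9) or np.any(c_out > 1.0 + 1e-9):
        raise SimulationError("concentrations must lie in [0, 1]")
    above = np.flatnonzero(c_out >= cfg.washout_threshold)
    if above.size:
        t_end = min(float(time_s[above[-1]]) + cfg.tail_s, float(time_s[-1]))
    else:
        t_end = float(time_s[-1])
    n_samp = int(math.floor(t_end * cfg.sampling_hz)) + 1
    t_samp = np.arange(n_samp) / cfg.sampling_hz
    c_samp = np.interp(t_samp, time_s, c_out)
    rng = np.random.default_rng(seed)
    base = cfg.baseline_intensity * intensity_scale
    signal = base * np.exp(-cfg.epsilon_path * c_samp)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=n_samp)
    return TCRecording(
        recording_id=recording_id,
        time_s=t_samp,
        signal=signal,
        sampling_hz=cfg.sampling_hz,
        **metadata,
    )


def simulate_recording(
    injector: InjectorConfig,
    protocol: InjectionProtocol,
    cfg: SimulationConfig,
    day: int = 1,
) -> TCRecording:
    """One synthetic bench recording for an (injector, protocol, day)."""
    profile = make_flow_profile(injector, protocol, cfg)
    transport = simulate_transport(
        profile, injector.line_volume_ml, protocol.cm_type, cfg
    )
    rec_seed = stable_seed(
        cfg.seed, injector.injector_id, protocol.protocol_id, day
    )
    day_rng = np.random.default_rng(stable_seed(cfg.seed, "day", day))
    jitter = 1.0 + cfg.day_jitter_frac * float(day_rng.standard_normal())
    rec_id = f"{injector.injector_id}__{protocol.protocol_id}__d{day}"
    return sensor_readout(
        transport.time_s,
        np.clip(transport.c_out, 0.0, 1.0),
        cfg,
        seed=rec_seed,
        intensity_scale=jitter,
        recording_id=rec_id,
        injector_id=injector.injector_id,
        protocol_id=protocol.protocol_id,
        day=day,
        cm_type=protocol.cm_type,
    )


def generate_study(
    design: StudyDesign, cfg: SimulationConfig
) -> list[TCRecording]:
    """All recordings of a bench study: one per (injector, protocol, day).

    Per-recording seeds derive from a stable hash of the master seed and
    the identifiers, so adding a protocol or injector never perturbs the
    existing recordings.
    """
    recordings = []
    for injector in design.injectors:
        for protocol in design.protocols:
            for day in range(1, design.days + 1):
                recordings.append(
                    simulate_recording(injector, protocol, cfg, day=day)
                )
    return recordings
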