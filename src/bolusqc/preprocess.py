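"""Baseline estimation, deflection conversion and recording validity.

The photometric sensor reports transmitted light, so dye in the probe line
*dips* the raw intensity.  Downstream analysis works on a positive-up
"deflection" proportional to dye concentration.  Two conversions are
available: ``beer_lambert`` (absorbance, physically correct for a
photometric cell) and ``linear`` (relative intensity drop, a
small-absorbance approximation).  A recording is only admitted to the
group statistics if its trace returns to baseline within two standard
deviations of the pre-injection baseline noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import TCRecording

__all__ = [
    "BaselineEstimate",
    "CleanCurve",
    "PreprocessingError",
    "estimate_baseline",
    "to_deflection",
    "check_validity",
    "clean_recording",
]

MIN_BASELINE_SAMPLES = 10


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineEstimate:
    """Mean and SD of the raw signal over the pre-injection window."""

    mean: float
    sd: float
    window: tuple[float, float]
    n_samples: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise PreprocessingError("baseline sd must be >= 0")


@dataclass
class CleanCurve:
    """Deflection (concentration-proportional) series for one recording."""

    recording_id: str
    time_s: np.ndarray
    deflection: np.ndarray
    baseline: BaselineEstimate
    mode: str
    noise_sd_deflection: float
    sampling_hz: float
    valid: bool = True
    validity_notes: list[str] = field(default_factory=list)
    validity_checked: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.time_s)


def estimate_baseline(
    rec: TCRecording, window_s: float = 10.0
) -> BaselineEstimate:
    """Mean/SD of the raw signal over the first ``window_s`` seconds.

    The bench protocol starts each injection with a contrast-delay so the
    first ~10 s of every recording are pure saline baseline.
    """
    if window_s < 1.0:
        raise PreprocessingError("baseline window must be at least 1 s")
    t0 = rec.time_s[0]
    mask = rec.time_s - t0 < window_s
    if rec.duration_s <= window_s:
        raise PreprocessingError(
            f"{rec.recording_id}: recording ({rec.duration_s:.2f} s) does "
            f"not extend beyond the baseline window ({window_s} s)"
        )
    n = int(mask.sum())
    if n < MIN_BASELINE_SAMPLES:
        raise PreprocessingError(
            f"{rec.recording_id}: only {n} baseline samples in first "
            f"{window_s} s (need >= {MIN_BASELINE_SAMPLES})"
        )
    vals = rec.signal[mask]
    return BaselineEstimate(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        window=(float(t0), float(t0 + window_s)),
        n_samples=n,
    )


def to_deflection(
    rec: TCRecording,
    baseline: BaselineEstimate,
    mode: str = "beer_lambert",
) -> CleanCurve:
    """Convert raw intensity to a positive-up concentration proxy.

    ``beer_lambert``: deflection = -log(signal / baseline mean), i.e. the
    absorbance relative to the saline-filled line; ``linear``: relative
    intensity drop (baseline - signal) / baseline.  In both modes the
    baseline noise SD is propagated to deflection units by the delta
    method (sd/mean to first order in both cases), so the two-SD
    return-to-baseline rule stays dimensionally coherent.
    """
    if mode not in ("beer_lambert", "linear"):
        raise PreprocessingError(f"unknown deflection mode {mode!r}")
    if baseline.mean <= 0:
        raise PreprocessingError("baseline mean must be positive")
    if mode == "beer_lambert":
        bad = np.flatnonzero(rec.signal <= 0)
        if bad.size:
            raise PreprocessingError(
                f"{rec.recording_id}: nonpositive signal at sample index "
                f"{int(bad[0])} (beer_lambert mode)"
            )
        deflection = -np.log(rec.signal / baseline.mean)
    else:
        deflection = (baseline.mean - rec.signal) / baseline.mean
    return CleanCurve(
        recording_id=rec.recording_id,
        time_s=rec.time_s.copy(),
        deflection=deflection,
        baseline=baseline,
        mode=mode,
        noise_sd_deflection=baseline.sd / baseline.mean,
        sampling_hz=rec.sampling_hz,
    )


def check_validity(
    curve: CleanCurve,
    k_sd: float = 2.0,
    tail_s: float = 2.0,
    baseline_stability_frac: float = 0.05,
) -> CleanCurve:
    """Annotate a curve with the bench recording-validity rules.

    A recording only counts if, over its final ``tail_s`` seconds, the
    mean deflection has returned to within ``k_sd`` baseline noise SDs of
    zero.  A second, advisory check flags baselines whose noise exceeds
    ``baseline_stability_frac`` of the peak deflection.  Idempotent.
    """
    notes: list[str] = []
    tail = curve.time_s >= curve.time_s[-1] - tail_s
    tail_mean = float(np.mean(curve.deflection[tail]))
    tol = k_sd * curve.noise_sd_deflection
    if abs(tail_mean) > tol:
        notes.append("no_return_to_baseline")
    w0, w1 = curve.baseline.window
    base = (curve.time_s >= w0) & (curve.time_s < w1)
    peak = float(np.max(np.abs(curve.deflection)))
    if peak > 0:
        base_sd = float(np.std(curve.deflection[base], ddof=1))
        if base_sd > baseline_stability_frac * peak:
            notes.append("unstable_baseline")
    return replace(
        curve,
        valid="no_return_to_baseline" not in notes,
        validity_notes=notes,
        validity_checked=True,
    )


def clean_recording(
    rec: TCRecording,
    window_s: float = 10.0,
    mode: str = "beer_lambert",
    k_sd: float = 2.0,
    tail_s: float = 2.0,
) -> CleanCurve:
    """Baseline -> deflection -> validity in one call."""
    baseline = estimate_baseline(rec, window_s=window_s)
    curve = to_deflection(rec, baseline, mode=mode)
    return check_validity(curve, k_sd=k_sd, tail_s=tail_s)
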