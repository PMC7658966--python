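import math

import numpy as np
import pytest

from bolusqc.preprocess import BaselineEstimate, CleanCurve

FS = 12.2


def make_curve(
    deflection,
    fs: float = FS,
    noise_sd_deflection: float = 0.0,
    recording_id: str = "test",
    valid: bool = True,
) -> CleanCurve:
    """Wrap a raw deflection array as a CleanCurve on a regular grid."""
    deflection = np.asarray(deflection, dtype=float)
    t = np.arange(deflection.size) / fs
    baseline = BaselineEstimate(
        mean=1000.0,
        sd=noise_sd_deflection * 1000.0,
        window=(0.0, max(1.0, t[-1] / 4)),
        n_samples=max(10, deflection.size // 4),
    )
    return CleanCurve(
        recording_id=recording_id,
        time_s=t,
        deflection=deflection,
        baseline=baseline,
        mode="beer_lambert",
        noise_sd_deflection=noise_sd_deflection,
        sampling_hz=fs,
        valid=valid,
    )


def boxcar_deflection(
    n: int, i_on: int, i_off: int, baseline: float = 0.0, plateau: float = 1.0
) -> np.ndarray:
    d = np.full(n, baseline)
    d[i_on:i_off] = plateau
    return d


def brute_force_boxcar_sse(d) -> float:
    """Independent exhaustive scan over every changepoint pair.

    Plain running-sum arithmetic, no shared code with the fitter: for
    each admissible (i_on, i_off) with non-empty outside region and
    plateau mean >= baseline mean, accumulate the two-level SSE and
    keep the minimum.
    """
    d = [float(x) for x in d]
    n = len(d)
    tot1 = sum(d)
    tot2 = sum(x * x for x in d)
    best = math.inf
    for i in range(n):
        s1 = 0.0
        s2 = 0.0
        for j in range(i + 1, n + 1):
            s1 += d[j - 1]
            s2 += d[j - 1] * d[j - 1]
            m = j - i
            n_out = n - m
            if n_out == 0:
                continue
            mean_in = s1 / m
            mean_out = (tot1 - s1) / n_out
            if mean_in < mean_out:
                continue
            sse = (
                (s2 - 2 * mean_in * s1 + m * mean_in**2)
                + ((tot2 - s2) - 2 * mean_out * (tot1 - s1) + n_out * mean_out**2)
            )
            if sse < best:
                best = sse
    return best


def random_test_curves(rng: np.random.Generator, n_curves: int, max_n: int):
    """Mixture of noisy boxcars, smoothed boluses and pure noise."""
    curves = []
    for _ in range(n_curves):
        n = int(rng.integers(20, max_n + 1))
        kind = rng.integers(3)
        if kind == 0:
            d = rng.normal(0.0, 1.0, n)
        else:
            i_on = int(rng.integers(1, n - 2))
            i_off = int(rng.integers(i_on + 1, n))
            d = boxcar_deflection(
                n, i_on, i_off, baseline=0.0, plateau=float(rng.uniform(0.5, 3))
            )
            d = d + rng.normal(0.0, 0.2, n)
            if kind == 2:  # blur the flanks
                k = np.ones(5) / 5
                d = np.convolve(d, k, mode="same")
        curves.append(d)
    return curves


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
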