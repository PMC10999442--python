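import numpy as np
import pandas as pd
import pytest

from ovitherm import TemperatureTrace


def make_trace(
    tc: np.ndarray,
    animal_id: str = "X-01",
    start: str = "2024-01-01",
    interval_min: int = 5,
    activity=None,
) -> TemperatureTrace:
    ts = pd.date_range(start, periods=len(tc), freq=f"{interval_min}min")
    return TemperatureTrace(animal_id=animal_id, timestamps=ts, tc=np.asarray(tc, float),
                            activity=activity)


def cosine_trace(
    mesor: float = 39.0,
    amplitude: float = 0.4,
    acrophase_h: float = 18.0,
    days: int = 3,
    interval_min: int = 5,
    start: str = "2024-01-01",
    noise: np.ndarray | None = None,
) -> TemperatureTrace:
    n = days * 1440 // interval_min
    t_h = np.arange(n) * interval_min / 60.0
    tc = mesor + amplitude * np.cos(2 * np.pi * (t_h - acrophase_h) / 24.0)
    if noise is not None:
        tc = tc + noise
    return make_trace(tc, start=start, interval_min=interval_min)


# --- independent brute-force oracles (kept naive on purpose) ---------------

def naive_running_mean(tc: np.ndarray, k: int, i: int) -> float:
    """Mean of tc over the index window [i-k, i+k], truncated at the edges."""
    lo, hi = max(0, i - k), min(len(tc) - 1, i + k)
    total = 0.0
    for j in range(lo, hi + 1):
        total += tc[j]
    return total / (hi - lo + 1)


def naive_sih(tc, timestamps, k, start, window_min, interval_min):
    """Enumerate the window samples and sum (tc - naive running mean) x dt."""
    start = pd.Timestamp(start)
    end = start + pd.Timedelta(minutes=window_min)
    total, peak = 0.0, -np.inf
    for i, t in enumerate(timestamps):
        if start <= t < end:
            d = tc[i] - naive_running_mean(tc, k, i)
            total += d
            peak = max(peak, d)
    return interval_min * total, peak


def grid_search_cosinor(t_hours, y, period_h=24.0, phase_step_h=0.005):
    """Scan acrophase on a fine grid; per phase the (M, A) fit is linear."""
    omega = 2 * np.pi / period_h
    best = None
    for phi in np.arange(0.0, period_h, phase_step_h):
        x = np.cos(omega * (t_hours - phi))
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, coef[0], coef[1], phi)
    rss, mesor, amp, phi = best
    if amp < 0:  # negative amplitude = the antiphase solution
        amp, phi = -amp, (phi + period_h / 2) % period_h
    return {"mesor": mesor, "amplitude": amp, "acrophase": phi, "rss": rss}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
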