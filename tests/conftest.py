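import numpy as np
import pandas as pd
import pytest

import polarsa as ps
from polarsa import receptor_models as rm
from polarsa.datasets import default_profiles


def hourly_frame(n_hours: int = 72, **overrides) -> pd.DataFrame:
    """Small well-formed hourly table with deterministic filler values."""
    rng = np.random.default_rng(7)
    idx = pd.date_range("2018-01-01", periods=n_hours, freq="h")
    df = pd.DataFrame(
        {
            "timestamp": idx,
            "ws": rng.uniform(0.5, 8, n_hours),
            "wd": rng.uniform(0, 360, n_hours),
            "temp": rng.uniform(2, 25, n_hours),
            "rh": rng.uniform(30, 95, n_hours),
            "pm25": rng.uniform(5, 40, n_hours),
            "pm10": rng.uniform(45, 90, n_hours),
            "nox": rng.uniform(10, 80, n_hours),
            "no2": rng.uniform(5, 30, n_hours),
            "co": rng.uniform(0.2, 2.5, n_hours),
            "so2": rng.uniform(1, 10, n_hours),
        }
    )
    for col, vals in overrides.items():
        df[col] = vals
    return df


def cmb_benchmark(seed: int, n_samples: int = 50, noise_cv: float = 0.05):
    """Two-source x four-species speciation simulation with known truth."""
    rng = np.random.default_rng(seed)
    prof = default_profiles(["traffic", "rwb"])
    prof = rm.ProfileMatrix(F=prof.F[["OC", "EC", "K", "Si"]])
    F = prof.F.to_numpy()
    g_true = np.abs(rng.normal([10, 30], [3, 8], (n_samples, 2)))
    x0 = g_true @ F
    sigma = noise_cv * x0 + 1e-3
    x = x0 + rng.normal(0, 1, x0.shape) * sigma
    samples = rm.SpeciatedSamples(
        X=pd.DataFrame(x, columns=prof.F.columns),
        sigma=pd.DataFrame(sigma, columns=prof.F.columns),
    )
    return samples, prof, g_true


def match_factors(F_hat: np.ndarray, F_true: np.ndarray) -> list[tuple[int, int]]:
    """Greedy best-correlation assignment of fitted factors to truth rows
    (handles PMF permutation ambiguity)."""
    p = F_true.shape[0]
    corr = np.corrcoef(np.vstack([F_hat, F_true]))[:p, p:]
    pairs, used_hat, used_true = [], set(), set()
    for _ in range(p):
        best = None
        for i in range(p):
            for j in range(p):
                if i in used_hat or j in used_true:
                    continue
                if best is None or corr[i, j] > corr[best]:
                    best = (i, j)
        pairs.append(best)
        used_hat.add(best[0])
        used_true.add(best[1])
    return pairs


def brute_force_inertia(X: np.ndarray, k: int) -> float:
    """Exhaustive-enumeration k-means optimum (oracle for tiny fixtures)."""
    from itertools import product

    n = len(X)
    best = np.inf
    for labels in product(range(k), repeat=n):
        inertia = 0.0
        for j in range(k):
            members = X[[i for i in range(n) if labels[i] == j]]
            if len(members):
                inertia += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return float(best)


@pytest.fixture(scope="session")
def temuco_run() -> ps.PipelineResult:
    """One-year wood-smoke-dominated scenario run end to end (shared)."""
    scenario, archetypes = ps.temuco_like_scenario(n_days=365)
    return ps.run_synthetic_pipeline(
        scenario, archetypes, "pm25", "temperature", k=3, seed=0, noise_cv=0.1
    )
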