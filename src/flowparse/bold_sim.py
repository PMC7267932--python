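"""Synthetic ROI BOLD time series and behavioural-rating simulation.

Generates region-of-interest time series with exactly the statistical
structure the GLM assumes — a known linear response to the design
matrix in percent-signal-change units around a grand mean of 100, slow
cosine drift, and stationary AR(1) noise — so that parameter-recovery
tests have a ground truth.  A companion generator draws visual-analog
self-/object-motion sensation ratings with the qualitative condition
structure observed behaviourally (Onboard evoking the strongest
self-motion sensation, Static the weakest sensations of either kind).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from flowparse.glm import DesignMatrix


@dataclass
class SimSpec:
    """Ground-truth generative parameters for one simulated scan.

    ``betas`` are per-regressor response amplitudes in PSC units
    (percent of the 100 baseline at regressor peak); ``drift_amplitudes``
    scale zero-mean cosines at the slowest scan frequencies (periods
    2nT/k), i.e. exactly the components a 128 s high-pass filter is
    meant to remove.
    """

    betas: np.ndarray
    rho: float = 0.4
    noise_sd: float = 1.0
    drift_amplitudes: tuple[float, ...] = (1.0, 0.5)
    seed: int = 0
    n_regions: int = 1
    n_volumes_expected: int | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_volumes_expected is not None and self.n_volumes_expected < 16:
            raise ValueError("simulated scans need at least 16 volumes")


def _ar1_noise(
    rng: np.random.Generator, n: int, m: int, rho: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal SD ``sd``, shape (n, m)."""
    if sd == 0:
        return np.zeros((n, m))
    e = np.empty((n, m))
    e[0] = rng.standard_normal(m) * sd
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    w = rng.standard_normal((n - 1, m)) * innov_sd
    for t in range(1, n):
        e[t] = rho * e[t - 1] + w[t - 1]
    return e


def simulate_roi_timeseries(
    X: DesignMatrix, spec: SimSpec
) -> tuple[np.ndarray, dict]:
    """Simulate ROI series from a design matrix and a truth spec.

    Y = 100 + centred task signal (X @ betas, PSC units) + centred
    drift + AR(1) noise, one column per region; the whole-scan mean is
    100 by construction up to noise.  Returns (Y, truth) where truth
    records the betas, rho and noise level for recovery assertions.
    """
    n = X.n_volumes
    if spec.n_volumes_expected is not None and spec.n_volumes_expected != n:
        raise ValueError("design length does not match the simulation spec")
    if spec.betas.shape[0] != X.matrix.shape[1]:
        raise ValueError(
            f"spec has {spec.betas.shape[0]} betas for "
            f"{X.matrix.shape[1]} regressors"
        )
    rng = np.random.default_rng(spec.seed)
    signal = X.matrix @ spec.betas
    signal = signal - signal.mean()

    t = np.arange(n)
    drift = np.zeros(n)
    for k, amp in enumerate(spec.drift_amplitudes, start=1):
        comp = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n))
        drift += amp * (comp - comp.mean())

    noise = _ar1_noise(rng, n, spec.n_regions, spec.rho, spec.noise_sd)
    Y = 100.0 + (signal + drift)[:, None] + noise
    truth = {
        "betas": spec.betas.copy(),
        "rho": spec.rho,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return Y, truth


def draw_subject_betas(
    group_betas: np.ndarray,
    n_subjects: int,
    between_subject_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subject-level betas around group means (normal random effects)."""
    group = np.asarray(group_betas, dtype=float)
    return group[None, :] + between_subject_sd * rng.standard_normal(
        (n_subjects, group.size)
    )


def save_timeseries(
    Y: np.ndarray, tr: float, path: str | Path, truth: dict | None = None
) -> None:
    """Write series as TSV (rows = volumes) with a JSON sidecar."""
    path = Path(path)
    cols = [f"region_{i:02d}" for i in range(Y.shape[1])]
    pd.DataFrame(Y, columns=cols).to_csv(path, sep="\t", index=False)
    sidecar = {"TR": tr, "n_volumes": int(Y.shape[0])}
    if truth is not None:
        sidecar["truth"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in truth.items()
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_timeseries(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a series TSV plus sidecar; returns (Y, TR)."""
    path = Path(path)
    Y = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Y, float(sidecar["TR"])


# ---------------------------------------------------------------------------
# Behavioural ratings
# ---------------------------------------------------------------------------

#: group-mean visual-analog scores (0-10) per condition, chosen to
#: reflect the behavioural pattern: self-motion sensation strongest when
#: riding the object (Onboard), object-motion sensation equally strong
#: whenever the object visibly moves, and near-floor sensations for
#: static frames.
SMS_MEANS = {"Static": 0.5, "Onboard": 8.0, "Joint": 5.0, "Disjoint": 5.5}
OMS_MEANS = {"Static": 0.5, "Offboard": 7.0, "Joint": 7.0, "Disjoint": 7.0}


def simulate_vas_ratings(
    seed: int, n_subjects: int = 14, subject_sd: float = 1.0
) -> dict[str, pd.DataFrame]:
    """Simulate SMS and OMS rating tables (subjects x conditions).

    SMS is undefined for Offboard (no self-motion component) and OMS
    for Onboard (no object on screen), so each table covers the four
    conditions for which the rating exists.  Scores are clipped to the
    0-10 visual-analog range.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, means in (("SMS", SMS_MEANS), ("OMS", OMS_MEANS)):
        conds = list(means)
        vals = np.array([means[c] for c in conds])
        scores = vals[None, :] + subject_sd * rng.standard_normal(
            (n_subjects, len(conds))
        )
        out[name] = pd.DataFrame(
            np.clip(scores, 0.0, 10.0),
            index=[f"sub{i + 1:02d}" for i in range(n_subjects)],
            columns=conds,
        )
    return out
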