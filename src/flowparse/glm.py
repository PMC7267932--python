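"""Parametric-modulation GLM for event-related ROI time series.

The train-experiment model has 15 task regressors per scan, in this
fixed order: a "movement" regressor spanning every non-Static trial
with its two objective modulators (movement*QoM, movement*SoM), the
five condition regressors (Offboard, Onboard, Joint, Disjoint, Static),
six subjective modulators (Offboard*OMS, Onboard*SMS, Joint*OMS,
Joint*SMS, Disjoint*OMS, Disjoint*SMS), and a "responses" regressor for
one-back target trials.  Modulator regressors are built from
mean-centred per-trial covariate values multiplied into the parent's
event train before HRF convolution, then serially orthogonalised
against every regressor listed before them, so each modulator carries
only variance not explained by earlier terms.

Fitting follows the standard fMRI pipeline: grand-mean scaling of each
series to 100, discrete-cosine high-pass filtering (128 s default
cutoff), AR(1) prewhitening with a coefficient pooled across series
within the scan, and least squares on the whitened system.  Condition
betas on the scaled data are directly interpretable as percent signal
change relative to the (fixation-implicit) baseline.

Note the full 15-regressor model is rank deficient by construction —
the movement regressor equals the sum of the four motion-condition
regressors — exactly as in the matrix-laboratory packages this design
originates from.  ``fit_glm_ar1`` refuses such matrices by default;
``rank_policy="pinv"`` selects the deterministic minimum-norm solution,
under which modulator betas and condition *differences* (the quantities
every downstream statistic consumes) are unique and estimable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from flowparse.design import ScanDesign

TASK_REGRESSOR_NAMES = [
    "movement",
    "movement*QoM",
    "movement*SoM",
    "Offboard",
    "Onboard",
    "Joint",
    "Disjoint",
    "Static",
    "Offboard*OMS",
    "Onboard*SMS",
    "Joint*OMS",
    "Joint*SMS",
    "Disjoint*OMS",
    "Disjoint*SMS",
    "responses",
]

#: indices of the parametrically modulated regressors (serially
#: orthogonalised against everything listed before them)
_MODULATED = {1, 2, 8, 9, 10, 11, 12, 13}

#: (regressor name, parent condition, modulator column) for the
#: subjective modulators
_SUBJECTIVE = [
    ("Offboard*OMS", "Offboard", "OMS"),
    ("Onboard*SMS", "Onboard", "SMS"),
    ("Joint*OMS", "Joint", "OMS"),
    ("Joint*SMS", "Joint", "SMS"),
    ("Disjoint*OMS", "Disjoint", "OMS"),
    ("Disjoint*SMS", "Disjoint", "SMS"),
]

DEFAULT_HIGHPASS_S = 128.0


@dataclass
class HRFSpec:
    """Double-gamma haemodynamic response parameters (seconds).

    Defaults are the conventional canonical form: response gamma with
    delay 6 s, undershoot gamma with delay 16 s, unit dispersions,
    undershoot one sixth of the peak, 32 s kernel.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    length: float = 32.0
    microtime_dt: float = 0.1

    def validate(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")
        if self.undershoot_ratio <= 0:
            raise ValueError("undershoot_ratio must be positive")
        if self.length < 24.0:
            raise ValueError("kernel length must cover at least 24 s")
        if self.microtime_dt <= 0:
            raise ValueError("microtime_dt must be positive")


@dataclass
class DesignMatrix:
    """TR-sampled design matrix with named task regressors."""

    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    tr: float
    highpass_cutoff: float = DEFAULT_HIGHPASS_S

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix columns must match regressor names")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class GLMFit:
    """Results of an AR(1)-prewhitened least-squares fit."""

    betas: np.ndarray          # (n_regressors, n_series)
    names: list[str]
    rho: float
    residual_variance: np.ndarray  # per series
    effective_df: float
    grand_mean_scale: np.ndarray   # per-series factor applied before fitting
    rank: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]


def _hrf_microtime(spec: HRFSpec) -> np.ndarray:
    t = np.arange(0.0, spec.length + spec.microtime_dt / 2, spec.microtime_dt)
    peak = stats.gamma.pdf(
        t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = stats.gamma.pdf(
        t,
        spec.undershoot_delay / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    h = peak - under / spec.undershoot_ratio
    if h.sum() <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return h / h.max()  # unit peak: an isolated event regressor peaks at 1


def canonical_hrf(spec: HRFSpec | None = None, tr: float = 2.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the repetition time.

    Built on a dense microtime grid then decimated to TR; the kernel is
    scaled to unit peak (near 5 s for the default parameters) so that
    regression coefficients are expressed in units of peak response.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    spec = spec or HRFSpec()
    spec.validate()
    h = _hrf_microtime(spec)
    step = max(int(round(tr / spec.microtime_dt)), 1)
    return h[::step]


def _orthogonalize_serial(x: np.ndarray, modulated: set[int]) -> np.ndarray:
    """Residualise each modulated column against all earlier columns."""
    out = x.copy()
    for i in range(out.shape[1]):
        if i not in modulated or i == 0:
            continue
        prev = out[:, :i]
        coef, *_ = np.linalg.lstsq(prev, out[:, i], rcond=None)
        out[:, i] = out[:, i] - prev @ coef
    return out


def build_design_matrix(
    design: ScanDesign,
    modulators: pd.DataFrame,
    n_volumes: int,
    tr: float = 2.0,
    hrf: HRFSpec | None = None,
    highpass_cutoff: float = DEFAULT_HIGHPASS_S,
    orthogonalize: bool = True,
) -> DesignMatrix:
    """Build the 15-regressor train-experiment design matrix.

    ``modulators`` is keyed by movie_id with columns QoM, SoM and the
    subjective ratings SMS/OMS where the condition requires them
    (OMS for Offboard, SMS for Onboard, both for Joint and Disjoint;
    Static trials carry no modulators).  Trial event trains are delta
    sticks at onsets on a microtime grid, convolved with the canonical
    HRF and sampled at volume acquisition times.
    """
    hrf = hrf or HRFSpec()
    hrf.validate()
    if tr <= 0:
        raise ValueError("TR must be positive")
    if n_volumes * tr + 1e-9 < design.scan_duration:
        raise ValueError(
            f"{n_volumes} volumes at TR={tr} do not cover the "
            f"{design.scan_duration} s design"
        )
    mods = modulators.set_index("movie_id") if "movie_id" in modulators else modulators

    def trial_value(movie_id: str, col: str) -> float:
        try:
            v = float(mods.loc[movie_id, col])
        except KeyError:
            raise KeyError(f"missing modulator {col} for movie {movie_id!r}")
        if np.isnan(v):
            raise KeyError(f"modulator {col} for movie {movie_id!r} is NaN")
        return v

    movement_trials = [t for t in design.trials if t.trial_type != "Static"]
    by_type = {
        c: [t for t in design.trials if t.trial_type == c]
        for c in ("Offboard", "Onboard", "Joint", "Disjoint", "Static")
    }
    targets = [t for t in design.trials if t.is_target]

    def centered(trials, col):
        vals = np.array([trial_value(t.movie_id, col) for t in trials])
        return vals - vals.mean()

    events: list[list[tuple[float, float]]] = []
    # 1-3: movement and objective modulators
    events.append([(t.onset, 1.0) for t in movement_trials])
    for col in ("QoM", "SoM"):
        amps = centered(movement_trials, col)
        events.append(
            [(t.onset, a) for t, a in zip(movement_trials, amps)]
        )
    # 4-8: conditions
    for cond in ("Offboard", "Onboard", "Joint", "Disjoint", "Static"):
        events.append([(t.onset, 1.0) for t in by_type[cond]])
    # 9-14: subjective modulators
    for _, cond, col in _SUBJECTIVE:
        trials = by_type[cond]
        amps = centered(trials, col)
        events.append([(t.onset, a) for t, a in zip(trials, amps)])
    # 15: one-back responses
    events.append([(t.onset, 1.0) for t in targets])

    dt = hrf.microtime_dt
    kernel = _hrf_microtime(hrf)
    n_micro = int(np.ceil(n_volumes * tr / dt)) + 1
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)

    columns = np.zeros((n_volumes, len(events)))
    for j, ev in enumerate(events):
        u = np.zeros(n_micro)
        for onset, amp in ev:
            u[int(round(onset / dt))] += amp
        conv = np.convolve(u, kernel)[:n_micro]
        columns[:, j] = conv[vol_idx]

    if orthogonalize:
        columns = _orthogonalize_serial(columns, _MODULATED)
    return DesignMatrix(columns, list(TASK_REGRESSOR_NAMES), tr, highpass_cutoff)


def dct_drift_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis: constant plus all components with
    period longer than ``cutoff`` seconds."""
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    n_comp = int(np.floor(2.0 * n * tr / cutoff))
    t = np.arange(n)
    basis = [np.ones(n) / np.sqrt(n)]
    for k in range(1, n_comp + 1):
        comp = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n))
        basis.append(comp * np.sqrt(2.0 / n))
    return np.column_stack(basis)


def highpass_filter(series: np.ndarray, cutoff: float, tr: float) -> np.ndarray:
    """Project low-frequency drift out of a time series (or series set).

    Removes the span of the discrete-cosine basis with periods above
    ``cutoff`` (constant included); the output is orthogonal to that
    basis.  Operates on 1D series or (time, series) matrices.
    """
    y = np.asarray(series, dtype=float)
    one_d = y.ndim == 1
    if one_d:
        y = y[:, None]
    if y.shape[0] < 8:
        raise ValueError("series too short to filter")
    basis = dct_drift_basis(y.shape[0], tr, cutoff)
    filtered = y - basis @ (basis.T @ y)
    return filtered[:, 0] if one_d else filtered


def _name_collinear(x: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    bad = diag <= tol * max(diag[0], 1.0)
    return [names[piv[i]] for i in np.nonzero(bad)[0]]


def _solve_rho_moment_matched(
    observed: float, xf: np.ndarray, basis: np.ndarray
) -> float:
    """AR(1) coefficient from the residual lag-1 autocorrelation.

    The raw Yule-Walker ratio on OLS residuals is biased toward zero:
    the residual-forming projection (drift basis plus the smooth,
    HRF-convolved regressors) absorbs part of the autocorrelated noise.
    This estimator inverts the bias by moment matching: for residuals
    e = R y with R the residual projector and y AR(1) noise with
    correlation C(rho), E[sum e_t e_{t+1}] / E[sum e_t^2] =
    tr(L R C R) / tr(R C R) with L the symmetrised lag-1 operator; the
    rho whose predicted ratio equals the observed one is returned
    (monotone in rho, solved by bisection).
    """
    n = xf.shape[0]
    p_x = xf @ np.linalg.pinv(xf, rcond=1e-10)
    r_mat = np.eye(n) - basis @ basis.T - p_x

    # with C(rho) Toeplitz, tr(M C) = sum_k rho^|k| (sum of k-th diagonal
    # of M); precomputing diagonal sums makes the ratio a polynomial in rho
    lag = np.zeros((n, n))
    idx = np.arange(n - 1)
    lag[idx, idx + 1] = lag[idx + 1, idx] = 0.5
    m_num = r_mat @ lag @ r_mat
    ks = np.arange(n)
    diag_num = np.array([np.trace(m_num, offset=k) for k in range(n)])
    diag_num[1:] *= 2.0  # C is symmetric: off-diagonals count twice
    diag_den = np.array([np.trace(r_mat, offset=k) for k in range(n)])
    diag_den[1:] *= 2.0

    def predicted(rho: float) -> float:
        powers = rho ** ks
        return float((diag_num @ powers) / (diag_den @ powers))

    lo, hi = -0.95, 0.95
    if observed <= predicted(lo):
        return lo
    if observed >= predicted(hi):
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if predicted(mid) < observed:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def _ar1_whiten(y: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(y)
    out[0] = np.sqrt(1.0 - rho**2) * y[0]
    out[1:] = y[1:] - rho * y[:-1]
    return out


def fit_glm_ar1(
    Y: np.ndarray,
    X: DesignMatrix,
    grand_mean_scale: bool = True,
    rank_policy: str = "error",
) -> GLMFit:
    """Fit the GLM with high-pass filtering and AR(1) prewhitening.

    Each series is scaled so its whole-scan mean is 100, drift is
    projected out of data and design with the discrete-cosine basis,
    a single AR(1) coefficient per scan is estimated from the pooled
    lag-1 autocorrelation of the OLS residuals (the same correlation
    structure is assumed for every series within a run), both sides are
    whitened with the AR(1) square-root-inverse transform, and the
    model is refit by least squares.

    ``rank_policy``: "error" rejects rank-deficient designs naming the
    collinear regressors; "pinv" accepts them and returns the unique
    minimum-norm solution.
    """
    if rank_policy not in ("error", "pinv"):
        raise ValueError(f"unknown rank_policy {rank_policy!r}")
    y = np.asarray(Y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != X.n_volumes:
        raise ValueError(
            f"data has {y.shape[0]} volumes but design has {X.n_volumes}"
        )

    if grand_mean_scale:
        means = y.mean(axis=0)
        if np.any(means <= 0):
            raise ValueError("grand-mean scaling requires positive-mean series")
        scale = 100.0 / means
    else:
        scale = np.ones(y.shape[1])
    ys = y * scale

    basis = dct_drift_basis(y.shape[0], X.tr, X.highpass_cutoff)
    yf = ys - basis @ (basis.T @ ys)
    xf = X.matrix - basis @ (basis.T @ X.matrix)

    rank = int(np.linalg.matrix_rank(xf, rtol=1e-10))
    if rank < xf.shape[1] and rank_policy == "error":
        bad = _name_collinear(xf, X.names)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear regressors: {bad}"
        )

    def solve(a, b):
        # explicit cutoff so numerically exact collinearity maps to the
        # minimum-norm solution instead of exploding
        return np.linalg.pinv(a, rcond=1e-10) @ b

    beta_ols = solve(xf, yf)
    resid = yf - xf @ beta_ols
    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid * resid))
    if den <= 1e-10 * ys.size:  # (near-)perfect fit: no noise to model
        rho = 0.0
    else:
        rho = _solve_rho_moment_matched(num / den, xf, basis)

    yw = _ar1_whiten(yf, rho)
    xw = _ar1_whiten(xf, rho)
    betas = solve(xw, yw)
    resid_w = yw - xw @ betas
    n_nuis = basis.shape[1]
    edf = max(y.shape[0] - n_nuis - rank, 1)
    sigma2 = np.sum(resid_w**2, axis=0) / edf
    return GLMFit(
        betas=betas,
        names=list(X.names),
        rho=rho,
        residual_variance=sigma2,
        effective_df=float(edf),
        grand_mean_scale=scale,
        rank=int(rank),
    )


def percent_signal_change(fit: GLMFit, condition: str) -> np.ndarray:
    """Condition response in percent of the grand-mean-scaled baseline.

    With series scaled so the whole-scan mean is 100 and unit-peak HRF
    regressors, the condition beta is already the peak response in
    percent of baseline; this accessor names that convention.
    """
    if condition not in fit.names:
        raise KeyError(f"no regressor named {condition!r}")
    return fit.beta(condition)
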