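"""Noisy encoding of disparity (NED) model: fusion probability and fitting.

The model describes the long-run probability that participant ``j``
reports a fusion percept for McGurk stimulus ``i`` as

    P(fusion | i, j) = Phi((T_j - D_i) / sigma_j)

where ``D_i`` is the stimulus's audiovisual disparity, ``T_j`` the
participant's disparity threshold, and ``sigma_j`` the participant's
sensory noise (the SD of the Gaussian trial-to-trial encoding of the
disparity): on each trial the encoded disparity X ~ N(D_i, sigma_j) is
compared against T_j and the percept fuses when X < T_j.

Parameters are estimated by minimizing the mean absolute error (MAE)
between predicted probabilities and observed per-cell fusion proportions.
Disparities and thresholds live on a unit interval by construction: the
probability depends only on (T - D)/sigma, so without box constraints the
parameters are identified only up to a common shift and scale. Bounding
D and T to [0, 1] anchors the scale; tests and downstream consumers rely
on prediction-space (not parameter-space) agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .scoring import FusionTable

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def fusion_probability(D, T, sigma):
    """P(fusion) = Phi((T - D) / sigma); broadcasts over array inputs.

    Strictly increasing in T, strictly decreasing in D, equal to 0.5 when
    T == D for any noise level. ``sigma`` must be strictly positive.
    """
    D = np.asarray(D, dtype=float)
    T = np.asarray(T, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    out = ndtr((T - D) / sigma)
    return float(out) if out.ndim == 0 else out


def predict_matrix(D, T, sigma):
    """Predicted fusion-probability matrix, participants (rows) x stimuli.

    Cell (j, i) = fusion_probability(D[i], T[j], sigma[j]). Predictions
    exist for every cell, including cells missing from the observed table.
    """
    D = np.asarray(D, dtype=float)
    T = np.asarray(T, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return ndtr((T[:, None] - D[None, :]) / sigma[:, None])


@dataclass
class NEDParams:
    """Fitted (or generating) model parameters with axis labels."""

    D: np.ndarray
    T: np.ndarray
    sigma: np.ndarray
    stimuli: list[str] = field(default_factory=list)
    participants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.T) != len(self.sigma):
            raise ValueError("T and sigma must have one entry per participant")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        """Long parameter table with columns id, role, value."""
        rows = [("disparity", s, d) for s, d in zip(self.stimuli, self.D)]
        rows += [("threshold", p, t) for p, t in zip(self.participants, self.T)]
        rows += [("sigma", p, s) for p, s in zip(self.participants, self.sigma)]
        return pd.DataFrame(rows, columns=["role", "id", "value"])


@dataclass
class FitResult:
    params: NEDParams
    predicted: np.ndarray
    mae_by_stimulus: np.ndarray
    mae_by_participant: np.ndarray
    mae_by_cell: np.ndarray
    objective_trace: np.ndarray
    converged: bool


def _vector_min(cost, lo, hi, current, n_grid=13, n_iter=40):
    """Minimize k independent bounded scalar problems simultaneously.

    ``cost`` maps a length-k vector of candidate values (one per problem)
    to a length-k vector of objective values. A fixed bracketing grid
    seeds a vectorized golden-section refinement; the incumbent value is
    always among the candidates, so the result never regresses.
    """
    lo = np.broadcast_to(np.asarray(lo, float), current.shape).copy()
    hi = np.broadcast_to(np.asarray(hi, float), current.shape).copy()
    grid = np.linspace(0.0, 1.0, n_grid)
    best_x = current.astype(float).copy()
    best_f = cost(best_x)
    xs = lo[None, :] + grid[:, None] * (hi - lo)[None, :]
    fs = np.empty_like(xs)
    for g in range(n_grid):
        fs[g] = cost(xs[g])
    gbest = np.argmin(fs, axis=0)
    k = np.arange(current.size)
    improve = fs[gbest, k] < best_f
    best_x = np.where(improve, xs[gbest, k], best_x)
    best_f = np.minimum(fs[gbest, k], best_f)
    # golden-section bracket: one grid spacing either side of the best point
    a = xs[np.maximum(gbest - 1, 0), k]
    c = xs[np.minimum(gbest + 1, n_grid - 1), k]
    x1 = c - _INVPHI * (c - a)
    x2 = a + _INVPHI * (c - a)
    for _ in range(n_iter):
        f1 = cost(x1)
        f2 = cost(x2)
        for x, f in ((x1, f1), (x2, f2)):
            better = f < best_f
            best_x = np.where(better, x, best_x)
            best_f = np.minimum(f, best_f)
        left = f1 < f2
        c = np.where(left, x2, c)
        a = np.where(left, a, x1)
        x1 = c - _INVPHI * (c - a)
        x2 = a + _INVPHI * (c - a)
    return best_x, best_f


def _polish_participant(obs_row, mask_row, D, t0, s0, t_bounds, sigma_bounds):
    """Joint 2-D refinement of one participant's (T, sigma).

    Alternating scalar line searches can stall on the nonsmooth MAE
    surface where the T and sigma directions couple; a bounded
    Nelder-Mead restart from the line-search solution escapes such
    points. Returns the incumbent if no improvement is found, so the
    objective never increases.
    """
    obs = obs_row[mask_row]
    d = D[mask_row]
    if obs.size == 0:
        return t0, s0

    def cost(z):
        t = np.clip(z[0], *t_bounds)
        s = np.clip(z[1], *sigma_bounds)
        return np.abs(ndtr((t - d) / s) - obs).sum()

    f0 = cost((t0, s0))
    res = minimize(
        cost, [t0, s0], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
    )
    if res.fun < f0:
        return (
            float(np.clip(res.x[0], *t_bounds)),
            float(np.clip(res.x[1], *sigma_bounds)),
        )
    return t0, s0


def _coerce_table(X):
    """Accept a FusionTable, DataFrame, or bare matrix."""
    if isinstance(X, FusionTable):
        return (
            np.asarray(X.fusion_prop, dtype=float),
            list(X.participants),
            list(X.stimuli),
        )
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            [str(i) for i in X.index],
            [str(c) for c in X.columns],
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D participants x stimuli matrix")
    return (
        arr,
        [f"p{j + 1:02d}" for j in range(arr.shape[0])],
        [f"s{i + 1}" for i in range(arr.shape[1])],
    )


class NEDModel(BaseEstimator):
    """Noisy-encoding-of-disparity estimator for a fusion-proportion table.

    Fits one disparity per stimulus (``disparity_``), plus a threshold
    (``threshold_``) and sensory noise (``sigma_``) per participant, by
    deterministic block-coordinate descent on cell-level mean absolute
    error. Within each block the coordinate subproblems are separable
    (each D_i touches only its column, each T_j/sigma_j only its row) and
    are solved together by a grid-seeded golden-section line search.

    Parameters
    ----------
    d_bounds, t_bounds : tuple of float
        Box constraints for disparities and thresholds. The unit interval
        anchors the otherwise shift/scale-unidentified disparity axis.
    sigma_bounds : tuple of float
        Box for sensory noise SD, default (0.01, 2.0).
    tol : float
        Stop when a full sweep improves the objective by less than this.
    max_sweeps : int
        Outer-iteration cap; the best-so-far fit is kept if reached.
    n_grid, gs_iter : int
        Bracketing-grid size and golden-section iterations per coordinate
        block. The defaults locate coordinate minima far below ``tol``.

    Attributes
    ----------
    disparity_, threshold_, sigma_ : ndarray
        Fitted parameters.
    predicted_ : ndarray
        Fitted fusion-probability matrix (all cells, including missing).
    objective_trace_ : ndarray
        Cell MAE after each outer sweep; non-increasing.
    converged_ : bool
    """

    def __init__(
        self,
        d_bounds=(0.0, 1.0),
        t_bounds=(0.0, 1.0),
        sigma_bounds=(0.01, 2.0),
        tol=1e-6,
        max_sweeps=500,
        n_grid=13,
        gs_iter=40,
        polish=True,
        max_polish_rounds=50,
    ):
        self.d_bounds = d_bounds
        self.t_bounds = t_bounds
        self.sigma_bounds = sigma_bounds
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.n_grid = n_grid
        self.gs_iter = gs_iter
        self.polish = polish
        self.max_polish_rounds = max_polish_rounds

    # -- objective helpers ------------------------------------------------
    @staticmethod
    def _abs_err(pred, obs, mask):
        return np.where(mask, np.abs(pred - obs), 0.0)

    def fit(self, X, y=None):
        """Fit to a participants x stimuli fusion table (NaN = missing)."""
        obs, participants, stimuli = _coerce_table(X)
        self.participants_ = participants
        self.stimuli_ = stimuli
        mask = ~np.isnan(obs)
        if mask.sum(axis=0).max(initial=0) < 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
            raise ValueError("need >= 2 participants and >= 2 stimuli with data")
        vals = obs[mask]
        if np.ptp(vals) == 0:
            warnings.warn(
                "all observed fusion proportions are identical; "
                "parameters are weakly identifiable",
                UserWarning,
            )
        obs0 = np.where(mask, obs, 0.0)
        n_cells = int(mask.sum())
        J, I = obs.shape

        d_lo, d_hi = self.d_bounds
        t_lo, t_hi = self.t_bounds
        s_lo, s_hi = self.sigma_bounds

        # data-driven start: probit-link moment match at sigma = 0.3
        col = np.nanmean(np.where(mask, obs, np.nan), axis=0)
        row = np.nanmean(np.where(mask, obs, np.nan), axis=1)
        col = np.where(np.isnan(col), 0.5, col)
        row = np.where(np.isnan(row), 0.5, row)
        D = np.clip(0.5 - 0.3 * ndtri(np.clip(col, 0.02, 0.98)), d_lo, d_hi)
        T = np.clip(
            D.mean() + 0.3 * ndtri(np.clip(row, 0.02, 0.98)), t_lo, t_hi
        )
        sigma = np.full(J, 0.3)
        sigma = np.clip(sigma, s_lo, s_hi)

        def col_cost(d_cand):
            pred = ndtr((T[:, None] - d_cand[None, :]) / sigma[:, None])
            return self._abs_err(pred, obs0, mask).sum(axis=0)

        def row_cost_T(t_cand):
            pred = ndtr((t_cand[:, None] - D[None, :]) / sigma[:, None])
            return self._abs_err(pred, obs0, mask).sum(axis=1)

        def row_cost_sigma(s_cand):
            pred = ndtr((T[:, None] - D[None, :]) / s_cand[:, None])
            return self._abs_err(pred, obs0, mask).sum(axis=1)

        def total():
            pred = ndtr((T[:, None] - D[None, :]) / sigma[:, None])
            return self._abs_err(pred, obs0, mask).sum() / n_cells

        trace = [total()]
        converged = False
        for _ in range(self.max_sweeps):
            D, _ = _vector_min(
                col_cost, d_lo, d_hi, D, n_grid=self.n_grid, n_iter=self.gs_iter
            )
            T, _ = _vector_min(
                row_cost_T, t_lo, t_hi, T, n_grid=self.n_grid, n_iter=self.gs_iter
            )
            sigma, _ = _vector_min(
                row_cost_sigma, s_lo, s_hi, sigma,
                n_grid=self.n_grid, n_iter=self.gs_iter,
            )
            trace.append(total())
            if trace[-2] - trace[-1] < self.tol:
                converged = True
                break

        if self.polish:
            # joint (T, sigma) refinement per participant to escape
            # nonsmooth coordinate stalls, interleaved with D re-solves
            for _ in range(self.max_polish_rounds):
                for j in range(J):
                    T[j], sigma[j] = _polish_participant(
                        obs[j], mask[j], D, T[j], sigma[j],
                        self.t_bounds, self.sigma_bounds,
                    )
                D, _ = _vector_min(
                    col_cost, d_lo, d_hi, D, n_grid=self.n_grid, n_iter=self.gs_iter
                )
                trace.append(total())
                if trace[-2] - trace[-1] < self.tol:
                    break

        self.disparity_ = D
        self.threshold_ = T
        self.sigma_ = sigma
        self.predicted_ = predict_matrix(D, T, sigma)
        self.objective_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        self.observed_ = obs
        self.mask_ = mask
        return self

    def predict(self, X=None):
        """Fitted fusion-probability matrix (rows follow ``participants_``)."""
        if not hasattr(self, "predicted_"):
            raise AttributeError("NEDModel is not fitted")
        return self.predicted_

    def params_(self) -> NEDParams:
        return NEDParams(
            D=self.disparity_,
            T=self.threshold_,
            sigma=self.sigma_,
            stimuli=self.stimuli_,
            participants=self.participants_,
        )

    def score(self, X=None, y=None):
        """Negative cell MAE of the fit (higher is better, sklearn style)."""
        return -float(self.objective_trace_[-1])


def mae_summaries(observed, predicted):
    """MAE at stimulus, participant, and cell level.

    ``by_stimulus[i]`` is |mean_j observed - mean_j predicted| for
    stimulus i (error of the stimulus-level mean); ``by_participant[j]``
    is the analogue across stimuli; ``by_cell`` is elementwise
    |observed - predicted| with NaN at missing cells. Missing cells are
    excluded from every mean.
    """
    obs, _, _ = _coerce_table(observed)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted shapes differ")
    mask = ~np.isnan(obs)
    obs_m = np.where(mask, obs, np.nan)
    pred_m = np.where(mask, pred, np.nan)
    by_stimulus = np.abs(np.nanmean(obs_m, axis=0) - np.nanmean(pred_m, axis=0))
    by_participant = np.abs(np.nanmean(obs_m, axis=1) - np.nanmean(pred_m, axis=1))
    by_cell = np.abs(obs_m - pred_m)
    return by_stimulus, by_participant, by_cell


def fit_ned(table, **kwargs) -> FitResult:
    """Fit the NED model to a fusion table and return a full report."""
    est = NEDModel(**kwargs).fit(table)
    by_stim, by_part, by_cell = mae_summaries(est.observed_, est.predicted_)
    return FitResult(
        params=est.params_(),
        predicted=est.predicted_,
        mae_by_stimulus=by_stim,
        mae_by_participant=by_part,
        mae_by_cell=by_cell,
        objective_trace=est.objective_trace_,
        converged=est.converged_,
    )


def stimulus_rank_consistency(table):
    """Per-participant Spearman correlation with the global stimulus rank.

    The global rank orders stimuli by grand-mean fusion across
    participants; each participant's own stimulus proportions are rank-
    correlated (average-rank ties) against it. Participants with zero
    variance across stimuli have undefined correlations and are excluded.

    Returns (per_participant r array with NaN for excluded, mean r).
    """
    obs, participants, _ = _coerce_table(table)
    if obs.shape[1] < 3:
        raise ValueError("need at least 3 stimuli for rank consistency")
    global_means = np.nanmean(obs, axis=0)
    rs = np.full(len(participants), np.nan)
    for j in range(obs.shape[0]):
        rowmask = ~np.isnan(obs[j])
        row = obs[j, rowmask]
        if row.size < 3 or np.ptp(row) == 0:
            continue
        rs[j] = stats.spearmanr(row, global_means[rowmask]).statistic
    return rs, float(np.nanmean(rs))
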