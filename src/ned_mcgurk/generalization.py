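"""Two-level hold-out generalization for the NED model.

For each participant, stimulus disparities are learned from everyone
else's data (leave-one-participant-out). Then, for each stimulus, the
held-out participant's threshold and sensory noise are re-estimated from
their remaining stimuli with the disparities frozen, and the held-out
(participant, stimulus) cell is predicted. Every prediction is therefore
unbiased by the very cell it predicts: the disparity stage never sees the
participant's row at all, and the participant stage never sees the
held-out cell.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import (
    NEDModel,
    _coerce_table,
    _polish_participant,
    _vector_min,
    fusion_probability,
)
from .scoring import FusionTable

logger = logging.getLogger(__name__)


def _fit_participant_row(
    obs_row: np.ndarray,
    mask_row: np.ndarray,
    D: np.ndarray,
    t_bounds=(0.0, 1.0),
    sigma_bounds=(0.01, 2.0),
    tol: float = 1e-6,
    max_sweeps: int = 200,
    n_grid: int = 13,
    gs_iter: int = 40,
) -> tuple[float, float]:
    """Estimate one participant's (T, sigma) with disparities frozen.

    Same alternating bounded line searches as the full fit, restricted to
    a single row; MAE objective over the row's non-missing cells.
    """
    from scipy.special import ndtr, ndtri

    obs = np.where(mask_row, obs_row, 0.0)
    n = int(mask_row.sum())
    m = float(np.clip(obs_row[mask_row].mean(), 0.02, 0.98)) if n else 0.5
    T = np.clip(np.array([D[mask_row].mean() + 0.3 * ndtri(m)]), *t_bounds)
    sigma = np.clip(np.array([0.3]), *sigma_bounds)

    def cost_T(t_cand):
        pred = ndtr((t_cand[:, None] - D[None, :]) / sigma[0])
        return np.where(mask_row, np.abs(pred - obs), 0.0).sum(axis=1)

    def cost_sigma(s_cand):
        pred = ndtr((T[0] - D[None, :]) / s_cand[:, None])
        return np.where(mask_row, np.abs(pred - obs), 0.0).sum(axis=1)

    prev = np.inf
    for _ in range(max_sweeps):
        T, _ = _vector_min(cost_T, *t_bounds, T, n_grid=n_grid, n_iter=gs_iter)
        sigma, f = _vector_min(
            cost_sigma, *sigma_bounds, sigma, n_grid=n_grid, n_iter=gs_iter
        )
        cur = float(f[0]) / max(n, 1)
        if prev - cur < tol:
            break
        prev = cur
    t, s = _polish_participant(obs_row, mask_row, D, float(T[0]), float(sigma[0]),
                               t_bounds, sigma_bounds)
    return t, s


def loo_disparities(table, participant_id: str, **model_kwargs) -> np.ndarray:
    """Stimulus disparities fit with one participant's row removed.

    The held-out participant's data never enters this fit, so the result
    is invariant to arbitrary corruption of that row.
    """
    obs, participants, stimuli = _coerce_table(table)
    j = participants.index(participant_id)
    keep = [k for k in range(len(participants)) if k != j]
    sub = FusionTable(
        [participants[k] for k in keep],
        stimuli,
        obs[keep],
        np.where(np.isnan(obs[keep]), 0, 1),
    )
    return NEDModel(**model_kwargs).fit(sub).disparity_


def holdout_predict(table, **model_kwargs) -> pd.DataFrame:
    """Predict every non-missing cell from data excluding it (two levels).

    Stage 1 (once per participant): fit the full model without that
    participant's row; freeze the disparities. Stage 2 (per stimulus):
    re-fit the participant's (T, sigma) on their row minus the held-out
    stimulus, then predict the held-out cell. Cells whose training row
    would have fewer than two observed cells are skipped and logged.

    Returns a tidy frame: participant_id, stimulus_id, observed,
    predicted, abs_error, n_training_cells. Deterministic.
    """
    obs, participants, stimuli = _coerce_table(table)
    if len(participants) < 3 or len(stimuli) < 3:
        raise ValueError("hold-out needs >= 3 participants and >= 3 stimuli")
    t_bounds = model_kwargs.get("t_bounds", (0.0, 1.0))
    sigma_bounds = model_kwargs.get("sigma_bounds", (0.01, 2.0))
    rows = []
    for j, pid in enumerate(participants):
        D = loo_disparities(table, pid, **model_kwargs)
        mask_row = ~np.isnan(obs[j])
        for i, sid in enumerate(stimuli):
            if not mask_row[i]:
                continue
            train = mask_row.copy()
            train[i] = False
            if train.sum() < 2:
                logger.warning(
                    "skipping hold-out cell (%s, %s): %d training cells",
                    pid, sid, int(train.sum()),
                )
                continue
            T, sigma = _fit_participant_row(
                obs[j], train, D, t_bounds=t_bounds, sigma_bounds=sigma_bounds
            )
            pred = fusion_probability(D[i], T, sigma)
            rows.append(
                {
                    "participant_id": pid,
                    "stimulus_id": sid,
                    "observed": obs[j, i],
                    "predicted": pred,
                    "abs_error": abs(pred - obs[j, i]),
                    "n_training_cells": int(train.sum()),
                }
            )
    return pd.DataFrame(rows)


def generalization_report(predictions: pd.DataFrame, fit_result=None) -> dict:
    """Summarize hold-out error, optionally against the trained fit.

    Reports the mean and SEM of |predicted - observed| both over cells
    and over participant means (the study does not say which its single
    number is, so both are emitted). When a training ``fit_result`` is
    supplied, its cell-level MAE is included and compared: untrained
    error at or above trained error is the expected no-overfitting
    pattern, and a violation is flagged rather than raised.
    """
    if predictions.empty:
        raise ValueError("no hold-out predictions to summarize")
    errs = predictions["abs_error"].to_numpy()
    per_participant = predictions.groupby("participant_id")["abs_error"].mean()
    report = {
        "untrained_mean_over_cells": float(errs.mean()),
        "untrained_sem_over_cells": float(errs.std(ddof=1) / np.sqrt(errs.size)),
        "untrained_mean_over_participants": float(per_participant.mean()),
        "untrained_sem_over_participants": float(
            per_participant.std(ddof=1) / np.sqrt(len(per_participant))
        ),
        "n_cells": int(errs.size),
    }
    if fit_result is not None:
        trained = fit_result.mae_by_cell
        trained = trained[~np.isnan(trained)]
        report["trained_mean_over_cells"] = float(trained.mean())
        report["untrained_exceeds_trained"] = bool(
            report["untrained_mean_over_cells"] >= report["trained_mean_over_cells"]
        )
        if not report["untrained_exceeds_trained"]:
            logger.warning(
                "hold-out error (%.4f) below trained error (%.4f); unusual",
                report["untrained_mean_over_cells"],
                report["trained_mean_over_cells"],
            )
    return report
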