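"""Regression of fitted NED parameters on participant and stimulus covariates.

Participant-level models relate the disparity threshold and sensory noise
to demographics (age, gender, English proficiency 0-6, education);
the stimulus-level model relates disparity to syllable voicing, talker
gender, and talker native language. Term selection is stepwise under BIC:
start from the full main-effects model, consider single-term deletions
and additions at each step, never generate interactions, and floor at the
intercept-only model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: Ordinal coding for highest completed education.
EDUCATION_LEVELS = {"high_school": 0, "professional": 1, "bachelor": 1, "higher": 2}


def encode_education(values: pd.Series) -> pd.Series:
    """Collapse education labels onto an ordinal scale (0 < 1 < 2)."""
    out = values.map(EDUCATION_LEVELS)
    if out.isna().any():
        bad = sorted(set(values[out.isna()]))
        raise ValueError(f"unknown education labels: {bad}")
    return out.astype(float)


def _design_block(x: pd.Series) -> pd.DataFrame:
    """Design-matrix columns for one predictor (dummies for categoricals)."""
    if pd.api.types.is_numeric_dtype(x):
        return x.astype(float).to_frame()
    dummies = pd.get_dummies(x.astype("category"), prefix=x.name, drop_first=True)
    return dummies.astype(float)


class StepwiseBICRegressor(BaseEstimator):
    """OLS with bidirectional stepwise term selection under BIC.

    Starts from the model containing all candidate predictors and, at
    each step, evaluates every single-term deletion and (when
    ``direction="bidirectional"``) re-addition; the move with the lowest
    BIC is taken if it strictly lowers BIC, otherwise selection stops.
    The intercept-only model is the floor; interactions are never
    generated. Ties are broken by the fixed candidate ordering (deletions
    first, each in the order predictors were supplied).

    Attributes
    ----------
    selected_ : list of str
        Predictors retained in the final model.
    results_ : statsmodels RegressionResults of the final OLS fit.
    bic_trace_ : list of (description, bic) pairs, one per accepted move.
    """

    def __init__(self, direction: str = "bidirectional"):
        self.direction = direction

    def _fit_ols(self, y, blocks, terms):
        X = pd.concat([blocks[t] for t in terms], axis=1) if terms else None
        design = sm.add_constant(
            X if X is not None else pd.DataFrame(index=y.index), has_constant="add"
        )
        return sm.OLS(y, design).fit()

    @staticmethod
    def _bic(res, y) -> float:
        """Gaussian BIC with the residual variance floored near machine zero.

        An exactly noiseless response drives RSS to rounding noise, where
        log-likelihood differences between perfect fits are numerical
        artifacts; flooring RSS at a 1e-12 fraction of the total sum of
        squares makes all perfect fits tie so the parameter penalty alone
        decides, and leaves regular fits untouched.
        """
        n = len(y)
        tss = float(np.sum((y - y.mean()) ** 2)) or 1.0
        rss = max(float(res.ssr), 1e-12 * tss)
        k = res.df_model + 2  # slopes + intercept + error variance
        return n * np.log(rss / n) + k * np.log(n)

    def fit(self, X: pd.DataFrame, y):
        if self.direction not in ("bidirectional", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        X = pd.DataFrame(X).copy()
        y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="response")
        keep = y.notna()
        for c in X.columns:
            keep &= X[c].notna()
        X, y = X[keep], y[keep]
        if len(y) < 3:
            raise ValueError("need at least 3 complete cases")

        blocks = {c: _design_block(X[c]) for c in X.columns}
        # drop predictors whose columns add nothing to the design rank
        terms: list[str] = []
        cur = np.ones((len(y), 1))
        for c in X.columns:
            cand = np.hstack([cur, blocks[c].to_numpy()])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
                terms.append(c)
                cur = cand
            else:
                warnings.warn(f"dropping collinear predictor {c!r}", UserWarning)
        candidates = list(terms)

        res = self._fit_ols(y, blocks, terms)
        cur_bic = self._bic(res, y)
        trace = [("start: full model", cur_bic)]
        while True:
            moves = []  # (bic, order, new_terms, description)
            order = 0
            for t in terms:
                trial = [u for u in terms if u != t]
                bic = self._bic(self._fit_ols(y, blocks, trial), y)
                moves.append((bic, order, trial, f"drop {t}"))
                order += 1
            if self.direction == "bidirectional":
                for t in candidates:
                    if t in terms:
                        continue
                    trial = terms + [t]
                    bic = self._bic(self._fit_ols(y, blocks, trial), y)
                    moves.append((bic, order, trial, f"add {t}"))
                    order += 1
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[1]))
            best_bic, _, best_terms, desc = moves[0]
            if best_bic < cur_bic - 1e-10:
                terms = best_terms
                res = self._fit_ols(y, blocks, terms)
                cur_bic = best_bic
                trace.append((desc, cur_bic))
            else:
                break

        self.selected_ = terms
        self.results_ = res
        self.bic_trace_ = trace
        self.n_obs_ = int(len(y))
        self._blocks_columns = {t: list(blocks[t].columns) for t in candidates}
        return self

    def predict(self, X: pd.DataFrame):
        X = pd.DataFrame(X)
        cols = []
        for t in self.selected_:
            block = _design_block(X[t]).reindex(
                columns=self._blocks_columns[t], fill_value=0.0
            )
            cols.append(block)
        design = sm.add_constant(
            pd.concat(cols, axis=1) if cols else pd.DataFrame(index=X.index),
            has_constant="add",
        )
        design = design.reindex(columns=self.results_.model.exog_names, fill_value=0.0)
        return np.asarray(self.results_.predict(design))

    def summary(self) -> dict:
        r = self.results_
        return {
            "selected": list(self.selected_),
            "coefficients": dict(r.params),
            "r_squared": float(r.rsquared),
            "f_statistic": float(r.fvalue) if r.df_model > 0 else float("nan"),
            "f_pvalue": float(r.f_pvalue) if r.df_model > 0 else float("nan"),
            "df_model": int(r.df_model),
            "df_resid": int(r.df_resid),
            "bic": float(r.bic),
            "n": self.n_obs_,
        }


def stepwise_bic(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    direction: str = "bidirectional",
) -> StepwiseBICRegressor:
    """Convenience wrapper: stepwise-BIC OLS of ``response`` on ``predictors``."""
    est = StepwiseBICRegressor(direction=direction)
    return est.fit(data[predictors], data[response])


@dataclass
class SimpleRegressionReport:
    """Slope, fit, and test statistics of a one-predictor OLS."""

    b: float
    r_squared: float
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def single_predictor_report(parameter, covariate) -> SimpleRegressionReport:
    """Simple linear regression of a fitted parameter on one covariate."""
    y = np.asarray(parameter, dtype=float)
    x = np.asarray(covariate, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SimpleRegressionReport(
        b=float(res.params[1]),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_value=float(res.f_pvalue),
        df_num=int(res.df_model),
        df_den=int(res.df_resid),
    )


def participant_parameter_regressions(
    params, metadata: pd.DataFrame
) -> dict[str, SimpleRegressionReport]:
    """The four exploratory pairings: sigma~age, T~age, T~english, sigma~english.

    ``metadata`` must carry participant_id, age, english_proficiency;
    rows are aligned to the fitted participant order.
    """
    meta = metadata.set_index(metadata["participant_id"].astype(str))
    meta = meta.loc[[str(p) for p in params.participants]]
    age = meta["age"].to_numpy(dtype=float)
    eng = meta["english_proficiency"].to_numpy(dtype=float)
    return {
        "sigma~age": single_predictor_report(params.sigma, age),
        "threshold~age": single_predictor_report(params.T, age),
        "threshold~english": single_predictor_report(params.T, eng),
        "sigma~english": single_predictor_report(params.sigma, eng),
    }


def voicing_contrast(table, specs) -> dict[str, float]:
    """Grand-mean fusion per voicing class (mean over stimulus means).

    Each stimulus contributes its across-participant mean; classes with
    no stimuli are reported as NaN.
    """
    from .model import _coerce_table

    obs, _, stimuli = _coerce_table(table)
    means = np.nanmean(obs, axis=0)
    out: dict[str, float] = {}
    for cls in ("voiced", "unvoiced"):
        vals = [m for s, m in zip(stimuli, means) if specs[s].voicing == cls]
        out[cls] = float(np.mean(vals)) if vals else float("nan")
        if not vals:
            logger.warning("no stimuli in voicing class %r", cls)
    return out
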