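"""Model tuning by AICc, four-metric replicate evaluation, and
sensitivity-plus-specificity thresholding.

Tuning fits every (regularization multiplier, feature class) candidate
on the full presence set and ranks by small-sample-corrected AIC
computed from landscape-renormalized raw scores, with the parameter
count K equal to the number of nonzero coefficients.  Evaluation
refits the chosen candidate on replicate 75/25 splits and reports
AUC (train and test), AUC_diff, the minimum-training-presence omission
rate, and the continuous Boyce index.  The binarization threshold is
the value maximizing training sensitivity plus specificity (MTSPS),
and the suitable range above it is divided into three equal-width
suitability levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .geo_io import EnvStack, OccurrenceSet
from .maxent_core import (
    FeatureSpec,
    FitSettings,
    MaxentModel,
    fit_maxent,
    predict_values,
    sample_background,
)
from .occprep import SplitSpec, split_replicates
from .varselect import extract_values

__all__ = [
    "ThresholdSet",
    "aicc",
    "aicc_value",
    "tune",
    "auc",
    "boyce_index",
    "or_mtp",
    "mtsps_threshold",
    "evaluate_replicates",
]


@dataclass(frozen=True)
class ThresholdSet:
    """A suitable/unsuitable cut plus the equal tripartition of [t, 1].

    ``bin_edges`` are ``(t, t + (1-t)/3, t + 2(1-t)/3, 1)``: the low /
    moderate / high suitability levels all have width ``(1-t)/3``.
    """

    t_mtsps: float

    def __post_init__(self) -> None:
        if not 0.0 < self.t_mtsps < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def bin_edges(self) -> tuple[float, float, float, float]:
        t = self.t_mtsps
        w = (1.0 - t) / 3.0
        return (t, t + w, t + 2.0 * w, 1.0)


def aicc_value(K: int, loglik: float, n: int) -> float:
    """Small-sample-corrected AIC: ``2K - 2 loglik + 2K(K+1)/(n-K-1)``.

    ``nan`` when the correction is undefined (``n - K - 1 <= 0``).
    """
    if n - K - 1 <= 0:
        return float("nan")
    return float(2.0 * K - 2.0 * loglik + 2.0 * K * (K + 1.0) / (n - K - 1.0))


def aicc(
    model: MaxentModel, presences: pd.DataFrame, landscape: EnvStack
) -> tuple[int, float, float]:
    """(K, log-likelihood, AICc) with full-landscape renormalization.

    Raw scores are standardized to sum to one over all valid landscape
    cells; the log-likelihood is the presence sum of the standardized
    log scores; ``K`` counts nonzero coefficients.  AICc is undefined
    (returned as ``nan``) when ``n - K - 1 <= 0``.
    """
    rows, cols = landscape.valid_rowcol()
    land = landscape.values_at(rows, cols)
    raw_land = predict_values(model, land, output="raw", clamp=False)
    raw_pres = predict_values(model, presences, output="raw", clamp=False)
    total = raw_land.sum()
    if not np.all(raw_pres > 0):
        raise ValueError("presence raw score of zero; cannot take log")
    loglik = float(np.log(raw_pres / total).sum())
    K = model.n_nonzero
    return K, loglik, aicc_value(K, loglik, len(presences))


def tune(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    landscape: EnvStack,
    rm_grid: tuple[float, ...] = (0.5, 1.0, 2.0),
    fc_grid: tuple[str, ...] = ("L", "LQ", "LQH"),
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """AICc tuning over a regularization-multiplier x feature-class grid.

    Returns one row per candidate with columns rm, fc, K, loglik, aicc,
    delta_aicc, valid and best; the best row (delta_aicc = 0) breaks
    ties by smaller K then smaller rm.  Raises if every candidate is
    invalid (over-parameterized for the presence count).
    """
    if not rm_grid or not fc_grid:
        raise ValueError("rm_grid and fc_grid must be non-empty")
    base = settings or FitSettings()
    rows = []
    for fc in fc_grid:
        for rm in rm_grid:
            s = FitSettings(
                rm=rm,
                max_iterations=base.max_iterations,
                background_max=base.background_max,
                convergence_tol=base.convergence_tol,
                kkt_tol=base.kkt_tol,
                seed=base.seed,
            )
            model = fit_maxent(
                presences, background, s, FeatureSpec(fc), record_trace=False
            )
            K, loglik, value = aicc(model, presences, landscape)
            rows.append(
                {
                    "rm": rm,
                    "fc": fc,
                    "K": K,
                    "loglik": loglik,
                    "aicc": value,
                    "valid": np.isfinite(value),
                }
            )
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError("every tuning candidate is invalid (K >= n - 1)")
    best_aicc = valid["aicc"].min()
    table["delta_aicc"] = table["aicc"] - best_aicc
    tied = valid[valid["aicc"] == best_aicc].sort_values(["K", "rm"])
    best_idx = tied.index[0]
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table


def auc(pred_presence: np.ndarray, pred_background: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC: P(presence outscores background), ties 1/2."""
    pred_presence = np.asarray(pred_presence, dtype=float)
    pred_background = np.asarray(pred_background, dtype=float)
    if len(pred_presence) == 0 or len(pred_background) == 0:
        raise ValueError("both prediction vectors must be non-empty")
    n1, n2 = len(pred_presence), len(pred_background)
    ranks = rankdata(np.concatenate([pred_presence, pred_background]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def boyce_index(
    pred_test_presence: np.ndarray,
    pred_background: np.ndarray,
    window_count: int = 10,
    resolution: int = 100,
) -> float | None:
    """Continuous Boyce index.

    Moving windows of width ``(max - min) / window_count`` slide over
    the background prediction range at ``resolution`` evenly spaced
    starts; per window, P is the fraction of test presences inside and
    E the fraction of background inside; windows with E = 0 are
    dropped, and the index is the Spearman rank correlation between
    P/E and the window midpoint.  Returns ``None`` when undefined (no
    usable windows or degenerate ranks).
    """
    pres = np.asarray(pred_test_presence, dtype=float)
    bg = np.asarray(pred_background, dtype=float)
    lo, hi = float(bg.min()), float(bg.max())
    if not hi > lo:
        raise ValueError("background predictions need >= 2 distinct values")
    width = (hi - lo) / window_count
    starts = np.linspace(lo, hi - width, resolution)
    mids, ratios = [], []
    for a in starts:
        b = a + width
        e = np.mean((bg >= a) & (bg <= b))
        if e == 0:
            continue
        p = np.mean((pres >= a) & (pres <= b))
        mids.append(a + width / 2.0)
        ratios.append(p / e)
    if len(mids) < 2:
        return None
    rho = spearmanr(ratios, mids).statistic
    if np.isnan(rho):
        return None
    return float(rho)


def or_mtp(
    pred_train_presence: np.ndarray, pred_test_presence: np.ndarray
) -> float:
    """Omission rate of test presences below the minimum training presence."""
    train = np.asarray(pred_train_presence, dtype=float)
    test = np.asarray(pred_test_presence, dtype=float)
    if len(train) == 0 or len(test) == 0:
        raise ValueError("both prediction vectors must be non-empty")
    t = train.min()
    return float(np.mean(test < t))


def mtsps_threshold(
    pred_train_presence: np.ndarray, pred_background: np.ndarray
) -> ThresholdSet:
    """Threshold maximizing training sensitivity plus specificity.

    Candidates are the distinct observed prediction values;
    sensitivity(t) is the fraction of presences >= t and specificity(t)
    the fraction of background < t; ties pick the smallest t.
    """
    pres = np.asarray(pred_train_presence, dtype=float)
    bg = np.asarray(pred_background, dtype=float)
    if len(pres) == 0 or len(bg) == 0:
        raise ValueError("both prediction vectors must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    best_t, best_sum = None, -np.inf
    for t in candidates:
        sens = np.mean(pres >= t)
        spec = np.mean(bg < t)
        total = sens + spec
        if total > best_sum + 1e-12:
            best_sum = total
            best_t = float(t)
    return ThresholdSet(min(max(best_t, np.nextafter(0, 1)), np.nextafter(1, 0)))


def evaluate_replicates(
    occ: OccurrenceSet,
    stack: EnvStack,
    rm: float,
    fc: str,
    split_spec: SplitSpec | None = None,
    settings: FitSettings | None = None,
) -> pd.DataFrame:
    """Refit the chosen candidate on replicate splits and score it.

    Per replicate: fit on the train presences against a seeded
    background sample, then report train/test AUC, their difference,
    the minimum-training-presence omission rate, and the continuous
    Boyce index of the test presences.  Aggregates (mean and sample SD)
    are attached in ``attrs["mean"]`` and ``attrs["sd"]``.
    """
    split_spec = split_spec or SplitSpec()
    base = settings or FitSettings()
    s = FitSettings(
        rm=rm,
        max_iterations=base.max_iterations,
        background_max=base.background_max,
        convergence_tol=base.convergence_tol,
        kkt_tol=base.kkt_tol,
        seed=base.seed,
    )
    brows, bcols = sample_background(stack, s.background_max, seed=s.seed)
    bg_table = stack.values_at(brows, bcols)
    rows = []
    for rep, (train, test) in enumerate(split_replicates(occ, split_spec)):
        train_table = extract_values(stack, train)
        test_table = extract_values(stack, test)
        model = fit_maxent(
            train_table, bg_table, s, FeatureSpec(fc), record_trace=False
        )
        p_train = predict_values(model, train_table)
        p_test = predict_values(model, test_table)
        p_bg = predict_values(model, bg_table)
        auc_train = auc(p_train, p_bg)
        auc_test = auc(p_test, p_bg)
        cbi = boyce_index(p_test, p_bg)
        rows.append(
            {
                "replicate": rep,
                "auc_train": auc_train,
                "auc_test": auc_test,
                "auc_diff": auc_train - auc_test,
                "or_mtp": or_mtp(p_train, p_test),
                "cbi": np.nan if cbi is None else cbi,
            }
        )
    report = pd.DataFrame(rows).set_index("replicate")
    report.attrs["mean"] = report.mean()
    report.attrs["sd"] = report.std(ddof=1)
    return report
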