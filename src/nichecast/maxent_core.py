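"""From-scratch maximum-entropy presence-background model.

The model estimates the Gibbs distribution of maximum entropy over
background cells subject to feature-mean constraints, which is
equivalent to minimizing the L1-penalized negative log-likelihood

    NLL(lambda) = -mean_presence(lambda . f)
                  + log sum_background exp(lambda . f)
                  + sum_j beta_j |lambda_j|

by cyclic coordinate descent with per-coordinate damped Newton steps
and soft-thresholding.  The objective is convex; convergence is
certified by the KKT conditions: for every feature j,
``|mean_presence(f_j) - E_raw[f_j]| <= beta_j`` with equality (at the
signed bound) whenever ``lambda_j != 0``.

Feature classes follow the standard presence-background vocabulary —
linear (L), quadratic (Q), product (P), hinge (H), threshold (T) — all
built on min-max-scaled predictors so that features lie in [0, 1] over
the training background.  Per-feature penalties are
``beta_j = rm * beta_class(m) * sd_j`` with the class schedules
interpolated by presence count from the published Maxent defaults and
``sd_j`` the feature's standard deviation over the fitting background.

Outputs: "raw" is the normalized Gibbs density over the training
background (projected to other grids as a density, not renormalized);
"logistic" is ``tau * e^H * raw / (1 + tau * e^H * raw)`` with
``tau = 0.5`` and ``H`` the entropy of the training raw distribution,
the familiar 0-1 suitability scale; "cloglog" is provided as an
alternative display.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geo_io import EnvStack, SuitabilityMap

__all__ = [
    "FeatureSpec",
    "FitSettings",
    "MaxentModel",
    "sample_background",
    "build_features",
    "fit_maxent",
    "predict",
    "predict_values",
    "kkt_violation",
    "variable_contributions",
    "jackknife",
    "response_curve",
    "beta_class",
]

FEATURE_CLASSES = "LQPHT"

# Published default regularization schedules, interpolated by presence
# count m.  Linear and quadratic share one schedule; hinge is constant.
_BETA_TABLE: dict[str, tuple[list[float], list[float]]] = {
    "L": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "Q": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "P": ([0.0, 10.0, 17.0, 30.0, 100.0], [2.6, 1.6, 1.1, 0.6, 0.05]),
    "T": ([0.0, 100.0], [2.0, 1.0]),
    "H": ([0.0, 100.0], [0.5, 0.5]),
}


def beta_class(m: int, cls: str) -> float:
    """Default regularization amount for a feature class at presence count m."""
    xs, ys = _BETA_TABLE[cls]
    return float(np.interp(m, xs, ys))


@dataclass
class FitSettings:
    """Solver and background-sampling settings.

    ``rm`` multiplies every default per-feature penalty;
    ``max_iterations`` caps coordinate-descent sweeps;
    ``background_max`` caps the number of background cells sampled from
    a landscape; ``convergence_tol`` is the minimum per-sweep decrease
    of the penalized NLL before stopping; ``kkt_tol`` is the
    certificate tolerance.
    """

    rm: float = 1.0
    max_iterations: int = 5000
    background_max: int = 20000
    convergence_tol: float = 1e-6
    kkt_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rm > 0:
            raise ValueError("rm must be positive")
        if self.background_max < 100:
            raise ValueError("background_max must be >= 100")


@dataclass
class FeatureSpec:
    """Feature classes plus the training-background scaling that grounds them.

    ``scaling`` maps each variable to its (min, max) over the training
    background; hinge/threshold knots sit at evenly spaced quantiles of
    the scaled background values.  ``fit`` must be called (with the
    background table) before ``transform``.
    """

    classes: str = "LQ"
    hinge_knots_per_var: int = 20
    threshold_knots_per_var: int = 20
    scaling: dict[str, tuple[float, float]] | None = None
    hinge_knots: dict[str, np.ndarray] | None = field(default=None, repr=False)
    threshold_knots: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        raw = self.classes.upper()
        bad = set(raw) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature class(es): {sorted(bad)}")
        self.classes = "".join(c for c in FEATURE_CLASSES if c in raw)
        if not self.classes:
            raise ValueError("feature classes must include at least one of LQPHT")

    def fit(self, background: pd.DataFrame) -> "FeatureSpec":
        """Derive scaling ranges and knots from the training background."""
        scaling = {}
        hinge = {}
        thresh = {}
        for name in background.columns:
            x = background[name].to_numpy(dtype=float)
            mn, mx = float(np.min(x)), float(np.max(x))
            scaling[name] = (mn, mx)
            span = mx - mn
            xs = (x - mn) / span if span > 0 else np.zeros_like(x)
            if "H" in self.classes:
                probs = np.arange(1, self.hinge_knots_per_var + 1) / (
                    self.hinge_knots_per_var + 1
                )
                hinge[name] = np.unique(np.quantile(xs, probs))
            if "T" in self.classes:
                probs = np.arange(1, self.threshold_knots_per_var + 1) / (
                    self.threshold_knots_per_var + 1
                )
                thresh[name] = np.unique(np.quantile(xs, probs))
        return replace(
            self, scaling=scaling, hinge_knots=hinge or None,
            threshold_knots=thresh or None,
        )

    # -- transformation -----------------------------------------------------

    def _scaled(self, table: pd.DataFrame) -> dict[str, np.ndarray]:
        assert self.scaling is not None, "FeatureSpec.fit must be called first"
        out = {}
        for name, (mn, mx) in self.scaling.items():
            if name not in table.columns:
                raise KeyError(f"variable {name!r} missing from value table")
            x = table[name].to_numpy(dtype=float)
            span = mx - mn
            out[name] = (x - mn) / span if span > 0 else np.zeros_like(x)
        return out

    def transform(
        self, table: pd.DataFrame
    ) -> tuple[np.ndarray, list[str], list[tuple[str, ...]]]:
        """Feature matrix plus column names and parent-variable tuples."""
        scaled = self._scaled(table)
        if not np.all([np.all(np.isfinite(v)) for v in scaled.values()]):
            raise ValueError("non-finite predictor values in feature input")
        names = list(scaled)
        cols: list[np.ndarray] = []
        fnames: list[str] = []
        parents: list[tuple[str, ...]] = []

        def add(col, fname, parent):
            cols.append(col)
            fnames.append(fname)
            parents.append(parent)

        if "L" in self.classes:
            for n in names:
                add(scaled[n], f"L({n})", (n,))
        if "Q" in self.classes:
            for n in names:
                add(scaled[n] ** 2, f"Q({n})", (n,))
        if "P" in self.classes:
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    add(scaled[a] * scaled[b], f"P({a}*{b})", (a, b))
        if "H" in self.classes:
            for n in names:
                for k in self.hinge_knots[n]:
                    if k < 1.0 - 1e-9:
                        add(
                            np.maximum(scaled[n] - k, 0.0) / (1.0 - k),
                            f"HF({n}@{k:.6g})",
                            (n,),
                        )
                    if k > 1e-9:
                        add(
                            np.maximum(k - scaled[n], 0.0) / k,
                            f"HR({n}@{k:.6g})",
                            (n,),
                        )
        if "T" in self.classes:
            for n in names:
                for k in self.threshold_knots[n]:
                    add((scaled[n] > k).astype(float), f"T({n}@{k:.6g})", (n,))
        F = np.column_stack(cols) if cols else np.empty((len(table), 0))
        return F, fnames, parents


def build_features(
    table: pd.DataFrame, spec: FeatureSpec
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for a value table under a fitted spec."""
    F, names, _ = spec.transform(table)
    return F, names


def sample_background(
    stack: EnvStack, background_max: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample (without replacement) of valid cells.

    Returns (rows, cols); all valid cells when fewer than the cap.
    """
    rows, cols = stack.valid_rowcol()
    n = len(rows)
    if n == 0:
        raise ValueError("stack has no valid cells")
    if n <= background_max:
        return rows, cols
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(n, size=background_max, replace=False))
    return rows[pick], cols[pick]


@dataclass
class MaxentModel:
    """A fitted model: everything needed to predict and project."""

    feature_spec: FeatureSpec
    feature_names: list[str]
    feature_parents: list[tuple[str, ...]]
    lambdas: np.ndarray
    betas: np.ndarray
    log_partition: float
    entropy: float
    n_presence: int
    rm: float
    clamp_ranges: dict[str, tuple[float, float]]
    background_means: dict[str, float]
    tau: float = 0.5
    converged: bool = True
    n_sweeps: int = 0
    kkt: float = float("nan")
    trace_credit: np.ndarray | None = field(default=None, repr=False)

    @property
    def variables(self) -> list[str]:
        return list(self.clamp_ranges)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.lambdas))

    def to_dict(self) -> dict:
        return {
            "classes": self.feature_spec.classes,
            "feature_names": self.feature_names,
            "lambdas": self.lambdas.tolist(),
            "betas": self.betas.tolist(),
            "log_partition": self.log_partition,
            "entropy": self.entropy,
            "tau": self.tau,
            "rm": self.rm,
            "n_presence": self.n_presence,
            "clamp_ranges": {k: list(v) for k, v in self.clamp_ranges.items()},
            "background_means": self.background_means,
        }


def _logsumexp(s: np.ndarray) -> float:
    smax = float(s.max())
    return smax + float(np.log(np.exp(s - smax).sum()))


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_maxent(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    settings: FitSettings | None = None,
    feature_spec: FeatureSpec | None = None,
    include_presences: bool = True,
    betas: np.ndarray | None = None,
    record_trace: bool = True,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    Parameters
    ----------
    presence, background
        Value tables (rows = points/cells, columns = predictor
        variables).  Feature scaling and knots come from the background.
    include_presences
        Add the presence rows to the background for partition-function
        purposes (the usual convention); disable for textbook toy
        problems where the background is exactly as given.
    betas
        Optional explicit per-feature penalty vector overriding the
        default ``rm * beta_class(m) * sd_j`` schedule.
    """
    settings = settings or FitSettings()
    feature_spec = feature_spec or FeatureSpec("LQ")
    m = len(presence)
    if m < 2:
        raise ValueError("need at least 2 presences")
    spec = feature_spec.fit(background)
    F_pres, fnames, parents = spec.transform(presence)
    F_bg, _, _ = spec.transform(background)
    F_fit = np.vstack([F_bg, F_pres]) if include_presences else F_bg
    if not np.all(np.isfinite(F_fit)):
        raise ValueError("non-finite feature values")
    N, J = F_fit.shape
    p_mean = F_pres.mean(axis=0)
    sd = F_fit.std(axis=0)
    active = sd > 1e-10
    if betas is None:
        # published default schedule: class amount at presence count m,
        # scaled by the feature spread and shrinking as 1/sqrt(m)
        beta = np.array(
            [
                settings.rm * beta_class(m, _cls_of(name)) * sd[j] / np.sqrt(m)
                for j, name in enumerate(fnames)
            ]
        )
    else:
        beta = np.asarray(betas, dtype=float)
        if beta.shape != (J,):
            raise ValueError(f"betas must have length {J}")

    lam, s, credit, converged, sweeps, viol = _solve(
        F_fit, p_mean, beta, active, settings
    )
    logZ = _logsumexp(s)
    q = np.exp(s - logZ)
    entropy = float(logZ - q @ s)
    model = MaxentModel(
        feature_spec=spec,
        feature_names=fnames,
        feature_parents=parents,
        lambdas=lam,
        betas=beta,
        log_partition=logZ,
        entropy=entropy,
        n_presence=m,
        rm=settings.rm,
        clamp_ranges=dict(spec.scaling),
        background_means={
            name: float(background[name].mean()) for name in background.columns
        },
        converged=converged,
        n_sweeps=sweeps,
        kkt=float(viol),
        trace_credit=credit if record_trace else None,
    )
    return model


def _quadratic_subproblem(
    lamW: np.ndarray,
    g: np.ndarray,
    H: np.ndarray,
    betaW: np.ndarray,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-threshold coordinate descent on the local quadratic model.

    Minimizes ``g.d + d'Hd/2 + beta.|lamW + d| - beta.|lamW|`` over the
    step ``d``; returns the step and the per-coordinate model-decrease
    credit used for contribution bookkeeping.
    """
    k = len(lamW)
    d = np.zeros(k)
    r = g.copy()  # gradient of the smooth model: g + H d
    credit = np.zeros(k)
    diag = np.diag(H)
    for _ in range(max_sweeps):
        max_change = 0.0
        for j in range(k):
            hjj = diag[j]
            if hjj < 1e-12:
                continue
            zold = lamW[j] + d[j]
            znew = _soft(zold - r[j] / hjj, betaW[j] / hjj)
            delta = znew - zold
            if delta == 0.0:
                continue
            credit[j] += (
                -r[j] * delta
                - 0.5 * hjj * delta * delta
                + betaW[j] * (abs(zold) - abs(znew))
            )
            d[j] += delta
            r += H[:, j] * delta
            max_change = max(max_change, abs(delta))
        if max_change < 1e-12:
            break
    return d, credit


def _solve(
    F: np.ndarray,
    p_mean: np.ndarray,
    beta: np.ndarray,
    active: np.ndarray,
    settings: FitSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int, float]:
    """Working-set proximal-Newton solver for the penalized NLL.

    Each iteration: (1) a screening pass (one matmul) evaluates the
    exact KKT certificate for every feature and collects the working
    set of nonzero or violating coordinates; (2) the L1-penalized local
    quadratic model on the working set is minimized by cyclic
    coordinate descent with soft-thresholding; (3) the step is accepted
    after a halving line search that keeps the true penalized NLL
    non-increasing.  The objective is convex, so monotone descent with
    full-gradient screening converges to the optimum; iteration stops
    once the certificate tolerance is met.
    """
    N, J = F.shape
    lam = np.zeros(J)
    s = np.zeros(N)
    lin = 0.0  # p_mean . lam
    pennorm = 0.0  # beta . |lam|
    pen = float(np.log(N))
    credit = np.zeros(J)
    converged = False
    iters = 0
    stalled = 0
    viol = np.inf
    while iters < settings.max_iterations:
        iters += 1
        # screening: full-gradient KKT check at the current point
        logZ = _logsumexp(s)
        q = np.exp(s - logZ)
        E = F.T @ q
        viol = _kkt_violation(p_mean, E, beta, lam, active)
        if viol <= 0.5 * settings.kkt_tol:
            converged = True
            break
        excess = np.abs(p_mean - E) - beta
        work = np.nonzero(
            active & ((lam != 0.0) | (excess > 0.1 * settings.kkt_tol))
        )[0]
        if len(work) == 0:
            converged = True
            break
        FW = F[:, work]
        EW = E[work]
        g = EW - p_mean[work]
        Fq = FW * q[:, None]
        H = FW.T @ Fq - np.outer(EW, EW)
        H[np.diag_indices_from(H)] += 1e-10
        d, model_credit = _quadratic_subproblem(lam[work], g, H, beta[work])
        if not np.any(d):
            stalled += 1
            if stalled >= 5:
                converged = viol <= settings.kkt_tol
                break
            continue
        ds = FW @ d
        step = 1.0
        accepted = False
        for _ in range(30):
            lam_c = lam.copy()
            lam_c[work] = lam[work] + step * d
            lin_c = lin + step * float(p_mean[work] @ d)
            pennorm_c = float(beta @ np.abs(lam_c))
            s_c = s + step * ds
            pen_c = -lin_c + _logsumexp(s_c) + pennorm_c
            if pen_c <= pen + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            stalled += 1
            if stalled >= 5:
                converged = viol <= settings.kkt_tol
                break
            continue
        decrease = pen - pen_c
        total_model = model_credit.clip(min=0.0).sum()
        if total_model > 0 and decrease > 0:
            credit[work] += decrease * model_credit.clip(min=0.0) / total_model
        lam = lam_c
        s = s_c
        lin = lin_c
        pennorm = pennorm_c
        pen = pen_c
        if decrease < settings.convergence_tol:
            stalled += 1
            if stalled >= 5:
                converged = viol <= settings.kkt_tol
                break
        else:
            stalled = 0
    if iters >= settings.max_iterations and not converged:
        converged = viol <= settings.kkt_tol
    return lam, s, credit, converged, iters, float(viol)


def _cls_of(feature_name: str) -> str:
    head = feature_name.split("(", 1)[0]
    return "H" if head in ("HF", "HR") else head


def _kkt_violation(
    p_mean: np.ndarray,
    E: np.ndarray,
    beta: np.ndarray,
    lam: np.ndarray,
    active: np.ndarray,
) -> float:
    diff = p_mean - E
    v_zero = np.maximum(np.abs(diff) - beta, 0.0)
    v_nonzero = np.abs(diff - np.sign(lam) * beta)
    v = np.where(lam != 0.0, v_nonzero, v_zero)
    v = np.where(active, v, 0.0)
    return float(v.max()) if len(v) else 0.0


def kkt_violation(
    model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame,
    include_presences: bool = True,
) -> float:
    """Recompute the KKT certificate of a fitted model from its data."""
    F_pres, _, _ = model.feature_spec.transform(presence)
    F_bg, _, _ = model.feature_spec.transform(background)
    F_fit = np.vstack([F_bg, F_pres]) if include_presences else F_bg
    s = F_fit @ model.lambdas
    q = np.exp(s - _logsumexp(s))
    E = F_fit.T @ q
    active = F_fit.std(axis=0) > 1e-10
    return _kkt_violation(F_pres.mean(axis=0), E, model.betas, model.lambdas, active)


# ---------------------------------------------------------------------------
# prediction


def _clamp_table(model: MaxentModel, table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for name, (mn, mx) in model.clamp_ranges.items():
        out[name] = out[name].clip(mn, mx)
    return out


def predict_values(
    model: MaxentModel,
    table: pd.DataFrame,
    output: str = "logistic",
    clamp: bool = True,
) -> np.ndarray:
    """Model output for a table of predictor values.

    "raw" values are densities normalized over the *training*
    background (not renormalized on projection data); "logistic" and
    "cloglog" are the bounded suitability displays.
    """
    missing = [v for v in model.variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables missing from input: {missing}")
    if clamp:
        table = _clamp_table(model, table)
    F, _, _ = model.feature_spec.transform(table)
    raw = np.exp(F @ model.lambdas - model.log_partition)
    if output == "raw":
        return raw
    scaled = model.tau * np.exp(model.entropy) * raw
    if output == "logistic":
        return scaled / (1.0 + scaled)
    if output == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise ValueError(f"unknown output {output!r}")


def predict(
    model: MaxentModel,
    stack: EnvStack,
    output: str = "logistic",
    clamp: bool = True,
) -> SuitabilityMap:
    """Project the model over every valid cell of a stack."""
    rows, cols = stack.valid_rowcol()
    table = stack.values_at(rows, cols)
    vals = predict_values(model, table, output=output, clamp=clamp)
    grid = np.full(stack.geometry.shape, np.nan)
    grid[rows, cols] = vals
    return SuitabilityMap(stack.geometry, grid)


# ---------------------------------------------------------------------------
# interpretation


def variable_contributions(model: MaxentModel) -> pd.Series:
    """Percent contribution per variable from the fit trace.

    Each coordinate-descent update's decrease of the penalized NLL is
    credited to the updated feature's parent variable(s) (product
    features split evenly); negative credits are floored at zero and
    the result is normalized to percentages summing to 100.
    """
    if model.trace_credit is None:
        raise ValueError("model was fitted without trace recording")
    credit: dict[str, float] = {v: 0.0 for v in model.variables}
    for j, parents in enumerate(model.feature_parents):
        c = max(model.trace_credit[j], 0.0)
        for p in parents:
            credit[p] += c / len(parents)
    total = sum(credit.values())
    if total <= 0:
        return pd.Series({v: 0.0 for v in credit}, name="contribution_pct")
    return pd.Series(
        {v: 100.0 * c / total for v, c in credit.items()}, name="contribution_pct"
    )


def _gain(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    settings: FitSettings,
    spec: FeatureSpec,
) -> float:
    model = fit_maxent(
        presence, background, settings, spec, record_trace=False
    )
    F_pres, _, _ = model.feature_spec.transform(presence)
    F_bg, _, _ = model.feature_spec.transform(background)
    F_fit = np.vstack([F_bg, F_pres])
    s = F_fit @ model.lambdas
    pen = (
        -float(F_pres.mean(axis=0) @ model.lambdas)
        + _logsumexp(s)
        + float(model.betas @ np.abs(model.lambdas))
    )
    return float(np.log(len(F_fit)) - pen)  # null NLL minus fitted NLL


def jackknife(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    settings: FitSettings | None = None,
    feature_spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Per-variable regularized training gain, alone and left out.

    Returns a frame with ``gain_alone`` and ``gain_without`` per
    variable plus the full-model gain in ``attrs["full_gain"]``.
    """
    settings = settings or FitSettings()
    spec = feature_spec or FeatureSpec("LQ")
    variables = list(presence.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    rows = {}
    for v in variables:
        alone = _gain(presence[[v]], background[[v]], settings, spec)
        rest = [w for w in variables if w != v]
        without = _gain(presence[rest], background[rest], settings, spec)
        rows[v] = {"gain_alone": alone, "gain_without": without}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["full_gain"] = _gain(presence, background, settings, spec)
    return out


def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100
) -> pd.DataFrame:
    """Marginal response: one variable sweeps its background range while
    all others sit at their background means; outputs logistic values."""
    if variable not in model.variables:
        raise KeyError(f"{variable!r} is not a model variable")
    mn, mx = model.clamp_ranges[variable]
    xs = np.linspace(mn, mx, n_points)
    table = pd.DataFrame(
        {v: np.full(n_points, model.background_means[v]) for v in model.variables}
    )
    table[variable] = xs
    ys = predict_values(model, table, output="logistic", clamp=True)
    return pd.DataFrame({"value": xs, "logistic": ys})
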