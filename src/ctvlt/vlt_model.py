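"""VLT prediction by multiple linear regression with stepwise selection.

The response is the reader-panel threshold ``vlt_rad``; the nine candidate
predictors are the five image features plus four DICOM header covariates
(effective mAs, section thickness ``st``, field of view ``fov``, and the
reconstruction filter encoded as the binary indicator ``filter_sharp``:
soft-tissue -> 0, medium-sharp -> 1).

Selection is backward stepwise under the likelihood-ratio criterion
(p = 0.10 for removal, p = 0.05 for re-entry) with a 4-fold
cross-validation guard: a removal or re-entry step is accepted only if it
does not increase the mean out-of-fold RMSE by more than ``cv_tol``
(default 2%). Folds are assigned by a seeded shuffle, so the whole
procedure is deterministic given (data, seed). The final model is refit
on the entire training set.

Variables are not standardized: coefficients stay in natural units.
Collinearity is monitored through the design-matrix condition number with
a logged warning above 1e6.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dicom_io import AcquisitionMeta
from .features import FeatureVector

__all__ = [
    "CANDIDATES",
    "DesignRow",
    "RegressionModel",
    "encode_design",
    "design_matrix",
    "fit_ols",
    "lr_pvalue",
    "cv_rmse",
    "backward_stepwise",
    "predict_vlt",
    "save_model",
    "load_model",
]

log = logging.getLogger(__name__)

#: canonical candidate ordering (ties in removal p-values are broken by
#: removing the variable appearing later in this list)
CANDIDATES = (
    "image_sd",
    "image_entropy",
    "percentage_lf",
    "variation_hf",
    "visual_complexity",
    "effective_mas",
    "st",
    "fov",
    "filter_sharp",
)

FILTER_ENCODING = {"soft-tissue": 0, "medium-sharp": 1}

PREDICTION_RANGE = (2.0, 40.0)

CONDITION_WARN = 1e6


@dataclass(frozen=True)
class DesignRow:
    """One observation of the nine candidate predictors."""

    image_sd: float
    image_entropy: float
    percentage_lf: float
    variation_hf: float
    visual_complexity: float
    effective_mas: float
    st: float
    fov: float
    filter_sharp: int

    def __post_init__(self) -> None:
        if self.filter_sharp not in (0, 1):
            raise ValueError("filter_sharp must be 0 or 1")
        for name in CANDIDATES:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass
class RegressionModel:
    """Fitted coefficients over a selected variable subset."""

    selected: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    residual_sd: float
    rss: float
    n_train: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.selected):
            raise ValueError("coefficients must exist exactly for selected variables")


def encode_design(meta: AcquisitionMeta, features: FeatureVector) -> DesignRow:
    """Assemble one design row from header covariates and image features."""
    if meta.recon_filter not in FILTER_ENCODING:
        raise ValueError(f"unknown reconstruction filter {meta.recon_filter!r}")
    return DesignRow(
        **features.as_dict(),
        effective_mas=meta.effective_mas,
        st=meta.section_thickness_mm,
        fov=meta.fov_mm,
        filter_sharp=FILTER_ENCODING[meta.recon_filter],
    )


def design_matrix(
    rows: list[DesignRow], subset: tuple[str, ...]
) -> np.ndarray:
    """n x (1+p) matrix with a leading intercept column."""
    X = np.empty((len(rows), len(subset) + 1), dtype=np.float64)
    X[:, 0] = 1.0
    for j, name in enumerate(subset, start=1):
        X[:, j] = [getattr(r, name) for r in rows]
    return X


def fit_ols(
    rows: list[DesignRow],
    y,
    subset: tuple[str, ...] | None = None,
) -> RegressionModel:
    """Ordinary least squares on a variable subset (default: all nine)."""
    subset = CANDIDATES if subset is None else tuple(subset)
    y = np.asarray(y, dtype=np.float64)
    n, p = len(rows), len(subset)
    if len(y) != n:
        raise ValueError("rows and y must have the same length")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    X = design_matrix(rows, subset)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}) for subset {subset}"
        )
    if p > 0:
        cond = np.linalg.cond(X)
        if cond > CONDITION_WARN:
            log.warning("design matrix condition number %.3g exceeds %g", cond, CONDITION_WARN)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p - 1
    residual_sd = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
    return RegressionModel(
        selected=subset,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(subset, beta[1:])},
        residual_sd=residual_sd,
        rss=rss,
        n_train=n,
    )


def lr_pvalue(full: RegressionModel, reduced: RegressionModel, n: int) -> float:
    """Likelihood-ratio p-value for nested Gaussian linear models.

    Statistic n*ln(RSS_reduced / RSS_full), chi-squared with df equal to
    the difference in variable counts.
    """
    if not set(reduced.selected) < set(full.selected):
        raise ValueError("models are not strictly nested")
    df = len(full.selected) - len(reduced.selected)
    if full.rss <= 0:
        return 0.0 if reduced.rss > full.rss else 1.0
    stat = n * np.log(reduced.rss / full.rss)
    return float(stats.chi2.sf(max(stat, 0.0), df))


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    idx = np.arange(n)
    np.random.default_rng(seed).shuffle(idx)
    assign = np.empty(n, dtype=int)
    for k, part in enumerate(np.array_split(idx, folds)):
        assign[part] = k
    return assign


def cv_rmse(
    rows: list[DesignRow],
    y,
    subset: tuple[str, ...],
    assign: np.ndarray,
) -> float:
    """Mean out-of-fold RMSE for one variable subset.

    ``assign`` is a fold-assignment vector, or a 2-D stack of them: with
    several seeded assignments the RMSE is averaged over repetitions,
    which reduces the Monte-Carlo noise of the estimate (the fold split
    is the only stochastic element of the selection procedure).
    """
    y = np.asarray(y, dtype=np.float64)
    X = design_matrix(rows, subset)
    assign = np.atleast_2d(np.asarray(assign))
    rmses = []
    for a in assign:
        for k in range(int(a.max()) + 1):
            tr, te = a != k, a == k
            beta, _, _, _ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
            err = y[te] - X[te] @ beta
            rmses.append(np.sqrt(np.mean(err**2)))
    return float(np.mean(rmses))


def backward_stepwise(
    rows: list[DesignRow],
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    folds: int = 4,
    seed: int = 0,
    cv_tol: float = 0.02,
    allow_reentry: bool = True,
    cv_repeats: int = 5,
    max_steps: int = 50,
) -> RegressionModel:
    """Backward stepwise selection with LR tests and a CV guard.

    Starts from all nine candidates. Each step removes the variable with
    the largest LR p-value above ``p_remove`` (ties broken toward the
    variable later in the canonical ordering); after each removal the
    excluded variables are re-tested for entry at ``p_enter``. Any step
    is accepted only if the mean 4-fold CV RMSE does not grow by more
    than ``cv_tol`` (relative). If every variable is removed the result
    is a flagged intercept-only model.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(rows)
    if n < 8 * len(CANDIDATES):
        log.warning("n=%d is below the recommended 8 observations per candidate", n)
    assign = np.stack(
        [_fold_assignment(n, folds, seed + 7919 * r) for r in range(cv_repeats)]
    )

    current = list(CANDIDATES)
    seen: set[tuple[str, ...]] = {tuple(current)}

    def fit(subset):
        return fit_ols(rows, y, tuple(subset))

    for _ in range(max_steps):
        changed = False
        # --- removal phase ---------------------------------------------
        # First the LR criterion: drop the variable with the largest
        # p-value above p_remove, provided the CV guard accepts. Once no
        # variable fails the LR test, cross-validation keeps pruning:
        # any variable whose removal leaves the mean out-of-fold RMSE
        # within the tolerance is redundant for prediction and is
        # removed (best candidate first). Genuinely informative
        # variables inflate the CV RMSE well beyond the tolerance when
        # dropped, so they are protected; pure-noise variables that
        # happen to pass the LR test by chance are not.
        if current:
            model = fit(current)
            pvals = []
            for v in current:
                reduced = fit([u for u in current if u != v])
                pvals.append((lr_pvalue(model, reduced, n), v))
            # largest p first; ties -> later canonical position first
            pvals.sort(key=lambda t: (-t[0], -CANDIDATES.index(t[1])))
            base_rmse = cv_rmse(rows, y, tuple(current), assign)
            for p, v in pvals:
                if p <= p_remove:
                    break
                trial = [u for u in current if u != v]
                if cv_rmse(rows, y, tuple(trial), assign) <= base_rmse * (1 + cv_tol):
                    current = trial
                    changed = True
                    break
            if not changed:
                # CV pruning stage
                cand = []
                for _, v in pvals:
                    trial = tuple(u for u in current if u != v)
                    cand.append((cv_rmse(rows, y, trial, assign), v))
                cand.sort(key=lambda t: (t[0], -CANDIDATES.index(t[1])))
                best_rmse, v = cand[0]
                if best_rmse <= base_rmse * (1 + cv_tol):
                    current = [u for u in current if u != v]
                    changed = True
        # --- re-entry phase --------------------------------------------
        if allow_reentry and changed:
            excluded = [v for v in CANDIDATES if v not in current]
            if excluded and len(current) < len(CANDIDATES):
                base = fit(current) if current else None
                entries = []
                for v in excluded:
                    bigger = fit(current + [v])
                    if base is None:
                        # compare against intercept-only RSS
                        rss0 = float(np.sum((y - y.mean()) ** 2))
                        stat = n * np.log(max(rss0, 1e-300) / max(bigger.rss, 1e-300))
                        p = float(stats.chi2.sf(max(stat, 0.0), 1))
                    else:
                        p = lr_pvalue(bigger, base, n)
                    entries.append((p, v))
                entries.sort(key=lambda t: (t[0], CANDIDATES.index(t[1])))
                p, v = entries[0]
                if p < p_enter:
                    trial = current + [v]
                    base_rmse = cv_rmse(rows, y, tuple(current), assign) if current else np.sqrt(np.mean((y - y.mean()) ** 2))
                    if cv_rmse(rows, y, tuple(trial), assign) <= base_rmse * (1 + cv_tol):
                        state = tuple(sorted(trial))
                        if state not in seen:  # guard against remove/add cycles
                            seen.add(state)
                            current = trial
                            changed = True
        if not changed:
            break

    current = [v for v in CANDIDATES if v in current]  # canonical order
    if not current:
        model = RegressionModel(
            selected=(),
            intercept=float(y.mean()),
            coefficients={},
            residual_sd=float(np.std(y, ddof=1)),
            rss=float(np.sum((y - y.mean()) ** 2)),
            n_train=n,
            flags=("intercept_only",),
        )
        return model
    return fit(current)


def predict_vlt(model: RegressionModel, row: DesignRow):
    """Linear prediction, clamped to the [2, 40] CR search range.

    Returns ``(vlt, flag)`` where flag is "clamped" when the raw linear
    predictor fell outside the range.
    """
    pred = model.intercept
    for name in model.selected:
        v = getattr(row, name, None)
        if v is None:
            raise ValueError(f"design row is missing selected variable {name!r}")
        pred += model.coefficients[name] * v
    lo, hi = PREDICTION_RANGE
    if pred < lo or pred > hi:
        return float(np.clip(pred, lo, hi)), "clamped"
    return float(pred), "ok"


def save_model(model: RegressionModel, path) -> None:
    payload = {
        "selected": list(model.selected),
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "residual_sd": model.residual_sd,
        "rss": model.rss,
        "n_train": model.n_train,
        "flags": list(model.flags),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> RegressionModel:
    with open(path) as fh:
        d = json.load(fh)
    return RegressionModel(
        selected=tuple(d["selected"]),
        intercept=float(d["intercept"]),
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        residual_sd=float(d["residual_sd"]),
        rss=float(d["rss"]),
        n_train=int(d["n_train"]),
        flags=tuple(d.get("flags", ())),
    )
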