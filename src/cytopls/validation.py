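"""Model validation: repeated one-third-holdout cross-validation, latent
variable selection by lowest CV error, and permutation-based confidence.

Cross-validation repeatedly holds out a stratified random one-third of the
samples, refits on the remaining two-thirds (Z-scaling constants and, for
regression, the response standardization come from the training fold only),
and scores the held-out third: classification accuracy for discriminant
models, RMSECV on the standardized response scale for regression models.

Model confidence compares the cross-validated metric of the true model with
the distribution of the identical metric from models fit after uniformly
permuting the response across samples while keeping the predictor block
intact (default 100 randomized models, latent-variable count held fixed).
Confidence is the mid-rank percentile of the true metric within that null:
the percentage of permuted models that perform strictly worse, with ties
counting one half.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .pls import PlsError, _nipals_pls1, encode_classes

DEFAULT_HOLDOUT = 1.0 / 3.0
DEFAULT_REPEATS = 100
DEFAULT_PERMUTATIONS = 100


class ValidationError(ValueError):
    pass


@dataclasses.dataclass
class ValidationResult:
    """Cross-validated metric, optionally with its permutation null."""

    metric_name: str  # "accuracy" | "rmsecv"
    cv_value: float
    per_repeat_values: np.ndarray
    L_selected: int
    null_distribution: np.ndarray | None = None
    confidence: float | None = None
    seed: int | None = None
    details: list | None = None  # per-repeat (train_idx, test_idx) if requested

    def summary(self) -> str:
        if self.metric_name == "accuracy":
            head = f"accuracy: {100 * self.cv_value:.2f}% ({self.L_selected}LV)"
        else:
            head = f"RMSECV: {self.cv_value:.3f} ({self.L_selected}LV)"
        if self.confidence is not None:
            head += f"; confidence: {self.confidence:.2f}%"
        return head


@dataclasses.dataclass
class LvSelection:
    """Chosen latent-variable count and the full CV error-vs-L table."""

    selected: int
    table: pd.DataFrame  # columns: L, cv_error, cv_metric


def _as_matrix(X) -> np.ndarray:
    if hasattr(X, "values") and hasattr(X, "analytes"):  # CleanedMatrix
        X = X.values
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; clean the panel first")
    return X


def _resolve_mode(y, mode: str) -> str:
    if mode in ("plsda", "discriminant"):
        return "discriminant"
    if mode in ("plsr", "regression"):
        return "regression"
    if mode == "auto":
        return "regression" if np.issubdtype(np.asarray(y).dtype, np.number) else "discriminant"
    raise ValidationError(f"unknown mode {mode!r}")


def _scale_train(Xtr: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise PlsError("zero-variance predictor inside a training fold")
    return mu, sd


def _predict(W, P, c, Xs, y_center):
    B = W @ np.linalg.solve(P.T @ W, c)
    return Xs @ B + y_center


def _cv_metrics(
    X: np.ndarray,
    y_num: np.ndarray,
    mode: str,
    L: int,
    n_repeats: int,
    holdout: float,
    rng: np.random.Generator,
    strata: np.ndarray | None,
    collect=None,
) -> np.ndarray:
    """Per-repeat CV metric (accuracy or standardized-scale RMSE)."""
    n = len(y_num)
    if strata is not None:
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
        n_test = [max(1, round(len(g) * holdout)) for g in groups]
        for g, nt in zip(groups, n_test):
            if len(g) - nt < 2:
                raise ValidationError("training fold would keep fewer than 2 samples of a class")
    else:
        nt_all = max(1, round(n * holdout))
        if n - nt_all < 3:
            raise ValidationError("too few samples for a one-third holdout")
    out = np.empty(n_repeats)
    for rep in range(n_repeats):
        if strata is not None:
            test_idx = np.concatenate(
                [rng.permutation(g)[:nt] for g, nt in zip(groups, n_test)]
            )
        else:
            test_idx = rng.permutation(n)[:nt_all]
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        Xtr, Xte = X[~mask], X[mask]
        ytr, yte = y_num[~mask], y_num[mask]
        mu, sd = _scale_train(Xtr)
        Xtr_s = (Xtr - mu) / sd
        Xte_s = (Xte - mu) / sd
        if mode == "regression":
            y_mu, y_sd = ytr.mean(), ytr.std(ddof=1)
            if y_sd == 0:
                raise ValidationError("constant response inside a training fold")
            ytr_s = (ytr - y_mu) / y_sd
            W, P, _, c, _ = _nipals_pls1(Xtr_s, ytr_s, L)
            pred = _predict(W, P, c, Xte_s, 0.0)
            out[rep] = float(np.sqrt(np.mean((pred - (yte - y_mu) / y_sd) ** 2)))
        else:
            y_center = ytr.mean()
            W, P, _, c, _ = _nipals_pls1(Xtr_s, ytr - y_center, L)
            pred = _predict(W, P, c, Xte_s, y_center)
            # sign rule; an exact zero counts as the larger training class
            tie_sign = 1.0 if (ytr == 1.0).sum() >= (ytr == -1.0).sum() else -1.0
            cls = np.where(pred > 0, 1.0, -1.0)
            cls[pred == 0] = tie_sign
            out[rep] = float((cls == yte).mean())
        if collect is not None:
            collect.append((np.flatnonzero(~mask), test_idx, mu, sd))
    return out


def cross_validate(
    X,
    y,
    L: int,
    mode: str = "auto",
    n_repeats: int = DEFAULT_REPEATS,
    holdout_fraction: float = DEFAULT_HOLDOUT,
    seed: int | np.random.Generator = 0,
    return_details: bool = False,
) -> ValidationResult:
    """Repeated stratified one-third-holdout cross-validation.

    Discriminant mode stratifies the holdout by class so no fold ever loses
    a class; regression mode holds out a simple random third. Identical
    seeds give identical fold assignments.
    """
    X = _as_matrix(X)
    mode = _resolve_mode(y, mode)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "discriminant":
        y_num, _, _ = encode_classes(y)
        strata = y_num
    else:
        y_num = np.asarray(y, dtype=float)
        strata = None
    if X.shape[0] != len(y_num):
        raise ValidationError("X and y have different lengths")
    collect: list | None = [] if return_details else None
    metrics = _cv_metrics(X, y_num, mode, L, n_repeats, holdout_fraction, rng, strata, collect)
    return ValidationResult(
        metric_name="accuracy" if mode == "discriminant" else "rmsecv",
        cv_value=float(metrics.mean()),
        per_repeat_values=metrics,
        L_selected=L,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        details=collect,
    )


def cv_error(result: ValidationResult) -> float:
    """CV error on a to-be-minimized scale (1−accuracy, or RMSECV)."""
    return 1.0 - result.cv_value if result.metric_name == "accuracy" else result.cv_value


def select_num_lvs(
    X,
    y,
    L_max: int,
    mode: str = "auto",
    n_repeats: int = DEFAULT_REPEATS,
    holdout_fraction: float = DEFAULT_HOLDOUT,
    seed: int = 0,
) -> LvSelection:
    """Choose L in 1..L_max minimizing CV error; ties go to the smaller L.

    Every candidate L is evaluated on the same fold sequence (same seed) so
    the comparison is paired; the full error-vs-L table is returned.
    """
    if L_max < 1:
        raise ValidationError("L_max must be >= 1")
    rows = []
    for L in range(1, L_max + 1):
        res = cross_validate(
            X, y, L, mode=mode, n_repeats=n_repeats,
            holdout_fraction=holdout_fraction, seed=seed,
        )
        rows.append((L, cv_error(res), res.cv_value))
    table = pd.DataFrame(rows, columns=["L", "cv_error", "cv_metric"])
    selected = int(table.loc[table["cv_error"].idxmin(), "L"])  # idxmin takes first min
    return LvSelection(selected=selected, table=table)


def permutation_confidence(
    X,
    y,
    L: int,
    mode: str = "auto",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    n_repeats: int = DEFAULT_REPEATS,
    holdout_fraction: float = DEFAULT_HOLDOUT,
    seed: int = 0,
) -> ValidationResult:
    """Confidence of the true model against label-permuted randomized models.

    Each of the ``n_permutations`` randomized models uses a uniform shuffle
    of the response rows against the intact predictor block and the identical
    CV procedure with the same (fixed) L. Confidence is the percentage of
    permuted CV metrics strictly worse than the true model's ("worse" =
    lower accuracy or higher RMSECV), with ties counting one half.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    X = _as_matrix(X)
    mode = _resolve_mode(y, mode)
    ss = np.random.SeedSequence(seed)
    child_true, child_shuffle, *child_perms = ss.spawn(2 + n_permutations)
    true = cross_validate(
        X, y, L, mode=mode, n_repeats=n_repeats,
        holdout_fraction=holdout_fraction, seed=np.random.default_rng(child_true),
    )
    rng_shuffle = np.random.default_rng(child_shuffle)
    y_arr = np.asarray(y)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        y_perm = rng_shuffle.permutation(y_arr)
        res_k = cross_validate(
            X, y_perm, L, mode=mode, n_repeats=n_repeats,
            holdout_fraction=holdout_fraction, seed=np.random.default_rng(child_perms[k]),
        )
        null[k] = res_k.cv_value
    if true.metric_name == "accuracy":
        worse = null < true.cv_value
    else:
        worse = null > true.cv_value
    ties = null == true.cv_value
    confidence = 100.0 * (worse.sum() + 0.5 * ties.sum()) / n_permutations
    return ValidationResult(
        metric_name=true.metric_name,
        cv_value=true.cv_value,
        per_repeat_values=true.per_repeat_values,
        L_selected=L,
        null_distribution=null,
        confidence=float(confidence),
        seed=int(seed),
    )
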