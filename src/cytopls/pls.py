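"""Single-response PLS (NIPALS) with LV1 orthogonalization and VIP scores.

Models are fit on mean-centered, unit-variance scaled (Z-scored) predictors.
Discriminant mode encodes the two classes as +1/−1 on a single response
column and classifies by the sign of the prediction; regression mode takes a
continuous response. After fitting, a model can be orthogonalized on its
first latent variable: a rotation of the fitted latent subspace that
concentrates the response-covarying variation on LV1 while leaving the
predictive operator unchanged.

VIP (variable importance in projection) for predictor j over L latent
variables with weights w_lj and per-LV explained response variation SS_l(Y):

    VIP_j = sqrt( m * sum_l w_lj^2 SS_l(Y) / sum_l SS_l(Y) )

Because each weight vector has unit norm, the average of the squared VIP
scores is exactly 1, so VIP > 1 marks an above-average contributor.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


class PlsError(ValueError):
    """Raised for invalid PLS inputs (rank, variance, class structure)."""


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScaledMatrix:
    """Z-scored predictor matrix with the original-scale means and SDs.

    The stored constants let held-out rows be transformed with *training*
    statistics, which is how every cross-validation fold must scale its
    held-out third.
    """

    X: np.ndarray
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, raw) -> np.ndarray:
        """Apply the stored (training) Z-transform to new raw rows."""
        arr = np.asarray(raw, dtype=float)
        return (arr - self.means) / self.sds


def zscore(values, ddof: int = 1) -> ScaledMatrix:
    """Mean-center and unit-variance scale each column (sample SD, n−1).

    Accepts a cleaned matrix, DataFrame, or ndarray. Missing values and
    zero-variance columns are rejected with the offending column named.
    """
    if hasattr(values, "values") and hasattr(values, "analytes"):  # CleanedMatrix
        values = values.values
    if isinstance(values, pd.DataFrame):
        columns = [str(c) for c in values.columns]
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        columns = [f"x{j}" for j in range(arr.shape[1])]
    if np.isnan(arr).any():
        bad = [columns[j] for j in np.nonzero(np.isnan(arr).any(axis=0))[0]]
        raise PlsError(
            f"missing values in column(s) {bad}; clean the panel (replicate averaging) first"
        )
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=ddof)
    zero = np.nonzero(sds == 0)[0]
    if zero.size:
        raise PlsError(f"zero-variance column(s): {[columns[j] for j in zero]}")
    return ScaledMatrix(X=(arr - means) / sds, columns=columns, means=means, sds=sds)


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

def _nipals_pls1(X: np.ndarray, yc: np.ndarray, L: int):
    """Extract L components from centered X and centered single y.

    Returns (W, P, T, c, ss_y): unit-norm weights, X-loadings, scores,
    response loadings, and the response sum-of-squares explained by each
    component. X is deflated after each component; for a single response the
    NIPALS inner iteration converges as soon as the weight vector is stable.
    """
    n, m = X.shape
    W = np.zeros((m, L))
    P = np.zeros((m, L))
    T = np.zeros((n, L))
    c = np.zeros(L)
    ss = np.zeros(L)
    Xd = X.copy()
    yr = yc.astype(float).copy()
    for l in range(L):
        w = Xd.T @ yr
        for _ in range(NIPALS_MAX_ITER):
            nrm = np.linalg.norm(w)
            if nrm <= np.finfo(float).eps * max(n, m):
                raise PlsError(
                    f"component {l + 1} exceeds the effective rank of X (weight vector vanished)"
                )
            w = w / nrm
            t = Xd @ w
            tt = t @ t
            if tt <= np.finfo(float).eps:
                raise PlsError(f"component {l + 1} exceeds the effective rank of X")
            cl = (yr @ t) / tt
            w_new = Xd.T @ (yr * cl)  # u = y * c for a single response column
            if np.linalg.norm(w_new / np.linalg.norm(w_new) - w) < NIPALS_TOL:
                break
            w = w_new
        p = Xd.T @ t / tt
        W[:, l], P[:, l], T[:, l], c[l] = w, p, t, cl
        ss[l] = cl * cl * tt
        Xd = Xd - np.outer(t, p)
        yr = yr - cl * t
    return W, P, T, c, ss


@dataclasses.dataclass
class PlsModel:
    """A fitted (optionally orthogonalized) single-response PLS model."""

    mode: str  # "discriminant" | "regression"
    L: int
    weights: np.ndarray  # (m, L), unit-norm columns
    x_loadings: np.ndarray  # (m, L)
    scores: np.ndarray  # (n, L)
    y_loadings: np.ndarray  # (L,)
    ss_y: np.ndarray  # (L,) response SS explained per LV
    total_ss_y: float
    y_center: float
    y_centered: np.ndarray  # training response after centering
    columns: list[str]
    y_encoding: dict | None = None  # class label -> ±1 (discriminant)
    tie_class: object | None = None  # label assigned to an exact-zero score
    orthogonalized: bool = False

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector B with ŷ = X_scaled @ B + y_center."""
        return self.weights @ np.linalg.solve(
            self.x_loadings.T @ self.weights, self.y_loadings
        )

    def predict(self, X_scaled) -> np.ndarray:
        """Numeric prediction for rows already on the training Z-scale."""
        return np.asarray(X_scaled, dtype=float) @ self.coefficients + self.y_center

    def classify(self, X_scaled) -> np.ndarray:
        """Class labels by the sign of the prediction (discriminant mode)."""
        if self.mode != "discriminant":
            raise PlsError("classify() requires a discriminant-mode model")
        yhat = self.predict(X_scaled)
        inv = {v: k for k, v in self.y_encoding.items()}
        labels = np.where(yhat > 0, inv[1.0], inv[-1.0])
        labels = np.where(yhat == 0, self.tie_class, labels)
        return labels

    def explained_y_fraction(self) -> np.ndarray:
        return self.ss_y / self.total_ss_y


def encode_classes(y) -> tuple[np.ndarray, dict, object]:
    """Map two class labels to ±1; returns (numeric y, encoding, tie class).

    The tie class (assigned when a prediction lands exactly on the boundary)
    is the larger training class; at equal counts the first sorted label.
    """
    labels = pd.Series(y)
    classes = sorted(labels.unique().tolist())
    if len(classes) < 2:
        raise PlsError(f"discriminant mode needs two classes, got only {classes}")
    if len(classes) > 2:
        raise PlsError(f"only two-class discriminant models are supported, got {classes}")
    encoding = {classes[0]: 1.0, classes[1]: -1.0}
    counts = labels.value_counts()
    tie = classes[0] if counts[classes[0]] >= counts[classes[1]] else classes[1]
    return labels.map(encoding).to_numpy(dtype=float), encoding, tie


def fit_pls(X, y, L: int, mode: str = "auto") -> PlsModel:
    """Fit an L-component NIPALS PLS model on Z-scored predictors.

    ``X`` is a :class:`ScaledMatrix` or an already-centered array. In
    discriminant mode ``y`` holds exactly two class labels (encoded +1/−1);
    in regression mode a continuous response. ``L`` must not exceed the rank
    of X.
    """
    if isinstance(X, ScaledMatrix):
        columns, Xc = X.columns, X.X
    else:
        Xc = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(Xc.shape[1])]
    y = np.asarray(y) if not isinstance(y, (pd.Series, list)) else np.asarray(pd.Series(y))
    if Xc.shape[0] != len(y):
        raise PlsError(f"X has {Xc.shape[0]} rows but y has {len(y)} entries")
    if mode == "auto":
        mode = "regression" if np.issubdtype(np.asarray(y).dtype, np.number) else "discriminant"
    if L < 1:
        raise PlsError("L must be >= 1")
    rank = np.linalg.matrix_rank(Xc)
    if L > rank:
        raise PlsError(f"L={L} exceeds rank(X)={rank}")

    encoding = tie = None
    if mode == "discriminant":
        y_num, encoding, tie = encode_classes(y)
    elif mode == "regression":
        y_num = np.asarray(y, dtype=float)
    else:
        raise PlsError(f"unknown mode {mode!r}")
    y_center = float(y_num.mean())
    yc = y_num - y_center
    if np.allclose(yc, 0):
        raise PlsError("response has no variation")

    W, P, T, c, ss = _nipals_pls1(Xc, yc, L)
    return PlsModel(
        mode=mode,
        L=L,
        weights=W,
        x_loadings=P,
        scores=T,
        y_loadings=c,
        ss_y=ss,
        total_ss_y=float(yc @ yc),
        y_center=y_center,
        y_centered=yc,
        columns=columns,
        y_encoding=encoding,
        tie_class=tie,
    )


# ---------------------------------------------------------------------------
# LV1 orthogonalization
# ---------------------------------------------------------------------------

def orthogonalize_lv1(model: PlsModel) -> PlsModel:
    """Rotate the fitted latent basis so LV1 maximally covaries with y.

    Among all rotations of the fitted subspace, the unit direction
    r1 ∝ Tᵀy maximizes cov(T r, y); the remaining rotated components are
    exactly uncorrelated with the response. Fitted values are unchanged
    (the prediction operator is invariant under rotation of the basis).
    A 1-LV model is returned unchanged.
    """
    if model.L == 1:
        return dataclasses.replace(model, orthogonalized=True)
    z = model.scores.T @ model.y_centered
    nz = np.linalg.norm(z)
    if nz == 0:
        raise PlsError("scores carry no response covariance; nothing to orthogonalize")
    r1 = z / nz
    # Orthonormal basis with first column r1 (Householder QR of r1).
    Q, _ = np.linalg.qr(r1[:, None], mode="complete")
    if Q[:, 0] @ r1 < 0:
        Q = -Q
    R = Q
    T = model.scores @ R
    ss = (T.T @ model.y_centered) ** 2 / np.einsum("ij,ij->j", T, T)
    ss[np.abs(ss) < 1e-12 * model.total_ss_y] = 0.0
    return dataclasses.replace(
        model,
        weights=model.weights @ R,
        x_loadings=model.x_loadings @ R,
        scores=T,
        y_loadings=R.T @ model.y_loadings,
        ss_y=ss,
        orthogonalized=True,
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VipScores:
    """Per-predictor VIP scores; mean of squared scores is 1 by construction."""

    vip: pd.Series  # indexed by predictor name, original order
    ranking: list[str]  # predictors by descending VIP

    def above_average(self) -> list[str]:
        """Predictors with VIP > 1 (above-average contribution)."""
        return [a for a in self.ranking if self.vip[a] > 1.0]


def vip_scores(model: PlsModel) -> VipScores:
    """VIP_j = sqrt(m Σ_l w_lj² SS_l(Y) / Σ_l SS_l(Y)) for every predictor."""
    total = model.ss_y.sum()
    if total == 0:
        raise PlsError("model explains no response variation; VIP undefined")
    v = np.sqrt(model.m * (model.weights**2 @ model.ss_y) / total)
    series = pd.Series(v, index=model.columns)
    ranking = list(series.sort_values(ascending=False, kind="stable").index)
    return VipScores(vip=series, ranking=ranking)


# ---------------------------------------------------------------------------
# Serialization and report tables
# ---------------------------------------------------------------------------

def save_model(model: PlsModel, scaler: ScaledMatrix | None, path: str | Path) -> None:
    """Serialize a model (and its Z-scaling constants) to a JSON text file."""
    doc = {
        "mode": model.mode,
        "L": model.L,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "scores": model.scores.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "ss_y": model.ss_y.tolist(),
        "total_ss_y": model.total_ss_y,
        "y_center": model.y_center,
        "y_centered": model.y_centered.tolist(),
        "columns": model.columns,
        "y_encoding": model.y_encoding,
        "tie_class": model.tie_class,
        "orthogonalized": model.orthogonalized,
        "scaler": None
        if scaler is None
        else {
            "columns": scaler.columns,
            "means": scaler.means.tolist(),
            "sds": scaler.sds.tolist(),
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> tuple[PlsModel, ScaledMatrix | None]:
    doc = json.loads(Path(path).read_text())
    scaler = None
    if doc["scaler"] is not None:
        s = doc["scaler"]
        means = np.asarray(s["means"], dtype=float)
        scaler = ScaledMatrix(
            X=np.empty((0, len(s["columns"]))),
            columns=s["columns"],
            means=means,
            sds=np.asarray(s["sds"], dtype=float),
        )
    model = PlsModel(
        mode=doc["mode"],
        L=doc["L"],
        weights=np.asarray(doc["weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        scores=np.asarray(doc["scores"], dtype=float),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        ss_y=np.asarray(doc["ss_y"], dtype=float),
        total_ss_y=doc["total_ss_y"],
        y_center=doc["y_center"],
        y_centered=np.asarray(doc["y_centered"], dtype=float),
        columns=doc["columns"],
        y_encoding=doc["y_encoding"],
        tie_class=doc["tie_class"],
        orthogonalized=doc["orthogonalized"],
    )
    return model, scaler


def scores_table(model: PlsModel, sample_ids, groups=None) -> pd.DataFrame:
    """Per-sample LV scores, the tabular form of a scores plot."""
    df = pd.DataFrame(
        model.scores,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"LV{l + 1}" for l in range(model.L)],
    )
    if groups is not None:
        df.insert(0, "group", list(groups))
    return df


def loadings_table(model: PlsModel, vip: VipScores | None = None) -> pd.DataFrame:
    """Per-analyte LV loadings with VIP and the VIP>1 flag."""
    df = pd.DataFrame(
        model.x_loadings,
        index=pd.Index(model.columns, name="analyte"),
        columns=[f"LV{l + 1}_loading" for l in range(model.L)],
    )
    if vip is None:
        vip = vip_scores(model)
    df["VIP"] = vip.vip
    df["VIP_gt_1"] = vip.vip > 1.0
    return df
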