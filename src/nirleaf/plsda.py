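"""Multi-class PLS-DA: dummy coding, NIPALS PLS-2, LV selection, prediction.

The response block Y is one-hot (dummy) coded: one column per class, 1 for
membership and 0 otherwise.  A PLS-2 regression of the centred spectra on the
centred dummy block yields latent variables (LVs) — linear combinations of
the spectral variables with maximum covariance with the class block — and a
regression-coefficient matrix B.  Predictions ``X_c B + y_means`` sit near 1
in the column of a sample's class and near 0 elsewhere; the hard assignment
is the argmax over class columns.  The number of LVs is chosen by
venetian-blinds cross-validation as the smallest count attaining the lowest
mean per-class classification error.

The decomposition is NIPALS with X-deflation only.  For each component ``a``:
``w_a = X'u / |X'u|``, ``t_a = X w_a``, ``q_a = Y't_a / t_a't_a``,
``u = Y q_a / q_a'q_a`` iterated to convergence, then ``p_a = X't_a /
t_a't_a`` and ``X <- X - t_a p_a'``.  The coefficient matrix in the original
(undeflated) X space is ``B = W (P'W)^-1 Q'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, RankError, ValidationError
from .preprocess import CenteringModel, apply_center, fit_mean_center
from .sampling import CVFolds
from .spectra import SpectraSet

_NIPALS_MAX_ITER = 500
_NIPALS_TOL = 1e-12


@dataclass
class DummyY:
    """One-hot class membership matrix with its column (class) order."""

    matrix: np.ndarray
    class_order: tuple


def dummy_code(labels, class_order) -> DummyY:
    """One-hot code ``labels`` against ``class_order``."""
    class_order = tuple(class_order)
    pos = {c: i for i, c in enumerate(class_order)}
    labels = np.asarray(labels)
    unknown = [l for l in labels if l not in pos]
    if unknown:
        raise ValidationError(f"label {unknown[0]!r} not in class_order")
    y = np.zeros((labels.size, len(class_order)))
    for i, l in enumerate(labels):
        y[i, pos[l]] = 1.0
    return DummyY(matrix=y, class_order=class_order)


@dataclass
class PLSDecomposition:
    """Raw NIPALS PLS-2 factors (on centred X and Y)."""

    x_weights: np.ndarray    # W, (p, a), unit columns
    x_loadings: np.ndarray   # P, (p, a)
    x_scores: np.ndarray     # T, (n, a)
    y_loadings: np.ndarray   # Q, (c, a)
    coef: np.ndarray         # B, (p, c)

    def coef_for(self, n_lv: int) -> np.ndarray:
        """Coefficient matrix using only the first ``n_lv`` components."""
        W = self.x_weights[:, :n_lv]
        P = self.x_loadings[:, :n_lv]
        Q = self.y_loadings[:, :n_lv]
        return W @ np.linalg.solve(P.T @ W, Q.T)


def fit_pls2(Xc: np.ndarray, Yc: np.ndarray, n_lv: int) -> PLSDecomposition:
    """NIPALS PLS-2 with X-deflation only on centred matrices."""
    X = np.array(Xc, dtype=float)
    Y = np.asarray(Yc, dtype=float)
    n, p = X.shape
    if n_lv < 1:
        raise ValidationError("n_lv must be >= 1")
    if n_lv > min(n - 1, p):
        raise RankError(f"n_lv={n_lv} exceeds min(n-1, p)={min(n - 1, p)}")
    x_norm0 = np.linalg.norm(X)
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    for a in range(n_lv):
        if np.linalg.norm(X) <= 1e-10 * max(x_norm0, 1.0):
            raise RankError(
                f"X residual exhausted after {a} components; "
                f"cannot extract LV {a + 1}"
            )
        # The NIPALS inner loop converges to the dominant eigenvector of
        # X'YY'X.  Solve that eigenproblem exactly on the small (c x c)
        # matrix (Y'X)(X'Y) to start at the fixed point, then run the
        # classical update until the tolerance is met.  This keeps the
        # deflation sequence identical while avoiding the slow power-like
        # convergence when the top eigenvalues are nearly degenerate.
        M = X.T @ Y
        eigvals, eigvecs = np.linalg.eigh(M.T @ M)
        w = M @ eigvecs[:, -1]
        nw = np.linalg.norm(w)
        if nw == 0 or eigvals[-1] <= 0:
            raise RankError(
                f"no X-Y covariance remaining; cannot extract LV {a + 1}"
            )
        w /= nw
        # classical sign convention: align with the first NIPALS step
        u0 = Y[:, np.argmax(Y.var(axis=0))]
        if u0.any() and w @ (X.T @ u0) < 0:
            w = -w
        t = X @ w
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError("zero weight vector in NIPALS")
            w /= nw
            t = X @ w
            if t_old is not None and np.linalg.norm(t - t_old) <= (
                _NIPALS_TOL * np.linalg.norm(t)
            ):
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS failed to converge for LV {a + 1} "
                f"after {_NIPALS_MAX_ITER} iterations"
            )
        q = Y.T @ t / (t @ t)
        p_vec = X.T @ t / (t @ t)
        X -= np.outer(t, p_vec)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_vec, t, q
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSDecomposition(W, P, T, Q, coef)


@dataclass
class PLSDAModel:
    """Fitted PLS-DA classifier.

    Holds the NIPALS factors, the coefficient matrix at the selected LV
    count, the training column means (centering) and response means, and the
    per-class diagnostic thresholds (the assignment rule itself is argmax).
    """

    decomposition: PLSDecomposition
    n_lv: int
    class_order: tuple
    centering: CenteringModel
    y_means: np.ndarray
    axis: np.ndarray
    thresholds: np.ndarray | None = None
    coef_matrix: np.ndarray | None = None  # cached B at n_lv (set on load)

    @property
    def coef(self) -> np.ndarray:
        if self.coef_matrix is not None:
            return self.coef_matrix
        return self.decomposition.coef_for(self.n_lv)

    @property
    def n_variables(self) -> int:
        return self.axis.size


@dataclass
class Prediction:
    """Continuous class scores and hard (argmax) assignments."""

    y_hat: np.ndarray
    assigned: np.ndarray
    class_order: tuple


def fit_plsda(
    train: SpectraSet, n_lv: int, class_order=None
) -> PLSDAModel:
    """Fit PLS-DA on preprocessed (uncentered) training spectra.

    Centering of X and Y is fitted here from the training data so that
    prediction of new spectra uses training means only.
    """
    class_order = tuple(class_order) if class_order else tuple(train.classes())
    centering = fit_mean_center(train)
    Xc = apply_center(train, centering).values
    dummy = dummy_code(train.labels, class_order)
    y_means = dummy.matrix.mean(axis=0)
    decomp = fit_pls2(Xc, dummy.matrix - y_means, n_lv)
    return PLSDAModel(
        decomposition=decomp,
        n_lv=n_lv,
        class_order=class_order,
        centering=centering,
        y_means=y_means,
        axis=train.axis.copy(),
    )


def predict(model: PLSDAModel, spectra: SpectraSet) -> Prediction:
    """Predict class scores and argmax assignments for preprocessed spectra.

    Ties in the argmax go to the earliest class in ``class_order``.
    """
    if spectra.axis.shape != model.axis.shape or not np.allclose(
        spectra.axis, model.axis
    ):
        raise ValidationError("spectra axis does not match the model's axis")
    Xc = spectra.values - model.centering.column_means
    y_hat = Xc @ model.coef + model.y_means
    assigned = np.array([model.class_order[i] for i in np.argmax(y_hat, axis=1)])
    return Prediction(y_hat=y_hat, assigned=assigned,
                      class_order=model.class_order)


# ---------------------------------------------------------------------------
# Cross-validated latent-variable selection
# ---------------------------------------------------------------------------

@dataclass
class CVSelection:
    """Out-of-fold CV results over candidate LV counts."""

    n_lv: int
    errors: np.ndarray          # mean per-class error per candidate LV count
    assignments: np.ndarray     # (n_cal, max_lv) out-of-fold hard assignments
    sample_ids: np.ndarray
    true_labels: np.ndarray

    def assignments_at(self, n_lv: int | None = None) -> np.ndarray:
        return self.assignments[:, (n_lv or self.n_lv) - 1]


def select_n_lv(
    calibration: SpectraSet,
    folds: CVFolds,
    max_lv: int = 20,
    class_order=None,
) -> CVSelection:
    """Venetian-blinds CV over 1..max_lv latent variables.

    Each fold refits the X/Y centering on its training part (no leakage).
    The mean per-class classification error of the pooled out-of-fold hard
    assignments is computed for every candidate LV count; the smallest count
    attaining the minimum error wins.
    """
    if max_lv < 1:
        raise ValidationError("max_lv must be >= 1")
    class_order = tuple(class_order) if class_order else tuple(
        calibration.classes()
    )
    ids = calibration.sample_id
    id_pos = {sid: i for i, sid in enumerate(ids)}
    n = calibration.n_samples
    max_lv = min(max_lv, calibration.n_wavenumbers)
    assignments = np.empty((n, max_lv), dtype=object)
    for k in range(folds.n_splits):
        val_ids = folds.fold_ids(k)
        val_idx = np.array([id_pos[s] for s in val_ids])
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        train = calibration.subset(train_mask)
        lv_cap = min(max_lv, train.n_samples - 1)
        centering = fit_mean_center(train)
        Xc = train.values - centering.column_means
        dummy = dummy_code(train.labels, class_order)
        y_means = dummy.matrix.mean(axis=0)
        decomp = fit_pls2(Xc, dummy.matrix - y_means, lv_cap)
        Xval = calibration.values[val_idx] - centering.column_means
        for a in range(1, max_lv + 1):
            B = decomp.coef_for(min(a, lv_cap))
            y_hat = Xval @ B + y_means
            for row, i in enumerate(val_idx):
                assignments[i, a - 1] = class_order[int(np.argmax(y_hat[row]))]
    errors = np.empty(max_lv)
    labels = calibration.labels
    for a in range(max_lv):
        per_class = []
        for cls in class_order:
            mask = labels == cls
            if not mask.any():
                continue
            per_class.append(np.mean(assignments[mask, a] != cls))
        errors[a] = float(np.mean(per_class))
    best = int(np.argmin(errors)) + 1  # argmin -> smallest LV count on ties
    return CVSelection(
        n_lv=best,
        errors=errors,
        assignments=assignments,
        sample_ids=ids.copy(),
        true_labels=labels.copy(),
    )


# ---------------------------------------------------------------------------
# Diagnostic per-class thresholds
# ---------------------------------------------------------------------------

def estimate_thresholds(model: PLSDAModel, prediction: Prediction,
                        true_labels) -> np.ndarray:
    """Per-class score thresholds minimizing calibration misclassification.

    For each class, candidate thresholds are the midpoints of adjacent sorted
    unique scores in that class's y_hat column; the candidate with the fewest
    in/out binary errors wins (lowest midpoint on ties).  These thresholds
    are diagnostics — hard assignment remains argmax.
    """
    true_labels = np.asarray(true_labels)
    thresholds = np.empty(len(model.class_order))
    for j, cls in enumerate(model.class_order):
        scores = prediction.y_hat[:, j]
        member = true_labels == cls
        if not member.any():
            raise ValidationError(f"class {cls!r} absent from calibration")
        uniq = np.unique(scores)
        if uniq.size < 2:
            raise ValidationError(
                f"cannot place a threshold for class {cls!r}: "
                "all scores identical"
            )
        candidates = (uniq[:-1] + uniq[1:]) / 2
        errors = [
            np.sum(member & (scores < thr)) + np.sum(~member & (scores >= thr))
            for thr in candidates
        ]
        thresholds[j] = candidates[int(np.argmin(errors))]
    model.thresholds = thresholds
    return thresholds


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: PLSDAModel, directory: str | Path) -> Path:
    """Persist a fitted model as CSV + flat key-value metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        model.coef, columns=list(model.class_order)
    ).assign(wavenumber=model.axis).set_index("wavenumber").to_csv(
        directory / "coefficients.csv", float_format="%.17g"
    )
    model.centering.to_csv(directory / "centering.csv")
    d = model.decomposition
    pd.DataFrame(
        d.x_weights[:, : model.n_lv],
        columns=[f"lv{a + 1}" for a in range(model.n_lv)],
    ).assign(wavenumber=model.axis).set_index("wavenumber").to_csv(
        directory / "x_weights.csv", float_format="%.17g"
    )
    ssy = [
        float((d.x_scores[:, a] @ d.x_scores[:, a])
              * (d.y_loadings[:, a] @ d.y_loadings[:, a]))
        for a in range(model.n_lv)
    ]
    lines = [
        f"n_lv: {model.n_lv}",
        f"class_order: {','.join(model.class_order)}",
        f"y_means: {','.join(repr(float(v)) for v in model.y_means)}",
        f"lv_ssy: {','.join(repr(float(v)) for v in ssy)}",
    ]
    if model.thresholds is not None:
        lines.append(f"thresholds: {','.join(repr(float(v)) for v in model.thresholds)}")
    (directory / "metadata.txt").write_text("\n".join(lines) + "\n")
    return directory


def load_model(directory: str | Path) -> PLSDAModel:
    """Load a model saved by :func:`save_model`.

    Only what prediction and variable importance need is restored: B, the
    X-weights of the retained LVs, per-LV explained-Y variance, centering,
    response means and thresholds.  Loadings/scores are left empty.
    """
    directory = Path(directory)
    meta = {}
    for line in (directory / "metadata.txt").read_text().splitlines():
        key, _, val = line.partition(":")
        meta[key.strip()] = val.strip()
    coef_df = pd.read_csv(directory / "coefficients.csv", index_col="wavenumber")
    weights_df = pd.read_csv(directory / "x_weights.csv", index_col="wavenumber")
    n_lv = int(meta["n_lv"])
    class_order = tuple(meta["class_order"].split(","))
    ssy = np.array([float(v) for v in meta["lv_ssy"].split(",")])
    # reconstruct scores/loadings placeholders carrying the SSY information:
    # store sqrt(ssy) as a 1-sample score with unit y-loading norm
    t_fake = np.sqrt(ssy)[None, :]
    q_fake = np.ones((len(class_order), n_lv)) / np.sqrt(len(class_order))
    decomp = PLSDecomposition(
        x_weights=weights_df.to_numpy(),
        x_loadings=np.zeros_like(weights_df.to_numpy()),
        x_scores=t_fake,
        y_loadings=q_fake,
        coef=coef_df.to_numpy(),
    )
    model = PLSDAModel(
        decomposition=decomp,
        n_lv=n_lv,
        class_order=class_order,
        centering=CenteringModel.from_csv(directory / "centering.csv"),
        y_means=np.array([float(v) for v in meta["y_means"].split(",")]),
        axis=coef_df.index.to_numpy(dtype=float),
        thresholds=np.array([float(v) for v in meta["thresholds"].split(",")])
        if "thresholds" in meta
        else None,
        coef_matrix=coef_df.to_numpy(),
    )
    return model
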