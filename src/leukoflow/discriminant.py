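"""SPSS-style linear discriminant analysis, written from first principles.

The multivariate machinery used to separate the study phenotypes:

* Wilks' lambda ``det(W)/det(T)`` with within-group (W) and total (T)
  cross-product matrices — the ratio of within-group to total variability.
* Stepwise variable selection on partial F statistics (Rao transformation
  of the lambda ratio) with entry/removal thresholds ``F_in = 3.84`` and
  ``F_out = 2.71``.
* Canonical discriminant functions from the eigen-decomposition of
  ``W^-1 B``; standardized coefficients use pooled within-group SDs.
* Fisher linear classification functions with configurable priors,
  leave-one-out validation on a fixed variable list, holdout evaluation,
  and per-variable variance inflation factors.
* Correlation-matrix PCA with eigenvalue > 1 retention and normalized
  varimax rotation (iterative pairwise planar rotations).

scikit-learn offers overlapping functionality; it is deliberately not
used here — it serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class MulticollinearityError(ValueError):
    """Raised when the requested variables are (numerically) aliased."""


class ConfigError(ValueError):
    pass


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _cross_products(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) sum-of-cross-product matrices."""
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(labels):
        sub = X[labels == g]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
    return W, T


def wilks_lambda(X, labels) -> float:
    """Wilks' lambda det(W)/det(T) of the given variables and grouping.

    Values near 0 indicate that most variance lies between groups; 1 means
    the group means coincide.  Raises :class:`MulticollinearityError` when
    the total cross-product matrix is singular, naming the offending
    variables.
    """
    Xm, names = _as_matrix(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 groups")
    W, T = _cross_products(Xm, labels)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or np.linalg.matrix_rank(T) < T.shape[0]:
        bad = _aliased_variables(Xm, names)
        raise MulticollinearityError(
            f"total cross-product matrix singular; aliased variables: {bad}")
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    lam = float(np.exp(logdet_w - logdet_t))
    return min(max(lam, 0.0), 1.0)


def _aliased_variables(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns linearly dependent on the preceding ones (rank-deficiency culprits)."""
    bad = []
    for j in range(1, X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1] - X[:, : j + 1].mean(axis=0))
        r_prev = np.linalg.matrix_rank(X[:, :j] - X[:, :j].mean(axis=0))
        if r == r_prev:
            bad.append(names[j])
    return bad


# ---------------------------------------------------------------------------
# stepwise selection


def _lambda_of(Xm: np.ndarray, labels: np.ndarray, cols: list[int]) -> float:
    if not cols:
        return 1.0
    return wilks_lambda(Xm[:, cols], labels)


def _partial_f(lam_small: float, lam_big: float, n: int, g: int, p_small: int) -> float:
    """Rao partial F for adding one variable to a ``p_small``-variable model."""
    if lam_big <= 0:
        return np.inf
    df2 = n - g - p_small
    if df2 <= 0:
        return 0.0
    return (df2 / (g - 1)) * (lam_small / lam_big - 1.0)


def stepwise_select(X, labels, f_in: float = 3.84, f_out: float = 2.71,
                    max_steps: int | None = None) -> tuple[list[str], pd.DataFrame]:
    """Stepwise Wilks-lambda variable selection.

    At each step the candidate that minimizes the new lambda enters if its
    partial F-to-enter is at least ``f_in``; after every entry, included
    variables whose F-to-remove falls below ``f_out`` are removed (worst
    first).  Ties are broken by column order.  Returns the ordered list of
    selected variable names and a per-step trace (step, action, variable,
    lambda, partial F).
    """
    if f_out >= f_in:
        raise ConfigError("f_out must be below f_in to prevent cycling")
    Xm, names = _as_matrix(X)
    labels = np.asarray(labels)
    n = Xm.shape[0]
    g = len(np.unique(labels))
    if g < 2:
        raise ValueError("need >= 2 groups")
    if max_steps is None:
        max_steps = 2 * Xm.shape[1] + 1

    included: list[int] = []
    trace_rows = []
    seen_states: set[tuple[int, ...]] = set()
    step = 0
    while step < max_steps:
        step += 1
        changed = False
        lam_cur = _lambda_of(Xm, labels, included)

        # --- entry
        best = None  # (new_lambda, col)
        for j in range(Xm.shape[1]):
            if j in included:
                continue
            try:
                lam_new = _lambda_of(Xm, labels, included + [j])
            except MulticollinearityError:
                continue
            if best is None or lam_new < best[0] - 1e-15:
                best = (lam_new, j)
        if best is not None:
            lam_new, j = best
            F = _partial_f(lam_cur, lam_new, n, g, len(included))
            if F >= f_in:
                included.append(j)
                changed = True
                trace_rows.append({"step": step, "action": "enter", "variable": names[j],
                                   "wilks_lambda": lam_new, "partial_F": F})
                lam_cur = lam_new

        # --- removal (repeat until stable)
        while len(included) > 1:
            worst = None  # (F_remove, idx_in_included)
            for k, j in enumerate(included):
                rest = [c for c in included if c != j]
                lam_rest = _lambda_of(Xm, labels, rest)
                F_rm = _partial_f(lam_rest, lam_cur, n, g, len(rest))
                if worst is None or F_rm < worst[0]:
                    worst = (F_rm, k)
            if worst is not None and worst[0] < f_out:
                j = included.pop(worst[1])
                lam_cur = _lambda_of(Xm, labels, included)
                changed = True
                trace_rows.append({"step": step, "action": "remove", "variable": names[j],
                                   "wilks_lambda": lam_cur, "partial_F": worst[0]})
            else:
                break

        state = tuple(sorted(included))
        if changed and state in seen_states:
            logger.warning("stepwise selection cycling detected; halting")
            break
        seen_states.add(state)
        if not changed:
            break

    trace = pd.DataFrame(trace_rows,
                         columns=["step", "action", "variable", "wilks_lambda", "partial_F"])
    return [names[j] for j in included], trace


# ---------------------------------------------------------------------------
# model fit


@dataclass
class DiscriminantModel:
    """Fitted linear discriminant model (canonical + Fisher classification form)."""

    selected_variables: list[str]
    groups: list[str]
    wilks_lambda: float
    eigenvalues: np.ndarray
    raw_coefficients: pd.DataFrame            # variables x functions
    standardized_coefficients: pd.DataFrame   # variables x functions
    classification_coefficients: pd.DataFrame  # variables x groups
    classification_constants: pd.Series        # per group
    priors: pd.Series
    vif: pd.Series
    group_means: pd.DataFrame                  # groups x variables
    pooled_covariance: pd.DataFrame

    def classify(self, X) -> np.ndarray:
        """Assign each row to the group with the highest Fisher score."""
        if isinstance(X, pd.DataFrame):
            X = X[self.selected_variables].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        scores = X @ self.classification_coefficients.to_numpy() + \
            self.classification_constants.to_numpy()
        return np.asarray(self.groups)[np.argmax(scores, axis=1)]


def _vif(Xs: np.ndarray, names: list[str]) -> pd.Series:
    """Variance inflation factor of each column regressed on the others."""
    p = Xs.shape[1]
    out = {}
    for j in range(p):
        if p == 1:
            out[names[j]] = 1.0
            continue
        y = Xs[:, j]
        others = np.delete(Xs, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            out[names[j]] = np.nan
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_classifier(X, labels, variables: list[str] | None = None,
                   priors: dict[str, float] | str | None = None) -> DiscriminantModel:
    """Fit canonical discriminant functions and Fisher classification functions.

    ``X`` is a DataFrame (or matrix) of observations; ``variables`` limits
    and orders the columns used.  Priors default to equal across groups
    (``"proportional"`` uses group frequencies).  Standardized canonical
    coefficients are raw coefficients scaled by the pooled within-group
    SDs.  Raises :class:`MulticollinearityError` when the pooled
    covariance is singular, listing the aliased variables.
    """
    if isinstance(X, pd.DataFrame):
        if variables is None:
            variables = list(X.columns)
        Xm = X[variables].to_numpy(dtype=float)
    else:
        Xm, names = _as_matrix(X)
        if variables is None:
            variables = names
        else:
            idx = [names.index(v) for v in variables]
            Xm = Xm[:, idx]
    labels = np.asarray(labels).astype(str)
    groups = sorted(np.unique(labels))
    g = len(groups)
    n, p = Xm.shape
    counts = {gr: int(np.sum(labels == gr)) for gr in groups}
    if min(counts.values()) < 2:
        raise ValueError("each group needs >= 2 observations")

    W, T = _cross_products(Xm, labels)
    B = T - W
    Sw = W / (n - g)
    if np.linalg.matrix_rank(Sw) < p:
        bad = _aliased_variables(Xm, variables)
        raise MulticollinearityError(f"pooled covariance singular; aliased: {bad}")
    lam = wilks_lambda(Xm, labels)

    # canonical functions: eigen-decomposition of W^-1 B
    m = min(g - 1, p)
    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(-evals.real)
    evals = evals.real[order][:m]
    evecs = evecs.real[:, order][:, :m]
    # scale so canonical scores have unit pooled within-group variance
    for k in range(m):
        v = evecs[:, k]
        s = float(v @ Sw @ v)
        if s > 0:
            evecs[:, k] = v / np.sqrt(s)
    func_names = [f"F{k+1}" for k in range(m)]
    raw = pd.DataFrame(evecs, index=variables, columns=func_names)
    within_sd = np.sqrt(np.diag(Sw))
    std = raw.mul(within_sd, axis=0)

    # priors
    if priors is None or priors == "equal":
        pr = pd.Series({gr: 1.0 / g for gr in groups})
    elif priors == "proportional":
        pr = pd.Series({gr: counts[gr] / n for gr in groups})
    else:
        pr = pd.Series(priors, dtype=float)
        pr = pr / pr.sum()

    # Fisher linear classification functions
    Sw_inv = np.linalg.inv(Sw)
    mu = np.vstack([Xm[labels == gr].mean(axis=0) for gr in groups])
    coef = Sw_inv @ mu.T                                  # p x g
    const = np.array([-0.5 * mu[k] @ Sw_inv @ mu[k] + np.log(pr[groups[k]])
                      for k in range(g)])

    # VIF on standardized variables
    sd = Xm.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xs = (Xm - Xm.mean(axis=0)) / sd
    vif = _vif(Xs, variables)

    return DiscriminantModel(
        selected_variables=list(variables),
        groups=groups,
        wilks_lambda=lam,
        eigenvalues=evals,
        raw_coefficients=raw,
        standardized_coefficients=std,
        classification_coefficients=pd.DataFrame(coef, index=variables, columns=groups),
        classification_constants=pd.Series(const, index=groups),
        priors=pr,
        vif=vif,
        group_means=pd.DataFrame(mu, index=groups, columns=variables),
        pooled_covariance=pd.DataFrame(Sw, index=variables, columns=variables),
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class CVResult:
    """Confusion matrix (rows = truth), per-class and overall accuracy in %."""

    confusion: pd.DataFrame
    per_class_accuracy: pd.Series
    overall_accuracy: float
    predictions: pd.Series
    skipped: list[int] = field(default_factory=list)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, groups: list[str]) -> CVResult:
    cm = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    row_sums = cm.sum(axis=1)
    per_class = pd.Series(
        {gr: (100.0 * cm.loc[gr, gr] / row_sums[gr]) if row_sums[gr] else np.nan
         for gr in groups})
    overall = 100.0 * float(np.mean(y_true == y_pred)) if len(y_true) else np.nan
    return CVResult(confusion=cm, per_class_accuracy=per_class,
                    overall_accuracy=overall,
                    predictions=pd.Series(y_pred))


def loo_cv(X, labels, variables: list[str] | None = None,
           priors: dict[str, float] | str | None = None) -> CVResult:
    """Leave-one-out validation with a FIXED variable list.

    Each observation is classified by Fisher functions refit on all other
    observations.  The variable list is held fixed across folds (the
    workflow that reproduces SPSS-style printed accuracies); re-running
    selection inside each fold is available via
    :func:`nested_loo_cv`.  A fold that would empty a group is skipped
    with a warning.
    """
    if isinstance(X, pd.DataFrame):
        if variables is None:
            variables = list(X.columns)
        df = X[variables].reset_index(drop=True)
    else:
        Xm, names = _as_matrix(X)
        variables = variables or names
        df = pd.DataFrame(Xm, columns=names)[variables]
    labels = np.asarray(labels).astype(str)
    groups = sorted(np.unique(labels))
    if min(np.sum(labels == gr) for gr in groups) < 3:
        raise ValueError("each group needs >= 3 observations for LOO")

    preds = []
    truths = []
    skipped = []
    for i in range(len(df)):
        mask = np.ones(len(df), dtype=bool)
        mask[i] = False
        rest_labels = labels[mask]
        if len(np.unique(rest_labels)) < len(groups):
            logger.warning("LOO fold %d would empty a group; skipped", i)
            skipped.append(i)
            continue
        try:
            model = fit_classifier(df.loc[mask], rest_labels, variables, priors)
        except MulticollinearityError as err:
            # a near-constant variable can go singular once its one
            # distinguishing row is held out
            logger.warning("LOO fold %d skipped (%s)", i, err)
            skipped.append(i)
            continue
        preds.append(model.classify(df.iloc[[i]])[0])
        truths.append(labels[i])
    res = _confusion(np.asarray(truths), np.asarray(preds), groups)
    res.skipped = skipped
    return res


def nested_loo_cv(X, labels, f_in: float = 3.84, f_out: float = 2.71,
                  priors: dict[str, float] | str | None = None) -> CVResult:
    """Honest LOO: stepwise selection re-run inside every fold.

    Less optimistic than :func:`loo_cv`; folds whose selection comes back
    empty are classified by priors alone.
    """
    if not isinstance(X, pd.DataFrame):
        Xm, names = _as_matrix(X)
        X = pd.DataFrame(Xm, columns=names)
    X = X.reset_index(drop=True)
    labels = np.asarray(labels).astype(str)
    groups = sorted(np.unique(labels))
    preds, truths = [], []
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        sel, _ = stepwise_select(X.loc[mask], labels[mask], f_in=f_in, f_out=f_out)
        if not sel:
            pr = (pd.Series({gr: np.mean(labels[mask] == gr) for gr in groups})
                  if priors == "proportional" else pd.Series(1.0, index=groups))
            preds.append(pr.idxmax())
        else:
            model = fit_classifier(X.loc[mask], labels[mask], sel, priors)
            preds.append(model.classify(X.iloc[[i]])[0])
        truths.append(labels[i])
    return _confusion(np.asarray(truths), np.asarray(preds), groups)


def holdout_eval(X, labels, train_ids, test_ids, variables: list[str],
                 priors: dict[str, float] | str | None = None) -> CVResult:
    """Fit on the training rows only and classify the held-out test rows.

    ``train_ids``/``test_ids`` are positional row indices and must be
    disjoint; every group must appear in training.  Test rows whose label
    never occurs in training are refused (flagged in ``skipped``).
    """
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test sets overlap")
    if not isinstance(X, pd.DataFrame):
        Xm, names = _as_matrix(X)
        X = pd.DataFrame(Xm, columns=names)
    X = X.reset_index(drop=True)
    labels = np.asarray(labels).astype(str)
    train_groups = sorted(np.unique(labels[train_ids]))
    if not test_ids:
        logger.warning("empty test set")
        return _confusion(np.empty(0, str), np.empty(0, str), train_groups)
    model = fit_classifier(X.loc[train_ids], labels[train_ids], variables, priors)
    keep, refused = [], []
    for i in test_ids:
        if labels[i] not in train_groups:
            logger.warning("test row %d has unseen group %r; refused", i, labels[i])
            refused.append(i)
        else:
            keep.append(i)
    preds = model.classify(X.loc[keep]) if keep else np.empty(0, str)
    res = _confusion(labels[keep], preds, train_groups)
    res.skipped = refused
    return res


# ---------------------------------------------------------------------------
# PCA with varimax rotation


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: pd.DataFrame
    rotated_loadings: pd.DataFrame
    retained: np.ndarray           # boolean mask over components
    scores: pd.DataFrame
    dropped_variables: list[str]


def varimax_rotate(loadings: np.ndarray, normalize: bool = True,
                   tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation by iterative pairwise planar rotations.

    With ``normalize=True`` rows are Kaiser-normalized before rotation and
    rescaled after.  Converges when a full sweep rotates every pair by
    less than ``tol`` radians.
    """
    L = np.array(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L
    h = np.sqrt(np.sum(L**2, axis=1)) if normalize else np.ones(p)
    h[h == 0] = 1.0
    A = L / h[:, None]
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(m - 1):
            for j in range(i + 1, m):
                u = A[:, i] ** 2 - A[:, j] ** 2
                v = 2.0 * A[:, i] * A[:, j]
                a, b = u.sum(), v.sum()
                c = np.sum(u**2 - v**2)
                d = np.sum(2.0 * u * v)
                num = d - 2.0 * a * b / p
                den = c - (a**2 - b**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                max_angle = max(max_angle, abs(phi))
                rot = np.array([[np.cos(phi), -np.sin(phi)],
                                [np.sin(phi), np.cos(phi)]])
                A[:, [i, j]] = A[:, [i, j]] @ rot
        if max_angle < tol:
            break
    return A * h[:, None]


def pca_varimax(X, eigen_threshold: float = 1.0) -> PCAResult:
    """Correlation-matrix PCA with eigenvalue > 1 retention and varimax.

    Columns are standardized internally; constant columns are dropped with
    a warning.  Loadings are eigenvectors scaled by sqrt(eigenvalue);
    varimax is applied to the retained loadings only.
    """
    if not isinstance(X, pd.DataFrame):
        Xm, names = _as_matrix(X)
        X = pd.DataFrame(Xm, columns=names)
    sd = X.std(ddof=1)
    dropped = list(X.columns[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping constant column(s): %s", dropped)
    X = X.drop(columns=dropped)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 non-constant variables and >= 3 observations")
    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(-evals)
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    pct = 100.0 * evals / evals.sum()
    comp_names = [f"PC{k+1}" for k in range(len(evals))]
    loadings = pd.DataFrame(evecs * np.sqrt(evals), index=X.columns, columns=comp_names)
    retained = evals > eigen_threshold
    if retained.sum() >= 1:
        rot = varimax_rotate(loadings.loc[:, retained].to_numpy())
        rotated = pd.DataFrame(rot, index=X.columns,
                               columns=[c for c, r in zip(comp_names, retained) if r])
    else:
        rotated = loadings.iloc[:, :0]
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=X.index, columns=comp_names)
    return PCAResult(eigenvalues=evals, percent_variance=pct, loadings=loadings,
                     rotated_loadings=rotated, retained=retained, scores=scores,
                     dropped_variables=dropped)
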