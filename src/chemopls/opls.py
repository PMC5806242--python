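"""Projection models: NIPALS PCA, OPLS-DA, cross-validation, CV-ANOVA and
|w*| latent-biomarker selection.

OPLS-DA splits the scaled data matrix X into a class-predictive part T P'
and an orthogonal (class-unrelated) part T_o P_o' plus residual.  Orthogonal
components are extracted first, by projecting the X-loading of a provisional
PLS component against the predictive weight(s) and deflating X by the
resulting orthogonal component; the predictive components are then fitted on
the filtered X.  For two classes (one centred dummy response) the fitted
responses of OPLS with 1 predictive + k orthogonal components coincide with
those of a (k+1)-component PLS1 model — the orthogonal split changes the
interpretation, not the fit.

Model significance follows the CV-ANOVA convention: the cross-validated
predictive residual sum of squares (PRESS) is compared with the total
response variation through an F statistic with df1 = total fitted
components, df2 = N - 1 - df1.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .errors import (
    DataError,
    DegenerateComponentError,
    FoldError,
    SelectionCollapseError,
    UsageError,
)
from .preprocess import ScalingParams, fit_scaling

_NIPALS_TOL = 1e-12
_NIPALS_MAXITER = 500
# PCA components are checked against eigensolvers; the power-iteration error
# after stopping is ~(score change)/(eigenvalue gap), so PCA iterates to a
# tighter floor than the PLS inner loops need
_PCA_TOL = 1e-14


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PcaModel:
    """NIPALS principal components with Hotelling-T2 outlier statistics."""

    scores: np.ndarray  # N x A
    loadings: np.ndarray  # M x A, orthonormal columns
    explained_variance_ratio: np.ndarray  # A,
    hotelling_t2: np.ndarray  # N,
    t2_limit_95: float


def fit_pca(X, n_components: int) -> PcaModel:
    """Extract ``n_components`` principal components by NIPALS with deflation.

    ``X`` must be column-centred.  Components beyond the rank of X come back
    with ~zero explained variance and a warning rather than an error, so an
    overview model never hard-fails on low-rank data.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    a_max = min(n, m)
    if not (1 <= n_components <= a_max):
        raise UsageError(f"n_components must be in [1, {a_max}]")
    total_ss = float((X**2).sum())
    if total_ss == 0.0:
        raise DataError("PCA on an all-zero matrix")
    Xd = X.copy()
    T = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    evr = np.zeros(n_components)
    for a in range(n_components):
        start = int(np.argmax((Xd**2).sum(axis=0)))
        t = Xd[:, start].copy()
        if float(t @ t) == 0.0:
            warnings.warn(
                f"component {a + 1} exceeds the rank of X; returned as zero",
                stacklevel=2,
            )
            continue
        for _ in range(_NIPALS_MAXITER):
            p = Xd.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = Xd @ p
            if np.linalg.norm(t_new - t) <= _PCA_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        p = Xd.T @ t / (t @ t)
        nrm = np.linalg.norm(p)
        p /= nrm
        t = Xd @ p
        T[:, a] = t
        P[:, a] = p
        evr[a] = float(t @ t) / total_ss
        if evr[a] < 1e-12:
            warnings.warn(
                f"component {a + 1} explains ~no variance (rank exceeded)",
                stacklevel=2,
            )
        Xd -= np.outer(t, p)
    # Hotelling T2 against the 95% F-based limit
    var = T.var(axis=0, ddof=1)
    var = np.where(var == 0.0, 1.0, var)
    t2 = ((T**2) / var).sum(axis=1)
    a_eff = n_components
    if n > a_eff:
        flim = scipy.stats.f.ppf(0.95, a_eff, n - a_eff)
        limit = a_eff * (n**2 - 1) / (n * (n - a_eff)) * flim
    else:
        limit = np.inf
    return PcaModel(T, P, evr, t2, float(limit))


# ---------------------------------------------------------------------------
# class encoding
# ---------------------------------------------------------------------------

def encode_classes(labels: Sequence[str]):
    """Encode K classes as K-1 non-redundant 0/1 dummy columns.

    The lexicographically first class is the reference (all-zero row).
    Returns (classes, Y_dummy) with Y uncentred.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError("need at least two classes")
    counts = {c: labels.count(c) for c in classes}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise DataError(f"class(es) with fewer than two samples: {small}")
    Y = np.zeros((len(labels), len(classes) - 1))
    for j, cls in enumerate(classes[1:]):
        Y[:, j] = [1.0 if lab == cls else 0.0 for lab in labels]
    return classes, Y


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OplsModel:
    """Fitted OPLS-DA decomposition X = T P' + T_o P_o' + E."""

    classes: list[str]
    W: np.ndarray  # M x A_pred, unit-norm predictive weights
    T: np.ndarray  # N x A_pred predictive scores
    P: np.ndarray  # M x A_pred predictive loadings
    C: np.ndarray  # (K-1) x A_pred response loadings
    w_star: np.ndarray  # M x A_pred, unit-norm variable contributions
    W_o: np.ndarray  # M x A_ortho
    T_o: np.ndarray  # N x A_ortho
    P_o: np.ndarray  # M x A_ortho
    y_mean: np.ndarray  # K-1,
    class_means_yhat: np.ndarray  # K x (K-1): fitted-response mean per class
    r2x: float
    r2y: float
    scaling: Optional[ScalingParams] = None

    @property
    def n_pred(self) -> int:
        return self.W.shape[1]

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    def fitted_y(self) -> np.ndarray:
        return self.T @ self.C.T + self.y_mean


def _pls_component(X: np.ndarray, Y: np.ndarray):
    """One NIPALS PLS component on (X, Y); Y may have several columns.

    Returns (w, t, p, c) with ``w`` unit norm.  Single-column Y has the
    closed form w = X'y / ||X'y||; multi-column Y iterates the NIPALS inner
    relation to convergence.
    """
    if Y.shape[1] == 1:
        w = X.T @ Y[:, 0]
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            raise DegenerateComponentError("predictive weight collapsed to zero")
        w = w / nw
        t = X @ w
    else:
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        t = np.zeros(X.shape[0])
        for _ in range(_NIPALS_MAXITER):
            w = X.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                raise DegenerateComponentError("predictive weight collapsed to zero")
            w = w / nw
            t_new = X @ w
            c_ = Y.T @ t_new / (t_new @ t_new)
            u = Y @ c_ / (c_ @ c_)
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
    tt = float(t @ t)
    if tt < 1e-300:
        raise DegenerateComponentError("predictive score collapsed to zero")
    p = X.T @ t / tt
    c = Y.T @ t / tt
    return w, t, p, c


def _pls_weights(X: np.ndarray, Y: np.ndarray, a: int) -> np.ndarray:
    """Weight set of a temporary ``a``-component NIPALS PLS fit on (X, Y)."""
    Xd, Yd = X.copy(), Y.copy()
    W = []
    for _ in range(a):
        w, t, p, c = _pls_component(Xd, Yd)
        W.append(w)
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, c)
    return np.column_stack(W)


def fit_oplsda(X, labels, n_pred: int = 1, n_ortho: int = 0,
               scaling: Optional[ScalingParams] = None) -> OplsModel:
    """Fit OPLS-DA on a centred/scaled matrix ``X`` with class ``labels``.

    ``n_pred`` predictive components (at most K-1 for K classes) and
    ``n_ortho`` orthogonal components.  ``scaling`` is carried along so new
    samples can be brought to training scale before projection.
    """
    X = np.asarray(X, dtype=float)
    classes, Y_raw = encode_classes(labels)
    k = len(classes)
    if not (1 <= n_pred <= k - 1):
        raise UsageError(f"n_pred must be in [1, {k - 1}] for {k} classes")
    if n_ortho < 0:
        raise UsageError("n_ortho must be >= 0")
    n, m = X.shape
    if n != len(labels):
        raise UsageError("X rows and labels differ in length")
    x_ss = float((X**2).sum())
    if x_ss == 0.0:
        raise DataError("OPLS-DA on an all-zero matrix")
    y_mean = Y_raw.mean(axis=0)
    Y = Y_raw - y_mean

    # -- orthogonal extraction loop -------------------------------------
    Xd = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        Wp = _pls_weights(Xd, Y, n_pred)
        w1, t1, p1, _c1 = _pls_component(Xd, Y)
        w_o = p1.copy()
        for kk in range(Wp.shape[1]):
            wk = Wp[:, kk]
            w_o -= (wk @ w_o) / (wk @ wk) * wk
        nrm = np.linalg.norm(w_o)
        if nrm <= 1e-10 * np.linalg.norm(p1):
            raise DegenerateComponentError(
                "no orthogonal variation left to extract (rank exhausted)"
            )
        w_o /= nrm
        t_o = Xd @ w_o
        tt = float(t_o @ t_o)
        if tt <= 1e-12 * x_ss / max(n, 1):
            raise DegenerateComponentError(
                "orthogonal component score is numerically zero"
            )
        p_o = Xd.T @ t_o / tt
        Xd -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    # -- predictive components on the filtered X ------------------------
    Xp, Yp = Xd, Y.copy()
    W, T, P, C = [], [], [], []
    for _ in range(n_pred):
        w, t, p, c = _pls_component(Xp, Yp)
        Xp = Xp - np.outer(t, p)
        Yp = Yp - np.outer(t, c)
        W.append(w)
        T.append(t)
        P.append(p)
        C.append(c)

    W = np.column_stack(W)
    T = np.column_stack(T)
    P = np.column_stack(P)
    C = np.column_stack(C)
    W_o = np.column_stack(W_o) if W_o else np.zeros((m, 0))
    T_o = np.column_stack(T_o) if T_o else np.zeros((n, 0))
    P_o = np.column_stack(P_o) if P_o else np.zeros((m, 0))

    # w*: unit-norm predictive weights on the filtered X
    w_star = W / np.linalg.norm(W, axis=0, keepdims=True)

    E = Xp
    r2x = 1.0 - float((E**2).sum()) / x_ss
    y_ss = float((Y**2).sum())
    yhat_c = T @ C.T
    r2y = 1.0 - float(((Y - yhat_c) ** 2).sum()) / y_ss if y_ss > 0 else 0.0
    r2y = float(min(max(r2y, 0.0), 1.0))

    yhat = yhat_c + y_mean
    class_means = np.vstack([
        yhat[[lab == cls for lab in labels]].mean(axis=0) for cls in classes
    ])

    return OplsModel(
        classes=classes,
        W=W, T=T, P=P, C=C, w_star=w_star,
        W_o=W_o, T_o=T_o, P_o=P_o,
        y_mean=y_mean, class_means_yhat=class_means,
        r2x=float(r2x), r2y=r2y, scaling=scaling,
    )


def predict(model: OplsModel, X_new):
    """Project new samples (already in training scale).

    Sequentially strips the orthogonal components, then computes predictive
    scores with predictive deflation; returns (t_pred, t_ortho, yhat,
    class_calls).  Class call = nearest class mean in fitted-response space,
    ties broken toward the reference (lexicographically first) class.
    """
    X = np.asarray(X_new, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.W.shape[0]:
        raise UsageError(
            f"X_new must have {model.W.shape[0]} columns, got {X.shape}"
        )
    Xd = X.copy()
    t_ortho = np.zeros((X.shape[0], model.n_ortho))
    for a in range(model.n_ortho):
        t_o = Xd @ model.W_o[:, a]
        Xd -= np.outer(t_o, model.P_o[:, a])
        t_ortho[:, a] = t_o
    t_pred = np.zeros((X.shape[0], model.n_pred))
    for a in range(model.n_pred):
        t = Xd @ model.W[:, a]
        Xd -= np.outer(t, model.P[:, a])
        t_pred[:, a] = t
    yhat = t_pred @ model.C.T + model.y_mean
    d2 = ((yhat[:, None, :] - model.class_means_yhat[None, :, :]) ** 2).sum(axis=2)
    # argmin takes the first minimum: classes are sorted, so exact ties fall
    # toward the reference class
    calls = [model.classes[j] for j in np.argmin(d2, axis=1)]
    return t_pred, t_ortho, yhat, calls


# ---------------------------------------------------------------------------
# cross-validation and CV-ANOVA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CvResult:
    """Cross-validated scores and model-significance statistics."""

    tcv: np.ndarray  # N x A_pred, out-of-fold predictive scores
    yhat_cv: np.ndarray  # N x (K-1), out-of-fold predicted responses
    press: float
    ss_tot: float
    q2: float
    f: float
    df1: int
    df2: int
    p: float
    folds: np.ndarray  # N, fold index per sample
    n_pred: int
    n_ortho: int


def assign_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified folds: samples are shuffled within class by
    the seeded RNG, then dealt round-robin to folds.

    Classes are visited in order of first occurrence (not by name), so a
    pure renaming of the classes cannot change the partition; the global
    deal counter makes n_folds = N degenerate to leave-one-out.
    """
    labels = list(labels)
    n = len(labels)
    if not (2 <= n_folds <= n):
        raise FoldError(f"n_folds must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds = np.full(n, -1, dtype=int)
    counter = 0
    for cls in dict.fromkeys(labels):
        idx = np.asarray([i for i, lab in enumerate(labels) if lab == cls])
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            folds[i] = counter % n_folds
            counter += 1
    return folds


def _cv_anova_stats(press: float, ss_tot: float, n: int, a_model: int):
    if ss_tot <= 0:
        raise DataError("SS_tot must be positive for CV-ANOVA")
    if press < 0:
        raise DataError("PRESS must be non-negative")
    df1 = a_model
    df2 = n - 1 - a_model
    if df2 <= 0:
        raise DataError(
            f"CV-ANOVA needs N - 1 - A > 0 (N={n}, A={a_model}): model larger "
            "than the data support"
        )
    if press == 0.0:
        return np.inf, df1, df2, 0.0
    ss_reg = max(ss_tot - press, 0.0)
    f = (ss_reg / df1) / (press / df2)
    p = float(scipy.stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def cv_anova(cv: CvResult, a_model: Optional[int] = None):
    """CV-ANOVA F test of the cross-validated model.

    F = (max(SS_tot - PRESS, 0)/df1) / (PRESS/df2), df1 = total fitted
    components, df2 = N - 1 - df1; p is the upper-tail F probability.
    PRESS = 0 maps to F = +inf, p = 0.
    """
    if a_model is None:
        a_model = cv.n_pred + cv.n_ortho
    n = len(cv.folds)
    return _cv_anova_stats(cv.press, cv.ss_tot, n, a_model)


def cross_validate(X, labels, n_pred: int = 1, n_ortho: int = 0,
                   n_folds: int = 7, seed: int = 0,
                   mode: str = "unit_variance", log_transform: bool = False
                   ) -> CvResult:
    """K-fold cross-validation with per-fold refit of the scaling.

    ``X`` is the unscaled (but IS-normalized / media-subtracted) matrix;
    centring and scaling are learned inside each training fold only, so no
    information leaks from held-out samples.  Returns out-of-fold predictive
    scores (tcv), predicted responses, PRESS, Q2 and the CV-ANOVA record at
    df1 = n_pred + n_ortho.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    classes, Y_raw = encode_classes(labels)
    folds = assign_folds(labels, n_folds, seed)
    n_folds_eff = int(folds.max()) + 1
    tcv = np.zeros((n, n_pred))
    yhat_cv = np.zeros((n, len(classes) - 1))
    for f_id in range(n_folds_eff):
        te = folds == f_id
        tr = ~te
        if not te.any():
            continue
        tr_labels = [lab for lab, m in zip(labels, tr) if m]
        for cls in classes:
            if tr_labels.count(cls) < 2:
                raise FoldError(
                    f"fold {f_id} leaves class {cls!r} with <2 training samples; "
                    "use fewer folds"
                )
        params = fit_scaling(X[tr], mode=mode, log_transform=log_transform)
        model = fit_oplsda(params.apply(X[tr]), tr_labels,
                           n_pred=n_pred, n_ortho=n_ortho, scaling=params)
        t_pred, _t_o, yhat, _calls = predict(model, params.apply(X[te]))
        tcv[te] = t_pred
        yhat_cv[te] = yhat
    press = float(((Y_raw - yhat_cv) ** 2).sum())
    ss_tot = float(((Y_raw - Y_raw.mean(axis=0)) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    f, df1, df2, p = _cv_anova_stats(press, ss_tot, n, n_pred + n_ortho)
    return CvResult(
        tcv=tcv, yhat_cv=yhat_cv, press=press, ss_tot=ss_tot, q2=float(q2),
        f=f, df1=df1, df2=df2, p=p, folds=folds, n_pred=n_pred, n_ortho=n_ortho,
    )


def choose_orthogonal(X, labels, n_pred: int = 1, max_ortho: int = 3,
                      n_folds: int = 7, seed: int = 0,
                      mode: str = "unit_variance", log_transform: bool = False
                      ) -> int:
    """Greedy orthogonal-component count: add components while cross-validated
    Q2 improves by more than 0.01; stop at ``max_ortho`` or when the data run
    out of extractable orthogonal structure."""
    if max_ortho < 0:
        raise UsageError("max_ortho must be >= 0")
    best = cross_validate(X, labels, n_pred=n_pred, n_ortho=0, n_folds=n_folds,
                          seed=seed, mode=mode, log_transform=log_transform).q2
    chosen = 0
    for k in range(1, max_ortho + 1):
        try:
            q2 = cross_validate(X, labels, n_pred=n_pred, n_ortho=k,
                                n_folds=n_folds, seed=seed, mode=mode,
                                log_transform=log_transform).q2
        except DegenerateComponentError:
            break
        if q2 > best + 0.01:
            best = q2
            chosen = k
        else:
            break
    return chosen


# ---------------------------------------------------------------------------
# |w*| variable selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionResult:
    """One-pass |w*| >= tau latent-biomarker selection with refit."""

    retained: list[str]
    discarded: list[str]
    tau: float
    w_abs: np.ndarray  # M, max |w*| across predictive components (full model)
    initial_model: OplsModel
    initial_cv: CvResult
    final_model: OplsModel
    final_cv: CvResult


def select_variables(X, labels, metabolite_ids=None, tau: float = 0.05,
                     n_pred: int = 1, n_ortho: int = 0, n_folds: int = 7,
                     seed: int = 0, mode: str = "unit_variance",
                     log_transform: bool = False) -> SelectionResult:
    """Discard metabolites with |w*| < tau, then refit model and CV.

    Single pass: the full model's predictive weights gate selection
    (orthogonal weights never do); the refitted model and its CV-ANOVA p are
    what the pipeline reports.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    ids = list(metabolite_ids) if metabolite_ids is not None else [
        f"var{j}" for j in range(m)
    ]
    if len(ids) != m:
        raise UsageError("metabolite_ids length does not match X columns")
    if tau < 0:
        raise UsageError("tau must be >= 0")

    params = fit_scaling(X, mode=mode, log_transform=log_transform,
                         metabolite_ids=ids)
    initial_model = fit_oplsda(params.apply(X), labels, n_pred=n_pred,
                               n_ortho=n_ortho, scaling=params)
    initial_cv = cross_validate(X, labels, n_pred=n_pred, n_ortho=n_ortho,
                                n_folds=n_folds, seed=seed, mode=mode,
                                log_transform=log_transform)
    w_abs = np.abs(initial_model.w_star).max(axis=1)
    keep = w_abs >= tau
    retained = [i for i, k in zip(ids, keep) if k]
    discarded = [i for i, k in zip(ids, keep) if not k]
    if len(retained) < 2:
        raise SelectionCollapseError(
            f"selection at tau={tau} retained {len(retained)} metabolite(s); "
            "lower the threshold"
        )
    if not discarded:
        final_model, final_cv = initial_model, initial_cv
    else:
        Xr = X[:, keep]
        params_r = fit_scaling(Xr, mode=mode, log_transform=log_transform,
                               metabolite_ids=retained)
        final_model = fit_oplsda(params_r.apply(Xr), labels, n_pred=n_pred,
                                 n_ortho=n_ortho, scaling=params_r)
        final_cv = cross_validate(Xr, labels, n_pred=n_pred, n_ortho=n_ortho,
                                  n_folds=n_folds, seed=seed, mode=mode,
                                  log_transform=log_transform)
    return SelectionResult(
        retained=retained, discarded=discarded, tau=tau, w_abs=w_abs,
        initial_model=initial_model, initial_cv=initial_cv,
        final_model=final_model, final_cv=final_cv,
    )
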