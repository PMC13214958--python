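"""Sparsity-scoring kernel entropy component analysis and baselines.

SSKECA is a kernel eigenprojection that ranks centered-kernel eigenpairs
by a *sparsity score* instead of by eigenvalue.  Given a feature matrix
``X`` (N samples x D features) the fit proceeds as:

1. z-score each column (population-SD convention);
2. choose the RBF bandwidth adaptively, ``BW = w * sigma1 / D`` with
   ``sigma1`` the largest singular value of the standardized matrix (an
   explicit override bandwidth short-circuits this);
3. build the RBF kernel ``K_ij = exp(-||x_i - x_j||^2 / (2 BW^2))``;
4. double-center it, ``Kc = H K H`` with ``H = I - 11'/N``;
5. eigendecompose the symmetrized ``Kc``, dropping negative and
   near-zero eigenvalues (relative tolerance ``tol``);
6. score each kept eigenpair ``(lambda_i, alpha_i)`` by
   ``s_i = G_i - beta * ||alpha_i||_1`` where
   ``G_i = lambda_i (e_i' kbar)`` is its entropy contribution -- the
   alignment of the unit-norm, sign-fixed eigenvector ``e_i`` with the
   mean kernel row ``kbar = K 1 / N`` of the *uncentered* kernel -- and
   ``beta`` the sparsity penalty;
7. keep the ``ncomp`` top-scoring pairs and project,
   ``Xtrans = Kc Asel (Lambda_sel + delta)^{-1/2}``.

A note on step 6: the textbook entropy contribution is the alignment
``e_i' 1`` with the all-ones vector, which is what
:func:`sparsity_scores` computes by default.  But double-centering puts
``1`` in the null space of ``Kc`` (``Kc 1 = 0``), so every retained
eigenvector of the centered kernel is *exactly* orthogonal to ``1`` and
that alignment vanishes identically -- a score built on it would reduce
to pure l1 minimization and select spiky noise components.  For an
uncentered kernel ``e' K 1 = lambda (e' 1)``, so the mean-map alignment
used here coincides with the classical quantity up to a positive
per-component factor, while remaining informative after centering.

With ``beta = 0`` the ranking is entropy-only.  The classical KECA
baseline ranks by ``lambda_i (e_i' 1)^2``, KPCA by eigenvalue, and PCA is
an SVD on the centered matrix; all four expose the same fit/transform
contract.  Out-of-sample rows are projected Nystrom-style: their kernel
rows against the training set are centered with the *training* row means
and grand mean, so cross-validation stays leak-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA as _SkPCA
from sklearn.linear_model import Lasso as _SkLasso

__all__ = [
    "ScalerParams",
    "BandwidthSpec",
    "KernelCentering",
    "EigenSystem",
    "SparsityScores",
    "zscore_fit",
    "zscore_apply",
    "adaptive_bandwidth",
    "rbf_kernel",
    "center_kernel_fit",
    "center_kernel_apply",
    "stable_eig",
    "sparsity_scores",
    "select_components",
    "SSKECA",
    "KECA",
    "KPCA",
    "PCATransform",
    "baseline_transform",
    "DegenerateKernelError",
]


class DegenerateKernelError(ValueError):
    """All eigenvalues were filtered out (kernel carries no information)."""


# ---------------------------------------------------------------------------
# elementary steps


@dataclass(frozen=True)
class ScalerParams:
    mean: np.ndarray
    sd: np.ndarray  # population convention (ddof=0)


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, ScalerParams]:
    """Column-wise z-scoring with the population-SD convention.

    Constant columns are rejected with an error naming their indices (a
    zero-variance feature cannot be standardized).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("zscore_fit requires an N x D matrix with N >= 2")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant feature column(s): {constant.tolist()}")
    return (X - mean) / sd, ScalerParams(mean=mean, sd=sd)


def zscore_apply(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: got {X.shape[-1]} features, scaler has {params.mean.shape[0]}"
        )
    return (X - params.mean) / params.sd


@dataclass(frozen=True)
class BandwidthSpec:
    w: float
    bw: float
    sigma1: float
    n_features: int
    override: float | None = None


def adaptive_bandwidth(
    Xnorm: np.ndarray, w: float = 1.0, override: float | None = None
) -> BandwidthSpec:
    """SVD-adaptive RBF bandwidth ``BW = w * sigma1 / D``.

    ``sigma1`` is the largest singular value of the standardized matrix; a
    wider data spread therefore widens the kernel.  An explicit
    ``override`` bandwidth bypasses the computation entirely.
    """
    Xnorm = np.asarray(Xnorm, dtype=float)
    D = Xnorm.shape[1]
    if override is not None:
        if override <= 0:
            raise ValueError("override bandwidth must be > 0")
        return BandwidthSpec(w=w, bw=float(override), sigma1=float("nan"), n_features=D, override=override)
    if w <= 0:
        raise ValueError("bandwidth scaling factor w must be > 0")
    sigma1 = float(np.linalg.svd(Xnorm, compute_uv=False)[0])
    if sigma1 == 0:
        raise ValueError("zero matrix: largest singular value is 0")
    return BandwidthSpec(w=w, bw=w * sigma1 / D, sigma1=sigma1, n_features=D)


def rbf_kernel(A: np.ndarray, B: np.ndarray, bw: float) -> np.ndarray:
    """RBF kernel ``exp(-||a - b||^2 / (2 BW^2))`` between row sets."""
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch between row sets")
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * bw**2))


@dataclass(frozen=True)
class KernelCentering:
    row_means: np.ndarray  # column means of the training kernel
    grand_mean: float


def center_kernel_fit(K: np.ndarray) -> tuple[np.ndarray, KernelCentering]:
    """Double-center a square kernel, ``Kc = H K H``; store the training means."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    row_means = K.mean(axis=0)
    grand_mean = float(row_means.mean())
    Kc = K - row_means[None, :] - row_means[:, None] + grand_mean
    return Kc, KernelCentering(row_means=row_means, grand_mean=grand_mean)


def center_kernel_apply(K_new: np.ndarray, centering: KernelCentering) -> np.ndarray:
    """Center out-of-sample kernel rows with the stored training means."""
    K_new = np.asarray(K_new, dtype=float)
    new_means = K_new.mean(axis=1, keepdims=True) if K_new.size else np.zeros((K_new.shape[0], 1))
    return K_new - centering.row_means[None, :] - new_means + centering.grand_mean


@dataclass(frozen=True)
class EigenSystem:
    """Kept eigenpairs of the symmetrized centered kernel, descending."""

    values: np.ndarray  # kept eigenvalues, descending
    vectors: np.ndarray  # N x n_kept, orthonormal columns
    n_dropped: int


def stable_eig(Kc: np.ndarray, tol: float = 1e-10) -> EigenSystem:
    """Symmetrize, eigendecompose, and filter small/negative eigenvalues.

    Eigenvalues ``<= tol * lambda_max`` (and all non-positive ones) are
    dropped; a kernel with nothing left raises
    :class:`DegenerateKernelError`.
    """
    Kc = np.asarray(Kc, dtype=float)
    sym = 0.5 * (Kc + Kc.T)
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam_max = vals[0] if vals.size else 0.0
    keep = vals > max(tol * lam_max, 0.0)
    if not keep.any():
        raise DegenerateKernelError("all eigenvalues filtered: degenerate kernel")
    return EigenSystem(values=vals[keep], vectors=vecs[:, keep], n_dropped=int((~keep).sum()))


@dataclass(frozen=True)
class SparsityScores:
    entropy: np.ndarray  # G_i = lambda_i * (e_i' 1), sign-fixed so G_i >= 0
    l1_norms: np.ndarray
    beta: float
    scores: np.ndarray  # s_i = G_i - beta * ||alpha_i||_1
    sign_flip: np.ndarray  # +-1 applied to each eigenvector


def sparsity_scores(
    eig: EigenSystem, beta: float = 0.01, align: np.ndarray | None = None
) -> SparsityScores:
    """Entropy contribution minus an l1 sparsity penalty, per eigenpair.

    The entropy contribution ``G_i = lambda_i (e_i' v)`` is linear in the
    eigenvector, so each eigenvector sign is fixed to make ``e_i' v >= 0``
    (otherwise the ranking would depend on the arbitrary sign returned by
    the eigensolver).  The alignment vector ``v`` defaults to the all-ones
    vector (the textbook form); :class:`SSKECA` passes the training mean
    kernel row instead, because centered-kernel eigenvectors are exactly
    orthogonal to ones (see module docstring).  The l1 norm of the
    (unit-l2) eigenvector penalizes dense components.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    A = eig.vectors
    v = np.ones(A.shape[0]) if align is None else np.asarray(align, dtype=float)
    proj = A.T @ v
    flip = np.where(proj < 0, -1.0, 1.0)
    norms2 = np.linalg.norm(A, axis=0)
    entropy = eig.values * (flip * proj) / norms2
    l1 = np.abs(A).sum(axis=0) / norms2
    return SparsityScores(
        entropy=entropy, l1_norms=l1, beta=float(beta), scores=entropy - beta * l1, sign_flip=flip
    )


def select_components(scores: SparsityScores, ncomp: int) -> np.ndarray:
    """Indices of the ``ncomp`` largest scores; ties favour the smaller
    eigen-rank index (i.e. the larger eigenvalue)."""
    n = scores.scores.size
    if not 1 <= ncomp <= n:
        raise ValueError(f"ncomp must be in 1..{n}, got {ncomp}")
    # stable sort on -score keeps original (eigen-rank) order within ties
    order = np.argsort(-scores.scores, kind="stable")
    return np.sort(order[:ncomp])


# ---------------------------------------------------------------------------
# fitted transforms


@dataclass
class _FittedState:
    scaler: ScalerParams
    bandwidth: BandwidthSpec
    X_train_norm: np.ndarray
    centering: KernelCentering
    eig: EigenSystem
    scores: SparsityScores
    selected: np.ndarray
    values_sel: np.ndarray
    vectors_sel: np.ndarray  # sign-fixed
    lasso_mask: np.ndarray | None = None


class SSKECA:
    """Sparsity-scoring kernel entropy component transform.

    Parameters
    ----------
    ncomp : int or None
        Number of components to keep; ``None`` keeps every eigenpair that
        survives the eigenvalue filter.
    w : float
        Bandwidth scaling factor of the adaptive rule ``BW = w sigma1 / D``.
    bw : float, optional
        Explicit bandwidth override (skips the adaptive rule).
    beta : float
        Sparsity penalty; ``beta = 0`` is entropy-only ranking.
    tol : float
        Relative eigenvalue filter threshold.
    ridge : float
        Offset ``delta`` inside the whitening ``(lambda + delta)^{-1/2}``,
        guarding against near-singular selected eigenvalues.
    lasso_penalty : float, optional
        When set and labels are passed to :meth:`fit`, an l1-regularized
        post-stage zeroes transformed coordinates whose lasso coefficient
        against the label vanishes.  Off by default (does not affect the
        core transform).
    """

    ranking = "sparsity"

    def __init__(
        self,
        ncomp: int | None = None,
        w: float = 1.0,
        bw: float | None = None,
        beta: float = 0.01,
        tol: float = 1e-10,
        ridge: float = 1e-12,
        lasso_penalty: float | None = None,
    ):
        self.ncomp = ncomp
        self.w = w
        self.bw = bw
        self.beta = beta
        self.tol = tol
        self.ridge = ridge
        self.lasso_penalty = lasso_penalty
        self.state_: _FittedState | None = None

    # ranking statistic, overridden by subclasses; `align` is the training
    # mean kernel row (uncentered), the alignment target of the entropy term
    def _component_scores(self, eig: EigenSystem, align: np.ndarray) -> SparsityScores:
        return sparsity_scores(eig, beta=self.beta, align=align)

    def fit(self, X: np.ndarray, y: np.ndarray | None = None) -> "SSKECA":
        Xn, scaler = zscore_fit(X)
        bwspec = adaptive_bandwidth(Xn, w=self.w, override=self.bw)
        K = rbf_kernel(Xn, Xn, bwspec.bw)
        Kc, centering = center_kernel_fit(K)
        eig = stable_eig(Kc, tol=self.tol)
        scores = self._component_scores(eig, centering.row_means)
        ncomp = scores.scores.size if self.ncomp is None else self.ncomp
        selected = select_components(scores, ncomp)
        vectors = eig.vectors * scores.sign_flip[None, :]
        self.state_ = _FittedState(
            scaler=scaler,
            bandwidth=bwspec,
            X_train_norm=Xn,
            centering=centering,
            eig=eig,
            scores=scores,
            selected=selected,
            values_sel=eig.values[selected],
            vectors_sel=vectors[:, selected],
        )
        self._Kc = Kc
        self._Xtrans = Kc @ self.state_.vectors_sel @ np.diag(
            (self.state_.values_sel + self.ridge) ** -0.5
        )
        if self.lasso_penalty is not None and y is not None:
            self.state_.lasso_mask = self._fit_lasso_mask(self._Xtrans, np.asarray(y))
            self._Xtrans = self._Xtrans * self.state_.lasso_mask
        return self

    def _fit_lasso_mask(self, Xtrans: np.ndarray, y: np.ndarray) -> np.ndarray:
        model = _SkLasso(alpha=self.lasso_penalty, max_iter=5000)
        model.fit(Xtrans, y.astype(float))
        mask = (np.abs(model.coef_) > 0).astype(float)
        if not mask.any():  # penalty killed everything: keep all coordinates
            mask = np.ones_like(mask)
        return mask

    def fit_transform(self, X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        return self.fit(X, y)._Xtrans

    @property
    def training_projection_(self) -> np.ndarray:
        self._check_fitted()
        return self._Xtrans

    def transform(self, Xnew: np.ndarray) -> np.ndarray:
        """Nystrom-style out-of-sample projection (leak-free centering)."""
        st = self._check_fitted()
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.size == 0:
            return np.zeros((0, st.selected.size))
        Xn = zscore_apply(Xnew, st.scaler)
        K_new = rbf_kernel(Xn, st.X_train_norm, st.bandwidth.bw)
        Kc_new = center_kernel_apply(K_new, st.centering)
        out = Kc_new @ st.vectors_sel @ np.diag((st.values_sel + self.ridge) ** -0.5)
        if st.lasso_mask is not None:
            out = out * st.lasso_mask
        return out

    def _check_fitted(self) -> _FittedState:
        if self.state_ is None:
            raise RuntimeError("transform is not fitted")
        return self.state_

    @property
    def n_components_(self) -> int:
        return int(self._check_fitted().selected.size)


class KECA(SSKECA):
    """Classical kernel entropy component analysis baseline.

    Ranks eigenpairs by the quadratic entropy contribution
    ``lambda_i (e_i' v)^2`` (a component orthogonal to the alignment
    vector contributes nothing and ranks last).  As in :class:`SSKECA`
    the alignment is the training mean kernel row, since the classical
    all-ones alignment vanishes identically on a centered kernel.
    """

    ranking = "entropy"

    def __init__(self, ncomp=None, w=1.0, bw=None, tol=1e-10, ridge=1e-12):
        super().__init__(ncomp=ncomp, w=w, bw=bw, beta=0.0, tol=tol, ridge=ridge)

    def _component_scores(self, eig: EigenSystem, align: np.ndarray) -> SparsityScores:
        base = sparsity_scores(eig, beta=0.0, align=align)
        quad = eig.values * (base.entropy / np.where(eig.values > 0, eig.values, 1.0)) ** 2
        return SparsityScores(
            entropy=base.entropy,
            l1_norms=base.l1_norms,
            beta=0.0,
            scores=quad,
            sign_flip=base.sign_flip,
        )


class KPCA(SSKECA):
    """Kernel PCA baseline: centered-kernel eigenprojection ranked by eigenvalue."""

    ranking = "eigenvalue"

    def __init__(self, ncomp=None, w=1.0, bw=None, tol=1e-10, ridge=1e-12):
        super().__init__(ncomp=ncomp, w=w, bw=bw, beta=0.0, tol=tol, ridge=ridge)

    def _component_scores(self, eig: EigenSystem, align: np.ndarray) -> SparsityScores:
        base = sparsity_scores(eig, beta=0.0, align=align)
        return SparsityScores(
            entropy=base.entropy,
            l1_norms=base.l1_norms,
            beta=0.0,
            scores=eig.values.copy(),
            sign_flip=base.sign_flip,
        )


class PCATransform:
    """Linear PCA via SVD on the centered matrix, same fit/transform contract."""

    ranking = "variance"

    def __init__(self, ncomp: int | None = None, **_ignored):
        self.ncomp = ncomp
        self._pca: _SkPCA | None = None

    def fit(self, X: np.ndarray, y=None) -> "PCATransform":
        X = np.asarray(X, dtype=float)
        ncomp = self.ncomp
        if ncomp is not None:
            ncomp = min(ncomp, min(X.shape))
        self._pca = _SkPCA(n_components=ncomp, svd_solver="full").fit(X)
        self._Xtrans = self._pca.transform(X)
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y)._Xtrans

    @property
    def training_projection_(self) -> np.ndarray:
        return self._Xtrans

    def transform(self, Xnew: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("transform is not fitted")
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.size == 0:
            return np.zeros((0, self._pca.n_components_))
        return self._pca.transform(Xnew)

    @property
    def n_components_(self) -> int:
        return int(self._pca.n_components_)


_METHODS = {"SSKECA": SSKECA, "KECA": KECA, "KPCA": KPCA, "PCA": PCATransform}


def make_transform(method: str = "SSKECA", **params):
    """Instantiate a transform by name (``SSKECA``, ``KECA``, ``KPCA``, ``PCA``)."""
    try:
        cls = _METHODS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown transform method {method!r}; choose from {sorted(_METHODS)}")
    return cls(**params)


def baseline_transform(X: np.ndarray, method: str, **params) -> tuple[np.ndarray, object]:
    """Fit a named transform on ``X`` and return (transformed matrix, model)."""
    model = make_transform(method, **params)
    return model.fit_transform(X), model
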