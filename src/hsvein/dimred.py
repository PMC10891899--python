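"""Dimensionality reduction for hyperspectral pixel matrices.

Three backends, all deterministic given their inputs:

``SpectralPCA``
    Classical principal-component analysis of the n x F pixel matrix.  The
    covariance of the mean-centered matrix, C = Xc' Xc / (n - 1), is
    eigen-decomposed; components are ordered by descending eigenvalue and the
    projection is Y = (X - mean) P with P the top-k eigenvectors.

``FoldedPCA``
    Folded PCA.  Each mean-centered spectral vector is reshaped row-wise into
    an H x W matrix A_i (H segments of W bands; the vector is zero-padded or
    truncated to length H*W), and the W x W partial covariance
    Cp = sum_i A_i' A_i / (nH - 1) is eigen-decomposed.  The per-pixel
    projection A_i V is flattened eigenvector-major (all H values of
    component 1, then component 2, ...) and truncated to the first k
    features, so "number of components" counts output features.  With H = 1
    and W = F this reduces exactly to ``SpectralPCA``, including the 1/(n-1)
    normalisation.

``WaLuMIBandSelector``
    Ward's-linkage band selection using mutual information.  Pairwise MI
    between quantized bands is turned into the bounded dissimilarity
    D_ij = 1 - MI_ij / sqrt(H_i H_j), bands are agglomerated under the Ward
    Lance-Williams recurrence, the dendrogram is cut into k clusters, and one
    representative band per cluster (the one with maximal total MI to its
    co-members, ties to the lowest index) is kept.  The transform is a pure
    band subset, so selected features remain physical wavelengths.

Sign convention: every eigenvector is flipped so its largest-magnitude entry
is positive, which makes all fits reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .envi import Hypercube

__all__ = [
    "SpectralPCA",
    "FoldedPCA",
    "WaLuMIBandSelector",
    "MIMatrix",
    "LinkageTree",
    "BandSelection",
    "ReducedCube",
    "fit_pca",
    "transform_pca",
    "fit_fpca",
    "transform_fpca",
    "mi_matrix",
    "ward_linkage",
    "cut_tree",
    "walumi_select",
    "reduce_cube",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


def _check_pixel_matrix(X, min_rows: int = 2) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"pixel matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} pixels, got {X.shape[0]}")
    if X.shape[1] < 1:
        raise ValueError("need at least one band")
    if not np.all(np.isfinite(X)):
        raise ValueError("pixel matrix contains non-finite values")
    return X


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so each largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _sorted_eigh(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose a symmetric matrix, descending eigenvalue order."""
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], _fix_signs(eigvecs[:, order])


class SpectralPCA(TransformerMixin, BaseEstimator):
    """PCA of an n-pixel x F-band matrix via covariance eigen-decomposition.

    Parameters
    ----------
    n_components : int or None
        Number k of leading components to keep; ``None`` keeps all F.

    Attributes
    ----------
    mean_ : ndarray (F,)            per-band training means
    components_ : ndarray (k, F)    top-k eigenvectors, row-wise
    explained_variance_ : ndarray (k,)
    eigenvalues_ : ndarray (F,)     full descending spectrum
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = _check_pixel_matrix(X)
        n, F = X.shape
        k = F if self.n_components is None else int(self.n_components)
        if not 1 <= k <= F:
            raise ValueError(f"n_components must be in [1, {F}], got {k}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        C = Xc.T @ Xc / (n - 1)
        eigvals, eigvecs = _sorted_eigh(C)
        self.eigenvalues_ = eigvals
        self.components_ = eigvecs[:, :k].T
        self.explained_variance_ = eigvals[:k]
        self.n_features_in_ = F
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} bands, got shape {X.shape}")
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Y) -> np.ndarray:
        return np.asarray(Y) @ self.components_ + self.mean_


class FoldedPCA(TransformerMixin, BaseEstimator):
    """Folded PCA: fold spectra into H x W matrices, partial W x W covariance.

    Parameters
    ----------
    n_components : int or None
        Number k of output features (eigenvector-major flattening of the
        H x W projection); ``None`` keeps all H*W.
    fold_height : int
        H, the number of spectral segments per pixel.
    fold_width : int or None
        W, bands per segment; defaults to ceil(F / H) at fit time.

    With ``fold_height=1`` the fit and transform coincide with
    :class:`SpectralPCA` (the stated degenerate limit of the fold).
    """

    def __init__(self, n_components: int | None = None, fold_height: int = 1, fold_width: int | None = None):
        self.n_components = n_components
        self.fold_height = fold_height
        self.fold_width = fold_width

    def _fold(self, Xc: np.ndarray) -> np.ndarray:
        """Pad/truncate centered rows to H*W and reshape to (n, H, W)."""
        n, F = Xc.shape
        H, W = self.fold_height_, self.fold_width_
        L = H * W
        if L > F:
            Xc = np.hstack([Xc, np.zeros((n, L - F))])
        elif L < F:
            Xc = Xc[:, :L]
        return Xc.reshape(n, H, W)

    def fit(self, X, y=None):
        X = _check_pixel_matrix(X)
        n, F = X.shape
        H = int(self.fold_height)
        if H < 1:
            raise ValueError("fold_height must be >= 1")
        W = int(self.fold_width) if self.fold_width is not None else -(-F // H)
        if W < 1:
            raise ValueError("fold_width must be >= 1")
        if H * W < F:
            logger.warning(
                "fold %dx%d covers %d of %d bands; trailing bands are dropped", H, W, H * W, F
            )
        k = H * W if self.n_components is None else int(self.n_components)
        if not 1 <= k <= H * W:
            raise ValueError(f"n_components must be in [1, {H * W}], got {k}")
        self.fold_height_, self.fold_width_ = H, W
        self.mean_ = X.mean(axis=0)
        A = self._fold(X - self.mean_)  # (n, H, W)
        stacked = A.reshape(n * H, W)
        Cp = stacked.T @ stacked / (n * H - 1)
        eigvals, eigvecs = _sorted_eigh(Cp)
        self.eigenvalues_ = eigvals
        self.eigenvectors_ = eigvecs  # (W, W), columns
        self.n_features_in_ = F
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} bands, got shape {X.shape}")
        A = self._fold(X - self.mean_)  # (n, H, W)
        Y = A @ self.eigenvectors_  # (n, H, W): column j = component j scores
        # eigenvector-major flatten: all H values of component 1, then 2, ...
        flat = Y.transpose(0, 2, 1).reshape(X.shape[0], -1)
        return flat[:, : self.n_components_]


# ---------------------------------------------------------------------------
# Mutual information and Ward linkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIMatrix:
    """Pairwise band mutual information (bits) with marginal entropies."""

    mi: np.ndarray  # (F, F), symmetric, mi[i, i] = entropy of band i
    entropies: np.ndarray  # (F,)
    bins: int


def _quantize(X: np.ndarray, bins: int) -> np.ndarray:
    """Uniform per-band quantization over each band's own [min, max]."""
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant band -> all code 0
    codes = np.floor((X - lo) / span * bins).astype(np.int64)
    return np.minimum(codes, bins - 1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mi_matrix(X, bins: int = 64) -> MIMatrix:
    """Plug-in mutual-information matrix between bands, in bits.

    Each band is uniformly quantized to ``bins`` levels over its own range;
    MI is computed from the joint histogram.  Symmetric by construction;
    the diagonal carries the marginal entropies.  A constant band has zero
    entropy and zero MI to every other band.
    """
    X = _check_pixel_matrix(X)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    n, F = X.shape
    codes = _quantize(X, bins)
    marg = np.stack([np.bincount(codes[:, i], minlength=bins) / n for i in range(F)])
    entropies = np.array([_entropy(marg[i]) for i in range(F)])
    M = np.zeros((F, F))
    np.fill_diagonal(M, entropies)
    log_marg = np.full((F, bins), -np.inf)
    np.log2(marg, out=log_marg, where=marg > 0)
    for i in range(F):
        ci = codes[:, i]
        for j in range(i + 1, F):
            joint = np.bincount(ci * bins + codes[:, j], minlength=bins * bins) / n
            joint = joint.reshape(bins, bins)
            nz = joint > 0
            outer_log = log_marg[i][:, None] + log_marg[j][None, :]
            mi = float((joint[nz] * (np.log2(joint[nz]) - outer_log[nz])).sum())
            M[i, j] = M[j, i] = max(mi, 0.0)
    return MIMatrix(mi=M, entropies=entropies, bins=bins)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history: (cluster_a, cluster_b, height, new_size).

    Leaves are numbered 0..F-1; the merge at step t creates cluster F+t,
    matching the scipy linkage convention.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    n_leaves: int

    def to_scipy(self) -> np.ndarray:
        """Return the (F-1, 4) scipy-format linkage array."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def ward_linkage(D) -> LinkageTree:
    """Agglomerate under the Ward Lance-Williams distance update.

    ``D`` is a symmetric, zero-diagonal, non-negative F x F dissimilarity
    matrix.  At every step the closest pair merges and distances to the new
    cluster follow

        d(ij, k)^2 = [ (n_i+n_k) d(i,k)^2 + (n_j+n_k) d(j,k)^2
                       - n_k d(i,j)^2 ] / (n_i+n_j+n_k)

    which makes merge heights non-decreasing.  Ties break to the smallest
    index pair, so the tree is deterministic.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    F = D.shape[0]
    if F < 2:
        raise ValueError("need at least two items to link")
    d2 = D.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    sizes = np.ones(F, dtype=int)
    labels = np.arange(F)  # current cluster id per active slot
    active = np.ones(F, dtype=bool)
    merges: list[tuple[int, int, float, int]] = []
    for step in range(F - 1):
        masked = np.where(active[:, None] & active[None, :], d2, np.inf)
        np.fill_diagonal(masked, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if i > j:
            i, j = j, i
        height = float(np.sqrt(d2[i, j]))
        ni, nj = sizes[i], sizes[j]
        new_size = ni + nj
        a, b = labels[i], labels[j]
        merges.append((int(min(a, b)), int(max(a, b)), height, int(new_size)))
        # Lance-Williams update into slot i
        k = active.copy()
        k[[i, j]] = False
        nk = sizes[k]
        d2_new = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * d2[i, j]) / (ni + nj + nk)
        d2[i, k] = d2_new
        d2[k, i] = d2_new
        sizes[i] = new_size
        labels[i] = F + step
        active[j] = False
        d2[j, :] = np.inf
        d2[:, j] = np.inf
    return LinkageTree(merges=tuple(merges), n_leaves=F)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut a linkage tree into k clusters; returns leaf -> cluster labels 0..k-1."""
    F = tree.n_leaves
    if not 1 <= k <= F:
        raise ValueError(f"k must be in [1, {F}], got {k}")
    parent = list(range(F + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _h, _s) in enumerate(tree.merges[: F - k]):
        new = F + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = {}
    labels = np.empty(F, dtype=int)
    for leaf in range(F):
        r = find(leaf)
        labels[leaf] = roots.setdefault(r, len(roots))
    return labels


@dataclass(frozen=True)
class BandSelection:
    """k selected band indices plus the cluster assignment that produced them."""

    indices: tuple[int, ...]
    k: int
    cluster_assignments: np.ndarray  # (F,) band -> cluster label

    def __post_init__(self) -> None:
        if len(self.indices) != self.k:
            raise ValueError("selection size must equal k")
        if not all(a < b for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")


def mi_to_distance(mim: MIMatrix) -> np.ndarray:
    """Bounded dissimilarity 1 - MI_ij / sqrt(H_i H_j) in [0, 1].

    Bands with zero entropy are maximally distant (D = 1) from everything;
    the diagonal is zero.
    """
    H = mim.entropies
    denom = np.sqrt(np.outer(H, H))
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 - np.where(denom > 0, mim.mi / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 1.0)


def walumi_select(X, k: int, bins: int = 64) -> BandSelection:
    """Ward-linkage mutual-information band selection.

    Quantize bands, compute pairwise MI, convert to the normalised MI
    dissimilarity, cluster with Ward's linkage, cut at k clusters, and keep
    the band with the largest total MI to its cluster co-members (ties to the
    lowest index).  Returns sorted, strictly increasing indices.
    """
    X = _check_pixel_matrix(X)
    F = X.shape[1]
    if not 1 <= k <= F:
        raise ValueError(f"k must be in [1, {F}], got {k}")
    mim = mi_matrix(X, bins=bins)
    if k == F:
        return BandSelection(indices=tuple(range(F)), k=k, cluster_assignments=np.arange(F))
    D = mi_to_distance(mim)
    tree = ward_linkage(D)
    labels = cut_tree(tree, k)
    indices = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 1:
            indices.append(int(members[0]))
            continue
        totals = mim.mi[np.ix_(members, members)].sum(axis=1) - mim.entropies[members]
        best = members[int(np.argmax(totals))]  # argmax takes first (lowest index) on ties
        indices.append(int(best))
    return BandSelection(indices=tuple(sorted(indices)), k=k, cluster_assignments=labels)


class WaLuMIBandSelector(TransformerMixin, BaseEstimator):
    """Band-subset transformer driven by :func:`walumi_select`.

    Parameters
    ----------
    n_bands : int
        Number of bands (clusters) to keep.
    bins : int
        Quantization levels for the MI estimator.
    """

    def __init__(self, n_bands: int = 40, bins: int = 64):
        self.n_bands = n_bands
        self.bins = bins

    def fit(self, X, y=None):
        X = _check_pixel_matrix(X)
        sel = walumi_select(X, self.n_bands, bins=self.bins)
        self.selection_ = sel
        self.selected_bands_ = np.array(sel.indices)
        self.n_features_in_ = X.shape[1]
        self.n_components_ = sel.k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} bands, got shape {X.shape}")
        return X[:, self.selected_bands_]


# ---------------------------------------------------------------------------
# Cube-level application and model persistence
# ---------------------------------------------------------------------------


@dataclass
class ReducedCube:
    """rows x cols x k feature cube with reduction provenance."""

    data: np.ndarray
    provenance: dict

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """Row-major (rows*cols, k) view of the feature cube."""
        return self.data.reshape(-1, self.data.shape[2])


def _method_name(model) -> str:
    return {SpectralPCA: "pca", FoldedPCA: "fpca", WaLuMIBandSelector: "walumi"}[type(model)]


def reduce_cube(cube: Hypercube, model) -> ReducedCube:
    """Apply a fitted reducer to a cube, pixel-wise, preserving geometry.

    Pixels are flattened row-major, pushed through ``model.transform`` and
    reshaped back to rows x cols x k.
    """
    if cube.bands != model.n_features_in_:
        raise ValueError(f"cube has {cube.bands} bands but model was fitted on {model.n_features_in_}")
    flat = cube.data.reshape(-1, cube.bands).astype(float)
    Y = model.transform(flat)
    data = Y.reshape(cube.rows, cube.cols, -1)
    prov = {"method": _method_name(model), **{k: v for k, v in model.get_params().items()}}
    return ReducedCube(data=data, provenance=prov)


def save_model(model, path: str | os.PathLike) -> None:
    """Serialize a fitted reducer to JSON (method, parameters, fitted state)."""
    method = _method_name(model)
    payload: dict = {"method": method, "params": model.get_params(), "n_features_in": int(model.n_features_in_)}
    if method == "pca":
        payload["mean"] = model.mean_.tolist()
        payload["components"] = model.components_.tolist()
        payload["eigenvalues"] = model.eigenvalues_.tolist()
    elif method == "fpca":
        payload["mean"] = model.mean_.tolist()
        payload["eigenvectors"] = model.eigenvectors_.tolist()
        payload["eigenvalues"] = model.eigenvalues_.tolist()
        payload["fold"] = [model.fold_height_, model.fold_width_]
        payload["n_components"] = model.n_components_
    else:
        payload["selected_bands"] = model.selected_bands_.tolist()
        payload["cluster_assignments"] = model.selection_.cluster_assignments.tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike):
    """Inverse of :func:`save_model`; returns a fitted reducer."""
    with open(path) as fh:
        payload = json.load(fh)
    method = payload["method"]
    if method == "pca":
        model = SpectralPCA(**payload["params"])
        model.mean_ = np.array(payload["mean"])
        model.components_ = np.array(payload["components"])
        model.eigenvalues_ = np.array(payload["eigenvalues"])
        model.explained_variance_ = model.eigenvalues_[: model.components_.shape[0]]
        model.n_components_ = model.components_.shape[0]
    elif method == "fpca":
        model = FoldedPCA(**payload["params"])
        model.mean_ = np.array(payload["mean"])
        model.eigenvectors_ = np.array(payload["eigenvectors"])
        model.eigenvalues_ = np.array(payload["eigenvalues"])
        model.fold_height_, model.fold_width_ = payload["fold"]
        model.n_components_ = payload["n_components"]
    elif method == "walumi":
        model = WaLuMIBandSelector(**payload["params"])
        model.selected_bands_ = np.array(payload["selected_bands"])
        model.selection_ = BandSelection(
            indices=tuple(int(b) for b in payload["selected_bands"]),
            k=len(payload["selected_bands"]),
            cluster_assignments=np.array(payload["cluster_assignments"]),
        )
        model.n_components_ = len(payload["selected_bands"])
    else:
        raise ValueError(f"unknown model method {method!r}")
    model.n_features_in_ = payload["n_features_in"]
    return model


# --- thin functional wrappers -------------------------------------------------


def fit_pca(X, k: int) -> SpectralPCA:
    """Fit a k-component PCA on a pixel matrix."""
    return SpectralPCA(n_components=k).fit(X)


def transform_pca(model: SpectralPCA, X) -> np.ndarray:
    return model.transform(X)


def fit_fpca(X, fold_height: int, fold_width: int | None, k: int) -> FoldedPCA:
    """Fit a Folded PCA with fold H x W keeping k output features."""
    return FoldedPCA(n_components=k, fold_height=fold_height, fold_width=fold_width).fit(X)


def transform_fpca(model: FoldedPCA, X) -> np.ndarray:
    return model.transform(X)
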