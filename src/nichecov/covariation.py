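"""Latent gene programs per cell type and their covariation across niches.

Per cell type, non-negative latent factors are learned on the shared gene
set either jointly from both modalities (integrative NMF with per-modality
heterogeneity terms, alternating non-negative least squares) or from the
reference alone with Kullback-Leibler NMF and a fixed-gene-factor transfer
of the loadings to the spatial modality. Factors are ordered by normalised
entropy of their cell loadings. Covariation between co-localised cell types
is then quantified by ridge regression of each central-cell factor on the
neighbourhood-averaged factors of its niche cell types, with the penalty
chosen by leave-one-out cross-validation and two-tailed t-statistic
p-values from the ridge sandwich covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats
from scipy.optimize import nnls
from scipy.spatial import cKDTree

from sklearn.linear_model import Ridge, RidgeCV

from .core_io import NOT_MAPPED, ReferenceDataset, SpatialDataset
from .interaction import InteractionModel, NeighborGraph

__all__ = [
    "FactorModel",
    "fit_inmf",
    "alignment_score",
    "alignment_from_counts",
    "select_lambda",
    "fit_onmf_transfer",
    "entropy_order",
    "regress_covariation",
    "fit_factor_models",
    "scale_genes",
]

DEFAULT_ETA_GRID = tuple(2.0 ** np.arange(-10, 11))


@dataclass
class FactorModel:
    """Shared gene factors W with per-modality cell loadings.

    ``W`` is (LF, G); ``H_sc``/``H_sp`` are cells-by-LF loadings for the
    reference and spatial modality. ``V_sc``/``V_sp`` are the per-modality
    heterogeneity terms of the integrative fit (``None`` for the transfer
    method). ``entropy`` holds the normalised per-factor entropy once
    :func:`entropy_order` has run; factors are then sorted by increasing
    entropy.
    """

    W: np.ndarray
    H_sc: np.ndarray
    H_sp: np.ndarray
    V_sc: Optional[np.ndarray]
    V_sp: Optional[np.ndarray]
    lam: float
    LF: int
    method: str  # 'inmf' or 'onmf'
    entropy: Optional[np.ndarray] = None
    alignment_path: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    gene_ids: Optional[np.ndarray] = None
    sc_cell_idx: Optional[np.ndarray] = None
    sp_cell_idx: Optional[np.ndarray] = None


def _check_nonneg(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size and x.min() < 0:
        raise ValueError(f"{name} must be non-negative")
    return x


# ---------------------------------------------------------------------------
# integrative NMF (alternating non-negative least squares)
# ---------------------------------------------------------------------------

def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_i - b_i|| with x_i >= 0 for every column b_i of B."""
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(B.shape[1]):
        out[:, i], _ = nnls(A, B[:, i])
    return out


def _inmf_objective(E_sc, E_sp, W, H_sc, H_sp, V_sc, V_sp, lam) -> float:
    o = np.linalg.norm(E_sc - H_sc @ (W + V_sc), "fro") ** 2
    o += lam * np.linalg.norm(H_sc @ V_sc, "fro") ** 2
    o += np.linalg.norm(E_sp - H_sp @ (W + V_sp), "fro") ** 2
    o += lam * np.linalg.norm(H_sp @ V_sp, "fro") ** 2
    return float(o)


def nndsvda(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD initialisation, zeros filled with the mean.

    Deterministic rank-k initialisation (H, W) with H (n, k), W (k, m)
    from the leading singular vectors of X; the standard construction takes
    the larger of the positive/negative parts of each singular pair.
    """
    n, m = X.shape
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    H = np.zeros((n, k))
    W = np.zeros((k, m))
    H[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    W[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, min(k, len(s))):
        x, y = u[:, j], vt[j]
        xp, xn = np.maximum(x, 0), np.maximum(-x, 0)
        yp, yn = np.maximum(y, 0), np.maximum(-y, 0)
        mp, mn = np.linalg.norm(xp) * np.linalg.norm(yp), np.linalg.norm(xn) * np.linalg.norm(yn)
        if mp >= mn:
            xx, yy, sig = xp / max(np.linalg.norm(xp), 1e-12), yp / max(np.linalg.norm(yp), 1e-12), mp
        else:
            xx, yy, sig = xn / max(np.linalg.norm(xn), 1e-12), yn / max(np.linalg.norm(yn), 1e-12), mn
        H[:, j] = np.sqrt(s[j] * sig) * xx
        W[j] = np.sqrt(s[j] * sig) * yy
    avg = X.mean()
    H[H == 0] = avg
    W[W == 0] = avg
    return H, W


def fit_inmf(
    E_sc: np.ndarray,
    E_sp: np.ndarray,
    LF: int = 3,
    lam: float = 0.0,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FactorModel:
    """Integrative NMF of two modalities with shared gene factors.

    Minimises

        ||E_sc - H_sc (W + V_sc)||_F^2 + lam ||H_sc V_sc||_F^2
      + ||E_sp - H_sp (W + V_sp)||_F^2 + lam ||H_sp V_sp||_F^2

    over non-negative W, H_x, V_x by block-coordinate descent where each
    block (rows of H_x, columns of V_x and W) is solved exactly by NNLS, so
    the objective is non-increasing. Stops at relative decrease < ``tol``
    or ``max_iter`` iterations. The per-iteration objective is recorded.
    """
    E_sc = _check_nonneg(E_sc, "E_sc")
    E_sp = _check_nonneg(E_sp, "E_sp")
    if E_sc.shape[1] != E_sp.shape[1]:
        raise ValueError("modalities must share the gene set")
    G = E_sc.shape[1]
    if LF > min(E_sc.shape[0], E_sp.shape[0], G):
        raise ValueError(f"LF={LF} exceeds the smallest input dimension")

    _, W = nndsvda(np.vstack([E_sc, E_sp]), LF)
    V_sc = np.zeros((LF, G))
    V_sp = np.zeros((LF, G))
    H_sc = _nnls_rows(W.T, E_sc.T).T
    H_sp = _nnls_rows(W.T, E_sp.T).T

    sq = np.sqrt(lam)
    objective = [_inmf_objective(E_sc, E_sp, W, H_sc, H_sp, V_sc, V_sp, lam)]
    for _ in range(max_iter):
        # H blocks: rows solve min ||[ (W+V)^T ; sqrt(lam) V^T ] h - [e; 0]||
        for E, V, which in ((E_sc, V_sc, "sc"), (E_sp, V_sp, "sp")):
            A = np.vstack([(W + V).T, sq * V.T]) if lam > 0 else (W + V).T
            B = np.vstack([E.T, np.zeros((G, E.shape[0]))]) if lam > 0 else E.T
            H = _nnls_rows(A, B).T
            if which == "sc":
                H_sc = H
            else:
                H_sp = H
        # V blocks: columns solve min ||[H; sqrt(lam) H] v - [e - H w; 0]||
        for E, H, which in ((E_sc, H_sc, "sc"), (E_sp, H_sp, "sp")):
            A = np.vstack([H, sq * H])
            B = np.vstack([E - H @ W, np.zeros_like(E)])
            V = _nnls_rows(A, B)
            if which == "sc":
                V_sc = V
            else:
                V_sp = V
        # W block: joint over both modalities
        A = np.vstack([H_sc, H_sp])
        B = np.vstack([E_sc - H_sc @ V_sc, E_sp - H_sp @ V_sp])
        W = _nnls_rows(A, B)
        obj = _inmf_objective(E_sc, E_sp, W, H_sc, H_sp, V_sc, V_sp, lam)
        objective.append(obj)
        prev = objective[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break

    return FactorModel(
        W, H_sc, H_sp, V_sc, V_sp, lam, LF, "inmf", objective=objective
    )


# ---------------------------------------------------------------------------
# alignment score and lambda selection
# ---------------------------------------------------------------------------

def alignment_from_counts(x_bar: float, K: int, n: int) -> float:
    """Closed-form alignment score: 1 - (x_bar - K/n) / (K - K/n)."""
    return float(1.0 - (x_bar - K / n) / (K - K / n))


def alignment_score(H_sc: np.ndarray, H_sp: np.ndarray, seed: int = 0) -> float:
    """Dataset-mixing statistic of the two loadings in factor space.

    The larger matrix is downsampled to the smaller one's size n; with
    K = max(1, round(0.01 n)) nearest neighbours in the merged factor space,
    x_bar is the mean number of same-dataset neighbours, and

        score = 1 - (x_bar - K/n) / (K - K/n).

    Perfectly separated datasets (x_bar = K) give 0.
    """
    if H_sc.shape[1] != H_sp.shape[1]:
        raise ValueError("loadings must share the factor dimension")
    n = min(H_sc.shape[0], H_sp.shape[0])
    if n < 2:
        raise ValueError("need at least 2 cells per modality")
    rng = np.random.default_rng(seed)
    a = H_sc if H_sc.shape[0] == n else H_sc[rng.choice(H_sc.shape[0], n, replace=False)]
    b = H_sp if H_sp.shape[0] == n else H_sp[rng.choice(H_sp.shape[0], n, replace=False)]
    merged = np.vstack([a, b])
    origin = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    K = max(1, int(round(0.01 * n)))
    tree = cKDTree(merged)
    _, idx = tree.query(merged, k=K + 1)
    idx = np.atleast_2d(idx)[:, 1:]  # drop self
    same = (origin[idx] == origin[:, None]).sum(axis=1)
    x_bar = same.mean()
    return alignment_from_counts(x_bar, K, n)


def select_lambda(
    E_sc: np.ndarray,
    E_sp: np.ndarray,
    LF: int = 3,
    seed: int = 0,
    lam_step: int = 2,
    lam_max: int = 40,
    stop_tol: float = 0.001,
    **inmf_kwargs,
) -> tuple[float, list]:
    """Scan the integration penalty over even integers until the alignment
    score stabilises (successive change < 0.001). Returns the selected value
    and the (lambda, score) path; warns if no stabilisation by ``lam_max``.
    """
    path = []
    prev_score = None
    lam = 0
    while lam <= lam_max:
        model = fit_inmf(E_sc, E_sp, LF=LF, lam=float(lam), seed=seed, **inmf_kwargs)
        score = alignment_score(model.H_sc, model.H_sp, seed=seed)
        path.append((float(lam), score))
        if prev_score is not None and abs(score - prev_score) < stop_tol:
            return float(lam), path
        prev_score = score
        lam += lam_step
    warnings.warn(f"alignment score did not stabilise by lambda={lam_max}")
    return float(path[-1][0]), path


# ---------------------------------------------------------------------------
# KL-NMF on the reference with fixed-W transfer to the spatial modality
# ---------------------------------------------------------------------------

def _kl_divergence(X: np.ndarray, Y: np.ndarray) -> float:
    eps = 1e-12
    Y = np.maximum(Y, eps)
    mask = X > 0
    term = np.where(mask, X * np.log(np.maximum(X, eps) / Y), 0.0)
    return float((term - X + Y).sum())


def kl_nmf(
    E: np.ndarray,
    LF: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list]:
    """KL-divergence NMF by multiplicative updates with nndsvda init.

    Returns (H, W, objective history); the KL objective is non-increasing
    under the multiplicative updates.
    """
    E = _check_nonneg(E, "E")
    H, W = nndsvda(E, LF)
    eps = 1e-12
    obj = [_kl_divergence(E, H @ W)]
    for _ in range(max_iter):
        WH = np.maximum(H @ W, eps)
        H *= ((E / WH) @ W.T) / np.maximum(W.sum(axis=1)[None, :], eps)
        WH = np.maximum(H @ W, eps)
        W *= (H.T @ (E / WH)) / np.maximum(H.sum(axis=0)[:, None], eps)
        obj.append(_kl_divergence(E, H @ W))
        if obj[-2] > 0 and abs(obj[-2] - obj[-1]) / max(obj[-2], eps) < tol:
            break
    return H, W, obj


def transfer_loadings(
    E_sp: np.ndarray,
    W: np.ndarray,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Spatial loadings under fixed gene factors W (multiplicative updates).

    Uses the Frobenius multiplicative update for the loading matrix,

        H <- H * (E W^T) / (H W W^T),

    iterated until the relative change of the reconstruction error drops
    below ``tol``. W is not modified. Zero rows of ``E_sp`` give zero
    loadings (with a warning).
    """
    E_sp = _check_nonneg(E_sp, "E_sp")
    eps = 1e-12
    zero_rows = E_sp.sum(axis=1) == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} zero rows in E_sp; loadings set to 0")
    rng = np.random.default_rng(seed)
    H = rng.uniform(0.1, 1.0, (E_sp.shape[0], W.shape[0])) * np.sqrt(
        max(E_sp.mean(), eps) / max(W.shape[0], 1)
    )
    EWt = E_sp @ W.T
    WWt = W @ W.T
    prev = np.linalg.norm(E_sp - H @ W, "fro") ** 2
    for _ in range(max_iter):
        H *= EWt / np.maximum(H @ WWt, eps)
        err = np.linalg.norm(E_sp - H @ W, "fro") ** 2
        if prev > 0 and abs(prev - err) / max(prev, eps) < tol:
            break
        prev = err
    H[zero_rows] = 0.0
    return H


def fit_onmf_transfer(
    E_sc: np.ndarray,
    E_sp: np.ndarray,
    LF: int = 3,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> FactorModel:
    """Reference-only KL-NMF followed by fixed-W transfer to spatial data.

    W and H_sc are learned from ``E_sc`` alone; the gene factors are then
    frozen (bit-identical before/after) and the spatial loadings H_sp are
    obtained by the fixed-W multiplicative update.
    """
    E_sc = _check_nonneg(E_sc, "E_sc")
    E_sp = _check_nonneg(E_sp, "E_sp")
    if E_sc.shape[1] != E_sp.shape[1]:
        raise ValueError("modalities must share the gene set")
    if LF > min(E_sc.shape[0], E_sc.shape[1]):
        raise ValueError(f"LF={LF} exceeds the reference dimensions")
    H_sc, W, obj = kl_nmf(E_sc, LF, max_iter=max_iter, tol=tol)
    H_sp = transfer_loadings(E_sp, W, seed=seed)
    return FactorModel(W, H_sc, H_sp, None, None, 0.0, LF, "onmf", objective=obj)


# ---------------------------------------------------------------------------
# entropy ordering
# ---------------------------------------------------------------------------

def entropy_order(model: FactorModel) -> FactorModel:
    """Sort factors by increasing normalised entropy of the H_sc loadings.

    Each column of H_sc is normalised to sum 1 and its Shannon entropy is
    divided by log2(n_cells), giving values in [0, 1] (0 for a one-hot
    column, 1 for a uniform one). H_sc, H_sp, W and the V terms are permuted
    jointly, so the reconstruction is unchanged.
    """
    H = model.H_sc
    n = H.shape[0]
    ent = np.empty(H.shape[1])
    for i in range(H.shape[1]):
        col = H[:, i]
        tot = col.sum()
        if tot == 0:
            warnings.warn(f"all-zero factor column {i}; entropy set to 1")
            ent[i] = 1.0
            continue
        p = col / tot
        nz = p > 0
        ent[i] = float(-(p[nz] * np.log2(p[nz])).sum() / np.log2(n))
    order = np.argsort(ent, kind="stable")
    model.entropy = ent[order]
    model.H_sc = model.H_sc[:, order]
    model.H_sp = model.H_sp[:, order]
    model.W = model.W[order, :]
    if model.V_sc is not None:
        model.V_sc = model.V_sc[order, :]
    if model.V_sp is not None:
        model.V_sp = model.V_sp[order, :]
    return model


# ---------------------------------------------------------------------------
# ridge covariation regression
# ---------------------------------------------------------------------------

def _ridge_pvalues(X: np.ndarray, y: np.ndarray, coef: np.ndarray, eta: float):
    """Two-tailed t-statistic p-values from the ridge sandwich covariance."""
    n, p = X.shape
    xtx = X.T @ X
    inv = np.linalg.inv(xtx + eta * np.eye(p))
    hat_trace = float(np.trace(X @ inv @ X.T))
    df = max(n - hat_trace, 1.0)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * inv @ xtx @ inv
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return np.clip(pvals, np.finfo(float).tiny, 1.0), tstat, df


def regress_covariation(
    central_type: str,
    factor_models: Dict[str, FactorModel],
    graph: NeighborGraph,
    labels: np.ndarray,
    interaction: InteractionModel,
    cutoff: float = 0.1,
    seed: int = 0,
    eta_grid: Sequence[float] = DEFAULT_ETA_GRID,
) -> pd.DataFrame:
    """Ridge regression of central-cell factors on niche-averaged factors.

    Niche cell types are those with normalised interaction coefficient above
    ``cutoff`` for the central type (and a fitted factor model). For each
    instance of the central type, each niche type's factors are averaged
    over its neighbours of that type; instances without any retained-type
    neighbour are excluded, and a missing single type is imputed at the
    column mean. Response and predictors are standardised; the penalty eta
    is selected from powers of two by leave-one-out negative mean squared
    error. Returns a table with one row per (central factor, niche type,
    niche factor): ridge coefficient alpha, two-tailed p-value, normalised
    score S = alpha / max|alpha|, the count of usable central cells per
    niche type, and the selected eta.
    """
    labels = np.asarray(labels, dtype=object)
    if central_type not in factor_models:
        raise KeyError(f"no factor model for central type {central_type!r}")
    model_k = factor_models[central_type]
    if model_k.sp_cell_idx is None:
        raise ValueError("factor models need sp_cell_idx linking H_sp rows to cells")

    type_list = list(interaction.type_names)
    k_pos = type_list.index(central_type)
    norm_beta = interaction.normalized_beta()[k_pos]
    niche_types = [
        t for j, t in enumerate(type_list)
        if norm_beta[j] > cutoff and t in factor_models
        and factor_models[t].sp_cell_idx is not None
    ]
    columns = ["central_type", "central_factor", "niche_type", "niche_factor",
               "alpha", "p", "S", "n_pairs", "eta"]
    if not niche_types:
        warnings.warn(f"no niche type passes cutoff {cutoff} for {central_type!r}")
        return pd.DataFrame(columns=columns)

    # map spatial cell index -> row of each niche model's H_sp
    row_of = {
        t: {int(c): r for r, c in enumerate(factor_models[t].sp_cell_idx)}
        for t in niche_types
    }
    adj = graph.adjacency
    instances = model_k.sp_cell_idx
    blocks = []  # per niche type: (n_inst, LF_m) with NaN for missing
    for t in niche_types:
        H_m = factor_models[t].H_sp
        block = np.full((len(instances), H_m.shape[1]), np.nan)
        for r, i in enumerate(instances):
            nbrs = [
                row_of[t][int(j)]
                for j in adj.indices[adj.indptr[int(i)]:adj.indptr[int(i) + 1]]
                if labels[j] == t and int(j) in row_of[t] and int(j) != int(i)
            ]
            if nbrs:
                block[r] = H_m[nbrs].mean(axis=0)
        blocks.append(block)

    design = np.hstack(blocks)
    usable = ~np.all(np.isnan(design), axis=1)
    if usable.sum() < 3:
        warnings.warn(f"too few usable instances of {central_type!r}")
        return pd.DataFrame(columns=columns)
    design = design[usable]
    n_pairs_by_type = {
        t: int(np.sum(~np.isnan(blocks[b][usable, 0]))) for b, t in enumerate(niche_types)
    }
    # impute missing type means at the column mean (0 after standardisation)
    col_mean = np.nanmean(design, axis=0)
    nan_mask = np.isnan(design)
    design[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (design - mu) / sd

    n, p = Xs.shape
    etas = np.asarray(sorted(eta_grid), dtype=float)
    if n <= p:
        warnings.warn("fewer instances than predictors; eta floor raised to 1")
        etas = etas[etas >= 1.0]

    H_k = model_k.H_sp[usable]
    rows = []
    col_names = [(t, l) for b, t in enumerate(niche_types)
                 for l in range(factor_models[t].H_sp.shape[1])]
    for i in range(H_k.shape[1]):
        y = H_k[:, i]
        ysd = y.std()
        ys = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
        cv = RidgeCV(alphas=etas, fit_intercept=False, scoring=None)
        cv.fit(Xs, ys)
        eta = float(cv.alpha_)
        coef = cv.coef_
        pvals, _, _ = _ridge_pvalues(Xs, ys, coef, eta)
        amax = np.max(np.abs(coef))
        S = coef / amax if amax > 0 else coef
        for c, (t, l) in enumerate(col_names):
            rows.append((central_type, i, t, l, coef[c], pvals[c], S[c],
                         n_pairs_by_type[t], eta))
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# per-cell-type pipeline
# ---------------------------------------------------------------------------

def scale_genes(E: np.ndarray) -> np.ndarray:
    """Divide each gene by its standard deviation, without centring.

    Keeps the matrix non-negative (required by the factorisations); constant
    genes are left unscaled.
    """
    E = np.asarray(E, dtype=float)
    sd = E.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return E / sd


def fit_factor_models(
    spatial: SpatialDataset,
    reference: ReferenceDataset,
    method: str = "inmf",
    LF: int = 3,
    lam: Optional[float] = None,
    seed: int = 0,
    min_cells: int = 10,
    **fit_kwargs,
) -> Dict[str, FactorModel]:
    """Fit an entropy-ordered factor model for every shared cell type.

    For each type present in both the annotated spatial data and the
    reference, the per-type submatrices are gene-scaled (no centring) and
    factorised with ``method`` ('inmf' with per-type lambda selection when
    ``lam`` is None, or 'onmf' transfer). Types with fewer than
    ``min_cells`` cells in either modality are skipped.
    """
    if spatial.labels is None:
        raise ValueError("spatial dataset must be annotated first")
    sp_dense = spatial.counts.to_dense()
    sc_dense = reference.counts.to_dense()
    shared_types = sorted(
        (set(spatial.labels) & set(reference.cluster_labels)) - {NOT_MAPPED}
    )
    models: Dict[str, FactorModel] = {}
    for t in shared_types:
        sp_idx = np.flatnonzero(spatial.labels == t)
        sc_idx = np.flatnonzero(reference.cluster_labels == t)
        if len(sp_idx) < min_cells or len(sc_idx) < min_cells:
            warnings.warn(f"type {t!r} skipped: too few cells")
            continue
        E_sp = scale_genes(sp_dense[sp_idx])
        E_sc = scale_genes(sc_dense[sc_idx])
        if method == "inmf":
            if lam is None:
                lam_t, path = select_lambda(E_sc, E_sp, LF=LF, seed=seed, **fit_kwargs)
            else:
                lam_t, path = float(lam), []
            model = fit_inmf(E_sc, E_sp, LF=LF, lam=lam_t, seed=seed, **fit_kwargs)
            model.alignment_path = path
        elif method == "onmf":
            model = fit_onmf_transfer(E_sc, E_sp, LF=LF, seed=seed, **fit_kwargs)
        else:
            raise ValueError(f"unknown method {method!r}")
        model.gene_ids = spatial.counts.gene_ids.copy()
        model.sc_cell_idx = sc_idx
        model.sp_cell_idx = sp_idx
        models[t] = entropy_order(model)
    return models
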