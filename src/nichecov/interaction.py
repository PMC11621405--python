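"""Niche-composition classification and the cell-type interaction graph.

For every cell, the local niche is the set of its spatial neighbours
(Delaunay contacts with a distance cutoff, or all cells within a radius R).
Neighbour counts per cell type are converted to enrichment ratios against
the global type frequencies,

    X_ij = Lambda_ij / (f_j * sum_k Lambda_ik),

and an L2-penalised multinomial logistic regression is trained to predict
the central cell's type from these ratios. The averaged cross-fold
coefficients beta quantify which niche types are predictive of each central
type; normalised coefficients above a cutoff define a directed interaction
graph. Domain-level consistency scores and standard annotation metrics
(ARI, per-type Jaccard) are provided for evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree

from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, confusion_matrix, precision_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .core_io import NOT_MAPPED

__all__ = [
    "NeighborGraph",
    "NicheFeatures",
    "InteractionModel",
    "InteractionGraph",
    "DomainScore",
    "build_neighborhoods",
    "enrichment_features",
    "fit_niche_classifier",
    "build_interaction_graph",
    "domain_consistency",
    "evaluate_annotation",
]

DEFAULT_C_GRID = tuple(np.logspace(-4, 4, 9))


@dataclass
class NeighborGraph:
    """Symmetric cell-neighbour adjacency with centroid distances."""

    adjacency: sp.csr_matrix  # (n, n) weights = centroid distance
    mode: str  # 'delaunay_R0' or 'radius_R'
    R: float
    max_dist: float

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        row = self.adjacency.getrow(i)
        return row.indices


@dataclass
class NicheFeatures:
    """Neighbourhood counts and enrichment ratios per labelled cell."""

    Lambda: np.ndarray  # (m, n_types) integer neighbour counts
    X: np.ndarray  # (m, n_types) enrichment ratios
    y: np.ndarray  # (m,) central type index
    f: np.ndarray  # (n_types,) global type frequencies, sums to 1
    type_names: np.ndarray
    cell_index: np.ndarray  # indices into the original dataset
    dropped_no_neighbors: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class InteractionModel:
    """Cross-fold averaged classifier coefficients and diagnostics.

    ``beta[i, j]`` is the averaged coefficient of niche type j for
    predicting central type i; ``beta_sd`` the fold standard deviation.
    ``confusion`` rows (true types) are normalised to 1.
    """

    beta: np.ndarray
    beta_sd: np.ndarray
    intercepts: np.ndarray
    confusion: np.ndarray
    C: float
    folds: int
    type_names: np.ndarray
    class_accuracy: np.ndarray  # per-class mean CV recall ("confidence")

    def normalized_beta(self) -> np.ndarray:
        """Each row divided by its maximum absolute coefficient."""
        out = np.zeros_like(self.beta)
        for i, row in enumerate(self.beta):
            m = np.max(np.abs(row))
            if m > 0:
                out[i] = row / m
        return out

    def coefficients_table(self) -> pd.DataFrame:
        rows = []
        for i, cen in enumerate(self.type_names):
            for j, nic in enumerate(self.type_names):
                rows.append((cen, nic, self.beta[i, j], self.beta_sd[i, j]))
        return pd.DataFrame(rows, columns=["central", "niche", "beta", "beta_sd"])


@dataclass
class InteractionGraph:
    """Directed graph: edge niche -> central where normalised beta > cutoff."""

    graph: nx.DiGraph
    cutoff: float


@dataclass
class DomainScore:
    """Per-(domain, type) enrichment z-scores and observed/expected ratios."""

    Z: np.ndarray  # (domains, types)
    ratio: np.ndarray
    f_dj: np.ndarray
    mu_j: np.ndarray
    sigma_j: np.ndarray
    domain_names: np.ndarray
    type_names: np.ndarray


# ---------------------------------------------------------------------------
# neighbourhoods
# ---------------------------------------------------------------------------

def build_neighborhoods(
    coords: np.ndarray,
    mode: str = "delaunay_R0",
    R: float = 0.0,
    max_dist: float = 100.0,
) -> NeighborGraph:
    """Build the spatial neighbour graph from cell centroids.

    ``delaunay_R0`` keeps Delaunay-triangulation contacts with centroid
    distance <= ``max_dist`` (juxtacrine niches); ``radius_R`` keeps all
    pairs within distance ``R`` (paracrine niches). Distances are in the
    units of ``coords``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if mode == "delaunay_R0":
        if n < 4:
            raise ValueError(f"Delaunay triangulation needs >=4 cells, got {n}")
        try:
            tri = Delaunay(coords)
        except Exception as exc:
            raise ValueError(f"degenerate geometry for {n} cells: {exc}") from exc
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((simplex[a], simplex[b]))
                    pairs.add((i, j))
        pairs = np.array(sorted(pairs), dtype=int)
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d <= max_dist
        pairs, d = pairs[keep], d[keep]
        cutoff_used = max_dist
    elif mode == "radius_R":
        if R <= 0:
            raise ValueError("radius mode needs R > 0")
        tree = cKDTree(coords)
        pairs = tree.query_pairs(R, output_type="ndarray")
        d = (
            np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            if len(pairs)
            else np.array([])
        )
        cutoff_used = R
    else:
        raise ValueError(f"unknown neighbourhood mode: {mode!r}")

    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.concatenate([d, d])
        # zero distances (coincident centroids) still need an explicit edge
        data = np.where(data == 0.0, 1e-300, data)
        adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n))
    return NeighborGraph(adj, mode, R, cutoff_used)


def enrichment_features(graph: NeighborGraph, labels: np.ndarray) -> NicheFeatures:
    """Neighbourhood composition enrichment against global frequencies.

    Cells labelled ``'NM'`` are excluded both as central cells and from the
    neighbour counts. Central cells with no (labelled) neighbours are
    dropped and reported. Types absent from the labelled cells are excluded
    with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    if graph.n_cells != len(labels):
        raise ValueError("labels length does not match graph size")
    labelled = np.array([l is not None and l != NOT_MAPPED for l in labels])
    type_names = np.array(sorted(set(labels[labelled])), dtype=object)
    t_index = {t: i for i, t in enumerate(type_names)}
    n_types = len(type_names)
    f = np.array([np.sum(labels[labelled] == t) for t in type_names], dtype=float)
    if (f == 0).any():
        warnings.warn("types with zero global frequency excluded")
        keep = f > 0
        type_names = type_names[keep]
        t_index = {t: i for i, t in enumerate(type_names)}
        n_types = len(type_names)
        f = f[keep]
    f = f / f.sum()

    cells = np.flatnonzero(labelled)
    Lam = np.zeros((len(cells), n_types), dtype=float)
    adj = graph.adjacency
    for row, i in enumerate(cells):
        for j in adj.indices[adj.indptr[i]:adj.indptr[i + 1]]:
            lab = labels[j]
            if lab is not None and lab != NOT_MAPPED:
                Lam[row, t_index[lab]] += 1

    rowsum = Lam.sum(axis=1)
    has_nbr = rowsum > 0
    dropped = cells[~has_nbr]
    if dropped.size:
        warnings.warn(f"{dropped.size} cells with empty neighbourhoods dropped")
    Lam = Lam[has_nbr]
    rowsum = rowsum[has_nbr]
    X = Lam / (f[None, :] * rowsum[:, None])
    y = np.array([t_index[labels[i]] for i in cells[has_nbr]], dtype=int)
    return NicheFeatures(Lam, X, y, f, type_names, cells[has_nbr], dropped)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def fit_niche_classifier(
    feat: NicheFeatures,
    seed: int = 0,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    folds: int = 5,
    max_iter: int = 2000,
) -> InteractionModel:
    """L2 multinomial logistic regression on standardised enrichment ratios.

    The inverse regularisation strength C is selected by grid search with
    stratified ``folds``-fold cross-validation and balanced class weights.
    Coefficients are then refit per fold at the selected C; ``beta`` is the
    fold mean, ``beta_sd`` the fold standard deviation, and ``confusion``
    the row-normalised mean held-out confusion matrix.
    """
    n_types = len(feat.type_names)
    if n_types < 2:
        raise ValueError("need at least 2 classes")
    class_counts = np.bincount(feat.y, minlength=n_types)
    small = class_counts < folds
    y, X = feat.y, feat.X
    if small.any():
        warnings.warn(
            f"classes with fewer than {folds} members excluded from training: "
            f"{list(feat.type_names[small])}"
        )
        keep = ~np.isin(y, np.flatnonzero(small))
        X, y = X[keep], y[keep]
        if len(np.unique(y)) < 2:
            raise ValueError("fewer than 2 trainable classes")

    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)

    base = LogisticRegression(
        solver="lbfgs",
        class_weight="balanced",
        max_iter=max_iter,
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, {"C": list(C_grid)}, cv=cv)
    search.fit(Xs, y)
    best_c = float(search.best_params_["C"])

    present = np.unique(y)
    coefs, intercepts = [], []
    conf_sum = np.zeros((n_types, n_types))
    for train, test in cv.split(Xs, y):
        clf = LogisticRegression(
            solver="lbfgs", class_weight="balanced",
            max_iter=max_iter, C=best_c,
        )
        clf.fit(Xs[train], y[train])
        coef = np.zeros((n_types, n_types))
        icpt = np.zeros(n_types)
        if len(clf.classes_) == 2 and clf.coef_.shape[0] == 1:
            # binary special case: one coefficient row for classes_[1]
            coef[clf.classes_[1]] = clf.coef_[0]
            coef[clf.classes_[0]] = -clf.coef_[0]
            icpt[clf.classes_[1]] = clf.intercept_[0]
            icpt[clf.classes_[0]] = -clf.intercept_[0]
        else:
            for row, cls in enumerate(clf.classes_):
                coef[cls] = clf.coef_[row]
                icpt[cls] = clf.intercept_[row]
        coefs.append(coef)
        intercepts.append(icpt)
        pred = clf.predict(Xs[test])
        conf_sum += confusion_matrix(y[test], pred, labels=np.arange(n_types))

    beta = np.mean(coefs, axis=0)
    beta_sd = np.std(coefs, axis=0)
    conf = conf_sum / folds
    row_tot = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf_norm = np.where(row_tot > 0, conf / row_tot, 0.0)
    class_acc = np.diag(conf_norm)
    return InteractionModel(
        beta, beta_sd, np.mean(intercepts, axis=0), conf_norm,
        best_c, folds, feat.type_names, class_acc,
    )


def build_interaction_graph(model: InteractionModel, cutoff: float = 0.01) -> InteractionGraph:
    """Directed interaction graph from row-normalised coefficients.

    Each coefficient row is divided by its maximum absolute value; an edge
    niche j -> central i is drawn wherever the normalised coefficient
    exceeds ``cutoff``, with the normalised value as edge weight.
    """
    norm = model.normalized_beta()
    g = nx.DiGraph()
    g.add_nodes_from(model.type_names)
    for i, cen in enumerate(model.type_names):
        for j, nic in enumerate(model.type_names):
            if norm[i, j] > cutoff:
                g.add_edge(nic, cen, weight=float(norm[i, j]))
    return InteractionGraph(g, cutoff)


# ---------------------------------------------------------------------------
# domain consistency and evaluation
# ---------------------------------------------------------------------------

def domain_consistency(
    domain_labels: np.ndarray,
    type_labels: np.ndarray,
    profiles: Optional[np.ndarray] = None,
) -> tuple[DomainScore, Optional[np.ndarray]]:
    """Cell-type enrichment per tissue domain, as z-scores and ratios.

    ``f_dj`` is the frequency of type j among cells of domain d. The
    z-score compares ``f_dj`` to the mean/sd (population sd) of type j
    across domains; domains of identical composition give Z = 0. The ratio
    is observed frequency over the global (expected) frequency.

    If ``profiles`` (rows of per-type scores, e.g. classifier coefficients
    or another method's domain profiles) is given, the Pearson correlation
    of each domain's Z row against every profile row is computed and the
    per-domain maximum returned as "best-match" correlations.
    """
    domain_labels = np.asarray(domain_labels, dtype=object)
    type_labels = np.asarray(type_labels, dtype=object)
    if len(domain_labels) != len(type_labels):
        raise ValueError("every cell needs a domain and a type")
    domains = np.array(sorted(set(domain_labels)), dtype=object)
    types = np.array(sorted(set(type_labels)), dtype=object)
    f_dj = np.zeros((len(domains), len(types)))
    for d, dom in enumerate(domains):
        sel = domain_labels == dom
        tot = sel.sum()
        for j, t in enumerate(types):
            f_dj[d, j] = np.sum(type_labels[sel] == t) / tot
    mu = f_dj.mean(axis=0)
    sigma = f_dj.std(axis=0)  # population sd across domains
    Z = np.zeros_like(f_dj)
    ok = sigma > 0
    if not ok.all():
        warnings.warn("types with zero variance across domains get Z = 0")
    Z[:, ok] = (f_dj[:, ok] - mu[ok]) / sigma[ok]
    global_f = np.array([np.mean(type_labels == t) for t in types])
    ratio = f_dj / global_f[None, :]
    score = DomainScore(Z, ratio, f_dj, mu, sigma, domains, types)

    best = None
    if profiles is not None:
        profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
        best = np.empty(len(domains))
        for d in range(len(domains)):
            corrs = []
            for p in profiles:
                if np.std(Z[d]) == 0 or np.std(p) == 0:
                    corrs.append(0.0)
                else:
                    corrs.append(np.corrcoef(Z[d], p)[0, 1])
            best[d] = max(corrs)
    return score, best


def evaluate_annotation(pred_labels: np.ndarray, truth_labels: np.ndarray) -> dict:
    """ARI, mean per-type Jaccard (over matched names) and weighted precision."""
    pred = np.asarray(pred_labels, dtype=object)
    truth = np.asarray(truth_labels, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("label vectors must cover the same cells")
    ari = adjusted_rand_score(truth.astype(str), pred.astype(str))
    shared = sorted(set(truth) & set(pred) - {NOT_MAPPED})
    if not shared:
        raise ValueError("no shared type names between prediction and truth")
    jac = []
    for t in shared:
        a = pred == t
        b = truth == t
        union = np.logical_or(a, b).sum()
        jac.append(np.logical_and(a, b).sum() / union if union else 0.0)
    wprec = precision_score(
        truth.astype(str), pred.astype(str), average="weighted", zero_division=0
    )
    return {"ARI": float(ari), "Jaccard": float(np.mean(jac)), "weighted_precision": float(wprec)}


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_interaction(
    coords: np.ndarray,
    labels: np.ndarray,
    radius: float = 0.0,
    max_dist: float = 100.0,
    cutoff: float = 0.01,
    seed: int = 0,
) -> tuple[InteractionModel, InteractionGraph, NicheFeatures]:
    """Neighbourhoods -> enrichment -> classifier -> interaction graph.

    ``radius=0`` selects Delaunay juxtacrine niches (with ``max_dist``
    pruning); any positive radius selects the paracrine radius mode.
    """
    mode = "delaunay_R0" if radius == 0 else "radius_R"
    graph = build_neighborhoods(coords, mode=mode, R=radius, max_dist=max_dist)
    feat = enrichment_features(graph, labels)
    model = fit_niche_classifier(feat, seed=seed)
    igraph = build_interaction_graph(model, cutoff=cutoff)
    return model, igraph, feat
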