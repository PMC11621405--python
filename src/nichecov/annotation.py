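"""Label transfer from an scRNA-seq reference to spatial data.

The annotation workflow is: variance-stabilised normalisation of both
modalities on the shared gene set (analytic negative-binomial Pearson
residuals), PCA into a common number of components, soft mutual-nearest-
neighbour anchor detection between the two embeddings, pruning of dispersed
anchors with the help of a low-resolution Leiden "guide" clustering of the
spatial data, and finally iterative majority-vote propagation of labels from
anchors to the remaining cells. Cells that cannot be assigned receive the
sentinel label ``'NM'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

import igraph as ig
import leidenalg
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .core_io import CountMatrix, NOT_MAPPED, ReferenceDataset, SpatialDataset

__all__ = [
    "ResidualMatrix",
    "Embedding",
    "AnchorSet",
    "normalize_residuals",
    "embed_top_pcs",
    "embed_joint_pcs",
    "guide_cluster",
    "find_anchors",
    "filter_anchors",
    "iterative_annotate",
    "annotate",
]

# anchor status codes
STATUS_ANCHOR = "anchor"
STATUS_CONFUSED = "confused_resolved"
STATUS_ITERATIVE = "iterative"
STATUS_NM = "NM"
STATUS_NONE = ""


@dataclass
class ResidualMatrix:
    """Variance-stabilised residuals, clipped to ``+/- clip_bound``."""

    values: np.ndarray
    clip_bound: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    dropped_genes: list = field(default_factory=list)


@dataclass
class Embedding:
    """Per-cell coordinates in the top principal components."""

    values: np.ndarray
    n_pcs: int
    standardized: bool
    explained_variance: np.ndarray


@dataclass
class AnchorSet:
    """Per-query-cell assignment state during label transfer.

    ``labels[i]`` is the assigned cell type (``None`` while unassigned,
    ``'NM'`` for unmappable cells); ``status[i]`` records how the assignment
    was obtained.
    """

    labels: np.ndarray  # object array; None = unassigned
    status: np.ndarray  # object array of status codes
    guide_labels: np.ndarray  # int array, per query cell
    params: dict = field(default_factory=dict)

    def n_assigned(self) -> int:
        return int(sum(l is not None and l != NOT_MAPPED for l in self.labels))

    def copy(self) -> "AnchorSet":
        return AnchorSet(self.labels.copy(), self.status.copy(), self.guide_labels.copy(), dict(self.params))


# ---------------------------------------------------------------------------
# normalisation and embedding
# ---------------------------------------------------------------------------

def normalize_residuals(counts: CountMatrix, theta: float = 100.0) -> ResidualMatrix:
    """Analytic NB Pearson residuals with fixed overdispersion.

    For gene g in cell c with observed count x_gc, the expected count under
    the null of no biological variation is mu_gc = depth_c * p_g, where p_g
    is the gene's share of all transcripts. The residual

        r_gc = (x_gc - mu_gc) / sqrt(mu_gc + mu_gc^2 / theta)

    is clipped to +/- sqrt(n_cells). Genes with zero total count are dropped
    and recorded.
    """
    x = counts.to_dense()
    if x.sum() == 0:
        raise ValueError("cannot normalise an all-zero count matrix")
    gene_tot = x.sum(axis=0)
    keep = gene_tot > 0
    dropped = list(counts.gene_ids[~keep])
    x = x[:, keep]
    gene_tot = gene_tot[keep]
    depth = x.sum(axis=1)
    p = gene_tot / gene_tot.sum()
    mu = np.outer(depth, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = (x - mu) / np.sqrt(mu + mu * mu / theta)
    res[~np.isfinite(res)] = 0.0
    bound = np.sqrt(x.shape[0])
    np.clip(res, -bound, bound, out=res)
    return ResidualMatrix(res, bound, counts.gene_ids[keep], counts.cell_ids.copy(), dropped)


def embed_top_pcs(res: ResidualMatrix, n_pcs: int = 50, seed: int = 0) -> Embedding:
    """Project residuals onto the top principal components and standardise.

    Components are ordered by decreasing explained variance. If ``n_pcs``
    exceeds the matrix rank it is reduced with a warning. Each output column
    is standardised to mean 0 / sd 1.
    """
    x = res.values
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank bound {max_pcs}; reduced")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    z = pca.fit_transform(x)
    sd = z.std(axis=0)
    mean = z.mean(axis=0)
    out = np.zeros_like(z)
    ok = sd > 1e-12
    out[:, ok] = (z[:, ok] - mean[ok]) / sd[ok]
    return Embedding(out, n_pcs, True, pca.explained_variance_)


def embed_joint_pcs(
    res_q: ResidualMatrix,
    res_r: ResidualMatrix,
    n_pcs: int = 50,
    seed: int = 0,
) -> tuple[Embedding, Embedding]:
    """Embed both modalities into a common principal-component space.

    The loadings are fitted on the row-wise concatenation of the two
    residual matrices (same shared-gene columns), so query and reference
    cells live in one coordinate system and cross-modal distances are
    meaningful; each modality's projection is then standardised per column.
    """
    if res_q.values.shape[1] != res_r.values.shape[1]:
        raise ValueError("residual matrices must share the gene columns")
    stacked = np.vstack([res_q.values, res_r.values])
    max_pcs = min(stacked.shape[0] - 1, stacked.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank bound {max_pcs}; reduced")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pca.fit(stacked)
    out = []
    for res in (res_q, res_r):
        z = pca.transform(res.values)
        sd = z.std(axis=0)
        mean = z.mean(axis=0)
        std = np.zeros_like(z)
        ok = sd > 1e-12
        std[:, ok] = (z[:, ok] - mean[ok]) / sd[ok]
        out.append(Embedding(std, n_pcs, True, pca.explained_variance_))
    return out[0], out[1]


def guide_cluster(
    emb: Embedding,
    resolution: float = 0.4,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a KNN graph of the embedding.

    Low resolution (default 0.4) yields coarse "guide" clusters used to
    prune dispersed anchors. Deterministic under a fixed seed.
    """
    n = emb.values.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells for guide clustering, got {n}")
    adj = kneighbors_graph(emb.values, n_neighbors, mode="connectivity", include_self=False)
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _knn_sets(source: np.ndarray, target: np.ndarray, k: int) -> np.ndarray:
    """Indices (n_source, k) of each source point's KNN among target points."""
    tree = cKDTree(target)
    _, idx = tree.query(source, k=k)
    if k == 1:
        idx = idx[:, None]
    return idx


def _majority_vote(labels, weights=None):
    """Return (winner, tied) for a list of labels with optional weights."""
    scores: dict = {}
    for i, lab in enumerate(labels):
        w = 1.0 if weights is None else weights[i]
        scores[lab] = scores.get(lab, 0.0) + w
    if not scores:
        return None, False
    best = max(scores.values())
    winners = [lab for lab, s in scores.items() if s == best]
    if len(winners) > 1:
        return None, True
    return winners[0], False


def find_anchors(
    d_q: Embedding,
    d_r: Embedding,
    ref_labels: np.ndarray,
    guide: np.ndarray,
    K: int = 50,
    weighted: bool = False,
    nm_fraction_trigger: float = 0.10,
) -> AnchorSet:
    """Soft mutual-nearest-neighbour anchor detection.

    A query cell q and reference cell r are mutual nearest neighbours (MNN)
    iff r is among the K reference-side KNN of q and q is among the K
    query-side KNN of r. Query cells whose MNN partners carry exactly one
    reference label become anchors with that label. Cells with partners of
    multiple labels are "confused" and resolved by majority vote over
    non-confused anchors among their K query-side neighbours, after pruning
    voters to the cell's guide cluster; unresolved ties give ``'NM'``.

    If ``weighted`` is set, or the fraction of ``'NM'`` cells exceeds
    ``nm_fraction_trigger``, votes are weighted by inverse distance, which
    avoids ties.
    """
    nq, nr = d_q.values.shape[0], d_r.values.shape[0]
    if K >= nq or K >= nr:
        raise ValueError(f"K={K} must be smaller than both modalities ({nq}, {nr})")
    if d_q.values.shape[1] != d_r.values.shape[1]:
        raise ValueError("embeddings must share the number of components")
    ref_labels = np.asarray(ref_labels, dtype=object)
    guide = np.asarray(guide, dtype=int)

    q_knn = _knn_sets(d_q.values, d_r.values, K)  # query -> reference
    r_knn = _knn_sets(d_r.values, d_q.values, K)  # reference -> query

    a = sp.csr_matrix(
        (np.ones(nq * K, bool), (np.repeat(np.arange(nq), K), q_knn.ravel())),
        shape=(nq, nr),
    )
    b = sp.csr_matrix(
        (np.ones(nr * K, bool), (np.repeat(np.arange(nr), K), r_knn.ravel())),
        shape=(nr, nq),
    )
    mutual = a.multiply(b.T).tocsr()  # (nq, nr) MNN incidence

    labels = np.full(nq, None, dtype=object)
    status = np.full(nq, STATUS_NONE, dtype=object)
    confused_idx = []
    for q in range(nq):
        partners = mutual.indices[mutual.indptr[q]:mutual.indptr[q + 1]]
        if partners.size == 0:
            continue
        labs = set(ref_labels[partners])
        if len(labs) == 1:
            labels[q] = next(iter(labs))
            status[q] = STATUS_ANCHOR
        else:
            confused_idx.append(q)

    anchors = AnchorSet(labels, status, guide, {"K": K, "weighted": weighted})
    if confused_idx:
        _resolve_confused(anchors, d_q, confused_idx, K, weighted, nm_fraction_trigger)
    return anchors


def _resolve_confused(anchors, d_q, confused_idx, K, weighted, nm_trigger):
    """Assign confused anchors by (optionally weighted) neighbour vote."""
    def run(use_weights):
        tree = cKDTree(d_q.values)
        dist, idx = tree.query(d_q.values[confused_idx], k=K + 1)
        for row, q in enumerate(confused_idx):
            nbrs = [(j, d) for j, d in zip(idx[row], dist[row]) if j != q]
            voters = [
                (anchors.labels[j], d)
                for j, d in nbrs
                if anchors.status[j] == STATUS_ANCHOR
                and anchors.guide_labels[j] == anchors.guide_labels[q]
            ]
            if not voters:
                anchors.labels[q] = NOT_MAPPED
                anchors.status[q] = STATUS_NM
                continue
            labs = [v[0] for v in voters]
            w = [1.0 / max(v[1], 1e-12) for v in voters] if use_weights else None
            winner, tied = _majority_vote(labs, w)
            if winner is None:
                anchors.labels[q] = NOT_MAPPED
                anchors.status[q] = STATUS_NM
            else:
                anchors.labels[q] = winner
                anchors.status[q] = STATUS_CONFUSED

    run(weighted)
    if not weighted:
        nm_frac = np.mean([anchors.labels[q] == NOT_MAPPED for q in confused_idx]) if confused_idx else 0.0
        frac_total = nm_frac * len(confused_idx) / max(len(anchors.labels), 1)
        if frac_total > nm_trigger:
            warnings.warn(
                f"{frac_total:.1%} of cells unmapped after majority vote; "
                "retrying confused anchors with inverse-distance weighting"
            )
            run(True)


def filter_anchors(anchors: AnchorSet, guide: Optional[np.ndarray] = None, r: float = 0.15) -> AnchorSet:
    """Remove dispersed anchors.

    For each cell-type label, anchors falling in a guide cluster that holds
    less than a fraction ``r`` of that label's anchors are removed (their
    state reverts to unassigned). The anchor set never grows.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("dispersion parameter r must lie in [0, 1]")
    out = anchors.copy()
    guide = out.guide_labels if guide is None else np.asarray(guide, dtype=int)
    is_anchor = np.array([s in (STATUS_ANCHOR, STATUS_CONFUSED) for s in out.status])
    for lab in set(out.labels[is_anchor]):
        sel = is_anchor & (out.labels == lab)
        total = sel.sum()
        clusters, counts = np.unique(guide[sel], return_counts=True)
        bad_clusters = set(clusters[counts / total < r])
        for q in np.flatnonzero(sel):
            if guide[q] in bad_clusters:
                out.labels[q] = None
                out.status[q] = STATUS_NONE
    out.params["dispersion_r"] = r
    return out


def iterative_annotate(
    anchors: AnchorSet,
    d_q: Embedding,
    guide: Optional[np.ndarray] = None,
    K: int = 50,
    max_iter: int = 3,
    weighted: bool = False,
) -> np.ndarray:
    """Propagate labels from anchors to all remaining query cells.

    In each of ``max_iter`` rounds (default 3), every unassigned cell takes
    the majority label of currently assigned cells among its K nearest query
    neighbours. The vote is accepted only if the winning label's most
    frequent guide cluster matches the cell's own guide cluster. Exact ties
    give ``'NM'`` (unless ``weighted``, where inverse-distance weights break
    them). Newly labelled cells vote in the next round. Cells still
    unassigned after the final round are ``'NM'``.
    """
    work = anchors.copy()
    guide = work.guide_labels if guide is None else np.asarray(guide, dtype=int)
    n = len(work.labels)
    assigned = np.array([l is not None and l != NOT_MAPPED for l in work.labels])
    if not assigned.any():
        raise ValueError("no anchors available for iterative annotation")
    tree = cKDTree(d_q.values)
    k_query = min(K + 1, n)

    for _ in range(max_iter):
        todo = np.flatnonzero([l is None for l in work.labels])
        if todo.size == 0:
            break
        # modal guide cluster per label, from current assignments
        label_guide_mode: dict = {}
        for lab in set(work.labels[assigned]):
            gl = guide[assigned & (work.labels == lab)]
            vals, cnts = np.unique(gl, return_counts=True)
            label_guide_mode[lab] = vals[np.argmax(cnts)]
        dist, idx = tree.query(d_q.values[todo], k=k_query)
        new_labels = {}
        for row, q in enumerate(todo):
            voters = [
                (work.labels[j], d)
                for j, d in zip(np.atleast_1d(idx[row]), np.atleast_1d(dist[row]))
                if j != q and assigned[j]
            ][:K]
            if not voters:
                continue
            labs = [v[0] for v in voters]
            w = [1.0 / max(v[1], 1e-12) for v in voters] if weighted else None
            winner, tied = _majority_vote(labs, w)
            if tied:
                new_labels[q] = (NOT_MAPPED, STATUS_NM)
            elif winner is not None and label_guide_mode.get(winner) == guide[q]:
                new_labels[q] = (winner, STATUS_ITERATIVE)
        if not new_labels:
            break
        for q, (lab, stat) in new_labels.items():
            work.labels[q] = lab
            work.status[q] = stat
            if lab != NOT_MAPPED:
                assigned[q] = True

    final = work.labels.copy()
    for q in range(n):
        if final[q] is None:
            final[q] = NOT_MAPPED
            work.status[q] = STATUS_NM
    anchors.labels = work.labels
    anchors.status = work.status
    return np.asarray(final, dtype=object)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def annotate(
    spatial: SpatialDataset,
    reference: ReferenceDataset,
    K: int = 50,
    dispersion: float = 0.15,
    guide_resolution: float = 0.4,
    n_pcs: int = 50,
    max_iter: int = 3,
    weighted: bool = False,
    min_count: int = 5,
    theta: float = 100.0,
    seed: int = 0,
) -> tuple[SpatialDataset, AnchorSet]:
    """Full annotation pipeline; returns a labelled copy of the spatial data.

    Both modalities are restricted to shared genes, normalised independently,
    embedded into ``n_pcs`` standardised principal components, anchored by
    soft MNN, pruned with a Leiden guide clustering at ``guide_resolution``,
    and completed by iterative majority voting.
    """
    from .core_io import align_shared_genes

    spc, ref = align_shared_genes(spatial, reference, min_count=min_count)
    res_q = normalize_residuals(spc.counts, theta=theta)
    res_r = normalize_residuals(ref.counts, theta=theta)
    # shared genes may differ after zero-total dropping; re-intersect
    shared = [g for g in res_r.gene_ids if g in set(res_q.gene_ids)]
    qi = {g: i for i, g in enumerate(res_q.gene_ids)}
    ri = {g: i for i, g in enumerate(res_r.gene_ids)}
    res_q.values = res_q.values[:, [qi[g] for g in shared]]
    res_r.values = res_r.values[:, [ri[g] for g in shared]]

    n_pcs_eff = min(n_pcs, res_q.values.shape[0] - 1, res_r.values.shape[0] - 1, len(shared))
    d_q, d_r = embed_joint_pcs(res_q, res_r, n_pcs_eff, seed=seed)
    guide = guide_cluster(d_q, resolution=guide_resolution, seed=seed)
    anchors = find_anchors(d_q, d_r, ref.cluster_labels, guide, K=K, weighted=weighted)
    anchors = filter_anchors(anchors, guide, r=dispersion)
    labels = iterative_annotate(anchors, d_q, guide, K=K, max_iter=max_iter, weighted=weighted)
    labelled = SpatialDataset(spc.counts, spc.coords, labels)
    return labelled, anchors
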