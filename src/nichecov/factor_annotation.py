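"""Transcriptome-wide annotation of latent factors and LR-pair nomination.

Factors are learned on the shared gene set only; to interpret them, every
gene of the full reference transcriptome is associated with each factor by
Spearman correlation (or cosine similarity) of its expression with the
factor's cell loadings. For a pair of covarying factors in a sender and a
receiver cell type, candidate ligand-receptor pairs are those expressed in
a minimum fraction of cells on both sides and correlated (in absolute
value) with the respective factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import CountMatrix

__all__ = [
    "FactorGeneAssociation",
    "LRDatabase",
    "associate_genes",
    "top_factor_genes",
    "select_lr_pairs",
    "load_lr_database",
    "toy_lr_database",
]


@dataclass
class FactorGeneAssociation:
    """Genes-by-factors association scores for one cell type."""

    values: np.ndarray  # (n_genes, LF)
    gene_ids: np.ndarray
    method: str  # 'spearman' or 'cosine'
    cell_type: str = ""
    constant_genes: np.ndarray = field(default_factory=lambda: np.array([], object))

    def score(self, gene: str, factor: int) -> float:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(gene)
        return float(self.values[idx[0], factor])


@dataclass
class LRDatabase:
    """Ligand-receptor pairs with a source tag; duplicates are rejected."""

    pairs: list  # of (ligand, receptor, source)

    def __post_init__(self) -> None:
        seen = set()
        for lig, rec, _src in self.pairs:
            if (lig, rec) in seen:
                raise ValueError(f"duplicate ligand-receptor pair ({lig}, {rec})")
            seen.add((lig, rec))

    def __len__(self) -> int:
        return len(self.pairs)


def load_lr_database(path) -> LRDatabase:
    """Read a 3-column TSV (ligand, receptor, source)."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise ValueError("LR database TSV needs 3 columns: ligand, receptor, source")
    return LRDatabase([tuple(r[:3]) for r in df.itertuples(index=False)])


def toy_lr_database() -> LRDatabase:
    """The small synthetic LR database shipped with the package."""
    here = Path(__file__).parent / "data" / "lr_pairs_toy.tsv"
    return load_lr_database(here)


# ---------------------------------------------------------------------------
# gene-factor association
# ---------------------------------------------------------------------------

def associate_genes(
    counts: CountMatrix,
    H: np.ndarray,
    method: str = "spearman",
    cell_type: str = "",
) -> FactorGeneAssociation:
    """Associate every gene with every factor across the cells of one type.

    ``counts`` holds the full-transcriptome expression of the cells whose
    loadings are the rows of ``H``. Spearman correlates ranked expression
    with ranked loadings; cosine takes the normalised dot product (in
    [0, 1] for non-negative data). Constant genes get score 0 and are
    flagged.
    """
    E = counts.to_dense()
    if E.shape[0] != H.shape[0]:
        raise ValueError("H rows must match the number of cells")
    if E.shape[0] < 3:
        raise ValueError("need at least 3 cells for association")
    if method == "spearman":
        rE = rankdata(E, axis=0)
        rH = rankdata(H, axis=0)
        rE = rE - rE.mean(axis=0)
        rH = rH - rH.mean(axis=0)
        sdE = np.sqrt((rE ** 2).sum(axis=0))
        sdH = np.sqrt((rH ** 2).sum(axis=0))
        const = sdE == 0
        sdE[const] = 1.0
        vals = (rE / sdE).T @ (rH / np.where(sdH == 0, 1.0, sdH))
        vals[const] = 0.0
        const_h = sdH == 0
        vals[:, const_h] = 0.0
    elif method == "cosine":
        nE = np.linalg.norm(E, axis=0)
        nH = np.linalg.norm(H, axis=0)
        const = nE == 0
        vals = (E / np.where(nE == 0, 1.0, nE)).T @ (H / np.where(nH == 0, 1.0, nH))
        vals[const] = 0.0
    else:
        raise ValueError(f"unknown association method {method!r}")
    flagged = counts.gene_ids[const]
    if flagged.size:
        warnings.warn(f"{flagged.size} constant genes assigned score 0")
    return FactorGeneAssociation(vals, counts.gene_ids.copy(), method, cell_type, flagged)


def top_factor_genes(
    assoc: FactorGeneAssociation,
    factor: int,
    k: int = 20,
    sign: int = 1,
) -> list:
    """The k most positively (sign=+1) or negatively (sign=-1) associated
    genes for one factor, ties broken lexicographically by gene id."""
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    n = len(assoc.gene_ids)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} genes; truncated")
        k = n
    scores = sign * assoc.values[:, factor]
    order = sorted(range(n), key=lambda i: (-scores[i], str(assoc.gene_ids[i])))
    return [assoc.gene_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# ligand-receptor candidate selection
# ---------------------------------------------------------------------------

def select_lr_pairs(
    db: LRDatabase,
    sender_counts: CountMatrix,
    sender_assoc: FactorGeneAssociation,
    sender_factor: int,
    receiver_counts: CountMatrix,
    receiver_assoc: FactorGeneAssociation,
    receiver_factor: int,
    f_lr: float = 0.1,
    c_lr: float = 0.1,
    sender_type: str = "",
    receiver_type: str = "",
) -> pd.DataFrame:
    """Filter candidate LR pairs for a covarying (sender, receiver) factor pair.

    A pair is retained if the ligand is expressed (raw count > 0) in at
    least ``f_lr`` of sender cells, the receptor in at least ``f_lr`` of
    receiver cells, and both have absolute factor association >= ``c_lr``
    with the respective covarying factor. All four metrics are reported.
    Pairs whose genes are missing from the expression data are skipped.
    """
    s_genes = {g: i for i, g in enumerate(sender_counts.gene_ids)}
    r_genes = {g: i for i, g in enumerate(receiver_counts.gene_ids)}
    sE = sender_counts.to_dense()
    rE = receiver_counts.to_dense()
    rows = []
    for lig, rec, _src in db.pairs:
        if lig not in s_genes or rec not in r_genes:
            continue
        frac_l = float(np.mean(sE[:, s_genes[lig]] > 0))
        frac_r = float(np.mean(rE[:, r_genes[rec]] > 0))
        try:
            corr_l = sender_assoc.score(lig, sender_factor)
            corr_r = receiver_assoc.score(rec, receiver_factor)
        except KeyError:
            continue
        if (frac_l >= f_lr and frac_r >= f_lr
                and abs(corr_l) >= c_lr and abs(corr_r) >= c_lr):
            rows.append((lig, rec, sender_type, receiver_type,
                         frac_l, frac_r, corr_l, corr_r))
    return pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "sender_type", "receiver_type",
                 "frac_ligand", "frac_receptor",
                 "corr_ligand_factor", "corr_receptor_factor"],
    )
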