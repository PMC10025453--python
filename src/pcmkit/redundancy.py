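"""Inter-module redundancy: overlap similarity and exemplar clustering.

Overlap between two modules is the modified Jaccard score
S(A,B) = |G_A ∩ G_B| / min(|G_A|, |G_B|) — the intersection normalized by
the smaller set, so a module nested inside a larger one scores 1. Modules
are collapsed to exemplars with affinity propagation on the similarity
matrix, run within module categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation

from pcmkit.io import GeneModule, ModuleCatalog

logger = logging.getLogger(__name__)

__all__ = ["modified_jaccard", "similarity_matrix", "ExemplarClustering",
           "cluster_exemplars", "cluster_by_category"]


def modified_jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def similarity_matrix(catalog: ModuleCatalog) -> pd.DataFrame:
    """Full symmetric modified-Jaccard matrix over a catalog."""
    if len(catalog) < 2:
        raise ValueError("need at least 2 modules")
    gene_sets = []
    for m in catalog:
        genes = m.genes if catalog.universe is None else m.genes & catalog.universe
        if not genes:
            raise ValueError(f"module {m.name!r} is empty in the universe")
        gene_sets.append(frozenset(genes))
    n = len(gene_sets)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = modified_jaccard(gene_sets[i], gene_sets[j])
    return pd.DataFrame(s, index=catalog.names, columns=catalog.names)


@dataclass
class ExemplarClustering:
    cluster_of: pd.Series  # module name -> cluster id
    exemplars: list[str]  # cluster id -> exemplar module name
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def cluster_exemplars(
    sim: pd.DataFrame,
    damping: float = 0.9,
    max_iter: int = 1000,
    seed: int = 0,
    preference: float | None = None,
) -> ExemplarClustering:
    """Affinity-propagation exemplar clustering of a similarity matrix.

    Preference defaults to the median off-diagonal similarity. If message
    passing does not converge, a greedy leader clustering at similarity
    0.5 is used instead and the result flagged (``converged=False``).
    Modules with zero similarity to their assigned exemplar carry no
    overlap evidence and are split off as singleton clusters (guards the
    degenerate all-tied case where the preference equals the off-diagonal
    similarities and message passing collapses everything).
    """
    s = sim.to_numpy(dtype=float)
    if s.shape[0] != s.shape[1] or not np.allclose(s, s.T):
        raise ValueError("similarity matrix must be square and symmetric")
    names = list(sim.index)
    if preference is None:
        off = s[~np.eye(len(names), dtype=bool)]
        preference = float(np.median(off)) if off.size else 0.0
    ap = AffinityPropagation(
        affinity="precomputed", damping=damping, max_iter=max_iter,
        convergence_iter=100, preference=preference, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = ap.fit_predict(s)
    if (labels < 0).any() or len(ap.cluster_centers_indices_) == 0:
        logger.warning("affinity propagation did not converge; greedy fallback")
        return _greedy_leader(sim, threshold=0.5)
    exemplars = [names[i] for i in ap.cluster_centers_indices_]
    cluster_of = pd.Series(labels, index=names)
    # no-overlap members become their own exemplars
    for i, name in enumerate(names):
        ex_idx = ap.cluster_centers_indices_[labels[i]]
        if i != ex_idx and s[i, ex_idx] <= 0:
            exemplars.append(name)
            cluster_of[name] = len(exemplars) - 1
    return ExemplarClustering(cluster_of, exemplars, True)


def _greedy_leader(sim: pd.DataFrame, threshold: float) -> ExemplarClustering:
    names = list(sim.index)
    leaders: list[str] = []
    assign = {}
    for name in names:
        for ci, leader in enumerate(leaders):
            if sim.loc[name, leader] >= threshold:
                assign[name] = ci
                break
        else:
            assign[name] = len(leaders)
            leaders.append(name)
    return ExemplarClustering(pd.Series(assign), leaders, False)


def cluster_by_category(
    catalog: ModuleCatalog,
    damping: float = 0.9,
    max_iter: int = 1000,
    seed: int = 0,
) -> dict[str, ExemplarClustering]:
    """Cluster modules within each category (DNA motifs with DNA motifs,
    linear RNA with linear RNA, and so on)."""
    out: dict[str, ExemplarClustering] = {}
    by_cat: dict[str, list[GeneModule]] = {}
    for m in catalog:
        by_cat.setdefault(m.category.value, []).append(m)
    for cat, mods in by_cat.items():
        if len(mods) < 2:
            out[cat] = ExemplarClustering(
                pd.Series({mods[0].name: 0}), [mods[0].name], True)
            continue
        sub = ModuleCatalog(mods, catalog.universe)
        out[cat] = cluster_exemplars(similarity_matrix(sub), damping, max_iter, seed)
    return out
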