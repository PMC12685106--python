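"""Joint lipid-protein correlation by cosine distance and clustering.

Modalities are normalized separately — lipid rows by each patient's total
lipid intensity, protein columns by each protein's maximum — then every
pair of species vectors (taken across the shared patients) is compared by
cosine distance.  The combined matrix (lipid-lipid, protein-protein and
lipid-protein blocks) feeds an agglomerative dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError


@dataclass
class CrossCorrResult:
    species_names: list[str]       # lipids first, then proteins
    modality: list[str]            # per-species tag {"lipid", "protein"}
    distance_matrix: np.ndarray    # cosine distances, symmetric, zero diagonal
    similarity_matrix: np.ndarray  # 1 - distance


def normalize_modalities(
    lipid_matrix: pd.DataFrame, protein_matrix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lipids: divide each patient row by its total; proteins: divide each
    column by its maximum (every antibody lands on (0, 1])."""
    totals = lipid_matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[int(np.argmax((totals <= 0).to_numpy()))]
        raise ValidationError(f"patient {bad!r}: non-positive total lipid intensity")
    maxima = protein_matrix.max(axis=0)
    if (maxima <= 0).any():
        bad = maxima.index[int(np.argmax((maxima <= 0).to_numpy()))]
        raise ValidationError(f"protein {bad!r}: non-positive maximum")
    return lipid_matrix.div(totals, axis=0), protein_matrix.div(maxima, axis=1)


def cosine_distance_matrix(
    lipid_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    lipids: list | None = None,
    proteins: list | None = None,
    normalize: bool = True,
) -> CrossCorrResult:
    """Pairwise cosine distances over the combined species set.

    Each species is the vector of its values across the patients shared by
    both modalities; distance(u, v) = 1 - u.v / (|u||v|).
    """
    shared = lipid_matrix.index.intersection(protein_matrix.index)
    if len(shared) == 0:
        raise ValidationError("no shared patients between modalities")
    L = lipid_matrix.loc[shared]
    P = protein_matrix.loc[shared]
    if normalize:
        L, P = normalize_modalities(L, P)
    if lipids is not None:
        L = L[list(lipids)]
    if proteins is not None:
        P = P[list(proteins)]
    names = [str(c) for c in L.columns] + [str(c) for c in P.columns]
    modality = ["lipid"] * L.shape[1] + ["protein"] * P.shape[1]
    V = np.column_stack([L.to_numpy(dtype=np.float64), P.to_numpy(dtype=np.float64)])
    norms = np.linalg.norm(V, axis=0)
    if np.any(norms == 0):
        bad = names[int(np.argmin(norms))]
        raise ValidationError(f"species {bad!r} has zero norm across patients")
    U = V / norms
    sim = np.clip(U.T @ U, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    return CrossCorrResult(
        species_names=names,
        modality=modality,
        distance_matrix=dist,
        similarity_matrix=sim,
    )


def hierarchical_cluster(
    distance_matrix: np.ndarray,
    species_names: list[str] | None = None,
    linkage: str = "average",
):
    """Agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix, the deterministic leaf order
    (species indices), and a Newick string with merge heights as branch
    lengths.  Allowed linkages: centroid, average, complete.
    """
    D = np.asarray(distance_matrix, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if linkage not in ("centroid", "average", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    n = D.shape[0]
    names = species_names or [f"sp{i}" for i in range(n)]
    if n == 1:
        return np.empty((0, 4)), [0], f"{names[0]};"
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaf_order = hierarchy.leaves_list(Z).tolist()
    newick = _to_newick(Z, names)
    return Z, leaf_order, newick


def _to_newick(Z: np.ndarray, names: list[str]) -> str:
    n = len(names)
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        bl = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{bl:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{bl:.6g}"

    assert n >= 2
    return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"
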