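"""Similarity computation: GIP kernels, functional similarity, and fusion.

Two complementary similarity sources are computed for each entity type:

* the Gaussian interaction profile (GIP) kernel, which compares the binary
  association profiles of two entities with a Gaussian of their squared
  Euclidean distance, the bandwidth normalized by the mean squared profile
  norm so that the kernel adapts to association density; and
* a best-match-average (BMA) functional similarity over annotated gene
  (disease side) or protein (microbe side) sets scored through a normalized
  log-likelihood-score network.

The two are fused conditionally: where no functional evidence exists the
GIP value is used as-is, otherwise a convex combination weighted by ``mu``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .datatypes import AssociationMatrix, SimilarityMatrix

__all__ = [
    "GeneNet",
    "gip_bandwidth",
    "gip_similarity",
    "normalize_lls",
    "bma_functional_similarity",
    "functional_similarity_matrix",
    "integrate",
]


class GeneNet:
    """Sparse symmetric gene-gene (or protein-protein) score map in [0, 1].

    Self-scores are defined as 1 (a gene is maximally associated with
    itself); pairs absent from the map score 0 (no evidence).
    """

    def __init__(self, scores: Mapping[tuple[str, str], float] | None = None):
        self._scores: dict[frozenset, float] = {}
        if scores:
            for (a, b), s in scores.items():
                self.set_score(a, b, s)

    def set_score(self, a: str, b: str, score: float) -> None:
        if a == b:
            return  # self-score fixed at 1
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score for ({a}, {b}) outside [0, 1]: {score}")
        self._scores[frozenset((a, b))] = score

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._scores.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        for key, s in self._scores.items():
            a, b = sorted(key)
            yield (a, b), s


def gip_bandwidth(profiles: Iterable[np.ndarray], lambda_prime: float = 1.0) -> float:
    """Normalized GIP kernel bandwidth.

    lambda = lambda' / (mean over profiles of ||profile||^2).  Raises if
    every profile is all-zero, since the mean squared norm is then zero and
    the kernel bandwidth is undefined.
    """
    P = np.asarray(list(profiles), dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("need at least one profile, all of equal length")
    mean_sq = float(np.mean((P ** 2).sum(axis=1)))
    if mean_sq == 0.0:
        raise ValueError("bandwidth undefined: no known associations")
    return float(lambda_prime) / mean_sq


def gip_similarity(
    A: AssociationMatrix, axis: str, lambda_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel similarity matrix.

    ``axis='microbe'`` compares column profiles of A (each microbe's vector
    of known disease links); ``axis='disease'`` compares row profiles.
    K(i, j) = exp(-lambda * ||p_i - p_j||^2) with the normalized bandwidth
    from :func:`gip_bandwidth`.
    """
    if axis == "microbe":
        profiles = A.values.T
        ids = A.microbe_ids
    elif axis == "disease":
        profiles = A.values
        ids = A.disease_ids
    else:
        raise ValueError("axis must be 'microbe' or 'disease'")
    lam = gip_bandwidth(profiles, lambda_prime)
    sq_norms = (profiles ** 2).sum(axis=1)
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i.p_j
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    K = np.exp(-lam * sq_dist)
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)  # exact symmetry
    return SimilarityMatrix(K, ids, kind="gip")


def normalize_lls(raw_scores: Mapping[tuple[str, str], float]) -> GeneNet:
    """Min-max normalize raw log-likelihood scores to [0, 1].

    Normalization is over the observed off-diagonal scores; if all raw
    scores are equal the degenerate range maps every score to 1.
    Self-pairs are ignored on input (self-score is fixed at 1).
    """
    off_diag = {k: float(v) for k, v in raw_scores.items() if k[0] != k[1]}
    if not off_diag:
        raise ValueError("need at least one gene pair score")
    vals = np.array(list(off_diag.values()))
    if not np.isfinite(vals).all():
        raise ValueError("non-finite raw score")
    lo, hi = vals.min(), vals.max()
    net = GeneNet()
    for (a, b), v in off_diag.items():
        net.set_score(a, b, 1.0 if hi == lo else (v - lo) / (hi - lo))
    return net


def bma_functional_similarity(
    annotation: Mapping[str, set],
    net: GeneNet,
    entity_a: str,
    entity_b: str,
) -> float:
    """Best-match-average similarity between two entities' gene sets.

    Each gene in one set contributes its best score against the other set;
    the two directed sums are pooled and divided by the total gene count.
    An unannotated entity yields 0, signalling absent functional evidence
    (the fusion step then falls back to the GIP value).
    """
    genes_a = annotation.get(entity_a)
    genes_b = annotation.get(entity_b)
    if not genes_a or not genes_b:
        return 0.0
    ga, gb = sorted(genes_a), sorted(genes_b)
    best_a = [max(net.score(x, y) for y in gb) for x in ga]
    best_b = [max(net.score(x, y) for x in ga) for y in gb]
    return (sum(best_a) + sum(best_b)) / (len(ga) + len(gb))


def functional_similarity_matrix(
    entity_ids: Iterable[str],
    annotation: Mapping[str, set],
    net: GeneNet,
) -> SimilarityMatrix:
    """Pairwise BMA functional similarity with diagonal 1 for annotated
    entities (identical sets are maximally similar) and 0 rows/columns for
    unannotated ones."""
    ids = tuple(entity_ids)
    n = len(ids)
    F = np.zeros((n, n))
    for i in range(n):
        if ids[i] in annotation:
            F[i, i] = 1.0
        for j in range(i + 1, n):
            s = bma_functional_similarity(annotation, net, ids[i], ids[j])
            F[i, j] = F[j, i] = s
    return SimilarityMatrix(F, ids, kind="functional")


def integrate(
    gip: SimilarityMatrix, functional: SimilarityMatrix, mu: float
) -> SimilarityMatrix:
    """Conditional fusion of GIP and functional similarity.

    Entry-wise: where the functional similarity is 0 the GIP value is kept,
    otherwise mu * gip + (1 - mu) * functional.
    """
    if gip.entity_ids != functional.entity_ids:
        raise ValueError("entity labels of the two similarity matrices differ")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    G, F = gip.values, functional.values
    fused = np.where(F == 0.0, G, mu * G + (1.0 - mu) * F)
    fused = 0.5 * (fused + fused.T)
    return SimilarityMatrix(fused, gip.entity_ids, kind="integrated")
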