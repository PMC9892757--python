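"""End-to-end fit/predict pipeline built from the individual stages.

Every cross-validation round goes through :func:`fit_predict`, which
recomputes the GIP similarities, the fusion, and the heterogeneous graph
from the *training* association matrix only - the held-out cells can never
leak into similarity profiles or the graph structure.
"""

from __future__ import annotations

from .config import RunConfig
from .datatypes import (
    AssociationMatrix,
    HeteroGraph,
    SampleSets,
    ScoreMatrix,
    SimilarityMatrix,
)
from .hetnet import build_hetnet, normalize_block
from .model import ModelState, predict, train
from .similarity import gip_similarity, integrate

__all__ = ["build_graph", "fit_predict", "fit"]


def build_graph(
    A_train: AssociationMatrix,
    config: RunConfig,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
) -> HeteroGraph:
    """Similarities -> fusion -> normalized blocks -> heterogeneous graph.

    ``fd``/``fm`` are optional precomputed functional similarity matrices for
    diseases and microbes; without them the integrated similarity reduces to
    the pure GIP kernel (the fusion's fallback branch applied everywhere).
    """
    gip_d = gip_similarity(A_train, "disease", config.lambda_prime)
    gip_m = gip_similarity(A_train, "microbe", config.lambda_prime)
    DS = integrate(gip_d, fd, config.mu) if fd is not None else gip_d
    MS = integrate(gip_m, fm, config.mu) if fm is not None else gip_m
    DS_star = normalize_block(DS, config.sim_norm)
    MS_star = normalize_block(MS, config.sim_norm)
    return build_hetnet(DS_star, MS_star, A_train, config.beta)


def fit(
    A_train: AssociationMatrix,
    config: RunConfig,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    seed: int | None = None,
    samples: SampleSets | None = None,
) -> tuple[ModelState, HeteroGraph]:
    """Train on ``A_train``; ``samples`` restricts the loss to a subset of
    cells (cold-start protocols exclude the held-out rows/columns so the
    model is not trained to score them as negatives)."""
    G = build_graph(A_train, config, fd=fd, fm=fm)
    state = train(G, A_train, config.model_config(seed=seed), samples=samples)
    return state, G


def fit_predict(
    A_train: AssociationMatrix,
    config: RunConfig,
    fd: SimilarityMatrix | None = None,
    fm: SimilarityMatrix | None = None,
    seed: int | None = None,
    samples: SampleSets | None = None,
) -> ScoreMatrix:
    state, G = fit(A_train, config, fd=fd, fm=fm, seed=seed, samples=samples)
    return predict(state, G)
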