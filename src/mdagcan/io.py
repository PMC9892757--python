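"""Readers and writers for the package's TSV interchange formats.

All files are UTF-8 tab-separated text; lines starting with ``#`` are
comments.  TSV rather than CSV because microbe names routinely contain
commas.  Readers reject malformed input with the offending line number
rather than silently coercing; every writer produces files its paired
reader parses losslessly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssociationMatrix, SimilarityMatrix
from .similarity import GeneNet

logger = logging.getLogger("mdagcan")

__all__ = [
    "read_association_table",
    "write_association_table",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_annotation_table",
    "read_gene_net",
    "write_gene_net",
    "write_annotation_table",
]

_HEADER_WORDS = {"disease", "disease_id", "microbe", "microbe_id", "entity",
                 "entity_id", "gene", "gene_id", "score", "protein",
                 "protein_id"}


def _data_lines(path, directives: dict | None = None) -> list[tuple[int, list[str]]]:
    """Split a TSV into (lineno, fields), skipping blanks and comments.

    Comment lines of the form ``#key<TAB>v1<TAB>v2...`` are collected into
    ``directives`` when a dict is passed (used to preserve label order
    across edge-list round trips)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                if directives is not None and "\t" in line:
                    key, *values = line.lstrip()[1:].split("\t")
                    directives[key.strip()] = [v for v in values if v]
                continue
            out.append((lineno, line.split("\t")))
    return out


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_WORDS for f in fields)


def read_association_table(path) -> AssociationMatrix:
    """Read a two-column ``disease_id<TAB>microbe_id`` edge list.

    A header row is auto-detected; labels are ordered by first appearance
    unless ``#diseases``/``#microbes`` directive comments fix the order
    (the writer emits them so round trips are exact even for entities
    whose labels never co-occur in row-major order); duplicate pairs are
    collapsed with a logged warning.
    """
    directives: dict = {}
    lines = _data_lines(path, directives)
    if not lines:
        raise ValueError(f"{path}: empty association table")
    if _looks_like_header(lines[0][1]):
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")
    pairs: list[tuple[str, str]] = []
    for lineno, fields in lines:
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}:{lineno}: expected disease<TAB>microbe")
        pairs.append((fields[0].strip(), fields[1].strip()))
    diseases = list(directives.get("diseases", []))
    microbes = list(directives.get("microbes", []))
    n_dup = 0
    for d, m in pairs:
        if d not in diseases:
            diseases.append(d)
        if m not in microbes:
            microbes.append(m)
    values = np.zeros((len(diseases), len(microbes)))
    d_idx = {d: i for i, d in enumerate(diseases)}
    m_idx = {m: j for j, m in enumerate(microbes)}
    for d, m in pairs:
        i, j = d_idx[d], m_idx[m]
        if values[i, j] == 1:
            n_dup += 1
        values[i, j] = 1.0
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association pairs", path, n_dup)
    return AssociationMatrix(values, tuple(diseases), tuple(microbes))


def write_association_table(A: AssociationMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#diseases\t" + "\t".join(A.disease_ids) + "\n")
        fh.write("#microbes\t" + "\t".join(A.microbe_ids) + "\n")
        fh.write("disease_id\tmicrobe_id\n")
        for i, d in enumerate(A.disease_ids):
            for j, m in enumerate(A.microbe_ids):
                if A.values[i, j] == 1:
                    fh.write(f"{d}\t{m}\n")


def read_similarity_matrix(path, kind: str = "functional") -> SimilarityMatrix:
    """Read a labeled square TSV (first row and first column are ids).

    Asymmetries are symmetrized by averaging, with a warning when the
    discrepancy exceeds 1e-8; entries are clipped to [0, 1] with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square, got {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    V = df.to_numpy(dtype=float)
    asym = np.abs(V - V.T).max()
    if asym > 1e-8:
        logger.warning("%s: asymmetric by %.3g; symmetrizing by averaging", path, asym)
    V = 0.5 * (V + V.T)
    if V.min() < 0.0 or V.max() > 1.0:
        logger.warning("%s: entries outside [0, 1]; clipping", path)
        V = np.clip(V, 0.0, 1.0)
    return SimilarityMatrix(V, tuple(str(x) for x in df.index), kind=kind)


def write_similarity_matrix(S: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(S.values, index=list(S.entity_ids), columns=list(S.entity_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation_table(path) -> dict[str, set]:
    """Read ``entity_id<TAB>gene_id`` rows into entity -> gene-set."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty annotation table")
    if _looks_like_header(lines[0][1]):
        lines = lines[1:]
    annotation: dict[str, set] = {}
    for lineno, fields in lines:
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}:{lineno}: expected entity<TAB>gene")
        annotation.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return annotation


def write_annotation_table(annotation: dict[str, set], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tgene_id\n")
        for entity in annotation:
            for gene in sorted(annotation[entity]):
                fh.write(f"{entity}\t{gene}\n")


def read_gene_net(path, normalized: bool = True) -> GeneNet | dict:
    """Read ``gene_id<TAB>gene_id<TAB>score`` rows.

    With ``normalized=True`` scores must already lie in [0, 1] and a
    :class:`GeneNet` is returned; otherwise the raw score map is returned
    for :func:`mdagcan.similarity.normalize_lls`.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty gene network table")
    if _looks_like_header(lines[0][1]):
        lines = lines[1:]
    raw: dict[tuple[str, str], float] = {}
    for lineno, fields in lines:
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected gene<TAB>gene<TAB>score")
        try:
            score = float(fields[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from None
        raw[(fields[0].strip(), fields[1].strip())] = score
    if not normalized:
        return raw
    net = GeneNet()
    for (a, b), s in raw.items():
        net.set_score(a, b, s)
    return net


def write_gene_net(net: GeneNet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgene_id\tscore\n")
        for (a, b), s in sorted(net.items()):
            fh.write(f"{a}\t{b}\t{s:.17g}\n")


def write_hetnet_debug(G, path) -> None:
    """Debug dump of the heterogeneous adjacency as labeled TSV."""
    df = pd.DataFrame(G.adjacency, index=list(G.node_ids), columns=list(G.node_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")
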