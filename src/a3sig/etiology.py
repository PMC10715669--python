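"""Pentanucleotide-profile clustering and A3A/A3B etiology assignment.

Samples are represented by 48-channel pentanucleotide frequency profiles of
C>T mutations at TCH (TCA/TCC/TCT; TCG excluded to avoid overlap with
spontaneous methyl-C deamination), clustered hierarchically with Euclidean
distance, and cut into k groups labelled by anchor samples of known
etiology (A3A-like, A3B-like, non-APOBEC).  A sample's position between the
two enzymes is summarized by a two-anchor mixture weight: the YTCW fraction
of its APOBEC3 signature mutations linearly interpolated between the A3B
anchor (0.472) and the A3A anchor (0.727), clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .signature_stats import PENTA_CT_CHANNELS, motif_fractions, penta_ct_channel
from .variant_io import OrientedContext

#: Default two-anchor YTCW fractions (A3B-like and A3A-like endpoints).
DEFAULT_ANCHOR_A3B = 0.472
DEFAULT_ANCHOR_A3A = 0.727


@dataclass
class ClusteringMatrix:
    samples: list[str]
    channels: list[str]
    frequencies: np.ndarray  # rows sum to 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, index=self.samples, columns=self.channels)


def build_clustering_matrix(
    contexts: Iterable[OrientedContext],
) -> ClusteringMatrix:
    """48-channel row-normalized pentanucleotide matrix of C>T at TCH.

    C>G mutations and TCG contexts are excluded; samples with zero qualifying
    mutations are dropped with a warning.
    """
    import logging

    index = {c: i for i, c in enumerate(PENTA_CT_CHANNELS)}
    counts: dict[str, np.ndarray] = {}
    order: list[str] = []
    for ctx in contexts:
        if ctx.flagged:
            continue
        ch = penta_ct_channel(ctx)
        if ch is None:
            continue
        sid = ctx.mutation.sample_id
        if sid not in counts:
            counts[sid] = np.zeros(len(PENTA_CT_CHANNELS), dtype=np.int64)
            order.append(sid)
        counts[sid][index[ch]] += 1
    kept, rows = [], []
    for sid in order:
        total = counts[sid].sum()
        if total == 0:
            logging.getLogger(__name__).warning(
                "sample %s has no qualifying C>T TCH mutations; excluded", sid
            )
            continue
        kept.append(sid)
        rows.append(counts[sid] / total)
    if not rows:
        raise ValueError("no samples with qualifying mutations")
    return ClusteringMatrix(kept, list(PENTA_CT_CHANNELS), np.vstack(rows))


@dataclass
class Dendrogram:
    samples: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format
    linkage: str
    distance: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.samples[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.samples, labels.tolist()))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.samples[node.id]
            return f"({walk(node.left)},{walk(node.right)})"

        return walk(tree) + ";"


def hierarchical_cluster(
    matrix: ClusteringMatrix, linkage: str = "complete"
) -> Dendrogram:
    """Hierarchical clustering of row profiles with Euclidean distance."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    dists = pdist(matrix.frequencies, metric="euclidean")
    z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(list(matrix.samples), z, linkage, "euclidean")


@dataclass
class EtiologyCall:
    sample_id: str
    group: str  # 'A3A-like' | 'A3B-like' | 'non-APOBEC'
    f_YTCW: float | None = None
    w: float | None = None
    a_A3B: float = DEFAULT_ANCHOR_A3B
    a_A3A: float = DEFAULT_ANCHOR_A3A


_GROUP_BY_CONDITION = {
    "A3A": "A3A-like",
    "A3B": "A3B-like",
    "non-APOBEC": "non-APOBEC",
}


def assign_etiology(
    dend: Dendrogram,
    anchors: Mapping[str, str],
    k: int = 3,
) -> list[EtiologyCall]:
    """Label dendrogram groups by the anchor samples they contain.

    ``anchors`` maps anchor sample ids to one of 'A3A', 'A3B', 'non-APOBEC'.
    The tree is cut into ``k`` groups; each group inherits the label of its
    anchors.  A group containing anchors of different conditions, or an
    anchor condition split across groups at this ``k``, raises an ambiguity
    error.
    """
    for cond in ("A3A", "A3B", "non-APOBEC"):
        if cond not in set(anchors.values()):
            raise ValueError(f"anchor condition {cond!r} missing")
    unknown = set(anchors) - set(dend.samples)
    if unknown:
        raise ValueError(f"anchor samples not in dendrogram: {sorted(unknown)}")
    cut = dend.cut(k)
    group_cond: dict[int, str] = {}
    cond_group: dict[str, int] = {}
    for sid, cond in anchors.items():
        g = cut[sid]
        if g in group_cond and group_cond[g] != cond:
            raise ValueError(
                f"ambiguous cut: group {g} contains anchors {group_cond[g]} and {cond}"
            )
        if cond in cond_group and cond_group[cond] != g:
            raise ValueError(f"ambiguous cut: anchor condition {cond} split across groups")
        group_cond[g] = cond
        cond_group[cond] = g
    calls: list[EtiologyCall] = []
    for sid in dend.samples:
        g = cut[sid]
        if g not in group_cond:
            raise ValueError(
                f"group {g} contains no anchor sample; increase anchors or change k"
            )
        calls.append(EtiologyCall(sid, _GROUP_BY_CONDITION[group_cond[g]]))
    return calls


def assign_etiology_nearest_anchor(
    matrix: ClusteringMatrix,
    anchor_profiles: Mapping[str, np.ndarray],
) -> list[EtiologyCall]:
    """Cosine nearest-anchor assignment for cohorts without cluster structure.

    ``anchor_profiles`` maps condition ('A3A'/'A3B'/'non-APOBEC') to a
    48-channel profile.
    """
    from .signature_stats import cosine_similarity

    calls = []
    for sid, row in zip(matrix.samples, matrix.frequencies):
        best = max(
            anchor_profiles.items(), key=lambda kv: cosine_similarity(row, kv[1])
        )
        calls.append(EtiologyCall(sid, _GROUP_BY_CONDITION[best[0]]))
    return calls


def a3_mixture_weight(
    f_YTCW: float,
    a_A3B: float = DEFAULT_ANCHOR_A3B,
    a_A3A: float = DEFAULT_ANCHOR_A3A,
) -> float:
    """Two-anchor mixture weight: 0 = fully A3B-like, 1 = fully A3A-like.

    Linear interpolation of the YTCW fraction between the anchors, clamped
    to [0, 1].
    """
    if not a_A3A > a_A3B:
        raise ValueError("anchors must satisfy a_A3A > a_A3B")
    return float(min(1.0, max(0.0, (f_YTCW - a_A3B) / (a_A3A - a_A3B))))


def etiology_calls(
    contexts_by_sample: Mapping[str, Sequence[OrientedContext]],
    anchors: Mapping[str, str],
    k: int = 3,
    a_A3B: float = DEFAULT_ANCHOR_A3B,
    a_A3A: float = DEFAULT_ANCHOR_A3A,
    linkage: str = "complete",
) -> list[EtiologyCall]:
    """Full etiology pipeline: matrix, clustering, group labels, mixture weights.

    The group comes from the anchor-labelled k-cut of the C>T pentanucleotide
    dendrogram; the YTCW fraction and mixture weight are computed on the
    APOBEC3 signature set (C>T and C>G at TCW) of each sample.
    """
    all_ctx = [c for ctxs in contexts_by_sample.values() for c in ctxs]
    matrix = build_clustering_matrix(all_ctx)
    dend = hierarchical_cluster(matrix, linkage=linkage)
    calls = assign_etiology(dend, anchors, k=k)
    by_id = {c.sample_id: c for c in calls}
    out: list[EtiologyCall] = []
    for sid, ctxs in contexts_by_sample.items():
        if sid not in by_id:
            continue
        base = by_id[sid]
        try:
            f = motif_fractions(ctxs).f_YTCW
            w = a3_mixture_weight(f, a_A3B, a_A3A)
        except ValueError:
            f, w = None, None
        out.append(EtiologyCall(sid, base.group, f, w, a_A3B, a_A3A))
    return out
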