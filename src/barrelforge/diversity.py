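"""Conformational clustering of fragments and backbone-diversity estimation.

Per-segment fragment conformations are clustered by greedy leader clustering
at an RMSD threshold (the field's standard way to count conformationally
unique backbones); the combinatorial diversity of the family is the product
over segments of cluster counts — every cluster representative of one segment
can in principle be recombined with every representative of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .family_db import ConformationDB, Fragment, fragment_rmsd


@dataclass
class ClusterAssignment:
    segment_name: str
    threshold: float
    labels: list[int]  # cluster id per fragment, in input order
    representatives: dict[int, Fragment]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_segment(
    fragments: list[Fragment],
    threshold: float,
    sort_by_source: bool = True,
) -> ClusterAssignment:
    """Greedy leader clustering of one segment's fragments.

    A fragment joins the first cluster whose representative (founder) lies
    within ``threshold`` Å local CA RMSD, else founds a new cluster.
    Fragments with different length profiles are never co-clustered (an
    indel is a different backbone by definition).  Input order is fixed to
    sorted source_id for determinism unless ``sort_by_source`` is False.
    """
    if not fragments:
        raise ValueError("cluster_segment needs at least one fragment")
    order = sorted(range(len(fragments)), key=lambda i: fragments[i].source_id) if sort_by_source \
        else list(range(len(fragments)))
    labels = [-1] * len(fragments)
    reps: dict[int, Fragment] = {}
    rep_order: list[int] = []
    for i in order:
        f = fragments[i]
        for cid in rep_order:
            rep = reps[cid]
            if rep.length_profile != f.length_profile:
                continue
            if fragment_rmsd(rep, f) <= threshold:
                labels[i] = cid
                break
        else:
            cid = len(rep_order)
            reps[cid] = f
            rep_order.append(cid)
            labels[i] = cid
    return ClusterAssignment(fragments[0].segment_name, threshold, labels, reps)


def cluster_db(db: ConformationDB, threshold: float = 1.0) -> dict[str, ClusterAssignment]:
    """Cluster every sampled segment of a conformation database."""
    return {name: cluster_segment(db.fragments[name], threshold) for name in db.segment_names}


def diversity_estimate(assignments: dict[str, ClusterAssignment] | list[ClusterAssignment]) -> tuple[int, float]:
    """Combinatorial backbone count: product of per-segment cluster counts.

    Returns (exact integer count, log10 of it)."""
    if isinstance(assignments, dict):
        assignments = list(assignments.values())
    if not assignments:
        raise ValueError("diversity_estimate needs at least one segment assignment")
    total = 1
    for a in assignments:
        total *= a.n_clusters
    return total, math.log10(total)
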