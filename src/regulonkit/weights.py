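"""Edge weights from precomputed motif-binding scores.

Raw motif occupancy / best-match scores (computed elsewhere — motif
scanning itself is out of scope) are shifted by a pseudocount and
max-normalized within a group: either all targets of a TF (``per_tf``) or
all regulators of a gene (``per_gene``).  Normalized weights lie in
(0, 1] with exactly one weight of 1 per group.  Low-weight edges can then
be pruned by a global weight quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from regulonkit.mor import RegulonNetwork


@dataclass(frozen=True)
class RawBindingScore:
    """A non-negative raw binding score for one TF–gene pair."""

    tf: str
    target: str
    score: float

    def __post_init__(self):
        if not np.isfinite(self.score) or self.score < 0:
            raise ValueError(f"score must be finite and >= 0, got {self.score}")


def normalize_weights(
    scores: Iterable[RawBindingScore],
    pseudocount: float = 1.0,
    mode: str = "per_tf",
) -> dict:
    """Pseudocount-shift and max-normalize binding scores into weights.

    ``weight = (score + pseudocount) / max_group(score + pseudocount)``
    where the group is the TF's targets (``per_tf``) or the gene's
    regulators (``per_gene``).  Returns ``{(tf, target): weight}``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if mode not in ("per_tf", "per_gene"):
        raise ValueError(f"mode must be 'per_tf' or 'per_gene', got {mode!r}")
    scores = list(scores)
    group_max: dict = {}
    for s in scores:
        g = s.tf if mode == "per_tf" else s.target
        shifted = s.score + pseudocount
        group_max[g] = max(group_max.get(g, 0.0), shifted)
    out: dict = {}
    for s in scores:
        g = s.tf if mode == "per_tf" else s.target
        out[(s.tf, s.target)] = (s.score + pseudocount) / group_max[g]
    return out


def apply_weights(network: RegulonNetwork, weight_table: dict) -> RegulonNetwork:
    """Attach normalized weights to a signed network; unmatched edges drop.

    The edge sign is kept; weight magnitudes modulate the univariate-model
    predictor as ``x = sign × weight``.
    """
    edges = []
    for e in network.edges:
        w = weight_table.get((e.tf, e.target))
        if w is not None:
            edges.append(replace(e, weight=w))
    meta = dict(network.metadata)
    meta["weighted"] = True
    return RegulonNetwork(edges=edges, metadata=meta)


def prune_by_quantile(network: RegulonNetwork, q: float) -> RegulonNetwork:
    """Remove edges with weight strictly below the global q-quantile.

    ``q = 0`` is the identity.  The quantile is taken over all edge
    weights in the network (a per-TF variant would prune within each
    regulon instead; globally matches the pruning of a single pooled
    weight distribution).
    """
    if not 0 <= q < 1:
        raise ValueError(f"q must be in [0, 1), got {q}")
    if q == 0 or not network.edges:
        return network
    weights = np.array([e.weight for e in network.edges])
    cut = float(np.quantile(weights, q))
    edges = [e for e in network.edges if e.weight >= cut]
    meta = dict(network.metadata)
    meta["pruned_quantile"] = q
    return RegulonNetwork(edges=edges, metadata=meta)
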