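"""Mode-of-regulation assignment: the sign-decision cascade.

Every TF–gene interaction receives a sign (+1 activating, −1 repressing)
from the first stage of an ordered cascade that resolves it:

1. ``pmid`` — prevalence of PMIDs annotated with a specific mode: more
   activation PMIDs than repression PMIDs gives +1, the reverse −1; a tie
   (including 0–0) leaves the edge undetermined and falls through.
2. ``regulon_majority`` — the TF is classified as an activator or repressor
   from the strict majority of its own PMID-signed edges; undetermined
   edges of that TF inherit the class sign.  Requires at least one
   PMID-signed edge; ties fall through.
3. ``prior_knowledge`` — TF-level role votes from GO classification,
   UniProt keywords, effector-domain characterization, and the KRAB-domain
   flag (a repressor vote).  The TF gets a role only when at least one
   non-abstaining vote exists and all votes agree.  This stage is
   implemented but excluded from the default cascade, where it was found
   to reduce benchmark recovery of perturbed TFs.

Edges unresolved by every stage get ``default_sign`` (default +1,
activating — the majority mode among literature-annotated edges).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from regulonkit.evidence import AggregatedInteraction
from regulonkit.regulators import PriorRoles, TFClassification

DEFAULT_STRATEGY = ("pmid", "regulon_majority")
KNOWN_STAGES = frozenset({"pmid", "regulon_majority", "prior_knowledge"})

PROVENANCE_VALUES = frozenset({"pmid", "regulon_majority", "prior_knowledge", "default"})


@dataclass(frozen=True)
class SignedEdge:
    """A signed, weighted TF→target edge with sign provenance."""

    tf: str
    target: str
    sign: int
    weight: float = 1.0
    provenance: str = "default"

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class RegulonNetwork:
    """Signed, weighted TF→target network.

    ``metadata`` records how the network was produced (sign-assignment
    strategy, seed, simulated gene universe, ...).
    """

    edges: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if (e.tf, e.target) in seen:
                raise ValueError(f"duplicate edge {(e.tf, e.target)}")
            seen.add((e.tf, e.target))

    @property
    def tfs(self) -> list:
        out, seen = [], set()
        for e in self.edges:
            if e.tf not in seen:
                seen.add(e.tf)
                out.append(e.tf)
        return out

    def regulon(self, tf: str) -> list:
        return [e for e in self.edges if e.tf == tf]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class MorSummary:
    """Network-level summary of the assigned modes of regulation."""

    n_tfs: int
    n_edges: int
    frac_activating: float
    frac_repressing: float
    tf_role_fractions: dict  # pure_activator / pure_repressor / dual
    provenance_counts: dict


def sign_from_pmids(interaction: AggregatedInteraction):
    """Sign by PMID prevalence: +1, −1, or None when tied (incl. 0–0)."""
    n_act = len(interaction.pmids_activation)
    n_rep = len(interaction.pmids_repression)
    if n_act > n_rep:
        return 1
    if n_rep > n_act:
        return -1
    return None


def classify_tf_from_regulon(pmid_signs: Sequence[int]):
    """TF role from the strict majority of its PMID-signed edges.

    Returns ``"activator"``, ``"repressor"``, or None on a tie or when no
    PMID-signed edge exists.
    """
    counts = Counter(pmid_signs)
    if counts[1] > counts[-1]:
        return "activator"
    if counts[-1] > counts[1]:
        return "repressor"
    return None


def classify_tf_from_prior(prior: PriorRoles):
    """TF role from prior-knowledge votes; unanimous non-abstaining votes win.

    GO role, UniProt role and effector role each vote their value unless
    ``unknown`` (abstain); a KRAB domain votes repressor.  Missing sources
    abstain rather than veto.
    """
    votes = [
        r for r in (prior.go_role, prior.uniprot_role, prior.effector_role)
        if r != "unknown"
    ]
    if prior.krab:
        votes.append("repressor")
    if votes and all(v == votes[0] for v in votes):
        return votes[0]
    return None


def assign_mor(
    interactions: Iterable[AggregatedInteraction],
    classification: TFClassification | None = None,
    strategy: Sequence[str] = DEFAULT_STRATEGY,
    default_sign: int = 1,
) -> RegulonNetwork:
    """Run the sign-decision cascade over aggregated interactions.

    Each edge gets the sign from the first stage that resolves it, with the
    matching provenance; edges unresolved by every stage get
    ``default_sign`` with provenance ``"default"``.  The regulon-majority
    stage always uses PMID-stage results computed on this same input,
    regardless of whether ``pmid`` precedes it in the cascade.
    """
    strategy = tuple(strategy)
    unknown = set(strategy) - KNOWN_STAGES
    if unknown:
        raise ValueError(f"unknown cascade stages: {sorted(unknown)}")
    if len(set(strategy)) != len(strategy):
        raise ValueError("cascade stages must not repeat")
    if default_sign not in (1, -1):
        raise ValueError("default_sign must be +1 or -1")
    if "prior_knowledge" in strategy and classification is None:
        raise ValueError("prior_knowledge stage requires a TFClassification")

    interactions = list(interactions)
    pmid_signs = {i.key: sign_from_pmids(i) for i in interactions}

    tf_regulon_role: dict = {}
    if "regulon_majority" in strategy:
        by_tf: dict = {}
        for inter in interactions:
            s = pmid_signs[inter.key]
            if s is not None:
                by_tf.setdefault(inter.tf, []).append(s)
        tf_regulon_role = {tf: classify_tf_from_regulon(s) for tf, s in by_tf.items()}

    role_sign = {"activator": 1, "repressor": -1}
    edges = []
    for inter in interactions:
        sign, provenance = None, None
        for stage in strategy:
            if stage == "pmid":
                sign = pmid_signs[inter.key]
            elif stage == "regulon_majority":
                role = tf_regulon_role.get(inter.tf)
                sign = role_sign.get(role)
            elif stage == "prior_knowledge":
                role = classify_tf_from_prior(classification.priors_of(inter.tf))
                sign = role_sign.get(role)
            if sign is not None:
                provenance = stage
                break
        if sign is None:
            sign, provenance = default_sign, "default"
        edges.append(SignedEdge(tf=inter.tf, target=inter.target, sign=sign,
                                provenance=provenance))
    return RegulonNetwork(
        edges=edges,
        metadata={"strategy": list(strategy), "default_sign": default_sign},
    )


def summarize_network(network: RegulonNetwork) -> MorSummary:
    """Count edges and TF roles; a TF is dual iff it has edges of both signs."""
    if not network.edges:
        raise ValueError("cannot summarize an empty network")
    n_edges = len(network.edges)
    n_act = sum(1 for e in network.edges if e.sign == 1)
    tf_signs: dict = {}
    prov = Counter(e.provenance for e in network.edges)
    for e in network.edges:
        tf_signs.setdefault(e.tf, set()).add(e.sign)
    n_tfs = len(tf_signs)
    roles = Counter(
        "dual" if signs == {1, -1} else ("pure_activator" if signs == {1} else "pure_repressor")
        for signs in tf_signs.values()
    )
    return MorSummary(
        n_tfs=n_tfs,
        n_edges=n_edges,
        frac_activating=n_act / n_edges,
        frac_repressing=(n_edges - n_act) / n_edges,
        tf_role_fractions={
            k: roles.get(k, 0) / n_tfs
            for k in ("pure_activator", "pure_repressor", "dual")
        },
        provenance_counts=dict(prov),
    )
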