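"""Aggregation of multi-source literature evidence for TF–gene interactions.

Each resource in a regulatory-interaction meta-collection asserts TF–gene
links, optionally annotated with a mode of regulation (activation or
repression) and supported by PubMed identifiers (PMIDs).  This module
harmonizes gene symbols, merges evidence between dimeric complexes (AP1,
NFKB) and their monomer constituents, and collapses all per-resource records
into one interaction per (TF, target) pair with deduplicated PMID sets split
by asserted mode.

A PMID counts as evidence for an interaction only once, no matter how many
resources curated it.  The single exception: when different resources assert
the *same* PMID with *different* modes, the PMID is kept in both mode sets,
so that it contributes to both sides when the sign is later decided by
prevalence.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

MOR_VALUES = frozenset({"activation", "repression", "unknown"})


@dataclass(frozen=True)
class EvidenceRecord:
    """One resource's assertion of a TF–gene link.

    Parameters
    ----------
    tf
        Regulator symbol; either a gene symbol or a complex name (AP1, NFKB).
    target
        Target gene symbol.
    resource
        Identifier of the asserting resource.
    pmids
        PubMed identifiers supporting the assertion; may be empty.  Stored
        as strings, no validation against PubMed is attempted.
    mor_annotation
        Per-record mode-of-regulation annotation: ``"activation"``,
        ``"repression"`` or ``"unknown"``.
    """

    tf: str
    target: str
    resource: str
    pmids: frozenset = frozenset()
    mor_annotation: str = "unknown"

    def __post_init__(self):
        if self.mor_annotation not in MOR_VALUES:
            raise ValueError(
                f"mor_annotation must be one of {sorted(MOR_VALUES)}, "
                f"got {self.mor_annotation!r}"
            )
        object.__setattr__(self, "pmids", frozenset(str(p) for p in self.pmids))


@dataclass
class AggregatedInteraction:
    """A TF–gene pair with PMID sets deduplicated across resources."""

    tf: str
    target: str
    pmids_all: set = field(default_factory=set)
    pmids_activation: set = field(default_factory=set)
    pmids_repression: set = field(default_factory=set)
    resources: set = field(default_factory=set)

    @property
    def key(self) -> tuple:
        return (self.tf, self.target)


def normalize_records(
    records: Iterable[EvidenceRecord],
    alias_map: Mapping[str, str] | None = None,
) -> list:
    """Uppercase all symbols and apply an alias map.

    Symbols are uppercased first, then replaced by their image in
    ``alias_map`` when present (the map is keyed on uppercase symbols).
    Records with an empty TF or target symbol are dropped with a warning
    rather than raising, since single malformed rows should not abort a
    multi-resource build.
    """
    alias_map = dict(alias_map or {})
    out = []
    for rec in records:
        tf = rec.tf.strip().upper()
        target = rec.target.strip().upper()
        if not tf or not target:
            logger.warning(
                "dropping evidence record with empty symbol (tf=%r, target=%r, resource=%r)",
                rec.tf, rec.target, rec.resource,
            )
            continue
        tf = alias_map.get(tf, tf)
        target = alias_map.get(target, target)
        out.append(replace(rec, tf=tf, target=target))
    return out


def expand_complex_members(
    records: Iterable[EvidenceRecord],
    complex_map: Mapping[str, str] | None = None,
) -> list:
    """Share evidence between complex members and their complex, per target.

    ``complex_map`` maps a member symbol (e.g. ``JUN``) to its complex name
    (e.g. ``AP1``).  For each target gene, evidence attached to a member
    entry is also attributed to the complex entry, and complex evidence is
    attributed back to every member that itself has evidence for that
    target.  Members without their own edge to a target never gain one from
    the complex alone; the complex edge, however, is created whenever any
    member has evidence, matching the explicit listing of complexes in
    downstream distributions.

    Sharing happens by emitting mirror records; PMID sets union during
    :func:`aggregate_evidence`.
    """
    records = list(records)
    complex_map = dict(complex_map or {})
    if not complex_map:
        return records
    bad = set(complex_map) & set(complex_map.values())
    if bad:
        raise ValueError(
            f"symbols are both complex names and member keys: {sorted(bad)}"
        )

    # per (complex, target): member records and complex records
    member_recs = defaultdict(list)
    complex_recs = defaultdict(list)
    complex_names = set(complex_map.values())
    for rec in records:
        if rec.tf in complex_map:
            member_recs[(complex_map[rec.tf], rec.target)].append(rec)
        elif rec.tf in complex_names:
            complex_recs[(rec.tf, rec.target)].append(rec)

    mirrored = []
    for (cname, target), mrecs in member_recs.items():
        # member evidence attributed to the complex entry
        mirrored.extend(replace(r, tf=cname) for r in mrecs)
        # complex evidence attributed back to members active on this target
        members_present = {r.tf for r in mrecs}
        for crec in complex_recs.get((cname, target), ()):
            mirrored.extend(replace(crec, tf=m) for m in sorted(members_present))
    return records + mirrored


def aggregate_evidence(records: Iterable[EvidenceRecord]) -> list:
    """Collapse per-resource records into one interaction per (tf, target).

    ``pmids_all`` is the deduplicated union over resources.  A PMID enters
    ``pmids_activation`` (resp. ``pmids_repression``) if *any* resource
    asserts it with that mode; a PMID asserted with different modes in
    different resources legitimately appears in both sets.  Records with an
    ``unknown`` mode contribute to ``pmids_all`` only.

    Output order follows first appearance of each (tf, target) pair.
    """
    interactions: dict = {}
    order = []
    for rec in records:
        key = (rec.tf, rec.target)
        if key not in interactions:
            interactions[key] = AggregatedInteraction(tf=rec.tf, target=rec.target)
            order.append(key)
        inter = interactions[key]
        inter.resources.add(rec.resource)
        inter.pmids_all.update(rec.pmids)
        if rec.mor_annotation == "activation":
            inter.pmids_activation.update(rec.pmids)
        elif rec.mor_annotation == "repression":
            inter.pmids_repression.update(rec.pmids)
    return [interactions[k] for k in order]


def drop_unreferenced(interactions: Iterable[AggregatedInteraction]) -> list:
    """Remove interactions lacking any literature reference (empty PMID set)."""
    return [i for i in interactions if i.pmids_all]
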