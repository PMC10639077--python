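"""Restriction of regulators to classified transcription factors.

Regulators are kept only if classified as DNA-binding (dbTF), co-regulatory
(coTF) or general-initiation (GTF) transcription factors.  Classification
lists ship as static two-column TSV snapshots (symbol, class); optional
TF-level prior annotations (GO-derived role, UniProt-keyword role, KRAB
domain flag, effector-domain role) feed the prior-knowledge stage of the
sign-assignment cascade.

Complex regulators (AP1, NFKB) are not gene symbols and cannot appear in
GO- or TFclass-derived lists; they are retained through an explicit
whitelist instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from regulonkit.evidence import AggregatedInteraction

logger = logging.getLogger(__name__)

TF_CLASSES = frozenset({"dbTF", "coTF", "GTF"})
ROLE_VALUES = frozenset({"activator", "repressor", "unknown"})

#: Complex regulators kept even though they are absent from classification
#: lists (they are dimer names, not gene symbols).
DEFAULT_COMPLEX_WHITELIST = frozenset({"AP1", "NFKB"})


@dataclass(frozen=True)
class PriorRoles:
    """TF-level prior regulatory-role annotations used for sign votes."""

    go_role: str = "unknown"
    uniprot_role: str = "unknown"
    krab: bool = False
    effector_role: str = "unknown"

    def __post_init__(self):
        for attr in ("go_role", "uniprot_role", "effector_role"):
            if getattr(self, attr) not in ROLE_VALUES:
                raise ValueError(
                    f"{attr} must be one of {sorted(ROLE_VALUES)}, "
                    f"got {getattr(self, attr)!r}"
                )


@dataclass
class TFClassification:
    """Per-symbol class memberships plus optional prior-role annotations."""

    class_membership: dict = field(default_factory=dict)
    prior_roles: dict = field(default_factory=dict)

    def classes_of(self, symbol: str) -> frozenset:
        return frozenset(self.class_membership.get(symbol, ()))

    def priors_of(self, symbol: str) -> PriorRoles:
        return self.prior_roles.get(symbol, PriorRoles())


def _parse_bool(text: str, path, lineno: int) -> bool:
    low = text.strip().lower()
    if low == "true":
        return True
    if low == "false":
        return False
    raise ValueError(f"{path}:{lineno}: expected true/false, got {text!r}")


def load_classification(class_file, prior_file=None) -> TFClassification:
    """Load TF class memberships and optional prior roles from TSV files.

    ``class_file`` rows are ``symbol<TAB>class`` with class in
    {dbTF, coTF, GTF}; duplicate rows merge by set union.  ``prior_file``
    rows are ``symbol  go_role  uniprot_role  krab  effector_role``.
    An unknown class label raises with the offending row named.
    """
    membership: dict = {}
    class_path = Path(class_file)
    with open(class_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"symbol", "tf"}:
                continue
            if len(fields) < 2:
                raise ValueError(f"{class_path}:{lineno}: expected 2 columns, got {line!r}")
            symbol, cls = fields[0].strip(), fields[1].strip()
            if cls not in TF_CLASSES:
                raise ValueError(
                    f"{class_path}:{lineno}: unknown class label {cls!r} for {symbol!r}"
                )
            membership.setdefault(symbol, set()).add(cls)

    priors: dict = {}
    if prior_file is not None:
        prior_path = Path(prior_file)
        with open(prior_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0].lower() in {"symbol", "tf"}:
                    continue
                if len(fields) < 5:
                    raise ValueError(
                        f"{prior_path}:{lineno}: expected 5 columns, got {line!r}"
                    )
                symbol = fields[0].strip()
                priors[symbol] = PriorRoles(
                    go_role=fields[1].strip(),
                    uniprot_role=fields[2].strip(),
                    krab=_parse_bool(fields[3], prior_path, lineno),
                    effector_role=fields[4].strip(),
                )
    return TFClassification(class_membership=membership, prior_roles=priors)


def filter_regulators(
    interactions: Iterable[AggregatedInteraction],
    classification: TFClassification,
    complex_whitelist: frozenset = DEFAULT_COMPLEX_WHITELIST,
) -> list:
    """Keep interactions whose regulator has any TF class, or is whitelisted.

    Any of the three classes suffices; target genes are never filtered.
    """
    kept = []
    for inter in interactions:
        if classification.classes_of(inter.tf) or inter.tf in complex_whitelist:
            kept.append(inter)
    return kept
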