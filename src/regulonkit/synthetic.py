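"""Synthetic ground truth: networks, noisy evidence, perturbation signatures.

The generators emulate the statistical structure the build-and-benchmark
workflow assumes, so every stage can be tested offline against a known
answer:

* a ground-truth signed network with a controlled repressor fraction;
* multi-resource evidence tables where each edge's PMIDs carry mode
  annotations that are wrong with a configurable per-PMID flip probability,
  PMIDs overlap across resources through a shared pool, and a fraction of
  records carry no references at all;
* knockdown/overexpression signatures where each target gene shifts by
  ``direction × edge sign × effect_size`` plus Gaussian noise, non-targets
  are pure noise, and the perturbed TF's own entry is set to its
  knockdown log fold change.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from regulonkit.activity import Signature
from regulonkit.benchmark import PerturbationExperiment
from regulonkit.evidence import EvidenceRecord
from regulonkit.mor import RegulonNetwork, SignedEdge


@dataclass
class EvidenceParams:
    """Knobs for the synthetic evidence generator.

    ``pmids_per_edge`` is the number of mode-annotated PMIDs drawn per edge
    (an odd count avoids prevalence ties).  ``shared_pool_p`` controls
    cross-resource PMID overlap: each additional resource re-reports a
    pool PMID with this probability.
    """

    n_resources: int = 3
    pmids_per_edge: int = 3
    sign_error_rate: float = 0.0
    unreferenced_fraction: float = 0.0
    shared_pool_p: float = 0.5

    def __post_init__(self):
        for name in ("sign_error_rate", "unreferenced_fraction", "shared_pool_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_resources < 1 or self.pmids_per_edge < 1:
            raise ValueError("n_resources and pmids_per_edge must be >= 1")


@dataclass
class PerturbationParams:
    """Effect model for a synthetic perturbation signature."""

    effect_size: float = 3.0
    noise_sd: float = 0.5
    perturbed_tf_logfc: float = -2.0
    direction: int = -1

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass
class SyntheticTruth:
    """A ground-truth network bundled with the parameters that produced it."""

    network: RegulonNetwork
    evidence_params: EvidenceParams = field(default_factory=EvidenceParams)
    perturbation_params: PerturbationParams = field(default_factory=PerturbationParams)
    seed: int = 0


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _tf_names(n: int) -> list:
    width = max(2, len(str(n)))
    return [f"TF{i:0{width}d}" for i in range(1, n + 1)]


def simulate_network(
    n_tf: int,
    targets_per_tf: int | tuple,
    repressor_fraction: float = 0.3,
    n_genes: int = 200,
    seed: int = 0,
) -> RegulonNetwork:
    """Ground-truth network: each TF regulates ``targets_per_tf`` distinct genes.

    ``targets_per_tf`` may be an ``(lo, hi)`` pair, in which case each TF's
    out-degree is drawn uniformly from that inclusive range (heterogeneous
    regulon sizes, as needed to probe size bias).  Targets are sampled
    uniformly without replacement from the gene universe; each edge is
    repressing (−1) independently with probability ``repressor_fraction``.
    The gene universe is recorded in ``metadata["genes"]`` so perturbation
    simulation knows which non-targets to emit.
    """
    if not 0 <= repressor_fraction <= 1:
        raise ValueError("repressor_fraction must be in [0, 1]")
    lo, hi = (
        (int(targets_per_tf), int(targets_per_tf))
        if np.isscalar(targets_per_tf)
        else (int(targets_per_tf[0]), int(targets_per_tf[1]))
    )
    if not 1 <= lo <= hi:
        raise ValueError("targets_per_tf must be >= 1 with lo <= hi")
    if hi > n_genes:
        raise ValueError("targets_per_tf cannot exceed n_genes")
    if n_tf < 1:
        raise ValueError("n_tf must be >= 1")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    edges = []
    for tf in _tf_names(n_tf):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(n_genes, size=k, replace=False)
        signs = np.where(rng.random(k) < repressor_fraction, -1, 1)
        for i, s in zip(idx, signs):
            edges.append(SignedEdge(tf=tf, target=genes[i], sign=int(s)))
    return RegulonNetwork(
        edges=edges,
        metadata={
            "synthetic": True,
            "seed": seed,
            "genes": genes,
            "repressor_fraction": repressor_fraction,
        },
    )


def simulate_evidence(
    network: RegulonNetwork,
    params: EvidenceParams | None = None,
    seed: int = 0,
) -> list:
    """Emit noisy multi-resource evidence records for a ground-truth network.

    Per edge, ``pmids_per_edge`` unique PMIDs are drawn; each PMID's mode
    annotation equals the true sign but is flipped independently with
    probability ``sign_error_rate`` (a PMID keeps its mode in every
    resource that reports it, as a real publication would).  The first
    resource reports the full pool; each further resource covering the
    edge re-reports each pool PMID with probability ``shared_pool_p``,
    adding a fresh private PMID when it would otherwise report nothing.
    A fraction ``unreferenced_fraction`` of records is emitted with the
    PMID set blanked and mode unknown.
    """
    params = params or EvidenceParams()
    rng = np.random.default_rng(seed)
    records = []
    next_pmid = 1
    mode_of = {1: "activation", -1: "repression"}
    for edge in network.edges:
        k = params.pmids_per_edge
        pool = [str(p) for p in range(next_pmid, next_pmid + k)]
        next_pmid += k
        flips = rng.random(k) < params.sign_error_rate
        pmid_mode = {
            p: mode_of[-edge.sign if f else edge.sign] for p, f in zip(pool, flips)
        }
        n_cover = int(rng.integers(1, params.n_resources + 1))
        resources = [f"R{r}" for r in range(1, n_cover + 1)]
        for r_i, res in enumerate(resources):
            if r_i == 0:
                carried = list(pool)
            else:
                carried = [p for p in pool if rng.random() < params.shared_pool_p]
                if not carried:
                    carried = [str(next_pmid)]
                    pmid_mode[carried[0]] = mode_of[
                        -edge.sign
                        if rng.random() < params.sign_error_rate
                        else edge.sign
                    ]
                    next_pmid += 1
            # one record per asserted mode, as resources annotate per entry
            by_mode: dict = {}
            for p in carried:
                by_mode.setdefault(pmid_mode[p], []).append(p)
            for mode, pmids in sorted(by_mode.items()):
                if rng.random() < params.unreferenced_fraction:
                    records.append(
                        EvidenceRecord(
                            tf=edge.tf, target=edge.target, resource=res,
                            pmids=frozenset(), mor_annotation="unknown",
                        )
                    )
                else:
                    records.append(
                        EvidenceRecord(
                            tf=edge.tf, target=edge.target, resource=res,
                            pmids=frozenset(pmids), mor_annotation=mode,
                        )
                    )
    return records


def simulate_perturbation(
    network: RegulonNetwork,
    perturbed_tf: str,
    params: PerturbationParams | None = None,
    seed: int = 0,
    experiment_id: str | None = None,
) -> PerturbationExperiment:
    """One perturbation signature over the network's full gene universe.

    Targets of the perturbed TF shift by ``direction × sign × effect_size``
    plus Gaussian noise; every other gene is pure noise; the perturbed
    TF's own entry is pinned to ``perturbed_tf_logfc`` (default −2, which
    survives the effective-knockdown filter at threshold −1).
    """
    params = params or PerturbationParams()
    regulon = {e.target: e.sign for e in network.regulon(perturbed_tf)}
    if not regulon:
        raise ValueError(f"TF {perturbed_tf!r} not in network")
    genes = network.metadata.get("genes")
    if genes is None:
        genes = sorted({e.target for e in network.edges})
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.noise_sd, size=len(genes))
    values = {}
    for g, eps in zip(genes, noise):
        shift = params.direction * regulon.get(g, 0) * params.effect_size
        values[g] = shift + eps
    values[perturbed_tf] = params.perturbed_tf_logfc
    exp_id = experiment_id or f"{perturbed_tf}_kd_{seed}"
    return PerturbationExperiment(
        id=exp_id,
        perturbed_tf=perturbed_tf,
        direction=params.direction,
        signature=Signature(values=values, experiment_id=exp_id),
        perturbed_tf_logfc=params.perturbed_tf_logfc,
    )


def simulate_compendium(
    network: RegulonNetwork,
    perturbed_tfs: Sequence[str] | None = None,
    params: PerturbationParams | None = None,
    seed: int = 0,
) -> list:
    """One perturbation experiment per TF (default: every TF in the network)."""
    params = params or PerturbationParams()
    if perturbed_tfs is None:
        perturbed_tfs = network.tfs
    seeds = np.random.SeedSequence(seed).spawn(len(perturbed_tfs))
    return [
        simulate_perturbation(
            network, tf, params=params,
            seed=np.random.default_rng(ss).integers(2**31),
            experiment_id=f"{tf}_exp{i}",
        )
        for i, (tf, ss) in enumerate(zip(perturbed_tfs, seeds))
    ]
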