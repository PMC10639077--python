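"""File formats, pipeline configuration, and the end-to-end runner.

Everything on disk is tab-separated UTF-8 with a header row and ``NA`` for
missing values.  Dialects:

* evidence:        ``tf  target  resource  pmids  mor`` — ``pmids`` is a
  ``;``-delimited list (empty allowed), ``mor`` in
  {activation, repression, unknown};
* alias / complex maps: two columns, ``from  to`` / ``member  complex``;
* network:         ``source  target  weight  mor  provenance`` — ``mor``
  is ±1 and ``weight`` is sign × magnitude;
* signature:       ``gene  value``;
* experiments:     ``id  perturbed_tf  direction  perturbed_tf_logfc
  signature_path`` (paths relative to the metadata file);
* activity matrix: experiments × TFs with ``NA`` for unscored entries;
* benchmark:       one row per permutation sample plus a ``median``
  summary row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from regulonkit.activity import ActivityMatrix, Signature, infer_activities
from regulonkit.benchmark import (
    BenchmarkResult,
    PerturbationExperiment,
    filter_experiments,
    global_benchmark,
    permute_network,
)
from regulonkit.evidence import (
    MOR_VALUES,
    EvidenceRecord,
    aggregate_evidence,
    drop_unreferenced,
    expand_complex_members,
    normalize_records,
)
from regulonkit.mor import RegulonNetwork, SignedEdge, assign_mor, summarize_network
from regulonkit.regulators import filter_regulators, load_classification

logger = logging.getLogger(__name__)

#: Default dimer membership: Jun/Fos-family monomers fold into AP1 and the
#: NF-kB subunits into NFKB.  Editable — pass a different map (or a
#: two-column TSV through the config) to override.
DEFAULT_COMPLEX_MAP = {
    "JUN": "AP1", "JUNB": "AP1", "JUND": "AP1",
    "FOS": "AP1", "FOSB": "AP1", "FOSL1": "AP1", "FOSL2": "AP1",
    "NFKB1": "NFKB", "NFKB2": "NFKB", "RELA": "NFKB", "RELB": "NFKB", "REL": "NFKB",
}


# ---------------------------------------------------------------------------
# evidence and map tables

def read_evidence_table(path) -> list:
    """Parse an evidence TSV into records, validating per line."""
    path = Path(path)
    records = []
    with open(path, encoding="utf-8", newline="") as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                required = ["tf", "target", "resource", "pmids", "mor"]
                if [c.strip().lower() for c in header[:5]] != required:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {required}, got {header}"
                    )
                continue
            if len(cells) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(cells)}")
            tf, target, resource, pmids_raw, mor = (c.strip() for c in cells[:5])
            if mor not in MOR_VALUES:
                raise ValueError(
                    f"{path}:{lineno}: invalid mor literal {mor!r} "
                    f"(expected one of {sorted(MOR_VALUES)})"
                )
            pmids = frozenset(p for p in pmids_raw.split(";") if p)
            records.append(
                EvidenceRecord(tf=tf, target=target, resource=resource,
                               pmids=pmids, mor_annotation=mor)
            )
    return records


def write_evidence_table(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\tresource\tpmids\tmor\n")
        for r in records:
            pmids = ";".join(sorted(r.pmids, key=lambda p: (len(p), p)))
            fh.write(f"{r.tf}\t{r.target}\t{r.resource}\t{pmids}\t{r.mor_annotation}\n")


def read_two_column_map(path) -> dict:
    """Read a two-column TSV (alias or complex map); header optional."""
    out = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = cells[0].strip(), cells[1].strip()
            if lineno == 1 and a.lower() in {"from", "member", "alias", "symbol"}:
                continue
            out[a] = b
    return out


# ---------------------------------------------------------------------------
# networks

def write_network(network: RegulonNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\tmor\tprovenance\n")
        for e in network.edges:
            fh.write(
                f"{e.tf}\t{e.target}\t{e.sign * e.weight:g}\t{e.sign:d}\t{e.provenance}\n"
            )


def read_network(path) -> RegulonNetwork:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"source": str, "target": str})
    required = {"source", "target", "weight", "mor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing network columns {sorted(missing)}")
    edges = []
    has_prov = "provenance" in df.columns
    for row in df.itertuples(index=False):
        sign = int(row.mor)
        edges.append(
            SignedEdge(
                tf=row.source, target=row.target, sign=sign,
                weight=abs(float(row.weight)) or 1.0,
                provenance=row.provenance if has_prov else "default",
            )
        )
    return RegulonNetwork(edges=edges, metadata={"path": str(path)})


def write_gmt(network: RegulonNetwork, path) -> None:
    """GMT export: one TF per line, targets as set members, sign dropped."""
    with open(path, "w", encoding="utf-8") as fh:
        for tf in network.tfs:
            targets = "\t".join(e.target for e in network.regulon(tf))
            fh.write(f"{tf}\tregulonkit\t{targets}\n")


# ---------------------------------------------------------------------------
# signatures, experiments, matrices, benchmark results

def read_signature(path, experiment_id: str = "") -> Signature:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    if not {"gene", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'gene' and 'value'")
    return Signature(
        values=dict(zip(df["gene"], df["value"].astype(float))),
        experiment_id=experiment_id or Path(path).stem,
    )


def write_signature(signature: Signature, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tvalue\n")
        for gene, value in pd.Series(signature.values).items():
            fh.write(f"{gene}\t{value:.10g}\n")


def read_experiments(metadata_path) -> list:
    """Read an experiments metadata TSV and the signatures it points to."""
    metadata_path = Path(metadata_path)
    df = pd.read_csv(metadata_path, sep="\t", comment="#", dtype={"id": str})
    required = {"id", "perturbed_tf", "direction", "perturbed_tf_logfc", "signature_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    experiments = []
    for row in df.itertuples(index=False):
        lfc = row.perturbed_tf_logfc
        lfc = None if pd.isna(lfc) else float(lfc)
        sig_path = metadata_path.parent / str(row.signature_path)
        experiments.append(
            PerturbationExperiment(
                id=row.id,
                perturbed_tf=row.perturbed_tf,
                direction=int(row.direction),
                signature=read_signature(sig_path, experiment_id=row.id),
                perturbed_tf_logfc=lfc,
            )
        )
    return experiments


def write_experiments(experiments, directory) -> Path:
    """Write a compendium: one signature TSV per experiment plus metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_path = directory / "experiments.tsv"
    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write("id\tperturbed_tf\tdirection\tperturbed_tf_logfc\tsignature_path\n")
        for exp in experiments:
            sig_name = f"{exp.id}.tsv"
            write_signature(exp.signature, directory / sig_name)
            lfc = "NA" if exp.perturbed_tf_logfc is None else f"{exp.perturbed_tf_logfc:g}"
            fh.write(f"{exp.id}\t{exp.perturbed_tf}\t{exp.direction:d}\t{lfc}\t{sig_name}\n")
    return meta_path


def write_activity_matrix(matrix: ActivityMatrix, path) -> None:
    matrix.activities.to_csv(path, sep="\t", na_rep="NA", index_label="experiment")


def read_activity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="experiment", na_values="NA")


def write_benchmark_result(result: BenchmarkResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("permutation\tauroc\tauprc\n")
        for k, (a, p) in enumerate(zip(result.auroc_samples, result.auprc_samples)):
            fh.write(f"{k}\t{a:.10g}\t{p:.10g}\n")
        fh.write(f"median\t{result.median_auroc:.10g}\t{result.median_auprc:.10g}\n")


# ---------------------------------------------------------------------------
# pipeline configuration and runner

@dataclass
class PipelineConfig:
    """Resolved configuration for an end-to-end run.

    Unknown keys in a config file are rejected outright, so typos cannot
    silently fall back to defaults.
    """

    evidence: str = ""
    classification: str = ""
    prior_roles: str | None = None
    alias_map: str | None = None
    complex_map: str | None = None
    experiments: str | None = None
    outdir: str = "results"
    strategy: list = field(default_factory=lambda: ["pmid", "regulon_majority"])
    default_sign: int = 1
    min_targets: int = 5
    min_experiments: int = 5
    logfc_threshold: float = -1.0
    n_perm: int = 1000
    seed: int = 0
    permuted_baseline: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def build_network_from_files(config: PipelineConfig) -> RegulonNetwork:
    """build → sign: evidence tables to a signed network."""
    records = read_evidence_table(config.evidence)
    alias = read_two_column_map(config.alias_map) if config.alias_map else {}
    cmap = (
        read_two_column_map(config.complex_map)
        if config.complex_map
        else DEFAULT_COMPLEX_MAP
    )
    records = normalize_records(records, alias)
    records = expand_complex_members(records, cmap)
    interactions = drop_unreferenced(aggregate_evidence(records))
    classification = load_classification(config.classification, config.prior_roles)
    interactions = filter_regulators(interactions, classification)
    return assign_mor(
        interactions,
        classification,
        strategy=tuple(config.strategy),
        default_sign=config.default_sign,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute build → sign → infer → benchmark, writing artifacts on disk.

    Returns a summary dict (also written as ``summary.json``) stamped with
    the config hash and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline config_hash=%s seed=%d", config.config_hash(), config.seed)

    network = build_network_from_files(config)
    write_network(network, outdir / "network.tsv")
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "network": {
            "n_tfs": len(network.tfs),
            "n_edges": len(network),
        },
    }
    if network.edges:
        ns = summarize_network(network)
        summary["network"].update(
            frac_activating=ns.frac_activating,
            frac_repressing=ns.frac_repressing,
            tf_role_fractions=ns.tf_role_fractions,
            provenance_counts=ns.provenance_counts,
        )

    if config.experiments:
        experiments = read_experiments(config.experiments)
        experiments = filter_experiments(experiments, config.logfc_threshold)
        matrix = infer_activities(experiments, network, min_targets=config.min_targets)
        write_activity_matrix(matrix, outdir / "activities.tsv")
        result = global_benchmark(
            matrix, experiments, n_perm=config.n_perm, seed=config.seed
        )
        write_benchmark_result(result, outdir / "benchmark.tsv")
        summary["benchmark"] = {
            "median_auroc": result.median_auroc,
            "median_auprc": result.median_auprc,
            "n_positives": result.n_positives,
            "n_negatives": result.n_negatives,
            "n_experiments": len(experiments),
        }
        if config.permuted_baseline:
            permuted = permute_network(network, seed=config.seed)
            pm_matrix = infer_activities(
                experiments, permuted, min_targets=config.min_targets
            )
            pm_result = global_benchmark(
                pm_matrix, experiments, n_perm=config.n_perm, seed=config.seed
            )
            write_benchmark_result(pm_result, outdir / "benchmark_permuted.tsv")
            summary["permuted_baseline"] = {
                "median_auroc": pm_result.median_auroc,
                "median_auprc": pm_result.median_auprc,
            }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
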