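"""Perturbation benchmark: can a regulon collection recover perturbed TFs?

Given an activity matrix over a compendium of TF knockdown/knockout (or
overexpression) experiments, each scored entry is sign-corrected by the
perturbation direction (knockdown −1, overexpression +1), flattened into a
single vector, and labelled positive when the entry's TF is the experiment's
perturbed TF.  Because positives are vastly outnumbered, AUROC and AUPRC
are computed on repeated class-balanced random subsets (downsampling
without replacement to ``min(#pos, #neg)`` per class, 1000 permutations by
default), yielding a distribution of performance values summarized by its
median.

A degree-preserving permuted network — (target, sign) pairs shuffled
against the fixed TF column — serves as the no-biology baseline, and
size-bias diagnostics quantify whether high |activity| merely tracks
regulon size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from regulonkit.activity import ActivityMatrix, Signature
from regulonkit.mor import RegulonNetwork, SignedEdge

logger = logging.getLogger(__name__)

DEFAULT_LOGFC_THRESHOLD = -1.0
DEFAULT_N_PERM = 1000
DEFAULT_MIN_EXPERIMENTS = 5


@dataclass
class PerturbationExperiment:
    """One perturbation experiment: a gene-level signature plus metadata.

    ``direction`` is −1 for knockdown/knockout and +1 for overexpression.
    ``perturbed_tf_logfc`` is the perturbed TF's own log fold change, used
    to filter out ineffective knockdowns.
    """

    id: str
    perturbed_tf: str
    direction: int
    signature: Signature
    perturbed_tf_logfc: float | None = None

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be -1 or +1, got {self.direction}")
        if not self.perturbed_tf:
            raise ValueError("perturbed_tf must be non-empty")


@dataclass
class BenchmarkResult:
    """Per-permutation AUROC/AUPRC samples with medians and the seed used."""

    auroc_samples: np.ndarray
    auprc_samples: np.ndarray
    median_auroc: float
    median_auprc: float
    n_positives: int
    n_negatives: int
    seed: int


def filter_experiments(
    experiments: Iterable[PerturbationExperiment],
    logfc_threshold: float = DEFAULT_LOGFC_THRESHOLD,
) -> list:
    """Exclude knockdowns where the perturbed TF was not markedly reduced.

    A knockdown/knockout experiment (direction −1) is retained only if the
    perturbed TF's own log fold change is at most ``logfc_threshold``
    (default −1; the boundary value itself is retained).  Knockdowns with a
    missing log fold change are excluded with a warning.  Overexpression
    experiments pass unfiltered.
    """
    kept = []
    for exp in experiments:
        if exp.direction == 1:
            kept.append(exp)
            continue
        lfc = exp.perturbed_tf_logfc
        if lfc is None or not np.isfinite(lfc):
            logger.warning(
                "experiment %s: knockdown without perturbed-TF logFC; excluded", exp.id
            )
            continue
        if lfc <= logfc_threshold:
            kept.append(exp)
    return kept


def rank_metrics(scores: Sequence[float], labels: Sequence[int]) -> tuple:
    """AUROC and AUPRC of ``scores`` against binary ``labels``.

    AUROC is the pair-counting (Mann–Whitney) statistic with ties
    contributing 1/2.  AUPRC is step-wise average precision: the mean of
    precision at each positive's rank with scores sorted descending; ties
    are broken by the stable input order, so callers control tie
    determinism through the order in which they flatten.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_metrics needs at least one positive and one negative")

    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2 pairs
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    cum_pos = np.cumsum(sorted_labels)
    ranks_1based = np.arange(1, len(labels) + 1)
    precision_at_pos = cum_pos[sorted_labels == 1] / ranks_1based[sorted_labels == 1]
    auprc = float(precision_at_pos.mean())
    return float(auroc), auprc


def _downsampled(
    scores: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    seed: int,
    rng: np.random.Generator | None = None,
) -> BenchmarkResult:
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("benchmark needs at least one positive and one negative entry")
    n = min(len(pos_idx), len(neg_idx))
    if rng is None:
        rng = np.random.default_rng(seed)
    aurocs = np.empty(n_perm)
    auprcs = np.empty(n_perm)
    for k in range(n_perm):
        take_pos = rng.choice(pos_idx, size=n, replace=False)
        take_neg = rng.choice(neg_idx, size=n, replace=False)
        take = np.sort(np.concatenate([take_pos, take_neg]))  # preserve flatten order
        aurocs[k], auprcs[k] = rank_metrics(scores[take], labels[take])
    return BenchmarkResult(
        auroc_samples=aurocs,
        auprc_samples=auprcs,
        median_auroc=float(np.median(aurocs)),
        median_auprc=float(np.median(auprcs)),
        n_positives=len(pos_idx),
        n_negatives=len(neg_idx),
        seed=seed,
    )


def _flatten(activities: ActivityMatrix, experiments: list) -> tuple:
    """Sign-correct and flatten the activity matrix.

    Experiments whose perturbed TF was not scored in their own row are
    dropped entirely (they could never be recovered and would only dilute
    the negatives).  Entries are emitted in (TF, experiment) order so that
    average-precision tie-breaking is deterministic.
    """
    acts = activities.activities
    by_id = {e.id: e for e in experiments}
    usable = []
    for exp_id in acts.index:
        exp = by_id.get(exp_id)
        if exp is None:
            continue
        if exp.perturbed_tf not in acts.columns or np.isnan(
            acts.at[exp_id, exp.perturbed_tf]
        ):
            logger.warning(
                "experiment %s: perturbed TF %s not scored; dropped",
                exp_id, exp.perturbed_tf,
            )
            continue
        usable.append(exp)

    scores, labels = [], []
    for tf in acts.columns:  # lexicographic by construction
        for exp in usable:
            val = acts.at[exp.id, tf]
            if np.isnan(val):
                continue
            scores.append(val * exp.direction)
            labels.append(1 if tf == exp.perturbed_tf else 0)
    return np.asarray(scores), np.asarray(labels), usable


def global_benchmark(
    activities: ActivityMatrix,
    experiments: Iterable[PerturbationExperiment],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> BenchmarkResult:
    """Class-balanced downsampled AUROC/AUPRC over the flattened matrix.

    Each scored (experiment, TF) entry becomes one observation with score
    ``activity × direction`` and label 1 iff the TF is the experiment's
    perturbed TF.  Per permutation, ``min(#pos, #neg)`` items are drawn
    from each class without replacement and ranked.  Identical seeds give
    identical results.
    """
    scores, labels, _ = _flatten(activities, list(experiments))
    if len(scores) == 0:
        raise ValueError("no scored entries to benchmark")
    return _downsampled(scores, labels, n_perm, seed)


def per_tf_benchmark(
    activities: ActivityMatrix,
    experiments: Iterable[PerturbationExperiment],
    min_experiments: int = DEFAULT_MIN_EXPERIMENTS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Benchmark each sufficiently-perturbed TF on its own activity column.

    For every TF perturbed in at least ``min_experiments`` usable
    experiments, the scores are that TF's sign-corrected column across all
    experiments, positives being the experiments that perturbed it.  Each
    TF gets an independent child stream of the seed, so results per TF do
    not depend on which other TFs are present.
    """
    experiments = list(experiments)
    _, _, usable = _flatten(activities, experiments)
    acts = activities.activities

    perturbed_counts: dict = {}
    for exp in usable:
        perturbed_counts[exp.perturbed_tf] = perturbed_counts.get(exp.perturbed_tf, 0) + 1
    eligible = sorted(tf for tf, c in perturbed_counts.items() if c >= min_experiments)
    if not eligible:
        logger.warning("no TF perturbed in >= %d experiments", min_experiments)
        return {}

    results: dict = {}
    for i, tf in enumerate(eligible):
        scores, labels = [], []
        for exp in usable:
            val = acts.at[exp.id, tf]
            if np.isnan(val):
                continue
            scores.append(val * exp.direction)
            labels.append(1 if exp.perturbed_tf == tf else 0)
        scores = np.asarray(scores)
        labels = np.asarray(labels)
        if labels.sum() == len(labels):
            logger.warning("TF %s has no negative experiments; skipped", tf)
            continue
        child = np.random.default_rng(np.random.SeedSequence(seed).spawn(i + 1)[-1])
        results[tf] = _downsampled(scores, labels, n_perm, seed, rng=child)
    return results


def permute_network(network: RegulonNetwork, seed: int = 0) -> RegulonNetwork:
    """Degree-preserving shuffle of (target, sign) pairs against TFs.

    The multiset of (target, sign) pairs is permuted jointly while the TF
    column stays fixed, preserving per-TF out-degree and the global sign
    balance.  Duplicate (tf, target) collisions are resolved by random
    swaps with other assignments until the network is collision-free.
    """
    if not network.edges:
        raise ValueError("cannot permute an empty network")
    rng = np.random.default_rng(seed)
    tfs = [e.tf for e in network.edges]
    items = [(e.target, e.sign) for e in network.edges]
    perm = rng.permutation(len(items))
    assigned = [items[p] for p in perm]

    def duplicate_positions() -> list:
        seen: set = set()
        dups = []
        for i, tf in enumerate(tfs):
            key = (tf, assigned[i][0])
            if key in seen:
                dups.append(i)
            else:
                seen.add(key)
        return dups

    n = len(assigned)
    for _ in range(100 * n):
        dups = duplicate_positions()
        if not dups:
            break
        i = dups[0]
        j = int(rng.integers(n))
        pair_counts: dict = {}
        for k, tf in enumerate(tfs):
            key = (tf, assigned[k][0])
            pair_counts[key] = pair_counts.get(key, 0) + 1
        new_i = (tfs[i], assigned[j][0])
        new_j = (tfs[j], assigned[i][0])
        old_i = (tfs[i], assigned[i][0])
        old_j = (tfs[j], assigned[j][0])
        counts = dict(pair_counts)
        for key in (old_i, old_j):
            counts[key] -= 1
        ok = True
        for key in (new_i, new_j):
            counts[key] = counts.get(key, 0) + 1
            if counts[key] > 1:
                ok = False
        if ok:
            assigned[i], assigned[j] = assigned[j], assigned[i]
    else:
        raise RuntimeError("could not resolve duplicate edges while permuting")

    edges = [
        SignedEdge(tf=tf, target=tgt, sign=sgn, weight=e.weight, provenance=e.provenance)
        for tf, (tgt, sgn), e in zip(tfs, assigned, network.edges)
    ]
    meta = dict(network.metadata)
    meta.update({"permuted": True, "permutation_seed": seed})
    return RegulonNetwork(edges=edges, metadata=meta)


def size_bias(
    activities: ActivityMatrix,
    network: RegulonNetwork,
    benchmark_tfs: Iterable[str],
) -> tuple:
    """Diagnose whether |activity| tracks regulon size.

    Per experiment, the Pearson correlation between |activity| and the
    TF's measured-target count; returns the mean over experiments, the
    per-experiment values, and a two-sided Welch t statistic comparing
    total target counts of benchmark vs non-benchmark TFs.
    Experiments with constant |activity| or constant counts are skipped
    with a warning.
    """
    benchmark_tfs = set(benchmark_tfs)
    acts = activities.activities
    nt = activities.n_targets

    per_exp: dict = {}
    for exp_id in acts.index:
        row = acts.loc[exp_id]
        mask = row.notna()
        if mask.sum() < 3:
            logger.warning("experiment %s: fewer than 3 scored TFs; skipped", exp_id)
            continue
        abs_act = row[mask].abs().to_numpy()
        counts = nt.loc[exp_id][mask].to_numpy(dtype=float)
        if np.ptp(abs_act) == 0 or np.ptp(counts) == 0:
            logger.warning("experiment %s: constant values, correlation undefined", exp_id)
            continue
        per_exp[exp_id] = float(stats.pearsonr(abs_act, counts).statistic)

    mean_r = float(np.mean(list(per_exp.values()))) if per_exp else float("nan")

    out_degree: dict = {}
    for e in network.edges:
        out_degree[e.tf] = out_degree.get(e.tf, 0) + 1
    in_bench = [c for tf, c in out_degree.items() if tf in benchmark_tfs]
    out_bench = [c for tf, c in out_degree.items() if tf not in benchmark_tfs]
    if len(in_bench) >= 2 and len(out_bench) >= 2:
        tt = stats.ttest_ind(in_bench, out_bench, equal_var=False)
        target_count_test = (float(tt.statistic), float(tt.pvalue))
    else:
        target_count_test = (float("nan"), float("nan"))
    return mean_r, per_exp, target_count_test
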