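"""TF activity scoring with a univariate linear model (ulm).

For each transcription factor, the gene-level signature ``y`` (logFC,
t-values or normalized expression over all measured genes) is regressed on
the TF's signed target-indicator vector ``x``: ``x(g)`` is the signed edge
weight if ``g`` is a target of the TF, else 0.  The activity is the slope
t-value of the ordinary least-squares fit with intercept,

    t = beta_hat / SE(beta_hat),   df = n − 2,

so a positive activity means the TF's activating targets are up (and/or its
repressed targets down) relative to the rest of the signature.  Only TFs
with at least ``min_targets`` targets among the measured genes are scored,
and the network is first restricted to genes present in the signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from regulonkit.mor import RegulonNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_TARGETS = 5


@dataclass
class Signature:
    """Gene-level statistic vector for one experiment or cell.

    Duplicate gene entries are averaged with a warning; non-finite values
    are dropped.  At least 3 genes must survive cleaning.
    """

    values: Mapping[str, float] | pd.Series
    experiment_id: str = ""

    def clean(self) -> pd.Series:
        s = pd.Series(self.values, dtype=float)
        if s.index.has_duplicates:
            logger.warning(
                "signature %r has duplicate gene entries; averaging",
                self.experiment_id,
            )
            s = s.groupby(level=0).mean()
        s = s[np.isfinite(s.values)]
        s = s.sort_index()  # canonical gene order: results invariant to input order
        if len(s) < 3:
            raise ValueError(
                f"signature {self.experiment_id!r} has {len(s)} usable genes; need >= 3"
            )
        return s


@dataclass
class ActivityMatrix:
    """Experiments × TFs activity t-values, with unscored entries as NaN.

    ``n_targets`` records, per scored entry, how many of the TF's targets
    were measured in that experiment (the regression support size).
    """

    activities: pd.DataFrame
    pvalues: pd.DataFrame
    n_targets: pd.DataFrame = field(default=None)

    @property
    def experiments(self) -> list:
        return list(self.activities.index)

    @property
    def tfs(self) -> list:
        return list(self.activities.columns)


def _ulm_fit(x: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression with intercept; returns (t, p)."""
    n = len(y)
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sxx = float(dx @ dx)
    if sxx == 0.0:
        return None  # constant predictor
    sxy = float(dx @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    df = n - 2
    sse = syy - slope * sxy
    # exact fits leave a rounding-level residual; treat it as zero
    if sse <= 64.0 * np.finfo(float).eps * max(syy, 1.0):
        logger.warning("zero residual variance in ulm fit; activity is signed infinity")
        t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
        return t, 0.0 if slope != 0 else 1.0
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def ulm_activity(
    signature: Signature,
    network: RegulonNetwork,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> dict:
    """Score every eligible TF in ``network`` against one signature.

    Returns ``{tf: (activity_t, pvalue)}`` for TFs with at least
    ``min_targets`` measured targets and a non-constant predictor; other
    TFs are omitted.  The regression universe is all measured genes, with
    non-targets at 0.
    """
    if min_targets < 2:
        raise ValueError("min_targets must be >= 2")
    y_series = signature.clean()
    gene_index = {g: i for i, g in enumerate(y_series.index)}
    y = y_series.to_numpy()

    # network restricted to measured genes
    by_tf: dict = {}
    for e in network.edges:
        i = gene_index.get(e.target)
        if i is not None:
            by_tf.setdefault(e.tf, []).append((i, e.sign * e.weight))

    out: dict = {}
    for tf in sorted(by_tf):
        targets = by_tf[tf]
        if len(targets) < min_targets:
            continue
        x = np.zeros(len(y))
        for i, w in targets:
            x[i] = w
        fit = _ulm_fit(x, y)
        if fit is None:
            logger.warning("TF %s has a constant predictor; omitted", tf)
            continue
        out[tf] = fit
    return out


def infer_activities(
    experiments: Iterable,
    network: RegulonNetwork,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> ActivityMatrix:
    """Build the experiments × TFs activity matrix from per-experiment fits.

    Accepts perturbation experiments (anything with ``id`` and
    ``signature`` attributes) or bare :class:`Signature` objects.  Columns
    are ordered lexicographically; entries where a TF could not be scored
    are NaN.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")

    rows: dict = {}
    pvals: dict = {}
    counts: dict = {}
    targets_by_tf: dict = {}
    for e in network.edges:
        targets_by_tf.setdefault(e.tf, set()).add(e.target)
    for exp in experiments:
        signature = getattr(exp, "signature", exp)
        exp_id = getattr(exp, "id", None) or signature.experiment_id
        try:
            scores = ulm_activity(signature, network, min_targets=min_targets)
        except ValueError as err:
            raise ValueError(f"experiment {exp_id!r}: {err}") from err
        rows[exp_id] = {tf: t for tf, (t, _) in scores.items()}
        pvals[exp_id] = {tf: p for tf, (_, p) in scores.items()}
        measured = set(signature.clean().index)
        counts[exp_id] = {
            tf: len(targets_by_tf[tf] & measured) for tf in scores
        }

    acts = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    acts = acts.reindex(index=list(rows))
    pv = pd.DataFrame.from_dict(pvals, orient="index").reindex_like(acts)
    nt = pd.DataFrame.from_dict(counts, orient="index").reindex_like(acts)
    return ActivityMatrix(activities=acts, pvalues=pv, n_targets=nt)
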