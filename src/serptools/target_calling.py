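"""Filter cascade and FDR-calibrated hit calling.

The per-gene statistic thresholded here is the no-bait-scaled AUC: the
fold-change AUC in the pulldown divided by the sum of pulldown and no-bait
fold-change AUCs, as a percentage.  A cut-off on that percentage is
calibrated against a curated true-positive gene list at a target empirical
FDR (default 1%).

FDR estimation with an incomplete positive list
-----------------------------------------------
The empirical FDR at a threshold is FP/(TP+FP) with TP counted on the curated
positives.  Which genes count as FP is configurable:

* by default every non-truth gene above the threshold is a false positive
  ("all genes as negatives").  This over-counts FP whenever the curated list
  is incomplete — genuine but un-curated targets score high and are booked
  as false discoveries — which makes the estimate conservative to the point
  of uselessness when a substantial fraction of real targets is missing from
  the list;
* when a curated *negative* list is supplied, only those genes count as FP
  and genes on neither list stay out of the calibration entirely, the way a
  literature-derived set of known non-cargoes would be used.

The threshold returned is the smallest candidate meeting the FDR constraint
(maximizing sensitivity at the constraint); candidates are the distinct
observed scaled-AUC values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import GeneScore


class CalibrationError(ValueError):
    """FDR calibration could not run (e.g. no truth genes survive prefilters)."""


@dataclass
class FilterConfig:
    """Thresholds of the pre-FDR filter cascade and the FDR target."""

    min_coverage: float = 80.0       # percent, both IP and total must reach it
    min_auc_ip: float = 5.0          # strict: auc_ip must exceed this
    require_fc_ge_wt: bool = True    # bait fold-change AUC >= no-bait fold-change AUC
    min_replicate_corr: float = 0.6  # mean pairwise Pearson r across replicates
    fdr: float = 0.01

    def __post_init__(self):
        if not (0 <= self.min_coverage <= 100):
            raise ValueError("min_coverage must be within [0, 100]")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be within (0, 1)")


@dataclass
class RocPoint:
    """One point of the threshold scan used for FDR calibration."""

    threshold: float
    tp: int
    fp: int
    fn: int
    fdr_estimate: float
    sensitivity: float


def scaled_auc(auc_fc_bait: float, auc_fc_wt: float) -> float:
    """No-bait-scaled AUC: 100 * bait / (bait + no-bait).

    Both inputs must be >= 0; when both are zero the statistic is undefined
    and NaN is returned (the gene is excluded downstream).
    """
    if auc_fc_bait < 0 or auc_fc_wt < 0:
        raise ValueError("fold-change AUCs must be non-negative")
    denom = auc_fc_bait + auc_fc_wt
    if denom == 0:
        return float("nan")
    return 100.0 * auc_fc_bait / denom


def apply_prefilters(scores: list[GeneScore], config: FilterConfig) -> list[GeneScore]:
    """Set the filter flags and the scaled AUC on each gene score (in place).

    Flags follow the cascade: coverage in both IP and total at least
    ``min_coverage``; pulldown AUC strictly larger than ``min_auc_ip``; bait
    fold-change AUC at least the no-bait fold-change AUC; mean replicate
    correlation at least ``min_replicate_corr`` (an undefined correlation
    fails).  Transposon genes are expected to have been excluded upstream.
    """
    for s in scores:
        s.coverage_ok = bool(
            s.coverage_ip >= config.min_coverage and s.coverage_total >= config.min_coverage
        )
        s.auc_ok = bool(s.auc_ip > config.min_auc_ip)
        s.fc_ok = bool(s.auc_fc >= s.auc_fc_wt) if config.require_fc_ge_wt else True
        s.corr_ok = bool(
            np.isfinite(s.mean_replicate_corr)
            and s.mean_replicate_corr >= config.min_replicate_corr
        )
        s.scaled_auc = scaled_auc(s.auc_fc, s.auc_fc_wt)
    return scores


def prefilter_pass(score: GeneScore) -> bool:
    """The pre-FDR cascade (correlation is applied later, at hit calling)."""
    return score.coverage_ok and score.auc_ok and score.fc_ok and np.isfinite(score.scaled_auc)


def calibrate_threshold(
    scaled_aucs: np.ndarray,
    is_truth: np.ndarray,
    fdr: float = 0.01,
    is_negative: np.ndarray | None = None,
) -> tuple[float, list[RocPoint]]:
    """Scan observed scaled-AUC values for the FDR-constrained cut-off.

    Parameters
    ----------
    scaled_aucs
        Scaled-AUC percentages of the prefiltered genes.
    is_truth
        Boolean mask marking curated true positives among them.
    fdr
        Target empirical FDR (fraction).
    is_negative
        Optional boolean mask of curated negatives.  When given, only these
        genes count as false positives and unlabeled genes are excluded from
        the scan; when omitted, every non-truth gene is a negative.

    Returns the smallest threshold whose fdr_estimate is <= ``fdr`` together
    with the full scan.  If no threshold qualifies the one minimizing the
    estimate is returned with a warning (ties resolved toward the largest,
    i.e. most conservative, threshold).
    """
    scaled_aucs = np.asarray(scaled_aucs, dtype=float)
    is_truth = np.asarray(is_truth, dtype=bool)
    if scaled_aucs.shape != is_truth.shape:
        raise ValueError("scaled_aucs and is_truth must have identical shapes")
    if is_negative is None:
        is_negative = ~is_truth
    else:
        is_negative = np.asarray(is_negative, dtype=bool)
        if np.any(is_negative & is_truth):
            raise CalibrationError("a gene is labeled both positive and negative")
    n_truth_total = int(np.count_nonzero(is_truth))
    if n_truth_total == 0:
        raise CalibrationError("no truth genes among the prefiltered genes; "
                               "check prefilter thresholds and the truth set")

    candidates = np.unique(scaled_aucs[np.isfinite(scaled_aucs)])
    roc: list[RocPoint] = []
    for thr in candidates:
        above = scaled_aucs >= thr
        tp = int(np.count_nonzero(above & is_truth))
        fp = int(np.count_nonzero(above & is_negative))
        fn = n_truth_total - tp
        fdr_est = fp / (tp + fp) if (tp + fp) > 0 else float("nan")
        roc.append(RocPoint(
            threshold=float(thr), tp=tp, fp=fp, fn=fn,
            fdr_estimate=fdr_est, sensitivity=tp / n_truth_total,
        ))

    qualifying = [p for p in roc if p.tp > 0 and np.isfinite(p.fdr_estimate)
                  and p.fdr_estimate <= fdr]
    if qualifying:
        chosen = min(qualifying, key=lambda p: p.threshold)
    else:
        # No threshold controls the FDR.  Calling anything would break the
        # guarantee, so fall back to the top of the score range (at most the
        # top-scoring genes get called) and report how close the scan got.
        defined = [p for p in roc if np.isfinite(p.fdr_estimate)]
        if not defined:
            raise CalibrationError("threshold scan produced no defined FDR estimate")
        best = min(p.fdr_estimate for p in defined)
        chosen = max(roc, key=lambda p: p.threshold)
        warnings.warn(
            f"no threshold reaches FDR <= {fdr:g} (best estimate {best:.3f}); "
            f"falling back to the top of the score range "
            f"({chosen.threshold:.2f}%)", stacklevel=2,
        )
    return chosen.threshold, roc


def call_hits(scores: list[GeneScore], threshold: float,
              config: FilterConfig) -> list[GeneScore]:
    """Final hit decision: prefilters AND scaled AUC >= threshold AND correlation.

    The ``inspected`` field stays "pending"; manual profile inspection is a
    recorded workflow step, not automated logic.
    """
    for s in scores:
        s.is_hit = bool(
            prefilter_pass(s)
            and s.scaled_auc >= threshold
            and s.corr_ok
        )
    return scores


def apply_inspection_overrides(scores: list[GeneScore],
                               overrides: dict[str, str]) -> list[GeneScore]:
    """Record manual inspection outcomes; 'rejected' genes lose hit status."""
    for s in scores:
        status = overrides.get(s.gene_id)
        if status is None:
            continue
        if status not in ("accepted", "rejected"):
            raise ValueError(f"{s.gene_id}: inspection status must be "
                             f"'accepted' or 'rejected', got {status!r}")
        s.inspected = status
        if status == "rejected":
            s.is_hit = False
    return scores
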