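"""Gene profiles and per-gene summary quantities.

A gene profile is the strand-oriented per-nucleotide count vector over the
gene's genomic span; index 0 corresponds to the first nucleotide of the ORF in
5'->3' mRNA orientation.  Intron positions stay in the vector (they are not
removed for smoothing) and are excluded only where the contracts say so: the
trapezoidal AUC drops intronic and undefined positions.

The canonical order of operations for enrichment is: smooth each replicate,
average replicates position-wise, then divide IP by total.  The enrichment
ratio is left undefined (NaN) wherever the smoothed total is zero; no
pseudocount is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import CountTrack, GeneModel, ValidationError

AVERAGED = "averaged"


@dataclass
class GeneProfile:
    """Strand-oriented per-nucleotide vector over one gene's genomic span."""

    gene_id: str
    condition: str
    bait: str
    replicate: int | str
    values: np.ndarray
    exon_mask: np.ndarray
    smoothed: bool = False
    window: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.exon_mask = np.asarray(self.exon_mask, dtype=bool)
        if self.values.shape != self.exon_mask.shape:
            raise ValidationError(f"{self.gene_id}: values and exon_mask lengths differ")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError(f"{self.gene_id}: profile values must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size

    def orf_values(self) -> np.ndarray:
        """Exonic positions concatenated 5'->3' (ORF coordinates)."""
        return self.values[self.exon_mask]


@dataclass
class EnrichmentProfile:
    """Position-wise IP/total ratio; NaN marks positions where total is zero."""

    gene_id: str
    bait: str
    values: np.ndarray
    exon_mask: np.ndarray
    source_window: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.exon_mask = np.asarray(self.exon_mask, dtype=bool)

    def __len__(self) -> int:
        return self.values.size

    def orf_values(self) -> np.ndarray:
        return self.values[self.exon_mask]


@dataclass
class GeneScore:
    """The per-gene decision record carried into target calling."""

    gene_id: str
    bait: str
    auc_ip: float = np.nan
    auc_total: float = np.nan
    auc_fc: float = np.nan
    auc_fc_wt: float = np.nan
    coverage_ip: float = np.nan
    coverage_total: float = np.nan
    mean_replicate_corr: float = np.nan
    scaled_auc: float = np.nan
    coverage_ok: bool = False
    auc_ok: bool = False
    fc_ok: bool = False
    corr_ok: bool = False
    is_hit: bool = False
    inspected: str = "pending"


# ---------------------------------------------------------------------------
# Profile operations
# ---------------------------------------------------------------------------

def extract_gene_profile(track: CountTrack, gene: GeneModel) -> GeneProfile:
    """Cut the gene's genomic span out of a count track, ORF-oriented.

    For minus-strand genes the vector (and exon mask) is reversed so index 0
    is the start-codon side.  Intron positions carry their genomic counts and
    are flagged False in the exon mask.
    """
    vec = track.counts.get(gene.chromosome)
    if vec is None:
        raise ValidationError(f"{gene.gene_id}: chromosome {gene.chromosome!r} not in track")
    start, end = gene.span
    if end > vec.size:
        raise ValidationError(f"{gene.gene_id}: gene extends beyond track "
                              f"({end} > {vec.size})")
    values = vec[start - 1 : end].copy()
    mask = gene.exon_mask()
    if gene.strand == "-":
        values = values[::-1].copy()
        mask = mask[::-1].copy()
    return GeneProfile(
        gene_id=gene.gene_id, condition=track.condition, bait=track.bait,
        replicate=track.replicate, values=values, exon_mask=mask,
    )


def _moving_average(values: np.ndarray, window: int, alignment: str) -> np.ndarray:
    """Mean over the window truncated to available positions (O(n) via cumsum).

    centered: window covers [i - w//2, i + (w - 1)//2];
    trailing: window covers [i - w + 1, i].
    """
    n = values.size
    if window == 1:
        return values.copy()
    if alignment == "centered":
        lo = np.arange(n) - window // 2
        hi = np.arange(n) + (window - 1) // 2
    elif alignment == "trailing":
        lo = np.arange(n) - window + 1
        hi = np.arange(n)
    else:
        raise ValueError(f"alignment must be 'centered' or 'trailing', got {alignment!r}")
    lo = np.clip(lo, 0, n - 1)
    hi = np.clip(hi, 0, n - 1)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smooth_profile(profile: GeneProfile, window: int = 100,
                   alignment: str = "centered") -> GeneProfile:
    """Sliding-window moving average over the full span (introns included).

    At the profile boundaries the window truncates to the available
    positions, so a constant profile stays exactly constant.  A window larger
    than 10x the profile length is clamped to the length with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(profile)
    if window > 10 * n:
        warnings.warn(
            f"{profile.gene_id}: smoothing window {window} exceeds 10x profile length "
            f"{n}; clamping to {n}", stacklevel=2,
        )
        window = n
    smoothed = _moving_average(profile.values, window, alignment)
    return replace(profile, values=smoothed, smoothed=True, window=window)


def average_replicates(profiles: list[GeneProfile]) -> GeneProfile:
    """Position-wise arithmetic mean across replicate profiles."""
    if not profiles:
        raise ValueError("no profiles to average")
    if len(profiles) == 1:
        warnings.warn(
            f"{profiles[0].gene_id}: averaging a single replicate", stacklevel=2,
        )
    n = len(profiles[0])
    for p in profiles[1:]:
        if len(p) != n:
            raise ValidationError(f"{p.gene_id}: replicate profile lengths differ")
    stack = np.stack([p.values for p in profiles])
    return replace(profiles[0], values=stack.mean(axis=0), replicate=AVERAGED)


def replicate_correlation(profiles: list[GeneProfile]) -> float:
    """Mean pairwise Pearson correlation across replicate profiles.

    Pairs where either vector has zero variance contribute no value; if every
    pair is undefined the result is NaN (which fails the correlation filter
    downstream).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 replicates for a correlation")
    n = len(profiles[0])
    for p in profiles[1:]:
        if len(p) != n:
            raise ValidationError(f"{p.gene_id}: replicate profile lengths differ")
    vectors = [p.values for p in profiles]
    rs = []
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            x, y = vectors[i], vectors[j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            xc, yc = x - x.mean(), y - y.mean()
            rs.append(float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))))
    return float(np.mean(rs)) if rs else float("nan")


def coverage_percent(profile: GeneProfile) -> float:
    """Percent of positions with value > 0 over the full vector (introns included)."""
    n = len(profile)
    if n == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(profile.values > 0)) / n


def enrichment_profile(ip: GeneProfile, total: GeneProfile) -> EnrichmentProfile:
    """Position-wise IP/total fold change; NaN where total is zero."""
    if len(ip) != len(total):
        raise ValidationError(f"{ip.gene_id}: IP and total profile lengths differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total.values > 0, ip.values / total.values, np.nan)
    return EnrichmentProfile(
        gene_id=ip.gene_id, bait=ip.bait, values=ratio,
        exon_mask=ip.exon_mask, source_window=ip.window,
    )


def auc(values: np.ndarray, exon_mask: np.ndarray | None = None) -> float:
    """Trapezoidal area under the curve over exonic, defined positions.

    Intronic and undefined (NaN) positions are dropped and the retained
    positions are integrated with unit spacing between consecutive survivors.
    With fewer than 2 usable positions the AUC is recorded as 0.
    """
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if exon_mask is not None:
        keep &= np.asarray(exon_mask, dtype=bool)
    usable = values[keep]
    if usable.size < 2:
        return 0.0
    return float(np.trapezoid(usable))


def enrichment_auc(enr: EnrichmentProfile) -> float:
    return auc(enr.values, enr.exon_mask)


# ---------------------------------------------------------------------------
# Per-gene scoring driver
# ---------------------------------------------------------------------------

def _condition_summary(tracks: list[CountTrack], gene: GeneModel, window: int,
                       alignment: str):
    """Smoothed replicate profiles + their average for one gene/condition."""
    smoothed = [
        smooth_profile(extract_gene_profile(t, gene), window, alignment) for t in tracks
    ]
    return smoothed, average_replicates(smoothed)


def score_gene(
    gene: GeneModel,
    bait_ip: list[CountTrack],
    bait_total: list[CountTrack],
    wt_ip: list[CountTrack],
    wt_total: list[CountTrack],
    window: int = 100,
    alignment: str = "centered",
) -> tuple[GeneScore, EnrichmentProfile, GeneProfile]:
    """Compute the full per-gene decision record for one bait.

    Returns the score, the bait enrichment profile (for onset detection) and
    the averaged smoothed bait *total* profile (for occupancy analyses).
    Replicate correlation is computed on the smoothed bait IP profiles, where
    the selective signal lives.
    """
    ip_reps, ip_avg = _condition_summary(bait_ip, gene, window, alignment)
    _, total_avg = _condition_summary(bait_total, gene, window, alignment)
    _, wt_ip_avg = _condition_summary(wt_ip, gene, window, alignment)
    _, wt_total_avg = _condition_summary(wt_total, gene, window, alignment)

    enr = enrichment_profile(ip_avg, total_avg)
    enr_wt = enrichment_profile(wt_ip_avg, wt_total_avg)

    score = GeneScore(
        gene_id=gene.gene_id,
        bait=bait_ip[0].bait,
        auc_ip=auc(ip_avg.values, ip_avg.exon_mask),
        auc_total=auc(total_avg.values, total_avg.exon_mask),
        auc_fc=enrichment_auc(enr),
        auc_fc_wt=enrichment_auc(enr_wt),
        coverage_ip=coverage_percent(ip_avg),
        coverage_total=coverage_percent(total_avg),
        mean_replicate_corr=(
            replicate_correlation(ip_reps) if len(ip_reps) >= 2 else float("nan")
        ),
    )
    return score, enr, total_avg
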