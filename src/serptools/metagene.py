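"""Length-normalized metagene profiles and onset-aligned occupancy.

Each gene profile is first mean-normalized (value x length / sum, so the
profile's mean becomes exactly 1) and then scaled onto a common 0-100%
coordinate by binning.  Confidence bands are the normal-approximation 95%
interval on the across-gene per-bin mean.

Onset-aligned occupancy aggregates *total* (translatome) profiles around the
detected binding onsets, asking whether ribosome occupancy before the onset
exceeds occupancy after it — the signature of a translational pause preceding
factor engagement.  The test is a paired two-sided t-test on the per-gene
before/after window means by default (an unpaired variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .onsets import OnsetCall
from .profiles import GeneProfile


@dataclass
class MetageneProfile:
    bins: np.ndarray          # 1..n_bins (percent-of-ORF bins)
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_genes: int


@dataclass
class OnsetAlignedProfile:
    offsets: np.ndarray       # nt relative to onset, -W..+W
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    before_mean: float        # mean of per-gene means over offsets < 0
    after_mean: float         # mean of per-gene means over offsets >= 0
    t_statistic: float
    p_value: float
    n_genes: int


def _nan_mean(mat: np.ndarray, axis: int) -> np.ndarray:
    """np.nanmean that stays quiet on all-NaN slices (they yield NaN)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=axis)


def _nan_sem(mat: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Column-wise SEM ignoring NaNs; columns with n <= 1 yield 0."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd), sd, 0.0)
    return sd / np.sqrt(np.maximum(n, 1))


class ZeroSumProfileError(ValueError):
    """A profile with zero total signal cannot be mean-normalized."""


def normalize_for_metagene(profile: GeneProfile) -> np.ndarray:
    """Mean-normalize: v -> v * L / sum(v), so the output mean is exactly 1."""
    v = profile.values
    total = v.sum()
    if total <= 0:
        raise ZeroSumProfileError(f"{profile.gene_id}: profile sum is zero")
    return v * (v.size / total)


def bin_assignments(length: int, bins: int = 100) -> np.ndarray:
    """Bin index (1-based) for each position: floor(bins * (i-1) / L) + 1."""
    i = np.arange(length)
    return (bins * i) // length + 1


def metagene_scaled(normalized: list[np.ndarray], bins: int = 100) -> MetageneProfile:
    """Scale profiles to 100% and aggregate per-bin by averaging.

    Per gene, each bin's value is the mean of that gene's positions falling
    in the bin (bins a short gene leaves empty are skipped for that gene).
    Across genes, the band is mean +/- 1.96 * SEM; at n = 1 the band collapses
    onto the mean.
    """
    if not normalized:
        raise ValueError("no profiles to aggregate")
    per_gene = np.full((len(normalized), bins), np.nan)
    for k, v in enumerate(normalized):
        which = bin_assignments(v.size, bins) - 1
        sums = np.bincount(which, weights=v, minlength=bins)
        counts = np.bincount(which, minlength=bins)
        nonempty = counts > 0
        per_gene[k, nonempty] = sums[nonempty] / counts[nonempty]

    n = np.sum(~np.isnan(per_gene), axis=0)
    mean = _nan_mean(per_gene, axis=0)
    sem = np.where(n > 1, _nan_sem(per_gene, n), 0.0)
    return MetageneProfile(
        bins=np.arange(1, bins + 1), mean=mean,
        ci_low=mean - 1.96 * sem, ci_high=mean + 1.96 * sem,
        n_genes=len(normalized),
    )


def onset_aligned_occupancy(
    profiles: dict[str, np.ndarray],
    onsets: list[OnsetCall],
    half_window: int = 90,
    paired: bool = True,
) -> OnsetAlignedProfile:
    """Aggregate normalized total-occupancy around onsets; test before vs after.

    ``profiles`` maps gene_id to a mean-normalized ORF occupancy vector
    (1 nt resolution, index 0 = ORF position 1).  Offsets run from
    -half_window to +half_window with offset 0 at the onset nucleotide; a
    gene whose window exceeds its ORF bounds contributes only the offsets it
    covers.  Genes without an onset are skipped.
    """
    W = half_window
    offsets = np.arange(-W, W + 1)
    rows = []
    for call in onsets:
        if call.onset_nt is None:
            continue
        v = profiles.get(call.gene_id)
        if v is None:
            continue
        window = np.full(2 * W + 1, np.nan)
        center = call.onset_nt - 1
        lo = max(0, center - W)
        hi = min(v.size, center + W + 1)
        window[(lo - center) + W : (hi - center) + W] = v[lo:hi]
        rows.append(window)
    if len(rows) < 2:
        raise ValueError("need >= 2 genes with onsets for an aligned profile")
    mat = np.vstack(rows)

    n = np.sum(~np.isnan(mat), axis=0)
    mean = _nan_mean(mat, axis=0)
    sem = np.where(n > 1, _nan_sem(mat, n), 0.0)

    before = _nan_mean(mat[:, offsets < 0], axis=1)
    after = _nan_mean(mat[:, offsets >= 0], axis=1)
    ok = np.isfinite(before) & np.isfinite(after)
    before, after = before[ok], after[ok]
    if paired:
        if np.allclose(before, after):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_rel(before, after)
    else:
        t_stat, p = stats.ttest_ind(before, after)
    return OnsetAlignedProfile(
        offsets=offsets, mean=mean, ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
        before_mean=float(np.mean(before)), after_mean=float(np.mean(after)),
        t_statistic=float(t_stat), p_value=float(p), n_genes=int(ok.sum()),
    )


def metagene_table(profile: MetageneProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "bin": profile.bins, "mean": profile.mean,
        "ci_low": profile.ci_low, "ci_high": profile.ci_high,
    })


def occupancy_table(profile: OnsetAlignedProfile) -> pd.DataFrame:
    df = pd.DataFrame({
        "offset_nt": profile.offsets, "mean": profile.mean,
        "ci_low": profile.ci_low, "ci_high": profile.ci_high,
    })
    df.attrs["t_statistic"] = profile.t_statistic
    df.attrs["p_value"] = profile.p_value
    return df
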