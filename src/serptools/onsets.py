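"""Binding-onset detection, release detection, binding-mode classification.

The onset is the first ORF position where the enrichment profile rises above
a fold threshold (default 2, with per-gene overrides mirroring exceptions
such as a 1.5 threshold for weakly enriched targets) and stays there for a
minimum run of nucleotides.  Binding that persists to the stop codon is
"enduring"; a sustained return below the threshold before the final stretch
of the ORF marks a release and classifies the gene "transient".

Codon indexing: codon c covers ORF nucleotides 3c-2..3c, so
onset_codon = ceil(onset_nt / 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import EnrichmentProfile


@dataclass
class OnsetConfig:
    threshold: float = 2.0      # fold enrichment that defines binding
    min_run: int = 30           # nt the profile must stay above threshold
    tail_exclusion: int = 90    # final nt in which a dip does not count as release

    def __post_init__(self):
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass
class OnsetCall:
    gene_id: str
    bait: str
    onset_nt: int | None        # 1-based ORF nucleotide
    onset_codon: int | None
    release_codon: int | None
    mode: str                   # enduring | transient | none
    threshold_used: float


def _first_run(condition: np.ndarray, min_run: int, start: int = 0) -> int | None:
    """Index of the first run of >= min_run consecutive True from ``start``."""
    n = condition.size
    run = 0
    for i in range(start, n):
        run = run + 1 if condition[i] else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def detect_onset(enr: EnrichmentProfile, config: OnsetConfig,
                 threshold: float | None = None) -> OnsetCall:
    """Find the first sustained threshold crossing in ORF coordinates.

    Undefined (NaN) positions break runs: binding must be observed, not
    interpolated.  Returns mode "none" when no qualifying run exists.
    """
    thr = config.threshold if threshold is None else threshold
    values = enr.orf_values()
    above = np.isfinite(values) & (values >= thr)
    idx = _first_run(above, config.min_run)
    if idx is None:
        return OnsetCall(enr.gene_id, enr.bait, None, None, None, "none", thr)
    onset_nt = idx + 1
    return OnsetCall(
        gene_id=enr.gene_id, bait=enr.bait, onset_nt=onset_nt,
        onset_codon=math.ceil(onset_nt / 3), release_codon=None,
        mode="enduring", threshold_used=thr,
    )


def detect_release(enr: EnrichmentProfile, onset: OnsetCall,
                   config: OnsetConfig) -> OnsetCall:
    """Look for a sustained post-onset drop below threshold; set the mode.

    The drop must be a run of >= min_run *defined* values below the threshold
    whose run ends before the final ``tail_exclusion`` nt — run-off decay at
    the stop codon (the ribosome exit tunnel's worth of codons) is not a
    release.
    """
    if onset.onset_nt is None:
        return onset
    values = enr.orf_values()
    n = values.size
    below = np.isfinite(values) & (values < onset.threshold_used)
    last_allowed_end = n - config.tail_exclusion  # 1-based position the run may end at
    idx = _first_run(below, config.min_run, start=onset.onset_nt)
    while idx is not None:
        run_end_nt = idx + config.min_run  # 1-based end of the qualifying run
        if run_end_nt <= last_allowed_end:
            release_nt = idx + 1
            onset.release_codon = math.ceil(release_nt / 3)
            onset.mode = "transient"
            return onset
        idx = _first_run(below, config.min_run, start=idx + 1)
    onset.mode = "enduring"
    return onset


def call_onset(enr: EnrichmentProfile, config: OnsetConfig,
               threshold: float | None = None) -> OnsetCall:
    """Onset followed by release detection (the usual entry point)."""
    return detect_release(enr, detect_onset(enr, config, threshold), config)


def onset_window_peptide(protein: str, onset_codon: int,
                         window: tuple[int, int] = (-50, -30)) -> str:
    """Residues in a codon-offset window around the onset, clipped to the protein.

    With the default window (-50, -30) an onset at codon 100 yields residues
    50..70.  An empty result (window fully upstream of the protein start)
    returns the empty string; callers flag it.
    """
    if onset_codon <= 0:
        raise ValueError("onset_codon must be >= 1")
    lo = max(1, onset_codon + window[0])
    hi = min(len(protein), onset_codon + window[1])
    if hi < lo:
        return ""
    return protein[lo - 1 : hi]


def onset_position_distribution(onsets: list[OnsetCall],
                                orf_codons: dict[str, int],
                                bins: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Relative onset positions (onset_codon / ORF codons) plus a histogram.

    Returns a per-gene table of relative positions in (0, 1] and histogram
    counts over ``bins`` equal bins of (0, 1].
    """
    rows = []
    for call in onsets:
        if call.onset_codon is None:
            continue
        length = orf_codons[call.gene_id]
        rows.append({
            "gene_id": call.gene_id, "bait": call.bait,
            "onset_codon": call.onset_codon, "orf_codons": length,
            "relative_position": call.onset_codon / length,
        })
    if not rows:
        raise ValueError("no onsets to summarize")
    table = pd.DataFrame(rows)
    counts, _ = np.histogram(table["relative_position"], bins=bins, range=(0.0, 1.0))
    return table, counts


def read_threshold_overrides(path) -> dict[str, float]:
    """Per-gene onset-threshold overrides (TSV: gene_id, threshold)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "threshold"],
                     comment="#", dtype={"gene_id": str})
    return {row.gene_id: float(row.threshold) for row in df.itertuples()}


def onset_table(onsets: list[OnsetCall]) -> pd.DataFrame:
    rows = [{
        "gene_id": o.gene_id, "bait": o.bait, "onset_nt": o.onset_nt,
        "onset_codon": o.onset_codon, "release_codon": o.release_codon,
        "mode": o.mode, "threshold_used": o.threshold_used,
    } for o in onsets]
    df = pd.DataFrame(rows, columns=["gene_id", "bait", "onset_nt", "onset_codon",
                                     "release_codon", "mode", "threshold_used"])
    return df.sort_values("gene_id").reset_index(drop=True)
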