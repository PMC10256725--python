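"""Sequence- and set-level statistics on hits and onset windows.

Covers amino-acid composition enrichment at binding onsets, isoelectric
points of cargo proteins, GO-term over-representation, two-sample
distribution tests and the NLS fragment-tiling scheme used to prepare
structure-prediction input lists.

Fisher's exact test uses the probability-mass definition of the two-sided
p-value (sum of hypergeometric probabilities of all tables, margins fixed,
whose probability does not exceed that of the observed table).  For modest
tables the sum is evaluated in exact integer arithmetic, which makes ties
unambiguous; very large tables are delegated to scipy's implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Integer-arithmetic Fisher path is used up to this table total; beyond it the
# float implementation in scipy is both accurate and much faster.
_EXACT_FISHER_LIMIT = 1000


@dataclass(frozen=True)
class PkaTable:
    """Side-chain and termini pKa values (EMBOSS set by default)."""

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    pka: dict[str, float] | None = None

    def __post_init__(self):
        if self.pka is None:
            object.__setattr__(self, "pka", {
                "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
                "K": 10.8, "R": 12.5, "Y": 10.1,
            })
        for name, value in [("n_terminus", self.n_terminus),
                            ("c_terminus", self.c_terminus), *self.pka.items()]:
            if not (0 < value < 14):
                raise ValueError(f"pKa for {name} out of (0, 14): {value}")


POSITIVE_GROUPS = ("K", "R", "H")
NEGATIVE_GROUPS = ("D", "E", "C", "Y")


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test (amino acid or GO term)."""

    item: str
    a: int  # item in foreground
    b: int  # other in foreground
    c: int  # item in background
    d: int  # other in background
    odds_ratio: float
    p_value: float
    p_adj: float = float("nan")
    flag: str = ""


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The odds ratio is the sample version a*d/(b*c);
    a zero denominator with non-zero numerator yields +inf and a 0/0 table
    yields NaN.  Any zero margin makes the table degenerate: p = 1 by
    convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("contingency counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)

    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)

    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return odds, 1.0

    n = r1 + r2
    if n <= _EXACT_FISHER_LIMIT:
        # Margins fixed: P(table with top-left a') is proportional to
        # C(r1, a') * C(r2, c1 - a'); exact integer comparison settles ties.
        lo, hi = max(0, c1 - r2), min(r1, c1)
        weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
        observed = weights[a - lo]
        p = sum(w for w in weights if w <= observed) / math.comb(n, c1)
        return odds, float(min(1.0, p))

    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


# ---------------------------------------------------------------------------
# Multiple testing, rank tests
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Rank-sum U statistic with midrank ties and a two-sided p-value.

    Exact enumeration for combined sample size <= 12 without ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def ks_two_sided(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic Kolmogorov distribution)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 observations")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Amino-acid composition at onsets
# ---------------------------------------------------------------------------

def _residue_counts(sequences) -> tuple[dict[str, int], int]:
    counts = {aa: 0 for aa in STANDARD_AA}
    skipped = 0
    for seq in sequences:
        for ch in seq.upper():
            if ch in counts:
                counts[ch] += 1
            else:
                skipped += 1
    return counts, skipped


def aa_enrichment(window_peptides, full_proteins) -> list[EnrichmentResult]:
    """Per-residue Fisher enrichment of onset windows vs full-length proteins.

    Pools residues across all window peptides (foreground) and all full
    proteins (background); one two-sided Fisher test per standard amino acid
    with BH adjustment across the 20 tests.  Non-standard residues are
    excluded from both counts and totals (with a warning).
    """
    import warnings

    windows = [w for w in window_peptides if w]
    if not windows or not full_proteins:
        raise ValueError("both the window set and the protein set must be non-empty")
    fg, fg_skip = _residue_counts(windows)
    bg, bg_skip = _residue_counts(full_proteins)
    if fg_skip or bg_skip:
        warnings.warn(f"excluded {fg_skip + bg_skip} non-standard residue(s)",
                      stacklevel=2)
    fg_total = sum(fg.values())
    bg_total = sum(bg.values())

    results = []
    for aa in STANDARD_AA:
        a, c = fg[aa], bg[aa]
        b, d = fg_total - a, bg_total - c
        odds, p = fisher_exact_two_sided(a, b, c, d)
        flag = "odds_infinite" if np.isinf(odds) else ""
        results.append(EnrichmentResult(aa, a, b, c, d, odds, p, flag=flag))
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    return results


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

def net_charge(sequence: str, ph: float, pka: PkaTable | None = None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    pka = pka or PkaTable()
    counts = {}
    for ch in sequence.upper():
        counts[ch] = counts.get(ch, 0) + 1
    positive = sum(
        counts.get(aa, 0) / (1 + 10 ** (ph - pka.pka[aa])) for aa in POSITIVE_GROUPS
    ) + 1 / (1 + 10 ** (ph - pka.n_terminus))
    negative = sum(
        counts.get(aa, 0) / (1 + 10 ** (pka.pka[aa] - ph)) for aa in NEGATIVE_GROUPS
    ) + 1 / (1 + 10 ** (pka.c_terminus - ph))
    return positive - negative


def isoelectric_point(sequence: str, pka: PkaTable | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge vanishes, by bisection on [0, 14].

    The termini always ionize, so the charge is positive at pH 0 and negative
    at pH 14 and a root exists.  Depends only on composition, not on residue
    order.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence.upper()) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    pka = pka or PkaTable()
    lo, hi = 0.0, 14.0
    mid = 7.0
    # converge the bracket itself, not just |Q| < tol: near-flat charge
    # curves would otherwise stop millipH-units away from the root
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2
        q = net_charge(sequence, mid, pka)
        if q > 0:
            lo = mid
        else:
            hi = mid
    if abs(net_charge(sequence, mid, pka)) > tol:
        raise ArithmeticError("net-charge root not bracketed")  # unreachable
    return mid


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def go_enrichment(
    hit_genes,
    background_genes,
    go_map: pd.DataFrame,
    min_term_size: int = 100,
    report_p: float = 0.1,
) -> pd.DataFrame:
    """Fisher odds enrichment of each GO term in the hit set vs the background.

    Only terms annotating strictly more than ``min_term_size`` background
    genes are tested.  Terms with unadjusted p <= ``report_p`` are flagged as
    reported (mirroring an unadjusted 0.1 screening convention); a BH column
    is emitted alongside for reference.
    """
    hits = set(hit_genes)
    background = set(background_genes)
    if not hits:
        raise ValueError("empty hit set")
    if not hits <= background:
        raise ValueError("hit set must be a subset of the background")

    rows = []
    for (term_id, term_name), group in go_map.groupby(["term_id", "term_name"]):
        members = set(group["gene_id"]) & background
        if len(members) <= min_term_size:
            continue
        a = len(hits & members)
        b = len(hits - members)
        c = len(members - hits)
        d = len(background - hits - members)
        odds, p = fisher_exact_two_sided(a, b, c, d)
        rows.append({
            "term_id": term_id, "term_name": term_name, "term_size": len(members),
            "hits_in_term": a, "hits_not_in_term": b,
            "background_in_term": c, "background_not_in_term": d,
            "odds_ratio": odds, "p_value": p,
        })
    df = pd.DataFrame(rows, columns=[
        "term_id", "term_name", "term_size", "hits_in_term", "hits_not_in_term",
        "background_in_term", "background_not_in_term", "odds_ratio", "p_value",
    ])
    if len(df):
        df["p_adj"] = bh_adjust(df["p_value"].to_numpy())
        df["reported"] = df["p_value"] <= report_p
        df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["reported"] = pd.Series(dtype=bool)
    return df


def set_overlap(hit_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise intersection/union counts across hit sets (Venn-style summary)."""
    names = sorted(hit_sets)
    rows = []
    for i, x in enumerate(names):
        for y in names[i:]:
            inter = hit_sets[x] & hit_sets[y]
            union = hit_sets[x] | hit_sets[y]
            rows.append({"set_a": x, "set_b": y, "size_a": len(hit_sets[x]),
                         "size_b": len(hit_sets[y]), "intersection": len(inter),
                         "union": len(union)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NLS fragment tiling
# ---------------------------------------------------------------------------

def nls_fragment_tiling(
    protein: str,
    frag_len: int = 100,
    overlap: int = 50,
    max_residue: int = 550,
) -> list[tuple[int, int, str]]:
    """Tile a protein into overlapping fragments for structure-prediction input.

    Fragments start at residue 1 and advance by ``frag_len - overlap`` until
    the start exceeds min(protein length, ``max_residue``); each fragment
    spans [start, min(start + frag_len - 1, L)].  The final short fragment is
    retained.  Returns (start, end, sequence) with 1-based inclusive bounds.
    """
    if not protein:
        raise ValueError("protein sequence must be non-empty")
    if overlap >= frag_len:
        raise ValueError("overlap must be smaller than frag_len")
    L = len(protein)
    step = frag_len - overlap
    fragments = []
    start = 1
    while start <= min(L, max_residue):
        end = min(start + frag_len - 1, L)
        fragments.append((start, end, protein[start - 1 : end]))
        if end == L:
            break
        start += step
    return fragments


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [{
        "item": r.item, "fg_count": r.a, "fg_other": r.b,
        "bg_count": r.c, "bg_other": r.d, "odds_ratio": r.odds_ratio,
        "p_value": r.p_value, "p_adj": r.p_adj, "flag": r.flag,
    } for r in results]
    return pd.DataFrame(rows)
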