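"""End-to-end orchestration: score -> call -> onsets -> metagene -> stats.

The pipeline can run fully in memory (``analyze_experiment``, used heavily in
testing and simulation studies) or from an on-disk dataset described by a
YAML config (``run_pipeline``), writing TSV tables plus a JSON manifest with
config/input checksums and per-stage gene counts.

A single calibration bait supplies the FDR threshold, which is then applied
to every analyzed bait — the way a curated truth list for one well-studied
factor is used to set the cut-off for a whole panel of pulldowns.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import feature_stats, metagene as metagene_mod
from .io_formats import (
    CountTrack, GenomeAnnotation, read_annotation, read_chrom_sizes,
    read_count_track, read_gene_list, read_go_map, read_protein_fasta,
    read_truth_set, track_filename, write_hit_table,
)
from .metagene import metagene_scaled, normalize_for_metagene, onset_aligned_occupancy
from .onsets import (
    OnsetCall, OnsetConfig, call_onset, onset_table, onset_window_peptide,
    read_threshold_overrides,
)
from .profiles import (
    EnrichmentProfile, GeneProfile, GeneScore, average_replicates,
    extract_gene_profile, score_gene,
)
from .target_calling import (
    CalibrationError, FilterConfig, RocPoint, apply_prefilters, calibrate_threshold,
    call_hits, prefilter_pass,
)

__version__ = "0.1.0"

TABLE_FLOAT_FORMAT = "%.6g"


class ConfigurationError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


@dataclass
class PipelineConfig:
    annotation: str
    chrom_sizes: str | None
    tracks_dir: str
    proteins: str | None
    truth_set: str | None
    output_dir: str
    baits: list[str]
    calibration_bait: str
    replicates: int = 4
    negative_set: str | None = None
    go_map: str | None = None
    onset_threshold_overrides: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    onsets: OnsetConfig = field(default_factory=OnsetConfig)
    smoothing_window: int = 100
    smoothing_alignment: str = "centered"
    metagene_bins: int = 100
    occupancy_half_window: int = 90
    occupancy_paired: bool = True
    fixed_threshold: float | None = None
    onset_window: tuple[int, int] = (-50, -30)
    seed: int = 0


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        paths = raw["paths"]
        base = Path(path).parent

        def resolve(key, default=None):
            value = paths.get(key, default)
            return str(base / value) if value is not None else None

        smoothing = raw.get("smoothing", {})
        met = raw.get("metagene", {})
        threshold = raw.get("threshold", {})
        return PipelineConfig(
            annotation=resolve("annotation"),
            chrom_sizes=resolve("chrom_sizes"),
            tracks_dir=resolve("tracks_dir", "."),
            proteins=resolve("proteins"),
            truth_set=resolve("truth_set"),
            negative_set=resolve("negative_set"),
            go_map=resolve("go_map"),
            onset_threshold_overrides=resolve("onset_threshold_overrides"),
            output_dir=resolve("output_dir", "results"),
            baits=list(raw["baits"]),
            calibration_bait=raw.get("calibration_bait", raw["baits"][0]),
            replicates=int(raw.get("replicates", 4)),
            filters=FilterConfig(**raw.get("filters", {})),
            onsets=OnsetConfig(**raw.get("onsets", {})),
            smoothing_window=int(smoothing.get("window", 100)),
            smoothing_alignment=smoothing.get("alignment", "centered"),
            metagene_bins=int(met.get("bins", 100)),
            occupancy_half_window=int(met.get("half_window", 90)),
            occupancy_paired=bool(met.get("paired", True)),
            fixed_threshold=threshold.get("fixed_percent"),
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing config key {exc}") from None


# ---------------------------------------------------------------------------
# In-memory analysis
# ---------------------------------------------------------------------------

@dataclass
class BaitAnalysis:
    """Everything computed for one bait against the no-bait control."""

    bait: str
    scores: list[GeneScore]
    threshold: float
    threshold_source: str                     # calibrated | fixed
    roc: list[RocPoint]
    enrichments: dict[str, EnrichmentProfile]
    onsets: list[OnsetCall]

    def hits(self) -> list[GeneScore]:
        return [s for s in self.scores if s.is_hit]

    def prefiltered(self) -> list[GeneScore]:
        return [s for s in self.scores if prefilter_pass(s)]


def _tracks_for(tracks: dict, bait: str, condition: str,
                replicates: int) -> list[CountTrack]:
    out = []
    for rep in range(1, replicates + 1):
        key = (bait, condition, rep)
        if key not in tracks:
            raise ConfigurationError(f"missing track {key}")
        out.append(tracks[key])
    return out


def analyze_experiment(
    annotation: GenomeAnnotation,
    tracks: dict[tuple[str, str, int], CountTrack],
    bait: str,
    truth_ids=None,
    negative_ids=None,
    filters: FilterConfig | None = None,
    onset_config: OnsetConfig | None = None,
    replicates: int = 4,
    window: int = 100,
    alignment: str = "centered",
    fixed_threshold: float | None = None,
    threshold_overrides: dict[str, float] | None = None,
    no_bait: str = "no_bait",
) -> BaitAnalysis:
    """Score all quantifiable genes for one bait, calibrate and call hits.

    Transposon-flagged genes are excluded before scoring.  When
    ``fixed_threshold`` is given calibration is skipped entirely.
    """
    filters = filters or FilterConfig()
    onset_config = onset_config or OnsetConfig()
    overrides = threshold_overrides or {}

    bait_ip = _tracks_for(tracks, bait, "ip", replicates)
    bait_total = _tracks_for(tracks, bait, "total", replicates)
    wt_ip = _tracks_for(tracks, no_bait, "ip", replicates)
    wt_total = _tracks_for(tracks, no_bait, "total", replicates)

    scores: list[GeneScore] = []
    enrichments: dict[str, EnrichmentProfile] = {}
    for gene in annotation.coding_genes():
        score, enr, _total = score_gene(
            gene, bait_ip, bait_total, wt_ip, wt_total,
            window=window, alignment=alignment,
        )
        scores.append(score)
        enrichments[gene.gene_id] = enr
    apply_prefilters(scores, filters)

    prefiltered = [s for s in scores if prefilter_pass(s)]
    if fixed_threshold is not None:
        threshold, roc, source = float(fixed_threshold), [], "fixed"
    else:
        if not truth_ids:
            raise ConfigurationError(
                "FDR calibration requested but no truth set supplied"
            )
        truth = set(truth_ids)
        if not prefiltered:
            raise CalibrationError("no genes survive the prefilters")
        scaled = np.array([s.scaled_auc for s in prefiltered])
        is_truth = np.array([s.gene_id in truth for s in prefiltered])
        is_negative = None
        if negative_ids:
            negatives = set(negative_ids)
            is_negative = np.array([s.gene_id in negatives for s in prefiltered])
        threshold, roc = calibrate_threshold(scaled, is_truth, filters.fdr,
                                             is_negative)
        source = "calibrated"
    call_hits(scores, threshold, filters)

    onset_calls = [
        call_onset(enrichments[s.gene_id], onset_config,
                   overrides.get(s.gene_id))
        for s in scores if s.is_hit
    ]
    return BaitAnalysis(bait=bait, scores=scores, threshold=threshold,
                        threshold_source=source, roc=roc,
                        enrichments=enrichments, onsets=onset_calls)


def occupancy_profiles(
    annotation: GenomeAnnotation,
    tracks: dict,
    bait: str,
    gene_ids,
    replicates: int = 4,
) -> dict[str, np.ndarray]:
    """Mean-normalized raw total-occupancy ORF vectors, replicate-averaged.

    Raw (unsmoothed) profiles keep a short pause bump sharp; normalization
    makes genes of different expression comparable.
    """
    totals = _tracks_for(tracks, bait, "total", replicates)
    by_id = annotation.by_id()
    out: dict[str, np.ndarray] = {}
    for gid in gene_ids:
        gene = by_id[gid]
        avg = average_replicates([extract_gene_profile(t, gene) for t in totals])
        orf = avg.orf_values()
        total = orf.sum()
        if total <= 0:
            continue
        out[gid] = orf * (orf.size / total)
    return out


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_tracks(config: PipelineConfig,
                chrom_lengths: dict[str, int]) -> dict:
    tracks = {}
    for bait in [*config.baits, "no_bait"]:
        for condition in ("ip", "total"):
            for rep in range(1, config.replicates + 1):
                path = Path(config.tracks_dir) / track_filename(bait, condition, rep)
                if not path.exists():
                    raise ConfigurationError(f"missing track file {path}")
                tracks[(bait, condition, rep)] = read_count_track(
                    path, condition, bait, rep, chrom_lengths
                )
    return tracks


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write tables plus a manifest; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_lengths = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
    annotation = read_annotation(config.annotation, chrom_lengths)
    tracks = load_tracks(config, annotation.chrom_lengths)
    proteins = read_protein_fasta(config.proteins) if config.proteins else {}
    truth = (read_truth_set(config.truth_set, annotation).gene_ids
             if config.truth_set else None)
    negatives = (read_gene_list(config.negative_set)
                 if config.negative_set else None)
    overrides = (read_threshold_overrides(config.onset_threshold_overrides)
                 if config.onset_threshold_overrides else None)

    if config.fixed_threshold is None and not truth:
        raise ConfigurationError("FDR calibration requires a truth set "
                                 "(or set threshold.fixed_percent)")

    # The calibration bait fixes the cut-off for the whole panel.
    shared_kwargs = dict(
        filters=config.filters, onset_config=config.onsets,
        replicates=config.replicates, window=config.smoothing_window,
        alignment=config.smoothing_alignment, threshold_overrides=overrides,
    )
    analyses: dict[str, BaitAnalysis] = {}
    calibration = analyze_experiment(
        annotation, tracks, config.calibration_bait, truth_ids=truth,
        negative_ids=negatives, fixed_threshold=config.fixed_threshold,
        **shared_kwargs,
    )
    analyses[config.calibration_bait] = calibration
    for bait in config.baits:
        if bait not in analyses:
            analyses[bait] = analyze_experiment(
                annotation, tracks, bait,
                fixed_threshold=calibration.threshold, **shared_kwargs,
            )
            analyses[bait].threshold_source = (
                f"from_{config.calibration_bait}_{calibration.threshold_source}"
            )

    by_id = annotation.by_id()
    stages: dict[str, dict] = {}
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT,
                  na_rep="NA")
        outputs.append(name)

    for bait, analysis in analyses.items():
        write_hit_table(analysis.scores, outdir / f"hits.{bait}.tsv")
        outputs.append(f"hits.{bait}.tsv")
        if analysis.roc:
            emit(pd.DataFrame([asdict(p) for p in analysis.roc]),
                 f"roc.{bait}.tsv")
        emit(onset_table(analysis.onsets), f"onsets.{bait}.tsv")

        hits = [s.gene_id for s in analysis.hits()]
        stages[bait] = {
            "quantified": len(analysis.scores),
            "prefiltered": len(analysis.prefiltered()),
            "hits": len(hits),
            "onsets": sum(1 for o in analysis.onsets if o.onset_nt is not None),
            "threshold": analysis.threshold,
            "threshold_source": analysis.threshold_source,
        }

        # Metagene of smoothed, averaged profiles over the hit set.
        if hits:
            for condition in ("ip", "total"):
                reps = _tracks_for(tracks, bait, condition, config.replicates)
                normalized = []
                for gid in hits:
                    from .profiles import smooth_profile
                    smoothed = [smooth_profile(extract_gene_profile(t, by_id[gid]),
                                               config.smoothing_window,
                                               config.smoothing_alignment)
                                for t in reps]
                    avg = average_replicates(smoothed)
                    if avg.values.sum() > 0:
                        normalized.append(normalize_for_metagene(avg))
                if normalized:
                    prof = metagene_scaled(normalized, config.metagene_bins)
                    emit(metagene_mod.metagene_table(prof),
                         f"metagene_{condition}.{bait}.tsv")

        with_onset = [o for o in analysis.onsets if o.onset_nt is not None]
        if len(with_onset) >= 2:
            occ = occupancy_profiles(annotation, tracks, bait,
                                     [o.gene_id for o in with_onset],
                                     config.replicates)
            try:
                aligned = onset_aligned_occupancy(
                    occ, with_onset, config.occupancy_half_window,
                    config.occupancy_paired,
                )
                table = metagene_mod.occupancy_table(aligned)
                table["t_statistic"] = aligned.t_statistic
                table["p_value"] = aligned.p_value
                emit(table, f"occupancy.{bait}.tsv")
                stages[bait]["occupancy_p"] = aligned.p_value
            except ValueError as exc:
                stages[bait]["occupancy_skipped"] = str(exc)

        # Sequence statistics over the hit set.
        if proteins and with_onset:
            windows = [
                onset_window_peptide(proteins[o.gene_id], o.onset_codon,
                                     config.onset_window)
                for o in with_onset if o.gene_id in proteins
            ]
            windows = [w for w in windows if w]
            hit_seqs = [proteins[g] for g in hits if g in proteins]
            if windows and hit_seqs:
                emit(feature_stats.enrichment_table(
                    feature_stats.aa_enrichment(windows, hit_seqs)),
                    f"aa_enrichment.{bait}.tsv")
        if proteins and hits:
            quantified = [s.gene_id for s in analysis.scores]
            pi_rows = [{
                "gene_id": gid,
                "pI": feature_stats.isoelectric_point(proteins[gid]),
                "is_hit": gid in set(hits),
            } for gid in quantified if gid in proteins]
            pi_df = pd.DataFrame(pi_rows)
            emit(pi_df, f"pi_values.{bait}.tsv")
            hit_pi = pi_df.loc[pi_df.is_hit, "pI"].to_numpy()
            other_pi = pi_df.loc[~pi_df.is_hit, "pI"].to_numpy()
            if hit_pi.size >= 1 and other_pi.size >= 1:
                u, p = feature_stats.mann_whitney_u(hit_pi, other_pi)
                emit(pd.DataFrame([{
                    "comparison": "hits_vs_quantified", "n_hits": hit_pi.size,
                    "n_other": other_pi.size, "U": u, "p_value": p,
                }]), f"pi_mwu.{bait}.tsv")
        if config.go_map and Path(config.go_map).exists() and hits:
            go_df = feature_stats.go_enrichment(
                hits, [s.gene_id for s in analysis.scores],
                read_go_map(config.go_map),
            )
            emit(go_df, f"go_enrichment.{bait}.tsv")

    if len(config.baits) >= 2:
        emit(compare_baits({b: analyses[b] for b in config.baits}),
             "bait_comparison.tsv")

    inputs = {}
    for label in ("annotation", "chrom_sizes", "proteins", "truth_set",
                  "negative_set", "go_map"):
        path = getattr(config, label)
        if path and Path(path).exists():
            inputs[label] = _sha256(path)

    manifest = {
        "tool": "serptools",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": inputs,
        "stages": stages,
        "outputs": sorted(outputs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def compare_baits(analyses: dict[str, BaitAnalysis]) -> pd.DataFrame:
    """Pairwise scaled-AUC Pearson correlation and hit-set overlap across baits."""
    names = sorted(analyses)
    scaled = {}
    hit_sets = {}
    for name in names:
        scaled[name] = {s.gene_id: s.scaled_auc for s in analyses[name].scores}
        hit_sets[name] = {s.gene_id for s in analyses[name].hits()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            common = sorted(set(scaled[a]) & set(scaled[b]))
            if not common:
                raise ValueError(f"baits {a} and {b} share no quantified genes")
            x = np.array([scaled[a][g] for g in common])
            y = np.array([scaled[b][g] for g in common])
            ok = np.isfinite(x) & np.isfinite(y)
            r = float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() >= 2 else float("nan")
            rows.append({
                "bait_a": a, "bait_b": b, "n_common": int(ok.sum()),
                "scaled_auc_pearson_r": r,
                "hits_a": len(hit_sets[a]), "hits_b": len(hit_sets[b]),
                "hit_intersection": len(hit_sets[a] & hit_sets[b]),
                "hit_union": len(hit_sets[a] | hit_sets[b]),
            })
    return pd.DataFrame(rows)
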