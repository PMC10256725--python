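"""Synthetic SeRP experiments with planted ground truth.

The generator emulates the structure of a selective-ribosome-profiling study:
four biological replicates of an affinity-purified (IP) and a matched total
translatome library for one tagged bait, plus the same pair for an untagged
no-bait control.  Footprint density is restricted to ORFs and overdispersed
(negative binomial around a per-gene lognormal expression level).  Planted
targets carry a step-like IP enrichment that starts at a planted onset codon
and either persists to the stop codon (enduring) or ends at a planted release
codon (transient); background genes and all no-bait genes get a lognormal
per-gene x replicate enrichment factor centered on 1.  An optional
multiplicative occupancy bump over the window preceding the onset emulates a
translational pause and is applied to the IP and total expectations alike
(it is a ribosome-occupancy effect, not a capture effect).

Enrichment acts on the *expectation*, not on realized counts: noise enters
only through the count draws.

Reproducibility contract: every track draws from its own generator seeded by
(seed, bait, condition, replicate), so any single file can be regenerated
independently of generation order; identical configs produce byte-identical
datasets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountTrack, GeneModel, GenomeAnnotation,
    track_filename, write_annotation, write_chrom_sizes, write_count_track,
    write_gene_list, write_protein_fasta,
)

CHROMOSOME = "chrSim"
AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class SizingError(ValueError):
    """The requested genes do not fit on the configured chromosome."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Lengths are in codons unless a field name says nt.  ``dispersion`` is the
    negative-binomial overdispersion alpha (variance = mu + alpha * mu^2);
    zero gives Poisson counts.
    """

    seed: int
    n_target_genes: int = 50
    n_background_genes: int = 250
    n_transposon_genes: int = 2
    gene_length_range: tuple[int, int] = (300, 600)
    replicates: int = 4
    depth_mean: float = 20.0
    dispersion: float = 0.3
    gene_mean_sigma: float = 0.5          # lognormal spread of per-gene expression
    enrichment_amplitude_range: tuple[float, float] = (4.0, 10.0)
    onset_codon_fraction_range: tuple[float, float] = (0.1, 0.5)
    p_transient: float = 0.1
    transient_duration_range: tuple[int, int] = (150, 250)
    pause_bump: float = 2.0               # occupancy factor over the pre-onset window
    pause_window_nt: int = 60
    background_enrichment_sd: float = 0.1  # lognormal sd of no-signal enrichment
    capture_scale: float = 1.0
    intron_fraction: float = 0.1
    intron_length_range: tuple[int, int] = (60, 200)
    gap_range: tuple[int, int] = (150, 300)
    kr_window_enrichment: float = 3.0     # K/R boost in the pre-onset peptide window
    kr_window: tuple[int, int] = (-50, -30)
    truth_fraction: float = 0.5           # share of targets on the curated positive list
    negative_fraction: float = 0.5        # share of background on the curated negative list
    bait: str = "bait"
    chrom_length: int | None = None       # fixed capacity; None grows as needed
    emit_go_map: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        for name in ("gene_length_range", "enrichment_amplitude_range",
                     "onset_codon_fraction_range", "intron_length_range",
                     "gap_range", "transient_duration_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is degenerate: {lo} > {hi}")
        if self.enrichment_amplitude_range[0] < 1:
            raise ValueError("enrichment amplitudes must be >= 1")
        if not (0 <= self.p_transient <= 1):
            raise ValueError("p_transient must be within [0, 1]")
        if self.depth_mean <= 0 or self.dispersion < 0:
            raise ValueError("depth_mean must be > 0 and dispersion >= 0")


@dataclass
class GeneTruth:
    """Planted ground truth for one gene."""

    gene_id: str
    is_target: bool
    onset_codon: int | None = None
    amplitude: float = 1.0
    release_codon: int | None = None
    pause_factor: float = 1.0
    expression_mean: float = 0.0   # generator-internal: expected counts/nt

    def __post_init__(self):
        if self.is_target and self.amplitude < 1:
            raise ValueError(f"{self.gene_id}: target amplitude must be >= 1")
        if (self.onset_codon is not None and self.release_codon is not None
                and not self.onset_codon < self.release_codon):
            raise ValueError(f"{self.gene_id}: onset must precede release")


def _rng_for(seed: int, *labels) -> np.random.Generator:
    words = [seed & 0x7FFFFFFF]
    for label in labels:
        if isinstance(label, str):
            words.append(zlib.crc32(label.encode()))
        else:
            words.append(int(label))
    return np.random.default_rng(words)


# ---------------------------------------------------------------------------
# Genome, proteins, truth
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig):
    """Build the synthetic chromosome: annotation, proteins and planted truth.

    Genes are placed non-overlapping with >= 150 nt gaps on one chromosome;
    about 10% receive a single intron (exercising intron exclusion in the
    AUC), and transposon-flagged decoy genes are appended.  Proteins are
    random sequences; in target genes the window upstream of the planted
    onset is enriched for lysine/arginine, emulating the basic residue
    signature of NLS-proximal binding sites.

    Returns (annotation, proteins, truth) with truth a gene_id -> GeneTruth map.
    """
    rng = _rng_for(config.seed, "genome")
    n_coding = config.n_target_genes + config.n_background_genes
    n_total = n_coding + config.n_transposon_genes
    if n_total < 1:
        raise ValueError("no genes requested")
    width = max(4, len(str(n_total)))

    genes: list[GeneModel] = []
    pos = 0
    for k in range(n_total):
        gene_id = f"gene_{k + 1:0{width}d}"
        gap = int(rng.integers(config.gap_range[0], config.gap_range[1] + 1))
        codons = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        exonic = 3 * codons
        start = pos + gap + 1
        strand = "+" if rng.random() < 0.5 else "-"
        has_intron = exonic >= 120 and rng.random() < config.intron_fraction
        if has_intron:
            intron = int(rng.integers(config.intron_length_range[0],
                                      config.intron_length_range[1] + 1))
            split = int(rng.integers(30, exonic - 29))  # nt of exon 1
            exons = (
                (start, start + split - 1),
                (start + split + intron, start + exonic + intron - 1),
            )
        else:
            exons = ((start, start + exonic - 1),)
        is_tn = k >= n_coding
        genes.append(GeneModel(gene_id, CHROMOSOME, strand, exons, is_tn))
        pos = exons[-1][1]

    chrom_length = pos + config.gap_range[0]
    if config.chrom_length is not None:
        if pos > config.chrom_length:
            raise SizingError(
                f"{n_total} genes need {pos} nt but chromosome is "
                f"{config.chrom_length} nt"
            )
        chrom_length = config.chrom_length
    annotation = GenomeAnnotation(genes, {CHROMOSOME: chrom_length})

    coding_ids = [g.gene_id for g in genes if not g.is_transposon]
    target_ids = set(
        rng.choice(coding_ids, size=config.n_target_genes, replace=False)
    ) if config.n_target_genes else set()

    lengths = {g.gene_id: g.n_codons for g in genes}
    truth: dict[str, GeneTruth] = {}
    pause = config.pause_bump if config.pause_bump and config.pause_bump != 1 else 1.0
    for g in genes:
        expression = config.depth_mean * float(np.exp(
            rng.normal(0.0, config.gene_mean_sigma) - config.gene_mean_sigma ** 2 / 2
        ))
        if g.gene_id in target_ids:
            codons = lengths[g.gene_id]
            frac = rng.uniform(*config.onset_codon_fraction_range)
            onset = int(np.clip(round(frac * codons), 10, max(10, codons - 40)))
            amplitude = float(rng.uniform(*config.enrichment_amplitude_range))
            release = None
            if rng.random() < config.p_transient:
                duration = int(rng.integers(config.transient_duration_range[0],
                                            config.transient_duration_range[1] + 1))
                candidate = onset + duration
                if candidate <= codons - 40:
                    release = candidate
            truth[g.gene_id] = GeneTruth(
                g.gene_id, True, onset_codon=onset, amplitude=amplitude,
                release_codon=release, pause_factor=pause,
                expression_mean=expression,
            )
        else:
            truth[g.gene_id] = GeneTruth(g.gene_id, False,
                                         expression_mean=expression)

    base_freqs = np.full(20, 1 / 20)
    proteins: dict[str, str] = {}
    for g in genes:
        codons = lengths[g.gene_id]
        residues = rng.choice(AA_ALPHABET, size=codons, p=base_freqs)
        rec = truth[g.gene_id]
        if rec.is_target and config.kr_window_enrichment != 1:
            lo = max(1, rec.onset_codon + config.kr_window[0])
            hi = min(codons, rec.onset_codon + config.kr_window[1])
            if hi >= lo:
                boosted = base_freqs.copy()
                for aa in ("K", "R"):
                    boosted[np.where(AA_ALPHABET == aa)[0][0]] *= config.kr_window_enrichment
                boosted /= boosted.sum()
                residues[lo - 1 : hi] = rng.choice(AA_ALPHABET, size=hi - lo + 1,
                                                   p=boosted)
        proteins[g.gene_id] = "".join(residues)
    return annotation, proteins, truth


# ---------------------------------------------------------------------------
# Count tracks
# ---------------------------------------------------------------------------

def _orf_to_genomic(gene: GeneModel) -> np.ndarray:
    """Genomic 0-based indices of ORF positions in 5'->3' mRNA order."""
    idx = np.concatenate([np.arange(s - 1, e) for s, e in gene.exons])
    return idx[::-1] if gene.strand == "-" else idx


def _total_expectation(gene: GeneModel, rec: GeneTruth,
                       config: SimulationConfig) -> np.ndarray:
    """Expected total counts along the ORF (mRNA order)."""
    n = gene.exonic_length
    mu = np.full(n, rec.expression_mean)
    if rec.is_target and rec.pause_factor != 1 and rec.onset_codon:
        onset_start = 3 * (rec.onset_codon - 1)      # 0-based ORF index
        lo = max(0, onset_start - config.pause_window_nt)
        mu[lo:onset_start] *= rec.pause_factor
    return mu


def _enrichment_step(rec: GeneTruth, n: int) -> np.ndarray:
    """The planted e(i) step along the ORF for a target gene."""
    e = np.ones(n)
    onset_start = 3 * (rec.onset_codon - 1)
    if rec.release_codon is not None:
        release_start = 3 * (rec.release_codon - 1)
        e[onset_start:release_start] = rec.amplitude
    else:
        e[onset_start:] = rec.amplitude
    return e


def _draw_counts(mu: np.ndarray, dispersion: float,
                 rng: np.random.Generator) -> np.ndarray:
    if dispersion < 1e-9:
        return rng.poisson(mu).astype(float)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _simulate_track(
    annotation: GenomeAnnotation,
    truth: dict[str, GeneTruth],
    config: SimulationConfig,
    bait: str,
    condition: str,
    replicate: int,
) -> CountTrack:
    rng = _rng_for(config.seed, "track", bait, condition, replicate)
    genes = annotation.genes
    # One lognormal background-enrichment draw per gene, consumed in a single
    # vectorized call so the stream is independent of later branching.
    bg_e = np.exp(rng.normal(0.0, config.background_enrichment_sd, size=len(genes)))

    chrom_length = annotation.chrom_lengths[CHROMOSOME]
    dense = np.zeros(chrom_length)
    indices, expectations = [], []
    selective = bait != "no_bait"
    for g, e_bg in zip(genes, bg_e):
        rec = truth[g.gene_id]
        mu = _total_expectation(g, rec, config)
        if condition == "ip":
            if selective and rec.is_target:
                e = _enrichment_step(rec, mu.size)
            else:
                e = e_bg
            mu = config.capture_scale * mu * e
        indices.append(_orf_to_genomic(g))
        expectations.append(mu)
    idx = np.concatenate(indices)
    mu_all = np.concatenate(expectations)
    dense[idx] = _draw_counts(mu_all, config.dispersion, rng)
    return CountTrack(condition=condition, bait=bait, replicate=replicate,
                      counts={CHROMOSOME: dense})


def simulate_total_track(annotation, truth, config: SimulationConfig,
                         replicate: int, bait: str | None = None) -> CountTrack:
    """Total-translatome counts for one replicate (negative binomial over ORFs)."""
    return _simulate_track(annotation, truth, config, bait or config.bait,
                           "total", replicate)


def simulate_ip_track(annotation, truth, config: SimulationConfig,
                      replicate: int, bait: str | None = None) -> CountTrack:
    """Affinity-purified counts: expectation = capture x total expectation x e(i).

    For the selective bait, planted targets get the step enrichment; all
    other genes (and every gene of the ``no_bait`` control) get a constant
    per-gene x replicate lognormal factor centered on 1.
    """
    return _simulate_track(annotation, truth, config, bait or config.bait,
                           "ip", replicate)


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """An in-memory experiment: everything the pipeline consumes."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    proteins: dict[str, str]
    truth: dict[str, GeneTruth]
    tracks: dict[tuple[str, str, int], CountTrack]   # (bait, condition, replicate)
    truth_set: list[str]
    negative_set: list[str]
    go_map: pd.DataFrame | None = None

    @property
    def baits(self) -> list[str]:
        return [self.config.bait, "no_bait"]

    def target_ids(self) -> list[str]:
        return sorted(g for g, r in self.truth.items() if r.is_target)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete experiment in memory (deterministic given config)."""
    annotation, proteins, truth = simulate_genome(config)
    tracks = {}
    for bait in (config.bait, "no_bait"):
        for condition in ("ip", "total"):
            for rep in range(1, config.replicates + 1):
                tracks[(bait, condition, rep)] = _simulate_track(
                    annotation, truth, config, bait, condition, rep
                )

    targets = sorted(g for g, r in truth.items() if r.is_target)
    background = sorted(
        g.gene_id for g in annotation.coding_genes() if not truth[g.gene_id].is_target
    )
    pick = _rng_for(config.seed, "curation")
    n_truth = int(round(config.truth_fraction * len(targets)))
    truth_set = sorted(pick.choice(targets, size=n_truth, replace=False)) if n_truth else []
    if not truth_set and background:
        # Null experiments without planted signal still need a curated list
        # to calibrate against; draw stand-in "positives" from the background.
        n_truth = max(1, int(round(config.truth_fraction * min(50, len(background)))))
        truth_set = sorted(pick.choice(background, size=n_truth, replace=False))
    remaining = sorted(set(background) - set(truth_set))
    n_neg = int(round(config.negative_fraction * len(remaining)))
    negative_set = sorted(pick.choice(remaining, size=n_neg, replace=False)) if n_neg else []

    go_map = _simulate_go_map(config, targets, background) if config.emit_go_map else None
    return SyntheticDataset(config, annotation, proteins, truth, tracks,
                            truth_set, negative_set, go_map)


def _simulate_go_map(config: SimulationConfig, targets, background) -> pd.DataFrame:
    """GO mapping with one term enriched for targets plus unenriched decoys."""
    rng = _rng_for(config.seed, "go")
    all_genes = sorted(targets) + sorted(background)
    rows = []
    if len(all_genes) > 110:
        n_fill = min(len(background), max(101 - len(targets) + 10, 62))
        fill = rng.choice(sorted(background), size=n_fill, replace=False)
        for gid in list(targets) + list(fill):
            rows.append({"gene_id": gid, "term_id": "GO:9000001",
                         "term_name": "planted_target_process"})
        for k in range(2, 5):
            size = int(rng.integers(105, 140))
            members = rng.choice(all_genes, size=min(size, len(all_genes)),
                                 replace=False)
            for gid in members:
                rows.append({"gene_id": gid, "term_id": f"GO:900000{k}",
                             "term_name": f"decoy_process_{k}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


def truth_table(truth: dict[str, GeneTruth]) -> pd.DataFrame:
    rows = [{
        "gene_id": r.gene_id, "is_target": r.is_target,
        "onset_codon": r.onset_codon, "amplitude": r.amplitude,
        "release_codon": r.release_codon, "pause_factor": r.pause_factor,
    } for r in sorted(truth.values(), key=lambda r: r.gene_id)]
    return pd.DataFrame(rows, columns=["gene_id", "is_target", "onset_codon",
                                       "amplitude", "release_codon", "pause_factor"])


def simulate_experiment(config: SimulationConfig, outdir,
                        overwrite: bool = False) -> dict:
    """Write a complete on-disk dataset consumable by the pipeline CLI.

    Layout: ``{bait}.{condition}.rep{k}.bedgraph`` tracks for the bait and
    the no-bait control, ``annotation.gtf``, ``chrom.sizes``,
    ``proteins.fasta``, ``true_positives.txt`` (the incomplete curated truth
    list), ``true_negatives.txt`` (curated background genes), ``truth.tsv``
    (the full planted ground truth, for evaluation only) and optionally
    ``go_map.tsv``.  Refuses to write into a non-empty directory unless
    ``overwrite`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty; "
                              "pass overwrite=True to replace it")
    outdir.mkdir(parents=True, exist_ok=True)

    ds = simulate_dataset(config)
    write_annotation(ds.annotation, outdir / "annotation.gtf")
    write_chrom_sizes(ds.annotation.chrom_lengths, outdir / "chrom.sizes")
    write_protein_fasta(ds.proteins, outdir / "proteins.fasta")
    write_gene_list(ds.truth_set, outdir / "true_positives.txt")
    write_gene_list(ds.negative_set, outdir / "true_negatives.txt")
    truth_table(ds.truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if ds.go_map is not None and len(ds.go_map):
        ds.go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
    paths = []
    for (bait, condition, rep), track in sorted(ds.tracks.items()):
        path = outdir / track_filename(bait, condition, rep)
        write_count_track(track, path)
        paths.append(str(path))
    return {
        "outdir": str(outdir),
        "tracks": paths,
        "n_genes": len(ds.annotation.genes),
        "n_targets": len(ds.target_ids()),
        "truth_set_size": len(ds.truth_set),
        "negative_set_size": len(ds.negative_set),
    }
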