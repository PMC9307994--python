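"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study inputs at
desk scale: an H3K27ac landscape with a diffuse brain-like background
and one dense tissue-specific block; restriction-fragment 4C profiles
with distance decay and planted preferential-contact territories per
viewpoint; multi-tissue peak sets with a controlled specific/pleiotropic
mix; and cross-species CNE pairs whose enhancer activity is conserved
in the matching tissue at a planted rate.

One master seed derives an independent child stream per component, so
adding a generator never perturbs earlier streams. Coverage is
simulated on a 10 bp grid rather than per base; every downstream
operation is grid-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cne import CNEPair
from .cre import Gene, GeneModel
from .fourc import AnchorSet, FourCProfile
from .genome import GenomeAssembly, GenomicInterval
from .io import CoverageTrack, PeakSet

__all__ = [
    "ViewpointConfig",
    "SimulationConfig",
    "simulate_coverage",
    "simulate_4c",
    "simulate_peaks_and_genes",
]

_STREAM = {"coverage": 1, "fourc": 2, "peaks": 3}

TISSUES = ("PT", "DFL", "PFL", "FB")  # posterior trunk, distal/proximal forelimb, forebrain


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM[component],))
    )


@dataclass(frozen=True)
class ViewpointConfig:
    """One simulated 4C viewpoint with its preferential-contact territory."""

    name: str
    position: int
    preferred_region: tuple[int, int]
    enrichment_fold: float = 3.0
    # Within a TAD the residual distance decay is shallow relative to the
    # territory structure (the steep proximal decay is what the +/-5 Mb
    # normalisation absorbs), so the default scale is landscape-wide.
    decay_scale: int = 2_500_000


def _default_viewpoints() -> tuple[ViewpointConfig, ...]:
    # Gene order mirrors the locus: the viewpoint closest to the landscape
    # contacts the nearest territory, giving the "reverse order" arrangement.
    return (
        ViewpointConfig("vp1", 90_000, (100_000, 550_000)),
        ViewpointConfig("vp4", 60_000, (550_000, 1_050_000)),
        ViewpointConfig("vp9", 30_000, (1_050_000, 1_500_000)),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults chosen to emulate
    the real landscape's scale and noise regime."""

    seed: int = 0
    # landscape / coverage
    landscape_chrom: str = "chrL"
    landscape_length: int = 1_600_000
    grid: int = 10  # bp per simulated coverage bin
    background_rate: float = 1.0  # mean signal per bp
    background_undulation: float = 0.1  # relative sd of the slow background wave
    coverage_noise_sd: float = 0.3  # relative sd of per-bin noise
    planted_mar: tuple[int, int, float] = (750_000, 850_000, 5.0)  # start, end, fold
    # 4C
    n_fragments: int = 600
    fourc_noise_sigma: float = 0.25  # lognormal sigma on fragment scores
    viewpoints: tuple[ViewpointConfig, ...] = field(default_factory=_default_viewpoints)
    # peaks / genes / CNEs (two-species genome)
    genome_length: int = 10_000_000
    tissues: tuple[str, ...] = TISSUES
    n_genes: int = 40
    n_pcre_loci: int = 200
    pleiotropy_rate: float = 0.3
    promoter_locus_fraction: float = 0.1
    cne_count: int = 500
    cne_length: int = 200
    cne_activity_rate: float = 0.3  # per tissue, species A
    conservation_rate: float = 0.3  # matched-tissue activity given species-A activity
    cne_background_rate: float = 0.1  # species-B activity when A is inactive
    exon_fraction: float = 0.5  # fraction of each gene body covered by exons

    def __post_init__(self) -> None:
        s, e, fold = self.planted_mar
        if not (0 <= s < e <= self.landscape_length):
            raise ValueError("planted MAR outside the landscape")
        if fold < 0:
            raise ValueError("negative fold enrichment")
        for vp in self.viewpoints:
            ps, pe = vp.preferred_region
            if not (0 <= ps < pe <= self.landscape_length):
                raise ValueError(f"preferred region of {vp.name} outside landscape")
        for rate in (
            self.pleiotropy_rate,
            self.cne_activity_rate,
            self.conservation_rate,
            self.cne_background_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def landscape_assembly(self) -> GenomeAssembly:
        return GenomeAssembly("sim", {self.landscape_chrom: self.landscape_length})

    def landscape_region(self) -> GenomicInterval:
        return GenomicInterval(self.landscape_chrom, 0, self.landscape_length)


# ---------------------------------------------------------------------------
# coverage


def _bins_to_segments(values: np.ndarray, grid: int):
    starts = np.arange(len(values), dtype=np.int64) * grid
    return list(zip(starts.tolist(), (starts + grid).tolist(), values.tolist()))


def simulate_coverage(
    cfg: SimulationConfig,
) -> tuple[CoverageTrack, CoverageTrack, GenomicInterval]:
    """Simulate a tissue H3K27ac track, a brain background track, and the
    planted enrichment block.

    Both tracks share one slowly undulating base coverage; the tissue
    track adds ``fold x base`` inside the planted block; each track
    carries its own independent per-bin noise (clipped at zero).
    """
    rng = _rng(cfg.seed, "coverage")
    n = cfg.landscape_length // cfg.grid
    wave = rng.normal(0.0, 1.0, n)
    kernel = np.ones(501) / 501  # ~5 kb smoothing of the background wave
    wave = np.convolve(wave, kernel, mode="same")
    wave = wave / max(wave.std(), 1e-12) * cfg.background_undulation
    base = cfg.background_rate * np.clip(1.0 + wave, 0.05, None)
    s, e, fold = cfg.planted_mar
    in_block = np.zeros(n)
    in_block[s // cfg.grid : e // cfg.grid] = 1.0
    noise_sd = cfg.coverage_noise_sd * cfg.background_rate
    chip = np.clip(base * (1.0 + fold * in_block) + rng.normal(0, noise_sd, n), 0, None)
    brain = np.clip(base + rng.normal(0, noise_sd, n), 0, None)
    assembly = cfg.landscape_assembly()
    chrom = cfg.landscape_chrom
    chip_track = CoverageTrack.from_segments(
        assembly, {chrom: _bins_to_segments(chip, cfg.grid)}
    )
    brain_track = CoverageTrack.from_segments(
        assembly, {chrom: _bins_to_segments(brain, cfg.grid)}
    )
    truth = GenomicInterval(chrom, s, e, name="planted_mar")
    return chip_track, brain_track, truth


# ---------------------------------------------------------------------------
# 4C


def _fragment_grid(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Random restriction-fragment boundaries over the landscape."""
    cuts = rng.choice(cfg.landscape_length - 1, size=cfg.n_fragments - 1, replace=False)
    return np.concatenate([[0], np.sort(cuts) + 1, [cfg.landscape_length]])


def simulate_4c(
    cfg: SimulationConfig,
) -> tuple[dict[str, FourCProfile], dict[tuple[str, str], Optional[int]], AnchorSet]:
    """Simulate raw fragment profiles for every configured viewpoint.

    Returns the profiles, the truth boundaries (bp position of the
    shared territory edge for each adjacent viewpoint pair, or None
    when their territories are not adjacent), and an anchor set with
    one anchor at each territory edge.
    """
    rng = _rng(cfg.seed, "fourc")
    cuts = _fragment_grid(cfg, rng)
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    profiles: dict[str, FourCProfile] = {}
    for vp in cfg.viewpoints:
        decay = np.exp(-np.abs(mids - vp.position) / vp.decay_scale)
        ps, pe = vp.preferred_region
        pref = (mids >= ps) & (mids < pe)
        noise = rng.lognormal(0.0, cfg.fourc_noise_sigma, len(mids))
        raw = decay * (1.0 + vp.enrichment_fold * pref) * noise
        df = pd.DataFrame({"start": cuts[:-1], "end": cuts[1:], "raw": raw})
        profiles[vp.name] = FourCProfile(
            viewpoint_name=vp.name,
            viewpoint_position=vp.position,
            chrom=cfg.landscape_chrom,
            fragments=df,
        )
    truth: dict[tuple[str, str], Optional[int]] = {}
    for a, b in zip(cfg.viewpoints, cfg.viewpoints[1:]):
        shared = a.preferred_region[1]
        if shared == b.preferred_region[0]:
            truth[(a.name, b.name)] = shared
        else:
            truth[(a.name, b.name)] = None  # non-adjacent territories
    edges = sorted(
        {edge for vp in cfg.viewpoints for edge in vp.preferred_region}
    )
    anchors = AnchorSet(
        {
            f"ANC{i + 1}": GenomicInterval(
                cfg.landscape_chrom, int(edge) - 50, int(edge) + 50, name=f"ANC{i + 1}"
            )
            for i, edge in enumerate(edges)
        }
    )
    return profiles, truth, anchors


# ---------------------------------------------------------------------------
# peaks, genes, CNE pairs


@dataclass
class TwoSpeciesTruth:
    """Planted truth labels for the peak/CNE simulation."""

    pcre_locus_tissues: list[tuple[GenomicInterval, frozenset]]
    pcre_locus_class: list[str]  # planted enhancer/promoter per locus
    cne_activity_a: pd.DataFrame  # CNE id x tissue booleans, species A
    cne_activity_b: pd.DataFrame


@dataclass
class TwoSpeciesData:
    assembly_a: GenomeAssembly
    assembly_b: GenomeAssembly
    peaks_a: dict[str, PeakSet]
    peaks_b: dict[str, PeakSet]
    genes_a: GeneModel
    genes_b: GeneModel
    cne_pairs: list[CNEPair]
    truth: TwoSpeciesTruth


def _make_genes(
    chrom: str, zone: tuple[int, int], n: int, exon_fraction: float, prefix: str
) -> GeneModel:
    lo, hi = zone
    pitch = (hi - lo) // n
    genes = []
    for i in range(n):
        tss = lo + i * pitch
        body = min(2_000, pitch // 2)
        exon_len = max(100, int(body * exon_fraction))
        exons = (GenomicInterval(chrom, tss, tss + exon_len),)
        genes.append(Gene(f"{prefix}gene{i + 1}", chrom, tss, "+", exons))
    return GeneModel(genes)


def _peak_at(
    chrom: str, center: int, rng: np.random.Generator, tissue: str
) -> GenomicInterval:
    half = int(rng.integers(150, 300))
    score = float(rng.gamma(4.0, 2.5))
    return GenomicInterval(
        chrom, center - half, center + half, name=f"{tissue}_{center}", score=score
    )


def simulate_peaks_and_genes(cfg: SimulationConfig) -> TwoSpeciesData:
    """Simulate tissue peak sets, gene models and CNE pairs for two species.

    The species-A genome carries three non-overlapping zones: genes
    (with a promoter-proximal peak stratum), pCRE loci with the planted
    specific/pleiotropic mix, and CNE loci. Species B carries matched
    genes and CNE loci; a CNE active in a species-A tissue is active in
    the matching species-B tissue with probability
    ``conservation_rate``, and otherwise at the background rate. Zone
    pitches keep extended peaks from distinct loci from ever merging,
    so planted labels are recoverable exactly.
    """
    rng = _rng(cfg.seed, "peaks")
    L = cfg.genome_length
    asm_a = GenomeAssembly("simA", {"chrA": L})
    asm_b = GenomeAssembly("simB", {"chrB": L})
    gene_zone = (50_000, 1_500_000)
    cne_zone = (2_000_000, 8_000_000)
    pcre_zone = (8_200_000, 9_800_000)

    genes_a = _make_genes("chrA", gene_zone, cfg.n_genes, cfg.exon_fraction, "mA_")
    genes_b = _make_genes("chrB", gene_zone, cfg.n_genes, cfg.exon_fraction, "cB_")

    tissues = list(cfg.tissues)
    peaks_a: dict[str, list[GenomicInterval]] = {t: [] for t in tissues}
    peaks_b: dict[str, list[GenomicInterval]] = {t: [] for t in tissues}

    # --- pCRE loci (species A only): planted specific/pleiotropic mix
    n_prom = int(round(cfg.n_pcre_loci * cfg.promoter_locus_fraction))
    n_enh = cfg.n_pcre_loci - n_prom
    pitch = (pcre_zone[1] - pcre_zone[0]) // max(n_enh, 1)
    if pitch < 4_000:
        raise ValueError("pCRE loci too dense for non-merging placement")
    locus_tissues: list[tuple[GenomicInterval, frozenset]] = []
    locus_class: list[str] = []
    centers = [pcre_zone[0] + i * pitch + pitch // 2 for i in range(n_enh)]
    gene_pitch = (gene_zone[1] - gene_zone[0]) // cfg.n_genes
    prom_genes = rng.choice(cfg.n_genes, size=n_prom, replace=False)
    prom_centers = [
        gene_zone[0] + int(g) * gene_pitch - 1_800 for g in sorted(prom_genes)
    ]
    for center, cls in [(c, "enhancer") for c in centers] + [
        (c, "promoter") for c in prom_centers
    ]:
        if rng.random() < cfg.pleiotropy_rate and len(tissues) > 1:
            k = int(rng.integers(2, len(tissues) + 1))
        else:
            k = 1
        chosen = frozenset(rng.choice(tissues, size=k, replace=False).tolist())
        lo = hi = None
        for t in chosen:
            pk = _peak_at("chrA", center, rng, t)
            peaks_a[t].append(pk)
            lo = pk.start if lo is None else min(lo, pk.start)
            hi = pk.end if hi is None else max(hi, pk.end)
        locus_tissues.append((GenomicInterval("chrA", lo, hi), chosen))
        locus_class.append(cls)

    # --- CNE loci in both species
    cne_pitch = (cne_zone[1] - cne_zone[0]) // cfg.cne_count
    if cne_pitch < 4_000:
        raise ValueError("CNE loci too dense for non-merging placement")
    pairs: list[CNEPair] = []
    act_a = np.zeros((cfg.cne_count, len(tissues)), dtype=bool)
    act_b = np.zeros_like(act_a)
    ids = [f"CNE{i + 1:04d}" for i in range(cfg.cne_count)]
    for i in range(cfg.cne_count):
        ca = cne_zone[0] + i * cne_pitch + cne_pitch // 2
        cb = cne_zone[0] + i * cne_pitch + cne_pitch // 3  # same order, shifted grid
        iva = GenomicInterval("chrA", ca, ca + cfg.cne_length, name=ids[i])
        ivb = GenomicInterval("chrB", cb, cb + cfg.cne_length, name=ids[i])
        pairs.append(CNEPair(ids[i], iva, ivb))
        for j, t in enumerate(tissues):
            active_a = rng.random() < cfg.cne_activity_rate
            if active_a:
                active_b = rng.random() < cfg.conservation_rate
            else:
                active_b = rng.random() < cfg.cne_background_rate
            act_a[i, j] = active_a
            act_b[i, j] = active_b
            if active_a:
                peaks_a[t].append(_peak_at("chrA", ca + cfg.cne_length // 2, rng, t))
            if active_b:
                peaks_b[t].append(_peak_at("chrB", cb + cfg.cne_length // 2, rng, t))

    truth = TwoSpeciesTruth(
        pcre_locus_tissues=locus_tissues,
        pcre_locus_class=locus_class,
        cne_activity_a=pd.DataFrame(act_a, index=ids, columns=tissues),
        cne_activity_b=pd.DataFrame(act_b, index=ids, columns=tissues),
    )
    return TwoSpeciesData(
        assembly_a=asm_a,
        assembly_b=asm_b,
        peaks_a={
            t: PeakSet(v, tissue=t, species="simA", assembly=asm_a)
            for t, v in peaks_a.items()
        },
        peaks_b={
            t: PeakSet(v, tissue=t, species="simB", assembly=asm_b)
            for t, v in peaks_b.items()
        },
        genes_a=genes_a,
        genes_b=genes_b,
        cne_pairs=pairs,
        truth=truth,
    )
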