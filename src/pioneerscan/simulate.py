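"""Seeded generators for every input the pipeline consumes.

The generator emulates the statistical structure the method assumes:
phased nucleosome arrays whose mono-nucleosome fragments are 120-180 bp
with a mode at 147 bp and centers jittered around the true dyads;
designated nucleosome-depleted stretches that receive no fragments;
optional 10-bp-periodic WW/SS dinucleotide structure under nucleosomes;
motif instances implanted at chosen superhelical locations (or inside
NDRs) with matching ChIP-seq narrowPeaks; DNase/histone-mark peaks; and
an expression table.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .intervals import FragmentRecord, GenomicInterval, NarrowPeakRecord
from .io import BASES, ExpressionTable, PositionFrequencyMatrix

__all__ = [
    "MotifPlacement",
    "SimulationConfig",
    "PlantedSite",
    "GenomeLayout",
    "Fixture",
    "make_pfm",
    "generate_genome",
    "generate_fragments",
    "implant_motifs",
    "generate_peaks_and_expression",
    "make_fixture",
    "DEFAULT_CONFIG",
]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MotifPlacement:
    """Where and how often one TF's motif is written into the genome.

    ``shl`` positions the motif center at ``round(shl * 10.5)`` bp from
    the dyad on BOTH nucleosomal halves (the canonical 10.5 bp/turn
    conversion); ``in_ndr`` instead plants sites inside the designated
    nucleosome-depleted stretches.  ``jitter`` (bp, uniform on
    [-jitter, jitter]) keeps the implanted band from being perfectly
    sharp, as real binding sites are not.
    """

    tf_name: str
    shl: float | None = None
    offset: int | None = None
    in_ndr: bool = False
    fraction: float = 1.0
    jitter: int = 2

    def center_offset(self, bp_per_shl: float = 10.5) -> int:
        if self.offset is not None:
            return self.offset
        if self.shl is None:
            raise ValueError("placement needs shl, offset or in_ndr")
        return round(self.shl * bp_per_shl)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults describe a ~0.1-Mb single-chromosome genome carrying 500
    well-phased nucleosomes (25 arrays of 20, spaced 200 bp) separated
    by 600-bp nucleosome-depleted stretches, sequenced to 50 fragments
    per nucleosome in 2 replicates.
    """

    seed: int = 0
    chrom: str = "chrS"
    gc_fraction: float = 0.5
    nucleosome_spacing: int = 200
    nucleosomes_per_array: int = 20
    n_arrays: int = 25
    ndr_length: int = 600
    margin: int = 1000
    dyad_jitter_sd: float = 2.0
    max_center_jitter: int = 5
    fragments_per_nucleosome: int = 100
    n_replicates: int = 2
    fragment_min: int = 120
    fragment_mode: int = 147
    fragment_max: int = 180
    motif_placements: tuple[MotifPlacement, ...] = ()
    peak_width: int = 200
    expression: Mapping[str, float] = field(default_factory=dict)
    periodic_dinucleotides: bool = False
    dinucleotide_period: int = 10
    dinucleotide_phase: int = 5

    @property
    def n_nucleosomes(self) -> int:
        return self.nucleosomes_per_array * self.n_arrays

    @property
    def genome_length(self) -> int:
        array_span = self.nucleosomes_per_array * self.nucleosome_spacing
        return (
            2 * self.margin
            + self.n_arrays * array_span
            + (self.n_arrays - 1) * self.ndr_length
        )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one implanted motif instance."""

    tf_name: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeLayout:
    """True dyad positions and designated NDR stretches of the fixture."""

    chrom: str
    true_dyads: list[int]
    ndr_stretches: list[GenomicInterval]
    chrom_sizes: dict[str, int]


@dataclass
class Fixture:
    """A complete synthetic data set plus its ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    layout: GenomeLayout
    fragments: dict[str, list[FragmentRecord]]  # replicate -> fragments
    pfms: dict[str, PositionFrequencyMatrix]
    chip_peaks: dict[str, list[NarrowPeakRecord]]  # tf -> peaks
    dnase_peaks: list[NarrowPeakRecord]
    h3k27ac_peaks: list[NarrowPeakRecord]
    h3k4me1_peaks: list[NarrowPeakRecord]
    expression: ExpressionTable
    truth: list[PlantedSite]

    def all_fragments(self) -> list[FragmentRecord]:
        out: list[FragmentRecord] = []
        for frags in self.fragments.values():
            out.extend(frags)
        return out


def make_pfm(
    tf_name: str, consensus: str, strength: float = 100.0
) -> PositionFrequencyMatrix:
    """An informative PFM whose argmax spells ``consensus``."""
    counts = np.ones((4, len(consensus)))
    for k, base in enumerate(consensus.upper()):
        counts[BASES.index(base), k] = strength
    return PositionFrequencyMatrix(tf_name, counts)


def _fragment_length_pmf(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discretized triangular distribution on [min, max] peaking at mode."""
    lengths = np.arange(cfg.fragment_min, cfg.fragment_max + 1)
    left = (lengths - cfg.fragment_min + 1) / (
        cfg.fragment_mode - cfg.fragment_min + 1
    )
    right = (cfg.fragment_max - lengths + 1) / (
        cfg.fragment_max - cfg.fragment_mode + 1
    )
    pmf = np.minimum(left, right)
    return lengths, pmf / pmf.sum()


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], GenomeLayout]:
    """I.i.d. random genome at the configured GC, with the nucleosome
    array / NDR layout and, optionally, 10-bp WW/SS periodicity written
    under every nucleosome."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.gc_fraction / 2
    a = (1 - config.gc_fraction) / 2
    seq = rng.choice(list("ACGT"), size=config.genome_length, p=[a, g, g, a])

    true_dyads: list[int] = []
    ndr_stretches: list[GenomicInterval] = []
    pos = config.margin
    array_span = config.nucleosomes_per_array * config.nucleosome_spacing
    for i in range(config.n_arrays):
        for k in range(config.nucleosomes_per_array):
            true_dyads.append(pos + config.nucleosome_spacing // 2
                              + k * config.nucleosome_spacing)
        pos += array_span
        if i < config.n_arrays - 1:
            ndr_stretches.append(
                GenomicInterval(config.chrom, pos, pos + config.ndr_length)
            )
            pos += config.ndr_length

    if config.periodic_dinucleotides:
        # WW (AA) dinucleotides at offsets == phase (mod period) from each dyad
        for dyad in true_dyads:
            for o in range(-73, 73):
                if o % config.dinucleotide_period == config.dinucleotide_phase:
                    seq[dyad + o] = "A"
                    seq[dyad + o + 1] = "A"

    genome = {config.chrom: "".join(seq)}
    layout = GenomeLayout(
        config.chrom,
        true_dyads,
        ndr_stretches,
        {config.chrom: config.genome_length},
    )
    return genome, layout


def generate_fragments(
    config: SimulationConfig,
    true_dyads: Sequence[int],
    rng: np.random.Generator | None = None,
) -> dict[str, list[FragmentRecord]]:
    """Mono-nucleosome fragments per replicate.

    Each nucleosome emits ``fragments_per_nucleosome`` fragments per
    replicate; lengths follow the triangular distribution and centers
    are the true dyad plus rounded-Gaussian jitter clipped to
    +/- ``max_center_jitter`` bp.  Designated NDR stretches receive no
    fragments because no nucleosome sits there.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lengths, pmf = _fragment_length_pmf(config)
    out: dict[str, list[FragmentRecord]] = {}
    for rep in range(1, config.n_replicates + 1):
        rep_id = f"rep{rep}"
        frags: list[FragmentRecord] = []
        for dyad in true_dyads:
            n = config.fragments_per_nucleosome
            ls = rng.choice(lengths, size=n, p=pmf)
            jitter = np.rint(
                rng.normal(0.0, config.dyad_jitter_sd, size=n)
            ).astype(int)
            jitter = np.clip(
                jitter, -config.max_center_jitter, config.max_center_jitter
            )
            centers = dyad + jitter
            # place so the floor-midpoint of the fragment is the center
            starts = centers - (ls - 1) // 2
            for s, l in zip(starts, ls):
                frags.append(
                    FragmentRecord(config.chrom, int(s), int(s + l), rep_id)
                )
        out[rep_id] = frags
    return out


def implant_motifs(
    genome: dict[str, str],
    layout: GenomeLayout,
    pfm: PositionFrequencyMatrix,
    placement: MotifPlacement,
    rng: np.random.Generator | None = None,
    bp_per_shl: float = 10.5,
) -> list[PlantedSite]:
    """Write the PFM consensus into the genome per the placement rule.

    Nucleosomal placements put the motif center at ``+offset`` and
    ``-offset`` from the dyad (both halves, keeping the profile
    symmetric) on the configured fraction of nucleosomes; NDR placements
    tile sites every 150 bp inside each designated NDR stretch.  Sites
    alternate strand.  Returns the planted-site truth table.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    chrom = layout.chrom
    seq = list(genome[chrom])
    consensus = pfm.consensus()
    L = pfm.length
    sites: list[PlantedSite] = []

    def plant(center: int, strand: str) -> None:
        start = center - L // 2
        end = start + L
        if start < 0 or end > len(seq):
            return
        word = consensus if strand == "+" else revcomp(consensus)
        seq[start:end] = list(word)
        sites.append(PlantedSite(pfm.tf_name, chrom, start, end, strand))

    if placement.in_ndr:
        for ndr in layout.ndr_stretches:
            for center in range(ndr.start + 75, ndr.end - 75, 150):
                if rng.random() < placement.fraction:
                    plant(center, "+" if len(sites) % 2 == 0 else "-")
    else:
        off = placement.center_offset(bp_per_shl)
        for dyad in layout.true_dyads:
            if rng.random() >= placement.fraction:
                continue
            j = int(rng.integers(-placement.jitter, placement.jitter + 1))
            plant(dyad + off + j, "+" if len(sites) % 2 == 0 else "-")
            if off != 0:
                j = int(rng.integers(-placement.jitter, placement.jitter + 1))
                plant(dyad - off + j, "+" if len(sites) % 2 == 0 else "-")

    genome[chrom] = "".join(seq)
    return sites


def generate_peaks_and_expression(
    config: SimulationConfig,
    layout: GenomeLayout,
    truth: Sequence[PlantedSite],
) -> tuple[
    dict[str, list[NarrowPeakRecord]],
    list[NarrowPeakRecord],
    ExpressionTable,
]:
    """ChIP narrowPeaks around every planted site (summit at the site
    start), DNase peaks over the designated NDR stretches, and the
    configured expression table."""
    size = layout.chrom_sizes[layout.chrom]
    chip: dict[str, list[NarrowPeakRecord]] = {}
    for i, site in enumerate(truth):
        pad = (config.peak_width - (site.end - site.start)) // 2
        start = max(site.start - pad, 0)
        end = min(site.end + pad, size)
        chip.setdefault(site.tf_name, []).append(
            NarrowPeakRecord(
                chrom=site.chrom,
                start=start,
                end=end,
                name=f"{site.tf_name}_peak{i}",
                score=1000,
                strand=".",
                signal_value=10.0,
                p_score=10.0,
                q_score=5.0,
                summit_offset=site.start - start,
            )
        )
    dnase = [
        NarrowPeakRecord(
            chrom=ndr.chrom,
            start=ndr.start,
            end=ndr.end,
            name=f"dnase{i}",
            score=1000,
            strand=".",
            signal_value=8.0,
            p_score=8.0,
            q_score=4.0,
            summit_offset=ndr.length // 2,
        )
        for i, ndr in enumerate(layout.ndr_stretches)
    ]
    expression = ExpressionTable(
        cell_line="synthetic", rpkm=dict(config.expression)
    )
    return chip, dnase, expression


DEFAULT_CONFIG = SimulationConfig(
    motif_placements=(
        MotifPlacement("TF_NR", shl=5.5, fraction=1.0),
        MotifPlacement("TF_NDR", in_ndr=True, fraction=1.0),
    ),
    expression={"TF_NR": 25.0, "TF_NDR": 12.0},
)

_DEFAULT_CONSENSUS = {
    "TF_NR": "ATGCACGTT",
    "TF_NDR": "GCTTAGGCA",
}


def make_fixture(
    seed: int = 0, config: SimulationConfig | None = None
) -> Fixture:
    """Build the complete default fixture: genome, implanted motifs,
    fragments, peaks and expression, all seeded."""
    cfg = replace(config or DEFAULT_CONFIG, seed=seed)
    rng = np.random.default_rng(seed)
    genome, layout = generate_genome(cfg, rng)
    pfms: dict[str, PositionFrequencyMatrix] = {}
    truth: list[PlantedSite] = []
    for placement in cfg.motif_placements:
        consensus = _DEFAULT_CONSENSUS.get(placement.tf_name)
        if consensus is None:
            import zlib

            tf_seed = zlib.crc32(placement.tf_name.encode()) % 2**31
            consensus = "".join(
                np.random.default_rng(tf_seed).choice(list("ACGT"), size=9)
            )
        pfm = make_pfm(placement.tf_name, consensus)
        pfms[placement.tf_name] = pfm
        truth.extend(implant_motifs(genome, layout, pfm, placement, rng))
    fragments = generate_fragments(cfg, layout.true_dyads, rng)
    chip, dnase, expression = generate_peaks_and_expression(
        cfg, layout, truth
    )
    # histone-mark peaks over the first half of the NDR stretches, so some
    # open regions qualify as active enhancers and others do not
    half = len(layout.ndr_stretches) // 2
    h3k27ac = [
        NarrowPeakRecord(
            p.chrom, p.start, p.end, name=f"ac{i}", score=500,
            strand=".", signal_value=5.0, p_score=5.0, q_score=3.0,
            summit_offset=-1,
        )
        for i, p in enumerate(layout.ndr_stretches[:half])
    ]
    h3k4me1 = list(h3k27ac)
    return Fixture(
        config=cfg,
        genome=genome,
        layout=layout,
        fragments=fragments,
        pfms=pfms,
        chip_peaks=chip,
        dnase_peaks=dnase,
        h3k27ac_peaks=h3k27ac,
        h3k4me1_peaks=h3k4me1,
        expression=expression,
        truth=truth,
    )
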