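"""Synthetic campaign data: toy genomes, mutagenized cohorts, screens, batches.

The generator emulates the study conditions of a chemical-mutagenesis /
biosensor-FACS campaign: ~180 mutations per genome (negative-binomial across
strains, clamped to the observed 47-470 range), a strong G:C→A:T transition
bias typical of MNNG alkylation, hotspot genes planted at a chosen per-strain
probability, plate screens with control triplicates, and noisy Monod batch
trajectories.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import CODON_TO_AA
from .bioprocess import BatchTimeCourse, MonodParameters, simulate_batch
from .genome_io import GeneFeature, ReferenceGenome, VariantRecord, reverse_complement
from .screen import ScreenRecord

__all__ = [
    "PlantedHotspot",
    "MutagenesisConfig",
    "ScreenSimConfig",
    "make_toy_genome",
    "write_genome_files",
    "simulate_mutagenesis",
    "write_strain_vcf",
    "simulate_screen",
    "simulate_fermentation",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedHotspot:
    """A gene seeded with an extra SNP in a chosen fraction of strains."""

    locus_tag: str
    per_strain_probability: float
    force_nonsynonymous: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.per_strain_probability <= 1.0):
            raise ValueError("per-strain probability must lie in [0, 1]")


@dataclass
class MutagenesisConfig:
    """Cohort-level mutagenesis settings.

    The per-strain mutation count is negative-binomial with mean
    ``mean_load`` and dispersion ``dispersion`` (variance = m + m^2/k),
    clamped to ``load_range`` — overdispersion matches the wide spread seen
    across independently mutagenized cultures.  ``gc_to_at_fraction`` of
    SNPs are drawn as G:C→A:T transitions; the rest spread uniformly over
    the remaining five classes.  A ``decoy_fraction`` of extra variants gets
    sub-0.5 read frequencies (mixed subpopulations) so frequency filtering
    has something to remove.  InDels are off by default.
    """

    n_strains: int = 100
    mean_load: float = 180.0
    load_range: tuple[int, int] = (47, 470)
    dispersion: float = 5.0
    gc_to_at_fraction: float = 0.9
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    decoy_fraction: float = 0.10
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.load_range
        if not (lo <= self.mean_load <= hi):
            raise ValueError("load_range must bracket mean_load")
        for frac in (self.gc_to_at_fraction, self.decoy_fraction, self.indel_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class ScreenSimConfig:
    """Plate-screen simulation settings (stage-2 style triplicates)."""

    n_variants: int = 45
    control_titer_mm: float = 11.5
    control_sd_mm: float = 0.3
    control_biomass: float = 18.4
    noise_cv: float = 0.05
    plate_size: int = 48
    controls_per_plate: int = 3
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_sd_mm < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.plate_size < self.controls_per_plate + 1:
            raise ValueError("plate must hold the controls plus at least one variant well")


# ---------------------------------------------------------------------------
# toy genome


def _random_codons(rng: np.random.Generator, n: int, gc_content: float) -> str:
    """Random non-stop codons with approximately the requested GC content."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])  # A C G T
    out = []
    while len(out) < n:
        draw = rng.choice(4, size=3 * (n - len(out)), p=probs)
        for i in range(0, len(draw), 3):
            codon = "".join(_BASES[draw[i : i + 3]])
            if codon not in _STOPS:
                out.append(codon)
            if len(out) == n:
                break
    return "".join(out)


def make_toy_genome(
    length: int,
    n_genes: int,
    gc_content: float = 0.54,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 600),
    topology: str = "circular",
) -> ReferenceGenome:
    """Generate a toy chromosome with non-overlapping, valid CDSs.

    Genes alternate between strands-by-draw, have lengths that are multiples
    of 3 within ``gene_length_range``, start with ATG and end with a stop
    codon, and contain no internal stop on the coding strand.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    if length < n_genes * lo:
        raise ValueError(f"genome of {length} bp cannot hold {n_genes} genes of >= {lo} bp")
    gene_lengths = (rng.integers(lo // 3, hi // 3 + 1, size=n_genes) * 3).astype(int)
    while gene_lengths.sum() > length - n_genes:  # keep >= 1 bp gaps
        gene_lengths = np.maximum(lo, gene_lengths - 3)
        if gene_lengths.sum() <= n_genes * lo:
            break
    slack = length - int(gene_lengths.sum())
    if slack < n_genes + 1:
        raise ValueError("infeasible gene packing: not enough intergenic room")
    gaps = rng.multinomial(slack - (n_genes + 1), np.full(n_genes + 1, 1.0 / (n_genes + 1))) + 1

    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    probs = np.array([p_at, p_gc, p_gc, p_at])

    parts: list[str] = []
    features: list[GeneFeature] = []
    cursor = 0
    for i in range(n_genes):
        gap = int(gaps[i])
        parts.append("".join(_BASES[rng.choice(4, size=gap, p=probs)]))
        cursor += gap
        glen = int(gene_lengths[i])
        coding = "ATG" + _random_codons(rng, glen // 3 - 2, gc_content) + _STOPS[rng.integers(3)]
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(coding if strand == "+" else reverse_complement(coding))
        features.append(
            GeneFeature(
                locus_tag=f"TOY{i:04d}",
                start=cursor,
                end=cursor + glen,
                strand=strand,
                kind="CDS",
                product=f"synthetic protein {i}",
            )
        )
        cursor += glen
    parts.append("".join(_BASES[rng.choice(4, size=int(gaps[-1]), p=probs)]))
    sequence = "".join(parts)
    assert len(sequence) == length
    return ReferenceGenome(id=f"toy_genome_{seed}", sequence=sequence, topology=topology, features=features)


def write_genome_files(genome: ReferenceGenome, out_dir: str | os.PathLike) -> tuple[Path, Path]:
    """Write the genome as FASTA + GFF3 (byte-stable for a fixed genome)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{genome.id}.fa"
    gff = out_dir / f"{genome.id}.gff"
    with open(fasta, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{genome.id}\tevohotspot\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )
    return fasta, gff


# ---------------------------------------------------------------------------
# mutagenesis cohort

_TRANSITION = {"G": "A", "C": "T", "A": "G", "T": "C"}
# non-G:C→A:T classes, as (reference base set, substitution map)
_OTHER_CLASSES = (
    ("AT", {"A": "G", "T": "C"}),  # A:T→G:C
    ("GC", {"G": "T", "C": "A"}),  # G:C→T:A
    ("GC", {"G": "C", "C": "G"}),  # G:C→C:G
    ("AT", {"A": "C", "T": "G"}),  # A:T→C:G
    ("AT", {"A": "T", "T": "A"}),  # A:T→T:A
)


def _nonsyn_snp_in_gene(
    genome: ReferenceGenome,
    feature: GeneFeature,
    rng: np.random.Generator,
    used: set[int],
    force_nonsynonymous: bool,
) -> Optional[tuple[int, str, str]]:
    """(position, ref, alt) of a SNP inside the gene, amino-acid-changing if
    requested.  Codon-wise rejection sampling; None if the gene is saturated."""
    cds = genome.feature_sequence(feature)
    n_codons = feature.length // 3
    for _ in range(200):
        codon_i = int(rng.integers(1, n_codons - 1))  # spare start and stop codons
        within = int(rng.integers(3))
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        ref_coding = codon[within]
        alt_choices = [b for b in "ACGT" if b != ref_coding]
        alt_coding = alt_choices[int(rng.integers(3))]
        if force_nonsynonymous:
            mutated = codon[:within] + alt_coding + codon[within + 1 :]
            if CODON_TO_AA[mutated] == CODON_TO_AA[codon] or CODON_TO_AA[mutated] == "*":
                continue
        offset = 3 * codon_i + within
        if feature.strand == "+":
            pos = feature.start + offset
            ref, alt = ref_coding, alt_coding
        else:
            pos = feature.start + (feature.length - 1 - offset)
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ref, alt = comp[ref_coding], comp[alt_coding]
        pos %= genome.length
        if pos in used:
            continue
        return pos, ref, alt
    return None


def simulate_mutagenesis(
    genome: ReferenceGenome, config: MutagenesisConfig
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Draw a mutagenized cohort and its complete ground-truth table.

    Returns (variants per strain, truth).  The truth table lists every
    emitted variant (1-based positions, as in VCF) with ``planted`` marking
    hotspot insertions and ``decoy`` marking sub-0.5-frequency records.
    """
    rng = np.random.default_rng(config.seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")
    gc_positions = np.flatnonzero((seq == "G") | (seq == "C"))
    at_positions = np.flatnonzero((seq == "A") | (seq == "T"))
    planted_feats = {
        p.locus_tag: genome.get_feature(p.locus_tag) for p in config.planted_hotspots
    }

    k = config.dispersion
    m = config.mean_load
    lo, hi = config.load_range
    variants_by_strain: dict[str, list[VariantRecord]] = {}
    truth_rows = []
    for s in range(config.n_strains):
        strain = f"strain{s + 1:04d}"
        load = int(np.clip(rng.negative_binomial(k, k / (k + m)), lo, hi))
        n_decoys = rng.binomial(load, config.decoy_fraction)
        used: set[int] = set()
        records: list[VariantRecord] = []

        def add_snp(planted: bool, decoy: bool, site: Optional[tuple[int, str, str]] = None):
            if site is None:
                if rng.random() < config.gc_to_at_fraction:
                    pool, sub = gc_positions, _TRANSITION
                else:
                    which, sub = _OTHER_CLASSES[int(rng.integers(5))]
                    pool = gc_positions if which == "GC" else at_positions
                for _ in range(100):
                    pos = int(pool[rng.integers(len(pool))])
                    if pos not in used:
                        break
                else:
                    return
                ref = genome.sequence[pos]
                alt = sub[ref]
            else:
                pos, ref, alt = site
            used.add(pos)
            freq = float(rng.uniform(0.05, 0.499)) if decoy else float(rng.uniform(0.5, 1.0))
            rec = VariantRecord(
                strain_id=strain,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                read_frequency=freq,
                depth=int(rng.integers(60, 140)),
            )
            records.append(rec)
            truth_rows.append(
                {
                    "strain": strain,
                    "position": pos + 1,
                    "ref": ref,
                    "alt": alt,
                    "read_frequency": freq,
                    "planted": planted,
                    "decoy": decoy,
                }
            )

        for i in range(load):
            add_snp(planted=False, decoy=i < n_decoys)
        for planted in config.planted_hotspots:
            if rng.random() < planted.per_strain_probability:
                site = _nonsyn_snp_in_gene(
                    genome, planted_feats[planted.locus_tag], rng, used,
                    planted.force_nonsynonymous,
                )
                if site is not None:
                    add_snp(planted=True, decoy=False, site=site)
        records.sort(key=lambda r: r.position)
        variants_by_strain[strain] = records

    truth = pd.DataFrame(
        truth_rows,
        columns=["strain", "position", "ref", "alt", "read_frequency", "planted", "decoy"],
    ).sort_values(["strain", "position"], kind="mergesort").reset_index(drop=True)
    return variants_by_strain, truth


def write_strain_vcf(
    records: Sequence[VariantRecord], genome: ReferenceGenome, sink: str | os.PathLike
) -> None:
    """Write one strain's variants as minimal VCF 4.2 with a VarScan-style
    percent FREQ INFO field."""
    with open(sink, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.id},length={genome.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=FREQ,Number=1,Type=String,Description="Alternate allele read frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: r.position):
            info = f"DP={r.depth if r.depth is not None else 100};FREQ={100 * r.read_frequency:.2f}%"
            fh.write(
                f"{genome.id}\t{r.position + 1}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# plate screen


def simulate_screen(
    config: ScreenSimConfig, genotype_table: Optional[pd.DataFrame] = None
) -> tuple[list[ScreenRecord], pd.DataFrame]:
    """Simulate stage-2-style plates: control triplicates plus variant
    triplicates, titers multiplicative-noisy around control mean x (1+effect).

    ``genotype_table`` columns: strain, titer_effect, biomass_effect
    (fractions; e.g. +0.20 for a 20% titer gain).  Strains not listed — and
    all variants when the table is None/empty — carry zero effect.  Returns
    (records, truth) where truth marks which variants were planted improved.
    """
    rng = np.random.default_rng(config.seed)
    effects: dict[str, tuple[float, float]] = {}
    if genotype_table is not None and len(genotype_table):
        for row in genotype_table.itertuples():
            effects[str(row.strain)] = (float(row.titer_effect), float(row.biomass_effect))

    wells_per_variant = config.replicates
    variants_per_plate = max(
        1, (config.plate_size - config.controls_per_plate) // wells_per_variant
    )
    records: list[ScreenRecord] = []
    truth_rows = []

    def noisy(mean: float) -> float:
        return max(float(mean * (1.0 + config.noise_cv * rng.standard_normal())), 0.0)

    for v in range(config.n_variants):
        plate_no = v // variants_per_plate
        plate = f"plate{plate_no + 1:03d}"
        if v % variants_per_plate == 0:
            plate_control_mean = float(
                rng.normal(config.control_titer_mm, config.control_sd_mm)
            )
            for rep in range(config.controls_per_plate):
                records.append(
                    ScreenRecord(
                        strain_id="control",
                        plate_id=plate,
                        replicate=rep + 1,
                        titer=noisy(plate_control_mean),
                        biomass=noisy(config.control_biomass),
                        is_control=True,
                    )
                )
        strain = f"variant{v + 1:04d}"
        titer_eff, biomass_eff = effects.get(strain, (0.0, 0.0))
        for rep in range(wells_per_variant):
            records.append(
                ScreenRecord(
                    strain_id=strain,
                    plate_id=plate,
                    replicate=rep + 1,
                    titer=noisy(plate_control_mean * (1.0 + titer_eff)),
                    biomass=noisy(config.control_biomass * (1.0 + biomass_eff)),
                    is_control=False,
                )
            )
        truth_rows.append(
            {
                "strain": strain,
                "plate": plate,
                "titer_effect": titer_eff,
                "biomass_effect": biomass_eff,
                "improved": titer_eff >= 0.10 and biomass_eff >= -0.35,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["strain", "plate", "titer_effect", "biomass_effect", "improved"]
    )
    return records, truth


# ---------------------------------------------------------------------------
# fermentation


def simulate_fermentation(
    params: MonodParameters | Sequence[MonodParameters],
    noise_cv: float = 0.01,
    n_batches: int = 3,
    seed: int = 0,
    init: tuple[float, float, float] = (0.25, 40.0, 0.0),
    t_end: float = 32.0,
    dt: float = 2.0,
) -> list[BatchTimeCourse]:
    """Noisy Monod batch trajectories sampled every ``dt`` hours.

    ``params`` may be one parameter set for all batches or one per batch
    (distinct local rates around shared constants).  Noise is multiplicative
    Gaussian at ``noise_cv`` per observation, floored at zero.
    """
    if isinstance(params, MonodParameters):
        param_list = [params] * n_batches
    else:
        param_list = list(params)
        if len(param_list) != n_batches:
            raise ValueError("need one parameter set per batch")
    rng = np.random.default_rng(seed)
    t_grid = np.arange(0.0, t_end + dt / 2, dt)
    courses = []
    for b in range(n_batches):
        clean = simulate_batch(param_list[b], init, t_grid, batch_id=f"batch{b + 1}")
        def jitter(arr):
            return np.maximum(arr * (1.0 + noise_cv * rng.standard_normal(len(arr))), 0.0)
        courses.append(
            BatchTimeCourse(
                batch_id=clean.batch_id,
                times=t_grid,
                biomass=jitter(clean.biomass),
                glucose=jitter(clean.glucose),
                histidine=jitter(clean.histidine),
                init=init,
            )
        )
    return courses
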