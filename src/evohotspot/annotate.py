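"""Variant effect annotation for evolved bacterial strain cohorts.

Each variant is assigned to a genomic region (CDS body, a 200 bp promoter
window upstream of a CDS start, or intergenic), classified by its coding
effect using the bacterial genetic code (translation table 11), and, for
SNPs, by its strand-symmetric substitution spectrum class.  The module also
implements the cohort-level filters (read frequency, synonymous drop),
per-strain mutation-load statistics, and read-depth anomaly flagging for
putative large deletions/duplications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import DepthProfile, GeneFeature, ReferenceGenome, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedMutation",
    "CoverageAnomaly",
    "SPECTRUM_CLASSES",
    "map_to_feature",
    "classify_coding_effect",
    "classify_spectrum",
    "annotate_variant",
    "annotate_variants",
    "filter_variants",
    "mutation_load",
    "spectrum_summary",
    "detect_coverage_anomalies",
]

# bacterial genetic code, stop codons as '*'
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six strand-symmetric substitution classes, transitions first
SPECTRUM_CLASSES = (
    "G:C→A:T",
    "A:T→G:C",
    "G:C→T:A",
    "G:C→C:G",
    "A:T→C:G",
    "A:T→T:A",
)

_SPECTRUM_LOOKUP = {
    ("G", "A"): "G:C→A:T",
    ("C", "T"): "G:C→A:T",
    ("A", "G"): "A:T→G:C",
    ("T", "C"): "A:T→G:C",
    ("G", "T"): "G:C→T:A",
    ("C", "A"): "G:C→T:A",
    ("G", "C"): "G:C→C:G",
    ("C", "G"): "G:C→C:G",
    ("A", "C"): "A:T→C:G",
    ("T", "G"): "A:T→C:G",
    ("A", "T"): "A:T→T:A",
    ("T", "A"): "A:T→T:A",
}

_PURINES = frozenset("AG")


@dataclass(frozen=True)
class AnnotatedMutation:
    """A :class:`~evohotspot.genome_io.VariantRecord` plus its annotation."""

    strain_id: str
    position: int
    ref_allele: str
    alt_allele: str
    read_frequency: float
    region: str  # CDS | promoter | intergenic
    locus_tag: Optional[str]
    effect: str  # synonymous | nonsynonymous | nonsense | promoter | small_indel | intergenic
    codon_index: Optional[int] = None  # 1-based residue number
    protein_change: Optional[str] = None
    spectrum_class: Optional[str] = None
    ti_tv: Optional[str] = None
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect in ("synonymous", "nonsynonymous", "nonsense"):
            if self.region != "CDS" or self.protein_change is None:
                raise ValueError(
                    f"coding effect {self.effect!r} requires a CDS region and protein change"
                )
        if (self.spectrum_class is not None) != self.is_snp:
            raise ValueError("spectrum class defined iff variant is a SNP")

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class CoverageAnomaly:
    """A depth-supported putative large deletion or duplication."""

    strain_id: str
    start: int
    end: int  # 0-based half-open
    kind: str  # putative_deletion | putative_duplication
    mean_fold: float


# ---------------------------------------------------------------------------
# genome index (built once per genome, cached on the object)


class _FeatureIndex:
    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.length = genome.length
        cds = [f for f in genome.features if f.kind == "CDS"]
        self.cds = sorted(cds, key=lambda f: (f.start, f.locus_tag))
        self.starts = np.array([f.start for f in self.cds], dtype=np.int64)
        self.ends = np.array([f.end for f in self.cds], dtype=np.int64)
        self.max_len = int((self.ends - self.starts).max()) if len(self.cds) else 0
        # promoter anchors: '+' CDS -> window ends at start; '-' CDS -> window
        # begins at end.  Sorted arrays for range queries.
        plus = [(f.start, f) for f in self.cds if f.strand == "+"]
        minus = [(f.end, f) for f in self.cds if f.strand == "-"]
        plus.sort(key=lambda t: t[0])
        minus.sort(key=lambda t: t[0])
        self.plus_anchor = np.array([a for a, _ in plus], dtype=np.int64)
        self.plus_feat = [f for _, f in plus]
        self.minus_anchor = np.array([a for a, _ in minus], dtype=np.int64)
        self.minus_feat = [f for _, f in minus]

    def cds_at(self, position: int) -> Optional[GeneFeature]:
        """First CDS covering ``position`` (lowest start, then locus tag)."""
        L = self.length
        circular = self.genome.topology == "circular"
        for pos in (position, position + L) if circular else (position,):
            # any feature covering pos starts in (pos - max_len, pos]
            hi = int(np.searchsorted(self.starts, pos, side="right"))
            lo = int(np.searchsorted(self.starts, pos - self.max_len, side="left"))
            for i in range(lo, hi):
                if self.ends[i] > pos:
                    return self.cds[i]
        return None

    def promoter_candidates(self, position: int, window: int):
        """(distance to CDS start, feature) pairs whose promoter window covers
        ``position``; distance counted on the CDS's strand."""
        L = self.length
        circular = self.genome.topology == "circular"
        shifts = (0, L, -L) if circular else (0,)
        out = []
        for shift in shifts:
            pos = position + shift
            # '+': position in [anchor - window, anchor - 1]
            lo = int(np.searchsorted(self.plus_anchor, pos + 1, side="left"))
            hi = int(np.searchsorted(self.plus_anchor, pos + window, side="right"))
            for i in range(lo, hi):
                out.append((int(self.plus_anchor[i] - pos), self.plus_feat[i]))
            # '-': position in [anchor, anchor + window - 1]
            lo = int(np.searchsorted(self.minus_anchor, pos - window + 1, side="left"))
            hi = int(np.searchsorted(self.minus_anchor, pos, side="right"))
            for i in range(lo, hi):
                out.append((int(pos - self.minus_anchor[i]) + 1, self.minus_feat[i]))
        return out


def _index(genome: ReferenceGenome) -> _FeatureIndex:
    idx = getattr(genome, "_feature_index", None)
    if idx is None or idx.genome is not genome:
        idx = _FeatureIndex(genome)
        genome._feature_index = idx  # type: ignore[attr-defined]
    return idx


# ---------------------------------------------------------------------------
# region mapping


def map_to_feature(
    position: int, genome: ReferenceGenome, promoter_window: int = 200
) -> tuple[str, Optional[str]]:
    """Assign a genomic position to (region, locus_tag).

    CDS membership wins over any promoter window.  A position inside the
    upstream window of several CDSs goes to the CDS whose start (on its own
    strand) is nearest; ties break to the lexicographically lower locus tag.
    Downstream (terminator-side) windows are deliberately not considered.
    """
    if not (0 <= position < genome.length):
        raise IndexError(f"position {position} outside genome of length {genome.length}")
    idx = _index(genome)
    hit = idx.cds_at(position)
    if hit is not None:
        return "CDS", hit.locus_tag
    cands = idx.promoter_candidates(position, promoter_window)
    if cands:
        dist, feat = min(cands, key=lambda t: (t[0], t[1].locus_tag))
        return "promoter", feat.locus_tag
    return "intergenic", None


# ---------------------------------------------------------------------------
# coding effect


def classify_spectrum(ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """Collapse a directed single-base substitution onto the six
    strand-symmetric spectrum classes and its transition/transversion type."""
    key = (ref_allele.upper(), alt_allele.upper())
    if key not in _SPECTRUM_LOOKUP:
        raise ValueError(f"not a single-base substitution: {ref_allele}->{alt_allele}")
    ti_tv = (
        "transition"
        if (key[0] in _PURINES) == (key[1] in _PURINES)
        else "transversion"
    )
    return _SPECTRUM_LOOKUP[key], ti_tv


def _coding_context(
    variant: VariantRecord, genome: ReferenceGenome, feature: GeneFeature
) -> tuple[str, str, int]:
    """(ref codon, alt codon, 1-based residue index) on the coding strand."""
    L = genome.length
    offset_fwd = variant.position - feature.start
    if offset_fwd < 0:
        if genome.topology != "circular":
            raise ValueError("position before feature start on a linear genome")
        offset_fwd += L
    if offset_fwd >= feature.length:
        raise ValueError(f"position {variant.position} not inside CDS {feature.locus_tag}")

    ref_base = genome.base(variant.position)
    if ref_base != variant.ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at position {variant.position + 1}: "
            f"VCF says {variant.ref_allele}, genome has {ref_base} "
            "(possible 0/1-based coordinate fault)"
        )

    if feature.strand == "+":
        offset = offset_fwd
        alt_coding = variant.alt_allele.upper()
    else:
        offset = feature.length - 1 - offset_fwd
        alt_coding = _COMPLEMENT[variant.alt_allele.upper()]

    cds_seq = genome.feature_sequence(feature)
    codon_i = offset // 3
    within = offset % 3
    ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:  # trailing partial codon of a length%3 != 0 CDS
        raise ValueError(
            f"CDS {feature.locus_tag}: variant falls in a partial trailing codon"
        )
    alt_codon = ref_codon[:within] + alt_coding + ref_codon[within + 1 :]
    return ref_codon, alt_codon, codon_i + 1


def classify_coding_effect(
    variant: VariantRecord, genome: ReferenceGenome, feature: Optional[GeneFeature] = None
) -> AnnotatedMutation:
    """Classify a CDS variant as synonymous / nonsynonymous / nonsense.

    SNPs are translated codon-wise under the bacterial code; minus-strand
    CDSs have their alleles complemented onto the coding strand.  Small
    InDels are classed ``small_indel`` without frameshift sub-typing.  A
    reference-allele/genome disagreement raises, it is never re-anchored.
    """
    if feature is None:
        idx = _index(genome)
        feature = idx.cds_at(variant.position)
        if feature is None:
            raise ValueError(f"position {variant.position} is not inside any CDS")

    spectrum = ti_tv = None
    if variant.is_snp:
        ref_codon, alt_codon, residue = _coding_context(variant, genome, feature)
        ref_aa = CODON_TO_AA[ref_codon]
        alt_aa = CODON_TO_AA[alt_codon]
        if alt_aa == ref_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "nonsense"
        else:
            effect = "nonsynonymous"
        protein_change = f"{ref_aa}{residue}{alt_aa}"
        spectrum, ti_tv = classify_spectrum(variant.ref_allele, variant.alt_allele)
        codon_index = residue
    else:
        effect = "small_indel"
        protein_change = None
        codon_index = None

    return AnnotatedMutation(
        strain_id=variant.strain_id,
        position=variant.position,
        ref_allele=variant.ref_allele,
        alt_allele=variant.alt_allele,
        read_frequency=variant.read_frequency,
        region="CDS",
        locus_tag=feature.locus_tag,
        effect=effect,
        codon_index=codon_index,
        protein_change=protein_change,
        spectrum_class=spectrum,
        ti_tv=ti_tv,
        depth=variant.depth,
    )


def annotate_variant(
    variant: VariantRecord, genome: ReferenceGenome, promoter_window: int = 200
) -> AnnotatedMutation:
    """Full annotation: region assignment plus effect/spectrum classification."""
    region, locus_tag = map_to_feature(variant.position, genome, promoter_window)
    if region == "CDS":
        return classify_coding_effect(variant, genome)
    spectrum = ti_tv = None
    if variant.is_snp:
        spectrum, ti_tv = classify_spectrum(variant.ref_allele, variant.alt_allele)
        effect = "promoter" if region == "promoter" else "intergenic"
    else:
        effect = "small_indel"
    return AnnotatedMutation(
        strain_id=variant.strain_id,
        position=variant.position,
        ref_allele=variant.ref_allele,
        alt_allele=variant.alt_allele,
        read_frequency=variant.read_frequency,
        region=region,
        locus_tag=locus_tag,
        effect=effect,
        spectrum_class=spectrum,
        ti_tv=ti_tv,
        depth=variant.depth,
    )


def annotate_variants(
    variants: Iterable[VariantRecord], genome: ReferenceGenome, promoter_window: int = 200
) -> list[AnnotatedMutation]:
    return [annotate_variant(v, genome, promoter_window) for v in variants]


# ---------------------------------------------------------------------------
# filters and cohort statistics


def filter_variants(
    variants: Sequence[AnnotatedMutation],
    min_read_frequency: float = 0.50,
    drop_synonymous: bool = True,
) -> list[AnnotatedMutation]:
    """Apply the cohort filters: discard variants with read frequency below
    the threshold (boundary kept) and, by default, all synonymous SNPs.
    Input order is preserved; the operation is idempotent."""
    kept = []
    n_low = n_syn = 0
    for v in variants:
        if v.read_frequency < min_read_frequency:
            n_low += 1
            continue
        if drop_synonymous and v.effect == "synonymous":
            n_syn += 1
            continue
        kept.append(v)
    logger.info(
        "filter_variants: kept %d / %d (dropped %d low-frequency, %d synonymous)",
        len(kept), len(variants), n_low, n_syn,
    )
    return kept


def mutation_load(
    variants_by_strain: Mapping[str, Sequence],
) -> tuple[pd.Series, dict]:
    """Per-strain mutation counts plus a cohort summary (mean, min, max)."""
    counts = pd.Series(
        {strain: len(vs) for strain, vs in variants_by_strain.items()},
        dtype=int,
        name="n_mutations",
    )
    if len(counts) == 0:
        return counts, {"n_strains": 0, "mean": None, "min": None, "max": None}
    summary = {
        "n_strains": int(len(counts)),
        "mean": float(counts.mean()),
        "min": int(counts.min()),
        "max": int(counts.max()),
    }
    return counts, summary


def spectrum_summary(annotated: Iterable[AnnotatedMutation]) -> pd.DataFrame:
    """Tally SNPs over the six substitution classes (class, count, fraction)."""
    tally = {c: 0 for c in SPECTRUM_CLASSES}
    total = 0
    for m in annotated:
        if m.spectrum_class is not None:
            tally[m.spectrum_class] += 1
            total += 1
    return pd.DataFrame(
        {
            "spectrum_class": list(SPECTRUM_CLASSES),
            "count": [tally[c] for c in SPECTRUM_CLASSES],
            "fraction": [tally[c] / total if total else 0.0 for c in SPECTRUM_CLASSES],
        }
    )


# ---------------------------------------------------------------------------
# coverage anomalies


def detect_coverage_anomalies(
    profile: DepthProfile,
    low_fold: float = 0.25,
    high_fold: float = 1.75,
    min_window: int = 500,
) -> list[CoverageAnomaly]:
    """Flag maximal runs of at least ``min_window`` consecutive bases whose
    depth is <= ``low_fold`` x genome median (putative large deletion) or
    >= ``high_fold`` x median (putative duplication)."""
    depth = profile.depth
    if len(depth) == 0:
        raise ValueError("empty depth profile")
    median = float(np.median(depth))
    if median == 0:
        raise ValueError("all-zero (or majority-zero) depth profile: missing data?")
    anomalies: list[CoverageAnomaly] = []
    for mask, kind in (
        (depth <= low_fold * median, "putative_deletion"),
        (depth >= high_fold * median, "putative_duplication"),
    ):
        padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_window:
                anomalies.append(
                    CoverageAnomaly(
                        strain_id=profile.strain_id,
                        start=int(s),
                        end=int(e),
                        kind=kind,
                        mean_fold=float(depth[s:e].mean() / median),
                    )
                )
    anomalies.sort(key=lambda a: a.start)
    return anomalies
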