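"""Reference genome, gene annotation and variant file handling.

All coordinates are 0-based half-open internally.  File I/O honours each
format's native convention (FASTA/GenBank/GFF3/VCF are converted on read and
write).  The reference chromosome may be circular; a gene wrapping the
replication origin is stored unwrapped, i.e. with ``end > genome.length`` and
positions taken modulo the genome length.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "ReferenceGenome",
    "VariantRecord",
    "DepthProfile",
    "read_reference",
    "read_variants",
    "read_depth_table",
    "write_mutation_table",
    "read_mutation_table",
    "MUTATION_TABLE_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the reference chromosome.

    ``start``/``end`` are 0-based half-open on the forward strand; for a
    feature wrapping the circular origin ``end`` exceeds the genome length.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    gene_name: Optional[str] = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.locus_tag}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.locus_tag}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceGenome:
    """A single (typically circular) bacterial chromosome plus its genes."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[GeneFeature] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"genome {self.id}: non-ACGT characters {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")
        self.features = sorted(self.features, key=lambda f: (f.start, f.locus_tag))
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus tags: {dup}")
        for f in self.features:
            if f.start >= self.length or (self.topology == "linear" and f.end > self.length):
                raise ValueError(
                    f"feature {f.locus_tag} [{f.start},{f.end}) outside genome of length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Forward-strand subsequence, honouring circular wrap-around."""
        if end <= self.length:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise IndexError(f"[{start},{end}) outside linear genome of length {self.length}")
        return self.sequence[start:] + self.sequence[: end - self.length]

    def base(self, position: int) -> str:
        return self.sequence[position % self.length]

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Coding-strand sequence of a feature (reverse-complemented for '-')."""
        s = self.slice(feature.start, feature.end)
        return reverse_complement(s) if feature.strand == "-" else s

    def get_feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"locus tag {locus_tag!r} not in genome {self.id}")


@dataclass(frozen=True)
class VariantRecord:
    """One substitution or small InDel observed in one strain.

    ``position`` is 0-based internal (VCF input is 1-based and converted on
    read).  ``read_frequency`` is the fraction of reads supporting the
    alternate allele, normalised to [0, 1].
    """

    strain_id: str
    position: int
    ref_allele: str
    alt_allele: str
    read_frequency: float
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.read_frequency <= 1.0):
            raise ValueError(
                f"read frequency {self.read_frequency} outside [0, 1] "
                f"({self.strain_id} @ {self.position + 1})"
            )
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNP"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def is_snp(self) -> bool:
        return self.kind == "SNP"


@dataclass
class DepthProfile:
    """Per-base read depth for one strain over the whole chromosome."""

    strain_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if (self.depth < 0).any():
            raise ValueError("negative depth values")


# ---------------------------------------------------------------------------
# reference loading


def _features_from_gff(path: Path, seq_id: str) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for feat in db.features_of_type("CDS"):
        if feat.seqid != seq_id:
            raise ValueError(f"GFF seqid {feat.seqid!r} does not match FASTA record {seq_id!r}")
        tag = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [None])[0]
        if tag is None:
            raise ValueError(f"CDS without locus_tag/ID at {feat.start}")
        features.append(
            GeneFeature(
                locus_tag=tag,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                kind="CDS",
                gene_name=(feat.attributes.get("gene") or [None])[0],
                product=(feat.attributes.get("product") or [""])[0],
            )
        )
    return features


def _features_from_genbank(record) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        tag = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
        if tag is None:
            raise ValueError("GenBank CDS without locus_tag")
        features.append(
            GeneFeature(
                locus_tag=tag,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                kind="CDS",
                gene_name=(quals.get("gene") or [None])[0],
                product=(quals.get("product") or [""])[0],
            )
        )
    return features


def read_reference(
    fasta_source: str | os.PathLike | None,
    annotation_source: str | os.PathLike,
    topology: str = "circular",
) -> ReferenceGenome:
    """Load the reference chromosome and its CDS annotation.

    ``annotation_source`` may be GFF3 (requires ``fasta_source``) or a GenBank
    flat file carrying its own sequence (``fasta_source`` then optional).
    Exactly one chromosome record is accepted.  CDS features whose length is
    not a multiple of 3 are kept but recorded in ``genome.warnings``.
    """
    annotation_source = Path(annotation_source)
    if not annotation_source.exists():
        raise FileNotFoundError(annotation_source)

    if annotation_source.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        records = list(SeqIO.parse(str(annotation_source), "genbank"))
        if len(records) != 1:
            raise ValueError(f"expected one GenBank record, found {len(records)}")
        record = records[0]
        seq = str(record.seq)
        if fasta_source is not None:
            fasta_recs = list(SeqIO.parse(str(fasta_source), "fasta"))
            if len(fasta_recs) != 1:
                raise ValueError("expected a single-record FASTA")
            if str(fasta_recs[0].seq).upper() != seq.upper():
                raise ValueError("FASTA sequence disagrees with GenBank record")
        features = _features_from_genbank(record)
        genome_id = record.id
    else:
        if fasta_source is None:
            raise ValueError("GFF3 annotation requires a FASTA sequence")
        fasta_source = Path(fasta_source)
        if not fasta_source.exists():
            raise FileNotFoundError(fasta_source)
        fasta_recs = list(SeqIO.parse(str(fasta_source), "fasta"))
        if len(fasta_recs) != 1:
            raise ValueError(f"expected a single-record FASTA, found {len(fasta_recs)} records")
        record = fasta_recs[0]
        seq = str(record.seq)
        genome_id = record.id
        features = _features_from_gff(annotation_source, genome_id)

    genome = ReferenceGenome(id=genome_id, sequence=seq, topology=topology, features=features)
    for f in genome.features:
        if f.kind == "CDS" and f.length % 3 != 0:
            genome.warnings.append(
                f"CDS {f.locus_tag}: length {f.length} not divisible by 3"
            )
    return genome


# ---------------------------------------------------------------------------
# variant loading


def _normalise_frequency(raw) -> float:
    """Accept VarScan-style percent strings ('53.2%') and plain proportions."""
    if isinstance(raw, (tuple, list)):
        raw = raw[0]
    if isinstance(raw, bytes):
        raw = raw.decode()
    if isinstance(raw, str):
        raw = raw.strip()
        if raw.endswith("%"):
            value = float(raw[:-1]) / 100.0
        else:
            value = float(raw)
            if value > 1.0:
                value /= 100.0
    else:
        value = float(raw)
        if value > 1.0:
            value /= 100.0
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"read frequency {raw!r} outside [0, 1] after normalisation")
    return value


def read_variants(
    vcf_source: str | os.PathLike,
    strain_id: str,
    frequency_key: str = "FREQ",
    genome: Optional[ReferenceGenome] = None,
) -> list[VariantRecord]:
    """Read one strain's VCF into :class:`VariantRecord` objects.

    The alternate-allele read frequency is taken from INFO or, failing that,
    from the first sample's FORMAT field under ``frequency_key``; percent
    strings and proportions are both accepted.  Multi-allelic sites yield one
    record per ALT allele.
    """
    vcf_source = os.fspath(vcf_source)
    if not os.path.exists(vcf_source):
        raise FileNotFoundError(vcf_source)
    records: list[VariantRecord] = []
    with pysam.VariantFile(vcf_source) as vcf:
        for rec in vcf:
            if genome is not None and not (1 <= rec.pos <= genome.length):
                raise ValueError(
                    f"{vcf_source}: position {rec.pos} outside genome of length {genome.length}"
                )
            if rec.info.get(frequency_key) is not None:
                freq = _normalise_frequency(rec.info[frequency_key])
            elif len(rec.samples) and frequency_key in rec.samples[0]:
                freq = _normalise_frequency(rec.samples[0][frequency_key])
            else:
                raise ValueError(
                    f"{vcf_source}: no {frequency_key!r} field at position {rec.pos}"
                )
            depth = rec.info.get("DP")
            for alt in rec.alts or ():
                records.append(
                    VariantRecord(
                        strain_id=strain_id,
                        position=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        read_frequency=freq,
                        depth=int(depth) if depth is not None else None,
                    )
                )
    return records


def read_depth_table(source: str | os.PathLike, strain_id: str, genome_length: int) -> DepthProfile:
    """Read a per-base depth table (TSV: position<TAB>depth, 1-based) or
    bedGraph (chrom, start, end, depth; 0-based half-open)."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    depth = np.zeros(genome_length, dtype=np.int64)
    if df.shape[1] >= 4:  # bedGraph
        for _, row in df.iterrows():
            depth[int(row[1]) : int(row[2])] = int(row[3])
    elif df.shape[1] >= 2:
        pos = df[0].to_numpy(dtype=np.int64) - 1
        depth[pos] = df[1].to_numpy(dtype=np.int64)
    else:
        raise ValueError("depth table needs >= 2 columns")
    return DepthProfile(strain_id=strain_id, depth=depth)


# ---------------------------------------------------------------------------
# mutation table

MUTATION_TABLE_COLUMNS = [
    "strain",
    "position",
    "ref",
    "alt",
    "locus_tag",
    "region",
    "effect",
    "protein_change",
    "spectrum_class",
    "read_frequency",
]


def write_mutation_table(annotated_mutations: Iterable, sink: str | os.PathLike) -> None:
    """Write annotated mutations as a TSV with a fixed column order.

    Rows are sorted by (strain, position) so output is bit-stable regardless
    of input order.  Positions are written 1-based, matching the VCF input.
    """
    rows = []
    for m in annotated_mutations:
        rows.append(
            {
                "strain": m.strain_id,
                "position": m.position + 1,
                "ref": m.ref_allele,
                "alt": m.alt_allele,
                "locus_tag": m.locus_tag if m.locus_tag is not None else "",
                "region": m.region,
                "effect": m.effect,
                "protein_change": m.protein_change or "",
                "spectrum_class": m.spectrum_class or "",
                "read_frequency": f"{m.read_frequency:.4f}",
            }
        )
    df = pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["strain", "position"], kind="mergesort")
    df.to_csv(sink, sep="\t", index=False)


def read_mutation_table(source: str | os.PathLike) -> pd.DataFrame:
    """Read a mutation table written by :func:`write_mutation_table`."""
    df = pd.read_csv(
        source,
        sep="\t",
        dtype={c: str for c in MUTATION_TABLE_COLUMNS if c not in ("position", "read_frequency")},
        keep_default_na=False,
    )
    missing = [c for c in MUTATION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    df["position"] = df["position"].astype(int)
    df["read_frequency"] = df["read_frequency"].astype(float)
    return df
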