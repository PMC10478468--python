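"""Cross-strain mutation aggregation, hotspot-gene calling and SNP ranking.

A *hotspot gene* carries (by default nonsynonymous or nonsense) mutations in
at least a threshold fraction — 10% — of the independently evolved strains.
This module builds the strains x genes count matrix, calls hotspots, computes
gene-length enrichment and co-mutation fractions, attributes genes to
metabolic pathways from an offline map, and ranks candidate SNPs by the
campaign's selection criteria (hotspot abundance, then screen performance).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedMutation
from .genome_io import ReferenceGenome

__all__ = [
    "GeneMutationMatrix",
    "HotspotEntry",
    "CandidateSNP",
    "build_matrix",
    "call_hotspots",
    "length_enrichment",
    "co_mutation",
    "rank_candidates",
    "attribute_pathways",
    "positional_totals",
]

DEFAULT_EFFECT_CLASSES = frozenset({"nonsynonymous", "nonsense"})


@dataclass
class GeneMutationMatrix:
    """Strains x genes counts of retained mutations.

    ``counts`` is a DataFrame indexed by strain with one column per locus
    tag; genes without any mutation are retained so enrichment denominators
    stay correct.  ``gene_lengths`` is indexed like the columns.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.gene_lengths.index):
            raise ValueError("counts columns and gene_lengths index disagree")
        if (self.gene_lengths <= 0).any():
            raise ValueError("all gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative mutation counts")

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_strains(self) -> int:
        return len(self.counts.index)

    @property
    def total_mutations(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass(frozen=True)
class HotspotEntry:
    locus_tag: str
    n_strains_mutated: int
    fraction_strains: float
    n_mutations: int
    rank: int
    enrichment_fold: Optional[float] = None
    pathway_tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CandidateSNP:
    """One (strain, hotspot-gene SNP) pair with its selection scores."""

    strain_id: str
    locus_tag: str
    protein_change: Optional[str]
    abundance_penalty: int  # other hotspot genes mutated in the same strain
    titer_improvement: Optional[float] = None  # percent vs same-plate control
    biomass_change: Optional[float] = None  # percent
    user_flag: Optional[str] = None  # metabolic-judgement placeholder

    def __post_init__(self) -> None:
        if self.abundance_penalty < 0:
            raise ValueError("abundance_penalty must be >= 0")


def build_matrix(
    annotated_mutations: Iterable[AnnotatedMutation],
    genome: ReferenceGenome,
    effect_classes: frozenset[str] | set[str] = DEFAULT_EFFECT_CLASSES,
    strains: Optional[Sequence[str]] = None,
) -> GeneMutationMatrix:
    """Count retained mutations per strain per gene.

    Only mutations assigned to a gene and whose effect is in
    ``effect_classes`` are counted (default: nonsynonymous + nonsense CDS
    mutations).  All annotated CDS genes appear as columns even when
    unmutated; pass ``strains`` to force the strain universe (strains with
    zero retained mutations would otherwise be dropped).
    """
    genes = [f.locus_tag for f in genome.features if f.kind == "CDS"]
    lengths = pd.Series(
        {f.locus_tag: f.length for f in genome.features if f.kind == "CDS"},
        name="length",
    ).loc[genes]
    seen_strains: list[str] = list(strains) if strains is not None else []
    tallies: dict[tuple[str, str], int] = {}
    for m in annotated_mutations:
        if strains is None and m.strain_id not in seen_strains:
            seen_strains.append(m.strain_id)
        if m.locus_tag is None or m.effect not in effect_classes:
            continue
        if m.locus_tag not in lengths.index:
            raise KeyError(f"mutation assigned to unknown gene {m.locus_tag!r}")
        key = (m.strain_id, m.locus_tag)
        tallies[key] = tallies.get(key, 0) + 1
    counts = pd.DataFrame(0, index=pd.Index(seen_strains, name="strain"), columns=genes, dtype=int)
    for (strain, gene), n in tallies.items():
        counts.at[strain, gene] = n
    return GeneMutationMatrix(counts=counts, gene_lengths=lengths)


def call_hotspots(
    matrix: GeneMutationMatrix,
    min_fraction: float = 0.10,
    enrichment: Optional[pd.Series] = None,
    pathway_map: Optional[Mapping[str, Sequence[str]]] = None,
) -> list[HotspotEntry]:
    """Return genes mutated in at least ``min_fraction`` of strains, ranked.

    Ordering: number of mutated strains descending, ties broken by total
    mutation count descending, then locus tag ascending.  Ranks are dense
    over descending strain counts.
    """
    if matrix.n_strains < 1:
        raise ValueError("matrix has no strains")
    mutated = (matrix.counts > 0).sum(axis=0)
    totals = matrix.counts.sum(axis=0)
    frac = mutated / matrix.n_strains
    keep = frac[frac >= min_fraction].index
    ordered = sorted(keep, key=lambda g: (-mutated[g], -totals[g], g))
    # dense rank over distinct strain counts
    entries: list[HotspotEntry] = []
    rank = 0
    prev = None
    for g in ordered:
        if mutated[g] != prev:
            rank += 1
            prev = mutated[g]
        entries.append(
            HotspotEntry(
                locus_tag=g,
                n_strains_mutated=int(mutated[g]),
                fraction_strains=float(frac[g]),
                n_mutations=int(totals[g]),
                rank=rank,
                enrichment_fold=float(enrichment[g]) if enrichment is not None else None,
                pathway_tags=tuple(pathway_map.get(g, ())) if pathway_map else (),
            )
        )
    return entries


def length_enrichment(
    matrix: GeneMutationMatrix,
    genome: Optional[ReferenceGenome] = None,
    background: str = "annotated",
) -> pd.Series:
    """Observed/expected mutation fold per gene under a length-proportional
    null.

    ``background='annotated'`` spreads the total over the summed gene lengths
    in the matrix; ``background='genome'`` spreads it over the full genome
    length (requires ``genome``), so folds then measure enrichment against a
    genome-wide uniform rate.  Genes with zero expectation report NaN.
    """
    total = matrix.total_mutations
    if total == 0:
        raise ValueError("no mutations: enrichment undefined")
    lengths = matrix.gene_lengths.astype(float)
    if background == "annotated":
        denom = float(lengths.sum())
    elif background == "genome":
        if genome is None:
            raise ValueError("background='genome' requires the genome")
        denom = float(genome.length)
    else:
        raise ValueError("background must be 'annotated' or 'genome'")
    expected = total * lengths / denom
    observed = matrix.counts.sum(axis=0).astype(float)
    fold = observed / expected
    fold[expected == 0] = np.nan
    fold.name = "enrichment_fold"
    return fold


def co_mutation(matrix: GeneMutationMatrix, gene_a: str, gene_b: str) -> float:
    """Fraction of strains mutated in ``gene_a`` that are also mutated in
    ``gene_b``."""
    for g in (gene_a, gene_b):
        if g not in matrix.counts.columns:
            raise KeyError(f"gene {g!r} not in matrix")
    in_a = matrix.counts[gene_a] > 0
    n_a = int(in_a.sum())
    if n_a == 0:
        raise ValueError(f"no strain mutated in {gene_a!r}: co-mutation undefined")
    both = int((in_a & (matrix.counts[gene_b] > 0)).sum())
    return both / n_a


def rank_candidates(
    matrix: GeneMutationMatrix,
    hotspots: Sequence[HotspotEntry],
    mutations: Iterable[AnnotatedMutation],
    screen_results: Optional[Mapping[str, tuple[float, float]]] = None,
    user_flags: Optional[Mapping[tuple[str, str], str]] = None,
) -> list[CandidateSNP]:
    """Score and order every (strain, hotspot-gene SNP) pair.

    Selection logic: prefer SNPs from strains with few *other* mutated
    hotspot genes (abundance criterion), then higher titer improvement, then
    the smaller biomass reduction (performance criterion).  ``screen_results``
    maps strain -> (titer_improvement %, biomass_change %); strains absent
    from it keep their candidates but rank last.  Expert metabolic judgement
    enters only as a pass-through ``user_flag``.
    """
    hot_genes = {h.locus_tag for h in hotspots}
    hot_counts = matrix.counts[[g for g in matrix.genes if g in hot_genes]]
    candidates: list[CandidateSNP] = []
    for m in mutations:
        if m.locus_tag not in hot_genes or not m.is_snp:
            continue
        if m.strain_id in matrix.counts.index:
            row = hot_counts.loc[m.strain_id]
            penalty = int((row.drop(labels=[m.locus_tag]) > 0).sum())
        else:
            penalty = 0
        perf = screen_results.get(m.strain_id) if screen_results else None
        candidates.append(
            CandidateSNP(
                strain_id=m.strain_id,
                locus_tag=m.locus_tag,
                protein_change=m.protein_change,
                abundance_penalty=penalty,
                titer_improvement=perf[0] if perf else None,
                biomass_change=perf[1] if perf else None,
                user_flag=(user_flags or {}).get((m.strain_id, m.locus_tag)),
            )
        )

    def sort_key(c: CandidateSNP):
        missing = c.titer_improvement is None
        return (
            missing,  # strains without screen data rank last
            c.abundance_penalty,
            -(c.titer_improvement if c.titer_improvement is not None else 0.0),
            -(c.biomass_change if c.biomass_change is not None else 0.0),
            c.locus_tag,
            c.strain_id,
        )

    return sorted(candidates, key=sort_key)


def attribute_pathways(
    genes: Sequence[str], pathway_map: str | os.PathLike | Mapping[str, Sequence[str]]
) -> dict[str, list[str]]:
    """Annotate genes with pathway tags from an offline locus_tag -> pathway
    map (TSV with two columns, one row per (gene, pathway) pair, or an
    in-memory mapping).  Unmapped genes get an empty list."""
    if isinstance(pathway_map, (str, os.PathLike)):
        df = pd.read_csv(pathway_map, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("pathway map needs two columns: locus_tag, pathway")
        mapping: dict[str, list[str]] = {}
        for tag, pathway in zip(df[0], df[1]):
            if pd.isna(tag) or pd.isna(pathway):
                raise ValueError("malformed pathway map row")
            mapping.setdefault(tag, []).append(pathway)
    else:
        mapping = {k: list(v) for k, v in pathway_map.items()}
    return {g: list(mapping.get(g, [])) for g in genes}


def positional_totals(matrix: GeneMutationMatrix, genome: ReferenceGenome) -> pd.DataFrame:
    """Per-gene mutation totals ordered by genomic start, for Manhattan-style
    plots of load along the chromosome.  A gene wrapping the circular origin
    is placed at its (unwrapped) start."""
    totals = matrix.counts.sum(axis=0)
    rows = []
    for f in genome.features:
        if f.kind != "CDS" or f.locus_tag not in totals.index:
            continue
        rows.append({"locus_tag": f.locus_tag, "start": f.start, "total_mutations": int(totals[f.locus_tag])})
    df = pd.DataFrame(rows, columns=["locus_tag", "start", "total_mutations"])
    return df.sort_values("start", kind="mergesort").reset_index(drop=True)
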