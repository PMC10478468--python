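# evohotspot

Downstream analytics for biosensor-guided random mutagenesis campaigns in
bacterial producer strains. After a chemical mutagen (typically MNNG) and a
FACS biosensor screen have delivered dozens of independently evolved isolates,
the remaining work is computational: map each isolate's variants onto the
reference genome, find the genes that are mutated in suspiciously many
independent isolates ("hotspot genes"), decide which plate-screen variants are
genuinely improved, and quantify the best strains' fermentation kinetics.
`evohotspot` implements that pipeline as a tested Python library with a thin
command-line interface, plus a synthetic-data generator so every stage runs
and is validated without access to sequencing data.

## What it computes

**Variant annotation.** Per-strain VCFs are mapped onto a single (circular)
reference chromosome. Each SNP is assigned to a CDS, to the 200 bp promoter
window upstream of a CDS start (strand-aware; no downstream window), or to
intergenic space; CDS SNPs are translated codon-wise under the bacterial
genetic code (table 11) into synonymous / nonsynonymous / nonsense calls with
protein changes like `D735G`, and classified onto the six strand-symmetric
substitution classes (G:C→A:T, A:T→G:C, …). Cohort filters drop variants with
alternate-read frequency < 0.50 and, by default, synonymous SNPs. Read-depth
profiles can be scanned for putative large deletions/duplications
(≥ 500 bp runs at ≤ 0.25× / ≥ 1.75× the genome-median depth).

**Hotspot genes.** A strains × genes count matrix of retained mutations feeds
threshold calling: a gene mutated in ≥ 10% of the independent strains is a
hotspot. The module also computes gene-length enrichment folds
(observed / expected under a length-proportional null), co-mutation fractions
between gene pairs, offline pathway attribution, and ranks candidate SNPs by
the campaign's selection criteria — few other mutated hotspot genes in the
same strain first, then titer improvement, then biomass retention.

**Screen decisions.** The two-step microtiter characterization: stage 1
(single measurements) passes a variant whose titer exceeds the upper bound of
the two-sided 90% *t*-confidence interval of the same-plate control mean *and*
beats it by ≥ 1 mM; stage 2 (triplicates) confirms when the mean titer clears
the control CI, the relative gain is ≥ +10%, and biomass loss is ≤ 35%.
Controls are always matched per plate.

**Bioprocess model.** Batch growth on glucose with product formation,
classical Monod kinetics:

    µ = µ_max · S/(K_S + S)
    dX/dt = µX,   dP/dt = q_P,max · S/(K_S+S) · X,
    dS/dt = −(µ/Y_XS)X − q_P X · M_His/(1000 · Y_PS)

with X in g CDW L⁻¹, S in g L⁻¹, P in mM. Several batches are fitted jointly
with user-declared global (shared) vs local (per-batch) parameters;
asymmetric confidence bounds come from a parametric bootstrap. KPIs (titer in
g L⁻¹, C-mol/C-mol, mol/mol and g/g yields, volumetric productivity) follow
from end-point measurements; for the C6→C6 glucose→histidine conversion the
C-mol and molar yields coincide.

## Worked example

```python
import numpy as np
from evohotspot import annotate, bioprocess, hotspots, screen, synthetic_data as synth

# a 50 kb toy chromosome with 30 genes, and a 40-strain mutagenized cohort
genome = synth.make_toy_genome(50_000, 30, seed=1)
cfg = synth.MutagenesisConfig(
    n_strains=40, mean_load=60, load_range=(15, 150), seed=1,
    planted_hotspots=[synth.PlantedHotspot("TOY0007", 0.30)])
cohort, truth = synth.simulate_mutagenesis(genome, cfg)

annotated = [m for recs in cohort.values()
             for m in annotate.annotate_variants(recs, genome)]
kept = annotate.filter_variants(annotated)            # freq >= 0.5, no synonymous
matrix = hotspots.build_matrix(kept, genome, strains=list(cohort))
for entry in hotspots.call_hotspots(matrix, min_fraction=0.10)[:3]:
    print(entry.locus_tag, entry.n_strains_mutated, f"{entry.fraction_strains:.2f}")

print(screen.round_half_away(screen.percent_improvement(20.9, 11.5)), "% improvement")
kpi = bioprocess.compute_kpis(29.1, 40.0, 90.0, 11.3)
print(f"{kpi.titer_g_l:.1f} g/L, {kpi.yield_cmol:.2f} C-mol/C-mol")
```

prints (seed 1):

```
TOY0007 17 0.42
TOY0015 14 0.35
TOY0026 14 0.35
82 % improvement
4.5 g/L, 0.13 C-mol/C-mol
```

The planted gene TOY0007 tops the ranking at 17/40 strains. The genes behind
it are pure mutational background — on a 50 kb toy chromosome a 60-mutation
load hits every gene often, so the 10% threshold alone cannot separate signal
from noise; the calibration suite therefore uses a 2 Mb genome where the
background per-gene rate (~2%) sits far below the threshold, as on a real
chromosome. A 20.9 mM titer against an 11.5 mM control is an 82% improvement,
and a 29.1 mM batch end point from 40 g L⁻¹ glucose corresponds to 4.5 g L⁻¹
and a 0.13 C-mol C-mol⁻¹ yield.

The same flows are scriptable from the shell:

```bash
evohotspot simulate campaign --out fixtures/ --seed 3
evohotspot annotate --ref fixtures/toy_genome_3.fa --gff fixtures/toy_genome_3.gff \
                    --vcf-dir fixtures/vcfs --out mutations.tsv
evohotspot hotspots --table mutations.tsv --ref fixtures/toy_genome_3.fa \
                    --gff fixtures/toy_genome_3.gff --out hotspots.tsv
```

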