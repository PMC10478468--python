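import numpy as np
import pytest
from Bio.Seq import Seq

from evohotspot import annotate as ann
from evohotspot import synthetic_data as synth
from evohotspot.genome_io import DepthProfile, GeneFeature, ReferenceGenome, VariantRecord


def snp(pos, ref, alt, strain="s1", freq=0.9):
    return VariantRecord(strain_id=strain, position=pos, ref_allele=ref,
                         alt_allele=alt, read_frequency=freq)


# ---------------------------------------------------------------------------
# region mapping


class TestMapToFeature:
    def test_position_inside_cds(self, two_gene_genome):
        assert ann.map_to_feature(40, two_gene_genome) == ("CDS", "geneA")
        assert ann.map_to_feature(90, two_gene_genome) == ("CDS", "geneB")

    def test_promoter_window_upstream_of_plus_strand(self, two_gene_genome):
        # geneA starts at 30 ('+'); 10 bp upstream is promoter
        assert ann.map_to_feature(20, two_gene_genome) == ("promoter", "geneA")

    def test_promoter_window_upstream_of_minus_strand(self, two_gene_genome):
        # geneB ends at 107 ('-' strand start); downstream-in-forward is its promoter
        assert ann.map_to_feature(110, two_gene_genome) == ("promoter", "geneB")

    def test_window_boundary_arithmetic_on_both_strands(self):
        # brute-force oracle over every position of a small two-strand genome
        genome = synth.make_toy_genome(6000, 4, seed=3, topology="linear")
        window = 200
        cds_ranges = [(f.start, f.end, f) for f in genome.features]
        for pos in range(0, genome.length, 7):
            region, tag = ann.map_to_feature(pos, genome, window)
            in_cds = [f for s, e, f in cds_ranges if s <= pos < e]
            if in_cds:
                assert region == "CDS" and tag == in_cds[0].locus_tag
                continue
            expected = []
            for f in genome.features:
                if f.strand == "+" and f.start - window <= pos < f.start:
                    expected.append((f.start - pos, f.locus_tag))
                if f.strand == "-" and f.end <= pos < f.end + window:
                    expected.append((pos - f.end + 1, f.locus_tag))
            if expected:
                assert region == "promoter" and tag == min(expected)[1]
            else:
                assert (region, tag) == ("intergenic", None)

    def test_position_just_outside_window_is_intergenic(self):
        seq = "A" * 500 + "ATG" + "AAA" * 8 + "TAA" + "A" * 170
        genome = ReferenceGenome(
            id="g", sequence=seq, topology="linear",
            features=[GeneFeature("only", 500, 530, "+")],
        )
        assert ann.map_to_feature(500 - 200, genome)[0] == "promoter"
        assert ann.map_to_feature(500 - 201, genome) == ("intergenic", None)

    def test_out_of_range_position(self, two_gene_genome):
        with pytest.raises(IndexError):
            ann.map_to_feature(500, two_gene_genome)

    def test_circular_wraparound_promoter(self):
        # '+' CDS at the very start of a circular genome: its promoter wraps
        seq = "ATG" + "AAA" * 8 + "TAA" + "C" * 970
        genome = ReferenceGenome(
            id="circ", sequence=seq, topology="circular",
            features=[GeneFeature("wrap", 0, 30, "+")],
        )
        assert ann.map_to_feature(len(seq) - 5, genome) == ("promoter", "wrap")


# ---------------------------------------------------------------------------
# coding effect


class TestCodingEffect:
    def test_nonsynonymous_substitution_named_like_d_to_g(self, two_gene_genome):
        # geneA codon 3 is GAC (Asp); GAC->GGC gives D3G
        pos = 30 + 7  # second base of codon 3
        m = ann.classify_coding_effect(snp(pos, "A", "G"), two_gene_genome)
        assert m.effect == "nonsynonymous"
        assert m.protein_change == "D3G"
        assert m.codon_index == 3

    def test_synonymous_leucine(self, two_gene_genome):
        # geneA codon 4 is CTG (Leu); CTG->CTA stays Leu
        pos = 30 + 11
        m = ann.classify_coding_effect(snp(pos, "G", "A"), two_gene_genome)
        assert m.effect == "synonymous"
        assert m.protein_change == "L4L"

    def test_nonsense_tryptophan_to_stop(self, two_gene_genome):
        # geneA codon 5 is TGG (Trp); TGG->TGA introduces a stop
        pos = 30 + 14
        m = ann.classify_coding_effect(snp(pos, "G", "A"), two_gene_genome)
        assert m.effect == "nonsense"
        assert m.protein_change == "W5*"

    def test_minus_strand_alleles_are_complemented(self, two_gene_genome):
        # geneB has the same coding sequence as geneA; its codon-3 GAC sits
        # reverse-complemented on the forward strand.  GAC->AAC (D->N) means
        # a forward-strand C->T at the complementary position.
        feature = two_gene_genome.get_feature("geneB")
        offset = 6  # first base of codon 3 on the coding strand
        pos = feature.start + (feature.length - 1 - offset)
        m = ann.classify_coding_effect(snp(pos, "C", "T"), two_gene_genome)
        assert m.effect == "nonsynonymous"
        assert m.protein_change == "D3N"

    def test_reference_mismatch_raises(self, two_gene_genome):
        actual = two_gene_genome.sequence[40]
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            ann.classify_coding_effect(snp(40, wrong, "G"), two_gene_genome)

    def test_variant_outside_cds_raises(self, two_gene_genome):
        with pytest.raises(ValueError, match="not inside any CDS"):
            ann.classify_coding_effect(snp(5, two_gene_genome.sequence[5], "A"), two_gene_genome)

    def test_small_indel_classified_without_frameshift_typing(self, two_gene_genome):
        v = VariantRecord("s1", 40, two_gene_genome.sequence[40],
                          two_gene_genome.sequence[40] + "AT", 0.8)
        m = ann.classify_coding_effect(v, two_gene_genome)
        assert m.effect == "small_indel"
        assert m.spectrum_class is None


def retranslation_oracle(genome, feature, variant):
    """Independent effect call: mutate the whole genome, re-extract and
    retranslate the CDS, diff the protein sequences."""
    mutated = genome.sequence[: variant.position] + variant.alt_allele + genome.sequence[variant.position + 1 :]
    mut_genome = ReferenceGenome(id="mut", sequence=mutated, topology=genome.topology,
                                 features=list(genome.features))
    before = str(Seq(genome.feature_sequence(feature)).translate(table=11))
    after = str(Seq(mut_genome.feature_sequence(feature)).translate(table=11))
    diffs = [(i, a, b) for i, (a, b) in enumerate(zip(before, after), start=1) if a != b]
    if not diffs:
        return "synonymous", None
    (idx, a, b) = diffs[0]
    effect = "nonsense" if b == "*" else "nonsynonymous"
    return effect, f"{a}{idx}{b}"


class TestOracleEquivalence:
    def test_random_snps_match_whole_cds_retranslation(self):
        """Codon-wise classification agrees with full retranslation diffing."""
        rng = np.random.default_rng(42)
        genome = synth.make_toy_genome(20_000, 15, seed=8)
        n_checked = 0
        while n_checked < 300:
            feature = genome.features[rng.integers(len(genome.features))]
            pos = int(rng.integers(feature.start, feature.end)) % genome.length
            ref = genome.base(pos)
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            variant = snp(pos, ref, alt)
            m = ann.classify_coding_effect(variant, genome)
            effect, change = retranslation_oracle(genome, feature, variant)
            assert m.effect == effect, (pos, ref, alt)
            if effect != "synonymous":
                assert m.protein_change == change
            n_checked += 1


def reverse_complement_genome(genome):
    from evohotspot.genome_io import reverse_complement

    L = genome.length
    features = [
        GeneFeature(
            locus_tag=f.locus_tag,
            start=L - f.end,
            end=L - f.start,
            strand="-" if f.strand == "+" else "+",
            kind=f.kind,
        )
        for f in genome.features
    ]
    return ReferenceGenome(id=genome.id + "_rc", sequence=reverse_complement(genome.sequence),
                           topology=genome.topology, features=features)


class TestStrandInvariance:
    def test_effects_unchanged_under_reverse_complement(self):
        """Reverse-complementing the genome (and remapping coordinates)
        must leave every effect class and protein change unchanged."""
        rng = np.random.default_rng(7)
        genome = synth.make_toy_genome(12_000, 8, seed=9, topology="linear")
        rc = reverse_complement_genome(genome)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(150):
            feature = genome.features[rng.integers(len(genome.features))]
            pos = int(rng.integers(feature.start, feature.end))
            ref = genome.base(pos)
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            fwd = ann.classify_coding_effect(snp(pos, ref, alt), genome)
            rc_pos = genome.length - 1 - pos
            rev = ann.classify_coding_effect(snp(rc_pos, comp[ref], comp[alt]), rc)
            assert fwd.effect == rev.effect
            assert fwd.protein_change == rev.protein_change
            assert fwd.spectrum_class == rev.spectrum_class


# ---------------------------------------------------------------------------
# spectrum


class TestSpectrum:
    @pytest.mark.parametrize(
        "ref,alt,expected_class,expected_titv",
        [
            ("G", "A", "G:C→A:T", "transition"),
            ("C", "T", "G:C→A:T", "transition"),  # strand symmetry
            ("A", "G", "A:T→G:C", "transition"),
            ("G", "T", "G:C→T:A", "transversion"),
            ("C", "G", "G:C→C:G", "transversion"),
            ("A", "T", "A:T→T:A", "transversion"),
            ("T", "G", "A:T→C:G", "transversion"),
        ],
    )
    def test_class_and_titv(self, ref, alt, expected_class, expected_titv):
        assert ann.classify_spectrum(ref, alt) == (expected_class, expected_titv)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            ann.classify_spectrum("N", "A")

    def test_class_counts_conserve_snp_total(self, toy_genome, small_cohort):
        cohort, _ = small_cohort
        annotated = []
        for recs in cohort.values():
            annotated.extend(ann.annotate_variants(recs, toy_genome))
        n_snps = sum(1 for a in annotated if a.is_snp)
        summary = ann.spectrum_summary(annotated)
        assert summary["count"].sum() == n_snps
        ti = sum(1 for a in annotated if a.ti_tv == "transition")
        tv = sum(1 for a in annotated if a.ti_tv == "transversion")
        assert ti + tv == n_snps


# ---------------------------------------------------------------------------
# filtering and load


class TestFilter:
    def _mut(self, freq, effect="nonsynonymous"):
        return ann.AnnotatedMutation(
            strain_id="s", position=1, ref_allele="G", alt_allele="A",
            read_frequency=freq, region="CDS", locus_tag="x", effect=effect,
            protein_change="D1N" if effect in ("nonsynonymous", "nonsense", "synonymous") else None,
            spectrum_class="G:C→A:T", ti_tv="transition",
        )

    def test_frequency_boundary_inclusive_at_half(self):
        kept = ann.filter_variants([self._mut(0.49), self._mut(0.50)])
        assert [m.read_frequency for m in kept] == [0.50]

    def test_synonymous_dropped_under_defaults(self):
        kept = ann.filter_variants([self._mut(0.9, "synonymous"), self._mut(0.9)])
        assert len(kept) == 1 and kept[0].effect == "nonsynonymous"
        kept_all = ann.filter_variants(
            [self._mut(0.9, "synonymous")], drop_synonymous=False
        )
        assert len(kept_all) == 1

    def test_empty_input_and_idempotence(self, toy_genome, small_cohort):
        assert ann.filter_variants([]) == []
        cohort, _ = small_cohort
        annotated = []
        for recs in cohort.values():
            annotated.extend(ann.annotate_variants(recs, toy_genome))
        once = ann.filter_variants(annotated)
        assert ann.filter_variants(once) == once


class TestMutationLoad:
    def test_counts_and_summary(self):
        counts, summary = ann.mutation_load({"a": [1, 2], "b": [1, 2, 3, 4]})
        assert counts["a"] == 2 and counts["b"] == 4
        assert summary == {"n_strains": 2, "mean": 3.0, "min": 2, "max": 4}

    def test_empty_cohort(self):
        counts, summary = ann.mutation_load({})
        assert len(counts) == 0
        assert summary["n_strains"] == 0 and summary["mean"] is None

    def test_generator_cohort_mean_near_target(self):
        genome = synth.make_toy_genome(50_000, 10, seed=2)
        cfg = synth.MutagenesisConfig(n_strains=100, mean_load=180, load_range=(47, 470), seed=12)
        cohort, _ = synth.simulate_mutagenesis(genome, cfg)
        _, summary = ann.mutation_load(cohort)
        assert summary["mean"] == pytest.approx(180, rel=0.10)
        assert summary["min"] >= 47 and summary["max"] <= 470


# ---------------------------------------------------------------------------
# coverage anomalies


class TestCoverageAnomalies:
    def test_zeroed_kilobase_is_a_deletion_call(self):
        depth = np.full(10_000, 100)
        depth[4000:5000] = 0
        calls = ann.detect_coverage_anomalies(DepthProfile("s1", depth))
        assert len(calls) == 1
        c = calls[0]
        assert (c.kind, c.start, c.end) == ("putative_deletion", 4000, 5000)
        assert c.mean_fold == pytest.approx(0.0)

    def test_doubled_kilobase_is_a_duplication_call(self):
        depth = np.full(10_000, 100)
        depth[2000:3000] = 200
        calls = ann.detect_coverage_anomalies(DepthProfile("s1", depth))
        # run-length oracle: exactly the planted window, fold 2.0
        assert [(c.kind, c.start, c.end) for c in calls] == [
            ("putative_duplication", 2000, 3000)
        ]
        assert calls[0].mean_fold == pytest.approx(2.0)

    def test_uniform_depth_yields_no_calls(self):
        assert ann.detect_coverage_anomalies(DepthProfile("s1", np.full(5000, 80))) == []

    def test_short_dip_below_min_window_ignored(self):
        depth = np.full(5000, 100)
        depth[100:400] = 0  # 300 bp < default 500 bp window
        assert ann.detect_coverage_anomalies(DepthProfile("s1", depth)) == []

    def test_all_zero_profile_signals_missing_data(self):
        with pytest.raises(ValueError):
            ann.detect_coverage_anomalies(DepthProfile("s1", np.zeros(1000, dtype=int)))
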