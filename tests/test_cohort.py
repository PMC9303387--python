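"""Strand-bias assignment/testing, DBS calling, correlation, screening."""

import numpy as np
import pytest
import scipy.stats as st

from trims.catalog import GenomeIndex, SNVRecord, revcomp
from trims.cohort import (
    GeneInterval,
    assign_transcription_strand,
    call_dbs,
    correlate_loads,
    read_bed6,
    screen_cohort,
    strand_bias_test,
)
from trims.enrichment import MotifSpec

import oracles
from conftest import make_catalog, random_genome, random_snvs


# --------------------------------------------- transcription strand labels

@pytest.fixture
def genic_genome():
    # one + gene covering 10..40 (0-based half-open) on a 60 bp chromosome
    return GenomeIndex({"c1": "ATGCATGCAT" "GCATGCATGCATGCATGCATGCATGCATGC"
                              "ATGCATGCATGCATGCATGC"})


def test_purine_on_coding_strand_is_nontranscribed(genic_genome):
    genes = [GeneInterval("c1", 10, 40, "+", "g1")]
    # G>T on top inside a + gene: damaged G on the coding strand
    snv = SNVRecord("c1", 15, "G", "T")
    assert genic_genome.base("c1", 15) == "G"
    assert assign_transcription_strand(snv, genes, genic_genome) == "non-transcribed"


def test_pyrimidine_on_coding_strand_is_transcribed(genic_genome):
    genes = [GeneInterval("c1", 10, 40, "+", "g1")]
    snv = SNVRecord("c1", 16, "C", "A")   # damaged G on the template strand
    assert genic_genome.base("c1", 16) == "C"
    assert assign_transcription_strand(snv, genes, genic_genome) == "transcribed"


def test_minus_gene_mirrors_labels(genic_genome):
    genes = [GeneInterval("c1", 10, 40, "-", "g1")]
    assert assign_transcription_strand(
        SNVRecord("c1", 15, "G", "T"), genes, genic_genome) == "transcribed"
    assert assign_transcription_strand(
        SNVRecord("c1", 16, "C", "A"), genes, genic_genome) == "non-transcribed"


def test_intergenic_and_conflicting_overlaps_excluded(genic_genome):
    genes = [GeneInterval("c1", 10, 40, "+", "a"),
             GeneInterval("c1", 30, 50, "-", "b")]
    # outside all genes
    assert assign_transcription_strand(
        SNVRecord("c1", 3, "G", "T"), genes, genic_genome) == "excluded"
    # inside both a (+) and b (-)
    assert assign_transcription_strand(
        SNVRecord("c1", 35, "G", "T"), genes, genic_genome) == "excluded"


def test_strand_labels_under_genome_complementation(rng):
    """Complementing the genome (and records) while keeping gene strands
    swaps transcribed/non-transcribed; additionally flipping the gene
    strands relabels the same physical molecule, so labels are preserved."""
    genome = random_genome(rng, n_chrom=1, length=2000)
    seq = genome.sequences["c1"]
    genes = [GeneInterval("c1", 200, 900, "+", "a"),
             GeneInterval("c1", 1200, 1800, "-", "b")]
    cat = random_snvs(rng, genome, 80, classes=("CA", "GT"))

    comp_genome = GenomeIndex({"c1": "".join(revcomp(b) for b in seq)})
    flipped_genes = [GeneInterval(g.chrom, g.start, g.end,
                                  "-" if g.strand == "+" else "+", g.name)
                     for g in genes]
    swap = {"transcribed": "non-transcribed",
            "non-transcribed": "transcribed", "excluded": "excluded"}
    for r in cat:
        lab1 = assign_transcription_strand(r, genes, genome)
        comp_r = SNVRecord(r.chrom, r.pos, revcomp(r.ref), revcomp(r.alt))
        assert assign_transcription_strand(comp_r, genes, comp_genome) \
            == swap[lab1]
        assert assign_transcription_strand(comp_r, flipped_genes, comp_genome) \
            == lab1


def test_read_bed6_roundtrip(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("c1\t10\t40\tg1\t0\t+\nc2\t5\t25\tg2\t0\t-\n")
    genes = read_bed6(p)
    assert genes[0] == GeneInterval("c1", 10, 40, "+", "g1")
    assert genes[1].strand == "-"


# ------------------------------------------------------ strand-bias test

def test_balanced_counts_no_bias():
    r = strand_bias_test(50, 50)
    assert r.p_value == pytest.approx(1.0)
    assert r.ratio == pytest.approx(1.0)


def test_chisquare_path_matches_reference_tail():
    r = strand_bias_test(10, 90)
    assert r.test == "chi-square"
    assert r.p_value == pytest.approx(float(st.chi2.sf(64, 1)), rel=1e-12)


def test_small_counts_use_exact_binomial():
    r = strand_bias_test(0, 3)
    assert r.test == "binomial"
    assert r.p_value == pytest.approx(0.25)    # 2 * (1/2)^3
    assert r.p_value == pytest.approx(oracles.binom_two_sided(3, 3))


def test_chisquare_and_binomial_agree_with_exact_binomial():
    # the plain chi-square approximation approaches the exact two-sided
    # binomial p: closely in absolute terms at moderate counts, within 10%
    # relative at large counts
    for nt, nn in [(40, 60), (45, 75), (70, 50), (100, 130)]:
        chi = strand_bias_test(nt, nn)
        exact = oracles.binom_two_sided(nn, nt + nn)
        assert chi.p_value == pytest.approx(exact, abs=0.02)
    for nt, nn in [(450, 550), (950, 1050), (400, 480)]:
        chi = strand_bias_test(nt, nn)
        exact = float(st.binomtest(nn, nt + nn, 0.5).pvalue)
        assert chi.p_value == pytest.approx(exact, rel=0.10)


def test_zero_total_flagged_undefined():
    r = strand_bias_test(0, 0)
    assert r.test == "undefined"
    assert np.isnan(r.p_value)


# ------------------------------------------------------------ DBS calls

def test_adjacent_cc_to_aa_called_once():
    cat = make_catalog([("c1", 100, "C", "A"), ("c1", 101, "C", "A")])
    dbs, used = call_dbs(cat)
    assert len(dbs) == 1
    assert (dbs[0].pos, dbs[0].ref_dinuc, dbs[0].alt_dinuc) == (100, "CC", "AA")
    assert used == {("c1", 100), ("c1", 101)}


def test_gg_to_tt_called_via_reverse_complement():
    cat = make_catalog([("c1", 100, "G", "T"), ("c1", 101, "G", "T")])
    dbs, _ = call_dbs(cat)
    assert len(dbs) == 1
    assert dbs[0].ref_dinuc == "GG"


def test_non_adjacent_and_mismatched_pairs_not_called():
    cat = make_catalog([("c1", 100, "C", "A"), ("c1", 102, "C", "A"),
                        ("c1", 200, "C", "A"), ("c1", 201, "G", "T")])
    dbs, _ = call_dbs(cat)
    assert dbs == []


def test_dbs_count_bounded_by_half_snv_count(rng):
    genome = random_genome(rng, n_chrom=1, length=300)
    for _ in range(10):
        cat = random_snvs(rng, genome, 60, classes=("CA", "GT"))
        dbs, _ = call_dbs(cat)
        assert len(dbs) <= len(cat) // 2


# ---------------------------------------------------------- correlation

def test_collinear_points_give_unit_correlation():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 4.0, 6.0, 8.0, 10.0]
    r = correlate_loads(x, y)
    assert r.pearson_r == pytest.approx(1.0)
    assert r.p_value < 1e-10
    assert r.slope == pytest.approx(2.0)


def test_constant_y_flagged_undefined():
    r = correlate_loads([1, 2, 3, 4], [5, 5, 5, 5])
    assert r.undefined is True


def test_pearson_matches_covariance_oracle():
    x = [1.0, 4.0, 2.5, 7.0, 3.3]
    y = [2.1, 3.9, 2.2, 8.8, 3.0]
    r = correlate_loads(x, y)
    assert r.pearson_r == pytest.approx(oracles.pearson_by_hand(x, y), abs=1e-12)
    # slope CI contains the point estimate and is finite
    lo, hi = r.ci95
    assert lo < r.slope < hi


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        correlate_loads([1, 2], [3, 4])


# ------------------------------------------------------------ screening

def test_null_cohort_rarely_flagged(rng):
    """Samples drawn uniformly over C sites carry no motif excess: with
    Bonferroni screening at alpha 0.05 essentially none should be flagged."""
    genome = random_genome(rng, n_chrom=2, length=3000)
    cohort = [random_snvs(rng, genome, 40, f"s{i}", classes=("CA", "GT"))
              for i in range(25)]
    out = screen_cohort(cohort, genome, MotifSpec.parse("gCn>A"))
    assert out["n_total"] == 25
    assert out["n_enriched"] <= 2
    assert np.isnan(out["mean_load_enriched"]) or out["n_enriched"] > 0


def test_single_sample_below_threshold_summary(rng):
    genome = random_genome(rng, n_chrom=1, length=2000)
    cohort = [random_snvs(rng, genome, 20, classes=("CT",))]  # wrong class
    out = screen_cohort(cohort, genome, MotifSpec.parse("gCn>A"))
    assert (out["n_enriched"], out["n_total"]) == (0, 1)
    assert np.isnan(out["mean_load_enriched"])
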