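"""Catalog I/O: FASTA/VCF reading, filtering, normalization."""

import textwrap

import pytest

from trims.catalog import (
    CatalogError,
    GenomeIndex,
    SNVRecord,
    dedupe_recurrent,
    iter_normalized,
    normalize_pyrimidine,
    read_genome,
    read_snvs,
    revcomp,
    subtract_normal,
)

from conftest import make_catalog, random_genome, random_snvs


# ------------------------------------------------------------- read_genome

def test_read_genome_roundtrip_and_case(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c1\nACGT\n>c2\nacgtN\n")
    g = read_genome(fa)
    assert g.lengths == {"c1": 4, "c2": 5}
    assert g.sequences["c2"] == "ACGTN"  # upper-cased, N preserved


def test_read_genome_duplicate_name_rejected(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c1\nACGT\n>c1\nTTTT\n")
    with pytest.raises(CatalogError, match="duplicate"):
        read_genome(fa)


# --------------------------------------------------------------- read_snvs

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=c1,length=1000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">
    ##FORMAT=<ID=AF,Number=1,Type=Float,Description="VAF">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tiso1
    """)


def write_vcf(tmp_path, body):
    p = tmp_path / "in.vcf"
    p.write_text(VCF_HEADER + body)
    return p


def test_vaf_filter_retains_and_drops(tmp_path):
    body = ("c1\t10\t.\tC\tA\t.\tPASS\t.\tGT:AF\t1/1:0.95\n"
            "c1\t20\t.\tC\tA\t.\tPASS\t.\tGT:AF\t1/1:0.50\n"
            "c1\t30\t.\tC\tA\t.\tPASS\t.\tGT:AF\t1/1:0.90\n")
    cat = read_snvs(write_vcf(tmp_path, body), min_vaf=0.9)
    assert [r.pos for r in cat] == [10, 30]  # threshold is inclusive
    assert cat.meta["dropped"]["below_vaf"] == 1


def test_non_snv_records_skipped_and_tallied(tmp_path):
    body = ("c1\t10\t.\tC\tA\t.\tPASS\t.\tGT:AF\t1/1:1.0\n"
            "c1\t20\t.\tCT\tC\t.\tPASS\t.\tGT:AF\t1/1:1.0\n"       # indel
            "c1\t30\t.\tC\tA,G\t.\tPASS\t.\tGT:AF\t1/1:1.0\n")     # multi-allelic
    cat = read_snvs(write_vcf(tmp_path, body), min_vaf=0.0)
    assert len(cat) == 1
    d = cat.meta["dropped"]
    # conservation: kept + dropped = VCF data lines
    assert len(cat) + sum(d.values()) == 3


def test_empty_vcf_gives_empty_catalog(tmp_path):
    cat = read_snvs(write_vcf(tmp_path, ""), min_vaf=0.9)
    assert len(cat) == 0


def test_missing_vaf_with_filter_fails_loudly(tmp_path):
    body = "c1\t10\t.\tC\tA\t.\tPASS\t.\tGT\t1/1\n"
    with pytest.raises(CatalogError, match="no 'AF'"):
        read_snvs(write_vcf(tmp_path, body), min_vaf=0.9)


# -------------------------------------------- subtraction and de-duplication

def test_subtract_normal_matches_on_full_variant_identity():
    treated = make_catalog([("c1", 5, "C", "T"), ("c1", 9, "C", "A")])
    normal = make_catalog([("c1", 5, "C", "G"), ("c1", 9, "C", "A")], "parent")
    out = subtract_normal(treated, normal)
    # same position, different alt survives; exact (chrom,pos,alt) removed
    assert [(r.pos, r.alt) for r in out] == [(5, "T")]
    assert out.meta["normal_subtracted"] == 1


def test_dedupe_recurrent_removes_shared_variants_everywhere():
    cats = [make_catalog([("c1", 5, "C", "A")], f"s{i}") for i in range(3)]
    cats.append(make_catalog([("c1", 7, "C", "A")], "s3"))
    out = dedupe_recurrent(cats, min_share=2)
    assert all(("c1", 5, "A") not in {r.key for r in c} for c in out)
    assert len(out[3]) == 1  # private variant retained


def test_dedupe_min_share_must_be_at_least_two():
    with pytest.raises(CatalogError):
        dedupe_recurrent([make_catalog([("c1", 5, "C", "A")])], min_share=1)


def test_subtract_then_dedupe_order_stable(rng):
    genome = random_genome(rng)
    normal = random_snvs(rng, genome, 15, "parent")
    cats = [random_snvs(rng, genome, 40, f"s{i}") for i in range(4)]
    a = dedupe_recurrent([subtract_normal(c, normal) for c in cats])
    b = [subtract_normal(c, normal) for c in dedupe_recurrent(cats)]
    for x, y in zip(a, b):
        assert [r.key for r in x] == [r.key for r in y]


# ---------------------------------------------------------- normalization

@pytest.mark.parametrize("ctx, ref, alt, expected", [
    ("AGC", "G", "T", ("G", "C", "T", "A")),   # purine: revcomp -> gCt, C>A
    ("GCA", "C", "A", ("G", "C", "A", "A")),   # pyrimidine: unchanged
    ("TTA", "T", "G", ("T", "T", "A", "G")),
])
def test_normalize_pyrimidine_channels(ctx, ref, alt, expected):
    g = GenomeIndex({"c1": "A" + ctx + "A"})
    n = normalize_pyrimidine(SNVRecord("c1", 3, ref, alt), g)
    assert (n.five_prime, n.channel_ref, n.three_prime, n.channel_alt) == expected
    assert n.pyr_strand == ("+" if ref in "CT" else "-")


def test_normalize_rejects_reference_mismatch():
    g = GenomeIndex({"c1": "ATTTA"})
    with pytest.raises(CatalogError, match="mismatch"):
        normalize_pyrimidine(SNVRecord("c1", 3, "C", "A"), g)


def test_terminus_records_excluded_and_tallied():
    g = GenomeIndex({"c1": "CATTC"})
    cat = make_catalog([("c1", 1, "C", "A"), ("c1", 3, "T", "G"),
                        ("c1", 5, "C", "A")])
    normalized, excluded = iter_normalized(cat, g)
    assert len(normalized) == 1
    assert excluded["terminus"] == 2


def test_normalization_involution_under_reverse_complement(rng):
    """Normalizing an SNV and normalizing its mirror on the reverse-
    complemented genome give identical channels."""
    genome = random_genome(rng, n_chrom=1, length=500)
    cat = random_snvs(rng, genome, 60)
    seq = genome.sequences["c1"]
    flipped = GenomeIndex({"c1": revcomp(seq)})
    for r in cat:
        n1 = normalize_pyrimidine(r, genome)
        mirror = SNVRecord("c1", len(seq) - r.pos + 1,
                           revcomp(r.ref), revcomp(r.alt), r.sample_id)
        n2 = normalize_pyrimidine(mirror, flipped)
        assert (n1.five_prime, n1.channel_ref, n1.three_prime, n1.channel_alt) \
            == (n2.five_prime, n2.channel_ref, n2.three_prime, n2.channel_alt)


def test_catalog_rejects_same_position_twice():
    with pytest.raises(CatalogError, match="duplicate"):
        make_catalog([("c1", 5, "C", "A"), ("c1", 5, "C", "T")])


# ------------------------------------------------------- property-based

from hypothesis import given, settings, strategies as stn

_dna = stn.text(alphabet="ACGT", min_size=5, max_size=60)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(seq=_dna, data=stn.data())
def test_normalization_properties(seq, data):
    """For any interior SNV: the channel is pyrimidine-centered, agrees
    with the genome context, and is invariant under reverse-complement
    mirroring of genome and record."""
    genome = GenomeIndex({"c1": seq})
    pos = data.draw(stn.integers(2, len(seq) - 1), label="pos")
    ref = seq[pos - 1]
    alt = data.draw(stn.sampled_from([b for b in "ACGT" if b != ref]),
                    label="alt")
    n = normalize_pyrimidine(SNVRecord("c1", pos, ref, alt), genome)
    assert n.channel_ref in "CT"
    assert n.channel_alt != n.channel_ref
    # flanks come from the genome context in the right orientation
    if ref in "CT":
        assert (n.five_prime, n.three_prime) == (seq[pos - 2], seq[pos])
    else:
        assert (n.five_prime, n.three_prime) == (revcomp(seq[pos]),
                                                 revcomp(seq[pos - 2]))
    # involution under reverse-complement mirroring
    mirror = SNVRecord("c1", len(seq) - pos + 1, revcomp(ref), revcomp(alt))
    m = normalize_pyrimidine(mirror, GenomeIndex({"c1": revcomp(seq)}))
    assert (m.five_prime, m.channel_ref, m.three_prime, m.channel_alt) \
        == (n.five_prime, n.channel_ref, n.three_prime, n.channel_alt)
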