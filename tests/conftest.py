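import numpy as np
import pytest

from trims.catalog import GenomeIndex, MutationCatalog, SNVRecord


@pytest.fixture
def toy_genome():
    #          123456789...
    return GenomeIndex({
        "c1": "AAGCAGCATTGCAGGCTTAA",
        "c2": "TTGCGCATAGCATGCATGCC",
    })


def make_catalog(records, sample_id="s1"):
    return MutationCatalog(
        sample_id, [SNVRecord(c, p, r, a, sample_id) for c, p, r, a in records]
    )


def random_genome(rng, n_chrom=2, length=2000, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return GenomeIndex({
        f"c{i+1}": "".join(bases[rng.choice(4, size=length, p=p)])
        for i in range(n_chrom)
    })


def random_snvs(rng, genome, n, sample_id="s1", classes=("CA", "GT", "CT", "GA")):
    """Random interior SNVs whose ref matches the genome."""
    recs = {}
    chroms = list(genome.sequences)
    tries = 0
    while len(recs) < n and tries < 50 * n:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = genome.sequences[chrom]
        pos0 = int(rng.integers(1, len(seq) - 1))
        ref = seq[pos0]
        alts = [c[1] for c in classes if c[0] == ref]
        if not alts or (chrom, pos0) in recs:
            continue
        alt = alts[int(rng.integers(len(alts)))]
        recs[(chrom, pos0)] = SNVRecord(chrom, pos0 + 1, ref, alt, sample_id)
    return MutationCatalog(sample_id, list(recs.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
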