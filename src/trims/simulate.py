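"""Synthetic genomes, gene annotations, and mutation catalogs with planted
signature structure.

The generator emulates the statistical structure of a telomere-uncapping
ssDNA mutagenesis experiment: multi-chromosome genomes of defined GC
content; per-isolate catalogs of single-base substitutions with a planted
fraction at 5'-flanked motif sites (``motif_fraction``), a planted fraction
near chromosome ends (``subtelomeric_fraction``), arm-dependent strand
asymmetry matching 5'→3' resection geometry (``resected_strand_fraction``),
optional transcriptional strand bias inside simulated genes
(``nontranscribed_fraction``), and adjacent CC→AA doublets (``dbs_rate``).
Every draw flows from one integer seed; identical (config, seed) pairs
produce byte-identical FASTA/VCF/BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import (
    COMPLEMENT,
    IUPAC,
    GenomeIndex,
    MutationCatalog,
    SNVRecord,
)
from .cohort import GeneInterval
from .enrichment import MotifSpec
from .spectrum import DEFAULT_SUBTELOMERE_BP


class SimulationError(ValueError):
    """Raised when a configuration cannot be realized on the genome."""


@dataclass
class SimConfig:
    """Planted-simulation parameters.

    Defaults describe the reporter-assay conditions this package models:
    a yeast-like GC content of 0.38, ~17 substitutions per isolate over 30
    isolates, 90% of mutations within 30 kb of a chromosome end, 90% with
    the purine lesion on the arm's resected strand, a planted 5'-gC motif
    fraction of 0.8, and essentially no double-base substitutions (the
    reporter data showed too few doublets to analyze; set ``dbs_rate`` > 0
    to emulate doublet-bearing cohorts).  Chromosome count and length are
    scaled down from a real yeast genome to keep simulation fast.
    """

    n_chromosomes: int = 8
    chromosome_length: int = 200_000
    gc_content: float = 0.38
    n_isolates: int = 30
    mutations_per_isolate: float = 17.0
    substitution: tuple[str, str] = ("C", "A")
    motif_fraction: float = 0.8
    subtelomeric_fraction: float = 0.9
    resected_strand_fraction: float = 0.9
    dbs_rate: float = 0.0
    n_genes: int = 30
    gene_length: int = 1500
    nontranscribed_fraction: float | None = None
    subtelomere_threshold: int = DEFAULT_SUBTELOMERE_BP
    motif: str = "gCn>A"
    seed: int = 0

    def __post_init__(self):
        for name in ("motif_fraction", "subtelomeric_fraction",
                     "resected_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.gc_content < 1.0:
            raise SimulationError(f"gc_content must be in (0,1), got {self.gc_content}")
        if self.nontranscribed_fraction is not None and \
                not 0.0 <= self.nontranscribed_fraction <= 1.0:
            raise SimulationError("nontranscribed_fraction must be in [0,1]")
        if self.chromosome_length <= 2 or self.n_chromosomes < 1:
            raise SimulationError("genome dimensions must be positive")
        if self.seed is None:
            raise SimulationError("a seed is mandatory")

    @property
    def motif_spec(self) -> MotifSpec:
        return MotifSpec.parse(self.motif)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, for parameter-recovery tests."""

    motif_fraction: float
    subtelomeric_fraction: float
    resected_strand_fraction: float
    nontranscribed_fraction: float | None
    expected_enrichment: float
    expected_enrichment_asymptotic: float
    planted: dict[str, list[tuple[str, int, str, str]]] = field(default_factory=dict)
    n_dbs: dict[str, int] = field(default_factory=dict)
    n_genic_motif: int = 0
    restrand_failures: int = 0


def simulate_genome(config: SimConfig, seed: int | None = None) -> GenomeIndex:
    """I.i.d. random genome at the configured GC fraction (deterministic)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = config.gc_content
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    bases = np.array(list("ACGT"))
    sequences = {}
    for i in range(config.n_chromosomes):
        draw = rng.choice(4, size=config.chromosome_length, p=p)
        sequences[f"chr{i + 1}"] = "".join(bases[draw])
    return GenomeIndex(sequences)


def _site_arrays(seq: str, motif: MotifSpec):
    """Per-position indicators: base-site (either strand pyrimidine of the
    motif class) and motif-site, plus plus/minus strand masks."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    base = motif.mutated_base.encode()
    comp = COMPLEMENT[motif.mutated_base].encode()
    is_plus = arr == base          # pyrimidine on top strand
    is_minus = arr == comp         # pyrimidine on bottom strand
    five = np.isin(arr, [c.encode() for c in IUPAC[motif.five_prime_pattern]])
    three = np.isin(arr, [c.encode() for c in IUPAC[motif.three_prime_pattern]])
    comp_five = np.isin(arr, [COMPLEMENT[c].encode()
                              for c in IUPAC[motif.five_prime_pattern]])
    comp_three = np.isin(arr, [COMPLEMENT[c].encode()
                               for c in IUPAC[motif.three_prime_pattern]])
    L = len(seq)
    motif_plus = np.zeros(L, bool)
    motif_minus = np.zeros(L, bool)
    if L >= 3:
        motif_plus[1:-1] = is_plus[1:-1] & five[:-2] & three[2:]
        # bottom-strand motif: 5' flank is the next top-strand base,
        # complemented; 3' flank the previous one
        motif_minus[1:-1] = is_minus[1:-1] & comp_five[2:] & comp_three[:-2]
    return is_plus, is_minus, motif_plus, motif_minus


class _SiteIndex:
    """Eligible interior positions stratified by (region, arm, pyr-strand,
    motif-ness) for one genome and motif."""

    def __init__(self, genome: GenomeIndex, motif: MotifSpec, threshold: int):
        self.strata: dict[tuple[str, str, str, bool], list[tuple[str, np.ndarray]]] = {}
        self.masks: dict[str, dict] = {}
        for chrom, seq in genome.sequences.items():
            L = len(seq)
            is_plus, is_minus, motif_plus, motif_minus = _site_arrays(seq, motif)
            idx = np.arange(L)
            interior = (idx >= 1) & (idx <= L - 2)
            dist = np.minimum(idx, L - 1 - idx)
            sub = dist <= threshold
            left = idx <= (L - 1 - idx)
            self.masks[chrom] = {
                "plus_motif": motif_plus, "minus_motif": motif_minus,
                "plus_non": is_plus & ~motif_plus & interior,
                "minus_non": is_minus & ~motif_minus & interior,
                "base": is_plus | is_minus,
                "motif": motif_plus | motif_minus,
                "sub": sub, "left": left, "interior": interior,
            }
            for region, rmask in (("sub", sub), ("mid", ~sub)):
                for arm, amask in (("left", left), ("right", ~left)):
                    for strand, smask_m, smask_n in (
                            ("+", motif_plus, is_plus & ~motif_plus),
                            ("-", motif_minus, is_minus & ~motif_minus)):
                        base_mask = rmask & amask & interior
                        for is_motif, smask in ((True, smask_m), (False, smask_n)):
                            key = (region, arm, strand, is_motif)
                            pos = idx[base_mask & smask]
                            if len(pos):
                                self.strata.setdefault(key, []).append((chrom, pos))

    def pool(self, region: str, arm: str | None, strand: str, is_motif: bool
             ) -> list[tuple[str, np.ndarray]]:
        if arm is not None:
            return self.strata.get((region, arm, strand, is_motif), [])
        out = []
        for a in ("left", "right"):
            out.extend(self.strata.get((region, a, strand, is_motif), []))
        return out


def _sample_site(pools, rng, used, chrom_len=None, max_tries: int = 2000):
    """Uniform draw over the concatenated pools, avoiding used positions."""
    if not pools:
        raise SimulationError("no eligible sites in the requested class")
    sizes = np.array([len(p) for _, p in pools])
    cum = np.cumsum(sizes)
    total = int(cum[-1])
    for _ in range(max_tries):
        j = int(rng.integers(total))
        k = int(np.searchsorted(cum, j, side="right"))
        chrom, positions = pools[k]
        pos0 = int(positions[j - (int(cum[k - 1]) if k else 0)])
        if (chrom, pos0) not in used:
            return chrom, pos0
    raise SimulationError("eligible site class exhausted (all positions used)")


def simulate_genes(genome: GenomeIndex, config: SimConfig,
                   seed: int | None = None) -> list[GeneInterval]:
    """Place non-overlapping gene intervals with random strands."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    chroms = list(genome.sequences)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneInterval] = []
    glen = config.gene_length
    for i in range(config.n_genes):
        for attempt in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = genome.lengths[chrom]
            if L <= glen:
                continue
            start = int(rng.integers(0, L - glen))
            end = start + glen
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneInterval(chrom, start, end, strand, f"gene{i + 1}"))
                break
        else:
            raise SimulationError(
                f"could not place gene {i + 1} of {config.n_genes} without overlap")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _gene_at(genes_by_chrom, chrom, pos0):
    for g in genes_by_chrom.get(chrom, ()):
        if g.start <= pos0 < g.end:
            return g
    return None


def simulate_catalogs(
    genome: GenomeIndex,
    config: SimConfig,
    seed: int | None = None,
    genes: Sequence[GeneInterval] | None = None,
) -> tuple[list[MutationCatalog], SimTruth]:
    """Generate per-isolate catalogs with the configured planted structure.

    Placement of each substitution: draw region (sub-telomeric vs mid) from
    ``subtelomeric_fraction``; for sub-telomeric draws pick an arm uniformly
    and put the purine lesion on that arm's resected strand with probability
    ``resected_strand_fraction`` (mid-chromosomal strands are uniform); draw
    motif-ness from ``motif_fraction`` and sample uniformly among eligible
    unused sites of that (region, arm, strand, motif) class.  When genes and
    ``nontranscribed_fraction`` (beta) are given, genic motif mutations are
    re-stranded within their gene so a fraction beta carry the purine on the
    coding (non-transcribed) strand.  CC→AA / GG→TT doublets are added at
    ``dbs_rate`` expected doublets per isolate.
    """
    motif = config.motif_spec
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    index = _SiteIndex(genome, motif, config.subtelomere_threshold)
    beta = config.nontranscribed_fraction
    genes_by_chrom: dict[str, list[GeneInterval]] = {}
    gene_sites: dict[str, dict] = {}
    if genes:
        for g in genes:
            genes_by_chrom.setdefault(g.chrom, []).append(g)

    def gene_class_sites(gene: GeneInterval, strand: str, is_motif: bool):
        key = (gene.chrom, gene.start, strand, is_motif)
        if key not in gene_sites:
            m = index.masks[gene.chrom]
            smask = (m["plus_motif"] if (strand, is_motif) == ("+", True) else
                     m["minus_motif"] if (strand, is_motif) == ("-", True) else
                     m["plus_non"] if strand == "+" else m["minus_non"])
            idx = np.arange(gene.start, gene.end)
            gene_sites[key] = idx[smask[gene.start:gene.end]]
        return gene_sites[key]

    alt_plus = motif.alt_base
    alt_minus = COMPLEMENT[motif.alt_base]
    ref_plus = motif.mutated_base
    ref_minus = COMPLEMENT[motif.mutated_base]

    catalogs: list[MutationCatalog] = []
    truth = SimTruth(
        motif_fraction=config.motif_fraction,
        subtelomeric_fraction=config.subtelomeric_fraction,
        resected_strand_fraction=config.resected_strand_fraction,
        nontranscribed_fraction=beta,
        expected_enrichment=planted_enrichment_expectation(genome, config),
        expected_enrichment_asymptotic=expected_enrichment(
            genome, config.motif_fraction, motif),
    )

    for iso in range(config.n_isolates):
        sid = f"isolate{iso + 1:03d}"
        n_mut = int(rng.poisson(config.mutations_per_isolate))
        used: set[tuple[str, int]] = set()
        records: list[SNVRecord] = []
        for _ in range(n_mut):
            sub = rng.random() < config.subtelomeric_fraction
            region = "sub" if sub else "mid"
            if sub:
                arm = "left" if rng.random() < 0.5 else "right"
                consistent = rng.random() < config.resected_strand_fraction
                # resection leaves the bottom strand ssDNA on left arms
                # (pyrimidine partner on top, '+') and vice versa
                strand = ("+" if consistent else "-") if arm == "left" else \
                         ("-" if consistent else "+")
            else:
                arm = None
                strand = "+" if rng.random() < 0.5 else "-"
            is_motif = rng.random() < config.motif_fraction
            chrom, pos0 = _sample_site(index.pool(region, arm, strand, is_motif),
                                       rng, used)
            if genes and beta is not None and is_motif:
                gene = _gene_at(genes_by_chrom, chrom, pos0)
                if gene is not None:
                    truth.n_genic_motif += 1
                    want_nontranscribed = rng.random() < beta
                    # purine strand is opposite the pyrimidine strand
                    purine = "-" if strand == "+" else "+"
                    on_nontranscribed = purine == gene.strand
                    if on_nontranscribed != want_nontranscribed:
                        new_strand = "-" if strand == "+" else "+"
                        cand = [p for p in gene_class_sites(gene, new_strand, True)
                                if (chrom, int(p)) not in used]
                        if cand:
                            pos0 = int(cand[int(rng.integers(len(cand)))])
                            strand = new_strand
                        else:
                            truth.restrand_failures += 1
            used.add((chrom, pos0))
            if strand == "+":
                records.append(SNVRecord(chrom, pos0 + 1, ref_plus, alt_plus, sid, 1.0))
            else:
                records.append(SNVRecord(chrom, pos0 + 1, ref_minus, alt_minus, sid, 1.0))

        n_dbs = int(rng.poisson(config.dbs_rate)) if config.dbs_rate > 0 else 0
        placed_dbs = 0
        if n_dbs:
            cc_sites = _dinuc_sites(genome, "CC")
            gg_sites = _dinuc_sites(genome, "GG")
            for _ in range(n_dbs):
                for _try in range(2000):
                    use_cc = rng.random() < 0.5
                    pool = cc_sites if use_cc else gg_sites
                    chrom, positions = pool[int(rng.integers(len(pool)))]
                    pos0 = int(positions[int(rng.integers(len(positions)))])
                    if (chrom, pos0) in used or (chrom, pos0 + 1) in used \
                            or pos0 < 1 or pos0 + 2 >= genome.lengths[chrom] - 1:
                        continue
                    used.update({(chrom, pos0), (chrom, pos0 + 1)})
                    if use_cc:
                        records.append(SNVRecord(chrom, pos0 + 1, "C", "A", sid, 1.0))
                        records.append(SNVRecord(chrom, pos0 + 2, "C", "A", sid, 1.0))
                    else:
                        records.append(SNVRecord(chrom, pos0 + 1, "G", "T", sid, 1.0))
                        records.append(SNVRecord(chrom, pos0 + 2, "G", "T", sid, 1.0))
                    placed_dbs += 1
                    break
                else:
                    raise SimulationError("could not place CC/GG doublet")
        truth.n_dbs[sid] = placed_dbs
        truth.planted[sid] = [(r.chrom, r.pos, r.ref, r.alt) for r in
                              sorted(records, key=lambda r: (r.chrom, r.pos))]
        catalogs.append(MutationCatalog(sid, records, {"simulated": True}))
    return catalogs, truth


def _dinuc_sites(genome: GenomeIndex, dinuc: str):
    pools = []
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        hits = np.where((arr[:-1] == dinuc[0].encode())
                        & (arr[1:] == dinuc[1].encode()))[0]
        if len(hits):
            pools.append((chrom, hits))
    if not pools:
        raise SimulationError(f"genome contains no {dinuc} dinucleotides")
    return pools


def expected_enrichment(genome: GenomeIndex, motif_fraction: float,
                        motif: MotifSpec) -> float:
    """Asymptotic planted enrichment phi * f_base / f_motif.

    ``f_motif`` and ``f_base`` are genome-wide both-strand frequencies of
    the motif context and the mutated base.  This is the large-window limit
    of the TriMS estimator; see :func:`planted_enrichment_expectation` for
    the finite-window value the estimator actually converges to.
    """
    n_motif = n_base = 0
    for seq in genome.sequences.values():
        is_plus, is_minus, motif_plus, motif_minus = _site_arrays(seq, motif)
        n_base += int(is_plus.sum() + is_minus.sum())
        n_motif += int(motif_plus.sum() + motif_minus.sum())
    if n_motif == 0:
        raise SimulationError("genome contains no motif context sites")
    return motif_fraction * n_base / n_motif


def _window_sums(mask: np.ndarray, halfwidth: int) -> np.ndarray:
    kernel = np.ones(2 * halfwidth + 1)
    return np.convolve(mask.astype(float), kernel, mode="same")


def planted_enrichment_expectation(
    genome: GenomeIndex, config: SimConfig
) -> float:
    """Finite-window expectation of the TriMS estimator under the planting
    scheme.

    The estimator's context windows are centered on mutations and include
    the mutated position, so window composition is not genome-representative
    at (and immediately around) the center: a planted motif mutation
    guarantees a motif site there (and its opposite-strand partner).  This
    oracle averages realized window motif/base counts over the eligible
    sites of every placement stratum — exactly the (region, arm, strand,
    motif-ness) strata and probabilities the placement scheme uses — and
    returns phi * E[c_base] / E[c_motif].
    """
    motif = config.motif_spec
    phi = config.motif_fraction
    h = motif.window_halfwidth
    f_sub = config.subtelomeric_fraction
    r = config.resected_strand_fraction

    # accumulate (sum wb, sum wm, n sites) per (region, arm, strand, motif)
    acc: dict[tuple, tuple[float, float, int]] = {}
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        is_plus, is_minus, motif_plus, motif_minus = _site_arrays(seq, motif)
        wb = _window_sums(is_plus | is_minus, h)
        wm = _window_sums(motif_plus | motif_minus, h)
        idx = np.arange(L)
        interior = (idx >= 1) & (idx <= L - 2)
        sub = np.minimum(idx, L - 1 - idx) <= config.subtelomere_threshold
        left = idx <= (L - 1 - idx)
        for region, rmask in (("sub", sub), ("mid", ~sub)):
            for arm, amask in (("left", left), ("right", ~left)):
                for strand, smask_m, smask_n in (
                        ("+", motif_plus, is_plus & ~motif_plus),
                        ("-", motif_minus, is_minus & ~motif_minus)):
                    for is_motif, smask in ((True, smask_m), (False, smask_n)):
                        mask = rmask & amask & interior & smask
                        key = (region, arm, strand, is_motif)
                        b, m, n = acc.get(key, (0.0, 0.0, 0))
                        acc[key] = (b + float(wb[mask].sum()),
                                    m + float(wm[mask].sum()),
                                    n + int(mask.sum()))

    def pool_mean(region, arms, strand, is_motif):
        b = m = n = 0.0
        for arm in arms:
            pb, pm, pn = acc.get((region, arm, strand, is_motif), (0.0, 0.0, 0))
            b, m, n = b + pb, m + pm, n + pn
        if n == 0:
            raise SimulationError(
                f"no eligible sites in stratum ({region}, {strand}, "
                f"motif={is_motif})")
        return b / n, m / n

    # placement strata with their exact probabilities
    strata: list[tuple[float, tuple]] = []
    for is_motif, p_motif in ((True, phi), (False, 1 - phi)):
        if p_motif == 0:
            continue
        if f_sub > 0:
            for arm in ("left", "right"):
                for consistent, p_cons in ((True, r), (False, 1 - r)):
                    if p_cons == 0:
                        continue
                    strand = ("+" if consistent else "-") if arm == "left" \
                        else ("-" if consistent else "+")
                    strata.append((f_sub * 0.5 * p_cons * p_motif,
                                   ("sub", (arm,), strand, is_motif)))
        if f_sub < 1:
            for strand in "+-":
                strata.append(((1 - f_sub) * 0.5 * p_motif,
                               ("mid", ("left", "right"), strand, is_motif)))

    e_cb = e_cm = 0.0
    for w, key in strata:
        mb, mm_ = pool_mean(*key)
        e_cb += w * mb
        e_cm += w * mm_
    return phi * e_cb / e_cm


def motif_fraction_for_enrichment(
    genome: GenomeIndex, target: float, config: SimConfig
) -> float:
    """Solve for the motif fraction phi whose finite-window planted
    expectation equals ``target``."""
    from scipy.optimize import brentq
    from dataclasses import replace

    def f(phi):
        return planted_enrichment_expectation(
            genome, replace(config, motif_fraction=phi)) - target

    lo, hi = 1e-9, 1 - 1e-9
    if f(hi) < 0:
        raise SimulationError(
            f"target enrichment {target} unattainable on this genome "
            f"(maximum {f(hi) + target:.3f} at phi=1)")
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------- file I/O

def write_fasta(genome: GenomeIndex, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.sequences:
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(catalog: MutationCatalog, genome: GenomeIndex,
              path: str | Path) -> None:
    """Write a catalog as a minimal single-sample VCF v4.2 with AF FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genome.lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,'
                 'Description="Variant allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{catalog.sample_id}\n")
        for r in catalog.records:
            af = 1.0 if r.vaf is None else r.vaf
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                     f"GT:AF\t1/1:{af:g}\n")


def write_bed6(genes: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    import json

    d = asdict(truth)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")
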