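"""Cohort screening, transcriptional strand bias, and CC→AA doublets.

Screens per-sample mutation catalogs for motif enrichment, tests whether
motif mutations prefer the non-transcribed (coding) strand of genes —
the strand transiently single-stranded during transcription — calls
adjacent CC→AA / GG→TT double-base substitutions, and correlates DBS
counts with motif mutation loads across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats as st
from intervaltree import IntervalTree

from .catalog import (
    GenomeIndex,
    MutationCatalog,
    SNVRecord,
    normalize_pyrimidine,
)
from .enrichment import (
    MotifSpec,
    run_trims,
)


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in 0-based half-open coordinates with a strand."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"need start < end, got [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class StrandBiasResult:
    n_transcribed: int
    n_nontranscribed: int
    ratio: float
    p_value: float
    p_corrected: float = float("nan")
    test: str = ""


@dataclass(frozen=True)
class DBSRecord:
    """Adjacent double-base substitution; pos is the 5' base (1-based)."""

    chrom: str
    pos: int
    ref_dinuc: str
    alt_dinuc: str
    sample_id: str


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    undefined: bool = False


def read_bed6(path) -> list[GeneInterval]:
    """Read gene intervals from a BED6 file (0-based half-open, col 6 strand)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 requires 6 columns, got {len(f)}: {line!r}")
            genes.append(GeneInterval(f[0], int(f[1]), int(f[2]), f[5], f[3]))
    return genes


def _gene_trees(genes: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    return trees


def assign_transcription_strand(
    snv: SNVRecord,
    genes: Sequence[GeneInterval] | dict[str, IntervalTree],
    genome: GenomeIndex,
) -> str:
    """Label a (motif-matching) SNV as transcribed / non-transcribed / excluded.

    The damaged base is the purine partner of the pyrimidine-normalized
    change (the mutated guanine of nGc→nTc).  For a gene on ``+`` the top
    strand is the coding, non-transcribed strand, so a mutated G on the top
    strand is non-transcribed damage and a mutated G on the bottom strand
    (seen as C→A on top) is transcribed damage; mirrored for ``-`` genes.
    SNVs outside all genes or inside genes of conflicting strands are
    excluded.
    """
    trees = genes if isinstance(genes, dict) else _gene_trees(genes)
    tree = trees.get(snv.chrom)
    if tree is None:
        return "excluded"
    hits = {iv.data.strand for iv in tree.overlap(snv.pos - 1, snv.pos)}
    if len(hits) != 1:
        return "excluded"
    gene_strand = hits.pop()
    norm = normalize_pyrimidine(snv, genome)
    purine_strand = "-" if norm.pyr_strand == "+" else "+"
    return "non-transcribed" if purine_strand == gene_strand else "transcribed"


def strand_bias_test(n_transcribed: int, n_nontranscribed: int) -> StrandBiasResult:
    """Goodness-of-fit test of strand counts against an expected 50:50 split.

    Chi-square (df=1) when both expected counts are >= 5, otherwise an exact
    two-sided binomial test.  The reported ratio is
    non-transcribed / transcribed.
    """
    if n_transcribed < 0 or n_nontranscribed < 0:
        raise ValueError("counts must be non-negative")
    total = n_transcribed + n_nontranscribed
    ratio = (n_nontranscribed / n_transcribed if n_transcribed > 0
             else float("inf") if n_nontranscribed > 0 else float("nan"))
    if total == 0:
        return StrandBiasResult(0, 0, ratio, float("nan"), test="undefined")
    expected = total / 2.0
    if expected >= 5:
        stat, p = st.chisquare([n_transcribed, n_nontranscribed])
        return StrandBiasResult(n_transcribed, n_nontranscribed, ratio,
                                float(p), test="chi-square")
    p = st.binomtest(n_nontranscribed, total, 0.5, alternative="two-sided").pvalue
    return StrandBiasResult(n_transcribed, n_nontranscribed, ratio,
                            float(p), test="binomial")


def cohort_strand_bias(
    catalogs: Sequence[MutationCatalog],
    genome: GenomeIndex,
    genes: Sequence[GeneInterval],
    motif: MotifSpec | None = None,
    correction_method: str = "benjamini-hochberg",
) -> list[StrandBiasResult]:
    """Per-sample strand-bias tests over a cohort, with corrected p-values.

    By default only motif-matching mutations are counted (pass
    ``motif=None`` to count every mutation of any class).
    """
    from .enrichment import adjust_pvalues

    trees = _gene_trees(genes)
    results = []
    for cat in catalogs:
        nt = nn = 0
        for r in cat.records:
            if motif is not None:
                try:
                    n = normalize_pyrimidine(r, genome)
                except IndexError:
                    continue
                if (n.channel_ref, n.channel_alt) != (motif.mutated_base,
                                                      motif.alt_base):
                    continue
                if not motif.matches_flanks(n.five_prime, n.three_prime):
                    continue
            label = assign_transcription_strand(r, trees, genome)
            if label == "transcribed":
                nt += 1
            elif label == "non-transcribed":
                nn += 1
        results.append(strand_bias_test(nt, nn))
    ps = [r.p_value for r in results]
    finite = [0.0 <= p <= 1.0 for p in ps]
    adj_in = [p if ok else 1.0 for p, ok in zip(ps, finite)]
    adj = adjust_pvalues(adj_in, correction_method)
    for r, pc, ok in zip(results, adj, finite):
        r.p_corrected = pc if ok else float("nan")
    return results


def call_dbs(
    catalog: MutationCatalog,
    ref_dinuc: str = "CC",
    alt_dinuc: str = "AA",
) -> tuple[list[DBSRecord], set[tuple[str, int]]]:
    """Call adjacent double-base substitutions (default CC→AA / GG→TT).

    Scans the sorted catalog for same-sample SNV pairs at (pos, pos+1)
    whose top-strand ref/alt dinucleotides match the target or its reverse
    complement.  Each qualifying pair is emitted once; the returned set of
    constituent (chrom, pos) lets callers avoid double-counting them as two
    independent single-base substitutions.
    """
    from .catalog import revcomp

    targets = {(ref_dinuc, alt_dinuc), (revcomp(ref_dinuc), revcomp(alt_dinuc))}
    dbs: list[DBSRecord] = []
    constituents: set[tuple[str, int]] = set()
    recs = catalog.records
    for a, b in zip(recs, recs[1:]):
        if a.chrom != b.chrom or b.pos != a.pos + 1:
            continue
        pair = (a.ref + b.ref, a.alt + b.alt)
        if pair in targets:
            dbs.append(DBSRecord(a.chrom, a.pos, pair[0], pair[1],
                                 catalog.sample_id))
            constituents.update({(a.chrom, a.pos), (b.chrom, b.pos)})
    return dbs, constituents


def correlate_loads(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """OLS regression + Pearson correlation of paired per-sample statistics.

    Typical use: x = per-sample CC→AA doublet counts, y = per-sample motif
    mutation loads.  Returns slope/intercept, r, the two-sided p from the
    t-distribution (n-2 df), and a 95% CI for the slope.  Zero variance in
    either variable yields an undefined (flagged) result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 float("nan"), (float("nan"), float("nan")),
                                 n, undefined=True)
    fit = st.linregress(x, y)
    tcrit = st.t.ppf(0.975, n - 2)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return CorrelationResult(fit.slope, fit.intercept, fit.rvalue,
                             fit.pvalue, ci, n)


def screen_cohort(
    cohort: Sequence[MutationCatalog],
    genome: GenomeIndex,
    motif: MotifSpec,
    enrich_threshold: float = 1.0,
    alpha: float = 0.05,
    correction_method: str = "bonferroni",
) -> dict:
    """Screen every sample of a cohort for motif-signature enrichment.

    A sample is flagged when enrichment >= ``enrich_threshold`` with
    corrected p <= alpha (the screening criterion uses an inclusive
    threshold, unlike the strictly-greater gate in the load formula).
    Returns per-sample results plus a cohort summary: flagged/total and the
    mean motif mutation load among flagged samples.
    """
    results = run_trims(cohort, genome, motif, pooling="per-sample",
                        correction_method=correction_method, alpha=alpha,
                        enrich_threshold=enrich_threshold,
                        strict_enrichment=False)
    flagged = [r for r in results if r.enriched_flag]
    mean_load = (sum(r.mutation_load for r in flagged) / len(flagged)
                 if flagged else float("nan"))
    return {
        "results": results,
        "n_enriched": len(flagged),
        "n_total": len(results),
        "mean_load_enriched": mean_load,
    }
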