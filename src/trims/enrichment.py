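"""The TriMS (Trinucleotide Mutation Signature) enrichment statistic.

TriMS asks whether substitutions of a given class (say C→A) occur at a
specific flanked motif (say 5'-gC, equivalently Gc-3' on the other strand)
more often than the motif's availability in the local sequence context
would predict.  Four counts enter:

* ``m_motif``  — substitutions matching the full motif,
* ``m_total``  — substitutions of the base change regardless of flanks,
* ``c_motif``  — motif-context occurrences inside +/-20 nt windows centered
  on each counted mutation,
* ``c_base``   — occurrences of the mutated base in the same windows,

all counted on both strands in pyrimidine orientation.  Then

    enrichment = (m_motif * c_base) / (m_total * c_motif)

with a one-sided Fisher's exact test on the corresponding 2x2 table, and a
mutation load m_motif * (E - 1) / E attributing the excess over baseline to
the motif-specific process (gated on E > 1 and corrected significance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Sequence

import scipy.stats as st

from .catalog import (
    COMPLEMENT,
    IUPAC,
    GenomeIndex,
    MutationCatalog,
    iter_normalized,
)

DEFAULT_WINDOW_HALFWIDTH = 20

_MOTIF_RE = re.compile(r"^([ACGTRYSWKMBDHVN])([CT])([ACGTRYSWKMBDHVN])>([ACGT])$",
                       re.IGNORECASE)


@dataclass(frozen=True)
class MotifSpec:
    """A flanked single-base substitution motif in pyrimidine orientation.

    ``five_prime_pattern`` / ``three_prime_pattern`` are IUPAC base classes
    at offsets -1 / +1.  The canonical acetaldehyde motif is ``gCn>A``:
    C→A with a 5' guanine, any 3' base.
    """

    mutated_base: str = "C"
    alt_base: str = "A"
    five_prime_pattern: str = "G"
    three_prime_pattern: str = "N"
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH

    def __post_init__(self):
        if self.mutated_base not in "CT":
            raise ValueError("mutated_base must be a pyrimidine (C or T)")
        if self.alt_base == self.mutated_base or self.alt_base not in "ACGT":
            raise ValueError(f"invalid alt base {self.alt_base!r}")
        for p in (self.five_prime_pattern, self.three_prime_pattern):
            if p not in IUPAC:
                raise ValueError(f"invalid IUPAC pattern {p!r}")
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")

    @classmethod
    def parse(cls, text: str, window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH
              ) -> "MotifSpec":
        """Parse the motif mini-language, e.g. ``gCn>A`` or ``tCw>T``."""
        m = _MOTIF_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse motif {text!r} (expected e.g. 'gCn>A')")
        five, base, three, alt = (g.upper() for g in m.groups())
        return cls(base, alt, five, three, window_halfwidth)

    def __str__(self) -> str:
        return (f"{self.five_prime_pattern.lower()}{self.mutated_base}"
                f"{self.three_prime_pattern.lower()}>{self.alt_base}")

    def matches_flanks(self, five: str, three: str) -> bool:
        return (five in IUPAC[self.five_prime_pattern]
                and three in IUPAC[self.three_prime_pattern])


@dataclass(frozen=True)
class MotifCounts:
    """The four counts entering the enrichment ratio and Fisher table."""

    m_motif: int
    m_total: int
    c_motif: int
    c_base: int

    def __post_init__(self):
        if not (0 <= self.m_motif <= self.m_total):
            raise ValueError("need 0 <= m_motif <= m_total")
        if not (0 <= self.c_motif <= self.c_base):
            raise ValueError("need 0 <= c_motif <= c_base")


@dataclass
class EnrichmentResult:
    """Per-sample (or pooled) TriMS outcome."""

    sample_id: str
    counts: MotifCounts
    enrichment: float | None
    p_value: float
    p_corrected: float = float("nan")
    mutation_load: float = 0.0
    enriched_flag: bool = False


def count_motif_mutations(
    catalog: MutationCatalog, genome: GenomeIndex, motif: MotifSpec
) -> tuple[int, int]:
    """Count (m_motif, m_total) for a catalog in pyrimidine orientation.

    A top-strand purine event is folded in via reverse complement, so a
    top-strand nGc→nTc counts toward gCn→gAn.  Records at chromosome
    termini are excluded (flanks undefined).
    """
    normalized, _ = iter_normalized(catalog, genome)
    m_total = m_motif = 0
    for n in normalized:
        if (n.channel_ref, n.channel_alt) != (motif.mutated_base, motif.alt_base):
            continue
        m_total += 1
        if motif.matches_flanks(n.five_prime, n.three_prime):
            m_motif += 1
    return m_motif, m_total


def _window_context_counts(
    seq: str, center0: int, motif: MotifSpec, halfwidth: int
) -> tuple[int, int]:
    """Motif-context and base occurrences within one window.

    The window covers positions ``center0 +/- halfwidth`` (0-based,
    truncated at chromosome ends) and includes the mutated position.  A
    motif occurrence is counted when its *central* base lies in the window;
    flanks are read from the genome and may extend one base past the window
    edge, but never past the chromosome.
    """
    base = motif.mutated_base
    comp = COMPLEMENT[base]
    five = IUPAC[motif.five_prime_pattern]
    three = IUPAC[motif.three_prime_pattern]
    lo = max(0, center0 - halfwidth)
    hi = min(len(seq) - 1, center0 + halfwidth)
    c_base = c_motif = 0
    for i in range(lo, hi + 1):
        b = seq[i]
        if b == base:
            # pyrimidine on the top strand: flanks read left-to-right
            c_base += 1
            if (i > 0 and seq[i - 1] in five
                    and i + 1 < len(seq) and seq[i + 1] in three):
                c_motif += 1
        elif b == comp:
            # pyrimidine on the bottom strand: 5' flank is at i+1, complemented
            c_base += 1
            if (i + 1 < len(seq) and COMPLEMENT[seq[i + 1]] in five
                    and i > 0 and COMPLEMENT[seq[i - 1]] in three):
                c_motif += 1
    return c_motif, c_base


def count_context(
    catalog: MutationCatalog, genome: GenomeIndex, motif: MotifSpec
) -> tuple[int, int]:
    """Count (c_motif, c_base) over +/-window_halfwidth windows.

    One window per mutation of the base-change class (the ``m_total`` set);
    overlapping windows are counted per-window, never merged, so two
    mutations with identical windows contribute exactly twice.
    """
    normalized, _ = iter_normalized(catalog, genome)
    c_motif = c_base = 0
    for n in normalized:
        if (n.channel_ref, n.channel_alt) != (motif.mutated_base, motif.alt_base):
            continue
        seq = genome.sequences[n.origin.chrom]
        cm, cb = _window_context_counts(seq, n.origin.pos - 1, motif,
                                        motif.window_halfwidth)
        c_motif += cm
        c_base += cb
    return c_motif, c_base


def enrichment(counts: MotifCounts) -> float | None:
    """Fold enrichment (m_motif * c_base) / (m_total * c_motif).

    Returns ``None`` (undefined, not zero) when a denominator term is zero
    with a non-zero numerator; 0.0 when m_motif is zero.
    """
    if counts.m_motif == 0:
        return 0.0
    if counts.m_total == 0 or counts.c_motif == 0:
        return None
    return (counts.m_motif * counts.c_base) / (counts.m_total * counts.c_motif)


def fisher_one_sided(counts: MotifCounts) -> float:
    """One-sided (greater) Fisher exact p on the TriMS 2x2 table.

    Table orientation is fixed as
    ``[[m_motif, m_total - m_motif], [c_motif, c_base - c_motif]]`` with
    alternative "greater" — exact hypergeometric tail, no approximation.
    Degenerate tables (any margin zero) return p = 1 by convention.
    """
    a, b = counts.m_motif, counts.m_total - counts.m_motif
    c, d = counts.c_motif, counts.c_base - counts.c_motif
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    return float(st.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def adjust_pvalues(
    ps: Sequence[float],
    method: Literal["bonferroni", "benjamini-hochberg", "bh"] = "benjamini-hochberg",
) -> list[float]:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up adjustment,
    order-preserving with the input."""
    from statsmodels.stats.multitest import multipletests

    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if len(ps) == 0:
        return []
    key = {"bonferroni": "bonferroni", "benjamini-hochberg": "fdr_bh",
           "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method {method!r}")
    return list(multipletests(list(ps), method=key)[1])


def mutation_load(
    counts: MotifCounts,
    enrichment_value: float | None,
    p_corrected: float,
    alpha: float = 0.05,
) -> float:
    """Mutations attributable to the motif process:
    m_motif * (E - 1) / E when E > 1 and p_corrected <= alpha, else 0."""
    if enrichment_value is None or enrichment_value <= 1.0:
        return 0.0
    if not (p_corrected <= alpha):
        return 0.0
    return counts.m_motif * (enrichment_value - 1.0) / enrichment_value


def run_trims(
    catalogs: Sequence[MutationCatalog],
    genome: GenomeIndex,
    motif: MotifSpec,
    pooling: Literal["per-sample", "pooled"] = "per-sample",
    correction_method: str = "benjamini-hochberg",
    alpha: float = 0.05,
    enrich_threshold: float = 1.0,
    strict_enrichment: bool = True,
) -> list[EnrichmentResult]:
    """Run TriMS over a set of catalogs.

    ``per-sample`` yields one result per catalog with p-values corrected
    across the sample set; ``pooled`` concatenates all catalogs into one
    virtual sample first.  ``enriched_flag`` is set when the enrichment
    reaches ``enrich_threshold`` (strictly greater when
    ``strict_enrichment``, else >=) at corrected significance.
    """
    if not catalogs:
        raise ValueError("run_trims requires at least one catalog")
    if pooling == "pooled":
        # records from different samples may share coordinates; pool by
        # summing counts per catalog instead of building one catalog object
        groups = [("pooled", list(catalogs))]
    elif pooling == "per-sample":
        groups = [(cat.sample_id, [cat]) for cat in catalogs]
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")

    results: list[EnrichmentResult] = []
    for label, cats in groups:
        mm = mt = cm = cb = 0
        for cat in cats:
            a, b = count_motif_mutations(cat, genome, motif)
            c, d = count_context(cat, genome, motif)
            mm, mt, cm, cb = mm + a, mt + b, cm + c, cb + d
        counts = MotifCounts(mm, mt, cm, cb)
        e = enrichment(counts)
        p = fisher_one_sided(counts)
        results.append(EnrichmentResult(label, counts, e, p))

    adj = adjust_pvalues([r.p_value for r in results], correction_method)
    for r, pc in zip(results, adj):
        r.p_corrected = pc
        r.mutation_load = mutation_load(r.counts, r.enrichment, pc, alpha)
        if r.enrichment is None:
            r.enriched_flag = False
        else:
            above = (r.enrichment > enrich_threshold if strict_enrichment
                     else r.enrichment >= enrich_threshold)
            r.enriched_flag = bool(above and pc <= alpha)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Tabulate EnrichmentResults as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([
        {"sample_id": r.sample_id, "m_motif": r.counts.m_motif,
         "m_total": r.counts.m_total, "c_motif": r.counts.c_motif,
         "c_base": r.counts.c_base,
         "enrichment": float("nan") if r.enrichment is None else r.enrichment,
         "p": r.p_value, "p_corrected": r.p_corrected,
         "load": r.mutation_load, "enriched_flag": r.enriched_flag}
        for r in results
    ])
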