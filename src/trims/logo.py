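"""Signed binomial log-probability logos for bases flanking a mutated site.

For each offset around the mutated base (default -2..+2, excluding 0) and
each base, the height is the exact binomial tail log-probability of seeing
the observed foreground count given the background frequency of that base
at that offset: positive heights mark over-representation
(-log10 P(X >= k)), negative heights under-representation
(+log10 P(X <= k)).  A Bonferroni-style threshold line at
-log10(0.05 / n_tests) marks significance, as in position-probability logo
tools for post-translational-modification motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import scipy.stats as st

from .catalog import COMPLEMENT, GenomeIndex, MutationCatalog, iter_normalized

DEFAULT_OFFSETS = (-2, -1, 1, 2)
LOG10 = math.log(10.0)


@dataclass
class LogoMatrix:
    """Signed heights per (offset, base) plus the background model used."""

    heights: dict[tuple[int, str], float]
    n_fg: int
    n_bg: int
    bg_freq: dict[tuple[int, str], float]
    fg_counts: dict[tuple[int, str], int]
    threshold_height: float
    low_background: bool = False

    def significant(self, offset: int, base: str) -> bool:
        return abs(self.heights[(offset, base)]) > self.threshold_height

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"offset": off, "base": b, "count": self.fg_counts[(off, b)],
             "bg_freq": self.bg_freq[(off, b)], "height": h,
             "significant": abs(h) > self.threshold_height}
            for (off, b), h in sorted(self.heights.items())
        ])


def collect_flank_counts(
    catalogs: MutationCatalog | Sequence[MutationCatalog],
    genome: GenomeIndex,
    substitution_class: tuple[str, str] | None = ("C", "A"),
    offsets: Sequence[int] = DEFAULT_OFFSETS,
) -> tuple[dict[tuple[int, str], int], int, dict]:
    """Per-offset base counts around matching mutations, in pyrimidine
    orientation.

    ``substitution_class`` is the (pyrimidine ref, alt) pair selecting the
    foreground; ``None`` counts every substitution.  A single catalog or a
    collection may be given (samples are pooled).  Purine-strand events are
    folded in: the offset axis always runs 5'→3' along the strand carrying
    the pyrimidine.  Records whose widest offset falls off the chromosome
    (or hits N) are excluded and tallied.
    """
    if 0 in offsets:
        raise ValueError("offset 0 is the mutated base itself")
    if isinstance(catalogs, MutationCatalog):
        catalogs = [catalogs]
    normalized = []
    for cat in catalogs:
        normalized.extend(iter_normalized(cat, genome)[0])
    counts = {(off, b): 0 for off in offsets for b in "ACGT"}
    n_used = 0
    excluded = {"terminus": 0, "ambiguous": 0}
    max_off = max(abs(o) for o in offsets)
    for n in normalized:
        if substitution_class is not None and \
                (n.channel_ref, n.channel_alt) != substitution_class:
            continue
        r = n.origin
        if r.pos - max_off < 1 or r.pos + max_off > genome.lengths[r.chrom]:
            excluded["terminus"] += 1
            continue
        seq = genome.sequences[r.chrom]
        flanks = {}
        ok = True
        for off in offsets:
            if n.pyr_strand == "+":
                b = seq[r.pos - 1 + off]
            else:
                b = COMPLEMENT[seq[r.pos - 1 - off]]
            if b == "N":
                ok = False
                break
            flanks[off] = b
        if not ok:
            excluded["ambiguous"] += 1
            continue
        for off, b in flanks.items():
            counts[(off, b)] += 1
        n_used += 1
    return counts, n_used, excluded


def logo_height(k: int, n: int, q: float) -> float:
    """Signed binomial tail log-probability for count k of n at background q.

    Over-represented branch (k/n >= q): height = -log10 P(X >= k);
    under-represented: height = +log10 P(X <= k), a negative number.  Exact
    tails via the binomial distribution, no normal approximation.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"background frequency must be in (0,1), got {q}")
    if n == 0:
        return 0.0
    if k / n >= q:
        return -st.binom.logsf(k - 1, n, q) / LOG10
    return st.binom.logcdf(k, n, q) / LOG10


def build_logo(
    fg_catalog: MutationCatalog | Sequence[MutationCatalog],
    genome: GenomeIndex,
    substitution_class: tuple[str, str] = ("C", "A"),
    offsets: Sequence[int] = DEFAULT_OFFSETS,
    alpha: float = 0.05,
    background: str = "other-substitutions",
    pseudocount: float = 0.5,
) -> LogoMatrix:
    """Build a flanking-base logo for one substitution class.

    Foreground = mutations matching ``substitution_class`` (e.g. C→A).
    Background (default) = mutations of the same reference base with any
    *other* alternate allele, whose flank composition defines the per-offset
    base frequencies; ``background="genome"`` uses genome-wide composition
    instead.  A small pseudocount keeps background frequencies strictly
    inside (0,1).  The significance line is -log10(alpha / (4 * n_offsets)).
    """
    ref_base, alt_base = substitution_class
    fg_counts, n_fg, _ = collect_flank_counts(
        fg_catalog, genome, substitution_class, offsets)

    bg_counts = {(off, b): 0.0 for off in offsets for b in "ACGT"}
    if background == "other-substitutions":
        n_bg = 0
        for alt in "ACGT":
            if alt in (ref_base, alt_base):
                continue
            c, n, _ = collect_flank_counts(fg_catalog, genome, (ref_base, alt),
                                           offsets)
            for key, v in c.items():
                bg_counts[key] += v
            n_bg += n
    elif background == "genome":
        comp = COMPLEMENT[ref_base]
        n_bg = 0
        base_totals = {b: 0 for b in "ACGT"}
        for seq in genome.sequences.values():
            for b in "ACGT":
                base_totals[b] += seq.count(b)
        # genome composition is offset-independent; fold strands so the
        # "5'->3' along the pyrimidine strand" axis sees base b at frequency
        # (count(b) + count(comp(b))) / (2 * total) -- which is symmetric.
        total = sum(base_totals.values())
        for off in offsets:
            for b in "ACGT":
                bg_counts[(off, b)] = (base_totals[b] + base_totals[COMPLEMENT[b]]) / 2
        n_bg = total
    else:
        raise ValueError(f"unknown background model {background!r}")

    bg_freq: dict[tuple[int, str], float] = {}
    for off in offsets:
        tot = sum(bg_counts[(off, b)] for b in "ACGT") + 4 * pseudocount
        for b in "ACGT":
            bg_freq[(off, b)] = (bg_counts[(off, b)] + pseudocount) / tot

    heights = {key: logo_height(fg_counts[key], n_fg, bg_freq[key])
               if n_fg > 0 else 0.0
               for key in fg_counts}
    n_tests = 4 * len(offsets)
    return LogoMatrix(
        heights=heights, n_fg=n_fg, n_bg=n_bg, bg_freq=bg_freq,
        fg_counts=fg_counts,
        threshold_height=-math.log10(alpha / n_tests),
        low_background=(n_bg < 10),
    )
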