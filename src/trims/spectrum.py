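"""96-channel substitution spectra and telomere / resection-strand geometry.

The reporter system this package models uncaps telomeres in a *cdc13-1*
yeast strain; 5'→3' resection then exposes long single-stranded tracts
(~30 kb) at chromosome ends.  Geometrically, resection leaves the *bottom*
strand single-stranded on left chromosome arms and the *top* strand on right
arms, so a lesion signature confined to resected ssDNA shows up as an
arm-dependent strand asymmetry of the mutated base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .catalog import (
    COMPLEMENT,
    GenomeIndex,
    MutationCatalog,
    SNVRecord,
    iter_normalized,
)

#: The six pyrimidine-centered base changes.
PYRIMIDINE_CHANGES = [("C", "A"), ("C", "G"), ("C", "T"),
                      ("T", "A"), ("T", "C"), ("T", "G")]

#: All 96 channel keys (five_prime, ref, three_prime, alt), lexicographic.
CHANNELS: list[tuple[str, str, str, str]] = [
    (five, ref, three, alt)
    for ref, alt in PYRIMIDINE_CHANGES
    for five in "ACGT"
    for three in "ACGT"
]

DEFAULT_SUBTELOMERE_BP = 30_000


@dataclass
class SpectrumTable:
    """Counts over the 96 pyrimidine-centered trinucleotide channels."""

    counts: dict[tuple[str, str, str, str], int]
    label: str = ""
    n_usable: int = 0

    def __post_init__(self):
        full = {ch: 0 for ch in CHANNELS}
        full.update(self.counts)
        if set(full) != set(CHANNELS):
            raise ValueError("spectrum contains keys outside the 96 channels")
        self.counts = full
        if self.n_usable == 0:
            self.n_usable = sum(full.values())

    def proportions(self) -> dict[tuple[str, str, str, str], float]:
        total = self.n_usable or 1
        return {ch: n / total for ch, n in self.counts.items()}

    def to_frame(self):
        """Spectrum as a pandas DataFrame (channel, count, proportion)."""
        import pandas as pd

        rows = [
            {"five_prime": f, "ref": r, "three_prime": t, "alt": a,
             "channel": f"{f.lower()}{r}{t.lower()}>{a}", "count": n}
            for (f, r, t, a), n in self.counts.items()
        ]
        df = pd.DataFrame(rows)
        df["proportion"] = df["count"] / (self.n_usable or 1)
        return df


@dataclass
class TelomereModel:
    """Chromosome-end geometry: both ends of every chromosome are telomeres
    and positions within ``subtelomere_threshold`` of either end are
    sub-telomeric (inclusive boundary)."""

    subtelomere_threshold: int = DEFAULT_SUBTELOMERE_BP

    def __post_init__(self):
        if self.subtelomere_threshold <= 0:
            raise ValueError("subtelomere threshold must be positive")


@dataclass(frozen=True)
class StrandClassification:
    """Arm / region / strand-consistency assignment for one SNV."""

    snv: SNVRecord
    arm: str                 # "left" | "right"
    distance_bp: int
    region: str              # "sub-telomeric" | "mid-chromosomal"
    ref_strand_change: str   # e.g. "C>A" as written on the top strand
    pyr_strand: str
    ssdna_consistent: bool


def telomere_distance(genome: GenomeIndex, chrom: str, pos: int) -> int:
    """Distance (bp) from a 1-based position to the nearer chromosome end."""
    if chrom not in genome.lengths:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = genome.lengths[chrom]
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    return min(pos - 1, length - pos)


def classify_region(distance: int, threshold: int = DEFAULT_SUBTELOMERE_BP) -> str:
    """Bin a telomere distance: sub-telomeric iff distance <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return "sub-telomeric" if distance <= threshold else "mid-chromosomal"


def build_spectrum(catalog: MutationCatalog, genome: GenomeIndex,
                   label: str | None = None) -> SpectrumTable:
    """Build the 96-channel spectrum of a catalog.

    Each SNV with both flanks available and unambiguous increments exactly
    one channel; terminus/N records are excluded and reflected in
    ``n_usable``.
    """
    normalized, _ = iter_normalized(catalog, genome)
    counts: dict[tuple[str, str, str, str], int] = {}
    for n in normalized:
        counts[n.channel] = counts.get(n.channel, 0) + 1
    return SpectrumTable(counts, label or catalog.sample_id, len(normalized))


def _region_predicate(
    genome: GenomeIndex,
    region_filter: str | None,
    threshold: int,
    exclude_chroms: Iterable[str] = (),
) -> Callable[[SNVRecord], bool]:
    exclude = set(exclude_chroms)

    def pred(r: SNVRecord) -> bool:
        if r.chrom in exclude:
            return False
        if region_filter is None:
            return True
        d = telomere_distance(genome, r.chrom, r.pos)
        return classify_region(d, threshold) == region_filter

    return pred


def mutation_density(
    catalogs: Sequence[MutationCatalog],
    genome: GenomeIndex,
    substitution_class: tuple[str, str] = ("C", "A"),
    region_filter: str | None = None,
    threshold: int = DEFAULT_SUBTELOMERE_BP,
    exclude_chroms: Iterable[str] = (),
) -> dict:
    """Substitution density of a pyrimidine class across a set of isolates.

    Primary output is per-isolate: matching substitutions (in pyrimidine
    orientation, so C→A counts both top-strand C→A and top-strand G→T)
    divided by the number of catalogs.  The secondary per-mutable-base
    density divides further by the number of class-matching reference bases
    (both strands, i.e. C plus G positions for a C class) in the region.
    """
    if not catalogs:
        raise ValueError("mutation_density requires at least one catalog")
    ref_base, alt_base = substitution_class
    pred = _region_predicate(genome, region_filter, threshold, exclude_chroms)
    n_match = 0
    for cat in catalogs:
        normalized, _ = iter_normalized(cat, genome)
        for n in normalized:
            if (n.channel_ref, n.channel_alt) == (ref_base, alt_base) and pred(n.origin):
                n_match += 1
    per_isolate = n_match / len(catalogs)

    comp = COMPLEMENT[ref_base]
    mutable = 0
    exclude = set(exclude_chroms)
    for chrom, seq in genome.sequences.items():
        if chrom in exclude:
            continue
        length = genome.lengths[chrom]
        for i, b in enumerate(seq):
            if b != ref_base and b != comp:
                continue
            if region_filter is not None:
                d = min(i, length - 1 - i)
                if classify_region(d, threshold) != region_filter:
                    continue
            mutable += 1
    per_base = per_isolate / mutable if mutable else float("nan")
    return {
        "n_substitutions": n_match,
        "n_isolates": len(catalogs),
        "per_isolate": per_isolate,
        "mutable_bases": mutable,
        "per_isolate_per_base": per_base,
    }


def resection_strand_classify(
    catalog: MutationCatalog,
    genome: GenomeIndex,
    model: TelomereModel | None = None,
) -> tuple[list[StrandClassification], dict]:
    """Classify each SNV by chromosome arm and resected-strand consistency.

    The purine partner of the pyrimidine-normalized change is the damaged
    base (lesions form on guanine).  On a left arm the resected,
    single-stranded DNA is the bottom strand, so a lesion there implies the
    pyrimidine sits on the top strand (``pyr_strand == '+'``); on a right
    arm the converse.  Arm ties at the exact midpoint go to the left arm.
    """
    model = model or TelomereModel()
    normalized, _ = iter_normalized(catalog, genome)
    out: list[StrandClassification] = []
    summary: dict[tuple[str, str], int] = {}
    for n in normalized:
        r = n.origin
        length = genome.lengths[r.chrom]
        d_left, d_right = r.pos - 1, length - r.pos
        arm = "left" if d_left <= d_right else "right"
        dist = min(d_left, d_right)
        region = classify_region(dist, model.subtelomere_threshold)
        consistent = (arm == "left") == (n.pyr_strand == "+")
        change = f"{r.ref}>{r.alt}"
        out.append(StrandClassification(r, arm, dist, region, change,
                                        n.pyr_strand, consistent))
        summary[(arm, change)] = summary.get((arm, change), 0) + 1
    n_cons = sum(1 for c in out if c.ssdna_consistent)
    return out, {
        "by_arm_change": summary,
        "n_classified": len(out),
        "n_consistent": n_cons,
        "consistent_fraction": n_cons / len(out) if out else float("nan"),
        "n_subtelomeric": sum(1 for c in out if c.region == "sub-telomeric"),
        "n_mid_chromosomal": sum(1 for c in out if c.region == "mid-chromosomal"),
    }
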