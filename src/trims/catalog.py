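"""Mutation catalogs, reference genomes, and pyrimidine normalization.

A mutation catalog is the set of clonal single-base substitutions called in
one sample (one yeast isolate, one tumor).  All downstream statistics work in
*pyrimidine orientation*: every substitution is reported with the mutated base
as C or T, folding purine-strand events in via reverse complement, so that a
top-strand ``G→T`` and a top-strand ``C→A`` belong to the same event class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
DNA = frozenset("ACGT")
PYRIMIDINES = frozenset("CT")

#: IUPAC single-base classes used for motif flank patterns.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N preserved)."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog / genome inputs."""


@dataclass(frozen=True)
class SNVRecord:
    """A single-base substitution on the top (reference) strand, 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    vaf: float | None = None

    def __post_init__(self):
        if self.ref not in DNA or self.alt not in DNA:
            raise CatalogError(f"ref/alt must be single DNA bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise CatalogError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise CatalogError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the variant: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)


@dataclass
class MutationCatalog:
    """Ordered, de-duplicated collection of SNVs for one sample."""

    sample_id: str
    records: list[SNVRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        seen: set[tuple[str, int]] = set()
        for r in self.records:
            if (r.chrom, r.pos) in seen:
                raise CatalogError(
                    f"duplicate record at {r.chrom}:{r.pos} in sample {self.sample_id}"
                )
            seen.add((r.chrom, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GenomeIndex:
    """In-memory reference genome: upper-case sequences and lengths."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.lengths = {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def context(self, chrom: str, pos: int, halfwidth: int = 1) -> str:
        """Top-strand context of +/- halfwidth around a 1-based position.

        Raises IndexError if the window would run off either chromosome end.
        """
        if pos - halfwidth < 1 or pos + halfwidth > self.lengths[chrom]:
            raise IndexError(f"context window off chromosome end at {chrom}:{pos}")
        return self.sequences[chrom][pos - halfwidth - 1 : pos + halfwidth]


@dataclass(frozen=True)
class NormalizedSNV:
    """An SNV re-expressed with the mutated base as a pyrimidine.

    ``pyr_strand`` records which reference strand carries the pyrimidine:
    ``+`` when the original call already had ref C/T, ``-`` when the context
    was reverse-complemented.
    """

    channel_ref: str
    channel_alt: str
    five_prime: str
    three_prime: str
    pyr_strand: str
    origin: SNVRecord

    @property
    def channel(self) -> tuple[str, str, str, str]:
        """96-channel key (five_prime, ref, three_prime, alt)."""
        return (self.five_prime, self.channel_ref, self.three_prime, self.channel_alt)


def read_genome(path: str | Path) -> GenomeIndex:
    """Read a FASTA reference into a :class:`GenomeIndex`.

    Sequences are upper-cased; ambiguous N bases are preserved.  Duplicate
    chromosome names are an error.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise CatalogError(f"duplicate chromosome name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise CatalogError(f"empty sequence for chromosome {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise CatalogError(f"no FASTA records found in {path}")
    return GenomeIndex(sequences)


def _record_vaf(vrec, vaf_field: str) -> float | None:
    """Pull a variant allele fraction from a pysam record (per-sample FORMAT
    field first, then INFO).  FREQ-style percent strings ("95%") and values
    on a 0-100 scale are converted to fractions."""
    raw = None
    if len(vrec.samples):
        fmt = next(iter(vrec.samples.values()))
        if vaf_field in fmt and fmt[vaf_field] is not None:
            raw = fmt[vaf_field]
    if raw is None:
        try:
            raw = vrec.info.get(vaf_field)
        except (KeyError, ValueError):  # field not declared in the header
            raw = None
    if raw is None:
        return None
    if isinstance(raw, (tuple, list)):
        raw = raw[0]
    if isinstance(raw, str):
        raw = raw.rstrip("%")
    val = float(raw)
    return val / 100.0 if val > 1.0 else val


def read_snvs(
    path: str | Path,
    min_vaf: float = 0.0,
    sample_id: str | None = None,
    vaf_field: str = "AF",
) -> MutationCatalog:
    """Read biallelic SNVs from a single-sample VCF, applying a VAF filter.

    Multi-allelic records, indels, and calls with VAF below ``min_vaf`` are
    dropped and tallied in ``catalog.meta``.  If ``min_vaf > 0`` and a record
    carries no VAF annotation the read fails loudly: the clonality filter is
    load-bearing and must not be silently skipped.
    """
    import pysam

    if not 0.0 <= min_vaf <= 1.0:
        raise CatalogError(f"min_vaf must be in [0,1], got {min_vaf}")
    path = str(path)
    dropped = {"multiallelic": 0, "not_snv": 0, "below_vaf": 0, "no_vaf": 0}
    records: list[SNVRecord] = []
    with pysam.VariantFile(path) as vcf:
        if sample_id is None:
            sample_id = next(iter(vcf.header.samples), Path(path).stem)
        for vrec in vcf:
            alts = vrec.alts or ()
            if len(alts) != 1:
                dropped["multiallelic"] += 1
                continue
            ref, alt = vrec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in DNA or alt not in DNA:
                dropped["not_snv"] += 1
                continue
            vaf = _record_vaf(vrec, vaf_field)
            if min_vaf > 0:
                if vaf is None:
                    raise CatalogError(
                        f"min_vaf={min_vaf} requested but record {vrec.chrom}:{vrec.pos} "
                        f"has no {vaf_field!r} annotation"
                    )
                # VCF Float FORMAT values are float32; tolerate that much
                # rounding at the inclusive threshold
                if vaf < min_vaf - 1e-6:
                    dropped["below_vaf"] += 1
                    continue
            records.append(SNVRecord(vrec.chrom, vrec.pos, ref, alt, sample_id, vaf))
    meta = {"source": path, "min_vaf": min_vaf, "dropped": dropped,
            "n_input": len(records) + sum(dropped.values())}
    return MutationCatalog(sample_id, records, meta)


def subtract_normal(treated: MutationCatalog, normal: MutationCatalog) -> MutationCatalog:
    """Remove every (chrom, pos, alt) present in the matched normal.

    Positions shared with the untreated parent are pre-existing variants,
    not mutagen-induced; matching is on the full variant identity, so a
    different alt allele at the same position survives.
    """
    normal_keys = {r.key for r in normal.records}
    kept = [r for r in treated.records if r.key not in normal_keys]
    meta = dict(treated.meta)
    meta["normal_subtracted"] = len(treated.records) - len(kept)
    return MutationCatalog(treated.sample_id, kept, meta)


def dedupe_recurrent(
    catalogs: Sequence[MutationCatalog], min_share: int = 2
) -> list[MutationCatalog]:
    """Drop variants recurring in >= ``min_share`` sibling catalogs.

    Isolates derived from one parent share pre-existing variants; a call seen
    independently in several isolates is treated as inherited rather than
    induced and removed from all of them.
    """
    if min_share < 2:
        raise CatalogError(f"min_share must be >= 2, got {min_share}")
    counts: dict[tuple[str, int, str], int] = {}
    for cat in catalogs:
        for r in cat.records:
            counts[r.key] = counts.get(r.key, 0) + 1
    shared = {k for k, n in counts.items() if n >= min_share}
    out = []
    for cat in catalogs:
        kept = [r for r in cat.records if r.key not in shared]
        meta = dict(cat.meta)
        meta["recurrent_removed"] = len(cat.records) - len(kept)
        out.append(MutationCatalog(cat.sample_id, kept, meta))
    return out


def normalize_pyrimidine(snv: SNVRecord, genome: GenomeIndex) -> NormalizedSNV:
    """Express an SNV with its mutated base as a pyrimidine.

    If the reference base is a purine the trinucleotide context is reverse
    complemented (flanks swapped and complemented) and ``pyr_strand`` is
    ``-``.  The genome must agree with the VCF reference allele, and both
    flanking bases must exist (interior positions only).
    """
    ref_in_genome = genome.base(snv.chrom, snv.pos)
    if ref_in_genome != snv.ref:
        raise CatalogError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: "
            f"VCF says {snv.ref}, genome has {ref_in_genome}"
        )
    ctx = genome.context(snv.chrom, snv.pos, 1)  # IndexError at termini
    if snv.ref in PYRIMIDINES:
        return NormalizedSNV(snv.ref, snv.alt, ctx[0], ctx[2], "+", snv)
    rc = revcomp(ctx)
    return NormalizedSNV(
        COMPLEMENT[snv.ref], COMPLEMENT[snv.alt], rc[0], rc[2], "-", snv
    )


def iter_normalized(
    catalog: MutationCatalog, genome: GenomeIndex
) -> tuple[list[NormalizedSNV], dict[str, int]]:
    """Normalize a whole catalog, excluding (and tallying) records at
    chromosome termini or with N in the +/-1 context."""
    out: list[NormalizedSNV] = []
    excluded = {"terminus": 0, "ambiguous_context": 0}
    for r in catalog.records:
        try:
            n = normalize_pyrimidine(r, genome)
        except IndexError:
            excluded["terminus"] += 1
            continue
        if "N" in (n.five_prime, n.three_prime, n.channel_ref):
            excluded["ambiguous_context"] += 1
            continue
        out.append(n)
    return out, excluded


def write_catalog_tsv(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog as TSV (sample_id, chrom, pos, ref, alt, vaf)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tvaf\n")
        for r in catalog.records:
            vaf = "" if r.vaf is None else f"{r.vaf:g}"
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{vaf}\n")


def write_filter_report(catalog: MutationCatalog, path: str | Path) -> None:
    """Write the catalog's filter provenance as JSON."""
    with open(path, "w") as fh:
        json.dump({"sample_id": catalog.sample_id, "n_records": len(catalog),
                   "meta": catalog.meta}, fh, indent=2)
        fh.write("\n")


def read_catalog_tsv(path: str | Path) -> list[MutationCatalog]:
    """Read one or more catalogs from a combined TSV
    (sample_id, chrom, pos, ref, alt[, vaf])."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cats = []
    for sid, grp in df.groupby("sample_id", sort=True):
        recs = [
            SNVRecord(row.chrom, int(row.pos), row.ref, row.alt, str(sid),
                      None if "vaf" not in df.columns or pd.isna(row.vaf) else float(row.vaf))
            for row in grp.itertuples()
        ]
        cats.append(MutationCatalog(str(sid), recs, {"source": str(path)}))
    return cats
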