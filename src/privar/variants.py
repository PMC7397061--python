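"""Multi-sample variant I/O and normalization.

The filtering stages of the package operate on a dense genotype matrix of
normalized, biallelic single-locus records.  This module reads and writes
VCF 4.x (via :mod:`pysam`), splits multi-allelic sites into per-ALT
records, and normalizes variant representations (allele trimming and
indel left-alignment) so that set operations on variants are
representation-independent.

Conventions
-----------
* All coordinates are 1-based inclusive, VCF-style.
* Genotypes are stored as alternate-allele counts per diploid sample:
  0 (hom-ref), 1 (het), 2 (hom-alt), or :data:`MISSING` (-1) when the
  call is absent or half-called.
* Variant identity for set operations is the normalized
  ``(contig, pos, ref, alt)`` tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Sentinel alternate-allele count for a missing or half-called genotype.
MISSING: int = -1

_VALID_BASES = frozenset("ACGTN")

#: Normalized variant identity tuple: (contig, pos, ref, alt).
VariantKey = tuple[str, int, str, str]


class VariantIOError(ValueError):
    """Raised for malformed variant files or inconsistent inputs."""


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A biallelic variant at a single locus.

    Parameters
    ----------
    contig : str
        Contig/chromosome identifier.
    pos : int
        1-based position of the first REF base.
    ref, alt : str
        Allele strings (uppercase over ACGTN); ``ref != alt``.
    vid : str, optional
        Free-form identifier (VCF ID column).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantIOError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _VALID_BASES:
                raise VariantIOError(
                    f"{name} allele {allele!r} must be non-empty uppercase ACGTN"
                )
        if self.ref == self.alt:
            raise VariantIOError(f"ref == alt ({self.ref!r}) at {self.contig}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class Sample:
    """One row of the sample sheet."""

    id: str
    status: str  # "case" | "control" | "unknown"
    breed: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control", "unknown"):
            raise VariantIOError(
                f"sample {self.id!r}: status must be case/control/unknown, "
                f"got {self.status!r}"
            )


@dataclass
class SampleSheet:
    """Ordered collection of samples with case/control status."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise VariantIOError(f"duplicate sample ids in sheet: {dupes}")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def by_status(self, status: str) -> list[Sample]:
        return [s for s in self.samples if s.status == status]

    @property
    def cases(self) -> list[Sample]:
        return self.by_status("case")

    @property
    def controls(self) -> list[Sample]:
        return self.by_status("control")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        """Read a tab-separated sheet with header ``sample status breed family``."""
        rows: list[Sample] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["sample", "status", "breed", "family"]
            if header[: len(expected)] != expected:
                raise VariantIOError(
                    f"sample sheet {path}: expected header {expected}, got {header}"
                )
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                parts += [""] * (4 - len(parts))
                sid, status, breed, family = parts[:4]
                rows.append(Sample(sid, status, breed, family or None))
        return cls(rows)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tstatus\tbreed\tfamily\n")
            for s in self.samples:
                fh.write(f"{s.id}\t{s.status}\t{s.breed}\t{s.family or ''}\n")


@dataclass
class GenotypeMatrix:
    """Variants x samples grid of alternate-allele counts.

    ``calls[i, j]`` is the alt-allele count of sample ``samples[j]`` at
    ``variants[i]``: 0, 1, 2 or :data:`MISSING`.
    """

    variants: list[VariantRecord]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise VariantIOError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise VariantIOError("duplicate sample ids in matrix")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise VariantIOError(f"invalid call values: {np.unique(self.calls[bad])}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise VariantIOError(f"sample {exc.args[0]!r} not in matrix") from None

    def keys(self) -> list[VariantKey]:
        return [v.key for v in self.variants]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# genotype decoding


def _decode_gt(gt: Sequence[int | None] | None, where: str) -> tuple[int | None, ...]:
    """Validate a raw pysam GT tuple; returns it unchanged.

    Haploid and >2-ploid calls are rejected: the analyses here model
    autosomal diploid genotypes only.  A fully missing call of any
    ploidy (``.`` / ``./.``) is accepted and treated as missing.
    """
    if gt is None:
        return (None, None)
    alleles = tuple(gt)
    if all(a is None for a in alleles):
        return (None, None)
    if len(alleles) != 2:
        raise VariantIOError(f"non-diploid genotype {alleles} at {where}")
    return alleles


def _alt_count(alleles: tuple[int | None, ...], alt_index: int) -> int:
    """Alt-allele count for one ALT of a possibly multi-allelic site.

    Any half-called genotype (one missing allele) is treated as MISSING:
    an unobserved allele is not evidence either way.
    """
    if any(a is None for a in alleles):
        return MISSING
    return sum(1 for a in alleles if a == alt_index)


@dataclass(frozen=True)
class MultiallelicSite:
    """Raw parsed site prior to ALT splitting."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[tuple[int | None, ...], ...]  # per sample, allele indices
    vid: str | None = None


def split_multiallelic(
    site: MultiallelicSite,
) -> list[tuple[VariantRecord, np.ndarray]]:
    """Split a site with k ALT alleles into k biallelic records.

    For each ALT the per-sample call counts only that allele; other ALT
    alleles present in a genotype contribute 0 to this record's count.
    Total alt-allele count per sample is conserved across the split.
    """
    out = []
    for k, alt in enumerate(site.alts, start=1):
        calls = np.array(
            [_alt_count(g, k) for g in site.genotypes], dtype=np.int8
        )
        rec = VariantRecord(site.contig, site.pos, site.ref.upper(), alt.upper(), site.vid)
        out.append((rec, calls))
    return out


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_vcf(
    path: str | Path,
    sheet: SampleSheet | None = None,
    pass_only: bool = False,
) -> tuple[GenotypeMatrix, SampleSheet]:
    """Read a multi-sample VCF into a genotype matrix.

    Multi-allelic records are split into one biallelic record per ALT.
    Diploid GTs decode as ``0/1``/``1/0`` -> 1, ``1/1`` -> 2, ``0/0`` -> 0,
    ``./.`` -> MISSING; phased separators are treated as unphased.

    Parameters
    ----------
    path
        VCF 4.x file with GT in FORMAT.
    sheet
        Optional sample sheet; its samples must all be present in the
        VCF and the matrix is restricted to them (in sheet order).  When
        omitted, every VCF sample is kept with status ``unknown``.
    pass_only
        When true, keep only records whose FILTER is PASS or missing.
        By default the FILTER column is ignored.
    """
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sheet is None:
            sheet = SampleSheet([Sample(s, "unknown") for s in vcf_samples])
        absent = [s.id for s in sheet if s.id not in set(vcf_samples)]
        if absent:
            raise VariantIOError(f"sheet samples absent from VCF {path}: {absent}")
        keep = sheet.ids

        variants: list[VariantRecord] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            where = f"{rec.contig}:{rec.pos}"
            if "GT" not in rec.format:
                raise VariantIOError(f"record {where} in {path} has no GT field")
            if rec.alts is None:
                continue
            if pass_only:
                flags = set(rec.filter.keys())
                if flags and flags != {"PASS"}:
                    continue
            gts = tuple(
                _decode_gt(rec.samples[s].get("GT"), where) for s in keep
            )
            site = MultiallelicSite(
                rec.contig, rec.pos, rec.ref, tuple(rec.alts), gts, rec.id
            )
            for vrec, calls in split_multiallelic(site):
                variants.append(vrec)
                rows.append(calls)

    calls = (
        np.vstack(rows) if rows else np.empty((0, len(keep)), dtype=np.int8)
    )
    return GenotypeMatrix(variants, list(keep), calls), sheet


_CALL_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(matrix: GenotypeMatrix, sheet: SampleSheet | None, path: str | Path) -> None:
    """Write a genotype matrix as a sorted VCF 4.2 with GT-only FORMAT.

    Records are emitted sorted by ``(contig, pos, ref, alt)``; unsorted
    input is sorted on write with a logged notice.
    """
    order = sorted(range(matrix.n_variants), key=lambda i: matrix.variants[i].key)
    if order != list(range(matrix.n_variants)):
        logger.info("write_vcf: input records were unsorted; sorting on write")

    header = pysam.VariantHeader()
    for contig in sorted({v.contig for v in matrix.variants}):
        header.add_line(f"##contig=<ID={contig}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            v = matrix.variants[i]
            rec = out.new_record(
                contig=v.contig,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                id=v.vid,
            )
            for j, s in enumerate(matrix.samples):
                rec.samples[s]["GT"] = _CALL_TO_GT[int(matrix.calls[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# reference access and normalization

Reference = Mapping[str, str]


def load_reference(path: str | Path) -> dict[str, str]:
    """Load a FASTA into an uppercase in-memory dict (desk-scale genomes)."""
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def _ref_slice(reference: Reference, contig: str, start: int, end: int) -> str:
    """1-based inclusive slice of the reference."""
    try:
        seq = reference[contig]
    except KeyError:
        raise VariantIOError(f"contig {contig!r} not in reference") from None
    if start < 1 or end > len(seq):
        raise VariantIOError(
            f"{contig}:{start}-{end} outside reference (length {len(seq)})"
        )
    return seq[start - 1 : end]


def normalize_variant(record: VariantRecord, reference: Reference) -> VariantRecord:
    """Return the canonical (trimmed, left-aligned) representation.

    Shared leading/trailing bases are trimmed keeping at least one base
    per allele; indels are shifted left through repeats until no further
    shift is possible.  Normalization is idempotent.

    Raises
    ------
    VariantIOError
        If the record's REF allele disagrees with the reference sequence.
    """
    observed = _ref_slice(reference, record.contig, record.pos,
                          record.pos + len(record.ref) - 1)
    if observed != record.ref:
        raise VariantIOError(
            f"REF mismatch at {record.contig}:{record.pos}: "
            f"record has {record.ref!r}, reference has {observed!r}"
        )

    pos, ref, alt = record.pos, record.ref, record.alt
    # Right-trim shared suffix bases, extending left through the
    # reference whenever an allele would become empty (left-alignment).
    while ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                raise VariantIOError(
                    f"cannot left-extend past contig start for {record}"
                )
            pos -= 1
            base = _ref_slice(reference, record.contig, pos, pos)
            ref, alt = base + ref, base + alt
    # Left-trim shared prefix bases while both alleles keep >= 1 base.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if (pos, ref, alt) == (record.pos, record.ref, record.alt):
        return record
    return replace(record, pos=pos, ref=ref, alt=alt)


def normalize_matrix(matrix: GenotypeMatrix, reference: Reference) -> GenotypeMatrix:
    """Normalize every record of a matrix (calls are unchanged)."""
    variants = [normalize_variant(v, reference) for v in matrix.variants]
    return GenotypeMatrix(variants, list(matrix.samples), matrix.calls.copy())
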