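"""Base-level IGH class quantification from aligned RNA-seq reads.

The quantifier walks each read's CIGAR string and allocates the read bases
that were aligned onto the reference (operations M, ``=`` and X) to the exon
intervals of the class model they fall in.  Reference-skipping operations
(N for splices, D for deletions) advance the reference position without
contributing bases; soft/hard clips, insertions and padding (S, I, H, P)
contribute nothing.  Per class ``c`` the allocated bases :math:`B_c` are
summed over all primary, non-duplicate, non-supplementary mapped reads with
mapping quality strictly above the threshold (default 10), and normalized by
the merged exon length :math:`L_c` and the total number of mapped reads in
the library :math:`N`:

.. math::

    \\mathrm{expr}_c = \\log_2\\!\\left(1 + 10^6 \\cdot
        \\frac{B_c}{L_c \\cdot N}\\right)

i.e. the log2 of counts per base per million mapped reads.  The library-size
denominator ``N`` is *not* MAPQ-filtered: the quality filter applies only to
the reads allocated to the locus, while ``N`` counts every primary mapped
read in the library.  Paired-end mates count as independent reads in both
numerator and denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

from .locus import GenomicInterval, LocusModel

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 10

# CIGAR operations that place read bases on the reference.
_ALIGNED_OPS = frozenset("M=X")
# Operations that advance the reference without consuming read bases.
_REF_SKIP_OPS = frozenset("DN")
# Operations that consume only the read (or nothing).
_NO_REF_OPS = frozenset("ISHP")
_VALID_OPS = _ALIGNED_OPS | _REF_SKIP_OPS | _NO_REF_OPS

_PYSAM_OPS = "MIDNSHP=X"  # pysam integer op codes 0..8


class CigarError(ValueError):
    """A CIGAR string contained an unknown operation."""


class EmptyLibraryError(ValueError):
    """The alignment file contains no mapped reads."""


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string like ``"10M200N10M"`` into (op, length) pairs."""
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch not in _VALID_OPS or not num:
                raise CigarError(f"malformed CIGAR {cigar!r} at {ch!r}")
            ops.append((ch, int(num)))
            num = ""
    if num:
        raise CigarError(f"malformed CIGAR {cigar!r}: trailing number")
    return ops


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read: the inputs to base allocation.

    ``cigar`` is an ordered list of (operation, length) pairs with operations
    in {M, I, D, N, S, H, P, =, X}; ``pos`` is the 0-based leftmost reference
    position.
    """

    chrom: str
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    is_mapped: bool = True
    is_primary: bool = True
    is_duplicate: bool = False
    is_supplementary: bool = False

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment) -> "AlignmentRecord":
        if seg.is_unmapped:
            return cls("", -1, 0, (), is_mapped=False,
                       is_primary=not seg.is_secondary,
                       is_duplicate=seg.is_duplicate,
                       is_supplementary=seg.is_supplementary)
        cigar = tuple(
            (_PYSAM_OPS[op], length) for op, length in (seg.cigartuples or ())
        )
        return cls(
            chrom=seg.reference_name or "",
            pos=seg.reference_start,
            mapq=seg.mapping_quality,
            cigar=cigar,
            is_mapped=True,
            is_primary=not seg.is_secondary,
            is_duplicate=seg.is_duplicate,
            is_supplementary=seg.is_supplementary,
        )

    def counts_toward_library(self) -> bool:
        return (self.is_mapped and self.is_primary
                and not self.is_supplementary and not self.is_duplicate)


@dataclass
class ClassBaseCounts:
    """Allocated bases per class plus the library-size denominator."""

    bases: dict[str, int]
    library_reads: int


@dataclass(frozen=True)
class ClassExpression:
    """One class's allocated bases and its normalized expression value."""

    value: float
    bases: int
    length: int
    library_reads: int


def allocate_bases(
    read: AlignmentRecord, intervals: Iterable[GenomicInterval]
) -> int:
    """Count the read bases aligned inside the union of ``intervals``.

    Only CIGAR operations M, ``=`` and X place read bases on the reference
    and can contribute; D and N advance the reference silently; S, I, H and P
    are ignored.  ``intervals`` must be sorted and disjoint (as produced by
    the locus model); intervals on other chromosomes contribute 0.
    """
    if not read.is_mapped:
        return 0
    ivs = [iv for iv in intervals if iv.chrom == read.chrom]
    if not ivs:
        return 0
    total = 0
    ref = read.pos
    for op, length in read.cigar:
        if op in _ALIGNED_OPS:
            seg_start, seg_end = ref, ref + length
            for iv in ivs:
                if iv.start >= seg_end:
                    break
                lo = max(seg_start, iv.start)
                hi = min(seg_end, iv.end)
                if hi > lo:
                    total += hi - lo
            ref = seg_end
        elif op in _REF_SKIP_OPS:
            ref += length
        elif op in _NO_REF_OPS:
            pass
        else:
            raise CigarError(f"unknown CIGAR operation {op!r}")
    return total


def count_mapped_reads(alignments: Iterable[AlignmentRecord]) -> int:
    """Count primary, non-supplementary, non-duplicate mapped reads.

    This is the library-size denominator; no MAPQ filter is applied here.
    """
    return sum(1 for rec in alignments if rec.counts_toward_library())


def count_class_bases(
    alignments: Iterable[AlignmentRecord],
    model: LocusModel,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> ClassBaseCounts:
    """Single-pass per-class base allocation over a stream of alignments.

    Reads contribute to a class's base count only if they pass the library
    flag filter *and* have MAPQ strictly above ``mapq_min``; every read
    passing the flag filter contributes to ``library_reads`` regardless of
    MAPQ.  A base inside intervals of two classes (degenerate annotation) is
    counted once per class.
    """
    bases = {cls: 0 for cls in model.classes}
    n_library = 0
    warned_overlap = False
    for rec in alignments:
        if not rec.counts_toward_library():
            continue
        n_library += 1
        if rec.mapq <= mapq_min:
            continue
        hit_classes = 0
        for cls, ivs in model.classes.items():
            b = allocate_bases(rec, ivs)
            if b:
                bases[cls] += b
                hit_classes += 1
        if hit_classes > 1 and not warned_overlap:
            logger.warning(
                "read at %s:%d overlaps intervals of %d classes; "
                "bases counted for each", rec.chrom, rec.pos, hit_classes,
            )
            warned_overlap = True
    return ClassBaseCounts(bases=bases, library_reads=n_library)


def normalize(B: int, L: int, N: int) -> ClassExpression:
    """log2(1 + 1e6 * B / (L * N)): counts per base per million mapped reads."""
    if L <= 0:
        raise ValueError(f"class length must be positive, got {L}")
    if N <= 0:
        raise ValueError(f"library read count must be positive, got {N}")
    if B < 0:
        raise ValueError(f"allocated bases must be non-negative, got {B}")
    value = math.log2(1.0 + 1e6 * B / (L * N))
    return ClassExpression(value=value, bases=B, length=L, library_reads=N)


def iter_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file (no index required)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            yield AlignmentRecord.from_pysam(seg)


def quantify_records(
    alignments: Iterable[AlignmentRecord],
    model: LocusModel,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> dict[str, ClassExpression]:
    """Quantify all classes from an in-memory alignment stream."""
    counts = count_class_bases(alignments, model, mapq_min=mapq_min)
    if counts.library_reads == 0:
        raise EmptyLibraryError("no mapped reads in library")
    return {
        cls: normalize(counts.bases[cls], model.class_length(cls), counts.library_reads)
        for cls in model.classes
    }


def quantify_sample(
    bam_path: str | Path,
    model: LocusModel,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> dict[str, ClassExpression]:
    """Quantify one sample's per-class expression from a SAM/BAM file.

    Composes base allocation, library-size counting and normalization in a
    single streaming pass; deterministic for a fixed input file.
    """
    return quantify_records(iter_alignments(bam_path), model, mapq_min=mapq_min)


def write_expression_tsv(
    results: Mapping[str, Mapping[str, ClassExpression]], path: str | Path
) -> None:
    """Write per-sample per-class quantification results as TSV."""
    lines = ["sample\tclass\tbases\tlength\tlibrary_reads\tlog2_cpbm"]
    for sample in results:
        for cls, expr in results[sample].items():
            lines.append(
                f"{sample}\t{cls}\t{expr.bases}\t{expr.length}"
                f"\t{expr.library_reads}\t{expr.value!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
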