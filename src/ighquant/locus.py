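"""Per-class exon interval model of the immunoglobulin heavy-chain (IGH) locus.

The IGH constant-region genes (IGHM, IGHD, IGHG1-4, IGHA1-2, IGHE) undergo
somatic rearrangement in B cells, which makes transcript-level annotation of
the locus unreliable for expression quantification.  The quantification used
here therefore works at the base level: every antibody class is represented by
the union of its annotated exon intervals, and reads are allocated to classes
by genomic overlap.  This module builds that model from a GTF or BED
annotation plus a feature-to-class map.

Coordinates are 0-based half-open everywhere internally.  GTF input (1-based,
inclusive) is shifted on read; BED input passes through unchanged.

Exons listed by several transcripts of the same class frequently overlap or
duplicate each other; by default they are collapsed to their union before the
total class length is computed, so no denominator base is counted twice.  The
``length_mode="listed"`` option retains the raw per-feature sum for
sensitivity checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class AnnotationFormatError(ValueError):
    """A line of the annotation file could not be parsed."""


class LocusValidationError(ValueError):
    """The parsed annotation does not yield a usable locus model."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals to a sorted, pairwise-disjoint cover of their union.

    The output covers exactly the union of input positions, is sorted by
    (chrom, start) and is idempotent under re-application.  Abutting intervals
    ([10,20) + [20,30)) are joined.
    """
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class LocusModel:
    """Per-class merged exon intervals and total exon lengths.

    ``classes`` maps a class identifier (e.g. ``IGHG1``, ``IGJ``) to a sorted
    list of pairwise-disjoint intervals.  ``lengths`` maps each class to its
    total exonic length in bases — the denominator of the counts-per-base
    normalization.  When built with ``length_mode="listed"`` the lengths are
    the raw per-feature sums and may exceed the union size.
    """

    classes: dict[str, list[GenomicInterval]]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classes:
            raise LocusValidationError("locus model has no classes")
        for cls, ivs in self.classes.items():
            if not ivs:
                raise LocusValidationError(f"class {cls!r} has zero intervals")
            if ivs != merge_intervals(ivs):
                raise LocusValidationError(
                    f"class {cls!r} intervals are not sorted and disjoint"
                )
        if not self.lengths:
            self.lengths = {
                cls: sum(len(iv) for iv in ivs) for cls, ivs in self.classes.items()
            }
        for cls, length in self.lengths.items():
            if length <= 0:
                raise LocusValidationError(f"class {cls!r} has non-positive length")

    def class_length(self, class_id: str) -> int:
        """Total exonic bases of ``class_id`` (sum of merged interval lengths)."""
        return self.lengths[class_id]

    # -- provenance serialization ------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": {
                cls: [[iv.chrom, iv.start, iv.end] for iv in ivs]
                for cls, ivs in self.classes.items()
            },
            "lengths": self.lengths,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LocusModel":
        payload = json.loads(Path(path).read_text())
        classes = {
            c: [GenomicInterval(ch, s, e) for ch, s, e in ivs]
            for c, ivs in payload["classes"].items()
        }
        return cls(classes=classes, lengths={k: int(v) for k, v in payload["lengths"].items()})


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping feature identifiers to class identifiers."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationFormatError(
                f"{path}: line {lineno}: expected 2 tab-separated columns"
            )
        mapping[parts[0]] = parts[1]
    return mapping


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _iter_annotation_features(path: Path, fmt: str):
    """Yield (lineno, chrom, start0, end0, feature_ids) from a GTF or BED file."""
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if fmt == "gtf":
            if len(fields) < 9:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: expected 9 GTF columns, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1  # GTF is 1-based inclusive
                end = int(fields[4])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gtf_attributes(fields[8])
            ids = [v for k, v in attrs.items() if k in ("gene_id", "gene_name", "transcript_id")]
            if not ids:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: no gene_id/gene_name/transcript_id attribute"
                )
            yield lineno, fields[0], start, end, ids
        else:  # BED4: chrom start end name, already 0-based half-open
            if len(fields) < 4:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: expected ≥4 BED columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            yield lineno, fields[0], start, end, [fields[3]]


def parse_annotation(
    annotation_path: str | Path,
    class_map: Mapping[str, str],
    *,
    fmt: str | None = None,
    length_mode: str = "union",
) -> LocusModel:
    """Build a :class:`LocusModel` from a GTF or BED exon annotation.

    Parameters
    ----------
    annotation_path:
        GTF (``.gtf``) or BED (``.bed``) file.  Format is inferred from the
        extension unless ``fmt`` is given explicitly.
    class_map:
        Feature identifier (gene_id / gene_name / transcript_id for GTF, name
        column for BED) → class identifier.  Features with no mapping are
        skipped; the skip count is logged.
    length_mode:
        ``"union"`` (default): class lengths are the merged-interval union
        size.  ``"listed"``: lengths are the raw sum of listed exon lengths,
        duplicates included (intervals are still stored merged).
    """
    if not class_map:
        raise LocusValidationError("class_map is empty: no classes to build")
    if length_mode not in ("union", "listed"):
        raise ValueError(f"unknown length_mode {length_mode!r}")
    path = Path(annotation_path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gtf"

    raw: dict[str, list[GenomicInterval]] = {}
    listed_lengths: dict[str, int] = {}
    skipped = 0
    for lineno, chrom, start, end, ids in _iter_annotation_features(path, fmt):
        cls = next((class_map[i] for i in ids if i in class_map), None)
        if cls is None:
            skipped += 1
            continue
        if start >= end:
            raise AnnotationFormatError(
                f"{path}: line {lineno}: empty or inverted interval [{start}, {end})"
            )
        raw.setdefault(cls, []).append(GenomicInterval(chrom, start, end))
        listed_lengths[cls] = listed_lengths.get(cls, 0) + (end - start)
    if skipped:
        logger.info("skipped %d features absent from class map", skipped)

    missing = sorted(set(class_map.values()) - set(raw))
    if missing:
        raise LocusValidationError(
            f"classes with zero intervals after parsing: {', '.join(missing)}"
        )
    classes = {cls: merge_intervals(ivs) for cls, ivs in sorted(raw.items())}
    lengths = listed_lengths if length_mode == "listed" else {}
    return LocusModel(classes=classes, lengths=dict(lengths))
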