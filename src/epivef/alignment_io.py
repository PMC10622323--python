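"""Alignment input/output.

Loads alignments carrying per-base methylation call strings from BAM,
projects query bases onto reference coordinates via CIGAR, and merges
mate pairs base-by-base by Phred quality into single templates, so that
every downstream count refers to sequenced DNA fragments (epihaplotypes)
rather than individual reads.

Coordinates are 0-based half-open throughout this package; report writers
convert to 1-based inclusive positions on output.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pysam

log = logging.getLogger("epivef")

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 20
DEFAULT_CALL_TAG = "XM"   # Bismark-dialect methylation call string
STRAND_TAG = "XG"         # bisulfite conversion strand: "CT" = OT, "GA" = OB

#: sentinel reference position of inserted / soft-clipped query bases
ABSENT = -1

NOCALL = ord(".")
MASKED_BASE = ord("N")

_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_VALID_OPS = frozenset("MIDNSH=X")

# pysam numeric CIGAR op codes -> characters
_PYSAM_OPS = "MIDNSHP=XB"


class FormatError(ValueError):
    """Malformed input record (CIGAR, BED line, VCF record, ...)."""


class ChimericPairError(ValueError):
    """Mates of one template map to different reference sequences."""


class MissingCallsError(ValueError):
    """Alignments carry no methylation call strings."""


# ---------------------------------------------------------------------------
# raw alignments
# ---------------------------------------------------------------------------

@dataclass
class RawAlignment:
    """One aligned read as stored in BAM (bases in reference orientation).

    ``call_string`` uses the Bismark XM dialect: '.' = no call,
    z/Z = un-/methylated CpG, x/X = CHG, h/H = CHH, u/U = unknown context.
    """

    query_name: str
    ref_name: str
    ref_start: int
    is_reverse: bool
    is_first_mate: bool
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    bases: str
    base_quals: np.ndarray
    call_string: str | None = None
    is_paired: bool = False
    bs_strand: str | None = None   # 'OT' / 'OB' when a conversion tag says so

    def __post_init__(self) -> None:
        self.base_quals = np.asarray(self.base_quals, dtype=np.uint8)
        if len(self.base_quals) != len(self.bases):
            raise FormatError(
                f"{self.query_name}: {len(self.bases)} bases but "
                f"{len(self.base_quals)} quality values")
        if self.call_string is not None and len(self.call_string) != len(self.bases):
            raise FormatError(
                f"{self.query_name}: call string length {len(self.call_string)} "
                f"!= read length {len(self.bases)}")

    @classmethod
    def from_pysam(cls, seg: pysam.AlignedSegment,
                   tag: str = DEFAULT_CALL_TAG) -> "RawAlignment":
        cigar = tuple((_PYSAM_OPS[op], length) for op, length in seg.cigartuples)
        call = seg.get_tag(tag) if seg.has_tag(tag) else None
        bs_strand = None
        if seg.has_tag(STRAND_TAG):
            xg = seg.get_tag(STRAND_TAG)
            bs_strand = {"CT": "OT", "GA": "OB"}.get(xg)
        return cls(
            query_name=seg.query_name,
            ref_name=seg.reference_name,
            ref_start=seg.reference_start,
            is_reverse=seg.is_reverse,
            is_first_mate=(seg.is_read1 or not seg.is_paired),
            mapq=seg.mapping_quality,
            cigar=cigar,
            bases=seg.query_sequence,
            base_quals=np.asarray(seg.query_qualities, dtype=np.uint8),
            call_string=call,
            is_paired=seg.is_paired,
            bs_strand=bs_strand,
        )


def flag_strand(aln: RawAlignment) -> str:
    """Bisulfite conversion strand from FLAG under the directional protocol.

    First mates read the strand the fragment derives from: forward -> OT
    (original top, methylation at reference C), reverse -> OB (original
    bottom, methylation at reference G). Second mates are sequenced from
    the opposite end, so the mapping is inverted. A conversion tag stored
    on the record (``bs_strand``) takes precedence.
    """
    if aln.bs_strand is not None:
        return aln.bs_strand
    if not aln.is_paired or aln.is_first_mate:
        return "OB" if aln.is_reverse else "OT"
    return "OT" if aln.is_reverse else "OB"


# ---------------------------------------------------------------------------
# CIGAR projection
# ---------------------------------------------------------------------------

class ProjectedBase(NamedTuple):
    ref_pos: int   # ABSENT (-1) for insertions / soft clips
    base: str
    qual: int
    call: str


class Projection(Sequence):
    """Array-backed sequence of :class:`ProjectedBase`, one per query base."""

    __slots__ = ("ref_pos", "base", "qual", "call")

    def __init__(self, ref_pos: np.ndarray, base: np.ndarray,
                 qual: np.ndarray, call: np.ndarray) -> None:
        self.ref_pos = ref_pos
        self.base = base
        self.qual = qual
        self.call = call

    def __len__(self) -> int:
        return len(self.ref_pos)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return ProjectedBase(int(self.ref_pos[i]), chr(self.base[i]),
                             int(self.qual[i]), chr(self.call[i]))

    def anchored(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays restricted to reference-anchored bases (ref_pos != ABSENT)."""
        keep = self.ref_pos != ABSENT
        return (self.ref_pos[keep], self.base[keep],
                self.qual[keep], self.call[keep])


def project_to_reference(aln: RawAlignment) -> Projection:
    """Resolve the CIGAR into one :class:`ProjectedBase` per query base.

    M/=/X bases receive their reference coordinate; I and S bases carry
    :data:`ABSENT`; D and N consume reference only; H is ignored.
    """
    n_query = 0
    for op, length in aln.cigar:
        if op not in _VALID_OPS:
            raise FormatError(f"{aln.query_name}: invalid CIGAR op {op!r}")
        if length <= 0:
            raise FormatError(f"{aln.query_name}: non-positive CIGAR length")
        if op in _QUERY_OPS:
            n_query += length
    if n_query != len(aln.bases):
        raise FormatError(
            f"{aln.query_name}: CIGAR consumes {n_query} query bases "
            f"but read has {len(aln.bases)}")

    ref_pos = np.empty(n_query, dtype=np.int64)
    q = 0
    r = aln.ref_start
    for op, length in aln.cigar:
        if op in "M=X":
            ref_pos[q:q + length] = np.arange(r, r + length)
            q += length
            r += length
        elif op in "IS":
            ref_pos[q:q + length] = ABSENT
            q += length
        elif op in "DN":
            r += length
        # H consumes neither

    base = np.frombuffer(aln.bases.encode("ascii"), dtype=np.uint8).copy()
    if aln.call_string is None:
        call = np.full(n_query, NOCALL, dtype=np.uint8)
    else:
        call = np.frombuffer(aln.call_string.encode("ascii"), dtype=np.uint8).copy()
    return Projection(ref_pos, base, aln.base_quals.copy(), call)


# ---------------------------------------------------------------------------
# merged templates
# ---------------------------------------------------------------------------

@dataclass
class MergedTemplate:
    """One sequenced DNA fragment after mate merging.

    ``pos`` is strictly increasing; each reference position appears once
    (mate overlap resolved by Phred quality). Only reference-anchored bases
    are retained — insertions and soft clips are excluded from all reports.
    """

    name: str
    ref_name: str
    source: str                     # 'single' | 'merged_pair'
    bs_strand: str | None
    pos: np.ndarray                 # int64
    base: np.ndarray                # uint8, ASCII
    qual: np.ndarray                # uint8
    call: np.ndarray                # uint8, ASCII; NOCALL when absent

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference interval covered by this template."""
        return int(self.pos[0]), int(self.pos[-1]) + 1

    @property
    def base_str(self) -> str:
        return self.base.tobytes().decode("ascii")

    @property
    def call_str(self) -> str:
        return self.call.tobytes().decode("ascii")


def merge_single(aln: RawAlignment) -> MergedTemplate:
    pos, base, qual, call = project_to_reference(aln).anchored()
    if len(pos) == 0:
        raise FormatError(f"{aln.query_name}: no reference-anchored bases")
    return MergedTemplate(aln.query_name, aln.ref_name, "single",
                          flag_strand(aln), pos, base, qual, call)


def merge_mates(first: RawAlignment, second: RawAlignment) -> MergedTemplate:
    """Merge a mate pair into one template, base-by-base by Phred quality.

    Positions covered by one mate keep that mate's base/qual/call triple;
    positions covered by both keep the triple of the mate with the strictly
    higher base quality, the first mate winning ties.
    """
    if first.query_name != second.query_name:
        raise ValueError(
            f"cannot merge {first.query_name!r} with {second.query_name!r}")
    if first.ref_name != second.ref_name:
        raise ChimericPairError(
            f"{first.query_name}: mates on {first.ref_name} and {second.ref_name}")

    pos1, base1, qual1, call1 = project_to_reference(first).anchored()
    pos2, base2, qual2, call2 = project_to_reference(second).anchored()

    common, i1, i2 = np.intersect1d(pos1, pos2, return_indices=True)
    if len(common):
        take2 = qual2[i2] > qual1[i1]   # strict: first mate wins ties
        base1 = base1.copy(); qual1 = qual1.copy(); call1 = call1.copy()
        base1[i1[take2]] = base2[i2[take2]]
        qual1[i1[take2]] = qual2[i2[take2]]
        call1[i1[take2]] = call2[i2[take2]]
        only2 = np.ones(len(pos2), dtype=bool)
        only2[i2] = False
    else:
        only2 = np.ones(len(pos2), dtype=bool)

    pos = np.concatenate([pos1, pos2[only2]])
    base = np.concatenate([base1, base2[only2]])
    qual = np.concatenate([qual1, qual2[only2]])
    call = np.concatenate([call1, call2[only2]])
    order = np.argsort(pos, kind="stable")
    return MergedTemplate(first.query_name, first.ref_name, "merged_pair",
                          flag_strand(first),
                          pos[order], base[order], qual[order], call[order])


def mask_low_quality(template: MergedTemplate, min_baseq: int) -> MergedTemplate:
    """Mask bases below ``min_baseq`` (base -> N, call -> '.') in place.

    Masked positions contribute to no count — neither C nor T — but the
    template itself is retained.
    """
    if min_baseq > 0:
        low = template.qual < min_baseq
        if low.any():
            template.base[low] = MASKED_BASE
            template.call[low] = NOCALL
    return template


def templates_from_pairs(
    pairs: Iterable[tuple[RawAlignment, ...]],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> list[MergedTemplate]:
    """Merge in-memory read pairs (or 1-tuples) into masked templates.

    Alignments with ``mapq < min_mapq`` are dropped individually; a pair
    whose both mates fail produces no template, a pair with one surviving
    mate is processed single-end. Chimeric pairs are skipped with a warning.
    """
    out: list[MergedTemplate] = []
    n_chimeric = 0
    for pair in pairs:
        kept = [a for a in pair if a.mapq >= min_mapq]
        if not kept:
            continue
        try:
            if len(kept) == 2:
                t = merge_mates(kept[0], kept[1])
            else:
                t = merge_single(kept[0])
        except ChimericPairError:
            n_chimeric += 1
            continue
        out.append(mask_low_quality(t, min_baseq))
    if n_chimeric:
        log.warning("skipped %d chimeric mate pairs", n_chimeric)
    return out


# ---------------------------------------------------------------------------
# BAM reading
# ---------------------------------------------------------------------------

def load_raw_alignments(bam_path: str | Path, tag: str = DEFAULT_CALL_TAG,
                        threads: int = 1) -> Iterator[RawAlignment]:
    """Yield primary mapped alignments (no filtering beyond record flags)."""
    with pysam.AlignmentFile(str(bam_path), "rb", threads=threads,
                             check_sq=False) as bam:
        for seg in bam:
            if (seg.is_unmapped or seg.is_secondary or
                    seg.is_supplementary or seg.is_duplicate):
                continue
            yield RawAlignment.from_pysam(seg, tag=tag)


def pair_alignments(
    alns: Iterable[RawAlignment],
) -> Iterator[tuple[RawAlignment, ...]]:
    """Group alignments into mate pairs by query name.

    Works on coordinate- or name-sorted input (the full file is buffered).
    Orphaned mates and single-end reads are yielded as 1-tuples; the
    orphan count is logged.
    """
    waiting: dict[str, RawAlignment] = {}
    n_orphans = 0
    for aln in alns:
        if not aln.is_paired:
            yield (aln,)
            continue
        mate = waiting.pop(aln.query_name, None)
        if mate is None:
            waiting[aln.query_name] = aln
        elif mate.is_first_mate:
            yield (mate, aln)
        else:
            yield (aln, mate)
    for aln in waiting.values():
        n_orphans += 1
        yield (aln,)
    if n_orphans:
        log.warning("processed %d orphaned mates as single-end templates",
                    n_orphans)


def load_templates(
    bam_path: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    tag: str = DEFAULT_CALL_TAG,
    require_calls: bool = True,
    threads: int = 1,
) -> list[MergedTemplate]:
    """Load, pair, merge and quality-mask templates from a BAM file.

    Unmapped, secondary, supplementary and duplicate-flagged records are
    dropped; alignments with ``mapq < min_mapq`` are dropped; bases with
    quality below ``min_baseq`` are masked but the template retained.
    """
    alns = list(load_raw_alignments(bam_path, tag=tag, threads=threads))
    if require_calls and alns and all(a.call_string is None for a in alns):
        raise MissingCallsError(
            f"{bam_path}: no methylation calls in tag {tag!r}; run the "
            f"'call' subcommand with a reference FASTA first")
    return templates_from_pairs(pair_alignments(alns),
                                min_mapq=min_mapq, min_baseq=min_baseq)


# ---------------------------------------------------------------------------
# BAM writing
# ---------------------------------------------------------------------------

def _header(ref_lengths: dict[str, int]) -> dict:
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length}
                   for name, length in ref_lengths.items()]}


def _strand_tag_value(bs_strand: str | None) -> str | None:
    return {"OT": "CT", "OB": "GA"}.get(bs_strand) if bs_strand else None


def write_pairs(bam_path: str | Path,
                pairs: Iterable[tuple[RawAlignment, ...]],
                ref_lengths: dict[str, int],
                tag: str = DEFAULT_CALL_TAG) -> None:
    """Write read pairs to a coordinate-sorted, indexed BAM file."""
    bam_path = str(bam_path)
    header = pysam.AlignmentHeader.from_dict(_header(ref_lengths))
    tid = {name: i for i, name in enumerate(ref_lengths)}
    records = []
    for pair in pairs:
        for i, aln in enumerate(pair):
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.query_name
            seg.reference_id = tid[aln.ref_name]
            seg.reference_start = aln.ref_start
            seg.mapping_quality = aln.mapq
            seg.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
            seg.query_sequence = aln.bases
            seg.query_qualities = [int(q) for q in aln.base_quals]
            flag = 0
            if aln.is_reverse:
                flag |= 0x10
            if len(pair) == 2:
                mate = pair[1 - i]
                flag |= 0x1 | 0x2
                flag |= 0x40 if aln.is_first_mate else 0x80
                if mate.is_reverse:
                    flag |= 0x20
                seg.next_reference_id = tid[mate.ref_name]
                seg.next_reference_start = mate.ref_start
            seg.flag = flag
            tags = []
            if aln.call_string is not None:
                tags.append((tag, aln.call_string))
            xg = _strand_tag_value(aln.bs_strand or flag_strand(aln))
            if xg:
                tags.append((STRAND_TAG, xg))
            seg.set_tags(tags)
            records.append(seg)
    records.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for seg in records:
            out.write(seg)
    pysam.index(bam_path)


def _template_cigar(pos: np.ndarray) -> str:
    """M/D CIGAR string reproducing the (possibly gapped) position run."""
    parts = []
    gaps = np.flatnonzero(np.diff(pos) > 1)
    prev = 0
    for g in gaps:
        parts.append(f"{g + 1 - prev}M{int(pos[g + 1] - pos[g] - 1)}D")
        prev = g + 1
    parts.append(f"{len(pos) - prev}M")
    return "".join(parts)


def write_templates(bam_path: str | Path,
                    templates: Iterable[MergedTemplate],
                    ref_lengths: dict[str, int],
                    tag: str = DEFAULT_CALL_TAG) -> None:
    """Write merged templates back to BAM as single-end records.

    Reloading such a file with ``min_mapq=0, min_baseq=0`` reproduces the
    projected (position, base, quality, call) arrays exactly.
    """
    bam_path = str(bam_path)
    header = pysam.AlignmentHeader.from_dict(_header(ref_lengths))
    tid = {name: i for i, name in enumerate(ref_lengths)}
    records = []
    for t in templates:
        seg = pysam.AlignedSegment(header)
        seg.query_name = t.name
        seg.reference_id = tid[t.ref_name]
        seg.reference_start = int(t.pos[0])
        seg.mapping_quality = 60
        seg.flag = 0
        seg.cigarstring = _template_cigar(t.pos)
        seg.query_sequence = t.base_str
        seg.query_qualities = [int(q) for q in t.qual]
        tags = [(tag, t.call_str)]
        xg = _strand_tag_value(t.bs_strand)
        if xg:
            tags.append((STRAND_TAG, xg))
        seg.set_tags(tags)
        records.append(seg)
    records.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for seg in records:
            out.write(seg)
    pysam.index(bam_path)
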