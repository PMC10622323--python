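"""Bisulfite read simulator with known ground truth.

Generates paired-end directional-protocol bisulfite alignments on a
synthetic reference: fragments are sampled uniformly (optionally within
amplicon regions), each fragment molecule draws per-CpG methylation
states i.i.d. and converts unmethylated cytosines, reads are cut from the
fragment ends with exponentially decaying Phred qualities and optional
substitution errors concentrated towards the 3' end. Two special
constructions mirror common benchmarking designs: duplicating every pair
as a fully converted copy at identical coordinates (producing a cytosine
conversion rate of exactly 50% wherever the input was fully methylated),
and admixing fully methylated fragments into a background at a chosen
fraction (low-frequency epimutation spike-ins).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace
from typing import TypeVar

import numpy as np
import pandas as pd

from .alignment_io import RawAlignment, flag_strand
from .methylation_calling import (CONTEXT_UPPER, ReferenceWindow,
                                  call_methylation)

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_Z = CONTEXT_UPPER["CG"]

Pair = tuple[RawAlignment, RawAlignment]
_SetT = TypeVar("_SetT")


@dataclass(frozen=True)
class SimProfile:
    """Simulation conditions for one read set.

    ``cg_methylation`` is the per-CpG probability that a fragment molecule
    is methylated at that CpG; ``ch_conversion`` the probability a non-CpG
    cytosine is converted (residual non-CpG methylation = 1 − ch_conversion).
    Base qualities follow Q(i) = floor + (start − floor)·exp(−i/decay) along
    the read; substitution errors are drawn per base with probabilities
    proportional to the quality-implied error, scaled to average
    ``error_rate`` over the read.
    """

    n_templates: int
    read_len: int = 151
    fragment_len: tuple[int, int] = (70, 400)
    cg_methylation: float = 0.0
    ch_conversion: float = 0.995
    error_rate: float = 0.0
    qual_start: float = 40.0
    qual_floor: float = 5.0
    qual_decay: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_len
        if not 1 <= lo <= hi:
            raise ValueError("invalid fragment length range")
        if self.read_len > hi:
            raise ValueError("read_len exceeds maximum fragment length")
        for name in ("cg_methylation", "ch_conversion", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def make_reference(length: int, gc_fraction: float = 0.5, seed: int = 0,
                   ref_name: str = "sim1") -> ReferenceWindow:
    """Reproducible random reference with exact GC content.

    The base multiset is fixed to the requested composition and shuffled,
    so GC content is exact to rounding. With near-balanced composition the
    expected CpG density is (gc/2)^2 per dinucleotide — ~6 CpGs per 100 bp
    at gc = 0.5, comfortably above 1 per 100 bp.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_gc = round(length * gc_fraction)
    n_at = length - n_gc
    arr = np.empty(length, dtype=np.uint8)
    arr[:n_gc // 2] = _G
    arr[n_gc // 2:n_gc] = _C
    arr[n_gc:n_gc + n_at // 2] = _A
    arr[n_gc + n_at // 2:] = _T
    rng.shuffle(arr)
    return ReferenceWindow(ref_name, 0, arr.tobytes().decode("ascii"))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _qual_profile(profile: SimProfile) -> np.ndarray:
    i = np.arange(profile.read_len)
    q = profile.qual_floor + (profile.qual_start - profile.qual_floor) * \
        np.exp(-i / profile.qual_decay)
    return np.maximum(q, profile.qual_floor).round().astype(np.uint8)


def _error_profile(profile: SimProfile, quals: np.ndarray) -> np.ndarray:
    """Per-cycle substitution probability, mean ``error_rate``, 3'-heavy."""
    w = 10.0 ** (-quals.astype(float) / 10.0)
    return profile.error_rate * w / w.mean()


def simulate_templates(
    ref: ReferenceWindow,
    profile: SimProfile,
    regions: Sequence[tuple[str, int, int]] | None = None,
    name_prefix: str = "sim",
) -> tuple[list[Pair], pd.DataFrame]:
    """Simulate read pairs and return them with a per-template truth table.

    Fragments are placed uniformly on the reference, or uniformly within
    the given 0-based half-open ``regions`` (amplicon mode, fragment
    length clipped to the region). Each fragment derives from the top
    (OT) or bottom (OB) strand with equal probability. Reads are cut from
    the fragment ends; fragments shorter than the read length yield
    fully overlapping truncated mates, as in real data. Methylation call
    strings are embedded by calling against the simulated reference.

    The truth table has one row per template: name, strand, fragment
    coordinates, CpG / non-CpG cytosine counts and how many of each were
    methylated on the molecule.
    """
    rng = np.random.default_rng(profile.seed)
    arr = ref.arr
    plus_codes, minus_codes = ref.context_codes
    is_c = arr == _C
    is_g = arr == _G
    lo, hi = profile.fragment_len
    rl = profile.read_len
    quals = _qual_profile(profile)
    errp = _error_profile(profile, quals) if profile.error_rate > 0 else None

    if regions is not None:
        for chrom, s, e in regions:
            if chrom != ref.ref_name or s < ref.start or e > ref.end:
                raise ValueError(f"region {chrom}:{s}-{e} outside reference")
            if e - s < lo:
                raise ValueError("region shorter than minimum fragment")

    pairs: list[Pair] = []
    truth_rows = []
    for i in range(profile.n_templates):
        if regions is not None:
            chrom, rs, re_ = regions[rng.integers(len(regions))]
            frag_len = int(rng.integers(lo, min(hi, re_ - rs) + 1))
            start = int(rng.integers(rs, re_ - frag_len + 1)) - ref.start
        else:
            frag_len = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, len(arr) - frag_len + 1))
        end = start + frag_len
        strand = "OT" if rng.random() < 0.5 else "OB"

        frag = arr[start:end].copy()
        if strand == "OT":
            cloc = np.flatnonzero(is_c[start:end])
            codes = plus_codes[start + cloc]
            converted_base = _T
        else:
            cloc = np.flatnonzero(is_g[start:end])
            codes = minus_codes[start + cloc]
            converted_base = _A
        is_cpg = codes == _Z
        meth = np.empty(len(cloc), dtype=bool)
        n_cpg = int(is_cpg.sum())
        meth[is_cpg] = rng.random(n_cpg) < profile.cg_methylation
        meth[~is_cpg] = rng.random(len(cloc) - n_cpg) >= profile.ch_conversion
        frag[cloc[~meth]] = converted_base

        name = f"{name_prefix}{i:08d}"
        eff_rl = min(rl, frag_len)
        # mate layout: read1 starts at the 5' end of the sequenced strand
        if strand == "OT":
            layout = ((start, False, True), (end - eff_rl, True, False))
        else:
            layout = ((end - eff_rl, True, True), (start, False, False))
        mates = []
        for m_start, m_rev, m_first in layout:
            bases = frag[m_start - start:m_start - start + eff_rl].copy()
            q = quals[:eff_rl]
            if m_rev:   # stored in reference orientation; 5' end is on the right
                q = q[::-1]
            if errp is not None:
                p = errp[:eff_rl][::-1] if m_rev else errp[:eff_rl]
                hit = np.flatnonzero(rng.random(eff_rl) < p)
                if len(hit):
                    shift = rng.integers(1, 4, size=len(hit))
                    idx = _base_index(bases[hit])
                    bases[hit] = _INDEX_BASE[(idx + shift) % 4]
            aln = RawAlignment(
                query_name=name, ref_name=ref.ref_name,
                ref_start=ref.start + m_start, is_reverse=bool(m_rev),
                is_first_mate=m_first, mapq=60,
                cigar=(("M", eff_rl),),
                bases=bases.tobytes().decode("ascii"),
                base_quals=q.copy(), is_paired=True, bs_strand=strand)
            mates.append(call_methylation(aln, ref, strand=strand))
        pairs.append((mates[0], mates[1]))
        truth_rows.append({
            "name": name, "strand": strand,
            "frag_start": ref.start + start, "frag_end": ref.start + end,
            "n_cpg": n_cpg, "n_cpg_meth": int(meth[is_cpg].sum()),
            "n_ch": len(cloc) - n_cpg,
            "n_ch_meth": int(meth[~is_cpg].sum()),
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "name", "strand", "frag_start", "frag_end",
        "n_cpg", "n_cpg_meth", "n_ch", "n_ch_meth"])
    return pairs, truth


_INDEX_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _base_index(bases: np.ndarray) -> np.ndarray:
    idx = np.zeros(len(bases), dtype=np.int64)
    idx[bases == _C] = 1
    idx[bases == _G] = 2
    idx[bases == _T] = 3
    return idx


# ---------------------------------------------------------------------------
# benchmark constructions
# ---------------------------------------------------------------------------

def duplicate_as_converted(pairs: Sequence[Pair]) -> list[Pair]:
    """Each input pair plus a fully converted copy at identical coordinates.

    The copy converts every convertible base of the sequenced strand
    (C -> T on OT templates, G -> A on OB, in any context), i.e., it is a
    fully unmethylated clone of the fragment; its methylation calls are
    the lower-cased originals. On fully methylated error-free input, the
    merged set therefore has beta exactly 0.5 at every covered cytosine.
    """
    out: list[Pair] = list(pairs)
    for pair in pairs:
        strand = flag_strand(pair[0])
        src, dst = ("C", "T") if strand == "OT" else ("G", "A")
        out.append(tuple(
            replace(a, query_name=a.query_name + "|conv",
                    bases=a.bases.replace(src, dst),
                    call_string=None if a.call_string is None
                    else a.call_string.lower())
            for a in pair))
    return out


def admix(background: Sequence[_SetT], methylated: Sequence[_SetT],
          fraction: float, seed: int = 0) -> list[_SetT]:
    """Background plus methylated templates spiked at ``fraction``.

    Adds round(fraction·|background|/(1−fraction)) templates sampled
    without replacement from ``methylated`` (renamed to stay unique), so
    the spiked proportion of the output equals ``fraction`` to rounding.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    n_add = round(fraction * len(background) / (1.0 - fraction))
    if n_add > len(methylated):
        raise ValueError(
            f"need {n_add} methylated templates, have {len(methylated)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(methylated), size=n_add, replace=False)
    out = list(background)
    for k, j in enumerate(picked):
        item = methylated[j]
        if isinstance(item, tuple):
            out.append(tuple(replace(a, query_name=f"{a.query_name}|s{k}")
                             for a in item))
        else:
            out.append(replace(item, name=f"{item.name}|s{k}"))
    return out


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def tile_regions(ref: ReferenceWindow, n_regions: int,
                 region_len: int = 400, spacing: int = 2000
                 ) -> list[tuple[str, int, int]]:
    """Evenly spaced amplicon-sized regions on a simulated reference."""
    need = n_regions * spacing
    if need > len(ref):
        raise ValueError("reference too short for requested panel")
    offset = (len(ref) - need) // 2 + (spacing - region_len) // 2
    return [(ref.ref_name, ref.start + offset + i * spacing,
             ref.start + offset + i * spacing + region_len)
            for i in range(n_regions)]


def truth_to_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)
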