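"""Reference-based methylation calling and reference-free context voting.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as
T) while methylated cytosines resist conversion. On an original-top (OT)
strand alignment, methylation is therefore read at reference C positions
(read C = methylated, read T = converted); on an original-bottom (OB)
strand alignment, symmetrically at reference G positions (read G / read
A), with the sequence context taken on the reverse complement.

Call characters follow the Bismark XM dialect: upper case = methylated,
lower case = unmethylated; Z/z = CpG, X/x = CHG, H/h = CHH, U/u = unknown
context (window edge or N in the trinucleotide), '.' = not a cytosine of
the converted strand / no call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Mapping

import numpy as np

from .alignment_io import (ABSENT, NOCALL, RawAlignment, flag_strand,
                           project_to_reference)

CONTEXTS = ("CG", "CHG", "CHH")

#: methylated (upper-case) call code per context; +32 gives the
#: unmethylated lower-case code
CONTEXT_UPPER = {"CG": ord("Z"), "CHG": ord("X"), "CHH": ord("H")}
UNKNOWN_UPPER = ord("U")

CALL_CONTEXT = {ord("z"): "CG", ord("Z"): "CG",
                ord("x"): "CHG", ord("X"): "CHG",
                ord("h"): "CHH", ord("H"): "CHH"}

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


class NoContextError(ValueError):
    """A position has no informative context observation."""


class ReferenceBoundsError(ValueError):
    """An alignment extends beyond the supplied reference window."""


# ---------------------------------------------------------------------------
# reference windows and their cytosine contexts
# ---------------------------------------------------------------------------

@dataclass
class ReferenceWindow:
    """A slice of reference sequence anchored at a 0-based coordinate."""

    ref_name: str
    start: int
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty reference window")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @cached_property
    def arr(self) -> np.ndarray:
        return np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)

    def base(self, ref_pos: int) -> str:
        if not self.start <= ref_pos < self.end:
            raise ReferenceBoundsError(
                f"position {ref_pos} outside window "
                f"{self.ref_name}:{self.start}-{self.end}")
        return self.seq[ref_pos - self.start]

    @cached_property
    def context_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-position methylated call codes for the + and − strands.

        ``plus[i]`` is Z/X/H/U at reference C positions (0 elsewhere);
        ``minus[i]`` likewise at reference G positions, with the context
        read on the reverse complement (towards lower coordinates).
        """
        return _context_codes(self.arr)


def _context_codes(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(arr)
    known = (arr == _A) | (arr == _C) | (arr == _G) | (arr == _T)

    def shifted(offset: int) -> tuple[np.ndarray, np.ndarray]:
        """(base, known) arrays displaced by ``offset``; edges unknown."""
        out = np.zeros(n, dtype=np.uint8)
        ok = np.zeros(n, dtype=bool)
        if offset > 0 and offset < n:
            out[:-offset] = arr[offset:]
            ok[:-offset] = known[offset:]
        elif offset < 0 and -offset < n:
            out[-offset:] = arr[:offset]
            ok[-offset:] = known[:offset]
        return out, ok

    def codes(is_site: np.ndarray, c1: np.ndarray, ok1: np.ndarray,
              c2: np.ndarray, ok2: np.ndarray, partner: int) -> np.ndarray:
        out = np.zeros(n, dtype=np.uint8)
        out[is_site & ok1 & (c1 == partner)] = CONTEXT_UPPER["CG"]
        rest = is_site & ok1 & (c1 != partner)
        out[rest & ok2 & (c2 == partner)] = CONTEXT_UPPER["CHG"]
        out[rest & ok2 & (c2 != partner)] = CONTEXT_UPPER["CHH"]
        out[is_site & ~ok1] = UNKNOWN_UPPER
        out[rest & ~ok2] = UNKNOWN_UPPER
        return out

    # + strand: cytosine at reference C, context from the next two bases
    c1, ok1 = shifted(1)
    c2, ok2 = shifted(2)
    plus = codes(arr == _C, c1, ok1, c2, ok2, _G)
    # − strand: cytosine at reference G; on the reverse complement the next
    # base is the complement of the previous reference base, so CG requires
    # a C immediately 5' of the G, CHG a C two bases 5'.
    p1, okp1 = shifted(-1)
    p2, okp2 = shifted(-2)
    minus = codes(arr == _G, p1, okp1, p2, okp2, _C)
    return plus, minus


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def infer_bisulfite_strand(aln: RawAlignment) -> str:
    """OT or OB under the directional protocol; a conversion tag wins."""
    return flag_strand(aln)


def call_methylation(aln: RawAlignment, ref: ReferenceWindow,
                     strand: str | None = None) -> RawAlignment:
    """Return a copy of ``aln`` with a freshly computed call string.

    Exactly one call character is emitted per query base; calls other than
    '.' occur only at reference C (OT) or reference G (OB) positions.
    """
    if strand is None:
        strand = infer_bisulfite_strand(aln)
    proj = project_to_reference(aln)
    anchored = proj.ref_pos != ABSENT
    pos = proj.ref_pos[anchored] - ref.start
    if len(pos) and (pos.min() < 0 or pos.max() >= len(ref)):
        raise ReferenceBoundsError(
            f"{aln.query_name}: alignment spans outside reference window "
            f"{ref.ref_name}:{ref.start}-{ref.end}")

    plus, minus = ref.context_codes
    if strand == "OT":
        ctx = plus[pos]
        meth_base, unmeth_base = _C, _T
    elif strand == "OB":
        ctx = minus[pos]
        meth_base, unmeth_base = _G, _A
    else:
        raise ValueError(f"unknown bisulfite strand {strand!r}")

    read = proj.base[anchored]
    call = np.full(len(pos), NOCALL, dtype=np.uint8)
    informative = ctx > 0
    call[informative & (read == meth_base)] = ctx[informative & (read == meth_base)]
    unmeth = informative & (read == unmeth_base)
    call[unmeth] = ctx[unmeth] + 32  # lower-case

    full = np.full(len(proj), NOCALL, dtype=np.uint8)
    full[np.flatnonzero(anchored)] = call
    return replace(aln, call_string=full.tobytes().decode("ascii"),
                   bs_strand=strand)


# ---------------------------------------------------------------------------
# reference-free context determination
# ---------------------------------------------------------------------------

def vote_context(counts: Mapping[str, int]) -> str:
    """Majority context across reads; ties broken CG > CHG > CHH.

    ``counts`` maps context names to observation counts at one position.
    """
    total = sum(counts.get(c, 0) for c in CONTEXTS)
    if total <= 0:
        raise NoContextError("no informative context observations")
    return max(CONTEXTS, key=lambda c: (counts.get(c, 0), -CONTEXTS.index(c)))


def tally_contexts(call_codes: np.ndarray) -> Counter:
    """Count definite contexts among a position's call characters."""
    tally: Counter = Counter()
    for code, count in zip(*np.unique(call_codes, return_counts=True)):
        ctx = CALL_CONTEXT.get(int(code))
        if ctx is not None:
            tally[ctx] += int(count)
    return tally


# ---------------------------------------------------------------------------
# whole-file calling (the `call` subcommand)
# ---------------------------------------------------------------------------

def call_bam(in_bam: str, out_bam: str, fasta_path: str,
             tag: str = "XM", threads: int = 1) -> int:
    """Call methylation for every record of a BAM against a FASTA reference.

    Writes the call string into ``tag`` (and the conversion strand into XG),
    leaving all other fields untouched. Returns the number of records called.
    Records whose strand cannot be reconciled are copied uncalled and counted.
    """
    import pysam

    from .alignment_io import STRAND_TAG

    n_called = 0
    windows: dict[str, ReferenceWindow] = {}
    with pysam.FastaFile(fasta_path) as fasta, \
            pysam.AlignmentFile(in_bam, "rb", threads=threads) as src, \
            pysam.AlignmentFile(out_bam, "wb", template=src) as dst:
        for seg in src:
            if seg.is_unmapped or seg.query_sequence is None:
                dst.write(seg)
                continue
            rname = seg.reference_name
            if rname not in windows:
                windows[rname] = ReferenceWindow(rname, 0, fasta.fetch(rname))
            aln = RawAlignment.from_pysam(seg, tag=tag)
            called = call_methylation(aln, windows[rname])
            seg.set_tag(tag, called.call_string)
            seg.set_tag(STRAND_TAG, {"OT": "CT", "OB": "GA"}[called.bs_strand])
            dst.write(seg)
            n_called += 1
    return n_called
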