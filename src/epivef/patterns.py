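"""Epiallele (methylation pattern) extraction with stable FNV-1a identifiers.

Each distinct ordered set of (position, methylation state) elements over a
queried region is one epiallele. Patterns may additionally include
non-cytosine bases of interest (e.g., a SNV position), in which case the
observed base symbol becomes the element state. The identifier is a 64-bit
FNV-1a hash of a canonical serialization and depends only on the elements
— never on read names, qualities, or input order — so a pattern of high
interest can be tracked across samples and studies.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import MASKED_BASE, MergedTemplate
from .methylation_calling import CONTEXT_UPPER, CONTEXTS

FNV64_OFFSET_BASIS = 14695981039346656037
FNV64_PRIME = 1099511628211
_MASK64 = (1 << 64) - 1

Element = tuple[int, str]   # (1-based position, 'M'/'U' or a base symbol)


@dataclass(frozen=True)
class Pattern:
    """One epiallele: its elements, per-read beta, id and multiplicity."""

    ref_name: str
    elements: tuple[Element, ...]
    n_context_sites: int
    mean_beta: float
    pattern_id: int
    multiplicity: int

    def elements_str(self) -> str:
        return ";".join(f"{p}={s}" for p, s in self.elements)


def fnv1a(data: bytes) -> int:
    """64-bit FNV-1a over a byte string."""
    h = FNV64_OFFSET_BASIS
    for b in data:
        h = ((h ^ b) * FNV64_PRIME) & _MASK64
    return h


def serialize_elements(elements: Iterable[Element]) -> bytes:
    """Canonical byte layout: per element (ascending position order), the
    decimal position text, one ':' separator byte, the state symbol byte."""
    return b"".join(f"{pos}:{state}".encode("ascii")
                    for pos, state in sorted(elements))


def fnv1a_id(elements: Iterable[Element]) -> int:
    """Stable pattern identifier; the empty pattern hashes to the offset basis."""
    return fnv1a(serialize_elements(elements))


def per_read_beta(template: MergedTemplate, context: str = "CG") -> float:
    """Mean methylation over the template's calls of one context; NaN if none."""
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    upper = CONTEXT_UPPER[context]
    counts = np.bincount(template.call, minlength=128)
    m, u = int(counts[upper]), int(counts[upper + 32])
    return m / (m + u) if m + u else math.nan


def extract_patterns(
    templates: Iterable[MergedTemplate],
    region: tuple[str, int, int],
    context: str = "CG",
    extra_positions: Sequence[int] | None = None,
) -> list[Pattern]:
    """All distinct epialleles over ``region`` (0-based half-open).

    Elements are the template's definite calls of ``context`` inside the
    region (state M/U), plus any requested 1-based ``extra_positions``
    carrying the observed base symbol. Templates contributing no element
    are skipped. Patterns are clipped to the region and sorted by
    descending multiplicity, then pattern id.
    """
    chrom, start, end = region
    if start >= end:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    extra0 = sorted(p - 1 for p in extra_positions) if extra_positions else []
    for p in extra0:
        if not start <= p < end:
            raise ValueError(f"extra position {p + 1} outside region")
    upper = CONTEXT_UPPER[context]
    lower = upper + 32

    buckets: dict[tuple[Element, ...], int] = {}
    for t in templates:
        if t.ref_name != chrom:
            continue
        t_start, t_end = t.span
        if t_start >= end or t_end <= start:
            continue
        sel = ((t.call == upper) | (t.call == lower)) & \
            (t.pos >= start) & (t.pos < end)
        elements = [(int(p) + 1, "M" if c == upper else "U")
                    for p, c in zip(t.pos[sel], t.call[sel])]
        for p0 in extra0:
            i = np.searchsorted(t.pos, p0)
            if i < len(t.pos) and t.pos[i] == p0 and t.base[i] != MASKED_BASE:
                elements.append((p0 + 1, chr(t.base[i])))
        if not elements:
            continue
        key = tuple(sorted(elements))
        buckets[key] = buckets.get(key, 0) + 1

    patterns = []
    for elements, mult in buckets.items():
        states = [s for _, s in elements if s in "MU"]
        n_meth = sum(s == "M" for s in states)
        patterns.append(Pattern(
            ref_name=chrom,
            elements=elements,
            n_context_sites=len(states),
            mean_beta=n_meth / len(states) if states else math.nan,
            pattern_id=fnv1a_id(elements),
            multiplicity=mult,
        ))
    patterns.sort(key=lambda p: (-p.multiplicity, p.pattern_id))
    return patterns


def patterns_to_frame(patterns: Sequence[Pattern]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pattern_id": p.pattern_id, "multiplicity": p.multiplicity,
          "n_sites": p.n_context_sites, "mean_beta": p.mean_beta,
          "elements": p.elements_str()} for p in patterns],
        columns=["pattern_id", "multiplicity", "n_sites", "mean_beta",
                 "elements"])
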