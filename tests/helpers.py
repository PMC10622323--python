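"""Test helpers: alignment builders and independent naive oracles.

The oracles are deliberately written as plain per-read double loops over
characters and dictionaries — no numpy, no shared code with the package
internals — so that exact agreement is a meaningful check.
"""

from __future__ import annotations

import math
from math import comb

import numpy as np

from epivef import RawAlignment

CONTEXT_OF_CHAR = {"z": "CG", "Z": "CG", "x": "CHG", "X": "CHG",
                   "h": "CHH", "H": "CHH"}
_PRIORITY = {"CG": 0, "CHG": 1, "CHH": 2}


def make_aln(name="r1", ref="chrT", start=0, bases="ACGT", quals=None,
             cigar=None, call=None, reverse=False, first=True, mapq=60,
             paired=False, bs_strand=None) -> RawAlignment:
    if quals is None:
        quals = [30] * len(bases)
    if cigar is None:
        cigar = (("M", len(bases)),)
    return RawAlignment(query_name=name, ref_name=ref, ref_start=start,
                        is_reverse=reverse, is_first_mate=first, mapq=mapq,
                        cigar=tuple(cigar), bases=bases,
                        base_quals=np.asarray(quals, dtype=np.uint8),
                        call_string=call, is_paired=paired,
                        bs_strand=bs_strand)


# ---------------------------------------------------------------------------
# naive threshold / report oracles
# ---------------------------------------------------------------------------

def naive_read_stats(template, policy):
    """Per-read threshold clauses evaluated by a plain character loop."""
    in_m = in_u = out_m = out_u = 0
    for ch in template.call_str:
        ctx = CONTEXT_OF_CHAR.get(ch)
        if ctx is None:
            continue
        meth = ch.isupper()
        if ctx == policy.context:
            in_m += meth
            in_u += not meth
        else:
            out_m += meth
            out_u += not meth
    n_in, n_out = in_m + in_u, out_m + out_u
    beta_in = in_m / n_in if n_in else 0.0
    beta_out = out_m / n_out if n_out else 0.0
    passes = (n_in >= policy.min_context_sites
              and beta_in >= policy.min_context_beta
              and beta_out <= policy.max_outofcontext_beta)
    return passes


def naive_cytosine_report(templates, policy):
    """{(chrom, 1-based pos, strand): (context, C, T, C_a)} by double loop."""
    acc = {}
    for t in templates:
        strand = "-" if t.bs_strand == "OB" else "+"
        passes = policy.enabled and naive_read_stats(t, policy)
        for pos, ch in zip(t.pos, t.call_str):
            ctx = CONTEXT_OF_CHAR.get(ch)
            if ctx is None:
                continue
            key = (t.ref_name, int(pos) + 1, strand)
            entry = acc.setdefault(key, {"CG": 0, "CHG": 0, "CHH": 0,
                                         "C": 0, "T": 0, "C_a": 0})
            entry[ctx] += 1
            if ch.isupper():
                entry["C"] += 1
                entry["C_a"] += passes
            else:
                entry["T"] += 1
    out = {}
    for key, e in acc.items():
        voted = max(("CG", "CHG", "CHH"),
                    key=lambda c: (e[c], -_PRIORITY[c]))
        out[key] = (voted, e["C"], e["T"], e["C_a"])
    return out


def naive_region_report(templates, regions, policy):
    """[(N, N_a)] per region by brute-force span intersection."""
    out = []
    for chrom, start, end in regions:
        n = n_a = 0
        for t in templates:
            s, e = t.span
            if t.ref_name == chrom and s < end and e > start:
                n += 1
                n_a += naive_read_stats(t, policy)
        out.append((n, n_a))
    return out


def naive_snv_table(templates, site, policy):
    """2x2 allele × pass counts by per-template loop."""
    pair = {site.ref_allele, site.alt_allele}
    excluded = "OT" if pair == {"C", "T"} else (
        "OB" if pair == {"G", "A"} else None)
    counts = [[0, 0], [0, 0]]
    for t in templates:
        if t.ref_name != site.ref_name:
            continue
        hit = [i for i, p in enumerate(t.pos) if p == site.pos - 1]
        if not hit:
            continue
        b = chr(t.base[hit[0]])
        if b == "N" or (excluded is not None and t.bs_strand == excluded):
            continue
        if b == site.ref_allele:
            row = 0
        elif b == site.alt_allele:
            row = 1
        else:
            continue
        counts[row][0 if naive_read_stats(t, policy) else 1] += 1
    return counts


# ---------------------------------------------------------------------------
# Fisher exact oracle: exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_enum(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# FNV-1a reference implementation (byte-wise, written independently)
# ---------------------------------------------------------------------------

def fnv1a_ref(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for byte in data:
        h = h ^ byte
        h = (h * 0x100000001B3) % (2 ** 64)
    return h
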