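"""Read-level thresholding and cytosine / region methylation reports.

Every merged template is classified by the average methylation of its
cytosines: a template passes the threshold when it carries at least
``min_context_sites`` cytosines of the target context, their mean
methylation (beta) is at least ``min_context_beta``, and the mean
methylation of cytosines in all other definite contexts is at most
``max_outofcontext_beta``. The defaults (CG, 2, 0.5, 0.1) select
hypermethylated epialleles while rejecting scattered methylation and
incomplete bisulfite conversion.

Per position, the conventional beta value is C/(C+T) over all templates;
the variant epiallele frequency is VEF = C_a/(C+T), where C_a counts
methylated observations from threshold-passing templates only. Per
region, VEF = N_a/N over overlapping templates.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import FormatError, MergedTemplate
from .methylation_calling import CONTEXTS, CONTEXT_UPPER

_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS)}   # CG=0 < CHG < CHH


@dataclass(frozen=True)
class ThresholdPolicy:
    """The read-level methylation filter."""

    context: str = "CG"
    min_context_sites: int = 2
    min_context_beta: float = 0.5
    max_outofcontext_beta: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.min_context_sites < 0:
            raise ValueError("min_context_sites must be >= 0")
        for name in ("min_context_beta", "max_outofcontext_beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")


#: conventional reporting mode — beta values only, no thresholding
CONVENTIONAL = ThresholdPolicy(enabled=False)


@dataclass(frozen=True)
class ReadStats:
    """Per-template threshold evaluation; betas are NaN when undefined."""

    n_context_sites: int
    beta_context: float
    n_out_sites: int
    beta_out: float
    passes: bool


def evaluate_threshold(template: MergedTemplate,
                       policy: ThresholdPolicy) -> ReadStats:
    """Evaluate the read-level threshold on one template.

    A template with no in-context sites cannot satisfy a positive
    ``min_context_sites`` and its undefined beta fails any positive
    ``min_context_beta``. An undefined out-of-context beta is treated as 0:
    the clause guards against incomplete conversion, and absence of
    non-target cytosines is no evidence of it. Unknown-context calls (u/U)
    count towards neither average.
    """
    counts = np.bincount(template.call, minlength=128)
    in_m = in_u = out_m = out_u = 0
    for ctx in CONTEXTS:
        upper = CONTEXT_UPPER[ctx]
        m, u = int(counts[upper]), int(counts[upper + 32])
        if ctx == policy.context:
            in_m, in_u = m, u
        else:
            out_m += m
            out_u += u
    n_in = in_m + in_u
    n_out = out_m + out_u
    beta_in = in_m / n_in if n_in else math.nan
    beta_out = out_m / n_out if n_out else math.nan
    passes = (
        n_in >= policy.min_context_sites
        and (beta_in if n_in else 0.0) >= policy.min_context_beta
        and (beta_out if n_out else 0.0) <= policy.max_outofcontext_beta
    )
    return ReadStats(n_in, beta_in, n_out, beta_out, passes)


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

_DEFINITE = np.zeros(128, dtype=bool)
_CLASS_OF = np.zeros(128, dtype=np.uint8)
_IS_METH = np.zeros(128, dtype=bool)
for _ctx, _up in CONTEXT_UPPER.items():
    for _code in (_up, _up + 32):
        _DEFINITE[_code] = True
        _CLASS_OF[_code] = _CONTEXT_INDEX[_ctx]
    _IS_METH[_up] = True


def generate_cytosine_report(
    templates: Iterable[MergedTemplate],
    policy: ThresholdPolicy = ThresholdPolicy(),
    contexts_to_report: Sequence[str] = ("CG",),
) -> pd.DataFrame:
    """Per-cytosine beta (and VEF) report.

    One row per (position, strand) with at least one definite-context
    observation; the reported context is the most frequent one across
    reads (ties CG > CHG > CHH). With ``policy.enabled`` False the report
    is conventional (beta only); otherwise C_a and VEF columns are added,
    with C_a accumulated from threshold-passing templates only. Rows are
    sorted by (chrom, pos, strand); positions are 1-based.
    """
    for ctx in contexts_to_report:
        if ctx not in CONTEXTS:
            raise ValueError(f"unknown context {ctx!r}")

    ref_names: list[str] = []
    ref_index: dict[str, int] = {}
    pos_parts, call_parts, strand_parts, pass_parts, ref_parts = \
        [], [], [], [], []
    for t in templates:
        sel = _DEFINITE[t.call]
        if not sel.any():
            continue
        if t.ref_name not in ref_index:
            ref_index[t.ref_name] = len(ref_names)
            ref_names.append(t.ref_name)
        n = int(sel.sum())
        pos_parts.append(t.pos[sel])
        call_parts.append(t.call[sel])
        # strand of the cytosine equals the template's conversion strand:
        # OT reads report reference C (+), OB reads reference G (−)
        strand_parts.append(
            np.full(n, 0 if t.bs_strand != "OB" else 1, dtype=np.uint8))
        passes = policy.enabled and evaluate_threshold(t, policy).passes
        pass_parts.append(np.full(n, passes, dtype=bool))
        ref_parts.append(np.full(n, ref_index[t.ref_name], dtype=np.int64))

    columns = ["chrom", "pos", "strand", "context", "C", "T"]
    if policy.enabled:
        columns += ["C_a"]
    columns += ["beta"] + (["VEF"] if policy.enabled else [])
    if not pos_parts:
        return pd.DataFrame(columns=columns)

    pos = np.concatenate(pos_parts)
    call = np.concatenate(call_parts)
    strand = np.concatenate(strand_parts)
    passing = np.concatenate(pass_parts)
    refidx = np.concatenate(ref_parts)

    # composite key: (ref, pos, strand) packed into one int64
    key = (refidx << 42) | (pos.astype(np.int64) << 1) | strand
    uniq, inv = np.unique(key, return_inverse=True)
    n_sites = len(uniq)

    meth = _IS_METH[call]
    C = np.bincount(inv[meth], minlength=n_sites)
    T = np.bincount(inv[~meth], minlength=n_sites)
    # context vote: counts per class, first maximum wins => CG > CHG > CHH
    cls = _CLASS_OF[call]
    cls_counts = np.bincount(inv * 3 + cls, minlength=n_sites * 3)
    voted = cls_counts.reshape(n_sites, 3).argmax(axis=1)

    out = {
        "chrom": pd.Categorical.from_codes(
            ((uniq >> 42) & 0x3FFFFF).astype(np.int64), categories=ref_names),
        "pos": ((uniq >> 1) & ((1 << 41) - 1)).astype(np.int64) + 1,
        "strand": np.where((uniq & 1).astype(bool), "-", "+"),
        "context": pd.Categorical.from_codes(voted, categories=list(CONTEXTS)),
        "C": C,
        "T": T,
    }
    if policy.enabled:
        out["C_a"] = np.bincount(inv[meth & passing], minlength=n_sites)
    df = pd.DataFrame(out)
    cov = df["C"] + df["T"]
    df["beta"] = df["C"] / cov
    if policy.enabled:
        df["VEF"] = df["C_a"] / cov
    df = df[df["context"].isin(contexts_to_report)]
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable",
                        ignore_index=True)
    df["chrom"] = df["chrom"].astype(str)
    df["context"] = df["context"].astype(str)
    return df


# ---------------------------------------------------------------------------
# region report
# ---------------------------------------------------------------------------

def generate_region_report(
    templates: Sequence[MergedTemplate],
    regions: Sequence[tuple[str, int, int]],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> pd.DataFrame:
    """Per-region read-pair counts and region VEF = N_a / N.

    ``regions`` are (chrom, start, end) 0-based half-open (BED convention);
    output coordinates are 1-based inclusive. A template counts in N when
    its span intersects the region by at least one base; templates are
    counted independently in every region they overlap. Regions with N = 0
    report VEF as NA.
    """
    chroms = np.array([t.ref_name for t in templates])
    starts = np.array([t.span[0] for t in templates], dtype=np.int64)
    ends = np.array([t.span[1] for t in templates], dtype=np.int64)
    passes = np.array([evaluate_threshold(t, policy).passes
                       for t in templates], dtype=bool)

    rows = []
    for chrom, start, end in regions:
        if start >= end or start < 0:
            raise FormatError(f"invalid region {chrom}:{start}-{end}")
        if len(templates):
            hit = (chroms == chrom) & (starts < end) & (ends > start)
            n = int(hit.sum())
            n_a = int((hit & passes).sum())
        else:
            n = n_a = 0
        rows.append({"chrom": chrom, "start": start + 1, "end": end,
                     "N": n, "N_a": n_a,
                     "VEF": n_a / n if n else math.nan})
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "N", "N_a", "VEF"])


# ---------------------------------------------------------------------------
# BED / TSV / bedGraph plumbing
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Parse a 3+ column BED file (0-based half-open intervals)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end}")
            regions.append((fields[0], start, end))
    return regions


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def to_bedgraph(df: pd.DataFrame, column: str = "beta") -> pd.DataFrame:
    """Cytosine report rows as a bedGraph table (0-based half-open)."""
    return pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"] - 1,
        "end": df["pos"],
        "value": df[column],
    })
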