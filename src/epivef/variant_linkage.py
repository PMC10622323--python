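"""Allele-specific methylation: SNV × threshold-status contingency tables.

For each biallelic SNV, templates covering the site are assigned to the
reference- or alternate-bearing row by their (unmasked) base at the SNV,
and to the pass/fail column by the read-level methylation threshold. A
two-sided Fisher exact test on the resulting 2×2 table quantifies the
balance or skewness of methylation between alleles — evidence for or
against allele-specific (e.g., single-event, clonally expanded)
epimutations.

Bisulfite conversion mimics C>T (on OT templates) and G>A (on OB
templates) variants, so templates whose conversion strand confounds the
allele pair are excluded per template.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .alignment_io import MASKED_BASE, MergedTemplate
from .reports import ThresholdPolicy, evaluate_threshold

log = logging.getLogger("epivef")

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvSite:
    """A biallelic single-nucleotide variant (1-based position)."""

    ref_name: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if (self.ref_allele not in _BASES or self.alt_allele not in _BASES
                or self.ref_allele == self.alt_allele):
            raise ValueError(f"not a biallelic SNV: "
                             f"{self.ref_allele}>{self.alt_allele}")


@dataclass(frozen=True)
class AlleleMethylationTable:
    site: SnvSite
    counts: tuple[tuple[int, int], tuple[int, int]]   # rows ref/alt, cols pass/fail
    p_value: float


def load_snvs(vcf_path: str | Path) -> list[SnvSite]:
    """Biallelic SNVs from a VCF (plain or bgzipped); other records skipped."""
    sites = []
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (len(alts) != 1 or rec.ref is None or len(rec.ref) != 1
                    or len(alts[0]) != 1 or rec.ref not in _BASES
                    or alts[0] not in _BASES):
                n_skipped += 1
                log.info("skipping non-SNV/multi-allelic record at %s:%d",
                         rec.chrom, rec.pos)
                continue
            sites.append(SnvSite(rec.chrom, rec.pos, rec.ref, alts[0]))
    if n_skipped:
        log.warning("skipped %d VCF records (multi-allelic or indel)",
                    n_skipped)
    return sites


def _confounded_strand(site: SnvSite) -> str | None:
    """Conversion strand on which this allele pair is unreadable."""
    pair = {site.ref_allele, site.alt_allele}
    if pair == {"C", "T"}:
        return "OT"
    if pair == {"G", "A"}:
        return "OB"
    return None


def tabulate_snv(
    templates: Iterable[MergedTemplate],
    site: SnvSite,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> np.ndarray:
    """2×2 counts: rows (ref-, alt-bearing templates) × cols (pass, fail).

    Templates not covering the site, masked at it, carrying a third base,
    or bisulfite-confounded for this allele pair are excluded.
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    pos0 = site.pos - 1
    excluded = _confounded_strand(site)
    ref_b, alt_b = ord(site.ref_allele), ord(site.alt_allele)
    for t in templates:
        if t.ref_name != site.ref_name:
            continue
        i = np.searchsorted(t.pos, pos0)
        if i >= len(t.pos) or t.pos[i] != pos0:
            continue
        b = int(t.base[i])
        if b == MASKED_BASE:
            continue
        if excluded is not None and t.bs_strand == excluded:
            continue
        if b == ref_b:
            row = 0
        elif b == alt_b:
            row = 1
        else:
            continue
        col = 0 if evaluate_threshold(t, policy).passes else 1
        counts[row, col] += 1
    return counts


def fisher_exact_2x2(counts) -> float:
    """Two-sided Fisher exact p-value (hypergeometric; degenerate margins -> 1)."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def vcf_report(
    templates: Sequence[MergedTemplate],
    sites: Iterable[SnvSite],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> pd.DataFrame:
    """Allele × threshold tables and Fisher p-values for a set of SNVs."""
    rows = []
    for site in sites:
        c = tabulate_snv(templates, site, policy)
        rows.append({
            "chrom": site.ref_name, "pos": site.pos,
            "ref": site.ref_allele, "alt": site.alt_allele,
            "n_ref_pass": int(c[0, 0]), "n_ref_fail": int(c[0, 1]),
            "n_alt_pass": int(c[1, 0]), "n_alt_fail": int(c[1, 1]),
            "p_value": fisher_exact_2x2(c),
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "n_ref_pass", "n_ref_fail",
                                       "n_alt_pass", "n_alt_fail", "p_value"])


def table_for(templates, site, policy=ThresholdPolicy()) -> AlleleMethylationTable:
    c = tabulate_snv(templates, site, policy)
    return AlleleMethylationTable(
        site, ((int(c[0, 0]), int(c[0, 1])), (int(c[1, 0]), int(c[1, 1]))),
        fisher_exact_2x2(c))
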