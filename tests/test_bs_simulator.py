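"""Bisulfite read simulator: determinism, ground-truth recovery, the
duplication and admixture constructions, and error injection."""

import math

import numpy as np
import pytest

from epivef import (CONVENTIONAL, ThresholdPolicy, generate_cytosine_report,
                    generate_region_report, templates_from_pairs)
from epivef.bs_simulator import (SimProfile, admix, duplicate_as_converted,
                                 make_reference, simulate_templates,
                                 tile_regions)


def test_reference_is_deterministic_with_exact_gc():
    a = make_reference(10_000, 0.5, seed=5)
    b = make_reference(10_000, 0.5, seed=5)
    c = make_reference(10_000, 0.5, seed=6)
    assert a.seq == b.seq and a.seq != c.seq
    gc = sum(ch in "GC" for ch in a.seq) / len(a.seq)
    assert gc == pytest.approx(0.5, abs=1e-3)
    low = make_reference(100_000, 0.4, seed=5)
    gc = sum(ch in "GC" for ch in low.seq) / len(low.seq)
    assert 0.39 <= gc <= 0.41


def test_reference_cpg_density():
    ref = make_reference(1_000, 0.5, seed=8)
    assert ref.seq.count("CG") >= 5
    big = make_reference(100_000, 0.5, seed=9)
    assert big.seq.count("CG") >= 1_000   # >=1 per 100 bp


def test_simulation_is_reproducible(small_ref):
    prof = SimProfile(n_templates=20, cg_methylation=0.5, seed=33)
    p1, t1 = simulate_templates(small_ref, prof)
    p2, t2 = simulate_templates(small_ref, prof)
    assert t1.equals(t2)
    for (a1, b1), (a2, b2) in zip(p1, p2):
        assert a1.bases == a2.bases and b1.call_string == b2.call_string


def test_truth_table_matches_read_calls(small_ref):
    """Reads of a fully methylated / fully converted set reproduce the
    molecule states recorded in the truth table."""
    prof = SimProfile(n_templates=50, cg_methylation=1.0, ch_conversion=1.0,
                      seed=44)
    pairs, truth = simulate_templates(small_ref, prof)
    assert (truth["n_cpg_meth"] == truth["n_cpg"]).all()
    assert (truth["n_ch_meth"] == 0).all()
    templates = templates_from_pairs(pairs, min_mapq=0, min_baseq=0)
    report = generate_cytosine_report(templates, CONVENTIONAL,
                                      contexts_to_report=("CG", "CHG", "CHH"))
    cg = report[report["context"] == "CG"]
    assert (cg["beta"] == 1.0).all()
    assert (report[report["context"] != "CG"]["beta"] == 0.0).all()


def test_fragment_shorter_than_read_truncates(small_ref):
    with pytest.raises(ValueError, match="read_len"):
        SimProfile(n_templates=1, fragment_len=(70, 100), read_len=151)
    prof = SimProfile(n_templates=40, fragment_len=(70, 151), read_len=151,
                      seed=55)
    pairs, truth = simulate_templates(small_ref, prof)
    n_short = 0
    for (r1, r2), (_, row) in zip(pairs, truth.iterrows()):
        frag_len = row["frag_end"] - row["frag_start"]
        if frag_len < prof.read_len:
            n_short += 1
            assert len(r1.bases) == len(r2.bases) == frag_len
            assert r1.ref_start == r2.ref_start == row["frag_start"]
    assert n_short > 10   # truncation actually exercised


def test_quality_profile_decays_towards_read_3prime(small_ref):
    prof = SimProfile(n_templates=5, seed=66)
    pairs, _ = simulate_templates(small_ref, prof)
    for r1, r2 in pairs:
        fwd = r1 if not r1.is_reverse else r2
        rev = r2 if not r1.is_reverse else r1
        q_fwd = fwd.base_quals.astype(int)
        assert (np.diff(q_fwd) <= 0).all() and q_fwd[0] > q_fwd[-1]
        # reverse-stored reads have their 3' (low-quality) end on the left
        assert (np.diff(rev.base_quals.astype(int)) >= 0).all()


def test_duplication_gives_exact_half_betas(small_ref):
    prof = SimProfile(n_templates=400, cg_methylation=1.0,
                      ch_conversion=0.995, seed=77)
    pairs, _ = simulate_templates(small_ref, prof)
    doubled = duplicate_as_converted(pairs)
    assert len(doubled) == 2 * len(pairs)
    assert duplicate_as_converted([]) == []
    one = duplicate_as_converted(pairs[:1])
    assert len(one) == 2
    assert one[1][0].ref_start == one[0][0].ref_start
    templates = templates_from_pairs(doubled, min_mapq=0, min_baseq=0)
    report = generate_cytosine_report(templates, CONVENTIONAL,
                                      contexts_to_report=("CG", "CHG", "CHH"))
    cg = report[report["context"] == "CG"]
    assert len(cg) > 500
    assert (cg["beta"] == 0.5).all()     # exactly, at every covered CpG
    ch = report[report["context"] != "CG"]
    # residual methylation halves: 0.005 in the methylated set -> 0.0025
    p = ch["beta"].mean()
    n_obs = int((ch["C"] + ch["T"]).sum())
    se = math.sqrt(0.0025 * (1 - 0.0025) / n_obs)
    assert abs(p - 0.0025) < 3 * se


def test_admix_arithmetic_and_determinism(small_ref):
    prof_bg = SimProfile(n_templates=200, seed=1)
    prof_sp = SimProfile(n_templates=50, cg_methylation=1.0, seed=2)
    bg, _ = simulate_templates(small_ref, prof_bg)
    sp, _ = simulate_templates(small_ref, prof_sp, name_prefix="meth")
    assert admix(bg, sp, 0.0, seed=3) == bg
    mixed = admix(bg, sp, 0.01, seed=3)
    n_add = round(0.01 * 200 / 0.99)
    assert len(mixed) == 200 + n_add
    names = [p[0].query_name for p in mixed]
    assert len(set(names)) == len(names)
    again = admix(bg, sp, 0.01, seed=3)
    assert [p[0].query_name for p in again] == names
    with pytest.raises(ValueError, match="methylated"):
        admix(bg, sp, 0.5, seed=3)


def test_admixture_fraction_recovered_as_region_vef(small_ref):
    """Region VEF under the default policy estimates the spiked fraction."""
    regions = tile_regions(small_ref, 2, 400, 2500)
    frags = (350, 400)   # amplicon mode: fragment spans most of the region
    bg, _ = simulate_templates(
        small_ref, SimProfile(n_templates=3_000, cg_methylation=0.005,
                              ch_conversion=0.9975, fragment_len=frags,
                              seed=11),
        regions=regions)
    sp, _ = simulate_templates(
        small_ref, SimProfile(n_templates=200, cg_methylation=1.0,
                              ch_conversion=0.9975, fragment_len=frags,
                              seed=12),
        regions=regions, name_prefix="meth")
    mixed = admix(bg, sp, 0.03, seed=13)
    templates = templates_from_pairs(mixed, min_mapq=0, min_baseq=0)
    df = generate_region_report(templates, regions, ThresholdPolicy())
    vef = df["N_a"].sum() / df["N"].sum()
    se = math.sqrt(0.03 * 0.97 / df["N"].sum())
    assert abs(vef - 0.03) < 3 * se


def test_error_rate_raises_non_cpg_beta_monotonically(small_ref):
    """Sequencing errors inflate apparent non-CpG methylation above the
    residual-conversion baseline, monotonically in the error rate."""
    means = []
    for err in (0.0, 0.003, 0.01):
        prof = SimProfile(n_templates=800, cg_methylation=0.5,
                          ch_conversion=0.995, error_rate=err, seed=21)
        pairs, _ = simulate_templates(small_ref, prof)
        templates = templates_from_pairs(pairs, min_mapq=0, min_baseq=0)
        report = generate_cytosine_report(templates, CONVENTIONAL,
                                          contexts_to_report=("CHG", "CHH"))
        w = report["C"].sum() + report["T"].sum()
        means.append(report["C"].sum() / w)
    assert means[0] < means[1] < means[2]
    assert means[0] == pytest.approx(0.005, rel=0.25)


def test_error_positions_follow_quality_profile(small_ref):
    """With a steep quality decay, most injected errors sit in the 3' half."""
    # ch_conversion=0 + full CpG methylation leaves every fragment equal to
    # the reference, so any mismatch against the reference is an injected error
    prof = SimProfile(n_templates=300, cg_methylation=1.0, ch_conversion=0.0,
                      error_rate=0.01, qual_decay=60.0, seed=31)
    pairs, _ = simulate_templates(small_ref, prof)
    first_half = second_half = 0
    for pair in pairs:
        for read in pair:
            n = len(read.bases)
            expected = small_ref.seq[read.ref_start:read.ref_start + n]
            for i, (a, b) in enumerate(zip(read.bases, expected)):
                if a != b:
                    cycle = n - 1 - i if read.is_reverse else i
                    if cycle < n // 2:
                        first_half += 1
                    else:
                        second_half += 1
    assert first_half + second_half > 100
    assert second_half > 2 * first_half
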