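"""Sample-level SMV summaries, concordance, binning and hotspots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smvkit.caller import AlleleSupport, LocusCall
from smvkit.catalogue import Motif, MstLocus
from smvkit.profile import (
    BinStat,
    between_sample_regression,
    bin_minor_fractions,
    compare_samples,
    concordance_null,
    depth_by_allele_count,
    gene_overlap_counts,
    hotspot_bins,
    region_partition_summary,
    sample_summary,
    second_allele_read_fractions,
)


def _sup(seq, n=20):
    return AlleleSupport(seq, n // 2, n - n // 2)


def _call(lid, zyg="homozygous", minors=(), depth=50, major="A" * 10, second=None):
    hap = [_sup(major, 30)]
    if zyg == "heterozygous":
        hap.append(_sup(second or "A" * 11, 15))
    return LocusCall(lid, depth, zyg, hap, [_sup(m, 4) for m in minors])


def _locus(lid, chrom="c", start=0, unit="A"):
    return MstLocus(chrom, start, start + 10, Motif(unit), 10, 1.0, locus_id=lid)


# ------------------------------------------------------------ summaries


def test_sample_summary_hand_counts():
    calls = [_call(f"l{i}") for i in range(19)]
    calls[3] = _call("l3", zyg="heterozygous")
    calls.append(_call("l19", minors=["A" * 12]))
    s = sample_summary(calls)
    assert s.n_genotyped == 20
    assert s.pct_homozygous == pytest.approx(95)
    assert s.pct_heterozygous == pytest.approx(5)
    assert s.pct_multi_allele == pytest.approx(5)
    assert s.pct_homozygous + s.pct_heterozygous == pytest.approx(100)


def test_sample_summary_all_homozygous():
    s = sample_summary([_call(f"l{i}") for i in range(10)])
    assert (s.pct_homozygous, s.pct_heterozygous, s.pct_multi_allele) == (100, 0, 0)


def test_sample_summary_requires_genotyped_loci():
    with pytest.raises(ValueError):
        sample_summary([LocusCall("l", 5, "uncalled")])


def test_depth_by_allele_count_hand_computation():
    calls = [
        _call("a", depth=40),
        _call("b", depth=60),
        _call("c", depth=55, minors=["A" * 12]),
    ]
    tab = depth_by_allele_count(calls)
    row1 = tab[tab.n_alleles == 1].iloc[0]
    row2 = tab[tab.n_alleles == 2].iloc[0]
    assert row1.mean_depth == pytest.approx(50)
    assert row1.n_loci == 2
    assert row2.mean_depth == pytest.approx(55)


def test_depth_increases_with_allele_count_under_pure_error(tmp_path):
    """More alleles at deeper loci when all minors are sequencing error."""
    import pysam

    from smvkit.caller import CallerConfig, call_sample
    from smvkit.simulator import SimulationConfig, simulate_sample

    cfg = SimulationConfig(n_loci=250, per_base_error=0.05, het_fraction=0.0, seed=47)
    ref, cat, truth, bam = simulate_sample(cfg, str(tmp_path))
    with pysam.AlignmentFile(bam) as af:
        calls = call_sample(af, cat, CallerConfig(min_reads_per_allele=2), reference=ref)
    tab = depth_by_allele_count(calls).sort_values("n_alleles")
    means = tab[tab.n_loci >= 5].mean_depth.tolist()
    assert len(means) >= 2
    assert means[-1] > means[0]


# ------------------------------------------------------------ binning


def test_bin_assignment_matches_brute_force():
    rng = np.random.default_rng(8)
    cat = []
    calls = []
    for i in range(300):
        start = int(rng.integers(0, 5_000_000))
        cat.append(_locus(f"l{i}", start=start))
        calls.append(_call(f"l{i}", minors=["A" * 12] if rng.random() < 0.1 else ()))
    bins, chrom_df = bin_minor_fractions(calls, cat, bin_size=1_000_000)
    by_key = {(b.chrom, b.bin_start): b for b in bins}
    # brute-force oracle
    expect: dict = {}
    for locus, call in zip(cat, calls):
        key = ("c", locus.start // 1_000_000 * 1_000_000)
        tot, minor = expect.get(key, (0, 0))
        expect[key] = (tot + 1, minor + bool(call.minor_alleles))
    assert set(by_key) == set(expect)
    for key, (tot, minor) in expect.items():
        assert by_key[key].n_loci == tot
        assert by_key[key].n_minor_loci == minor
    assert sum(b.n_minor_loci for b in bins) == sum(bool(c.minor_alleles) for c in calls)
    assert chrom_df.iloc[0]["n_loci"] == 300


def test_single_bin_fraction():
    cat = [_locus(f"l{i}", start=i * 20) for i in range(100)]
    calls = [_call(f"l{i}", minors=["A" * 12] if i < 5 else ()) for i in range(100)]
    bins, _ = bin_minor_fractions(calls, cat)
    assert len(bins) == 1
    assert bins[0].fraction == pytest.approx(0.05)


# ------------------------------------------------------------ hotspots


def test_uniform_bins_yield_no_hotspots():
    bins = [BinStat("c", i * 10**6, 200, 10, 0.05) for i in range(20)]
    assert hotspot_bins(bins, alpha=0.01) == []


def test_tenfold_excess_bin_flagged_and_matches_direct_chi2():
    bins = [BinStat("c", i * 10**6, 200, 10, 0.05) for i in range(20)]
    bins.append(BinStat("c", 20 * 10**6, 200, 100, 0.5))
    flagged = hotspot_bins(bins, alpha=0.01)
    assert [b.bin_start for b in flagged] == [20 * 10**6]
    rate = (20 * 10 + 100) / (21 * 200)
    expected = rate * 200
    x2 = (100 - expected) ** 2 / expected
    assert stats.chi2.sf(x2, 1) == pytest.approx(flagged[0].p_value)


def test_hotspot_flags_invariant_under_reordering():
    rng = np.random.default_rng(9)
    bins = [
        BinStat("c", i * 10**6, int(rng.integers(50, 300)), int(rng.integers(0, 40)), 0.0)
        for i in range(30)
    ]
    a = {b.bin_start for b in hotspot_bins([BinStat(**vars(b)) for b in bins])}
    shuffled = bins[::-1]
    b_ = {b.bin_start for b in hotspot_bins([BinStat(**vars(x)) for x in shuffled])}
    assert a == b_


def test_hotspot_flag_monotone_in_excess():
    base = [BinStat("c", i * 10**6, 200, 10, 0.05) for i in range(20)]
    flags = []
    for obs in (12, 20, 30, 45):
        bins = [BinStat(**vars(b)) for b in base] + [BinStat("c", 99 * 10**6, 200, obs, obs / 200)]
        flags.append(bool(hotspot_bins(bins, alpha=0.01)))
    assert flags == sorted(flags)  # once flagged, stays flagged as excess grows


# ------------------------------------------------------------ concordance


def test_identical_call_sets_fully_concordant():
    calls = [_call(f"l{i}", minors=["A" * 12] if i % 4 == 0 else ()) for i in range(20)]
    res = compare_samples(calls, calls)
    assert res.pct_genotype_discordance == 0
    assert res.pct_minor_discordant == 0
    assert res.pct_minor_concordant == pytest.approx(25)
    assert (
        res.pct_minor_concordant + res.pct_minor_discordant + res.pct_no_minor_concordant
        == pytest.approx(100)
    )


def test_ten_locus_minor_overlap_percentages():
    a = [_call(f"l{i}", minors=["A" * 12] if i in (1, 2, 3) else ()) for i in range(10)]
    b = [_call(f"l{i}", minors=["A" * 12] if i in (2, 3, 4) else ()) for i in range(10)]
    res = compare_samples(a, b)
    assert res.n_shared_loci == 10
    assert res.pct_minor_concordant == pytest.approx(20)
    assert res.pct_minor_discordant == pytest.approx(20)
    assert res.pct_no_minor_concordant == pytest.approx(60)


def test_genotype_discordance_breakdown():
    # l0: same second allele, but below het threshold in b -> boundary case
    a = [_call("l0", zyg="heterozygous", second="A" * 11)]
    b = [_call("l0", minors=["A" * 11])]
    res = compare_samples(a, b)
    assert res.n_genotype_discordant == 1
    assert res.n_discordant_threshold_boundary == 1
    assert res.n_discordant_sequence == 0
    # l1: truly different haplotype sequences
    a = [_call("l1", major="A" * 10)]
    b = [_call("l1", major="A" * 12)]
    res = compare_samples(a, b)
    assert res.n_discordant_sequence == 1


def test_minor_categories_symmetric():
    a = [_call(f"l{i}", minors=["A" * 12] if i < 3 else ()) for i in range(10)]
    b = [_call(f"l{i}", minors=["A" * 12] if i in (2, 5) else ()) for i in range(10)]
    r1 = compare_samples(a, b)
    r2 = compare_samples(b, a)
    assert r1.pct_minor_concordant == r2.pct_minor_concordant
    assert r1.pct_minor_discordant == r2.pct_minor_discordant
    assert r1.pct_no_minor_concordant == r2.pct_no_minor_concordant


def test_compare_requires_shared_loci():
    with pytest.raises(ValueError):
        compare_samples([_call("a1")], [_call("b1")])


def test_replicate_simulations_nearly_concordant(tmp_path):
    """Two read-level replicates of one truth agree on nearly every locus."""
    import pysam

    from smvkit.caller import CallerConfig, call_sample
    from smvkit.simulator import (
        SimulationConfig, assign_truth, build_synthetic_reference,
        generate_reads, write_alignments,
    )

    cfg = SimulationConfig(n_loci=120, per_base_error=0.005, het_fraction=0.1, seed=55)
    ref, cat = build_synthetic_reference(cfg)
    truth = assign_truth(cat, cfg, reference=ref)
    call_sets = []
    for rep in (1, 2):
        cfg_rep = SimulationConfig(
            n_loci=120, per_base_error=0.005, het_fraction=0.1, seed=55 + 1000 * rep
        )
        reads = generate_reads(ref, cat, truth, cfg_rep)
        bam = str(tmp_path / f"r{rep}.bam")
        write_alignments(reads, ref, bam)
        with pysam.AlignmentFile(bam) as af:
            call_sets.append(call_sample(af, cat, CallerConfig(), reference=ref))
    res = compare_samples(*call_sets)
    assert res.n_shared_loci > 100
    assert res.pct_genotype_discordance < 5
    assert res.pct_no_minor_concordant > 90


# ------------------------------------------------------------ null model


def test_concordance_null_product_formula():
    null = concordance_null(100_000, 0.054, 0.053, observed_concordant=3400)
    assert null.expected_fraction == pytest.approx(0.002862)
    assert null.p_value < 1e-6  # observed far above random expectation


def test_concordance_null_degenerate_zero():
    null = concordance_null(1000, 0.0, 0.0, observed_concordant=0)
    assert null.expected_fraction == 0
    assert null.p_value == 1.0


def test_concordance_null_monte_carlo_matches_analytic():
    null = concordance_null(2000, 0.1, 0.2, observed_concordant=40, n_reps=1000, seed=3)
    # binomial-ish s.e. of the MC mean fraction
    se = np.sqrt(0.1 * 0.2 / 2000 / 1000) * 30  # generous 3-sigma-style bound
    assert null.mc_mean_fraction == pytest.approx(0.02, abs=max(se, 0.002))


# ------------------------------------------------------------ regression


def test_regression_perfect_line():
    r = between_sample_regression([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.r_squared == pytest.approx(1.0)
    assert r.slope == pytest.approx(1.0)


def test_regression_matches_closed_form():
    x = np.array([0.5, 1.0, 2.0, 3.0, 4.5])
    y = np.array([0.8, 1.1, 1.8, 3.4, 4.1])
    r = between_sample_regression(x, y)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    assert r.slope == pytest.approx(sxy / sxx)
    assert r.r_squared == pytest.approx(sxy**2 / (sxx * syy))


def test_regression_invariant_to_joint_permutation():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 1, 10)
    y = x + rng.normal(0, 0.1, 10)
    perm = rng.permutation(10)
    assert between_sample_regression(x, y).r_squared == pytest.approx(
        between_sample_regression(x[perm], y[perm]).r_squared
    )


def test_regression_rejects_constant_predictor():
    with pytest.raises(ValueError):
        between_sample_regression([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------ read fractions


def test_minor_read_fraction_hand_computation():
    call = LocusCall(
        "l0", 100, "homozygous",
        [_sup("A" * 10, 80)],
        [AlleleSupport("A" * 11, 3, 3), AlleleSupport("A" * 9, 1, 1)],
    )
    s = second_allele_read_fractions([call])
    assert s.n_minor_loci == 1
    assert s.mean_minor_fraction == pytest.approx(0.08)
    assert s.mean_second_allele_fraction == pytest.approx(0.06)


def test_no_minor_loci_is_empty():
    s = second_allele_read_fractions([_call("l0")])
    assert s.empty


def test_planted_minor_fraction_recovered(noisy_sim, noisy_calls):
    cfg, _, _, truth, _ = noisy_sim
    s = second_allele_read_fractions(noisy_calls)
    assert not s.empty
    lo, hi = cfg.minor_read_fraction_range
    # recovered mean within the planted range, allowing support-threshold bias
    assert lo - 0.03 <= s.mean_minor_fraction <= hi + 0.03


# ------------------------------------------------------------ regions


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def test_exonic_assignment_any_overlap():
    cat = [_locus("in", start=100), _locus("edge", start=195), _locus("out", start=500)]
    calls = [_call("in"), _call("edge"), _call("out")]
    bed = _bed([("c", 50, 150, "G1"), ("c", 190, 200, "G2")])
    part = region_partition_summary(calls, cat, bed)
    assert part.exonic.n_genotyped == 2
    assert part.untranslated.n_genotyped == 1


def test_gene_report_lists_multi_minor_gene():
    cat = [_locus("a", start=100), _locus("b", start=300), _locus("d", start=600)]
    calls = [
        _call("a", minors=["A" * 12, "A" * 9]),  # 2 minors -> reported
        _call("b", minors=["A" * 12]),           # 1 minor -> below threshold
        _call("d"),
    ]
    bed = _bed([("c", 90, 120, "GENE1"), ("c", 290, 320, "GENE2"), ("c", 590, 620, "GENE3")])
    part = region_partition_summary(calls, cat, bed)
    assert part.gene_report["gene"].tolist() == ["GENE1"]
    counts = gene_overlap_counts({"s1": part.gene_report, "s2": part.gene_report})
    assert counts.iloc[0]["n_samples"] == 2


def test_empty_annotation_warns():
    cat = [_locus("a")]
    calls = [_call("a")]
    with pytest.warns(UserWarning):
        part = region_partition_summary(calls, cat, None)
    assert part.exonic is None
    assert part.untranslated.n_genotyped == 1


# ------------------------------------------------------------ parameter recovery


def test_profile_recovers_generator_parameters(noisy_sim, noisy_calls):
    """Het fraction and planting rate recovered within binomial 99% CIs."""
    cfg, _, _, truth, _ = noisy_sim
    s = sample_summary(noisy_calls)
    n = s.n_genotyped
    lo, hi = stats.binom.interval(0.99, n, cfg.het_fraction)
    assert lo <= round(s.pct_heterozygous / 100 * n) <= hi
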