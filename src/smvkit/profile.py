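"""Sample-level somatic microsatellite variation (SMV) statistics.

Summaries over one sample's locus calls (zygosity percentages, fraction of
loci carrying minor alleles, variant spectra), pairwise concordance between
samples with an analytic and Monte-Carlo random null, chromosome and 1-Mb
bin minor-allele fractions with chi-square hotspot flags, between-sample
regression, second-allele read fractions, and exon-vs-untranslated /
gene-level reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .caller import HETEROZYGOUS, HOMOZYGOUS, LocusCall
from .classify import SpectrumSummary, variant_spectrum
from .catalogue import MstLocus


@dataclass
class SmvSummary:
    """Sample-level genotype and minor-allele percentages.

    ``pct_multi_allele`` is the percent of genotyped loci carrying at
    least one minor allele — the sample's SMV rate.
    """

    n_genotyped: int
    pct_homozygous: float
    pct_heterozygous: float
    pct_multi_allele: float
    spectrum: SpectrumSummary | None = None


def sample_summary(
    calls: list[LocusCall], catalogue: list[MstLocus] | None = None
) -> SmvSummary:
    """Zygosity and minor-allele percentages over genotyped loci."""
    genotyped = [c for c in calls if c.genotyped]
    n = len(genotyped)
    if n == 0:
        raise ValueError("no genotyped loci")
    n_hom = sum(c.zygosity == HOMOZYGOUS for c in genotyped)
    n_het = sum(c.zygosity == HETEROZYGOUS for c in genotyped)
    n_multi = sum(c.has_minor for c in genotyped)
    spectrum = variant_spectrum(genotyped, catalogue) if catalogue is not None else None
    return SmvSummary(
        n_genotyped=n,
        pct_homozygous=100.0 * n_hom / n,
        pct_heterozygous=100.0 * n_het / n,
        pct_multi_allele=100.0 * n_multi / n,
        spectrum=spectrum,
    )


def depth_by_allele_count(calls: list[LocusCall]) -> pd.DataFrame:
    """Mean locus depth for each total-allele-count value."""
    if not calls:
        raise ValueError("no calls")
    genotyped = [c for c in calls if c.genotyped]
    df = pd.DataFrame(
        {"n_alleles": [c.n_alleles_total for c in genotyped], "depth": [c.depth for c in genotyped]}
    )
    out = df.groupby("n_alleles")["depth"].agg(mean_depth="mean", n_loci="count").reset_index()
    return out


@dataclass
class BinStat:
    """Minor-allele fraction in one genomic bin."""

    chrom: str
    bin_start: int
    n_loci: int
    n_minor_loci: int
    fraction: float
    hotspot_flag: bool = False
    p_value: float = float("nan")


def bin_minor_fractions(
    calls: list[LocusCall],
    catalogue: list[MstLocus],
    bin_size: int = 1_000_000,
) -> tuple[list[BinStat], pd.DataFrame]:
    """Assign genotyped loci to fixed-width bins and per-chromosome groups.

    Returns per-bin statistics and a per-chromosome table of minor-loci
    fractions (minor-bearing / genotyped on that chromosome).
    """
    coords = {l.locus_id: (l.chrom, l.start) for l in catalogue}
    per_bin: dict[tuple[str, int], list[bool]] = {}
    per_chrom: dict[str, list[bool]] = {}
    for c in calls:
        if not c.genotyped or c.locus_id not in coords:
            continue
        chrom, start = coords[c.locus_id]
        b = (start // bin_size) * bin_size
        per_bin.setdefault((chrom, b), []).append(c.has_minor)
        per_chrom.setdefault(chrom, []).append(c.has_minor)
    bins = [
        BinStat(
            chrom=chrom,
            bin_start=b,
            n_loci=len(flags),
            n_minor_loci=sum(flags),
            fraction=sum(flags) / len(flags),
        )
        for (chrom, b), flags in sorted(per_bin.items())
    ]
    chrom_df = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "n_loci": len(flags),
                "n_minor_loci": sum(flags),
                "fraction": sum(flags) / len(flags),
            }
            for chrom, flags in sorted(per_chrom.items())
        ]
    )
    return bins, chrom_df


def hotspot_bins(
    bins: list[BinStat], alpha: float = 0.01, bonferroni: bool = False
) -> list[BinStat]:
    """Flag bins whose minor-locus count exceeds the genome-wide rate.

    Each non-empty bin gets a one-cell goodness-of-fit statistic
    (observed - expected)^2 / expected with expected = genome-wide
    fraction x n_loci, tested upper-tail against chi-square with 1 df;
    a bin is flagged when the observed count exceeds expectation and
    p < alpha (optionally Bonferroni-corrected across non-empty bins).
    Returns the flagged bins; ``hotspot_flag``/``p_value`` are set on all.
    """
    tot_loci = sum(b.n_loci for b in bins)
    tot_minor = sum(b.n_minor_loci for b in bins)
    if tot_loci == 0:
        return []
    rate = tot_minor / tot_loci
    nonempty = [b for b in bins if b.n_loci > 0]
    thresh = alpha / len(nonempty) if bonferroni else alpha
    flagged = []
    for b in nonempty:
        expected = rate * b.n_loci
        if expected == 0:
            b.p_value = 1.0
            b.hotspot_flag = False
            continue
        x2 = (b.n_minor_loci - expected) ** 2 / expected
        b.p_value = float(stats.chi2.sf(x2, df=1))
        b.hotspot_flag = bool(b.n_minor_loci > expected and b.p_value < thresh)
        if b.hotspot_flag:
            flagged.append(b)
    return flagged


@dataclass
class ConcordanceResult:
    """Pairwise concordance/discordance over loci genotyped in both samples.

    Minor-allele categories partition the shared loci: minor alleles in
    both samples (concordant), in exactly one (discordant), in neither
    (no-minor concordant). Genotype discordance (zygosity or haplotype
    sequence disagreement) is broken down into threshold-boundary cases —
    the same second allele present in both samples but crossing the
    heterozygote support rule in only one — versus true allele-sequence
    differences.
    """

    n_shared_loci: int
    pct_genotype_discordance: float
    pct_minor_concordant: float
    pct_minor_discordant: float
    pct_no_minor_concordant: float
    n_genotype_discordant: int
    n_discordant_threshold_boundary: int
    n_discordant_sequence: int
    chi_square_stat: float = float("nan")
    p_value: float = float("nan")


def compare_samples(calls_a: list[LocusCall], calls_b: list[LocusCall]) -> ConcordanceResult:
    """Concordance of haplotype and minor-allele status between two samples."""
    a_by_id = {c.locus_id: c for c in calls_a if c.genotyped}
    b_by_id = {c.locus_id: c for c in calls_b if c.genotyped}
    shared = sorted(set(a_by_id) & set(b_by_id))
    n = len(shared)
    if n == 0:
        raise ValueError("no loci genotyped in both samples")
    n_geno_disc = 0
    n_boundary = 0
    n_seq = 0
    n_minor_both = 0
    n_minor_one = 0
    n_minor_neither = 0
    for lid in shared:
        ca, cb = a_by_id[lid], b_by_id[lid]
        hap_a = {al.allele_sequence for al in ca.haplotype_alleles}
        hap_b = {al.allele_sequence for al in cb.haplotype_alleles}
        if hap_a != hap_b:
            n_geno_disc += 1
            # threshold-boundary: the alleles missing from one haplotype are
            # nonetheless present in the other sample as minor alleles
            minors_a = {al.allele_sequence for al in ca.minor_alleles}
            minors_b = {al.allele_sequence for al in cb.minor_alleles}
            if (hap_a - hap_b) <= minors_b and (hap_b - hap_a) <= minors_a:
                n_boundary += 1
            else:
                n_seq += 1
        if ca.has_minor and cb.has_minor:
            n_minor_both += 1
        elif ca.has_minor or cb.has_minor:
            n_minor_one += 1
        else:
            n_minor_neither += 1
    return ConcordanceResult(
        n_shared_loci=n,
        pct_genotype_discordance=100.0 * n_geno_disc / n,
        pct_minor_concordant=100.0 * n_minor_both / n,
        pct_minor_discordant=100.0 * n_minor_one / n,
        pct_no_minor_concordant=100.0 * n_minor_neither / n,
        n_genotype_discordant=n_geno_disc,
        n_discordant_threshold_boundary=n_boundary,
        n_discordant_sequence=n_seq,
    )


@dataclass
class ConcordanceNull:
    """Random-cohort expectation for minor-allele concordance."""

    expected_fraction: float  # analytic product frac_a x frac_b
    expected_count: float
    mc_mean_fraction: float | None
    chi_square_stat: float
    p_value: float


def concordance_null(
    n_shared: int,
    frac_a: float,
    frac_b: float,
    observed_concordant: int,
    n_reps: int = 1000,
    seed: int | None = None,
) -> ConcordanceNull:
    """Probability that randomly chosen minor-allele loci coincide.

    The analytic expectation for the concordant fraction is
    frac_a x frac_b (independent random subsets); a Monte-Carlo null draws
    random subsets of sizes frac x n and intersects them. The observed
    concordant count is tested against the expectation with a 1-df
    Pearson goodness-of-fit statistic over the concordant/non-concordant
    partition.
    """
    if n_shared <= 0:
        raise ValueError("n_shared must be positive")
    if not (0 <= frac_a <= 1 and 0 <= frac_b <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    exp_frac = frac_a * frac_b
    exp_count = exp_frac * n_shared
    mc_mean = None
    if n_reps > 0 and seed is not None:
        rng = np.random.default_rng(seed)
        na, nb = int(round(frac_a * n_shared)), int(round(frac_b * n_shared))
        hits = np.empty(n_reps)
        for i in range(n_reps):
            a = rng.choice(n_shared, size=na, replace=False)
            b = rng.choice(n_shared, size=nb, replace=False)
            hits[i] = np.intersect1d(a, b, assume_unique=True).size
        mc_mean = float(hits.mean() / n_shared)
    if exp_count in (0.0,) or exp_count == n_shared:
        # degenerate expectation: identical only if observation matches it
        x2 = 0.0 if observed_concordant == exp_count else float("inf")
        p = 1.0 if observed_concordant == exp_count else 0.0
    else:
        exp_non = n_shared - exp_count
        obs_non = n_shared - observed_concordant
        x2 = (observed_concordant - exp_count) ** 2 / exp_count + (obs_non - exp_non) ** 2 / exp_non
        p = float(stats.chi2.sf(x2, df=1))
    return ConcordanceNull(
        expected_fraction=exp_frac,
        expected_count=exp_count,
        mc_mean_fraction=mc_mean,
        chi_square_stat=float(x2),
        p_value=p,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def between_sample_regression(fractions_a, fractions_b) -> RegressionResult:
    """OLS of sample-b fractions on sample-a fractions (paired bins/chroms)."""
    x = np.asarray(fractions_a, dtype=float)
    y = np.asarray(fractions_b, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


@dataclass
class ReadFractionSummary:
    """Mean per-locus read fractions at minor-bearing loci."""

    n_minor_loci: int
    mean_minor_fraction: float
    mean_second_allele_fraction: float
    empty: bool = False


def second_allele_read_fractions(calls: list[LocusCall]) -> ReadFractionSummary:
    """Average fractions of reads behind minor alleles and second alleles.

    Scope: loci with at least one minor allele. The minor fraction sums
    all minor-allele support over depth; the second-allele fraction is the
    support of the second allele overall (second haplotype allele when
    heterozygous, top minor allele otherwise) over depth.
    """
    minor_fracs = []
    second_fracs = []
    for c in calls:
        if not c.genotyped or not c.has_minor or c.depth == 0:
            continue
        minor_fracs.append(sum(a.n_total for a in c.minor_alleles) / c.depth)
        ordered = sorted(c.called_alleles, key=lambda a: -a.n_total)
        if len(ordered) >= 2:
            second_fracs.append(ordered[1].n_total / c.depth)
    if not minor_fracs:
        return ReadFractionSummary(0, float("nan"), float("nan"), empty=True)
    return ReadFractionSummary(
        n_minor_loci=len(minor_fracs),
        mean_minor_fraction=float(np.mean(minor_fracs)),
        mean_second_allele_fraction=float(np.mean(second_fracs)) if second_fracs else float("nan"),
    )


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end [, name]); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df[cols]


@dataclass
class RegionPartitionSummary:
    exonic: SmvSummary | None
    untranslated: SmvSummary | None
    gene_report: pd.DataFrame | None = None


def region_partition_summary(
    calls: list[LocusCall],
    catalogue: list[MstLocus],
    exon_annotation: pd.DataFrame | None,
    gene_names: dict[str, str] | None = None,
    min_minor_alleles: int = 2,
) -> RegionPartitionSummary:
    """Split loci by exon overlap and report multi-minor-allele genes.

    A locus is exonic iff it overlaps any exon interval by >= 1 bp. The
    gene report lists genes whose exonic loci carry at least
    ``min_minor_alleles`` minor alleles (``gene_names`` maps locus_id to
    gene; absent that, the BED name column labels overlapped intervals).
    """
    if exon_annotation is None or len(exon_annotation) == 0:
        warnings.warn("no exon annotation; all loci treated as untranslated")
        return RegionPartitionSummary(
            exonic=None, untranslated=sample_summary(calls, catalogue), gene_report=None
        )
    coords = {l.locus_id: (l.chrom, l.start, l.end) for l in catalogue}
    exon_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    has_name = "name" in exon_annotation.columns
    for row in exon_annotation.itertuples():
        name = str(row.name) if has_name else ""
        exon_by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end), name))

    exonic_calls, utr_calls = [], []
    gene_minor_counts: dict[str, int] = {}
    gene_loci: dict[str, list[str]] = {}
    for c in calls:
        if c.locus_id not in coords:
            continue
        chrom, start, end = coords[c.locus_id]
        genes = {
            nm for s, e, nm in exon_by_chrom.get(chrom, ()) if s < end and start < e
        }
        if genes:
            exonic_calls.append(c)
            for g in genes or {""}:
                gene = gene_names.get(c.locus_id, g) if gene_names else g
                if gene:
                    gene_minor_counts[gene] = gene_minor_counts.get(gene, 0) + len(c.minor_alleles)
                    if c.minor_alleles:
                        gene_loci.setdefault(gene, []).append(c.locus_id)
        else:
            utr_calls.append(c)
    report = pd.DataFrame(
        [
            {"gene": g, "n_minor_alleles": n, "loci": ",".join(gene_loci.get(g, []))}
            for g, n in sorted(gene_minor_counts.items())
            if n >= min_minor_alleles
        ],
        columns=["gene", "n_minor_alleles", "loci"],
    )
    return RegionPartitionSummary(
        exonic=sample_summary(exonic_calls, catalogue) if any(c.genotyped for c in exonic_calls) else None,
        untranslated=sample_summary(utr_calls, catalogue) if any(c.genotyped for c in utr_calls) else None,
        gene_report=report,
    )


def gene_overlap_counts(gene_reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Across samples: in how many samples each gene recurs.

    ``gene_reports`` maps sample name to its gene report; the result lists
    each gene with the number and identity of samples reporting it.
    """
    presence: dict[str, list[str]] = {}
    for sample, rep in gene_reports.items():
        for g in rep["gene"]:
            presence.setdefault(g, []).append(sample)
    return pd.DataFrame(
        [
            {"gene": g, "n_samples": len(ss), "samples": ",".join(sorted(ss))}
            for g, ss in sorted(presence.items())
        ],
        columns=["gene", "n_samples", "samples"],
    )
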