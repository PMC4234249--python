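"""Tumor-only microsatellite allele calling from aligned reads.

At each catalogued locus, reads that fully span the repeat plus a fixed
flanking anchor on each side are collected (subject to mapping- and
base-quality filters); the read substring between the two flank anchors is
the observed allele, so insertions or deletions inside the repeat change
its length. Distinct allele sequences are tallied with strand-aware
support, and an allele is *called* only when it reaches the read-support
minimum with at least one read on each strand. The most common allele is
the first haplotype allele; the second most common joins the haplotype
(heterozygous call) when its support exceeds 25% of the locus depth, or
50% of the major allele's support when it falls below that 25% mark.
Every other called allele — and a second allele failing the heterozygote
test — is a *minor* allele: evidence of a cell subpopulation, the unit of
somatic microsatellite variation (SMV).

No matched normal is required: the haplotype is inferred from the same
sample the minor alleles are read from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .catalogue import MstLocus

logger = logging.getLogger(__name__)

#: Zygosity labels
HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
UNCALLED = "uncalled"


@dataclass
class CallerConfig:
    """Filters and thresholds for allele calling.

    Parameters
    ----------
    flank_length : int
        Anchor length on each side of the repeat a read must match exactly
        (5 or 7 typical).
    min_base_quality : int
        Minimum Phred base quality for every base inside the repeat.
    min_mapping_quality : int
        Reads below this MAPQ are discarded.
    min_reads_per_allele : int
        Support minimum for an allele to be called (2–4 typical).
    min_locus_depth : int
        Loci with fewer retained observations are left ungenotyped.
    het_total_fraction, het_major_fraction : float
        The heterozygote rule: the second most common allele joins the
        haplotype when support > het_total_fraction x depth, or
        > het_major_fraction x major-allele support otherwise.
    require_both_strands : bool
        When True (default) a called allele needs >= 1 forward and >= 1
        reverse read.
    flank_mismatches_allowed : int
        Mismatches tolerated inside each flank anchor (0 by default).
    """

    flank_length: int = 5
    min_base_quality: int = 28
    min_mapping_quality: int = 10
    min_reads_per_allele: int = 3
    min_locus_depth: int = 15
    het_total_fraction: float = 0.25
    het_major_fraction: float = 0.50
    require_both_strands: bool = True
    flank_mismatches_allowed: int = 0

    def __post_init__(self) -> None:
        if self.flank_length < 1:
            raise ValueError("flank_length must be >= 1")
        if self.min_reads_per_allele < 2:
            raise ValueError("min_reads_per_allele must be >= 2")
        for f in (self.het_total_fraction, self.het_major_fraction):
            if not 0 < f < 1:
                raise ValueError("het fractions must lie in (0, 1)")


@dataclass(frozen=True)
class ReadObservation:
    """One spanning read's view of a locus."""

    locus_id: str
    allele_sequence: str
    strand: str  # "+" or "-"
    read_name: str = ""


@dataclass
class AlleleSupport:
    """A distinct allele sequence with strand-aware read support."""

    allele_sequence: str
    n_forward: int = 0
    n_reverse: int = 0

    @property
    def n_total(self) -> int:
        return self.n_forward + self.n_reverse

    @property
    def length(self) -> int:
        return len(self.allele_sequence)


@dataclass
class LocusCall:
    """Per-locus calling result.

    ``depth`` is the number of retained observations (after quality and
    spanning filters, before the per-allele support threshold) — the
    denominator of the heterozygote-rule fractions.
    """

    locus_id: str
    depth: int
    zygosity: str
    haplotype_alleles: list[AlleleSupport] = field(default_factory=list)
    minor_alleles: list[AlleleSupport] = field(default_factory=list)
    reason: str = ""

    @property
    def n_alleles_total(self) -> int:
        return len(self.haplotype_alleles) + len(self.minor_alleles)

    @property
    def called_alleles(self) -> list[AlleleSupport]:
        return self.haplotype_alleles + self.minor_alleles

    @property
    def genotyped(self) -> bool:
        return self.zygosity in (HOMOZYGOUS, HETEROZYGOUS)

    @property
    def has_minor(self) -> bool:
        return len(self.minor_alleles) > 0

    @property
    def major_allele(self) -> AlleleSupport | None:
        return self.haplotype_alleles[0] if self.haplotype_alleles else None


def _anchor_matches(observed: str, expected: str, tolerated: int) -> bool:
    if len(observed) != len(expected):
        return False
    mism = sum(a != b for a, b in zip(observed, expected))
    return mism <= tolerated


def extract_observations(
    alignments: pysam.AlignmentFile,
    locus: MstLocus,
    config: CallerConfig,
    reference: dict[str, str] | None = None,
    flank_left: str | None = None,
    flank_right: str | None = None,
) -> list[ReadObservation]:
    """Collect allele observations from reads spanning ``locus``.

    A read is retained when it (a) covers the window
    ``[start - flank_length, end + flank_length)`` entirely, (b) has
    MAPQ >= ``min_mapping_quality``, (c) has base quality >=
    ``min_base_quality`` at every aligned base inside the repeat, and
    (d) matches both flank anchors exactly (up to
    ``flank_mismatches_allowed``). The allele sequence is the read
    substring strictly between the anchors.

    Flank anchor sequences are taken from ``reference`` (or passed
    explicitly); they delimit the allele within the read so that indels
    inside the repeat shift the allele length.
    """
    fl = config.flank_length
    w_start = locus.start - fl
    w_end = locus.end + fl
    if flank_left is None or flank_right is None:
        if reference is None:
            raise ValueError("need reference sequences or explicit flank anchors")
        chrom_seq = str(reference[locus.chrom]).upper()
        if w_start < 0 or w_end > len(chrom_seq):
            return []  # locus too close to a contig edge for anchoring
        flank_left = chrom_seq[w_start : locus.start]
        flank_right = chrom_seq[locus.end : w_end]

    out: list[ReadObservation] = []
    n_malformed = 0
    for read in alignments.fetch(locus.chrom, max(0, w_start), w_end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < config.min_mapping_quality:
            continue
        try:
            pairs = read.get_aligned_pairs(matches_only=False)
            seq = read.query_sequence
            quals = read.query_qualities
        except Exception:  # pragma: no cover - defensive
            n_malformed += 1
            continue
        if seq is None or quals is None:
            n_malformed += 1
            continue
        # map reference window edges to query coordinates; read must align
        # a base at both window edges (full span including both anchors)
        ref_to_query: dict[int, int] = {
            rpos: qpos for qpos, rpos in pairs if rpos is not None and qpos is not None
        }
        covered = read.reference_start <= w_start and read.reference_end is not None and read.reference_end >= w_end
        if not covered:
            continue
        # query index of the first anchor base and of the base following the
        # right anchor's last base
        q_left = ref_to_query.get(w_start)
        q_right_last = ref_to_query.get(w_end - 1)
        q_rep_first = ref_to_query.get(locus.start - 1)  # last base of left anchor
        q_rep_last = ref_to_query.get(locus.end)  # first base of right anchor
        if None in (q_left, q_right_last, q_rep_first, q_rep_last):
            continue  # an anchor boundary base is deleted in the read
        left_anchor = seq[q_left : q_rep_first + 1]
        right_anchor = seq[q_rep_last : q_right_last + 1]
        if not _anchor_matches(left_anchor, flank_left, config.flank_mismatches_allowed):
            continue
        if not _anchor_matches(right_anchor, flank_right, config.flank_mismatches_allowed):
            continue
        allele = seq[q_rep_first + 1 : q_rep_last]
        rep_quals = quals[q_rep_first + 1 : q_rep_last]
        if len(rep_quals) and min(rep_quals) < config.min_base_quality:
            continue
        out.append(
            ReadObservation(
                locus_id=locus.locus_id or f"{locus.chrom}:{locus.start}-{locus.end}",
                allele_sequence=allele,
                strand="-" if read.is_reverse else "+",
                read_name=read.query_name or "",
            )
        )
    if n_malformed:
        logger.debug("%s: skipped %d malformed records", locus.locus_id, n_malformed)
    return out


def tally_alleles(
    observations: list[ReadObservation], config: CallerConfig
) -> list[AlleleSupport]:
    """Group observations by allele sequence and keep called alleles only.

    An allele is called iff its total support reaches
    ``min_reads_per_allele`` and (when ``require_both_strands``) it has at
    least one read on each strand. Output is sorted by support descending,
    ties broken by longer allele then lexicographic sequence.
    """
    counts: dict[str, AlleleSupport] = {}
    for obs in observations:
        sup = counts.setdefault(obs.allele_sequence, AlleleSupport(obs.allele_sequence))
        if obs.strand == "+":
            sup.n_forward += 1
        else:
            sup.n_reverse += 1
    called = [
        s
        for s in counts.values()
        if s.n_total >= config.min_reads_per_allele
        and (not config.require_both_strands or (s.n_forward >= 1 and s.n_reverse >= 1))
    ]
    called.sort(key=lambda s: (-s.n_total, -s.length, s.allele_sequence))
    return called


def call_locus(
    alleles: list[AlleleSupport], depth: int, config: CallerConfig, locus_id: str = ""
) -> LocusCall:
    """Apply the zygosity rules to the called alleles of one locus.

    With depth below ``min_locus_depth`` the locus is left ungenotyped.
    Otherwise the top allele is haplotype allele 1; the runner-up joins the
    haplotype when its support exceeds ``het_total_fraction`` of the depth,
    or — failing that — ``het_major_fraction`` of the top allele's support.
    All other called alleles (including a runner-up failing the test) are
    minor alleles.
    """
    if depth < config.min_locus_depth:
        return LocusCall(locus_id, depth, UNCALLED, reason="low_depth")
    if not alleles:
        return LocusCall(locus_id, depth, UNCALLED, reason="no_called_alleles")
    alleles = sorted(alleles, key=lambda s: (-s.n_total, -s.length, s.allele_sequence))
    major = alleles[0]
    haplotype = [major]
    minors: list[AlleleSupport] = []
    zygosity = HOMOZYGOUS
    if len(alleles) > 1:
        second = alleles[1]
        is_het = second.n_total > config.het_total_fraction * depth or (
            second.n_total > config.het_major_fraction * major.n_total
        )
        if is_het:
            haplotype.append(second)
            zygosity = HETEROZYGOUS
        else:
            minors.append(second)
        minors.extend(alleles[2:])
    return LocusCall(locus_id, depth, zygosity, haplotype, minors)


def call_sample(
    alignments: pysam.AlignmentFile,
    catalogue: list[MstLocus],
    config: CallerConfig | None = None,
    reference: dict[str, str] | None = None,
) -> list[LocusCall]:
    """Call every catalogue locus with at least one spanning read.

    Output order equals catalogue order; a summary (loci attempted /
    genotyped / with minor alleles) is logged.
    """
    if config is None:
        config = CallerConfig()
    calls: list[LocusCall] = []
    for locus in catalogue:
        obs = extract_observations(alignments, locus, config, reference=reference)
        if not obs:
            continue
        alleles = tally_alleles(obs, config)
        calls.append(call_locus(alleles, len(obs), config, locus_id=obs[0].locus_id))
    n_geno = sum(c.genotyped for c in calls)
    n_minor = sum(c.has_minor for c in calls)
    logger.info(
        "attempted %d loci, %d with reads, %d genotyped, %d with minor alleles",
        len(catalogue), len(calls), n_geno, n_minor,
    )
    return calls


def calls_to_frame(calls: list[LocusCall]) -> pd.DataFrame:
    """Tidy per-locus table; per-allele columns are pipe-joined lists."""
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "depth": c.depth,
                "zygosity": c.zygosity,
                "n_alleles_total": c.n_alleles_total,
                "allele_lengths": "|".join(str(a.length) for a in c.called_alleles),
                "allele_seqs": "|".join(a.allele_sequence for a in c.called_alleles),
                "n_forward": "|".join(str(a.n_forward) for a in c.called_alleles),
                "n_reverse": "|".join(str(a.n_reverse) for a in c.called_alleles),
                "n_haplotype": len(c.haplotype_alleles),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id", "depth", "zygosity", "n_alleles_total",
            "allele_lengths", "allele_seqs", "n_forward", "n_reverse", "n_haplotype",
        ],
    )


def write_calls(calls: list[LocusCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[LocusCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out: list[LocusCall] = []
    for row in df.itertuples():
        supports: list[AlleleSupport] = []
        if row.allele_seqs:
            seqs = row.allele_seqs.split("|")
            nf = [int(x) for x in row.n_forward.split("|")]
            nr = [int(x) for x in row.n_reverse.split("|")]
            supports = [AlleleSupport(s, f, r) for s, f, r in zip(seqs, nf, nr)]
        n_hap = int(row.n_haplotype)
        out.append(
            LocusCall(
                locus_id=row.locus_id,
                depth=int(row.depth),
                zygosity=row.zygosity,
                haplotype_alleles=supports[:n_hap],
                minor_alleles=supports[n_hap:],
            )
        )
    return out
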