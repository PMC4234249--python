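"""Synthetic exome-like read simulation over planted microsatellites.

Builds a synthetic reference of perfect tandem repeats separated by
non-repetitive flanks, assigns each locus a diploid genotype (a fraction of
loci heterozygous, with the second allele an in-phase repeat-unit change)
and optionally a planted subclonal minor allele at a low read fraction,
then emits error-bearing 2x``read_length`` paired-end reads as positioned
alignments (SAM/BAM) plus FASTQ — alignment is bypassed by construction,
so the caller can be evaluated in isolation from mapping error.

Per-base errors are a configurable mix of substitutions and 1-nt indels
(default 90:10, an SNP-dominated error spectrum). Per-locus spanning depth
is drawn either from an overdispersed gamma-Poisson model (default,
mimicking real exome capture) or a plain Poisson ("uniform" mode,
wgsim-like). Everything is reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .caller import LocusCall
from .catalogue import (
    CatalogueConfig,
    Motif,
    MstLocus,
    min_rotation,
    scan_tandem_repeats,
)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for the error-characterization simulation.

    Defaults reproduce the exome-like setting: ~2,000 diploid loci with
    motif lengths 1–6 and locus lengths 8–44 nt, 2x100 bp paired reads at a
    mean spanning depth of 50 (overdispersed), 5% heterozygous loci with
    in-phase second alleles, per-base error in the 0.5–5% sweep range with
    a 90:10 substitution:indel mix.
    """

    n_loci: int = 2000
    motif_length_weights: tuple[float, ...] = (0.40, 0.25, 0.15, 0.10, 0.05, 0.05)
    copies_range: tuple[int, int] = (3, 20)
    locus_length_range: tuple[int, int] = (8, 44)
    flank_length_genomic: int = 500
    read_length: int = 100
    fragment_length: int = 300
    mean_depth: float = 50.0
    depth_dispersion: float = 8.0
    coverage_mode: str = "overdispersed"  # or "uniform"
    per_base_error: float = 0.01
    error_indel_fraction: float = 0.10
    error_low_quality_prob: float = 0.0
    base_quality: int = 35
    error_base_quality: int = 20
    het_fraction: float = 0.05
    minor_planting_rate: float = 0.0
    minor_read_fraction_range: tuple[float, float] = (0.06, 0.18)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_indel_fraction <= 1):
            raise ValueError("error_indel_fraction must lie in [0, 1]")
        if self.minor_read_fraction_range[1] >= 0.25:
            raise ValueError("planted minor fractions must stay below the het threshold (0.25)")
        if self.coverage_mode not in ("overdispersed", "uniform"):
            raise ValueError("coverage_mode must be 'overdispersed' or 'uniform'")
        if not (0.0 <= self.per_base_error <= 0.05):
            warnings.warn(
                f"per_base_error {self.per_base_error} outside the characterized 0.5–5% sweep"
            )


@dataclass
class TruthRecord:
    """Planted genotype and subclonal alleles for one locus."""

    locus_id: str
    true_alleles: list[str]  # one (homozygous) or two (heterozygous) sequences
    allele_fractions: list[float]  # 1.0, or 0.5/0.5, scaled down by minor mass
    planted_minor_alleles: list[str] = field(default_factory=list)
    minor_fractions: list[float] = field(default_factory=list)
    zygosity_truth: str = HOMOZYGOUS


def _random_nonrepetitive(rng: np.random.Generator, length: int, scan_config: CatalogueConfig) -> str:
    """A random sequence free of catalogue-grade repeats.

    Short incidental near-repeats below the copy-number filter are
    tolerated (as in real intergenic sequence); anything the catalogue
    scanner + filters would accept as an MST locus forces a redraw.
    """
    seq = list("".join(rng.choice(list(_BASES), size=length)))
    for _ in range(50):
        cands = scan_tandem_repeats({"_": "".join(seq)}, scan_config)
        bad = [c for c in cands if c.copies >= scan_config.min_motif_copies]
        if not bad:
            return "".join(seq)
        # re-randomize the offending windows rather than redrawing the flank
        for c in bad:
            for i in range(c.start, c.end):
                seq[i] = _BASES[int(rng.integers(0, 4))]
    raise RuntimeError("could not draw a non-repetitive flank")  # pragma: no cover


def _primitive_unit(rng: np.random.Generator, k: int) -> str:
    """A random motif unit of length k that is not itself periodic."""
    while True:
        unit = "".join(rng.choice(list(_BASES), size=k))
        if all(unit != unit[d:] + unit[:d] for d in range(1, k)):
            return unit


_JUNCTION_MARGIN = 60  # nt of flank examined on each side of a junction


def _junction_clean(
    left_repeat: str, flank: str, right_repeat: str, scan_cfg: CatalogueConfig
) -> bool:
    """True when scanning across both flank junctions reproduces the
    planted repeat intervals exactly (no extension into the flank and no
    incidental candidate overlapping a repeat)."""
    m = _JUNCTION_MARGIN
    if left_repeat:
        seg = left_repeat + flank[:m]
        planted = (0, len(left_repeat))
        for c in scan_tandem_repeats({"_": seg}, scan_cfg):
            if c.start < planted[1] and c.end > planted[0] and (c.start, c.end) != planted:
                return False
    if right_repeat:
        off = len(flank[-m:])
        seg = flank[-m:] + right_repeat
        planted = (off, off + len(right_repeat))
        for c in scan_tandem_repeats({"_": seg}, scan_cfg):
            if c.start < planted[1] and c.end > planted[0] and (c.start, c.end) != planted:
                return False
    return True


def _flank_between(
    rng: np.random.Generator,
    length: int,
    scan_cfg: CatalogueConfig,
    prev_rep: str,
    prev_unit: str,
    next_rep: str,
    next_unit: str,
) -> str:
    """A non-repetitive flank whose edges cannot extend the adjacent repeats.

    The first/last 2k flank bases are drawn from the three bases that
    mismatch the neighbouring repeat's continued template, which blocks
    purity extension across the junction (a bridge would need a template
    match within a k-base gap). The junction scan then verifies.
    """
    for _ in range(50):
        f = list(_random_nonrepetitive(rng, length, scan_cfg))
        if prev_unit:
            k = len(prev_unit)
            for i in range(min(2 * k, length)):
                tb = prev_unit[(len(prev_rep) + i) % k]
                choices = [b for b in _BASES if b != tb]
                f[i] = choices[int(rng.integers(0, 3))]
        if next_unit:
            k = len(next_unit)
            for j in range(min(2 * k, length)):
                tb = next_unit[(-(j + 1)) % k]
                choices = [b for b in _BASES if b != tb]
                f[length - 1 - j] = choices[int(rng.integers(0, 3))]
        flank = "".join(f)
        cands = scan_tandem_repeats({"_": flank}, scan_cfg)
        if any(c.copies >= scan_cfg.min_motif_copies for c in cands):
            continue  # edge edits created a repeat; redraw
        if _junction_clean(prev_rep, flank, next_rep, scan_cfg):
            return flank
    raise RuntimeError("could not place a clean junction flank")  # pragma: no cover


def build_synthetic_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[MstLocus]]:
    """Plant ``n_loci`` perfect repeats separated by non-repetitive flanks.

    Each locus is a perfect tandem repetition of a primitive 1–6 nt unit
    with an integer copy number chosen so the locus length falls in
    ``locus_length_range``. Junctions are verified with the catalogue
    scanner: the flank adjoining each repeat is redrawn until a local scan
    finds exactly the planted interval, so the emitted catalogue matches a
    reference scan at the planted coordinates.
    """
    rng = np.random.default_rng(config.seed)
    scan_cfg = CatalogueConfig()
    weights = np.asarray(config.motif_length_weights, dtype=float)
    weights = weights / weights.sum()
    lmin, lmax = config.locus_length_range
    cmin, cmax = config.copies_range

    repeats: list[tuple[str, int]] = []  # (unit, copies)
    for _ in range(config.n_loci):
        for _try in range(200):
            k = int(rng.choice(6, p=weights)) + 1
            lo = max(cmin, -(-lmin // k), 2)  # >= 2 units, >= min length
            hi = min(cmax, lmax // k)
            if lo > hi:
                continue
            copies = int(rng.integers(lo, hi + 1))
            unit = _primitive_unit(rng, k)
            rep = unit * copies
            # the bare repeat must scan to exactly the planted interval
            # (units with internal near-periodicity, e.g. ACACAG, do not)
            found = {(c.start, c.end) for c in scan_tandem_repeats({"_": rep}, scan_cfg)}
            if found == {(0, len(rep))}:
                repeats.append((unit, copies))
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a scannable repeat unit")

    chrom = "sim1"
    parts: list[str] = []
    pos = 0
    catalogue: list[MstLocus] = []
    prev_repeat = ""
    prev_unit = ""
    for i, (unit, copies) in enumerate(repeats):
        rep = unit * copies
        flank = _flank_between(
            rng, config.flank_length_genomic, scan_cfg,
            prev_repeat, prev_unit, rep, unit,
        )
        parts.append(flank)
        pos += len(flank)
        start = pos
        parts.append(rep)
        pos += len(rep)
        catalogue.append(
            MstLocus(
                chrom=chrom,
                start=start,
                end=pos,
                motif=Motif(min_rotation(unit)),
                copies=float(copies),
                purity=1.0,
                locus_id=f"mst{i:05d}",
            )
        )
        prev_repeat = rep
        prev_unit = unit
    # trailing flank, junction-checked against the last repeat
    parts.append(
        _flank_between(
            rng, config.flank_length_genomic, scan_cfg, prev_repeat, prev_unit, "", ""
        )
    )
    return {chrom: "".join(parts)}, catalogue


def _shift_repeat_allele(unit: str, copies: int, delta_units: int) -> str:
    return unit * (copies + delta_units)


def assign_truth(
    catalogue: list[MstLocus],
    config: SimulationConfig,
    reference: dict[str, str] | None = None,
) -> list[TruthRecord]:
    """Draw diploid genotypes and planted subclonal minor alleles.

    ``het_fraction`` of loci receive a second haplotype allele differing by
    an in-phase unit-count change (±1 or ±2 units, redrawn on collision
    with the reference allele or on leaving the spannable length range);
    ``minor_planting_rate`` of loci receive one subclonal allele (±1 unit
    off a haplotype allele) at a read fraction drawn uniformly from
    ``minor_read_fraction_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    max_len = config.read_length - 2 * 7  # must remain spannable with 7-nt anchors
    out: list[TruthRecord] = []
    for locus in catalogue:
        unit_canon = locus.motif.canonical_form
        k = len(unit_canon)
        copies = int(round(locus.copies))
        if reference is not None:
            ref_allele = str(reference[locus.chrom])[locus.start : locus.end]
            unit = ref_allele[:k]
        else:
            unit = unit_canon
            ref_allele = unit * copies
        alleles = [ref_allele]
        fractions = [1.0]
        zyg = HOMOZYGOUS
        if rng.random() < config.het_fraction:
            for _ in range(20):
                mag = 1 if rng.random() < 0.7 else 2
                delta = mag if rng.random() < 0.5 else -mag
                new_copies = copies + delta
                new_len = new_copies * k
                if new_copies >= 2 and new_len >= 2 and new_len <= max_len:
                    second = _shift_repeat_allele(unit, copies, delta)
                    if second != ref_allele:
                        alleles = [ref_allele, second]
                        fractions = [0.5, 0.5]
                        zyg = HETEROZYGOUS
                        break
        minors: list[str] = []
        minor_fracs: list[float] = []
        if config.minor_planting_rate > 0 and rng.random() < config.minor_planting_rate:
            for _ in range(20):
                base_idx = int(rng.integers(0, len(alleles)))
                delta = 1 if rng.random() < 0.5 else -1
                cand_copies = int(len(alleles[base_idx]) / k) + delta
                cand = unit * cand_copies
                if cand_copies >= 2 and len(cand) <= max_len and cand not in alleles:
                    minors.append(cand)
                    f = rng.uniform(*config.minor_read_fraction_range)
                    minor_fracs.append(float(f))
                    break
        if minors:
            scale = 1.0 - sum(minor_fracs)
            fractions = [f * scale for f in fractions]
        out.append(
            TruthRecord(
                locus_id=locus.locus_id,
                true_alleles=alleles,
                allele_fractions=fractions,
                planted_minor_alleles=minors,
                minor_fractions=minor_fracs,
                zygosity_truth=zyg,
            )
        )
    return out


class _SimRead:
    __slots__ = ("name", "chrom", "ref_start", "seq", "quals", "cigar", "is_reverse", "is_read1", "mate_ref_start", "mate_is_reverse")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _compose_read(
    columns: list[tuple[int | None, str]],
    rng: np.random.Generator,
    sub_rate: float,
    indel_rate: float,
    tail: list[tuple[int | None, str]],
    target_len: int,
) -> tuple[list[tuple[int | None, str]], list[bool]]:
    """Inject per-base errors into aligned read columns.

    Each column is (reference position or None, base). Substitution flips
    the base; an indel error inserts a random base (None column) or drops
    the column. Read length is restored to ``target_len`` from ``tail``
    (continuation of the template) or by truncation. Returns the error-bearing
    columns and a per-column is-error flag.
    """
    out: list[tuple[int | None, str]] = []
    err: list[bool] = []
    half_indel = indel_rate / 2.0
    for ref_pos, base in columns:
        r = rng.random()
        if r < sub_rate:
            out.append((ref_pos, _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]))
            err.append(True)
        elif r < sub_rate + half_indel:
            # insertion error: keep the base, add a random extra one
            out.append((ref_pos, base))
            err.append(False)
            out.append((None, _BASES[int(rng.integers(0, 4))]))
            err.append(True)
        elif r < sub_rate + indel_rate:
            continue  # deletion error: drop the column
        else:
            out.append((ref_pos, base))
            err.append(False)
    ti = 0
    while len(out) < target_len and ti < len(tail):
        out.append(tail[ti])
        err.append(False)
        ti += 1
    if len(out) > target_len:
        out = out[:target_len]
        err = err[:target_len]
    return out, err


def _columns_to_cigar(columns: list[tuple[int | None, str]]) -> list[tuple[int, int]]:
    """CIGAR (M/I/D ops) from aligned columns; ref-position jumps become D."""
    cigar: list[tuple[int, int]] = []

    def push(op: int, length: int) -> None:
        if length <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))

    prev_ref: int | None = None
    for ref_pos, _ in columns:
        if ref_pos is None:
            push(1, 1)  # I
        else:
            if prev_ref is not None and ref_pos - prev_ref > 1:
                push(2, ref_pos - prev_ref - 1)  # D
            push(0, 1)  # M
            prev_ref = ref_pos
    return cigar


def generate_reads(
    reference: dict[str, str],
    catalogue: list[MstLocus],
    truth: list[TruthRecord],
    config: SimulationConfig,
) -> list[_SimRead]:
    """Generate positioned, error-bearing read pairs for every locus.

    For each locus the spanning-read count is drawn from the coverage
    model; each spanning read carries an allele drawn by the truth
    fractions and fully covers the repeat plus 7-nt anchors (so both the
    5- and 7-nt flank settings are usable), on a uniformly random strand.
    Its mate is a non-spanning reference-content read at fragment
    distance. Errors are injected per base at ``per_base_error`` with the
    configured substitution:indel mix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sub_rate = config.per_base_error * (1.0 - config.error_indel_fraction)
    indel_rate = config.per_base_error * config.error_indel_fraction
    L = config.read_length
    frag = config.fragment_length
    truth_by_id = {t.locus_id: t for t in truth}
    reads: list[_SimRead] = []
    anchor = 7  # spanning guarantee covers the widest supported flank

    for locus in catalogue:
        t = truth_by_id[locus.locus_id]
        chrom_seq = str(reference[locus.chrom])
        if config.coverage_mode == "overdispersed":
            lam = rng.gamma(config.depth_dispersion, config.mean_depth / config.depth_dispersion)
        else:
            lam = config.mean_depth
        depth = int(rng.poisson(lam))
        if depth == 0:
            continue
        # Allocate reads to alleles: planted minors are drawn binomially at
        # their read fraction (so recovery follows a binomial support model);
        # the remaining reads split between the haplotype alleles in exact
        # proportion (so genotype recovery is deterministic when error-free).
        assignment: list[str] = []
        for seq, f in zip(t.planted_minor_alleles, t.minor_fractions):
            assignment.extend([seq] * int(rng.binomial(depth, f)))
        rem = max(depth - len(assignment), 0)
        if len(t.true_alleles) == 2:
            n_first = rem // 2 + (int(rng.integers(0, 2)) if rem % 2 else 0)
            assignment.extend([t.true_alleles[0]] * n_first)
            assignment.extend([t.true_alleles[1]] * (rem - n_first))
        else:
            assignment.extend([t.true_alleles[0]] * rem)
        assignment = assignment[:depth]
        rng.shuffle(assignment)
        ref_len = locus.end - locus.start
        for j, allele in enumerate(assignment):
            la = len(allele)
            # haplotype template: reference with this locus's repeat replaced
            M = L  # margin on each side of the repeat
            hap_start = locus.start - M
            left = chrom_seq[hap_start : locus.start]
            right = chrom_seq[locus.end : locus.end + M]
            hapseq = left + allele + right
            # aligned columns of the template
            cols: list[tuple[int | None, str]] = []
            for i2, b in enumerate(left):
                cols.append((hap_start + i2, b))
            nm = min(la, ref_len)
            for i2 in range(la):
                cols.append((locus.start + i2, allele[i2]) if i2 < nm else (None, allele[i2]))
            # deletion (ref longer than allele) appears as a ref-pos jump
            for i2, b in enumerate(right):
                cols.append((locus.end + i2, b))
            # spanning-read offset: must cover [M - anchor, M + la + anchor)
            o_hi = M - anchor
            o_lo = M + la + anchor - L
            o = int(rng.integers(o_lo, o_hi + 1))
            span_cols = cols[o : o + L]
            tail = cols[o + L : o + L + 12]
            span_cols, span_err = _compose_read(span_cols, rng, sub_rate, indel_rate, tail, L)
            is_reverse = bool(rng.random() < 0.5)
            name = f"sim_{locus.locus_id}_{j:04d}"
            # mate: reference-content read at fragment distance, away from loci
            if is_reverse:
                mate_start = hap_start + o + L - frag
                mate_ref = chrom_seq[mate_start : mate_start + L]
                mate_cols = [(mate_start + i2, b) for i2, b in enumerate(mate_ref)]
                mate_tail = [(mate_start + L + i2, b) for i2, b in enumerate(chrom_seq[mate_start + L : mate_start + L + 12])]
            else:
                mate_start = hap_start + o + frag - L
                mate_ref = chrom_seq[mate_start : mate_start + L]
                mate_cols = [(mate_start + i2, b) for i2, b in enumerate(mate_ref)]
                mate_tail = [(mate_start + L + i2, b) for i2, b in enumerate(chrom_seq[mate_start + L : mate_start + L + 12])]
            mate_cols, mate_err = _compose_read(mate_cols, rng, sub_rate, indel_rate, mate_tail, L)

            for cols_i, err_i, rev_i, first_i in (
                (span_cols, span_err, is_reverse, True),
                (mate_cols, mate_err, not is_reverse, False),
            ):
                seq = "".join(b for _, b in cols_i)
                quals = [
                    config.error_base_quality
                    if (e and rng.random() < config.error_low_quality_prob)
                    else config.base_quality
                    for e in err_i
                ]
                ref_positions = [p for p, _ in cols_i if p is not None]
                reads.append(
                    _SimRead(
                        name=name,
                        chrom=locus.chrom,
                        ref_start=ref_positions[0],
                        seq=seq,
                        quals=quals,
                        cigar=_columns_to_cigar(cols_i),
                        is_reverse=rev_i,
                        is_read1=first_i,
                        mate_ref_start=None,
                        mate_is_reverse=None,
                    )
                )
            reads[-2].mate_ref_start = reads[-1].ref_start
            reads[-2].mate_is_reverse = reads[-1].is_reverse
            reads[-1].mate_ref_start = reads[-2].ref_start
            reads[-1].mate_is_reverse = reads[-2].is_reverse
    return reads


def write_alignments(
    reads: list[_SimRead],
    reference: dict[str, str],
    bam_path: str,
    fastq_prefix: str | None = None,
) -> str:
    """Write reads as a coordinate-sorted, indexed BAM (plus FASTQ pair).

    Returns the BAM path. Use a ``.sam`` suffix on ``bam_path`` for a
    plain-text SAM (not indexed, so region fetches are unavailable).
    """
    chroms = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(str(reference[c]))} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(reads, key=lambda r: (tid[r.chrom], r.ref_start, r.name, not r.is_read1))
    is_sam = str(bam_path).endswith(".sam")
    mode = "wh" if is_sam else "wb"
    with pysam.AlignmentFile(str(bam_path), mode, header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = r.quals
            a.reference_id = tid[r.chrom]
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigar = r.cigar
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = r.is_read1
            a.is_read2 = not r.is_read1
            a.is_reverse = r.is_reverse
            a.mate_is_reverse = bool(r.mate_is_reverse)
            a.next_reference_id = tid[r.chrom]
            a.next_reference_start = r.mate_ref_start
            out.write(a)
    if not is_sam:
        pysam.index(str(bam_path))
    if fastq_prefix is not None:
        by_name: dict[str, dict[bool, _SimRead]] = {}
        for r in reads:
            by_name.setdefault(r.name, {})[r.is_read1] = r
        with open(f"{fastq_prefix}_1.fastq", "w") as f1, open(f"{fastq_prefix}_2.fastq", "w") as f2:
            for name in sorted(by_name):
                for first, fh in ((True, f1), (False, f2)):
                    r = by_name[name][first]
                    seq = _revcomp(r.seq) if r.is_reverse else r.seq
                    quals = r.quals[::-1] if r.is_reverse else r.quals
                    fh.write(f"@{name}/{1 if first else 2}\n{seq}\n+\n")
                    fh.write("".join(chr(q + 33) for q in quals) + "\n")
    return str(bam_path)


def write_truth(truth: list[TruthRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "locus_id": t.locus_id,
                "zygosity_truth": t.zygosity_truth,
                "true_alleles": "|".join(t.true_alleles),
                "allele_fractions": "|".join(f"{f:.10g}" for f in t.allele_fractions),
                "planted_minor_alleles": "|".join(t.planted_minor_alleles),
                "minor_fractions": "|".join(f"{f:.10g}" for f in t.minor_fractions),
            }
            for t in truth
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[TruthRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out = []
    for row in df.itertuples():
        out.append(
            TruthRecord(
                locus_id=row.locus_id,
                true_alleles=row.true_alleles.split("|"),
                allele_fractions=[float(x) for x in row.allele_fractions.split("|")],
                planted_minor_alleles=row.planted_minor_alleles.split("|") if row.planted_minor_alleles else [],
                minor_fractions=[float(x) for x in row.minor_fractions.split("|")] if row.minor_fractions else [],
                zygosity_truth=row.zygosity_truth,
            )
        )
    return out


@dataclass
class EvaluationSummary:
    """Caller-vs-truth scores for one simulated sample."""

    n_evaluated: int
    n_genotyped: int
    zygosity_accuracy: float
    false_allele_free_fraction: float
    minor_sensitivity: float | None
    depth_by_allele_count: dict[int, tuple[float, int]]
    n_unmatched: int = 0


def evaluate_against_truth(
    calls: list[LocusCall], truth: list[TruthRecord]
) -> EvaluationSummary:
    """Score calls against the planted truth.

    Reports zygosity accuracy over genotyped loci, the fraction of
    genotyped loci at which every called allele is a truth allele
    (haplotype or planted minor), sensitivity of planted-minor recovery,
    and the mean depth per total-allele-count table.
    """
    truth_by_id = {t.locus_id: t for t in truth}
    n_unmatched = sum(1 for c in calls if c.locus_id not in truth_by_id)
    if n_unmatched:
        warnings.warn(f"{n_unmatched} calls had no matching truth record")
    matched = [c for c in calls if c.locus_id in truth_by_id]
    genotyped = [c for c in matched if c.genotyped]
    n_zyg_ok = 0
    n_clean = 0
    minor_hit = 0
    minor_tot = 0
    depth_tab: dict[int, list[int]] = {}
    for c in genotyped:
        t = truth_by_id[c.locus_id]
        if c.zygosity == t.zygosity_truth:
            n_zyg_ok += 1
        truthful = set(t.true_alleles) | set(t.planted_minor_alleles)
        if all(a.allele_sequence in truthful for a in c.called_alleles):
            n_clean += 1
        if t.planted_minor_alleles:
            minor_tot += 1
            called_seqs = {a.allele_sequence for a in c.called_alleles}
            if set(t.planted_minor_alleles) <= called_seqs:
                minor_hit += 1
        depth_tab.setdefault(c.n_alleles_total, []).append(c.depth)
    n = len(genotyped)
    return EvaluationSummary(
        n_evaluated=len(matched),
        n_genotyped=n,
        zygosity_accuracy=n_zyg_ok / n if n else float("nan"),
        false_allele_free_fraction=n_clean / n if n else float("nan"),
        minor_sensitivity=minor_hit / minor_tot if minor_tot else None,
        depth_by_allele_count={
            k: (float(np.mean(v)), len(v)) for k, v in sorted(depth_tab.items())
        },
        n_unmatched=n_unmatched,
    )


def simulate_sample(
    config: SimulationConfig, workdir: str, fastq: bool = False
) -> tuple[dict[str, str], list[MstLocus], list[TruthRecord], str]:
    """Build reference + truth + BAM under ``workdir``; returns the BAM path."""
    import os

    reference, catalogue = build_synthetic_reference(config)
    truth = assign_truth(catalogue, config, reference=reference)
    reads = generate_reads(reference, catalogue, truth, config)
    bam = os.path.join(workdir, "sim.bam")
    write_alignments(reads, reference, bam, fastq_prefix=os.path.join(workdir, "sim") if fastq else None)
    return reference, catalogue, truth, bam
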