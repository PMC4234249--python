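"""Microsatellite (MST) locus catalogue construction.

A microsatellite is a tandem repeat of a 1–6 nt motif. This module scans a
reference sequence for repeat runs, scores each candidate by *purity* (the
fraction of bases matching a perfect tandem repetition of the best-phase
motif), filters candidates by length (>=8 nt), copy number (>=3) and purity
(>=0.85), resolves overlaps deterministically, and samples fixed-length
non-repetitive control loci for background comparisons.

Coordinates are 0-based half-open throughout; the catalogue TSV is
BED3-compatible in its first three columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = frozenset("ACGT")

CATALOGUE_COLUMNS = ["chrom", "start", "end", "motif", "copies", "purity", "locus_id"]


class InvalidMotifError(ValueError):
    """Raised for motifs with non-ACGT characters or invalid length."""


@dataclass(frozen=True)
class Motif:
    """A repeat unit of 1–6 nt, stored with its canonical rotation.

    Two motifs that are rotations of each other (e.g. ``AC`` and ``CA``)
    describe the same repeat; ``canonical_form`` is the lexicographically
    minimal rotation and is used for de-duplication and reporting.
    """

    sequence: str
    canonical_form: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or not set(seq) <= DNA_ALPHABET:
            raise InvalidMotifError(f"motif must be non-empty A/C/G/T: {self.sequence!r}")
        if len(seq) > 6:
            raise InvalidMotifError(f"motif longer than 6 nt: {self.sequence!r}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "canonical_form", min_rotation(seq))

    def __len__(self) -> int:
        return len(self.sequence)


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s``."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def canonical_motif(motif: str) -> Motif:
    """Return the canonical :class:`Motif` for a repeat-unit string.

    All rotations of the same unit map to the same canonical form:
    ``canonical_motif("CA").canonical_form == "AC"``.
    """
    m = Motif(motif)
    return Motif(m.canonical_form)


@dataclass(frozen=True)
class MstLocus:
    """One catalogued microsatellite locus (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    motif: Motif
    copies: float
    purity: float
    locus_id: str = ""

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "MstLocus") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CatalogueConfig:
    """Filter thresholds for the MST catalogue.

    Defaults follow the standard exome MST-catalogue filters: loci shorter
    than 8 nt, with fewer than 3 motif copies, or below 85% purity are
    discarded; control segments are 15 nt.
    """

    min_locus_length: int = 8
    min_motif_copies: float = 3.0
    min_purity: float = 0.85
    motif_length_range: tuple[int, int] = (1, 6)
    non_mst_segment_length: int = 15

    def __post_init__(self) -> None:
        if self.min_locus_length <= 0 or self.min_motif_copies <= 0 or self.min_purity <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_purity > 1:
            raise ValueError("min_purity must be <= 1")
        lo, hi = self.motif_length_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("motif lengths must lie in [1, 6]")


def compute_purity(locus_sequence: str, motif: Motif | str) -> float:
    """Fraction of positions matching the best perfect tandem repetition.

    The candidate templates are ungapped tilings of every rotation of the
    motif across the locus; purity is the maximum Hamming match fraction
    over rotations (tiling each rotation from position 0 covers all start
    phases). Equals 1.0 iff the sequence is an exact tandem repetition of
    some rotation of the motif.
    """
    unit = motif.sequence if isinstance(motif, Motif) else motif.upper()
    if not unit or not set(unit) <= DNA_ALPHABET:
        raise InvalidMotifError(f"motif must be non-empty A/C/G/T: {unit!r}")
    seq = locus_sequence.upper()
    if not seq:
        raise ValueError("locus_sequence must be non-empty")
    if len(unit) > len(seq):
        raise ValueError("motif longer than locus sequence")
    return _purity(seq, unit)


def _purity(seq: str, unit: str) -> float:
    """compute_purity core on validated uppercase strings."""
    k = len(unit)
    n = len(seq)
    best = 0
    for r in range(k):
        rot = unit[r:] + unit[:r]
        template = (rot * (n // k + 1))[:n]
        matches = sum(a == b for a, b in zip(seq, template))
        if matches > best:
            best = matches
    return best / n


def _best_motif_for_window(seq: str, motif_lengths: range) -> tuple[str, float]:
    """Best (unit, purity) for a window, shortest motif winning ties.

    The candidate unit for each length k is the window's leading k-mer.
    """
    best_unit = ""
    best_purity = -1.0
    for k in motif_lengths:
        if k > len(seq):
            break
        unit = seq[:k]
        p = _purity(seq, unit)
        if p > best_purity + 1e-12:
            best_unit = unit
            best_purity = p
    assert best_unit
    return best_unit, best_purity


def _exact_runs(seq: str, k: int) -> list[tuple[int, int]]:
    """Maximal runs of period k with >= 2 full units (seq[t] == seq[t-k])."""
    n = len(seq)
    if n < 2 * k:
        return []
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    acgt = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))
    ok = (a[k:] == a[:-k]) & acgt[k:] & acgt[:-k]
    # boundaries of True stretches in ok; stretch [s, e) -> run [s, e + k)
    padded = np.concatenate(([False], ok, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e) + k) for s, e in zip(starts, ends) if (e + k) - s >= 2 * k]


def _extend_run(seq: str, start: int, end: int, unit: str, min_purity: float) -> tuple[int, int, int]:
    """Extend an exact run across short interruptions while purity holds.

    The template fixes base t to unit[(t - start0) mod k] with the phase
    anchored at the original run start. An extension step jumps over at most
    k consecutive mismatching (A/C/G/T) bases to the next stretch of
    template-matching bases and is accepted iff the enlarged window still
    meets ``min_purity``. N always terminates. Returns (start, end, matches).
    """
    k = len(unit)
    n = len(seq)
    anchor = start
    matches = end - start

    # rightward
    while True:
        t = end
        gap = 0
        while t < n and gap < k and seq[t] in DNA_ALPHABET and seq[t] != unit[(t - anchor) % k]:
            t += 1
            gap += 1
        m2 = 0
        while t + m2 < n and seq[t + m2] in DNA_ALPHABET and seq[t + m2] == unit[(t + m2 - anchor) % k]:
            m2 += 1
        if m2 == 0:
            break
        new_end = t + m2
        if (matches + m2) / (new_end - start) >= min_purity:
            matches += m2
            end = new_end
        else:
            break
    # leftward
    while True:
        t = start - 1
        gap = 0
        while t >= 0 and gap < k and seq[t] in DNA_ALPHABET and seq[t] != unit[(t - anchor) % k]:
            t -= 1
            gap += 1
        m2 = 0
        while t - m2 >= 0 and seq[t - m2] in DNA_ALPHABET and seq[t - m2] == unit[(t - m2 - anchor) % k]:
            m2 += 1
        if m2 == 0:
            break
        new_start = t - m2 + 1
        if (matches + m2) / (end - new_start) >= min_purity:
            matches += m2
            start = new_start
        else:
            break
    return start, end, matches


def scan_tandem_repeats(
    reference: dict[str, str],
    config: CatalogueConfig | None = None,
) -> list[MstLocus]:
    """Detect candidate tandem-repeat loci in a set of reference sequences.

    For each motif length k in the configured range, every maximal exact
    period-k run of at least two units is located, then extended across
    interruptions of up to k mismatching bases as long as the window purity
    stays at or above ``config.min_purity`` (see :func:`_extend_run`).
    Windows spanning at least ``min_locus_length`` nt are reported with
    their canonical motif, copies (length / motif length) and purity.
    A window whose best-fitting motif is shorter than k is suppressed (it
    is reported at its own period); ambiguity codes (N) terminate runs.
    Candidates of different motif lengths may overlap; overlap resolution
    happens in :func:`filter_and_dedupe`.
    """
    if config is None:
        config = CatalogueConfig()
    lo, hi = config.motif_length_range
    out: list[MstLocus] = []
    for chrom in reference:
        seq = str(reference[chrom]).upper()
        seen: set[tuple[int, int, str]] = set()
        for k in range(lo, hi + 1):
            for r0, r1 in _exact_runs(seq, k):
                unit = seq[r0 : r0 + k]
                start, end, matches = _extend_run(seq, r0, r1, unit, config.min_purity)
                if end - start < config.min_locus_length:
                    continue
                window = seq[start:end]
                # report the declared metric (max over rotations), which is
                # >= the phase-anchored fraction used during extension
                purity = _purity(window, unit)
                if purity < config.min_purity:
                    continue
                best_motif, best_purity = _best_motif_for_window(window, range(lo, k + 1))
                if len(best_motif) < k and best_purity >= purity - 1e-9:
                    continue  # shorter motif explains it at least as well
                key = (start, end, canonical_motif(unit).canonical_form)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    MstLocus(
                        chrom=chrom,
                        start=start,
                        end=end,
                        motif=canonical_motif(unit),
                        copies=(end - start) / k,
                        purity=purity,
                    )
                )
    out.sort(key=lambda l: (l.chrom, l.start, l.end, l.motif.canonical_form))
    return out


def filter_and_dedupe(
    candidates: list[MstLocus], config: CatalogueConfig | None = None
) -> list[MstLocus]:
    """Apply catalogue filters and resolve overlaps to one locus each.

    Filters: ref_length >= min_locus_length, copies >= min_motif_copies,
    purity >= min_purity. Overlapping survivors are resolved by higher
    purity, then greater length, then leftmost start, then shortest motif —
    a total order, so the result is deterministic. Output is sorted by
    (chrom, start).
    """
    if config is None:
        config = CatalogueConfig()
    passing = [
        c
        for c in candidates
        if c.ref_length >= config.min_locus_length
        and c.copies >= config.min_motif_copies
        and c.purity >= config.min_purity
    ]
    # priority order: best first
    passing.sort(
        key=lambda l: (-l.purity, -(l.ref_length), l.chrom, l.start, len(l.motif), l.motif.canonical_form)
    )
    kept: list[MstLocus] = []
    kept_by_chrom: dict[str, list[MstLocus]] = {}
    for cand in passing:
        if any(cand.overlaps(k) for k in kept_by_chrom.get(cand.chrom, ())):
            continue
        kept.append(cand)
        kept_by_chrom.setdefault(cand.chrom, []).append(cand)
    kept.sort(key=lambda l: (l.chrom, l.start))
    return [
        MstLocus(
            chrom=l.chrom,
            start=l.start,
            end=l.end,
            motif=l.motif,
            copies=l.copies,
            purity=l.purity,
            locus_id=l.locus_id or f"{l.chrom}:{l.start}-{l.end}",
        )
        for l in kept
    ]


def build_catalogue(
    reference: dict[str, str], config: CatalogueConfig | None = None
) -> list[MstLocus]:
    """Scan + filter + dedupe in one call."""
    return filter_and_dedupe(scan_tandem_repeats(reference, config), config)


def sample_non_mst_loci(
    reference: dict[str, str],
    catalogue: list[MstLocus],
    n: int,
    seed: int,
    config: CatalogueConfig | None = None,
) -> list[MstLocus]:
    """Sample ``n`` fixed-length control segments avoiding catalogued MSTs.

    Segments are uniform over the reference, contain no N, and intersect no
    catalogue locus. If the reference cannot host ``n`` such segments a
    partial list is returned with a warning. Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if config is None:
        config = CatalogueConfig()
    seg = config.non_mst_segment_length
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for loc in catalogue:
        by_chrom.setdefault(loc.chrom, []).append((loc.start, loc.end))
    chroms = sorted(reference)
    lengths = np.array([len(str(reference[c])) for c in chroms], dtype=float)
    valid = lengths >= seg
    if not valid.any():
        warnings.warn("reference too small for any control segment")
        return []
    probs = np.where(valid, lengths, 0.0)
    probs /= probs.sum()
    out: list[MstLocus] = []
    attempts = 0
    max_attempts = max(10_000, 200 * n)
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        seq = str(reference[chrom]).upper()
        if len(seq) < seg:
            continue
        start = int(rng.integers(0, len(seq) - seg + 1))
        end = start + seg
        window = seq[start:end]
        if not set(window) <= DNA_ALPHABET:
            continue
        if any(start < e and s < end for s, e in by_chrom.get(chrom, ())):
            continue
        out.append(
            MstLocus(
                chrom=chrom,
                start=start,
                end=end,
                motif=Motif("A"),  # placeholder unit; control loci carry no repeat motif
                copies=0.0,
                purity=0.0,
                locus_id=f"nonmst:{chrom}:{start}-{end}",
            )
        )
    if len(out) < n:
        warnings.warn(f"placed only {len(out)} of {n} control segments")
    out.sort(key=lambda l: (l.chrom, l.start))
    return out


def catalogue_to_frame(catalogue: list[MstLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start": l.start,
                "end": l.end,
                "motif": l.motif.canonical_form,
                "copies": l.copies,
                "purity": l.purity,
                "locus_id": l.locus_id or f"{l.chrom}:{l.start}-{l.end}",
            }
            for l in catalogue
        ],
        columns=CATALOGUE_COLUMNS,
    )


def write_catalogue(catalogue: list[MstLocus], path) -> None:
    """Write the catalogue as BED3+-compatible TSV."""
    catalogue_to_frame(catalogue).to_csv(path, sep="\t", index=False)


def read_catalogue(path) -> list[MstLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        MstLocus(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            motif=Motif(row.motif),
            copies=float(row.copies),
            purity=float(row.purity),
            locus_id=str(row.locus_id),
        )
        for row in df.itertuples()
    ]
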