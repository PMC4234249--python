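"""Classification of non-haplotype alleles at microsatellite loci.

Each called allele other than the most common one is classified relative
to the major allele by its length difference: same length but different
sequence is a SNP-class allele; longer is an expansion; shorter is a
contraction. A length change that is an exact multiple of the motif
length is *in phase* — the signature of polymerase slippage, which biases
microsatellite mutation toward whole-unit INDELs (a dimer expands or
contracts by 2N nt, a trimer by 3N).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .caller import AlleleSupport, LocusCall
from .catalogue import Motif, MstLocus

SNP = "SNP"
EXPANSION = "expansion"
CONTRACTION = "contraction"

MINOR_ONLY = "minor_only"
ALL_NON_MAJOR = "all_non_major"


@dataclass(frozen=True)
class VariantClass:
    """Class of one non-major allele.

    ``length_delta`` is allele length minus major-allele length;
    ``in_phase`` is True when the delta is a non-zero multiple of the
    motif length.
    """

    kind: str
    length_delta: int
    in_phase: bool


def classify_minor_allele(
    major: AlleleSupport, other: AlleleSupport, motif: Motif | str
) -> VariantClass:
    """Classify ``other`` against the locus's major allele.

    Same-length alleles count as one SNP-class allele regardless of how
    many positions differ; length changes are expansions/contractions by
    the sign of the delta alone.
    """
    if other.allele_sequence == major.allele_sequence:
        raise ValueError("allele identical to the major allele cannot be classified")
    k = len(motif.sequence if isinstance(motif, Motif) else motif)
    delta = other.length - major.length
    if delta == 0:
        kind = SNP
    elif delta > 0:
        kind = EXPANSION
    else:
        kind = CONTRACTION
    return VariantClass(kind=kind, length_delta=delta, in_phase=(delta != 0 and delta % k == 0))


def classified_alleles_frame(
    calls: list[LocusCall],
    catalogue: list[MstLocus],
    scope: str = MINOR_ONLY,
) -> pd.DataFrame:
    """Per-allele classification table for a sample.

    ``scope`` selects which non-major alleles are classified: minor
    alleles only (the somatic-variation reading) or every allele besides
    the major one, which additionally classifies second haplotype alleles
    (useful for loss-of-heterozygosity style analyses).
    """
    if scope not in (MINOR_ONLY, ALL_NON_MAJOR):
        raise ValueError(f"unknown scope {scope!r}")
    motif_by_id = {l.locus_id: l.motif for l in catalogue}
    rows = []
    for call in calls:
        major = call.major_allele
        if major is None or call.locus_id not in motif_by_id:
            continue
        motif = motif_by_id[call.locus_id]
        others: list[tuple[AlleleSupport, bool]] = [(a, True) for a in call.minor_alleles]
        if scope == ALL_NON_MAJOR:
            others += [(a, False) for a in call.haplotype_alleles[1:]]
        for allele, is_minor in others:
            vc = classify_minor_allele(major, allele, motif)
            rows.append(
                {
                    "locus_id": call.locus_id,
                    "allele_len": allele.length,
                    "kind": vc.kind,
                    "length_delta": vc.length_delta,
                    "in_phase": vc.in_phase,
                    "support": allele.n_total,
                    "is_minor": is_minor,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "allele_len", "kind", "length_delta", "in_phase", "support", "is_minor"],
    )


@dataclass
class SpectrumSummary:
    """SNP / expansion / contraction percentages over classified alleles."""

    n_alleles: int
    pct_snp: float
    pct_expansion: float
    pct_contraction: float
    pct_in_phase: float
    empty: bool = False


def variant_spectrum(
    calls: list[LocusCall],
    catalogue: list[MstLocus],
    scope: str = MINOR_ONLY,
) -> SpectrumSummary:
    """Percent SNP / expansion / contraction (and percent in-phase).

    Percentages are over all classified alleles in scope and sum to 100
    up to rounding; an empty scope yields a flagged empty summary.
    """
    df = classified_alleles_frame(calls, catalogue, scope)
    n = len(df)
    if n == 0:
        return SpectrumSummary(0, float("nan"), float("nan"), float("nan"), float("nan"), empty=True)
    counts = df["kind"].value_counts()
    return SpectrumSummary(
        n_alleles=n,
        pct_snp=100.0 * counts.get(SNP, 0) / n,
        pct_expansion=100.0 * counts.get(EXPANSION, 0) / n,
        pct_contraction=100.0 * counts.get(CONTRACTION, 0) / n,
        pct_in_phase=100.0 * int(df["in_phase"].sum()) / n,
    )


def motif_length_spectrum(
    calls: list[LocusCall], catalogue: list[MstLocus]
) -> pd.Series:
    """Percent of minor-allele-bearing loci by motif length (1–6).

    Fractions are over loci with at least one minor allele and sum
    to 100.
    """
    motif_by_id = {l.locus_id: len(l.motif) for l in catalogue}
    lengths = [
        motif_by_id[c.locus_id]
        for c in calls
        if c.has_minor and c.locus_id in motif_by_id
    ]
    s = pd.Series(lengths, dtype=int).value_counts().reindex(range(1, 7), fill_value=0)
    total = s.sum()
    out = 100.0 * s / total if total else s.astype(float)
    out.index.name = "motif_length"
    out.name = "pct_minor_loci"
    return out
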