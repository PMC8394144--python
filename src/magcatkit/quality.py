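"""Genome-bin quality: N50, quality score, intactness score, QC filter, tiers.

Completeness and contamination are CheckM-style estimates supplied as
metadata (percent scale).  The intactness score

    S = completeness - 5 * contamination + 0.5 * log10(N50)

ranks genomes within a species cluster so the most intact one can represent
the cluster.  Quality tiers follow the MIMAG-style convention: high-quality
(HQ) genomes carry all three rRNAs and >= 18 tRNAs on top of the
near-complete (NC) thresholds (>= 90% completeness, < 5% contamination);
medium-quality (MQ) covers [50, 90)% completeness at < 5% contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: QC filter thresholds: minimum completeness, maximum contamination,
#: minimum quality score (completeness - 5 * contamination).
MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 5.0
MIN_QUALITY_SCORE = 50.0


@dataclass
class GenomeBin:
    """A genome bin (MAG or isolate assembly) with its QC metadata.

    ``contigs`` holds the nucleotide sequences; ``contig_ids`` is generated
    when not supplied.  ``completeness`` and ``contamination`` are on the
    percent scale in [0, 100].
    """

    bin_id: str
    contigs: list[str]
    sample_id: str = "S0"
    country: str = "NA"
    completeness: float = 100.0
    contamination: float = 0.0
    has_5S: bool = False
    has_16S: bool = False
    has_23S: bool = False
    trna_count: int = 0
    source: str = "MAG"
    contig_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"bin {self.bin_id}: at least one contig required")
        if any(len(c) == 0 for c in self.contigs):
            raise ValueError(f"bin {self.bin_id}: empty contig")
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"bin {self.bin_id}: completeness out of [0, 100]")
        if not (0 <= self.contamination <= 100):
            raise ValueError(f"bin {self.bin_id}: contamination out of [0, 100]")
        if not self.contig_ids:
            self.contig_ids = [f"{self.bin_id}_c{i}" for i in range(len(self.contigs))]
        elif len(self.contig_ids) != len(self.contigs):
            raise ValueError(f"bin {self.bin_id}: contig_ids/contigs length mismatch")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class QualityReport:
    bin_id: str
    n50: int
    qs: float
    intactness: float
    tier: str  # HQ | NC | MQ | FAIL


def compute_n50(contigs: list[str] | list[int]) -> int:
    """Standard N50: smallest length L such that contigs >= L cover half the total."""
    if not contigs:
        raise ValueError("compute_n50: empty contig list")
    lengths = sorted(
        (c if isinstance(c, int) else len(c) for c in contigs), reverse=True
    )
    if lengths[-1] <= 0:
        raise ValueError("compute_n50: non-positive contig length")
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 * contamination (percent scale; may be negative)."""
    if not (0 <= completeness <= 100):
        raise ValueError("completeness out of [0, 100]")
    if not (0 <= contamination <= 100):
        raise ValueError("contamination out of [0, 100]")
    return completeness - 5.0 * contamination


def intactness_score(completeness: float, contamination: float, n50: int) -> float:
    """S = QS + 0.5 * log10(N50), with N50 in bp."""
    if n50 < 1:
        raise ValueError("n50 must be >= 1")
    return quality_score(completeness, contamination) + 0.5 * math.log10(n50)


def passes_bin_filter(bin: GenomeBin) -> bool:
    """QC filter: completeness >= 50, contamination <= 5, QS >= 50 (all inclusive)."""
    qs = quality_score(bin.completeness, bin.contamination)
    return (
        bin.completeness >= MIN_COMPLETENESS
        and bin.contamination <= MAX_CONTAMINATION
        and qs >= MIN_QUALITY_SCORE
    )


def classify_tier(bin: GenomeBin) -> str:
    """Quality tier: HQ, NC, MQ or FAIL.

    HQ additionally requires 5S + 16S + 23S rRNA and >= 18 tRNAs.  MQ keeps
    the strict < 5% contamination bound because tiering is applied to bins
    that already passed the 5%-contamination QC filter upstream.
    """
    comp, cont = bin.completeness, bin.contamination
    if comp >= 90 and cont < 5:
        if bin.has_5S and bin.has_16S and bin.has_23S and bin.trna_count >= 18:
            return "HQ"
        return "NC"
    if 50 <= comp < 90 and cont < 5:
        return "MQ"
    return "FAIL"


def quality_report(bin: GenomeBin) -> QualityReport:
    n50 = compute_n50(bin.contigs)
    return QualityReport(
        bin_id=bin.bin_id,
        n50=n50,
        qs=quality_score(bin.completeness, bin.contamination),
        intactness=intactness_score(bin.completeness, bin.contamination, n50),
        tier=classify_tier(bin),
    )


def qc_table(bins: list[GenomeBin]) -> pd.DataFrame:
    """Per-bin QC report as a DataFrame (bin_id, n50, qs, intactness, tier, pass)."""
    rows = []
    for b in bins:
        r = quality_report(b)
        rows.append(
            {
                "bin_id": r.bin_id,
                "n50": r.n50,
                "qs": r.qs,
                "intactness": r.intactness,
                "tier": r.tier,
                "passes_filter": passes_bin_filter(b),
            }
        )
    return pd.DataFrame(rows)
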