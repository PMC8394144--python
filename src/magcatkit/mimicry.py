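"""Epitope cross-reactivity (molecular mimicry) scoring and disease association.

Self-antigen epitopes are aligned against the proteins of each species
representative; an epitope-to-gene alignment scores

    AS = (match length - gap length) / epitope length

where match length counts identical aligned residues, so AS = 1 holds
exactly when the epitope occurs in the protein as a full-length, gap-free,
identical match.  Genes with at least one AS = 1 epitope are
epitope-containing genes (ECGs); ECG counts are normalized by proteome size,
clades are screened for ECG-density enrichment (Mann-Whitney + fold
change), high cross-reactivity taxa (enriched clades at P < 1e-05 and their
descendants) are contrasted against the rest for disease annotation odds
ratios with Fisher's exact test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .stats import fisher_exact, mann_whitney_u

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
MIN_EPITOPE_LENGTH = 5
ENRICHMENT_P_THRESHOLD = 1e-5
DISEASE_MIN_TAXA = 40
_MAX_OPTIMAL_ALIGNMENTS = 64


@dataclass(frozen=True)
class EpitopeAlignment:
    epitope_id: str
    gene_id: str
    match_length: int
    gap_length: int
    epitope_length: int
    score: float  # alignment score (BLOSUM62, -11/-1)

    @property
    def AS(self) -> float:
        return (self.match_length - self.gap_length) / self.epitope_length


@dataclass(frozen=True)
class EcgProfile:
    species_id: str
    ecg_count: int
    gene_count: int

    @property
    def density(self) -> float:
        return self.ecg_count / self.gene_count


def filter_epitopes(raw: pd.DataFrame) -> list[tuple[str, str]]:
    """Filter an IEDB-style epitope table to usable unique peptides.

    Expects columns ``epitope_id``, ``peptide`` and ``requires_ptm``.  Drops
    peptides shorter than 5 residues, rows requiring post-translational
    modification, rows with non-amino-acid characters (warned), and
    duplicate peptides (first id kept).
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for row in raw.itertuples(index=False):
        pep = str(row.peptide).strip().upper()
        if bool(row.requires_ptm):
            continue
        if len(pep) < MIN_EPITOPE_LENGTH:
            continue
        if set(pep) - VALID_AA:
            warnings.warn(f"epitope {row.epitope_id}: non-amino-acid characters, dropped")
            continue
        if pep in seen:
            continue
        seen.add(pep)
        out.append((str(row.epitope_id), pep))
    return out


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def align_epitope(
    epitope: str, protein: str, epitope_id: str = "e", gene_id: str = "g"
) -> EpitopeAlignment | None:
    """Best local alignment of an epitope to a protein (BLOSUM62, gap 11/1).

    Among optimal-score alignments the one maximizing AS is reported;
    returns None when no positive-scoring local alignment exists.
    """
    if not epitope or not protein:
        raise ValueError("epitope and protein must be non-empty")
    aligner = _aligner()
    alignments = aligner.align(epitope, protein)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    best: EpitopeAlignment | None = None
    for i, aln in enumerate(alignments):
        if i >= _MAX_OPTIMAL_ALIGNMENTS:
            break
        counts = aln.counts()
        cand = EpitopeAlignment(
            epitope_id=epitope_id,
            gene_id=gene_id,
            match_length=counts.identities,
            gap_length=counts.gaps,
            epitope_length=len(epitope),
            score=float(alignments.score),
        )
        if best is None or cand.AS > best.AS:
            best = cand
    return best


def count_ecgs(
    proteins: list[tuple[str, str]], epitopes: list[tuple[str, str]], species_id: str = "sp"
) -> EcgProfile:
    """Count epitope-containing genes in a species proteome.

    AS = 1 is equivalent to verbatim full-length occurrence of the epitope
    in the protein (match length = epitope length, no gaps), so the scan is
    an exact substring search; a gene counts once regardless of how many
    epitopes hit it.
    """
    if not proteins:
        raise ValueError("empty proteome")
    peps = [p for _, p in epitopes]
    ecg = sum(1 for _, seq in proteins if any(p in seq for p in peps))
    return EcgProfile(species_id=species_id, ecg_count=ecg, gene_count=len(proteins))


def ecg_hits(
    proteins: list[tuple[str, str]], epitopes: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-hit table (gene_id, epitope_id) of AS = 1 matches."""
    rows = [
        {"gene_id": gid, "epitope_id": eid}
        for gid, seq in proteins
        for eid, pep in epitopes
        if pep in seq
    ]
    return pd.DataFrame(rows, columns=["gene_id", "epitope_id"])


def clade_enrichment(
    profiles: list[EcgProfile], clade_members: set[str]
) -> tuple[float, float]:
    """ECG-density enrichment of a clade against the all-species background.

    Returns (fold change of median densities, two-sided Mann-Whitney p).
    The background is the full species set, clade included, mirroring a
    clade-vs-entire-catalog comparison.
    """
    clade = [p.density for p in profiles if p.species_id in clade_members]
    allv = [p.density for p in profiles]
    if len(clade) < 3:
        raise ValueError("clade must have >= 3 members")
    all_median = float(pd.Series(allv).median())
    if all_median == 0:
        return float("nan"), mann_whitney_u(clade, allv).p_value
    fold = float(pd.Series(clade).median()) / all_median
    return fold, mann_whitney_u(clade, allv).p_value


def partition_cross_reactivity(
    enrichments: dict[str, tuple[float, float]],
    taxonomy: dict[str, list[str]],
    p_threshold: float = ENRICHMENT_P_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """High/low cross-reactivity partition of all taxa.

    A clade enters the high set when its enrichment is significant
    (p < 1e-05) *and* its fold change exceeds 1; all its descendant taxa
    are included.  Everything else is low cross-reactivity.
    """
    universe: set[str] = set(taxonomy)
    for children in taxonomy.values():
        universe.update(children)
    high: set[str] = set()
    stack = [
        t for t, (fold, p) in enrichments.items()
        if p < p_threshold and not math.isnan(fold) and fold > 1
    ]
    while stack:
        t = stack.pop()
        if t in high:
            continue
        high.add(t)
        stack.extend(taxonomy.get(t, []))
    return high, universe - high


def disease_association(
    annotations: pd.DataFrame,
    high: set[str],
    all_taxa: set[str],
    min_taxa: int = DISEASE_MIN_TAXA,
) -> pd.DataFrame:
    """Per-disease odds ratios contrasting high vs low cross-reactivity taxa.

    Only diseases with more than ``min_taxa`` annotated taxa are tested.
    OR_assoc comes from the 2x2 (high/low x annotated/not) over
    ``all_taxa``; OR_direction from (high/low x increase/decrease) among
    the annotated taxa.  Significance by two-sided Fisher's exact test.
    """
    low = all_taxa - high
    rows = []
    for disease, sub in annotations.groupby("disease"):
        annotated = set(sub["taxon"]) & all_taxa
        if len(annotated) <= min_taxa:
            continue
        a = len(annotated & high)
        b = len(high - annotated)
        c = len(annotated & low)
        d = len(low - annotated)
        assoc = fisher_exact(a, b, c, d)
        inc = set(sub.loc[sub["direction"] == "increase", "taxon"]) & all_taxa
        dec = annotated - inc
        direction = fisher_exact(len(inc & high), len(dec & high), len(inc & low), len(dec & low))
        rows.append(
            {
                "disease": disease,
                "n_annotated": len(annotated),
                "or_assoc": assoc.odds_ratio,
                "p_assoc": assoc.p_value,
                "or_direction": direction.odds_ratio,
                "p_direction": direction.p_value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["disease", "n_annotated", "or_assoc", "p_assoc", "or_direction", "p_direction"],
    )


def find_identical_proteins(
    proteins: list[tuple[str, str]]
) -> tuple[list[list[str]], int]:
    """Groups of byte-identical protein sequences (singletons omitted).

    Returns (groups of gene ids, redundant count = sum of group size - 1).
    """
    by_seq: dict[str, list[str]] = {}
    for gid, seq in proteins:
        by_seq.setdefault(seq, []).append(gid)
    groups = [ids for ids in by_seq.values() if len(ids) > 1]
    redundant = sum(len(g) - 1 for g in groups)
    return groups, redundant
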