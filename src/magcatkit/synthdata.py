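"""Synthetic genomes, proteomes, annotation tables and communities with planted truth.

Every downstream stage of the catalog pipeline is exercised on data from
this module: unrelated ancestor genomes, conspecific descendants at a
controlled substitution rate, MAG-style degradation (incompleteness,
foreign-contig contamination, fragmentation), proteomes with planted
epitope occurrences, taxon-disease contingency structure, and multinomially
sampled community read counts.  All randomness flows from explicit integer
seeds through ``numpy.random.default_rng``; identical seeds and arguments
reproduce byte-identical outputs.

The generators emulate the *structure* of real data (identity levels,
completeness/contamination ranges, composition profiles) — not sequencing
error, codon usage, or assembly artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quality import GenomeBin

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TruthSet:
    """Planted ground truth for a synthetic study."""

    seed: int
    ancestor_of: dict[str, str] = field(default_factory=dict)
    sub_rate_of: dict[str, float] = field(default_factory=dict)
    cluster_of: dict[str, str] = field(default_factory=dict)
    completeness_of: dict[str, float] = field(default_factory=dict)  # fraction
    contamination_of: dict[str, float] = field(default_factory=dict)  # fraction
    snv_positions: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    epitope_occurrences: list[tuple[str, str]] = field(default_factory=list)
    composition: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for g, r in self.sub_rate_of.items():
            if not (0 <= r <= 0.35):
                raise ValueError(f"{g}: substitution rate {r} outside [0, 0.35]")
        for d in (self.completeness_of, self.contamination_of):
            for g, v in d.items():
                if not (0 <= v <= 1):
                    raise ValueError(f"{g}: fraction {v} outside [0, 1]")
        if self.composition and abs(sum(self.composition.values()) - 1) > 1e-12:
            raise ValueError("composition does not sum to 1")


def generate_ancestors(
    n: int, length: int, gc: float = 0.5, seed: int = 0
) -> list[str]:
    """``n`` i.i.d. random DNA sequences of ``length`` bp at the given GC content."""
    if n < 1 or length < 10_000:
        raise ValueError("need n >= 1 and length >= 10,000")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    out = []
    for _ in range(n):
        idx = rng.choice(4, size=length, p=probs)
        out.append(_DNA[idx].tobytes().decode("ascii"))
    return out


def evolve_genome(
    ancestor: str, sub_rate: float, indel_rate: float = 0.0, seed: int = 0
) -> tuple[str, list[int]]:
    """Mutate an ancestor into a conspecific descendant.

    Each site is substituted independently with probability ``sub_rate``,
    uniformly to one of the 3 alternative bases; short 1-5 bp indels occur
    at rate ``indel_rate`` per site.  Returns the evolved sequence and the
    substituted positions in the *ancestor's* (0-based) coordinates.
    """
    if not ancestor:
        raise ValueError("empty ancestor")
    if sub_rate + indel_rate >= 0.5:
        raise ValueError("sub_rate + indel_rate must be < 0.5")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8).copy()
    codes = np.searchsorted(_DNA, arr)  # ACGT -> 0..3 (ancestors are ACGT-only)
    sub_mask = rng.random(arr.size) < sub_rate
    positions = np.flatnonzero(sub_mask)
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size)
        codes[positions] = (codes[positions] + shift) % 4
        arr = _DNA[codes]
    seq = arr.tobytes().decode("ascii")
    if indel_rate > 0:
        events = np.flatnonzero(rng.random(len(seq)) < indel_rate)
        pieces: list[str] = []
        cursor = 0
        for pos in events:
            if pos < cursor:
                continue  # swallowed by an earlier deletion
            pieces.append(seq[cursor:pos])
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # insertion
                ins = _DNA[rng.integers(0, 4, size=size)].tobytes().decode("ascii")
                pieces.append(ins + seq[pos])
                cursor = pos + 1
            else:  # deletion
                cursor = pos + size
        pieces.append(seq[cursor:])
        seq = "".join(pieces)
    return seq, positions.tolist()


def degrade_to_bin(
    genome: str,
    completeness: float,
    contamination: float = 0.0,
    contaminant: str | None = None,
    n_contigs: int = 20,
    seed: int = 0,
    bin_id: str = "bin0",
    sample_id: str = "S0",
    country: str = "NA",
    has_rrna: bool = True,
    trna_count: int = 20,
) -> GenomeBin:
    """Degrade a complete genome into a MAG-style bin.

    The genome is fragmented into ``n_contigs`` pieces at random breakpoints;
    a random subset totaling ``completeness`` of the length is retained (the
    last kept contig is trimmed so the realized fraction is exact); foreign
    fragments cut from ``contaminant`` totaling ``contamination`` x retained
    length are appended.  Stored completeness/contamination metadata reflect
    the realized values (percent scale).
    """
    if not (0 < completeness <= 1):
        raise ValueError("completeness must be in (0, 1]")
    if not (0 <= contamination <= 0.2):
        raise ValueError("contamination must be in [0, 0.2]")
    if contamination > 0 and not contaminant:
        raise ValueError("contaminant sequence required when contamination > 0")
    rng = np.random.default_rng(seed)
    L = len(genome)
    if n_contigs > 1:
        # jittered even spacing: random breakpoints that avoid tiny slivers
        jitter = rng.uniform(0.3, 0.7, size=n_contigs - 1)
        cuts = [round(L * (i + 1 + j - 0.5) / n_contigs) for i, j in enumerate(jitter)]
        bounds = [0, *cuts, L]
        contigs = [genome[bounds[i] : bounds[i + 1]] for i in range(n_contigs)]
    else:
        contigs = [genome]
    target = max(1, round(completeness * L))
    order = rng.permutation(len(contigs))
    kept: list[str] = []
    total = 0
    for i in order:
        if total >= target:
            break
        c = contigs[i]
        take = min(len(c), target - total)
        kept.append(c[:take])
        total += take
    realized_comp = total / L
    cont_target = round(contamination * total)
    cont_total = 0
    if cont_target > 0:
        assert contaminant is not None
        while cont_total < cont_target:
            size = min(int(rng.integers(2_000, 8_001)), cont_target - cont_total)
            size = max(size, 1)
            start = int(rng.integers(0, max(1, len(contaminant) - size)))
            kept.append(contaminant[start : start + size])
            cont_total += size
    realized_cont = cont_total / total if total else 0.0
    return GenomeBin(
        bin_id=bin_id,
        contigs=[c for c in kept if c],
        sample_id=sample_id,
        country=country,
        completeness=100.0 * realized_comp,
        contamination=100.0 * realized_cont,
        has_5S=has_rrna,
        has_16S=has_rrna,
        has_23S=has_rrna,
        trna_count=trna_count,
    )


def generate_proteome(
    n_genes: int,
    gene_len_range: tuple[int, int] = (100, 400),
    epitopes: list[tuple[str, str]] | None = None,
    planted: list[tuple[int, str]] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Random proteome with epitopes planted verbatim into designated genes.

    ``epitopes`` is a list of (epitope_id, peptide); ``planted`` a list of
    (gene index, epitope_id).  Unplanted genes are redrawn until they contain
    no epitope by chance, so the truth list is exact.  Returns
    (genes as (gene_id, sequence), truth as (gene_id, epitope_id)).
    """
    epitopes = epitopes or []
    planted = planted or []
    ep_by_id = dict(epitopes)
    for _, pep in epitopes:
        if set(pep) - set(AMINO_ACIDS):
            raise ValueError(f"epitope {pep!r} uses non-standard amino acids")
    for gi, eid in planted:
        if gi >= n_genes:
            raise ValueError(f"planted gene index {gi} >= n_genes")
        if eid not in ep_by_id:
            raise ValueError(f"unknown epitope id {eid}")
    rng = np.random.default_rng(seed)
    lo, hi = gene_len_range
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    plants_for: dict[int, list[str]] = {}
    for gi, eid in planted:
        plants_for.setdefault(gi, []).append(eid)
    all_peps = [p for _, p in epitopes]

    def random_protein(length: int) -> str:
        return aas[rng.integers(0, 20, size=length)].tobytes().decode("ascii")

    genes: list[tuple[str, str]] = []
    truth: list[tuple[str, str]] = []
    for gi in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        gene_id = f"g{gi:05d}"
        if gi in plants_for:
            eids = plants_for[gi]
            longest = max(len(ep_by_id[e]) for e in eids)
            if longest > length:
                raise ValueError(f"epitope longer than gene {gene_id} ({length} aa)")
            seq = random_protein(length)
            for eid in eids:
                pep = ep_by_id[eid]
                off = int(rng.integers(0, length - len(pep) + 1))
                seq = seq[:off] + pep + seq[off + len(pep) :]
            # overlapping plants can clobber each other; record what survived
            for eid in eids:
                if ep_by_id[eid] in seq:
                    truth.append((gene_id, eid))
        else:
            seq = random_protein(length)
            while any(p in seq for p in all_peps):
                seq = random_protein(length)
        genes.append((gene_id, seq))
    return genes, truth


def generate_disease_table(
    n_high: int,
    n_low: int,
    p_annot_high: float,
    p_annot_low: float,
    p_increase_high: float = 0.5,
    p_increase_low: float = 0.5,
    disease: str = "disease_X",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Taxon-disease annotation table with Bernoulli structure.

    High-group taxa are named ``H####``, low-group ``L####``.  Returns the
    annotation table (taxon, disease, direction) and the true 2x2 counts
    {a: high annotated, b: high not, c: low annotated, d: low not}.
    """
    for p in (p_annot_high, p_annot_low, p_increase_high, p_increase_low):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    counts = {"a": 0, "b": 0, "c": 0, "d": 0}
    for prefix, n, p_annot, p_inc, kk in (
        ("H", n_high, p_annot_high, p_increase_high, ("a", "b")),
        ("L", n_low, p_annot_low, p_increase_low, ("c", "d")),
    ):
        annot = rng.random(n) < p_annot
        direction = np.where(rng.random(n) < p_inc, "increase", "decrease")
        for i in range(n):
            if annot[i]:
                rows.append(
                    {"taxon": f"{prefix}{i:04d}", "disease": disease, "direction": direction[i]}
                )
        counts[kk[0]] += int(annot.sum())
        counts[kk[1]] += int(n - annot.sum())
    return pd.DataFrame(rows, columns=["taxon", "disease", "direction"]), counts


def generate_community_counts(
    composition: dict[str, float], depth: int, seed: int = 0
) -> pd.Series:
    """One multinomial draw of ``depth`` reads over the community composition."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    taxa = list(composition)
    probs = np.array([composition[t] for t in taxa], dtype=float)
    if np.any(probs < 0):
        raise ValueError("negative probabilities")
    if abs(probs.sum() - 1) > 1e-9:
        raise ValueError("composition must sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs / probs.sum())
    return pd.Series(counts, index=taxa, name="count")


def log_uniform_composition(n_taxa: int, lo: float = 1e-7, hi: float = 1e-1, seed: int = 0) -> dict[str, float]:
    """Community composition with relative abundances log-uniform on [lo, hi], normalized."""
    rng = np.random.default_rng(seed)
    raw = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_taxa)
    raw /= raw.sum()
    return {f"taxon{i:05d}": float(v) for i, v in enumerate(raw)}


def simulate_catalog_bins(
    n_ancestors: int = 6,
    bins_per_ancestor: int = 5,
    length: int = 100_000,
    max_sub_rate: float = 0.03,
    min_completeness: float = 0.8,
    max_completeness: float = 0.93,
    n_contigs: int = 40,
    seed: int = 0,
) -> tuple[list[GenomeBin], TruthSet]:
    """Standard study scenario: several unrelated species, conspecific MAGs each.

    ``max_sub_rate`` caps the *pairwise* substitution divergence within a
    species: each descendant's branch rate is drawn uniformly in
    (0.002, max_sub_rate/2], so any two conspecific genomes differ by at
    most ``max_sub_rate`` and stay on the >= 95% identity side of the
    species boundary.  Bins are degraded to completeness in
    [min_completeness, max_completeness].  Returns bins and planted truth.
    """
    rng = np.random.default_rng(seed)
    ancestors = generate_ancestors(n_ancestors, length, seed=int(rng.integers(2**31)))
    truth = TruthSet(seed=seed)
    bins: list[GenomeBin] = []
    for ai, anc in enumerate(ancestors):
        anc_id = f"anc{ai}"
        for bi in range(bins_per_ancestor):
            bin_id = f"A{ai}B{bi}"
            sub = float(rng.uniform(0.002, max_sub_rate / 2)) if bi else 0.0
            genome, subs = evolve_genome(anc, sub, seed=int(rng.integers(2**31)))
            comp = float(rng.uniform(min_completeness, max_completeness))
            b = degrade_to_bin(
                genome,
                completeness=comp,
                n_contigs=n_contigs,
                seed=int(rng.integers(2**31)),
                bin_id=bin_id,
                sample_id=f"S{ai}{bi}",
                country=["Korea", "India", "Japan"][ai % 3],
            )
            bins.append(b)
            truth.ancestor_of[bin_id] = anc_id
            truth.sub_rate_of[bin_id] = sub
            truth.cluster_of[bin_id] = anc_id
            truth.completeness_of[bin_id] = b.completeness / 100
            truth.contamination_of[bin_id] = b.contamination / 100
            truth.snv_positions[(anc_id, bin_id)] = subs
    truth.validate()
    return bins, truth
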