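"""Conspecific genome alignment, SNV calling and SNV-density statistics.

Every non-representative genome g in a species cluster G is aligned to the
representative r; substitution columns are SNVs; the per-cluster density is

    SNV per kb = [ sum_{g in G-{r}} #SNV_{r,g} / (aligned_length_{r,g}/1000) ] / (n(G)-1)

computed for clusters with enough members (density analyses restrict to
>= 10 genomes to limit sampling bias).  Chimerism is screened by chunking
the aligned region (50-kb chunks when the density exceeds 5 per kb,
100-kb otherwise) and testing per-chunk SNV counts for normality with a
one-sample Kolmogorov-Smirnov test, Benjamini-Hochberg corrected across
pairs.

Alignment is by unique-anchor chaining: maximal exact matches seeded from
k-mers unique in both genomes are chained collinearly; inter-anchor gaps up
to 5 kb are closed by global (edit-distance) alignment; the result is a set
of gapless blocks, one-to-one on the representative.  At the >= 95% identity
this module targets, anchor chaining recovers essentially the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
import pandas as pd
import scipy.stats

from .quality import GenomeBin
from .stats import ks_normal, bh_qvalues, mann_whitney_u

ANCHOR_MIN = 31
MAX_GAP = 5_000
CONTIG_SEPARATOR = "N" * 100
MIN_GENOMES_FOR_SNV = 3
MIN_GENOMES_FOR_DENSITY = 10
DENSITY_CHUNK_THRESHOLD = 5.0  # SNV per kb
CHUNK_SMALL = 50_000
CHUNK_LARGE = 100_000
MIN_CHUNKS = 5


@dataclass
class AlignmentBlocks:
    """Gapless alignment blocks between a representative and a member genome.

    Coordinates are 0-based on the concatenated (separator-joined) genomes;
    blocks are non-overlapping and sorted along the representative.
    """

    rep_seq: str
    g_seq: str
    blocks: list[tuple[int, int, int]]  # (rep_start, g_start, length)

    @property
    def aligned_length(self) -> int:
        return sum(b[2] for b in self.blocks)


@dataclass
class SnvCatalogEntry:
    rep_id: str
    genome_id: str
    snvs: list[tuple[int, str, str]]  # (1-based rep position, ref base, alt base)
    aligned_length: int


@dataclass
class SnvSummary:
    species_id: str
    n_genomes: int
    snv_per_kb: float
    zero_alignment_pairs: list[str] = field(default_factory=list)


@dataclass
class ChunkNormality:
    rep_id: str
    genome_id: str
    chunk_size: int
    counts: np.ndarray
    tested: bool
    ks_statistic: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    normal: bool | None = None


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _anchor_runs(r_seq: str, g_seq: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact-match runs (r_start, g_start, length) from shared unique k-mers."""
    ur = _unique_kmers(r_seq, k)
    ug = _unique_kmers(g_seq, k)
    shared = sorted(set(ur) & set(ug), key=ur.get)
    if not shared:
        return []
    r_pos = np.array([ur[s] for s in shared])
    g_pos = np.array([ug[s] for s in shared])
    order = np.argsort(r_pos)
    r_pos, g_pos = r_pos[order], g_pos[order]
    # merge anchors that continue the same diagonal contiguously
    runs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(r_pos) + 1):
        if (
            i == len(r_pos)
            or r_pos[i] - r_pos[i - 1] != g_pos[i] - g_pos[i - 1]
            or r_pos[i] - r_pos[i - 1] > k
        ):
            length = int(r_pos[i - 1] - r_pos[start]) + k
            runs.append((int(r_pos[start]), int(g_pos[start]), length))
            start = i
    return runs


def _chain_runs(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Best collinear chain of runs (weighted LIS on both coordinates)."""
    if not runs:
        return []
    runs = sorted(runs)
    n = len(runs)
    score = [float(r[2]) for r in runs]
    prev = [-1] * n
    for i in range(n):
        ri, gi, li = runs[i]
        for j in range(i):
            rj, gj, lj = runs[j]
            if rj + lj <= ri and gj + lj <= gi:
                cand = score[j] + li
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(runs[best])
        best = prev[best]
    return chain[::-1]


def _close_gap(
    r_seq: str, g_seq: str, r0: int, r1: int, g0: int, g1: int
) -> list[tuple[int, int, int]]:
    """Globally align the gap between two chained runs; return gapless blocks."""
    sub_r = r_seq[r0:r1]
    sub_g = g_seq[g0:g1]
    if not sub_r or not sub_g:
        return []
    res = edlib.align(sub_g, sub_r, mode="NW", task="path")
    blocks = []
    rp, gp = r0, g0
    for length, op in _parse_cigar(res["cigar"]):
        if op in "=XM":
            blocks.append((rp, gp, length))
            rp += length
            gp += length
        elif op == "I":  # insertion in g relative to r
            gp += length
        elif op == "D":
            rp += length
    # merge adjacent same-diagonal blocks
    merged: list[tuple[int, int, int]] = []
    for b in blocks:
        if merged and merged[-1][0] + merged[-1][2] == b[0] and merged[-1][1] + merged[-1][2] == b[1]:
            merged[-1] = (merged[-1][0], merged[-1][1], merged[-1][2] + b[2])
        else:
            merged.append(b)
    return merged


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def concat_bin(bin: GenomeBin) -> str:
    return CONTIG_SEPARATOR.join(bin.contigs)


def align_conspecific(
    rep: GenomeBin, g: GenomeBin, anchor_min: int = ANCHOR_MIN, max_gap: int = MAX_GAP
) -> AlignmentBlocks:
    """Align a member genome to the species representative by anchor chaining.

    Returns gapless blocks on the concatenated genomes; no anchors means an
    empty alignment (not an error).
    """
    r_seq = concat_bin(rep)
    g_seq = concat_bin(g)
    runs = _anchor_runs(r_seq, g_seq, anchor_min)
    chain = _chain_runs(runs)
    if not chain:
        return AlignmentBlocks(rep_seq=r_seq, g_seq=g_seq, blocks=[])
    blocks: list[tuple[int, int, int]] = [chain[0]]
    for cur in chain[1:]:
        pr, pg, pl = blocks[-1]
        gap_r = cur[0] - (pr + pl)
        gap_g = cur[1] - (pg + pl)
        if 0 < max(gap_r, gap_g) and gap_r <= max_gap and gap_g <= max_gap:
            blocks.extend(_close_gap(r_seq, g_seq, pr + pl, cur[0], pg + pl, cur[1]))
        blocks.append(cur)
    # merge adjacent same-diagonal blocks
    merged: list[tuple[int, int, int]] = []
    for b in sorted(blocks):
        if merged and merged[-1][0] + merged[-1][2] == b[0] and merged[-1][1] + merged[-1][2] == b[1]:
            merged[-1] = (merged[-1][0], merged[-1][1], merged[-1][2] + b[2])
        else:
            merged.append(b)
    return AlignmentBlocks(rep_seq=r_seq, g_seq=g_seq, blocks=merged)


def call_snvs(blocks: AlignmentBlocks, rep_id: str = "rep", genome_id: str = "g") -> SnvCatalogEntry:
    """Report substitution columns within alignment blocks as SNVs.

    Positions are 1-based on the (concatenated) representative; indels are
    excluded by construction; separator (N) columns never count.
    """
    snvs: list[tuple[int, str, str]] = []
    aligned = 0
    for r0, g0, length in blocks.blocks:
        rs = blocks.rep_seq[r0 : r0 + length]
        gs = blocks.g_seq[g0 : g0 + length]
        aligned += length
        for i in range(length):
            if rs[i] != gs[i] and rs[i] != "N" and gs[i] != "N":
                snvs.append((r0 + i + 1, rs[i], gs[i]))
    return SnvCatalogEntry(rep_id=rep_id, genome_id=genome_id, snvs=snvs, aligned_length=aligned)


def snv_per_kb(entries: list[SnvCatalogEntry], species_id: str = "sp") -> SnvSummary:
    """Per-cluster SNV density normalized by aligned length and member count."""
    if not entries:
        raise ValueError("snv_per_kb undefined for clusters with fewer than 2 genomes")
    total = 0.0
    flagged = []
    for e in entries:
        if e.aligned_length == 0:
            flagged.append(e.genome_id)
            continue
        total += len(e.snvs) / (e.aligned_length / 1000.0)
    return SnvSummary(
        species_id=species_id,
        n_genomes=len(entries) + 1,
        snv_per_kb=total / len(entries),
        zero_alignment_pairs=flagged,
    )


def chunk_size_for_density(species_snv_per_kb: float) -> int:
    """50-kb chunks for densities above 5 per kb, 100-kb at or below."""
    return CHUNK_SMALL if species_snv_per_kb > DENSITY_CHUNK_THRESHOLD else CHUNK_LARGE


def chunk_counts(
    entry: SnvCatalogEntry,
    blocks: AlignmentBlocks | None,
    chunk_size: int,
) -> np.ndarray:
    """Per-chunk SNV counts over the concatenated aligned region.

    The aligned blocks are laid end-to-end into a single coordinate system;
    SNV positions are mapped into it; consecutive non-overlapping chunks are
    counted, the trailing partial chunk dropped.  When ``blocks`` is None
    the entry's aligned_length is treated as one contiguous region (useful
    for planted catalogs).
    """
    if blocks is not None:
        # map rep position -> offset in the concatenated aligned coordinate
        offsets = []
        acc = 0
        for r0, _, length in blocks.blocks:
            offsets.append((r0, r0 + length, acc))
            acc += length
        virtual = []
        for pos, _, _ in entry.snvs:
            p = pos - 1
            for r0, r1, off in offsets:
                if r0 <= p < r1:
                    virtual.append(off + (p - r0))
                    break
        total = acc
        positions = np.array(virtual, dtype=np.int64)
    else:
        total = entry.aligned_length
        positions = np.array([p - 1 for p, _, _ in entry.snvs], dtype=np.int64)
    n_chunks = total // chunk_size
    if n_chunks == 0:
        return np.empty(0, dtype=np.int64)
    positions = positions[positions < n_chunks * chunk_size]
    return np.bincount(positions // chunk_size, minlength=n_chunks).astype(np.int64)


def chunk_normality(
    entry: SnvCatalogEntry,
    species_snv_per_kb: float,
    blocks: AlignmentBlocks | None = None,
) -> ChunkNormality:
    """KS normality screen of per-chunk SNV counts for one r-g pair.

    Pairs with fewer than 5 chunks are skipped (recorded untested);
    q-values are assigned across pairs by :func:`normality_screen`.
    """
    size = chunk_size_for_density(species_snv_per_kb)
    counts = chunk_counts(entry, blocks, size)
    out = ChunkNormality(
        rep_id=entry.rep_id, genome_id=entry.genome_id, chunk_size=size,
        counts=counts, tested=False,
    )
    if counts.size < MIN_CHUNKS:
        return out
    res = ks_normal(counts)
    out.tested = True
    out.ks_statistic = res.statistic
    out.p_value = res.p_value
    return out


def normality_screen(results: list[ChunkNormality], alpha: float = 0.05) -> list[ChunkNormality]:
    """Benjamini-Hochberg across all tested pairs; pair is normal iff q > alpha."""
    tested = [r for r in results if r.tested]
    if tested:
        qs = bh_qvalues([r.p_value for r in tested])
        for r, q in zip(tested, qs):
            r.q_value = float(q)
            r.normal = bool(q > alpha)
    return results


def nearest_species_distance(
    tree: "dendropy.Tree | str", species: str, k_nearest: int = 5
) -> float:
    """Mean patristic distance from a species to its k nearest leaves."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    if species not in taxa:
        raise ValueError(f"leaf {species!r} not in tree")
    focal = taxa[species]
    dists = sorted(
        pdm.patristic_distance(focal, t) for t in tree.taxon_namespace if t is not focal
    )
    if len(dists) < k_nearest:
        raise ValueError(f"tree has only {len(dists)} other leaves, need {k_nearest}")
    return float(np.mean(dists[:k_nearest]))


def density_speciation_association(
    summaries: list[SnvSummary], distances: dict[str, float]
) -> dict:
    """Spearman correlation of SNV density with nearest-species distance, plus
    a two-sided Mann-Whitney comparison of the closest decile vs the rest.

    Species are sorted from the lowest average phylogenetic distance; the
    top decile holds floor(0.1 n) species (ties broken by species id).
    """
    pairs = [(s.species_id, s.snv_per_kb, distances[s.species_id])
             for s in summaries if s.species_id in distances]
    if len(pairs) < 20:
        raise ValueError("need >= 20 species with both density and distance")
    df = pd.DataFrame(pairs, columns=["species", "snv_per_kb", "distance"])
    if df["snv_per_kb"].nunique() == 1 or df["distance"].nunique() == 1:
        rho, rho_p = float("nan"), float("nan")
    else:
        rho, rho_p = scipy.stats.spearmanr(df["snv_per_kb"], df["distance"])
    df = df.sort_values(["distance", "species"]).reset_index(drop=True)
    n_top = int(np.floor(0.1 * len(df)))
    top = df.iloc[:n_top]["snv_per_kb"]
    rest = df.iloc[n_top:]["snv_per_kb"]
    mwu = mann_whitney_u(top, rest)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "n_top": n_top,
        "top_median": float(top.median()),
        "rest_median": float(rest.median()),
        "mwu_u": mwu.u_statistic,
        "mwu_p": mwu.p_value,
    }
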