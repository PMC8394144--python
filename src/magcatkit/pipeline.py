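"""End-to-end orchestration of the catalog pipeline stages.

``RunConfig`` aggregates every tunable threshold at its standard default;
``run_catalog`` composes QC filtering, two-step species clustering and
non-redundant counting; ``run_snv``, ``run_mimicry`` and ``run_depth`` are
thin orchestration over the owning modules.  All randomness derives from
the single root seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import derep, depthprof, mimicry, quality, snv
from .quality import GenomeBin


@dataclass
class RunConfig:
    seed: int = 0
    k: int = 21
    sketch_size: int = 10_000
    hash_seed: int = 42
    mash_cutoff: float = 0.2
    pairing_cutoff: float = 0.1
    redundancy_cutoff: float = 0.001
    ani_cutoff: float = 0.05
    coverage_cap: float = 0.8
    frag_len: int = 1_000
    min_completeness: float = 50.0
    max_contamination: float = 5.0
    min_quality_score: float = 50.0
    snv_min_genomes: int = 3
    density_min_genomes: int = 10
    density_chunk_threshold: float = 5.0
    ecg_p_threshold: float = 1e-5
    disease_min_taxa: int = 40
    stratum_bounds: list[float] = field(
        default_factory=lambda: (10.0 ** np.arange(-7, 1)).tolist()
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        tag = zlib.crc32(stage.encode())
        return int(np.random.default_rng([self.seed, tag]).integers(2**31))


@dataclass
class CatalogBundle:
    qc: pd.DataFrame
    clusters: list[derep.SpeciesCluster]
    cluster_table: pd.DataFrame
    nonredundant: int
    n_filtered: int


def run_catalog(bins: list[GenomeBin], config: RunConfig | None = None) -> CatalogBundle:
    """QC -> filter -> two-step species clustering -> non-redundant count."""
    config = config or RunConfig()
    if not bins:
        raise ValueError("run_catalog: no input bins")
    qc = quality.qc_table(bins)
    kept = [b for b in bins if quality.passes_bin_filter(b)]
    if not kept:
        raise ValueError("run_catalog: no bins pass the QC filter")
    clusters = derep.two_step_species_clustering(
        kept,
        mash_cutoff=config.mash_cutoff,
        ani_cutoff=config.ani_cutoff,
        k=config.k,
        s=config.sketch_size,
        hash_seed=config.hash_seed,
        frag_len=config.frag_len,
    )
    species_of = {m: f"sp{i:05d}" for i, cl in enumerate(clusters) for m in cl.members}
    nonred = derep.count_nonredundant(
        kept,
        species_of,
        k=config.k,
        s=config.sketch_size,
        hash_seed=config.hash_seed,
        component_cutoff=config.pairing_cutoff,
        redundancy_cutoff=config.redundancy_cutoff,
    )
    rows = [
        {
            "species_id": f"sp{i:05d}",
            "representative": cl.representative,
            "n_members": len(cl.members),
            "members": ",".join(sorted(cl.members)),
            "iteration": cl.iteration_found,
        }
        for i, cl in enumerate(clusters)
    ]
    return CatalogBundle(
        qc=qc,
        clusters=clusters,
        cluster_table=pd.DataFrame(rows),
        nonredundant=nonred,
        n_filtered=len(kept),
    )


def run_snv(
    bins_by_id: dict[str, GenomeBin],
    clusters: list[derep.SpeciesCluster],
    config: RunConfig | None = None,
) -> tuple[list[snv.SnvSummary], list[snv.ChunkNormality]]:
    """SNV calling, per-cluster density and chunk-normality screen."""
    config = config or RunConfig()
    summaries = []
    norm_results = []
    for i, cl in enumerate(clusters):
        if len(cl.members) < config.snv_min_genomes:
            continue
        rep = bins_by_id[cl.representative]
        entries = []
        block_map = {}
        for gid in sorted(cl.members - {cl.representative}):
            blocks = snv.align_conspecific(rep, bins_by_id[gid])
            entry = snv.call_snvs(blocks, rep_id=cl.representative, genome_id=gid)
            entries.append(entry)
            block_map[gid] = blocks
        summary = snv.snv_per_kb(entries, species_id=f"sp{i:05d}")
        summaries.append(summary)
        if len(cl.members) >= config.density_min_genomes:
            for entry in entries:
                norm_results.append(
                    snv.chunk_normality(entry, summary.snv_per_kb, block_map[entry.genome_id])
                )
    snv.normality_screen(norm_results)
    return summaries, norm_results


def run_mimicry(
    proteomes: dict[str, list[tuple[str, str]]],
    epitopes: list[tuple[str, str]],
    taxonomy: dict[str, list[str]] | None = None,
    clade_members: dict[str, set[str]] | None = None,
    annotations: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> dict:
    """ECG profiling per species, optional clade enrichment and disease ORs."""
    config = config or RunConfig()
    profiles = [
        mimicry.count_ecgs(prots, epitopes, species_id=sp) for sp, prots in proteomes.items()
    ]
    out: dict = {"profiles": profiles}
    if clade_members:
        enrich = {
            taxon: mimicry.clade_enrichment(profiles, members)
            for taxon, members in clade_members.items()
        }
        out["enrichment"] = enrich
        if taxonomy is not None:
            high, low = mimicry.partition_cross_reactivity(
                enrich, taxonomy, p_threshold=config.ecg_p_threshold
            )
            out["high"], out["low"] = high, low
            if annotations is not None:
                out["disease"] = mimicry.disease_association(
                    annotations, high, high | low, min_taxa=config.disease_min_taxa
                )
    return out


def run_depth(
    reference_counts: pd.Series,
    depths: list[int],
    config: RunConfig | None = None,
    mode: str = "multinomial",
) -> pd.DataFrame:
    """Depth-correlation curve over the configured abundance strata."""
    config = config or RunConfig()
    return depthprof.depth_correlation_curve(
        reference_counts, depths, seed=config.stage_seed("depth"), mode=mode
    )
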