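"""Standard-format I/O: FASTA bins and proteomes, TSV metadata and reports.

FASTA goes through Biopython; metadata follows the schema
(bin_id, sample_id, country, completeness_pct, contamination_pct,
has_5S, has_16S, has_23S, trna_count).  Output tables carry a provenance
header line (# magcatkit <version> seed=... config=...).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .quality import GenomeBin

META_COLUMNS = [
    "bin_id",
    "sample_id",
    "country",
    "completeness_pct",
    "contamination_pct",
    "has_5S",
    "has_16S",
    "has_23S",
    "trna_count",
]


def write_bins(bins: list[GenomeBin], outdir: str | Path) -> Path:
    """Write one multi-FASTA per bin plus a metadata TSV; returns the TSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bins:
        records = [
            SeqRecord(Seq(seq), id=cid, description="")
            for cid, seq in zip(b.contig_ids, b.contigs)
        ]
        SeqIO.write(records, outdir / f"{b.bin_id}.fasta", "fasta")
        rows.append(
            {
                "bin_id": b.bin_id,
                "sample_id": b.sample_id,
                "country": b.country,
                "completeness_pct": b.completeness,
                "contamination_pct": b.contamination,
                "has_5S": int(b.has_5S),
                "has_16S": int(b.has_16S),
                "has_23S": int(b.has_23S),
                "trna_count": b.trna_count,
            }
        )
    meta = outdir / "metadata.tsv"
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta, sep="\t", index=False)
    return meta


def read_bins(bins_dir: str | Path, meta_path: str | Path | None = None) -> list[GenomeBin]:
    """Load bins from a directory of FASTA files plus the metadata TSV."""
    bins_dir = Path(bins_dir)
    meta_path = Path(meta_path) if meta_path else bins_dir / "metadata.tsv"
    meta = pd.read_csv(meta_path, sep="\t")
    bins = []
    for row in meta.itertuples(index=False):
        fasta = bins_dir / f"{row.bin_id}.fasta"
        if not fasta.exists():
            raise FileNotFoundError(f"missing FASTA for bin {row.bin_id}: {fasta}")
        records = list(SeqIO.parse(str(fasta), "fasta"))
        bins.append(
            GenomeBin(
                bin_id=str(row.bin_id),
                contigs=[str(r.seq).upper() for r in records],
                contig_ids=[r.id for r in records],
                sample_id=str(row.sample_id),
                country=str(row.country),
                completeness=float(row.completeness_pct),
                contamination=float(row.contamination_pct),
                has_5S=bool(row.has_5S),
                has_16S=bool(row.has_16S),
                has_23S=bool(row.has_23S),
                trna_count=int(row.trna_count),
            )
        )
    return bins


def write_proteome(proteins: list[tuple[str, str]], path: str | Path, genome_id: str = "genome") -> None:
    """Protein FASTA with ``gene_id|genome_id`` headers."""
    records = [
        SeqRecord(Seq(seq), id=f"{gid}|{genome_id}", description="") for gid, seq in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_proteome(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read a protein FASTA with ``gene_id|genome_id`` headers, grouped by genome."""
    out: dict[str, list[tuple[str, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, _, genome_id = rec.id.partition("|")
        out.setdefault(genome_id or "genome", []).append((gene_id, str(rec.seq)))
    return out


def read_epitope_table(path: str | Path) -> pd.DataFrame:
    """Epitope TSV with columns epitope_id, peptide, requires_ptm."""
    df = pd.read_csv(path, sep="\t")
    missing = {"epitope_id", "peptide", "requires_ptm"} - set(df.columns)
    if missing:
        raise ValueError(f"epitope table missing columns: {sorted(missing)}")
    return df


def provenance_header(seed: int | None = None, config: dict | None = None) -> str:
    cfg_hash = (
        hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
        if config
        else "none"
    )
    return f"# magcatkit {__version__} seed={seed} config_sha={cfg_hash}"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None, config: dict | None = None) -> None:
    """TSV with a one-line provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
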