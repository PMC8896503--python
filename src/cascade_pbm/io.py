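"""Input readers: FASTA regions, BED intervals plus a genome, SNP tables."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .design import SnpSpec
from .seq import validate_dna

SNP_COLUMNS = ["rsid", "chrom", "pos", "ref", "nonref", "qtl_class"]


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {record id: upper-case sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def read_bed_regions(bed_path, genome: dict[str, str]) -> dict[str, str]:
    """BED3+name intervals (0-based half-open) extracted from a genome dict."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][:4],
    )
    out: dict[str, str] = {}
    for _, row in bed.iterrows():
        chrom = str(row["chrom"])
        if chrom not in genome:
            raise ValueError(f"{bed_path}: chromosome {chrom} not in genome FASTA")
        start, end = int(row["start"]), int(row["end"])
        if not 0 <= start < end <= len(genome[chrom]):
            raise ValueError(f"{bed_path}: interval {chrom}:{start}-{end} out of range")
        name = str(row["name"]) if "name" in bed.columns and pd.notna(row.get("name")) else f"{chrom}:{start}-{end}"
        out[name] = validate_dna(genome[chrom][start:end], name)
    if not out:
        raise ValueError(f"{bed_path}: no intervals")
    return out


def read_snp_tsv(path, genome: dict[str, str] | None = None) -> list[SnpSpec]:
    """SNP table -> specs.

    Required columns: rsid, chrom, pos (1-based), ref, nonref, qtl_class.
    Flanking sequence comes from either a ``target`` column (the 26-mer
    centred at the SNP, checked against the ref allele), explicit
    ``flank5``/``flank3`` columns, or the supplied genome FASTA.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    specs = []
    for _, row in df.iterrows():
        kw = dict(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            qtl_class=row["qtl_class"],
        )
        if "target" in df.columns and pd.notna(row.get("target")):
            specs.append(
                SnpSpec.from_target(
                    row["rsid"], row["target"],
                    nonref_allele=row["nonref"], ref_allele=row["ref"], **kw,
                )
            )
        elif "flank5" in df.columns and "flank3" in df.columns:
            specs.append(
                SnpSpec(
                    rsid=row["rsid"], ref_allele=row["ref"],
                    nonref_allele=row["nonref"],
                    flank5_seq=row["flank5"], flank3_seq=row["flank3"], **kw,
                )
            )
        elif genome is not None:
            chrom, pos = row["chrom"], int(row["pos"])  # pos is 1-based
            if chrom not in genome:
                raise ValueError(f"{path}: chromosome {chrom} not in genome FASTA")
            seq = genome[chrom]
            i = pos - 1
            if i - 13 < 0 or i + 13 > len(seq):
                raise ValueError(f"{path}: {row['rsid']} too close to contig edge")
            target = seq[i - 13 : i + 13].upper()
            specs.append(
                SnpSpec.from_target(
                    row["rsid"], target,
                    nonref_allele=row["nonref"], ref_allele=row["ref"], **kw,
                )
            )
        else:
            raise ValueError(
                f"{path}: {row['rsid']}: no flank source (need target or "
                "flank5/flank3 columns, or a genome FASTA)"
            )
    return specs
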