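"""Per-sample read 3'-end tables from aligned long reads or TSV.

The 3' end of a read is taken on the *gene's* strand: cDNA reads may align
antisense, but the unique gene assignment fixes the transcription orientation.
Soft-clipped bases (adapter / poly(A)) are excluded — only aligned reference
bases count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

COLUMNS = ["read_id", "gene_id", "chrom", "strand", "end3", "sample_id"]


@dataclass
class ReadEndTable:
    """Validated table of read 3'-end records plus a sample->condition map."""

    df: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"read-end table missing column(s): {', '.join(missing)}")
        bad_strand = set(self.df["strand"].unique()) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strand value(s): {sorted(bad_strand)}")
        if (self.df["end3"] < 0).any():
            raise ValueError("end3 coordinates must be non-negative")
        dup = self.df.duplicated(subset=["sample_id", "read_id"])
        if dup.any():
            offender = self.df.loc[dup, ["sample_id", "read_id"]].iloc[0]
            raise ValueError(
                f"duplicate read {offender.read_id!r} in sample {offender.sample_id!r}"
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def samples_for(self, condition: str) -> list[str]:
        return sorted(s for s, c in self.conditions.items() if c == condition)

    def concat(self, other: "ReadEndTable") -> "ReadEndTable":
        df = pd.concat([self.df, other.df], ignore_index=True)
        return ReadEndTable(df, {**self.conditions, **other.conditions})


def extract_read_ends(
    bam_path: str | Path,
    assignments_path: str | Path,
    sample_id: str,
    gene_strands: dict[str, str] | None = None,
) -> ReadEndTable:
    """Extract strand-aware 3' ends of uniquely assigned primary alignments.

    ``assignments_path`` is an IsoQuant-style TSV with at least read_id,
    gene_id and (optionally) assignment_type columns; rows whose
    assignment_type does not start with "unique" are dropped, as are reads
    assigned to more than one gene. ``gene_strands`` maps gene_id -> strand
    (e.g. from parsed gene models); genes absent from it are skipped with a
    logged count.

    end3 is the last aligned reference base for '+' genes and the first for
    '-' genes (0-based, soft clips excluded).
    """
    asn = pd.read_csv(assignments_path, sep="\t", comment=None, dtype=str)
    asn.columns = [c.lstrip("#") for c in asn.columns]
    if "read_id" not in asn.columns or "gene_id" not in asn.columns:
        raise ValueError("assignment TSV needs read_id and gene_id columns")
    if "assignment_type" in asn.columns:
        n0 = len(asn)
        asn = asn[asn["assignment_type"].str.startswith("unique")]
        logger.info("dropped %d non-unique assignment rows", n0 - len(asn))
    multi = asn.groupby("read_id")["gene_id"].nunique()
    ambiguous = set(multi[multi > 1].index)
    if ambiguous:
        logger.info("dropped %d reads assigned to multiple genes", len(ambiguous))
        asn = asn[~asn["read_id"].isin(ambiguous)]
    read2gene = dict(zip(asn["read_id"], asn["gene_id"]))

    records = []
    seen: set[str] = set()
    n_unknown_gene = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for aln in bam.fetch():
            if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                continue
            gene = read2gene.get(aln.query_name)
            if gene is None:
                continue
            if gene_strands is not None and gene not in gene_strands:
                n_unknown_gene += 1
                continue
            strand = gene_strands[gene] if gene_strands is not None else (
                "-" if aln.is_reverse else "+"
            )
            end3 = aln.reference_end - 1 if strand == "+" else aln.reference_start
            records.append(
                (aln.query_name, gene, aln.reference_name, strand, end3, sample_id)
            )
            seen.add(aln.query_name)
    n_missing = len(set(read2gene) - seen)
    if n_missing:
        logger.info("%d assigned reads absent from BAM (or non-primary only)", n_missing)
    if n_unknown_gene:
        logger.info("%d alignments skipped: gene not in annotation", n_unknown_gene)
    df = pd.DataFrame(records, columns=COLUMNS)
    return ReadEndTable(df)


def load_read_end_table(
    tsv_path: str | Path, conditions: dict[str, str] | None = None
) -> ReadEndTable:
    """Load a read-end TSV (header: read_id gene_id chrom strand end3 sample_id)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{tsv_path}: missing column(s): {', '.join(missing)}")
    try:
        df["end3"] = df["end3"].astype(int)
    except ValueError:
        bad = df[~df["end3"].str.fullmatch(r"-?\d+")].index[0]
        raise ValueError(f"{tsv_path}: non-integer end3 at data line {bad + 1}") from None
    return ReadEndTable(df[COLUMNS], conditions or {})


def write_read_end_table(table: ReadEndTable, tsv_path: str | Path) -> None:
    table.df.to_csv(tsv_path, sep="\t", index=False, columns=COLUMNS)
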