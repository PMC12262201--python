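"""Gene annotation, reference PAS sets, and genome sequence access.

All coordinates are 0-based half-open internally. GTF input (1-based,
end-inclusive) and BED input (already 0-based half-open) are converted at the
boundary, so downstream modules never see mixed conventions.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, sorted and merged (touching intervals fuse)."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def point_in_intervals(pos: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


@dataclass
class GeneModel:
    """One gene's structure in 0-based half-open genomic coordinates.

    ``last_exon_union`` is the union, over the gene's transcripts, of each
    transcript's strand-wise 3'-most exon; it is where tandem 3'UTR PASs live.
    ``stop_codon_pos`` is the transcription-wise 3'-most base of the 3'-most
    annotated stop codon (None for non-coding genes).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    last_exon_union: list[Interval] = field(default_factory=list)
    stop_codon_pos: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in ("exons", "cds", "utr3", "last_exon_union"):
            for s, e in getattr(self, name):
                if not (self.start <= s < e <= self.end):
                    raise ValueError(
                        f"{self.gene_id}: {name} interval ({s},{e}) outside "
                        f"gene span [{self.start},{self.end})"
                    )


@dataclass
class ReferencePASSet:
    """Annotated PAS coordinates, sorted per (chrom, strand).

    ``genes[(chrom, strand)][i]`` carries the optional host-gene label of the
    i-th coordinate (None when the BED name column is uninformative).
    """

    coords: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    genes: dict[tuple[str, str], list[str | None]] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, pos: int, gene: str | None = None) -> None:
        key = (chrom, strand)
        cs = self.coords.setdefault(key, [])
        gs = self.genes.setdefault(key, [])
        i = bisect_left(cs, pos)
        while i < len(cs) and cs[i] == pos:
            if gs[i] == gene:
                return
            i += 1
        cs.insert(i, pos)
        gs.insert(i, gene)

    def __len__(self) -> int:
        return sum(len(v) for v in self.coords.values())


class GenomeSequence:
    """FASTA-backed genome with strand-aware, always-uppercase access."""

    def __init__(self, fasta_path: str | Path):
        self._fa = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); minus strand returns the reverse complement."""
        if chrom not in self._fa:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            return ""
        seq = str(self._fa[chrom][start:end])
        return reverse_complement(seq) if strand == "-" else seq

    def close(self) -> None:
        self._fa.close()


def _transcript_last_exon(exons: list[Interval], strand: str) -> Interval:
    return max(exons) if strand == "+" else min(exons)


def parse_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Parse a GENCODE-dialect GTF into per-gene models.

    Transcripts without exons are skipped with a warning. Genes without CDS
    get an empty 3'UTR and no stop-codon position. GENCODE ``UTR`` features
    are assigned to the 3'UTR when they lie transcription-wise 3' of the
    gene's stop codon.
    """
    with open(gtf_path) as fh:
        for ln, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"malformed GTF line {ln} in {gtf_path}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise ValueError(
                    f"malformed GTF line {ln} in {gtf_path}: non-integer coordinates"
                )
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line-level failures
        raise ValueError(f"malformed GTF {gtf_path}: {exc}") from exc

    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        gene_name = gene.attributes.get("gene_name", [gene_id])[0]
        strand = gene.strand
        if strand not in ("+", "-"):
            logger.warning("gene %s has strand %r; skipped", gene_id, strand)
            continue
        g_start, g_end = gene.start - 1, gene.end

        exons: list[Interval] = []
        cds: list[Interval] = []
        utr: list[Interval] = []
        stop_iv: list[Interval] = []
        last_exons: list[Interval] = []

        transcripts = list(db.children(gene, featuretype="transcript"))
        containers = transcripts if transcripts else [gene]
        for tx in containers:
            tx_exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            if not tx_exons:
                logger.warning("transcript %s of %s has no exons; skipped", tx.id, gene_id)
                continue
            exons.extend(tx_exons)
            last_exons.append(_transcript_last_exon(tx_exons, strand))
            cds.extend((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
            stop_iv.extend(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="stop_codon")
            )
            for f in db.children(tx, featuretype=("UTR", "three_prime_utr", "3UTR")):
                utr.append((f.start - 1, f.end))

        stop_codon_pos: int | None = None
        if stop_iv:
            # transcription-wise 3'-most base of the 3'-most stop codon
            if strand == "+":
                stop_codon_pos = max(e for _, e in stop_iv) - 1
            else:
                stop_codon_pos = min(s for s, _ in stop_iv)

        utr3: list[Interval] = []
        if stop_codon_pos is not None:
            for s, e in utr:
                if strand == "+" and s >= stop_codon_pos:
                    utr3.append((s, e))
                elif strand == "-" and e <= stop_codon_pos + 1:
                    utr3.append((s, e))

        models[gene_id] = GeneModel(
            gene_id=gene_id,
            gene_name=gene_name,
            chrom=gene.seqid,
            strand=strand,
            start=g_start,
            end=g_end,
            exons=merge_intervals(exons),
            cds=merge_intervals(cds),
            utr3=merge_intervals(utr3),
            last_exon_union=merge_intervals(last_exons),
            stop_codon_pos=stop_codon_pos,
        )
    return models


def write_gene_models_gtf(models: dict[str, GeneModel], path: str | Path) -> None:
    """Write gene models back to a minimal GENCODE-dialect GTF.

    Each gene is emitted as one synthetic transcript carrying the merged exon,
    CDS, UTR and stop-codon features; round-tripping through
    :func:`parse_gene_models` reproduces the interval sets.
    """
    with open(path, "w") as fh:
        for gm in models.values():
            tx_id = f"{gm.gene_id}.t1"
            attrs_g = f'gene_id "{gm.gene_id}"; gene_name "{gm.gene_name}";'
            attrs_t = attrs_g + f' transcript_id "{tx_id}";'

            def line(feature: str, s: int, e: int, attrs: str) -> str:
                return (
                    f"{gm.chrom}\tlrapa\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{gm.strand}\t.\t{attrs}\n"
                )

            fh.write(line("gene", gm.start, gm.end, attrs_g))
            fh.write(line("transcript", gm.start, gm.end, attrs_t))
            for s, e in gm.exons:
                fh.write(line("exon", s, e, attrs_t))
            for s, e in gm.cds:
                fh.write(line("CDS", s, e, attrs_t))
            for s, e in gm.utr3:
                fh.write(line("UTR", s, e, attrs_t))
            if gm.stop_codon_pos is not None:
                if gm.strand == "+":
                    s = gm.stop_codon_pos - 2
                    e = gm.stop_codon_pos + 1
                else:
                    s = gm.stop_codon_pos
                    e = gm.stop_codon_pos + 3
                fh.write(line("stop_codon", max(s, gm.start), min(e, gm.end), attrs_t))


def load_reference_pas(bed_path: str | Path) -> ReferencePASSet:
    """Load an annotated PAS set from BED6.

    The PAS coordinate is the strand-wise 3' base of each interval (end-1 on
    '+', start on '-'). The name column, when not '.', is kept as the host
    gene label and used for match classification.
    """
    ref = ReferencePASSet()
    with open(bed_path) as fh:
        for ln, raw in enumerate(fh, 1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t") if "\t" in raw else raw.split()
            if len(parts) < 6:
                raise ValueError(
                    f"{bed_path}:{ln}: reference PAS BED needs 6 columns "
                    f"(strand is required), got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{bed_path}:{ln}: invalid strand {strand!r}")
            s, e = int(start), int(end)
            pos = e - 1 if strand == "+" else s
            ref.add(chrom, strand, pos, None if name in (".", "") else name)
    return ref


def fetch_flank(
    genome: GenomeSequence,
    chrom: str,
    pos: int,
    upstream: int,
    downstream: int,
    strand: str,
) -> str:
    """Transcription-oriented window around ``pos`` (inclusive).

    Covers ``upstream`` nt 5' of pos through ``downstream`` nt 3' of pos; on
    the minus strand the genomic window is reverse-complemented so string
    indices always run 5'->3'. Windows overhanging a chromosome end are
    clipped (logged); a window entirely off-chromosome raises ValueError.
    """
    clen = genome.chrom_length(chrom)
    if strand == "+":
        g_start, g_end = pos - upstream, pos + downstream + 1
    else:
        g_start, g_end = pos - downstream, pos + upstream + 1
    if g_end <= 0 or g_start >= clen:
        raise ValueError(
            f"window [{g_start},{g_end}) fully outside {chrom} (length {clen})"
        )
    c_start, c_end = max(g_start, 0), min(g_end, clen)
    clipped = (c_start - g_start) + (g_end - c_end)
    if clipped:
        logger.info("flank at %s:%d clipped by %d nt", chrom, pos, clipped)
    return genome.fetch(chrom, c_start, c_end, strand)
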