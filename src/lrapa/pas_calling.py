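"""PAS peak calling, classification and artifact flagging.

A PAS is a peak of read 3' ends: reads from one site cluster within a short
window (<= 20 nt by default) around the maximum-depth coordinate. Calling
pools reads across all samples so every condition shares one catalog; peaks
below the overall-usage cutoff (default 1% of the gene's pooled reads) are
removed together with their reads.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from lrapa.annotation_io import (
    GeneModel,
    GenomeSequence,
    ReferencePASSet,
    fetch_flank,
    point_in_intervals,
)
from lrapa.read_end_ingest import ReadEndTable

logger = logging.getLogger(__name__)


class Cluster(NamedTuple):
    peak: int
    members: dict[int, int]  # coordinate -> multiplicity
    depth: int


@dataclass
class PAS:
    pas_id: str
    gene_id: str
    chrom: str
    strand: str
    peak: int
    counts: dict[str, int]
    overall_pau: float
    ref_class: str | None = None  # match / proximity / novel
    ref_distance: int | None = None
    region: str | None = None  # utr3_exon / cds_exon / intron / downstream / other
    internal_priming: bool = False
    rank: int = 0  # 1..K proximal -> distal

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class PASCatalog:
    genes: dict[str, list[PAS]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def all_pas(self) -> list[PAS]:
        return [p for pas_list in self.genes.values() for p in pas_list]

    def get(self, pas_id: str) -> PAS:
        for p in self.all_pas():
            if p.pas_id == pas_id:
                return p
        raise KeyError(pas_id)


def _oriented(pos: int, strand: str) -> int:
    """Transcription-oriented coordinate: larger = more distal (3')."""
    return pos if strand == "+" else -pos


def cluster_read_ends(
    ends: Iterable[int], window: int = 20, strand: str = "+"
) -> list[Cluster]:
    """Greedy maximum-depth-first clustering of 3'-end coordinates.

    Repeatedly select the unassigned coordinate with the most reads as a peak
    (depth ties broken toward the transcription-proximal coordinate) and
    absorb every unassigned coordinate within ``window`` nt. Every end
    belongs to exactly one cluster. Clusters are returned proximal -> distal.
    """
    counts = Counter(ends)
    if not counts:
        return []
    if window < 0:
        raise ValueError("window must be >= 0")
    order = sorted(counts, key=lambda c: (-counts[c], _oriented(c, strand)))
    coords = sorted(counts)
    assigned: set[int] = set()
    clusters: list[Cluster] = []
    for peak in order:
        if peak in assigned:
            continue
        lo = bisect_left(coords, peak - window)
        hi = bisect_left(coords, peak + window + 1)
        members = {
            c: counts[c] for c in coords[lo:hi] if c not in assigned
        }
        assigned.update(members)
        clusters.append(Cluster(peak, members, sum(members.values())))
    clusters.sort(key=lambda cl: _oriented(cl.peak, strand))
    return clusters


def classify_vs_reference(
    peak: int,
    chrom: str,
    strand: str,
    gene_id: str,
    ref: ReferencePASSet,
    max_dist: int = 20,
) -> tuple[str, int | None]:
    """Classify a peak against annotated PASs: match / proximity / novel.

    A match requires distance 0 and, when the reference entry carries a gene
    label, the same host gene; proximity is within ``max_dist`` nt (signed
    distance reported transcription-wise: positive = reference downstream of
    the peak). Anything farther is novel.
    """
    key = (chrom, strand)
    coords = ref.coords.get(key, [])
    if not coords:
        return "novel", None
    labels = ref.genes[key]
    i = bisect_left(coords, peak)
    best: tuple[int, int] | None = None  # (|distance|, index)
    is_match = False
    for j in range(max(0, i - 2), min(len(coords), i + 2)):
        d = abs(coords[j] - peak)
        if d == 0 and (labels[j] is None or labels[j] == gene_id):
            is_match = True
        if best is None or d < best[0]:
            best = (d, j)
    assert best is not None
    if is_match:
        return "match", 0
    dist_abs, j = best
    if dist_abs <= max_dist:
        signed = coords[j] - peak
        if strand == "-":
            signed = -signed
        return "proximity", signed
    return "novel", None


def annotate_region(peak: int, model: GeneModel) -> str:
    """Locate a peak within gene structure.

    Priority: 3'UTR exon > CDS exon > intron > downstream (strand-wise 3' of
    the gene span) > other.
    """
    if point_in_intervals(peak, model.utr3):
        return "utr3_exon"
    if point_in_intervals(peak, model.cds):
        return "cds_exon"
    within = model.start <= peak < model.end
    if within and not point_in_intervals(peak, model.exons):
        return "intron"
    if not within:
        past_end = peak >= model.end if model.strand == "+" else peak < model.start
        if past_end:
            return "downstream"
    return "other"


def flag_internal_priming(
    peak: int,
    chrom: str,
    strand: str,
    genome: GenomeSequence,
    window: int = 10,
    min_a: int = 7,
) -> bool:
    """Flag likely oligo-dT internal-priming artifacts.

    True iff the ``window``-nt stretch immediately 5' OR immediately 3' of
    the peak (transcription-oriented, peak base excluded) contains at least
    ``min_a`` adenosines on the sense strand. A's need not be consecutive;
    with the defaults the rule is strictly "more than 6 A in 10 nt".
    Windows clipped at chromosome ends are evaluated on the available bases.
    """
    clen = genome.chrom_length(chrom)
    if strand == "+":
        up = genome.fetch(chrom, max(peak - window, 0), max(peak, 0), "+")
        down = genome.fetch(chrom, min(peak + 1, clen), min(peak + 1 + window, clen), "+")
    else:
        up = genome.fetch(chrom, min(peak + 1, clen), min(peak + 1 + window, clen), "-")
        down = genome.fetch(chrom, max(peak - window, 0), max(peak, 0), "-")
    return up.count("A") >= min_a or down.count("A") >= min_a


def classify_gene_apa_type(pas_list: list[PAS], model: GeneModel) -> str:
    """Gene APA architecture: single / last_exon_tandem / mixed.

    ``last_exon_tandem`` means every alternative PAS lies in the last-exon
    union (or strand-wise downstream of the gene) — pure 3'UTR APA; a gene
    also using intronic or internal-exon PASs is ``mixed``.
    """
    if len(pas_list) <= 1:
        return "single"
    for pas in pas_list:
        in_last = point_in_intervals(pas.peak, model.last_exon_union)
        downstream = annotate_region(pas.peak, model) == "downstream"
        if not (in_last or downstream):
            return "mixed"
    return "last_exon_tandem"


def call_pas(
    table: ReadEndTable,
    models: dict[str, GeneModel],
    min_overall_pau: float = 0.01,
    window: int = 20,
    reference: ReferencePASSet | None = None,
    genome: GenomeSequence | None = None,
    max_ref_dist: int = 20,
    ip_window: int = 10,
    ip_min_a: int = 7,
) -> PASCatalog:
    """Call the PAS catalog from pooled read 3' ends.

    Reads are pooled across samples per gene and clustered; peaks whose
    overall usage (cluster depth / gene's pooled reads) is below
    ``min_overall_pau`` are dropped with their reads. Retained PASs are
    ranked proximal -> distal; ``overall_pau`` stays the fraction of *all*
    pooled gene reads (not renormalized). When a reference set and/or genome
    are supplied, each PAS is classified against the reference, located in
    gene structure, and checked for internal priming.
    """
    catalog = PASCatalog(
        params=dict(
            window=window,
            min_overall_pau=min_overall_pau,
            max_ref_dist=max_ref_dist,
            ip_window=ip_window,
            ip_min_a=ip_min_a,
        )
    )
    for gene_id, gdf in table.df.groupby("gene_id", sort=True):
        model = models.get(gene_id)
        if model is None:
            logger.warning("gene %s absent from annotation; skipped", gene_id)
            continue
        ends = gdf["end3"].to_numpy()
        clusters = cluster_read_ends(ends, window=window, strand=model.strand)
        total = len(ends)
        retained = [cl for cl in clusters if cl.depth / total >= min_overall_pau]
        pas_list: list[PAS] = []
        for rank, cl in enumerate(retained, start=1):
            member_set = cl.members.keys()
            in_cluster = gdf[gdf["end3"].isin(member_set)]
            counts = in_cluster.groupby("sample_id").size().to_dict()
            pas = PAS(
                pas_id=f"{gene_id}:PAS{rank}",
                gene_id=gene_id,
                chrom=model.chrom,
                strand=model.strand,
                peak=cl.peak,
                counts=counts,
                overall_pau=cl.depth / total,
                rank=rank,
            )
            if reference is not None:
                pas.ref_class, pas.ref_distance = classify_vs_reference(
                    cl.peak, model.chrom, model.strand, gene_id, reference, max_ref_dist
                )
            pas.region = annotate_region(cl.peak, model)
            if genome is not None:
                pas.internal_priming = flag_internal_priming(
                    cl.peak, model.chrom, model.strand, genome, ip_window, ip_min_a
                )
            pas_list.append(pas)
        if pas_list:
            catalog.genes[gene_id] = pas_list
    return catalog


def catalog_to_bed(catalog: PASCatalog, path) -> None:
    """Write the catalog as BED6+ (extra columns: overall_pau, ref_class,
    ref_distance, region, internal_priming)."""
    rows = []
    for pas in catalog.all_pas():
        rows.append(
            (
                pas.chrom,
                pas.peak,
                pas.peak + 1,
                pas.pas_id,
                pas.depth,
                pas.strand,
                f"{pas.overall_pau:.6g}",
                pas.ref_class or ".",
                "." if pas.ref_distance is None else pas.ref_distance,
                pas.region or ".",
                int(pas.internal_priming),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
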