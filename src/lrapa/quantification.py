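"""PAS x sample count matrix, per-sample PAS usage (PAU) and usage changes.

PAU is compositional: within a gene and sample the usages of the retained
PASs sum to 1, provided the gene-sample depth meets the eligibility cutoff
(default 10 reads); below it the PAU is undefined (NaN) for that gene-sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lrapa.pas_calling import PASCatalog
from lrapa.read_end_ingest import ReadEndTable

logger = logging.getLogger(__name__)


@dataclass
class PAUMatrix:
    counts: pd.DataFrame  # PAS x sample, int
    pau: pd.DataFrame  # PAS x sample, float with NaN where ineligible
    gene_totals: pd.DataFrame  # gene x sample (retained-PAS reads only)
    pas_meta: pd.DataFrame  # index pas_id; columns gene_id, rank, internal_priming
    conditions: dict[str, str] = field(default_factory=dict)
    dropped: pd.Series | None = None  # per-gene count of unassignable reads
    min_gene_reads: int = 10

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]


def assign_reads_to_pas(
    ends: np.ndarray, peaks: np.ndarray, strand: str, window: int = 20
) -> np.ndarray:
    """Index of the assigned PAS per read end, or -1 if none within window.

    Each end goes to the nearest peak within ``window`` nt; exact distance
    ties go to the transcription-proximal PAS. ``peaks`` must be in
    proximal->distal (rank) order.
    """
    if len(peaks) == 0:
        return np.full(len(ends), -1, dtype=int)
    order = np.argsort(peaks)
    sorted_peaks = peaks[order]
    pos = np.searchsorted(sorted_peaks, ends)
    left = np.clip(pos - 1, 0, len(peaks) - 1)
    right = np.clip(pos, 0, len(peaks) - 1)
    d_left = np.abs(ends - sorted_peaks[left])
    d_right = np.abs(ends - sorted_peaks[right])
    # candidates in genomic order; ranks break ties toward the proximal PAS
    rank_left = order[left]
    rank_right = order[right]
    use_left = (d_left < d_right) | ((d_left == d_right) & (rank_left < rank_right))
    best_idx = np.where(use_left, rank_left, rank_right)
    best_d = np.minimum(d_left, d_right)
    return np.where(best_d <= window, best_idx, -1)


def count_reads_at_pas(
    table: ReadEndTable,
    catalog: PASCatalog,
    window: int | None = None,
    min_gene_reads: int = 10,
) -> PAUMatrix:
    """Tally reads at each retained PAS per sample.

    Reads farther than ``window`` nt (default: the catalog's calling window)
    from every retained peak of their gene are dropped and counted per gene.
    """
    if window is None:
        window = catalog.params.get("window", 20)
    samples = table.samples
    pas_rows: list[str] = []
    meta_rows = []
    counts_rows = []
    dropped: dict[str, int] = {}
    for gene_id, pas_list in catalog.genes.items():
        gdf = table.df[table.df["gene_id"] == gene_id]
        peaks = np.array([p.peak for p in pas_list])
        strand = pas_list[0].strand
        idx = assign_reads_to_pas(gdf["end3"].to_numpy(), peaks, strand, window)
        dropped[gene_id] = int((idx == -1).sum())
        sample_codes = pd.Categorical(gdf["sample_id"], categories=samples).codes
        mat = np.zeros((len(pas_list), len(samples)), dtype=int)
        ok = idx >= 0
        np.add.at(mat, (idx[ok], sample_codes[ok]), 1)
        for i, pas in enumerate(pas_list):
            pas_rows.append(pas.pas_id)
            meta_rows.append((pas.gene_id, pas.rank, pas.internal_priming))
            counts_rows.append(mat[i])
    counts = pd.DataFrame(counts_rows, index=pas_rows, columns=samples, dtype=int)
    meta = pd.DataFrame(
        meta_rows, index=pas_rows, columns=["gene_id", "rank", "internal_priming"]
    )
    mat = compute_pau(counts, meta["gene_id"], min_gene_reads=min_gene_reads)
    mat.conditions = dict(table.conditions)
    mat.pas_meta = meta
    mat.dropped = pd.Series(dropped, name="dropped_reads")
    return mat


def compute_pau(
    counts: pd.DataFrame, pas_gene: pd.Series, min_gene_reads: int = 10
) -> PAUMatrix:
    """PAU(i,s) = counts(i,s) / gene-sample total, NaN below the depth cutoff."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    gene_totals = counts.groupby(pas_gene).sum()
    totals_per_pas = gene_totals.loc[pas_gene].set_axis(counts.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        pau = counts / totals_per_pas
    pau = pau.where(totals_per_pas >= min_gene_reads)
    meta = pd.DataFrame({"gene_id": pas_gene})
    meta["rank"] = meta.groupby("gene_id").cumcount() + 1
    meta["internal_priming"] = False
    return PAUMatrix(
        counts=counts,
        pau=pau,
        gene_totals=gene_totals,
        pas_meta=meta,
        min_gene_reads=min_gene_reads,
    )


def delta_pau(
    matrix: PAUMatrix, condition_a: str, condition_b: str
) -> pd.Series:
    """Per-PAS mean PAU(b) - mean PAU(a) over depth-eligible samples.

    NaN when a condition has no eligible sample for the gene.
    """
    sa = matrix.samples_for(condition_a)
    sb = matrix.samples_for(condition_b)
    if not sa or not sb:
        raise ValueError(
            f"no samples for condition(s): "
            f"{condition_a if not sa else ''} {condition_b if not sb else ''}".strip()
        )
    mean_a = matrix.pau[sa].mean(axis=1)
    mean_b = matrix.pau[sb].mean(axis=1)
    return (mean_b - mean_a).rename("delta_pau")
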