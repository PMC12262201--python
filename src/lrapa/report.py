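"""Per-gene and transcriptome-wide visualization.

Every plot also writes its underlying arrays as TSV next to the figure, so
downstream checks and reanalyses never have to read pixels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from lrapa.apa_stats import oriented_positions  # noqa: E402
from lrapa.pas_calling import PASCatalog  # noqa: E402
from lrapa.quantification import PAUMatrix, delta_pau  # noqa: E402
from lrapa.read_end_ingest import ReadEndTable  # noqa: E402

logger = logging.getLogger(__name__)


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def plot_gene(
    gene_id: str,
    table: ReadEndTable,
    catalog: PASCatalog,
    matrix: PAUMatrix,
    condition_a: str,
    condition_b: str,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Three-panel single-gene view: 3'-end density per condition, cumulative
    3'-end (PAU) curves, and per-PAS delta-PAU bars.

    Returns the written file paths; the cumulative-curve and bar arrays are
    also emitted as TSV.
    """
    if gene_id not in catalog.genes:
        raise KeyError(f"gene {gene_id!r} not in PAS catalog")
    pas_list = catalog.genes[gene_id]
    strand = pas_list[0].strand
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gdf = table.df[table.df["gene_id"] == gene_id]
    ends = {
        cond: oriented_positions(
            gdf.loc[
                gdf["sample_id"].isin(table.samples_for(cond)), "end3"
            ].to_numpy(),
            strand,
        )
        for cond in (condition_a, condition_b)
    }
    for cond, e in ends.items():
        if len(e) == 0:
            raise ValueError(f"gene {gene_id}: no reads in condition {cond!r}")

    fig, axes = plt.subplots(3, 1, figsize=(7, 9))
    ax = axes[0]
    bins = 60
    for cond, color in zip((condition_a, condition_b), ("tab:blue", "tab:red")):
        ax.hist(ends[cond], bins=bins, density=True, alpha=0.5, label=cond,
                color=color)
    for pas in pas_list:
        ax.axvline(oriented_positions([pas.peak], strand)[0], ls=":", c="gray", lw=0.8)
    ax.set_xlabel("3' end (transcription-oriented)")
    ax.set_ylabel("density")
    ax.set_title(f"{gene_id} ({strand})")
    ax.legend()

    ax = axes[1]
    curve_frames = []
    for cond, color in zip((condition_a, condition_b), ("tab:blue", "tab:red")):
        x, y = _ecdf(ends[cond])
        ax.step(x, y, where="post", label=cond, color=color)
        curve_frames.append(
            pd.DataFrame({"condition": cond, "position": x, "cumulative": y})
        )
    ax.set_ylabel("cumulative fraction of 3' ends")
    ax.set_ylim(0, 1.02)
    ax.legend()
    curves_tsv = out_dir / f"{gene_id}.cumulative.tsv"
    pd.concat(curve_frames).to_csv(curves_tsv, sep="\t", index=False)

    ax = axes[2]
    dp = delta_pau(matrix, condition_a, condition_b)
    ids = [p.pas_id for p in pas_list if p.pas_id in dp.index]
    vals = [dp[i] for i in ids]
    ranks = [p.rank for p in pas_list if p.pas_id in ids]
    ax.bar(ranks, vals, color=["tab:red" if v > 0 else "tab:blue" for v in vals])
    ax.axhline(0, c="black", lw=0.8)
    ax.set_xlabel("PAS rank (proximal -> distal)")
    ax.set_ylabel(f"PAU change ({condition_b} - {condition_a})")
    bars_tsv = out_dir / f"{gene_id}.delta_pau.tsv"
    pd.DataFrame({"pas_id": ids, "rank": ranks, "delta_pau": vals}).to_csv(
        bars_tsv, sep="\t", index=False
    )

    fig.tight_layout()
    fig_path = out_dir / f"{gene_id}.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return {"figure": fig_path, "cumulative_tsv": curves_tsv, "delta_pau_tsv": bars_tsv}


def plot_volcano(
    gene_results: pd.DataFrame,
    out_path: str | Path,
    alpha: float = 0.05,
    tau: float = 0.1,
) -> dict[str, Path]:
    """Volcano plot of gene-level results: APA change vs -log10 q-value."""
    if gene_results.empty:
        raise ValueError("no gene-level results to plot")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    q = np.clip(gene_results["qvalue"].to_numpy(dtype=float), 1e-300, 1.0)
    x = gene_results["apa_change"].to_numpy(dtype=float)
    y = -np.log10(q)
    colors = np.where(
        (q < alpha) & (x > tau),
        "tab:red",
        np.where((q < alpha) & (x < -tau), "tab:blue", "lightgray"),
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(x, y, c=colors, s=8)
    ax.axhline(-np.log10(alpha), ls="--", c="gray", lw=0.8)
    ax.axvline(tau, ls="--", c="gray", lw=0.8)
    ax.axvline(-tau, ls="--", c="gray", lw=0.8)
    ax.set_xlim(-1.05, 1.05)
    ax.set_xlabel("APA change (signed KS)")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    tsv_path = out_path.with_suffix(".tsv")
    pd.DataFrame(
        {"gene_id": gene_results["gene_id"], "apa_change": x, "neg_log10_q": y,
         "color": colors}
    ).to_csv(tsv_path, sep="\t", index=False)
    return {"figure": out_path, "tsv": tsv_path}
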