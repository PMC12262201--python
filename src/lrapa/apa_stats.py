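"""Gene-level and PAS-level differential APA statistics.

Gene level: a signed two-sample Kolmogorov-Smirnov statistic on the
transcription-oriented 3'-end distributions of the two conditions. The
signed value ("APA change") is the larger one-sided supremum with its sign,
so it lies in [-1, 1]; positive means the experimental condition's 3' ends
are stochastically more distal — 3'UTR lengthening.

PAS level: a per-PAS negative-binomial GLM likelihood-ratio test on the
two-column (this PAS vs rest of gene) counts, in the style of differential
exon usage analysis: the null model has sample and column effects, the
alternative adds a condition x column interaction, and the LRT statistic is
referred to chi-square with 1 df. Dispersions are method-of-moments
estimates shrunk toward a mean-dispersion trend fitted across all PASs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from lrapa.pas_calling import PASCatalog, classify_gene_apa_type
from lrapa.quantification import PAUMatrix, assign_reads_to_pas, delta_pau
from lrapa.read_end_ingest import ReadEndTable

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def oriented_positions(ends, strand: str) -> np.ndarray:
    """Map genomic 3'-end coordinates so larger always means more distal.

    '+' strand is the identity; '-' strand is negated (genomically leftmost =
    transcription-wise most distal).
    """
    arr = np.asarray(list(ends) if not isinstance(ends, np.ndarray) else ends)
    if arr.size == 0:
        return arr.astype(float)
    return arr if strand == "+" else -arr


@dataclass
class KSResult:
    apa_change: float  # signed, in [-1, 1]; positive = b more distal
    statistic: float  # D = max one-sided supremum
    pvalue: float
    n_a: int
    n_b: int


def _bridge_max_sf(h: np.ndarray, z: float, n_grid: int = 121) -> float:
    """P(max_i |B(h_i)| >= z) for a Brownian bridge B observed at times h.

    ``h`` must be sorted and lie strictly inside (0, 1). Computed by the
    Markov recursion of the bridge over a barrier grid at +/-z, with exact
    Gaussian cell-mass transitions so the step variance may be far smaller
    than the grid spacing. The closed-form Kolmogorov survival function is an
    upper bound (it is the supremum over the *whole* bridge path) and is
    returned directly when it is already negligible.
    """
    if z <= 0:
        return 1.0
    upper = float(special.kolmogorov(z))
    if upper < 1e-9 or len(h) == 0:
        return upper
    x = np.linspace(-z, z, n_grid)
    dx = x[1] - x[0]
    edges = np.clip(np.concatenate([[x[0] - dx / 2], x + dx / 2]), -z, z)
    sd0 = np.sqrt(h[0] * (1 - h[0]))
    p = np.diff(special.ndtr(edges / sd0))
    prev = h[0]
    for t in h[1:]:
        var = (t - prev) * (1 - t) / (1 - prev)
        if var <= 0:
            prev = t
            continue
        shrink = (1 - t) / (1 - prev)
        trans = np.diff(
            special.ndtr((edges[:, None] - x[None, :] * shrink) / np.sqrt(var)),
            axis=0,
        )
        p = trans @ p
        prev = t
    return float(np.clip(1.0 - p.sum(), 0.0, upper))


def ks_signed(ends_a, ends_b, max_tie_support: int = 200) -> KSResult:
    """Signed two-sample KS statistic on oriented 3'-end positions.

    With empirical CDFs F_a, F_b evaluated at every distinct position,
    D = max |F_a - F_b| and the signed APA change is the CDF difference at
    the (most proximal) argmax, i.e. +D when the one-sided supremum
    max(F_a - F_b) attains D (condition b stochastically more distal =
    lengthening) and -D otherwise.

    The p-value is asymptotic with effective n = n_a n_b / (n_a + n_b) and
    Stephens' finite-sample argument refinement. Because read 3' ends are
    heavily tied (discrete coordinates), the limiting null is the maximum of
    a Brownian bridge over the pooled-support CDF points rather than over the
    whole path; that maximum is computed exactly when the support has at most
    ``max_tie_support`` distinct positions, and falls back to the classical
    (continuous-data, slightly conservative) Kolmogorov distribution beyond.
    """
    a = np.sort(np.asarray(ends_a, dtype=float))
    b = np.sort(np.asarray(ends_b, dtype=float))
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.union1d(a, b)
    f_a = np.searchsorted(a, grid, side="right") / n_a
    f_b = np.searchsorted(b, grid, side="right") / n_b
    diff = f_a - f_b
    # signed value = CDF difference at the argmax of |F_a - F_b|; argmax ties
    # break at the most proximal position (first on the oriented grid), which
    # keeps the statistic antisymmetric even when D+ == D- exactly
    i = int(np.argmax(np.abs(diff)))
    d = float(np.abs(diff[i]))
    apa_change = float(diff[i]) if diff[i] != 0 else 0.0
    n_eff = n_a * n_b / (n_a + n_b)
    z = (np.sqrt(n_eff) + 0.12 + 0.11 / np.sqrt(n_eff)) * d
    h = (n_a * f_a + n_b * f_b) / (n_a + n_b)
    h = h[(h > 1e-12) & (h < 1 - 1e-12)]
    if 0 < len(h) <= max_tie_support:
        pvalue = _bridge_max_sf(h, z)
    else:
        pvalue = float(np.clip(special.kolmogorov(z), 0.0, 1.0))
    return KSResult(apa_change, d, pvalue, n_a, n_b)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _restricted_ends(
    table: ReadEndTable,
    catalog: PASCatalog,
    exclude_internal_priming: bool,
    all_reads: bool,
    window: int,
) -> dict[str, pd.DataFrame]:
    """Per-gene read-end frames, optionally restricted to retained-PAS reads."""
    out: dict[str, pd.DataFrame] = {}
    for gene_id, pas_list in catalog.genes.items():
        kept = [
            p for p in pas_list if not (exclude_internal_priming and p.internal_priming)
        ]
        if len(kept) < 2:
            continue
        gdf = table.df[table.df["gene_id"] == gene_id]
        if not all_reads:
            peaks = np.array([p.peak for p in kept])
            idx = assign_reads_to_pas(
                gdf["end3"].to_numpy(), peaks, kept[0].strand, window
            )
            gdf = gdf[idx >= 0]
        out[gene_id] = gdf
    return out


def gene_level_apa(
    table: ReadEndTable,
    catalog: PASCatalog,
    condition_a: str,
    condition_b: str,
    min_reads: int = 10,
    alpha: float = 0.05,
    tau: float = 0.1,
    models: dict | None = None,
    exclude_internal_priming: bool = False,
    all_reads: bool = False,
) -> pd.DataFrame:
    """Gene-level APA test between two conditions (a = control, b = experimental).

    Reads are pooled across replicates within each condition; genes need >= 2
    retained PASs and >= ``min_reads`` pooled reads per condition. Returns a
    frame with columns gene_id, apa_change, statistic, pvalue, qvalue, n_a,
    n_b, direction (lengthening / shortening / none; called at qvalue < alpha
    and |apa_change| > tau) and apa_type (last_exon_tandem / mixed).
    """
    samples_a = set(table.samples_for(condition_a))
    samples_b = set(table.samples_for(condition_b))
    if not samples_a or not samples_b:
        raise ValueError("both conditions need at least one sample")
    window = catalog.params.get("window", 20)
    per_gene = _restricted_ends(
        table, catalog, exclude_internal_priming, all_reads, window
    )
    rows = []
    for gene_id, gdf in sorted(per_gene.items()):
        strand = catalog.genes[gene_id][0].strand
        ends_a = gdf.loc[gdf["sample_id"].isin(samples_a), "end3"].to_numpy()
        ends_b = gdf.loc[gdf["sample_id"].isin(samples_b), "end3"].to_numpy()
        if len(ends_a) < min_reads or len(ends_b) < min_reads:
            continue
        res = ks_signed(
            oriented_positions(ends_a, strand), oriented_positions(ends_b, strand)
        )
        apa_type = None
        if models is not None and gene_id in models:
            apa_type = classify_gene_apa_type(catalog.genes[gene_id], models[gene_id])
        rows.append(
            (gene_id, res.apa_change, res.statistic, res.pvalue, res.n_a, res.n_b,
             apa_type)
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "apa_change", "statistic", "pvalue", "n_a", "n_b",
                 "apa_type"],
    )
    if df.empty:
        df["qvalue"] = []
        df["direction"] = []
        return df
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["direction"] = "none"
    sig = df["qvalue"] < alpha
    df.loc[sig & (df["apa_change"] > tau), "direction"] = "lengthening"
    df.loc[sig & (df["apa_change"] < -tau), "direction"] = "shortening"
    return df[
        ["gene_id", "apa_change", "statistic", "pvalue", "qvalue", "n_a", "n_b",
         "direction", "apa_type"]
    ]


def estimate_dispersion(counts, conditions=None) -> float:
    """Method-of-moments NB dispersion for one PAS, floored at 1e-8.

    ``counts`` is (n_samples,) — counts across samples — or (n_samples, 2),
    the (this PAS, rest-of-gene) columns. For the two-column form the fitted
    means condition on each sample's total (the sample effect of the usage
    GLM), so library-size variation does not inflate the estimate: within
    each condition the usage proportion p is pooled, mu = total * p, and
    alpha solves sum[(y-mu)^2] (df-corrected) = sum[mu] + alpha sum[mu^2].
    For the one-column form alpha is the classic (var - mean)/mean^2 pooled
    across condition groups.
    """
    y = np.asarray(counts, dtype=float)
    if conditions is None:
        cond = np.zeros(y.shape[0])
    else:
        cond = np.asarray(conditions)
    group_labels = pd.unique(cond)

    if y.ndim == 1:
        est_num = est_den = 0.0
        for g in group_labels:
            v = y[cond == g]
            if len(v) < 2:
                continue
            mu = v.mean()
            if mu <= 0:
                continue
            est_num += mu * (v.var(ddof=1) - mu) / mu**2
            est_den += mu
        if est_den == 0:
            return DISPERSION_FLOOR
        return float(max(est_num / est_den, DISPERSION_FLOOR))

    if y.shape[1] != 2:
        raise ValueError("counts must be 1-D or have two columns (this, rest)")
    totals = y.sum(axis=1)
    mu = np.zeros_like(y)
    n_groups = 0
    for g in group_labels:
        sel = cond == g
        t = totals[sel].sum()
        if t <= 0:
            continue
        p = y[sel, 0].sum() / t
        mu[sel, 0] = totals[sel] * p
        mu[sel, 1] = totals[sel] * (1 - p)
        n_groups += 1
    n = y.shape[0]
    df = n - n_groups  # free residuals given totals, minus fitted proportions
    ok = mu > 0
    if df <= 0 or not ok.any():
        return DISPERSION_FLOOR
    ss = ((y[ok] - mu[ok]) ** 2).sum() * n / df
    alpha = (ss - mu[ok].sum()) / (mu[ok] ** 2).sum()
    return float(max(alpha, DISPERSION_FLOOR))


def fit_dispersion_trend(raw: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Trended dispersion alpha(mu) = a0 + a1/mu fitted over all PASs.

    Least-squares on the raw estimates with non-negative clipping; when the
    fit is degenerate (few points, flat means) the trend falls back to the
    median raw dispersion.
    """
    raw = np.asarray(raw, dtype=float)
    means = np.asarray(means, dtype=float)
    ok = (means > 0) & np.isfinite(raw)
    if ok.sum() < 3:
        med = float(np.median(raw[ok])) if ok.any() else DISPERSION_FLOOR
        return np.full_like(raw, max(med, DISPERSION_FLOOR))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    coef, *_ = np.linalg.lstsq(x, raw[ok], rcond=None)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(means > 0, means, np.nan)
    trend = np.where(np.isfinite(trend), trend, np.nanmedian(raw))
    return np.maximum(trend, DISPERSION_FLOOR)


def shrink_dispersions(
    raw: np.ndarray, means: np.ndarray, weight_raw: float = 0.5
) -> np.ndarray:
    """Shrink raw per-PAS dispersions toward the fitted trend (weighted average)."""
    trend = fit_dispersion_trend(raw, means)
    return np.maximum(weight_raw * raw + (1 - weight_raw) * trend, DISPERSION_FLOOR)


def _nb_lrt(
    y_this: np.ndarray,
    y_rest: np.ndarray,
    is_b: np.ndarray,
    dispersion: float,
) -> float:
    """LRT p-value for a condition x column interaction in an NB GLM.

    Observations are the stacked (this, rest) counts; the null has a sample
    effect and a column effect, the alternative adds is_b x column.
    """
    n = len(y_this)
    y = np.concatenate([y_this, y_rest])
    col_this = np.concatenate([np.ones(n), np.zeros(n)])
    sample_dummies = np.tile(np.eye(n), (2, 1))
    x_null = np.column_stack([sample_dummies, col_this])
    x_alt = np.column_stack([x_null, col_this * np.concatenate([is_b, is_b])])
    fam = sm.families.NegativeBinomial(alpha=max(dispersion, DISPERSION_FLOOR))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit0 = sm.GLM(y, x_null, family=fam).fit(maxiter=200)
            fit1 = sm.GLM(y, x_alt, family=fam).fit(maxiter=200)
        except Exception:
            return np.nan
    lrt = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    return float(stats.chi2.sf(lrt, df=1))


def pas_usage_test(
    matrix: PAUMatrix,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    exclude_internal_priming: bool = True,
    dispersion_weight_raw: float = 0.5,
) -> pd.DataFrame:
    """Per-PAS differential usage test (NB-GLM likelihood-ratio, df = 1).

    Requires >= 2 replicates per condition. Single-PAS genes are not tested;
    internal-priming-flagged PASs are excluded by default. Usage fold change
    is mean PAU(b) / mean PAU(a) with a 0.5/gene-total pseudo-usage guard;
    ``significant`` requires |FC| beyond ``fc_threshold`` and q < alpha.
    """
    sa = matrix.samples_for(condition_a)
    sb = matrix.samples_for(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            "PAS-level testing needs >= 2 replicates per condition; "
            "use gene-level KS analysis for unreplicated designs"
        )
    samples = sa + sb
    is_b = np.array([0.0] * len(sa) + [1.0] * len(sb))
    cond = np.array([condition_a] * len(sa) + [condition_b] * len(sb))

    meta = matrix.pas_meta
    multi = meta.groupby("gene_id")["gene_id"].transform("size") > 1
    testable = multi & (~meta["internal_priming"] if exclude_internal_priming else True)
    pas_ids = [p for p in matrix.counts.index[testable]]

    rows = []
    raw_disp, mean_this = [], []
    data = []
    for pas_id in pas_ids:
        gene = meta.loc[pas_id, "gene_id"]
        y_this = matrix.counts.loc[pas_id, samples].to_numpy(dtype=float)
        total = matrix.gene_totals.loc[gene, samples].to_numpy(dtype=float)
        y_rest = total - y_this
        if y_this.sum() == 0:
            continue
        y2 = np.column_stack([y_this, y_rest])
        raw_disp.append(estimate_dispersion(y2, cond))
        mean_this.append(y_this.mean())
        data.append((pas_id, gene, y_this, y_rest, total))
    if not data:
        return pd.DataFrame(
            columns=["pas_id", "gene_id", "log2fc_usage", "pvalue", "qvalue",
                     "significant"]
        )
    disp = shrink_dispersions(
        np.array(raw_disp), np.array(mean_this), weight_raw=dispersion_weight_raw
    )

    for (pas_id, gene, y_this, y_rest, total), d in zip(data, disp):
        with np.errstate(invalid="ignore", divide="ignore"):
            pau = np.where(total > 0, y_this / total, np.nan)
            guard = np.where(total > 0, 0.5 / total, np.nan)
        m_a = np.nanmean(pau[: len(sa)])
        m_b = np.nanmean(pau[len(sa):])
        g_a = np.nanmean(guard[: len(sa)])
        g_b = np.nanmean(guard[len(sa):])
        log2fc = float(np.log2(max(m_b, g_b) / max(m_a, g_a)))
        pvalue = _nb_lrt(y_this, y_rest, is_b, d)
        rows.append((pas_id, gene, log2fc, pvalue))

    df = pd.DataFrame(rows, columns=["pas_id", "gene_id", "log2fc_usage", "pvalue"])
    tested = df["pvalue"].notna()
    df["qvalue"] = np.nan
    df.loc[tested, "qvalue"] = bh_adjust(df.loc[tested, "pvalue"].to_numpy())
    df["significant"] = (
        (df["qvalue"] < alpha) & (np.abs(df["log2fc_usage"]) > np.log2(fc_threshold))
    )
    return df


def proximal_distal_correlation(
    gene_results: pd.DataFrame,
    matrix: PAUMatrix,
    condition_a: str,
    condition_b: str,
) -> tuple[float | None, float | None]:
    """Pearson correlations of gene APA change vs delta-PAU at the proximal
    (rank-1) and distal (highest-rank) PAS.

    Returns (r_proximal, r_distal); a correlation is None when its input is
    degenerate (zero variance). Requires >= 3 genes with both quantities.
    """
    dp = delta_pau(matrix, condition_a, condition_b)
    meta = matrix.pas_meta
    prox_rows, dist_rows = [], []
    for gene_id, apa_change in zip(gene_results["gene_id"], gene_results["apa_change"]):
        sel = meta[meta["gene_id"] == gene_id]
        if sel.empty:
            continue
        prox_id = sel.index[sel["rank"].argmin()]
        dist_id = sel.index[sel["rank"].argmax()]
        if np.isfinite(dp[prox_id]) and np.isfinite(dp[dist_id]):
            prox_rows.append((apa_change, dp[prox_id]))
            dist_rows.append((apa_change, dp[dist_id]))
    if len(prox_rows) < 3:
        raise ValueError("need >= 3 genes with gene-level and PAS-level changes")

    def _corr(pairs) -> float | None:
        x, y = np.array(pairs).T
        if np.std(x) == 0 or np.std(y) == 0:
            return None
        return float(stats.pearsonr(x, y)[0])

    return _corr(prox_rows), _corr(dist_rows)
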