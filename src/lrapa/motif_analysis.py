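"""Nucleotide composition and motif incidence around cleavage sites.

Sequences are transcription-oriented RNA (-U..+D with the cleavage/peak base
at position 0, T converted to U), so upstream poly(A)-signal elements such as
AAUAAA (canonical hexamer, typically -35..-10) and UGUA appear at negative
positions regardless of strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lrapa.annotation_io import GenomeSequence, fetch_flank
from lrapa.quantification import PAUMatrix, delta_pau

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")


@dataclass
class PositionalProfile:
    positions: np.ndarray  # -U..+D, 0 = the site base
    fractions: dict[str, np.ndarray]  # base -> per-position fraction (NaN if no data)
    n_sequences: int
    smooth_window: int | None = None

    def smoothed(self, window: int = 5) -> "PositionalProfile":
        """Centered moving-average track for plotting."""
        kernel = np.ones(window) / window
        sm = {
            b: np.convolve(np.nan_to_num(v), kernel, mode="same")
            for b, v in self.fractions.items()
        }
        return PositionalProfile(self.positions, sm, self.n_sequences, window)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, **self.fractions})


@dataclass
class MotifIncidence:
    motif: str
    positions: np.ndarray  # match *start* positions relative to the site
    fraction: np.ndarray  # fraction of sequences with a match starting there
    window: tuple[int, int] | None = None
    window_fraction: float | None = None  # any-match within window
    n_sequences: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "fraction": self.fraction})


def site_sequences(
    sites,
    genome: GenomeSequence,
    up: int = 100,
    down: int = 100,
    clip_policy: str = "drop",
) -> tuple[list[str], int]:
    """Transcription-oriented RNA windows around (chrom, pos, strand) sites.

    Each unclipped sequence has length up + 1 + down with index ``up`` at the
    site base. Sites whose window overhangs a chromosome end are dropped
    (default) or N-padded to full length (clip_policy="pad"). Returns the
    sequences and the number of dropped sites.
    """
    if clip_policy not in ("drop", "pad"):
        raise ValueError("clip_policy must be 'drop' or 'pad'")
    full = up + 1 + down
    seqs: list[str] = []
    n_dropped = 0
    for chrom, pos, strand in sites:
        seq = fetch_flank(genome, chrom, pos, up, down, strand)
        if len(seq) < full:
            if clip_policy == "drop":
                n_dropped += 1
                continue
            clen = genome.chrom_length(chrom)
            if strand == "+":
                left = max(up - pos, 0)
            else:
                left = max(up - (clen - 1 - pos), 0)
            seq = "N" * left + seq
            seq = seq + "N" * (full - len(seq))
        seqs.append(seq.replace("T", "U"))
    if n_dropped:
        logger.info("dropped %d sites with clipped windows", n_dropped)
    return seqs, n_dropped


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.array([list(s) for s in seqs])


def nucleotide_profile(seqs: list[str], up: int | None = None) -> PositionalProfile:
    """Column-wise base fractions (A/C/G/U); N bases excluded from numerator
    and denominator at their column. ``up`` defaults to centering position 0
    mid-window for odd lengths, else len//2."""
    mat = _seq_matrix(seqs)
    length = mat.shape[1]
    if up is None:
        up = length // 2
    valid = mat != "N"
    denom = valid.sum(axis=0).astype(float)
    fractions = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for base in RNA_BASES:
            fractions[base] = np.where(denom > 0, (mat == base).sum(axis=0) / denom,
                                       np.nan)
    positions = np.arange(length) - up
    return PositionalProfile(positions, fractions, len(seqs))


def motif_incidence(
    seqs: list[str],
    motif: str,
    window: tuple[int, int] | None = None,
    up: int | None = None,
) -> MotifIncidence:
    """Per-position motif start fractions and an any-match window aggregate.

    Overlapping occurrences are all counted; the window aggregate is the
    fraction of sequences with >= 1 match whose *start* lies in
    [window[0], window[1]] (relative positions, inclusive).
    """
    motif = motif.upper()
    if set(motif) - set(RNA_BASES):
        raise ValueError(f"motif must be RNA over A/C/G/U, got {motif!r}")
    mat = _seq_matrix(seqs)
    n, length = mat.shape
    m = len(motif)
    if m > length:
        raise ValueError("motif longer than sequences")
    if up is None:
        up = length // 2
    n_starts = length - m + 1
    hits = np.ones((n, n_starts), dtype=bool)
    for offset, base in enumerate(motif):
        hits &= mat[:, offset: offset + n_starts] == base
    fraction = hits.mean(axis=0)
    positions = np.arange(n_starts) - up
    inc = MotifIncidence(motif, positions, fraction, n_sequences=n)
    if window is not None:
        lo, hi = window
        sel = (positions >= lo) & (positions <= hi)
        inc.window = (lo, hi)
        inc.window_fraction = float(hits[:, sel].any(axis=1).mean())
    return inc


def group_sites(
    matrix: PAUMatrix,
    condition_a: str,
    condition_b: str,
    delta: float = 0.1,
    min_reads: int = 20,
) -> dict[str, list[str]]:
    """Partition PASs into condition-enriched and all-expressed groups.

    Depth criterion: every sample's count at the PAS exceeds ``min_reads``.
    Among depth-passing PASs, enriched_b: delta-PAU > delta; enriched_a:
    delta-PAU < -delta; all_expressed: the depth criterion alone.
    """
    dp = delta_pau(matrix, condition_a, condition_b)
    deep = (matrix.counts > min_reads).all(axis=1)
    groups: dict[str, list[str]] = {"enriched_a": [], "enriched_b": [],
                                    "all_expressed": []}
    for pas_id in matrix.counts.index:
        if not deep[pas_id]:
            continue
        groups["all_expressed"].append(pas_id)
        if np.isfinite(dp[pas_id]):
            if dp[pas_id] > delta:
                groups["enriched_b"].append(pas_id)
            elif dp[pas_id] < -delta:
                groups["enriched_a"].append(pas_id)
    return groups
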