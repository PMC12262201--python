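"""Self-contained synthetic inputs with known ground truth.

The generator emulates a two-condition long-read 3'-end experiment: a random
genome carrying two-exon genes on both strands, each with 2-5 true PASs
(tandem 3'UTR sites, optionally one intronic site), AAUAAA poly(A) signals
planted 15-30 nt upstream of each true site, optional A-rich internal-priming
decoys, per-gene-sample read depths with negative-binomial noise, multinomial
PAS usage, and discretized-normal cleavage jitter truncated at +/-15 nt so
true clusters stay inside the default 20-nt calling window.

What it does NOT emulate: basecalling/alignment error, transcript-level
splicing ambiguity, expression-level differences between conditions, and
spatially structured (non-random) genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lrapa.annotation_io import GeneModel, write_gene_models_gtf
from lrapa.read_end_ingest import COLUMNS, ReadEndTable

# local (transcription) layout of every simulated gene
EXON1 = (0, 300)
INTRON = (300, 800)
LAST_EXON_START = 800
GENE_LOCAL_LEN = 2200
CDS_LOCAL = [(100, 300), (800, 900)]
STOP_LOCAL = (900, 903)  # stop codon; 3'-most base local 902
UTR3_LOCAL_START = 903
GENE_GAP = 300


@dataclass
class SimulatedGene:
    model: GeneModel
    pas_positions: list[int]  # genomic, proximal -> distal (rank order)
    usage_a: np.ndarray  # simplex over PASs, condition a (control)
    usage_b: np.ndarray  # condition b (experimental)
    effect: str  # null / lengthening / shortening
    delta_pau: float
    mixed: bool  # rank-1 PAS intronic
    artifact_positions: list[int] = field(default_factory=list)
    jitter_sd: float = 2.0


@dataclass
class SimulatedReference:
    fasta_path: Path
    gtf_path: Path
    bed_path: Path
    genes: list[SimulatedGene]
    models: dict[str, GeneModel]
    chrom: str
    genome_len: int


def _to_genomic(local: int, start: int, end: int, strand: str) -> int:
    return start + local if strand == "+" else end - 1 - local


def _interval_to_genomic(
    iv: tuple[int, int], start: int, end: int, strand: str
) -> tuple[int, int]:
    a, b = iv
    return (start + a, start + b) if strand == "+" else (end - b, end - a)


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _write_local(
    seq: np.ndarray, start: int, end: int, strand: str, local_start: int, dna: str
) -> None:
    """Write a sense-strand (transcription-oriented) DNA word into the genome."""
    if strand == "+":
        g = start + local_start
        seq[g: g + len(dna)] = list(dna)
    else:
        g_end = end - local_start  # exclusive
        rc = "".join(_RC[c] for c in reversed(dna))
        seq[g_end - len(dna): g_end] = list(rc)


def _local_window(
    seq: np.ndarray, start: int, end: int, strand: str, lo: int, hi: int
) -> np.ndarray:
    """Indices of local positions [lo, hi) in genome order."""
    if strand == "+":
        return np.arange(start + lo, start + hi)
    return np.arange(end - hi, end - lo)


def _sense_a_count(seq: np.ndarray, idx: np.ndarray, strand: str) -> int:
    target = "A" if strand == "+" else "T"
    return int((seq[idx] == target).sum())


def _usage_vectors(
    k: int, effect: str, delta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if effect == "null":
        a = 0.6 * rng.dirichlet(np.full(k, 2.0)) + 0.4 / k
        return a, a.copy()
    src, dst = (0, k - 1) if effect == "lengthening" else (k - 1, 0)
    a = np.empty(k)
    if k == 2:
        a[src] = delta + 0.25 + 0.1 * rng.random()
        a[dst] = 1.0 - a[src]
    else:
        a[src] = delta + 0.15 + 0.1 * rng.random()
        a[dst] = 0.1
        middle = [i for i in range(k) if i not in (src, dst)]
        rest = 1.0 - a[src] - a[dst]
        w = 0.6 * rng.dirichlet(np.full(len(middle), 2.0)) + 0.4 / len(middle)
        a[middle] = rest * w
    b = a.copy()
    b[src] -= delta
    b[dst] += delta
    return a, b


def simulate_reference(
    n_genes: int,
    seed: int = 0,
    out_dir: str | Path = ".",
    genome_len: int | None = None,
    frac_lengthening: float = 0.0,
    frac_shortening: float = 0.0,
    delta_pau: float = 0.3,
    frac_mixed: float = 0.25,
    frac_artifact_genes: float = 0.0,
    n_pas_range: tuple[int, int] = (2, 5),
    motif_offset_range: tuple[int, int] = (15, 30),
    jitter_sd: float = 2.0,
    chrom: str = "chr1",
) -> SimulatedReference:
    """Generate genome FASTA, GTF, reference PAS BED and ground truth.

    Each gene gets 2-5 true PASs at least 60 nt apart; effect genes move
    ``delta_pau`` of usage between the proximal and distal PAS in condition b.
    AAUAAA is planted with its start ``motif_offset_range`` nt upstream of
    every true PAS; clean flanks (<= 6 A per 10-nt window) are enforced by
    rejection except at requested artifact sites, which get a >= 7-A upstream
    decoy. Fully deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    span = GENE_LOCAL_LEN + GENE_GAP
    needed = n_genes * span + GENE_GAP
    if genome_len is None:
        genome_len = needed
    elif genome_len < needed:
        raise ValueError(
            f"genome_len {genome_len} too small for {n_genes} genes (need {needed})"
        )
    seq = rng.choice(np.array(list("ACGT")), size=genome_len)

    n_len = int(round(frac_lengthening * n_genes))
    n_short = int(round(frac_shortening * n_genes))
    effects = (
        ["lengthening"] * n_len
        + ["shortening"] * n_short
        + ["null"] * (n_genes - n_len - n_short)
    )
    effects = [effects[i] for i in rng.permutation(n_genes)]

    genes: list[SimulatedGene] = []
    models: dict[str, GeneModel] = {}
    bed_rows: list[tuple[int, str, str]] = []

    for gi in range(n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        gstart = GENE_GAP + gi * span
        gend = gstart + GENE_LOCAL_LEN
        effect = effects[gi]
        mixed = bool(rng.random() < frac_mixed)
        k = int(rng.integers(n_pas_range[0], n_pas_range[1] + 1))
        if mixed and k < 2:
            k = 2

        # local PAS positions, proximal -> distal
        locals_: list[int] = []
        if mixed:
            locals_.append(int(rng.integers(450, 650)))
        n_tandem = k - len(locals_)
        pos = 980
        for _ in range(n_tandem):
            locals_.append(pos)
            pos += int(rng.integers(60, 140))

        # plant the poly(A) signal upstream of every true site
        for t in locals_:
            offset = int(rng.integers(motif_offset_range[0], motif_offset_range[1] + 1))
            _write_local(seq, gstart, gend, strand, t - offset, "AATAAA")

        # enforce clean (or decoy) A-content in the two 10-nt flanks
        artifact_local: list[int] = []
        if rng.random() < frac_artifact_genes:
            artifact_local.append(GENE_LOCAL_LEN - 80)
        for t in locals_:
            for lo, hi in ((t - 10, t), (t + 1, t + 11)):
                idx = _local_window(seq, gstart, gend, strand, lo, hi)
                tries = 0
                while _sense_a_count(seq, idx, strand) > 6:
                    repl = rng.choice(np.array(list("ACGT")), size=len(idx))
                    seq[idx] = repl
                    tries += 1
                    if tries > 50:
                        seq[idx] = "C" if strand == "+" else "G"
                        break
        for t in artifact_local:
            decoy = np.array(list("AAAAAAAACG"))
            rng.shuffle(decoy)
            idx = _local_window(seq, gstart, gend, strand, t - 10, t)
            target = decoy if strand == "+" else np.array([_RC[c] for c in decoy])
            seq[idx] = target

        exons = [
            _interval_to_genomic(EXON1, gstart, gend, strand),
            _interval_to_genomic((LAST_EXON_START, GENE_LOCAL_LEN), gstart, gend, strand),
        ]
        cds = [_interval_to_genomic(iv, gstart, gend, strand) for iv in CDS_LOCAL]
        utr3 = [
            _interval_to_genomic(
                (UTR3_LOCAL_START, GENE_LOCAL_LEN), gstart, gend, strand
            )
        ]
        last_exon = [
            _interval_to_genomic((LAST_EXON_START, GENE_LOCAL_LEN), gstart, gend, strand)
        ]
        model = GeneModel(
            gene_id=gene_id,
            gene_name=gene_id,
            chrom=chrom,
            strand=strand,
            start=gstart,
            end=gend,
            exons=sorted(exons),
            cds=sorted(cds),
            utr3=utr3,
            last_exon_union=last_exon,
            stop_codon_pos=_to_genomic(STOP_LOCAL[1] - 1, gstart, gend, strand)
            if strand == "+"
            else _to_genomic(STOP_LOCAL[1] - 1, gstart, gend, strand),
        )
        usage_a, usage_b = _usage_vectors(k, effect, delta_pau, rng)
        pas_genomic = [_to_genomic(t, gstart, gend, strand) for t in locals_]
        genes.append(
            SimulatedGene(
                model=model,
                pas_positions=pas_genomic,
                usage_a=usage_a,
                usage_b=usage_b,
                effect=effect,
                delta_pau=delta_pau if effect != "null" else 0.0,
                mixed=mixed,
                artifact_positions=[
                    _to_genomic(t, gstart, gend, strand) for t in artifact_local
                ],
                jitter_sd=jitter_sd,
            )
        )
        models[gene_id] = model
        for p in pas_genomic:
            bed_rows.append((p, strand, gene_id))

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for i in range(0, len(s), 60):
            fh.write(s[i: i + 60] + "\n")
    fai = Path(str(fasta_path) + ".fai")
    if fai.exists():
        fai.unlink()  # force re-index after overwrite

    gtf_path = out_dir / "genes.gtf"
    write_gene_models_gtf(models, gtf_path)

    bed_path = out_dir / "reference_pas.bed"
    with open(bed_path, "w") as fh:
        for p, strand, gene_id in sorted(bed_rows):
            fh.write(f"{chrom}\t{p}\t{p + 1}\t{gene_id}\t0\t{strand}\n")

    return SimulatedReference(
        fasta_path=fasta_path,
        gtf_path=gtf_path,
        bed_path=bed_path,
        genes=genes,
        models=models,
        chrom=chrom,
        genome_len=genome_len,
    )


def _truncated_jitter(
    rng: np.random.Generator, n: int, sd: float, bound: int = 15
) -> np.ndarray:
    """Discretized normal(0, sd) jitter truncated (by resampling) at +/-bound."""
    if sd == 0 or n == 0:
        return np.zeros(n, dtype=int)
    j = np.rint(rng.normal(0.0, sd, size=n)).astype(int)
    bad = np.abs(j) > bound
    while bad.any():
        j[bad] = np.rint(rng.normal(0.0, sd, size=int(bad.sum()))).astype(int)
        bad = np.abs(j) > bound
    return j


def simulate_read_ends(
    ref: SimulatedReference,
    depth_mean: float = 200.0,
    n_replicates: int = 3,
    jitter_sd: float | None = None,
    seed: int = 0,
    depth_dispersion: float = 0.1,
    conditions: tuple[str, str] = ("control", "treated"),
    artifact_rate: float = 0.0,
) -> ReadEndTable:
    """Simulate per-sample read 3'-end tables from the ground truth.

    Per gene and sample the read total is NB(depth_mean, dispersion); reads
    are allocated to PASs multinomially by the condition's usage vector and
    jittered by a discretized normal truncated at +/-15 nt (transcription
    orientation). With ``artifact_rate`` > 0, genes carrying planted A-rich
    decoys additionally emit Binomial(total, rate) reads at those positions.
    """
    rng = np.random.default_rng(seed)
    cond_a, cond_b = conditions
    records: list[tuple] = []
    sample_conditions: dict[str, str] = {}
    for ci, cond in enumerate(conditions):
        for r in range(n_replicates):
            sample_id = f"{cond}{r + 1}"
            sample_conditions[sample_id] = cond
            for gene in ref.genes:
                gm = gene.model
                usage = gene.usage_a if ci == 0 else gene.usage_b
                disp = depth_dispersion
                if disp > 0:
                    size = 1.0 / disp
                    total = int(rng.negative_binomial(size, size / (size + depth_mean)))
                else:
                    total = int(rng.poisson(depth_mean))
                alloc = rng.multinomial(total, usage)
                sd = gene.jitter_sd if jitter_sd is None else jitter_sd
                i_read = 0
                for pas_pos, n_reads in zip(gene.pas_positions, alloc):
                    jit = _truncated_jitter(rng, int(n_reads), sd)
                    if gm.strand == "-":
                        jit = -jit
                    for j in jit:
                        records.append(
                            (
                                f"{sample_id}:{gm.gene_id}:{i_read}",
                                gm.gene_id,
                                gm.chrom,
                                gm.strand,
                                max(int(pas_pos + j), 0),
                                sample_id,
                            )
                        )
                        i_read += 1
                if artifact_rate > 0 and gene.artifact_positions:
                    n_art = int(rng.binomial(max(total, 1), artifact_rate))
                    per_site = rng.multinomial(
                        n_art, np.full(len(gene.artifact_positions), 1.0 / len(gene.artifact_positions))
                    )
                    for art_pos, n_reads in zip(gene.artifact_positions, per_site):
                        jit = _truncated_jitter(rng, int(n_reads), sd)
                        if gm.strand == "-":
                            jit = -jit
                        for j in jit:
                            records.append(
                                (
                                    f"{sample_id}:{gm.gene_id}:{i_read}",
                                    gm.gene_id,
                                    gm.chrom,
                                    gm.strand,
                                    max(int(art_pos + j), 0),
                                    sample_id,
                                )
                            )
                            i_read += 1
    df = pd.DataFrame(records, columns=COLUMNS)
    return ReadEndTable(df, sample_conditions)


# --- coordinate-mirroring helpers (used to check strand invariance) ---------


def mirror_gene_model(gm: GeneModel, genome_len: int) -> GeneModel:
    """Reflect a gene model through the genome midpoint and flip its strand."""
    c = genome_len

    def miv(iv: tuple[int, int]) -> tuple[int, int]:
        return (c - iv[1], c - iv[0])

    return GeneModel(
        gene_id=gm.gene_id,
        gene_name=gm.gene_name,
        chrom=gm.chrom,
        strand="-" if gm.strand == "+" else "+",
        start=c - gm.end,
        end=c - gm.start,
        exons=sorted(miv(iv) for iv in gm.exons),
        cds=sorted(miv(iv) for iv in gm.cds),
        utr3=sorted(miv(iv) for iv in gm.utr3),
        last_exon_union=sorted(miv(iv) for iv in gm.last_exon_union),
        stop_codon_pos=None if gm.stop_codon_pos is None else c - 1 - gm.stop_codon_pos,
    )


def mirror_read_table(table: ReadEndTable, genome_len: int) -> ReadEndTable:
    """Reflect every read end (x -> C-1-x) and flip strands."""
    df = table.df.copy()
    df["end3"] = genome_len - 1 - df["end3"]
    df["strand"] = df["strand"].map({"+": "-", "-": "+"})
    return ReadEndTable(df, dict(table.conditions))
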