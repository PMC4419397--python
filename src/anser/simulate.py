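"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: genomes
and shotgun reads for the k-mer size estimator, codon-alignment pairs
evolved at a target omega for the Ka/Ks stage, two-library Poisson count
matrices with planted fold changes for the differential-expression test,
and self-alignment block tables with planted segmental duplications.

A single integer seed is propagated to independent per-generator random
streams, so the outputs of the different generators do not couple and a
fixed seed reproduces every file byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dge import CountMatrix
from .kaks import GENETIC_CODE, STOP_CODONS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# distinct spawn keys per generator: one global seed, independent streams
_STREAMS = {"genome": 1, "reads": 2, "codon": 3, "counts": 4, "blocks": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Bundle of generator parameters for a full synthetic run."""

    seed: int = 0
    genome_length: int = 100_000
    read_length: int = 100
    depth: float = 30.0
    error_rate: float = 0.005
    n_genes: int = 1000
    lib_sizes: tuple[int, int] = (1_000_000, 1_000_000)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    target_omega: float = 0.5
    n_codons: int = 2000

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def make_genome(length: int, gc: float = 0.41, seed: int = 0) -> str:
    """Random genome with the given expected GC fraction.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed, "genome")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[arr == b] = i
    return codes


def make_reads(genome: str, depth: float, read_length: int,
               error_rate: float = 0.0, seed: int = 0) -> list[tuple[str, str]]:
    """Uniform-coverage shotgun reads with i.i.d. substitution errors.

    Reads are drawn uniformly with replacement from both strands; the
    total read bases equal ``depth * len(genome)`` to within one read.
    Returns (read_id, sequence) pairs.
    """
    glen = len(genome)
    if read_length > glen:
        raise ValueError("read_length exceeds genome length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(seed, "reads")
    n_reads = int(round(depth * glen / read_length))
    codes = _encode(genome)
    starts = rng.integers(0, glen - read_length + 1, size=n_reads)
    mat = codes[starts[:, None] + np.arange(read_length)]
    rev = rng.random(n_reads) < 0.5
    # reverse complement: A<->T, C<->G is 3 - code under ACGT=0123
    mat[rev] = 3 - mat[rev][:, ::-1]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape)
        mat = np.where(err, (mat + shift) % 4, mat)
    seqs = _BASES[mat]
    return [(f"read_{i}", seqs[i].tobytes().decode()) for i in range(n_reads)]


@dataclass
class CodonPairSim:
    """An aligned coding-sequence pair plus the true accepted-change counts."""

    seq_a: str
    seq_b: str
    n_syn_accepted: int
    n_nonsyn_accepted: int


def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    sense = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
    idx = rng.integers(0, len(sense), size=n_codons)
    return [sense[i] for i in idx]


def make_codon_pair(n_codons: int, branch_length: float, target_omega: float,
                    seed: int = 0) -> CodonPairSim:
    """Evolve one lineage of a codon sequence at a target omega.

    Proposals are single-nucleotide codon changes at uniform positions.
    Stop-creating proposals are rejected outright; nonsynonymous
    proposals are accepted with probability ``min(1, target_omega)`` and
    synonymous ones with probability ``min(1, 1/target_omega)`` (i.e.
    synonymous changes are always accepted for omega <= 1, and are
    down-accepted for omega > 1 so that the nonsynonymous/synonymous
    rate ratio equals omega over the whole range).  Evolution continues
    until ``round(branch_length * n_codons)`` changes have been
    accepted, so the realized Ka/Ks tracks the target omega under
    uniform mutation.
    """
    if n_codons < 10:
        raise ValueError("need at least 10 codons")
    if target_omega < 0:
        raise ValueError("target_omega must be >= 0")
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = _rng(seed, "codon")
    codons = _random_cds(n_codons, rng)
    seq_a = "".join(codons)
    n_target = int(round(branch_length * n_codons))
    n_syn = n_nonsyn = 0
    bases = "ACGT"
    guard = 0
    while n_syn + n_nonsyn < n_target:
        guard += 1
        if guard > 1000 * max(n_target, 1):
            raise RuntimeError("codon simulator failed to accept enough changes")
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        others = [b for b in bases if b != old[pos]]
        new_base = others[int(rng.integers(0, 3))]
        new = old[:pos] + new_base + old[pos + 1:]
        if new in STOP_CODONS:
            continue
        if GENETIC_CODE[new] == GENETIC_CODE[old]:
            p_syn = 1.0 if target_omega <= 1 else 1.0 / target_omega
            if rng.random() < p_syn:
                codons[ci] = new
                n_syn += 1
        elif rng.random() < min(1.0, target_omega):
            codons[ci] = new
            n_nonsyn += 1
    return CodonPairSim(seq_a, "".join(codons), n_syn, n_nonsyn)


def make_count_matrix(n_genes: int, lib_sizes: tuple[int, int],
                      planted_log2fc: np.ndarray | list[float] | float = 0.0,
                      baseline_rpkm: np.ndarray | list[float] | float = 30.0,
                      gene_lengths: np.ndarray | list[int] | int = 1000,
                      seed: int = 0) -> CountMatrix:
    """Two-library Poisson counts with planted per-gene fold changes.

    Control counts are Poisson with mean
    ``baseline_rpkm * gene_length * lib_size / 1e9`` (the RPKM identity
    inverted); treatment means are additionally scaled by
    ``2**planted_log2fc``.
    """
    if lib_sizes[0] <= 0 or lib_sizes[1] <= 0:
        raise ValueError("lib_sizes must be positive")
    rng = _rng(seed, "counts")
    fc = np.broadcast_to(np.asarray(planted_log2fc, dtype=float), (n_genes,))
    base = np.broadcast_to(np.asarray(baseline_rpkm, dtype=float), (n_genes,))
    if np.any(base < 0):
        raise ValueError("baseline_rpkm must be non-negative")
    lengths = np.broadcast_to(np.asarray(gene_lengths, dtype=int), (n_genes,))
    mean_c = base * lengths * lib_sizes[0] / 1e9
    mean_t = base * lengths * lib_sizes[1] / 1e9 * np.exp2(fc)
    counts_c = rng.poisson(mean_c)
    counts_t = rng.poisson(mean_t)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    return CountMatrix(gene_ids=genes, lengths=lengths.copy(),
                       count_control=counts_c, count_treatment=counts_t,
                       lib_control=int(lib_sizes[0]), lib_treatment=int(lib_sizes[1]))


def make_block_set(genome_length: int,
                   planted_duplications: list[tuple[tuple[int, int], tuple[int, int], float]],
                   noise_blocks: int = 0, seed: int = 0, chrom: str = "chr1"):
    """Self-alignment block table with planted duplications.

    ``planted_duplications`` holds ((q_start, q_end), (t_start, t_end),
    percent_identity) triples; each is emitted as one alignment block.
    Noise blocks are generated below both segmental-duplication
    thresholds (length <= 1 kb and identity <= 90%).  Returns a pandas
    DataFrame in the standard block-table layout.
    """
    import pandas as pd

    rng = _rng(seed, "blocks")
    rows = []
    for (qs, qe), (ts, te), ident in planted_duplications:
        if not (0 <= qs < qe <= genome_length and 0 <= ts < te <= genome_length):
            raise ValueError("planted interval outside genome bounds")
        if (qs, qe) == (ts, te):
            raise ValueError("planted pair is a self-hit (identical diagonal intervals)")
        rows.append((chrom, qs, qe, chrom, ts, te, "+", float(ident)))
    for _ in range(noise_blocks):
        ln = int(rng.integers(100, 1000))  # never exceeds the >1 kb bound
        qs = int(rng.integers(0, genome_length - ln))
        ts = int(rng.integers(0, genome_length - ln))
        ident = float(rng.uniform(70.0, 90.0))  # never exceeds the >90% bound
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, qs, qs + ln, chrom, ts, ts + ln, strand, ident))
    return pd.DataFrame(rows, columns=["chrom_q", "start_q", "end_q",
                                       "chrom_t", "start_t", "end_t",
                                       "strand", "pct_identity"])
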