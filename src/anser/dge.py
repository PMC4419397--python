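"""RPKM and Poisson-model differential expression for a two-library design.

Expression is reported as reads per kilobase of transcript per million
mapped reads, RPKM = 1e9 * count / (lib_size * gene_length).  The
Poisson-model test is the conditional (Audic–Claverie) exact test: given
the two counts' sum, the control count is Binomial(x + y, N_x/(N_x+N_y))
under the null of equal Poisson rates; the two-sided p-value doubles the
smaller tail, capped at 1.  Genes are called differentially expressed
when they show at least a 2-fold change and a Benjamini–Hochberg
adjusted p-value below 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CountMatrix:
    """Two-condition gene counts plus library totals."""

    gene_ids: list[str]
    lengths: np.ndarray
    count_control: np.ndarray
    count_treatment: np.ndarray
    lib_control: int = 0    # 0 -> use column sum
    lib_treatment: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.count_control = np.asarray(self.count_control, dtype=int)
        self.count_treatment = np.asarray(self.count_treatment, dtype=int)
        n = len(self.gene_ids)
        if not (len(self.lengths) == len(self.count_control) == len(self.count_treatment) == n):
            raise ValueError("column lengths disagree")
        if (self.count_control < 0).any() or (self.count_treatment < 0).any():
            raise ValueError("negative counts")
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1")
        if self.lib_control == 0:
            self.lib_control = int(self.count_control.sum())
        if self.lib_treatment == 0:
            self.lib_treatment = int(self.count_treatment.sum())
        if self.lib_control < self.count_control.sum() or self.lib_treatment < self.count_treatment.sum():
            raise ValueError("library totals below column sums")

    @classmethod
    def from_tsv(cls, path: str | Path, lib_sizes: tuple[int, int] | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        required = ["gene_id", "length_bp", "count_control", "count_treatment"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        libs = lib_sizes or (0, 0)
        return cls(df["gene_id"].astype(str).tolist(), df["length_bp"].to_numpy(),
                   df["count_control"].to_numpy(), df["count_treatment"].to_numpy(),
                   libs[0], libs[1])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids, "length_bp": self.lengths,
                      "count_control": self.count_control,
                      "count_treatment": self.count_treatment}).to_csv(
            path, sep="\t", index=False)


def rpkm(count: float, gene_length: int, lib_size: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if gene_length <= 0 or lib_size <= 0:
        raise ValueError("gene_length and lib_size must be positive")
    return 1e9 * count / (lib_size * gene_length)


def log2_ratio(rpkm_treatment: float, rpkm_control: float) -> float:
    """log2(treatment / control); NaN when both are zero."""
    if rpkm_treatment < 0 or rpkm_control < 0:
        raise ValueError("RPKM values must be non-negative")
    if rpkm_treatment == 0 and rpkm_control == 0:
        return math.nan
    if rpkm_control == 0:
        return math.inf
    if rpkm_treatment == 0:
        return -math.inf
    return math.log2(rpkm_treatment / rpkm_control)


def poisson_de_pvalue(x: int, y: int, n_x: int, n_y: int) -> float:
    """Conditional exact two-sided p-value for equality of two Poisson counts.

    Given x + y, x ~ Binomial(x + y, n_x / (n_x + n_y)) under the null;
    the smaller of the two tail probabilities is doubled and capped at 1.
    """
    if n_x <= 0 or n_y <= 0:
        raise ValueError("library sizes must be positive")
    if x < 0 or y < 0 or x + y < 1:
        raise ValueError("need non-negative counts with x + y >= 1")
    n = x + y
    p = n_x / (n_x + n_y)
    lower = stats.binom.cdf(x, n, p)
    upper = stats.binom.sf(x - 1, n, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def call_de(matrix: CountMatrix, fold_threshold: float = 2.0,
            fdr_threshold: float = 0.001) -> pd.DataFrame:
    """Full differential-expression table with Up/Down/NotDE calls.

    BH adjustment runs over all genes with at least one read.  The call
    is the conjunction of the fold rule (|log2 ratio| >= log2(fold),
    inclusive) and the FDR rule (adjusted p < ``fdr_threshold``).  For
    genes where exactly one count is zero the reported log2 ratio uses a
    half-count pseudo-value; the exact test itself never does.
    """
    n = len(matrix.gene_ids)
    lib_c, lib_t = matrix.lib_control, matrix.lib_treatment
    rpkm_c = 1e9 * matrix.count_control / (lib_c * matrix.lengths)
    rpkm_t = 1e9 * matrix.count_treatment / (lib_t * matrix.lengths)

    log2r = np.full(n, np.nan)
    for i in range(n):
        xc, xt = matrix.count_control[i], matrix.count_treatment[i]
        if xc == 0 and xt == 0:
            continue
        # half-count pseudo-value for reporting only
        rc = rpkm_c[i] if xc > 0 else rpkm(0.5, matrix.lengths[i], lib_c)
        rt = rpkm_t[i] if xt > 0 else rpkm(0.5, matrix.lengths[i], lib_t)
        log2r[i] = math.log2(rt / rc)

    pvals = np.ones(n)
    tested = (matrix.count_control + matrix.count_treatment) >= 1
    for i in np.flatnonzero(tested):
        pvals[i] = poisson_de_pvalue(int(matrix.count_control[i]),
                                     int(matrix.count_treatment[i]), lib_c, lib_t)
    fdr = np.ones(n)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    log2_cut = math.log2(fold_threshold)
    call = np.where(
        (log2r >= log2_cut) & (fdr < fdr_threshold), "Up",
        np.where((log2r <= -log2_cut) & (fdr < fdr_threshold), "Down", "NotDE"))
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "rpkm_control": rpkm_c,
        "rpkm_treatment": rpkm_t,
        "log2_ratio": log2r,
        "call": call,
        "p_value": pvals,
        "fdr": fdr,
    })
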