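"""Pairwise Ka/Ks estimation and GO-category evolution screening.

omega = Ka/Ks, where Ka is the number of nonsynonymous substitutions per
nonsynonymous site and Ks the number of synonymous substitutions per
synonymous site.  Sites and substitutions are counted with the
Nei–Gojobori (1986) fractional scheme: each codon position contributes
the fraction of its three possible single-nucleotide mutations that are
synonymous, and multi-step codon differences are averaged over all
mutational pathways that avoid stop codons.  Observed proportions are
corrected for multiple hits with the Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``.

The category screen aggregates per-gene omega within GO categories of
at least 10 genes, normalizes by the median gene omega of the species
pair, and assigns significance by permutation of gene labels, with
Benjamini–Hochberg FDR control in each tail (rapid / slow).

``lrt_fdr`` post-processes branch-site likelihood-ratio tests: the
statistic 2*dlnL is referred to the 50:50 mixture of a point mass at
zero and chi-square with 1 df, followed by BH adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from Bio.Data import CodonTable

_table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
GENETIC_CODE: dict[str, str] = dict(_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """A gapless pairwise codon alignment for one gene."""

    gene_id: str
    seq_a: str
    seq_b: str
    species_pair: str = ""

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            if set(seq) - set(_BASES):
                raise ValueError(f"{self.gene_id}: non-ACGT character in alignment")
            for i in range(0, len(seq) - 3, 3):  # internal stops only
                if seq[i:i + 3] in STOP_CODONS:
                    raise ValueError(f"{self.gene_id}: internal stop codon at {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass
class KaKsResult:
    gene_id: str
    ka: float
    ks: float
    omega: float            # NaN when undefined (Ks == 0)
    n_sites: float          # nonsynonymous sites
    s_sites: float          # synonymous sites
    nd: float               # nonsynonymous substitutions (fractional)
    sd: float               # synonymous substitutions (fractional)
    saturated: bool = False  # JC correction undefined (p >= 3/4)

    @property
    def omega_defined(self) -> bool:
        return math.isfinite(self.omega)


def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the 3 positions contributes the fraction of its single-base
    mutations that preserve the amino acid; mutations to stop codons are
    excluded from the denominator.  The two counts sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS or codon not in GENETIC_CODE:
        raise ValueError(f"not a sense codon: {codon}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1:] for b in _BASES if b != codon[pos]]
        non_stop = [m for m in muts if m not in STOP_CODONS]
        if not non_stop:
            continue
        frac = sum(GENETIC_CODE[m] == aa for m in non_stop) / len(non_stop)
        syn += frac
    return syn, 3.0 - syn


def count_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) change counts between codons.

    Codons differing at d positions are compared along all d! orderings
    of the single-base steps; orderings that pass through a stop codon
    are skipped and the per-step synonymous/nonsynonymous tallies are
    averaged over the remaining pathways.  If every pathway hits a stop,
    the d changes are split equally between the two classes.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in GENETIC_CODE:
            raise ValueError(f"not a sense codon: {c}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot = nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        d = len(diff)
        return d / 2.0, d / 2.0
    return syn_tot / n_paths, nonsyn_tot / n_paths


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); NaN when p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori Ka, Ks and omega for one pairwise codon alignment.

    omega is NaN (undefined) when Ks = 0; a saturated alignment (either
    observed proportion >= 3/4, outside Jukes–Cantor validity) is
    flagged and excluded from category aggregation downstream.
    """
    if alignment.n_codons < 10:
        raise ValueError("alignment shorter than 10 codons")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(alignment.seq_a), 3):
        ca, cb = alignment.seq_a[i:i + 3], alignment.seq_b[i:i + 3]
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        s, n = count_substitutions(ca, cb)
        sd += s
        nd += n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = math.isnan(ks) or math.isnan(ka)
    if saturated or ks == 0.0:
        omega = math.nan  # undefined when Ks = 0 (or correction invalid)
    elif ka == 0.0:
        omega = 0.0
    else:
        omega = ka / ks
    return KaKsResult(alignment.gene_id, ka, ks, omega, n_sites, s_sites,
                      nd, sd, saturated)


@dataclass
class CategoryScore:
    go_id: str
    n_genes: int
    raw_omega: float
    norm_omega: float
    p_value: float
    q_value: float
    direction: str  # "rapid" or "slow"


def category_screen(gene_omegas: dict[str, float], go_map: dict[str, list[str]],
                    n_perm: int = 10_000, seed: int = 0, min_genes: int = 10,
                    aggregate: str = "mean") -> list[CategoryScore]:
    """Permutation screen for rapidly and slowly evolving GO categories.

    For every category with at least ``min_genes`` member genes with a
    defined omega, the aggregate (mean by default, median optional)
    omega is normalized by the median omega over all genes of the
    species pair.  The permutation null redraws same-size gene sets
    ``n_perm`` times; two one-sided tails are scored (rapid: elevated
    aggregate; slow: depressed) and BH-adjusted within each tail.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not go_map:
        raise ValueError("empty gene->GO map")
    usable = {g: w for g, w in gene_omegas.items() if math.isfinite(w)}
    n_dropped = len(gene_omegas) - len(usable)
    if n_dropped:
        import logging
        logging.getLogger("anser").info("excluded %d genes with undefined omega", n_dropped)
    if not usable:
        raise ValueError("no genes with defined omega")
    genes = np.array(sorted(usable))
    omegas = np.array([usable[g] for g in genes])
    median_omega = float(np.median(omegas))
    agg = np.mean if aggregate == "mean" else np.median

    cats: dict[str, np.ndarray] = {}
    gene_idx = {g: i for i, g in enumerate(genes)}
    by_cat: dict[str, list[int]] = {}
    for g, cat_list in go_map.items():
        if g not in gene_idx:
            continue
        for c in cat_list:
            by_cat.setdefault(c, []).append(gene_idx[g])
    cats = {c: np.array(sorted(set(idx))) for c, idx in by_cat.items()
            if len(set(idx)) >= min_genes}
    if not cats:
        return []

    rng = np.random.default_rng(seed)
    # one permutation-null distribution per distinct category size
    sizes = sorted({len(v) for v in cats.values()})
    null: dict[int, np.ndarray] = {}
    for size in sizes:
        draws = rng.integers(0, len(genes), size=(n_perm, size))
        null[size] = agg(omegas[draws], axis=1)

    rows = []
    for c in sorted(cats):
        idx = cats[c]
        obs = float(agg(omegas[idx]))
        dist = null[len(idx)]
        # add-one correction keeps permutation p-values in (0, 1]
        p_rapid = (np.count_nonzero(dist >= obs) + 1) / (n_perm + 1)
        p_slow = (np.count_nonzero(dist <= obs) + 1) / (n_perm + 1)
        rows.append((c, len(idx), obs, obs / median_omega, p_rapid, p_slow))

    out: list[CategoryScore] = []
    for tail, col in (("rapid", 4), ("slow", 5)):
        pvals = np.array([r[col] for r in rows])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for (c, n, obs, norm, *_), p, q in zip(rows, pvals, qvals):
            out.append(CategoryScore(c, n, obs, norm, float(p), float(q), tail))
    return out


def lrt_fdr(lnl_null: dict[str, float], lnl_alt: dict[str, float],
            q_threshold: float = 0.05, tolerance: float = 1e-6) -> pd.DataFrame:
    """Branch-site LRT post-processing with BH FDR control.

    The statistic 2(lnL1 - lnL0) is referred to the 50:50 mixture of a
    point mass at zero and chi-square(1): p = 1 at the boundary, else
    half the chi-square(1) upper tail.  Returns a per-gene table with a
    ``selected`` column marking q < ``q_threshold``.
    """
    genes = sorted(lnl_null)
    if set(genes) != set(lnl_alt):
        raise ValueError("gene sets of the two likelihood columns differ")
    stats_2dl = []
    for g in genes:
        s = 2.0 * (lnl_alt[g] - lnl_null[g])
        if s < -tolerance:
            raise ValueError(f"{g}: alternative likelihood below null (2dlnL={s:.3g})")
        stats_2dl.append(max(s, 0.0))
    pvals = np.array([1.0 if s == 0.0 else 0.5 * stats.chi2.sf(s, df=1)
                      for s in stats_2dl])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": genes,
        "two_delta_lnl": stats_2dl,
        "p_value": pvals,
        "q_value": qvals,
        "selected": qvals < q_threshold,
    })
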