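"""Two-library differential expression for tag-count data.

Expression is normalized to tags per million (TPM = count / library clean
total x 1e6).  Significance of a count difference between two libraries
is assessed with the Audic-Claverie exact test: conditioning on the count
x observed in library 1 (size N1), the count y in library 2 (size N2)
follows

    P(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative-binomial distribution in y.  The one-tail p-value is the
smaller of the lower and upper tail sums at y; the two-sided p doubles it
(capped at 1).  Genes are called differential on three simultaneous
thresholds: p, Benjamini-Hochberg FDR, and |log2 fold change| of the
(zero-floored) TPMs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

DEFAULT_ZERO_FLOOR = 0.01
DEFAULT_P_MAX = 0.001
DEFAULT_FDR_MAX = 0.001
DEFAULT_LFC_MIN = 2.0


@dataclass
class LibraryCounts:
    """Gene-level unambiguous tag counts of one library.

    ``total_clean`` is the library's clean-tag total (the TPM denominator);
    gene-assigned tags are a subset of clean tags, so the gene counts can
    sum to less than it.
    """

    label: str
    gene_counts: dict[str, int] = field(default_factory=dict)
    total_clean: int = 0

    def __post_init__(self) -> None:
        if self.total_clean < sum(self.gene_counts.values()):
            raise ValueError(
                f"{self.label}: total_clean smaller than summed gene counts"
            )


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    log2fc: float
    p_value: float
    fdr: float
    significant: bool


def normalize_tpm(count: int, total_clean: int,
                  zero_floor: float = DEFAULT_ZERO_FLOOR) -> float:
    """Tags per million; zero counts report the floor so fold changes of
    presence/absence genes stay defined."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return zero_floor
    return count / total_clean * 1e6


def _logaddexp(a: float, b: float) -> float:
    if a < b:
        a, b = b, a
    if b == -math.inf:
        return a
    return a + math.log1p(math.exp(b - a))


def _log_tail_sums(x: int, y: int, log_r: float, log_1mr: float) -> tuple[float, float]:
    """log lower tail P(Y<=y) and log upper tail P(Y>=y) for Y ~ NB(x+1, .).

    log pmf(j) = lgamma(x+j+1) - lgamma(x+1) - lgamma(j+1) + j*log_r
                 + (x+1)*log_1mr, summed term by term in log space.
    The upper tail is an infinite series; terms beyond j are summed until
    they no longer move the accumulator (geometric decay guarantees
    convergence).
    """

    def log_pmf(j: int) -> float:
        return (math.lgamma(x + j + 1) - math.lgamma(x + 1) - math.lgamma(j + 1)
                + j * log_r + (x + 1) * log_1mr)

    # lower tail: j = 0 .. y via the ratio recurrence
    lp = log_pmf(0)
    lower = lp
    for j in range(y):
        lp += math.log((x + j + 1) / (j + 1)) + log_r
        lower = _logaddexp(lower, lp)

    # upper tail: j = y, y+1, ... until numerically converged
    lp = log_pmf(y)
    upper = lp
    j = y
    while True:
        lp += math.log((x + j + 1) / (j + 1)) + log_r
        new = _logaddexp(upper, lp)
        j += 1
        if new == upper and lp < upper - 40.0:
            break
        upper = new
    return float(lower), float(upper)


def ac_test(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Audic-Claverie exact p-value for counts x/N1 vs y/N2.

    Computed in log space; the doubled smaller tail is capped at 1.
    """
    if min(x, y) < 0 or min(n1, n2) <= 0:
        raise ValueError("counts must be >= 0 and library sizes > 0")
    ratio = n2 / n1
    log_r = math.log(ratio) - math.log1p(ratio)      # log(N2/(N1+N2))
    log_1mr = -math.log1p(ratio)                     # log(N1/(N1+N2))
    log_lower, log_upper = _log_tail_sums(x, y, log_r, log_1mr)
    one_tail = math.exp(min(log_lower, log_upper))
    return min(1.0, 2.0 * one_tail)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def call_de(
    a: LibraryCounts,
    b: LibraryCounts,
    p_max: float = DEFAULT_P_MAX,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> list[DEResult]:
    """Differential calls over the union of both gene universes.

    A gene absent from one library counts 0 there and its TPM takes the
    floor, so presence/absence genes remain callable.  Significant means
    p < p_max AND fdr < fdr_max AND |log2fc| > lfc_min.  Results are
    sorted by FDR ascending.
    """
    genes = sorted(set(a.gene_counts) | set(b.gene_counts))
    rows = []
    for g in genes:
        x = a.gene_counts.get(g, 0)
        y = b.gene_counts.get(g, 0)
        tpm_a = normalize_tpm(x, a.total_clean, zero_floor)
        tpm_b = normalize_tpm(y, b.total_clean, zero_floor)
        rows.append((g, x, y, tpm_a, tpm_b, math.log2(tpm_a / tpm_b),
                     ac_test(x, a.total_clean, y, b.total_clean)))
    fdrs = bh_fdr([r[6] for r in rows])
    results = [
        DEResult(g, x, y, tpm_a, tpm_b, lfc, p, fdr,
                 significant=(p < p_max and fdr < fdr_max and abs(lfc) > lfc_min))
        for (g, x, y, tpm_a, tpm_b, lfc, p), fdr in zip(rows, fdrs)
    ]
    return sorted(results, key=lambda r: (r.fdr, r.p_value, r.gene_id))


def library_overlap_stats(
    a: LibraryCounts,
    b: LibraryCounts,
    high_expr_fraction: float = 1e-4,
) -> dict[str, float]:
    """Shared/unique gene proportions of the combined expression universe.

    ``high_expr_fraction`` flags genes whose count exceeds that fraction
    of the library's clean total (0.01% by default).
    """
    genes_a = {g for g, c in a.gene_counts.items() if c > 0}
    genes_b = {g for g, c in b.gene_counts.items() if c > 0}
    universe = genes_a | genes_b
    n = len(universe)
    high_a = sum(1 for g in genes_a
                 if a.gene_counts[g] / a.total_clean > high_expr_fraction)
    high_b = sum(1 for g in genes_b
                 if b.gene_counts[g] / b.total_clean > high_expr_fraction)
    return {
        "n_universe": n,
        "n_unique_a": len(genes_a - genes_b),
        "n_unique_b": len(genes_b - genes_a),
        "n_shared": len(genes_a & genes_b),
        "pct_unique_a": 100.0 * len(genes_a - genes_b) / n if n else 0.0,
        "pct_unique_b": 100.0 * len(genes_b - genes_a) / n if n else 0.0,
        "pct_high_expr_a": 100.0 * high_a / n if n else 0.0,
        "pct_high_expr_b": 100.0 * high_b / n if n else 0.0,
    }


def proportion_of_universe(count: int, universe: int) -> float:
    """Percentage a gene-set count represents of the combined universe."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    return 100.0 * count / universe


def write_de_table_tsv(results: list[DEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tcount_a\tcount_b\ttpm_a\ttpm_b\tlog2fc\t"
                 "p_value\tfdr\tsignificant\n")
        for r in results:
            fh.write(f"{r.gene_id}\t{r.count_a}\t{r.count_b}\t"
                     f"{r.tpm_a:.4f}\t{r.tpm_b:.4f}\t{r.log2fc:.4f}\t"
                     f"{r.p_value:.6g}\t{r.fdr:.6g}\t{int(r.significant)}\n")
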