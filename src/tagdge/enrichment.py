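"""Hypergeometric GO-term and pathway enrichment with Bonferroni control.

Given n differential genes drawn from a background universe of N genes,
a term annotating K background genes and k of the differential genes is
scored with the upper-tail hypergeometric probability P(X >= k).  The
Q-value is the Bonferroni-adjusted p (p times the number of terms tested
within the same category), and a term is enriched when Q < 0.05.  The
background defaults to the genes detected in the expression data rather
than the full genome annotation; genes without any term annotation still
count in N.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom

BIOLOGICAL_PROCESS = "biological_process"
CELLULAR_COMPONENT = "cellular_component"
MOLECULAR_FUNCTION = "molecular_function"
PATHWAY = "pathway"

DEFAULT_Q_MAX = 0.05


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    category: str
    member_genes: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int       # differential genes in the term
    K: int       # background genes in the term
    n: int       # differential genes total
    N: int       # background universe size
    p_value: float
    q_value: float
    significant: bool


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    de_genes: set[str],
    background: set[str],
    terms: Iterable[TermAnnotation],
    q_max: float = DEFAULT_Q_MAX,
) -> list[EnrichmentResult]:
    """Score every term; Bonferroni correction is applied within each
    category (GO namespaces and pathways are corrected separately).

    Term memberships are intersected with the background before counting;
    terms with no background member are skipped.
    """
    stray = de_genes - background
    if stray:
        raise ValueError(
            f"differential genes outside the background: {sorted(stray)[:10]}"
        )
    N = len(background)
    n = len(de_genes)
    scored: list[tuple[TermAnnotation, int, int, float]] = []
    per_category: dict[str, int] = defaultdict(int)
    for term in terms:
        members = term.member_genes & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_genes)
        p = hypergeom_pvalue(k, K, n, N)
        scored.append((term, k, K, p))
        per_category[term.category] += 1

    results = []
    for term, k, K, p in scored:
        q = min(1.0, p * per_category[term.category])
        results.append(EnrichmentResult(
            term.term_id, term.term_name, term.category, k, K, n, N,
            p_value=p, q_value=q, significant=q < q_max,
        ))
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.term_id))


def read_term_membership_tsv(path, metadata_path=None) -> list[TermAnnotation]:
    """Two-column (term_id, gene_id) membership, with optional metadata TSV
    (term_id, term_name, category); unannotated terms default to pathway."""
    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        with open(metadata_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                term_id, name, category = line.rstrip("\n").split("\t")[:3]
                meta[term_id] = (name, category)
    members: dict[str, set[str]] = defaultdict(set)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            term_id, gene_id = line.rstrip("\n").split("\t")[:2]
            members[term_id].add(gene_id)
    out = []
    for term_id in sorted(members):
        name, category = meta.get(term_id, (term_id, PATHWAY))
        out.append(TermAnnotation(term_id, name, category, members[term_id]))
    return out


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("#term_id\tterm_name\tcategory\tk\tK\tn\tN\t"
                 "p_value\tq_value\tsignificant\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.term_name}\t{r.category}\t{r.k}\t{r.K}\t"
                     f"{r.n}\t{r.N}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                     f"{int(r.significant)}\n")
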