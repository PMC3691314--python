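"""GO-term and pathway enrichment of predicted target genes.

With N annotated genes in the genome, n of them carrying a specific
term, M annotated genes among the predicted targets and m target genes
carrying the term, the fold enrichment (E-ratio) is

    E = (m / M) / (n / N)

and significance comes from the hypergeometric upper tail
P(X >= m), equivalently a one-sided Fisher's exact test on the 2x2
table.  A GO term is called significant at E > 2 and p < 0.05; a
pathway at E > 1.5 and p < 0.05 (both strict, as printed).  No
multiple-testing correction is applied by default; Benjamini-Hochberg
q-values are available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import false_discovery_control, hypergeom

GO_E_RATIO_THRESHOLD = 2.0
PATHWAY_E_RATIO_THRESHOLD = 1.5
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one term: genome (N, n) and target set (M, m)."""

    N: int
    n: int
    M: int
    m: int

    def __post_init__(self):
        if not (0 <= self.n <= self.N and 0 <= self.M <= self.N):
            raise ValueError("need n <= N and M <= N")
        if not 0 <= self.m <= min(self.n, self.M):
            raise ValueError("need 0 <= m <= min(n, M)")


@dataclass
class EnrichmentResult:
    term: str
    description: str
    m: int
    M: int
    n: int
    N: int
    e_ratio: float
    p_value: float
    significant: bool
    q_value: float | None = None


def e_ratio(inp: EnrichmentInput) -> float:
    """Fold enrichment (m/M)/(n/N); 0 when m = 0."""
    if inp.M == 0 or inp.n == 0:
        raise ZeroDivisionError("E-ratio undefined for M = 0 or n = 0")
    return (inp.m / inp.M) / (inp.n / inp.N)


def hypergeometric_tail_p(inp: EnrichmentInput) -> float:
    """P(X >= m) for X ~ Hypergeom(N, n, M), computed in log space."""
    # sf(m-1) is the upper tail including m; scipy works in log space
    # internally, so extreme tails stay accurate
    return float(min(1.0, hypergeom.sf(inp.m - 1, inp.N, inp.n, inp.M)))


def fisher_exact_p(inp: EnrichmentInput) -> float:
    """One-sided (enrichment) Fisher's exact p on the 2x2 table.

    The table is [[m, M-m], [n-m, N-M-n+m]]; the one-sided p equals the
    hypergeometric upper tail with the table's own margins.
    """
    a, b = inp.m, inp.M - inp.m
    c, d = inp.n - inp.m, inp.N - inp.M - inp.n + inp.m
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    return float(min(1.0, hypergeom.sf(a - 1, a + b + c + d, a + c, a + b)))


def enrich(
    gene_terms: dict[str, list[str]],
    target_genes: set[str] | list[str],
    universe_genes: set[str] | list[str],
    e_ratio_threshold: float = GO_E_RATIO_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    descriptions: dict[str, str] | None = None,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment of every term with at least one target gene.

    Only annotated genes (present in ``gene_terms``) enter the counts,
    mirroring the N/n/M/m definitions above.  Results are sorted by
    E-ratio descending, ties by ascending p then term id.
    """
    universe = set(universe_genes)
    targets = set(target_genes)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    if not universe:
        raise ValueError("empty universe")
    annotated = {g for g in universe if gene_terms.get(g)}
    N = len(annotated)
    M = len(targets & annotated)
    if N == 0 or M == 0:
        return []
    term_genes: dict[str, set[str]] = {}
    for g in annotated:
        for t in gene_terms[g]:
            term_genes.setdefault(t, set()).add(g)
    results = []
    for term, genes in term_genes.items():
        m = len(genes & targets)
        if m == 0:
            continue
        inp = EnrichmentInput(N=N, n=len(genes), M=M, m=m)
        er = e_ratio(inp)
        p = hypergeometric_tail_p(inp)
        results.append(EnrichmentResult(
            term=term,
            description=(descriptions or {}).get(term, term),
            m=m, M=M, n=len(genes), N=N,
            e_ratio=er, p_value=p,
            significant=(er > e_ratio_threshold and p < p_threshold),
        ))
    results.sort(key=lambda r: (-r.e_ratio, r.p_value, r.term))
    if bh_correction and results:
        qs = false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results
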