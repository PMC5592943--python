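"""Gene-set enrichment and modifier-allele concordance.

Enrichment of a query gene set (e.g. the genes of one trans-band) in
annotation categories is tested with the upper-tail hypergeometric
distribution on unique genes, Bonferroni-corrected over the categories
tested; a category passes only when the corrected p is below alpha, the
category holds more than 3 genes and the overlap exceeds 2 genes.

Concordance compares, for the genes of a trans-band, the signed allelic
effect from eQTL mapping with the expression difference measured between
transgenic lines carrying the two alleles of a candidate modifier gene:
agreement in sign and a high R^2 support the candidate as the causal
polymorphism behind the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    category: str
    category_size: int
    query_size: int
    overlap: int
    p_raw: float
    p_bonferroni: float
    passed: bool


def enrich(
    query_genes: set[str],
    categories: pd.DataFrame,
    universe: set[str],
    alpha: float = 0.05,
    min_category_size: int = 4,
    min_overlap: int = 3,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per annotation category.

    ``categories`` is a two-column table (``category_id``, ``gene_id``).
    Genes are deduplicated and restricted to ``universe`` before testing;
    the Bonferroni factor is the number of categories meeting the size
    filter (the hypotheses actually tested).  A result passes when the
    corrected p < ``alpha``, category size >= ``min_category_size``
    (i.e. > 3 by default) and overlap >= ``min_overlap`` (> 2 by default).
    """
    if not universe:
        raise ValueError("universe must not be empty")
    query = set(query_genes) & universe
    cats = categories[categories["gene_id"].isin(universe)]
    by_cat = {
        str(c): set(sub["gene_id"]) for c, sub in cats.groupby("category_id", sort=True)
    }
    tested = {c: g for c, g in by_cat.items() if len(g) >= min_category_size}
    n_tests = max(len(tested), 1)

    M, n = len(universe), len(query)
    results: list[EnrichmentResult] = []
    for cat, genes in sorted(by_cat.items()):
        K = len(genes)
        k = len(genes & query)
        # P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        p_adj = min(1.0, p * n_tests)
        results.append(
            EnrichmentResult(
                category=cat,
                category_size=K,
                query_size=n,
                overlap=k,
                p_raw=p,
                p_bonferroni=p_adj,
                passed=(p_adj < alpha) and (K >= min_category_size) and (k >= min_overlap),
            )
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.category, r.category_size, r.query_size, r.overlap, r.p_raw, r.p_bonferroni, r.passed)
            for r in results
        ],
        columns=["category", "category_size", "query_size", "overlap", "p_raw", "p_bonferroni", "passed"],
    )


@dataclass
class ConcordanceResult:
    """Agreement between eQTL allelic effects and transgenic allelic differences."""

    n_genes: int
    n_concordant: int
    pearson_r: float
    r_squared: float
    pairs: pd.DataFrame  # gene_id, eqtl_effect, transgenic_diff, concordant

    @property
    def concordance(self) -> float:
        return self.n_concordant / self.n_genes


def allelic_concordance(
    records_at_locus: pd.DataFrame,
    transgenic_diff: pd.Series,
) -> ConcordanceResult:
    """Compare eQTL effects at a locus with transgenic allelic differences.

    ``records_at_locus`` is an eQTL table (one row per spot; effects are
    averaged per gene), ``transgenic_diff`` maps gene id -> allelic
    expression difference on the same sign convention (positive = higher
    on the N2 allele).  Genes with a zero transgenic difference count as
    discordant.  Requires at least 3 shared genes.
    """
    eqtl = records_at_locus.groupby("gene_id")["effect"].mean()
    shared = sorted(set(eqtl.index) & set(transgenic_diff.index))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared; need at least 3")
    x = eqtl.loc[shared].to_numpy(dtype=float)
    y = transgenic_diff.loc[shared].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    concordant = (np.sign(x) == np.sign(y)) & (np.sign(y) != 0)
    pairs = pd.DataFrame(
        {
            "gene_id": shared,
            "eqtl_effect": x,
            "transgenic_diff": y,
            "concordant": concordant,
        }
    )
    return ConcordanceResult(
        n_genes=len(shared),
        n_concordant=int(concordant.sum()),
        pearson_r=r,
        r_squared=r * r,
        pairs=pairs,
    )
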