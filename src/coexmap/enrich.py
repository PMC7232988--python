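"""Annotation overrepresentation: per-term Fisher's exact test of a study
gene set against a reference catalogue, with Benjamini-Hochberg FDR.

For each term with population count K in a reference population of N genes,
a study list of n genes containing k members of the term gives the 2x2
table (k, n-k, K-k, N-n-K+k).  The default test is one-sided
overrepresentation: p = P(X >= k) under the hypergeometric null.  BH
adjustment is computed with statsmodels; terms are reported significant at
q < alpha (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexmap.geometry import AnnotationCatalogue

VALID_SIDEDNESS = ("greater", "two-sided")


@dataclass
class EnrichmentResult:
    """One term's 2x2 counts and test results."""

    term_id: str
    term_name: str
    category: str | None
    k: int  # study genes in term
    n: int  # study size
    K: int  # population genes in term
    N: int  # population size
    p_value: float
    q_value: float = np.nan
    study_gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError(
                f"term {self.term_id}: k={self.k} outside [0, min(n={self.n}, "
                f"K={self.K})]"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"term {self.term_id}: p={self.p_value} outside [0, 1]")


def fisher_overrepresentation(
    study,
    catalogue: AnnotationCatalogue,
    sidedness: str = "greater",
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Per-term Fisher's exact test of ``study`` against the catalogue.

    ``sidedness="greater"`` (default) is the one-sided overrepresentation
    p-value, the hypergeometric upper tail P(X >= k); ``"two-sided"`` sums
    tables with probability <= the observed one.  Study genes outside the
    population are dropped with a warning.  Terms with fewer than
    ``min_term_size`` population genes are untestable singletons and are
    skipped (logged via warning at the end if any).
    """
    if sidedness not in VALID_SIDEDNESS:
        raise ValueError(f"sidedness must be one of {VALID_SIDEDNESS}: {sidedness!r}")
    population = catalogue.population
    if not population:
        raise ValueError("annotation catalogue has an empty population")
    study = {str(g) for g in study}
    stray = study - set(population)
    if stray:
        warnings.warn(
            f"{len(stray)} study genes absent from the reference population "
            "were dropped",
            stacklevel=2,
        )
        study &= set(population)
    if not study:
        raise ValueError("study set is empty after intersecting with the population")
    n, N = len(study), len(population)
    results = []
    skipped = 0
    for term_id, (name, category, genes) in catalogue.terms.items():
        K = len(genes)
        if K < min_term_size:
            skipped += 1
            continue
        hits = study & genes
        k = len(hits)
        if sidedness == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - n - (K - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=name,
                category=category,
                k=k,
                n=n,
                K=K,
                N=N,
                p_value=min(p, 1.0),
                study_gene_ids=sorted(hits),
            )
        )
    if skipped:
        warnings.warn(
            f"{skipped} terms with K < {min_term_size} population genes skipped",
            stacklevel=2,
        )
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_results(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill each result's q_value by BH adjustment across all terms."""
    if not results:
        return results
    q = bh_fdr([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def significant_terms(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with q < alpha (strict), sorted by q ascending then term_id."""
    sig = [r for r in results if np.isfinite(r.q_value) and r.q_value < alpha]
    sig.sort(key=lambda r: (r.q_value, r.term_id))
    return sig
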