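"""Contingency tests, Fisher combined probability, and gene-set enrichment.

``fisher_combined`` is the meta-analysis workhorse: k independent p-values
combine as -2 sum(ln p_i) ~ chi-square with 2k degrees of freedom, so
consistent moderate evidence across cohorts (none individually significant)
can reach combined significance.  ``chisq_test`` is the Pearson chi-square
without continuity correction, the convention under which published
clinicopathological 2x2 tables reproduce exactly.  ``geneset_enrichment``
is the one-sided hypergeometric test used, e.g., to ask whether polycomb
group target (PCGT) genes are over-represented among the hypermethylated
signature CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from scipy import stats

from .cohort_io import ValidationError


@dataclass
class ContingencyTable:
    """An r x c grid of non-negative integer counts with labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if (self.counts < 0).any() or self.counts.sum() == 0:
            raise ValidationError("counts must be non-negative with positive total")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(self.counts.shape[1])]


@dataclass
class CombinedTest:
    """Fisher's combined probability test result."""

    statistic: float
    df: int
    p: float
    pvalues: list[float]
    labels: list[str] = field(default_factory=list)


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of a gene set in a signature."""

    overlap: int
    signature_size: int
    geneset_size: int
    background_size: int
    fold_enrichment: float
    p: float
    overlap_genes: list[str] = field(default_factory=list)


def chisq_test(table: ContingencyTable | Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, df, p) with df = (r-1)(c-1).  Expected counts below
    5 only warn; a zero row or column total is an error.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValidationError("chisq_test: zero row or column total")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        import warnings

        warnings.warn(
            f"{int((expected < 5).sum())} expected counts below 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    return float(stat), int(df), float(p)


def fisher_combined(pvalues: Sequence[float], labels: Sequence[str] | None = None) -> CombinedTest:
    """Fisher's combined probability test over independent p-values.

    statistic = -2 sum(ln p_i), referred to chi-square with 2k df.  A single
    p-value round-trips: the combined p equals the input.
    """
    ps = [float(p) for p in pvalues]
    if not ps:
        raise ValidationError("fisher_combined needs at least one p-value")
    if any(p <= 0.0 or p > 1.0 for p in ps):
        raise ValidationError(f"p-values must lie in (0, 1], got {ps}")
    statistic = -2.0 * float(np.sum(np.log(ps)))
    df = 2 * len(ps)
    return CombinedTest(
        statistic=statistic,
        df=df,
        p=float(stats.chi2.sf(statistic, df)),
        pvalues=ps,
        labels=list(labels) if labels is not None else [f"set{i}" for i in range(len(ps))],
    )


def meta_interaction(
    per_set_results: Sequence[tuple[str, object]], stratum: str = "univariate"
) -> CombinedTest:
    """Combine per-cohort interaction p-values with Fisher's method.

    ``per_set_results`` pairs a cohort label with either a bare p-value or an
    object exposing ``.p`` (e.g. an InteractionResult).  With four cohorts
    the combined statistic has 8 df; with two, 4 df.
    """
    if not per_set_results:
        raise ValidationError("meta_interaction needs at least one result")
    labels, ps = [], []
    for label, res in per_set_results:
        labels.append(str(label))
        ps.append(float(getattr(res, "p", res)))
    out = fisher_combined(ps, labels=labels)
    out.labels = [f"{l} [{stratum}]" for l in out.labels]
    return out


def geneset_enrichment(
    signature_genes: Iterable[str],
    gene_set: Iterable[str],
    background: Iterable[str],
) -> EnrichmentResult:
    """Hypergeometric upper-tail test for gene-set over-representation.

    Genes are de-duplicated; the gene set is intersected with the background
    before testing.  fold = (overlap/signature) / (set/background); p is
    P(overlap >= observed) under sampling without replacement.
    """
    bg = set(background)
    if not bg:
        raise ValidationError("background gene universe is empty")
    sig = set(signature_genes)
    if not sig <= bg:
        raise ValidationError(
            f"{len(sig - bg)} signature genes missing from background, e.g. "
            f"{sorted(sig - bg)[:3]}"
        )
    gset = set(gene_set) & bg
    overlap_genes = sorted(sig & gset)
    k, n_sig, K, N = len(overlap_genes), len(sig), len(gset), len(bg)
    if n_sig == 0:
        raise ValidationError("signature gene list is empty")
    fold = (k / n_sig) / (K / N) if K else float("nan")
    p = float(stats.hypergeom.sf(k - 1, N, K, n_sig)) if K else 1.0
    return EnrichmentResult(
        overlap=k,
        signature_size=n_sig,
        geneset_size=K,
        background_size=N,
        fold_enrichment=fold,
        p=p,
        overlap_genes=overlap_genes,
    )


def read_gene_set(path) -> list[str]:
    """Read a one-symbol-per-line gene-set file (blank lines ignored)."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]
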