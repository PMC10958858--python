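"""GO-term over-representation by the hypergeometric test.

The universe is the background gene set restricted to genes with at
least one GO annotation.  Per term, p = P(X >= k) for
hypergeometric(N, K, n) with k study genes carrying the term, K
background genes carrying it, n the study size and N the universe
size; BH controls the FDR across terms.  Two background modes mirror
the study's usage: all methylated genes (for VMP and clock gene
lists), or all differentially methylated genes (for the consistent
hyper/hypo sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diffmeth import _group_columns, weighted_methylation
from .errors import DataError, ValidationError
from .types import GeneFeature, GOMap, MethylationMatrix


def methylated_background(
    matrix: MethylationMatrix,
    genes: Sequence[GeneFeature],
    threshold: float = 0.05,
) -> set:
    """Genes counted as methylated for enrichment backgrounds.

    A gene qualifies when its weighted methylation (total meth over
    total coverage across its CpGs), averaged over the replicates of a
    sex x age group, is strictly greater than ``threshold`` — the
    lambda-spike weighted methylation level — in at least one group.
    Genes with no covered CpGs are excluded with a warning.
    """
    groups = sorted({(s.sex, s.age_days) for s in matrix.samples})
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _ in matrix.sites}:
        idx = np.array([i for i, (c, _) in enumerate(matrix.sites) if c == chrom])
        pos = np.array([matrix.sites[i][1] for i in idx])
        by_chrom[chrom] = (pos, idx)

    out = set()
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="right")
        rows = idx[lo:hi]
        if len(rows) == 0:
            continue
        if matrix.coverage[rows].sum() == 0:
            warnings.warn(f"gene {gene.gene_id}: no covered CpGs; excluded")
            continue
        for sex, age in groups:
            cols = _group_columns(matrix.samples, sex, age)
            if not cols:
                continue
            wms = [
                weighted_methylation(matrix.meth[rows, j], matrix.coverage[rows, j])
                for j in cols
            ]
            wms = [w for w in wms if not np.isnan(w)]
            if wms and float(np.mean(wms)) > threshold:
                out.add(gene.gene_id)
                break
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's over-representation in the study set."""

    term: str
    k: int   # study genes with the term
    K: int   # background (universe) genes with the term
    n: int   # study genes in the universe
    N: int   # universe size
    p: float
    q: float

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def hypergeometric_enrichment(
    study: Iterable[str],
    background: Iterable[str],
    go: GOMap,
    q_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of every term with K >= 1.

    ``study`` must be a subset of ``background``; genes without GO
    annotation drop out of the universe (they carry no information for
    the model).  Results are sorted by q then p.
    """
    study = set(study)
    background = set(background)
    stray = study - background
    if stray:
        raise ValidationError(
            f"study genes missing from background: {sorted(stray)[:10]}"
        )
    universe = {g for g in background if go.get(g)}
    study_u = study & universe
    N, n = len(universe), len(study_u)
    if N == 0:
        raise DataError("empty universe: no annotated background genes")

    term_to_universe: dict[str, int] = {}
    term_to_study: dict[str, int] = {}
    for gene in universe:
        for term in go[gene]:
            term_to_universe[term] = term_to_universe.get(term, 0) + 1
            if gene in study_u:
                term_to_study[term] = term_to_study.get(term, 0) + 1

    terms = sorted(term_to_universe)
    pvals = []
    for term in terms:
        K = term_to_universe[term]
        k = term_to_study.get(term, 0)
        # P(X >= k) over hypergeometric(N, K, n)
        pvals.append(float(stats.hypergeom.sf(k - 1, N, K, n)))
    if not terms:
        return []
    _, qvals, _, _ = multipletests(np.minimum(pvals, 1.0), method="fdr_bh")
    results = [
        EnrichmentResult(term=t, k=term_to_study.get(t, 0), K=term_to_universe[t],
                         n=n, N=N, p=p, q=float(q))
        for t, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult], analysis: str = "") -> pd.DataFrame:
    df = pd.DataFrame({
        "term": [r.term for r in results],
        "k": [r.k for r in results],
        "K": [r.K for r in results],
        "n": [r.n for r in results],
        "N": [r.N for r in results],
        "p": [r.p for r in results],
        "q": [r.q for r in results],
    })
    if analysis:
        df.insert(0, "analysis", analysis)
    return df
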