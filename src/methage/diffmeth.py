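"""Differential methylation between ages within each sex.

Per CpG, replicate counts are compared between two age groups with a
binomial logistic regression on the group indicator.  With a single
binary covariate the maximum-likelihood fit has a closed form — the
fitted proportions are the pooled group fractions — so the deviance
2(l_alt - l_null) is computed exactly and referred to chi-square with
one degree of freedom.  Calls require both a q-value below ``q_max``
(BH within comparison) and a pooled-fraction difference strictly above
``min_delta``.  Gene-level calls need at least two significant CpGs in
the feature and a weighted-methylation difference of at least 15%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ValidationError
from .types import GeneFeature, MethylationMatrix, SampleRecord, SiteKey


@dataclass(frozen=True)
class DMPResult:
    """Per-site differential methylation between two age groups."""

    site: SiteKey
    comparison: str
    delta: float
    deviance: float
    p: float
    q: float
    status: str  # hyper / hypo / ns


def _binom_loglike(meth: np.ndarray, cov: np.ndarray, p) -> np.ndarray:
    """Grouped binomial log-likelihood (constants dropped); xlogy handles 0."""
    return xlogy(meth, p) + xlogy(cov - meth, 1.0 - p)


def dmp_test(
    meth_a: Sequence[int], cov_a: Sequence[int],
    meth_b: Sequence[int], cov_b: Sequence[int],
) -> tuple[float, float, float]:
    """Likelihood-ratio test of one CpG between groups A and B.

    Returns ``(delta, deviance, p)`` with delta the pooled-fraction
    difference B - A.  Perfect separation is handled exactly: boundary
    MLEs contribute 0·log 0 = 0 terms, never an overflow.
    """
    ma, ca = np.asarray(meth_a, float), np.asarray(cov_a, float)
    mb, cb = np.asarray(meth_b, float), np.asarray(cov_b, float)
    if ca.sum() == 0 or cb.sum() == 0:
        raise DataError("a group has zero total coverage")
    delta, dev = _dmp_test_arrays(ma[None, :], ca[None, :], mb[None, :], cb[None, :])
    p = stats.chi2.sf(dev, df=1)
    return float(delta[0]), float(dev[0]), float(p[0])


def _dmp_test_arrays(ma, ca, mb, cb) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised deviance over sites (rows); columns are replicates."""
    sum_ma, sum_ca = ma.sum(axis=1), ca.sum(axis=1)
    sum_mb, sum_cb = mb.sum(axis=1), cb.sum(axis=1)
    p_a = sum_ma / sum_ca
    p_b = sum_mb / sum_cb
    p_0 = (sum_ma + sum_mb) / (sum_ca + sum_cb)
    ll_alt = (_binom_loglike(sum_ma, sum_ca, p_a)
              + _binom_loglike(sum_mb, sum_cb, p_b))
    ll_null = (_binom_loglike(sum_ma, sum_ca, p_0)
               + _binom_loglike(sum_mb, sum_cb, p_0))
    dev = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return p_b - p_a, dev


def _status(delta: np.ndarray, q: np.ndarray, q_max: float, min_delta: float):
    out = np.full(delta.shape, "ns", dtype=object)
    out[(q < q_max) & (delta > min_delta)] = "hyper"
    out[(q < q_max) & (delta < -min_delta)] = "hypo"
    return out


@dataclass
class DmpCalls:
    """All per-site results plus the union of age-significant sites."""

    frame: pd.DataFrame
    union_sites: list[SiteKey]
    q_max: float
    min_delta: float


def _group_columns(samples: Sequence[SampleRecord], sex: str, age: int) -> list[int]:
    return [i for i, s in enumerate(samples) if s.sex == sex and s.age_days == age]


def call_dmps(
    matrix: MethylationMatrix,
    comparisons: Sequence[tuple[str, int, int]] | None = None,
    q_max: float = 0.05,
    min_delta: float = 0.15,
) -> DmpCalls:
    """Run ``dmp_test`` per site for every (sex, ageA, ageB) comparison.

    ``comparisons`` defaults to all ordered age pairs within each sex
    present in the matrix's samples.  BH correction is applied within
    each comparison.  A site is "age significant" (member of
    ``union_sites``) if called hyper or hypo in at least one comparison.
    """
    samples = matrix.samples
    if comparisons is None:
        comparisons = []
        for sex in ("F", "M"):
            ages = sorted({s.age_days for s in samples if s.sex == sex})
            comparisons.extend(
                (sex, a, b) for i, a in enumerate(ages) for b in ages[i + 1:]
            )
    rows = []
    for sex, age_a, age_b in comparisons:
        idx_a = _group_columns(samples, sex, age_a)
        idx_b = _group_columns(samples, sex, age_b)
        if len(idx_a) < 2 or len(idx_b) < 2:
            raise ValidationError(
                f"comparison ({sex}, {age_a} vs {age_b}) needs >= 2 replicates "
                f"per side, found {len(idx_a)} and {len(idx_b)}"
            )
        delta, dev = _dmp_test_arrays(
            matrix.meth[:, idx_a], matrix.coverage[:, idx_a],
            matrix.meth[:, idx_b], matrix.coverage[:, idx_b],
        )
        p = stats.chi2.sf(dev, df=1)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        status = _status(delta, q, q_max, min_delta)
        label = f"{sex}:{age_a}v{age_b}"
        rows.append(pd.DataFrame({
            "chrom": [c for c, _ in matrix.sites],
            "pos": [pp for _, pp in matrix.sites],
            "comparison": label,
            "sex": sex,
            "age_a": age_a,
            "age_b": age_b,
            "delta": delta,
            "deviance": dev,
            "p": p,
            "q": q,
            "status": status,
        }))
    frame = pd.concat(rows, ignore_index=True)
    sig = frame[frame["status"] != "ns"]
    union = sorted({(c, int(pp)) for c, pp in zip(sig["chrom"], sig["pos"])})
    return DmpCalls(frame=frame, union_sites=union, q_max=q_max, min_delta=min_delta)


def classify_consistent(
    calls: DmpCalls, sex: str, ages: Sequence[int] = (0, 8, 16)
) -> dict[str, set]:
    """Partition one sex's sites by direction consistency across ageing.

    ``consistent_hyper``: significant hyper in both successive
    comparisons (age0→age1 and age1→age2); ``consistent_hypo`` the same
    for hypo; everything else significant somewhere goes to ``other``.
    The hyper and hypo sets are disjoint by construction.
    """
    frame = calls.frame
    steps = [f"{sex}:{ages[0]}v{ages[1]}", f"{sex}:{ages[1]}v{ages[2]}"]
    for label in steps:
        if not (frame["comparison"] == label).any():
            raise DataError(f"comparison {label} missing from DMP results")

    def sites_with(label: str, status: str) -> set:
        sub = frame[(frame["comparison"] == label) & (frame["status"] == status)]
        return {(c, int(p)) for c, p in zip(sub["chrom"], sub["pos"])}

    hyper = sites_with(steps[0], "hyper") & sites_with(steps[1], "hyper")
    hypo = sites_with(steps[0], "hypo") & sites_with(steps[1], "hypo")
    any_sig = set()
    for label in steps:
        any_sig |= sites_with(label, "hyper") | sites_with(label, "hypo")
    return {
        "consistent_hyper": hyper,
        "consistent_hypo": hypo,
        "other": any_sig - hyper - hypo,
    }


def weighted_methylation(meth: Iterable[int], coverage: Iterable[int]) -> float:
    """Total methylated reads over total coverage within a region.

    Returns NaN (missing, not 0) when the region has no coverage.
    """
    meth = np.asarray(list(meth), dtype=float)
    cov = np.asarray(list(coverage), dtype=float)
    total = cov.sum()
    if total == 0:
        return float("nan")
    return float(meth.sum() / total)


@dataclass(frozen=True)
class GeneDMResult:
    """Feature-level differential methylation call."""

    gene_id: str
    comparison: str
    n_dm_cpgs: int
    weighted_meth_a: float
    weighted_meth_b: float
    weighted_delta: float
    status: str  # dm / ns


def _gene_site_rows(matrix: MethylationMatrix, gene: GeneFeature) -> list[int]:
    return [
        i for i, (c, p) in enumerate(matrix.sites)
        if c == gene.chrom and gene.start <= p <= gene.end
    ]


def gene_level_dm(
    calls: DmpCalls,
    genes: Sequence[GeneFeature],
    matrix: MethylationMatrix,
    min_dm_cpgs: int = 2,
    min_weighted_delta: float = 0.15,
) -> pd.DataFrame:
    """Aggregate DMPs to genes: count significant CpGs in the feature and
    compare weighted methylation between the two groups over *all* of the
    feature's analysed CpGs.  A CpG overlapping two genes counts in both.
    """
    frame = calls.frame
    comparisons = frame[["comparison", "sex", "age_a", "age_b"]].drop_duplicates()

    # index sites once per chromosome for interval lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _ in matrix.sites}:
        idx = np.array([i for i, (c, _) in enumerate(matrix.sites) if c == chrom])
        pos = np.array([matrix.sites[i][1] for i in idx])
        by_chrom[chrom] = (pos, idx)

    sig_lookup: dict[str, set] = {}
    for label in comparisons["comparison"]:
        sub = frame[(frame["comparison"] == label) & (frame["status"] != "ns")]
        sig_lookup[label] = {(c, int(p)) for c, p in zip(sub["chrom"], sub["pos"])}

    out = []
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="right")
        rows = idx[lo:hi]
        if len(rows) == 0:
            continue
        gene_keys = {matrix.sites[i] for i in rows}
        for _, comp in comparisons.iterrows():
            label, sex = comp["comparison"], comp["sex"]
            idx_a = _group_columns(matrix.samples, sex, comp["age_a"])
            idx_b = _group_columns(matrix.samples, sex, comp["age_b"])
            wm_a = weighted_methylation(
                matrix.meth[np.ix_(rows, idx_a)].ravel(),
                matrix.coverage[np.ix_(rows, idx_a)].ravel(),
            )
            wm_b = weighted_methylation(
                matrix.meth[np.ix_(rows, idx_b)].ravel(),
                matrix.coverage[np.ix_(rows, idx_b)].ravel(),
            )
            n_dm = len(gene_keys & sig_lookup[label])
            wdelta = wm_b - wm_a
            status = (
                "dm"
                if n_dm >= min_dm_cpgs and abs(wdelta) >= min_weighted_delta
                else "ns"
            )
            out.append({
                "gene_id": gene.gene_id,
                "comparison": label,
                "n_dm_cpgs": n_dm,
                "weighted_meth_a": wm_a,
                "weighted_meth_b": wm_b,
                "weighted_delta": wdelta,
                "status": status,
            })
    return pd.DataFrame(
        out,
        columns=["gene_id", "comparison", "n_dm_cpgs", "weighted_meth_a",
                 "weighted_meth_b", "weighted_delta", "status"],
    )


def weighted_methylation_summary(matrix: MethylationMatrix) -> pd.DataFrame:
    """Fixed-effects summary of weighted methylation by sex x age.

    Inspection table: pooled weighted methylation over all sites per
    sex/age group, with replicate-level values alongside.
    """
    rows = []
    for sex in ("F", "M"):
        for age in sorted({s.age_days for s in matrix.samples if s.sex == sex}):
            idx = _group_columns(matrix.samples, sex, age)
            if not idx:
                continue
            reps = [
                weighted_methylation(matrix.meth[:, j], matrix.coverage[:, j])
                for j in idx
            ]
            rows.append({
                "sex": sex,
                "age_days": age,
                "n_replicates": len(idx),
                "weighted_methylation": weighted_methylation(
                    matrix.meth[:, idx].ravel(), matrix.coverage[:, idx].ravel()
                ),
                "replicate_mean": float(np.mean(reps)),
                "replicate_sd": float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
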