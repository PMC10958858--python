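"""From raw per-CpG counts to the methylated analysis set.

Order of operations mirrors the methylKit-style sequence: destrand
(merge top/bottom strand into one CpG) → per-sample coverage filter →
unite across samples → coverage normalisation → exact binomial
methylation call against the lambda-spike conversion-error rate, with
Benjamini–Hochberg control across all site×sample tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ValidationError
from .types import CpGSite, MethylationMatrix, SiteKey


# ---------------------------------------------------------------------------
# destranding
# ---------------------------------------------------------------------------

def merge_strands(sites: list[CpGSite]) -> list[CpGSite]:
    """Pool top- and bottom-strand cytosines of one CpG.

    A ``+`` strand C at position p pairs with the ``-`` strand C at
    p+1; their counts are summed and reported at p.  Unpaired sites pass
    through at their plus-strand-equivalent coordinate (a lone ``-``
    site at p is reported at p-1).  Input must still be stranded.
    """
    if any(s.strand == "merged" for s in sites):
        raise DataError(
            "input already strand-collapsed ('merged'); skip strand merging"
        )
    plus = {(s.chrom, s.pos): s for s in sites if s.strand == "+"}
    minus = {(s.chrom, s.pos): s for s in sites if s.strand == "-"}

    merged: dict[SiteKey, CpGSite] = {}
    for (chrom, pos), p_site in plus.items():
        m_site = minus.pop((chrom, pos + 1), None)
        meth = p_site.meth + (m_site.meth if m_site else 0)
        unmeth = p_site.unmeth + (m_site.unmeth if m_site else 0)
        merged[(chrom, pos)] = CpGSite(chrom, pos, "merged", meth, unmeth)
    for (chrom, pos), m_site in minus.items():  # unpaired bottom-strand
        if pos < 2:
            # a CpG's G cannot sit at position 1; no plus-strand coordinate
            raise DataError(f"unpaired bottom-strand site at {chrom}:{pos}")
        merged[(chrom, pos - 1)] = CpGSite(chrom, pos - 1, "merged",
                                           m_site.meth, m_site.unmeth)
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# conversion error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConversionError:
    """Bisulfite C→T non-conversion rate estimated from the lambda spike."""

    rate: float
    total_coverage: int
    total_meth: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValidationError(f"rate must lie in [0, 1], got {self.rate}")


def estimate_conversion_error(lambda_sites: list[CpGSite]) -> ConversionError:
    """Pooled Σmeth/Σcoverage over the unmethylated lambda genome.

    A zero estimate is replaced by half a pseudo-count (0.5/Σcoverage)
    so the binomial null stays non-degenerate.
    """
    if not lambda_sites:
        raise DataError("no lambda sites supplied")
    total_cov = sum(s.coverage for s in lambda_sites)
    total_meth = sum(s.meth for s in lambda_sites)
    if total_cov == 0:
        raise DataError("lambda sites have zero total coverage")
    rate = total_meth / total_cov
    if rate == 0.0:
        rate = 0.5 / total_cov
    return ConversionError(rate=rate, total_coverage=total_cov, total_meth=total_meth)


# ---------------------------------------------------------------------------
# coverage filter and normalisation
# ---------------------------------------------------------------------------

def filter_by_coverage(
    sites: list[CpGSite],
    min_cov: int = 10,
    upper_percentile: float = 99.0,
) -> list[CpGSite]:
    """Drop low-coverage and abnormally-high-coverage sites of one sample.

    Sites with coverage below ``min_cov`` are removed, as are sites
    strictly above the sample's empirical ``upper_percentile`` coverage
    (linear-interpolation percentile, computed on the pre-filter
    distribution).
    """
    if min_cov < 1:
        raise ValidationError(f"min_cov must be >= 1, got {min_cov}")
    if not sites:
        return []
    covs = np.array([s.coverage for s in sites], dtype=float)
    upper = np.percentile(covs, upper_percentile)  # type-7 percentile
    return [s for s in sites if s.coverage >= min_cov and s.coverage <= upper]


def normalize_coverage(matrix: MethylationMatrix) -> MethylationMatrix:
    """Scale each sample's counts to the maximum of the sample medians.

    Sample s gets factor f_s = M*/M_s with M_s its median coverage and
    M* the largest median; meth and unmeth counts are scaled and rounded
    half-up, preserving meth <= coverage.
    """
    medians = np.median(matrix.coverage, axis=0)
    if (medians == 0).any():
        bad = [matrix.sample_ids[j] for j in np.where(medians == 0)[0]]
        raise DataError(f"all-zero coverage in sample(s) {bad}")
    factors = medians.max() / medians

    def round_half_up(x: np.ndarray) -> np.ndarray:
        return np.floor(x + 0.5).astype(np.int64)

    meth = round_half_up(matrix.meth * factors[None, :])
    unmeth = round_half_up((matrix.coverage - matrix.meth) * factors[None, :])
    return MethylationMatrix(matrix.sites, matrix.samples, meth, meth + unmeth)


# ---------------------------------------------------------------------------
# binomial methylation call
# ---------------------------------------------------------------------------

@dataclass
class MethylationCallSet:
    """Per-cell binomial evidence of methylation above conversion error."""

    matrix: MethylationMatrix
    p: np.ndarray          # sites x samples upper-tail binomial p
    q: np.ndarray          # BH-adjusted across all cells jointly
    methylated: np.ndarray  # q < fdr
    fdr: float

    @property
    def methylated_in_any(self) -> np.ndarray:
        """Per-site flag: methylated in at least one sample."""
        return self.methylated.any(axis=1)

    def methylated_sites(self) -> list[SiteKey]:
        flags = self.methylated_in_any
        return [k for k, f in zip(self.matrix.sites, flags) if f]


def call_methylated(
    matrix: MethylationMatrix,
    err: ConversionError,
    fdr: float = 0.05,
) -> MethylationCallSet:
    """One-sided exact binomial test of each cell against the error rate.

    p = P(X >= meth | n = coverage, p0 = err.rate), upper tail: the null
    is that apparent methylation is pure non-conversion error, so only
    excess methylation is evidence.  BH is applied jointly across all
    site x sample cells; downstream analyses keep sites methylated in at
    least one sample.
    """
    if not (0.0 < err.rate < 1.0):
        raise ValidationError(f"error rate must lie in (0, 1), got {err.rate}")
    if not (0.0 < fdr < 1.0):
        raise ValidationError(f"fdr must lie in (0, 1), got {fdr}")
    if (matrix.coverage == 0).any():
        raise DataError("coverage-0 cell in a united matrix; unite with require_all")
    # upper tail P(X >= m) = sf(m - 1)
    p = stats.binom.sf(matrix.meth - 1, matrix.coverage, err.rate)
    p = np.minimum(p, 1.0)
    _, q_flat, _, _ = multipletests(p.ravel(), method="fdr_bh")
    q = q_flat.reshape(p.shape)
    return MethylationCallSet(matrix=matrix, p=p, q=q, methylated=q < fdr, fdr=fdr)
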