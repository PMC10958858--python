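"""Core domain containers.

Everything downstream operates on per-CpG methylated/unmethylated read
counts.  A :class:`CpGSite` is one cytosine (or a destranded CpG) in one
sample; a :class:`MethylationMatrix` holds the united counts for all
samples over a common, sorted site list.  Coordinates are 1-based
inclusive throughout; chromosome names are compared as exact strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

STRANDS = ("+", "-", "merged")

#: a site key: (chromosome, 1-based position)
SiteKey = tuple[str, int]


@dataclass(frozen=True)
class CpGSite:
    """Per-sample methylated/unmethylated read counts at one cytosine."""

    chrom: str
    pos: int
    strand: str
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValidationError(
                f"counts must be non-negative, got meth={self.meth} unmeth={self.unmeth}"
            )

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def fraction(self) -> float | None:
        """Methylation fraction meth/coverage; None where coverage is 0."""
        cov = self.coverage
        return self.meth / cov if cov > 0 else None

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class SampleRecord:
    """One WGBS library: identity, sex, chronological age and file path."""

    sample_id: str
    sex: str
    age_days: int
    replicate: int
    path: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_days < 0:
            raise ValidationError(f"age_days must be >= 0, got {self.age_days}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval (1-based inclusive) used for feature-level calls."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


#: mapping gene_id -> set of GO term identifiers
GOMap = dict[str, set]


class MethylationMatrix:
    """Sites x samples methylated-count and coverage matrices.

    Rows are unique ``(chrom, pos)`` keys sorted lexicographically by
    chromosome then position; columns follow the sample order given at
    construction.  ``0 <= meth <= coverage`` holds elementwise.
    """

    def __init__(
        self,
        sites: Sequence[SiteKey],
        samples: Sequence[SampleRecord],
        meth: np.ndarray,
        coverage: np.ndarray,
    ) -> None:
        sites = [(str(c), int(p)) for c, p in sites]
        meth = np.asarray(meth, dtype=np.int64)
        coverage = np.asarray(coverage, dtype=np.int64)
        if meth.shape != (len(sites), len(samples)) or coverage.shape != meth.shape:
            raise ValidationError(
                f"matrix shapes {meth.shape}/{coverage.shape} do not match "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        if sorted(set(sites)) != sites:
            raise ValidationError("site keys must be sorted by (chrom, pos) and unique")
        if (meth < 0).any() or (meth > coverage).any():
            raise ValidationError("requires 0 <= meth <= coverage elementwise")
        self.sites: list[SiteKey] = sites
        self.samples: list[SampleRecord] = list(samples)
        self.meth = meth
        self.coverage = coverage
        self._site_index = {k: i for i, k in enumerate(sites)}

    # -- basic queries ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def site_index(self, key: SiteKey) -> int:
        return self._site_index[(str(key[0]), int(key[1]))]

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def fractions(self) -> np.ndarray:
        """Methylation fractions; NaN where coverage is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.meth / self.coverage
        return np.where(self.coverage > 0, f, np.nan)

    # -- subsetting ---------------------------------------------------

    def subset_sites(self, keys: Iterable[SiteKey]) -> "MethylationMatrix":
        keys = sorted({(str(c), int(p)) for c, p in keys})
        idx = [self._site_index[k] for k in keys]
        return MethylationMatrix(keys, self.samples, self.meth[idx], self.coverage[idx])

    def select_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return MethylationMatrix(
            self.sites,
            [self.samples[i] for i in idx],
            self.meth[:, idx],
            self.coverage[:, idx],
        )

    # -- I/O ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data: dict = {
            "chrom": [c for c, _ in self.sites],
            "pos": [p for _, p in self.sites],
        }
        for j, sid in enumerate(self.sample_ids):
            data[f"{sid}.meth"] = self.meth[:, j]
            data[f"{sid}.cov"] = self.coverage[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, samples: Sequence[SampleRecord]) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t")
        sites = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
        meth = np.column_stack([df[f"{s.sample_id}.meth"] for s in samples])
        cov = np.column_stack([df[f"{s.sample_id}.cov"] for s in samples])
        return cls(sites, samples, meth, cov)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MethylationMatrix({self.n_sites} sites x {self.n_samples} samples)"


def format_site(key: SiteKey) -> str:
    return f"{key[0]}:{key[1]}"


def parse_site(text: str) -> SiteKey:
    chrom, _, pos = text.rpartition(":")
    return (chrom, int(pos))
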