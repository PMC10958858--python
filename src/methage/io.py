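"""Readers and writers for the formats the pipeline touches.

Supported inputs: Bismark coverage files (6-column TSV, strand-collapsed),
Bismark cytosine reports (7-column TSV, stranded), a TSV sample sheet,
GFF3 (or a BED-like 1-based TSV) gene annotation and a two-column
gene-to-GO TSV.  All coordinates are kept 1-based inclusive internally.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError, ParseError, ValidationError
from .types import CpGSite, GeneFeature, GOMap, MethylationMatrix, SampleRecord, SiteKey


# ---------------------------------------------------------------------------
# per-CpG count files
# ---------------------------------------------------------------------------

def read_coverage_file(path) -> list[CpGSite]:
    """Read a Bismark coverage file: chrom, start, end, %meth, meth, unmeth.

    The percentage column is ignored in favour of the raw counts, and the
    strand is set to ``merged`` (coverage files are strand-collapsed by
    convention).  ``start`` is taken as the position; start == end lines
    are accepted.
    """
    sites: list[CpGSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, _end, _pct, meth, unmeth = fields
            try:
                pos, m, u = int(start), int(meth), int(unmeth)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})")
            try:
                sites.append(CpGSite(chrom, pos, "merged", m, u))
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
    return sites


def write_coverage_file(sites: Iterable[CpGSite], path) -> None:
    """Write sites in the Bismark coverage dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        for s in sites:
            pct = 100.0 * s.meth / s.coverage if s.coverage > 0 else 0.0
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos}\t{pct:g}\t{s.meth}\t{s.unmeth}\n")


def read_cytosine_report(path, context_filter: str = "CpG") -> list[CpGSite]:
    """Read a Bismark cytosine report, keeping rows in ``context_filter``.

    Columns: chrom, pos, strand, meth, unmeth, context, trinucleotide.
    Strand is preserved as read; only ``+`` and ``-`` are legal.
    """
    sites: list[CpGSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}: line {lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context, _tri = fields
            if context != context_filter:
                continue
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: unknown strand symbol {strand!r}"
                )
            try:
                sites.append(CpGSite(chrom, int(pos), strand, int(meth), int(unmeth)))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
    return sites


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ("sample_id", "sex", "age_days", "replicate", "path")


def read_sample_sheet(path) -> list[SampleRecord]:
    """Read the TSV sample sheet (header sample_id/sex/age_days/replicate/path).

    Relative count-file paths are resolved against the sheet's directory,
    so a fixture directory is relocatable as a unit.
    """
    base = Path(path).parent
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"]
            if sid in seen:
                raise ParseError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            raw_path = row["path"] or None
            if raw_path and not Path(raw_path).is_absolute():
                raw_path = str(base / raw_path)
            try:
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        sex=row["sex"],
                        age_days=int(row["age_days"]),
                        replicate=int(row["replicate"]),
                        path=raw_path,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}: sample {sid!r}: {exc}")
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for s in samples:
            p = Path(s.path).name if s.path else ""
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.age_days}\t{s.replicate}\t{p}\n")


# ---------------------------------------------------------------------------
# uniting per-sample site lists
# ---------------------------------------------------------------------------

def unite(
    site_lists: Sequence[Sequence[CpGSite]],
    samples: Sequence[SampleRecord],
    require_all: bool = True,
) -> MethylationMatrix:
    """Assemble per-sample site lists into one counts matrix.

    With ``require_all`` (the default) rows are the intersection of the
    per-sample ``(chrom, pos)`` keys — the per-site models downstream need
    every library observed.  Otherwise rows are the union, with coverage 0
    where a sample lacks the site.
    """
    if len(site_lists) != len(samples):
        raise ValidationError(
            f"{len(site_lists)} site lists for {len(samples)} samples"
        )
    per_sample: list[dict[SiteKey, CpGSite]] = []
    for sample, sites in zip(samples, site_lists):
        d: dict[SiteKey, CpGSite] = {}
        for s in sites:
            if s.key in d:
                raise DataError(
                    f"sample {sample.sample_id}: duplicate site {s.chrom}:{s.pos}"
                )
            d[s.key] = s
        per_sample.append(d)

    keysets = [set(d) for d in per_sample]
    if require_all:
        keys = set.intersection(*keysets) if keysets else set()
    else:
        keys = set.union(*keysets) if keysets else set()
    sites = sorted(keys)

    meth = np.zeros((len(sites), len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for j, d in enumerate(per_sample):
        for i, k in enumerate(sites):
            s = d.get(k)
            if s is not None:
                meth[i, j] = s.meth
                cov[i, j] = s.coverage
    return MethylationMatrix(sites, samples, meth, cov)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path) -> list[GeneFeature]:
    """Read gene features from GFF3, or from a BED-like 1-based TSV.

    GFF3 lines are recognised by their 9 columns; only feature type
    ``gene`` is retained and the ``ID`` attribute is required.  The
    TSV dialect is ``gene_id chrom start end [strand]`` with 1-based
    inclusive coordinates.
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == 9:  # GFF3
                    chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
                    if ftype != "gene":
                        continue
                    attrd = _parse_gff3_attributes(attrs)
                    if "ID" not in attrd:
                        raise ParseError(
                            f"{path}: line {lineno}: gene record lacks an ID attribute"
                        )
                    gene_id = attrd["ID"].split(":")[-1]
                elif len(fields) in (4, 5):  # BED-like 1-based TSV
                    gene_id, chrom, start, end = fields[:4]
                    strand = fields[4] if len(fields) == 5 else "+"
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 9 (GFF3) or 4-5 (TSV) "
                        f"columns, got {len(fields)}"
                    )
                genes.append(
                    GeneFeature(gene_id, chrom, int(start), int(end),
                                strand if strand in ("+", "-") else "+")
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
            except ValidationError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
    return genes


def read_go_map(path) -> GOMap:
    """Read a 2-column gene_id -> GO-term TSV, aggregating terms per gene."""
    go: GOMap = defaultdict(set)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[1]:
                raise ParseError(
                    f"{path}: line {lineno}: expected gene_id<TAB>GO_term"
                )
            go[fields[0]].add(fields[1])
    return dict(go)


def write_go_map(go: GOMap, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go):
            for term in sorted(go[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotations(gff_path, go_path) -> tuple[list[GeneFeature], GOMap]:
    """Read the gene annotation and the GO map together."""
    return read_gene_annotation(gff_path), read_go_map(go_path)


def write_gene_annotation(genes: Sequence[GeneFeature], path) -> None:
    """Write genes as minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tmethage\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
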