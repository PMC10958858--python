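"""Synthetic WGBS methylome generator.

Emulates the study design the downstream statistics assume: two sexes x
three timepoints (day 0, 8, 16) x three replicate libraries of pooled
individuals, with per-CpG counts drawn from a beta-binomial parameterised
by mean ``mu`` and precision ``phi`` (shape1 = mu*phi, shape2 =
(1-mu)*phi), so that age-increasing variability ("drift") is a pure
``phi`` effect while mean trends live in ``mu``.

Site classes
------------
``null_unmeth``
    True methylation equals the bisulfite non-conversion error; the bulk
    of the genome.  Precision is effectively infinite (read-sampling
    noise only), mirroring the binomial lambda spike.
``stable``
    Constant mid-range methylation, no age effect — the null class for
    differential-methylation error control.
``dmp_hyper`` / ``dmp_hypo``
    Linear age trend on the logit scale, rising from a low baseline
    (hyper) or falling from a high one (hypo).  Default slopes give a
    day-0 to day-16 difference of ~0.30 on the proportion scale, and the
    trends point toward 0.5 so the differentially methylated compartment
    becomes more entropic with age, as a mostly-unmethylated genome
    gaining methylation does.
``vmp``
    Constant mean, precision interpolating ``phi_young -> phi_old`` with
    age: the variably-methylated (heteroscedastic) class.
``clock``
    Deterministic linear mean trend (slope per day on the proportion
    scale) with small beta-binomial noise — the signal an elastic-net
    age predictor can exploit.

A 1% -style unmethylated lambda spike is emitted on a separate
chromosome (``lambda``) with binomial(coverage, conversion_error)
counts, exercising conversion-error estimation end to end.

Each site class draws from its own seeded substream, so changing the
size of one class never reshuffles the counts of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError
from .io import write_coverage_file, write_sample_sheet
from .types import CpGSite, GeneFeature, GOMap, SampleRecord, format_site, parse_site

DEFAULT_DESIGN = (
    ("F", 0, 3), ("F", 8, 3), ("F", 16, 3),
    ("M", 0, 3), ("M", 8, 3), ("M", 16, 3),
)

# fixed substream ids per class (order must never change)
_CLASS_STREAMS = {
    "null_unmeth": 1,
    "stable": 2,
    "dmp_hyper": 3,
    "dmp_hypo": 4,
    "vmp": 5,
    "clock": 6,
    "lambda": 7,
    "annotation": 9,
}

SITE_CLASSES = ("null_unmeth", "stable", "dmp_hyper", "dmp_hypo", "vmp", "clock")

TRUTH_COLUMNS = ("site_key", "class", "mu_params", "phi_params")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment."""

    seed: int = 0
    design: tuple = DEFAULT_DESIGN
    n_null_unmethylated: int = 15000
    n_stable_methylated: int = 2000
    n_dmp_hyper: int = 200
    n_dmp_hypo: int = 200
    n_vmp: int = 300
    n_clock: int = 40
    #: logit-units per day; with the default baselines this gives a
    #: day0->day16 proportion difference of ~0.30 (0.15->0.45, 0.85->0.55)
    dmp_slope: float = 0.0959
    dmp_mu0_hyper: float = 0.15
    dmp_mu0_hypo: float = 0.85
    #: which sexes carry the DMP age trend ("both", "F" or "M")
    dmp_sex: str = "both"
    #: (phi_young, phi_old) precision schedule for the drift class
    precision_schedule: tuple = (80.0, 10.0)
    #: precision for the stable/dmp classes
    phi_stable: float = 80.0
    #: precision for the near-deterministic clock class
    phi_clock: float = 300.0
    #: precision for the unmethylated bulk (effectively binomial)
    phi_null: float = 1e6
    clock_slope: float = 0.02
    coverage_mean: float = 30.0
    coverage_dispersion: float = 20.0
    conversion_error: float = 0.005
    lambda_n_sites: int = 200
    lambda_coverage: float = 30.0
    chrom: str = "chrS"
    lambda_chrom: str = "lambda"
    site_spacing: int = 50

    def validate(self) -> None:
        counts = (
            self.n_null_unmethylated, self.n_stable_methylated, self.n_dmp_hyper,
            self.n_dmp_hypo, self.n_vmp, self.n_clock, self.lambda_n_sites,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("site-class counts must be non-negative")
        if not (0.0 < self.conversion_error <= 0.05):
            raise ValidationError(
                f"conversion_error must lie in (0, 0.05], got {self.conversion_error}"
            )
        phi_young, phi_old = self.precision_schedule
        if not (phi_young > phi_old > 0):
            raise ValidationError(
                f"precision schedule requires phi_young > phi_old > 0, got "
                f"{self.precision_schedule}"
            )
        if self.coverage_mean <= 0 or self.lambda_coverage <= 0:
            raise ValidationError("coverage means must be positive")
        if self.coverage_dispersion <= 0:
            raise ValidationError("coverage_dispersion must be positive")
        if self.dmp_sex not in ("both", "F", "M"):
            raise ValidationError(f"dmp_sex must be both/F/M, got {self.dmp_sex!r}")
        if not self.design:
            raise ValidationError("design must list at least one (sex, age, n) cell")
        for sex, age, n in self.design:
            if sex not in ("F", "M") or age < 0 or n < 1:
                raise ValidationError(f"invalid design cell {(sex, age, n)}")

    def samples(self) -> list[SampleRecord]:
        out = []
        for sex, age, n in self.design:
            for rep in range(1, n + 1):
                out.append(SampleRecord(f"{sex}{age}d_r{rep}", sex, age, rep))
        return out


@dataclass
class SimulatedExperiment:
    """Per-sample site lists, the sample sheet, and the ground truth."""

    config: SimulationConfig
    samples: list[SampleRecord]
    site_lists: dict[str, list[CpGSite]]
    truth: pd.DataFrame


def _class_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _CLASS_STREAMS[name]]))


def _draw_coverage(rng, mean: float, dispersion: float, shape) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=shape)
    return np.maximum(cov, 1)  # truncation at >= 1


def _beta_binomial(rng, cov, mu, phi) -> np.ndarray:
    mu = np.clip(mu, 1e-9, 1 - 1e-9)
    p = rng.beta(mu * phi, (1.0 - mu) * phi)
    return rng.binomial(cov, p)


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate counts for every site class under ``config``.

    Identical configs (same seed) give identical output, file for file.
    """
    config.validate()
    samples = config.samples()
    ages = np.array([s.age_days for s in samples], dtype=float)
    is_f = np.array([s.sex == "F" for s in samples])
    n_samp = len(samples)
    max_age = ages.max() if ages.max() > 0 else 1.0
    phi_young, phi_old = config.precision_schedule

    sex_mask = {
        "both": np.ones(n_samp, dtype=bool),
        "F": is_f,
        "M": ~is_f,
    }[config.dmp_sex]

    blocks: list[tuple[str, np.ndarray, np.ndarray, dict, dict]] = []

    def meth_matrix(name, n_sites, site_fn):
        """site_fn(rng, i) -> (per-sample mu, phi, truth-info dict)."""
        if n_sites == 0:
            return
        rng = _class_rng(config.seed, name)
        cov = _draw_coverage(rng, config.coverage_mean, config.coverage_dispersion,
                             (n_sites, n_samp))
        meth = np.empty_like(cov)
        mus, phis, infos = [], [], []
        for i in range(n_sites):
            mu, phi, info = site_fn(rng, i)
            mus.append(mu)
            phis.append(phi)
            infos.append(info)
        for i in range(n_sites):
            meth[i] = _beta_binomial(rng, cov[i], mus[i], phis[i])
        blocks.append((name, meth, cov, infos, {}))

    # null_unmeth: mu = conversion error, effectively binomial
    meth_matrix(
        "null_unmeth", config.n_null_unmethylated,
        lambda rng, i: (
            np.full(n_samp, config.conversion_error),
            config.phi_null,
            {"mu": config.conversion_error, "phi": config.phi_null},
        ),
    )

    # stable: constant mid-range methylation
    def stable_mu(rng, i):
        mu = rng.uniform(0.2, 0.8)
        return np.full(n_samp, mu), config.phi_stable, {"mu": mu, "phi": config.phi_stable}

    meth_matrix("stable", config.n_stable_methylated, stable_mu)

    # dmp classes: logit-linear age trend in the configured sexes
    def dmp_mu(mu0, slope):
        base = _logit(mu0)

        def fn(rng, i):
            eta = base + slope * ages
            eta = np.where(sex_mask, eta, base)
            mu = 1.0 / (1.0 + np.exp(-eta))
            return mu, config.phi_stable, {
                "mu0": mu0, "logit_slope": slope, "sexes": config.dmp_sex,
                "phi": config.phi_stable,
            }
        return fn

    meth_matrix("dmp_hyper", config.n_dmp_hyper,
                dmp_mu(config.dmp_mu0_hyper, config.dmp_slope))
    meth_matrix("dmp_hypo", config.n_dmp_hypo,
                dmp_mu(config.dmp_mu0_hypo, -config.dmp_slope))

    # vmp: constant mean, precision decaying with age
    def vmp_mu(rng, i):
        mu = rng.uniform(0.35, 0.65)
        phi = phi_young + (phi_old - phi_young) * ages / max_age
        return np.full(n_samp, mu), phi, {
            "mu": mu, "phi_young": phi_young, "phi_old": phi_old,
        }

    meth_matrix("vmp", config.n_vmp, vmp_mu)

    # clock: deterministic proportion-scale trend, tight precision
    def clock_mu(rng, i):
        base = rng.uniform(0.10, 0.55)
        mu = np.clip(base + config.clock_slope * ages, 0.02, 0.98)
        return mu, config.phi_clock, {
            "base": base, "slope": config.clock_slope, "phi": config.phi_clock,
        }

    meth_matrix("clock", config.n_clock, clock_mu)

    # assemble genome positions per block, in class order
    site_lists: dict[str, list[CpGSite]] = {s.sample_id: [] for s in samples}
    truth_rows = []
    pos = 1
    for name, meth, cov, infos, _ in blocks:
        for i in range(meth.shape[0]):
            info = infos[i]
            mu_params = ";".join(
                f"{k}={info[k]!r}" for k in info if not k.startswith("phi")
            )
            phi_params = ";".join(f"{k}={info[k]!r}" for k in info if k.startswith("phi"))
            truth_rows.append((format_site((config.chrom, pos)), name,
                               mu_params, phi_params))
            for j, s in enumerate(samples):
                m = int(meth[i, j])
                site_lists[s.sample_id].append(
                    CpGSite(config.chrom, pos, "merged", m, int(cov[i, j]) - m)
                )
            pos += config.site_spacing

    # lambda spike: pure binomial at the conversion-error rate
    if config.lambda_n_sites:
        rng = _class_rng(config.seed, "lambda")
        lcov = _draw_coverage(rng, config.lambda_coverage, config.coverage_dispersion,
                              (config.lambda_n_sites, n_samp))
        lmeth = rng.binomial(lcov, config.conversion_error)
        for i in range(config.lambda_n_sites):
            lpos = 1 + i * config.site_spacing
            for j, s in enumerate(samples):
                m = int(lmeth[i, j])
                site_lists[s.sample_id].append(
                    CpGSite(config.lambda_chrom, lpos, "merged", m, int(lcov[i, j]) - m)
                )

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return SimulatedExperiment(config, samples, site_lists, truth)


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV (lossless round trip)."""
    if truth is None or len(truth) == 0:
        raise DataError("refusing to write an empty truth table")
    truth.loc[:, list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns) != list(TRUTH_COLUMNS):
        raise DataError(f"{path}: unexpected truth columns {list(df.columns)}")
    return df


def truth_classes(truth: pd.DataFrame) -> dict[str, set]:
    """Map class label -> set of (chrom, pos) site keys."""
    out: dict[str, set] = {}
    for cls, grp in truth.groupby("class"):
        out[cls] = {parse_site(k) for k in grp["site_key"]}
    return out


# ---------------------------------------------------------------------------
# synthetic annotation (genes + GO) over the simulated chromosome
# ---------------------------------------------------------------------------

def make_annotation(
    experiment: SimulatedExperiment,
    genes_span: int = 10,
    n_background_terms: int = 40,
) -> tuple[list[GeneFeature], GOMap]:
    """Tile the simulated chromosome with synthetic genes and GO terms.

    Genes cover ``genes_span`` consecutive CpGs each.  Every gene gets a
    few uniformly drawn background terms; genes falling inside an
    age-responsive block additionally get class-flavoured terms with
    probability 0.6, so enrichment has signal to find.
    """
    cfg = experiment.config
    rng = _class_rng(cfg.seed, "annotation")
    truth = experiment.truth
    keys = [parse_site(k) for k in truth["site_key"]]
    classes = list(truth["class"])

    flavour = {
        "dmp_hyper": ["GO:1000001", "GO:1000002"],
        "dmp_hypo": ["GO:1000003", "GO:1000004"],
        "vmp": ["GO:1000005", "GO:1000006"],
        "clock": ["GO:1000007", "GO:1000008"],
    }
    background = [f"GO:{i:07d}" for i in range(1, n_background_terms + 1)]

    genes: list[GeneFeature] = []
    go: GOMap = {}
    for gi, start_idx in enumerate(range(0, len(keys), genes_span)):
        block = keys[start_idx:start_idx + genes_span]
        block_classes = set(classes[start_idx:start_idx + genes_span])
        gene_id = f"g{gi + 1:05d}"
        genes.append(
            GeneFeature(gene_id, cfg.chrom, block[0][1], block[-1][1], "+")
        )
        terms = set(rng.choice(background, size=rng.integers(2, 5), replace=False))
        for cls in block_classes:
            if cls in flavour and rng.random() < 0.6:
                terms.update(flavour[cls])
        go[gene_id] = terms
    return genes, go


# ---------------------------------------------------------------------------
# writing the whole experiment
# ---------------------------------------------------------------------------

def write_experiment(
    experiment: SimulatedExperiment,
    outdir,
    with_annotation: bool = True,
) -> dict[str, Path]:
    """Write coverage files, sample sheet, truth table (and annotation).

    Returns a name -> path map of everything written.  Reruns with the
    same config are byte-identical.
    """
    from .io import write_gene_annotation, write_go_map  # local: avoid cycle noise

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    samples = []
    for s in experiment.samples:
        cov_path = outdir / f"{s.sample_id}.cov"
        write_coverage_file(experiment.site_lists[s.sample_id], cov_path)
        samples.append(replace(s, path=str(cov_path)))
        paths[s.sample_id] = cov_path
    sheet = outdir / "sample_sheet.tsv"
    write_sample_sheet(samples, sheet)
    paths["sample_sheet"] = sheet
    truth_path = outdir / "truth.tsv"
    write_truth(experiment.truth, truth_path)
    paths["truth"] = truth_path
    if with_annotation:
        genes, go = make_annotation(experiment)
        gff = outdir / "genes.gff3"
        gomap = outdir / "go_map.tsv"
        write_gene_annotation(genes, gff)
        write_go_map(go, gomap)
        paths["genes"] = gff
        paths["go_map"] = gomap
    return paths
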