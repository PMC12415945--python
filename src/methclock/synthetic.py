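"""Synthetic methylation cohorts with planted age signal.

The generator emulates the statistical shape of reduced-representation
bisulphite data from a wild bird population: per-sample CpG call sets that
differ through dropout, per-site coverage with a heavy right tail, strand-
split counts, and a minority of CpGs whose methylation drifts logit-linearly
with age (hyper- or hypomethylation) among a majority of age-invariant sites.

Model, per CpG ``j`` and sample ``i``::

    p_ij   = expit(baseline_j + slope_j * epigenetic_age_i)
    cov_ij ~ 1 + NegativeBinomial(coverage_dispersion, coverage_mean - 1)
    meth_ij ~ Binomial(cov_ij, p_ij)

with the coverage split ``Binomial(cov, 0.5)`` between strands and the
methylated reads allocated hypergeometrically, so strand records are
consistent with the site totals.  ``epigenetic_age`` is the chronological age
plus the treatment's additive shift; with all shifts zero the two coincide.

Baselines are drawn from a three-component mixture (near-0, near-1 and
intermediate methylation) so that the downstream variability filter removes a
realistic fraction of sites.  Age-associated CpGs are planted among the
intermediate component, where a logit-linear trend is observable.

Determinism: one master seed; per-sample substreams derive from
``numpy.random.SeedSequence(seed).spawn``, so the same config yields
byte-identical call files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CALL_COLUMNS, read_calls, write_calls

__all__ = [
    "AgesYears",
    "AgesDays",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "simulate_cohort",
    "summarize_site_counts",
    "simulate_treatment_cohort",
]


@dataclass(frozen=True)
class AgesYears:
    """Continuous ages in years, uniform on [min_years, max_years] (adults)."""

    min_years: float = 0.13
    max_years: float = 6.03

    @property
    def degenerate(self) -> bool:
        return self.max_years <= self.min_years

    unit = "years"


@dataclass(frozen=True)
class AgesDays:
    """Integer ages in days drawn uniformly from ``values`` (nestlings)."""

    values: tuple[int, ...] = tuple(range(6, 16))

    @property
    def degenerate(self) -> bool:
        return len(set(self.values)) < 2

    unit = "days"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated methylation cohort.

    Defaults describe a modest adult cohort: uniform ages over the range
    observed in a long-lived nest-box population (0.13–6.03 years), deep
    coverage (mean 50 reads per site, negative-binomial with dispersion 10,
    giving a heavy right tail while keeping nearly all sites above a 10x
    floor), and ~7% of CpGs carrying a logit-linear age trend of roughly
    0.35 logit-units per year, comparable to the strongest clock CpGs.
    """

    n_samples: int = 40
    age_model: AgesYears | AgesDays = field(default_factory=AgesYears)
    n_cpgs: int = 1000
    n_age_cpgs: int = 70
    slope_scale: float = 0.35
    baseline_concentration: float = 10.0
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    dropout_rate: float = 0.0
    n_chromosomes: int = 10
    brood_size: int = 4
    treatment_levels: tuple[str, ...] = ("control",)
    treatment_shift: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1 or self.n_samples < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")
        if self.brood_size < 1:
            raise ValueError("brood_size must be positive")
        if not (0 <= self.n_age_cpgs <= self.n_cpgs):
            raise ValueError("n_age_cpgs must lie in [0, n_cpgs]")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.coverage_mean <= 1 or self.coverage_dispersion <= 0:
            raise ValueError("coverage_mean must exceed 1, dispersion be positive")
        if self.slope_scale < 0 or self.baseline_concentration <= 0:
            raise ValueError("slope_scale >= 0 and baseline_concentration > 0 required")
        if self.n_age_cpgs > 0 and self.age_model.degenerate:
            raise ValueError(
                "age model spans a single age: age-associated CpGs are "
                "unrecoverable; widen the age range or set n_age_cpgs = 0"
            )
        unknown = set(self.treatment_shift) - set(self.treatment_levels)
        if unknown:
            raise ValueError(f"treatment_shift for unknown levels: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters of a simulated cohort, for recovery tests."""

    site_id: np.ndarray          # "chrom:pos" per CpG
    chromosome: np.ndarray       # chromosome label per CpG
    position: np.ndarray         # forward-strand C coordinate per CpG
    baseline_logit: np.ndarray   # logit methylation at age 0 per CpG
    slope: np.ndarray            # logit-units per age-unit; 0 = not age-associated
    epigenetic_age: pd.Series    # per sample: chronological age + treatment shift

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "baseline_logit": self.baseline_logit,
                "slope": self.slope,
            }
        )


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: per-sample call tables, metadata and ground truth."""

    calls: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    truth: GroundTruth


# mixture weights of the baseline-methylation components (near-0 / near-1 /
# intermediate); bisulphite data is strongly bimodal with a thin middle
_BASELINE_WEIGHTS = (0.3, 0.3, 0.4)


def _draw_baselines(
    rng: np.random.Generator, n: int, kappa: float
) -> tuple[np.ndarray, np.ndarray]:
    comp = rng.choice(3, size=n, p=_BASELINE_WEIGHTS)
    m = np.empty(n)
    m[comp == 0] = rng.beta(1.0, kappa, size=int((comp == 0).sum()))
    m[comp == 1] = rng.beta(kappa, 1.0, size=int((comp == 1).sum()))
    m[comp == 2] = rng.beta(kappa / 4.0, kappa / 4.0, size=int((comp == 2).sum()))
    return np.clip(m, 1e-3, 1 - 1e-3), comp


def _draw_coverage(
    rng: np.random.Generator, n: int, mean: float, dispersion: float
) -> np.ndarray:
    # shifted NB keeps every record's coverage >= 1 while preserving the
    # heavy right tail; parameterised by mean of the NB part = mean - 1
    mu = mean - 1.0
    p = dispersion / (dispersion + mu)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> Cohort:
    """Simulate a methylation cohort.

    Returns per-sample strand-resolved call tables (the format consumed by
    the filtering pipeline), a metadata table (sample, age, age_unit, sex,
    brood, treatment) and the planted :class:`GroundTruth`.  If ``out_dir``
    is given, one ``<sample>.calls.tsv`` per sample plus ``metadata.tsv`` and
    ``truth.tsv`` are written there.
    """
    root = np.random.SeedSequence(config.seed)
    cohort_ss, *sample_ss = root.spawn(config.n_samples + 1)
    rng = np.random.default_rng(cohort_ss)

    # --- CpG map: chromosome sizes decay linearly, positions spaced >= 2 so
    # complementary pairs of neighbouring CpGs never collide
    sizes = np.linspace(2.0, 1.0, config.n_chromosomes)
    chrom_of = rng.choice(
        config.n_chromosomes, size=config.n_cpgs, p=sizes / sizes.sum()
    )
    chrom_of.sort()
    chrom_labels = np.array([f"chr{c + 1}" for c in chrom_of])
    position = np.empty(config.n_cpgs, dtype=np.int64)
    for c in range(config.n_chromosomes):
        mask = chrom_of == c
        gaps = rng.integers(2, 200, size=int(mask.sum()))
        position[mask] = 1 + np.cumsum(gaps)
    site_id = np.array(
        [f"{c}:{p}" for c, p in zip(chrom_labels, position)], dtype=object
    )

    baseline_m, comp = _draw_baselines(
        rng, config.n_cpgs, config.baseline_concentration
    )
    baseline = logit(baseline_m)

    slope = np.zeros(config.n_cpgs)
    if config.n_age_cpgs:
        mid = np.flatnonzero(comp == 2)
        pool = mid if mid.size >= config.n_age_cpgs else np.arange(config.n_cpgs)
        age_idx = rng.choice(pool, size=config.n_age_cpgs, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_age_cpgs)
        slope[age_idx] = signs * config.slope_scale * rng.uniform(
            0.5, 1.5, size=config.n_age_cpgs
        )

    # --- sample frame: ages, sex, brood blocks, treatment assigned per brood
    if isinstance(config.age_model, AgesYears):
        ages = rng.uniform(
            config.age_model.min_years, config.age_model.max_years, config.n_samples
        ).round(2)
    else:
        ages = rng.choice(config.age_model.values, size=config.n_samples).astype(float)
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    brood = np.arange(config.n_samples) // config.brood_size
    levels = list(config.treatment_levels)
    treatment = np.array([levels[b % len(levels)] for b in brood], dtype=object)
    shift = np.array(
        [float(config.treatment_shift.get(t, 0.0)) for t in treatment]
    )
    epi_age = ages + shift
    sex = rng.choice(["F", "M"], size=config.n_samples)
    metadata = pd.DataFrame(
        {
            "sample": sample_ids,
            "age": ages,
            "age_unit": config.age_model.unit,
            "sex": sex,
            "brood": [f"B{b:03d}" for b in brood],
            "treatment": treatment,
        }
    )
    truth = GroundTruth(
        site_id=site_id,
        chromosome=chrom_labels,
        position=position,
        baseline_logit=baseline,
        slope=slope,
        epigenetic_age=pd.Series(epi_age, index=sample_ids, name="epigenetic_age"),
    )

    calls: dict[str, pd.DataFrame] = {}
    for i, sid in enumerate(sample_ids):
        srng = np.random.default_rng(sample_ss[i])
        keep = (
            srng.random(config.n_cpgs) >= config.dropout_rate
            if config.dropout_rate > 0
            else np.ones(config.n_cpgs, dtype=bool)
        )
        idx = np.flatnonzero(keep)
        cov = _draw_coverage(
            srng, idx.size, config.coverage_mean, config.coverage_dispersion
        )
        p = expit(baseline[idx] + slope[idx] * epi_age[i])
        meth = srng.binomial(cov, p)
        cov_f = srng.binomial(cov, 0.5)
        meth_f = srng.hypergeometric(meth, cov - meth, cov_f)
        cov_r = cov - cov_f
        meth_r = meth - meth_f

        fwd = cov_f >= 1
        rev = cov_r >= 1
        chroms = np.concatenate([chrom_labels[idx][fwd], chrom_labels[idx][rev]])
        poss = np.concatenate([position[idx][fwd], position[idx][rev] + 1])
        strands = np.concatenate(
            [np.full(int(fwd.sum()), "+"), np.full(int(rev.sum()), "-")]
        )
        meths = np.concatenate([meth_f[fwd], meth_r[rev]])
        unmeths = np.concatenate(
            [(cov_f - meth_f)[fwd], (cov_r - meth_r)[rev]]
        )
        table = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": poss.astype(np.int64),
                "strand": strands,
                "meth": meths.astype(np.int64),
                "unmeth": unmeths.astype(np.int64),
            }
        ).sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)
        calls[sid] = table[CALL_COLUMNS]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, table in calls.items():
            write_calls(table, out / f"{sid}.calls.tsv")
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        tf = truth.frame()
        tf.to_csv(out / "truth.tsv", sep="\t", index=False)
        truth.epigenetic_age.rename_axis("sample").to_csv(
            out / "epigenetic_age.tsv", sep="\t"
        )
    return Cohort(calls=calls, metadata=metadata, truth=truth)


def summarize_site_counts(
    calls: Mapping[str, pd.DataFrame] | str | Path,
) -> pd.Series:
    """Unique CpG positions per sample, counting complementary pairs once.

    Accepts either in-memory call tables or a directory of
    ``*.calls.tsv`` files.

    Raises
    ------
    MethylationParseError
        If a file in the directory cannot be parsed.
    """
    if not isinstance(calls, Mapping):
        directory = Path(calls)
        tables = {}
        for path in sorted(directory.glob("*.calls.tsv")):
            tables[path.name.removesuffix(".calls.tsv")] = read_calls(path)
        calls = tables
    counts = {}
    for sample, table in calls.items():
        if table.empty:
            counts[sample] = 0
            continue
        key = table["pos"].to_numpy(np.int64) - (
            table["strand"] == "-"
        ).to_numpy(np.int64)
        counts[sample] = int(
            pd.MultiIndex.from_arrays([table["chrom"], key]).nunique()
        )
    return pd.Series(counts, name="n_cpgs", dtype=np.int64)


def simulate_treatment_cohort(
    n_broods: int = 32,
    brood_size: int = 3,
    shifts: Mapping[str, float] | None = None,
    brood_sd: float = 0.3,
    resid_sd: float = 0.8,
    base_age: float = 13.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate estimated epigenetic ages under a brood-manipulation design.

    Each brood receives one treatment (cycled over the shift keys) and a
    shared random intercept ``N(0, brood_sd**2)``; nestling epigenetic age is
    ``base_age + shift + brood effect + N(0, resid_sd**2)``.  Returns a tidy
    frame with columns sample, brood, treatment, epi_age — the direct input
    of the treatment mixed model.
    """
    if shifts is None:
        shifts = {"control": 0.0, "enlarged": 0.25, "reduced": 0.6}
    rng = np.random.default_rng(seed)
    levels = list(shifts)
    rows = []
    for b in range(n_broods):
        treatment = levels[b % len(levels)]
        u = rng.normal(0.0, brood_sd)
        for k in range(brood_size):
            rows.append(
                {
                    "sample": f"N{b:03d}_{k}",
                    "brood": f"B{b:03d}",
                    "treatment": treatment,
                    "epi_age": base_age
                    + shifts[treatment]
                    + u
                    + rng.normal(0.0, resid_sd),
                }
            )
    return pd.DataFrame(rows)
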