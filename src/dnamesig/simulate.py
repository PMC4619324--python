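"""Synthetic methylation cohorts with planted signal.

Generates cohorts carrying the statistical structure the downstream analysis
assumes: per-probe beta values from Beta distributions around probe-specific
baseline means, a planted subset of probes whose marker-positive group mean is
shifted by +delta (hypermethylated) or -delta (hypomethylated), and survival
from an exponential proportional-hazards model in which the marker's hazard
ratio depends on the treatment arm, with independent exponential censoring.

The exponential choice gives closed-form sanity checks (event fraction,
expected log hazard ratio); no particular parametric survival family is
claimed for real tumours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    BetaMatrix,
    Cohort,
    SampleAnnotation,
    TREATMENTS,
    ValidationError,
    write_beta_matrix,
    write_sample_sheet,
)


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Sample sizes default to a discovery-scale cohort; probe count defaults to
    2,000, a desk-scale stand-in for a 27k array.  ``delta`` is the planted
    group difference in mean beta, ``precision`` the Beta-distribution
    concentration (higher = less per-probe noise), and
    ``hr_marker_by_treatment`` maps each arm to the hazard ratio of
    marker-positive versus marker-negative samples.
    """

    n_pos: int = 35
    n_neg: int = 28
    n_probes: int = 2000
    n_informative: int = 50
    frac_hyper: float = 0.5
    delta: float = 0.2
    precision: float = 50.0
    baseline_mean_range: tuple[float, float] = (0.2, 0.8)
    hr_marker_by_treatment: dict[str, float] = field(
        default_factory=lambda: {"carboplatin": 3.5, "cisplatin": 1.0, "none": 1.0}
    )
    baseline_hazard: float = 0.15
    censor_rate: float = 0.08
    treatment_probs: dict[str, float] = field(
        default_factory=lambda: {"carboplatin": 0.47, "cisplatin": 0.41, "none": 0.12}
    )
    missing_rate: float = 0.0
    seed: int = 0
    #: seed for probe-level population structure (baseline means, planted
    #: probe identities/directions).  Cohorts sharing a population_seed share
    #: the same underlying biology, as discovery and validation cohorts drawn
    #: from the same disease population would; None means use ``seed``.
    population_seed: int | None = None

    def validate(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_probes) <= 0 or self.n_informative < 0:
            raise ConfigError("sample and probe counts must be positive")
        if self.n_informative > self.n_probes:
            raise ConfigError("n_informative exceeds n_probes")
        if not 0.0 <= self.frac_hyper <= 1.0:
            raise ConfigError("frac_hyper must lie in [0, 1]")
        if not 0.0 <= self.delta <= 0.5:
            raise ConfigError("delta must lie in [0, 0.5]")
        lo, hi = self.baseline_mean_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("baseline_mean_range must be inside (0, 1)")
        # baseline means are drawn from the open interval, so equality at the
        # range endpoints is safe; only a strict overshoot is a config error
        if self.delta > 0 and (lo - self.delta < 0.0 or hi + self.delta > 1.0):
            raise ConfigError(
                f"delta={self.delta} pushes target means outside (0, 1) for "
                f"baseline_mean_range={self.baseline_mean_range}"
            )
        if set(self.treatment_probs) - set(TREATMENTS):
            raise ConfigError(f"treatment_probs keys must be among {TREATMENTS}")
        if abs(sum(self.treatment_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("treatment_probs must sum to 1")
        if set(self.hr_marker_by_treatment) != set(TREATMENTS):
            raise ConfigError(f"hr_marker_by_treatment must cover {TREATMENTS}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.precision <= 0 or self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ConfigError("precision/baseline_hazard must be > 0, censor_rate >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["baseline_mean_range"] = list(self.baseline_mean_range)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "baseline_mean_range" in d:
            d["baseline_mean_range"] = tuple(d["baseline_mean_range"])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    informative_probes: dict[str, int]  # probe_id -> +1 (hyper) / -1 (hypo)
    marker_status: dict[str, str]  # sample_id -> positive/negative
    hr_marker_by_treatment: dict[str, float]


def simulate_cohort(config: SimulationConfig, name: str = "synthetic") -> tuple[Cohort, SimulationTruth]:
    """Draw one cohort and its ground truth from ``config``.

    Betas: probe ``j`` has baseline mean ``m_j ~ U(baseline_mean_range)``;
    each value is Beta-distributed with that mean and concentration
    ``precision``.  Informative probes shift the positive-group mean to
    ``m_j + delta`` (hyper) or ``m_j - delta`` (hypo).  Survival: death time
    ~ Exp(baseline_hazard x HR^marker) with the arm-specific HR; censoring
    ~ Exp(censor_rate); observed time is the minimum (floored away from zero),
    event = 1 iff death came first.  The same seed reproduces the cohort
    byte-identically.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pop_rng = np.random.default_rng(
        config.seed if config.population_seed is None else config.population_seed
    )
    n = config.n_pos + config.n_neg
    sample_ids = [f"S{i:04d}" for i in range(n)]
    probe_ids = [f"cg{j:06d}" for j in range(config.n_probes)]
    is_pos = np.array([True] * config.n_pos + [False] * config.n_neg)

    baseline = pop_rng.uniform(*config.baseline_mean_range, size=config.n_probes)
    n_hyper = int(round(config.frac_hyper * config.n_informative))
    directions = np.zeros(config.n_probes, dtype=int)
    informative = pop_rng.choice(config.n_probes, size=config.n_informative, replace=False)
    directions[informative[:n_hyper]] = 1
    directions[informative[n_hyper:]] = -1

    # per-cell target mean, then Beta draw with fixed concentration
    mu = np.tile(baseline[:, None], (1, n))
    mu[:, is_pos] += config.delta * directions[:, None]
    if (mu <= 0).any() or (mu >= 1).any():
        raise ConfigError("a planted target mean landed outside (0, 1)")
    a = mu * config.precision
    b = (1.0 - mu) * config.precision
    values = rng.beta(a, b)
    # Beta draws are in (0,1) a.s.; clip floating underflow away from the edges
    np.clip(values, 1e-12, 1 - 1e-12, out=values)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    arms = list(config.treatment_probs)
    probs = np.array([config.treatment_probs[t] for t in arms])
    treatment = rng.choice(arms, size=n, p=probs)
    hr = np.array([config.hr_marker_by_treatment[t] for t in treatment])
    hazard = config.baseline_hazard * np.where(is_pos, hr, 1.0)
    death = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    time = np.maximum(np.minimum(death, censor), 1e-6)
    event = (death <= censor).astype(int)

    samples = [
        SampleAnnotation(
            sample_id=sample_ids[i],
            marker_status="positive" if is_pos[i] else "negative",
            treatment=str(treatment[i]),
            time=float(time[i]),
            event=int(event[i]),
            age=float(np.round(rng.normal(62.0, 10.0), 1)),
            stage=str(rng.choice(["I/II", "III/IV"], p=[0.28, 0.72])),
            grade=str(rng.choice(["I/II", "III"], p=[0.6, 0.4])),
            residual=str(rng.choice(["none", "<=2cm", ">2cm"], p=[0.35, 0.28, 0.37])),
        )
        for i in range(n)
    ]
    beta = BetaMatrix(probe_ids, sample_ids, values)
    truth = SimulationTruth(
        informative_probes={
            probe_ids[j]: int(directions[j]) for j in sorted(informative)
        },
        marker_status={sid: ("positive" if p else "negative") for sid, p in zip(sample_ids, is_pos)},
        hr_marker_by_treatment=dict(config.hr_marker_by_treatment),
    )
    return Cohort(beta, samples, name), truth


def simulate_null_pvalues(k: int, seed: int) -> np.ndarray:
    """``k`` i.i.d. Uniform(0, 1) draws — null p-values for meta-analysis tests."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return np.random.default_rng(seed).uniform(size=k)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Write planted-probe directions as TSV (probe_id, direction)."""
    pd.DataFrame(
        {"probe_id": list(truth.informative_probes), "direction": list(truth.informative_probes.values())}
    ).to_csv(Path(path), sep="\t", index=False)


def write_simulated_cohort(
    cohort: Cohort, truth: SimulationTruth, config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write beta/sheet/truth/config files and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / f"{cohort.name}_beta.tsv",
        "samples": outdir / f"{cohort.name}_samples.tsv",
        "truth": outdir / f"{cohort.name}_truth.tsv",
        "config": outdir / f"{cohort.name}_config.json",
    }
    write_beta_matrix(cohort.beta, paths["beta"])
    write_sample_sheet(cohort.samples, paths["samples"])
    write_truth(truth, paths["truth"])
    paths["config"].write_text(config.to_json() + "\n")
    return paths
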