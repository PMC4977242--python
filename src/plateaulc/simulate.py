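"""Seeded synthetic-data generator for the repeated-measures study design.

The generator emulates the structure the method assumes: each subject has
one true value (stable anatomy, normally distributed across the
population) and every measurement on that subject is the true value plus
independent Gaussian measurement error whose standard deviation shrinks
along a smooth-join quadratic-plateau learning curve as the operator works
through subjects in chronological order.

Defaults mirror an ocular-ultrasound study design: 120 subjects, four
measurements each ({left,right} eye x {horizontal,sagittal} plane),
population mean 3.68 mm, between-subject sd 0.38 mm, 65 of 120 male, and a
learning curve plateauing at variance 2.78 (tenths-of-mm scale) at subject
21.  Lengths are truncated at zero by redraw; with these parameters the
truncation probability is negligible (< 1e-10).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError
from .records import DEFAULT_SITES, MeasurementRecord, SubjectSummary


@dataclass(frozen=True)
class LearningCurve:
    """Smooth-join quadratic-plateau curve (P, c, K) on the variance scale:
    variance(I) = P + c*(K - I)**2 for I <= K, else P."""

    plateau: float = 2.78
    curvature: float = 0.03843
    knot: float = 21.0

    def __call__(self, index):
        idx = np.asarray(index, dtype=float)
        out = np.where(
            idx <= self.knot,
            self.plateau + self.curvature * (idx - self.knot) ** 2,
            self.plateau,
        )
        return float(out) if np.isscalar(index) else out


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the emulated study's conditions.

    ``scale_factor`` links the curve's variance scale to mm: the
    measurement-error sd at index I is sqrt(curve(I)) / scale_factor mm.
    ``sex_mean_offset`` (mm, male minus female) defaults to 0 so the null
    simulation is exactly null; set ~0.3 to echo a male-female difference.
    """

    n_subjects: int = 120
    n_measurements: int = 4
    population_mean: float = 3.68
    between_subject_sd: float = 0.38
    curve: LearningCurve = field(default_factory=LearningCurve)
    scale_factor: float = 10.0
    noise_model: str = "gaussian"
    sex_fraction_male: float = 65 / 120
    sex_mean_offset: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_measurements < 1:
            problems.append(f"n_measurements must be >= 1, got {self.n_measurements}")
        if self.between_subject_sd < 0:
            problems.append("between_subject_sd must be >= 0")
        if self.population_mean <= 0:
            problems.append("population_mean must be positive")
        if self.curve.plateau < 0 or self.curve.curvature < 0:
            problems.append("curve plateau and curvature must be >= 0")
        if not 0 <= self.sex_fraction_male <= 1:
            problems.append("sex_fraction_male must lie in [0, 1]")
        if self.scale_factor <= 0:
            problems.append("scale_factor must be positive")
        if self.noise_model != "gaussian":
            problems.append(f"unknown noise_model {self.noise_model!r}")
        if problems:
            raise ConfigError(problems)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _sites(n: int) -> list[str]:
    """Site labels for n measurements: cycle the default four, numbering
    repeats beyond them."""
    labels = []
    for i in range(n):
        base = DEFAULT_SITES[i % len(DEFAULT_SITES)]
        rep = i // len(DEFAULT_SITES)
        labels.append(base if rep == 0 else f"{base}_{rep + 1}")
    return labels


def simulate_dataset(config: SimulationConfig) -> list[MeasurementRecord]:
    """Draw a full measurement table under the configured design.

    Deterministic for a fixed seed, including record order.  Per subject I
    (1-based chronological index): true mean ~ Normal(population_mean +-
    sex offset, between_subject_sd); measurements ~ Normal(true mean,
    sigma(I)) with sigma(I)**2 = curve(I) / scale_factor**2, redrawn while
    non-positive.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_measurements

    n_male = int(round(config.sex_fraction_male * n))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex)

    offsets = np.where(sex == "male", config.sex_mean_offset / 2, -config.sex_mean_offset / 2)
    true_means = rng.normal(
        config.population_mean + offsets, config.between_subject_sd, size=n
    )
    indices = np.arange(1, n + 1)
    error_sd = np.sqrt(config.curve(indices)) / config.scale_factor

    sites = _sites(m)
    width = len(str(n))
    records = []
    for i in range(n):
        values = rng.normal(true_means[i], error_sd[i], size=m)
        bad = values <= 0
        while np.any(bad):  # truncate lengths at zero by redraw
            values[bad] = rng.normal(true_means[i], error_sd[i], size=int(bad.sum()))
            bad = values <= 0
        sid = f"S{i + 1:0{width}d}"
        for site, value in zip(sites, values):
            records.append(
                MeasurementRecord(
                    subject_index=int(indices[i]),
                    subject_id=sid,
                    site=site,
                    value=float(value),
                    sex=str(sex[i]),
                )
            )
    return records


def simulate_variance_series(
    curve: LearningCurve,
    n_subjects: int,
    noise_sd: float,
    seed: int,
    mean_placeholder: float = 3.68,
) -> list[SubjectSummary]:
    """Simulate the regression response directly: variance(I) = max(0,
    curve(I) + Normal(0, noise_sd)).  Means are a constant placeholder;
    use :func:`simulate_dataset` when means matter."""
    if noise_sd < 0:
        raise ConfigError(["noise_sd must be >= 0"])
    if n_subjects < 1:
        raise ConfigError(["n_subjects must be >= 1"])
    rng = np.random.default_rng(seed)
    indices = np.arange(1, n_subjects + 1)
    values = np.maximum(0.0, curve(indices) + rng.normal(0.0, noise_sd, size=n_subjects))
    return [
        SubjectSummary(
            subject_index=int(i),
            subject_id=f"S{i}",
            n_measurements=4,
            mean=mean_placeholder,
            within_variance=float(v),
        )
        for i, v in zip(indices, values)
    ]
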