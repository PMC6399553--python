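"""Synthetic preoperative EHR cohort generator.

The original hospital cohort is not publicly available, so this module
generates cohorts with the statistical structure the downstream analysis
assumes:

* irregular per-test measurement days from an inhomogeneous Poisson point
  process whose intensity is densest just before surgery (piecewise-constant
  day weights 3 : 1.5 : 1 over the short/medium/long windows, normalized so
  that the expected count over the 30 days closest to surgery equals the
  catalog ``rate30``) — daily missingness lands in the ~90–98% range the
  preoperative grid exhibits;
* ~20% SSI prevalence with the case count fixed exactly to
  ``round(n * prevalence)``;
* two planted case-group signals: an elevated CRP level in the medium
  window (an underlying inflammatory process), and an elevated testing
  frequency in the medium window for a configurable set of tests — the
  "physician suspicion" signal that count-type features pick up;
* optionally, a raised probability that a case value falls above the
  reference range, giving value-only feature sets signal beyond CRP.

Everything is reproducible from ``CohortSpec.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import TestCatalogEntry

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "PatientRecord",
    "LabMeasurement",
    "generate_cohort",
]

# Default window boundaries (days before surgery) used to place case effects;
# must match the default feature windows.
DEFAULT_S_HI = 2
DEFAULT_M_HI = 15

#: day-weight of the short/medium/long windows in the sampling intensity
INTENSITY_WEIGHTS = (3.0, 1.5, 1.0)


@dataclass(frozen=True)
class EffectSpec:
    """Planted case-vs-control differences.

    crp_shift_M
        Standardized upward shift of case CRP values in the medium window.
    test_rate_multiplier
        Multiplies the medium-window sampling intensity of ``boosted_tests``
        for cases (>= 1); 1 disables the testing-frequency signal.
    abn_prob_shift
        Extra probability that a case value of an ``abnormal_tests`` test is
        drawn above the reference range.
    """

    crp_shift_M: float = 1.0
    test_rate_multiplier: float = 1.5
    abn_prob_shift: float = 0.1
    boosted_tests: tuple[str, ...] = ("Leukocytes", "Sodium", "Hemoglobin", "Thrombocytes")
    abnormal_tests: tuple[str, ...] = ("Leukocytes", "Potassium")

    def __post_init__(self) -> None:
        if self.crp_shift_M < 0:
            raise ValueError("crp_shift_M must be >= 0")
        if self.test_rate_multiplier < 1:
            raise ValueError("test_rate_multiplier must be >= 1")
        if not 0 <= self.abn_prob_shift <= 1:
            raise ValueError("abn_prob_shift must be in [0, 1]")

    @classmethod
    def neutral(cls) -> "EffectSpec":
        """No case/control difference: labels carry no signal."""
        return cls(crp_shift_M=0.0, test_rate_multiplier=1.0, abn_prob_shift=0.0)


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    prevalence: float = 0.2013
    obs_days: int = 60
    seed: int = 0
    effects: EffectSpec = field(default_factory=EffectSpec)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.obs_days <= 0:
            raise ValueError("obs_days must be positive")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: int
    ssi: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


@dataclass(frozen=True)
class LabMeasurement:
    """One blood-test value, ``day`` days before surgery (0 = surgery day)."""

    patient_id: str
    test_name: str
    day: int
    value: float

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if not np.isfinite(self.value):
            raise ValueError("value must be finite")


def _day_weights(obs_days: int, s_hi: int = DEFAULT_S_HI, m_hi: int = DEFAULT_M_HI) -> np.ndarray:
    """Sampling-intensity weight per day, indexed by day-before-surgery."""
    days = np.arange(obs_days + 1)
    w_s, w_m, w_l = INTENSITY_WEIGHTS
    return np.where(days <= s_hi, w_s, np.where(days <= m_hi, w_m, w_l))


def generate_cohort(
    spec: CohortSpec, catalog: list[TestCatalogEntry]
) -> tuple[list[PatientRecord], list[LabMeasurement]]:
    """Generate patient records and long-format lab measurements.

    The case count is exactly ``round(n_patients * prevalence)``.  Per patient
    and test, the number of values on each preoperative day is Poisson with a
    piecewise-constant intensity normalized so the expected count over the 30
    days closest to surgery equals the test's ``rate30`` (times the medium-
    window boost for cases on designated tests).  Values are Gaussian around
    the reference midpoint with sd one sixth of the reference width; case
    effects shift CRP in the medium window and push designated tests above
    the upper reference bound with extra probability.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    eff = spec.effects
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    n_cases = int(round(n * spec.prevalence))
    ssi = np.zeros(n, dtype=int)
    ssi[rng.permutation(n)[:n_cases]] = 1
    age = rng.uniform(40.0, 85.0, size=n)
    sex = rng.integers(0, 2, size=n)
    width = len(str(n))
    patients = [
        PatientRecord(patient_id=f"P{i + 1:0{width}d}", age=float(age[i]),
                      sex=int(sex[i]), ssi=int(ssi[i]))
        for i in range(n)
    ]

    weights = _day_weights(spec.obs_days)
    days = np.arange(spec.obs_days + 1)
    in_m = (days > DEFAULT_S_HI) & (days <= DEFAULT_M_HI)
    # normalize over the most recent 30 days (or the whole interval if shorter)
    recent = days <= min(29, spec.obs_days)
    norm = weights[recent].sum()

    measurements: list[LabMeasurement] = []
    for i, patient in enumerate(patients):
        is_case = ssi[i] == 1
        for entry in catalog:
            lam = entry.rate30 / norm * weights
            if is_case and entry.test_name in eff.boosted_tests:
                lam = lam.copy()
                lam[in_m] *= eff.test_rate_multiplier
            counts = rng.poisson(lam)
            for day in np.flatnonzero(counts):
                k = counts[day]
                vals = entry.mid + entry.spread * rng.standard_normal(k)
                if is_case:
                    if entry.test_name == "CRP" and in_m[day]:
                        vals = vals + eff.crp_shift_M * entry.spread
                    if entry.test_name in eff.abnormal_tests and eff.abn_prob_shift > 0:
                        flip = rng.random(k) < eff.abn_prob_shift
                        vals = np.where(
                            flip,
                            entry.ref_high + np.abs(rng.standard_normal(k)) * entry.spread,
                            vals,
                        )
                for v in vals:
                    measurements.append(
                        LabMeasurement(
                            patient_id=patient.patient_id,
                            test_name=entry.test_name,
                            day=int(day),
                            value=float(v),
                        )
                    )
    return patients, measurements
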