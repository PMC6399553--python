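"""Blood-test catalog: prices, reference ranges and sampling rates.

The catalog drives three things downstream: abnormal-value flags (values
outside ``[ref_low, ref_high]``), price-derived penalty factors for the
cost-sensitive lasso, and the per-test measurement intensity of the
synthetic cohort generator (``rate30`` = expected number of measurements
in the 30 days closest to surgery).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TestCatalogEntry",
    "default_catalog",
    "read_catalog_json",
    "write_catalog_json",
    "catalog_prices",
]


@dataclass(frozen=True)
class TestCatalogEntry:
    """One blood test: price (NOK), reference range and sampling rate."""

    test_name: str
    price: float
    ref_low: float
    ref_high: float
    rate30: float

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError(f"{self.test_name}: price must be positive")
        if self.rate30 <= 0:
            raise ValueError(f"{self.test_name}: rate30 must be positive")
        if not self.ref_low < self.ref_high:
            raise ValueError(f"{self.test_name}: need ref_low < ref_high")

    @property
    def mid(self) -> float:
        return 0.5 * (self.ref_low + self.ref_high)

    @property
    def spread(self) -> float:
        """One 'standard deviation' of a typical healthy value.

        The reference interval is read as mean +/- 3 sd, so the spread is a
        sixth of its width.
        """
        return (self.ref_high - self.ref_low) / 6.0


# (name, rate30, ref_low, ref_high, price-or-None), ordered by measurement
# frequency.  Only three prices are public (leukocytes and thrombocytes at
# 58 NOK, glucose at 23 NOK); the rest default to evenly spaced values on
# [23, 58] in catalog order and can be overridden from JSON.  Reference
# ranges are standard adult intervals in conventional Norwegian lab units.
_DEFAULT_TESTS: list[tuple[str, float, float, float, float | None]] = [
    ("Hemoglobin", 5.37, 11.7, 16.6, None),        # g/dL
    ("Leukocytes", 4.43, 3.5, 10.0, 58.0),         # 10^9/L
    ("Sodium", 4.24, 137.0, 145.0, None),          # mmol/L
    ("CRP", 4.11, 0.0, 5.0, None),                 # mg/L
    ("Potassium", 3.97, 3.5, 5.0, None),           # mmol/L
    ("Albumin", 2.87, 36.0, 48.0, None),           # g/L
    ("Creatinine", 1.94, 50.0, 100.0, None),       # umol/L
    ("Thrombocytes", 1.53, 145.0, 390.0, 58.0),    # 10^9/L
    ("ALAT", 1.23, 10.0, 70.0, None),              # U/L
    ("Bilirubin.total", 1.22, 5.0, 25.0, None),    # umol/L
    ("ASAT", 1.14, 15.0, 45.0, None),              # U/L
    ("Glucose", 1.06, 4.0, 6.3, 23.0),             # mmol/L
    ("Amylase", 1.06, 25.0, 120.0, None),          # U/L
    ("ALP", 1.04, 35.0, 105.0, None),              # U/L
]


def default_catalog() -> list[TestCatalogEntry]:
    """The 14 most frequent preoperative blood tests with default pricing."""
    unknown = [i for i, t in enumerate(_DEFAULT_TESTS) if t[4] is None]
    fill = np.linspace(23.0, 58.0, len(unknown) + 2)[1:-1]
    prices = {i: round(float(v), 2) for i, v in zip(unknown, fill)}
    entries = []
    for i, (name, rate30, lo, hi, price) in enumerate(_DEFAULT_TESTS):
        entries.append(
            TestCatalogEntry(
                test_name=name,
                price=price if price is not None else prices[i],
                ref_low=lo,
                ref_high=hi,
                rate30=rate30,
            )
        )
    return entries


def write_catalog_json(catalog: list[TestCatalogEntry], path: str | Path) -> None:
    Path(path).write_text(json.dumps([asdict(e) for e in catalog], indent=2))


def read_catalog_json(path: str | Path) -> list[TestCatalogEntry]:
    raw = json.loads(Path(path).read_text())
    return [TestCatalogEntry(**entry) for entry in raw]


def catalog_prices(catalog: list[TestCatalogEntry]) -> dict[str, float]:
    return {e.test_name: e.price for e in catalog}
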