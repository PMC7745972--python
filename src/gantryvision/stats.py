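"""Evaluation and dataset statistics.

Classifier test results on n images with k correct are binomial: point
accuracy k/n, standard error sqrt(p(1-p)/n), and — because test sets here
are often small — the exact Clopper-Pearson confidence interval from beta
quantiles.  Class weights counteract class imbalance when training on the
generated datasets: each class is weighted by total/(class count), so the
weighted class masses are equal.  Dataset summaries count labeled subimages
per species across a directory of metadata records.
"""

from __future__ import annotations

import decimal
import json
from fractions import Fraction
from pathlib import Path

import pandas as pd
from scipy import stats as sps

__all__ = [
    "accuracy_percent",
    "binomial_se_percent",
    "clopper_pearson",
    "class_weights",
    "ClassWeights",
    "dataset_summary",
    "DatasetSummary",
]


def _round_half_up(value: float, decimals: int) -> float:
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def accuracy_percent(k: int, n: int, decimals: int = 1) -> float:
    """Accuracy 100*k/n as a percentage, rounded half-up to ``decimals``."""
    if n <= 0:
        raise ZeroDivisionError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    return _round_half_up(100.0 * k / n, decimals)


def binomial_se_percent(k: int, n: int, decimals: int = 1) -> float:
    """Binomial standard error 100*sqrt(p(1-p)/n) with p = k/n, as a percentage."""
    if n <= 0:
        raise ZeroDivisionError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    p = k / n
    return _round_half_up(100.0 * (p * (1.0 - p) / n) ** 0.5, decimals)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval (proportions) via beta quantiles.

    Lower bound is 0 when k = 0 and upper bound 1 when k = n, by convention.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need n > 0 and 0 <= k <= n")
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper


class ClassWeights(dict):
    """Mapping class -> weight with the defining counts kept alongside."""

    def __init__(self, weights: dict[str, Fraction], counts: dict[str, int]):
        super().__init__({k: float(v) for k, v in weights.items()})
        self.exact = weights
        self.counts = counts

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def class_weights(counts: dict[str, int]) -> ClassWeights:
    """Weight each class by total/(class count), computed in exact arithmetic.

    The weighted class masses weight * count are then all equal to the total,
    balancing the classes during training.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be > 0")
    total = sum(counts.values())
    weights = {k: Fraction(total, c) for k, c in counts.items()}
    return ClassWeights(weights, dict(counts))


class DatasetSummary:
    """Per-species subimage counts over a metadata directory."""

    def __init__(self, counts: pd.Series, errors: list[str]):
        self.counts = counts
        self.errors = errors

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.rename("n_subimages").to_frame()
        df.loc["Total"] = self.total
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="label")

    def __repr__(self) -> str:
        lines = [f"{label}\t{n}" for label, n in self.counts.items()]
        lines.append(f"Total\t{self.total}")
        if self.errors:
            lines.append(f"({len(self.errors)} unreadable record(s) skipped)")
        return "\n".join(lines)


def dataset_summary(metadata_dir: str | Path) -> DatasetSummary:
    """Count labeled subimages per species label in a directory of records.

    Unreadable or invalid records are reported in ``errors`` and skipped.
    """
    from .labeler import read_metadata, MetadataSchemaError

    counts: dict[str, int] = {}
    errors: list[str] = []
    for path in sorted(Path(metadata_dir).glob("*.json")):
        if path.name == "manifest.json":
            continue
        try:
            record = read_metadata(path)
        except (MetadataSchemaError, json.JSONDecodeError, OSError) as exc:
            errors.append(f"{path.name}: {exc}")
            continue
        for bb in record.bounding_boxes:
            counts[bb.label] = counts.get(bb.label, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index() if counts else pd.Series(dtype=int)
    return DatasetSummary(series, errors)
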