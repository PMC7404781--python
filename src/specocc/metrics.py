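"""Confusion-matrix metrics for one-class screening.

Sensitivity and specificity are group-wise correct-classification rates and
total accuracy the overall correct fraction.  Two naming conventions are in
circulation for screening studies and both are supported:

* ``results_adulterated_positive`` (default) — sensitivity counts detected
  adulterated samples, specificity counts accepted pure samples.  This is
  the convention under which screening results tables are usually printed.
* ``eq12_pure_positive`` — sensitivity over pure samples, specificity over
  adulterated ones (the formula-sheet convention).

Accuracy is identical under both.  Reported percentages are truncated (not
rounded) at two decimals, the convention used in the tables this package's
report layer mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_DOWN
from typing import Sequence

import numpy as np
import pandas as pd

CONVENTIONS = ("results_adulterated_positive", "eq12_pure_positive")


class MetricsError(ValueError):
    pass


def truncate2(x: float) -> float:
    """Truncate a percentage toward zero at two decimals (100.0 stays 100.0)."""
    # guard against float representation error just below a clean value
    return float(Decimal(repr(round(float(x), 9))).quantize(Decimal("0.01"), ROUND_DOWN))


@dataclass
class ConfusionSummary:
    """Counts and derived rates for one validation group."""

    n_pure: int
    n_adulterated: int
    pure_accepted: int
    adulterated_rejected: int
    convention: str = "results_adulterated_positive"

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise MetricsError(f"unknown convention {self.convention!r}")
        if not (0 <= self.pure_accepted <= self.n_pure):
            raise MetricsError("pure_accepted outside [0, n_pure]")
        if not (0 <= self.adulterated_rejected <= self.n_adulterated):
            raise MetricsError("adulterated_rejected outside [0, n_adulterated]")
        if self.n_pure + self.n_adulterated == 0:
            raise MetricsError("empty confusion summary")

    # raw percentages ---------------------------------------------------
    @property
    def accuracy(self) -> float:
        correct = self.pure_accepted + self.adulterated_rejected
        return 100.0 * correct / (self.n_pure + self.n_adulterated)

    @property
    def sensitivity(self) -> float:
        if self.convention == "results_adulterated_positive":
            return self._rate(self.adulterated_rejected, self.n_adulterated)
        return self._rate(self.pure_accepted, self.n_pure)

    @property
    def specificity(self) -> float:
        if self.convention == "results_adulterated_positive":
            return self._rate(self.pure_accepted, self.n_pure)
        return self._rate(self.adulterated_rejected, self.n_adulterated)

    @staticmethod
    def _rate(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    # printed (two-decimal truncated) form ------------------------------
    def printed(self) -> dict[str, float]:
        return {
            "sensitivity": truncate2(self.sensitivity),
            "specificity": truncate2(self.specificity),
            "accuracy": truncate2(self.accuracy),
        }

    def swapped(self) -> "ConfusionSummary":
        """Same counts under the other convention."""
        other = (
            "eq12_pure_positive"
            if self.convention == "results_adulterated_positive"
            else "results_adulterated_positive"
        )
        return ConfusionSummary(
            self.n_pure,
            self.n_adulterated,
            self.pure_accepted,
            self.adulterated_rejected,
            convention=other,
        )

    def to_row(self, group: str = "") -> dict:
        if self.convention == "results_adulterated_positive":
            sens_counts = f"{self.adulterated_rejected}/{self.n_adulterated}"
            spec_counts = f"{self.pure_accepted}/{self.n_pure}"
        else:
            sens_counts = f"{self.pure_accepted}/{self.n_pure}"
            spec_counts = f"{self.adulterated_rejected}/{self.n_adulterated}"
        p = self.printed()
        return {
            "group": group,
            "sensitivity_pct": p["sensitivity"],
            "sensitivity_counts": sens_counts,
            "specificity_pct": p["specificity"],
            "specificity_counts": spec_counts,
            "accuracy_pct": p["accuracy"],
        }


def confusion_summary(
    truth: Sequence[str],
    accepted: Sequence[bool],
    convention: str = "results_adulterated_positive",
) -> ConfusionSummary:
    """Summarize accept/reject decisions against pure/adulterated truth."""
    truth = list(truth)
    accepted = list(accepted)
    if len(truth) == 0:
        raise MetricsError("empty input")
    if len(truth) != len(accepted):
        raise MetricsError("truth and accepted must have equal length")
    unknown = sorted(set(truth) - {"pure", "adulterated"})
    if unknown:
        raise MetricsError(f"unknown class labels: {unknown}")
    t = np.asarray(truth)
    a = np.asarray(accepted, dtype=bool)
    return ConfusionSummary(
        n_pure=int((t == "pure").sum()),
        n_adulterated=int((t == "adulterated").sum()),
        pure_accepted=int(((t == "pure") & a).sum()),
        adulterated_rejected=int(((t == "adulterated") & ~a).sum()),
        convention=convention,
    )


def per_level_detection(
    concentration: Sequence[float], accepted: Sequence[bool]
) -> pd.DataFrame:
    """Rejection rate per adulteration level.

    Returns one row per unique concentration (including 0, where the rate is
    the false-rejection rate of pure samples) with columns
    ``concentration, n, rejected, rejection_rate``.
    """
    conc = np.asarray(list(concentration), dtype=float)
    acc = np.asarray(list(accepted), dtype=bool)
    if conc.size != acc.size:
        raise MetricsError("concentration and accepted must have equal length")
    rows = []
    for level in np.unique(conc):
        mask = conc == level
        rejected = int((~acc[mask]).sum())
        rows.append(
            {
                "concentration": float(level),
                "n": int(mask.sum()),
                "rejected": rejected,
                "rejection_rate": rejected / int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
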