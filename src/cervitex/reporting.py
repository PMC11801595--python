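"""Evaluation tables: per-class rates and truncated averages.

The classification rate of a class is its recall on the test split, reported
as a percent.  Reported numbers are truncated (not rounded) to two decimals;
full-precision values are kept internally and written to a companion CSV.
The report grid is 3 algorithms (jsd, hd, td) x 16 wavelet families x 3
classes, with a per-family row average (mean of the three class rates), a
per-algorithm average over the 16 families, and a grand average of the three
algorithm averages per modality.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cervitex.classifier import DIVERGENCES, TrainedClassifier, predict_table
from cervitex.image_io import LABELS
from cervitex.wavelets import WAVELET_FAMILIES


class EvaluationError(ValueError):
    """Raised for malformed prediction/truth inputs or missing models."""


def _dec(x) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def truncate2(value) -> float:
    """Truncate toward zero at two decimals (98.888... -> 98.88).

    Decimal arithmetic on the printed-precision operands avoids binary
    floating-point artifacts at the truncation boundary.
    """
    return float(_dec(value).quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def _trunc_mean(values: Sequence) -> float:
    total = sum((_dec(v) for v in values), Decimal(0))
    return float((total / len(values)).quantize(Decimal("0.01"),
                                                rounding=ROUND_DOWN))


def per_class_rate(predictions: Sequence[str], truth: Sequence[str],
                   target_class: str) -> float:
    """Class recall in percent, full precision (truncate at reporting time)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise EvaluationError("predictions and truth differ in length")
    mask = truth == target_class
    if not mask.any():
        raise EvaluationError(f"class {target_class!r} absent from truth")
    return 100.0 * float((predictions[mask] == target_class).mean())


def family_algorithm_average(class_rates: Sequence) -> float:
    """Mean of the three per-class rates of one (family, algorithm) cell."""
    if len(class_rates) != 3:
        raise EvaluationError("expected exactly three class rates")
    return _trunc_mean(class_rates)


def algorithm_average(family_averages: Sequence) -> float:
    """Mean over the 16 per-family averages of one algorithm."""
    if len(family_averages) != 16:
        raise EvaluationError("expected exactly sixteen family averages")
    return _trunc_mean(family_averages)


def grand_average(algorithm_averages: Sequence) -> float:
    """Mean of the three per-algorithm averages of one modality."""
    if len(algorithm_averages) != 3:
        raise EvaluationError("expected exactly three algorithm averages")
    return _trunc_mean(algorithm_averages)


@dataclass
class EvaluationReport:
    """Full-precision rate grid plus the truncated summary numbers."""

    modality: str
    rates: np.ndarray  # (3 algorithms, 16 families, 3 classes), percent
    algorithms: tuple[str, ...] = DIVERGENCES
    families: tuple[str, ...] = WAVELET_FAMILIES
    classes: tuple[str, ...] = LABELS

    def row_averages(self) -> np.ndarray:
        """(3, 16) truncated per-family means of the three class rates."""
        out = np.empty(self.rates.shape[:2])
        for a in range(self.rates.shape[0]):
            for f in range(self.rates.shape[1]):
                out[a, f] = family_algorithm_average(
                    [truncate2(r) for r in self.rates[a, f]])
        return out

    def algorithm_averages(self) -> np.ndarray:
        rows = self.row_averages()
        return np.array([algorithm_average(list(rows[a])) for a in
                         range(rows.shape[0])])

    def grand_average(self) -> float:
        return grand_average(list(self.algorithm_averages()))

    def to_frame(self, truncated: bool = True) -> pd.DataFrame:
        """Table mirroring the published layout: class rows per algorithm
        followed by the algorithm's per-family average row."""
        rows = {}
        row_avg = self.row_averages()
        for a, alg in enumerate(self.algorithms):
            for c, cls in enumerate(self.classes):
                vals = self.rates[a, :, c]
                if truncated:
                    vals = [truncate2(v) for v in vals]
                rows[f"{cls}_{alg}"] = list(vals)
            rows[f"average_{alg}"] = list(row_avg[a])
        return pd.DataFrame(rows, index=list(self.families)).T

    def write_csv(self, path: str | Path) -> None:
        """Write the truncated report and a *_fullprec companion."""
        path = Path(path)
        self.to_frame(truncated=True).to_csv(path)
        full = path.with_name(path.stem + "_fullprec" + path.suffix)
        self.to_frame(truncated=False).to_csv(full)


def build_report(models: Mapping[tuple[str, str], TrainedClassifier],
                 test_features: pd.DataFrame, modality: str,
                 families: Sequence[str] = WAVELET_FAMILIES,
                 algorithms: Sequence[str] = DIVERGENCES) -> EvaluationReport:
    """Evaluate every (family, divergence) classifier on the test table.

    ``models`` maps ``(family, divergence)`` to a trained classifier;
    ``test_features`` must carry ``label`` and ``family`` columns plus the 40
    feature columns.  Raises if any pair is missing.
    """
    missing = [(f, a) for a in algorithms for f in families
               if (f, a) not in models]
    if missing:
        raise EvaluationError(f"missing trained models for {missing}")
    rates = np.empty((len(algorithms), len(families), len(LABELS)))
    for fi, fam in enumerate(families):
        sub = test_features[test_features["family"] == fam]
        if sub.empty:
            raise EvaluationError(f"no test features for family {fam!r}")
        truth = sub["label"].to_numpy()
        for ai, alg in enumerate(algorithms):
            pred = predict_table(models[(fam, alg)], sub).to_numpy()
            for ci, cls in enumerate(LABELS):
                rates[ai, fi, ci] = per_class_rate(pred, truth, cls)
    return EvaluationReport(modality=modality, rates=rates,
                            algorithms=tuple(algorithms),
                            families=tuple(families))
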