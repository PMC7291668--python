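"""Inter-rater agreement statistics: confusion matrix and Cohen's kappa.

Unweighted Cohen's kappa κ = (p_o − p_e) / (1 − p_e) where p_o is the
observed proportion of agreement and p_e the agreement expected by chance
from the raters' marginals.  The standard error is the large-sample
asymptotic variance of κ that does not assume chance agreement
(Fleiss, Cohen & Everitt 1969), as printed by standard statistical packages;
the confidence interval is the two-sided Wald interval κ ± z·SE truncated to
[−1, 1].

Descriptive interpretation bands: κ < 0.40 "below moderate",
0.40 ≤ κ < 0.60 "moderate", 0.60 ≤ κ < 0.80 "substantial",
κ ≥ 0.80 "excellent".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats import inter_rater as _inter_rater

from .events import HeadacheLabel

DEFAULT_CATEGORIES: tuple[HeadacheLabel, ...] = (
    HeadacheLabel.MO,
    HeadacheLabel.MA,
    HeadacheLabel.TTH,
    HeadacheLabel.NOT_CLASSIFIABLE,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square cross-tabulation of two raters over a fixed category order.

    Rows are rater A (e.g. the neurologist), columns rater B (e.g. the
    algorithm).
    """

    counts: np.ndarray
    categories: tuple[HeadacheLabel, ...] = DEFAULT_CATEGORIES

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_agree(self) -> int:
        """Diagonal sum: number of events both raters labelled identically."""
        return int(np.trace(self.counts))

    @property
    def n_disagree(self) -> int:
        """Off-diagonal sum."""
        return self.n - self.n_agree

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in self.categories]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col=0)
        categories = tuple(HeadacheLabel(name) for name in frame.index)
        if tuple(HeadacheLabel(name) for name in frame.columns) != categories:
            raise ValueError("row and column categories differ")
        return cls(counts=frame.to_numpy(), categories=categories)


def build_confusion(
    labels_a: Sequence[HeadacheLabel],
    labels_b: Sequence[HeadacheLabel],
    categories: tuple[HeadacheLabel, ...] = DEFAULT_CATEGORIES,
) -> ConfusionMatrix:
    """Cross-tabulate two aligned label vectors (rater A rows, rater B columns)."""
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("label vectors are empty")
    index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(labels_a, labels_b):
        counts[index[HeadacheLabel(a)], index[HeadacheLabel(b)]] += 1
    return ConfusionMatrix(counts=counts, categories=categories)


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa with its Wald confidence interval."""

    p_observed: float
    p_expected: float
    kappa: float
    se: float
    ci_lower: float
    ci_upper: float
    n: int
    confidence: float
    interpretation: str = field(default="")

    def summary(self) -> str:
        return (
            f"n = {self.n}\n"
            f"observed agreement  p_o = {self.p_observed:.3f}\n"
            f"chance agreement    p_e = {self.p_expected:.3f}\n"
            f"unweighted kappa    k   = {self.kappa:.3f}\n"
            f"asymptotic SE           = {self.se:.3f}\n"
            f"{self.confidence:.0%} CI                  = "
            f"[{self.ci_lower:.3f}, {self.ci_upper:.3f}]\n"
            f"agreement level         = {self.interpretation}"
        )


def cohens_kappa(matrix: ConfusionMatrix, confidence: float = 0.95) -> KappaResult:
    """Unweighted Cohen's kappa with asymptotic SE and Wald CI.

    Raises on a degenerate table where chance agreement p_e = 1 (kappa is
    undefined there).
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    counts = matrix.counts
    n = matrix.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    p = counts / n
    p_observed = float(np.trace(p))
    p_expected = float(p.sum(axis=1) @ p.sum(axis=0))
    if 1.0 - p_expected <= 0:
        raise ValueError(
            "chance agreement is 1 (all mass on one category pair); kappa undefined"
        )
    with warnings.catch_warnings():
        # statsmodels takes sqrt(var_kappa) eagerly; var can round off below 0
        # at perfect agreement
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _inter_rater.cohens_kappa(counts, return_results=True)
    kappa = float(res.kappa)
    # Fleiss-Cohen-Everitt large-sample variance, not assuming the null;
    # clip tiny negative round-off at the kappa = 1 boundary.
    se = float(np.sqrt(max(res.var_kappa, 0.0)))
    z = scipy.stats.norm.ppf(0.5 + confidence / 2.0)
    ci_lower = max(-1.0, kappa - z * se)
    ci_upper = min(1.0, kappa + z * se)
    return KappaResult(
        p_observed=p_observed,
        p_expected=p_expected,
        kappa=kappa,
        se=se,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        n=n,
        confidence=confidence,
        interpretation=interpret_kappa(kappa),
    )


def interpret_kappa(kappa: float) -> str:
    """Descriptive agreement band for a kappa value.

    Gap-free half-open bands: [0.40, 0.60) moderate, [0.60, 0.80)
    substantial, [0.80, 1] excellent, anything lower "below moderate".
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of range [-1, 1]: {kappa}")
    if kappa >= 0.80:
        return "excellent"
    if kappa >= 0.60:
        return "substantial"
    if kappa >= 0.40:
        return "moderate"
    return "below moderate"
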