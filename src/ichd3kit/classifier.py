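"""Scikit-learn estimator facade over the ICHD-3 rule engine.

The rule engine has no learned parameters — ``fit`` validates the
configuration and freezes it into fitted attributes, after which ``predict``
labels diary events.  The estimator composes with sklearn model-selection
utilities (``clone``, ``get_params``/``set_params``, ``score``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .engine import ClassificationResult, RuleConfig, classify_event
from .events import HeadacheEvent, HeadacheLabel, PatientHistory


def _as_events(X) -> list[HeadacheEvent]:
    if isinstance(X, pd.DataFrame):
        from .io import frame_to_events

        return frame_to_events(X)
    events = list(X)
    for e in events:
        if not isinstance(e, HeadacheEvent):
            raise TypeError(
                "X must be a diary DataFrame or a sequence of HeadacheEvent, "
                f"got element of type {type(e).__name__}"
            )
    return events


class ICHD3Classifier(ClassifierMixin, BaseEstimator):
    """Rule-based classifier of single headache attacks.

    Assigns each diary event one of the four labels MO (migraine without
    aura), MA (migraine with aura), TTH (tension-type headache) or
    NOT_CLASSIFIABLE, by operationalized ICHD-3 criteria with the
    probable-diagnosis hierarchy, the triptan-response rule and the
    short-duration rule.

    Parameters
    ----------
    migraine_min_h, migraine_max_h : float, default 4, 72
        Closed duration window (hours) of the migraine B criterion.
    tth_min_h, tth_max_h : float, default 0.5, 168
        Closed duration window (hours) of the TTH B criterion.
    short_duration_h : float, default 0.5
        Attacks strictly shorter are marked not classifiable.
    assume_migraine_history, assume_tth_history : bool, default True
        Criterion-A stand-ins: whether patients are assumed to carry a prior
        migraine / TTH diagnosis (gates the probable diagnoses).

    Attributes
    ----------
    classes_ : ndarray of shape (4,)
        Label strings in canonical order.
    rule_config_ : RuleConfig
        Frozen numeric constants used for prediction.
    history_ : PatientHistory
        Frozen criterion-A assumption.

    Examples
    --------
    >>> clf = ICHD3Classifier().fit()
    >>> clf.predict(events)          # doctest: +SKIP
    array(['MO', 'TTH', ...], dtype='<U16')
    """

    def __init__(
        self,
        migraine_min_h: float = 4.0,
        migraine_max_h: float = 72.0,
        tth_min_h: float = 0.5,
        tth_max_h: float = 168.0,
        short_duration_h: float = 0.5,
        assume_migraine_history: bool = True,
        assume_tth_history: bool = True,
    ):
        self.migraine_min_h = migraine_min_h
        self.migraine_max_h = migraine_max_h
        self.tth_min_h = tth_min_h
        self.tth_max_h = tth_max_h
        self.short_duration_h = short_duration_h
        self.assume_migraine_history = assume_migraine_history
        self.assume_tth_history = assume_tth_history

    def fit(self, X=None, y=None) -> "ICHD3Classifier":
        """Validate parameters and freeze the rule configuration.

        ``X`` and ``y`` are accepted for pipeline compatibility and ignored:
        the rules are fixed by ICHD-3, not learned.
        """
        self.rule_config_ = RuleConfig(
            migraine_duration_h=(self.migraine_min_h, self.migraine_max_h),
            tth_duration_h=(self.tth_min_h, self.tth_max_h),
            short_duration_h=self.short_duration_h,
        )
        self.history_ = PatientHistory(
            has_migraine_history=self.assume_migraine_history,
            has_tth_history=self.assume_tth_history,
        )
        self.classes_ = np.array([label.value for label in HeadacheLabel])
        return self

    def classify(self, X) -> list[ClassificationResult]:
        """Full per-event results with certainty, provenance and criteria traces."""
        check_is_fitted(self, "rule_config_")
        return [
            classify_event(e, self.history_, self.rule_config_) for e in _as_events(X)
        ]

    def predict(self, X) -> np.ndarray:
        """Label strings for a diary DataFrame or a sequence of events."""
        results = self.classify(X)
        return np.array([r.label.value for r in results], dtype="<U16")

    @classmethod
    def from_config(
        cls, config: RuleConfig, history: PatientHistory | None = None
    ) -> "ICHD3Classifier":
        """Build a fitted classifier from a :class:`RuleConfig`."""
        history = history or PatientHistory()
        return cls(
            migraine_min_h=config.migraine_duration_h[0],
            migraine_max_h=config.migraine_duration_h[1],
            tth_min_h=config.tth_duration_h[0],
            tth_max_h=config.tth_duration_h[1],
            short_duration_h=config.short_duration_h,
            assume_migraine_history=history.has_migraine_history,
            assume_tth_history=history.has_tth_history,
        ).fit()


def predict_labels(
    events: Sequence[HeadacheEvent],
    history: PatientHistory | None = None,
    config: RuleConfig | None = None,
) -> list[HeadacheLabel]:
    """Thin functional wrapper: labels for a sequence of events."""
    clf = ICHD3Classifier.from_config(config or RuleConfig(), history)
    return [HeadacheLabel(v) for v in clf.predict(events)]
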