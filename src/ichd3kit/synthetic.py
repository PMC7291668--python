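"""Seeded generator of synthetic headache-diary events and noisy rater labels.

Events are drawn from clinical *archetypes* rather than independent symptom
flags: independent sampling at realistic marginal frequencies almost never
assembles a definite diagnosis, so each targeted archetype proposes an event
biased toward its diagnosis and then verifies it against the rule engine,
resampling until the event actually classifies to the archetype's target
label (construct-then-verify).  The ``ambiguous`` background archetype draws
every flag independently at the configured marginal frequencies and takes
whatever label the classifier assigns as its truth.

Marginal frequencies, mean pain intensity (4.8/10), mean duration (13.5 h)
and the duration support (12 min to ~4.3 days) default to the summary
statistics of a validation sample of 102 real diary attacks.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta
from typing import NamedTuple, Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.stats
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import RuleConfig, classify_event
from .events import Certainty, HeadacheEvent, HeadacheLabel, PatientHistory

ARCHETYPES = (
    "definite_MO",
    "definite_MA",
    "definite_TTH",
    "probable_MO",
    "probable_TTH",
    "short_duration",
    "ambiguous",
)

#: Target label per archetype (None: take the classifier's own label).
ARCHETYPE_TARGETS: dict[str, Optional[HeadacheLabel]] = {
    "definite_MO": HeadacheLabel.MO,
    "definite_MA": HeadacheLabel.MA,
    "definite_TTH": HeadacheLabel.TTH,
    "probable_MO": HeadacheLabel.MO,
    "probable_TTH": HeadacheLabel.TTH,
    "short_duration": HeadacheLabel.NOT_CLASSIFIABLE,
    "ambiguous": None,
}

_DEFAULT_WEIGHTS = {
    "definite_MO": 0.22,
    "definite_MA": 0.08,
    "definite_TTH": 0.15,
    "probable_MO": 0.20,
    "probable_TTH": 0.10,
    "short_duration": 0.05,
    "ambiguous": 0.20,
}

_DEFAULT_MARGINALS = {
    "pulsating": 0.46,
    "pressing": 0.54,
    "one_sided": 0.56,
    "both_sided": 0.44,
    "aggravated_by_activity": 0.38,
    "aura": 0.18,
    "vomiting": 0.02,
    "nausea": 0.25,
    "phonophobia": 0.33,
    "photophobia": 0.44,
    "medication_taken": 0.41,
}


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic diary generator.

    ``duration_mean_h``/``duration_log_sigma``/``duration_bounds_h`` define a
    truncated log-normal attack-duration model whose *truncated* mean is
    calibrated to ``duration_mean_h``; ``pain_mean`` sets the mean of the
    discretized NRS distribution (1 + Binomial(9, p), support 1-10).
    """

    model_config = ConfigDict(frozen=True)

    n_events: int = Field(ge=0)
    seed: int
    archetype_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    symptom_marginals: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_MARGINALS)
    )
    duration_mean_h: float = 13.5
    duration_log_sigma: float = 1.1
    duration_bounds_h: tuple[float, float] = (0.2, 102.5)
    pain_mean: float = 4.8
    triptan_assignment_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    max_resample: int = 1000

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        unknown = set(self.archetype_weights) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        total = sum(self.archetype_weights.values())
        if self.archetype_weights and not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"archetype weights must sum to 1, got {total}")
        if any(w < 0 for w in self.archetype_weights.values()):
            raise ValueError("archetype weights must be non-negative")
        for name, freq in self.symptom_marginals.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"marginal frequency for {name} outside [0, 1]")
        lo, hi = self.duration_bounds_h
        if not 0 < lo < hi:
            raise ValueError("duration bounds must be positive and ordered")
        if not lo < self.duration_mean_h < hi:
            raise ValueError("duration_mean_h must lie inside the truncation bounds")
        return self


class SimulatedEvent(NamedTuple):
    """A generated event with its archetype and intended true label."""

    event: HeadacheEvent
    archetype: str
    true_label: HeadacheLabel


class _DurationModel:
    """Truncated log-normal sampler with mean calibrated on the truncated scale."""

    def __init__(self, mean_h: float, log_sigma: float, bounds: tuple[float, float]):
        self.sigma = log_sigma
        self.lo, self.hi = bounds
        self.mu = self._solve_mu(mean_h)
        dist = scipy.stats.lognorm(s=self.sigma, scale=math.exp(self.mu))
        self._dist = dist
        self._cdf_lo = dist.cdf(self.lo)
        self._cdf_hi = dist.cdf(self.hi)

    def _trunc_mean(self, mu: float) -> float:
        s = self.sigma
        norm = scipy.stats.norm
        za, zb = (math.log(self.lo) - mu) / s, (math.log(self.hi) - mu) / s
        mass = norm.cdf(zb) - norm.cdf(za)
        return (
            math.exp(mu + s**2 / 2)
            * (norm.cdf(zb - s) - norm.cdf(za - s))
            / mass
        )

    def _solve_mu(self, target: float) -> float:
        return scipy.optimize.brentq(
            lambda mu: self._trunc_mean(mu) - target, -2.0, 6.0, xtol=1e-10
        )

    def sample(self, rng: np.random.Generator, window: tuple[float, float]) -> float:
        """One draw from the model conditioned on ``window`` (inverse-CDF)."""
        lo = max(window[0], self.lo)
        hi = min(window[1], self.hi)
        if not lo < hi:
            raise ValueError(f"empty duration window {window}")
        a, b = self._dist.cdf(lo), self._dist.cdf(hi)
        return float(self._dist.ppf(rng.uniform(a, b)))


def _sample_pain(rng: np.random.Generator, mean: float, lo: int = 1, hi: int = 10) -> int:
    # 1 + Binomial(9, p): discrete on 1..10 with mean 1 + 9p.
    p = (mean - 1.0) / 9.0
    return int(np.clip(1 + rng.binomial(9, p), lo, hi))


class DiaryGenerator:
    """Stateful generator bound to one :class:`GeneratorConfig`."""

    _BASE_TIME = datetime(2017, 1, 1, 8, 0)

    def __init__(self, config: GeneratorConfig, rule_config: RuleConfig | None = None):
        self.config = config
        self.rule_config = rule_config or RuleConfig()
        self.history = PatientHistory()  # study setting: both histories assumed
        self._durations = _DurationModel(
            config.duration_mean_h, config.duration_log_sigma, config.duration_bounds_h
        )

    # -- flag helpers -----------------------------------------------------
    def _quality(self, rng) -> tuple[bool, bool]:
        """(pulsating, pressing), mutually exclusive at the marginal rate."""
        pulsating = rng.random() < self.config.symptom_marginals["pulsating"]
        return pulsating, not pulsating

    def _side(self, rng) -> tuple[bool, bool]:
        """(one_sided, both_sided), mutually exclusive at the marginal rate."""
        one = rng.random() < self.config.symptom_marginals["one_sided"]
        return one, not one

    def _flag(self, rng, name: str) -> bool:
        return rng.random() < self.config.symptom_marginals[name]

    # -- archetype proposals ---------------------------------------------
    def _propose(self, archetype: str, rng: np.random.Generator) -> HeadacheEvent:
        m = self.config.symptom_marginals
        cfg = self.rule_config
        mig_window = cfg.migraine_duration_h
        tth_window = (cfg.tth_duration_h[0], self.config.duration_bounds_h[1])
        pulsating, pressing = self._quality(rng)
        one_sided, both_sided = self._side(rng)
        aggravated = self._flag(rng, "aggravated_by_activity")
        aura = self._flag(rng, "aura")
        nausea = self._flag(rng, "nausea")
        vomiting = self._flag(rng, "vomiting")
        photophobia = self._flag(rng, "photophobia")
        phonophobia = self._flag(rng, "phonophobia")
        medication = self._flag(rng, "medication_taken")
        triptan: Optional[bool] = None
        pain = _sample_pain(rng, self.config.pain_mean)

        if archetype in ("definite_MO", "definite_MA"):
            aura = archetype == "definite_MA"
            duration = self._durations.sample(rng, mig_window)
            # repair C to >= 2 items and ensure D
            items = {
                "one_sided": one_sided,
                "pulsating": pulsating,
                "pain": pain >= 4,
                "aggravated": aggravated,
            }
            need = 2 - sum(items.values())
            for name in rng.permutation(sorted(items)):
                if need <= 0:
                    break
                if not items[name]:
                    items[name] = True
                    need -= 1
            one_sided, both_sided = items["one_sided"], both_sided and not items["one_sided"]
            pulsating, pressing = items["pulsating"], pressing and not items["pulsating"]
            aggravated = items["aggravated"]
            if items["pain"] and pain < 4:
                pain = int(rng.integers(4, 11))
            if not (nausea or vomiting or (photophobia and phonophobia)):
                if rng.random() < 0.7:
                    nausea = True
                else:
                    photophobia = phonophobia = True
            if medication:
                triptan = bool(rng.random() < self.config.triptan_assignment_rate)
        elif archetype == "definite_TTH":
            aura = False
            duration = self._durations.sample(rng, tth_window)
            one_sided, both_sided = False, True
            pulsating, pressing = False, True
            aggravated = False
            pain = _sample_pain(rng, min(self.config.pain_mean, 4.0), 1, 6)
            nausea = vomiting = False
            if photophobia and phonophobia:  # D allows at most one of the two
                if rng.random() < 0.5:
                    photophobia = False
                else:
                    phonophobia = False
            triptan = False if medication else None
        elif archetype == "probable_MO":
            aura = False
            failed = rng.choice(["B", "C", "D"])
            if failed == "B":
                # strong migraine C and D, duration outside the migraine window
                duration = self._sample_outside_migraine_window(rng)
                one_sided, both_sided = True, False
                pulsating, pressing = True, False
                pain = int(rng.integers(7, 11))
                aggravated = True
                nausea = True
            elif failed == "C":
                # no migraine C item at all (the probable-with-c_count-0 case)
                duration = self._durations.sample(rng, mig_window)
                one_sided, both_sided = False, True
                pulsating, pressing = False, True
                pain = int(rng.integers(1, 4))
                aggravated = False
                nausea = True
            else:  # failed == "D"
                duration = self._durations.sample(rng, mig_window)
                one_sided, both_sided = True, False
                pulsating, pressing = True, False
                pain = int(rng.integers(7, 11))
                aggravated = True
                nausea = vomiting = False
                if photophobia and phonophobia:
                    phonophobia = False
            triptan = False if medication else None
        elif archetype == "probable_TTH":
            aura = False
            if rng.random() < 0.5:
                # TTH D fails (associated symptoms); migraine B and C must fail too
                duration = self._sample_outside_migraine_window(rng)
                one_sided, both_sided = False, True
                pulsating, pressing = False, True
                pain = int(rng.integers(1, 4))
                aggravated = False
                nausea = True
            else:
                # TTH C fails (0 items); migraine B and D must fail
                duration = self._sample_outside_migraine_window(rng)
                one_sided, both_sided = True, False
                pulsating, pressing = True, False
                pain = int(rng.integers(7, 11))
                aggravated = True
                nausea = vomiting = False
                if photophobia and phonophobia:
                    photophobia = False
            triptan = False if medication else None
        elif archetype == "short_duration":
            duration = self._durations.sample(rng, (self.config.duration_bounds_h[0],
                                                    cfg.short_duration_h * 0.98))
            triptan = False if medication else None
        elif archetype == "ambiguous":
            duration = self._durations.sample(rng, self.config.duration_bounds_h)
            if medication:
                triptan = bool(rng.random() < self.config.triptan_assignment_rate)
        else:
            raise ValueError(f"unknown archetype: {archetype}")

        start = self._BASE_TIME + timedelta(days=int(rng.integers(0, 365)),
                                            minutes=int(rng.integers(0, 1440)))
        minutes = max(1, round(duration * 60))
        return HeadacheEvent(
            event_id="pending",
            start_time=start,
            end_time=start + timedelta(minutes=minutes),
            pain_nrs=pain,
            pulsating=pulsating,
            pressing=pressing,
            one_sided=one_sided,
            both_sided=both_sided,
            aggravated_by_activity=aggravated,
            aura=aura,
            nausea=nausea,
            vomiting=vomiting,
            photophobia=photophobia,
            phonophobia=phonophobia,
            medication_taken=medication,
            triptan_taken_and_effective=triptan,
        )

    def _sample_outside_migraine_window(self, rng) -> float:
        """Duration in [short, mig_lo) ∪ (mig_hi, upper], mass-weighted."""
        cfg = self.rule_config
        below = (cfg.tth_duration_h[0], cfg.migraine_duration_h[0] * 0.99)
        above = (cfg.migraine_duration_h[1] * 1.01, self.config.duration_bounds_h[1])
        dist = self._durations._dist
        w_below = max(dist.cdf(below[1]) - dist.cdf(below[0]), 0.0)
        w_above = max(dist.cdf(above[1]) - dist.cdf(above[0]), 0.0)
        window = below if rng.random() < w_below / (w_below + w_above) else above
        return self._durations.sample(rng, window)

    # -- verification -----------------------------------------------------
    def _matches_target(self, archetype: str, event: HeadacheEvent) -> bool:
        result = classify_event(event, self.history, self.rule_config)
        target = ARCHETYPE_TARGETS[archetype]
        if target is None:
            return True
        if result.label is not target:
            return False
        if archetype.startswith("definite"):
            return result.certainty is Certainty.DEFINITE
        if archetype.startswith("probable"):
            return result.probable_based
        if archetype == "short_duration":
            return result.short_duration_flag
        return True

    def generate(self) -> list[SimulatedEvent]:
        """Generate the configured number of events (construct-then-verify)."""
        rng = np.random.default_rng(self.config.seed)
        names = [a for a in ARCHETYPES if self.config.archetype_weights.get(a, 0.0) > 0]
        weights = np.array([self.config.archetype_weights[a] for a in names])
        weights = weights / weights.sum()
        out: list[SimulatedEvent] = []
        for i in range(self.config.n_events):
            archetype = str(rng.choice(names, p=weights))
            for _ in range(self.config.max_resample):
                event = self._propose(archetype, rng)
                if self._matches_target(archetype, event):
                    break
            else:
                raise RuntimeError(
                    f"could not satisfy archetype {archetype!r} in "
                    f"{self.config.max_resample} proposals"
                )
            event = event.model_copy(update={"event_id": f"ev-{i:05d}"})
            target = ARCHETYPE_TARGETS[archetype]
            if target is None:
                target = classify_event(event, self.history, self.rule_config).label
            out.append(SimulatedEvent(event=event, archetype=archetype, true_label=target))
        return out


def generate_events(
    config: GeneratorConfig, rule_config: RuleConfig | None = None
) -> list[SimulatedEvent]:
    """Generate synthetic diary events with their intended true labels."""
    return DiaryGenerator(config, rule_config).generate()


def simulate_rater(
    true_labels: Sequence[HeadacheLabel], error_rate: float, seed: int
) -> list[HeadacheLabel]:
    """Emulate an imperfect human rater.

    Each label is independently replaced, with probability ``error_rate``, by
    a category chosen uniformly among the three other categories.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    categories = list(HeadacheLabel)
    out = []
    for label in true_labels:
        label = HeadacheLabel(label)
        if rng.random() < error_rate:
            others = [c for c in categories if c is not label]
            label = others[int(rng.integers(0, len(others)))]
        out.append(label)
    return out
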