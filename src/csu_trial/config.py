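"""Trial configuration: arms, effects, schedule, missingness and seeds.

The default configuration mirrors the design of a four-arm, placebo-controlled
dose-ranging trial in antihistamine-refractory chronic spontaneous urticaria
(CSU): ~23 patients per arm, an 8-week treatment period with a 4-week
follow-up, a baseline UAS7 around 27.5 (s.d. 7.3), dose-dependent week-8 UAS7
reductions from about -11 (placebo) to about -21 (highest dose), ~41% of
patients positive on the basophil histamine release assay (BHRA), and ~14%
early discontinuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    """A trial configuration failed validation; the message names the field."""


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: label, target enrolment, and effect parameters.

    ``week8_change`` is the target mean change from baseline in UAS7 at week 8
    (score points, negative = improvement) for patients outside the latent
    autoimmunity class.  ``autoimmune_shift`` is an additional change applied
    to patients in that class (type IIb autoimmunity), reflecting the greater
    benefit seen at lower doses in BHRA-positive patients.
    ``reactivity_change`` is the median proportional change in relative
    IgG-anti-FcεRI reactivity from baseline to week 8 (e.g. -0.44 = -44%).
    """

    label: str
    n: int
    week8_change: float
    autoimmune_shift: float = 0.0
    reactivity_change: float = 0.0


_DEFAULT_ARMS = (
    ArmSpec("placebo", 23, -11.2, 0.0, 0.20),
    ArmSpec("feneb_50mg_qd", 23, -11.7, -4.0, -0.44),
    ArmSpec("feneb_150mg_qd", 24, -17.6, -3.0, -0.54),
    ArmSpec("feneb_200mg_bid", 23, -20.7, 0.0, -0.44),
)

_DEFAULT_COUNTRIES = (("US", 0.40), ("Canada", 0.35), ("Germany", 0.25))


@dataclass
class TrialConfig:
    """Full specification of a simulated CSU trial.

    Attributes
    ----------
    arms
        Treatment arms in randomization order; arm 0 is the reference
        (placebo) arm.
    visit_weeks
        Scheduled analysis weeks. Week 0 is the baseline week (the 7 days
        before the first dose); treatment runs through week 8 (last dose
        day 56); weeks 9-12 are follow-up.
    baseline_uas7_mean, baseline_uas7_sd
        Population mean and s.d. of the baseline UAS7 (score points, 0-42).
    onset_days
        Time constant (days) of the exponential-onset effect profile,
        1 - exp(-t / onset_days); small values give the rapid onset seen
        with effective treatment.
    ar1_rho, daily_noise_sd
        AR(1) autocorrelation and stationary s.d. of the day-level latent
        noise (daily-UAS units, 0-6 scale).
    session_noise_sd
        S.d. of the independent per-session, per-component latent
        perturbation (single-component units, 0-3 scale).
    bhra_pos_prevalence
        Marginal prevalence of the latent type IIb autoimmunity class.
    dropout_rate
        Probability a patient discontinues during the 8-week treatment
        period (discontinuation day uniform over days 1..56).
    session_missing_rate
        Probability an individual post-baseline diary session is missing.
    assay_noise_sd
        Absorbance noise s.d. on ELISA wells (OD units); 0 gives exact
        biomarker round-trips.
    treatment_days
        Last dosing day (day 56 = end of week 8).
    """

    arms: tuple[ArmSpec, ...] = _DEFAULT_ARMS
    visit_weeks: tuple[int, ...] = tuple(range(0, 13))
    baseline_uas7_mean: float = 27.5
    baseline_uas7_sd: float = 7.3
    onset_days: float = 7.0
    ar1_rho: float = 0.6
    daily_noise_sd: float = 1.0
    session_noise_sd: float = 0.35
    bhra_pos_prevalence: float = 0.41
    dropout_rate: float = 0.14
    session_missing_rate: float = 0.03
    assay_noise_sd: float = 0.02
    treatment_days: int = 56
    followup_days: int = 84
    mid_uas7: float = 11.0
    mid_itch: float = 5.0
    countries: tuple[tuple[str, float], ...] = _DEFAULT_COUNTRIES
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.arms:
            raise ConfigError("arms: at least one arm is required")
        for arm in self.arms:
            if arm.n < 1:
                raise ConfigError(f"arms[{arm.label}].n: must be >= 1, got {arm.n}")
        for name in ("bhra_pos_prevalence", "dropout_rate", "session_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must be in [0, 1], got {v}")
        weeks = list(self.visit_weeks)
        if weeks != sorted(set(weeks)):
            raise ConfigError("visit_weeks: must be strictly increasing")
        if self.baseline_uas7_sd <= 0:
            raise ConfigError("baseline_uas7_sd: must be > 0")
        if not 0.0 < self.baseline_uas7_mean < 42.0:
            raise ConfigError("baseline_uas7_mean: must be in (0, 42)")
        if self.onset_days <= 0:
            raise ConfigError("onset_days: must be > 0")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho: must be in (-1, 1)")
        if self.treatment_days < 7:
            raise ConfigError("treatment_days: must be >= 7")
        wtot = sum(w for _, w in self.countries)
        if not self.countries or wtot <= 0:
            raise ConfigError("countries: need nonempty list with positive weights")

    @property
    def n_total(self) -> int:
        return sum(a.n for a in self.arms)

    @property
    def arm_labels(self) -> list[str]:
        return [a.label for a in self.arms]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = [asdict(a) for a in self.arms]
        d["countries"] = [list(c) for c in self.countries]
        d["visit_weeks"] = list(self.visit_weeks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "arms" in d:
            d["arms"] = tuple(ArmSpec(**a) for a in d["arms"])
        if "countries" in d:
            d["countries"] = tuple((str(c), float(w)) for c, w in d["countries"])
        if "visit_weeks" in d:
            d["visit_weeks"] = tuple(int(w) for w in d["visit_weeks"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("config file: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
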