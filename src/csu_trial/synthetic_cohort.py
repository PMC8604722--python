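"""Synthetic CSU trial cohorts: patients, eDiary trajectories and assay data.

The generator produces everything the downstream analysis consumes: patient
profiles with a latent type IIb autoimmunity class, twice-daily itch/hive
diary records, and raw immunoassay readings (ELISA plate absorbances, basophil
histamine release amounts) that the quantification modules invert.

Diary model
-----------
Each patient carries a latent daily disease intensity on the daily-UAS scale
(0-6):

    y(d) = b_i + E_arm * f(d) + S_auto * f(d) + eps(d)

where ``b_i`` is the patient's baseline level (normal across patients),
``f(d) = (1 - exp(-d/tau)) / (1 - exp(-T/tau))`` is an exponential-onset
profile reaching 1 at the last dose day ``T``, ``S_auto`` is an extra latent
shift for the autoimmunity class, and ``eps`` is stationary AR(1) noise.
Each diary session score (itch and hive, 0-3) is the latent component value
``y/2`` plus session noise, clipped to [0, 3] and stochastically rounded so
that the conditional mean of the ordinal score equals the clipped latent value
exactly.  Because of that, the population mean of any weekly score has a
closed form (a doubly-censored normal mean), and the generator calibrates the
latent baseline and per-arm effects against it: the expected baseline UAS7 and
expected week-8 change equal the configured values by construction.

Assay model
-----------
ELISA standards follow a four-parameter logistic absorbance-concentration
curve; a patient's control-protein-spiked wells read background + true
relative reactivity while antigen-spiked wells read background only, so
quantification recovers the true reactivity by subtraction.  BHRA raw amounts
encode the true percentage release against a per-batch healthy donor panel.
With ``assay_noise_sd = 0`` every biomarker round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .config import TrialConfig, ConfigError

__all__ = [
    "Cohort",
    "generate_cohort",
    "generate_profiles",
    "simulate_diary_trajectory",
    "apply_missingness_and_dropout",
    "simulate_assay_measurements",
    "expected_weekly_mean",
    "FOURPL_TRUE",
    "STANDARD_CONCS",
]

SESSIONS = ("AM", "PM")

# Forward 4PL used to synthesize plate absorbances:
# A(c) = high + (low - high) / (1 + (c / mid)**slope); increasing in c.
FOURPL_TRUE = {"low": 0.04, "high": 3.0, "mid": 0.8, "slope": 1.1}

# 7-point threefold dilution series spanning ~0.014-10 ng/ml.
STANDARD_CONCS = tuple(10.0 / 3.0**k for k in range(7))

_A630_OFFSET = 0.04
_BHRA_TOTAL = 120.0  # histamine content of lysed donor basophils (arbitrary units)

VISIT_DAYS = {"screening": -14, "day1": 1, "day57": 57, "day85": 85}


# --------------------------------------------------------------------------
# calibration of the latent scale
# --------------------------------------------------------------------------

def _censored_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """E[clip(X, lo, hi)] for X ~ Normal(mu, sd)."""
    if sd <= 0:
        return float(np.clip(mu, lo, hi))
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    return float(
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + mu * (norm.cdf(b) - norm.cdf(a))
        + sd * (norm.pdf(a) - norm.pdf(b))
    )


def _component_sd(config: TrialConfig) -> float:
    """Marginal s.d. of the latent single-component (0-3 scale) value."""
    sd_patient_day = config.baseline_uas7_sd / 7.0
    var_daily = sd_patient_day**2 + config.daily_noise_sd**2
    return float(np.sqrt(var_daily / 4.0 + config.session_noise_sd**2))


def expected_weekly_mean(latent_daily_mean: float, config: TrialConfig) -> float:
    """Population-expected UAS7 for a given latent daily mean (0-6 scale).

    A week sums 7 daily scores; each daily score averages two session sums of
    two ordinal components whose conditional mean is the clipped latent value,
    so the weekly expectation is 14x the censored-normal component mean.
    """
    s = _component_sd(config)
    return 14.0 * _censored_normal_mean(latent_daily_mean / 2.0, s, 0.0, 3.0)


def _latent_for_target(target_uas7: float, config: TrialConfig) -> float:
    """Invert expected_weekly_mean: latent daily mean achieving a target UAS7."""
    target = float(np.clip(target_uas7, 1e-6, 42.0 - 1e-6))
    return brentq(
        lambda m: expected_weekly_mean(m, config) - target, -20.0, 26.0, xtol=1e-10
    )


def _calibrate(config: TrialConfig) -> dict:
    """Latent baseline mean and per-arm latent effect/shift (daily-UAS units)."""
    m0 = _latent_for_target(config.baseline_uas7_mean, config)
    out = {"m0": m0, "effects": {}, "shifts": {}}
    for arm in config.arms:
        m8 = _latent_for_target(config.baseline_uas7_mean + arm.week8_change, config)
        out["effects"][arm.label] = m8 - m0
        if arm.autoimmune_shift:
            m8s = _latent_for_target(
                config.baseline_uas7_mean + arm.week8_change + arm.autoimmune_shift,
                config,
            )
            out["shifts"][arm.label] = m8s - m8
        else:
            out["shifts"][arm.label] = 0.0
    return out


# --------------------------------------------------------------------------
# cohort container
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """A complete simulated trial: profiles, diary and raw assay readings."""

    config: TrialConfig
    profiles: pd.DataFrame
    diary: pd.DataFrame
    assays: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write profiles/diary/assays CSVs; returns {name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("profiles", self.profiles),
            ("diary", self.diary),
            ("assays", self.assays),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    """Deterministic substream: adding patients never perturbs existing ones."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------

def generate_profiles(config: TrialConfig, seed: int) -> pd.DataFrame:
    labels = [c for c, _ in config.countries]
    weights = np.array([w for _, w in config.countries], dtype=float)
    weights /= weights.sum()
    sd_patient_day = config.baseline_uas7_sd / 7.0
    m0 = _calibrate(config)["m0"]

    rows = []
    idx = 0
    for arm in config.arms:
        for _ in range(arm.n):
            rng = _rng(seed, 1, idx)
            auto = bool(rng.random() < config.bhra_pos_prevalence)
            if auto:
                release = float(np.clip(rng.normal(15.0, 5.0), 0.5, 95.0))
                reactivity = float(np.clip(rng.lognormal(np.log(2.0), 0.5), 0.02, 8.0))
                ige = float(rng.lognormal(np.log(25.0), 0.8))
            else:
                release = float(np.clip(rng.normal(1.5, 1.0), 0.0, 95.0))
                reactivity = float(np.clip(rng.lognormal(np.log(0.08), 0.6), 0.005, 8.0))
                ige = float(rng.lognormal(np.log(120.0), 1.0))
            dropout = (
                int(rng.integers(1, config.treatment_days + 1))
                if rng.random() < config.dropout_rate
                else np.nan
            )
            rows.append(
                {
                    "patient_id": f"P{idx + 1:03d}",
                    "arm": arm.label,
                    "country": labels[int(rng.choice(len(labels), p=weights))],
                    "latent_baseline_intensity": float(rng.normal(m0, sd_patient_day)),
                    "autoimmune_class": auto,
                    "true_bhra_release": release,
                    "true_reactivity_baseline": reactivity,
                    "total_ige": ige,
                    "dropout_day": dropout,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# diary
# --------------------------------------------------------------------------

def _onset_profile(days: np.ndarray, config: TrialConfig) -> np.ndarray:
    """Fraction of the full effect in place on each study day (0 pre-dose)."""
    tau = config.onset_days
    T = config.treatment_days
    t = np.clip(days, 0, None).astype(float)
    f = (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-T / tau))
    return np.where(days <= 0, 0.0, np.minimum(f, 1.0))


def simulate_diary_trajectory(
    profile: dict | pd.Series, config: TrialConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one patient's full diary (days -6 .. followup_days).

    The baseline week (the 7 days ending on day 0) is always complete,
    matching the eligibility requirement of full diary coverage in the 7 days
    before the first dose; missingness is applied later.
    """
    arm = str(profile["arm"])
    cal = _calibrate(config)
    effect = cal["effects"][arm]
    if bool(profile["autoimmune_class"]):
        effect = effect + cal["shifts"][arm]

    days = np.arange(-6, config.followup_days + 1)
    nd = len(days)
    f = _onset_profile(days, config)

    # stationary AR(1) day-level noise
    rho, s = config.ar1_rho, config.daily_noise_sd
    eps = np.empty(nd)
    eps[0] = rng.normal(0.0, s)
    innov = rng.normal(0.0, s * np.sqrt(1.0 - rho**2), nd - 1)
    for i in range(1, nd):
        eps[i] = rho * eps[i - 1] + innov[i - 1]

    latent_daily = float(profile["latent_baseline_intensity"]) + effect * f + eps

    # per-day, per-session, per-component ordinal scores
    comp = latent_daily[:, None, None] / 2.0 + rng.normal(
        0.0, config.session_noise_sd, (nd, 2, 2)
    )
    clipped = np.clip(comp, 0.0, 3.0)
    scores = np.floor(clipped + rng.random((nd, 2, 2))).astype(int)
    scores = np.minimum(scores, 3)

    p_rescue = 0.85 * np.clip(latent_daily, 0.0, 6.0) / 6.0
    rescue = rng.random((nd, 2)) < p_rescue[:, None]

    return pd.DataFrame(
        {
            "patient_id": str(profile["patient_id"]),
            "study_day": np.repeat(days, 2),
            "session": np.tile(SESSIONS, nd),
            "itch": scores[:, :, 0].ravel(),
            "hive": scores[:, :, 1].ravel(),
            "rescue": rescue.ravel(),
            "missing": False,
        }
    )


def apply_missingness_and_dropout(cohort: Cohort, seed: int | None = None) -> Cohort:
    """Flag diary sessions missing: everything after a patient's dropout day,
    plus sporadic post-baseline sessions at ``session_missing_rate``.

    Assay samples at visits after the dropout day are removed.  Scores of
    missing sessions are set to NA.  Deterministic given (cohort, seed);
    with dropout and missingness rates both zero the cohort is unchanged.
    """
    config = cohort.config
    seed = config.seed if seed is None else seed
    diary = cohort.diary.copy()
    dropout = cohort.profiles.set_index("patient_id")["dropout_day"]

    dd = diary["patient_id"].map(dropout).to_numpy(dtype=float)
    miss = np.zeros(len(diary), dtype=bool)
    with np.errstate(invalid="ignore"):
        miss |= np.where(np.isnan(dd), False, diary["study_day"].to_numpy() > dd)

    if config.session_missing_rate > 0:
        ids = cohort.profiles["patient_id"].tolist()
        postbase = diary["study_day"].to_numpy() > 0
        for i, pid in enumerate(ids):
            sel = (diary["patient_id"] == pid).to_numpy() & postbase
            r = _rng(seed, 4, i).random(int(sel.sum()))
            miss[np.flatnonzero(sel)] |= r < config.session_missing_rate

    diary["missing"] = miss
    diary[["itch", "hive"]] = diary[["itch", "hive"]].astype(float)
    diary.loc[miss, ["itch", "hive"]] = np.nan
    diary["rescue"] = diary["rescue"].astype("boolean")
    diary.loc[miss, "rescue"] = pd.NA

    assays = cohort.assays
    if len(assays):
        vd = assays["visit"].map(VISIT_DAYS).to_numpy(dtype=float)
        ad = assays["patient_id"].map(dropout).to_numpy(dtype=float)
        keep = np.isnan(ad) | (vd <= ad) | (assays["role"] != "sample").to_numpy()
        assays = assays.loc[keep].reset_index(drop=True)

    return Cohort(config=config, profiles=cohort.profiles, diary=diary, assays=assays)


# --------------------------------------------------------------------------
# assays
# --------------------------------------------------------------------------

def _fourpl(conc, p=FOURPL_TRUE):
    conc = np.asarray(conc, dtype=float)
    return p["high"] + (p["low"] - p["high"]) / (1.0 + (conc / p["mid"]) ** p["slope"])


def _elisa_wells(batch, patient_id, role, spike, conc, noise_sd, rng, n_dup=2):
    rows = []
    for _ in range(n_dup):
        signal = float(_fourpl(conc)) if conc is not None else 0.0
        a450 = signal + _A630_OFFSET + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        a630 = _A630_OFFSET
        rows.append(
            {
                "batch": batch,
                "patient_id": patient_id,
                "visit": batch,
                "assay": "elisa",
                "role": role,
                "spike": spike,
                "nominal_conc": np.nan if conc is None else conc,
                "a450": a450,
                "a630": a630,
                "hr_sample": np.nan,
                "hr_total": np.nan,
            }
        )
    return rows


def _batch_fixtures(batch: str, config: TrialConfig, rng: np.random.Generator) -> list[dict]:
    """Standards, blanks and the 16-donor healthy ELISA panel for one batch."""
    rows = []
    for conc in STANDARD_CONCS:
        rows += _elisa_wells(batch, "STD", "standard", "none", conc, config.assay_noise_sd, rng)
    rows += _elisa_wells(batch, "BLANK", "blank", "none", None, config.assay_noise_sd, rng)
    for h in range(16):
        bg = float(np.clip(rng.lognormal(np.log(0.15), 0.3), 0.02, 2.0))
        rr = float(np.clip(rng.normal(0.10, 0.06), 0.0, 1.0))
        hid = f"HV{h + 1:02d}"
        rows += _elisa_wells(batch, hid, "healthy_control", "control_protein",
                             bg + rr, config.assay_noise_sd, rng)
        rows += _elisa_wells(batch, hid, "healthy_control", "antigen",
                             bg, config.assay_noise_sd, rng)
    return rows


def _bhra_fixtures(config: TrialConfig, rng: np.random.Generator) -> list[dict]:
    """Healthy 5-donor panel for the basophil histamine release assay."""
    rows = []
    for h in range(5):
        pct = float(np.clip(rng.normal(2.5, 0.75), 0.1, 20.0))
        rows.append(
            {
                "batch": "screening",
                "patient_id": f"HD{h + 1}",
                "visit": "screening",
                "assay": "bhra",
                "role": "healthy_control",
                "spike": "none",
                "nominal_conc": np.nan,
                "a450": np.nan,
                "a630": np.nan,
                "hr_sample": pct / 100.0 * _BHRA_TOTAL,
                "hr_total": _BHRA_TOTAL,
            }
        )
    return rows


def simulate_assay_measurements(
    profile: dict | pd.Series, config: TrialConfig, rng: np.random.Generator
) -> list[dict]:
    """Raw assay rows for one patient: ELISA wells at each serum visit and a
    screening BHRA measurement."""
    rows = []
    rr0 = float(profile["true_reactivity_baseline"])
    arm = next(a for a in config.arms if a.label == str(profile["arm"]))
    bg = float(np.clip(rng.lognormal(np.log(0.15), 0.3), 0.02, 1.5))
    noise = config.assay_noise_sd
    for visit in ("screening", "day1", "day57", "day85"):
        if visit in ("screening", "day1"):
            rr = rr0
        else:
            mult = 1.0 + arm.reactivity_change
            if noise > 0:
                mult *= float(rng.lognormal(0.0, 0.25))
            rr = float(np.clip(rr0 * max(mult, 0.0), 0.0, 8.0))
        rows += _elisa_wells(visit, str(profile["patient_id"]), "sample",
                             "control_protein", bg + rr, noise, rng)
        rows += _elisa_wells(visit, str(profile["patient_id"]), "sample",
                             "antigen", bg, noise, rng)
    # BHRA on the screening serum
    rows.append(
        {
            "batch": "screening",
            "patient_id": str(profile["patient_id"]),
            "visit": "screening",
            "assay": "bhra",
            "role": "sample",
            "spike": "none",
            "nominal_conc": np.nan,
            "a450": np.nan,
            "a630": np.nan,
            "hr_sample": float(profile["true_bhra_release"]) / 100.0 * _BHRA_TOTAL,
            "hr_total": _BHRA_TOTAL,
        }
    )
    return rows


# --------------------------------------------------------------------------
# top-level generator
# --------------------------------------------------------------------------

def generate_cohort(
    config: TrialConfig, seed: int | None = None, apply_missingness: bool = True
) -> Cohort:
    """Generate a complete synthetic trial.

    Deterministic: identical (config, seed) yield byte-identical serialized
    cohorts.  Per-patient random substreams are derived from the master seed,
    so enlarging the trial does not perturb already-generated patients.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)

    profiles = generate_profiles(config, seed)
    diary = pd.concat(
        [
            simulate_diary_trajectory(row, config, _rng(seed, 2, i))
            for i, row in profiles.iterrows()
        ],
        ignore_index=True,
    )

    assay_rows = []
    for bi, batch in enumerate(("screening", "day1", "day57", "day85")):
        assay_rows += _batch_fixtures(batch, config, _rng(seed, 5, bi))
    assay_rows += _bhra_fixtures(config, _rng(seed, 6))
    for i, row in profiles.iterrows():
        assay_rows += simulate_assay_measurements(row, config, _rng(seed, 3, i))
    assays = pd.DataFrame(assay_rows)

    cohort = Cohort(config=config, profiles=profiles, diary=diary, assays=assays)
    if apply_missingness:
        cohort = apply_missingness_and_dropout(cohort, seed)
    return cohort
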