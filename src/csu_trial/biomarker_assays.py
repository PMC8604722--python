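"""Biomarker assay quantification: BHRA scaling and IgG-anti-FcεRI ELISA.

Two bespoke assays mark type IIb autoimmune CSU:

* **BHRA** (basophil histamine release assay): patient serum is applied to
  donor basophils.  Percentage histamine release is HR_sample / HR_total x
  100 where HR_total is the histamine content of lysed donor cells.  The
  serum's BHRA value is %HR_sample / %HR_healthy x 10, where %HR_healthy is
  the mean + 2 s.d. of the percentage release induced by a panel of healthy
  control sera; values >= 10 are BHRA-positive.

* **Competition ELISA** for IgG autoantibodies against the high-affinity IgE
  receptor FcεRI: serum is pre-incubated with the receptor antigen
  (which absorbs specific IgG) or a nonspecific control protein, both are
  quantified against a four-parameter-logistic standard curve
  (dual-wavelength background-corrected, A450 - A630), and the relative
  reactivity (RR) is the control-spiked minus antigen-spiked concentration.
  The per-experiment positivity threshold (UNR, upper normal range) is the
  mean + 3 s.d. of RR over a healthy panel; RR > UNR is positive.  Percent
  change from baseline floors both values at the UNR first.

Standard deviations use the n-1 (sample) convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "AssayError",
    "StandardCurveFit",
    "BhraResult",
    "ReactivityResult",
    "correct_absorbance",
    "fit_standard_curve",
    "quantify_concentration",
    "compute_relative_reactivity",
    "compute_unr_and_status",
    "percent_change_reactivity",
    "compute_bhra",
    "classify_low_ige",
    "quantify_assays",
]

LOW_IGE_THRESHOLD = 43.0  # IU/ml; low-IgE marker of type IIb autoimmunity


class AssayError(ValueError):
    pass


def correct_absorbance(a450, a630):
    """Dual-wavelength background correction: A450 - A630.

    Either reading missing (NaN/None) marks the well unusable (returns NaN).
    """
    a450 = np.asarray(a450, dtype=float)
    a630 = np.asarray(a630, dtype=float)
    out = a450 - a630
    return float(out) if out.ndim == 0 else out


def _fourpl(conc, low, high, mid, slope):
    """Four-parameter logistic, increasing in concentration for slope > 0."""
    return high + (low - high) / (1.0 + (conc / mid) ** slope)


@dataclass
class StandardCurveFit:
    """Converged 4PL calibration with its usable concentration range."""

    low: float
    high: float
    mid: float
    slope: float
    residual_sd: float
    converged: bool
    conc_min: float
    conc_max: float
    plate: str = ""

    def predict(self, conc):
        return _fourpl(np.asarray(conc, dtype=float), self.low, self.high,
                       self.mid, self.slope)

    def inverse(self, absorbance):
        """Concentration for a corrected absorbance, clamped to the
        calibration range (with a warning) outside it."""
        if not self.converged:
            raise AssayError(f"standard curve on plate {self.plate!r} did not converge")
        a = np.atleast_1d(np.asarray(absorbance, dtype=float))
        lo, hi = sorted((self.low, self.high))
        a_min = float(self.predict(self.conc_min))
        a_max = float(self.predict(self.conc_max))
        a_lo, a_hi = sorted((a_min, a_max))
        out = np.empty_like(a)
        clamped = (a <= a_lo) | (a >= a_hi)
        if clamped.any():
            warnings.warn(
                f"{int(clamped.sum())} absorbance value(s) outside the "
                f"calibration range on plate {self.plate!r}; clamped",
                stacklevel=2,
            )
        inside = ~clamped
        ratio = (self.low - self.high) / (a[inside] - self.high) - 1.0
        out[inside] = self.mid * ratio ** (1.0 / self.slope)
        # clamp to whichever range endpoint the absorbance fell beyond
        lo_end = self.conc_min if a_min < a_max else self.conc_max
        hi_end = self.conc_max if a_min < a_max else self.conc_min
        out[a <= a_lo] = lo_end
        out[a >= a_hi] = hi_end
        res = np.clip(out, self.conc_min, self.conc_max)
        return float(res[0]) if np.isscalar(absorbance) or np.ndim(absorbance) == 0 else res


def fit_standard_curve(
    absorbances, concentrations, plate: str = ""
) -> StandardCurveFit:
    """Fit the 4PL calibration to standard wells (duplicates averaged).

    Raises :class:`AssayError` for degenerate (flat or non-monotone) standards
    or non-convergence.
    """
    df = pd.DataFrame(
        {"conc": np.asarray(concentrations, float), "a": np.asarray(absorbances, float)}
    ).dropna()
    df = df.groupby("conc", sort=True)["a"].mean().reset_index()
    if len(df) < 4:
        raise AssayError(f"plate {plate!r}: need >= 4 usable standard levels, got {len(df)}")
    conc = df["conc"].to_numpy()
    a = df["a"].to_numpy()
    if np.ptp(a) < 1e-9:
        raise AssayError(f"plate {plate!r}: degenerate standards (constant absorbance)")
    rho = np.corrcoef(np.log(conc), a)[0, 1]
    if abs(rho) < 0.8:
        raise AssayError(f"plate {plate!r}: standards not monotone in concentration")

    lo0, hi0 = float(a.min()), float(a.max())
    p0 = [lo0, hi0, float(np.exp(np.median(np.log(conc)))), 1.0 if rho > 0 else -1.0]
    try:
        popt, _ = curve_fit(
            _fourpl, conc, a, p0=p0, maxfev=20000,
            bounds=([-1.0, lo0 - 1.0, conc.min() / 100, 0.05],
                    [hi0 + 1.0, hi0 + 10.0, conc.max() * 100, 20.0]),
        )
    except RuntimeError as exc:
        raise AssayError(f"plate {plate!r}: standard curve fit failed: {exc}") from exc
    resid = a - _fourpl(conc, *popt)
    return StandardCurveFit(
        low=float(popt[0]), high=float(popt[1]), mid=float(popt[2]),
        slope=float(popt[3]),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
        converged=True, conc_min=float(conc.min()), conc_max=float(conc.max()),
        plate=plate,
    )


def quantify_concentration(fit: StandardCurveFit, corrected_absorbances) -> float:
    """Mean concentration over duplicate wells, inverted individually."""
    a = np.atleast_1d(np.asarray(corrected_absorbances, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    concs = np.atleast_1d(fit.inverse(a))
    if concs.size >= 2:
        cv = np.std(concs, ddof=1) / max(np.mean(concs), 1e-12)
        if cv > 0.20:
            warnings.warn(
                f"discordant duplicates on plate {fit.plate!r} (CV {cv:.0%})",
                stacklevel=2,
            )
    return float(np.mean(concs))


def compute_relative_reactivity(conc_control_spiked: float, conc_antigen_spiked: float) -> float:
    """RR = control-protein-spiked minus antigen-spiked concentration (ng/ml).

    Negative values are allowed before thresholding against the UNR.
    """
    return float(conc_control_spiked) - float(conc_antigen_spiked)


def compute_unr_and_status(healthy_rr, patient_rr: float) -> tuple[float, bool]:
    """UNR = healthy mean + 3 s.d.; positive iff RR strictly exceeds it."""
    h = np.asarray(healthy_rr, dtype=float)
    h = h[~np.isnan(h)]
    if h.size < 2:
        raise AssayError(f"need >= 2 healthy reactivity values, got {h.size}")
    unr = float(h.mean() + 3.0 * h.std(ddof=1))
    return unr, bool(patient_rr > unr)


def percent_change_reactivity(rr_baseline: float, rr_followup: float, unr: float) -> float:
    """Percent change in RR with both values floored at the UNR first."""
    b = max(float(rr_baseline), float(unr))
    f = max(float(rr_followup), float(unr))
    if b == 0.0:
        raise AssayError("floored baseline reactivity is zero; percent change undefined")
    return 100.0 * (f - b) / b


@dataclass
class BhraResult:
    patient_id: str
    pct_release_sample: float
    pct_release_healthy_threshold: float
    bhra_value: float
    positive: bool


def compute_bhra(
    hr_sample: float, hr_total: float, healthy_pct_releases, patient_id: str = ""
) -> BhraResult:
    """BHRA value = %HR_sample / (healthy mean + 2 s.d.) x 10; >= 10 positive."""
    if not hr_total > 0:
        raise AssayError(f"total lysate histamine must be > 0, got {hr_total}")
    h = np.asarray(healthy_pct_releases, dtype=float)
    h = h[~np.isnan(h)]
    if h.size < 2:
        raise AssayError(f"need >= 2 healthy panel values, got {h.size}")
    pct = 100.0 * float(hr_sample) / float(hr_total)
    threshold = float(h.mean() + 2.0 * h.std(ddof=1))
    if threshold <= 0:
        raise AssayError("healthy-panel threshold must be positive")
    value = 10.0 * pct / threshold
    # inclusive boundary with a float guard: a release exactly at the healthy
    # threshold scores 10 and is positive regardless of rounding in the ratio
    positive = bool(value >= 10.0 or np.isclose(value, 10.0, rtol=1e-12, atol=0.0))
    return BhraResult(
        patient_id=patient_id,
        pct_release_sample=pct,
        pct_release_healthy_threshold=threshold,
        bhra_value=value,
        positive=positive,
    )


def classify_low_ige(total_ige: float) -> bool:
    """Low serum total IgE marker: strictly below 43 IU/ml."""
    if total_ige < 0:
        raise ValueError(f"total IgE must be >= 0, got {total_ige}")
    return total_ige < LOW_IGE_THRESHOLD


@dataclass
class ReactivityResult:
    patient_id: str
    visit: str
    conc_control_spiked: float
    conc_antigen_spiked: float
    relative_reactivity: float
    unr: float
    positive: bool
    pct_change_from_baseline: float | None = None


# --------------------------------------------------------------------------
# plate-level pipeline
# --------------------------------------------------------------------------

def _batch_reactivities(batch_df: pd.DataFrame, plate: str) -> tuple[pd.DataFrame, float]:
    """Quantify all ELISA RRs on one plate; returns (rr table, UNR)."""
    corrected = correct_absorbance(batch_df["a450"], batch_df["a630"])
    batch_df = batch_df.assign(corrected=corrected)
    std = batch_df[batch_df["role"] == "standard"]
    fit = fit_standard_curve(std["corrected"], std["nominal_conc"], plate=plate)

    rows = []
    samples = batch_df[batch_df["role"].isin(["sample", "healthy_control"])]
    for (pid, role), grp in samples.groupby(["patient_id", "role"]):
        ctrl = grp.loc[grp["spike"] == "control_protein", "corrected"]
        anti = grp.loc[grp["spike"] == "antigen", "corrected"]
        if ctrl.empty or anti.empty:
            raise AssayError(f"plate {plate!r}: patient {pid} missing a spike condition")
        c_ctrl = quantify_concentration(fit, ctrl)
        c_anti = quantify_concentration(fit, anti)
        rows.append(
            {"patient_id": pid, "role": role, "conc_control": c_ctrl,
             "conc_antigen": c_anti,
             "rr": compute_relative_reactivity(c_ctrl, c_anti)}
        )
    rr = pd.DataFrame(rows)
    healthy = rr.loc[rr["role"] == "healthy_control", "rr"].to_numpy()
    if healthy.size < 2:
        raise AssayError(f"plate {plate!r}: healthy ELISA panel missing")
    unr = float(healthy.mean() + 3.0 * healthy.std(ddof=1))
    return rr, unr


def quantify_assays(
    assays: pd.DataFrame,
    baseline_visit: str = "day1",
    followup_visits: tuple[str, ...] = ("day57", "day85"),
) -> pd.DataFrame:
    """Run the full assay pipeline on a long plate table.

    Per ELISA batch (visit): fit the standard curve, quantify both spike
    conditions per serum, compute RR, recompute the batch UNR from the healthy
    panel and call positivity.  Percent change from baseline is computed for
    follow-up visits in patients positive at baseline, flooring at the
    baseline batch's UNR.  BHRA rows yield the scaled release value against
    the healthy donor panel.  Returns one row per patient with visit-level RR
    columns plus BHRA results.
    """
    elisa = assays[assays["assay"] == "elisa"]
    per_visit: dict[str, pd.DataFrame] = {}
    unrs: dict[str, float] = {}
    for visit, batch in elisa.groupby("visit"):
        rr, unr = _batch_reactivities(batch, plate=str(visit))
        per_visit[str(visit)] = rr.set_index("patient_id")
        unrs[str(visit)] = unr

    bhra = assays[assays["assay"] == "bhra"]
    healthy_pct = (
        100.0 * bhra.loc[bhra["role"] == "healthy_control", "hr_sample"]
        / bhra.loc[bhra["role"] == "healthy_control", "hr_total"]
    ).to_numpy()

    patients = sorted(
        set(elisa.loc[elisa["role"] == "sample", "patient_id"]).union(
            bhra.loc[bhra["role"] == "sample", "patient_id"]
        )
    )
    out = []
    for pid in patients:
        row: dict = {"patient_id": pid}
        base_rr = np.nan
        if baseline_visit in per_visit and pid in per_visit[baseline_visit].index:
            r = per_visit[baseline_visit].loc[pid]
            base_rr = float(r["rr"])
            row["rr_baseline"] = base_rr
            row["unr_baseline"] = unrs[baseline_visit]
            row["igg_fceri_pos"] = base_rr > unrs[baseline_visit]
        for visit in followup_visits:
            if visit in per_visit and pid in per_visit[visit].index:
                r = per_visit[visit].loc[pid]
                row[f"rr_{visit}"] = float(r["rr"])
                if row.get("igg_fceri_pos") and not np.isnan(base_rr):
                    row[f"pct_change_{visit}"] = percent_change_reactivity(
                        base_rr, float(r["rr"]), unrs[baseline_visit]
                    )
        b = bhra[(bhra["role"] == "sample") & (bhra["patient_id"] == pid)]
        if len(b):
            res = compute_bhra(
                float(b["hr_sample"].iloc[0]), float(b["hr_total"].iloc[0]),
                healthy_pct, patient_id=str(pid),
            )
            row["bhra_value"] = res.bhra_value
            row["bhra_pos"] = res.positive
        out.append(row)
    return pd.DataFrame(out)
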