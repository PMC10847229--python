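"""One-compartment oral-absorption pharmacokinetics with allometric scaling.

The structural model is first-order absorption into a single central
compartment with apparent clearance CL/F and apparent volume V/F:

    C(t) = D * ka / (V * (ka - ke)) * (exp(-ke * t) - exp(-ka * t)),
    ke = CL / V,

with CL/F and V/F allometrically scaled to body weight using fixed
exponents 0.75 and 1.0 respectively, and an optional dose covariate on
both (power form on dose normalized to 30 mg/kg by default).  Under linear
kinetics the total exposure is AUC(0-inf) = D / CL, which is how per-animal
exposure is predicted for downstream PK/PD modeling.

Module contents:

* :func:`apply_allometry` / :func:`simulate_concentration` — forward model.
* :func:`run_nca` — noncompartmental analysis (Cmax, Tmax, lambda_z,
  linear-up/log-down trapezoid AUC).
* :class:`PopulationPKModel` — simplified population estimation (pooled
  least squares on log concentrations) with likelihood-ratio-style dose
  covariate selection at a 3.84 objective-function drop.
* :func:`predict_individual_auc` — exposure from fitted parameters.
* :func:`exposure_concentration_regression` — OLS of predicted AUC on the
  0.5 h plasma concentration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PKParameterSet",
    "ConcentrationProfile",
    "NCAResult",
    "ExposureEstimate",
    "apply_allometry",
    "one_compartment_concentration",
    "simulate_concentration",
    "run_nca",
    "PopulationPKModel",
    "PopulationPKResults",
    "predict_individual_auc",
    "exposure_concentration_regression",
    "ExposureRegression",
]

#: mg/L (== ug/mL) to ng/mL
_MG_L_TO_NG_ML = 1000.0


@dataclass(frozen=True)
class PKParameterSet:
    """Structural + variability parameters of the population PK model.

    ``cl_f_typ`` (L/h) and ``v_f_typ`` (L) are the typical values at
    ``ref_weight_kg``.  Allometric exponents are fixed at 0.75 (CL/F) and
    1.0 (V/F).  ``dose_effect_cl``/``dose_effect_v`` parameterize the dose
    covariate; with ``dose_covariate_form="power"`` the multiplier is
    ``(dose / ref_dose)^theta``, with ``"proportional"`` it is
    ``1 + theta * (dose / ref_dose - 1)``.
    """

    ka: float
    cl_f_typ: float
    v_f_typ: float
    ref_weight_kg: float = 0.025
    exp_cl: float = 0.75
    exp_v: float = 1.0
    dose_effect_cl: float = 0.0
    dose_effect_v: float = 0.0
    dose_covariate_form: str = "power"
    ref_dose_mg_per_kg: float = 30.0
    bsv_sd_cl: float = 0.0
    bsv_sd_v: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka", "cl_f_typ", "v_f_typ", "ref_weight_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dose_covariate_form not in ("power", "proportional"):
            raise ValueError("dose_covariate_form must be 'power' or 'proportional'")
        if self.bsv_sd_cl < 0 or self.bsv_sd_v < 0:
            raise ValueError("between-subject SDs must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConcentrationProfile:
    """A single animal's concentration-time course."""

    times_h: np.ndarray
    conc_ng_per_ml: np.ndarray
    dose_mg: float
    weight_kg: float
    animal_id: str = ""
    sex: str = ""
    dose_mg_per_kg: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_ng_per_ml = np.asarray(self.conc_ng_per_ml, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.conc_ng_per_ml.shape:
            raise ValueError("times and concentrations must be 1-D and aligned")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc_ng_per_ml < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class NCAResult:
    cmax: float
    tmax: float
    lambda_z: float | None
    auc_0_last: float
    auc_0_inf: float | None
    cl_f_obs: float | None
    lambda_z_n_points: int = 0
    lambda_z_r2adj: float | None = None
    lambda_z_message: str = ""


@dataclass
class ExposureEstimate:
    """Predicted per-animal exposure: AUC = dose / individual CL/F.

    ``auc`` is in mg*h/L (equivalently ug*h/mL); ``auc_daily_bid`` is the
    steady-state daily exposure under twice-daily dosing, (2*dose)/CL.
    """

    animal_id: str
    auc: float
    cl_f_ind: float
    dose_mg: float
    auc_daily_bid: float


def _dose_multiplier(theta: float, form: str, dose_mg_per_kg: float | None,
                     ref_dose: float) -> float:
    if dose_mg_per_kg is None or theta == 0.0:
        return 1.0
    x = dose_mg_per_kg / ref_dose
    if form == "power":
        return x ** theta
    return 1.0 + theta * (x - 1.0)


def apply_allometry(params: PKParameterSet, weight_kg: float,
                    dose_mg_per_kg: float | None = None) -> tuple[float, float]:
    """Weight- and dose-scaled (CL/F, V/F) for one animal.

    CL/F = cl_f_typ * (W / W_ref)^0.75 * g_cl(dose)
    V/F  = v_f_typ  * (W / W_ref)^1.0  * g_v(dose)
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    wr = weight_kg / params.ref_weight_kg
    cl = params.cl_f_typ * wr ** params.exp_cl * _dose_multiplier(
        params.dose_effect_cl, params.dose_covariate_form, dose_mg_per_kg,
        params.ref_dose_mg_per_kg)
    v = params.v_f_typ * wr ** params.exp_v * _dose_multiplier(
        params.dose_effect_v, params.dose_covariate_form, dose_mg_per_kg,
        params.ref_dose_mg_per_kg)
    return cl, v


def one_compartment_concentration(times_h, dose_mg: float, ka: float,
                                  cl_f: float, v_f: float) -> np.ndarray:
    """Closed-form concentration (mg/L) after a single oral dose.

    Switches to the analytic equal-rate limit C(t) = (D*ka*t/V) e^{-ka t}
    when ka and ke coincide to relative 1e-9.
    """
    t = np.asarray(times_h, dtype=float)
    ke = cl_f / v_f
    if abs(ka - ke) / ke < 1e-9:
        return dose_mg * ka * t / v_f * np.exp(-ka * t)
    return (dose_mg * ka / (v_f * (ka - ke))
            * (np.exp(-ke * t) - np.exp(-ka * t)))


def simulate_concentration(params: PKParameterSet, dose_mg: float,
                           weight_kg: float, times_h: Sequence[float],
                           dose_mg_per_kg: float | None = None,
                           eta_cl: float = 0.0, eta_v: float = 0.0,
                           animal_id: str = "", sex: str = "") -> ConcentrationProfile:
    """Noise-free predicted profile for one animal (ng/mL).

    ``eta_cl``/``eta_v`` are individual lognormal deviations: the
    individual parameter is the scaled typical value times exp(eta).
    """
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    cl, v = apply_allometry(params, weight_kg, dose_mg_per_kg)
    cl *= math.exp(eta_cl)
    v *= math.exp(eta_v)
    conc = one_compartment_concentration(t, dose_mg, params.ka, cl, v)
    return ConcentrationProfile(
        times_h=t, conc_ng_per_ml=conc * _MG_L_TO_NG_ML, dose_mg=dose_mg,
        weight_kg=weight_kg, animal_id=animal_id, sex=sex,
        dose_mg_per_kg=dose_mg_per_kg)


def tmax_closed_form(ka: float, ke: float) -> float:
    """Time of the concentration peak, ln(ka/ke)/(ka-ke)."""
    if abs(ka - ke) / ke < 1e-9:
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """Trapezoid AUC: linear when rising or near zero, log when falling."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def run_nca(profile: ConcentrationProfile, max_lambda_z_points: int = 6) -> NCAResult:
    """Noncompartmental summary of one profile.

    lambda_z is fit by log-linear regression over the last k terminal
    observations, k in 3..max_lambda_z_points, excluding the Cmax point and
    non-positive concentrations, keeping the candidate with the best
    adjusted R^2.  AUC(0-last) uses the linear-up/log-down trapezoid;
    AUC(0-inf) = AUC(0-last) + C_last / lambda_z.
    """
    t, c = profile.times_h, profile.conc_ng_per_ml
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last = _auc_lin_up_log_down(t, c)

    # terminal phase candidates: strictly after tmax, positive concentrations
    term = np.where((np.arange(len(t)) > imax) & (c > 0))[0]
    best = None
    for k in range(3, max_lambda_z_points + 1):
        if len(term) < k:
            break
        idx = term[-k:]
        x, y = t[idx], np.log(c[idx])
        slope, intercept, r, _, _ = stats.linregress(x, y)
        if slope >= 0:
            continue
        r2adj = 1 - (1 - r ** 2) * (k - 1) / (k - 2)
        if best is None or r2adj > best[1] + 1e-12:
            best = (-slope, r2adj, k)
    if best is None:
        return NCAResult(cmax=cmax, tmax=tmax, lambda_z=None,
                         auc_0_last=auc_last, auc_0_inf=None, cl_f_obs=None,
                         lambda_z_message="terminal slope not estimable "
                         "(need >=3 positive post-Tmax points with decline)")
    lam, r2adj, k = best
    c_last = c[term[-1]]
    auc_inf = auc_last + c_last / lam
    # AUC is in ng*h/mL = mg*h/L * 1000; CL/F in L/h
    cl_f_obs = profile.dose_mg / (auc_inf / _MG_L_TO_NG_ML)
    return NCAResult(cmax=cmax, tmax=tmax, lambda_z=lam, auc_0_last=auc_last,
                     auc_0_inf=auc_inf, cl_f_obs=cl_f_obs,
                     lambda_z_n_points=k, lambda_z_r2adj=r2adj)


# ---------------------------------------------------------------------------
# population estimation
# ---------------------------------------------------------------------------

class PopulationPKModel:
    """Simplified population PK estimation (two-stage or pooled).

    The default ``method="two_stage"`` fits each animal's profile by
    nonlinear least squares on the log concentration scale, then regresses
    the individual log parameters (allometry-corrected with the fixed
    exponents) on the dose covariate; the covariate is retained when it
    drops the stage-two objective n*log(RSS/n) by at least
    ``lrt_threshold`` (3.84 ~ chi2(1), p<0.05).  Because individual
    parameter estimates are independent across animals, the covariate test
    keeps its nominal level in the presence of between-animal variability.
    The stage-two residual SDs double as estimates of the lognormal BSV.

    ``method="pooled"`` minimizes squared log-scale residuals over all
    observations at once — exact for variability-free data but with
    anticonservative covariate tests when BSV is present (residuals of one
    animal share its random effect).

    Parameters
    ----------
    observations
        Long table with columns animal_id, dose_mg, weight_kg,
        dose_mg_per_kg, time_h, conc_ng_per_ml. Non-positive concentrations
        and t=0 rows are dropped for fitting.
    """

    _COLS = ("animal_id", "dose_mg", "weight_kg", "dose_mg_per_kg",
             "time_h", "conc_ng_per_ml")

    def __init__(self, observations: pd.DataFrame,
                 ref_weight_kg: float = 0.025,
                 ref_dose_mg_per_kg: float = 30.0,
                 dose_covariate_form: str = "power"):
        missing = set(self._COLS) - set(observations.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        obs = observations.loc[
            (observations["conc_ng_per_ml"] > 0) & (observations["time_h"] > 0)
        ].reset_index(drop=True)
        if obs.empty:
            raise ValueError("no positive concentration observations to fit")
        self.observations = obs
        self.ref_weight_kg = ref_weight_kg
        self.ref_dose_mg_per_kg = ref_dose_mg_per_kg
        self.dose_covariate_form = dose_covariate_form

    @classmethod
    def from_profiles(cls, profiles: Sequence[ConcentrationProfile],
                      **kwargs) -> "PopulationPKModel":
        rows = []
        for p in profiles:
            for t, c in zip(p.times_h, p.conc_ng_per_ml):
                rows.append(dict(animal_id=p.animal_id, dose_mg=p.dose_mg,
                                 weight_kg=p.weight_kg,
                                 dose_mg_per_kg=p.dose_mg_per_kg,
                                 time_h=t, conc_ng_per_ml=c))
        return cls(pd.DataFrame(rows), **kwargs)

    # -- internals ----------------------------------------------------------

    def _predict_log(self, theta: np.ndarray, with_dose_cl: bool,
                     with_dose_v: bool) -> np.ndarray:
        obs = self.observations
        ka = math.exp(theta[0])
        cl_typ = math.exp(theta[1])
        v_typ = math.exp(theta[2])
        i = 3
        th_cl = theta[i] if with_dose_cl else 0.0
        i += with_dose_cl
        th_v = theta[i] if with_dose_v else 0.0
        wr = obs["weight_kg"].to_numpy() / self.ref_weight_kg
        dose_ratio = obs["dose_mg_per_kg"].to_numpy() / self.ref_dose_mg_per_kg
        if self.dose_covariate_form == "power":
            g_cl = dose_ratio ** th_cl
            g_v = dose_ratio ** th_v
        else:
            g_cl = 1.0 + th_cl * (dose_ratio - 1.0)
            g_v = 1.0 + th_v * (dose_ratio - 1.0)
        cl = cl_typ * wr ** 0.75 * g_cl
        v = v_typ * wr ** 1.0 * g_v
        ke = cl / v
        t = obs["time_h"].to_numpy()
        d = obs["dose_mg"].to_numpy()
        safe = np.abs(ka - ke) / ke > 1e-9
        conc = np.where(
            safe,
            d * ka / (v * (ka - ke + ~safe)) * (np.exp(-ke * t) - np.exp(-ka * t)),
            d * ka * t / v * np.exp(-ka * t),
        )
        return np.log(np.maximum(conc * _MG_L_TO_NG_ML, 1e-300))

    def _fit_one(self, with_dose_cl: bool, with_dose_v: bool,
                 x0: np.ndarray | None = None):
        obs = self.observations
        y = np.log(obs["conc_ng_per_ml"].to_numpy())
        n_par = 3 + with_dose_cl + with_dose_v

        def resid(theta):
            return self._predict_log(theta, with_dose_cl, with_dose_v) - y

        if x0 is None:
            # crude initials from NCA-like heuristics
            cmax_guess = obs["conc_ng_per_ml"].max() / _MG_L_TO_NG_ML
            v0 = max(obs["dose_mg"].median() / max(cmax_guess, 1e-12), 1e-6)
            x0 = np.array([math.log(1.5), math.log(0.2 * v0), math.log(v0)]
                          + [0.0] * (n_par - 3))
        sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
        rss = float(np.sum(sol.fun ** 2))
        n = len(y)
        ofv = n * math.log(max(rss / n, 1e-300))
        return sol, rss, ofv

    def _fit_individuals(self) -> pd.DataFrame:
        """Per-animal nonlinear least squares of (ka, CL/F, V/F) on log C."""
        rows = []
        for aid, g in self.observations.groupby("animal_id", sort=False):
            if len(g) < 4:
                continue
            t = g["time_h"].to_numpy()
            y = np.log(g["conc_ng_per_ml"].to_numpy())
            d = float(g["dose_mg"].iloc[0])
            w = float(g["weight_kg"].iloc[0])

            def resid(theta):
                ka, cl, v = np.exp(theta)
                ke = cl / v
                if abs(ka - ke) / ke < 1e-9:
                    conc = d * ka * t / v * np.exp(-ka * t)
                else:
                    conc = (d * ka / (v * (ka - ke))
                            * (np.exp(-ke * t) - np.exp(-ka * t)))
                return np.log(np.maximum(conc * _MG_L_TO_NG_ML, 1e-300)) - y

            cmax = g["conc_ng_per_ml"].max() / _MG_L_TO_NG_ML
            v0 = max(d / max(cmax, 1e-12), 1e-6)
            x0 = np.log([1.5, 0.2 * v0, v0])
            sol = optimize.least_squares(resid, x0, method="lm",
                                         max_nfev=20000)
            rows.append(dict(animal_id=aid, weight_kg=w,
                             dose_mg_per_kg=float(g["dose_mg_per_kg"].iloc[0]),
                             log_ka=sol.x[0], log_cl=sol.x[1],
                             log_v=sol.x[2], converged=bool(sol.success)))
        if not rows:
            raise RuntimeError("no animal had >= 4 positive observations")
        ind = pd.DataFrame(rows)
        if not ind["converged"].all():
            bad = ind.loc[~ind["converged"], "animal_id"].tolist()
            raise RuntimeError(f"individual PK fits failed for {bad}")
        return ind

    def _stage2_regression(self, y: np.ndarray, dose_ratio: np.ndarray,
                           with_dose: bool):
        """Regress allometry-corrected log parameters on the dose covariate.

        Power form: log-linear in log(dose ratio).  Proportional form:
        linear on the exponentiated scale in (ratio - 1), since
        typ*(1 + theta*(x-1)) = a + b*(x-1) with theta = b/a.
        Returns (log_typical, dose_effect, ofv, se_typ, se_dose, resid_sd).
        """
        n = len(y)
        if self.dose_covariate_form == "power":
            yy = y
            x = np.log(dose_ratio)
        else:
            yy = np.exp(y)
            x = dose_ratio - 1.0
        X = (np.column_stack([np.ones(n), x]) if with_dose
             else np.ones((n, 1)))
        beta, _, _, _ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        rss = float(resid @ resid)
        ofv = n * math.log(max(rss / n, 1e-300))
        dof = max(n - X.shape[1], 1)
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        if self.dose_covariate_form == "power":
            log_typ = beta[0]
            theta = beta[1] if with_dose else 0.0
            se_typ, se_th = se[0], (se[1] if with_dose else np.nan)
        else:
            log_typ = math.log(max(beta[0], 1e-300))
            theta = (beta[1] / beta[0]) if with_dose else 0.0
            se_typ = se[0] / max(beta[0], 1e-300)  # delta method on log
            se_th = (se[1] / max(beta[0], 1e-300)) if with_dose else np.nan
        return log_typ, float(theta), ofv, se_typ, se_th, math.sqrt(sigma2)

    def _fit_two_stage(self, covariate_selection: str,
                       lrt_threshold: float) -> "PopulationPKResults":
        ind = self._fit_individuals()
        wr = np.log(ind["weight_kg"].to_numpy() / self.ref_weight_kg)
        dose_ratio = ind["dose_mg_per_kg"].to_numpy() / self.ref_dose_mg_per_kg
        y_cl = ind["log_cl"].to_numpy() - 0.75 * wr
        y_v = ind["log_v"].to_numpy() - 1.0 * wr
        base_cl = self._stage2_regression(y_cl, dose_ratio, False)
        base_v = self._stage2_regression(y_v, dose_ratio, False)
        cov_cl = self._stage2_regression(y_cl, dose_ratio, True)
        cov_v = self._stage2_regression(y_v, dose_ratio, True)
        decisions: dict[str, bool] = {}
        if covariate_selection == "none":
            use_cl = use_v = False
        elif covariate_selection == "full":
            use_cl = use_v = True
        else:
            use_cl = (base_cl[2] - cov_cl[2]) >= lrt_threshold
            use_v = (base_v[2] - cov_v[2]) >= lrt_threshold
            decisions = {"dose_on_cl": bool(use_cl), "dose_on_v": bool(use_v)}
        fin_cl = cov_cl if use_cl else base_cl
        fin_v = cov_v if use_v else base_v
        log_ka = float(ind["log_ka"].mean())
        se_ka = float(ind["log_ka"].std(ddof=1) / math.sqrt(len(ind))
                      if len(ind) > 1 else np.nan)
        params = PKParameterSet(
            ka=math.exp(log_ka), cl_f_typ=math.exp(fin_cl[0]),
            v_f_typ=math.exp(fin_v[0]), ref_weight_kg=self.ref_weight_kg,
            dose_effect_cl=fin_cl[1] if use_cl else 0.0,
            dose_effect_v=fin_v[1] if use_v else 0.0,
            dose_covariate_form=self.dose_covariate_form,
            ref_dose_mg_per_kg=self.ref_dose_mg_per_kg,
            bsv_sd_cl=fin_cl[5], bsv_sd_v=fin_v[5])
        theta = [log_ka, fin_cl[0], fin_v[0]]
        se = [se_ka, fin_cl[3], fin_v[3]]
        if use_cl:
            theta.append(fin_cl[1])
            se.append(fin_cl[4])
        if use_v:
            theta.append(fin_v[1])
            se.append(fin_v[4])
        return PopulationPKResults(
            model=self, params=params, theta=np.array(theta),
            theta_se=np.array(se), rss=float("nan"),
            ofv=fin_cl[2] + fin_v[2], ofv_base=base_cl[2] + base_v[2],
            n_obs=len(self.observations), covariate_decisions=decisions,
            with_dose_cl=bool(use_cl), with_dose_v=bool(use_v),
            residual_sd_log=float(np.hypot(fin_cl[5], fin_v[5])),
            method="two_stage", n_animals=len(ind))

    def fit(self, covariate_selection: str = "select",
            lrt_threshold: float = 3.84,
            method: str = "two_stage") -> "PopulationPKResults":
        """Estimate the model.

        covariate_selection: "none" (base model), "full" (dose on both
        CL/F and V/F), or "select" (LRT-style selection at
        ``lrt_threshold``).  method: "two_stage" (default) or "pooled".
        """
        if covariate_selection not in ("none", "full", "select"):
            raise ValueError("covariate_selection must be none|full|select")
        if method not in ("two_stage", "pooled"):
            raise ValueError("method must be two_stage|pooled")
        if method == "two_stage":
            return self._fit_two_stage(covariate_selection, lrt_threshold)
        sol0, rss0, ofv0 = self._fit_one(False, False)
        decisions: dict[str, bool] = {}
        if covariate_selection == "none":
            use_cl = use_v = False
        elif covariate_selection == "full":
            use_cl = use_v = True
        else:
            x0 = np.append(sol0.x, 0.0)
            _, _, ofv_cl = self._fit_one(True, False, x0)
            _, _, ofv_v = self._fit_one(False, True, x0)
            use_cl = (ofv0 - ofv_cl) >= lrt_threshold
            use_v = (ofv0 - ofv_v) >= lrt_threshold
            # test the second covariate on top of the first retained one
            if use_cl or use_v:
                base_ofv = ofv_cl if use_cl else ofv_v
                if use_cl and not use_v:
                    solc, _, _ = self._fit_one(True, False, x0)
                    _, _, ofv_b = self._fit_one(True, True, np.append(solc.x, 0.0))
                    use_v = (base_ofv - ofv_b) >= lrt_threshold
                elif use_v and not use_cl:
                    solv, _, _ = self._fit_one(False, True, x0)
                    xb = np.concatenate([solv.x[:3], [0.0], solv.x[3:]])
                    _, _, ofv_b = self._fit_one(True, True, xb)
                    use_cl = (base_ofv - ofv_b) >= lrt_threshold
            decisions = {"dose_on_cl": bool(use_cl), "dose_on_v": bool(use_v)}

        x0 = np.concatenate([sol0.x, [0.0] * (use_cl + use_v)])
        sol, rss, ofv = self._fit_one(use_cl, use_v, x0)
        if not sol.success:
            raise RuntimeError(
                f"population PK fit did not converge: {sol.message} "
                f"(nfev={sol.nfev}, cost={sol.cost:.4g})")
        theta = sol.x
        i = 3
        th_cl = float(theta[i]) if use_cl else 0.0
        i += use_cl
        th_v = float(theta[i]) if use_v else 0.0
        params = PKParameterSet(
            ka=math.exp(theta[0]), cl_f_typ=math.exp(theta[1]),
            v_f_typ=math.exp(theta[2]), ref_weight_kg=self.ref_weight_kg,
            dose_effect_cl=th_cl, dose_effect_v=th_v,
            dose_covariate_form=self.dose_covariate_form,
            ref_dose_mg_per_kg=self.ref_dose_mg_per_kg)
        n = len(self.observations)
        dof = max(n - len(theta), 1)
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(len(theta), np.nan)
        return PopulationPKResults(
            model=self, params=params, theta=theta, theta_se=se,
            rss=rss, ofv=ofv, ofv_base=ofv0, n_obs=n,
            covariate_decisions=decisions,
            with_dose_cl=use_cl, with_dose_v=use_v,
            residual_sd_log=math.sqrt(sigma2))


@dataclass
class PopulationPKResults:
    """Estimates, uncertainties and covariate decisions from a pooled fit."""

    model: PopulationPKModel
    params: PKParameterSet
    theta: np.ndarray
    theta_se: np.ndarray
    rss: float
    ofv: float
    ofv_base: float
    n_obs: int
    covariate_decisions: dict
    with_dose_cl: bool
    with_dose_v: bool
    residual_sd_log: float
    method: str = "pooled"
    n_animals: int | None = None

    @property
    def param_names(self) -> list[str]:
        names = ["log_ka", "log_cl_f_typ", "log_v_f_typ"]
        if self.with_dose_cl:
            names.append("dose_effect_cl")
        if self.with_dose_v:
            names.append("dose_effect_v")
        return names

    def summary(self) -> str:
        rows = pd.DataFrame({
            "estimate": self.theta, "se": self.theta_se,
        }, index=self.param_names)
        lines = [
            f"Population PK fit (method: {self.method})",
            f"n_obs = {self.n_obs}, OFV = {self.ofv:.3f} "
            f"(base {self.ofv_base:.3f}), residual SD(log) = "
            f"{self.residual_sd_log:.4f}",
            f"typical ka = {self.params.ka:.4g} 1/h, "
            f"CL/F = {self.params.cl_f_typ:.4g} L/h, "
            f"V/F = {self.params.v_f_typ:.4g} L "
            f"(at {self.params.ref_weight_kg*1000:.0f} g)",
            f"covariate decisions: {self.covariate_decisions or 'n/a'}",
            rows.to_string(float_format=lambda v: f"{v:.5g}"),
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "params": self.params.to_dict(),
            "theta": list(map(float, self.theta)),
            "theta_se": [float(s) for s in self.theta_se],
            "param_names": self.param_names,
            "rss": self.rss, "ofv": self.ofv, "ofv_base": self.ofv_base,
            "n_obs": self.n_obs,
            "covariate_decisions": self.covariate_decisions,
            "residual_sd_log": self.residual_sd_log,
        }, indent=2)


def predict_individual_auc(params: PKParameterSet, animal_id: str,
                           dose_mg: float, weight_kg: float,
                           dose_mg_per_kg: float | None = None,
                           eta_cl: float = 0.0) -> ExposureEstimate:
    """Exposure from clearance: AUC(0-inf) = dose / CL/F (mg*h/L).

    ``auc_daily_bid`` is the steady-state daily exposure under twice-daily
    dosing of the same amount, (2*dose)/CL, valid under linear kinetics.
    """
    cl, _ = apply_allometry(params, weight_kg, dose_mg_per_kg)
    cl *= math.exp(eta_cl)
    auc = dose_mg / cl
    return ExposureEstimate(animal_id=animal_id, auc=auc, cl_f_ind=cl,
                            dose_mg=dose_mg, auc_daily_bid=2.0 * auc)


@dataclass
class ExposureRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def exposure_concentration_regression(auc: Sequence[float],
                                      c_half_hour: Sequence[float]
                                      ) -> ExposureRegression:
    """OLS of predicted AUC on the 0.5 h plasma concentration."""
    x = np.asarray(c_half_hour, dtype=float)
    y = np.asarray(auc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D samples required")
    if len(x) < 3:
        raise ValueError("need at least 3 animals")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the 0.5 h concentrations; "
                         "regression undefined")
    res = stats.linregress(x, y)
    return ExposureRegression(slope=res.slope, intercept=res.intercept,
                              r_squared=res.rvalue ** 2, p_value=res.pvalue,
                              n=len(x))
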