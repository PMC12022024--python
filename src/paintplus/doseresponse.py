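"""Benchmark-concentration (BMC) modeling of feature concentration responses.

Per feature x compound, the well-level robust z-scores (median of the
three technical replicates per biological replicate) are fitted with five
curve families:

    cnst   f(x) = 0
    poly1  f(x) = a*x
    poly2  f(x) = b1*x + b2*x^2
    pow    f(x) = a*x^p,                     p in [0.3, 8]
    hill   f(x) = tp / (1 + (ga/x)^p),       ga in tested range x [0.1, 10],
                                             p in [0.3, 8]

The best fit (lowest AIC, Gaussian likelihood; ties broken by fewer
parameters, then the fixed order cnst < poly1 < pow < poly2 < hill) is
inverted for the benchmark concentration: the smallest concentration at
which |f(x)| reaches the benchmark response

    BMR = 1.349 * SD,   SD = 1.4826 * MAD of the control wells' scores,

so BMR = 1.349 * 1.4826 * MAD.  Classification: no crossing -> NA;
crossing above the highest non-cytotoxic tested concentration -> HIGH
(inactive); crossing below the lowest tested concentration -> LOW, with
the reported BMC adjusted half-log below the lowest tested concentration
(log10 BMC_LOW = log10(lowest) - 0.5); otherwise OK.

Series are only modeled when they offer at least four non-cytotoxic
concentrations and at least three biological replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .profiling import mad, ROBUST_Z_CONSTANT

logger = logging.getLogger(__name__)

BMR_SD_MULTIPLIER = 1.349           # approx. one IQR for Gaussian data
POW_P_BOUNDS = (0.3, 8.0)
HILL_P_BOUNDS = (0.3, 8.0)
HILL_GA_RANGE_FACTOR = (0.1, 10.0)  # ga bounds relative to tested range
MIN_CONC_COUNT = 4
MIN_BIOL_REPS = 3

CLASS_OK = "OK"
CLASS_NA = "NA"
CLASS_HIGH = "HIGH"
CLASS_LOW = "LOW"

MODEL_ORDER = {"cnst": 0, "poly1": 1, "pow": 2, "poly2": 3, "hill": 4}
MODEL_NPARAMS = {"cnst": 0, "poly1": 1, "poly2": 2, "pow": 2, "hill": 3}


def model_predict(model: str, params: dict[str, float], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if model == "cnst":
        return np.zeros_like(x)
    if model == "poly1":
        return params["a"] * x
    if model == "poly2":
        return params["b1"] * x + params["b2"] * x ** 2
    if model == "pow":
        return params["a"] * np.power(x, params["p"])
    if model == "hill":
        with np.errstate(divide="ignore", over="ignore"):
            return np.where(x > 0,
                            params["tp"] / (1.0 + (params["ga"] / np.maximum(x, 1e-300)) ** params["p"]),
                            0.0)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class FittedModel:
    model: str
    params: dict[str, float]
    rss: float
    n_obs: int
    aic: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return model_predict(self.model, self.params, x)


@dataclass
class BMCRecord:
    """Fitted-model record for one feature x compound series."""

    feature: str
    compound_id: str
    model: str | None
    params: dict[str, float] = dc_field(default_factory=dict)
    aic: float = np.nan
    bmr: float = np.nan
    bmc_uM: float | None = None
    bmc_class: str = CLASS_NA
    reason: str = ""
    direction: int = 0
    concentrations_uM: tuple[float, ...] = ()
    highest_nontoxic_uM: float = np.nan

    @property
    def log10_bmc(self) -> float:
        return np.log10(self.bmc_uM) if self.bmc_uM else np.nan

    def as_row(self) -> dict:
        return dict(feature=self.feature, compound_id=self.compound_id,
                    model=self.model or "", params=json.dumps(self.params),
                    aic=self.aic, BMR=self.bmr,
                    BMC_uM=self.bmc_uM if self.bmc_uM is not None else np.nan,
                    log10_BMC=self.log10_bmc, bmc_class=self.bmc_class,
                    reason=self.reason)


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian likelihood with profiled variance; +1 for the variance itself
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * (k + 1)


def gate_inputs(series: pd.DataFrame,
                min_conc: int = MIN_CONC_COUNT,
                min_reps: int = MIN_BIOL_REPS) -> tuple[pd.DataFrame | None, str]:
    """Admissibility gate for one feature x compound series.

    ``series`` columns: concentration_uM, biol_rep, response (well z, one
    row per biological replicate x concentration after the technical-
    replicate median), cytotoxic (bool).  Returns (admissible series or
    None, reason).
    """
    ok = series[~series["cytotoxic"]] if "cytotoxic" in series.columns else series
    n_conc = ok["concentration_uM"].nunique()
    n_reps = ok["biol_rep"].nunique()
    if n_conc < min_conc:
        return None, f"gated: {n_conc} non-cytotoxic concentrations < {min_conc}"
    if n_reps < min_reps:
        return None, f"gated: {n_reps} biological replicates < {min_reps}"
    return ok, ""


def technical_median_series(well_table: pd.DataFrame, feature: str,
                            compound_id: str) -> pd.DataFrame:
    """Response points for fitting: per biological replicate x concentration,
    the median of the feature's well-level z over technical replicates."""
    df = well_table[(well_table["compound_id"] == compound_id)
                    & (well_table["role"] != "solvent_control")]
    keys = ["concentration_uM", "biol_rep"]
    agg = {feature: "median"}
    if "cytotoxic" in df.columns:
        agg["cytotoxic"] = "max"
    out = df.groupby(keys, sort=True).agg(agg).reset_index()
    out = out.rename(columns={feature: "response"})
    if "cytotoxic" in out.columns:
        out["cytotoxic"] = out["cytotoxic"].astype(bool)
    return out


def compute_bmr(control_well_scores: np.ndarray) -> float:
    """BMR = 1.349 * 1.4826 * MAD of the feature's control well-level scores."""
    s = mad(np.asarray(control_well_scores, dtype=float))
    if not np.isfinite(s) or s == 0:
        raise ValueError("control MAD is zero or undefined; feature should be excluded upstream")
    return BMR_SD_MULTIPLIER * ROBUST_Z_CONSTANT * s


def _fit_cnst(x, y):
    return {}, float(np.sum(y ** 2))


def _fit_poly1(x, y):
    denom = float(np.sum(x ** 2))
    a = float(np.sum(x * y) / denom) if denom > 0 else 0.0
    resid = y - a * x
    return {"a": a}, float(np.sum(resid ** 2))


def _fit_poly2(x, y):
    X = np.column_stack([x, x ** 2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return {"b1": float(coef[0]), "b2": float(coef[1])}, float(np.sum(resid ** 2))


def _fit_pow(x, y):
    def rss_for_p(p):
        xp = np.power(x, p)
        denom = float(np.sum(xp ** 2))
        a = float(np.sum(xp * y) / denom) if denom > 0 else 0.0
        return float(np.sum((y - a * xp) ** 2)), a

    res = minimize_scalar(lambda p: rss_for_p(p)[0], bounds=POW_P_BOUNDS,
                          method="bounded", options={"xatol": 1e-8})
    p = float(res.x)
    rss, a = rss_for_p(p)
    return {"a": a, "p": p}, rss


def _fit_hill(x, y, seed: int, n_restarts: int = 5):
    lo, hi = x[x > 0].min(), x.max()
    ga_lo, ga_hi = lo * HILL_GA_RANGE_FACTOR[0], hi * HILL_GA_RANGE_FACTOR[1]
    p_lo, p_hi = HILL_P_BOUNDS
    tp_scale = max(np.max(np.abs(y)), 1e-6)

    def residual(theta):
        tp, log_ga, p = theta
        return model_predict("hill", {"tp": tp, "ga": 10 ** log_ga, "p": p}, x) - y

    rng = np.random.default_rng(seed)
    best = None
    base_starts = [
        (np.sign(y[np.argmax(np.abs(y))]) * tp_scale, np.log10(np.sqrt(lo * hi)), 1.5),
    ]
    for i in range(n_restarts):
        if i < len(base_starts):
            tp0, lga0, p0 = base_starts[i]
        else:
            tp0 = rng.uniform(-2, 2) * tp_scale
            lga0 = rng.uniform(np.log10(ga_lo), np.log10(ga_hi))
            p0 = rng.uniform(p_lo, p_hi)
        try:
            res = least_squares(
                residual, x0=[tp0, lga0, p0],
                bounds=([-np.inf, np.log10(ga_lo), p_lo],
                        [np.inf, np.log10(ga_hi), p_hi]),
                method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
                max_nfev=200)
        except Exception:  # pragma: no cover - optimizer failure
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
    if best is None:
        raise RuntimeError("hill fit failed in all restarts")
    (tp, lga, p), rss = best
    return {"tp": float(tp), "ga": float(10 ** lga), "p": float(p)}, rss


def fit_models(x: np.ndarray, y: np.ndarray, seed: int = 0) -> list[FittedModel]:
    """Least-squares fits of the five families on signed responses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("too few observations to fit")
    n = x.size
    fits: list[FittedModel] = []
    fitters = {"cnst": _fit_cnst, "poly1": _fit_poly1, "poly2": _fit_poly2,
               "pow": _fit_pow}
    for name, fn in fitters.items():
        try:
            params, rss = fn(x, y)
        except Exception as exc:
            logger.warning("%s fit failed: %s", name, exc)
            continue
        fits.append(FittedModel(name, params, rss, n, _aic(rss, n, MODEL_NPARAMS[name])))
    try:
        params, rss = _fit_hill(x, y, seed=seed)
        fits.append(FittedModel("hill", params, rss, n, _aic(rss, n, MODEL_NPARAMS["hill"])))
    except Exception as exc:
        logger.warning("hill fit failed: %s", exc)
    return fits


def select_best(candidates: list[FittedModel]) -> FittedModel:
    """Lowest AIC wins; ties go to fewer parameters, then fixed family order."""
    if not candidates:
        raise ValueError("no successful fits")
    return min(candidates, key=lambda f: (round(f.aic, 10),
                                          MODEL_NPARAMS[f.model],
                                          MODEL_ORDER[f.model]))


def _first_crossing(fit: FittedModel, bmr: float, lo: float, hi: float,
                    n_grid: int = 2048, rel_tol: float = 1e-6) -> float | None:
    """Smallest x in [lo, hi] with |f(x)| = bmr (log-spaced bracket + bisection)."""
    if hi <= lo:
        return None
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    g = np.abs(fit.predict(grid)) - bmr
    if g[0] >= 0:
        return lo  # already beyond the cutoff at the bracket floor
    idx = np.flatnonzero(np.diff(np.sign(g)) > 0)
    if idx.size == 0:
        return None
    a, b = grid[idx[0]], grid[idx[0] + 1]
    for _ in range(200):
        m = np.sqrt(a * b)
        if np.abs(fit.predict(np.array([m]))[0]) >= bmr:
            b = m
        else:
            a = m
        if (b - a) / b < rel_tol:
            break
    return float(b)


def compute_bmc(best: FittedModel, bmr: float, concentrations_uM: np.ndarray,
                highest_nontoxic_uM: float, feature: str = "",
                compound_id: str = "") -> BMCRecord:
    """Invert the best fit at the BMR and classify the result."""
    concs = np.sort(np.asarray(concentrations_uM, dtype=float))
    concs = concs[concs > 0]
    lowest = concs.min()
    highest_tested = concs.max()
    rec = BMCRecord(feature=feature, compound_id=compound_id, model=best.model,
                    params=best.params, aic=best.aic, bmr=bmr,
                    concentrations_uM=tuple(concs),
                    highest_nontoxic_uM=highest_nontoxic_uM)
    pred = best.predict(concs)
    rec.direction = int(np.sign(pred[np.argmax(np.abs(pred))])) if np.any(pred) else 0
    if best.model == "cnst":
        rec.bmc_class, rec.reason = CLASS_NA, "constant model selected"
        return rec
    floor = lowest / 10 ** 0.5
    crossing = _first_crossing(best, bmr, floor, highest_nontoxic_uM)
    if crossing is None:
        # does the curve cross somewhere above the non-cytotoxic range?
        above = _first_crossing(best, bmr, max(highest_nontoxic_uM, floor), highest_tested)
        if above is not None and above > highest_nontoxic_uM:
            rec.bmc_class = CLASS_HIGH
            rec.reason = "crossing above highest non-cytotoxic concentration"
        else:
            rec.bmc_class, rec.reason = CLASS_NA, "no BMR crossing"
        return rec
    if crossing < lowest:
        rec.bmc_class = CLASS_LOW
        rec.bmc_uM = 10 ** (np.log10(lowest) - 0.5)
        rec.reason = "crossing below lowest tested concentration (half-log adjusted)"
        return rec
    rec.bmc_class = CLASS_OK
    rec.bmc_uM = crossing
    return rec


def bmc_for_feature_compound(well_table: pd.DataFrame, feature: str,
                             compound_id: str, seed: int = 0,
                             min_conc: int = MIN_CONC_COUNT,
                             min_reps: int = MIN_BIOL_REPS) -> BMCRecord:
    """Full per-series BMC pipeline: gate, BMR, fit, select, invert."""
    series = technical_median_series(well_table, feature, compound_id)
    admissible, reason = gate_inputs(series, min_conc=min_conc, min_reps=min_reps)
    if admissible is None:
        return BMCRecord(feature=feature, compound_id=compound_id, model=None,
                         bmc_class=CLASS_NA, reason=reason)
    ctrl = well_table[well_table["role"] == "solvent_control"]
    try:
        bmr = compute_bmr(ctrl[feature].to_numpy())
    except ValueError as exc:
        return BMCRecord(feature=feature, compound_id=compound_id, model=None,
                         bmc_class=CLASS_NA, reason=str(exc))
    x = admissible["concentration_uM"].to_numpy()
    y = admissible["response"].to_numpy()
    fits = fit_models(x, y, seed=seed)
    best = select_best(fits)
    rec = compute_bmc(best, bmr, np.unique(x), float(x.max()),
                      feature=feature, compound_id=compound_id)
    return rec


def bmc_table(well_table: pd.DataFrame, features: list[str],
              compounds: list[str] | None = None, seed: int = 0,
              min_conc: int = MIN_CONC_COUNT,
              min_reps: int = MIN_BIOL_REPS) -> tuple[pd.DataFrame, list[BMCRecord]]:
    """BMC records for every feature x compound pair.

    Equivalent to calling :func:`bmc_for_feature_compound` per pair, but the
    technical-replicate medians and control BMRs are computed once for all
    features.
    """
    if compounds is None:
        compounds = sorted(well_table.loc[well_table["role"] != "solvent_control",
                                          "compound_id"].unique())
    ctrl = well_table[well_table["role"] == "solvent_control"]
    bmrs: dict[str, float | None] = {}
    for f in features:
        s = mad(ctrl[f].to_numpy())
        bmrs[f] = BMR_SD_MULTIPLIER * ROBUST_Z_CONSTANT * s if np.isfinite(s) and s > 0 else None

    df = well_table[well_table["role"] != "solvent_control"]
    agg_spec = {f: "median" for f in features}
    has_flags = "cytotoxic" in df.columns
    if has_flags:
        agg_spec["cytotoxic"] = "max"
    agg = (df.groupby(["compound_id", "concentration_uM", "biol_rep"], sort=True)
           .agg(agg_spec).reset_index())

    records = []
    rng = np.random.default_rng(seed)
    for cmpd in compounds:
        sub = agg[agg["compound_id"] == cmpd]
        ok = sub[~sub["cytotoxic"].astype(bool)] if has_flags else sub
        n_conc = ok["concentration_uM"].nunique()
        n_reps = ok["biol_rep"].nunique()
        gated = None
        if n_conc < min_conc:
            gated = f"gated: {n_conc} non-cytotoxic concentrations < {min_conc}"
        elif n_reps < min_reps:
            gated = f"gated: {n_reps} biological replicates < {min_reps}"
        x = ok["concentration_uM"].to_numpy()
        concs = np.unique(x)
        for feat in features:
            fit_seed = int(rng.integers(2 ** 31))
            if gated is not None:
                records.append(BMCRecord(feature=feat, compound_id=cmpd,
                                         model=None, bmc_class=CLASS_NA, reason=gated))
                continue
            if bmrs[feat] is None:
                records.append(BMCRecord(
                    feature=feat, compound_id=cmpd, model=None, bmc_class=CLASS_NA,
                    reason="control MAD is zero or undefined; feature should be excluded upstream"))
                continue
            y = ok[feat].to_numpy()
            fits = fit_models(x, y, seed=fit_seed)
            best = select_best(fits)
            records.append(compute_bmc(best, bmrs[feat], concs, float(x.max()),
                                       feature=feat, compound_id=cmpd))
    out = pd.DataFrame([r.as_row() for r in records])
    return out, records


def bmc_for_downstream(records: list[BMCRecord], context: str,
                       max_tested_uM: float = 100.0) -> pd.DataFrame:
    """Numeric BMC table (log10 uM) with class-NA/HIGH substitution rules.

    context 'proportion_profiles': NA/HIGH -> the global maximum tested
    concentration; context 'correlation': NA/HIGH -> the compound's own
    maximum non-cytotoxic concentration.  OK/LOW records keep their BMC.
    """
    if context not in ("proportion_profiles", "correlation"):
        raise ValueError(f"unknown context {context!r}")
    rows = []
    for r in records:
        if r.bmc_uM is not None:
            v = r.bmc_uM
        elif context == "proportion_profiles":
            v = max_tested_uM
        else:
            v = r.highest_nontoxic_uM
            if not np.isfinite(v):
                v = max_tested_uM
        rows.append(dict(feature=r.feature, compound_id=r.compound_id,
                         bmc_class=r.bmc_class, log10_BMC=float(np.log10(v))))
    return pd.DataFrame(rows)
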