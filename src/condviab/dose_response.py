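"""Dose-response modeling of predicted viability curves.

Predictions over a log-spaced concentration grid are quality-controlled
(recursive high-concentration hook removal, minimum point count, minimum
viability gate), fit with a log-logistic function

    v(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with a 4 -> 3 -> 2 parameter fallback (3-parameter fixes c = 0, 2-parameter
fixes c = 0 and d = 1), and summarized as pharmacodynamic quantities: IC50
(absolute 50% viability crossing), normalized AUC over log-concentration,
min-max scaled AUC per compound across a cohort, and ED50 relative potency
with a delta-method t-test on the log-ED50 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit", "default_grid", "predict_curve", "qc_curve",
    "fit_log_logistic", "derive_ic50", "derive_auc", "scale_auc",
    "compare_ed50", "classify_response", "log_logistic", "fits_to_frame",
]

GRID_MIN_UM = 1e-3
GRID_MAX_UM = 300.0
GRID_POINTS = 32
EC50_RANGE = (GRID_MIN_UM, GRID_MAX_UM)


def default_grid() -> np.ndarray:
    """32 concentrations, log10-uniform from 1e-3 to 300 uM inclusive."""
    return np.logspace(np.log10(GRID_MIN_UM), np.log10(GRID_MAX_UM),
                       GRID_POINTS)


def log_logistic(x, b, c, d, e):
    x = np.asarray(x, dtype=np.float64)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


@dataclass
class DoseResponseFit:
    b: float = np.nan            # slope
    c_lower: float = np.nan      # lower asymptote
    d_upper: float = np.nan      # upper asymptote
    e_mid: float = np.nan        # inflection concentration (EC50), uM
    n_params: int = 0
    points_used: int = 0
    qc_status: str = "fit_failed"
    covariance: np.ndarray | None = None   # over free params, fit order
    free_params: tuple = ()
    residual_df: int = 0
    var_log_e: float | None = None

    @property
    def params(self):
        return self.b, self.c_lower, self.d_upper, self.e_mid

    def viability(self, x):
        return log_logistic(x, *self.params)


def predict_curve(model, expression: np.ndarray, compound_vector: np.ndarray,
                  grid: np.ndarray | None = None,
                  log_concentration: bool = False) -> list[tuple[float, float]]:
    """Predicted (concentration, viability) pairs along the grid.

    ``compound_vector`` is a 513-length fingerprint+concentration vector; the
    concentration slot is overwritten with each grid point (log10-transformed
    when the model was trained on log concentrations).  ``model`` is a
    fitted regressor or ensemble.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    expression = np.asarray(expression, dtype=np.float64).ravel()
    compound_vector = np.asarray(compound_vector, dtype=np.float64).ravel()
    X = np.empty((len(grid), len(expression) + len(compound_vector)))
    X[:, :len(expression)] = expression
    X[:, len(expression):] = compound_vector
    X[:, -1] = np.log10(grid) if log_concentration else grid
    pred = model.predict(X)
    return list(zip(grid.tolist(), np.asarray(pred, dtype=np.float64).tolist()))


def qc_curve(points, rel_increase: float = 0.20, min_points: int = 16,
             min_viability_gate: float = 0.4, absolute: bool = False):
    """Quality-control cascade over a sorted dose-response curve.

    While any of the four largest concentrations' viabilities shows an
    increase of ``rel_increase`` or more over the fifth largest's (relative
    by default: ``v >= (1 + rel) * v_ref``; ``absolute=True`` switches to
    ``v >= v_ref + rel``), the single largest point is dropped and the rule
    re-checked on the remaining points.  The surviving curve is rejected if
    fewer than ``min_points`` remain or its minimum viability exceeds
    ``min_viability_gate``.

    Returns ``(kept_points, qc_status)`` with status in
    {"pass", "rejected_min_points", "rejected_high_min_viability"}.
    """
    pts = [(float(x), float(v)) for x, v in points]
    if len(pts) < 5:
        raise ValueError("need at least 5 points for the QC hook rule")
    if any(pts[i][0] >= pts[i + 1][0] for i in range(len(pts) - 1)):
        raise ValueError("points must be sorted by strictly increasing "
                         "concentration")
    kept = list(pts)
    while len(kept) >= 5:
        ref = kept[-5][1]
        top = [v for _, v in kept[-4:]]
        if absolute:
            hook = any(v >= ref + rel_increase for v in top)
        else:
            hook = any(v >= (1.0 + rel_increase) * ref for v in top)
        if not hook:
            break
        kept.pop()
    if len(kept) < min_points:
        return kept, "rejected_min_points"
    if min(v for _, v in kept) > min_viability_gate:
        return kept, "rejected_high_min_viability"
    return kept, "pass"


def _ls_fit(x, v, free, fixed, e_starts):
    """Bounded least squares over the free log-logistic parameters with
    multi-start on e.  Returns (params dict, cov, cost, success)."""
    names = list(free)

    def unpack(theta):
        p = dict(fixed)
        p.update({n: t for n, t in zip(names, theta)})
        return p

    def resid(theta):
        p = unpack(theta)
        e = np.exp(p["log_e"])
        return log_logistic(x, p["b"], p["c"], p["d"], e) - v

    bounds_all = {"b": (1e-3, 50.0), "c": (-1.0, 1.5), "d": (-0.5, 2.5),
                  "log_e": (np.log(1e-5), np.log(1e4))}
    lo = np.array([bounds_all[n][0] for n in names])
    hi = np.array([bounds_all[n][1] for n in names])

    d0 = float(np.clip(np.max(v), 0.5, 2.4))
    c0 = float(np.clip(np.min(v), -0.9, 1.4))
    best = None
    for e0 in e_starts:
        theta0 = []
        for n in names:
            theta0.append({"b": 1.0, "c": min(c0, d0 - 1e-3), "d": d0,
                           "log_e": np.log(e0)}[n])
        theta0 = np.clip(np.asarray(theta0, dtype=np.float64),
                         lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                resid, theta0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success or not np.all(np.isfinite(best.x)):
        return None
    # parameter pinned at a bound counts as an optimizer failure
    margin = 1e-6 * np.maximum(1.0, np.abs(hi - lo))
    if np.any(best.x <= lo + margin) or np.any(best.x >= hi - margin):
        return None
    p = unpack(best.x)
    n, k = len(x), len(names)
    cov = None
    if n > k:
        try:
            jtj = best.jac.T @ best.jac
            sigma2 = 2.0 * best.cost / (n - k)
            cov = np.linalg.inv(jtj) * sigma2
        except np.linalg.LinAlgError:
            cov = None
    return p, cov, names, n - k


def fit_log_logistic(points, fallback: bool = True) -> DoseResponseFit:
    """Fit the log-logistic model with 4 -> 3 -> 2 parameter fallback.

    4-parameter frees (b, c, d, e); on optimizer failure 3-parameter fixes
    c = 0, then 2-parameter fixes c = 0, d = 1.  A converged fit whose
    EC50 leaves the screening range [1e-3, 300] uM is flagged
    ``filtered_ec50_range``; if every fit attempt fails the status is
    ``fit_failed``.
    """
    pts = np.asarray([(x, v) for x, v in points], dtype=np.float64)
    x, v = pts[:, 0], pts[:, 1]
    e_starts = np.geomspace(max(x.min(), 1e-4), x.max(), 5)
    attempts = [({"b", "c", "d", "log_e"}, {}),
                ({"b", "d", "log_e"}, {"c": 0.0}),
                ({"b", "log_e"}, {"c": 0.0, "d": 1.0})]
    if not fallback:
        attempts = attempts[:1]
    for free, fixed in attempts:
        order = ["b", "c", "d", "log_e"]
        names = [n for n in order if n in free]
        out = _ls_fit(x, v, names, fixed, e_starts)
        if out is None:
            continue
        p, cov, names, dof = out
        e = float(np.exp(p["log_e"]))
        fit = DoseResponseFit(
            b=float(p["b"]), c_lower=float(p["c"]), d_upper=float(p["d"]),
            e_mid=e, n_params=len(names), points_used=len(x),
            qc_status="pass", covariance=cov, free_params=tuple(names),
            residual_df=dof)
        if cov is not None:
            fit.var_log_e = float(cov[names.index("log_e"),
                                      names.index("log_e")])
        if not (EC50_RANGE[0] <= e <= EC50_RANGE[1]):
            fit.qc_status = "filtered_ec50_range"
        return fit
    return DoseResponseFit(points_used=len(x), qc_status="fit_failed")


def derive_ic50(fit: DoseResponseFit) -> float | None:
    """Concentration at which the fitted curve crosses absolute viability
    0.5, or None when the curve never crosses 0.5 on (0, inf)."""
    b, c, d, e = fit.params
    if not np.all(np.isfinite([b, c, d, e])):
        return None
    denom = 0.5 - c
    numer = d - 0.5
    if denom == 0 or numer / denom <= 0:
        return None
    ic50 = float(e * (numer / denom) ** (1.0 / b))
    if not np.isfinite(ic50) or ic50 <= 0:
        return None
    return ic50


def derive_auc(points, grid=None) -> float:
    """Trapezoidal integral of viability over log10 concentration,
    normalized by the log-range: a flat v = 1 curve gives AUC = 1."""
    pts = np.asarray([(x, v) for x, v in points], dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("need >= 2 points for AUC")
    logx = np.log10(pts[:, 0])
    return float(np.trapezoid(pts[:, 1], logx) / (logx[-1] - logx[0]))


def scale_auc(aucs) -> pd.Series:
    """Min-max scale a cohort's AUCs for one compound into [0, 1]."""
    s = pd.Series(aucs, dtype=np.float64)
    if len(s) < 2:
        raise ValueError("auc_scaled undefined with a single sample")
    lo, hi = s.min(), s.max()
    if hi == lo:
        return pd.Series(np.zeros(len(s)), index=s.index)
    return (s - lo) / (hi - lo)


def compare_ed50(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> dict:
    """Relative potency at the median effective dose.

    ED50 of the log-logistic curve is its inflection e.  The ratio
    e_a / e_b is tested against 1 via the delta method on log-ED50s: the
    t statistic is the log-ratio over its standard error, with the combined
    residual degrees of freedom.
    """
    ratio = float(fit_a.e_mid / fit_b.e_mid)
    out = {"ratio": ratio, "se": None, "t_value": None, "p_value": None}
    if fit_a.var_log_e is None or fit_b.var_log_e is None:
        return out
    var = fit_a.var_log_e + fit_b.var_log_e
    if var <= 0:
        return out
    log_ratio = np.log(fit_a.e_mid) - np.log(fit_b.e_mid)
    se_log = float(np.sqrt(var))
    t = float(log_ratio / se_log)
    df = fit_a.residual_df + fit_b.residual_df
    out.update(se=float(ratio * se_log), t_value=t,
               p_value=float(2.0 * stats.t.sf(abs(t), df)))
    return out


def classify_response(auc_scaled: float, threshold: float) -> str:
    """Responder iff scaled AUC <= threshold (inclusive): lower predicted
    AUC means greater predicted sensitivity."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return "responder" if auc_scaled <= threshold else "non_responder"


def fits_to_frame(rows: list[dict]) -> pd.DataFrame:
    """One row per sample x compound: qc_status, n_params, parameters and
    pharmacodynamics, ready for CSV export."""
    cols = ["sample_id", "compound_id", "qc_status", "n_params",
            "points_used", "b", "c", "d", "e", "ic50_um", "auc", "auc_scaled"]
    return pd.DataFrame(rows, columns=cols)
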