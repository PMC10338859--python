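"""Steady-state 1:1 analysis of biolayer-interferometry binding data.

The association phase of a 1:1 (Langmuir) interaction follows

    R(t) = Req(C) * (1 - exp(-(ka*C + kd_off) * t)),   Req(C) = Rmax * C / (C + Kd)

with Kd = kd_off / ka.  The primary analysis is steady-state: estimate the
equilibrium response Req at each analyte concentration from the trace
plateau (or by single-exponential extrapolation when the trace was stopped
short of the plateau), then fit the binding isotherm Req(C) by non-linear
least squares to obtain Kd and Rmax.  Replicate Kds are compared between
groups with a two-tailed unpaired t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def association_response(t, conc, ka, kd_off, rmax):
    """Noiseless 1:1 association trace R(t) at analyte concentration ``conc``."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd_off
    kd = kd_off / ka
    req = rmax * conc / (conc + kd)
    return req * (1.0 - np.exp(-kobs * t))


def isotherm(conc, kd, rmax):
    """Steady-state 1:1 binding isotherm Req(C) = Rmax*C/(C+Kd)."""
    conc = np.asarray(conc, dtype=float)
    return rmax * conc / (conc + kd)


def equilibrium_response(
    times: np.ndarray,
    responses: np.ndarray,
    tail_fraction: float = 0.1,
    slope_tol: float = 0.01,
) -> tuple[float, bool]:
    """Estimate the equilibrium response of one association trace.

    Req is the mean response over the final ``tail_fraction`` of time points.
    The trace is considered at plateau when the response change across the
    tail is below ``slope_tol`` * Req per 10% of the trace duration; otherwise
    a single-exponential R(t) = R_inf*(1-exp(-k t)) is fitted and its
    asymptote returned, with the non-plateau flag raised.

    Returns ``(Req, extrapolated)``.
    """
    times = np.asarray(times, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(times) != len(responses):
        raise ValueError("times and responses differ in length")
    n_tail = max(int(np.ceil(tail_fraction * len(times))), 2)
    if n_tail < 5 and len(times) >= 5:
        n_tail = 5
    if len(times) < 5:
        raise ValueError("trace too short: need at least 5 points in the tail")
    tail_t, tail_r = times[-n_tail:], responses[-n_tail:]
    req = float(tail_r.mean())
    if req == 0.0:
        return 0.0, False
    # response drift across the tail, scaled to a 10%-of-duration span
    span = times[-1] - times[0]
    slope = np.polyfit(tail_t, tail_r, 1)[0]
    drift = abs(slope) * 0.1 * span / abs(req)
    if drift <= slope_tol:
        return req, False
    # stopped short of plateau: extrapolate with a single exponential
    k0 = 1.0 / max(span, 1e-12)
    popt, _ = optimize.curve_fit(
        lambda t, rinf, k: rinf * (1.0 - np.exp(-k * t)),
        times,
        responses,
        p0=[responses[-1] * 1.5, k0],
        maxfev=20000,
    )
    return float(popt[0]), True


@dataclass
class EquilibriumFit:
    """Result of a steady-state 1:1 isotherm fit."""

    kd: float
    rmax: float
    kd_stderr: float
    rmax_stderr: float
    rss: float
    points: pd.DataFrame  # concentration_M, req, req_normalized
    low_confidence: bool = False

    def __post_init__(self):
        if self.kd <= 0 or self.rmax <= 0:
            raise ValueError("fitted Kd and Rmax must be positive")


def fit_equilibrium_kd(concentrations, reqs) -> EquilibriumFit:
    """Fit Req(C) = Rmax*C/(C+Kd) by non-linear least squares.

    Initialisation: Rmax0 = max(Req); Kd0 = concentration at half-maximal
    response, linearly interpolated.  Data that do not reach half of the
    fitted Rmax are flagged low-confidence (Kd poorly constrained beyond the
    sampled range).
    """
    conc = np.asarray(concentrations, dtype=float)
    req = np.asarray(reqs, dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    rmax0 = float(req.max())
    if rmax0 <= 0:
        raise ValueError("all equilibrium responses are non-positive")
    half = 0.5 * rmax0
    order = np.argsort(conc)
    cs, rs = conc[order], req[order]
    above = np.nonzero(rs >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        f = (half - rs[i - 1]) / (rs[i] - rs[i - 1])
        kd0 = float(cs[i - 1] + f * (cs[i] - cs[i - 1]))
    else:
        kd0 = float(np.median(cs))
    kd0 = max(kd0, cs[0] * 1e-3)
    # x_scale: Kd is O(1e-9) in molar units, so scale steps by the initial guess
    popt, pcov = optimize.curve_fit(
        isotherm,
        conc,
        req,
        p0=[kd0, rmax0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        x_scale=[kd0, rmax0],
        xtol=1e-12,
        maxfev=20000,
    )
    kd, rmax = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    resid = req - isotherm(conc, kd, rmax)
    pts = pd.DataFrame({"concentration_M": conc, "req": req, "req_normalized": req / rmax})
    low_conf = bool(req.max() < 0.5 * rmax)
    return EquilibriumFit(
        kd=kd,
        rmax=rmax,
        kd_stderr=float(perr[0]),
        rmax_stderr=float(perr[1]),
        rss=float(np.sum(resid**2)),
        points=pts,
        low_confidence=low_conf,
    )


def fit_bli_experiment(traces: pd.DataFrame, tail_fraction: float = 0.1) -> pd.DataFrame:
    """Per-replicate steady-state fits of a tidy trace table.

    ``traces`` columns: replicate, concentration_M, time_s, response.
    Returns one row per replicate with Kd, Rmax, their standard errors, RSS
    and flags.  Kd is fitted per replicate and replicates summarised
    afterwards, matching reporting of mean +/- SD over independent
    experiments.
    """
    required = {"replicate", "concentration_M", "time_s", "response"}
    if not required.issubset(traces.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    rows = []
    for rep, grp in traces.groupby("replicate"):
        concs, reqs, any_extrap = [], [], False
        for conc, tr in grp.groupby("concentration_M"):
            tr = tr.sort_values("time_s")
            req, extrap = equilibrium_response(tr.time_s.to_numpy(), tr.response.to_numpy(), tail_fraction)
            concs.append(conc)
            reqs.append(req)
            any_extrap = any_extrap or extrap
        fit = fit_equilibrium_kd(concs, reqs)
        rows.append(
            {
                "replicate": rep,
                "kd": fit.kd,
                "rmax": fit.rmax,
                "kd_stderr": fit.kd_stderr,
                "rmax_stderr": fit.rmax_stderr,
                "rss": fit.rss,
                "low_confidence": fit.low_confidence,
                "extrapolated": any_extrap,
            }
        )
    return pd.DataFrame(rows)


def compare_affinities(kds_a, kds_b) -> dict:
    """Two-tailed unpaired t test between replicate Kd groups.

    Returns group means and SDs plus the p-value.  Degenerate zero-variance
    groups are handled explicitly: identical groups give p = 1; fully
    separated zero-variance groups give a p below the smallest positive
    float, reported with ``degenerate=True``.
    """
    a = np.asarray(kds_a, dtype=float)
    b = np.asarray(kds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    out = {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "degenerate": False,
    }
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        out["degenerate"] = True
        out["p_value"] = 1.0 if a.mean() == b.mean() else 5e-324
        return out
    t, p = stats.ttest_ind(a, b, equal_var=True)
    out["t_statistic"] = float(t)
    out["p_value"] = float(p)
    return out


def global_kinetic_fit(traces: pd.DataFrame) -> dict:
    """Optional secondary analysis: global 1:1 kinetic fit of ka, kd_off, Rmax
    across all concentrations of one replicate's association traces."""
    conc = traces.concentration_M.to_numpy(dtype=float)
    t = traces.time_s.to_numpy(dtype=float)
    r = traces.response.to_numpy(dtype=float)

    def model(x, ka, kd_off, rmax):
        tt, cc = x
        kobs = ka * cc + kd_off
        return rmax * cc / (cc + kd_off / ka) * (1.0 - np.exp(-kobs * tt))

    p0 = [1e5, 1e-3, max(r.max(), 1e-6)]
    popt, pcov = optimize.curve_fit(
        model, (t, conc), r, p0=p0, bounds=([1e-2, 1e-9, 1e-9], [1e12, 1e3, 1e6]), maxfev=50000
    )
    perr = np.sqrt(np.diag(pcov))
    return {
        "ka": float(popt[0]),
        "kd_off": float(popt[1]),
        "rmax": float(popt[2]),
        "Kd": float(popt[1] / popt[0]),
        "stderr": {"ka": float(perr[0]), "kd_off": float(perr[1]), "rmax": float(perr[2])},
    }
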