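"""Gompertz growth-curve fitting for individual weight trajectories.

The expected weight of pig *i* at age *t* (days) is modelled as
``W(t) = A * exp(-B * exp(-k*t))`` with asymptotic weight ``A`` (kg), shape
``B`` and rate ``k`` (per day), all positive, giving a monotone increasing
sigmoid. Daily feeding-station weights in the test window may be
supplemented with manually recorded anchor weights (birth, 14 d,
start/end of test) to pin the curve outside the window; the residuals used
by deviation traits are computed on the in-window daily records only, so
traits stay comparable between animals with and without anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["GompertzFit", "gompertz_predict", "fit_gompertz"]


def gompertz_predict(A: float, B: float, k: float, t) -> np.ndarray:
    """Evaluate ``A * exp(-B * exp(-k*t))``; parameters must be positive."""
    if min(A, B, k) <= 0:
        raise ValueError("Gompertz parameters must be positive")
    return A * np.exp(-B * np.exp(-k * np.asarray(t, dtype=float)))


@dataclass
class GompertzFit:
    A: float
    B: float
    k: float
    converged: bool
    n_iter: int
    rss: float
    residual_ages: np.ndarray  # in-window ages the residuals belong to
    residuals: np.ndarray  # observed - fitted, kg

    def predict(self, t) -> np.ndarray:
        return gompertz_predict(self.A, self.B, self.k, t)


def _model(p, t):
    A, B, k = p
    with np.errstate(over="ignore", invalid="ignore"):
        return A * np.exp(-B * np.exp(np.clip(-k * t, None, 500.0)))


def _jac(p, t):
    A, B, k = p
    with np.errstate(over="ignore", invalid="ignore"):
        ekt = np.exp(np.clip(-k * t, None, 500.0))
        core = np.exp(np.clip(-B * ekt, -500.0, 500.0))
        return np.column_stack((core, -A * ekt * core, A * B * t * ekt * core))


def fit_gompertz(
    ages,
    weights,
    anchor_ages=None,
    anchor_weights=None,
    window: tuple[int, int] = (95, 155),
    max_iter: int = 200,
) -> GompertzFit:
    """Nonlinear least-squares Gompertz fit to one animal's weights.

    ``ages``/``weights`` are the daily in-window records; anchors, when
    given, enter the fit but never the residual series. Requires at least 4
    points spanning at least 20 days. Non-convergence (or a fit leaving the
    positive-parameter region) is flagged, not raised, so downstream trait
    derivation can set curve-based traits to missing.
    """
    ages = np.asarray(ages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = ~np.isnan(weights)
    ages, weights = ages[keep], weights[keep]
    t_all, w_all = ages, weights
    if anchor_ages is not None and len(anchor_ages):
        t_all = np.concatenate([ages, np.asarray(anchor_ages, dtype=float)])
        w_all = np.concatenate([weights, np.asarray(anchor_weights, dtype=float)])
    if len(t_all) < 4:
        raise ValueError("Gompertz fit needs at least 4 points")
    if t_all.max() - t_all.min() < 20:
        raise ValueError("Gompertz fit needs points spanning at least 20 days")

    order = np.argsort(t_all)
    t_all, w_all = t_all[order], w_all[order]
    w_pos = np.clip(w_all, 0.05, None)

    a0 = max(2.0 * w_pos.max(), w_pos.max() + 5.0)
    k0 = 0.014
    t_ref, w_ref = t_all[-1], w_pos[-1]
    b0 = max(-np.log(min(w_ref / a0, 0.999)) * np.exp(k0 * t_ref), 0.5)
    p0 = np.array([a0, b0, k0])

    try:
        sol = least_squares(
            lambda p: _model(p, t_all) - w_all,
            p0,
            jac=lambda p: _jac(p, t_all),
            method="lm",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=max_iter * 3,
        )
        A, B, k = sol.x
        converged = bool(sol.success and min(A, B, k) > 0 and np.isfinite(sol.cost))
        n_iter = int(sol.nfev)
    except Exception:
        A = B = k = np.nan
        converged, n_iter = False, 0

    in_win = (ages >= window[0]) & (ages <= window[1])
    if converged:
        resid = weights[in_win] - _model((A, B, k), ages[in_win])
        rss = float(np.sum((_model((A, B, k), t_all) - w_all) ** 2))
    else:
        resid = np.full(in_win.sum(), np.nan)
        rss = np.nan
    return GompertzFit(
        A=float(A), B=float(B), k=float(k),
        converged=converged, n_iter=n_iter, rss=rss,
        residual_ages=ages[in_win], residuals=resid,
    )
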