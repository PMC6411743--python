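"""Four-parameter logistic dose-response fitting.

The alternative model for a responding protein is the sigmoid

    mu(x) = c + (d - c) / (1 + exp(b * (x - e)))

in x = log10(dose in molar), with slope ``b``, lower level ``c``, maximal
level ``d`` and inflection ``e``.  The null model is a flat intercept whose
least-squares optimum is the mean of y.  The evidence for a dose effect is
the relative residual reduction (RSS0 - RSS1) / RSS1.

Sign convention: since x is the log10 molar dose, the inflection ``e`` equals
log10(EC50) and the reported affinity is pEC50 = -e, which is positive for
EC50s below 1 M.

Fitting happens in two deterministic stages, vectorized over many series at
once (the permutation FDR refits every protein-window for each of ~100
permuted datasets, so per-series optimizer calls are ruled out):

1. a grid over (b, e) with the conditionally linear pair (c, d) profiled out
   by ordinary least squares -- the model is linear in (c, d) once the
   logistic basis is fixed;
2. a projected Levenberg-Marquardt refinement of all four parameters with
   analytic Jacobians, run simultaneously for every series.

Box constraints keep fits from running away on monotone-but-unsaturated
data: c, d in [0, 10 * max(y)], |b| <= 50, e within the observed x range
padded by two decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EXP_CLIP = 500.0

#: Pseudo-dose placement of the vehicle point: two decades below the lowest
#: tested dose (standard dose-response practice).
VEHICLE_DECADES_BELOW = 2.0

#: Sentinel x for vehicle points fitted at the no-ligand asymptote: large
#: enough that the clipped logistic saturates exactly in float64, so the
#: model value at the vehicle is the lower (or, for falling curves, upper)
#: plateau -- the true dose-0 limit.  Grid candidates and parameter boxes
#: ignore x values at or below this threshold.
VEHICLE_ASYMPTOTE_X = -1000.0
_SENTINEL_THRESH = -900.0


@dataclass
class DoseSeries:
    """Paired log10-molar doses and positive relative fold changes."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if not np.isfinite(self.x).all():
            raise ValueError("doses must be finite (vehicle handled before construction)")


@dataclass
class NullFit:
    """Flat intercept fit: c is the arithmetic mean of y (its LS optimum)."""

    c: float
    rss: float


@dataclass
class SigmoidFit:
    b: float
    c: float
    d: float
    e: float
    rss: float
    converged: bool

    @property
    def pec50(self) -> float:
        return -self.e


def sigmoid(x, b, c, d, e):
    """Evaluate the four-parameter logistic at log10-molar dose x."""
    s = np.clip(b * (np.asarray(x, dtype=float) - e), -_EXP_CLIP, _EXP_CLIP)
    return c + (d - c) / (1.0 + np.exp(s))


def pseudo_vehicle_x(concentrations_mM) -> float:
    """log10 molar pseudo-dose assigned to the vehicle (0 mM) point."""
    conc = np.asarray(concentrations_mM, dtype=float)
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("need at least one nonzero dose")
    return float(np.log10(nonzero.min() * 1e-3) - VEHICLE_DECADES_BELOW)


def to_dose_series(
    concentrations_mM,
    fold_changes,
    min_points: int = 5,
    include_vehicle: bool = True,
    vehicle_mode: str = "pseudo_dose",
) -> DoseSeries | None:
    """Build a :class:`DoseSeries` from doses in mM (0 = vehicle).

    ``vehicle_mode`` places the vehicle point either at a pseudo-dose two
    decades below the lowest tested dose (``"pseudo_dose"``) or at the
    no-ligand asymptote of the model (``"asymptote"``); the latter avoids
    the systematic inflection bias the finite pseudo-dose induces when the
    EC50 approaches the bottom of the dose range.  Returns None (a skip
    signal, not an error) when fewer than ``min_points`` usable points
    remain.
    """
    conc = np.asarray(concentrations_mM, dtype=float)
    y = np.asarray(fold_changes, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("concentrations and fold changes must align")
    keep = np.isfinite(y)
    vehicle = conc == 0
    if not include_vehicle:
        keep &= ~vehicle
    conc, y, vehicle = conc[keep], y[keep], vehicle[keep]
    if conc.size < min_points:
        return None
    x = np.empty_like(conc)
    x[~vehicle] = np.log10(conc[~vehicle] * 1e-3)
    if vehicle.any():
        if vehicle_mode == "pseudo_dose":
            x[vehicle] = pseudo_vehicle_x(conc)
        elif vehicle_mode == "asymptote":
            x[vehicle] = VEHICLE_ASYMPTOTE_X
        else:
            raise ValueError(f"unknown vehicle_mode {vehicle_mode!r}")
    return DoseSeries(x, y)


def fit_null(series: DoseSeries) -> NullFit:
    """Closed-form intercept fit under the no-effect null."""
    if series.y.size == 0:
        raise ValueError("empty series")
    c = float(series.y.mean())
    return NullFit(c=c, rss=float(((series.y - c) ** 2).sum()))


def f_component(rss0: float, rss1: float) -> float:
    """Relative residual reduction (RSS0 - RSS1)/RSS1, floored at zero.

    A perfect alternative fit (rss1 == 0) against nonzero null residuals
    returns +inf as a sentinel for the caller to regularize; two exact fits
    (both zero) carry no evidence and return 0.
    """
    if rss1 < 0 or rss0 < 0:
        raise ValueError("residual sums of squares must be nonnegative")
    if rss1 == 0.0:
        return float("inf") if rss0 > 0 else 0.0
    return max((rss0 - rss1) / rss1, 0.0)


# ---------------------------------------------------------------------------
# batched fitting machinery


def _observed_x(x: np.ndarray) -> np.ndarray:
    """Dose locations excluding any vehicle asymptote sentinel."""
    obs = x[x > _SENTINEL_THRESH]
    return obs if obs.size else x


def _param_boxes(x: np.ndarray, Y: np.ndarray):
    obs = _observed_x(x)
    ymax = np.maximum(Y.max(axis=1), 1e-12)
    lo = np.empty((Y.shape[0], 4))
    hi = np.empty((Y.shape[0], 4))
    lo[:, 0], hi[:, 0] = -50.0, 50.0
    lo[:, 1], hi[:, 1] = 0.0, 10.0 * ymax
    lo[:, 2], hi[:, 2] = 0.0, 10.0 * ymax
    lo[:, 3], hi[:, 3] = obs.min() - 2.0, obs.max() + 2.0
    return lo, hi


def _grid_candidates(x: np.ndarray):
    ux = np.unique(_observed_x(x))
    mids = (ux[:-1] + ux[1:]) / 2.0
    e_cands = np.unique(np.concatenate([ux, mids, [np.median(ux)]]))
    b_cands = np.array([-30.0, -10.0, -3.0, -1.0, -0.3, 0.3, 1.0, 3.0, 10.0, 30.0])
    return e_cands, b_cands


def _grid_init(x: np.ndarray, Y: np.ndarray):
    """Variable-projection grid search: best (b, c, d, e) per series."""
    n, m = Y.shape
    best_rss = np.full(n, np.inf)
    best = np.zeros((n, 4))
    e_cands, b_cands = _grid_candidates(x)
    Yt = Y.T  # (m, n)
    for e in e_cands:
        for b in b_cands:
            s = np.clip(b * (x - e), -_EXP_CLIP, _EXP_CLIP)
            g = 1.0 / (1.0 + np.exp(s))
            D = np.column_stack([1.0 - g, g])  # y = c*(1-g) + d*g
            A = D.T @ D + 1e-12 * np.eye(2)
            B = D.T @ Yt
            coef = np.linalg.solve(A, B)  # (2, n)
            resid = Yt - D @ coef
            rss = np.einsum("mn,mn->n", resid, resid)
            better = rss < best_rss
            if better.any():
                best_rss[better] = rss[better]
                best[better, 0] = b
                best[better, 1] = coef[0, better]
                best[better, 2] = coef[1, better]
                best[better, 3] = e
    return best, best_rss


def _model(x: np.ndarray, P: np.ndarray) -> np.ndarray:
    b, c, d, e = P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4]
    s = np.clip(b * (x[None, :] - e), -_EXP_CLIP, _EXP_CLIP)
    g = 1.0 / (1.0 + np.exp(s))
    return c + (d - c) * g


def _model_and_jacobian(x: np.ndarray, P: np.ndarray):
    b, c, d, e = P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4]
    dx = x[None, :] - e
    s = np.clip(b * dx, -_EXP_CLIP, _EXP_CLIP)
    g = 1.0 / (1.0 + np.exp(s))
    mu = c + (d - c) * g
    amp_gg = (d - c) * g * (1.0 - g)
    J = np.empty(P.shape[:1] + x.shape + (4,))
    J[:, :, 0] = -amp_gg * dx
    J[:, :, 1] = 1.0 - g
    J[:, :, 2] = g
    J[:, :, 3] = amp_gg * b
    return mu, J


def fit_sigmoid_batch(
    x: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 60,
    rss_tol: float = 1e-10,
) -> dict:
    """Fit the 4PL to every row of ``Y`` against the shared dose vector ``x``.

    Returns arrays ``b, c, d, e, rss, rss0, converged``.  The contract
    rss <= rss0 is enforced: series where optimization fails to beat the
    intercept are returned as null-equivalent, flagged unconverged.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, m = Y.shape
    mean = Y.mean(axis=1)
    rss0 = ((Y - mean[:, None]) ** 2).sum(axis=1)

    out = {
        "b": np.zeros(n), "c": mean.copy(), "d": mean.copy(),
        "e": np.full(n, np.median(x)), "rss": rss0.copy(),
        "rss0": rss0, "converged": np.zeros(n, dtype=bool),
    }
    if np.ptp(x) == 0.0 or m < 2:
        return out  # degenerate dose axis: null-equivalent, unconverged

    lo, hi = _param_boxes(x, Y)
    P, rss = _grid_init(x, Y)
    P = np.clip(P, lo, hi)
    mu, _ = _model_and_jacobian(x, P)
    rss = ((Y - mu) ** 2).sum(axis=1)

    lam = np.full(n, 1e-3)
    active = np.arange(n)
    for _ in range(max_iter):
        if active.size == 0:
            break
        Pa = P[active]
        mu, J = _model_and_jacobian(x, Pa)
        r = Y[active] - mu
        Jt = J.transpose(0, 2, 1)
        grad = np.matmul(Jt, r[..., None])[..., 0]
        H = np.matmul(Jt, J)
        diag = np.maximum(np.einsum("npp->np", H), 1e-12)
        Haug = H + lam[active, None, None] * diag[:, None, :] * np.eye(4)
        try:
            step = np.linalg.solve(Haug, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Haug = Haug + 1e-8 * np.eye(4)
            step = np.linalg.solve(Haug, grad[..., None])[..., 0]
        trial = np.clip(Pa + step, lo[active], hi[active])
        rss_t = ((Y[active] - _model(x, trial)) ** 2).sum(axis=1)

        improved = rss_t < rss[active]
        gain = rss[active] - rss_t
        idx_imp = active[improved]
        P[idx_imp] = trial[improved]
        rss[idx_imp] = rss_t[improved]
        lam[idx_imp] *= 0.3
        idx_rej = active[~improved]
        lam[idx_rej] *= 4.0
        np.clip(lam, 1e-12, 1e12, out=lam)

        # converged: a vanishing accepted gain, an exact fit, or a rejected
        # step from an already conservative (large-lambda) trust region
        done_imp = improved & (gain <= rss_tol * np.maximum(rss_t, 1e-20))
        done_abs = rss[active] <= 1e-26
        done_stuck = ~improved & (lam[active] >= 1e5)
        done = done_imp | done_abs | done_stuck
        active = active[~done]

    worse = rss > rss0
    ok = ~worse
    out["b"][ok] = P[ok, 0]
    out["c"][ok] = P[ok, 1]
    out["d"][ok] = P[ok, 2]
    out["e"][ok] = P[ok, 3]
    out["rss"][ok] = rss[ok]
    out["converged"][ok] = True
    # series beaten by the intercept stay null-equivalent (converged=False)
    return out


def component_batch(x: np.ndarray, Y: np.ndarray, min_points: int):
    """Per-row F components and fit metadata, tolerating missing cells.

    Rows of ``Y`` with NaNs are regrouped by missingness pattern and fitted
    against the reduced dose vector; rows with fewer than ``min_points``
    usable points are skipped (component NaN).  Returns (component, e,
    converged) arrays of length ``Y.shape[0]``; components use
    :func:`f_component` (so perfect fits surface as +inf for the caller to
    regularize).
    """
    Y = np.atleast_2d(Y)
    n = Y.shape[0]
    comp = np.full(n, np.nan)
    e = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    mask = np.isfinite(Y)
    complete = mask.all(axis=1)

    def run(rows: np.ndarray, xs: np.ndarray, ys: np.ndarray):
        res = fit_sigmoid_batch(xs, ys)
        for k, row in enumerate(rows):
            comp[row] = f_component(float(res["rss0"][k]), float(res["rss"][k]))
            e[row] = res["e"][k]
            converged[row] = res["converged"][k]

    rows = np.nonzero(complete)[0]
    if rows.size and x.size >= min_points:
        run(rows, x, Y[rows])
    incomplete = np.nonzero(~complete)[0]
    if incomplete.size:
        patterns: dict[bytes, list[int]] = {}
        for row in incomplete:
            patterns.setdefault(mask[row].tobytes(), []).append(row)
        for key, rws in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if m.sum() < min_points:
                continue
            run(np.asarray(rws), x[m], Y[np.ix_(rws, np.nonzero(m)[0])])
    return comp, e, converged


def fit_sigmoid(series: DoseSeries) -> SigmoidFit:
    """Fit one dose-response series; see :func:`fit_sigmoid_batch`."""
    res = fit_sigmoid_batch(series.x, series.y[None, :])
    return SigmoidFit(
        b=float(res["b"][0]), c=float(res["c"][0]), d=float(res["d"][0]),
        e=float(res["e"][0]), rss=float(res["rss"][0]),
        converged=bool(res["converged"][0]),
    )
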