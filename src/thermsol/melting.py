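"""Melting-curve analysis: Tm extraction, co-melting, heating solubilization.

The fraction of non-denatured protein as a function of temperature T (degC)
is modeled by a plateau sigmoid in 1/T,

    f(T) = (1 - p) / (1 + exp(b - a/T)) + p,

the functional family standard in thermal proteome profiling.  The melting
point Tm is the temperature at which the fitted curve crosses 0.5 (defined
only when the plateau p < 0.5 and the crossing falls near the measured
range).  A fit is considered valid when r2 >= 0.8 and p < 0.3 (configurable).

Co-melting of complex subunits is quantified by the average squared
deviation per temperature between two [0, 1]-valued melting profiles; the
published cutoff of 0.02 on ten-point profiles is only dimensionally
plausible for an averaged quantity, so that is the default, with a
root-sum-square variant available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig


@dataclass
class MeltingProfile:
    """Relative non-denatured fraction over a temperature gradient.

    ``fraction`` is normalized so the value at the lowest temperature is 1.
    """

    protein_id: str
    condition: str
    temperatures: np.ndarray
    fraction: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.temperatures.shape != self.fraction.shape:
            raise ValueError("temperatures and fractions must align")
        order = np.argsort(self.temperatures)
        self.temperatures = self.temperatures[order]
        self.fraction = self.fraction[order]


@dataclass
class MeltingCurveFit:
    a: float
    b: float
    plateau: float
    tm: float | None
    r2: float
    rss: float
    valid: bool


@dataclass
class CoMeltResult:
    complex_id: str
    observed: float
    p_value: float
    pair_distances: pd.DataFrame = field(repr=False)
    proximity_pairs: int = 0
    n_pairs: int = 0


def plateau_sigmoid(T, a, b, p):
    """Fraction non-denatured at temperature T (degC)."""
    T = np.asarray(T, dtype=float)
    s = np.clip(b - a / T, -500, 500)
    return (1.0 - p) / (1.0 + np.exp(s)) + p


def tm_from_params(a: float, b: float, p: float) -> float | None:
    """Temperature where the plateau sigmoid crosses 0.5, or None."""
    if p >= 0.5:
        return None
    denom = b - np.log(0.5 / (0.5 - p))
    if denom <= 0:
        return None
    return float(a / denom)


def melting_params_for_tm(tm: float, p: float, a: float = 550.0) -> tuple:
    """Choose (a, b, p) so the curve melts at ``tm`` with plateau ``p``."""
    if not 0 <= p < 0.5:
        raise ValueError("plateau must lie in [0, 0.5) for a defined Tm")
    b = a / tm + np.log(0.5 / (0.5 - p))
    return a, b, p


def fit_melting_curve(
    profile: MeltingProfile, cfg: AnalysisConfig | None = None
) -> MeltingCurveFit:
    """Least-squares fit of the plateau sigmoid to one melting profile.

    Multi-start over plateau and slope initializations; the Tm
    initialization interpolates the first 0.5 crossing of the data.
    Non-convergence yields an invalid fit without a melting point.
    """
    cfg = cfg or AnalysisConfig()
    T = profile.temperatures
    y = profile.fraction
    if T.size < 5:
        return MeltingCurveFit(0.0, 0.0, 0.0, None, 0.0, float("inf"), False)

    # initialize Tm at the interpolated 0.5 crossing, else mid-range
    tm0 = float(np.median(T))
    below = np.nonzero(y < 0.5)[0]
    if below.size and below[0] > 0:
        i = below[0]
        t_lo, t_hi = T[i - 1], T[i]
        y_lo, y_hi = y[i - 1], y[i]
        if y_lo != y_hi:
            tm0 = float(t_lo + (y_lo - 0.5) / (y_lo - y_hi) * (t_hi - t_lo))

    def residual(theta):
        a, b, p = theta
        return plateau_sigmoid(T, a, b, p) - y

    best = None
    for p0 in (0.0, 0.1, 0.25):
        for a0 in (300.0, 550.0, 1100.0):
            b0 = a0 / tm0 + np.log(0.5 / (0.5 - min(p0, 0.49)))
            try:
                sol = optimize.least_squares(
                    residual,
                    x0=[a0, b0, p0],
                    bounds=([1.0, -1e3, 0.0], [1e5, 1e3, 1.0 - 1e-9]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return MeltingCurveFit(0.0, 0.0, 0.0, None, 0.0, float("inf"), False)

    rss, sol = best
    a, b, p = (float(v) for v in sol.x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    tm = tm_from_params(a, b, p)
    if tm is not None and not (T.min() - 5.0 <= tm <= T.max() + 5.0):
        tm = None
    valid = (
        sol.success
        and tm is not None
        and r2 >= cfg.melting_r2_min
        and p < cfg.melting_plateau_max
    )
    return MeltingCurveFit(a, b, p, tm, r2, rss, bool(valid))


def delta_tm(treated: MeltingCurveFit, vehicle: MeltingCurveFit) -> float | None:
    """Tm(treated) - Tm(vehicle); None when either melting point is absent."""
    if not treated.valid or not vehicle.valid:
        return None
    if treated.tm is None or vehicle.tm is None:
        return None
    return treated.tm - vehicle.tm


def comelt_distance(
    a: MeltingProfile, b: MeltingProfile, mode: str = "mean_sq"
) -> float | None:
    """Profile distance between two melting curves on their shared grid.

    ``mean_sq`` (default): average squared deviation per temperature.
    ``rss``: Euclidean root-sum-square.  Returns None with fewer than five
    shared temperatures.
    """
    shared, ia, ib = np.intersect1d(a.temperatures, b.temperatures, return_indices=True)
    if shared.size < 5:
        return None
    diff = a.fraction[ia] - b.fraction[ib]
    if mode == "mean_sq":
        return float(np.mean(diff**2))
    if mode == "rss":
        return float(np.sqrt(np.sum(diff**2)))
    raise ValueError(f"unknown distance mode {mode!r}")


def _mean_pairwise(profiles: np.ndarray, mode: str) -> float:
    k = profiles.shape[0]
    total, n = 0.0, 0
    for i in range(k):
        diff = profiles[i + 1:] - profiles[i]
        if mode == "mean_sq":
            total += float(np.mean(diff**2, axis=1).sum())
        else:
            total += float(np.sqrt(np.sum(diff**2, axis=1)).sum())
        n += diff.shape[0]
    return total / n


def complex_comelt_test(
    subunits: list[MeltingProfile],
    background: list[MeltingProfile],
    n_rand: int = 999,
    seed: int = 0,
    cfg: AnalysisConfig | None = None,
) -> CoMeltResult:
    """Randomization test for co-melting of a protein complex.

    The observed statistic is the mean pairwise profile distance among the
    complex's quantified subunits (>= 3 required).  The null distribution is
    the same statistic for random same-size subsets drawn without
    replacement from all quantified background proteins; the p-value uses
    the add-one correction p = (1 + #{null <= observed}) / (1 + n_rand),
    which is valid (stochastically >= uniform) under the null.
    """
    cfg = cfg or AnalysisConfig()
    if len(subunits) < 3:
        raise ValueError("complex must have at least three quantified subunits")
    if len(background) < len(subunits):
        raise ValueError("background smaller than the complex")
    grid = subunits[0].temperatures
    for s in subunits + background:
        if not np.array_equal(s.temperatures, grid):
            raise ValueError("all profiles must share one temperature grid")

    mode = cfg.comelt_distance_mode
    sub = np.vstack([s.fraction for s in subunits])
    bg = np.vstack([s.fraction for s in background])
    observed = _mean_pairwise(sub, mode)

    rng = np.random.default_rng(seed)
    k = sub.shape[0]
    null = np.empty(n_rand)
    for r in range(n_rand):
        idx = rng.choice(bg.shape[0], size=k, replace=False)
        null[r] = _mean_pairwise(bg[idx], mode)
    p = (1.0 + np.count_nonzero(null <= observed)) / (1.0 + n_rand)

    rows = []
    prox = 0
    for i in range(k):
        for j in range(i + 1, k):
            d = comelt_distance(subunits[i], subunits[j], mode)
            close = d is not None and d < cfg.comelt_cutoff
            prox += bool(close)
            rows.append((subunits[i].protein_id, subunits[j].protein_id, d, close))
    pairs = pd.DataFrame(rows, columns=["protein_a", "protein_b", "distance", "proximal"])
    complex_id = getattr(subunits[0], "complex_id", "") or "complex"
    return CoMeltResult(
        complex_id=complex_id, observed=observed, p_value=float(p),
        pair_distances=pairs, proximity_pairs=prox, n_pairs=len(rows),
    )


@dataclass
class HeatingResponse:
    max_fold_change: float
    log2_max_fold_change: float
    argmax_temperature: float


def max_fold_change_on_heating(
    temperatures, values, reference_temperature: float = 37.0
) -> HeatingResponse:
    """Maximal soluble-abundance gain on heating, relative to the reference.

    Proteins with an insoluble subpopulation can *gain* soluble signal when
    heated (a phase transition into solution) before denaturing; this
    statistic captures that as the maximum fold change vs the reference
    temperature over all hotter/other temperatures (log2 reported as well).
    """
    T = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    ref_idx = np.nonzero(T == reference_temperature)[0]
    if ref_idx.size == 0:
        raise ValueError(f"reference temperature {reference_temperature} not present")
    ref = v[ref_idx[0]]
    if ref <= 0:
        raise ValueError("reference value must be positive")
    mask = np.ones(T.size, dtype=bool)
    mask[ref_idx[0]] = False
    fc = v[mask] / ref
    i = int(np.argmax(fc))
    return HeatingResponse(
        max_fold_change=float(fc[i]),
        log2_max_fold_change=float(np.log2(fc[i])),
        argmax_temperature=float(T[mask][i]),
    )


def solubility_corrected_curve(
    protein_id: str,
    condition: str,
    temperatures,
    raw_values,
    spp_fold_change: float | None,
) -> tuple[MeltingProfile, bool]:
    """Divide a treated melting curve by its solubility fold change.

    Separates a ligand's solubility effect from its stability effect: the
    raw treated intensities are divided pointwise by the protein's
    solubility fold change at the matching dose *before* normalizing to the
    lowest temperature.  When the solubility value is missing the
    uncorrected curve is returned with ``corrected=False``.
    """
    values = np.asarray(raw_values, dtype=float)
    corrected = False
    if spp_fold_change is not None and np.isfinite(spp_fold_change):
        if spp_fold_change == 0:
            raise ValueError("solubility fold change of 0 leaves correction undefined")
        values = values / spp_fold_change
        corrected = True
    T = np.asarray(temperatures, dtype=float)
    order = np.argsort(T)
    base = values[order][0]
    if base <= 0:
        raise ValueError("value at the lowest temperature must be positive")
    return (
        MeltingProfile(protein_id, condition, T[order], values[order] / base),
        corrected,
    )


def melting_profiles(quant, samples) -> dict:
    """Median-over-replicates melting profiles per (protein, condition).

    Intensities are combined by their replicate median at each temperature
    and normalized to the lowest temperature.  Returns
    {(protein_id, condition): MeltingProfile}.
    """
    from .data import validate_layout  # deferred: avoid import cycle at module load

    validate_layout(samples, "TPP_TR")
    meta = {s.sample_id: s for s in samples}
    df = quant.df.copy()
    df["temperature"] = df["sample_id"].map(lambda s: meta[s].temperature)
    df["condition"] = df["sample_id"].map(lambda s: meta[s].condition)
    med = (
        df.groupby(["protein_id", "condition", "temperature"])["value"]
        .median()
        .reset_index()
    )
    out = {}
    for (pid, cond), grp in med.groupby(["protein_id", "condition"]):
        grp = grp.sort_values("temperature")
        vals = grp["value"].to_numpy()
        if vals[0] <= 0:
            continue
        out[(pid, cond)] = MeltingProfile(
            pid, cond, grp["temperature"].to_numpy(), vals / vals[0]
        )
    return out


def run_tpp_tr(quant, samples, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Fit melting curves for every protein and condition; report Tm shifts.

    Returns one row per protein with per-condition melting points, fit
    diagnostics, and the treated-minus-vehicle Tm difference where both
    fits are valid.
    """
    cfg = cfg or AnalysisConfig()
    profiles = melting_profiles(quant, samples)
    rows = {}
    for (pid, cond), prof in profiles.items():
        fit = fit_melting_curve(prof, cfg)
        row = rows.setdefault(pid, {"protein_id": pid})
        row[f"tm_{cond}"] = fit.tm
        row[f"r2_{cond}"] = fit.r2
        row[f"plateau_{cond}"] = fit.plateau
        row[f"valid_{cond}"] = fit.valid
        row[f"_fit_{cond}"] = fit
    out = []
    for pid, row in sorted(rows.items()):
        ft, fv = row.pop("_fit_treated", None), row.pop("_fit_vehicle", None)
        row["delta_tm"] = delta_tm(ft, fv) if ft and fv else None
        out.append(row)
    return pd.DataFrame(out)


def group_shift_test(values_a, values_b, paired: bool = False):
    """Location-shift test between two groups of (e.g.) melting-point changes.

    Wilcoxon signed-rank when paired, Wilcoxon rank-sum (Mann-Whitney)
    otherwise.  Returns (statistic, p); p is NaN when the paired differences
    are all ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if np.all(a == b):
            return 0.0, float("nan")
        stat, p = stats.wilcoxon(a, b)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
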