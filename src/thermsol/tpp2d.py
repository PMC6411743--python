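"""Dose x temperature (2D) analysis: sliding-window F-statistics with
stratified permutation FDR and affinity (pEC50) assignment.

Stages, per the screening design:

1. fold changes versus the vehicle of the same temperature/plex/replicate,
   then median-centering of log2 fold changes within each TMT channel;
2. per protein, replicate, and window of adjacent temperatures: pool the
   (dose, fold change) points of the window, fit the 4PL and the intercept
   null, form the relative residual reduction, and take the median over
   replicates (F_ij);
3. per protein: sum ln(F_ij) over windows whose most extreme fold change
   passes the gate (> h or < 1/h) -- a log-scale combination that behaves
   like a geometric mean and blunts single-window outliers;
4. stratified permutations -- fold changes shuffled across proteins and
   doses within (temperature x qupm-bin) strata, vehicle untouched -- yield
   the null score distribution and an average FDR per threshold;
5. hits at the FDR cutoff get a pEC50: the median over replicates of -e at
   the lowest temperature where the gate fold change was reached in at
   least two replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data import QuantTable, SampleMeta, validate_layout
from .doseresp import VEHICLE_ASYMPTOTE_X, component_batch, pseudo_vehicle_x
from .permfdr import permutation_fdr

log = logging.getLogger("thermsol")

_INF_FALLBACK = 1e6  # replacement when a dataset has no finite positive component


@dataclass
class FoldChangeData:
    """Dense fold-change cube for one 2D experiment.

    ``fc[i, r, t, c]`` is the fold change of protein i, replicate r at
    temperature index t and concentration index c; index c = 0 is the
    vehicle, pinned to 1.  Missing cells are NaN.
    """

    proteins: list[str]
    replicates: np.ndarray
    temperatures: np.ndarray
    concentrations_mM: np.ndarray
    fc: np.ndarray
    qupm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.proteins, self.replicates, self.temperatures, self.concentrations_mM],
            names=["protein_id", "replicate", "temperature", "concentration_mM"],
        )
        df = pd.DataFrame({"fold_change": self.fc.ravel()}, index=idx).reset_index()
        df["qupm"] = np.repeat(self.qupm, self.fc[0].size)
        return df


@dataclass
class WindowResults:
    """Per-window statistics and retained per-replicate fits."""

    window_temps: list[tuple]
    F: np.ndarray              # (n_prot, n_windows) median-over-replicates
    components: np.ndarray     # (n_prot, n_rep, n_windows)
    phi_extreme: np.ndarray    # (n_prot, n_windows) most extreme fold change
    e: np.ndarray              # (n_prot, n_rep, n_windows) inflection estimates
    converged: np.ndarray      # (n_prot, n_rep, n_windows)


@dataclass
class Tpp2dResult:
    scores: pd.DataFrame
    fdr_curve: pd.DataFrame
    hits: pd.DataFrame
    fold_changes: FoldChangeData = field(repr=False)
    windows: WindowResults = field(repr=False)


def preprocess_2dtpp(
    quant: QuantTable, samples: list[SampleMeta], cfg: AnalysisConfig | None = None
) -> FoldChangeData:
    """Intensities -> vehicle-relative fold changes, median-centered per channel.

    Fold change = intensity(treated) / intensity(vehicle at the same
    temperature, plex and replicate).  log2 fold changes are then shifted so
    the median within each TMT channel (sample) is zero, and vehicle entries
    are re-pinned to exactly 1.  Temperatures whose vehicle is missing in a
    replicate are dropped for that replicate and logged.
    """
    cfg = cfg or AnalysisConfig()
    validate_layout(samples, "TPP_2D")
    meta = {s.sample_id: s for s in samples}
    reps = np.array(sorted({s.replicate for s in samples}))
    temps = np.array(sorted({s.temperature for s in samples}))
    concs = np.array(sorted({s.concentration_mM for s in samples}))
    proteins = quant.proteins
    pidx = {p: i for i, p in enumerate(proteins)}
    ridx = {r: i for i, r in enumerate(reps)}
    tidx = {t: i for i, t in enumerate(temps)}
    cidx = {c: i for i, c in enumerate(concs)}

    intensity = np.full((len(proteins), reps.size, temps.size, concs.size), np.nan)
    qupm = np.full(len(proteins), 2, dtype=int)
    df = quant.df
    rows = df["protein_id"].map(pidx).to_numpy()
    for prot, sid, value, q in zip(rows, df["sample_id"], df["value"], df["qupm"]):
        s = meta[sid]
        intensity[prot, ridx[s.replicate], tidx[s.temperature], cidx[s.concentration_mM]] = value
        qupm[prot] = q

    vehicle = intensity[:, :, :, 0:1]
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(vehicle > 0, intensity / vehicle, np.nan)
    n_dropped = int(np.isnan(vehicle).sum())
    if n_dropped:
        log.info("2D preprocessing: %d replicate-temperature cells lack a vehicle "
                 "and were dropped", n_dropped)

    # per-channel median centering on the log2 scale (vehicle channels are
    # identically 1, their median shift is zero by construction)
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2(fc)
    for r in range(reps.size):
        for t in range(temps.size):
            for c in range(1, concs.size):
                col = lfc[:, r, t, c]
                good = np.isfinite(col)
                if good.any():
                    lfc[good, r, t, c] = col[good] - np.median(col[good])
    fc = 2.0 ** lfc
    fc[:, :, :, 0] = np.where(np.isnan(fc[:, :, :, 0]), np.nan, 1.0)

    log.info("2D preprocessing: %d proteins, %d replicates, %d temperatures, "
             "%d concentrations", len(proteins), reps.size, temps.size, concs.size)
    return FoldChangeData(proteins, reps, temps, concs, fc, qupm)


def _window_x(concs: np.ndarray, n_temps: int, cfg: AnalysisConfig) -> np.ndarray:
    per_temp = []
    if cfg.include_vehicle_point:
        if cfg.vehicle_mode == "asymptote":
            per_temp.append(VEHICLE_ASYMPTOTE_X)
        else:
            per_temp.append(pseudo_vehicle_x(concs))
    per_temp.extend(np.log10(concs[concs > 0] * 1e-3))
    return np.tile(per_temp, n_temps)


def window_scores(fcd: FoldChangeData, cfg: AnalysisConfig | None = None) -> WindowResults:
    """Sliding-window dose-response statistics for every protein."""
    cfg = cfg or AnalysisConfig()
    n_prot, n_rep, n_temp, n_conc = fcd.fc.shape
    if n_temp < cfg.window_size:
        raise ValueError("need at least one full temperature window")
    w = cfg.window_size
    n_win = n_temp - w + 1
    x = _window_x(fcd.concentrations_mM, w, cfg)

    components = np.full((n_prot, n_rep, n_win), np.nan)
    e = np.full((n_prot, n_rep, n_win), np.nan)
    converged = np.zeros((n_prot, n_rep, n_win), dtype=bool)
    phi_extreme = np.full((n_prot, n_win), np.nan)
    window_temps = []

    for j in range(n_win):
        block = fcd.fc[:, :, j:j + w, :]
        window_temps.append(tuple(fcd.temperatures[j:j + w]))
        if cfg.include_vehicle_point:
            Y = block.reshape(n_prot * n_rep, w * n_conc)
        else:
            Y = block[:, :, :, 1:].reshape(n_prot * n_rep, w * (n_conc - 1))
        comp, ee, conv = component_batch(x, Y, cfg.min_points_per_fit)
        components[:, :, j] = comp.reshape(n_prot, n_rep)
        e[:, :, j] = ee.reshape(n_prot, n_rep)
        converged[:, :, j] = conv.reshape(n_prot, n_rep)

        treated = block[:, :, :, 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.abs(np.log2(treated))
        flat = treated.reshape(n_prot, -1)
        devf = dev.reshape(n_prot, -1)
        devf = np.where(np.isfinite(devf), devf, -np.inf)
        best = np.argmax(devf, axis=1)
        has_any = np.isfinite(devf).any(axis=1) & (devf.max(axis=1) > -np.inf)
        phi_extreme[has_any, j] = flat[np.arange(n_prot), best][has_any]

    # regularize perfect fits: +inf components take the largest finite value
    finite = components[np.isfinite(components)]
    repl = finite.max() if finite.size and finite.max() > 0 else _INF_FALLBACK
    components = np.where(np.isposinf(components), repl, components)

    with np.errstate(all="ignore"):
        F = np.nanmedian(components, axis=1)
    return WindowResults(window_temps, F, components, phi_extreme, e, converged)


def combined_scores(
    wr: WindowResults, cfg: AnalysisConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein combined score and direction from gated windows.

    Windows enter the sum only when their extreme fold change passes the
    gate; by default ln(F) terms below zero are excluded (a window whose
    sigmoid fit barely beats the intercept carries no evidence and would
    otherwise cancel real signal in other windows).
    """
    cfg = cfg or AnalysisConfig()
    F = wr.F
    phi = wr.phi_extreme
    with np.errstate(invalid="ignore", divide="ignore"):
        up = phi > cfg.h
        down = phi < 1.0 / cfg.h
    gated = (up | down) & np.isfinite(F)

    with np.errstate(invalid="ignore", divide="ignore"):
        lnF = np.where(gated & (F > 0), np.log(np.where(F > 0, F, 1.0)), 0.0)
    if not cfg.allow_negative_log_terms:
        lnF = np.maximum(lnF, 0.0)
    scores = lnF.sum(axis=1)

    n_prot = F.shape[0]
    direction = np.array(["none"] * n_prot, dtype=object)
    any_up = (up & gated).any(axis=1)
    any_down = (down & gated).any(axis=1)
    direction[any_up & ~any_down] = "stabilized"
    direction[any_down & ~any_up] = "destabilized"
    both = any_up & any_down
    if both.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            dev = np.abs(np.log2(phi))
        dev = np.where(gated & np.isfinite(dev), dev, -np.inf)
        for i in np.nonzero(both)[0]:
            j = int(np.argmax(dev[i]))
            direction[i] = "stabilized" if phi[i, j] > 1 else "destabilized"
    return scores, direction


def permute_dataset(fcd: FoldChangeData, seed) -> FoldChangeData:
    """Stratified null dataset: fold changes shuffled within strata.

    Within each (temperature x qupm-bin) stratum all non-vehicle fold
    changes are shuffled jointly across proteins, doses and replicates; the
    vehicle reference entries stay untouched.  The multiset of values per
    stratum is exactly preserved.
    """
    rng = np.random.default_rng(seed)
    fc = fcd.fc.copy()
    n_temp = fcd.temperatures.size
    for t in range(n_temp):
        for q in np.unique(fcd.qupm):
            sel = fcd.qupm == q
            block = fc[sel, :, t, 1:]
            flat = block.ravel()
            good = np.isfinite(flat)
            vals = flat[good]
            flat[good] = vals[rng.permutation(vals.size)]
            fc[sel, :, t, 1:] = flat.reshape(block.shape)
    return FoldChangeData(
        fcd.proteins, fcd.replicates, fcd.temperatures,
        fcd.concentrations_mM, fc, fcd.qupm,
    )


def fdr_estimate(
    original_scores: np.ndarray,
    permuted_scores: list[np.ndarray],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Average permutation FDR per candidate threshold (see permfdr)."""
    return permutation_fdr(original_scores, permuted_scores)


def assign_pec50(
    fcd: FoldChangeData,
    wr: WindowResults,
    directions: np.ndarray,
    hit_mask: np.ndarray,
    cfg: AnalysisConfig | None = None,
) -> np.ndarray:
    """Affinity per hit: median -e at the lowest gate-reaching temperature.

    A temperature qualifies when the direction's gate fold change (>= h for
    stabilization, <= 1/h for destabilization) is reached at any dose in at
    least two replicates.  The per-replicate inflection estimates of the
    window anchored at that temperature are combined by their median; the
    result is clipped to the informative range [pEC50 of the highest dose
    minus 1, pEC50 of the vehicle pseudo-dose].
    """
    cfg = cfg or AnalysisConfig()
    n_prot, n_rep, n_temp, _ = fcd.fc.shape
    n_win = len(wr.window_temps)
    concs = fcd.concentrations_mM
    lo = -np.log10(concs.max() * 1e-3) - 1.0
    hi = -pseudo_vehicle_x(concs)
    # inflection estimates pinned at the optimizer's box edge are runaway
    # solutions, not affinity estimates; they are excluded from the median
    x_min = (pseudo_vehicle_x(concs) if cfg.vehicle_mode == "pseudo_dose"
             else np.log10(concs[concs > 0].min() * 1e-3))
    e_box_lo = x_min - 2.0 + 1e-6
    e_box_hi = np.log10(concs.max() * 1e-3) + 2.0 - 1e-6

    pec50 = np.full(n_prot, np.nan)
    treated = fcd.fc[:, :, :, 1:]
    with np.errstate(invalid="ignore"):
        reach_up = (treated >= cfg.h).any(axis=3)       # (prot, rep, temp)
        reach_down = (treated <= 1.0 / cfg.h).any(axis=3)
    for i in np.nonzero(hit_mask)[0]:
        reach = reach_up[i] if directions[i] == "stabilized" else reach_down[i]
        counts = reach.sum(axis=0)  # replicates per temperature
        qual = np.nonzero(counts >= 2)[0]
        if qual.size == 0:
            continue
        t_star = int(qual[0])
        # all windows containing t*; pool their per-replicate inflections
        windows = sorted({j for j in (t_star - 1, t_star) if 0 <= j < n_win})
        es = wr.e[i, :, windows]
        comp = wr.components[i, :, windows]
        ok = (wr.converged[i, :, windows]
              & (es > e_box_lo) & (es < e_box_hi)
              & np.isfinite(comp) & (comp > 0))
        if ok.any():
            pec50[i] = float(np.clip(np.median(-es[ok]), lo, hi))
    return pec50


def call_hits(scores_df: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Proteins at or below the FDR cutoff with a nonzero combined score."""
    cfg = cfg or AnalysisConfig()
    mask = (scores_df["fdr"] <= cfg.fdr_cutoff) & (scores_df["F_comb"] > 0)
    return scores_df.loc[mask].reset_index(drop=True)


def run_tpp2d(
    quant: QuantTable,
    samples: list[SampleMeta],
    cfg: AnalysisConfig | None = None,
) -> Tpp2dResult:
    """Full 2D analysis: preprocess, score, permute, call hits, assign pEC50."""
    cfg = cfg or AnalysisConfig()
    fcd = preprocess_2dtpp(quant, samples, cfg)
    wr = window_scores(fcd, cfg)
    scores, direction = combined_scores(wr, cfg)

    perm_scores = []
    for b in range(cfg.n_permutations):
        seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(b,))
        pfcd = permute_dataset(fcd, seed)
        pwr = window_scores(pfcd, cfg)
        ps, _ = combined_scores(pwr, cfg)
        perm_scores.append(ps)
    fdr_curve, protein_fdr = fdr_estimate(scores, perm_scores)

    scores_df = pd.DataFrame({
        "protein_id": fcd.proteins,
        "F_comb": scores,
        "direction": direction,
        "fdr": protein_fdr,
    })
    hits = call_hits(scores_df, cfg)
    hit_mask = scores_df["protein_id"].isin(hits["protein_id"]).to_numpy()
    pec50 = assign_pec50(fcd, wr, direction, hit_mask, cfg)
    scores_df["pec50"] = pec50
    hits = scores_df.loc[hit_mask].reset_index(drop=True)
    log.info("2D analysis: %d/%d proteins called at FDR <= %g",
             len(hits), len(fcd.proteins), cfg.fdr_cutoff)
    return Tpp2dResult(scores_df, fdr_curve, hits, fcd, wr)
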