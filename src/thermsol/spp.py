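"""Solubility profiling analysis: normalization, insoluble-proteome
classification, and FDR-controlled detection of dose-dependent
(de-)solubilization.

The SDS-extracted vehicle sample measures each protein's total abundance,
the NP40-extracted vehicle its soluble share; a SDS/NP40 ratio of at least
1.5 (50% more protein extractable by the strong detergent) defines the
insoluble proteome.  Proteins whose NP40 abundance changes at least
h = 1.5-fold at some ligand dose are candidates: one joint 4PL fit pooled
across replicates against the intercept null yields a per-protein
F-statistic, and the same permutation-FDR machinery as the thermal screen
(strata reduced to qupm bins -- the design has a single temperature)
controls the hit list, which also requires the median fold-change gate.

Intensity normalization is a simplified variance-stabilizing transform:
a robust (least-trimmed-squares) affine calibration of every sample against
the across-sample reference, followed by a generalized log2 whose inverse
is applied before fold changes are formed.  The contract is variance
flattening across the intensity range, not bit-compatibility with any
particular published implementation.
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


@dataclass
class SppData:
    """Calibrated SPP intensities and vehicle-relative fold changes.

    ``np40[i, r, c]``: calibrated NP40 intensity of protein i, replicate r,
    concentration index c (index 0 = vehicle).  ``fc`` holds the same cube
    divided by its vehicle column.  ``sds[i, r]``: calibrated SDS vehicle.
    """

    proteins: list[str]
    replicates: np.ndarray
    concentrations_mM: np.ndarray
    np40: np.ndarray
    sds: np.ndarray
    fc: np.ndarray
    qupm: np.ndarray
    # raw (uncalibrated) within-plex vehicle channels; the SDS/NP40 contrast
    # compares two channels of the same plex, where reporter intensities are
    # directly comparable and calibration would only add reference noise
    sds_raw: np.ndarray | None = None
    np40_vehicle_raw: np.ndarray | None = None


@dataclass
class SppResult:
    profiles: pd.DataFrame
    fdr_curve: pd.DataFrame
    hits: pd.DataFrame
    data: SppData = field(repr=False)


def lts_affine(y: np.ndarray, ref: np.ndarray, keep: float = 0.5, n_iter: int = 10):
    """Least-trimmed-squares affine fit y ~ a + b * ref.

    Trimming acts on *relative* residuals (the fit regresses y/ref on
    1/ref), because intensity data are heteroscedastic across orders of
    magnitude: trimming absolute residuals would keep low-intensity
    proteins rather than unchanged ones.  With the default half-trimming
    the fit is exact whenever a majority of proteins is truly unchanged,
    the standard assumption behind sample calibration.
    """
    good = np.isfinite(y) & np.isfinite(ref) & (ref > 0)
    yv, rv = y[good], ref[good]
    if yv.size < 3:
        return 0.0, 1.0
    z = yv / rv          # = b + a * (1/ref) for points on the affine line
    u = 1.0 / rv
    sel = np.ones(yv.size, dtype=bool)
    a, b = 0.0, 1.0
    h = max(int(np.ceil(keep * yv.size)), 3)
    for _ in range(n_iter):
        A = np.column_stack([np.ones(sel.sum()), u[sel]])
        coef, *_ = np.linalg.lstsq(A, z[sel], rcond=None)
        b, a = float(coef[0]), float(coef[1])
        resid2 = (z - (b + a * u)) ** 2
        new_sel = np.zeros(yv.size, dtype=bool)
        new_sel[np.argsort(resid2, kind="stable")[:h]] = True
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel
    if b <= 0:  # degenerate; fall back to a pure median-ratio scale
        return 0.0, float(max(np.median(z), 1e-12))
    return a, b


def glog2(v: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: ~log2(v) for v >> c, defined and smooth near 0."""
    return np.log2(v + np.sqrt(v**2 + c**2)) - 1.0


def glog2_inverse(g: np.ndarray, c: float) -> np.ndarray:
    u = 2.0 ** (g + 1.0)
    return (u**2 - c**2) / (2.0 * u)


def vsn_like_normalize(matrix: np.ndarray, groups=None) -> np.ndarray:
    """Variance-stabilizing calibration of a protein x sample matrix.

    Each sample is affinely calibrated (LTS) against the per-protein median
    reference of its calibration group, then passed through the generalized
    log2 and back, leaving values on the calibrated raw scale ready for
    ratio formation.

    ``groups`` assigns each column to a calibration group (default: one
    group).  Channels measuring genuinely different quantities -- the SDS
    totals versus the NP40 soluble pools -- must be calibrated within their
    own group: scaling an SDS channel against a soluble-pool reference
    would erase the insoluble-proteome signal itself.
    """
    if groups is None:
        groups = np.zeros(matrix.shape[1], dtype=int)
    groups = np.asarray(groups)
    out = np.full_like(matrix, np.nan)
    for grp in np.unique(groups):
        cols = np.nonzero(groups == grp)[0]
        ref = np.nanmedian(matrix[:, cols], axis=1)
        for k in cols:
            col = matrix[:, k]
            if not np.isfinite(col).any() or np.nanmax(col) <= 0:
                log.info("SPP normalization: sample column %d is empty, excluded", k)
                continue
            a, b = lts_affine(col, ref)
            out[:, k] = (col - a) / b
    pos = out[np.isfinite(out) & (out > 0)]
    c = 0.05 * np.median(pos) if pos.size else 1.0
    return glog2_inverse(glog2(out, c), c)


def normalize_spp(
    quant: QuantTable, samples: list[SampleMeta], cfg: AnalysisConfig | None = None
) -> SppData:
    """Calibrate intensities and form NP40 fold changes vs vehicle."""
    cfg = cfg or AnalysisConfig()
    validate_layout(samples, "SPP")
    meta = {s.sample_id: s for s in samples}
    reps = np.array(sorted({s.replicate for s in samples}))
    concs = np.array(sorted({s.concentration_mM for s in samples if s.detergent == "NP40"}))
    proteins = quant.proteins
    pidx = {p: i for i, p in enumerate(proteins)}
    ridx = {r: i for i, r in enumerate(reps)}
    cidx = {c: i for i, c in enumerate(concs)}

    order = sorted(meta)  # deterministic column order
    matrix = np.full((len(proteins), len(order)), np.nan)
    qupm = np.full(len(proteins), 2, dtype=int)
    df = quant.df
    col_of = {sid: k for k, sid in enumerate(order)}
    rows = df["protein_id"].map(pidx).to_numpy()
    cols = df["sample_id"].map(col_of).to_numpy()
    matrix[rows, cols] = df["value"].to_numpy()
    for prot, q in zip(rows, df["qupm"]):
        qupm[prot] = q

    groups = np.array([0 if meta[sid].detergent == "NP40" else 1 for sid in order])
    calibrated = vsn_like_normalize(matrix, groups)

    np40 = np.full((len(proteins), reps.size, concs.size), np.nan)
    sds = np.full((len(proteins), reps.size), np.nan)
    sds_raw = np.full((len(proteins), reps.size), np.nan)
    np40_vehicle_raw = np.full((len(proteins), reps.size), np.nan)
    for sid, k in col_of.items():
        s = meta[sid]
        if s.detergent == "SDS":
            sds[:, ridx[s.replicate]] = calibrated[:, k]
            sds_raw[:, ridx[s.replicate]] = matrix[:, k]
        else:
            np40[:, ridx[s.replicate], cidx[s.concentration_mM]] = calibrated[:, k]
            if s.concentration_mM == 0:
                np40_vehicle_raw[:, ridx[s.replicate]] = matrix[:, k]

    vehicle = np40[:, :, 0:1]
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(vehicle > 0, np40 / vehicle, np.nan)
    fc[:, :, 0] = np.where(np.isfinite(fc[:, :, 0]), 1.0, np.nan)
    log.info("SPP normalization: %d proteins, %d replicates, %d doses",
             len(proteins), reps.size, concs.size - 1)
    return SppData(proteins, reps, concs, np40, sds, fc, qupm,
                   sds_raw=sds_raw, np40_vehicle_raw=np40_vehicle_raw)


def sds_np40_ratio(spd: SppData) -> np.ndarray:
    """SDS/NP40 vehicle ratio: replicate median of within-plex ratios.

    Both channels sit in the same TMT plex, so their raw reporter
    intensities are directly comparable; forming the ratio per replicate
    and taking the median makes the classification exactly invariant to
    rescaling whole replicates.
    """
    sds = spd.sds_raw if spd.sds_raw is not None else spd.sds
    np40v = (spd.np40_vehicle_raw if spd.np40_vehicle_raw is not None
             else spd.np40[:, :, 0])
    with np.errstate(all="ignore"):
        per_rep = np.where(np40v > 0, sds / np.where(np40v > 0, np40v, 1.0), np.inf)
        per_rep = np.where(np.isfinite(sds), per_rep, np.nan)
        ratio = np.nanmedian(per_rep, axis=1)
    return ratio


def classify_insoluble(spd: SppData, cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Insoluble-proteome flag: SDS/NP40 >= insoluble_ratio (boundary in)."""
    cfg = cfg or AnalysisConfig()
    ratio = sds_np40_ratio(spd)
    with np.errstate(invalid="ignore"):
        return ratio >= cfg.insoluble_ratio


def _median_extreme_fc(fc: np.ndarray) -> np.ndarray:
    """Per protein: the replicate-median dose fold change most extreme in log."""
    with np.errstate(all="ignore"):
        med = np.nanmedian(fc[:, :, 1:], axis=1)  # (n_prot, n_doses)
        dev = np.abs(np.log2(med))
    dev = np.where(np.isfinite(dev), dev, -np.inf)
    out = np.full(fc.shape[0], np.nan)
    has = dev.max(axis=1) > -np.inf
    best = np.argmax(dev, axis=1)
    out[has] = med[np.arange(fc.shape[0]), best][has]
    return out


def spp_scores(spd: SppData, cfg: AnalysisConfig | None = None):
    """F-statistic per candidate protein from one pooled dose-response fit.

    The fitting trigger -- an at-least-h-fold median change at one or more
    doses -- is applied before any model is fitted, exactly matching the
    candidate definition of the screen; non-candidates score 0.
    """
    cfg = cfg or AnalysisConfig()
    n_prot, n_rep, n_conc = spd.fc.shape
    extreme = _median_extreme_fc(spd.fc)
    with np.errstate(invalid="ignore"):
        trigger = (extreme >= cfg.h) | (extreme <= 1.0 / cfg.h)
    trigger &= np.isfinite(extreme)

    concs = spd.concentrations_mM
    per_rep = []
    if cfg.include_vehicle_point:
        per_rep.append(VEHICLE_ASYMPTOTE_X if cfg.vehicle_mode == "asymptote"
                       else pseudo_vehicle_x(concs))
    per_rep.extend(np.log10(concs[concs > 0] * 1e-3))
    x = np.tile(per_rep, n_rep)

    F = np.zeros(n_prot)
    e = np.full(n_prot, np.nan)
    cand = np.nonzero(trigger)[0]
    if cand.size:
        if cfg.include_vehicle_point:
            Y = spd.fc[cand].reshape(cand.size, n_rep * n_conc)
        else:
            Y = spd.fc[cand, :, 1:].reshape(cand.size, n_rep * (n_conc - 1))
        if cfg.fit_on_log:
            with np.errstate(all="ignore"):
                Y = np.log2(Y)
        comp, ee, conv = component_batch(x, Y, cfg.min_points_per_fit)
        comp = np.where(np.isnan(comp), 0.0, comp)
        finite = comp[np.isfinite(comp)]
        repl = finite.max() if finite.size and finite.max() > 0 else 1e6
        comp = np.where(np.isposinf(comp), repl, comp)
        F[cand] = comp
        e[cand] = np.where(conv, ee, np.nan)
    return F, e, extreme, trigger


def permute_spp(spd: SppData, seed) -> SppData:
    """Null dataset: dose fold changes shuffled within qupm strata.

    The design has a single temperature, so the thermal strata collapse to
    qupm bins; vehicle references stay untouched and per-stratum multisets
    are preserved.
    """
    rng = np.random.default_rng(seed)
    fc = spd.fc.copy()
    for q in np.unique(spd.qupm):
        sel = spd.qupm == q
        block = fc[sel, :, 1:]
        flat = block.ravel()
        good = np.isfinite(flat)
        vals = flat[good]
        flat[good] = vals[rng.permutation(vals.size)]
        fc[sel, :, 1:] = flat.reshape(block.shape)
    return SppData(spd.proteins, spd.replicates, spd.concentrations_mM,
                   spd.np40, spd.sds, fc, spd.qupm)


def run_spp(
    quant: QuantTable,
    samples: list[SampleMeta],
    cfg: AnalysisConfig | None = None,
) -> SppResult:
    """Full SPP analysis: normalize, classify, score, permute, call hits."""
    cfg = cfg or AnalysisConfig()
    spd = normalize_spp(quant, samples, cfg)
    ratio = sds_np40_ratio(spd)
    insoluble = classify_insoluble(spd, cfg)
    F, e, extreme, trigger = spp_scores(spd, cfg)

    perm_scores = []
    for b in range(cfg.n_permutations):
        seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(b,))
        pF, _, _, _ = spp_scores(permute_spp(spd, seed), cfg)
        perm_scores.append(pF)
    fdr_curve, protein_fdr = permutation_fdr(F, perm_scores)

    with np.errstate(invalid="ignore"):
        direction = np.where(extreme >= cfg.h, "solubilized",
                             np.where(extreme <= 1.0 / cfg.h, "desolubilized", "none"))
    direction = np.where(trigger, direction, "none").astype(object)

    concs = spd.concentrations_mM
    lo = -np.log10(concs.max() * 1e-3) - 1.0
    hi = -np.log10(concs[concs > 0].min() * 1e-3) + 1.0
    hit = (protein_fdr <= cfg.fdr_cutoff) & (F > 0) & trigger
    pec50_s = np.where(hit & np.isfinite(e), np.clip(-e, lo, hi), np.nan)

    profiles = pd.DataFrame({
        "protein_id": spd.proteins,
        "sds_np40_ratio": ratio,
        "insoluble": insoluble,
        "max_median_fc": extreme,
        "F": F,
        "fdr": protein_fdr,
        "direction": direction,
        "pec50_s": pec50_s,
        "hit": hit,
    })
    hits = profiles.loc[profiles["hit"]].reset_index(drop=True)
    log.info("SPP analysis: %d insoluble proteins, %d/%d solubility hits",
             int(np.nansum(insoluble)), len(hits), len(spd.proteins))
    return SppResult(profiles, fdr_curve, hits, spd)
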