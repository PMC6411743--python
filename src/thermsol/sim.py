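"""Synthetic TPP-TR, 2D-TPP and SPP datasets with known ground truth.

The generators emit reporter-style intensity tables in the exact plex
layouts of the real designs (TMT10 plexes spanning two neighboring
temperatures for the 2D design; one NP40 vehicle + eight NP40 doses + one
SDS vehicle per SPP plex; one full temperature gradient per TR plex),
together with a ground-truth sidecar per protein.  They are pure functions
of (config, seed): the same config reproduces the same tables bit for bit.

Thermal truth: each protein carries a plateau-sigmoid melting curve
(:func:`thermsol.melting.plateau_sigmoid`) with a vehicle melting point and,
for affected proteins, a condition shift.  Dose truth: fold changes versus
vehicle follow the four-parameter logistic in log10 molar dose with the
protein's true pEC50; in the 2D design the effect amplitude ramps in with
the fraction of vehicle protein already denatured, so low temperatures show
no dose effect -- the physical rationale for the sliding-window statistic.
Solubility truth: an SDS-extractable total is split into soluble and
insoluble pools; ligand doses move a protein-specific share of the
insoluble pool into solution (or out of it).

Noise is multiplicative lognormal with the configured coefficient of
variation, matching the ratio-based downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .data import QuantTable, SampleMeta
from .doseresp import sigmoid
from .melting import melting_params_for_tm, plateau_sigmoid

TMT10_LABELS = ("126", "127L", "127H", "128L", "128H", "129L", "129H", "130L", "130H", "131")

TRUTH_COLUMNS = (
    "protein_id", "effect_class", "true_pec50", "true_tm_vehicle",
    "true_tm_shift", "insoluble_fraction", "complex_id",
)


@dataclass
class SimResult:
    """One simulated experiment: quantification, sample metadata, truth."""

    quant: QuantTable
    samples: list[SampleMeta]
    truth: pd.DataFrame


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    classes = sorted(cfg.fractions)
    counts = {}
    remainders = []
    total = 0
    for cls in classes:
        exact = cfg.fractions[cls] * cfg.n_proteins
        counts[cls] = int(np.floor(exact))
        remainders.append((exact - counts[cls], cls))
        total += counts[cls]
    for _, cls in sorted(remainders, reverse=True)[: cfg.n_proteins - total]:
        counts[cls] += 1
    labels = np.concatenate([[cls] * counts[cls] for cls in classes])
    return rng.permutation(labels)


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=shape) - sigma**2 / 2.0)


def _melting_truth(cfg: SimConfig, rng: np.random.Generator, n: int):
    tm = rng.uniform(*cfg.tm_range, size=n)
    plateau = rng.uniform(*cfg.plateau_range, size=n)
    slope_a = cfg.slope_scale * rng.uniform(0.9, 1.1, size=n)
    return tm, plateau, slope_a


def _qupm(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice([2, 3, 4, 5], size=n, p=[0.15, 0.15, 0.2, 0.5])


def _base_intensity(rng: np.random.Generator, n: int) -> np.ndarray:
    return 10.0 ** rng.uniform(5.0, 7.0, size=n)


def _dose_effect(conc_mM: np.ndarray, pec50: float, hill: float = 1.0) -> np.ndarray:
    """Fractional effect in [0, 1] at each dose; exactly 0 at the vehicle."""
    out = np.zeros_like(conc_mM, dtype=float)
    nz = conc_mM > 0
    x = np.log10(conc_mM[nz] * 1e-3)
    # rising logistic: negative slope so the effect grows with dose
    out[nz] = sigmoid(x, b=-hill, c=0.0, d=1.0, e=-pec50)
    return out


def _finish(rows: list, samples: list[SampleMeta], truth_rows: list) -> SimResult:
    quant = QuantTable(
        pd.DataFrame(rows, columns=["protein_id", "sample_id", "value", "qupm"]),
        value_kind="intensity",
    )
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return SimResult(quant=quant, samples=samples, truth=truth)


def simulate_tpp_tr(cfg: SimConfig) -> SimResult:
    """Melting-range experiment: vehicle vs treated over a temperature gradient.

    Complex members (``n_complexes`` groups of ``complex_size`` proteins,
    drawn from the null class) share one melting template; ``complex_jitter``
    adds independent per-temperature wiggle to each member's noise-free
    fraction profile so that intra-complex profile distances scale with it.
    """
    rng = np.random.default_rng(cfg.seed)
    temps = np.asarray(cfg.temperatures, dtype=float)
    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    classes = _assign_classes(cfg, rng)
    tm, plateau, slope_a = _melting_truth(cfg, rng, n)
    shift_mag = rng.uniform(*cfg.tm_shift_range, size=n)
    shift = np.where(classes == "stabilized", shift_mag,
                     np.where(classes == "destabilized", -shift_mag, 0.0))
    qupm = _qupm(rng, n)
    base = _base_intensity(rng, n)

    complex_id = np.array([""] * n, dtype=object)
    if cfg.n_complexes:
        null_idx = np.nonzero(classes == "null")[0]
        need = cfg.n_complexes * cfg.complex_size
        if need > null_idx.size:
            raise ValueError("not enough null proteins to host the requested complexes")
        members = rng.choice(null_idx, size=need, replace=False)
        for ci in range(cfg.n_complexes):
            grp = members[ci * cfg.complex_size:(ci + 1) * cfg.complex_size]
            complex_id[grp] = f"C{ci:03d}"
            tm[grp] = tm[grp[0]]
            plateau[grp] = plateau[grp[0]]
            slope_a[grp] = slope_a[grp[0]]

    rows = []
    samples: list[SampleMeta] = []
    for rep in range(1, cfg.n_replicates + 1):
        for cond in ("vehicle", "treated"):
            plex = f"r{rep}_{cond}"
            for ti, temp in enumerate(temps):
                sid = f"{plex}_T{temp:g}"
                samples.append(SampleMeta(
                    sample_id=sid, replicate=rep, temperature=float(temp),
                    concentration_mM=0.0, detergent="none", tmt_plex=plex,
                    tmt_label=TMT10_LABELS[ti % 10], condition=cond,
                ))
    # noise-free fraction profiles per protein x condition (normalized at T_min)
    frac = {}
    for cond, tshift in (("vehicle", 0.0), ("treated", 1.0)):
        tms = np.clip(tm + tshift * shift, 1.0, None)
        prof = np.empty((n, temps.size))
        for i in range(n):
            a, b, p = melting_params_for_tm(tms[i], min(plateau[i], 0.49), slope_a[i])
            f = plateau_sigmoid(temps, a, b, p)
            prof[i] = f / f[0]
        if cfg.complex_jitter > 0:
            has_cx = complex_id != ""
            prof[has_cx] = np.clip(
                prof[has_cx] + rng.normal(0, cfg.complex_jitter, prof[has_cx].shape),
                1e-6, None,
            )
        frac[cond] = prof

    for s in samples:
        ti = int(np.nonzero(temps == s.temperature)[0][0])
        vals = base * frac[s.condition][:, ti] * _noise(rng, cfg.noise_cv, n)
        rows.extend(zip(proteins, [s.sample_id] * n, vals, qupm))

    truth_rows = [
        (proteins[i], classes[i], np.nan, tm[i], shift[i], np.nan, complex_id[i])
        for i in range(n)
    ]
    return _finish(rows, samples, truth_rows)


def simulate_2dtpp(cfg: SimConfig) -> SimResult:
    """Dose x temperature experiment in TMT10 plexes over temperature pairs.

    Stabilized proteins gain abundance with dose at temperatures where the
    vehicle curve has decayed: the dose-effect amplitude is
    (max_effect - 1) * (1 - vehicle fraction remaining), driven through a
    logistic in log10 dose centered at the protein's true pEC50.
    """
    rng = np.random.default_rng(cfg.seed)
    temps = np.asarray(cfg.temperatures, dtype=float)
    if temps.size % 2:
        raise ValueError("2D design needs an even number of temperatures (plex pairs)")
    conc = np.asarray(cfg.concentrations_mM, dtype=float)
    if conc[0] != 0:
        raise ValueError("first concentration must be the vehicle (0 mM)")
    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    classes = _assign_classes(cfg, rng)
    tm, plateau, slope_a = _melting_truth(cfg, rng, n)
    pec50 = np.where(
        np.isin(classes, ["stabilized", "destabilized"]),
        rng.uniform(*cfg.pec50_range, size=n), np.nan,
    )
    qupm = _qupm(rng, n)
    base = _base_intensity(rng, n)

    # vehicle melting profile, normalized to the lowest 2D temperature
    vehicle_frac = np.empty((n, temps.size))
    for i in range(n):
        a, b, p = melting_params_for_tm(tm[i], min(plateau[i], 0.49), slope_a[i])
        f = plateau_sigmoid(temps, a, b, p)
        vehicle_frac[i] = f / f[0]
    ramp = 1.0 - vehicle_frac  # denatured share of the vehicle pool

    samples: list[SampleMeta] = []
    for rep in range(1, cfg.n_replicates + 1):
        for pi in range(temps.size // 2):
            plex = f"r{rep}_plex{pi + 1}"
            li = 0
            for temp in temps[2 * pi:2 * pi + 2]:
                for c in conc:
                    sid = f"r{rep}_T{temp:g}_c{c:g}"
                    samples.append(SampleMeta(
                        sample_id=sid, replicate=rep, temperature=float(temp),
                        concentration_mM=float(c), detergent="none", tmt_plex=plex,
                        tmt_label=TMT10_LABELS[li],
                        condition="vehicle" if c == 0 else "treated",
                    ))
                    li += 1

    # expected fold change vs vehicle per (protein, temperature, dose)
    effect = np.zeros((n, temps.size, conc.size))
    for i in range(n):
        if classes[i] == "stabilized":
            amp = (cfg.max_effect - 1.0) * ramp[i]
            effect[i] = amp[:, None] * _dose_effect(conc, pec50[i])[None, :]
        elif classes[i] == "destabilized":
            amp = (1.0 - 1.0 / cfg.max_effect) * ramp[i]
            effect[i] = -amp[:, None] * _dose_effect(conc, pec50[i])[None, :]
    fold_change = 1.0 + effect

    rows = []
    for s in samples:
        ti = int(np.nonzero(temps == s.temperature)[0][0])
        ci = int(np.nonzero(conc == s.concentration_mM)[0][0])
        vals = (base * vehicle_frac[:, ti] * fold_change[:, ti, ci]
                * _noise(rng, cfg.noise_cv, n))
        rows.extend(zip(proteins, [s.sample_id] * n, vals, qupm))

    truth_rows = [
        (proteins[i], classes[i], pec50[i], tm[i], 0.0, np.nan, "")
        for i in range(n)
    ]
    return _finish(rows, samples, truth_rows)


def simulate_spp(cfg: SimConfig) -> SimResult:
    """Solubility experiment: SDS total vs NP40-extractable across doses.

    Mass balance per protein: SDS vehicle carries the total signal; the NP40
    vehicle carries the soluble share (1 - insoluble_fraction); each ligand
    dose releases ``release * insoluble_fraction`` of the total into the
    NP40-soluble pool through a logistic in log10 dose (or removes a share
    of the soluble pool, for proteins that lose solubility).  The expected
    NP40 signal therefore never exceeds the SDS signal.
    """
    rng = np.random.default_rng(cfg.seed)
    conc = np.asarray(cfg.concentrations_mM, dtype=float)
    if conc[0] != 0 or conc.size < 2:
        raise ValueError("SPP concentrations must start with the 0 mM vehicle")
    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    classes = _assign_classes(cfg, rng)

    insoluble = np.empty(n)
    for i in range(n):
        if classes[i] == "solubilized":
            insoluble[i] = rng.uniform(*cfg.insoluble_fraction_range)
        elif classes[i] == "desolubilized":
            insoluble[i] = rng.uniform(0.0, 0.3)
        elif rng.uniform() < cfg.soluble_background_fraction:
            insoluble[i] = rng.uniform(0.0, 0.2)
        else:
            insoluble[i] = rng.uniform(0.4, 0.7)
    if (insoluble < 0).any() or (insoluble > 1).any():
        raise ValueError("insoluble fractions must lie in [0, 1]")
    release = rng.uniform(*cfg.release_range, size=n)
    loss = rng.uniform(0.4, 0.8, size=n)
    pec50 = np.where(
        np.isin(classes, ["solubilized", "desolubilized"]),
        rng.uniform(*cfg.pec50_range, size=n), np.nan,
    )
    qupm = _qupm(rng, n)
    base = _base_intensity(rng, n)

    samples: list[SampleMeta] = []
    for rep in range(1, cfg.n_replicates + 1):
        plex = f"r{rep}"
        li = 0
        for c in conc:
            sid = f"r{rep}_NP40_c{c:g}"
            samples.append(SampleMeta(
                sample_id=sid, replicate=rep, temperature=37.0,
                concentration_mM=float(c), detergent="NP40", tmt_plex=plex,
                tmt_label=TMT10_LABELS[li],
                condition="vehicle" if c == 0 else "treated",
            ))
            li += 1
        samples.append(SampleMeta(
            sample_id=f"r{rep}_SDS_c0", replicate=rep, temperature=37.0,
            concentration_mM=0.0, detergent="SDS", tmt_plex=plex,
            tmt_label=TMT10_LABELS[li], condition="vehicle",
        ))

    # expected NP40-soluble share of the total, per protein x dose
    soluble_share = np.empty((n, conc.size))
    for i in range(n):
        s0 = 1.0 - insoluble[i]
        if classes[i] == "solubilized":
            soluble_share[i] = s0 + insoluble[i] * release[i] * _dose_effect(conc, pec50[i])
        elif classes[i] == "desolubilized":
            soluble_share[i] = s0 * (1.0 - loss[i] * _dose_effect(conc, pec50[i]))
        else:
            soluble_share[i] = s0

    rows = []
    for s in samples:
        if s.detergent == "SDS":
            share = np.ones(n)
        else:
            ci = int(np.nonzero(conc == s.concentration_mM)[0][0])
            share = soluble_share[:, ci]
        vals = base * share * _noise(rng, cfg.noise_cv, n)
        rows.extend(zip(proteins, [s.sample_id] * n, vals, qupm))

    truth_rows = [
        (proteins[i], classes[i], pec50[i], np.nan, 0.0, insoluble[i], "")
        for i in range(n)
    ]
    return _finish(rows, samples, truth_rows)


def simulate(cfg: SimConfig) -> SimResult:
    """Dispatch on ``cfg.kind``."""
    if cfg.kind == "tpp_tr":
        return simulate_tpp_tr(cfg)
    if cfg.kind == "tpp2d":
        return simulate_2dtpp(cfg)
    if cfg.kind == "spp":
        return simulate_spp(cfg)
    raise ValueError(f"unknown simulation kind {cfg.kind!r}")
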