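"""Permutation-based FDR estimation for combined protein scores.

Candidate thresholds are the distinct positive scores observed in the
original data.  For threshold theta, r counts original scores >= theta and
v_b counts scores >= theta in permuted dataset b; the raw estimate averages
2*v_b / (r + v_b) over permutations.  Ties between original and permuted
scores count the permuted score as exceeding the threshold (conservative).

The raw estimate is not monotone and can exceed 1 for small r; the reported
per-threshold FDR is q(theta) = min over thresholds theta' <= theta of the
raw estimate, clipped to [0, 1], which is non-increasing in theta (a more
stringent threshold never reports a larger FDR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def permutation_fdr(
    original_scores: np.ndarray,
    permuted_scores: list[np.ndarray],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Estimate the FDR at every candidate threshold.

    Parameters
    ----------
    original_scores : array of per-protein combined scores
    permuted_scores : list with one score array per permuted dataset

    Returns
    -------
    fdr_table : DataFrame with columns theta (descending), r, v_mean,
        fdr_raw, fdr (monotonized).
    protein_fdr : FDR assigned to each original protein at its own score;
        proteins with score <= 0 receive 1.
    """
    orig = np.asarray(original_scores, dtype=float)
    B = len(permuted_scores)
    if B < 1:
        raise ValueError("need at least one permutation")

    thetas = np.unique(orig[orig > 0])[::-1]  # descending
    protein_fdr = np.ones(orig.size)
    if thetas.size == 0:
        table = pd.DataFrame(columns=["theta", "r", "v_mean", "fdr_raw", "fdr"])
        return table, protein_fdr

    orig_sorted = np.sort(orig)
    r = orig.size - np.searchsorted(orig_sorted, thetas, side="left")

    terms = np.zeros(thetas.size)
    v_sum = np.zeros(thetas.size)
    for perm in permuted_scores:
        ps = np.sort(np.asarray(perm, dtype=float))
        v = ps.size - np.searchsorted(ps, thetas, side="left")
        v_sum += v
        denom = r + v
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(denom > 0, 2.0 * v / np.maximum(denom, 1), 0.0)
        terms += term
    fdr_raw = terms / B

    # monotonize: q(theta) = min raw FDR over thresholds <= theta
    fdr = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    fdr = np.clip(fdr, 0.0, 1.0)

    table = pd.DataFrame(
        {"theta": thetas, "r": r, "v_mean": v_sum / B, "fdr_raw": fdr_raw, "fdr": fdr}
    )
    pos = orig > 0
    idx = np.searchsorted(-thetas, -orig[pos], side="left")
    # orig[pos] values are exactly among thetas; map each to its threshold row
    protein_fdr[pos] = fdr[idx]
    return table, protein_fdr


def brute_force_fdr(original_scores, permuted_scores) -> pd.DataFrame:
    """Direct-counting reference implementation (independent of the above)."""
    orig = [s for s in original_scores]
    thetas = sorted({s for s in orig if s > 0}, reverse=True)
    rows = []
    B = len(permuted_scores)
    for theta in thetas:
        r = sum(1 for s in orig if s >= theta)
        total = 0.0
        for perm in permuted_scores:
            v = sum(1 for s in perm if s >= theta)
            if r + v > 0:
                total += 2.0 * v / (r + v)
        rows.append((theta, r, total / B))
    df = pd.DataFrame(rows, columns=["theta", "r", "fdr_raw"])
    mono = []
    for i in range(len(df)):
        mono.append(min(df["fdr_raw"].iloc[i:]))
    df["fdr"] = np.clip(mono, 0.0, 1.0)
    return df
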