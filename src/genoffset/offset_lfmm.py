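"""Genetic-gap genomic offset.

The genetic gap measures maladaptation risk as the mean, over candidate
loci, of the squared genotypic change predicted by the fitted
environmental effect sizes:

    G(e_cur, e_fut) = Δeᵀ · C_b · Δe,    C_b = B·Bᵀ / L,  Δe = e_fut − e_cur,

with B the d × L effect-size matrix on training-scaled predictors. The
form is a quadratic distance in climate space weighted by the covariance
of effect sizes across loci; it is symmetric in the two climates, zero
when they coincide, and scales quadratically with the shift.

A prose-literal variant (effect-size-weighted mean of |Δe|) is provided
for comparison; the quadratic form is the default throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["genetic_gap", "genetic_gap_literal", "site_mean_offsets"]


def _delta(B: np.ndarray, e_cur, e_fut) -> tuple[np.ndarray, bool]:
    B = np.asarray(B, dtype=float)
    e_cur = np.asarray(e_cur, dtype=float)
    e_fut = np.asarray(e_fut, dtype=float)
    if e_cur.shape != e_fut.shape:
        raise ValueError("current/future climate shapes differ")
    scalar = e_cur.ndim == 1
    dE = np.atleast_2d(e_fut - e_cur)
    if dE.shape[1] != B.shape[0]:
        raise ValueError(
            f"climate has {dE.shape[1]} variables but B has {B.shape[0]} rows")
    return dE, scalar


def genetic_gap(B: np.ndarray, e_cur, e_fut):
    """Quadratic-form genetic gap for one climate vector or a stack of them.

    ``B`` is d × L (variables × candidate loci) on scaled predictors;
    ``e_cur``/``e_fut`` are length-d vectors or (n × d) matrices scaled
    with the training scaler. Returns a scalar or length-n array.
    """
    dE, scalar = _delta(B, e_cur, e_fut)
    L = B.shape[1]
    # Δeᵀ (B Bᵀ / L) Δe  ==  mean over loci of (Σ_j b_jl Δe_j)²
    proj = dE @ B                      # n × L predicted per-locus change
    out = (proj ** 2).sum(axis=1) / L
    return float(out[0]) if scalar else out


def genetic_gap_literal(B: np.ndarray, e_cur, e_fut):
    """Prose-literal variant: weighted mean of |Δe| with per-variable
    weights equal to the mean absolute effect size across loci."""
    dE, scalar = _delta(B, e_cur, e_fut)
    w = np.abs(np.asarray(B, dtype=float)).mean(axis=1)
    out = (np.abs(dE) * w[None, :]).mean(axis=1)
    return float(out[0]) if scalar else out


def site_mean_offsets(offsets: pd.DataFrame,
                      value_col: str = "offset") -> pd.DataFrame:
    """Arithmetic mean offset per sampling site.

    ``offsets`` needs columns ``site_id`` and ``value_col``; an optional
    boolean ``flagged`` column excludes trees with error-flagged climate
    (exclusions are counted, not silently dropped).
    """
    df = offsets.copy()
    if "site_id" not in df.columns:
        raise ValueError("offsets table must carry a site_id column")
    flagged = df["flagged"].astype(bool) if "flagged" in df.columns else (
        pd.Series(False, index=df.index))
    out = []
    for site, grp in df.groupby("site_id"):
        use = grp[~flagged.loc[grp.index]]
        if use.empty:
            raise ValueError(f"site {site} has no usable trees")
        out.append({"site_id": site,
                    "mean_offset": float(use[value_col].mean()),
                    "n_used": int(len(use)),
                    "n_excluded": int(len(grp) - len(use))})
    return pd.DataFrame(out)
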