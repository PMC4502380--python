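"""Single-QTL genome scans by Haley-Knott regression.

Phenotypes are optionally log-transformed and adjusted for standard
length and sex by ordinary least squares (residuals re-centered at the
grand mean).  At each marker the adjusted phenotype is regressed on the
expected additive and dominance dosages computed from the genotype
posterior, and

    LOD = (n / 2) * log10(RSS_0 / RSS_1)

compares the two-dosage model against the intercept-only model.
Genome-wide significance thresholds are the (1 - alpha) quantile of the
maximum LOD over phenotype permutations, and the percent variance
explained of a peak is PVE = 100 * (1 - 10^(-2 LOD / n)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import A, B, C, D, H, MISSING

log = logging.getLogger(__name__)

_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def adjust_phenotype(
    values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    log_transform: bool = False,
    use: tuple[str, ...] = ("standard_length", "sex"),
) -> np.ndarray:
    """Covariate-adjusted phenotype: OLS residuals plus the grand mean.

    ``covariates`` may carry ``standard_length`` (numeric) and ``sex``
    (XX/XY or any two labels, dummy-coded); ``use`` selects which enter
    the model.  With ``log_transform`` the values are log-transformed
    first (zero or negative values are an error naming the fish).
    """
    y = np.asarray(values, dtype=float)
    if log_transform:
        bad = np.flatnonzero(y <= 0)
        if len(bad):
            raise ValueError(f"log transform undefined for fish at rows "
                             f"{bad.tolist()} (non-positive values)")
        y = np.log(y)
    cols = []
    if covariates is not None:
        if "standard_length" in use and "standard_length" in covariates:
            cols.append(covariates["standard_length"].to_numpy(dtype=float))
        if "sex" in use and "sex" in covariates:
            sex = covariates["sex"].to_numpy()
            labels = pd.unique(sex)
            if len(labels) > 1:
                cols.append((sex == labels[0]).astype(float))
    if not cols:
        return y.copy()
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X, missing="raise").fit()
    return fit.resid + y.mean()


def genotype_probabilities(
    posteriors: np.ndarray, codes: np.ndarray
) -> np.ndarray:
    """Per-marker genotype probabilities for the scan.

    Called markers (hard or composite) keep their posterior; missing
    calls fall back to the 1:2:1 F2 prior.
    """
    probs = np.array(posteriors, dtype=float, copy=True)
    probs[codes == MISSING] = _F2_PRIOR
    return probs


def _design_dosages(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive (E[dosage] - 1 in -1..1) and dominance (P[het]) regressors."""
    xa = probs[..., B] - probs[..., A]
    xd = probs[..., H]
    return xa, xd


def _marker_bases(probs: np.ndarray) -> np.ndarray:
    """Orthonormal basis of each marker's [1, additive, dominance] design.

    Columns belonging to (numerically) rank-deficient directions --
    e.g. a marker whose dosages are constant -- are zeroed so the
    projection never exceeds the true column space.
    """
    xa, xd = _design_dosages(probs)
    n_markers, n = xa.shape
    X = np.empty((n_markers, n, 3))
    X[..., 0] = 1.0
    X[..., 1] = xa
    X[..., 2] = xd
    Q, R = np.linalg.qr(X)  # stacked thin QR per marker
    diag = np.abs(np.diagonal(R, axis1=-2, axis2=-1))
    tol = 1e-8 * np.sqrt(n)
    return np.where((diag > tol)[:, None, :], Q, 0.0)


def scanone_hk(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Haley-Knott LOD at each marker; probs shape (n_markers, n_f2, 3)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 == 0:
        return np.zeros(probs.shape[0])
    Q = _marker_bases(probs)
    proj = np.einsum("mnk,n->mk", Q, y)
    rss1 = np.maximum(y @ y - (proj**2).sum(axis=1), 1e-300)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    return np.maximum(lod, 0.0)


def permutation_threshold(
    probs: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """(1 - alpha) quantile of genome-wide max LOD over phenotype permutations."""
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable quantile; refuse")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    perm = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    n_markers = probs.shape[0]
    Q = _marker_bases(probs)
    # stacked projection of all permuted traits through every marker's basis
    proj = np.swapaxes(Q, 1, 2).reshape(n_markers * 3, n) @ perm
    proj = proj.reshape(n_markers, 3, n_perm)
    yty = (perm**2).sum(axis=0)
    rss0 = np.maximum(yty - n * (perm.mean(axis=0) ** 2), 1e-300)
    rss1 = np.clip(yty[None, :] - (proj**2).sum(axis=1), 1e-300, None)
    lods = np.maximum((n / 2.0) * np.log10(rss0[None, :] / rss1), 0.0)
    max_lod = lods.max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha))


def pve(lod: float, n: int) -> float:
    """Percent variance explained, 100 * (1 - 10^(-2 LOD / n))."""
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


def summarize_qtl(
    scan: pd.DataFrame,
    probs: np.ndarray,
    codes: np.ndarray,
    y: np.ndarray,
    threshold: float,
    lod_drop: float = 1.5,
) -> pd.DataFrame:
    """One row per linkage group whose peak LOD clears the threshold.

    ``scan`` needs columns (marker, group, cM, lod) in map order.  The
    support interval spans the outermost markers within ``lod_drop`` of
    the peak on the peak's group; class means use hard calls only.
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for group, sub in scan.groupby("group", sort=False):
        peak_pos = int(sub["lod"].idxmax())
        peak_lod = float(sub.loc[peak_pos, "lod"])
        if peak_lod < threshold:
            continue
        within = sub[sub["lod"] >= peak_lod - lod_drop]
        mi = scan.index.get_loc(peak_pos)
        class_stats = {}
        for code, name in ((A, "MM"), (H, "MF"), (B, "FF")):
            sel = codes[mi] == code
            vals = y[sel]
            class_stats[f"mean_{name}"] = float(vals.mean()) if len(vals) else np.nan
            class_stats[f"se_{name}"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1
                else np.nan
            )
        rows.append({
            "group": group,
            "peak_marker": sub.loc[peak_pos, "marker"],
            "peak_cM": float(sub.loc[peak_pos, "cM"]),
            "lod": peak_lod,
            "pve": pve(peak_lod, len(y)),
            "interval_left": within["marker"].iloc[0],
            "interval_right": within["marker"].iloc[-1],
            "n": len(y),
            **class_stats,
        })
    return pd.DataFrame(rows)


def conditioned_scan(
    probs: np.ndarray,
    codes: np.ndarray,
    y: np.ndarray,
    scan_info: pd.DataFrame,
    condition_marker: int,
    condition_code: int,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, int]:
    """Scan within the fish carrying one hard genotype at a marker.

    Subsets F2s with ``codes[condition_marker] == condition_code``,
    reruns the Haley-Knott scan and its permutation threshold, and
    returns (scan table with lod column, threshold, subset size).
    Fewer than 10 fish in the class is an error; fewer than 30 warns.
    """
    sel = codes[condition_marker] == condition_code
    n_sub = int(sel.sum())
    if n_sub == 0:
        raise ValueError("conditioning genotype class absent at that marker")
    if n_sub < 10:
        raise ValueError(f"only {n_sub} fish in the conditioning class; refuse")
    if n_sub < 30:
        warnings.warn(f"conditioning class has only {n_sub} fish; "
                      "scan will be underpowered", stacklevel=2)
    sub_probs = probs[:, sel, :]
    sub_y = np.asarray(y, dtype=float)[sel]
    lods = scanone_hk(sub_probs, sub_y)
    threshold = permutation_threshold(sub_probs, sub_y, n_perm=n_perm,
                                      alpha=alpha, seed=seed)
    out = scan_info.copy()
    out["lod"] = lods
    return out, threshold, n_sub
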