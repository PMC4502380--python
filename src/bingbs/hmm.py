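"""Fine-map recombination breakpoints with a three-state HMM.

Hidden states are the F2 genotypes (MM, MF, FF) along one chromosome of
one fish.  Between consecutive SNPs separated by d bp, the per-meiosis
recombination fraction under the Haldane model is
r = (1 - exp(-2 * rho * d)) / 2 (rho in Morgans per bp), and because an
F2 is the product of two independent meioses the transition matrix is

    [[(1-r)^2,      2r(1-r),        r^2    ],
     [r(1-r),       (1-r)^2 + r^2,  r(1-r) ],
     [r^2,          2r(1-r),        (1-r)^2]]

Emissions are binomial: at a SNP with m marine and f freshwater reads,
the freshwater-read probability is eps, 1/2, or 1 - eps for MM, MF, FF.
SNPs with zero reads contribute flat emissions.  Decoding is log-space
forward-backward (posteriors) plus Viterbi (the breakpoint path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import STATE_NAMES

_INITIAL = np.array([0.25, 0.5, 0.25])


@dataclass
class HmmSpec:
    rho_cm_per_mb: float = 4.0  # chromosome-wide rate, e.g. total cM / total Mb
    error_rate: float = 0.02
    initial: np.ndarray = field(default_factory=lambda: _INITIAL.copy())

    def recomb_fraction(self, d_bp) -> np.ndarray:
        """Haldane r for inter-SNP distance(s) in bp."""
        d_morgans = self.rho_cm_per_mb * np.asarray(d_bp, dtype=float) / 1e6 / 100.0
        return (1.0 - np.exp(-2.0 * d_morgans)) / 2.0


def transition_matrix(r) -> np.ndarray:
    """Two-meiosis genotype transition matrix; shape (..., 3, 3)."""
    r = np.asarray(r, dtype=float)
    one = 1.0 - r
    P = np.empty(r.shape + (3, 3))
    P[..., 0, 0] = one**2
    P[..., 0, 1] = 2 * r * one
    P[..., 0, 2] = r**2
    P[..., 1, 0] = r * one
    P[..., 1, 1] = one**2 + r**2
    P[..., 1, 2] = r * one
    P[..., 2, 0] = r**2
    P[..., 2, 1] = 2 * r * one
    P[..., 2, 2] = one**2
    return P


def emission_loglik(m: np.ndarray, f: np.ndarray, error_rate: float) -> np.ndarray:
    """Per-SNP log emission for (MM, MF, FF); binomial coefficient dropped.

    Zero-read SNPs give identical (zero) log-likelihood in every state.
    """
    ps = np.array([error_rate, 0.5, 1.0 - error_rate])
    m = np.asarray(m, dtype=float)[:, None]
    f = np.asarray(f, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = f * np.log(ps)[None, :] + m * np.log(1.0 - ps)[None, :]
    return np.where(np.isnan(ll), -np.inf, ll)


def decode_chromosome(
    m: np.ndarray,
    f: np.ndarray,
    positions: np.ndarray,
    spec: HmmSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward posteriors and Viterbi path for one F2 chromosome.

    SNPs must be sorted by position.  Returns (posteriors (n, 3),
    viterbi path (n,), total log-likelihood).
    """
    spec = spec or HmmSpec()
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        raise ValueError("empty chromosome")
    if np.any(np.diff(positions) < 0):
        raise ValueError("SNP positions must be sorted")
    if np.any(np.asarray(m) < 0) or np.any(np.asarray(f) < 0):
        raise ValueError("negative read counts")

    e = emission_loglik(m, f, spec.error_rate)  # (n, 3)
    r = spec.recomb_fraction(np.diff(positions))
    with np.errstate(divide="ignore"):
        logT = np.log(transition_matrix(r))  # (n-1, 3, 3)
        log_init = np.log(spec.initial)

    # forward
    alpha = np.empty((n, 3))
    alpha[0] = log_init + e[0]
    for t in range(1, n):
        alpha[t] = e[t] + logsumexp(alpha[t - 1][:, None] + logT[t - 1], axis=0)
    loglik = float(logsumexp(alpha[-1]))

    # backward
    beta = np.zeros((n, 3))
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(logT[t] + (e[t + 1] + beta[t + 1])[None, :], axis=1)

    logpost = alpha + beta - loglik
    post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))

    # Viterbi
    delta = np.empty((n, 3))
    psi = np.zeros((n, 3), dtype=np.int64)
    delta[0] = log_init + e[0]
    for t in range(1, n):
        scores = delta[t - 1][:, None] + logT[t - 1]
        psi[t] = np.argmax(scores, axis=0)
        delta[t] = e[t] + np.max(scores, axis=0)
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return post, path, loglik


def extract_breakpoints(
    positions: np.ndarray,
    path: np.ndarray,
    post: np.ndarray,
    tau: float = 0.95,
    min_separation: int = 1_000_000,
) -> pd.DataFrame:
    """One interval per Viterbi state change.

    ``left_bp`` is the position of the last SNP (at or before the
    change) whose posterior for the departing state reaches ``tau``;
    ``right_bp`` the first SNP after the change whose posterior for the
    arriving state reaches ``tau``.  When no SNP qualifies the flanking
    SNPs of the transition are used.  Breakpoints closer than
    ``min_separation`` to the previous one are flagged as possible
    unreliable double crossovers.
    """
    positions = np.asarray(positions)
    changes = np.flatnonzero(np.diff(path) != 0)
    rows = []
    prev_right = -np.inf
    for t in changes:
        s_from, s_to = int(path[t]), int(path[t + 1])
        left_idx = t
        for i in range(t, -1, -1):
            if post[i, s_from] >= tau:
                left_idx = i
                break
        right_idx = t + 1
        for i in range(t + 1, len(path)):
            if post[i, s_to] >= tau:
                right_idx = i
                break
        left_bp, right_bp = int(positions[left_idx]), int(positions[right_idx])
        rows.append({
            "left_bp": left_bp, "right_bp": right_bp,
            "from_state": STATE_NAMES[s_from], "to_state": STATE_NAMES[s_to],
            "double_crossover_flag": bool(left_bp - prev_right < min_separation),
        })
        prev_right = right_bp
    return pd.DataFrame(rows, columns=["left_bp", "right_bp", "from_state",
                                       "to_state", "double_crossover_flag"])


@dataclass
class QtlInterval:
    left_bp: float
    right_bp: float
    consistent: bool
    offending_f2: list[str] = field(default_factory=list)


def minimal_qtl_interval(
    recombinants: pd.DataFrame,
    region: tuple[int, int],
    state_class: dict[str, str],
) -> QtlInterval:
    """Maximal genomic interval consistent with every recombinant's phenotype.

    ``recombinants`` needs columns (f2, left_bp, right_bp, from_state,
    to_state, pheno_class); ``state_class`` maps genotype states to the
    phenotype classes they produce (e.g. {"MF": "high", "FF": "low"}).
    A causal position x is consistent with a fish when the fish's
    genotype at x is either unknown (inside its breakpoint uncertainty)
    or maps to the fish's phenotype class.  A fish whose phenotype
    matches its departing (left) state therefore bounds the interval on
    the right at its right_bp; one matching the arriving state bounds it
    on the left at its left_bp.  Contradictory constraints yield an
    explicit no-consistent-interval result naming the offending fish.
    """
    lo, hi = float(region[0]), float(region[1])
    lo_owner: list[str] = []
    hi_owner: list[str] = []
    for rec in recombinants.itertuples(index=False):
        matches_from = state_class.get(rec.from_state) == rec.pheno_class
        matches_to = state_class.get(rec.to_state) == rec.pheno_class
        if matches_from == matches_to:
            raise ValueError(
                f"recombinant {rec.f2}: phenotype class must match exactly one "
                f"flanking state"
            )
        if matches_from:
            if rec.right_bp < hi:
                hi, hi_owner = float(rec.right_bp), [rec.f2]
            elif rec.right_bp == hi:
                hi_owner.append(rec.f2)
        else:
            if rec.left_bp > lo:
                lo, lo_owner = float(rec.left_bp), [rec.f2]
            elif rec.left_bp == lo:
                lo_owner.append(rec.f2)
    if lo >= hi:
        return QtlInterval(lo, hi, False, sorted(set(lo_owner + hi_owner)))
    return QtlInterval(lo, hi, True, [])
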