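"""Turn linkage maps into a revised scaffold order and orientation.

A scaffold's chromosome comes from the linkage group of its markers
(markers are named ``<scaffold>_<bin>``), its rank from the median
marker cM, and its orientation from the sign of the rank correlation
between within-scaffold bp and map cM.  Two crosses merge into a
consensus; residual scaffolds are placed by correlating their bin
genotype dosages with every placed marker across F2s; a strand-aware
liftover maps coordinates between the original scaffolds and the
revised chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import LinkageMap, split_marker_name

log = logging.getLogger(__name__)

DEFAULT_GAP_BP = 1000  # inter-scaffold N gap in the revised sequence


def orient_scaffold(bp: np.ndarray, cm: np.ndarray) -> str:
    """Orientation from the rank correlation of bp vs cM: '+', '-', or '?'."""
    bp = np.asarray(bp, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if len(bp) < 2 or len(np.unique(cm)) < 2 or len(np.unique(bp)) < 2:
        return "?"
    rho = stats.spearmanr(bp, cm).statistic
    if np.isnan(rho) or rho == 0:
        return "?"
    return "+" if rho > 0 else "-"


def _longest_increasing_subsequence(seq: np.ndarray) -> np.ndarray:
    """Indices of one longest strictly increasing subsequence (deterministic)."""
    n = len(seq)
    if n == 0:
        return np.array([], dtype=int)
    tails: list[int] = []
    parent = np.full(n, -1)
    index_of = []
    for i in range(n):
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if seq[tails[mid]] < seq[i]:
                lo = mid + 1
            else:
                hi = mid
        if lo > 0:
            parent[i] = tails[lo - 1]
        if lo == len(tails):
            tails.append(i)
        else:
            tails[lo] = i
        index_of.append(lo)
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = parent[i]
    return np.array(out[::-1], dtype=int)


def anchor_scaffolds(
    linkage_map: LinkageMap,
    markers: pd.DataFrame,
    prior: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place scaffolds from one cross's map; returns (placements, changes, conflicts).

    ``markers`` maps marker -> (scaffold, bin midpoint bp); ``prior`` is
    a placement table (scaffold, chromosome, rank, orientation).  Each
    linkage group is labelled with a chromosome by majority vote of its
    prior-placed member scaffolds (otherwise it keeps its group id).
    Scaffolds whose markers split across linkage groups become conflict
    records and are not placed.  The change list labels each scaffold
    newly_anchored / reoriented / rearranged / unchanged relative to the
    prior; within-chromosome rearrangements are scaffolds outside the
    longest increasing subsequence of prior ranks in map order.
    """
    mt = linkage_map.table[linkage_map.table["group"] != "ungrouped"].copy()
    mt["scaffold"] = [split_marker_name(m)[0] for m in mt["marker"]]
    mt = mt.merge(markers[["marker", "midpoint_bp"]], on="marker", how="left")
    prior_idx = prior.set_index("scaffold")

    # label linkage groups with chromosomes via prior-placed scaffolds
    # label groups with chromosomes by global greedy assignment: each
    # chromosome goes to the linkage group with the strongest claim
    # (prior-placed scaffold count, then marker count), so a single
    # misplaced scaffold cannot steal a chromosome name from the group
    # holding its resident scaffolds
    claims = []  # (strength, group, chromosome)
    group_votes: dict = {}
    for g, sub in mt.groupby("group", sort=False):
        votes: dict = {}  # chromosome -> [n_scaffolds, n_markers]
        for s, n_mk in sub.groupby("scaffold").size().items():
            if s in prior_idx.index and pd.notna(prior_idx.at[s, "chromosome"]):
                c = prior_idx.at[s, "chromosome"]
                tally = votes.setdefault(c, [0, 0])
                tally[0] += 1
                tally[1] += int(n_mk)
        group_votes[g] = votes
        for c, (n_s, n_m) in votes.items():
            claims.append(((n_s, n_m), g, c))
    claims.sort(key=lambda x: (-x[0][0], -x[0][1], str(x[1]), str(x[2])))
    group_label: dict[str, object] = {}
    taken: set = set()
    for _, g, c in claims:
        if g not in group_label and c not in taken:
            group_label[g] = c
            taken.add(c)
    for g in mt["group"].unique():
        group_label.setdefault(g, g)

    place_rows, conflict_rows = [], []
    for s, sub in mt.groupby("scaffold", sort=False):
        groups = sub["group"].unique()
        if len(groups) > 1:
            conflict_rows.append({
                "scaffold": s,
                "chromosomes": sorted(str(group_label[g]) for g in groups),
                "n_markers": len(sub),
            })
            continue
        cm = sub["cM"].to_numpy(dtype=float)
        place_rows.append({
            "scaffold": s,
            "chromosome": group_label[groups[0]],
            "median_cM": float(np.median(cm)),
            "orientation": orient_scaffold(sub["midpoint_bp"].to_numpy(), cm),
            "n_markers": len(sub),
            "cM_span": float(cm.max() - cm.min()),
        })
    placements = pd.DataFrame(
        place_rows, columns=["scaffold", "chromosome", "median_cM", "orientation",
                             "n_markers", "cM_span"]
    )

    # ranks within chromosome; ties broken by prior rank then scaffold id
    def _prior_rank(s: str) -> float:
        if s in prior_idx.index and pd.notna(prior_idx.at[s, "rank"]):
            return float(prior_idx.at[s, "rank"])
        return np.inf

    if len(placements):
        placements["_prior_rank"] = placements["scaffold"].map(_prior_rank)
        placements = placements.sort_values(
            ["chromosome", "median_cM", "_prior_rank", "scaffold"]
        ).reset_index(drop=True)
        placements["rank"] = placements.groupby("chromosome").cumcount()
        placements = placements.drop(columns="_prior_rank")
    else:
        placements["rank"] = pd.Series(dtype=int)

    # orientation of the map itself is arbitrary per group: if most
    # orientation calls on a chromosome disagree with the prior, the whole
    # group is flipped (reverse ranks and orientations) before comparison.
    for chrom, sub in placements.groupby("chromosome", sort=False):
        agree = disagree = 0
        for rec in sub.itertuples():
            if rec.scaffold in prior_idx.index:
                po = prior_idx.at[rec.scaffold, "orientation"]
                if po in ("+", "-") and rec.orientation in ("+", "-"):
                    if po == rec.orientation:
                        agree += 1
                    else:
                        disagree += 1
        prior_ranks = [
            _prior_rank(r.scaffold) for r in sub.itertuples()
            if np.isfinite(_prior_rank(r.scaffold))
        ]
        rank_reversed = False
        if len(set(prior_ranks)) >= 2:
            rho = stats.spearmanr(np.arange(len(prior_ranks)), prior_ranks).statistic
            rank_reversed = bool(rho < 0)
        if disagree > agree or (disagree == agree and rank_reversed):
            idx = sub.index
            placements.loc[idx, "rank"] = sub["rank"].max() - sub["rank"]
            placements.loc[idx, "orientation"] = sub["orientation"].map(
                {"+": "-", "-": "+", "?": "?"}
            )
        placements.loc[sub.index, "flipped_group"] = disagree > agree

    changes = _change_list(placements, prior_idx)
    conflicts = pd.DataFrame(conflict_rows,
                             columns=["scaffold", "chromosomes", "n_markers"])
    placements = placements.sort_values(["chromosome", "rank"]).reset_index(drop=True)
    return placements, changes, conflicts


def _change_list(placements: pd.DataFrame, prior_idx: pd.DataFrame) -> pd.DataFrame:
    rows = []
    rearranged: set = set()
    for chrom, sub in placements.groupby("chromosome", sort=False):
        sub = sub.sort_values("rank")
        both = [r.scaffold for r in sub.itertuples()
                if r.scaffold in prior_idx.index
                and pd.notna(prior_idx.at[r.scaffold, "chromosome"])
                and prior_idx.at[r.scaffold, "chromosome"] == chrom]
        pranks = np.array([float(prior_idx.at[s, "rank"]) for s in both])
        if len(pranks) >= 2:
            lis = set(_longest_increasing_subsequence(pranks))
            rearranged |= {both[i] for i in range(len(both)) if i not in lis}
    for rec in placements.itertuples(index=False):
        s = rec.scaffold
        if s not in prior_idx.index or pd.isna(prior_idx.at[s, "chromosome"]):
            label = "newly_anchored"
            detail = f"-> {rec.chromosome}:{rec.rank}"
        elif prior_idx.at[s, "chromosome"] != rec.chromosome:
            label = "rearranged"
            detail = (f"{prior_idx.at[s, 'chromosome']}:{prior_idx.at[s, 'rank']} "
                      f"-> {rec.chromosome}:{rec.rank}")
        elif s in rearranged:
            label = "rearranged"
            detail = (f"{rec.chromosome}:{prior_idx.at[s, 'rank']} -> "
                      f"{rec.chromosome}:{rec.rank}")
        elif (rec.orientation in ("+", "-")
              and prior_idx.at[s, "orientation"] in ("+", "-")
              and rec.orientation != prior_idx.at[s, "orientation"]):
            label = "reoriented"
            detail = f"{prior_idx.at[s, 'orientation']} -> {rec.orientation}"
        else:
            label = "unchanged"
            detail = ""
        rows.append({"scaffold": s, "change": label, "detail": detail})
    return pd.DataFrame(rows, columns=["scaffold", "change", "detail"])


def consensus_map(
    placements_a: pd.DataFrame, placements_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge two crosses' placements; returns (consensus, conflicts).

    Agreement on chromosome -> consensus evidence, rank by cross-
    averaged cM; placed in one cross only -> accepted with single-cross
    evidence; chromosome conflict -> excluded and reported.  Orientation
    is the agreed value, the single known value, or '?'.
    """
    a = placements_a.set_index("scaffold")
    b = placements_b.set_index("scaffold")
    rows, conflict_rows = [], []
    for s in sorted(set(a.index) | set(b.index)):
        in_a, in_b = s in a.index, s in b.index
        if in_a and in_b:
            if a.at[s, "chromosome"] != b.at[s, "chromosome"]:
                conflict_rows.append({
                    "scaffold": s,
                    "chromosome_a": a.at[s, "chromosome"],
                    "chromosome_b": b.at[s, "chromosome"],
                })
                continue
            oa, ob = a.at[s, "orientation"], b.at[s, "orientation"]
            if oa == ob:
                orientation = oa
            elif "?" in (oa, ob):
                orientation = oa if ob == "?" else ob
            else:
                orientation = "?"
            rows.append({
                "scaffold": s, "chromosome": a.at[s, "chromosome"],
                "median_cM": (float(a.at[s, "median_cM"])
                              + float(b.at[s, "median_cM"])) / 2.0,
                "orientation": orientation, "evidence": "consensus",
                "n_markers": int(a.at[s, "n_markers"]) + int(b.at[s, "n_markers"]),
            })
        else:
            src, tag = (a, "map_crossA") if in_a else (b, "map_crossB")
            rows.append({
                "scaffold": s, "chromosome": src.at[s, "chromosome"],
                "median_cM": float(src.at[s, "median_cM"]),
                "orientation": src.at[s, "orientation"], "evidence": tag,
                "n_markers": int(src.at[s, "n_markers"]),
            })
    consensus = pd.DataFrame(
        rows, columns=["scaffold", "chromosome", "median_cM", "orientation",
                       "evidence", "n_markers"]
    )
    if len(consensus):
        consensus = consensus.sort_values(
            ["chromosome", "median_cM", "scaffold"]
        ).reset_index(drop=True)
        consensus["rank"] = consensus.groupby("chromosome").cumcount()
    else:
        consensus["rank"] = pd.Series(dtype=int)
    conflicts = pd.DataFrame(conflict_rows,
                             columns=["scaffold", "chromosome_a", "chromosome_b"])
    return consensus, conflicts


def correlate_unplaced(
    unplaced_dosage: np.ndarray,
    placed_dosage: np.ndarray,
    placed_info: pd.DataFrame,
    threshold: float = 0.5,
    margin: float = 0.1,
) -> pd.DataFrame:
    """Place residual bins by read-count (dosage) correlation across F2s.

    ``*_dosage`` are (n_bins, n_f2) arrays on a 0..1 freshwater scale
    with NaN for missing; ``placed_info`` gives (marker, chromosome, cM)
    per placed row.  A bin is assigned to the best-correlated placed
    marker when the correlation reaches ``threshold`` and exceeds the
    best marker on any other chromosome by ``margin``; its position is
    that marker's cM.  Missing dosages are mean-imputed per marker
    before correlating (slightly conservative, biased toward 0).
    """
    U = np.asarray(unplaced_dosage, dtype=float)
    P = np.asarray(placed_dosage, dtype=float)

    def _standardize(X: np.ndarray) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            mu = np.nanmean(X, axis=1, keepdims=True)
        mu = np.nan_to_num(mu)
        Xc = np.where(np.isnan(X), mu, X) - mu
        sd = np.sqrt((Xc**2).mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sd > 0, Xc / sd, 0.0)

    Zu, Zp = _standardize(U), _standardize(P)
    corr = (Zu @ Zp.T) / U.shape[1]
    chrom = placed_info["chromosome"].to_numpy()
    rows = []
    for i in range(U.shape[0]):
        if np.all(np.isnan(U[i])) or not np.any(corr[i] > 0):
            rows.append({"best_marker": None, "correlation": np.nan,
                         "chromosome": None, "cM": np.nan, "placed": False})
            continue
        j = int(np.argmax(corr[i]))
        best_c = chrom[j]
        other = corr[i][chrom != best_c]
        runner_up = float(other.max()) if len(other) else -np.inf
        ok = corr[i, j] >= threshold and corr[i, j] - runner_up >= margin
        rows.append({
            "best_marker": placed_info["marker"].iloc[j],
            "correlation": float(corr[i, j]),
            "chromosome": best_c if ok else None,
            "cM": float(placed_info["cM"].iloc[j]) if ok else np.nan,
            "placed": bool(ok),
        })
    return pd.DataFrame(rows)


@dataclass
class Liftover:
    """Strand-aware affine mapping between scaffold and chromosome coordinates."""

    table: pd.DataFrame  # scaffold, length, strand, chromosome, chrom_start, chrom_end

    @classmethod
    def from_placements(
        cls,
        placements: pd.DataFrame,
        scaffold_lengths: dict[str, int],
        gap_bp: int = DEFAULT_GAP_BP,
    ) -> "Liftover":
        rows = []
        for chrom, sub in placements.sort_values(["chromosome", "rank"]).groupby(
            "chromosome", sort=True
        ):
            offset = 0
            for rec in sub.itertuples(index=False):
                L = scaffold_lengths[rec.scaffold]
                rows.append({
                    "scaffold": rec.scaffold, "length": L,
                    "strand": rec.orientation if rec.orientation in ("+", "-") else "+",
                    "chromosome": chrom,
                    "chrom_start": offset + 1, "chrom_end": offset + L,
                })
                offset += L + gap_bp
        return cls(pd.DataFrame(rows))

    def forward(self, scaffold: str, bp: int):
        """(scaffold, bp) -> (chromosome, bp) or None when unplaced."""
        hit = self.table[self.table["scaffold"] == scaffold]
        if hit.empty:
            return None
        rec = hit.iloc[0]
        if not 1 <= bp <= rec["length"]:
            raise ValueError(f"position {bp} outside scaffold {scaffold} "
                             f"(1..{rec['length']})")
        if rec["strand"] == "+":
            return rec["chromosome"], int(rec["chrom_start"] + bp - 1)
        return rec["chromosome"], int(rec["chrom_start"] + rec["length"] - bp)

    def inverse(self, chromosome, bp: int):
        """(chromosome, bp) -> (scaffold, bp) or None when in a gap."""
        hit = self.table[
            (self.table["chromosome"] == chromosome)
            & (self.table["chrom_start"] <= bp)
            & (self.table["chrom_end"] >= bp)
        ]
        if hit.empty:
            return None
        rec = hit.iloc[0]
        if rec["strand"] == "+":
            return rec["scaffold"], int(bp - rec["chrom_start"] + 1)
        return rec["scaffold"], int(rec["chrom_start"] + rec["length"] - bp)
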