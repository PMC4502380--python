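"""Shared containers and genotype-code conventions.

Genotype codes follow the R/qtl "csv" dialect for an F2 intercross:

====  =====  ==========================================
code  char   meaning (M = marine allele, F = freshwater)
====  =====  ==========================================
0     A      MM homozygote
1     H      MF heterozygote
2     B      FF homozygote
3     C      not A, i.e. MF or FF (uncertain composite)
4     D      not B, i.e. MM or MF (uncertain composite)
5     -      missing
====  =====  ==========================================

Coordinates are 1-based with inclusive spans throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype codes
A, H, B, C, D, MISSING = 0, 1, 2, 3, 4, 5
CODE_CHARS = np.array(["A", "H", "B", "C", "D", "-"])
CHAR_TO_CODE = {c: i for i, c in enumerate(CODE_CHARS)}
STATE_NAMES = {A: "MM", H: "MF", B: "FF", C: "MF/FF", D: "MM/MF", MISSING: "missing"}

#: true states compatible with each observable code
COMPATIBLE = {A: (A,), H: (H,), B: (B,), C: (H, B), D: (A, H)}


@dataclass
class AlleleCountMatrix:
    """Per-(SNP, F2) marine/freshwater read counts plus per-F2 totals.

    ``snps`` is a DataFrame with columns ``scaffold`` (str) and ``pos``
    (1-based int), one row per SNP in the same order as the rows of the
    count matrices.  ``m`` and ``f`` are (n_snp, n_f2) integer arrays of
    reads supporting the marine and freshwater allele.  ``total_reads``
    holds each F2's total mapped reads (the RPMM denominator).
    """

    snps: pd.DataFrame
    f2_ids: list[str]
    m: np.ndarray
    f: np.ndarray
    total_reads: np.ndarray

    def __post_init__(self) -> None:
        n_snp, n_f2 = self.m.shape
        if self.f.shape != (n_snp, n_f2):
            raise ValueError("m and f count matrices must have identical shape")
        if len(self.snps) != n_snp:
            raise ValueError("snps table and count matrices disagree on SNP count")
        if len(self.f2_ids) != n_f2 or len(self.total_reads) != n_f2:
            raise ValueError("f2_ids/total_reads length must match count columns")
        if (self.m < 0).any() or (self.f < 0).any():
            raise ValueError("negative read counts")

    @property
    def n_snps(self) -> int:
        return self.m.shape[0]

    @property
    def n_f2(self) -> int:
        return self.m.shape[1]

    def subset_snps(self, index: np.ndarray) -> "AlleleCountMatrix":
        """Row-subset (SNP axis) by positional index, preserving order."""
        return AlleleCountMatrix(
            self.snps.iloc[index].reset_index(drop=True),
            self.f2_ids,
            self.m[index],
            self.f[index],
            self.total_reads,
        )


@dataclass
class LinkageMap:
    """Ordered markers with cM positions, one group per chromosome."""

    table: pd.DataFrame  # columns: group, marker, order, cM
    mapping_function: str = "haldane"

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    @property
    def total_cM(self) -> float:
        return float(self.table.groupby("group", sort=False)["cM"].max().sum())


def marker_name(scaffold: str, bin_index: int) -> str:
    """Marker naming convention ``<scaffold>_<bin>``, e.g. ``17_8``."""
    return f"{scaffold}_{bin_index}"


def split_marker_name(name: str) -> tuple[str, int]:
    scaffold, _, bin_index = name.rpartition("_")
    return scaffold, int(bin_index)
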