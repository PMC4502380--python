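"""Readers and writers for the pipeline's interchange formats.

All coordinates are 1-based with inclusive spans.  Formats:

* count table: TSV with header ``f2 scaffold pos m_reads f_reads``,
  one row per (F2, SNP) with nonzero or zero reads, plus a two-column
  totals sidecar ``f2 total_reads``;
* scaffold index: two-column ``name length`` TSV (a .fai works);
* R/qtl "csv" cross file: phenotype columns then markers, with
  chromosome and cM header rows, genotype codes A/H/B/C/D/-;
* AGP v2.0 describing the revised chromosomes (W component lines, U gap
  lines of the configured gap size);
* run configuration as JSON (unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .binning import BinningConfig, GenoConfig, QcConfig
from .core import CODE_CHARS, CHAR_TO_CODE, AlleleCountMatrix
from .sieve import SieveConfig

_COUNT_COLS = ["f2", "scaffold", "pos", "m_reads", "f_reads"]


def write_count_table(counts: AlleleCountMatrix, counts_path, totals_path) -> None:
    """Long-format TSV of nonzero (F2, SNP) read counts plus totals sidecar."""
    snp_idx, f2_idx = np.nonzero((counts.m + counts.f) > 0)
    table = pd.DataFrame({
        "f2": np.asarray(counts.f2_ids, dtype=object)[f2_idx],
        "scaffold": counts.snps["scaffold"].to_numpy()[snp_idx],
        "pos": counts.snps["pos"].to_numpy()[snp_idx],
        "m_reads": counts.m[snp_idx, f2_idx],
        "f_reads": counts.f[snp_idx, f2_idx],
    })
    table.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame({"f2": counts.f2_ids, "total_reads": counts.total_reads}).to_csv(
        totals_path, sep="\t", index=False
    )


def read_count_table(counts_path, totals_path,
                     snps: pd.DataFrame | None = None) -> AlleleCountMatrix:
    """Parse the count TSV + totals sidecar into an AlleleCountMatrix.

    ``snps`` optionally fixes the SNP universe (scaffold, pos) so SNPs
    with no reads anywhere are retained; otherwise the SNP set is the
    one observed in the file.  Malformed or negative rows and duplicate
    (f2, SNP) rows raise with the offending line number.
    """
    table = pd.read_csv(counts_path, sep="\t", dtype={"scaffold": str})
    if list(table.columns) != _COUNT_COLS:
        raise ValueError(f"{counts_path}: expected columns {_COUNT_COLS}, "
                         f"got {list(table.columns)}")
    for col in ("pos", "m_reads", "f_reads"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if col == "pos":
            bad |= vals < 1
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{counts_path}: malformed {col} at line {line}")
        table[col] = vals.astype(np.int64)
    dup = table.duplicated(subset=["f2", "scaffold", "pos"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{counts_path}: duplicate (f2, SNP) row at line {line}")

    totals = pd.read_csv(totals_path, sep="\t")
    f2_ids = totals["f2"].astype(str).tolist()
    unknown = set(table["f2"].astype(str)) - set(f2_ids)
    if unknown:
        raise ValueError(f"{counts_path}: F2 ids missing from totals sidecar: "
                         f"{sorted(unknown)[:5]}")

    if snps is None:
        snps = (
            table[["scaffold", "pos"]]
            .drop_duplicates()
            .sort_values(["scaffold", "pos"])
            .reset_index(drop=True)
        )
    snp_key = {(s, p): i for i, (s, p) in
               enumerate(zip(snps["scaffold"], snps["pos"]))}
    f2_key = {f2: j for j, f2 in enumerate(f2_ids)}
    m = np.zeros((len(snps), len(f2_ids)), dtype=np.int64)
    f = np.zeros_like(m)
    for rec in table.itertuples(index=False):
        key = (rec.scaffold, rec.pos)
        if key not in snp_key:
            raise ValueError(f"{counts_path}: SNP {rec.scaffold}:{rec.pos} "
                             "not in the provided SNP table")
        i, j = snp_key[key], f2_key[str(rec.f2)]
        m[i, j] = rec.m_reads
        f[i, j] = rec.f_reads
    return AlleleCountMatrix(
        snps.reset_index(drop=True), f2_ids, m, f,
        totals["total_reads"].to_numpy(dtype=np.int64),
    )


def read_scaffold_index(path) -> dict[str, int]:
    """Two-column name/length TSV (.fai-compatible subset)."""
    table = pd.read_csv(path, sep="\t", header=None, dtype={0: str},
                        usecols=[0, 1], names=["name", "length"])
    return dict(zip(table["name"], table["length"].astype(int)))


def write_scaffold_index(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{length}\n")


def write_rqtl_csv(
    codes: np.ndarray,
    markers: list[str],
    groups: list,
    cm: np.ndarray,
    phenotypes: pd.DataFrame,
    path,
) -> None:
    """R/qtl "csv" cross export.

    Row 1: phenotype names then marker names; row 2: blanks then
    chromosome/group ids; row 3: blanks then cM; then one row per F2.
    Genotypes use A/H/B plus C (not MM), D (not FF) and ``-`` (missing).
    """
    n_markers, n_f2 = codes.shape
    if len(phenotypes) != n_f2:
        raise ValueError("phenotype rows must match genotype columns")
    pheno_cols = list(phenotypes.columns)
    chars = CODE_CHARS[codes]
    with open(path, "w") as fh:
        fh.write(",".join(pheno_cols + list(markers)) + "\n")
        fh.write(",".join([""] * len(pheno_cols) + [str(g) for g in groups]) + "\n")
        fh.write(",".join([""] * len(pheno_cols)
                          + [f"{x:.6g}" for x in cm]) + "\n")
        for j in range(n_f2):
            pvals = [str(phenotypes.iloc[j][c]) for c in pheno_cols]
            fh.write(",".join(pvals + list(chars[:, j])) + "\n")


def read_rqtl_csv(path, n_pheno: int) -> tuple[np.ndarray, list[str], list[str],
                                               np.ndarray, pd.DataFrame]:
    """Inverse of :func:`write_rqtl_csv`; returns (codes, markers, groups, cM, pheno)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        groups_row = fh.readline().rstrip("\n").split(",")
        cm_row = fh.readline().rstrip("\n").split(",")
        body = [line.rstrip("\n").split(",") for line in fh if line.strip()]
    pheno_cols = header[:n_pheno]
    markers = header[n_pheno:]
    groups = groups_row[n_pheno:]
    cm = np.array([float(x) for x in cm_row[n_pheno:]])
    pheno = pd.DataFrame([row[:n_pheno] for row in body], columns=pheno_cols)
    codes = np.array(
        [[CHAR_TO_CODE[v] for v in row[n_pheno:]] for row in body], dtype=np.int8
    ).T
    return codes, markers, groups, cm, pheno


def write_agp(
    placements: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    path,
    gap_bp: int = 1000,
) -> None:
    """AGP v2.0 for the revised chromosomes.

    One W line per scaffold in rank order (orientation '?' permitted),
    with U gap lines of ``gap_bp`` between consecutive scaffolds.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for chrom, sub in placements.sort_values(["chromosome", "rank"]).groupby(
            "chromosome", sort=True
        ):
            offset = 0
            part = 0
            rows = list(sub.itertuples(index=False))
            for k, rec in enumerate(rows):
                L = scaffold_lengths[rec.scaffold]
                part += 1
                orient = rec.orientation if rec.orientation in ("+", "-") else "?"
                fh.write(
                    f"chr{chrom}\t{offset + 1}\t{offset + L}\t{part}\tW\t"
                    f"{rec.scaffold}\t1\t{L}\t{orient}\n"
                )
                offset += L
                if k < len(rows) - 1:
                    part += 1
                    fh.write(
                        f"chr{chrom}\t{offset + 1}\t{offset + gap_bp}\t{part}\tU\t"
                        f"{gap_bp}\tscaffold\tyes\tmap\n"
                    )
                    offset += gap_bp


def read_agp(path) -> pd.DataFrame:
    """Parse an AGP back to component rows; validates contiguity."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(parts)
    out = []
    last_end: dict[str, int] = {}
    for parts in rows:
        obj, beg, end = parts[0], int(parts[1]), int(parts[2])
        if beg != last_end.get(obj, 0) + 1:
            raise ValueError(f"AGP object {obj}: non-contiguous at {beg}")
        last_end[obj] = end
        if parts[4] == "W":
            out.append({
                "object": obj, "object_beg": beg, "object_end": end,
                "component": parts[5], "component_beg": int(parts[6]),
                "component_end": int(parts[7]), "orientation": parts[8],
            })
    return pd.DataFrame(out)


def write_genotype_matrix(codes: np.ndarray, markers: list[str],
                          f2_ids: list[str], path) -> None:
    """Markers x F2s genotype matrix TSV with A/H/B/C/D/- codes."""
    df = pd.DataFrame(CODE_CHARS[codes], index=markers, columns=f2_ids)
    df.to_csv(path, sep="\t", index_label="marker")


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="marker")
    codes = np.vectorize(CHAR_TO_CODE.get)(df.to_numpy()).astype(np.int8)
    return codes, [str(m) for m in df.index], [str(c) for c in df.columns]


def write_pooled_matrix(matrix: np.ndarray, markers: list[str],
                        f2_ids: list[str], path) -> None:
    pd.DataFrame(matrix, index=markers, columns=f2_ids).to_csv(
        path, sep="\t", index_label="marker"
    )


def read_pooled_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="marker")
    return (df.to_numpy(dtype=np.int64), [str(m) for m in df.index],
            [str(c) for c in df.columns])


@dataclasses.dataclass
class RunConfig:
    """Umbrella configuration for the CLI pipeline; JSON round-trippable."""

    seed: int = 0
    sieve: SieveConfig = dataclasses.field(default_factory=SieveConfig)
    binning: BinningConfig = dataclasses.field(default_factory=BinningConfig)
    genotyping: GenoConfig = dataclasses.field(default_factory=GenoConfig)
    qc: QcConfig = dataclasses.field(default_factory=QcConfig)
    sex_thresholds: tuple[float, float] = (0.65, 0.85)
    sex_min_reads: int = 200
    lod_min: float = 6.0
    rf_max: float = 0.35
    mapping_function: str = "haldane"
    hmm_rho_cm_per_mb: float = 4.0
    n_perm: int = 1000
    alpha: float = 0.05
    gap_bp: int = 1000

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(data) - set(field_types)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        nested = {"sieve": SieveConfig, "binning": BinningConfig,
                  "genotyping": GenoConfig, "qc": QcConfig}
        for key, value in data.items():
            if key in nested:
                sub_cls = nested[key]
                sub_fields = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(value) - sub_fields
                if sub_unknown:
                    raise ValueError(f"unknown {key} config keys: "
                                     f"{sorted(sub_unknown)}")
                if "prior" in value:
                    value = {**value, "prior": tuple(value["prior"])}
                kwargs[key] = sub_cls(**value)
            elif key == "sex_thresholds":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
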