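"""Readers and writers for the genetics file formats the pipeline touches.

Covers delimited GWAS summary statistics, PLINK bed/bim/fam filesets
(bit-exact 2-bit decoding of the SNP-major bed layout), the PLINK
``.clumped`` table dialect, 3-column ``--score`` files, and the package's
own per-sample PRS TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = np.int8(-1)  # sentinel for a missing dosage

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major bed header

#: default header names for summary-statistics columns
DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "p_value": "P",
}


class FormatError(ValueError):
    """A file violates the expected format or an invariant."""


@dataclass
class SummaryStats:
    """Base-GWAS per-SNP records: effect allele, log-odds beta, p-value."""

    table: pd.DataFrame  # columns: snp_id, chrom, pos, effect_allele, other_allele, beta, p_value

    def __post_init__(self) -> None:
        t = self.table
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id in summary statistics: {dup!r}")
        if ((t["p_value"] <= 0) | (t["p_value"] > 1)).any():
            raise FormatError("p_value outside (0, 1] in summary statistics")
        if not np.isfinite(t["beta"]).all():
            raise FormatError("non-finite beta in summary statistics")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise FormatError("effect_allele equals other_allele for some SNP")

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self, snp_ids: Sequence[str]) -> pd.DataFrame:
        return self.table.set_index("snp_id").loc[list(snp_ids)].reset_index()


@dataclass
class GenotypeCohort:
    """A samples x SNPs dosage matrix with case/control labels.

    ``dosages[i, j]`` counts copies of ``a1`` for SNP j in sample i, in
    {0, 1, 2} with -1 for missing.  ``phenotype`` is 0=control, 1=case,
    -1 = missing (sample retained but excluded from evaluation).
    """

    cohort_id: str
    sample_ids: list[str]
    phenotype: np.ndarray  # int8: 0 control, 1 case, -1 missing
    snps: pd.DataFrame  # columns: snp_id, chrom, pos, a1, a2
    dosages: np.ndarray  # int8 (n_samples, n_snps)

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise FormatError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(self.phenotype) != n:
            raise FormatError("phenotype length does not match sample count")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise FormatError("dosages must be in {0,1,2} or missing (-1)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def evaluable(self) -> np.ndarray:
        """Boolean mask of samples with a non-missing phenotype."""
        return self.phenotype >= 0

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeCohort":
        idx = self.snps.index[self.snps["snp_id"].isin(set(snp_ids))].to_numpy()
        return GenotypeCohort(
            cohort_id=self.cohort_id,
            sample_ids=list(self.sample_ids),
            phenotype=self.phenotype,
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["snp_id"])}


@dataclass
class ScoreFile:
    """PLINK ``--score``-style records: snp_id, effect_allele, beta."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, beta

    def __post_init__(self) -> None:
        self.table = self.table.assign(beta=self.table["beta"].astype(float))
        if self.table["snp_id"].duplicated().any():
            dup = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise FormatError(f"duplicate snp_id in score file: {dup!r}")
        if not np.isfinite(self.table["beta"]).all():
            raise FormatError("non-finite beta in score file")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, float]]) -> "ScoreFile":
        return cls(pd.DataFrame(records, columns=["snp_id", "effect_allele", "beta"]))


@dataclass
class ClumpTable:
    """Ordered LD clumps, each an index SNP plus member SNPs."""

    clumps: pd.DataFrame  # columns: clump_id (1..k), index_snp, members (list of str)
    unclumped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.clumps["clump_id"].to_numpy()
        if len(ids) and not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise FormatError("clump_ids must be consecutive from 1 in order")
        seen: set[str] = set()
        for _, row in self.clumps.iterrows():
            for s in [row["index_snp"], *row["members"]]:
                if s in seen:
                    raise FormatError(f"SNP {s!r} appears in more than one clump")
                seen.add(s)

    def __len__(self) -> int:
        return len(self.clumps)

    def all_snps(self) -> set[str]:
        out: set[str] = set()
        for _, row in self.clumps.iterrows():
            out.add(row["index_snp"])
            out.update(row["members"])
        return out


def read_summary_stats(
    path: str | Path, column_map: Mapping[str, str] | None = None, sep: str | None = None
) -> SummaryStats:
    """Read delimited base summary statistics.

    ``column_map`` maps the canonical field names (snp_id, chrom, pos,
    effect_allele, other_allele, beta, p_value) to the file's header names;
    defaults cover the common SNP/CHR/BP/A1/A2/BETA/P layout.  A column
    mapped as ``or`` instead of ``beta`` (map key ``odds_ratio``) is
    converted to beta = ln(OR) at read time.  Rows with missing beta or p
    are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    use_or = False
    if column_map:
        cm = dict(column_map)
        if "odds_ratio" in cm:
            use_or = True
            cm["beta"] = cm.pop("odds_ratio")
        cmap.update(cm)
    df = pd.read_csv(path, sep=sep, engine="python")
    missing_cols = [v for v in cmap.values() if v not in df.columns]
    if missing_cols:
        raise FormatError(f"summary statistics missing mapped column(s): {missing_cols}")
    df = df.rename(columns={v: k for k, v in cmap.items()})[list(cmap)]
    n0 = len(df)
    df = df.dropna(subset=["beta", "p_value"]).reset_index(drop=True)
    if len(df) < n0:
        log.info("read_summary_stats: dropped %d rows with missing beta/p", n0 - len(df))
    if use_or:
        log.info("read_summary_stats: converting odds ratios to beta = ln(OR)")
        df["beta"] = np.log(df["beta"].astype(float))
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    df["beta"] = df["beta"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    return SummaryStats(df)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    out = stats.table.rename(columns={k: v for k, v in DEFAULT_COLUMN_MAP.items()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

# 2-bit codes in the bed format (low bits = first sample of the byte):
#   00 -> homozygous A1  (dosage 2)
#   01 -> missing
#   10 -> heterozygous   (dosage 1)
#   11 -> homozygous A2  (dosage 0)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, int(MISSING): 0b01}


def read_plink_cohort(prefix: str | Path, cohort_id: str | None = None) -> GenotypeCohort:
    """Read a PLINK bed/bim/fam fileset into a :class:`GenotypeCohort`.

    Dosages count the .bim A1 allele.  .fam phenotypes follow the PLINK
    convention (1=control, 2=case, -9/0=missing); missing-phenotype samples
    are retained but flagged excluded from evaluation (phenotype -1).
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic number (not a SNP-major bed file)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: size implies a sample/SNP count mismatch with .fam/.bim"
        )
    mat = body.reshape(m, bytes_per_snp)
    # unpack the four 2-bit genotypes per byte, low bits first
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()  # (samples, snps)

    pheno_raw = fam["pheno"].to_numpy()
    phenotype = np.full(n, -1, dtype=np.int8)
    phenotype[pheno_raw == 1] = 0
    phenotype[pheno_raw == 2] = 1
    n_excl = int((phenotype < 0).sum())
    if n_excl:
        log.info("read_plink_cohort: %d samples have missing phenotype (excluded from evaluation)", n_excl)
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy().reset_index(drop=True)
    return GenotypeCohort(
        cohort_id=cohort_id or prefix.name,
        sample_ids=list(fam["iid"]),
        phenotype=phenotype,
        snps=snps,
        dosages=dosages,
    )


def write_plink_cohort(cohort: GenotypeCohort, prefix: str | Path) -> None:
    """Write a cohort as a PLINK bed/bim/fam fileset (SNP-major bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = cohort.dosages.shape
    pheno_out = np.where(cohort.phenotype == 1, 2, np.where(cohort.phenotype == 0, 1, -9))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid, ph in zip(cohort.sample_ids, pheno_out):
            fh.write(f"{iid} {iid} 0 0 0 {ph}\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in cohort.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\t{row['a1']}\t{row['a2']}\n")
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0b01  # pad slots encode as missing
    lut = np.array([_DOSAGE_TO_CODE[0], _DOSAGE_TO_CODE[1], _DOSAGE_TO_CODE[2]], dtype=np.uint8)
    d = cohort.dosages.T  # (snps, samples)
    c = np.where(d == MISSING, 0b01, lut[np.clip(d, 0, 2)]).astype(np.uint8)
    codes[:, :n] = c
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Score files


def write_score_file(scores: ScoreFile, path: str | Path) -> None:
    """Write a 3-column whitespace score file consumable by PLINK --score."""
    if len(scores) == 0:
        raise FormatError("refusing to write an empty score file")
    with open(path, "w") as fh:
        for _, row in scores.table.iterrows():
            # %.10g keeps sign and avoids scientific notation above 1e-4 magnitudes
            fh.write(f"{row['snp_id']} {row['effect_allele']} {row['beta']:.10g}\n")


def read_score_file(path: str | Path) -> ScoreFile:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["snp_id", "effect_allele", "beta"])
    return ScoreFile(df)


# ---------------------------------------------------------------------------
# PLINK .clumped table dialect

_SP2_ANNOT = re.compile(r"\(\d+\)$")


def read_clump_table(path: str | Path) -> ClumpTable:
    """Read a PLINK ``.clumped``-style whitespace table into a ClumpTable.

    Expects at least CHR, SNP, BP, P and SP2 columns; SP2 is the
    comma-separated member list with optional trailing "(1)"-style allele
    annotations, or the literal NONE for a singleton clump.  Clumps are
    numbered in file order.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    header = lines[0].split()
    for col in ("CHR", "SNP", "BP", "P", "SP2"):
        if col not in header:
            raise FormatError(f"clump table missing column {col}")
    isnp, isp2 = header.index("SNP"), header.index("SP2")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) <= max(isnp, isp2):
            raise FormatError(f"clump table line {lineno}: unparsable row")
        sp2 = parts[isp2]
        if sp2 == "NONE":
            members: list[str] = []
        else:
            members = []
            for tok in sp2.split(","):
                tok = tok.strip()
                if not tok:
                    raise FormatError(f"clump table line {lineno}: unparsable SP2 field")
                members.append(_SP2_ANNOT.sub("", tok))
        rows.append({"clump_id": len(rows) + 1, "index_snp": parts[isnp], "members": members})
    return ClumpTable(pd.DataFrame(rows, columns=["clump_id", "index_snp", "members"]))


def write_clump_table(table: ClumpTable, path: str | Path, stats: "SummaryStats | None" = None) -> None:
    """Write a ClumpTable in the .clumped dialect (CHR/SNP/BP/P/SP2 columns)."""
    meta = None
    if stats is not None:
        meta = stats.table.set_index("snp_id")
    with open(path, "w") as fh:
        fh.write(" CHR    SNP           BP        P    SP2\n")
        for _, row in table.clumps.iterrows():
            snp = row["index_snp"]
            if meta is not None and snp in meta.index:
                chrom, bp, p = meta.at[snp, "chrom"], meta.at[snp, "pos"], meta.at[snp, "p_value"]
            else:
                chrom, bp, p = "0", 0, 1.0
            sp2 = ",".join(f"{m}(1)" for m in row["members"]) or "NONE"
            fh.write(f" {chrom}    {snp}    {bp}    {p:.4g}    {sp2}\n")


def write_prs_table(prs: pd.DataFrame, path: str | Path) -> None:
    """Per-sample PRS output TSV: sample_id, phenotype, score, n_snps_used."""
    prs.to_csv(path, sep="\t", index=False)
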