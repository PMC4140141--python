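"""Domain types and tabular readers/writers.

All inputs and outputs are UTF-8 tab-separated text with a header row;
missing values are written as ``.`` and read as NaN (``.`` or empty).
Genomic positions are 1-based; they are converted once to signed
TSS-relative offsets (:func:`tss_relative_offset`) and every downstream
module works exclusively in that coordinate system: offset 0 is the
transcription start site, positive offsets run downstream into the gene
body, negative offsets upstream into the promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("methylprofile")

MISSING = "."

CONDITIONS = ("disease", "healthy")

#: recognised gene-group labels; "other" marks probes outside the study sets
GROUPS = ("immune", "cellcycle", "stable", "other")

ANNOTATION_COLUMNS = ["probe_id", "gene_id", "group", "tss_offset", "gene_end_offset"]


class DataError(ValueError):
    """Raised when an input file violates its documented schema."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id with one column per sample; entries
        are methylation fractions in [0, 1] or NaN for missing.
    condition
        Series mapping sample_id -> condition label (``disease`` or
        ``healthy``), in the same order as ``values.columns``.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = list(self.values.columns[self.condition.isna()])
            raise DataError(f"samples missing from sample sheet: {missing}")
        bad_cond = set(self.condition) - set(CONDITIONS)
        if bad_cond:
            raise DataError(f"unknown condition label(s): {sorted(bad_cond)}")
        for cond in CONDITIONS:
            if (self.condition == cond).sum() < 2:
                raise DataError(f"need >=2 samples with condition '{cond}'")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()][:5]
            raise DataError(f"duplicate probe ids: {list(dups)}")
        arr = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"beta value out of [0,1]: probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r} = {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Sub-matrix of the samples with the given condition label."""
        return self.values.loc[:, self.condition == condition]

    @property
    def disease(self) -> pd.DataFrame:
        return self.condition_values("disease")

    @property
    def healthy(self) -> pd.DataFrame:
        return self.condition_values("healthy")


@dataclass
class GeneSet:
    """Named set of gene identifiers (one analysis group)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING, ""], keep_default_na=False)


def load_beta_matrix(path, sample_sheet) -> BetaMatrix:
    """Load a beta-value matrix plus its sample sheet.

    ``path`` is a TSV whose first column is the probe id and remaining
    columns are samples; ``sample_sheet`` is a TSV with columns
    ``sample_id`` and ``condition``. Probes whose values are all missing
    are dropped (logged); any value outside [0, 1] is a hard error naming
    the offending probe and sample.
    """
    table = _read_tsv(path)
    table = table.set_index(table.columns[0])
    table.index.name = "probe_id"
    sheet = _read_tsv(sample_sheet)
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise DataError("sample sheet needs columns 'sample_id' and 'condition'")
    condition = sheet.set_index("sample_id")["condition"]
    all_missing = table.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d probes with all-missing beta values", all_missing.sum())
        table = table.loc[~all_missing]
    return BetaMatrix(values=table, condition=condition)


def save_beta_matrix(bm: BetaMatrix, path, sample_sheet) -> None:
    bm.values.to_csv(path, sep="\t", na_rep=MISSING)
    sheet = pd.DataFrame(
        {"sample_id": bm.sample_ids, "condition": bm.condition.to_numpy()}
    )
    sheet.to_csv(sample_sheet, sep="\t", index=False)


def tss_relative_offset(probe_pos, tss_pos, strand):
    """Signed TSS-relative offset of a probe, in bp.

    On the + strand the offset is ``probe_pos - tss_pos``; on the − strand
    it is ``tss_pos - probe_pos``, so positive offsets are always
    downstream of the TSS in the direction of transcription. Accepts
    scalars or aligned arrays; positions are 1-based and assumed to lie on
    the same chromosome.
    """
    strand_arr = np.asarray(strand)
    valid = np.atleast_1d(np.isin(strand_arr, ["+", "-"]))
    if not valid.all():
        bad = np.unique(np.atleast_1d(strand_arr)[~valid])
        raise DataError(f"strand must be '+' or '-', got {list(bad)}")
    sign = np.where(strand_arr == "+", 1, -1)
    out = sign * (np.asarray(probe_pos) - np.asarray(tss_pos))
    if np.isscalar(probe_pos) and np.isscalar(tss_pos) and strand_arr.ndim == 0:
        return int(out)
    return out


def load_annotation(path) -> pd.DataFrame:
    """Load probe annotation: probe -> gene, group, TSS-relative offset.

    Columns: probe_id, gene_id, group, tss_offset, gene_end_offset.
    One row per probe x gene assignment. Offsets must satisfy
    −2,500 ≤ tss_offset ≤ gene_end_offset (the initial selection window).
    """
    df = _read_tsv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["tss_offset"] = df["tss_offset"].astype(int)
    df["gene_end_offset"] = df["gene_end_offset"].astype(int)
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise DataError(f"unknown gene group(s): {sorted(bad_group)}")
    out_of_range = (df["tss_offset"] < -2500) | (df["tss_offset"] > df["gene_end_offset"])
    if out_of_range.any():
        row = df[out_of_range].iloc[0]
        raise DataError(
            f"probe {row.probe_id!r} offset {row.tss_offset} outside "
            f"[-2500, gene end {row.gene_end_offset}]"
        )
    if df.duplicated(["probe_id", "gene_id"]).any():
        raise DataError("duplicate probe x gene annotation rows")
    return df


def save_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=MISSING)


def annotate_probes(probe_positions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Build a TSS-relative annotation from genomic coordinates.

    ``probe_positions`` has columns (probe_id, gene_id, pos);
    ``genes`` has columns (gene_id, group, tss, strand, gene_end) with
    gene_end a genomic position. Rows outside the initial selection
    window (−2,500 to gene end) are dropped with a logged count.
    """
    merged = probe_positions.merge(genes, on="gene_id", how="inner", validate="m:1")
    off = tss_relative_offset(
        merged["pos"].to_numpy(), merged["tss"].to_numpy(), merged["strand"].to_numpy()
    )
    end_off = tss_relative_offset(
        merged["gene_end"].to_numpy(), merged["tss"].to_numpy(), merged["strand"].to_numpy()
    )
    merged["tss_offset"] = off
    merged["gene_end_offset"] = end_off
    keep = (merged["tss_offset"] >= -2500) & (merged["tss_offset"] <= merged["gene_end_offset"])
    if (~keep).any():
        logger.info("annotate_probes: dropped %d probes outside selection window", (~keep).sum())
    return merged.loc[keep, ANNOTATION_COLUMNS].reset_index(drop=True)


def load_gene_sets(paths: dict) -> list[GeneSet]:
    """Load gene sets from plain-text files (one gene symbol per line).

    ``paths`` maps set name -> file path. Duplicate lines within a file
    are deduplicated with a warning; a symbol present in several files is
    kept in every set (analyses run per-set). An empty file is an error.
    """
    sets: list[GeneSet] = []
    seen: dict[str, str] = {}
    for name, path in paths.items():
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        symbols = [ln for ln in lines if ln]
        if not symbols:
            raise DataError(f"gene set file {path} is empty")
        if len(set(symbols)) < len(symbols):
            logger.warning(
                "gene set %r: %d duplicate lines collapsed", name, len(symbols) - len(set(symbols))
            )
        for sym in set(symbols):
            if sym in seen:
                logger.info("gene %s is in both %r and %r; kept in both", sym, seen[sym], name)
            seen.setdefault(sym, name)
        sets.append(GeneSet(name=name, members=frozenset(symbols)))
    return sets


def save_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gs.members)) + "\n")


def load_expression(path) -> pd.DataFrame:
    """Load a per-gene differential-expression table.

    Accepts TSV with columns (gene_id, delta_mrna) or
    (gene_id, array_probe_id, delta_mrna). With several array probes per
    gene the mean delta is used. Genes whose resulting delta is exactly 0
    are excluded (logged) — a zero carries no direction to correlate with.
    """
    df = _read_tsv(path)
    if "delta_mrna" not in df.columns or "gene_id" not in df.columns:
        raise DataError("expression table needs columns 'gene_id' and 'delta_mrna'")
    if df["delta_mrna"].isna().any():
        raise DataError("non-numeric or missing delta_mrna values")
    df["delta_mrna"] = pd.to_numeric(df["delta_mrna"], errors="raise")
    per_gene = df.groupby("gene_id", as_index=False)["delta_mrna"].mean()
    zero = per_gene["delta_mrna"] == 0.0
    if zero.any():
        logger.info("load_expression: excluded %d genes with delta_mrna == 0", zero.sum())
    return per_gene.loc[~zero].reset_index(drop=True)


def save_expression(expr: pd.DataFrame, path) -> None:
    expr[["gene_id", "delta_mrna"]].to_csv(path, sep="\t", index=False, na_rep=MISSING)
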