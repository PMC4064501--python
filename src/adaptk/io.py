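"""Reading intensity data and writing genotype-call tables.

Two input pathways are supported: a GenomeStudio-style long-format final
report (tab or csv), and a pair of SNP x sample numeric matrices plus a SNP
annotation table. Output is a flat tab-delimited call table (the method
produces genotype symbols without REF/ALT nucleotides, so VCF is out of
scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError

VALID_CHROMOSOMES = frozenset([str(c) for c in range(1, 23)] + ["X", "Y", "XY", "MT"])

#: Default GenomeStudio final-report column names; exports drift, so callers
#: may override any of these via ``column_map``.
DEFAULT_COLUMN_MAP = {
    "snp": "SNP Name",
    "sample": "Sample ID",
    "x": "X Raw",
    "y": "Y Raw",
}

GENOTYPE_LABELS = {0: "NC", 1: "AA", 2: "AB", 3: "BB"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}


@dataclass(frozen=True)
class SNPAnnotation:
    """Identity and genomic location of one SNP ("XY" = pseudo-autosomal)."""

    snp_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMOSOMES:
            raise DataError(
                f"chromosome {self.chromosome!r} for SNP {self.snp_id!r} not in "
                f"allowed vocabulary"
            )
        if self.position < 0:
            raise DataError(f"negative position for SNP {self.snp_id!r}")

    @property
    def is_autosomal_scope(self) -> bool:
        """True for SNPs called through the autosomal path (autosomes + PAR)."""
        return self.chromosome not in ("X", "Y")


@dataclass
class IntensityDataset:
    """Raw two-channel intensities with SNP/sample metadata.

    X holds allele-A and Y allele-B intensities (SNP x sample). Missing
    entries are flagged in ``mask`` (True = missing) and carried as NaN in
    the matrices — never silently zero.
    """

    X: np.ndarray
    Y: np.ndarray
    snps: list[SNPAnnotation]
    samples: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape:
            raise DataError("X and Y must have identical dimensions")
        if self.mask is None:
            self.mask = np.isnan(self.X) | np.isnan(self.Y)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.X.shape:
                raise DataError("mask shape must match X/Y")
        if len(self.snps) != self.X.shape[0]:
            raise DataError("snps length must equal row count")
        if len(self.samples) != self.X.shape[1]:
            raise DataError("samples length must equal column count")
        if len(set(s.snp_id for s in self.snps)) != len(self.snps):
            raise DataError("duplicate snp_id in dataset")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample id in dataset")
        unmasked_x = self.X[~self.mask]
        unmasked_y = self.Y[~self.mask]
        if not (np.all(np.isfinite(unmasked_x)) and np.all(np.isfinite(unmasked_y))):
            raise DataError("non-finite intensity outside the missing-data mask")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def _find_header_row(path: str, sep: str, required: list[str]) -> int:
    """Locate the header line (GenomeStudio reports carry a preamble)."""
    with open(path, "r") as fh:
        for i, line in enumerate(fh):
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if all(col in fields for col in required):
                return i
            if i > 500:
                break
    raise FormatError(
        f"no header row containing columns {required} found in {path!r}"
    )


def read_genomestudio_report(
    path: str,
    dialect: str = "tab",
    column_map: dict[str, str] | None = None,
) -> IntensityDataset:
    """Read a long-format GenomeStudio-style final report.

    Parameters
    ----------
    path : str
        Report file, one row per (SNP, sample) pair.
    dialect : {"tab", "csv"}
        Field delimiter.
    column_map : dict, optional
        Overrides for the default column names (keys: snp, sample, x, y).
    """
    if dialect not in ("tab", "csv"):
        raise FormatError(f"dialect must be 'tab' or 'csv', got {dialect!r}")
    sep = "\t" if dialect == "tab" else ","
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    required = [cmap["snp"], cmap["sample"], cmap["x"], cmap["y"]]
    header_row = _find_header_row(path, sep, required)
    df = pd.read_csv(path, sep=sep, skiprows=header_row, dtype=str)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from report {path!r}")
    snp_col, sample_col = cmap["snp"], cmap["sample"]

    dup = df.duplicated(subset=[snp_col, sample_col])
    if dup.any():
        r = df.loc[dup.idxmax()]
        raise DataError(
            f"duplicate (SNP, sample) pair ({r[snp_col]!r}, {r[sample_col]!r}) in report"
        )
    snp_order = pd.unique(df[snp_col])
    sample_order = pd.unique(df[sample_col])

    mats = {}
    for key in ("x", "y"):
        vals = pd.to_numeric(df[cmap[key]], errors="coerce")
        bad = vals.isna() & df[cmap[key]].notna() & (df[cmap[key]].str.strip() != "")
        if bad.any():
            i = bad.idxmax()
            raise FormatError(
                f"non-numeric value {df.loc[i, cmap[key]]!r} in column "
                f"{cmap[key]!r} at row {i}"
            )
        wide = (
            df.assign(_v=vals)
            .pivot(index=snp_col, columns=sample_col, values="_v")
            .reindex(index=snp_order, columns=sample_order)
        )
        mats[key] = wide

    # missing (SNP, sample) rows are a structural error, not a masked cell
    n_cells = len(snp_order) * len(sample_order)
    if len(df) != n_cells:
        present = set(zip(df[snp_col], df[sample_col]))
        for s in snp_order:
            for smp in sample_order:
                if (s, smp) not in present:
                    raise DataError(f"missing report row for SNP {s!r}, sample {smp!r}")

    snps = [SNPAnnotation(snp_id=str(s), chromosome="1", position=0) for s in snp_order]
    return IntensityDataset(
        X=mats["x"].to_numpy(dtype=float),
        Y=mats["y"].to_numpy(dtype=float),
        snps=snps,
        samples=[str(s) for s in sample_order],
    )


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"non-numeric value {df.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} of {path!r}"
            )
        df[col] = vals
    return df


def read_annotation(path: str) -> pd.DataFrame:
    """Read a SNP annotation table with columns snp_id, chromosome, position."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in ("snp_id", "chromosome", "position"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path!r} lacks required column {col!r}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise DataError(f"duplicate snp_id {dup!r} in annotation")
    return df


def read_matrix_pair(x_path: str, y_path: str, annot_path: str) -> IntensityDataset:
    """Read X/Y matrices and a SNP annotation table, aligning on shared ids.

    Rows and columns are canonicalized (sorted by id), so the result is
    invariant to the input row/column order of either matrix.
    """
    X = _read_matrix(x_path)
    Y = _read_matrix(y_path)
    shared_snps = sorted(set(X.index) & set(Y.index))
    shared_samples = sorted(set(X.columns) & set(Y.columns))
    if not shared_snps or not shared_samples:
        raise AlignmentError("X and Y matrices share no SNP ids or no sample ids")
    X = X.loc[shared_snps, shared_samples]
    Y = Y.loc[shared_snps, shared_samples]

    annot = read_annotation(annot_path).set_index("snp_id")
    missing = [s for s in shared_snps if s not in annot.index]
    if missing:
        raise AlignmentError(f"annotation missing SNP(s): {', '.join(missing[:10])}")
    snps = [
        SNPAnnotation(
            snp_id=s,
            chromosome=str(annot.loc[s, "chromosome"]),
            position=int(annot.loc[s, "position"]),
        )
        for s in shared_snps
    ]
    return IntensityDataset(
        X=X.to_numpy(dtype=float),
        Y=Y.to_numpy(dtype=float),
        snps=snps,
        samples=list(shared_samples),
    )


def write_calls(calls, path: str) -> None:
    """Write a tab-delimited call table (SNP-major, then sample order).

    Columns: snp_id, sample_id, genotype (AA/AB/BB/NC), confidence (6 dp),
    predicted_k.
    """
    with open(path, "w") as fh:
        fh.write("snp_id\tsample_id\tgenotype\tconfidence\tpredicted_k\n")
        for i, snp_id in enumerate(calls.snp_ids):
            k = int(calls.predicted_k[i])
            for j, sample_id in enumerate(calls.sample_ids):
                code = int(calls.calls[i, j])
                conf = calls.confidence[i, j]
                conf_str = "nan" if np.isnan(conf) else f"{conf:.6f}"
                fh.write(
                    f"{snp_id}\t{sample_id}\t{GENOTYPE_LABELS[code]}\t{conf_str}\t{k}\n"
                )


def read_calls(path: str):
    """Read a call table written by :func:`write_calls` back into memory."""
    from .k_model import GenotypeCalls  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "sample_id": str})
    for col in ("snp_id", "sample_id", "genotype", "confidence", "predicted_k"):
        if col not in df.columns:
            raise FormatError(f"call table {path!r} lacks required column {col!r}")
    snp_ids = list(pd.unique(df["snp_id"]))
    sample_ids = list(pd.unique(df["sample_id"]))
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    codes = np.zeros((len(snp_ids), len(sample_ids)), dtype=np.int64)
    conf = np.full((len(snp_ids), len(sample_ids)), np.nan)
    pred_k = np.zeros(len(snp_ids), dtype=np.int64)
    for row in df.itertuples(index=False):
        i, j = snp_pos[row.snp_id], sample_pos[row.sample_id]
        if row.genotype not in GENOTYPE_CODES:
            raise DataError(f"unknown genotype symbol {row.genotype!r} in {path!r}")
        codes[i, j] = GENOTYPE_CODES[row.genotype]
        conf[i, j] = float(row.confidence)
        pred_k[i] = int(row.predicted_k)
    return GenotypeCalls(
        calls=codes,
        confidence=conf,
        predicted_k=pred_k,
        k_probabilities=np.full((len(snp_ids), 3), np.nan),
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )
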