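"""Readers and writers for every table the pipeline touches, plus TPM computation.

All tables are UTF-8 TSV with a header row; missing values are encoded as
``NA``. Tabular data is held in pandas DataFrames with documented schemas;
sample metadata travels in a sidecar TSV rather than being packed into
column names.

Schemas
-------
expression TSV      : ``gene_id`` then one column per sample (TPM values)
metadata TSV        : sample_id, cross, maternal_parent, paternal_parent,
                      maternal_ploidy, paternal_ploidy, tissue, stage, replicate
triad TSV           : triad_id, gene_A, gene_B, gene_D (``NA`` in 2-genome mode)
allele-count TSV    : gene_id, cross, stage, tissue, replicate,
                      maternal_reads, paternal_reads
transcript quant    : quant.sf dialect (Name, Length, EffectiveLength, TPM,
                      NumReads) plus a mapping TSV ``transcript_id<TAB>gene_id``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleMeta",
    "ExpressionMatrix",
    "tissue_for_stage",
    "tpm_from_counts",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_triad_map",
    "write_triad_map",
    "read_allele_counts",
    "write_allele_counts",
    "read_transcript_quant",
    "write_transcript_quant",
]

EMBRYO_STAGES = tuple(f"E{i}" for i in range(1, 8))
ENDOSPERM_STAGES = ("E8", "E9")
ALL_STAGES = EMBRYO_STAGES + ENDOSPERM_STAGES

NA_REP = "NA"


class ValidationError(ValueError):
    """Raised when an input table violates its schema or invariants."""


def tissue_for_stage(stage: str) -> str:
    """Map a developmental stage to its tissue: E1–E7 embryo, E8–E9 endosperm."""
    if stage in EMBRYO_STAGES:
        return "embryo"
    if stage in ENDOSPERM_STAGES:
        return "endosperm"
    raise ValidationError(f"unknown stage {stage!r}; expected one of {ALL_STAGES}")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample of a reciprocal cross pair.

    ``cross`` is maternal-first (e.g. ``"AxC"`` = A as female parent).
    Embryo samples span stages E1–E7; endosperm samples are E8 or E9.
    """

    sample_id: str
    cross: str
    maternal_parent: str
    paternal_parent: str
    maternal_ploidy: int
    paternal_ploidy: int
    tissue: str
    stage: str
    replicate: int

    def __post_init__(self):
        if self.tissue not in ("embryo", "endosperm"):
            raise ValidationError(f"{self.sample_id}: unknown tissue {self.tissue!r}")
        if tissue_for_stage(self.stage) != self.tissue:
            raise ValidationError(
                f"{self.sample_id}: stage {self.stage} is inconsistent with tissue {self.tissue}"
            )
        if self.maternal_ploidy not in (4, 6) or self.paternal_ploidy not in (4, 6):
            raise ValidationError(f"{self.sample_id}: ploidy must be 4 or 6")
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")


class ExpressionMatrix:
    """Gene × sample TPM matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids with one column per sample id,
        all values non-negative.
    samples
        One :class:`SampleMeta` per column, in any order; the set of
        ``sample_id`` values must equal the column set.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleMeta]):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if (values.values < 0).any():
            gene = values.index[np.where(values.values < 0)[0][0]]
            raise ValidationError(f"negative expression value at gene {gene!r}")
        meta_ids = [s.sample_id for s in samples]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValidationError("duplicate sample ids in metadata")
        missing = set(values.columns) - set(meta_ids)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        extra = set(meta_ids) - set(values.columns)
        if extra:
            raise ValidationError(f"metadata for unknown samples: {sorted(extra)}")
        keys = {(s.cross, s.stage, s.replicate) for s in samples}
        if len(keys) != len(samples):
            raise ValidationError("(cross, stage, replicate) must be unique across samples")
        self.values = values.astype(float)
        self.samples = {s.sample_id: s for s in samples}

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        return self.samples[sample_id]

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame, one row per sample column."""
        return pd.DataFrame([vars(self.samples[s]) for s in self.sample_ids])


def tpm_from_counts(counts, effective_lengths) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    ``rate_i = count_i / efflen_i``; ``TPM_i = rate_i / sum(rate) * 1e6``.
    An all-zero count vector yields all-zero TPM (not an error).
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValidationError("counts and effective_lengths must have equal length")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    if (lengths <= 0).any():
        raise ValidationError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


# ---------------------------------------------------------------------------
# expression matrix + metadata


def read_sample_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    required = [
        "sample_id", "cross", "maternal_parent", "paternal_parent",
        "maternal_ploidy", "paternal_ploidy", "tissue", "stage", "replicate",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata file {path} missing columns: {missing}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            cross=str(r.cross),
            maternal_parent=str(r.maternal_parent),
            paternal_parent=str(r.paternal_parent),
            maternal_ploidy=int(r.maternal_ploidy),
            paternal_ploidy=int(r.paternal_ploidy),
            tissue=str(r.tissue),
            stage=str(r.stage),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_sample_metadata(samples: Sequence[SampleMeta], path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(
        path, sep="\t", index=False, na_rep=NA_REP
    )


def read_expression_matrix(path, metadata_path) -> ExpressionMatrix:
    """Read an expression TSV (``gene_id`` + sample columns) and its metadata sidecar."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    samples = read_sample_metadata(metadata_path)
    return ExpressionMatrix(df, samples)


def write_expression_matrix(expr: ExpressionMatrix, path, metadata_path=None) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP)
    if metadata_path is not None:
        write_sample_metadata(list(expr.samples.values()), metadata_path)


# ---------------------------------------------------------------------------
# triad map


def read_triad_map(path) -> pd.DataFrame:
    """Read a triad TSV; returns columns triad_id, gene_A, gene_B, gene_D.

    ``gene_D`` is NaN in two-genome (tetraploid) mode. Every gene may appear
    in at most one triad.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_REP], keep_default_na=False)
    required = ["triad_id", "gene_A", "gene_B"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"triad file {path} missing columns: {missing}")
    if "gene_D" not in df.columns:
        df["gene_D"] = pd.NA
    if df["triad_id"].duplicated().any():
        dup = df.loc[df["triad_id"].duplicated(), "triad_id"].iloc[0]
        raise ValidationError(f"duplicate triad id {dup!r}")
    genes = pd.concat([df["gene_A"], df["gene_B"], df["gene_D"].dropna()])
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValidationError(f"gene {dup!r} appears in more than one triad")
    return df[["triad_id", "gene_A", "gene_B", "gene_D"]]


def write_triad_map(triads: pd.DataFrame, path) -> None:
    triads.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# allele-specific counts


def read_allele_counts(path) -> pd.DataFrame:
    """Read per-gene maternal/paternal SNP-read counts.

    Columns: gene_id, cross, stage, tissue, replicate, maternal_reads,
    paternal_reads. Counts must be non-negative integers and
    (gene_id, cross, stage, replicate) unique.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    required = [
        "gene_id", "cross", "stage", "tissue", "replicate",
        "maternal_reads", "paternal_reads",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"allele-count file {path} missing columns: {missing}")
    return validate_allele_counts(df)


def validate_allele_counts(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("maternal_reads", "paternal_reads"):
        if (df[col] < 0).any():
            row = df.index[df[col] < 0][0]
            raise ValidationError(f"negative {col} at row {row}")
        if not np.allclose(df[col] % 1, 0):
            raise ValidationError(f"{col} must be integer-valued")
    key = ["gene_id", "cross", "stage", "replicate"]
    if df.duplicated(subset=key).any():
        dup = df.loc[df.duplicated(subset=key), key].iloc[0].tolist()
        raise ValidationError(f"duplicate allele-count record for {dup}")
    for stage, tissue in df[["stage", "tissue"]].drop_duplicates().itertuples(index=False):
        if tissue_for_stage(stage) != tissue:
            raise ValidationError(f"stage {stage} inconsistent with tissue {tissue}")
    out = df.copy()
    out["maternal_reads"] = out["maternal_reads"].astype(int)
    out["paternal_reads"] = out["paternal_reads"].astype(int)
    return out


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


# ---------------------------------------------------------------------------
# transcript-level quantifications (quant.sf dialect)

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


def read_transcript_quant(quant_path, tx2gene_path, sample_id: str) -> pd.DataFrame:
    """Read one quant.sf-style table plus a transcript→gene mapping.

    Returns a DataFrame with columns transcript_id, gene_id, length,
    effective_length, tpm, num_reads, sample_id. A transcript without a gene
    mapping is an error naming the transcript.
    """
    quant = pd.read_csv(quant_path, sep="\t")
    missing = [c for c in QUANT_COLUMNS if c not in quant.columns]
    if missing:
        raise ValidationError(f"quant file {quant_path} missing columns: {missing}")
    t2g = pd.read_csv(tx2gene_path, sep="\t", dtype=str)
    if list(t2g.columns[:2]) != ["transcript_id", "gene_id"]:
        raise ValidationError(
            f"mapping file {tx2gene_path} must have columns transcript_id, gene_id"
        )
    if quant["Name"].duplicated().any():
        dup = quant.loc[quant["Name"].duplicated(), "Name"].iloc[0]
        raise ValidationError(f"duplicate transcript {dup!r} in {quant_path}")
    mapping = t2g.set_index("transcript_id")["gene_id"]
    if mapping.index.has_duplicates:
        dup = mapping.index[mapping.index.duplicated()][0]
        raise ValidationError(f"transcript {dup!r} mapped to more than one gene")
    unmapped = quant.loc[~quant["Name"].isin(mapping.index), "Name"]
    if len(unmapped):
        raise ValidationError(f"transcript {unmapped.iloc[0]!r} has no gene mapping")
    if (quant["TPM"] < 0).any() or (quant["NumReads"] < 0).any():
        raise ValidationError(f"negative quantification value in {quant_path}")
    if (quant["EffectiveLength"] <= 0).any():
        raise ValidationError(f"non-positive effective length in {quant_path}")
    out = pd.DataFrame(
        {
            "transcript_id": quant["Name"].astype(str),
            "gene_id": quant["Name"].map(mapping).astype(str),
            "length": quant["Length"].astype(float),
            "effective_length": quant["EffectiveLength"].astype(float),
            "tpm": quant["TPM"].astype(float),
            "num_reads": quant["NumReads"].astype(float),
        }
    )
    out["sample_id"] = sample_id
    return out


def write_transcript_quant(quant: pd.DataFrame, quant_path, tx2gene_path=None) -> None:
    """Write one sample's quantifications in the quant.sf dialect."""
    out = pd.DataFrame(
        {
            "Name": quant["transcript_id"],
            "Length": quant["length"],
            "EffectiveLength": quant["effective_length"],
            "TPM": quant["tpm"],
            "NumReads": quant["num_reads"],
        }
    )
    out.to_csv(quant_path, sep="\t", index=False)
    if tx2gene_path is not None:
        quant[["transcript_id", "gene_id"]].drop_duplicates().to_csv(
            tx2gene_path, sep="\t", index=False
        )
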