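"""Readers, writers and validated containers for the pipeline's file formats.

All formats are plain text: phenotype TSV (one row per participant),
beta-value matrix TSV (probes × samples), Illumina-manifest-style
annotation CSV, results TSVs, DMR BED and a ground-truth JSON.
Annotation positions are 1-based (manifest convention); BED output is
0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MethylationData",
    "SchemaError",
    "read_phenotype",
    "read_beta_matrix",
    "read_annotation",
    "load_methylation",
    "write_phenotype",
    "write_methylation",
    "write_dmr_bed",
    "write_table",
    "write_metadata_sidecar",
]

PHENOTYPE_REQUIRED = ["sample_id", "age", "sex", "site"]
ANNOTATION_REQUIRED = ["probe_id", "chromosome", "position", "gene", "feature"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


class AlignmentError(ValueError):
    """Sample or probe identifiers disagree between files."""


@dataclass
class MethylationData:
    """Beta-value matrix plus probe annotation.

    ``beta`` is probes × samples with probe ids as index; ``annotation``
    is indexed by probe id with chromosome / position / gene / feature
    columns, sorted by (chromosome, position).
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(dtype=float)
        if np.isnan(b).any():
            raise SchemaError("beta matrix contains missing values")
        bad = np.argwhere((b < 0) | (b > 1))
        if bad.size:
            i, j = bad[0]
            raise SchemaError(
                f"beta value {b[i, j]} outside [0, 1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        if self.beta.index.duplicated().any():
            dup = self.beta.index[self.beta.index.duplicated()][:5].tolist()
            raise SchemaError(f"duplicated probe ids: {dup}")
        missing = set(self.beta.index) - set(self.annotation.index)
        if missing:
            raise AlignmentError(
                f"probes without annotation: {sorted(missing)[:10]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return len(self.beta)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def m_values(self, epsilon: float = 1e-6) -> np.ndarray:
        from .dmp import beta_to_mvalue

        return beta_to_mvalue(self.beta.to_numpy(dtype=float), epsilon)

    def sorted_by_position(self) -> "MethylationData":
        """Return a copy with probes ordered by (chromosome, position)."""
        ann = self.annotation.sort_values(["chromosome", "position"], kind="mergesort")
        present = set(self.beta.index)
        common = [p for p in ann.index if p in present]
        return MethylationData(beta=self.beta.loc[common], annotation=ann)


def read_phenotype(path) -> pd.DataFrame:
    """Read and validate the participant table (TSV, ``sample_id`` index)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"][:5].tolist()
        raise SchemaError(f"duplicated sample ids in {path}: {dup}")
    return df.set_index("sample_id")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read the probes × samples beta matrix (TSV, probe-id index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    return df


def read_annotation(path) -> pd.DataFrame:
    """Read the probe annotation CSV, sorted by (chromosome, position)."""
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation file {path} missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"][:5].tolist()
        raise SchemaError(f"duplicated probe ids in {path}: {dup}")
    return df.set_index("probe_id").sort_values(
        ["chromosome", "position"], kind="mergesort"
    )


def load_methylation(beta_path, annotation_path) -> MethylationData:
    """Load and cross-validate the beta matrix and its annotation."""
    return MethylationData(
        beta=read_beta_matrix(beta_path), annotation=read_annotation(annotation_path)
    ).sorted_by_position()


def check_sample_alignment(methylation: MethylationData, phenotype: pd.DataFrame):
    mism = sorted(set(methylation.sample_ids) ^ set(phenotype.index))
    if mism:
        raise AlignmentError(
            f"sample ids differ between beta matrix and phenotype: {mism[:10]}"
        )


def write_phenotype(phenotype: pd.DataFrame, path) -> None:
    phenotype.to_csv(path, sep="\t", index_label="sample_id")


def write_methylation(data: MethylationData, beta_path, annotation_path) -> None:
    data.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    data.annotation.to_csv(annotation_path, index_label="probe_id")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_dmr_bed(dmrs, path) -> None:
    """Write regions as BED6: 0-based half-open, score = ⌊1000·(1−FWER)⌋.

    ``dmrs`` is an iterable of DMRResult (or any object with chromosome,
    start, end, fwer and gene attributes).  An empty list yields a
    header-only file.
    """
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    for d in dmrs:
        fwer = d.fwer if d.fwer is not None else 1.0
        score = int(np.floor(1000 * (1 - fwer)))
        gene = getattr(d, "gene", None) or "NA"
        lines.append(f"{d.chromosome}\t{d.start - 1}\t{d.end}\t{gene}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata_sidecar(path, seed, config: dict | None = None, **extra) -> None:
    """Record version, seed and a config hash next to an output file."""
    from . import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        **extra,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
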