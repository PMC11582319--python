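"""In-memory containers for count matrices and sample sheets, plus disk I/O.

Counts travel as MatrixMarket files with TSV sidecars for feature/sample
identifiers; sample annotations travel as a plain CSV.  The oncRNA matrix is
kept sparse (CSR) because any individual oncRNA is observed in only a few
samples; the endogenous matrix is small and dense.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "OncCountMatrix",
    "EndogenousCountMatrix",
    "SampleAnnotations",
    "write_counts",
    "read_counts",
]

#: columns every sample sheet must carry
ANNOTATION_COLUMNS = (
    "sample_id",
    "patient_id",
    "label",
    "supplier",
    "experiment_id",
    "replicate_group",
)


@dataclass
class OncCountMatrix:
    """Sparse non-negative integer counts of oncRNAs, samples x features."""

    values: sp.csr_matrix
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = np.asarray(self.feature_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("shape does not match sample/feature identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense(), dtype=np.float64)

    def subset_samples(self, idx) -> "OncCountMatrix":
        return OncCountMatrix(self.values[idx], self.feature_ids, self.sample_ids[idx])

    def subset_features(self, idx) -> "OncCountMatrix":
        return OncCountMatrix(self.values[:, idx], self.feature_ids[idx], self.sample_ids)


@dataclass
class EndogenousCountMatrix:
    """Dense counts of annotated highly-expressed smRNAs (library-depth proxy)."""

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_ids = np.asarray(self.feature_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("shape does not match sample/feature identifiers")
        if self.values.min() < 0:
            raise ValueError("counts must be non-negative")
        if np.any(self.values.sum(axis=1) <= 0):
            raise ValueError(
                "every sample needs a positive endogenous read total; "
                "log library size is undefined otherwise"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def subset_samples(self, idx) -> "EndogenousCountMatrix":
        return EndogenousCountMatrix(
            self.values[idx], self.feature_ids, self.sample_ids[idx]
        )


@dataclass
class SampleAnnotations:
    """Sample sheet: labels, confounders, patient and replicate structure."""

    df: pd.DataFrame
    confounders: tuple[str, ...] = ("supplier", "experiment_id")

    def __post_init__(self):
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        for c in self.confounders:
            if c not in self.df.columns:
                raise ValueError(f"confounder column '{c}' missing from sample sheet")
            if self.df[c].isna().any():
                raise ValueError(f"confounder column '{c}' has missing values")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=np.int64)

    @property
    def suppliers(self) -> np.ndarray:
        return self.df["supplier"].to_numpy()

    @property
    def patient_ids(self) -> np.ndarray:
        return self.df["patient_id"].to_numpy()

    def confounder_codes(self) -> np.ndarray:
        """Integer-coded confounder matrix, samples x c."""
        cols = [pd.factorize(self.df[c])[0] for c in self.confounders]
        return np.stack(cols, axis=1)

    def subset(self, idx) -> "SampleAnnotations":
        return SampleAnnotations(
            self.df.iloc[np.asarray(idx)].reset_index(drop=True), self.confounders
        )


# ------------------------------------------------------------------------- I/O
def write_counts(out_dir: str, x: OncCountMatrix, r: EndogenousCountMatrix,
                 annotations: SampleAnnotations) -> None:
    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "x.mtx"), sp.coo_matrix(x.values))
    mmwrite(os.path.join(out_dir, "r.mtx"), sp.coo_matrix(r.values))
    pd.Series(x.feature_ids).to_csv(
        os.path.join(out_dir, "x_features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(r.feature_ids).to_csv(
        os.path.join(out_dir, "r_features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(x.sample_ids).to_csv(
        os.path.join(out_dir, "samples.tsv"), sep="\t", index=False, header=False
    )
    annotations.df.to_csv(os.path.join(out_dir, "samples.csv"), index=False)


def read_counts(in_dir: str, confounders=("supplier", "experiment_id")):
    x_vals = sp.csr_matrix(mmread(os.path.join(in_dir, "x.mtx")))
    r_vals = np.asarray(mmread(os.path.join(in_dir, "r.mtx")).todense())
    x_feats = pd.read_csv(
        os.path.join(in_dir, "x_features.tsv"), sep="\t", header=None
    )[0].to_numpy()
    r_feats = pd.read_csv(
        os.path.join(in_dir, "r_features.tsv"), sep="\t", header=None
    )[0].to_numpy()
    samples = pd.read_csv(
        os.path.join(in_dir, "samples.tsv"), sep="\t", header=None
    )[0].to_numpy()
    ann = SampleAnnotations(
        pd.read_csv(os.path.join(in_dir, "samples.csv")), tuple(confounders)
    )
    x = OncCountMatrix(x_vals, x_feats, samples)
    r = EndogenousCountMatrix(r_vals, r_feats, samples)
    return x, r, ann
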