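"""Beta-value data model, I/O, splitting and feature selection.

The central container is :class:`MethylationArray`: a samples x CpGs matrix
of beta values (fraction of methylated copies at a locus, in [0, 1]) plus a
phenotype table aligned row-for-row on sample id.  Everything downstream —
embedding, prediction, interpretation — consumes and produces this type.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    JoinError,
    StratificationError,
    ValidationError,
)

CONTAINER_FORMAT_VERSION = "1"


def _as_str_index(values) -> pd.Index:
    return pd.Index([str(v) for v in values])


@dataclass
class MethylationArray:
    """Beta matrix plus aligned phenotype table.

    Parameters
    ----------
    beta : pandas.DataFrame
        Samples x CpGs matrix; index = sample ids, columns = CpG ids.
        Every entry must be finite and in [0, 1].
    pheno : pandas.DataFrame
        Phenotype table indexed by sample id; reordered to beta row order
        on construction.
    """

    beta: pd.DataFrame
    pheno: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.beta = self.beta.copy()
        self.beta.index = _as_str_index(self.beta.index)
        self.beta.columns = _as_str_index(self.beta.columns)
        pheno = self.pheno.copy()
        pheno.index = _as_str_index(pheno.index)

        if self.beta.index.has_duplicates:
            dup = self.beta.index[self.beta.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if self.beta.columns.has_duplicates:
            dup = self.beta.columns[self.beta.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate CpG ids: {dup}")

        missing_in_pheno = set(self.beta.index) - set(pheno.index)
        missing_in_beta = set(pheno.index) - set(self.beta.index)
        if missing_in_pheno or missing_in_beta:
            raise JoinError(missing_in_pheno, missing_in_beta)
        # align pheno rows to beta row order
        self.pheno = pheno.loc[self.beta.index]

        if self.validate:
            values = self.beta.to_numpy(dtype=float)
            bad = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"beta value {values[i, j]!r} out of [0, 1] at "
                    f"(sample {self.beta.index[i]!r}, cpg {self.beta.columns[j]!r})"
                )

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Beta matrix as a float64 ndarray (copy)."""
        return self.beta.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "MethylationArray":
        sample_ids = [str(s) for s in sample_ids]
        return MethylationArray(
            self.beta.loc[sample_ids], self.pheno.loc[sample_ids], validate=False
        )

    def subset_cpgs(self, cpg_ids) -> "MethylationArray":
        cpg_ids = [str(c) for c in cpg_ids]
        return MethylationArray(self.beta[cpg_ids], self.pheno, validate=False)

    def equals(self, other: "MethylationArray", tol: float = 1e-12) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.cpg_ids == other.cpg_ids
            and np.allclose(self.values, other.values, atol=tol, rtol=0.0)
            and self.pheno.equals(other.pheno)
        )


@dataclass
class SplitResult:
    """Disjoint train/test/val partition of a MethylationArray."""

    train: MethylationArray
    test: MethylationArray
    val: MethylationArray
    fractions: tuple[float, float, float]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def load_methylation_array(beta_source, pheno_source) -> MethylationArray:
    """Load beta matrix + phenotype table from delimited text.

    Beta: header row of CpG ids, first column sample ids, '.' decimal.
    Pheno: first column sample ids.  Sample-id sets must match exactly.
    """
    beta = _read_table(beta_source)
    pheno = _read_table(pheno_source)
    return MethylationArray(beta, pheno)


def save_methylation_array(arr: MethylationArray, dest, format: str = "csv"):
    """Persist an array; round-trip restores beta within 1e-12.

    format="csv": writes ``<dest>/beta.csv`` and ``<dest>/pheno.csv``.
    format="container": single HDF5 file at ``dest`` (float64 beta, string
    id arrays, pheno serialised column-wise, attribute "format_version").
    """
    dest = str(dest)
    if format == "csv":
        os.makedirs(dest, exist_ok=True)
        arr.beta.to_csv(os.path.join(dest, "beta.csv"))
        arr.pheno.to_csv(os.path.join(dest, "pheno.csv"))
        return dest
    if format == "container":
        with h5py.File(dest, "w") as f:
            f.attrs["format_version"] = CONTAINER_FORMAT_VERSION
            f.create_dataset("beta", data=arr.values)
            str_dt = h5py.string_dtype(encoding="utf-8")
            f.create_dataset("sample_ids", data=np.array(arr.sample_ids, dtype=object), dtype=str_dt)
            f.create_dataset("cpg_ids", data=np.array(arr.cpg_ids, dtype=object), dtype=str_dt)
            pg = f.create_group("pheno")
            pg.attrs["columns"] = [str(c) for c in arr.pheno.columns]
            for col in arr.pheno.columns:
                series = arr.pheno[col]
                if pd.api.types.is_numeric_dtype(series):
                    pg.create_dataset(str(col), data=series.to_numpy())
                else:
                    pg.create_dataset(
                        str(col),
                        data=np.array([str(v) for v in series], dtype=object),
                        dtype=str_dt,
                    )
        return dest
    raise ConfigError(f"unknown format {format!r}; use 'csv' or 'container'")


def load_container(path) -> MethylationArray:
    """Load a MethylationArray from the single-file HDF5 container."""
    with h5py.File(path, "r") as f:
        beta = np.asarray(f["beta"], dtype=float)
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"]]
        cpg_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["cpg_ids"]]
        cols = list(f["pheno"].attrs["columns"])
        pheno = {}
        for col in cols:
            data = f["pheno"][col][()]
            if data.dtype.kind in ("O", "S"):
                data = [v.decode() if isinstance(v, bytes) else str(v) for v in data]
            pheno[col] = data
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=cpg_ids)
    pheno_df = pd.DataFrame(pheno, index=sample_ids)
    return MethylationArray(beta_df, pheno_df)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _split_counts(n: int, test_frac: float, val_frac: float) -> tuple[int, int, int]:
    """Two-stage ceiling convention: test carved first, then val from remainder."""
    n_test = math.ceil(test_frac * n)
    n_val = math.ceil(val_frac / (1.0 - test_frac) * (n - n_test))
    n_train = n - n_test - n_val
    return n_train, n_test, n_val


def train_test_val_split(
    arr: MethylationArray,
    train_frac: float = 0.7,
    test_frac: float = 0.2,
    val_frac: float = 0.1,
    stratify_col: str | None = None,
    seed: int = 42,
) -> SplitResult:
    """Partition samples into train/test/val.

    Sizes follow a two-stage ceiling convention: the test set is carved out
    first with ``ceil(test_frac * n)`` samples, then the validation set takes
    ``ceil(val_frac / (1 - test_frac) * remainder)`` of what is left.  On 719
    samples at 70/20/10 this yields 503 train / 144 test / 72 val.

    With ``stratify_col`` the convention is applied within each stratum
    (every stratum needs >= 3 samples).
    """
    fracs = (train_frac, test_frac, val_frac)
    if any(f <= 0 for f in fracs):
        raise ConfigError(f"fractions must be positive, got {fracs}")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fracs} (sum {sum(fracs)})")

    rng = np.random.default_rng(seed)
    ids = np.array(arr.sample_ids, dtype=object)

    def partition(indices: np.ndarray):
        perm = indices[rng.permutation(len(indices))]
        _, n_test, n_val = _split_counts(len(indices), test_frac, val_frac)
        return perm[n_test + n_val:], perm[:n_test], perm[n_test:n_test + n_val]

    if stratify_col is None:
        tr, te, va = partition(np.arange(arr.n_samples))
    else:
        if stratify_col not in arr.pheno.columns:
            raise ConfigError(f"stratify column {stratify_col!r} not in pheno")
        tr_parts, te_parts, va_parts = [], [], []
        labels = arr.pheno[stratify_col]
        for stratum in labels.unique():
            idx = np.flatnonzero((labels == stratum).to_numpy())
            if len(idx) < 3:
                raise StratificationError(
                    f"stratum {stratum!r} has {len(idx)} samples (< 3)"
                )
            t, s, v = partition(idx)
            tr_parts.append(t)
            te_parts.append(s)
            va_parts.append(v)
        tr = np.concatenate(tr_parts)
        te = np.concatenate(te_parts)
        va = np.concatenate(va_parts)

    return SplitResult(
        train=arr.subset_samples(ids[np.sort(tr)]),
        test=arr.subset_samples(ids[np.sort(te)]),
        val=arr.subset_samples(ids[np.sort(va)]),
        fractions=fracs,
    )


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_top_mad(arr: MethylationArray, k: int, stat: str = "mean") -> MethylationArray:
    """Keep the k most dispersed CpGs.

    Dispersion is the mean absolute deviation about the per-CpG mean
    (``stat="mean"``, default) or the median absolute deviation about the
    median (``stat="median"``).  Ties are broken by input CpG order; the
    selected CpGs keep their original relative order.
    """
    if not 1 <= k <= arr.n_cpgs:
        raise ConfigError(f"k={k} out of range [1, {arr.n_cpgs}]")
    x = arr.values
    if stat == "mean":
        dev = np.abs(x - x.mean(axis=0)).mean(axis=0)
    elif stat == "median":
        dev = np.median(np.abs(x - np.median(x, axis=0)), axis=0)
    else:
        raise ConfigError(f"stat must be 'mean' or 'median', got {stat!r}")
    # stable sort on -dev keeps input order among ties
    order = np.argsort(-dev, kind="stable")[:k]
    keep = np.sort(order)  # preserve original CpG order
    return arr.subset_cpgs([arr.cpg_ids[i] for i in keep])
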