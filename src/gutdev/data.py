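"""Core data containers, readers/writers, and normalisation primitives.

The central object is :class:`AbundanceTable`, a thin wrapper around a
samples x features :class:`pandas.DataFrame` of non-negative values that
also tracks what the numbers mean (raw ``counts``, ``relative``
abundances, or ``css``-normalised counts).  Sample metadata, SCFA
concentration profiles and distance matrices are plain DataFrames with a
few validation helpers, which keeps everything interoperable with the
wider pandas ecosystem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "AGE_BINS",
    "GROUPS",
    "SCFA_NAMES",
    "age_bin_of",
    "validate_metadata",
    "validate_scfa",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "to_relative",
    "filter_features",
    "css_normalize",
]

#: Chronological age bins (months).  Boundary months belong to the bin
#: whose printed range contains them (closed ranges).
AGE_BINS = ("m6", "m7_12", "m13_24", "m25_36")

#: Phenotype groups: healthy reference, mild and moderate-to-severe
#: atopic dermatitis.
GROUPS = ("nonAD", "mildAD", "modsevAD")

#: The six short-chain fatty acids quantified per sample (umol / g feces).
SCFA_NAMES = (
    "acetate",
    "propionate",
    "butyrate",
    "iso-butyrate",
    "valerate",
    "iso-valerate",
)

Kind = Literal["counts", "relative", "css"]

_REL_TOL = 1e-9


def age_bin_of(age_months: float) -> str:
    """Map an age in months onto one of the four study age bins."""
    if age_months < 6 or age_months > 36:
        raise ValueError(f"age {age_months} months outside the 6-36 month range")
    if age_months <= 6:
        return "m6"
    if age_months <= 12:
        return "m7_12"
    if age_months <= 24:
        return "m13_24"
    return "m25_36"


@dataclass
class AbundanceTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and feature ids (taxa or gene
        families) as columns; entries must be non-negative.
    kind
        ``"counts"`` for raw counts, ``"relative"`` for rows summing to
        one, ``"css"`` for cumulative-sum-scaled counts.
    """

    values: pd.DataFrame
    kind: Kind = "counts"

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            v = pd.DataFrame(v)
            self.values = v
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        if arr.size and np.min(arr) < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at sample {v.index[i]!r}, feature {v.columns[j]!r}"
            )
        if self.kind == "relative" and arr.size:
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-6
            if bad.any():
                raise ValueError(
                    f"relative table rows must sum to 1; sample {v.index[int(np.argmax(bad))]!r} "
                    f"sums to {sums[bad][0]:.6g}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(ids)], kind=self.kind)

    def subset_features(self, ids: Iterable[str]) -> "AbundanceTable":
        # subsetting features breaks the rows-sum-to-one invariant, so a
        # relative table degrades to plain non-negative values ("counts")
        out = AbundanceTable(self.values.loc[:, list(ids)], kind="counts")
        out.kind = self.kind if self.kind != "relative" else "counts"
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_kind(arr: np.ndarray) -> Kind:
    if arr.size == 0:
        return "counts"
    if np.allclose(arr, np.round(arr)):
        return "counts"
    sums = arr.sum(axis=1)
    if np.allclose(sums, 1.0, atol=1e-4):
        return "relative"
    return "counts"


def read_abundance_table(
    path: str | Path, fmt: str = "tsv", transpose: bool = False
) -> AbundanceTable:
    """Read a features-in-rows TSV (or BIOM 2.x HDF5) abundance table.

    The TSV dialect is the dominant microbiome convention: features as
    rows, samples as columns, first column the feature id;
    ``transpose=True`` accepts samples-in-rows files instead.  ``kind``
    is inferred: integer-valued tables are counts, tables whose sample
    rows sum to ~1 are relative abundances.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "biom":
        return _read_biom(path)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.isna().any().any():
        raise ValueError(f"ragged or non-numeric rows in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # features are rows on disk; in memory we keep samples x features
    values = df if transpose else df.T
    arr = values.to_numpy(dtype=float)
    table = AbundanceTable(values, kind="counts")
    table.kind = _infer_kind(arr)
    if table.kind == "relative":
        # renormalise away file rounding, then re-validate
        table = AbundanceTable(values.div(values.sum(axis=1), axis=0), kind="relative")
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write features-in-rows TSV with full float precision."""
    df = table.values.T
    df.index.name = "feature_id"
    df.to_csv(Path(path), sep="\t", float_format="%.17g")


def _read_biom(path: Path) -> AbundanceTable:
    """Minimal BIOM 2.x (HDF5, CSR-by-observation) reader."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() for x in f["observation/ids"][:]]
        samp_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    mat = sparse.csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(samp_ids)))
    values = pd.DataFrame(mat.toarray().T, index=samp_ids, columns=obs_ids)
    table = AbundanceTable(values, kind="counts")
    table.kind = _infer_kind(values.to_numpy(dtype=float))
    return table


_META_COLS = ["sample_id", "subject_id", "age_months", "group", "age_bin"]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and complete a per-sample metadata table.

    Requires ``sample_id``, ``subject_id``, ``age_months`` and ``group``
    columns; recomputes ``age_bin`` deterministically from age.  Any
    further columns are treated as covariates.
    """
    meta = meta.copy()
    for col in ("sample_id", "subject_id", "age_months", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    bad = ~meta["group"].isin(GROUPS)
    if bad.any():
        raise ValueError(f"unknown group label {meta.loc[bad, 'group'].iloc[0]!r}")
    meta["age_bin"] = meta["age_months"].map(age_bin_of)
    return meta.set_index("sample_id", drop=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(Path(path), sep="\t"))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = _META_COLS + [c for c in meta.columns if c not in _META_COLS]
    meta.loc[:, cols].to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def validate_scfa(scfa: pd.DataFrame) -> pd.DataFrame:
    """Validate an SCFA concentration table (samples x six metabolites)."""
    unknown = [c for c in scfa.columns if c not in SCFA_NAMES]
    if unknown:
        raise ValueError(f"unknown metabolite column(s): {unknown}")
    if (scfa.to_numpy(dtype=float) < 0).any():
        raise ValueError("SCFA concentrations must be non-negative")
    return scfa


# ---------------------------------------------------------------------------
# normalisation / filtering
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample's row by its total; ``kind`` becomes relative."""
    if table.kind == "relative":
        raise ValueError("table is already relative; to_relative expects counts")
    sums = table.values.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total abundance")
    return AbundanceTable(table.values.div(sums, axis=0), kind="relative")


def _as_relative(table: AbundanceTable) -> AbundanceTable:
    return table if table.kind == "relative" else to_relative(table)


def filter_features(
    table: AbundanceTable,
    groups: pd.Series | None = None,
    min_prevalence: float = 0.10,
    min_mean_rel: float = 0.0001,
) -> AbundanceTable:
    """Prevalence / mean-abundance feature filter.

    Keeps features exceeding ``min_prevalence`` (fraction of samples
    with a strictly positive entry) *and* ``min_mean_rel`` (mean
    relative abundance) in at least one group.  Defaults are the
    standard >10 % prevalence and >0.01 % mean relative abundance
    thresholds used ahead of indicator-species analysis.  With no
    ``groups`` the whole cohort is a single group.
    """
    rel = _as_relative(table)
    if groups is None:
        groups = pd.Series("all", index=rel.values.index)
    else:
        groups = groups.reindex(rel.values.index)
        if groups.isna().any():
            missing = groups.index[groups.isna()][0]
            raise ValueError(f"sample {missing!r} has no group label")
    keep = np.zeros(rel.shape[1], dtype=bool)
    for _, idx in groups.groupby(groups).groups.items():
        sub = rel.values.loc[idx]
        prevalence = (sub > 0).mean(axis=0).to_numpy()
        mean_rel = sub.mean(axis=0).to_numpy()
        keep |= (prevalence > min_prevalence) & (mean_rel > min_mean_rel)
    if not keep.any():
        warnings.warn("no features survive the prevalence/abundance filter")
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    out = AbundanceTable(table.values.loc[:, kept], kind="counts")
    out.kind = table.kind
    return out


def css_normalize(
    table: AbundanceTable, quantile: float = 0.5, scale: float = 1000.0
) -> AbundanceTable:
    """Cumulative sum scaling of a count table.

    For each sample the scaling factor is the sum of its counts that lie
    at or below the ``quantile``-th quantile of its *non-zero* counts;
    entries are divided by the factor and multiplied by ``scale``.  The
    quantile is fixed (default median) rather than chosen adaptively.
    """
    if table.kind != "counts":
        raise ValueError("css_normalize expects a count table")
    arr = table.matrix()
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        row = arr[i]
        nz = row[row > 0]
        if nz.size == 0:
            raise ValueError(f"sample {table.sample_ids[i]!r} is all zero")
        q = np.quantile(nz, quantile)
        factor = row[row <= q].sum()
        if factor <= 0:
            raise ValueError(
                f"CSS scaling factor is zero for sample {table.sample_ids[i]!r}"
            )
        out[i] = row / factor * scale
    result = AbundanceTable(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        kind="counts",
    )
    result.kind = "css"
    return result
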