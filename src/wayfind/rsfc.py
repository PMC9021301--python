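"""Resting-state connectivity features: the network-by-network matrix
and its flattening into a regression design.

ROI-level Pearson correlations are reduced to a symmetric
network-by-network matrix (default 13 networks) by Fisher-z averaging
of all ROI pairs spanning each pair of networks, with self-pairs
excluded on the diagonal blocks. The upper triangle (including the
diagonal) of that matrix — 91 cells for 13 networks — plus driver age
forms the 92-column feature row used by the stability-selection engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Default network labels. Illustrative of a 13-network cortical +
#: subcortical parcellation; the label set is fully configurable.
DEFAULT_NETWORKS: tuple[str, ...] = (
    "VIS", "SMN", "AUD", "CO", "SAL", "VAN", "DAN", "FP", "DMN",
    "SubCort", "MTL", "Reward", "Unassigned",
)

AGE_FEATURE = "age"


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric network-by-network connectivity on the correlation scale.

    Diagonal entries are *intra*-network averages — they are not forced
    to 1. Entries may be NaN where a block is undefined (single-ROI
    network diagonal)."""

    networks: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "networks", tuple(self.networks))
        k = len(self.networks)
        if v.shape != (k, k):
            raise ValueError(f"values shape {v.shape} != ({k}, {k})")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("correlation-scale entries must lie in [-1, 1]")

    def cell(self, a: str, b: str) -> float:
        i, j = self.networks.index(a), self.networks.index(b)
        return float(self.values[i, j])


def roi_connectivity(timeseries: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of ROI time series.

    ``timeseries``: rows are timepoints, columns are ROI ids. ROIs with
    zero variance are dropped with a warning. Returns a symmetric,
    unit-diagonal ROI-by-ROI DataFrame.
    """
    if timeseries.shape[1] < 2:
        raise ValueError("need >= 2 ROIs")
    if timeseries.shape[0] < 3:
        raise ValueError("need >= 3 timepoints")
    sd = timeseries.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        warnings.warn(f"excluding zero-variance ROIs: {dead}", stacklevel=2)
        timeseries = timeseries.drop(columns=dead)
        if timeseries.shape[1] < 2:
            raise ValueError("fewer than 2 ROIs with nonzero variance")
    corr = np.corrcoef(timeseries.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=timeseries.columns, columns=timeseries.columns)


def network_reduce(
    roi_corr: pd.DataFrame,
    assignment: Mapping[str, str],
    networks: Sequence[str] = DEFAULT_NETWORKS,
) -> ConnectivityMatrix:
    """Reduce an ROI-pair correlation matrix to network blocks.

    Block (i, j) is the inverse-Fisher transform of the mean Fisher z of
    every ROI pair spanning networks i and j; ROI self-pairs are
    excluded on diagonal blocks. A network containing a single ROI has
    an undefined diagonal block (NaN, flagged with a warning). Every ROI
    in ``roi_corr`` must be assigned; every listed network must contain
    at least one ROI.
    """
    rois = list(roi_corr.index)
    missing = [r for r in rois if r not in assignment]
    if missing:
        raise ValueError(f"unassigned ROIs: {missing}")
    networks = tuple(networks)
    members = {net: [r for r in rois if assignment[r] == net] for net in networks}
    empty = [net for net, m in members.items() if not m]
    if empty:
        raise ValueError(f"networks with no ROIs: {empty}")

    C = roi_corr.to_numpy(dtype=float)
    # clip |r|=1 (e.g. duplicated ROIs) so atanh stays finite
    z = np.arctanh(np.clip(C, -1.0 + 1e-12, 1.0 - 1e-12))
    pos = {r: k for k, r in enumerate(rois)}
    k = len(networks)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            ri = [pos[r] for r in members[networks[i]]]
            rj = [pos[r] for r in members[networks[j]]]
            block = z[np.ix_(ri, rj)]
            if i == j:
                n = len(ri)
                if n < 2:
                    warnings.warn(
                        f"network {networks[i]!r} has a single ROI; "
                        "intra-network value undefined",
                        stacklevel=2,
                    )
                    continue
                vals = block[np.triu_indices(n, k=1)]
            else:
                vals = block.ravel()
            out[i, j] = out[j, i] = float(np.tanh(np.mean(vals)))
    return ConnectivityMatrix(networks, out)


def feature_names(networks: Sequence[str] = DEFAULT_NETWORKS) -> list[str]:
    """Canonical connectivity feature names: row-major upper triangle
    including the diagonal, ``NETixNETj`` with i <= j in network order."""
    networks = tuple(networks)
    return [
        f"{networks[i]}x{networks[j]}"
        for i in range(len(networks))
        for j in range(i, len(networks))
    ]


def cell_feature_name(a: str, b: str, networks: Sequence[str] = DEFAULT_NETWORKS) -> str:
    """Feature name of the (a, b) network cell in canonical order."""
    networks = tuple(networks)
    i, j = networks.index(a), networks.index(b)
    if i > j:
        i, j = j, i
    return f"{networks[i]}x{networks[j]}"


def vectorize(cm: ConnectivityMatrix, age: float) -> pd.Series:
    """Flatten a connectivity matrix plus age into one feature row.

    Row-major upper triangle including the diagonal (k(k+1)/2 values;
    91 for 13 networks) followed by ``age`` — 92 features total.
    """
    k = len(cm.networks)
    iu = np.triu_indices(k)
    vals = cm.values[iu]
    names = feature_names(cm.networks) + [AGE_FEATURE]
    return pd.Series(np.append(vals, float(age)), index=names)


def unvectorize(
    row: pd.Series | np.ndarray, networks: Sequence[str] = DEFAULT_NETWORKS
) -> tuple[ConnectivityMatrix, float | None]:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix (and
    the age value, if present)."""
    networks = tuple(networks)
    k = len(networks)
    m = k * (k + 1) // 2
    if isinstance(row, pd.Series):
        vals = row.reindex(feature_names(networks)).to_numpy(dtype=float)
        age = float(row[AGE_FEATURE]) if AGE_FEATURE in row.index else None
    else:
        arr = np.asarray(row, dtype=float)
        if arr.size not in (m, m + 1):
            raise ValueError(f"expected {m} or {m + 1} values, got {arr.size}")
        vals = arr[:m]
        age = float(arr[m]) if arr.size == m + 1 else None
    out = np.empty((k, k))
    iu = np.triu_indices(k)
    out[iu] = vals
    out[(iu[1], iu[0])] = vals
    return ConnectivityMatrix(networks, out), age


def build_feature_table(
    matrices: Mapping[str, ConnectivityMatrix],
    ages: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Drivers-by-features design matrix: one :func:`vectorize` row per
    driver (inner join of connectivity and age on driver id)."""
    common = [d for d in matrices if d in ages]
    if not common:
        raise ValueError("no drivers present in both connectivity and age inputs")
    rows = {d: vectorize(matrices[d], float(ages[d])) for d in common}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "driver_id"
    if df.isna().any().any():
        raise ValueError("feature table contains missing cells")
    return df


# --- I/O -------------------------------------------------------------------

def save_connectivity_csv(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(cm.values, index=cm.networks, columns=cm.networks).to_csv(path)


def load_connectivity_csv(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("connectivity CSV must have matching row/column labels")
    return ConnectivityMatrix(tuple(df.index), df.to_numpy(dtype=float))
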