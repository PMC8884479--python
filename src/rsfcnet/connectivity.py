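"""Subject-level connectivity and the three feature families.

From a cleaned T x N ROI time-series matrix the pipeline derives

* the N x N Pearson correlation matrix r,
* its Fisher-z transform z = atanh(r) (variance-stabilising, used for the
  network- and edge-level group statistics),
* an exponentially converted matrix c(r) = exp(r - 1) whose off-diagonal row
  means give the nodal connectivity degree eta (the "integrity" of a node:
  its average connectivity to the rest of the brain),

and aggregates them into three feature families per subject: 90 integrity
values, 8 intra- + 28 inter-network means, and the 4005 upper-triangle edges.

The exponential conversion is pluggable (``conversion=``): the default
``exp_shift`` maps r in [-1, 1] monotonically onto (e^-2, 1] with c(1) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation, network_blocks
from .preprocess import SubjectTimeSeries

__all__ = [
    "ConnectivityMatrix", "ZMatrix", "correlation_matrix", "fisher_z",
    "exponential_conversion", "nodal_integrity", "network_fc",
    "edge_features", "edge_names", "build_feature_tables", "CONVERSIONS",
]

log = logging.getLogger(__name__)

#: Named, strictly increasing conversions r -> nodal-degree contribution.
CONVERSIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "exp_shift": lambda r: np.exp(r - 1.0),
}


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N Pearson correlation matrix for one subject."""

    subject_id: str
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {r.shape}")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal must be 1")
        off = r[~np.eye(r.shape[0], dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-12).any():
            raise ValueError("correlations outside [-1, 1]")
        object.__setattr__(self, "r", r)

    @property
    def n(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class ZMatrix:
    """Fisher-z transformed correlations; diagonal stored as 0 by convention."""

    subject_id: str
    z: np.ndarray
    clip_r: float

    @property
    def n(self) -> int:
        return self.z.shape[0]


def correlation_matrix(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI columns."""
    if ts.stage != "cleaned":
        raise ValueError(
            f"correlation requires a cleaned series, got stage '{ts.stage}'")
    if ts.n_timepoints < 3:
        raise ValueError("correlation needs T >= 3")
    if ts.bad_rois:
        raise ValueError(
            f"zero-variance ROI columns {list(ts.bad_rois)}; drop or flag "
            "them before computing correlations")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, r=r)


def fisher_z(cm: ConnectivityMatrix, clip_r: float = 0.999999) -> ZMatrix:
    """z = atanh(r) off-diagonal, with |r| clipped so the transform is finite."""
    z = np.arctanh(np.clip(cm.r, -clip_r, clip_r))
    np.fill_diagonal(z, 0.0)
    return ZMatrix(subject_id=cm.subject_id, z=z, clip_r=clip_r)


def exponential_conversion(cm: ConnectivityMatrix,
                           conversion: str = "exp_shift") -> np.ndarray:
    """Apply the named strictly increasing conversion off-diagonal.

    Returns an N x N matrix with the diagonal set to 0 (excluded from all
    aggregates).  The default maps r = 1 -> 1 and r = -1 -> e^-2.
    """
    try:
        fn = CONVERSIONS[conversion]
    except KeyError:
        raise ValueError(
            f"unknown conversion '{conversion}'; known: {sorted(CONVERSIONS)}")
    c = fn(cm.r)
    np.fill_diagonal(c, 0.0)
    return c


def nodal_integrity(converted: np.ndarray) -> np.ndarray:
    """eta_i = mean over j != i of the converted connectivity c(r_ij)."""
    c = np.asarray(converted, dtype=float)
    n = c.shape[0]
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValueError("converted matrix must be symmetric")
    return (c.sum(axis=1) - np.diag(c)) / (n - 1)


def network_fc(zm: ZMatrix, parc: AtlasParcellation) -> pd.Series:
    """Intra- and inter-network means of the transformed correlations.

    intra(A) is the mean over unordered ROI pairs within network A; a
    singleton network has no pairs and yields NaN (flagged missing, never 0).
    inter(A, B) is the mean over all pairs with one node in each network.
    Index order is the canonical network order, intra block first.
    """
    if parc.n_nodes != zm.n:
        raise ValueError(
            f"parcellation has {parc.n_nodes} nodes, matrix is {zm.n}x{zm.n}")
    blocks, pairs = network_blocks(parc)
    idx = {net: nodes - 1 for net, nodes in blocks.items()}  # 0-based
    out: dict[str, float] = {}
    for net, ii in idx.items():
        if len(ii) < 2:
            log.warning("network %s has a single node; intra FC is missing", net)
            out[f"intra_{net}"] = np.nan
            continue
        sub = zm.z[np.ix_(ii, ii)]
        m = len(ii)
        out[f"intra_{net}"] = sub[np.triu_indices(m, k=1)].mean()
    for a, b in pairs:
        out[f"inter_{a}_{b}"] = zm.z[np.ix_(idx[a], idx[b])].mean()
    return pd.Series(out)


def edge_names(n: int) -> list[str]:
    """Upper-triangle feature names ``i_j`` (1-based node ids, i < j)."""
    iu, ju = np.triu_indices(n, k=1)
    return [f"{i + 1}_{j + 1}" for i, j in zip(iu, ju)]


def edge_features(zm: ZMatrix) -> pd.Series:
    """Flatten the upper triangle (i < j, row-major) into N(N-1)/2 features."""
    iu, ju = np.triu_indices(zm.n, k=1)
    return pd.Series(zm.z[iu, ju], index=edge_names(zm.n))


def build_feature_tables(subjects: Sequence[SubjectTimeSeries],
                         parc: AtlasParcellation, *,
                         conversion: str = "exp_shift",
                         clip_r: float = 0.999999,
                         ) -> dict[str, pd.DataFrame]:
    """Per-subject feature tables at the three analysis levels.

    Returns ``{"integrity": n_subj x N, "network": n_subj x (K intra + pairs),
    "edge": n_subj x N(N-1)/2}`` DataFrames indexed by subject id, with
    deterministic column order.  Subjects with flagged zero-variance ROIs get
    NaN in every feature that depends on an affected node, and the affected
    features are logged.
    """
    if not subjects:
        raise ValueError("no subjects supplied")
    n = parc.n_nodes
    integrity_rows, network_rows, edge_rows, sids = [], [], [], []
    for ts in subjects:
        if ts.n_rois != n:
            raise ValueError(
                f"subject {ts.subject_id}: {ts.n_rois} ROIs != parcellation "
                f"size {n}")
        sids.append(ts.subject_id)
        if ts.bad_rois:
            log.warning(
                "subject %s: zero-variance ROIs %s; dependent features "
                "marked missing", ts.subject_id, list(ts.bad_rois))
            good = np.setdiff1d(np.arange(n), np.array(ts.bad_rois))
            from dataclasses import replace as _rep
            sub = _rep(ts, data=ts.data[:, good], bad_rois=())
            cm_good = correlation_matrix(sub)
            r = np.full((n, n), np.nan)
            np.fill_diagonal(r, 1.0)
            r[np.ix_(good, good)] = cm_good.r
            z = np.full((n, n), np.nan)
            np.fill_diagonal(z, 0.0)
            z[np.ix_(good, good)] = fisher_z(cm_good, clip_r).z
            c = np.full((n, n), np.nan)
            np.fill_diagonal(c, 0.0)
            c[np.ix_(good, good)] = exponential_conversion(cm_good, conversion)
            eta = np.full(n, np.nan)
            eta[good] = nodal_integrity(c[np.ix_(good, good)])
            zm = ZMatrix(subject_id=ts.subject_id, z=z, clip_r=clip_r)
            net = _network_fc_with_nan(zm, parc)
            iu, ju = np.triu_indices(n, k=1)
            edges = pd.Series(z[iu, ju], index=edge_names(n))
        else:
            cm = correlation_matrix(ts)
            zm = fisher_z(cm, clip_r)
            eta = nodal_integrity(exponential_conversion(cm, conversion))
            net = network_fc(zm, parc)
            edges = edge_features(zm)
        integrity_rows.append(eta)
        network_rows.append(net)
        edge_rows.append(edges)

    node_cols = [f"node_{i}" for i in parc.node_ids]
    return {
        "integrity": pd.DataFrame(np.vstack(integrity_rows), index=sids,
                                  columns=node_cols),
        "network": pd.DataFrame(network_rows, index=sids),
        "edge": pd.DataFrame(edge_rows, index=sids),
    }


def _network_fc_with_nan(zm: ZMatrix, parc: AtlasParcellation) -> pd.Series:
    """network_fc that propagates NaN entries (from flagged ROIs) with nanmean
    only when a block still has valid pairs; a fully missing block stays NaN."""
    blocks, pairs = network_blocks(parc)
    idx = {net: nodes - 1 for net, nodes in blocks.items()}
    out: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        for net, ii in idx.items():
            if len(ii) < 2:
                out[f"intra_{net}"] = np.nan
                continue
            sub = zm.z[np.ix_(ii, ii)]
            vals = sub[np.triu_indices(len(ii), k=1)]
            out[f"intra_{net}"] = np.nan if np.isnan(vals).any() else vals.mean()
        for a, b in pairs:
            vals = zm.z[np.ix_(idx[a], idx[b])]
            out[f"inter_{a}_{b}"] = (np.nan if np.isnan(vals).any()
                                     else vals.mean())
    return pd.Series(out)
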