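"""Parcellation handling: the 90-node AAL partition and its resting-state networks.

The analysis operates on 90 cortical and subcortical regions of interest
(45 per hemisphere, cerebellum excluded).  Cortical regions are grouped into
seven canonical resting-state networks (visual, somatomotor, dorsal attention,
ventral attention, limbic, frontoparietal, default mode) and the bilateral
caudate, putamen, pallidum and thalamus form an eighth deep gray matter
network.  The per-region network assignment is shipped as an editable TSV
(``data/aal90_networks.tsv``): it is a documented reconstruction of the
Yeo-style clustering convention and users may supply their own table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical network label order; fixes feature indexing across the package.
NETWORK_ORDER: tuple[str, ...] = (
    "VSN", "SMN", "DAN", "VAN", "LBN", "FPN", "DMN", "DGN")

#: The eight deep-gray-matter nuclei (bilateral caudate, putamen, pallidum,
#: thalamus) that constitute the DGN in the packaged atlas.
DGN_REGIONS: frozenset[str] = frozenset(
    f"{base}_{h}" for base in ("Caudate", "Putamen", "Pallidum", "Thalamus")
    for h in ("L", "R"))

_HEMISPHERES = {"left", "right"}


class ParcellationError(ValueError):
    """Raised when a parcellation table violates its invariants."""


@dataclass(frozen=True)
class AtlasParcellation:
    """Validated node → network partition.

    Parameters
    ----------
    table
        DataFrame with columns ``node_id`` (1..N, contiguous), ``node_name``,
        ``hemisphere`` (left/right) and ``network`` (one of
        :data:`NETWORK_ORDER`), sorted by ``node_id``.
    strict
        True when the table was validated against the full 90-node contract
        (90 nodes, 45 per hemisphere, DGN = the 8 deep nuclei).
    """

    table: pd.DataFrame
    strict: bool = True

    def __post_init__(self) -> None:
        _validate_table(self.table, strict=self.strict)

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = set(self.table["network"])
        return tuple(n for n in NETWORK_ORDER if n in present)

    def network_nodes(self) -> dict[str, np.ndarray]:
        """Mapping network → sorted array of node ids, canonical order."""
        groups = self.table.groupby("network")["node_id"]
        return {net: np.sort(groups.get_group(net).to_numpy())
                for net in self.networks}

    def node_names(self) -> list[str]:
        return self.table["node_name"].tolist()


def _validate_table(table: pd.DataFrame, strict: bool) -> None:
    required = {"node_id", "node_name", "hemisphere", "network"}
    missing = required - set(table.columns)
    if missing:
        raise ParcellationError(f"parcellation table missing columns: {sorted(missing)}")

    ids = table["node_id"].to_numpy()
    n = len(ids)
    if n < 2:
        raise ParcellationError("parcellation needs at least 2 nodes")
    if len(np.unique(ids)) != n:
        dupes = table["node_id"][table["node_id"].duplicated()].tolist()
        raise ParcellationError(f"duplicate node_ids: {dupes}")
    if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
        raise ParcellationError(f"node_ids must be contiguous 1..{n}")

    bad_hemi = set(table["hemisphere"]) - _HEMISPHERES
    if bad_hemi:
        raise ParcellationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    bad_net = set(table["network"]) - set(NETWORK_ORDER)
    if bad_net:
        raise ParcellationError(
            f"unknown network labels: {sorted(bad_net)}; "
            f"expected a subset of {NETWORK_ORDER}")

    if strict:
        if n != 90:
            raise ParcellationError(f"expected 90 nodes, got {n}")
        hemi_counts = table["hemisphere"].value_counts()
        if not (hemi_counts.get("left", 0) == hemi_counts.get("right", 0) == 45):
            raise ParcellationError(
                f"expected 45 nodes per hemisphere, got {hemi_counts.to_dict()}")
        empty = set(NETWORK_ORDER) - set(table["network"])
        if empty:
            raise ParcellationError(f"networks with no nodes: {sorted(empty)}")
        dgn = set(table.loc[table["network"] == "DGN", "node_name"])
        if dgn != set(DGN_REGIONS):
            raise ParcellationError(
                "DGN must contain exactly the bilateral caudate, putamen, "
                f"pallidum and thalamus; got {sorted(dgn)}")


def default_parcellation_path() -> Path:
    """Path of the packaged AAL-90 → 8-network table."""
    return Path(str(importlib.resources.files("rsfcnet").joinpath(
        "data/aal90_networks.tsv")))


def load_parcellation(table: str | Path | None = None, *,
                      strict: bool = True) -> AtlasParcellation:
    """Load and validate a node → network table.

    Parameters
    ----------
    table
        Path to a TSV with columns ``node_id  node_name  hemisphere
        network``; ``None`` loads the packaged AAL-90 default.
    strict
        Enforce the full 90-node contract.  Set False only for toy atlases
        in tests; this relaxes the node count, hemisphere balance and the
        non-empty-network/DGN-composition checks but nothing else.
    """
    path = Path(table) if table is not None else default_parcellation_path()
    df = pd.read_csv(path, sep="\t", dtype={"node_id": int})
    df = df.sort_values("node_id").reset_index(drop=True)
    return AtlasParcellation(table=df, strict=strict)


def network_blocks(parc: AtlasParcellation) -> tuple[
        dict[str, np.ndarray], list[tuple[str, str]]]:
    """Node sets per network plus the canonical list of unordered network pairs.

    The pair list enumerates the K(K-1)/2 unordered pairs of the K networks
    present, ordered by the fixed label order :data:`NETWORK_ORDER`; for the
    full atlas this yields the 28 pairs of the 8 networks.
    """
    blocks = parc.network_nodes()
    pairs = list(combinations(parc.networks, 2))
    return blocks, pairs
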