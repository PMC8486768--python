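"""Density heatmaps: per-target signal windows ("barcodes"), ranked by signal.

Rows are the same windows the aggregation module averages, so the column
means of a matrix reproduce the meta-profile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import AnchorSet, extract_windows
from .profiles import BinnedProfile

RANK_KEYS = ("total", "max", "center")


@dataclass
class SignalMatrix:
    """Anchors x offsets matrix of normalized signal windows."""

    row_ids: list[str]
    offsets: np.ndarray
    values: np.ndarray
    row_order: np.ndarray
    n_dropped: int = 0
    kind: str = "TSS"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.offsets)):
            raise ValueError("matrix shape does not match row_ids x offsets")
        if sorted(self.row_order.tolist()) != list(range(len(self.row_ids))):
            raise ValueError("row_order is not a permutation of the rows")

    def ordered(self) -> "SignalMatrix":
        """Materialize the row permutation."""
        perm = self.row_order
        return SignalMatrix(
            row_ids=[self.row_ids[i] for i in perm],
            offsets=self.offsets,
            values=self.values[perm],
            row_order=np.arange(len(perm)),
            n_dropped=self.n_dropped,
            kind=self.kind,
        )

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        m = self.ordered()
        return pd.DataFrame(m.values, index=pd.Index(m.row_ids, name="row_id"),
                            columns=[f"{p:g}" for p in m.offsets])


def build_matrix(profile: BinnedProfile, anchor_set: AnchorSet) -> SignalMatrix:
    """One row per retained anchor: its signal window, strand-flipped for −."""
    positions, matrix, row_ids, dropped = extract_windows(profile, anchor_set)
    if matrix.shape[0] == 0:
        raise ValueError("all anchors dropped (windows exceed chromosome bounds)")
    return SignalMatrix(
        row_ids=row_ids,
        offsets=positions,
        values=matrix,
        row_order=np.arange(matrix.shape[0]),
        n_dropped=dropped,
        kind=anchor_set.kind,
    )


def build_matrix_difference(
    a: BinnedProfile, b: BinnedProfile, anchor_set: AnchorSet
) -> SignalMatrix:
    """Matrix over ``a - b``; equals build_matrix(a) − build_matrix(b) elementwise."""
    from .profiles import subtract

    return build_matrix(subtract(a, b), anchor_set)


def _rank_value(values: np.ndarray, offsets: np.ndarray, key: str) -> np.ndarray:
    if key == "total":
        return values.sum(axis=1)
    if key == "max":
        return values.max(axis=1)
    if key == "center":
        center_col = int(np.argmin(np.abs(offsets)))
        return values[:, center_col]
    raise ValueError(f"unknown rank key {key!r} (choose from {RANK_KEYS})")


def rank_rows(m: SignalMatrix, key: str = "total") -> tuple[SignalMatrix, pd.DataFrame]:
    """Sort rows descending by ``key`` (ties broken by row_id, ascending).

    Returns the re-ordered matrix and a rank table (row_id, key value, rank).
    Idempotent: ranking an already-ranked matrix reproduces the same order.
    """
    keyvals = _rank_value(m.values, m.offsets, key)
    order = sorted(range(len(m.row_ids)), key=lambda i: (-keyvals[i], m.row_ids[i]))
    perm = np.array(order, dtype=int)
    ranked = SignalMatrix(
        row_ids=m.row_ids,
        offsets=m.offsets,
        values=m.values,
        row_order=perm,
        n_dropped=m.n_dropped,
        kind=m.kind,
    )
    table = pd.DataFrame(
        {
            "row_id": [m.row_ids[i] for i in perm],
            key: keyvals[perm],
            "rank": np.arange(1, len(perm) + 1),
        }
    )
    return ranked, table


def render_heatmap(
    m: SignalMatrix,
    path: str | Path,
    tsv_path: str | Path | None = None,
    cmap: str = "viridis",
    saturate_quantile: float = 0.95,
    diverging: bool = False,
) -> None:
    """Render the matrix (rows in row_order) to PDF/PNG and write the TSV.

    The color scale saturates at ``saturate_quantile`` of the values so a few
    extreme loci do not flatten the map; the TSV always carries the full-
    precision data.  ``diverging`` centers the scale at zero (subtraction maps).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = m.ordered()
    vals = ordered.values
    if diverging:
        vmax = float(np.quantile(np.abs(vals), saturate_quantile))
        vmax = vmax if vmax > 0 else 1.0
        vmin = -vmax
        cmap = "RdBu_r"
    else:
        vmin = float(vals.min())
        vmax = float(np.quantile(vals, saturate_quantile))
        if vmax <= vmin:  # degenerate (constant matrix) -> unit range
            vmax = vmin + 1.0
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(vals, aspect="auto", interpolation="nearest", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xlabel("position")
    ax.set_ylabel(f"{len(ordered.row_ids)} targets")
    ticks = [0, vals.shape[1] - 1]
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{ordered.offsets[t]:g}" for t in ticks])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    if tsv_path is not None:
        ordered.to_frame().to_csv(tsv_path, sep="\t", float_format="%.17g")
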