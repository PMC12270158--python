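"""Reference-atlas cell-type deconvolution of bin-level beta values.

Per-sample proportions are the non-negative least-squares fit of the sample's
marker-bin betas against the atlas columns, renormalized to sum to one (an
exact simplex-constrained refinement is available). Downstream, proportions
are compared between low- and high-fibrosis groups with the rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from methbin.association import fibrosis_group, wilcoxon_rank_sum

log = logging.getLogger(__name__)

DEFAULT_MIN_SEPARATION = 0.5
DEFAULT_MIN_MARKER_FRACTION = 0.5


@dataclass
class ReferenceAtlas:
    """Cell types x marker bins reference beta matrix (``A`` is markers x types)."""

    cell_types: tuple[str, ...]
    marker_bins: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.marker_bins), len(self.cell_types)):
            raise ValueError(
                f"atlas matrix shape {self.A.shape} does not match "
                f"{len(self.marker_bins)} markers x {len(self.cell_types)} cell types"
            )
        if not np.isfinite(self.A).all():
            raise ValueError("atlas betas must be finite")
        if (self.A < 0).any() or (self.A > 1).any():
            raise ValueError("atlas betas must lie in [0, 1]")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def check_separation(self, min_separation: float = DEFAULT_MIN_SEPARATION) -> None:
        """Require every marker row to spread >= ``min_separation`` across types."""
        spread = self.A.max(axis=1) - self.A.min(axis=1)
        bad = spread < min_separation
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} marker rows have max-min spread below "
                f"{min_separation} (worst: {spread.min():.3f})"
            )


@dataclass
class DeconvolutionResult:
    sample_id: str
    w: np.ndarray  # (K,) non-negative, sums to 1
    residual_norm: float
    n_markers_used: int
    unstable: bool = False

    def __post_init__(self) -> None:
        if (self.w < 0).any():
            raise ValueError("proportions must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def estimate_proportions(
    atlas: ReferenceAtlas,
    sample_beta: Sequence[float] | pd.Series,
    sample_id: str = "",
    min_marker_fraction: float = DEFAULT_MIN_MARKER_FRACTION,
    solver: str = "nnls",
) -> DeconvolutionResult:
    """Estimate the cell-type mixture of one sample.

    ``sample_beta`` is aligned with the atlas marker rows (a Series indexed
    by marker id, or a plain vector); missing (NaN) rows are dropped
    pairwise. Fewer than ``min_marker_fraction`` covered markers is an
    error. ``solver='nnls'`` renormalizes the NNLS solution;
    ``solver='simplex'`` refines it under an exact sum-to-one constraint.
    """
    if solver not in ("nnls", "simplex"):
        raise ValueError(f"unknown solver {solver!r}")
    if isinstance(sample_beta, pd.Series):
        b = sample_beta.reindex(list(atlas.marker_bins)).to_numpy(dtype=float)
    else:
        b = np.asarray(sample_beta, dtype=float)
    if b.shape != (len(atlas.marker_bins),):
        raise ValueError("sample_beta length does not match atlas markers")
    mask = ~np.isnan(b)
    frac = mask.mean()
    if frac < min_marker_fraction:
        raise ValueError(
            f"sample {sample_id or '<unnamed>'}: only {frac:.0%} of marker bins "
            f"covered (< {min_marker_fraction:.0%})"
        )
    A = atlas.A[mask]
    bb = b[mask]
    unstable = False
    if np.linalg.matrix_rank(A) < atlas.n_cell_types:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'}: atlas rank-deficient after "
            "dropping missing markers; estimate flagged unstable",
            stacklevel=2,
        )
        unstable = True
    w, _ = optimize.nnls(A, bb)
    total = w.sum()
    if total <= 0:
        warnings.warn(
            f"sample {sample_id or '<unnamed>'}: NNLS returned the zero vector; "
            "falling back to uniform proportions",
            stacklevel=2,
        )
        w = np.full(atlas.n_cell_types, 1.0 / atlas.n_cell_types)
        unstable = True
    else:
        w = w / total
    if solver == "simplex":
        res = optimize.minimize(
            lambda v: 0.5 * np.sum((A @ v - bb) ** 2),
            w,
            jac=lambda v: A.T @ (A @ v - bb),
            bounds=[(0.0, 1.0)] * atlas.n_cell_types,
            constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success:
            w = np.clip(res.x, 0.0, None)
            w = w / w.sum()
    residual = float(np.linalg.norm(A @ w - bb))
    return DeconvolutionResult(
        sample_id=sample_id,
        w=w,
        residual_norm=residual,
        n_markers_used=int(mask.sum()),
        unstable=unstable,
    )


def estimate_proportions_matrix(
    atlas: ReferenceAtlas,
    beta: pd.DataFrame,
    min_marker_fraction: float = DEFAULT_MIN_MARKER_FRACTION,
    solver: str = "nnls",
) -> pd.DataFrame:
    """Deconvolve every column of a markers x samples beta matrix.

    Returns a samples x cell-types proportion table with a ``residual_norm``
    column appended.
    """
    rows = {}
    resid = {}
    for sample in beta.columns:
        res = estimate_proportions(
            atlas, beta[sample], sample_id=str(sample),
            min_marker_fraction=min_marker_fraction, solver=solver,
        )
        rows[sample] = res.w
        resid[sample] = res.residual_norm
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(atlas.cell_types))
    out.index.name = "sample_id"
    out["residual_norm"] = pd.Series(resid)
    return out


def compare_proportions_by_fibrosis(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_type: str,
    sample_type: str | None = None,
    cut: int = 2,
) -> float:
    """Rank-sum p-value for a cell type's proportions, low vs high fibrosis.

    ``proportions`` is samples x cell types (as produced by
    :func:`estimate_proportions_matrix`); ``sample_type`` optionally
    restricts to tissue or cfDNA samples. Each fibrosis group must contain
    at least two samples.
    """
    if cell_type not in proportions.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    meta = metadata[metadata["sample_id"].isin(proportions.index)]
    if sample_type is not None:
        meta = meta[meta["sample_type"] == sample_type]
    groups = {"low": [], "high": []}
    for sid, stage in zip(meta["sample_id"], meta["fibrosis_stage"]):
        groups[fibrosis_group(stage, cut)].append(proportions.loc[sid, cell_type])
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"fibrosis group {name!r} has fewer than 2 samples")
    return wilcoxon_rank_sum(groups["low"], groups["high"])


def compare_all(
    proportions: pd.DataFrame,
    metadata: pd.DataFrame,
    cut: int = 2,
) -> pd.DataFrame:
    """Low/high fibrosis comparison for every cell type x sample type stratum."""
    rows = []
    cell_types = [c for c in proportions.columns if c != "residual_norm"]
    for sample_type in sorted(metadata["sample_type"].unique()):
        meta = metadata[
            metadata["sample_type"].eq(sample_type)
            & metadata["sample_id"].isin(proportions.index)
        ]
        stages = meta["fibrosis_stage"].to_numpy()
        n_low = int((stages < cut).sum())
        n_high = int((stages >= cut).sum())
        for ct in cell_types:
            try:
                p = compare_proportions_by_fibrosis(
                    proportions, metadata, ct, sample_type=sample_type, cut=cut
                )
            except ValueError:
                p = np.nan
            rows.append((ct, sample_type, n_low, n_high, p))
    return pd.DataFrame(
        rows, columns=["cell_type", "sample_type", "n_low", "n_high", "p_value"]
    )


# ---------------------------------------------------------------------------
# on-disk formats


def read_atlas(path: str | Path, min_separation: float | None = DEFAULT_MIN_SEPARATION) -> ReferenceAtlas:
    """Read an atlas TSV (rows = marker bins, columns = cell types)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    atlas = ReferenceAtlas(
        cell_types=tuple(df.columns),
        marker_bins=tuple(str(i) for i in df.index),
        A=df.to_numpy(dtype=float),
    )
    if min_separation is not None:
        atlas.check_separation(min_separation)
    return atlas


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    pd.DataFrame(
        atlas.A, index=list(atlas.marker_bins), columns=list(atlas.cell_types)
    ).rename_axis("marker_bin").to_csv(path, sep="\t", float_format="%.8g")


def read_proportions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_proportions(proportions: pd.DataFrame, path: str | Path) -> None:
    proportions.to_csv(path, sep="\t", float_format="%.8g")
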