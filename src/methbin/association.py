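"""Per-bin association screening against fibrosis stage within base groups.

Each of the four sex x sample-type strata is screened independently with
Kendall's tau-b; bins observed in fewer than four individuals, or whose beta
values collapse to fewer than three unique values, are filtered before
significance is assessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methbin.binning import BinBetaMatrix

log = logging.getLogger(__name__)

BASE_GROUPS = ("male_tissue", "male_cfDNA", "female_tissue", "female_cfDNA")

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_INDIVIDUALS = 4
DEFAULT_MIN_UNIQUE = 3
#: beta values are rounded to this many decimals before counting unique values
UNIQUE_DECIMALS = 6
DEFAULT_FIBROSIS_CUT = 2


class DegenerateDataError(ValueError):
    """Raised when a correlation is undefined (a vector is constant)."""


@dataclass(frozen=True)
class AssociationResult:
    bin_index: int
    base_group: str
    n_obs: int
    n_unique: int
    tau_b: float
    p_value: float
    significant: bool
    filtered: bool


def kendall_tau_b(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    ``method='asymptotic'`` uses the normal approximation with tie-corrected
    variance; ``method='exact'`` enumerates all permutations of ``y``
    (only feasible for n <= 8) and returns the permutation p-value for
    ``|C - D|``. Ties are permitted in both vectors; a constant vector makes
    tau undefined and raises :class:`DegenerateDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("tau-b undefined: all values tied in one vector")
    if method == "asymptotic":
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p only supported for n <= 8")
        tau, _ = kendall_tau_b(x, y, method="asymptotic")
        s_obs = abs(_concordance_s(x, y))
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_concordance_s(x, y[list(perm)])) >= s_obs - 1e-9:
                count += 1
        return tau, count / total
    raise ValueError(f"unknown method {method!r}")


def _concordance_s(x: np.ndarray, y: np.ndarray) -> int:
    """C - D by direct pair counting."""
    s = 0
    n = len(x)
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1 :] - x[i]) * np.sign(y[i + 1 :] - y[i])))
    return s


def screen_bins(
    matrix: BinBetaMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    base_group: str,
    alpha: float = DEFAULT_ALPHA,
    min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
    min_unique: int = DEFAULT_MIN_UNIQUE,
) -> pd.DataFrame:
    """Kendall screen of every bin against fibrosis stage in one base group.

    Returns one row per bin: ``bin_index, base_group, n_obs, n_unique,
    tau_b, p_value, significant, filtered``. Missing betas are dropped
    pairwise; bins failing the observation or uniqueness filters (or with a
    degenerate stage vector after dropping) are marked ``filtered`` and are
    never significant. Significance is strict: ``p_value < alpha``.
    """
    if base_group not in BASE_GROUPS:
        raise ValueError(f"base_group must be one of {BASE_GROUPS}")
    beta = matrix.beta_frame() if isinstance(matrix, BinBetaMatrix) else matrix
    if "base_group" not in metadata.columns:
        raise ValueError("metadata must carry a base_group column (see validate_metadata)")
    meta = metadata[metadata["base_group"] == base_group]
    meta = meta[meta["sample_id"].isin(beta.columns)]
    if meta.empty:
        raise ValueError(f"no samples in group {base_group}")
    sub = beta[meta["sample_id"].tolist()].to_numpy(dtype=float)
    stages = meta["fibrosis_stage"].to_numpy(dtype=float)

    rows = []
    for i, bin_index in enumerate(beta.index.to_numpy()):
        b = sub[i]
        obs = ~np.isnan(b)
        n_obs = int(obs.sum())
        bb = b[obs]
        n_unique = int(np.unique(np.round(bb, UNIQUE_DECIMALS)).size)
        tau = np.nan
        p = np.nan
        filtered = n_obs < min_individuals or n_unique < min_unique
        if not filtered:
            try:
                tau, p = kendall_tau_b(bb, stages[obs])
            except DegenerateDataError:
                filtered = True
        significant = (not filtered) and bool(p < alpha)
        rows.append((int(bin_index), base_group, n_obs, n_unique, tau, p, significant, filtered))
    return pd.DataFrame(
        rows,
        columns=[
            "bin_index",
            "base_group",
            "n_obs",
            "n_unique",
            "tau_b",
            "p_value",
            "significant",
            "filtered",
        ],
    )


def screen_all_groups(
    matrix: BinBetaMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
    min_unique: int = DEFAULT_MIN_UNIQUE,
) -> dict[str, pd.DataFrame]:
    """Run :func:`screen_bins` for all four base groups."""
    return {
        g: screen_bins(matrix, metadata, g, alpha, min_individuals, min_unique)
        for g in BASE_GROUPS
    }


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both groups have n <= 10 and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size <= 10 and b.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def fibrosis_group(stage: int, cut: int = DEFAULT_FIBROSIS_CUT) -> str:
    """Dichotomize a fibrosis stage: ``low`` below the cut, ``high`` at or above."""
    stage = int(stage)
    if not 0 <= stage <= 4:
        raise ValueError(f"fibrosis stage must be in 0..4, got {stage}")
    return "low" if stage < cut else "high"


def write_association_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_association_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
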