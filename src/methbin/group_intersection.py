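"""Cross-group intersection labeling of screened bins.

A bin significant in two or more base groups that share a sex or a sample
type receives that shared dimension as its label; bins significant in all
four groups are labeled ``All``. Pairs differing in both sex and sample
type are invalid and yield no label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from methbin.association import BASE_GROUPS

log = logging.getLogger(__name__)

MT, MC, FT, FC = BASE_GROUPS  # male_tissue, male_cfDNA, female_tissue, female_cfDNA

LABELS = ("Tissue", "cfDNA", "Male", "Female", "All", "none")

#: the pair of base groups defining each shared-dimension label
LABEL_PAIRS: dict[str, frozenset[str]] = {
    "Tissue": frozenset({MT, FT}),
    "cfDNA": frozenset({MC, FC}),
    "Male": frozenset({MT, MC}),
    "Female": frozenset({FT, FC}),
}

#: priority when several pairs are present (tissue first, then cfDNA, then sex)
DEFAULT_PRIORITY = ("Tissue", "cfDNA", "Male", "Female")

#: base groups whose significance a label asserts
LABEL_GROUPS: dict[str, frozenset[str]] = dict(
    LABEL_PAIRS, All=frozenset(BASE_GROUPS)
)


@dataclass(frozen=True)
class IntersectionLabel:
    bin_index: int
    label: str
    contributing_groups: frozenset[str]


def assign_label(
    significant_groups: Iterable[str],
    bin_index: int = -1,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> IntersectionLabel:
    """Map the set of significant base groups of a bin to its label.

    Total on all 16 subsets: all four groups -> ``All``; otherwise the first
    label in ``priority`` whose defining pair is fully contained wins; sets
    without any same-sex or same-type pair (singletons, the empty set, and
    the two diagonal pairs) -> ``none``.
    """
    s = frozenset(significant_groups)
    unknown = s - set(BASE_GROUPS)
    if unknown:
        raise ValueError(f"unknown base groups: {sorted(unknown)}")
    if set(priority) != set(DEFAULT_PRIORITY):
        raise ValueError(f"priority must be a permutation of {DEFAULT_PRIORITY}")
    if len(s) == 4:
        label = "All"
    else:
        label = "none"
        for cand in priority:
            if LABEL_PAIRS[cand] <= s:
                label = cand
                break
    return IntersectionLabel(bin_index=bin_index, label=label, contributing_groups=s)


def label_all_bins(
    results_by_group: Mapping[str, pd.DataFrame],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Assign an intersection label to every bin of a shared bin universe.

    ``results_by_group`` maps each of the four base groups to its screening
    table (needing ``bin_index`` and ``significant`` columns). Returns
    ``bin_index, label, contributing_groups`` (comma-joined) and logs the
    per-label counts.
    """
    missing = set(BASE_GROUPS) - set(results_by_group)
    if missing:
        raise ValueError(f"missing results for base groups: {sorted(missing)}")
    universes = {}
    for g in BASE_GROUPS:
        universes[g] = np.sort(results_by_group[g]["bin_index"].to_numpy())
    ref = universes[BASE_GROUPS[0]]
    for g, u in universes.items():
        if u.shape != ref.shape or (u != ref).any():
            raise ValueError(f"bin universe of {g} differs from {BASE_GROUPS[0]}")

    sig = {}
    for g in BASE_GROUPS:
        df = results_by_group[g].set_index("bin_index")
        sig[g] = df.loc[ref, "significant"].to_numpy(dtype=bool)

    rows = []
    for i, bin_index in enumerate(ref):
        groups = frozenset(g for g in BASE_GROUPS if sig[g][i])
        lab = assign_label(groups, bin_index=int(bin_index), priority=priority)
        rows.append((int(bin_index), lab.label, ",".join(sorted(lab.contributing_groups))))
    out = pd.DataFrame(rows, columns=["bin_index", "label", "contributing_groups"])
    counts = out["label"].value_counts()
    log.info("intersection label counts: %s", counts.to_dict())
    return out


def write_labels_tsv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df
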