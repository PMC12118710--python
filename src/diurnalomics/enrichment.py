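"""Phase set enrichment (PSEA) and over-representation analysis (ORA).

PSEA asks whether the acrophases of a gene set are non-uniformly placed on
the 24-h circle relative to a background phase distribution; the two-sample
Kuiper test (rotation-invariant circular analogue of Kolmogorov-Smirnov)
supplies the p-value, and the set-level phase is the circular median of the
member acrophases.  Sets of similar biology can then be merged through a
curated mapping into broader categories whose phase is the circular mean of
member set phases; category phases of two groups are compared by wrapped
difference.

ORA is a one-sided hypergeometric (Fisher) over-representation test of a
hit list against gene sets within a stated background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phase import (
    circular_mean_hours,
    circular_median_hours,
    kuiper_two_sample,
    wrap_phase_difference,
)

__all__ = [
    "GeneSetResult",
    "read_gmt",
    "write_gmt",
    "psea_kuiper",
    "set_phase_median",
    "psea_analysis",
    "merge_categories",
    "category_phase_difference",
    "ora_fisher",
    "round_phases_half_up",
]


@dataclass
class GeneSetResult:
    """One gene set's enrichment outcome."""

    set_id: str
    description: str
    n_members_in_background: int
    p_enrichment: float
    set_phase: float  # hours in [0, 24)
    category: str | None = None


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: name <tab> description <tab> member..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = (desc, [m for m in members if m])
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, (desc, members) in sets.items():
            handle.write("\t".join([name, desc, *members]) + "\n")


def round_phases_half_up(phases: Mapping[str, float]) -> dict[str, float]:
    """Round acrophases to integer hours (half-up), staying within [0, 24)."""
    return {k: float(np.floor(v + 0.5) % 24.0) for k, v in phases.items()}


def psea_kuiper(set_phases, background_phases) -> float:
    """Two-sample Kuiper p-value of a set's phases against the background."""
    _, p = kuiper_two_sample(set_phases, background_phases)
    return p


def set_phase_median(set_phases) -> float:
    """Set-level phase: circular median of the member acrophases."""
    return circular_median_hours(set_phases)


def psea_analysis(
    phases: Mapping[str, float],
    sets: Mapping[str, tuple[str, Sequence[str]]],
    min_genes: int = 10,
    alpha: float = 0.01,
    round_to_hours: bool = True,
) -> pd.DataFrame:
    """Phase set enrichment over a gene-set collection.

    ``phases`` maps each background feature (typically every consensus-
    rhythmic gene of one group) to its acrophase; the same phases act as the
    enrichment background.  Sets with fewer than ``min_genes`` members in
    the background are skipped with a reason rather than erroring.  Returns
    a DataFrame (set, description, n_members, V-free p, set_phase,
    significant, skip_reason) sorted by p.
    """
    if round_to_hours:
        phases = round_phases_half_up(phases)
    background = np.array(list(phases.values()), dtype=float)
    rows = []
    for set_id, (desc, members) in sets.items():
        member_phases = [phases[m] for m in members if m in phases]
        if len(member_phases) < min_genes:
            rows.append(
                {
                    "set": set_id,
                    "description": desc,
                    "n_members": len(member_phases),
                    "p_enrichment": np.nan,
                    "set_phase": np.nan,
                    "significant": False,
                    "skip_reason": f"fewer than {min_genes} members in background",
                }
            )
            continue
        p = psea_kuiper(member_phases, background)
        rows.append(
            {
                "set": set_id,
                "description": desc,
                "n_members": len(member_phases),
                "p_enrichment": p,
                "set_phase": set_phase_median(member_phases),
                "significant": p < alpha,
                "skip_reason": "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set", "description", "n_members", "p_enrichment",
            "set_phase", "significant", "skip_reason",
        ],
    )
    return table.sort_values(
        ["p_enrichment", "set"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def merge_categories(
    results: Sequence[GeneSetResult] | pd.DataFrame,
    mapping: Mapping[str, str],
) -> dict[str, float]:
    """Average set phases into curated broader categories (circular mean).

    ``mapping`` sends set ids to category labels (the manual curation step).
    Set ids in the mapping that are absent from the results are skipped with
    a warning; categories left without members are dropped.
    """
    if isinstance(results, pd.DataFrame):
        phase_of = {
            str(r["set"]): float(r["set_phase"])
            for _, r in results.iterrows()
            if np.isfinite(r["set_phase"])
        }
    else:
        phase_of = {r.set_id: r.set_phase for r in results}
    members: dict[str, list[float]] = {}
    for set_id, category in mapping.items():
        if set_id not in phase_of:
            warnings.warn(f"set {set_id!r} absent from results; skipped")
            continue
        members.setdefault(category, []).append(phase_of[set_id])
    return {cat: circular_mean_hours(ph) for cat, ph in members.items()}


def category_phase_difference(
    cat_phases_g1: Mapping[str, float], cat_phases_g2: Mapping[str, float]
) -> dict[str, float]:
    """Wrapped per-category phase difference (group2 - group1, hours).

    Positive values are delays of group 2.  Categories present in only one
    group are omitted with a warning.
    """
    out: dict[str, float] = {}
    for cat in set(cat_phases_g1) | set(cat_phases_g2):
        if cat not in cat_phases_g1 or cat not in cat_phases_g2:
            warnings.warn(f"category {cat!r} present in only one group; omitted")
            continue
        out[cat] = float(
            wrap_phase_difference(cat_phases_g2[cat] - cat_phases_g1[cat])
        )
    return out


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping set id -> category label."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: category map needs two columns (set, category)")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def ora_fisher(
    hits: set[str],
    background: set[str],
    sets: Mapping[str, tuple[str, Sequence[str]]],
    min_genes: int = 3,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a hit list.

    For each gene set with at least ``min_genes`` hits, the p-value is the
    hypergeometric upper tail P(X >= overlap) drawn from a universe of
    ``len(background)`` features of which ``len(hits)`` are hits.  Results
    are sorted by p; with ``adjust=True`` a Benjamini-Hochberg column is
    added.  Hits outside the background are an error.
    """
    hits = set(hits)
    background = set(background)
    stray = sorted(hits - background)
    if stray:
        raise ValueError(f"hits outside the background: {stray}")
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for set_id, (desc, members) in sets.items():
        in_bg = set(members) & background
        overlap = len(in_bg & hits)
        if overlap < min_genes:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_hits))
        rows.append(
            {
                "set": set_id,
                "description": desc,
                "n_set_in_background": len(in_bg),
                "n_overlap": overlap,
                "p_enrichment": p,
                "significant": p < alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set", "description", "n_set_in_background", "n_overlap",
            "p_enrichment", "significant",
        ],
    ).sort_values(["p_enrichment", "set"], kind="mergesort").reset_index(drop=True)
    if adjust and len(table):
        from statsmodels.stats.multitest import multipletests

        table["fdr"] = multipletests(table["p_enrichment"], method="fdr_bh")[1]
    return table
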