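"""Per-condition summary statistics and group comparisons.

Aggregates per-nucleus tables into the study's summary measures — percent
of cells with at least one DSB focus ("cwf"), mean foci per damaged cell,
percent pan-γ-H2AX and percent caspase-3⁺ cells — with the section as the
replication unit (unweighted mean ± SD across sections).  Group comparisons
use one-way ANOVA followed by Tukey's HSD multiple-comparison test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthetic_tissue import SectionDataset

__all__ = [
    "SUMMARY_COLUMNS",
    "ComparisonResult",
    "summarize_sections",
    "group_summary",
    "compare_groups",
    "time_course",
]

SUMMARY_COLUMNS = [
    "geometry",
    "time_h",
    "model_id",
    "section_id",
    "n_cells",
    "pct_cwf",
    "mean_foci_53bp1",
    "mean_foci_gh2ax",
    "mean_foci_coloc",
    "pct_pan",
    "pct_caspase3",
]


def _summarize_one(nuclei: pd.DataFrame) -> dict:
    n = len(nuclei)
    if n == 0:
        raise ValueError("empty per-nucleus table")
    b = nuclei["foci_53bp1"].to_numpy(float)
    g = nuclei["foci_gh2ax"].to_numpy(float)
    sh = nuclei["foci_shared"].to_numpy(float)
    damaged = (b + g) > 0
    nd = int(damaged.sum())
    return {
        "n_cells": n,
        "pct_cwf": 100.0 * nd / n,
        # conditional on carrying at least one focus; undefined when no cell does
        "mean_foci_53bp1": float(b[damaged].mean()) if nd else np.nan,
        "mean_foci_gh2ax": float(g[damaged].mean()) if nd else np.nan,
        "mean_foci_coloc": float(sh[damaged].mean()) if nd else np.nan,
        "pct_pan": 100.0 * float(nuclei["pan_gh2ax"].astype(bool).mean()),
        "pct_caspase3": 100.0 * float(nuclei["caspase3"].astype(bool).mean()),
    }


def summarize_sections(sections, keys: list[dict] | None = None) -> pd.DataFrame:
    """Per-section summary rows.

    ``sections`` is an iterable of :class:`SectionDataset` or of per-nucleus
    DataFrames; in the latter case ``keys`` supplies one dict per table with
    at least ``geometry`` and ``time_h`` (``model_id``/``section_id``
    optional).
    """
    rows = []
    for i, item in enumerate(sections):
        if isinstance(item, SectionDataset):
            nuclei = item.nuclei
            key = {
                "geometry": item.geometry_label,
                "time_h": item.time_h,
                "model_id": item.meta.get("model_id", 0),
                "section_id": item.meta.get("section_id", i),
            }
        else:
            nuclei = item
            key = dict(keys[i]) if keys is not None else {}
            key.setdefault("geometry", "unknown")
            key.setdefault("time_h", np.nan)
            key.setdefault("model_id", 0)
            key.setdefault("section_id", i)
        rows.append({**key, **_summarize_one(nuclei)})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def group_summary(
    summary: pd.DataFrame, by: tuple[str, ...] = ("geometry", "time_h")
) -> pd.DataFrame:
    """Unweighted mean ± SD of each response across sections in a group."""
    responses = [c for c in SUMMARY_COLUMNS if c not in (*by, "model_id", "section_id")]
    out = summary.groupby(list(by), dropna=False)[responses].agg(["mean", "std", "count"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out.reset_index()


@dataclass
class ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise follow-up."""

    factor: str
    response: str
    levels: list
    f_stat: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(
    summary: pd.DataFrame,
    response: str = "pct_cwf",
    factor: str = "geometry",
    alpha: float = 0.05,
) -> ComparisonResult:
    """One-way ANOVA across factor levels followed by Tukey's HSD.

    Requires ≥ 2 levels with ≥ 2 observations each; raises on degenerate
    input with zero within-group variance everywhere.
    """
    data = summary[[factor, response]].dropna()
    groups = [g[response].to_numpy(float) for _, g in data.groupby(factor)]
    levels = sorted(data[factor].unique().tolist(), key=str)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two levels with two observations each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f_stat, p_value = sps.f_oneway(*groups)
    tk = pairwise_tukeyhsd(
        data[response].to_numpy(float), data[factor].astype(str).to_numpy(), alpha=alpha
    )
    from itertools import combinations

    pairs = list(combinations(tk.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": np.asarray(tk.meandiffs, float),
            "p_adj": np.asarray(tk.pvalues, float),
            "reject": np.asarray(tk.reject, bool),
        }
    )
    return ComparisonResult(
        factor=factor,
        response=response,
        levels=levels,
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey=tukey,
        alpha=alpha,
    )


def time_course(
    summary: pd.DataFrame,
    response: str = "pct_cwf",
    sham_label: str = "sham",
    convergence_tol: float = 5.0,
    final_time: float = 72.0,
) -> pd.DataFrame:
    """Long-format per-geometry trajectory of one response over repair time.

    Adds a ``converged_to_sham`` flag per geometry: whether the mean at the
    final time point lies within ``convergence_tol`` (same units as the
    response) of sham, quantifying the return of damage to baseline.
    """
    grouped = (
        summary.groupby(["geometry", "time_h"])[response]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": f"{response}_mean", "std": f"{response}_sd", "count": "n"})
    )
    sham_final = grouped.loc[
        (grouped["geometry"] == sham_label) & (grouped["time_h"] == final_time),
        f"{response}_mean",
    ]
    sham_val = float(sham_final.iloc[0]) if len(sham_final) else np.nan
    flags = {}
    for geom, sub in grouped.groupby("geometry"):
        final = sub.loc[sub["time_h"] == final_time, f"{response}_mean"]
        if len(final) == 0 or np.isnan(sham_val):
            flags[geom] = np.nan
        else:
            flags[geom] = bool(abs(float(final.iloc[0]) - sham_val) <= convergence_tol)
    grouped["converged_to_sham"] = grouped["geometry"].map(flags)
    missing = []
    for geom, sub in grouped.groupby("geometry"):
        lacking = {0.5, 6.0, 24.0, 72.0} - set(sub["time_h"].astype(float))
        if lacking:
            missing.append((geom, sorted(lacking)))
    grouped.attrs["missing_time_points"] = missing
    return grouped
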