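"""EBV standardisation, truncation selection and correlated-response reports.

EBVs of traits measured on different scales are standardised to z-scores;
animals (or pens) in the lowest fraction of a criterion — a single trait's
EBV or the equal-weight eigenvector-clustering index — are selected, and
the mean +/- SE of the skin-lesion EBVs or phenotypes in the selected
group quantifies the expected correlated response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass
class SelectionReport:
    """Selected-group means of target columns, with the population baseline."""

    criterion: str
    selected_ids: np.ndarray
    group_mean: pd.Series
    group_se: pd.Series
    population_mean: pd.Series
    n_selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.group_mean.index,
                "group_mean": self.group_mean.to_numpy(),
                "group_se": self.group_se.to_numpy(),
                "population_mean": self.population_mean.to_numpy(),
            }
        )


def standardize_ebv(
    ebv_table: pd.DataFrame, columns: list[str] | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Z-score EBV columns: (x - mean) / SD, sample SD by default.

    Columns named ``ebv_*`` are standardised unless ``columns`` is given;
    id/pen columns pass through untouched.
    """
    if len(ebv_table) < 2:
        raise ValueError("need at least 2 animals to standardize")
    cols = columns or [
        c for c in ebv_table.columns
        if c.startswith("ebv_") and not c.startswith("ebv_sd_")
    ]
    out = ebv_table.copy()
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = x.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"column {c!r} has zero SD; cannot standardize")
        out[c] = (x - x.mean()) / sd
    return out


def build_index(
    z_eigen: pd.Series, z_clustering: pd.Series, weights: tuple[float, float] = (1.0, 1.0)
) -> pd.Series:
    """Weighted sum of two standardised EBV series (equal weights by default).

    Inputs must share an identical index (animal ids); a mismatch raises.
    """
    if not z_eigen.index.equals(z_clustering.index):
        raise KeyError("eigenvector and clustering EBV series are not aligned")
    return weights[0] * z_eigen + weights[1] * z_clustering


def select_lowest(values: pd.Series, fraction: float = 0.10) -> np.ndarray:
    """Ids of the floor(fraction * n) animals with the smallest values.

    Ties at the cut are broken by stable id order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_sel = int(np.floor(fraction * len(values)))
    order = values.sort_values(kind="stable")
    return order.index[:n_sel].to_numpy()


def correlated_response(
    selected_ids: np.ndarray,
    target_table: pd.DataFrame,
    target_columns: list[str] | None = None,
    criterion: str = "",
) -> SelectionReport:
    """Mean +/- SE of target columns within the selected set.

    ``target_table`` must be indexed by animal id.  SE = SD / sqrt(n) over
    the selected animals; the population mean of each target is reported
    for contrast.
    """
    if len(selected_ids) == 0:
        raise ValueError("empty selection")
    cols = target_columns or [c for c in target_table.columns if c.startswith("ebv_")]
    sub = target_table.loc[selected_ids, cols]
    return SelectionReport(
        criterion=criterion,
        selected_ids=np.asarray(selected_ids),
        group_mean=sub.mean(),
        group_se=sub.std(ddof=1) / np.sqrt(len(sub)),
        population_mean=target_table[cols].mean(),
        n_selected=len(sub),
    )


def pen_rank_select(
    ebv_table: pd.DataFrame,
    criterion: str,
    stat: str = "mean",
    fraction: float = 0.20,
    target_columns: list[str] | None = None,
) -> SelectionReport:
    """Select the lowest pens by per-pen mean or SD of a criterion column.

    Per-pen SD ranks pens by EBV diversity; singleton pens are excluded
    from SD ranking with a warning.  The report aggregates target columns
    over all animals in the selected pens.
    """
    if stat not in ("mean", "sd"):
        raise ValueError("stat must be 'mean' or 'sd'")
    if "pen" not in ebv_table.columns:
        raise KeyError("ebv_table needs a 'pen' column")
    groups = ebv_table.groupby("pen")[criterion]
    if stat == "mean":
        pen_stat = groups.mean()
    else:
        sizes = groups.size()
        singletons = sizes[sizes < 2].index
        if len(singletons):
            warnings.warn(
                f"excluding {len(singletons)} singleton pen(s) from SD ranking",
                stacklevel=2,
            )
        pen_stat = groups.std(ddof=1).drop(index=singletons)
    n_sel = int(np.floor(fraction * len(pen_stat)))
    if n_sel == 0:
        raise ValueError("fraction selects zero pens")
    if pen_stat.nunique() == 1:
        warnings.warn("degenerate pen ranking: all pens tie", stacklevel=2)
    sel_pens = pen_stat.sort_values(kind="stable").index[:n_sel]
    members = ebv_table[ebv_table["pen"].isin(sel_pens)]
    cols = target_columns or [c for c in ebv_table.columns if c.startswith("ebv_")]
    return SelectionReport(
        criterion=f"pen_{stat}:{criterion}",
        selected_ids=members.index.to_numpy(),
        group_mean=members[cols].mean(),
        group_se=members[cols].std(ddof=1) / np.sqrt(len(members)),
        population_mean=ebv_table[cols].mean(),
        n_selected=len(sel_pens),
    )


def spearman_matrix(trait_table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (average ranks for ties).

    Pairs with fewer than 3 complete observations, or a constant column,
    yield NaN with a warning.
    """
    k = len(columns)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = trait_table[[columns[i], columns[j]]].dropna()
            if len(sub) < 3:
                warnings.warn(
                    f"fewer than 3 complete rows for {columns[i]}/{columns[j]}",
                    stacklevel=2,
                )
                rho = np.nan
            elif sub[columns[i]].nunique() == 1 or sub[columns[j]].nunique() == 1:
                warnings.warn(
                    f"constant column in pair {columns[i]}/{columns[j]}", stacklevel=2
                )
                rho = np.nan
            else:
                rho = spearmanr(sub[columns[i]], sub[columns[j]]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=columns, columns=columns)
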