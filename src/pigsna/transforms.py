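"""Variable transformations linking raw records to the modelled traits.

Lesion counts at 24 h post-mixing are adjusted for pre-mixing lesions
(subtraction, clamped at zero) and log(x+1)-transformed; 3-week counts are
fresh-lesion recounts and use the raw count before the log.  The skewed
continuous centralities take a square-root transform.  Column naming is
fixed: ``sl_{region}_{24h|3wk}`` for lesions, ``sna_{trait}`` for network
traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REGIONS = ("anterior", "central", "posterior")
TIMEPOINTS = ("premix", "24h", "3wk")

#: continuous network traits that get the square-root transform
SQRT_SNA = ["degree", "betweenness", "closeness", "eigenvector", "clustering"]

LESION_COLUMNS = [f"sl_{r}_{t}" for t in ("24h", "3wk") for r in REGIONS]


@dataclass
class LesionRecord:
    animal_id: int
    region: str
    timepoint: str
    count: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.count < 0:
            raise ValueError("lesion count must be non-negative")


def net_lesions(count_24h, count_premix):
    """Fresh 24 h lesions: post-mixing count minus the pre-mixing count.

    Negative differences (lesions healed or miscounted between the two
    inspections) are clamped to 0; clamped records are counted in a log
    message so data problems stay visible.
    """
    c24 = np.asarray(count_24h)
    cpre = np.asarray(count_premix)
    if np.any(c24 < 0) or np.any(cpre < 0):
        raise ValueError("lesion counts must be non-negative")
    diff = c24 - cpre
    clamped = int(np.sum(diff < 0))
    if clamped:
        log.warning("net_lesions: clamped %d negative net count(s) to 0", clamped)
    return np.maximum(diff, 0)


def log1_transform(count):
    """Natural log of (count + 1); maps count 0 to exactly 0."""
    x = np.asarray(count, dtype=float)
    if np.any(x < 0):
        raise ValueError("log1 transform requires non-negative input")
    return np.log(x + 1.0)


def sqrt_transform(value):
    """Square root; used to de-skew the continuous centrality traits."""
    x = np.asarray(value, dtype=float)
    if np.any(x < 0):
        raise ValueError("sqrt transform requires non-negative input")
    return np.sqrt(x)


def lesions_to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    """Pivot lesion records to one row per animal, columns region x timepoint."""
    raw = pd.DataFrame(
        [(r.animal_id, r.region, r.timepoint, r.count) for r in records],
        columns=["animal", "region", "timepoint", "count"],
    )
    dup = raw.duplicated(["animal", "region", "timepoint"])
    if dup.any():
        raise ValueError("duplicate lesion record(s) per animal x region x timepoint")
    wide = raw.pivot(index="animal", columns=["region", "timepoint"], values="count")
    wide.columns = [f"{r}_{t}" for r, t in wide.columns]
    return wide.reset_index()


def transform_lesions(wide: pd.DataFrame) -> pd.DataFrame:
    """Modelled lesion traits from wide per-animal counts.

    24 h traits: log(net + 1) with net = max(24h - premix, 0); missing
    premix columns are treated as zero pre-mixing lesions.  3-week traits:
    log(count + 1) of the fresh-lesion recount.
    """
    out = pd.DataFrame({"animal": wide["animal"]})
    for region in REGIONS:
        c24 = wide.get(f"{region}_24h")
        if c24 is not None:
            pre = wide.get(f"{region}_premix")
            net = net_lesions(c24.to_numpy(), pre.to_numpy() if pre is not None else 0)
            out[f"sl_{region}_24h"] = log1_transform(net)
        c3 = wide.get(f"{region}_3wk")
        if c3 is not None:
            out[f"sl_{region}_3wk"] = log1_transform(c3.to_numpy())
    return out


def transform_sna(sna_table: pd.DataFrame) -> pd.DataFrame:
    """Square-root the continuous centralities; keep binaries as 0/1."""
    out = pd.DataFrame({"animal": sna_table["animal"]})
    for trait in SQRT_SNA:
        out[f"sna_{trait}"] = sqrt_transform(sna_table[f"sna_{trait}"].to_numpy())
    out["sna_clique_member"] = sna_table["sna_clique_member"].astype(int)
    if "sna_betweenness_cat" in sna_table.columns:
        out["sna_betweenness_cat"] = sna_table["sna_betweenness_cat"].astype(int)
    return out


def assemble_trait_table(
    sna_table: pd.DataFrame,
    lesion_wide: pd.DataFrame | None,
    assignment: pd.DataFrame,
) -> pd.DataFrame:
    """Join transformed traits with pen assignment and fixed effects.

    ``assignment`` needs columns animal, pen, litter, sex, line, batch,
    weight.  Animal id sets must line up; offenders are listed in the error
    so upstream joins are debuggable.
    """
    sna_t = transform_sna(sna_table)
    base_ids = set(assignment["animal"])
    missing = sorted(set(sna_t["animal"]) - base_ids)
    if missing:
        raise KeyError(f"SNA rows for animals not in assignment: {missing}")
    table = assignment.merge(sna_t, on="animal", how="left")
    if lesion_wide is not None:
        les_t = transform_lesions(lesion_wide)
        missing = sorted(set(les_t["animal"]) - base_ids)
        if missing:
            raise KeyError(f"lesion rows for animals not in assignment: {missing}")
        table = table.merge(les_t, on="animal", how="left")
    return table
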