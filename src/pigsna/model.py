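"""Model specification and design-system assembly for the animal models.

The mixed model is ``y = Xb + Za + Wc + e`` with fixed effects line, sex
and batch plus a centred weight-at-mixing covariate, a pedigree-structured
additive genetic effect per animal (prior N(0, A kron G0)), and an iid
common pen effect (N(0, I kron C0)).  ``build_design`` turns a trait table
plus a pedigree into the numeric arrays the Gibbs kernels consume: the
incidence structure is stored as index vectors (record -> pedigree
position, record -> pen index) rather than explicit Z, W matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pigsna.pedigree import Pedigree

log = logging.getLogger(__name__)

DEFAULT_FACTORS = ("line", "sex", "batch")
DEFAULT_COVARIATES = ("weight",)

LINEAR = "linear"
THRESHOLD = "threshold"


class SeparationError(ValueError):
    """A threshold-model response has an empty category."""


@dataclass
class ModelSpec:
    """One- or two-trait animal-model specification.

    ``kinds`` entries are "linear" or "threshold"; at most one threshold
    trait is allowed in a bivariate model (the threshold-threshold variant
    is accepted but experimental).
    """

    traits: list[str]
    kinds: list[str] | None = None
    factors: tuple[str, ...] = DEFAULT_FACTORS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    pen_effect: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("ModelSpec supports 1 or 2 traits")
        if self.kinds is None:
            self.kinds = [LINEAR] * len(self.traits)
        if len(self.kinds) != len(self.traits):
            raise ValueError("kinds must match traits")
        for kd in self.kinds:
            if kd not in (LINEAR, THRESHOLD):
                raise ValueError(f"unknown trait kind {kd!r}")

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class DesignSystem:
    """Numeric design for the Gibbs kernels.

    y has one column per trait with NaN marking per-trait missingness
    (bivariate only; univariate rows with a missing response are dropped).
    ``animal_index`` maps records to pedigree positions; ``pen_index`` maps
    records to 0-based pen slots.  Binary responses additionally carry the
    observed category in ``binary`` (liabilities replace y during
    sampling).
    """

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    animal_index: np.ndarray
    pen_index: np.ndarray
    pen_ids: np.ndarray
    record_ids: np.ndarray
    pedigree: Pedigree
    spec: ModelSpec
    binary: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_animals(self) -> int:
        return len(self.pedigree)

    @property
    def n_pens(self) -> int:
        return len(self.pen_ids)


def _design_matrix(
    table: pd.DataFrame, factors, covariates
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for f in factors:
        levels = sorted(pd.unique(table[f]).tolist(), key=str)
        if len(levels) < 2:
            warnings.warn(
                f"factor {f!r} has a single observed level; column dropped "
                "(rank deficiency)", stacklevel=3,
            )
            continue
        for lev in levels[1:]:  # first level is the reference
            cols.append((table[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    for cv in covariates:
        x = table[cv].to_numpy(dtype=float)
        cols.append(x - x.mean())
        names.append(cv)
    return np.column_stack(cols), names


def build_design(
    trait_table: pd.DataFrame, spec: ModelSpec, pedigree: Pedigree
) -> DesignSystem:
    """Assemble y, X and the Z/W index maps for a model specification.

    Univariate: records with a missing response are dropped (count logged).
    Bivariate: records missing both responses are dropped; single-trait
    missingness is retained and handled by data augmentation in the
    sampler.  Threshold responses must be binary 0/1 with both categories
    observed.
    """
    for col in list(spec.traits) + list(spec.factors) + list(spec.covariates):
        if col not in trait_table.columns:
            raise KeyError(f"column {col!r} not in trait table")
    sub = trait_table.copy()
    resp = sub[spec.traits].to_numpy(dtype=float)
    if spec.n_traits == 1:
        keep = ~np.isnan(resp[:, 0])
    else:
        keep = ~np.all(np.isnan(resp), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("build_design: dropped %d record(s) with missing response", dropped)
    sub = sub.loc[keep].reset_index(drop=True)
    if sub.empty:
        raise ValueError("no records with an observed response")
    y = sub[spec.traits].to_numpy(dtype=float)

    binary = None
    if THRESHOLD in spec.kinds:
        binary = np.full(y.shape, -1, dtype=np.int8)
        for t, kd in enumerate(spec.kinds):
            if kd != THRESHOLD:
                continue
            obs = y[:, t][~np.isnan(y[:, t])]
            vals = np.unique(obs)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"threshold trait {spec.traits[t]!r} must be 0/1")
            if len(vals) < 2:
                raise SeparationError(
                    f"threshold trait {spec.traits[t]!r} has a single observed category"
                )
            mask = ~np.isnan(y[:, t])
            binary[mask, t] = y[mask, t].astype(np.int8)

    X, x_names = _design_matrix(sub, spec.factors, spec.covariates)
    animal_index = np.array(
        [pedigree.position(a) for a in sub["animal"]], dtype=np.int64
    )
    pen_ids, pen_index = np.unique(sub["pen"].to_numpy(), return_inverse=True)
    return DesignSystem(
        y=y,
        X=X,
        x_names=x_names,
        animal_index=animal_index,
        pen_index=pen_index.astype(np.int64),
        pen_ids=pen_ids,
        record_ids=sub["animal"].to_numpy(),
        pedigree=pedigree,
        spec=spec,
        binary=binary,
        n_dropped=dropped,
    )
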