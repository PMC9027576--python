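"""Canned synthetic-data studies: parameter recovery and selection response.

These functions bundle the generator, the samplers and the summaries into
reproducible experiments: simulate data with known parameters, fit the
matching animal model, and report how well the truth is recovered.  They
back both the validation suite and the reproduction script.

Default problem sizes are chosen to resolve the quantities of interest on
one CPU in minutes: 2,000 phenotyped offspring of 80 sires in 78 pens for
recovery studies (posterior SD of h2 about 0.05 at h2 = 0.3), and the
full study-scale population (82 sires, 217 dams, 78 pens of 15) for the
selection-response sign studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pigsna.gibbs import MCMCSettings, gibbs_bivariate, gibbs_linear, gibbs_threshold
from pigsna.model import THRESHOLD, ModelSpec, build_design
from pigsna.pedigree import build_A_inverse
from pigsna.selection import build_index, correlated_response, select_lowest, standardize_ebv
from pigsna.simulate import realistic_dataset, recovery_dataset, simulate_binary_trait
from pigsna.summaries import summarize

#: reduced desk-scale chain protocol for recovery studies
REDUCED_CHAIN = dict(n_iter=50_000, burn_in=5_000, thin=10)


def linear_recovery(
    seed: int,
    n_replicates: int = 20,
    n_animals: int = 2_000,
    n_sires: int = 80,
    n_dams: int = 400,
    n_pens: int = 78,
    h2: float = 0.30,
    c2: float = 0.10,
    chain: dict | None = None,
) -> pd.DataFrame:
    """Replicated univariate linear-model recovery of h2 and c2.

    Each replicate simulates a fresh population and chain seed derived from
    ``seed``.  Returns one row per replicate with posterior means, HPD
    bounds and coverage indicators.
    """
    chain = chain or REDUCED_CHAIN
    rows = []
    for rep in range(n_replicates):
        dseed = (seed * 1_009 + 7_919 * rep) % 2**31
        ds = recovery_dataset(
            n_animals=n_animals, n_sires=n_sires, n_dams=n_dams, n_pens=n_pens,
            h2=h2, c2=c2, seed=dseed,
        )
        design = build_design(ds.trait_table, ModelSpec(["trait_1"]), ds.pedigree)
        samples = gibbs_linear(
            design, build_A_inverse(ds.pedigree),
            MCMCSettings(seed=(dseed + 1) % 2**31, **chain),
        )
        su = summarize(samples)
        h, c = su.h2["trait_1"], su.c2["trait_1"]
        rows.append(
            {
                "replicate": rep,
                "h2_mean": h.mean, "h2_lo": h.hpd_lower, "h2_hi": h.hpd_upper,
                "h2_covered": h.covers(h2),
                "c2_mean": c.mean, "c2_lo": c.hpd_lower, "c2_hi": c.hpd_upper,
                "c2_covered": c.covers(c2),
            }
        )
    return pd.DataFrame(rows)


def threshold_recovery(
    seed: int,
    h2: float = 0.20,
    c2: float = 0.10,
    prevalence: float = 0.25,
    n_animals: int = 2_000,
    n_sires: int = 80,
    n_dams: int = 400,
    n_pens: int = 78,
    chain: dict | None = None,
) -> dict:
    """Threshold-liability recovery of a liability-scale heritability.

    The binary trait is cut from a simulated liability at the quantile
    giving the requested prevalence.  Uses the proper weakly-informative
    covariance prior: with binary data the flat prior can leave the
    liability-scale variances effectively improper.
    """
    chain = chain or dict(n_iter=60_000, burn_in=10_000, thin=10)
    dseed = seed % 2**31
    ds = recovery_dataset(
        n_animals=n_animals, n_sires=n_sires, n_dams=n_dams, n_pens=n_pens,
        h2=h2, c2=c2, seed=dseed,
    )
    tt = ds.trait_table.copy()
    liab = tt["trait_1"].to_numpy()
    cut = float(np.quantile(liab, 1.0 - prevalence))
    tt["binary"] = simulate_binary_trait(liab, cut).astype(float)
    design = build_design(tt, ModelSpec(["binary"], kinds=[THRESHOLD]), ds.pedigree)
    samples = gibbs_threshold(
        design, build_A_inverse(ds.pedigree),
        MCMCSettings(seed=(dseed + 1) % 2**31, prior="weak", **chain),
    )
    h = summarize(samples).h2["binary"]
    return {
        "true_h2": h2,
        "prevalence": float(tt["binary"].mean()),
        "h2_mean": h.mean,
        "h2_lo": h.hpd_lower,
        "h2_hi": h.hpd_upper,
        "h2_covered": h.covers(h2),
        "n": len(tt),
    }


def bivariate_recovery(
    seed: int,
    rg: float = 0.90,
    h2: tuple[float, float] = (0.30, 0.30),
    c2: tuple[float, float] = (0.10, 0.10),
    n_animals: int = 2_000,
    n_sires: int = 80,
    n_dams: int = 400,
    n_pens: int = 78,
    chain: dict | None = None,
) -> dict:
    """Bivariate linear-model recovery of a genetic correlation."""
    chain = chain or dict(n_iter=40_000, burn_in=5_000, thin=10)
    dseed = seed % 2**31
    ds = recovery_dataset(
        n_animals=n_animals, n_sires=n_sires, n_dams=n_dams, n_pens=n_pens,
        h2=list(h2), c2=list(c2), rg=rg, seed=dseed,
    )
    design = build_design(
        ds.trait_table, ModelSpec(["trait_1", "trait_2"]), ds.pedigree
    )
    samples = gibbs_bivariate(
        design, build_A_inverse(ds.pedigree),
        MCMCSettings(seed=(dseed + 1) % 2**31, **chain),
    )
    r = summarize(samples).rg
    return {
        "true_rg": rg,
        "rg_mean": r.mean,
        "rg_lo": r.hpd_lower,
        "rg_hi": r.hpd_upper,
        "rg_covered": r.covers(rg),
        "n": len(ds.trait_table),
    }


@dataclass
class SelectionSignResult:
    """Per-replicate correlated-response means, in z-score units."""

    seed: int
    eig_selected_mean: float  # mean eigenvector EBV of the selected 10%
    clu_selected_mean: float
    index_selected_mean: float
    eig_to_anterior_24h: float  # mean anterior-SL24h EBV under eig selection
    clu_to_posterior_3wk: float


def selection_sign_study(
    seed: int,
    n_seeds: int = 10,
    n_sires: int = 82,
    n_dams: int = 217,
    n_pens: int = 78,
    fraction: float = 0.10,
    chain: dict | None = None,
) -> list[SelectionSignResult]:
    """Directional reproduction of the correlated selection response.

    For each replicate a study-scale population is generated under the
    realistic preset (strong negative eigenvector-clustering genetic
    correlation; positive eigenvector x anterior-SL24h and clustering x
    posterior-SL3wk correlations).  Univariate fits give EBVs for the two
    centralities and the two lesion traits; the lowest-EBV tenth is
    selected and the mean standardized lesion EBVs of the selected animals
    are recorded.  The expected pattern is a negative anterior-SL24h mean
    under eigenvector selection and a negative posterior-SL3wk mean under
    clustering selection.
    """
    chain = chain or dict(n_iter=8_000, burn_in=1_500, thin=5)
    traits = ["sna_eigenvector", "sna_clustering", "sl_anterior_24h",
              "sl_posterior_3wk"]
    results = []
    for rep in range(n_seeds):
        dseed = (seed * 6_007 + 104_729 * rep) % 2**31
        ds = realistic_dataset(seed=dseed, n_sires=n_sires, n_dams=n_dams,
                                n_pens=n_pens)
        ainv = build_A_inverse(ds.pedigree)
        ebv = None
        for k, trait in enumerate(traits):
            design = build_design(ds.trait_table, ModelSpec([trait]), ds.pedigree)
            samples = gibbs_linear(
                design, ainv, MCMCSettings(seed=(dseed + k + 1) % 2**31, **chain)
            )
            cols = summarize(samples).ebv[["animal", f"ebv_{trait}"]]
            ebv = cols if ebv is None else ebv.merge(cols, on="animal")
        penned = ds.trait_table[["animal"]]
        ebv = penned.merge(ebv, on="animal").set_index("animal")
        z = standardize_ebv(ebv)
        z["index"] = build_index(
            z["ebv_sna_eigenvector"], z["ebv_sna_clustering"]
        )
        sel_eig = select_lowest(z["ebv_sna_eigenvector"], fraction)
        sel_clu = select_lowest(z["ebv_sna_clustering"], fraction)
        sel_idx = select_lowest(z["index"], fraction)
        rep_eig = correlated_response(
            sel_eig, z, target_columns=["ebv_sl_anterior_24h"]
        )
        rep_clu = correlated_response(
            sel_clu, z, target_columns=["ebv_sl_posterior_3wk"]
        )
        results.append(
            SelectionSignResult(
                seed=dseed,
                eig_selected_mean=float(
                    z.loc[sel_eig, "ebv_sna_eigenvector"].mean()
                ),
                clu_selected_mean=float(
                    z.loc[sel_clu, "ebv_sna_clustering"].mean()
                ),
                index_selected_mean=float(z.loc[sel_idx, "index"].mean() / 2.0),
                eig_to_anterior_24h=float(rep_eig.group_mean.iloc[0]),
                clu_to_posterior_3wk=float(rep_clu.group_mean.iloc[0]),
            )
        )
    return results
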