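"""Synthetic pig populations with the structure the analyses assume.

The generator emulates a two-generation commercial pig population: founder
sires and dams, litters of offspring, same-sex same-line pens of 15 animals
drawn 3-per-litter from 5 litters, batch structure, a weight-at-mixing
covariate, genetically structured aggression networks, and lesion/centrality
phenotypes drawn from the additive-genetic + pen + residual model that the
Gibbs samplers fit.  Defaults mirror the study population scale: 82 sires,
217 dams, litters of about 10 (so roughly 2400 animals in the pedigree),
78 pens of 15, 14 batches.

Phenotypes are emitted directly on the modelled (transformed) scale, since
parameter recovery is checked on that scale; raw Poisson lesion counts are
offered separately for exercising the count-to-trait transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from pigsna.network import InteractionRecord
from pigsna.pedigree import Pedigree, inbreeding

SEXES = ("male", "female", "castrated")
LINES = ("Y", "YxL")


class CompositionError(ValueError):
    """Pen composition constraints cannot be met by the pedigree."""


@dataclass
class EdgeModel:
    """Logistic link from latent aggressiveness to dyadic interaction odds.

    For pen-mates i, j the probability of at least one fight is
    ``sigmoid(fight_intercept + fight_slope * (l_i + l_j))`` and analogously
    for bullying, with l the latent aggressiveness (simulated as a
    unit-variance heritable trait).  Defaults give a mean of roughly 5-6
    interaction partners per animal in a 15-pig pen.
    """

    fight_intercept: float = -1.0
    fight_slope: float = 0.8
    bully_intercept: float = -1.6
    bully_slope: float = 0.8


@dataclass
class TrueParameters:
    """Generating values for the variance-component model.

    G0, C0, R0 are k-trait covariance matrices (additive genetic, common
    pen, residual).  ``fixed_effect_values`` maps factor name to a
    {level: k-vector} dict plus optional "intercept" and "weight_slope"
    k-vectors.  The implied per-trait heritability must lie in (0, 1).
    """

    trait_names: list[str]
    G0: np.ndarray
    C0: np.ndarray
    R0: np.ndarray
    fixed_effect_values: dict = field(default_factory=dict)
    edge_model: EdgeModel = field(default_factory=EdgeModel)

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        for name in ("G0", "C0", "R0"):
            m = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
            setattr(self, name, m)
        vp = np.diag(self.G0) + np.diag(self.C0) + np.diag(self.R0)
        h2 = np.diag(self.G0) / vp
        if np.any(vp <= 0) or np.any(h2 >= 1.0):
            raise ValueError("implied heritabilities must lie in (0, 1)")

    @property
    def h2(self) -> np.ndarray:
        vp = np.diag(self.G0) + np.diag(self.C0) + np.diag(self.R0)
        return np.diag(self.G0) / vp

    @property
    def c2(self) -> np.ndarray:
        vp = np.diag(self.G0) + np.diag(self.C0) + np.diag(self.R0)
        return np.diag(self.C0) / vp


def simulate_pedigree(
    n_sires: int = 82,
    n_dams: int = 217,
    offspring_per_dam: float = 9.8,
    seed: int = 0,
) -> Pedigree:
    """Two-generation pedigree: unrelated founders plus one litter per dam.

    Each dam is mated to one uniformly chosen sire; her litter size is
    ``floor(offspring_per_dam)`` plus a Bernoulli on the fractional part, so
    the expected total matches ``n_dams * offspring_per_dam``.  Ids are
    1..n_sires for sires, then dams, then offspring.
    """
    if n_sires < 1 or n_dams < 1 or offspring_per_dam <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    sire_ids = np.arange(1, n_sires + 1)
    dam_ids = np.arange(n_sires + 1, n_sires + n_dams + 1)
    base = int(np.floor(offspring_per_dam))
    frac = offspring_per_dam - base
    litter_sizes = base + (rng.random(n_dams) < frac).astype(int)
    mates = rng.integers(0, n_sires, size=n_dams)

    ids = [sire_ids, dam_ids]
    sires = [np.zeros(n_sires, dtype=np.int64), np.zeros(n_dams, dtype=np.int64)]
    dams = [np.zeros(n_sires, dtype=np.int64), np.zeros(n_dams, dtype=np.int64)]
    gens = [np.zeros(n_sires, dtype=np.int64), np.zeros(n_dams, dtype=np.int64)]
    next_id = n_sires + n_dams + 1
    off_s, off_d = [], []
    for d in range(n_dams):
        off_s.extend([sire_ids[mates[d]]] * litter_sizes[d])
        off_d.extend([dam_ids[d]] * litter_sizes[d])
    n_off = len(off_s)
    ids.append(np.arange(next_id, next_id + n_off))
    sires.append(np.asarray(off_s, dtype=np.int64))
    dams.append(np.asarray(off_d, dtype=np.int64))
    gens.append(np.ones(n_off, dtype=np.int64))
    return Pedigree(
        np.concatenate(ids), np.concatenate(sires), np.concatenate(dams),
        generation=np.concatenate(gens),
    )


def assign_pens(
    pedigree: Pedigree,
    n_pens: int = 78,
    pen_size: int = 15,
    per_litter: int = 3,
    litters_per_pen: int = 5,
    n_batches: int = 14,
    line_fractions: tuple[float, float] = (0.61, 0.39),
    weight_mean: float = 28.0,
    weight_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Form same-sex, same-line pens of ``pen_size`` from litters.

    Each pen takes ``per_litter`` animals from each of ``litters_per_pen``
    distinct litters of the same genetic line (a litter = one dam's
    offspring; lines are assigned at the litter level).  Sex is constant
    within a pen and cycled across pens; batches are allocated round-robin
    (pens mixed the same day share a batch).  Offspring left over once
    ``n_pens`` are filled are returned with ``pen = -1`` (unpenned).

    Raises :class:`CompositionError` if the litters cannot supply the
    requested number of pens.
    """
    if pen_size != per_litter * litters_per_pen:
        raise CompositionError(
            f"pen_size {pen_size} != per_litter {per_litter} x litters_per_pen {litters_per_pen}"
        )
    rng = np.random.default_rng(seed)
    off_mask = ~pedigree.founder_mask
    offspring = pedigree.ids[off_mask]
    off_dam = pedigree.dam[off_mask]
    dams = np.unique(off_dam)
    n_lines = len(line_fractions)
    dam_line = rng.choice(n_lines, size=len(dams), p=np.asarray(line_fractions))
    line_of_dam = dict(zip(dams.tolist(), dam_line.tolist()))

    # per-litter pools of unassigned offspring, grouped by line
    pools: dict[int, dict[int, list[int]]] = {li: {} for li in range(n_lines)}
    for dam in dams:
        members = offspring[off_dam == dam].tolist()
        rng.shuffle(members)
        pools[line_of_dam[int(dam)]][int(dam)] = members

    rows = []
    for pen in range(n_pens):
        # prefer the line with more remaining capacity so both lines get pens
        capacity = {
            li: sum(len(v) // per_litter for v in pools[li].values())
            for li in range(n_lines)
        }
        feasible = [
            li
            for li in range(n_lines)
            if sum(1 for v in pools[li].values() if len(v) >= per_litter) >= litters_per_pen
        ]
        if not feasible:
            raise CompositionError(
                f"only {pen} of {n_pens} pens formable: too few litters with "
                f">= {per_litter} unassigned animals"
            )
        li = max(feasible, key=lambda l: capacity[l])
        eligible = [d for d, v in pools[li].items() if len(v) >= per_litter]
        chosen = rng.choice(len(eligible), size=litters_per_pen, replace=False)
        sex = SEXES[pen % len(SEXES)]
        batch = pen % n_batches
        for ci in chosen:
            dam = eligible[ci]
            for _ in range(per_litter):
                animal = pools[li][dam].pop()
                rows.append((animal, pen, dam, sex, LINES[li] if li < 2 else f"L{li}", batch))
    for li in range(n_lines):
        for dam, members in pools[li].items():
            for animal in members:
                rows.append((animal, -1, dam, "unassigned",
                             LINES[li] if li < 2 else f"L{li}", -1))
    out = pd.DataFrame(rows, columns=["animal", "pen", "litter", "sex", "line", "batch"])
    out["weight"] = np.round(rng.normal(weight_mean, weight_sd, size=len(out)), 2)
    return out.sort_values("animal", ignore_index=True)


def _psd_factor(G0: np.ndarray) -> np.ndarray:
    """Factor L with L L' = G0, valid for merely positive semi-definite G0."""
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    if not np.allclose(G0, G0.T):
        raise ValueError("covariance matrix must be symmetric")
    w, v = np.linalg.eigh(G0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("covariance matrix must be positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_breeding_values(
    pedigree: Pedigree, G0: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Additive genetic values gene-dropped through the pedigree.

    Founders are iid N(0, G0); each offspring is the parent average plus a
    Mendelian-sampling deviation with covariance ``(1/2 - (F_s + F_d)/4) G0``
    (3/4-rule for a single known parent).  Over replicates the values have
    covariance ``A (kron) G0``.  Returns an (n_pedigree x k) matrix in
    pedigree order.
    """
    L = _psd_factor(G0)
    k = L.shape[0]
    rng = np.random.default_rng(seed)
    spos, dpos = pedigree.parent_positions
    F = inbreeding(pedigree)
    n = len(pedigree)
    a = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = spos[i], dpos[i]
        if s < 0 and d < 0:
            a[i] = L @ z[i]
        else:
            mean = np.zeros(k)
            if s >= 0 and d >= 0:
                mean = 0.5 * (a[s] + a[d])
                ms_var = 0.5 - 0.25 * (F[s] + F[d])
            else:
                p = s if s >= 0 else d
                mean = 0.5 * a[p]
                ms_var = 0.75 - 0.25 * F[p]
            a[i] = mean + np.sqrt(ms_var) * (L @ z[i])
    return a


def simulate_phenotypes(
    assignment: pd.DataFrame,
    breeding_values: np.ndarray,
    pedigree: Pedigree,
    params: TrueParameters,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes for penned animals: fixed effects + a + pen + residual.

    One pen-effect draw from N(0, C0) per pen (shared by all pen-mates) and
    independent residuals from N(0, R0).  The weight covariate enters
    centred.  Returns the trait table (one row per penned animal) with
    columns named after ``params.trait_names``.
    """
    rng = np.random.default_rng(seed)
    penned = assignment[assignment["pen"] >= 0].reset_index(drop=True)
    if penned.empty:
        raise ValueError("no penned animals in the assignment")
    k = len(params.trait_names)
    n = len(penned)
    Lc = _psd_factor(params.C0)
    Lr = _psd_factor(params.R0)
    pens = np.unique(penned["pen"].to_numpy())
    pen_eff = {int(p): Lc @ rng.standard_normal(k) for p in pens}

    fe = params.fixed_effect_values
    y = np.tile(np.asarray(fe.get("intercept", np.zeros(k)), dtype=float), (n, 1))
    for factor in ("line", "sex", "batch"):
        levels = fe.get(factor)
        if levels:
            y += np.stack([
                np.asarray(levels.get(v, np.zeros(k)), dtype=float)
                for v in penned[factor]
            ])
    slope = np.asarray(fe.get("weight_slope", np.zeros(k)), dtype=float)
    wc = penned["weight"].to_numpy() - penned["weight"].mean()
    y += np.outer(wc, slope)

    pos = np.array([pedigree.position(a) for a in penned["animal"]])
    y += breeding_values[pos]
    y += np.stack([pen_eff[int(p)] for p in penned["pen"]])
    y += rng.standard_normal((n, k)) @ Lr.T

    out = penned.copy()
    for t, name in enumerate(params.trait_names):
        out[name] = y[:, t]
    return out


def simulate_interactions(
    assignment: pd.DataFrame,
    latent_aggressiveness: dict | pd.Series,
    edge_model: EdgeModel | None = None,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Dyadic fight/bully records from latent aggressiveness.

    Each within-pen dyad fights with probability
    ``sigmoid(intercept + slope (l_i + l_j))``; bullying is drawn
    independently with its own parameters.  The initiator is chosen
    uniformly and an exponential duration is attached (unused downstream).
    """
    em = edge_model or EdgeModel()
    rng = np.random.default_rng(seed)
    lat = dict(latent_aggressiveness)
    records: list[InteractionRecord] = []
    penned = assignment[assignment["pen"] >= 0]
    for pen, group in penned.groupby("pen"):
        members = group["animal"].tolist()
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                i, j = members[ii], members[jj]
                s = lat[i] + lat[j]
                for kind, b0, b1, scale in (
                    ("fight", em.fight_intercept, em.fight_slope, 20.0),
                    ("bully", em.bully_intercept, em.bully_slope, 10.0),
                ):
                    p = expit(b0 + b1 * s)
                    if rng.random() < p:
                        init, recv = (i, j) if rng.random() < 0.5 else (j, i)
                        records.append(
                            InteractionRecord(int(pen), int(init), int(recv), kind,
                                              float(np.round(rng.exponential(scale), 1)))
                        )
    return records


def simulate_binary_trait(liability_values: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Observed binary trait: 1 where the latent liability exceeds the threshold."""
    return (np.asarray(liability_values, dtype=float) > threshold).astype(int)


def simulate_lesion_counts(
    trait_table: pd.DataFrame,
    lesion_traits: list[str],
    premix_mean: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw Poisson lesion counts consistent with log-scale lesion traits.

    For each modelled-scale value m the count is Poisson(exp(m) - 1), so
    log(count + 1) recovers m in expectation up to Poisson noise; a small
    Poisson pre-mixing count is added for the 24 h traits so the
    net-lesion subtraction is exercised.  Column names follow the
    ``{region}_{timepoint}`` wide-count convention.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"animal": trait_table["animal"]})
    for col in lesion_traits:
        region, tp = col.removeprefix("sl_").rsplit("_", 1)
        lam = np.clip(np.exp(trait_table[col].to_numpy()) - 1.0, 0.0, None)
        fresh = rng.poisson(lam)
        if tp == "24h":
            pre = rng.poisson(premix_mean, size=len(out))
            out[f"{region}_premix"] = pre
            out[f"{region}_24h"] = fresh + pre
        else:
            out[f"{region}_{tp}"] = fresh
    return out


# ---------------------------------------------------------------------------
# parameter presets and dataset bundles


def nearest_correlation(R: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest valid correlation matrix by alternating eigenvalue clipping
    and unit-diagonal rescaling.

    Pairwise-assembled correlation tables (each entry estimated from a
    separate bivariate fit) are routinely indefinite; this projection is how
    they become usable as a joint generating matrix.
    """
    X = np.array(R, dtype=float)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(X)
        if w.min() >= -tol and np.allclose(np.diag(X), 1.0, atol=tol):
            break
        X = (v * np.clip(w, 1e-6, None)) @ v.T
        d = np.sqrt(np.diag(X))
        X = X / np.outer(d, d)
        X = 0.5 * (X + X.T)
        np.fill_diagonal(X, 1.0)
    return X


#: continuous traits of the "realistic" preset, in fixed order
REALISTIC_TRAITS = [
    "sna_betweenness",
    "sna_closeness",
    "sna_degree",
    "sna_eigenvector",
    "sna_clustering",
    "sl_anterior_24h",
    "sl_central_24h",
    "sl_posterior_24h",
    "sl_anterior_3wk",
    "sl_central_3wk",
    "sl_posterior_3wk",
]


def realistic_parameters() -> TrueParameters:
    """Generating parameters for the realistic preset.

    Heritabilities, pen-effect ratios and phenotypic variances of the five
    continuous centrality traits are set to published posterior means for
    this kind of data (h2 0.09-0.26, c2 0.01-0.59); lesion traits use
    h2 = 0.20 and c2 = 0.10 with phenotypic variances matching the reported
    log-scale trait SDs.  The genetic correlation matrix reproduces the
    reported pairwise structure (strong positive correlations among the
    centralities, strong negative correlations of the clustering
    coefficient with them, positive centrality x anterior-SL24h and
    negative centrality x SL3wk correlations) and is projected to the
    nearest valid correlation matrix, since pairwise estimates do not form
    a jointly positive-definite matrix.  Pen effects are uncorrelated
    across traits; residual correlations are a 0.4-shrunk copy of the
    genetic ones, giving phenotypic correlations in the same direction but
    weaker — the pattern reported for these traits.
    """
    h2 = np.array([0.26, 0.09, 0.26, 0.22, 0.18, 0.20, 0.20, 0.20, 0.20, 0.20, 0.20])
    c2 = np.array([0.02, 0.59, 0.14, 0.01, 0.23, 0.10, 0.10, 0.10, 0.10, 0.10, 0.10])
    vp = np.array([0.015, 0.006, 0.010, 0.006, 0.008,
                   1.166, 1.210, 1.040, 0.325, 0.360, 0.504])

    k = len(REALISTIC_TRAITS)
    Rg = np.eye(k)

    def set_rg(t1: str, t2: str, val: float) -> None:
        i, j = REALISTIC_TRAITS.index(t1), REALISTIC_TRAITS.index(t2)
        Rg[i, j] = Rg[j, i] = val

    # centrality x centrality
    set_rg("sna_betweenness", "sna_closeness", 0.97)
    set_rg("sna_betweenness", "sna_degree", 0.99)
    set_rg("sna_betweenness", "sna_eigenvector", 0.96)
    set_rg("sna_betweenness", "sna_clustering", -0.95)
    set_rg("sna_closeness", "sna_degree", 0.98)
    set_rg("sna_closeness", "sna_eigenvector", 0.97)
    set_rg("sna_closeness", "sna_clustering", -0.98)
    set_rg("sna_degree", "sna_eigenvector", 0.98)
    set_rg("sna_degree", "sna_clustering", -0.88)
    set_rg("sna_eigenvector", "sna_clustering", -0.95)
    # centrality x SL24h
    for t, a, c, p in (
        ("sna_betweenness", 0.46, -0.10, -0.27),
        ("sna_closeness", 0.49, 0.10, -0.23),
        ("sna_degree", 0.62, 0.01, -0.02),
        ("sna_eigenvector", 0.54, -0.19, -0.13),
        ("sna_clustering", -0.14, 0.63, 0.73),
    ):
        set_rg(t, "sl_anterior_24h", a)
        set_rg(t, "sl_central_24h", c)
        set_rg(t, "sl_posterior_24h", p)
    # centrality x SL3wk
    for t, a, c, p in (
        ("sna_betweenness", -0.57, -0.49, -0.78),
        ("sna_closeness", -0.33, -0.28, -0.06),
        ("sna_degree", -0.37, -0.18, 0.06),
        ("sna_eigenvector", -0.47, -0.23, -0.17),
        ("sna_clustering", 0.68, 0.62, 0.40),
    ):
        set_rg(t, "sl_anterior_3wk", a)
        set_rg(t, "sl_central_3wk", c)
        set_rg(t, "sl_posterior_3wk", p)
    # lesion x lesion (not reported; modest within-timepoint association)
    lesions = REALISTIC_TRAITS[5:]
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            same_tp = lesions[i].rsplit("_", 1)[1] == lesions[j].rsplit("_", 1)[1]
            set_rg(lesions[i], lesions[j], 0.3 if same_tp else 0.1)

    Rg = nearest_correlation(Rg)
    sg = np.sqrt(h2 * vp)
    G0 = Rg * np.outer(sg, sg)
    C0 = np.diag(c2 * vp)
    Re = 0.6 * np.eye(k) + 0.4 * Rg
    se = np.sqrt((1.0 - h2 - c2) * vp)
    R0 = Re * np.outer(se, se)

    rng = np.random.default_rng(20220323)
    fixed = {
        "intercept": np.zeros(k),
        "line": {"Y": np.zeros(k), "YxL": 0.1 * np.sqrt(vp)},
        "sex": {s: rng.normal(0.0, 0.1) * np.sqrt(vp) for s in SEXES},
        "batch": {b: rng.normal(0.0, 0.1) * np.sqrt(vp) for b in range(14)},
        "weight_slope": 0.01 * np.sqrt(vp),
    }
    return TrueParameters(list(REALISTIC_TRAITS), G0, C0, R0, fixed)


@dataclass
class SyntheticDataset:
    """Bundle of generator outputs consumed by the downstream stages."""

    pedigree: Pedigree
    assignment: pd.DataFrame
    breeding_values: np.ndarray
    trait_table: pd.DataFrame
    params: TrueParameters


def realistic_dataset(
    seed: int = 0,
    n_sires: int = 82,
    n_dams: int = 217,
    offspring_per_dam: float = 9.8,
    n_pens: int = 78,
) -> SyntheticDataset:
    """Full study-scale dataset under the realistic preset."""
    params = realistic_parameters()
    ped = simulate_pedigree(n_sires, n_dams, offspring_per_dam, seed=seed)
    assignment = assign_pens(ped, n_pens=n_pens, seed=seed + 1)
    bv = simulate_breeding_values(ped, params.G0, seed=seed + 2)
    traits = simulate_phenotypes(assignment, bv, ped, params, seed=seed + 3)
    return SyntheticDataset(ped, assignment, bv, traits, params)


def recovery_dataset(
    n_animals: int = 2000,
    n_sires: int = 80,
    n_dams: int = 400,
    n_pens: int = 78,
    h2=0.30,
    c2=0.10,
    vp=1.0,
    rg: float = 0.0,
    trait_names: list[str] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simple balanced dataset for parameter-recovery studies.

    Offspring are spread over ``n_pens`` pens at random (pen composition is
    irrelevant to variance-component recovery), with pen-level sex, line
    and batch and an animal-level weight covariate.  Scalar ``h2``/``c2``
    give a univariate trait; length-2 sequences plus ``rg`` give a
    bivariate one.
    """
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    c2 = np.atleast_1d(np.asarray(c2, dtype=float))
    vp = np.broadcast_to(np.atleast_1d(np.asarray(vp, dtype=float)), h2.shape).astype(float)
    k = len(h2)
    names = trait_names or [f"trait_{t + 1}" for t in range(k)]
    Rg = np.eye(k)
    if k == 2:
        Rg[0, 1] = Rg[1, 0] = rg
    sg = np.sqrt(h2 * vp)
    G0 = Rg * np.outer(sg, sg)
    C0 = np.diag(c2 * vp)
    R0 = np.diag((1.0 - h2 - c2) * vp)

    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(n_sires, n_dams, n_animals / n_dams, seed=seed)
    off = ped.ids[~ped.founder_mask]
    pen = rng.integers(0, n_pens, size=len(off))
    # pen-level factors drawn independently so no factor is an exact linear
    # combination of another (batch levels still cover 1..14 evenly)
    pen_sex = rng.choice(len(SEXES), size=n_pens)
    pen_line = rng.choice(2, size=n_pens)
    pen_batch = rng.permutation(n_pens) % 14
    assignment = pd.DataFrame(
        {
            "animal": off,
            "pen": pen,
            "litter": ped.dam[~ped.founder_mask],
            "sex": [SEXES[pen_sex[p]] for p in pen],
            "line": [LINES[pen_line[p]] for p in pen],
            "batch": pen_batch[pen],
            "weight": np.round(rng.normal(28.0, 3.0, size=len(off)), 2),
        }
    )
    fixed = {
        "intercept": np.full(k, 1.0),
        "line": {"Y": np.zeros(k), "YxL": np.full(k, 0.2) * np.sqrt(vp)},
        "sex": {s: np.full(k, v) * np.sqrt(vp)
                for s, v in zip(SEXES, (0.0, -0.15, 0.1))},
        "batch": {b: np.full(k, x)
                  for b, x in enumerate(np.random.default_rng(seed + 9).normal(0, 0.1, 14))},
        "weight_slope": np.full(k, 0.02),
    }
    params = TrueParameters(names, G0, C0, R0, fixed)
    bv = simulate_breeding_values(ped, G0, seed=seed + 1)
    traits = simulate_phenotypes(assignment, bv, ped, params, seed=seed + 2)
    return SyntheticDataset(ped, assignment, bv, traits, params)
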