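"""Posterior summaries: heritabilities, genetic correlations, HPD intervals,
EBV tables and chain convergence diagnostics.

Derived chains are computed draw by draw — h2 = s2a / (s2a + s2c + s2e),
c2 analogously, Vp as the sum, and rg = G0[0,1] / sqrt(G0[0,0] G0[1,1]) —
then summarised by posterior mean, SD and the 95% highest posterior
density interval (shortest interval containing 95% of the draws).  For a
threshold trait the residual variance in the denominator is the fixed
liability-scale 1, so its h2 is on the liability scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pigsna.gibbs import PosteriorSamples
from pigsna.model import THRESHOLD


def hpd_interval(chain: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over sorted draws holding ``mass``.

    Uses ceil(mass * n) draws; among equally short windows the one with the
    smallest lower bound wins.
    """
    x = np.sort(np.asarray(chain, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 draws for an HPD interval")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    m = math.ceil(mass * n)
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))  # argmin takes the first = smallest lower bound
    return float(x[k]), float(x[k + m - 1])


@dataclass
class ParameterSummary:
    mean: float
    sd: float
    hpd_lower: float
    hpd_upper: float

    @classmethod
    def from_chain(cls, chain: np.ndarray, mass: float = 0.95) -> "ParameterSummary":
        lo, hi = hpd_interval(chain, mass)
        return cls(float(np.mean(chain)), float(np.std(chain)), lo, hi)

    def covers(self, value: float) -> bool:
        return self.hpd_lower <= value <= self.hpd_upper


@dataclass
class PosteriorSummary:
    """Per-trait h2, c2, Vp (and rg for bivariate fits) plus EBV means."""

    trait_names: list[str]
    h2: dict[str, ParameterSummary]
    c2: dict[str, ParameterSummary]
    vp: dict[str, ParameterSummary]
    rg: ParameterSummary | None
    ebv: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trait_names:
            row = {"trait": t}
            for name, d in (("h2", self.h2), ("c2", self.c2), ("vp", self.vp)):
                s = d[t]
                row.update(
                    {
                        f"{name}_mean": s.mean,
                        f"{name}_sd": s.sd,
                        f"{name}_hpd_lo": s.hpd_lower,
                        f"{name}_hpd_hi": s.hpd_upper,
                    }
                )
            if self.rg is not None:
                row.update(
                    {
                        "rg_mean": self.rg.mean,
                        "rg_sd": self.rg.sd,
                        "rg_hpd_lo": self.rg.hpd_lower,
                        "rg_hpd_hi": self.rg.hpd_upper,
                    }
                )
            rows.append(row)
        return pd.DataFrame(rows)


def derived_chains(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    """Per-draw h2/c2/Vp chains for each trait, and rg for two traits."""
    out: dict[str, np.ndarray] = {}
    k = len(samples.trait_names)
    for t, name in enumerate(samples.trait_names):
        s2a = samples.G0[:, t, t]
        s2c = samples.C0[:, t, t]
        s2e = samples.R0[:, t, t]
        vp = s2a + s2c + s2e
        out[f"h2:{name}"] = s2a / vp
        out[f"c2:{name}"] = s2c / vp
        out[f"vp:{name}"] = vp
    if k == 2:
        out["rg"] = samples.G0[:, 0, 1] / np.sqrt(
            samples.G0[:, 0, 0] * samples.G0[:, 1, 1]
        )
    return out


def summarize(samples: PosteriorSamples, mass: float = 0.95) -> PosteriorSummary:
    """Posterior mean, SD and HPD of h2, c2, Vp (and rg), plus EBV means."""
    if samples.n_stored < 100:
        raise ValueError(
            f"only {samples.n_stored} stored draws; need >= 100 for summaries"
        )
    chains = derived_chains(samples)
    h2, c2, vp = {}, {}, {}
    for t in samples.trait_names:
        h2[t] = ParameterSummary.from_chain(chains[f"h2:{t}"], mass)
        c2[t] = ParameterSummary.from_chain(chains[f"c2:{t}"], mass)
        vp[t] = ParameterSummary.from_chain(chains[f"vp:{t}"], mass)
    rg = ParameterSummary.from_chain(chains["rg"], mass) if "rg" in chains else None
    ebv = pd.DataFrame({"animal": samples.animal_ids})
    for t, name in enumerate(samples.trait_names):
        ebv[f"ebv_{name}"] = samples.ebv[:, t]
        ebv[f"ebv_sd_{name}"] = samples.ebv_sd[:, t]
    return PosteriorSummary(list(samples.trait_names), h2, c2, vp, rg, ebv)


def liability_note(samples: PosteriorSamples) -> list[str]:
    """Traits whose h2 is on the liability scale (threshold kinds)."""
    return [t for t, kd in zip(samples.trait_names, samples.kinds) if kd == THRESHOLD]


# ---------------------------------------------------------------------------
# convergence diagnostics


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS via Geyer's initial positive sequence of autocovariances."""
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("chain too short for an ESS estimate")
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    # sum of adjacent pairs must stay positive (Geyer 1992)
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        s += pair
    tau = 1.0 + 2.0 * s
    return float(n / max(tau, 1.0))


@dataclass
class RafteryLewisReport:
    """Raftery–Lewis run-length diagnostic for a quantile estimate.

    ``n_min`` is the iid requirement, ``n_burn``/``n_required`` the
    recommended burn-in and post-burn-in length, ``thin_k`` the sub-sampling
    interval at which the dichotomised chain is first-order Markov, and
    ``dependence_factor`` = (n_burn + n_required) / n_min (values near 1
    mean near-iid mixing).
    """

    quantile: float
    accuracy: float
    probability: float
    thin_k: int
    n_burn: int
    n_required: int
    n_min: int
    dependence_factor: float
    ess: float


def raftery_lewis(
    chain: np.ndarray,
    q: float = 0.025,
    r: float = 0.005,
    s: float = 0.95,
    converge_eps: float = 0.001,
) -> RafteryLewisReport:
    """Run-length diagnostic of Raftery & Lewis for estimating the
    q-quantile to within +/- r with probability s.

    The chain is dichotomised at its empirical q-quantile; the binary chain
    is thinned by k = 1, 2, ... until a first-order Markov chain is
    preferred over a second-order one by BIC; the fitted transition
    probabilities then give the recommended burn-in and run length.
    """
    from scipy.stats import norm

    x = np.asarray(chain, dtype=float)
    phi = norm.ppf(0.5 * (1.0 + s))
    n_min = int(math.ceil(q * (1.0 - q) * (phi / r) ** 2))
    if len(x) < n_min:
        raise ValueError(
            f"chain of length {len(x)} too short for the pilot estimate "
            f"(need >= {n_min})"
        )
    cut = np.quantile(x, q)
    z = (x <= cut).astype(np.int8)

    def bic_prefers_first_order(zz: np.ndarray) -> bool:
        # compare first- vs second-order Markov via G2 - log(n) * df
        n = len(zz)
        if n < 8:
            return True
        tri = np.zeros((2, 2, 2))
        for i in range(n - 2):
            tri[zz[i], zz[i + 1], zz[i + 2]] += 1
        g2 = 0.0
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    o = tri[i, j, k]
                    if o == 0:
                        continue
                    fitted = tri[i, j, :].sum() * tri[:, j, k].sum() / max(
                        tri[:, j, :].sum(), 1.0
                    )
                    g2 += 2.0 * o * math.log(o / fitted)
        bic = g2 - math.log(n - 2) * 2.0
        return bic < 0.0

    k = 1
    while k < max(2, len(z) // 50):
        if bic_prefers_first_order(z[::k]):
            break
        k += 1
    zz = z[::k]
    trans = np.zeros((2, 2))
    for i in range(len(zz) - 1):
        trans[zz[i], zz[i + 1]] += 1
    alpha = trans[0, 1] / max(trans[0].sum(), 1.0)  # P(0 -> 1)
    beta = trans[1, 0] / max(trans[1].sum(), 1.0)  # P(1 -> 0)
    alpha = min(max(alpha, 1e-8), 1 - 1e-8)
    beta = min(max(beta, 1e-8), 1 - 1e-8)
    lam = 1.0 - alpha - beta
    if abs(lam) < 1e-12:
        n_burn = k
    else:
        m = math.log(converge_eps * (alpha + beta) / max(alpha, beta)) / math.log(
            abs(lam)
        )
        n_burn = int(math.ceil(max(m, 0.0))) * k
    n_req = (
        int(
            math.ceil(
                alpha * beta * (2.0 - alpha - beta) / (alpha + beta) ** 3 * (phi / r) ** 2
            )
        )
        * k
    )
    return RafteryLewisReport(
        quantile=q,
        accuracy=r,
        probability=s,
        thin_k=k,
        n_burn=n_burn,
        n_required=n_req,
        n_min=n_min,
        dependence_factor=(n_burn + n_req) / n_min,
        ess=effective_sample_size(x),
    )
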