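"""Gibbs samplers for the pedigree-based animal models.

Single-site Gauss–Seidel Gibbs sampling of the mixed-model equations (the
scheme used by the classical animal-breeding Gibbs samplers): each fixed
effect, each animal's additive genetic effect and each pen effect is drawn
from its scalar (or 2x2, bivariate) normal full conditional given the
current residual vector, then the covariance components are drawn from
their scaled inverse chi-square / inverse-Wishart full conditionals.
Threshold-liability traits add a data-augmentation step drawing each
record's liability from a truncated normal; identifiability is fixed by
threshold = 0 and unit liability residual variance (imposed by rescaling
in the bivariate sampler).

The iteration kernels are numba-compiled, which is what makes chain
protocols of 50k-1M iterations practical on one CPU.  Chains are
bit-reproducible for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from pigsna.model import LINEAR, THRESHOLD, DesignSystem
from pigsna.pedigree import RelationshipInverse


class SamplerError(RuntimeError):
    """Numerical failure inside a chain (non-PD covariance draw etc.)."""


@dataclass
class MCMCSettings:
    """Chain protocol and covariance priors.

    The full-scale protocol for final analyses is 1,000,000 iterations with
    100,000 burn-in and thinning lag 20; the reduced desk-scale default is
    50,000 / 5,000 / 10.  ``prior`` is "flat" (improper inverse-Wishart
    with nu = -(k+1), zero scale) or "weak" (proper, nu = k+1, scale
    0.1 I) — the weak prior is the guard for small datasets where flat
    covariance priors can wander into impropriety.
    """

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    prior: str = "flat"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior not in ("flat", "weak"):
            raise ValueError("prior must be 'flat' or 'weak'")

    def hyper(self, k: int) -> tuple[float, float]:
        """(nu, scale multiplier) of the covariance prior for k traits."""
        if self.prior == "flat":
            return -(k + 1.0), 0.0
        return k + 1.0, 0.1

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def full_scale(cls, seed: int = 0, prior: str = "flat") -> "MCMCSettings":
        return cls(n_iter=1_000_000, burn_in=100_000, thin=20, seed=seed, prior=prior)


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws plus per-animal EBV posterior means.

    G0/C0/R0 draws are (n_stored, k, k); every stored draw is positive
    definite (asserted during sampling).  ``ebv`` holds the posterior mean
    additive genetic effect of every pedigree animal (phenotyped or not),
    ``ebv_sd`` the corresponding posterior standard deviations.
    """

    trait_names: list[str]
    kinds: list[str]
    G0: np.ndarray
    C0: np.ndarray
    R0: np.ndarray
    b: np.ndarray
    x_names: list[str]
    ebv: np.ndarray
    ebv_sd: np.ndarray
    animal_ids: np.ndarray
    pen_ids: np.ndarray
    n_records: int
    settings: MCMCSettings = field(repr=False, default_factory=MCMCSettings)

    @property
    def n_stored(self) -> int:
        return self.G0.shape[0]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, inline="always")
def _tn_above(a):
    """Draw Z ~ N(0,1) conditional on Z > a."""
    if a < 0.45:
        while True:
            z = np.random.standard_normal()
            if z > a:
                return z
    # Robert's translated-exponential rejection for the upper tail
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        x = a - np.log(np.random.random()) / lam
        d = x - lam
        if np.random.random() <= np.exp(-0.5 * d * d):
            return x


@njit(cache=True)
def _kernel_uni(y, bin_y, X, ai_ptr, ai_idx, ai_val,
                ra_ptr, ra_idx, rp_ptr, rp_idx,
                n_iter, burn_in, thin, seed,
                nu, scale_mult, s2a, s2c, s2e,
                threshold, fix_var):
    np.random.seed(seed)
    n, p = X.shape
    q = ai_ptr.size - 1
    npen = rp_ptr.size - 1
    b = np.zeros(p)
    a = np.zeros(q)
    c = np.zeros(npen)
    yw = y.copy()
    if threshold:
        for r in range(n):
            yw[r] = 0.7 if bin_y[r] == 1 else -0.7
    e = yw.copy()
    xtx = np.zeros(p)
    for j in range(p):
        for r in range(n):
            xtx[j] += X[r, j] * X[r, j]

    n_store = (n_iter - burn_in) // thin
    s2a_d = np.empty(n_store)
    s2c_d = np.empty(n_store)
    s2e_d = np.empty(n_store)
    b_d = np.empty((n_store, p))
    a_sum = np.zeros(q)
    a_sq = np.zeros(q)
    # scalar prior: nu = -(1+1) flat; scale = nu * 0.1 if proper
    pscale = scale_mult * max(nu, 0.0)
    kstore = 0
    for it in range(1, n_iter + 1):
        if threshold:
            for r in range(n):
                mu = yw[r] - e[r]
                if bin_y[r] == 1:
                    ynew = mu + _tn_above(-mu)
                else:
                    ynew = mu - _tn_above(mu)
                e[r] += ynew - yw[r]
                yw[r] = ynew
        for j in range(p):
            bj = b[j]
            s = 0.0
            for r in range(n):
                er = e[r] + X[r, j] * bj
                e[r] = er
                s += X[r, j] * er
            bnew = s / xtx[j] + np.sqrt(s2e / xtx[j]) * np.random.standard_normal()
            b[j] = bnew
            for r in range(n):
                e[r] -= X[r, j] * bnew
        lam_a = s2e / s2a
        for i in range(q):
            aold = a[i]
            s = 0.0
            cnt = ra_ptr[i + 1] - ra_ptr[i]
            for t in range(ra_ptr[i], ra_ptr[i + 1]):
                r = ra_idx[t]
                er = e[r] + aold
                e[r] = er
                s += er
            dii = 0.0
            nsum = 0.0
            for t in range(ai_ptr[i], ai_ptr[i + 1]):
                j = ai_idx[t]
                if j == i:
                    dii = ai_val[t]
                else:
                    nsum += ai_val[t] * a[j]
            denom = cnt + lam_a * dii
            anew = (s - lam_a * nsum) / denom + np.sqrt(s2e / denom) * np.random.standard_normal()
            a[i] = anew
            for t in range(ra_ptr[i], ra_ptr[i + 1]):
                e[ra_idx[t]] -= anew
        if npen > 0:
            lam_c = s2e / s2c
            for pp in range(npen):
                cold = c[pp]
                s = 0.0
                cnt = rp_ptr[pp + 1] - rp_ptr[pp]
                for t in range(rp_ptr[pp], rp_ptr[pp + 1]):
                    r = rp_idx[t]
                    er = e[r] + cold
                    e[r] = er
                    s += er
                denom = cnt + lam_c
                cnew = s / denom + np.sqrt(s2e / denom) * np.random.standard_normal()
                c[pp] = cnew
                for t in range(rp_ptr[pp], rp_ptr[pp + 1]):
                    e[rp_idx[t]] -= cnew
        if not fix_var:
            qa = 0.0
            for i in range(q):
                for t in range(ai_ptr[i], ai_ptr[i + 1]):
                    qa += a[i] * ai_val[t] * a[ai_idx[t]]
            s2a = (qa + pscale) / (2.0 * np.random.standard_gamma(0.5 * (q + nu)))
            if s2a <= 0.0 or not np.isfinite(s2a):
                raise ValueError("non-positive genetic variance draw")
            if npen > 0:
                qc = 0.0
                for pp in range(npen):
                    qc += c[pp] * c[pp]
                s2c = (qc + pscale) / (2.0 * np.random.standard_gamma(0.5 * (npen + nu)))
            if not threshold:
                qe = 0.0
                for r in range(n):
                    qe += e[r] * e[r]
                s2e = (qe + pscale) / (2.0 * np.random.standard_gamma(0.5 * (n + nu)))
        if it > burn_in and (it - burn_in) % thin == 0:
            s2a_d[kstore] = s2a
            s2c_d[kstore] = s2c if npen > 0 else 0.0
            s2e_d[kstore] = s2e
            for j in range(p):
                b_d[kstore, j] = b[j]
            for i in range(q):
                a_sum[i] += a[i]
                a_sq[i] += a[i] * a[i]
            kstore += 1
    return s2a_d, s2c_d, s2e_d, b_d, a_sum, a_sq


@njit(cache=True, inline="always")
def _invwishart2(s00, s01, s11, df):
    """One draw from InvWishart_2(scale S, df) via Bartlett on S^{-1}."""
    det = s00 * s11 - s01 * s01
    if det <= 0.0 or s00 <= 0.0:
        raise ValueError("non-PD scale matrix in inverse-Wishart draw")
    i00 = s11 / det
    i01 = -s01 / det
    i11 = s00 / det
    l00 = np.sqrt(i00)
    l10 = i01 / l00
    l11 = np.sqrt(i11 - l10 * l10)
    c00 = np.sqrt(2.0 * np.random.standard_gamma(0.5 * df))
    c10 = np.random.standard_normal()
    c11 = np.sqrt(2.0 * np.random.standard_gamma(0.5 * (df - 1.0)))
    # T = L_bartlett; W = T T'
    t00 = l00 * c00
    t10 = l10 * c00 + l11 * c10
    t11 = l11 * c11
    w00 = t00 * t00
    w01 = t00 * t10
    w11 = t10 * t10 + t11 * t11
    dw = w00 * w11 - w01 * w01
    if dw <= 0.0:
        raise ValueError("singular Wishart draw")
    return w11 / dw, -w01 / dw, w00 / dw


@njit(cache=True, inline="always")
def _draw_mvn2(p00, p01, p11, r0, r1):
    """Draw from N(P^{-1} r, P^{-1}) for a 2x2 precision P."""
    det = p00 * p11 - p01 * p01
    v00 = p11 / det
    v01 = -p01 / det
    v11 = p00 / det
    m0 = v00 * r0 + v01 * r1
    m1 = v01 * r0 + v11 * r1
    l00 = np.sqrt(v00)
    l10 = v01 / l00
    l11 = np.sqrt(v11 - l10 * l10)
    z0 = np.random.standard_normal()
    z1 = np.random.standard_normal()
    return m0 + l00 * z0, m1 + l10 * z0 + l11 * z1


@njit(cache=True)
def _kernel_bi(y, miss, bin_y, kinds, X,
               ai_ptr, ai_idx, ai_val,
               ra_ptr, ra_idx, rp_ptr, rp_idx,
               n_iter, burn_in, thin, seed,
               nu, scale_mult, G0, C0, R0):
    np.random.seed(seed)
    n, p = X.shape
    q = ai_ptr.size - 1
    npen = rp_ptr.size - 1
    b = np.zeros((p, 2))
    a = np.zeros((q, 2))
    c = np.zeros((npen, 2))
    yw = y.copy()
    for r in range(n):
        for t in range(2):
            if miss[r, t] == 1:
                yw[r, t] = 0.0
            elif kinds[t] == 1:
                yw[r, t] = 0.7 if bin_y[r, t] == 1 else -0.7
    e = yw.copy()
    xtx = np.zeros(p)
    for j in range(p):
        for r in range(n):
            xtx[j] += X[r, j] * X[r, j]

    g00, g01, g11 = G0[0, 0], G0[0, 1], G0[1, 1]
    c00, c01, c11 = C0[0, 0], C0[0, 1], C0[1, 1]
    r00, r01, r11 = R0[0, 0], R0[0, 1], R0[1, 1]
    pr = scale_mult * max(nu, 0.0)  # proper-prior scale (times identity)

    n_store = (n_iter - burn_in) // thin
    G_d = np.empty((n_store, 3))
    C_d = np.empty((n_store, 3))
    R_d = np.empty((n_store, 3))
    b_d = np.empty((n_store, p, 2))
    a_sum = np.zeros((q, 2))
    a_sq = np.zeros((q, 2))
    kstore = 0
    for it in range(1, n_iter + 1):
        # residual-scale data augmentation: missing responses and liabilities
        for r in range(n):
            for t in range(2):
                o = 1 - t
                rtt = r00 if t == 0 else r11
                roo = r11 if t == 0 else r00
                if miss[r, t] == 1:
                    cm = (r01 / roo) * e[r, o]
                    cv = rtt - r01 * r01 / roo
                    enew = cm + np.sqrt(cv) * np.random.standard_normal()
                elif kinds[t] == 1:
                    fitted = yw[r, t] - e[r, t]
                    cm = (r01 / roo) * e[r, o]
                    cv = rtt - r01 * r01 / roo
                    sd = np.sqrt(cv)
                    aa = (-fitted - cm) / sd
                    if bin_y[r, t] == 1:
                        enew = cm + sd * _tn_above(aa)
                    else:
                        enew = cm - sd * _tn_above(-aa)
                else:
                    continue
                fitted = yw[r, t] - e[r, t]
                e[r, t] = enew
                yw[r, t] = fitted + enew
        # R0 inverse
        rdet = r00 * r11 - r01 * r01
        ri00 = r11 / rdet
        ri01 = -r01 / rdet
        ri11 = r00 / rdet
        # fixed effects (2-vectors, coupled through R0^{-1})
        for j in range(p):
            b0, b1 = b[j, 0], b[j, 1]
            s0 = 0.0
            s1 = 0.0
            for r in range(n):
                x = X[r, j]
                e0 = e[r, 0] + x * b0
                e1 = e[r, 1] + x * b1
                e[r, 0] = e0
                e[r, 1] = e1
                s0 += x * e0
                s1 += x * e1
            rhs0 = ri00 * s0 + ri01 * s1
            rhs1 = ri01 * s0 + ri11 * s1
            nb0, nb1 = _draw_mvn2(xtx[j] * ri00, xtx[j] * ri01, xtx[j] * ri11, rhs0, rhs1)
            b[j, 0] = nb0
            b[j, 1] = nb1
            for r in range(n):
                x = X[r, j]
                e[r, 0] -= x * nb0
                e[r, 1] -= x * nb1
        # G0 inverse
        gdet = g00 * g11 - g01 * g01
        gi00 = g11 / gdet
        gi01 = -g01 / gdet
        gi11 = g00 / gdet
        for i in range(q):
            a0, a1 = a[i, 0], a[i, 1]
            s0 = 0.0
            s1 = 0.0
            cnt = ra_ptr[i + 1] - ra_ptr[i]
            for t in range(ra_ptr[i], ra_ptr[i + 1]):
                r = ra_idx[t]
                e0 = e[r, 0] + a0
                e1 = e[r, 1] + a1
                e[r, 0] = e0
                e[r, 1] = e1
                s0 += e0
                s1 += e1
            dii = 0.0
            ns0 = 0.0
            ns1 = 0.0
            for t in range(ai_ptr[i], ai_ptr[i + 1]):
                j = ai_idx[t]
                if j == i:
                    dii = ai_val[t]
                else:
                    ns0 += ai_val[t] * a[j, 0]
                    ns1 += ai_val[t] * a[j, 1]
            p00 = cnt * ri00 + dii * gi00
            p01 = cnt * ri01 + dii * gi01
            p11 = cnt * ri11 + dii * gi11
            rhs0 = ri00 * s0 + ri01 * s1 - (gi00 * ns0 + gi01 * ns1)
            rhs1 = ri01 * s0 + ri11 * s1 - (gi01 * ns0 + gi11 * ns1)
            na0, na1 = _draw_mvn2(p00, p01, p11, rhs0, rhs1)
            a[i, 0] = na0
            a[i, 1] = na1
            for t in range(ra_ptr[i], ra_ptr[i + 1]):
                r = ra_idx[t]
                e[r, 0] -= na0
                e[r, 1] -= na1
        if npen > 0:
            cdet = c00 * c11 - c01 * c01
            ci00 = c11 / cdet
            ci01 = -c01 / cdet
            ci11 = c00 / cdet
            for pp in range(npen):
                p0, p1 = c[pp, 0], c[pp, 1]
                s0 = 0.0
                s1 = 0.0
                cnt = rp_ptr[pp + 1] - rp_ptr[pp]
                for t in range(rp_ptr[pp], rp_ptr[pp + 1]):
                    r = rp_idx[t]
                    e0 = e[r, 0] + p0
                    e1 = e[r, 1] + p1
                    e[r, 0] = e0
                    e[r, 1] = e1
                    s0 += e0
                    s1 += e1
                pp00 = cnt * ri00 + ci00
                pp01 = cnt * ri01 + ci01
                pp11 = cnt * ri11 + ci11
                rhs0 = ri00 * s0 + ri01 * s1
                rhs1 = ri01 * s0 + ri11 * s1
                np0, np1 = _draw_mvn2(pp00, pp01, pp11, rhs0, rhs1)
                c[pp, 0] = np0
                c[pp, 1] = np1
                for t in range(rp_ptr[pp], rp_ptr[pp + 1]):
                    r = rp_idx[t]
                    e[r, 0] -= np0
                    e[r, 1] -= np1
        # covariance components
        sa00 = pr
        sa01 = 0.0
        sa11 = pr
        for i in range(q):
            for t in range(ai_ptr[i], ai_ptr[i + 1]):
                j = ai_idx[t]
                v = ai_val[t]
                sa00 += v * a[i, 0] * a[j, 0]
                sa01 += v * a[i, 0] * a[j, 1]
                sa11 += v * a[i, 1] * a[j, 1]
        g00, g01, g11 = _invwishart2(sa00, sa01, sa11, q + nu)
        if npen > 0:
            sc00 = pr
            sc01 = 0.0
            sc11 = pr
            for pp in range(npen):
                sc00 += c[pp, 0] * c[pp, 0]
                sc01 += c[pp, 0] * c[pp, 1]
                sc11 += c[pp, 1] * c[pp, 1]
            c00, c01, c11 = _invwishart2(sc00, sc01, sc11, npen + nu)
        se00 = pr
        se01 = 0.0
        se11 = pr
        for r in range(n):
            se00 += e[r, 0] * e[r, 0]
            se01 += e[r, 0] * e[r, 1]
            se11 += e[r, 1] * e[r, 1]
        r00, r01, r11 = _invwishart2(se00, se01, se11, n + nu)
        # threshold identifiability: rescale so liability residual var = 1
        for t in range(2):
            if kinds[t] == 1:
                lam = np.sqrt(r11 if t == 1 else r00)
                for r in range(n):
                    yw[r, t] /= lam
                    e[r, t] /= lam
                for j in range(p):
                    b[j, t] /= lam
                for i in range(q):
                    a[i, t] /= lam
                for pp in range(npen):
                    c[pp, t] /= lam
                if t == 0:
                    g00 /= lam * lam
                    g01 /= lam
                    c00 /= lam * lam
                    c01 /= lam
                    r00 = 1.0
                    r01 /= lam
                else:
                    g11 /= lam * lam
                    g01 /= lam
                    c11 /= lam * lam
                    c01 /= lam
                    r11 = 1.0
                    r01 /= lam
        if it > burn_in and (it - burn_in) % thin == 0:
            G_d[kstore, 0] = g00
            G_d[kstore, 1] = g01
            G_d[kstore, 2] = g11
            C_d[kstore, 0] = c00
            C_d[kstore, 1] = c01
            C_d[kstore, 2] = c11
            R_d[kstore, 0] = r00
            R_d[kstore, 1] = r01
            R_d[kstore, 2] = r11
            for j in range(p):
                b_d[kstore, j, 0] = b[j, 0]
                b_d[kstore, j, 1] = b[j, 1]
            for i in range(q):
                a_sum[i, 0] += a[i, 0]
                a_sum[i, 1] += a[i, 1]
                a_sq[i, 0] += a[i, 0] * a[i, 0]
                a_sq[i, 1] += a[i, 1] * a[i, 1]
            kstore += 1
    return G_d, C_d, R_d, b_d, a_sum, a_sq


# ---------------------------------------------------------------------------
# python wrappers


def _records_csr(index: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR mapping group -> record indices."""
    order = np.argsort(index, kind="stable")
    counts = np.bincount(index, minlength=size)
    ptr = np.zeros(size + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order.astype(np.int64)


def _check_conformable(design: DesignSystem, A_inverse: RelationshipInverse) -> None:
    if A_inverse.A_inv.shape[0] != len(design.pedigree):
        raise ValueError("A-inverse order does not match the design's pedigree")
    if not np.array_equal(A_inverse.ids, design.pedigree.ids):
        raise ValueError("A-inverse animal order differs from the pedigree order")


def _ebv_stats(a_sum: np.ndarray, a_sq: np.ndarray, n_stored: int):
    mean = a_sum / n_stored
    var = np.clip(a_sq / n_stored - mean**2, 0.0, None)
    return mean, np.sqrt(var)


def gibbs_linear(
    design: DesignSystem,
    A_inverse: RelationshipInverse,
    settings: MCMCSettings | None = None,
    fix_variances: tuple[float, float, float] | None = None,
) -> PosteriorSamples:
    """Univariate linear animal model.

    ``fix_variances`` freezes (sigma2_a, sigma2_c, sigma2_e) instead of
    sampling them — useful for validating the location-effect conditionals
    against generalised least squares.
    """
    st = settings or MCMCSettings()
    if design.spec.n_traits != 1 or design.spec.kinds[0] != LINEAR:
        raise ValueError("gibbs_linear expects a univariate linear design")
    return _run_uni(design, A_inverse, st, threshold=False, fix_variances=fix_variances)


def gibbs_threshold(
    design: DesignSystem,
    A_inverse: RelationshipInverse,
    settings: MCMCSettings | None = None,
) -> PosteriorSamples:
    """Univariate threshold-liability model for a binary trait.

    The liability of each record is drawn from its truncated-normal full
    conditional; the threshold is fixed at 0 and the liability residual
    variance at 1, so heritability is reported on the liability scale.
    """
    st = settings or MCMCSettings()
    if design.spec.n_traits != 1 or design.spec.kinds[0] != THRESHOLD:
        raise ValueError("gibbs_threshold expects a univariate threshold design")
    return _run_uni(design, A_inverse, st, threshold=True, fix_variances=None)


def _run_uni(design, A_inverse, st, threshold, fix_variances):
    _check_conformable(design, A_inverse)
    y = design.y[:, 0].copy()
    n = len(y)
    q = len(design.pedigree)
    ai = A_inverse.A_inv
    ra_ptr, ra_idx = _records_csr(design.animal_index, q)
    if design.spec.pen_effect:
        rp_ptr, rp_idx = _records_csr(design.pen_index, design.n_pens)
    else:
        rp_ptr = np.zeros(1, dtype=np.int64)
        rp_idx = np.zeros(0, dtype=np.int64)
    nu, scale_mult = st.hyper(1)
    if design.spec.pen_effect and design.n_pens + nu <= 0:
        raise SamplerError(
            f"{design.n_pens} pen(s) leave no degrees of freedom for the pen "
            "variance under the flat prior; use prior='weak' or pen_effect=False"
        )
    vy = float(np.var(y)) if not threshold else 1.0
    if fix_variances is not None:
        s2a, s2c, s2e = (float(v) for v in fix_variances)
    else:
        s2a, s2c, s2e = 0.3 * vy, 0.1 * vy, (0.6 * vy if not threshold else 1.0)
    bin_y = (
        design.binary[:, 0].astype(np.int8) if design.binary is not None
        else np.zeros(n, dtype=np.int8)
    )
    try:
        s2a_d, s2c_d, s2e_d, b_d, a_sum, a_sq = _kernel_uni(
            y, bin_y, design.X,
            ai.indptr.astype(np.int64), ai.indices.astype(np.int64), ai.data,
            ra_ptr, ra_idx, rp_ptr, rp_idx,
            st.n_iter, st.burn_in, st.thin, st.seed,
            nu, scale_mult, s2a, s2c, s2e if not threshold else 1.0,
            threshold, fix_variances is not None,
        )
    except ValueError as exc:  # raised inside the kernel on bad draws
        raise SamplerError(str(exc)) from exc
    ns = st.n_stored
    G0 = s2a_d.reshape(ns, 1, 1)
    C0 = s2c_d.reshape(ns, 1, 1)
    R0 = s2e_d.reshape(ns, 1, 1)
    ebv, ebv_sd = _ebv_stats(a_sum.reshape(-1, 1), a_sq.reshape(-1, 1), ns)
    return PosteriorSamples(
        trait_names=list(design.spec.traits),
        kinds=list(design.spec.kinds),
        G0=G0, C0=C0, R0=R0,
        b=b_d.reshape(ns, -1, 1),
        x_names=list(design.x_names),
        ebv=ebv, ebv_sd=ebv_sd,
        animal_ids=design.pedigree.ids.copy(),
        pen_ids=design.pen_ids.copy(),
        n_records=n,
        settings=st,
    )


def gibbs_bivariate(
    design: DesignSystem,
    A_inverse: RelationshipInverse,
    settings: MCMCSettings | None = None,
) -> PosteriorSamples:
    """Bivariate animal model: linear-linear or linear-threshold.

    2x2 genetic, pen and residual covariance matrices are sampled from
    inverse-Wishart full conditionals; per-trait missing responses are
    handled by residual data augmentation.  A threshold trait's liability
    residual variance is pinned to 1 by rescaling after each residual
    covariance draw (its residual covariance with the other trait stays
    free).  The threshold-threshold combination runs but is experimental.
    """
    st = settings or MCMCSettings()
    if design.spec.n_traits != 2:
        raise ValueError("gibbs_bivariate expects a two-trait design")
    if design.spec.kinds.count(THRESHOLD) == 2:
        warnings.warn("threshold-threshold bivariate model is experimental", stacklevel=2)
    _check_conformable(design, A_inverse)
    y = design.y.copy()
    miss = np.isnan(y).astype(np.int8)
    y[np.isnan(y)] = 0.0
    kinds = np.array(
        [1 if kd == THRESHOLD else 0 for kd in design.spec.kinds], dtype=np.int8
    )
    bin_y = (
        design.binary.astype(np.int8) if design.binary is not None
        else np.zeros_like(miss)
    )
    n = y.shape[0]
    q = len(design.pedigree)
    ai = A_inverse.A_inv
    ra_ptr, ra_idx = _records_csr(design.animal_index, q)
    if design.spec.pen_effect:
        rp_ptr, rp_idx = _records_csr(design.pen_index, design.n_pens)
    else:
        rp_ptr = np.zeros(1, dtype=np.int64)
        rp_idx = np.zeros(0, dtype=np.int64)
    nu, scale_mult = st.hyper(2)
    if design.spec.pen_effect and design.n_pens + nu <= 2:
        raise SamplerError(
            f"{design.n_pens} pen(s) leave no degrees of freedom for the pen "
            "covariance under the flat prior; use prior='weak' or pen_effect=False"
        )
    v = np.array(
        [np.nanvar(design.y[:, t]) if kinds[t] == 0 else 1.0 for t in range(2)]
    )
    G0 = np.diag(0.3 * v)
    C0 = np.diag(0.1 * v)
    R0 = np.diag(np.where(kinds == 1, 1.0, 0.6 * v))
    try:
        G_d, C_d, R_d, b_d, a_sum, a_sq = _kernel_bi(
            y, miss, bin_y, kinds, design.X,
            ai.indptr.astype(np.int64), ai.indices.astype(np.int64), ai.data,
            ra_ptr, ra_idx, rp_ptr, rp_idx,
            st.n_iter, st.burn_in, st.thin, st.seed,
            nu, scale_mult, G0, C0, R0,
        )
    except ValueError as exc:
        raise SamplerError(str(exc)) from exc
    ns = st.n_stored

    def unpack(d):
        out = np.empty((ns, 2, 2))
        out[:, 0, 0] = d[:, 0]
        out[:, 0, 1] = out[:, 1, 0] = d[:, 1]
        out[:, 1, 1] = d[:, 2]
        return out

    ebv, ebv_sd = _ebv_stats(a_sum, a_sq, ns)
    return PosteriorSamples(
        trait_names=list(design.spec.traits),
        kinds=list(design.spec.kinds),
        G0=unpack(G_d), C0=unpack(C_d), R0=unpack(R_d),
        b=b_d,
        x_names=list(design.x_names),
        ebv=ebv, ebv_sd=ebv_sd,
        animal_ids=design.pedigree.ids.copy(),
        pen_ids=design.pen_ids.copy(),
        n_records=n,
        settings=st,
    )
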