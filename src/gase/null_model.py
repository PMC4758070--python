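"""Beta-binomial null model for allele counts at no-ASE sites.

Read counts at a heterozygous site are modelled as beta-binomial,
an overdispersed binomial: the alt count at a site of depth n is
Binomial(n, theta) with theta ~ Beta(alpha, beta). We use the intraclass-
correlation parameterization (p, rho) with

    alpha = p (1 - rho) / rho,    beta = (1 - p)(1 - rho) / rho,

so p is the mean alt fraction and rho in [0, 1) the overdispersion;
rho = 0 recovers the ordinary binomial. The null BB(p0, rho0) is fitted
once, by maximum likelihood, from DNA-sequencing allele counts, where no
allelic imbalance in coverage is expected and any spread beyond binomial
reflects technical noise shared with the RNA data.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

from .io import BetaBinomNull

__all__ = [
    "betabinom_alpha_beta",
    "betabinom_logpmf",
    "betabinom_loglik",
    "fit_betabinomial",
    "sample_betabinomial",
]

# below this rho the beta-binomial is numerically indistinguishable from
# the binomial at the depths we handle; use the exact binomial limit
_RHO_BINOMIAL_LIMIT = 1e-12


def betabinom_alpha_beta(p0: float, rho0: float) -> tuple[float, float]:
    """Map (mean, overdispersion) to the Beta shape parameters."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not 0.0 < rho0 < 1.0:
        raise ValueError(f"rho0 must lie in (0, 1) for the Beta mapping, got {rho0}")
    s = (1.0 - rho0) / rho0
    return p0 * s, (1.0 - p0) * s


def betabinom_logpmf(alt, depth, p0: float, rho0: float):
    """Log pmf of the alt count; exact binomial at rho0 = 0, continuous in rho."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if not 0.0 <= rho0 < 1.0:
        raise ValueError(f"rho0 must lie in [0, 1), got {rho0}")
    if rho0 < _RHO_BINOMIAL_LIMIT:
        return stats.binom.logpmf(alt, depth, p0)
    a, b = betabinom_alpha_beta(p0, rho0)
    # ascending-factorial form of the Beta ratio: stable for any (a, b),
    # including the near-binomial regime where a, b are huge and the
    # betaln difference cancels catastrophically
    alt_i = np.asarray(alt, dtype=int)
    n_i = np.asarray(depth, dtype=int)
    nmax = int(n_i.max())
    idx = np.arange(nmax, dtype=float)
    cum_a = np.concatenate([[0.0], np.cumsum(np.log(a + idx))])
    cum_b = np.concatenate([[0.0], np.cumsum(np.log(b + idx))])
    cum_ab = np.concatenate([[0.0], np.cumsum(np.log(a + b + idx))])
    out = (
        special.gammaln(n_i + 1.0)
        - special.gammaln(alt_i + 1.0)
        - special.gammaln(n_i - alt_i + 1.0)
        + cum_a[alt_i]
        + cum_b[n_i - alt_i]
        - cum_ab[n_i]
    )
    return out if np.asarray(alt).ndim or np.asarray(depth).ndim else float(out)


def betabinom_loglik(counts, p0: float, rho0: float) -> float:
    """Total log-likelihood of (ref, alt) count pairs under BB(p0, rho0).

    ``counts`` is an array-like of shape (n, 2) with columns (ref, alt), or
    a DataFrame with ``ref_count``/``alt_count`` columns.
    """
    ref, alt = _as_ref_alt(counts)
    return float(np.sum(betabinom_logpmf(alt, ref + alt, p0, rho0)))


def _as_ref_alt(counts) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(counts, "columns"):
        return counts["ref_count"].to_numpy(), counts["alt_count"].to_numpy()
    arr = np.asarray(counts)
    return arr[:, 0], arr[:, 1]


def _moments_start(ref: np.ndarray, alt: np.ndarray) -> tuple[float, float]:
    """Method-of-moments starting point for the ML fit."""
    n = ref + alt
    p = float(alt.sum() / n.sum())
    p = min(max(p, 1e-4), 1 - 1e-4)
    frac = alt / n
    # E[(frac - p)^2] = p(1-p)(1 + (n-1) rho)/n at each depth
    with np.errstate(invalid="ignore"):
        rho_site = (n * (frac - p) ** 2 / (p * (1 - p)) - 1) / np.maximum(n - 1, 1)
    rho = float(np.clip(np.nanmean(rho_site), 1e-4, 0.5))
    return p, rho


def fit_betabinomial(
    dna_counts,
    min_depth: int = 10,
    min_sites: int = 50,
) -> BetaBinomNull:
    """Maximum-likelihood fit of the variant null model BB(p0, rho0).

    ``dna_counts`` is a (ref, alt) array or a DataFrame from
    :func:`gase.io.read_dna_counts` (its ``pass_depth`` flag, or the
    ``min_depth`` floor, removes shallow sites first). The likelihood is
    maximized over (p0, rho0) with box constraints from a method-of-moments
    start; the optimum never falls below the starting log-likelihood.
    """
    ref, alt = _as_ref_alt(dna_counts)
    depth = ref + alt
    keep = depth >= min_depth
    ref, alt = ref[keep], alt[keep]
    if ref.size < min_sites:
        raise ValueError(
            f"need at least {min_sites} sites at depth >= {min_depth} to fit "
            f"the null model, got {ref.size}"
        )
    pairs = np.column_stack([ref, alt])
    p_start, rho_start = _moments_start(ref.astype(float), alt.astype(float))

    def nll(theta):
        p, rho = theta
        return -betabinom_loglik(pairs, p, rho)

    res = optimize.minimize(
        nll,
        x0=[p_start, rho_start],
        method="L-BFGS-B",
        bounds=[(1e-6, 1 - 1e-6), (1e-9, 0.999)],
    )
    if not res.success:
        # L-BFGS-B's line search can abort when the optimum sits on the
        # rho = 0 boundary (no overdispersion); a derivative-free polish
        # with clipped parameters handles that case
        def nll_clipped(theta):
            p = float(np.clip(theta[0], 1e-6, 1 - 1e-6))
            r = float(np.clip(theta[1], 0.0, 0.999))
            return -betabinom_loglik(pairs, p, r)

        res_nm = optimize.minimize(
            nll_clipped,
            x0=[p_start, rho_start],
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 4000},
        )
        if res_nm.fun <= res.fun or not np.isfinite(res.fun):
            res = res_nm
        res.x = np.array(
            [np.clip(res.x[0], 1e-6, 1 - 1e-6), np.clip(res.x[1], 0.0, 0.999)]
        )
        if res.fun > -betabinom_loglik(pairs, p_start, rho_start) + 1e-9:
            raise RuntimeError(
                "beta-binomial fit did not converge; "
                f"moments estimate p0={p_start:.4f}, rho0={rho_start:.4f}"
            )
    p0, rho0 = res.x
    # report a clean zero when the optimum sits on the lower rho bound
    if rho0 <= 2e-9:
        rho0 = 0.0
    return BetaBinomNull(
        p0=float(p0), rho0=float(rho0), n_sites=int(ref.size), loglik=float(-res.fun)
    )


def sample_betabinomial(
    n_draws: int,
    depth,
    p0: float,
    rho0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw alt-allele counts from BB(p0, rho0) at the given depth(s).

    ``depth`` may be a scalar or an array broadcastable to ``n_draws``
    (an array of shape (n_draws,) gives one draw per depth). Sampling is
    compound: theta ~ Beta(alpha, beta), count ~ Binomial(depth, theta);
    at rho0 = 0 the draws are plain binomial.
    """
    depth = np.asarray(depth)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1")
    shape = (n_draws,) if depth.ndim == 0 else np.broadcast_shapes((n_draws,), depth.shape)
    if rho0 < _RHO_BINOMIAL_LIMIT:
        return rng.binomial(depth, p0, size=shape)
    a, b = betabinom_alpha_beta(p0, rho0)
    theta = rng.beta(a, b, size=shape)
    return rng.binomial(depth, theta)
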