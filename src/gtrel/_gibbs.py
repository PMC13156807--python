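"""Conditionally-conjugate Gibbs sampler for crossed random-effects models.

The model is the GT linear decomposition

    y_n = mu_{c(n)} + sum_b u_b[idx_b(n)] + e_n,
    e_n ~ N(0, sigma2_e[g(n)]),  u_b[l] ~ N(0, sigma2_b[vg(l)]),

with fixed-facet cell means ``mu_c`` (flat prior), random-effect blocks
``b`` (person, trial, interactions, ...), and residual variances that
may differ by group ``g`` (heteroscedastic location-scale).

Priors on component SDs are half-Student-t with ``df`` degrees of
freedom and scale ``A``, implemented through the Huang-Wand auxiliary
representation

    sigma2 | a ~ InvGamma(df/2, df/a),   a ~ InvGamma(1/2, 1/A^2),

which keeps every full conditional an inverse gamma and guarantees
strictly positive variance draws.  When the residual is heteroscedastic
the groups share one auxiliary ``a``, placing the group variances under
a common higher-level distribution.

Convergence is checked with split R-hat (via arviz) on every variance
parameter and cell mean; the sampler is a Gibbs scheme, so there is no
divergence diagnostic — the R-hat rule is the whole convergence gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConvergenceError

__all__ = [
    "EffectBlock",
    "MCMCConfig",
    "PriorConfig",
    "GibbsResult",
    "sample_model",
    "check_rhat",
]


@dataclass(frozen=True)
class EffectBlock:
    """One random-effect term of the decomposition.

    Parameters
    ----------
    name : str
        Effect label ("p", "i", "pi,e"-style labels are assigned by the
        caller; the residual is *not* a block).
    idx : ndarray of int, shape (n_obs,)
        Maps each observation to its effect level.
    n_levels : int
    var_group : ndarray of int, shape (n_levels,)
        Maps each level to a variance parameter (one entry per fixed
        level for per-condition components; all zeros otherwise).
    n_var_groups : int
    margins : tuple of (parent name, ndarray)
        For interaction blocks: each entry maps this block's levels to
        the levels of a parent main-effect block, enabling the exact
        margin-recentering moves that keep crossed designs mixing.
    """

    name: str
    idx: np.ndarray
    n_levels: int
    var_group: np.ndarray
    n_var_groups: int = 1
    margins: tuple = ()


@dataclass
class MCMCConfig:
    """Chains/draws/warmup settings; the seed is supplied separately."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 500
    thin: int = 1
    rhat_threshold: float = 1.01


@dataclass
class PriorConfig:
    """Half-Student-t prior on each component SD.

    ``sd_scale`` defaults to the observed score SD, a weakly-informative
    choice that adapts to the units of the modality.
    """

    sd_df: float = 3.0
    sd_scale: float | None = None


@dataclass
class GibbsResult:
    """Posterior draws, shaped (chains, draws) per scalar parameter."""

    variances: dict[str, np.ndarray]          # "block:group" -> draws
    resid_variances: np.ndarray               # (chains, draws, n_groups)
    cell_means: np.ndarray                    # (chains, draws, n_cells)
    rhat: dict[str, float] = field(default_factory=dict)


def _invgamma(rng: np.random.Generator, shape, rate):
    """Draw from InvGamma(shape, rate) elementwise."""
    return rate / rng.gamma(shape, 1.0, size=np.shape(rate))


def sample_model(
    y: np.ndarray,
    blocks: Sequence[EffectBlock],
    *,
    cell_idx: np.ndarray | None = None,
    n_cells: int = 1,
    resid_group: np.ndarray | None = None,
    n_resid_groups: int = 1,
    seed: int,
    prior: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> GibbsResult:
    """Run the Gibbs sampler and enforce the convergence rule.

    Raises
    ------
    ConvergenceError
        If any monitored parameter has split R-hat above the threshold.
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    if cell_idx is None:
        cell_idx = np.zeros(n, dtype=np.intp)
    if resid_group is None:
        resid_group = np.zeros(n, dtype=np.intp)
    nu = prior.sd_df
    A = prior.sd_scale if prior.sd_scale is not None else float(np.std(y))
    if A <= 0:
        A = 1.0  # degenerate constant input; prior scale is arbitrary then

    n_chain_draws = mcmc.draws
    var_store = {
        f"{b.name}:{g}": np.empty((mcmc.chains, n_chain_draws))
        for b in blocks
        for g in range(b.n_var_groups)
    }
    resid_store = np.empty((mcmc.chains, n_chain_draws, n_resid_groups))
    mean_store = np.empty((mcmc.chains, n_chain_draws, n_cells))

    blocks_list = list(blocks)
    block_index = {b.name: i for i, b in enumerate(blocks_list)}
    seeds = np.random.SeedSequence(seed).spawn(mcmc.chains)
    cell_counts = np.bincount(cell_idx, minlength=n_cells).astype(float)
    resid_counts = np.bincount(resid_group, minlength=n_resid_groups)

    for chain in range(mcmc.chains):
        rng = np.random.default_rng(seeds[chain])
        # --- initialisation: cell means at data means, effects at zero
        cell_sums = np.bincount(cell_idx, weights=y, minlength=n_cells)
        mu = cell_sums / np.maximum(cell_counts, 1.0)
        mu = mu + rng.normal(0.0, 0.1 * A, size=n_cells)  # overdisperse
        u = [np.zeros(b.n_levels) for b in blocks]
        sig2 = [
            np.full(b.n_var_groups, (0.5 * A) ** 2 * rng.uniform(0.5, 2.0))
            for b in blocks
        ]
        aux = [np.ones(b.n_var_groups) for b in blocks]
        sig2_e = np.full(n_resid_groups, (0.5 * A) ** 2 * rng.uniform(0.5, 2.0))
        aux_e = 1.0

        fit = mu[cell_idx].copy()  # running fitted values

        n_iter = mcmc.warmup + n_chain_draws * mcmc.thin
        for it in range(n_iter):
            w = 1.0 / sig2_e[resid_group]          # per-obs precision
            # --- random-effect blocks
            for k, b in enumerate(blocks):
                fit -= u[k][b.idx]
                resid = y - fit
                sw = np.bincount(b.idx, weights=resid * w,
                                 minlength=b.n_levels)
                nw = np.bincount(b.idx, weights=w, minlength=b.n_levels)
                prec = nw + 1.0 / sig2[k][b.var_group]
                mean = sw / prec
                u[k] = mean + rng.standard_normal(b.n_levels) / np.sqrt(prec)
                fit += u[k][b.idx]
                # exact recentering move: shift each variance group's
                # effect mean into the cell mean along the likelihood-
                # invariant direction, sampling the shift from its full
                # conditional N(-ubar, sigma2/m).  Without it the flat
                # cell mean and the effect means mix very slowly.
                m = np.bincount(b.var_group, minlength=b.n_var_groups)
                ubar = (np.bincount(b.var_group, weights=u[k],
                                    minlength=b.n_var_groups) / m)
                delta = -ubar + rng.standard_normal(
                    b.n_var_groups) * np.sqrt(sig2[k] / m)
                u[k] = u[k] + delta[b.var_group]
                if b.n_var_groups == n_cells:
                    mu = mu - delta
                else:  # single variance group spanning all cells
                    mu = mu - delta[0]
                # margin recentering: shift the interaction's per-parent
                # means into the parent main effect (same exact move,
                # one level up)
                for pname, pmap in b.margins:
                    j = block_index[pname]
                    pb = blocks_list[j]
                    mq = np.bincount(pmap, minlength=pb.n_levels).astype(
                        float)
                    ubar_q = np.bincount(pmap, weights=u[k],
                                         minlength=pb.n_levels) / mq
                    s2_int = sig2[k][pb.var_group]
                    s2_par = sig2[j][pb.var_group]
                    prec_q = mq / s2_int + 1.0 / s2_par
                    mean_q = (-mq * ubar_q / s2_int
                              + u[j] / s2_par) / prec_q
                    dq = mean_q + rng.standard_normal(
                        pb.n_levels) / np.sqrt(prec_q)
                    u[k] = u[k] + dq[pmap]
                    u[j] = u[j] - dq
                # variance + auxiliary updates (Huang-Wand)
                ss = np.bincount(b.var_group, weights=u[k] ** 2,
                                 minlength=b.n_var_groups)
                m = np.bincount(b.var_group, minlength=b.n_var_groups)
                sig2[k] = _invgamma(rng, (nu + m) / 2.0,
                                    nu / aux[k] + ss / 2.0)
                aux[k] = _invgamma(rng, (nu + 1.0) / 2.0,
                                   nu / sig2[k] + 1.0 / A ** 2)
            # --- fixed-cell means (flat prior)
            fit -= mu[cell_idx]
            resid = y - fit
            sw = np.bincount(cell_idx, weights=resid * w, minlength=n_cells)
            nw = np.bincount(cell_idx, weights=w, minlength=n_cells)
            mu = sw / nw + rng.standard_normal(n_cells) / np.sqrt(nw)
            fit += mu[cell_idx]
            # --- residual variances (shared auxiliary across groups)
            resid = y - fit
            ss_e = np.bincount(resid_group, weights=resid ** 2,
                               minlength=n_resid_groups)
            sig2_e = _invgamma(rng, (nu + resid_counts) / 2.0,
                               nu / aux_e + ss_e / 2.0)
            aux_e = _invgamma(
                rng,
                (nu * n_resid_groups + 1.0) / 2.0,
                float(np.sum(nu / sig2_e)) + 1.0 / A ** 2,
            )

            if it >= mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                d = (it - mcmc.warmup) // mcmc.thin
                for k, b in enumerate(blocks):
                    for g in range(b.n_var_groups):
                        var_store[f"{b.name}:{g}"][chain, d] = sig2[k][g]
                resid_store[chain, d] = sig2_e
                mean_store[chain, d] = mu

    result = GibbsResult(
        variances=var_store,
        resid_variances=resid_store,
        cell_means=mean_store,
    )
    result.rhat = _compute_rhat(result, n_resid_groups, n_cells)
    bad = {k: v for k, v in result.rhat.items()
           if np.isfinite(v) and v > mcmc.rhat_threshold}
    if bad:
        worst = max(bad.items(), key=lambda kv: kv[1])
        raise ConvergenceError(
            f"split R-hat above {mcmc.rhat_threshold} for "
            f"{sorted(bad)} (worst: {worst[0]}={worst[1]:.3f}); "
            "increase draws/warmup or simplify the model"
        )
    return result


def _compute_rhat(result: GibbsResult, n_resid_groups: int,
                  n_cells: int) -> dict[str, float]:
    import arviz as az

    data = {k.replace(":", "_g"): v[:, :, None]
            for k, v in result.variances.items()}
    data["resid"] = result.resid_variances
    data["cell_mean"] = result.cell_means
    ds = az.from_dict(posterior=data)
    rh = az.rhat(ds)
    out: dict[str, float] = {}
    for name, da in rh.data_vars.items():
        vals = np.atleast_1d(np.asarray(da))
        for j, v in enumerate(vals.ravel()):
            out[f"{name}[{j}]"] = float(v)
    return out


def check_rhat(rhat: dict[str, float], threshold: float = 1.01) -> bool:
    """True when every monitored parameter satisfies the R-hat rule."""
    return all(not (np.isfinite(v) and v > threshold)
               for v in rhat.values())
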