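"""Bivariate Gibbs sampler for measure-pair covariance components.

One-facet design (Persons x Trials) with two measures X and Y:

    X_pi = muX + uX_p + vX_i + eX_pi
    Y_pj = muY + uY_p + vY_j + eY_pj

The person effects (uX_p, uY_p) are always bivariate normal with an
inverse-Wishart prior on their 2x2 covariance, giving the person-level
covariance sigmaXY(p).  When the measures are concurrent (observed on
the same trials, j = i), the trial effects and the residuals are
bivariate as well, giving sigmaXY(i) and sigmaXY(pi,e).  When they are
not concurrent the error-level blocks are univariate per measure and
their covariances are exactly zero — non-co-occurring events cannot
share error.

Inverse-Wishart priors (df 3, scale matrix diag of the observed
per-measure variances) keep every covariance draw inside the
Cauchy-Schwarz bound by construction (each draw is a positive-definite
matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from ._gibbs import MCMCConfig, PriorConfig, _invgamma
from .core import MEASURE, PERSON, SCORE, TRIAL
from .exceptions import ConvergenceError, DesignError


def _sample_bivariate_effects(rng, resid_x, resid_y, idx, n_levels,
                              prec_e, sig_inv):
    """Conditional draw of paired effects (uX_l, uY_l) for all levels.

    ``prec_e`` is the 2x2 error precision; ``sig_inv`` the 2x2 prior
    precision of the effect pair.  Vectorized 2x2 solve per level.
    """
    sx = np.bincount(idx, weights=resid_x * prec_e[0, 0]
                     + resid_y * prec_e[0, 1], minlength=n_levels)
    sy = np.bincount(idx, weights=resid_x * prec_e[1, 0]
                     + resid_y * prec_e[1, 1], minlength=n_levels)
    counts = np.bincount(idx, minlength=n_levels).astype(float)
    # posterior precision per level: counts * prec_e + sig_inv
    a = counts * prec_e[0, 0] + sig_inv[0, 0]
    b = counts * prec_e[0, 1] + sig_inv[0, 1]
    d = counts * prec_e[1, 1] + sig_inv[1, 1]
    det = a * d - b * b
    mx = (d * sx - b * sy) / det
    my = (a * sy - b * sx) / det
    # Cholesky of the 2x2 covariance (inverse of precision) per level
    cov_a = d / det
    cov_b = -b / det
    cov_d = a / det
    l11 = np.sqrt(cov_a)
    l21 = cov_b / l11
    l22 = np.sqrt(cov_d - l21 ** 2)
    z1 = rng.standard_normal(n_levels)
    z2 = rng.standard_normal(n_levels)
    return mx + l11 * z1, my + l21 * z1 + l22 * z2


def sample_bivariate_one_facet(
    df: pd.DataFrame,
    label_x: str,
    label_y: str,
    *,
    concurrent: bool,
    seed: int,
    prior: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    family: str = "gaussian",
):
    from .gstudy import CovarianceComponentSet, _transform_scores

    prior = prior or PriorConfig()
    mcmc = mcmc or MCMCConfig()
    nu = prior.sd_df
    nu0 = 3.0  # inverse-Wishart df for 2x2 blocks (weakly informative)

    dx = df[df[MEASURE] == label_x]
    dy = df[df[MEASURE] == label_y]
    if concurrent:
        wide = pd.merge(
            dx[[PERSON, TRIAL, SCORE]].rename(columns={SCORE: "_x"}),
            dy[[PERSON, TRIAL, SCORE]].rename(columns={SCORE: "_y"}),
            on=[PERSON, TRIAL], how="inner",
        )
        if len(wide) != len(dx) or len(wide) != len(dy):
            raise DesignError(
                "concurrent pair requires X and Y on the same trials"
            )
        x = _transform_scores(wide["_x"].to_numpy(float), family)
        y = _transform_scores(wide["_y"].to_numpy(float), family)
        p_idx, p_lv = pd.factorize(wide[PERSON], sort=True)
        i_idx, i_lv = pd.factorize(wide[TRIAL], sort=True)
    else:
        x = _transform_scores(dx[SCORE].to_numpy(float), family)
        y = _transform_scores(dy[SCORE].to_numpy(float), family)
        persons = sorted(set(dx[PERSON]) & set(dy[PERSON]))
        pmap = {p: k for k, p in enumerate(persons)}
        px = dx[PERSON].map(pmap).to_numpy(np.intp)
        py = dy[PERSON].map(pmap).to_numpy(np.intp)
        ix, ix_lv = pd.factorize(dx[TRIAL], sort=True)
        iy, iy_lv = pd.factorize(dy[TRIAL], sort=True)
        p_lv = persons

    n_p = len(p_lv)
    sx2 = float(np.var(x)) or 1.0
    sy2 = float(np.var(y)) or 1.0
    psi_p = np.diag([sx2, sy2])

    n_keep = mcmc.draws
    keys = ["p", "i", "pi,e"] if concurrent else ["p"]
    store = {k: np.empty((mcmc.chains, n_keep)) for k in keys}
    var_store = {k: np.empty((mcmc.chains, n_keep))
                 for k in ("x_p", "y_p", "x_i", "y_i", "x_e", "y_e")}

    seeds = np.random.SeedSequence(seed).spawn(mcmc.chains)
    for chain in range(mcmc.chains):
        rng = np.random.default_rng(seeds[chain])
        sig_p = psi_p.copy() * rng.uniform(0.5, 2.0)
        mu_x, mu_y = float(np.mean(x)), float(np.mean(y))
        u_x = np.zeros(n_p)
        u_y = np.zeros(n_p)
        if concurrent:
            n_i = len(i_lv)
            v_x = np.zeros(n_i)
            v_y = np.zeros(n_i)
            sig_i = np.diag([sx2, sy2]) * rng.uniform(0.5, 2.0)
            sig_e = np.diag([sx2, sy2]) * rng.uniform(0.5, 2.0)
        else:
            v_x = np.zeros(len(ix_lv))
            v_y = np.zeros(len(iy_lv))
            s2_ix = sx2 * rng.uniform(0.5, 2.0)
            s2_iy = sy2 * rng.uniform(0.5, 2.0)
            s2_ex = sx2 * rng.uniform(0.5, 2.0)
            s2_ey = sy2 * rng.uniform(0.5, 2.0)
            aux = {k: 1.0 for k in ("ix", "iy", "ex", "ey")}

        for it in range(mcmc.warmup + n_keep):
            if concurrent:
                prec_e = np.linalg.inv(sig_e)
                # person pairs
                rx = x - mu_x - v_x[i_idx]
                ry = y - mu_y - v_y[i_idx]
                u_x, u_y = _sample_bivariate_effects(
                    rng, rx, ry, p_idx, n_p, prec_e, np.linalg.inv(sig_p))
                sig_p = invwishart.rvs(
                    df=nu0 + n_p,
                    scale=psi_p + np.array(
                        [[u_x @ u_x, u_x @ u_y], [u_x @ u_y, u_y @ u_y]]),
                    random_state=rng)
                # trial pairs
                rx = x - mu_x - u_x[p_idx]
                ry = y - mu_y - u_y[p_idx]
                v_x, v_y = _sample_bivariate_effects(
                    rng, rx, ry, i_idx, n_i, prec_e, np.linalg.inv(sig_i))
                sig_i = invwishart.rvs(
                    df=nu0 + n_i,
                    scale=psi_p + np.array(
                        [[v_x @ v_x, v_x @ v_y], [v_x @ v_y, v_y @ v_y]]),
                    random_state=rng)
                # means: joint bivariate conditional under flat prior
                rx = x - u_x[p_idx] - v_x[i_idx]
                ry = y - u_y[p_idx] - v_y[i_idx]
                mu_x, mu_y = rng.multivariate_normal(
                    [rx.mean(), ry.mean()], sig_e / len(x))
                # residual pairs
                ex = rx - mu_x
                ey = ry - mu_y
                sig_e = invwishart.rvs(
                    df=nu0 + len(x),
                    scale=psi_p + np.array(
                        [[ex @ ex, ex @ ey], [ex @ ey, ey @ ey]]),
                    random_state=rng)
            else:
                # person pairs: X has nX_p obs at precision 1/s2_ex etc.
                rx_all = x - mu_x - v_x[ix]
                ry_all = y - mu_y - v_y[iy]
                swx = np.bincount(px, weights=rx_all, minlength=n_p) / s2_ex
                swy = np.bincount(py, weights=ry_all, minlength=n_p) / s2_ey
                nx = np.bincount(px, minlength=n_p) / s2_ex
                ny = np.bincount(py, minlength=n_p) / s2_ey
                sinv = np.linalg.inv(sig_p)
                a = nx + sinv[0, 0]
                b = np.full(n_p, sinv[0, 1])
                d = ny + sinv[1, 1]
                det = a * d - b * b
                mx = (d * swx - b * swy) / det
                my = (a * swy - b * swx) / det
                l11 = np.sqrt(d / det)
                l21 = (-b / det) / l11
                l22 = np.sqrt(a / det - l21 ** 2)
                z1 = rng.standard_normal(n_p)
                z2 = rng.standard_normal(n_p)
                u_x = mx + l11 * z1
                u_y = my + l21 * z1 + l22 * z2
                sig_p = invwishart.rvs(
                    df=nu0 + n_p,
                    scale=psi_p + np.array(
                        [[u_x @ u_x, u_x @ u_y], [u_x @ u_y, u_y @ u_y]]),
                    random_state=rng)
                # univariate trial effects and residuals per measure
                for (arr, pidx, iidx, nlev, s2_i_key, s2_e_key, vv, uu) in (
                    ("x", px, ix, len(ix_lv), "ix", "ex", v_x, u_x),
                    ("y", py, iy, len(iy_lv), "iy", "ey", v_y, u_y),
                ):
                    yy = x if arr == "x" else y
                    mu = mu_x if arr == "x" else mu_y
                    s2_e = s2_ex if arr == "x" else s2_ey
                    s2_i = s2_ix if arr == "x" else s2_iy
                    r = yy - mu - uu[pidx]
                    sw = np.bincount(iidx, weights=r, minlength=nlev) / s2_e
                    nw = np.bincount(iidx, minlength=nlev) / s2_e
                    prec = nw + 1.0 / s2_i
                    vnew = sw / prec + rng.standard_normal(nlev) / np.sqrt(
                        prec)
                    s2_i = float(_invgamma(
                        rng, (nu + nlev) / 2.0,
                        nu / aux[s2_i_key] + np.sum(vnew ** 2) / 2.0))
                    aux[s2_i_key] = float(_invgamma(
                        rng, (nu + 1.0) / 2.0,
                        nu / s2_i + 1.0 / (sx2 if arr == "x" else sy2)))
                    resid = yy - mu - uu[pidx] - vnew[iidx]
                    mu = rng.normal(
                        float(np.mean(resid)) + mu,
                        np.sqrt(s2_e / len(yy)))
                    resid = yy - mu - uu[pidx] - vnew[iidx]
                    s2_e = float(_invgamma(
                        rng, (nu + len(yy)) / 2.0,
                        nu / aux[s2_e_key] + np.sum(resid ** 2) / 2.0))
                    aux[s2_e_key] = float(_invgamma(
                        rng, (nu + 1.0) / 2.0,
                        nu / s2_e + 1.0 / (sx2 if arr == "x" else sy2)))
                    if arr == "x":
                        v_x, mu_x, s2_ix, s2_ex = vnew, mu, s2_i, s2_e
                    else:
                        v_y, mu_y, s2_iy, s2_ey = vnew, mu, s2_i, s2_e

            if it >= mcmc.warmup:
                dcol = it - mcmc.warmup
                store["p"][chain, dcol] = sig_p[0, 1]
                var_store["x_p"][chain, dcol] = sig_p[0, 0]
                var_store["y_p"][chain, dcol] = sig_p[1, 1]
                if concurrent:
                    store["i"][chain, dcol] = sig_i[0, 1]
                    store["pi,e"][chain, dcol] = sig_e[0, 1]
                    var_store["x_i"][chain, dcol] = sig_i[0, 0]
                    var_store["y_i"][chain, dcol] = sig_i[1, 1]
                    var_store["x_e"][chain, dcol] = sig_e[0, 0]
                    var_store["y_e"][chain, dcol] = sig_e[1, 1]
                else:
                    var_store["x_i"][chain, dcol] = s2_ix
                    var_store["y_i"][chain, dcol] = s2_iy
                    var_store["x_e"][chain, dcol] = s2_ex
                    var_store["y_e"][chain, dcol] = s2_ey

    rhat = _rhat_from_arrays({**store, **var_store})
    bad = {k: v for k, v in rhat.items()
           if np.isfinite(v) and v > mcmc.rhat_threshold}
    if bad:
        raise ConvergenceError(
            f"split R-hat above {mcmc.rhat_threshold} for {sorted(bad)}"
        )
    cov = {"p": float(np.median(store["p"]))}
    draws = {"p": store["p"].reshape(-1)}
    if concurrent:
        cov["pi,e"] = float(np.median(store["pi,e"]))
        draws["pi,e"] = store["pi,e"].reshape(-1)
    else:
        cov["pi,e"] = 0.0
    return CovarianceComponentSet(
        covariances=cov, concurrent=concurrent, estimator="bayes",
        draws=draws, clipped={k: False for k in cov},
    )


def _rhat_from_arrays(arrays: dict[str, np.ndarray]) -> dict[str, float]:
    import arviz as az

    ds = az.from_dict(posterior={k.replace(",", "_").replace(":", "_"): v
                                 for k, v in arrays.items()})
    rh = az.rhat(ds)
    return {name: float(np.asarray(da)) for name, da in rh.data_vars.items()}
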