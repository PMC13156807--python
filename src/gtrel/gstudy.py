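"""G study: variance (and covariance) component estimation.

Two estimators are provided.  ``estimate_ems`` solves the expected
mean-square equations of the random-effects ANOVA exactly; it is the
oracle for balanced Gaussian designs but can return negative raw
components (reported, truncated to zero, and flagged).  ``estimate_bayes``
fits the same decomposition as a Bayesian multilevel model by Gibbs
sampling; every posterior draw of every component is strictly positive,
unbalanced tables are handled naturally, non-Gaussian families are
modeled on a transformed scale, and residual variances can differ by
condition (location-scale heteroscedasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import core
from ._gibbs import EffectBlock, GibbsResult, MCMCConfig, PriorConfig, sample_model
from .core import (
    LAYOUT_ONE_FACET,
    LAYOUT_SPLITS,
    LAYOUT_TWO_FACET,
    MEASURE,
    OCCASION,
    PERSON,
    SCORE,
    SPLIT,
    TRIAL,
    DesignSpec,
    ObservationTable,
    validate_design,
)
from .exceptions import (
    BalanceError,
    DesignError,
    FamilyError,
    IncompleteComponentsError,
)

__all__ = [
    "VarianceComponentSet",
    "CovarianceComponentSet",
    "MCMCConfig",
    "PriorConfig",
    "estimate_ems",
    "estimate_bayes",
    "components_by_fixed_level",
    "estimate_covariances",
]

#: scale on which the linear decomposition is modeled, per family
FAMILY_SCALE = {"gaussian": "identity", "lognormal": "log",
                "gamma_chisq": "sqrt"}


def _transform_scores(y: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        return y
    if family == "lognormal":
        if np.any(y <= 0):
            raise FamilyError(
                "lognormal family requires strictly positive scores"
            )
        return np.log(y)
    if family == "gamma_chisq":
        if np.any(y < 0):
            raise FamilyError(
                "gamma_chisq family requires nonnegative scores"
            )
        return np.sqrt(y)
    raise FamilyError(f"unknown family {family!r}")


@dataclass
class VarianceComponentSet:
    """Nonnegative variance per effect, with optional posterior draws.

    ``components`` maps effect labels (``"p"``, ``"i"``, ``"pi,e"`` ...)
    to point estimates on the modeling scale named by ``scale``.  The
    highest-order interaction label carries the ``",e"`` suffix: with a
    single observation per cell it is confounded with residual error.
    When ``draws`` are present the point estimate of each component is
    the posterior median of its draws.
    """

    components: dict[str, float]
    grand_mean: float
    estimator: str                       # "ems" | "bayes"
    layout: str
    family: str = "gaussian"
    scale: str = "identity"
    raw_components: dict[str, float] | None = None
    truncation_flags: dict[str, bool] = field(default_factory=dict)
    draws: dict[str, np.ndarray] | None = None
    grand_mean_draws: np.ndarray | None = None
    fixed_facet: str | None = None
    by_fixed_level: dict[str, "VarianceComponentSet"] | None = None
    hidden_levels: dict[str, object] | None = None
    diagnostics: dict | None = None
    n_observed: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for label, value in self.components.items():
            if value < 0:
                raise ValueError(
                    f"stored component {label!r} is negative ({value}); "
                    "raw negatives belong in raw_components"
                )
        if self.draws is not None:
            for label, d in self.draws.items():
                if np.any(d <= 0):
                    raise ValueError(
                        f"Bayesian draws for {label!r} contain nonpositive "
                        "values"
                    )

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))

    @property
    def residual_label(self) -> str:
        return core.LAYOUT_EFFECTS[self.layout][-1]

    def credible_intervals(self, prob: float = 0.95) -> dict[str, tuple]:
        if self.draws is None:
            return {}
        lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
        return {
            k: (float(np.quantile(v, lo)), float(np.quantile(v, hi)))
            for k, v in self.draws.items()
        }

    def to_dict(self) -> dict:
        out = {
            "components": {k: float(v) for k, v in self.components.items()},
            "grand_mean": float(self.grand_mean),
            "estimator": self.estimator,
            "layout": self.layout,
            "family": self.family,
            "scale": self.scale,
            "truncation_flags": dict(self.truncation_flags),
        }
        if self.raw_components is not None:
            out["raw_components"] = {
                k: float(v) for k, v in self.raw_components.items()
            }
        if self.draws is not None:
            out["credible_intervals_95"] = {
                k: list(v) for k, v in self.credible_intervals().items()
            }
        if self.diagnostics is not None:
            out["diagnostics"] = {
                k: v for k, v in self.diagnostics.items() if k != "rhat_all"
            }
        if self.by_fixed_level:
            out["by_fixed_level"] = {
                str(k): v.to_dict() for k, v in self.by_fixed_level.items()
            }
        return out


@dataclass
class CovarianceComponentSet:
    """Covariance between measures X and Y per shared effect.

    Keys mirror the person-level effect labels: ``"p"``, ``"pi,e"``,
    ``"po"``, ``"pio,e"``, ``"p(i:s)"``.  For non-concurrent measures
    every error-level covariance is exactly zero — the events never
    co-occur, so their errors cannot covary.  Each covariance is bounded
    by Cauchy-Schwarz against the per-measure variances.
    """

    covariances: dict[str, float]
    concurrent: bool
    estimator: str = "ems"
    draws: dict[str, np.ndarray] | None = None
    clipped: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.concurrent:
            for k, v in self.covariances.items():
                if k != "p" and v != 0.0:
                    raise ValueError(
                        f"non-concurrent pair has nonzero error covariance "
                        f"{k!r}={v}"
                    )

    def to_dict(self) -> dict:
        return {
            "covariances": {k: float(v) for k, v in self.covariances.items()},
            "concurrent": self.concurrent,
            "estimator": self.estimator,
            "clipped": dict(self.clipped),
        }


# ======================================================================
# Expected mean squares (balanced designs)
# ======================================================================
def _require_balanced_crossing(df: pd.DataFrame, cols: list[str]) -> tuple:
    """Check complete crossing with one observation per cell."""
    sizes = [df[c].nunique() for c in cols]
    if len(df) != int(np.prod(sizes)):
        raise BalanceError(
            "table is not a complete balanced crossing of "
            f"{cols} ({len(df)} rows vs expected {int(np.prod(sizes))}); "
            "use estimate_bayes for unbalanced data"
        )
    if df.groupby(cols, observed=True).size().max() != 1:
        raise BalanceError(
            f"duplicate observations per {cols} cell; "
            "use estimate_bayes for unbalanced data"
        )
    return tuple(sizes)


def _ems_one_facet(df: pd.DataFrame) -> tuple[dict, float]:
    n_p, n_i = _require_balanced_crossing(df, [PERSON, TRIAL])
    y = df[SCORE].to_numpy()
    grand = y.mean()
    pm = df.groupby(PERSON, observed=True)[SCORE].mean().to_numpy()
    im = df.groupby(TRIAL, observed=True)[SCORE].mean().to_numpy()
    ss_p = n_i * np.sum((pm - grand) ** 2)
    ss_i = n_p * np.sum((im - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_pi = ss_tot - ss_p - ss_i
    ms_p = ss_p / (n_p - 1)
    ms_i = ss_i / (n_i - 1)
    ms_pi = ss_pi / ((n_p - 1) * (n_i - 1))
    raw = {
        "pi,e": ms_pi,
        "i": (ms_i - ms_pi) / n_p,
        "p": (ms_p - ms_pi) / n_i,
    }
    return raw, float(grand)


def _ems_two_facet(df: pd.DataFrame) -> tuple[dict, float]:
    n_p, n_i, n_o = _require_balanced_crossing(df, [PERSON, TRIAL, OCCASION])
    y = df[SCORE].to_numpy()
    grand = y.mean()

    def ssq(cols):
        m = df.groupby(cols, observed=True)[SCORE].mean()
        weight = len(df) / len(m)
        return weight * np.sum((m.to_numpy() - grand) ** 2)

    ss = {
        "p": ssq([PERSON]),
        "i": ssq([TRIAL]),
        "o": ssq([OCCASION]),
    }
    ss["pi"] = ssq([PERSON, TRIAL]) - ss["p"] - ss["i"]
    ss["po"] = ssq([PERSON, OCCASION]) - ss["p"] - ss["o"]
    ss["oi"] = ssq([OCCASION, TRIAL]) - ss["o"] - ss["i"]
    ss_tot = np.sum((y - grand) ** 2)
    ss["pio,e"] = ss_tot - sum(ss.values())
    df_ = {
        "p": n_p - 1, "i": n_i - 1, "o": n_o - 1,
        "pi": (n_p - 1) * (n_i - 1),
        "po": (n_p - 1) * (n_o - 1),
        "oi": (n_o - 1) * (n_i - 1),
        "pio,e": (n_p - 1) * (n_i - 1) * (n_o - 1),
    }
    ms = {k: ss[k] / df_[k] for k in ss}
    raw = {
        "pio,e": ms["pio,e"],
        "pi": (ms["pi"] - ms["pio,e"]) / n_o,
        "po": (ms["po"] - ms["pio,e"]) / n_i,
        "oi": (ms["oi"] - ms["pio,e"]) / n_p,
        "p": (ms["p"] - ms["pi"] - ms["po"] + ms["pio,e"]) / (n_i * n_o),
        "i": (ms["i"] - ms["pi"] - ms["oi"] + ms["pio,e"]) / (n_p * n_o),
        "o": (ms["o"] - ms["po"] - ms["oi"] + ms["pio,e"]) / (n_p * n_i),
    }
    return raw, float(grand)


def _ems_splits(df: pd.DataFrame) -> tuple[dict, float]:
    # Persons x (Trials:Splits): trials carry unique indices nested in
    # splits, so the (person, trial) crossing is complete.
    n_p, n_trials = _require_balanced_crossing(df, [PERSON, TRIAL])
    n_s = df[SPLIT].nunique()
    per_split = df.groupby(SPLIT, observed=True)[TRIAL].nunique()
    if per_split.nunique() != 1:
        raise BalanceError(
            "unequal trials per split; re-run enforce_split_convention "
            "or use estimate_bayes"
        )
    k = int(per_split.iloc[0])
    y = df[SCORE].to_numpy()
    grand = y.mean()

    def ssq(cols):
        m = df.groupby(cols, observed=True)[SCORE].mean()
        weight = len(df) / len(m)
        return weight * np.sum((m.to_numpy() - grand) ** 2)

    ss_p = ssq([PERSON])
    ss_s = ssq([SPLIT])
    ss_is = ssq([TRIAL]) - ss_s                    # trials within splits
    ss_ps = ssq([PERSON, SPLIT]) - ss_p - ss_s
    ss_tot = np.sum((y - grand) ** 2)
    ss_res = ss_tot - ss_p - ss_s - ss_is - ss_ps
    ms = {
        "p": ss_p / (n_p - 1),
        "s": ss_s / (n_s - 1),
        "i:s": ss_is / (n_s * (k - 1)),
        "ps": ss_ps / ((n_p - 1) * (n_s - 1)),
        "p(i:s),e": ss_res / ((n_p - 1) * n_s * (k - 1)),
    }
    raw = {
        "p(i:s),e": ms["p(i:s),e"],
        "ps": (ms["ps"] - ms["p(i:s),e"]) / k,
        "i:s": (ms["i:s"] - ms["p(i:s),e"]) / n_p,
        "s": (ms["s"] - ms["ps"] - ms["i:s"] + ms["p(i:s),e"]) / (n_p * k),
        "p": (ms["p"] - ms["ps"]) / (k * n_s),
    }
    return raw, float(grand)


_EMS_DISPATCH = {
    LAYOUT_ONE_FACET: _ems_one_facet,
    LAYOUT_TWO_FACET: _ems_two_facet,
    LAYOUT_SPLITS: _ems_splits,
}


def _truncate(raw: Mapping[str, float]) -> tuple[dict, dict]:
    comps = {k: max(0.0, float(v)) for k, v in raw.items()}
    flags = {k: bool(v < 0) for k, v in raw.items()}
    return comps, flags


def _hidden_levels(table: ObservationTable,
                   design: DesignSpec) -> dict[str, object]:
    out = {}
    for name in design.declared_hidden:
        if name in table.data.columns:
            vals = table.data[name].unique()
            if len(vals) == 1:
                out[name] = vals[0]
    return out


def estimate_ems(table: ObservationTable,
                 design: DesignSpec) -> VarianceComponentSet:
    """Exact expected-mean-squares solution for a balanced design.

    Negative raw solutions (a known artifact of the method, e.g. when a
    facet contributes no variance) are truncated to zero for downstream
    coefficients and flagged in ``truncation_flags``; the raw values are
    kept in ``raw_components``.

    With a fixed facet in the design, components are estimated
    separately inside each fixed-facet cell (each must itself be
    balanced); the top-level component map is the unweighted mean across
    cells and the per-cell sets are available through
    :func:`components_by_fixed_level`.
    """
    if design.family != "gaussian":
        raise FamilyError(
            "estimate_ems supports the gaussian family only; use "
            "estimate_bayes for transformed families"
        )
    if design.layout not in _EMS_DISPATCH:
        raise DesignError(
            f"no EMS solution implemented for layout {design.layout!r}"
        )
    validate_design(table, design)
    df = table.data
    solver = _EMS_DISPATCH[design.layout]

    fixed = [f.name for f in design.fixed_facets]
    if fixed:
        by_level: dict[str, VarianceComponentSet] = {}
        for level, sub in df.groupby(fixed[0] if len(fixed) == 1 else fixed,
                                     observed=True):
            raw, grand = solver(sub)
            comps, flags = _truncate(raw)
            by_level[level if np.isscalar(level) else str(level)] = (
                VarianceComponentSet(
                    components=comps, grand_mean=grand, estimator="ems",
                    layout=design.layout, raw_components=dict(raw),
                    truncation_flags=flags,
                )
            )
        labels = next(iter(by_level.values())).components.keys()
        mean_comps = {
            k: float(np.mean([v.components[k] for v in by_level.values()]))
            for k in labels
        }
        mean_raw = {
            k: float(np.mean([v.raw_components[k]
                              for v in by_level.values()]))
            for k in labels
        }
        flags = {
            k: any(v.truncation_flags[k] for v in by_level.values())
            for k in labels
        }
        return VarianceComponentSet(
            components=mean_comps,
            grand_mean=float(df[SCORE].mean()),
            estimator="ems", layout=design.layout,
            raw_components=mean_raw, truncation_flags=flags,
            fixed_facet=fixed[0] if len(fixed) == 1 else ",".join(fixed),
            by_fixed_level=by_level,
            hidden_levels=_hidden_levels(table, design),
        )

    raw, grand = solver(df)
    comps, flags = _truncate(raw)
    return VarianceComponentSet(
        components=comps, grand_mean=grand, estimator="ems",
        layout=design.layout, raw_components=dict(raw),
        truncation_flags=flags,
        hidden_levels=_hidden_levels(table, design),
    )


# ======================================================================
# Bayesian multilevel estimation
# ======================================================================
def _codes(values: pd.Series) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(values, sort=True)
    return codes.astype(np.intp), len(uniques)


def _pair_codes(a: np.ndarray, na: int, b: np.ndarray,
                nb: int) -> tuple[np.ndarray, int]:
    return (a * nb + b).astype(np.intp), na * nb


def _blocks_for_layout(layout: str, df: pd.DataFrame,
                       cell: np.ndarray, n_cells: int) -> list[EffectBlock]:
    """Random-effect blocks, nested inside fixed-facet cells.

    Each block's levels are (fixed cell, facet level) pairs and its
    variance parameters are indexed by fixed cell, which is what lets a
    single joint model return per-condition components.
    """
    p, n_p = _codes(df[PERSON])

    def nest(idx: np.ndarray, n: int) -> tuple[np.ndarray, int, np.ndarray]:
        levels, n_levels = _pair_codes(cell, n_cells, idx, n)
        var_group = (np.arange(n_levels) // n).astype(np.intp)
        return levels, n_levels, var_group

    def block(name, idx, n, margins=()):
        levels, n_levels, vg = nest(idx, n)
        return EffectBlock(name, levels, n_levels, vg, n_cells,
                           margins=margins)

    def margin_maps(na: int, nb: int):
        """Maps from (cell x a x b) interaction levels to parent levels."""
        lv = np.arange(n_cells * na * nb)
        c, r = lv // (na * nb), lv % (na * nb)
        return (c * na + r // nb).astype(np.intp), \
            (c * nb + r % nb).astype(np.intp)

    if layout == LAYOUT_ONE_FACET:
        i, n_i = _codes(df[TRIAL])
        return [block("p", p, n_p), block("i", i, n_i)]
    if layout == LAYOUT_TWO_FACET:
        i, n_i = _codes(df[TRIAL])
        o, n_o = _codes(df[OCCASION])
        pi, n_pi = _pair_codes(p, n_p, i, n_i)
        po, n_po = _pair_codes(p, n_p, o, n_o)
        oi, n_oi = _pair_codes(o, n_o, i, n_i)
        m_pi = margin_maps(n_p, n_i)
        m_po = margin_maps(n_p, n_o)
        m_oi = margin_maps(n_o, n_i)
        return [
            block("p", p, n_p), block("i", i, n_i), block("o", o, n_o),
            block("pi", pi, n_pi, (("p", m_pi[0]), ("i", m_pi[1]))),
            block("po", po, n_po, (("p", m_po[0]), ("o", m_po[1]))),
            block("oi", oi, n_oi, (("o", m_oi[0]), ("i", m_oi[1]))),
        ]
    if layout == LAYOUT_SPLITS:
        s, n_s = _codes(df[SPLIT])
        i, n_i = _codes(df[TRIAL])          # trial indices unique in splits
        ps, n_ps = _pair_codes(p, n_p, s, n_s)
        m_ps = margin_maps(n_p, n_s)
        return [
            block("p", p, n_p), block("s", s, n_s),
            block("i:s", i, n_i),
            block("ps", ps, n_ps, (("p", m_ps[0]), ("s", m_ps[1]))),
        ]
    raise DesignError(
        f"no Bayesian model implemented for layout {layout!r}"
    )


def estimate_bayes(
    table: ObservationTable,
    design: DesignSpec,
    *,
    seed: int,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
    heteroscedastic_by: str | None = None,
) -> VarianceComponentSet:
    """Bayesian multilevel variance components by Gibbs sampling.

    The seed is mandatory: there is no silent default stream.  Posterior
    draws of every component are strictly positive by construction.
    Families other than gaussian are modeled on a transformed scale
    (lognormal: log scores; gamma_chisq: square-root scores, a
    variance-stabilizing choice for power-like, zero-bounded measures);
    all components and downstream coefficients are then reported on that
    scale, named in ``scale``.

    With ``heteroscedastic_by`` set (or whenever the design has a fixed
    facet), residual variances are estimated per condition under a
    shared higher-level prior (location-scale model), and — for fixed
    facets — person/trial components are likewise estimated per
    condition from the single joint fit.

    Raises :class:`ConvergenceError` when any monitored parameter has
    split R-hat above the threshold (default 1.01).
    """
    validate_design(table, design)
    if mcmc is None:
        # crossed interactions mix more slowly than main effects; thin
        # the chains in interaction-bearing layouts so the retained
        # draws carry the same information
        plain = design.layout == LAYOUT_ONE_FACET and not design.fixed_facets
        mcmc = MCMCConfig() if plain else MCMCConfig(thin=5, warmup=800)
    df = table.data
    y = _transform_scores(df[SCORE].to_numpy(dtype=float), design.family)

    fixed = [f.name for f in design.fixed_facets]
    if fixed:
        fixed_key = df[fixed[0]] if len(fixed) == 1 else (
            df[fixed].astype(str).agg("|".join, axis=1)
        )
        cell, n_cells = _codes(fixed_key)
        cell_labels = list(pd.factorize(fixed_key, sort=True)[1])
    else:
        cell = np.zeros(len(df), dtype=np.intp)
        n_cells, cell_labels = 1, [None]

    if heteroscedastic_by is not None:
        if heteroscedastic_by not in df.columns:
            raise DesignError(
                f"heteroscedastic_by facet {heteroscedastic_by!r} not in "
                "table"
            )
        rg, n_rg = _codes(df[heteroscedastic_by])
        rg_labels = list(pd.factorize(df[heteroscedastic_by], sort=True)[1])
    else:
        rg, n_rg, rg_labels = cell, n_cells, cell_labels

    blocks = _blocks_for_layout(design.layout, df, cell, n_cells)
    result = sample_model(
        y, blocks, cell_idx=cell, n_cells=n_cells,
        resid_group=rg, n_resid_groups=n_rg,
        seed=seed, prior=priors, mcmc=mcmc,
    )
    return _vcs_from_gibbs(result, design, table, cell_labels, rg_labels,
                           n_cells)


def _vcs_from_gibbs(result: GibbsResult, design: DesignSpec,
                    table: ObservationTable, cell_labels: list,
                    rg_labels: list, n_cells: int) -> VarianceComponentSet:
    residual = design.residual_effect
    effect_names = [b for b in design.effects[:-1] if b != "p"]
    block_names = ["p"] + effect_names  # order irrelevant; keys by name

    def flat(a: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(a).reshape(-1)

    # per-cell draws
    per_level: dict[str, dict[str, np.ndarray]] = {}
    for g in range(n_cells):
        level_draws = {
            name: flat(result.variances[f"{name}:{g}"])
            for name in block_names
        }
        # residual groups coincide with cells unless heteroscedastic_by
        # named a different facet; then per-cell residuals are not
        # available and the group draws are exposed via diagnostics.
        if len(rg_labels) == n_cells:
            level_draws[residual] = flat(result.resid_variances[:, :, g])
        else:
            level_draws[residual] = flat(
                result.resid_variances.mean(axis=2)
            )
        per_level[str(cell_labels[g]) if cell_labels[g] is not None
                  else "_all"] = level_draws

    mean_draws = flat(result.cell_means.mean(axis=2))
    resid_group_draws = {
        str(rg_labels[j]): flat(result.resid_variances[:, :, j])
        for j in range(result.resid_variances.shape[2])
    }
    diagnostics = {
        "rhat_max": max(result.rhat.values()),
        "rhat_all": result.rhat,
        "residual_variance_by_group": {
            k: float(np.median(v)) for k, v in resid_group_draws.items()
        },
    }

    def build(level_draws: dict[str, np.ndarray],
              grand: np.ndarray) -> VarianceComponentSet:
        comps = {k: float(np.median(v)) for k, v in level_draws.items()}
        return VarianceComponentSet(
            components=comps,
            grand_mean=float(np.median(grand)),
            estimator="bayes", layout=design.layout,
            family=design.family, scale=FAMILY_SCALE[design.family],
            draws=level_draws, grand_mean_draws=grand,
            diagnostics=diagnostics,
        )

    if n_cells == 1:
        vcs = build(per_level["_all"] if "_all" in per_level
                    else next(iter(per_level.values())), mean_draws)
        vcs.hidden_levels = _hidden_levels(table, design)
        vcs.diagnostics["residual_group_draws"] = resid_group_draws
        return vcs

    by_level = {}
    for g, label in enumerate(cell_labels):
        grand_g = flat(result.cell_means[:, :, g])
        by_level[label] = build(per_level[str(label)], grand_g)
    # top-level: pooled draws = mean of per-level draws (equal weight)
    labels0 = design.effects
    pooled = {
        k: np.mean([per_level[str(label)][k] for label in cell_labels],
                   axis=0)
        for k in labels0
    }
    vcs = build(pooled, mean_draws)
    fixed = [f.name for f in design.fixed_facets]
    vcs.fixed_facet = fixed[0] if len(fixed) == 1 else ",".join(fixed)
    vcs.by_fixed_level = by_level
    vcs.hidden_levels = _hidden_levels(table, design)
    return vcs


def components_by_fixed_level(
    fit: VarianceComponentSet, fixed_facet: str
) -> dict[str, VarianceComponentSet]:
    """Per-condition component sets from a single joint fit.

    For a design whose ``fixed_facet`` was modeled, returns one
    :class:`VarianceComponentSet` per condition, enabling per-condition
    reliability coefficients and posterior contrasts.  For a design in
    which the facet was declared hidden (a single sampled condition),
    returns a one-entry map: the global fit, conditional on that
    condition.
    """
    if fit.fixed_facet == fixed_facet and fit.by_fixed_level:
        return dict(fit.by_fixed_level)
    if fit.hidden_levels and fixed_facet in fit.hidden_levels:
        return {fit.hidden_levels[fixed_facet]: fit}
    raise DesignError(
        f"facet {fixed_facet!r} is not a fixed facet of this fit "
        "(and was not a declared-hidden column of the source table)"
    )


# ======================================================================
# Covariance components (difference-score support)
# ======================================================================
def _split_measures(table: ObservationTable) -> tuple[pd.DataFrame, list]:
    df = table.data
    if MEASURE not in df.columns:
        raise DesignError(
            "estimate_covariances requires a 'measure' column with "
            "exactly two labels"
        )
    labels = sorted(df[MEASURE].unique().tolist())
    if len(labels) != 2:
        raise DesignError(
            f"exactly two measure labels required, found {labels}"
        )
    return df, labels


def _cross_products_one_facet(wide: pd.DataFrame) -> dict[str, float]:
    """Bivariate EMS analog: mean cross-products for Persons x Trials."""
    n_p = wide[PERSON].nunique()
    n_i = wide[TRIAL].nunique()
    x = wide["_x"].to_numpy()
    yv = wide["_y"].to_numpy()
    gx, gy = x.mean(), yv.mean()
    pm = wide.groupby(PERSON, observed=True)[["_x", "_y"]].mean()
    im = wide.groupby(TRIAL, observed=True)[["_x", "_y"]].mean()
    sp_p = n_i * np.sum((pm["_x"] - gx) * (pm["_y"] - gy))
    sp_i = n_p * np.sum((im["_x"] - gx) * (im["_y"] - gy))
    sp_tot = np.sum((x - gx) * (yv - gy))
    sp_pi = sp_tot - sp_p - sp_i
    mcp_p = sp_p / (n_p - 1)
    mcp_pi = sp_pi / ((n_p - 1) * (n_i - 1))
    return {"pi,e": float(mcp_pi), "p": float((mcp_p - mcp_pi) / n_i)}


def _cross_products_two_facet(wide: pd.DataFrame) -> dict[str, float]:
    n_p = wide[PERSON].nunique()
    n_i = wide[TRIAL].nunique()
    n_o = wide[OCCASION].nunique()
    x, yv = wide["_x"].to_numpy(), wide["_y"].to_numpy()
    gx, gy = x.mean(), yv.mean()

    def sp(cols):
        m = wide.groupby(cols, observed=True)[["_x", "_y"]].mean()
        weight = len(wide) / len(m)
        return weight * np.sum((m["_x"] - gx) * (m["_y"] - gy))

    s = {"p": sp([PERSON]), "i": sp([TRIAL]), "o": sp([OCCASION])}
    s["pi"] = sp([PERSON, TRIAL]) - s["p"] - s["i"]
    s["po"] = sp([PERSON, OCCASION]) - s["p"] - s["o"]
    s["oi"] = sp([OCCASION, TRIAL]) - s["o"] - s["i"]
    s["pio,e"] = np.sum((x - gx) * (yv - gy)) - sum(s.values())
    dfree = {
        "p": n_p - 1, "pi": (n_p - 1) * (n_i - 1),
        "po": (n_p - 1) * (n_o - 1),
        "pio,e": (n_p - 1) * (n_i - 1) * (n_o - 1),
    }
    mcp = {k: s[k] / dfree[k] for k in dfree}
    return {
        "pio,e": float(mcp["pio,e"]),
        "pi": float((mcp["pi"] - mcp["pio,e"]) / n_o),
        "po": float((mcp["po"] - mcp["pio,e"]) / n_i),
        "p": float((mcp["p"] - mcp["pi"] - mcp["po"] + mcp["pio,e"])
                   / (n_i * n_o)),
    }


def estimate_covariances(
    table: ObservationTable,
    design: DesignSpec,
    *,
    concurrent: bool,
    estimator: str = "ems",
    seed: int | None = None,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> CovarianceComponentSet:
    """Covariance components between two measures X and Y.

    The person-level covariance is always estimable.  Error-level
    covariances (``pi,e`` etc.) exist only for concurrent measures —
    X and Y observed on the same trials; for non-concurrent pairs they
    are fixed at exactly zero.  Estimates are clipped to the
    Cauchy-Schwarz bound implied by the per-measure components (clips
    are flagged, never silent).

    The ``bayes`` estimator (one-facet designs) uses bivariate
    random-effect blocks with inverse-Wishart priors so that every draw
    satisfies the bound by construction.
    """
    df, labels = _split_measures(table)
    lx, ly = labels
    if estimator == "bayes":
        if design.layout != LAYOUT_ONE_FACET:
            raise DesignError(
                "bayes covariance estimation is implemented for the "
                "one-facet design; use estimator='ems'"
            )
        if seed is None:
            raise ValueError("seed is required for the bayes estimator")
        from ._bivariate import sample_bivariate_one_facet
        return sample_bivariate_one_facet(
            df, lx, ly, concurrent=concurrent, seed=seed,
            prior=priors, mcmc=mcmc, family=design.family,
        )
    if estimator != "ems":
        raise ValueError(f"unknown estimator {estimator!r}")

    sub = {m: table.data[table.data[MEASURE] == m] for m in labels}
    per_measure = {}
    for m in labels:
        t = ObservationTable(sub[m].drop(columns=[MEASURE]))
        per_measure[m] = estimate_ems(t, design)

    if concurrent:
        join_cols = [PERSON, TRIAL] + (
            [OCCASION] if design.layout == LAYOUT_TWO_FACET else []
        )
        wide = pd.merge(
            sub[lx][join_cols + [SCORE]].rename(columns={SCORE: "_x"}),
            sub[ly][join_cols + [SCORE]].rename(columns={SCORE: "_y"}),
            on=join_cols, how="inner",
        )
        if len(wide) != len(sub[lx]) or len(wide) != len(sub[ly]):
            raise DesignError(
                "concurrent covariance estimation requires X and Y "
                "observed on the same trials"
            )
        if design.layout == LAYOUT_ONE_FACET:
            cov = _cross_products_one_facet(wide)
        elif design.layout == LAYOUT_TWO_FACET:
            cov = _cross_products_two_facet(wide)
        else:
            raise DesignError(
                f"covariance estimation not implemented for layout "
                f"{design.layout!r}"
            )
    else:
        pm_x = sub[lx].groupby(PERSON, observed=True)[SCORE].mean()
        pm_y = sub[ly].groupby(PERSON, observed=True)[SCORE].mean()
        aligned = pd.concat([pm_x, pm_y], axis=1, join="inner")
        aligned.columns = ["_x", "_y"]
        # with independent errors the error terms cancel in expectation,
        # so the covariance of person means estimates sigmaXY(p) directly
        cov_p = float(np.cov(aligned["_x"], aligned["_y"], ddof=1)[0, 1])
        error_labels = [e for e in design.effects
                        if e.startswith("p") and e != "p"]
        cov = {"p": cov_p, **{e: 0.0 for e in error_labels}}

    clipped = {}
    for eff in cov:
        vx = per_measure[lx].components.get(eff)
        vy = per_measure[ly].components.get(eff)
        if vx is None or vy is None:
            raise IncompleteComponentsError(
                f"per-measure component {eff!r} missing for the "
                "Cauchy-Schwarz bound"
            )
        bound = float(np.sqrt(vx * vy))
        if abs(cov[eff]) > bound:
            cov[eff] = float(np.sign(cov[eff]) * bound)
            clipped[eff] = True
        else:
            clipped[eff] = False
    return CovarianceComponentSet(
        covariances=cov, concurrent=concurrent, estimator="ems",
        clipped=clipped,
    )
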