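"""Synthetic data from the GT linear decomposition with known components.

Scores are built as grand mean + person effect + facet effects +
interactions + residual, each drawn with its stated variance, so every
estimator and coefficient in the package can be validated by parameter
recovery without any external data.  Non-Gaussian families transform a
latent Gaussian decomposition: ``lognormal`` exponentiates it (skewed,
strictly positive scores such as spectral power), ``gamma_chisq``
squares it (power-like scores with a hard noise floor at zero — the
square of an amplitude can never be negative).  Component variances are
therefore specified on the latent (log / square-root) scale for those
families, matching the scale on which the estimators model them.

Per-person unbalance emulates artifact rejection: each trial is
retained independently with a stated probability, independent of its
score — missingness is ignorable by construction, which is exactly the
assumption the estimators make.  Zero-inflation (EDA nonresponse
trials zeroed out) is applied after the family transform.

One global seed governs all draws; sub-streams are derived with fixed
spawn keys per purpose so that adding a facet never reshuffles the
draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

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
    ObservationTable,
)

__all__ = ["SimulationSpec", "SimulationTruth", "simulate",
           "make_worked_example"]

# stable sub-stream keys: adding a purpose appends, never reorders
_STREAMS = {
    "person": 0, "trial": 1, "occasion": 2, "split": 3,
    "pi": 4, "po": 5, "oi": 6, "ps": 7, "is": 8,
    "residual": 9, "retention": 10, "zero": 11, "measure": 12,
}


def _rng(seed: int, purpose: str, level: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(_STREAMS[purpose], level))
    )


@dataclass
class SimulationSpec:
    """Generating conditions for one synthetic dataset.

    ``components`` maps effect labels of the target layout (``"p"``,
    ``"i"``, ``"pi,e"``, ...) to true variances on the modeling scale.
    ``fixed_levels`` adds a fixed facet: each level may override
    components, the grand mean, and the retention probability.
    ``covariances`` turns the dataset into a measure pair (X/Y) with the
    stated person-level (and, when ``concurrent``, error-level)
    covariances; per-effect variances are shared by X and Y unless
    ``components_y`` overrides them.
    """

    n_persons: int
    n_trials: int
    components: dict[str, float]
    mu: float = 0.0
    n_occasions: int | None = None
    trials_per_split: int | None = None
    family: str = "gaussian"
    retention: float = 1.0
    zero_inflation: float = 0.0
    fixed_facet: str | None = None
    fixed_levels: dict[str, dict] | None = None
    covariances: dict[str, float] | None = None
    concurrent: bool = True
    components_y: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.components.items():
            if v < 0:
                raise ValueError(f"variance {k!r} is negative")
        if not (0.0 <= self.retention <= 1.0):
            raise ValueError("retention must be in [0,1]")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must be in [0,1]")
        if self.covariances is not None:
            comps_y = self.components_y or self.components
            for eff, c in self.covariances.items():
                vx = self.components.get(eff, 0.0)
                vy = comps_y.get(eff, 0.0)
                if abs(c) > np.sqrt(vx * vy) + 1e-12:
                    raise ValueError(
                        f"covariance {eff!r}={c} violates Cauchy-Schwarz "
                        f"against variances ({vx}, {vy})"
                    )

    @property
    def layout(self) -> str:
        if self.trials_per_split is not None:
            return LAYOUT_SPLITS
        if self.n_occasions is not None:
            return LAYOUT_TWO_FACET
        return LAYOUT_ONE_FACET


@dataclass
class SimulationTruth:
    """The generating values, kept alongside the simulated table."""

    components: dict[str, float]
    mu: float
    family: str
    layout: str
    seed: int
    by_fixed_level: dict[str, dict] = field(default_factory=dict)
    covariances: dict[str, float] | None = None
    realized_trials_per_person: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "components": self.components,
            "mu": self.mu,
            "family": self.family,
            "layout": self.layout,
            "seed": self.seed,
            "by_fixed_level": self.by_fixed_level,
            "covariances": self.covariances,
            "realized_trials_per_person": {
                str(k): int(v)
                for k, v in self.realized_trials_per_person.items()
            },
        }


def _latent_mu(mu: float, family: str) -> float:
    if family == "gaussian":
        return mu
    if family == "lognormal":
        if mu <= 0:
            raise ValueError("lognormal family needs a positive grand mean")
        return float(np.log(mu))
    if family == "gamma_chisq":
        if mu < 0:
            raise ValueError("gamma_chisq family needs a nonnegative mean")
        return float(np.sqrt(mu))
    raise ValueError(f"unknown family {family!r}")


def _transform(latent: np.ndarray, family: str) -> np.ndarray:
    if family == "gaussian":
        return latent
    if family == "lognormal":
        return np.exp(latent)
    return latent ** 2  # gamma_chisq: squared amplitude, floor at zero


def _sd(components: Mapping[str, float], label: str) -> float:
    return float(np.sqrt(components.get(label, 0.0)))


def _simulate_level(spec: SimulationSpec, components: Mapping[str, float],
                    mu: float, retention: float, level_idx: int,
                    n_trials: int) -> pd.DataFrame:
    """One fixed-facet level (or the whole table when no fixed facet)."""
    n_p = spec.n_persons
    layout = spec.layout
    persons = np.arange(n_p)
    trials = np.arange(1, n_trials + 1)
    lm = _latent_mu(mu, spec.family)

    if layout == LAYOUT_ONE_FACET:
        p_eff = _rng(spec.seed, "person", level_idx).normal(
            0, _sd(components, "p"), n_p)
        i_eff = _rng(spec.seed, "trial", level_idx).normal(
            0, _sd(components, "i"), n_trials)
        resid = _rng(spec.seed, "residual", level_idx).normal(
            0, _sd(components, "pi,e"), (n_p, n_trials))
        latent = lm + p_eff[:, None] + i_eff[None, :] + resid
        df = pd.DataFrame({
            PERSON: np.repeat(persons, n_trials),
            TRIAL: np.tile(trials, n_p),
            SCORE: latent.ravel(),
        })
    elif layout == LAYOUT_TWO_FACET:
        n_o = spec.n_occasions
        occasions = np.arange(1, n_o + 1)
        p_eff = _rng(spec.seed, "person", level_idx).normal(
            0, _sd(components, "p"), n_p)
        i_eff = _rng(spec.seed, "trial", level_idx).normal(
            0, _sd(components, "i"), n_trials)
        o_eff = _rng(spec.seed, "occasion", level_idx).normal(
            0, _sd(components, "o"), n_o)
        pi = _rng(spec.seed, "pi", level_idx).normal(
            0, _sd(components, "pi"), (n_p, n_trials))
        po = _rng(spec.seed, "po", level_idx).normal(
            0, _sd(components, "po"), (n_p, n_o))
        oi = _rng(spec.seed, "oi", level_idx).normal(
            0, _sd(components, "oi"), (n_o, n_trials))
        resid = _rng(spec.seed, "residual", level_idx).normal(
            0, _sd(components, "pio,e"), (n_p, n_trials, n_o))
        latent = (lm + p_eff[:, None, None] + i_eff[None, :, None]
                  + o_eff[None, None, :] + pi[:, :, None]
                  + po[:, None, :] + oi.transpose(1, 0)[None, :, :]
                  + resid)
        idx = pd.MultiIndex.from_product(
            [persons, trials, occasions], names=[PERSON, TRIAL, OCCASION])
        df = pd.DataFrame({SCORE: latent.ravel()}, index=idx).reset_index()
    elif layout == LAYOUT_SPLITS:
        k = spec.trials_per_split
        n_s = n_trials // k
        n_use = n_s * k
        splits = np.repeat(np.arange(1, n_s + 1), k)
        p_eff = _rng(spec.seed, "person", level_idx).normal(
            0, _sd(components, "p"), n_p)
        s_eff = _rng(spec.seed, "split", level_idx).normal(
            0, _sd(components, "s"), n_s)
        is_eff = _rng(spec.seed, "is", level_idx).normal(
            0, _sd(components, "i:s"), n_use)
        ps = _rng(spec.seed, "ps", level_idx).normal(
            0, _sd(components, "ps"), (n_p, n_s))
        resid = _rng(spec.seed, "residual", level_idx).normal(
            0, _sd(components, "p(i:s),e"), (n_p, n_use))
        latent = (lm + p_eff[:, None] + s_eff[splits - 1][None, :]
                  + is_eff[None, :] + ps[:, splits - 1] + resid)
        df = pd.DataFrame({
            PERSON: np.repeat(persons, n_use),
            TRIAL: np.tile(np.arange(1, n_use + 1), n_p),
            SPLIT: np.tile(splits, n_p),
            SCORE: latent.ravel(),
        })
    else:  # pragma: no cover
        raise ValueError(f"simulation not implemented for {layout!r}")

    df[SCORE] = _transform(df[SCORE].to_numpy(), spec.family)
    if spec.zero_inflation > 0:
        zero = _rng(spec.seed, "zero", level_idx).random(len(df))
        df.loc[zero < spec.zero_inflation, SCORE] = 0.0
    if retention < 1.0:
        keep = _rng(spec.seed, "retention", level_idx).random(
            len(df)) < retention
        # guarantee two trials per person so no cell degenerates; the
        # top-up restores the person's first trials, a choice made
        # before any score is looked at (missingness stays ignorable)
        rank = df.groupby(PERSON, observed=True)[TRIAL].rank(method="first")
        kept_count = pd.Series(keep, index=df.index).groupby(
            df[PERSON], observed=True).transform("sum")
        keep |= (kept_count < 2).to_numpy() & (rank <= 2).to_numpy()
        df = df[keep]
    return df


def simulate(spec: SimulationSpec) -> tuple[ObservationTable, SimulationTruth]:
    """Draw one dataset (and its truth record) from the decomposition."""
    truth = SimulationTruth(
        components=dict(spec.components), mu=spec.mu, family=spec.family,
        layout=spec.layout, seed=spec.seed,
        covariances=dict(spec.covariances) if spec.covariances else None,
    )
    if spec.covariances is not None:
        df = _simulate_pair(spec)
    elif spec.fixed_facet:
        frames = []
        for li, (level, over) in enumerate(sorted(
                (spec.fixed_levels or {}).items())):
            comps = {**spec.components, **over.get("components", {})}
            frame = _simulate_level(
                spec, comps, over.get("mu", spec.mu),
                over.get("retention", spec.retention), li,
                over.get("n_trials", spec.n_trials),
            )
            frame[spec.fixed_facet] = level
            frames.append(frame)
            truth.by_fixed_level[level] = {
                "components": comps,
                "mu": over.get("mu", spec.mu),
                "retention": over.get("retention", spec.retention),
            }
        df = pd.concat(frames, ignore_index=True)
    else:
        df = _simulate_level(spec, spec.components, spec.mu,
                             spec.retention, 0, spec.n_trials)
    df[PERSON] = df[PERSON].map(lambda i: f"P{i + 1:04d}")
    truth.realized_trials_per_person = (
        df.groupby(PERSON, observed=True)[SCORE].size().to_dict()
    )
    return ObservationTable(df), truth


def _simulate_pair(spec: SimulationSpec) -> pd.DataFrame:
    """Two measures X/Y with person-level (and error-level) covariance."""
    if spec.layout != LAYOUT_ONE_FACET:
        raise ValueError(
            "measure-pair simulation is implemented for the one-facet "
            "design"
        )
    comps_x = spec.components
    comps_y = spec.components_y or spec.components
    cov = spec.covariances or {}
    n_p, n_i = spec.n_persons, spec.n_trials
    lm = _latent_mu(spec.mu, spec.family)

    def bivariate(rng, vx, vy, c, size):
        cm = np.array([[vx, c], [c, vy]])
        z = rng.standard_normal(size=(*np.atleast_1d(size), 2))
        chol = np.linalg.cholesky(cm + 1e-12 * np.eye(2))
        return z @ chol.T

    up = bivariate(_rng(spec.seed, "person"), comps_x.get("p", 0.0),
                   comps_y.get("p", 0.0), cov.get("p", 0.0), n_p)
    vi_x = _rng(spec.seed, "trial", 0).normal(0, _sd(comps_x, "i"), n_i)
    vi_y = _rng(spec.seed, "trial", 1).normal(0, _sd(comps_y, "i"), n_i)
    if spec.concurrent:
        e = bivariate(_rng(spec.seed, "residual"),
                      comps_x.get("pi,e", 0.0), comps_y.get("pi,e", 0.0),
                      cov.get("pi,e", 0.0), (n_p, n_i))
        ex, ey = e[..., 0], e[..., 1]
    else:
        ex = _rng(spec.seed, "residual", 0).normal(
            0, _sd(comps_x, "pi,e"), (n_p, n_i))
        ey = _rng(spec.seed, "residual", 1).normal(
            0, _sd(comps_y, "pi,e"), (n_p, n_i))
    lat_x = lm + up[:, 0][:, None] + vi_x[None, :] + ex
    lat_y = lm + up[:, 1][:, None] + vi_y[None, :] + ey
    persons = np.arange(n_p)
    trials = np.arange(1, n_i + 1)
    frames = []
    for label, lat in (("X", lat_x), ("Y", lat_y)):
        frames.append(pd.DataFrame({
            PERSON: np.repeat(persons, n_i),
            TRIAL: np.tile(trials, n_p),
            MEASURE: label,
            SCORE: _transform(lat.ravel(), spec.family),
        }))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# Worked example: three error-monitoring tasks
# ----------------------------------------------------------------------
#: per-task commission-error rates: only error trials yield an
#: error-related score, so a harder task retains more usable trials
WORKED_ERROR_RATES = {"flanker": 0.21, "stroop": 0.17, "gonogo": 0.12}
WORKED_COMPONENTS = {"p": 1.0, "i": 0.5, "pi,e": 10.0}
WORKED_MU = -8.0          # uV; error-related negativity is a negative wave
WORKED_N_TRIALS = 420


def make_worked_example(
    seed: int, n_persons: int = 100
) -> tuple[ObservationTable, SimulationTruth]:
    """Three tasks, identical per-trial components, unequal usable trials.

    Emulates an error-monitoring study in which the same component is
    scored from flanker, Stroop, and go/no-go tasks of 420 trials each.
    All three tasks share the same generating person, trial, and
    residual variances — the per-trial signal quality is identical — but
    commission-error rates differ (21%, 17%, 12%), so the number of
    usable (error) trials differs.  Per-trial ICCs should therefore
    match across tasks while dependability at the observed trial counts
    is ordered by retained-trial count; forcing a common trial count in
    the D study makes the differences vanish.
    """
    spec = SimulationSpec(
        n_persons=n_persons,
        n_trials=WORKED_N_TRIALS,
        components=dict(WORKED_COMPONENTS),
        mu=WORKED_MU,
        fixed_facet="task",
        fixed_levels={
            task: {"retention": rate}
            for task, rate in WORKED_ERROR_RATES.items()
        },
        seed=seed,
    )
    return simulate(spec)
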