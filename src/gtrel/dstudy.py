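"""D study: closed-form reliability coefficients and projections.

Given a set of variance components, a D study evaluates reliability for
specified replicate counts (n' trials, occasions, splits).  Relative
error variance contains only person-interaction terms and drives the
generalizability coefficient Erho2; absolute error variance adds the
facet mean-level terms and drives the dependability coefficient phi.
When the component set carries posterior draws, every coefficient is
evaluated per draw and summarized by its median and a 95% equal-tailed
credible interval (the value at the median components is not in general
the median of the per-draw values).

Coefficient kinds
-----------------
``G``/``D``
    Generalizability / dependability at the scenario's replicate
    counts.  For the two-facet design these coincide with ``CES_G`` /
    ``CES_D`` (trial equivalence and stability combined).
``ICC_rel``/``ICC_abs``
    Per-replicate intraclass correlations (n' = 1 structure).
``CE_G``/``CE_D``
    Coefficients of equivalence: person-by-occasion variance counts as
    universe score (internal-reliability analog).
``CS_G``/``CS_D``
    Coefficients of stability: person-by-trial variance counts as
    universe score (test-retest analog).
``CUT``
    Cut-score dependability: adds the squared deviation of the cut
    score from the grand mean to the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    LAYOUT_ONE_FACET,
    LAYOUT_SPLITS,
    LAYOUT_SPLITS_OCCASIONS,
    LAYOUT_TWO_FACET,
    DesignSpec,
)
from .exceptions import (
    DesignError,
    IncompleteComponentsError,
    UndefinedCoefficientError,
)
from .gstudy import VarianceComponentSet

__all__ = [
    "DStudyScenario",
    "ReliabilityEstimate",
    "ProjectionResult",
    "COEFFICIENTS",
    "error_variances",
    "coefficient",
    "cut_score_coefficient",
    "project",
    "contrast",
]

COEFFICIENTS = (
    "G", "D", "ICC_rel", "ICC_abs",
    "CE_G", "CE_D", "CS_G", "CS_D", "CES_G", "CES_D", "CUT",
)


@dataclass
class DStudyScenario:
    """Replicate counts and coefficient choice for one D-study row.

    ``n_trials`` is the number of trials per replicate (n'i); for split
    designs ``n_splits`` and ``n_trials_per_split`` play that role and
    ``n_trials`` is ignored by the formulas.  ``math.inf`` is accepted
    for asymptote evaluation.
    """

    n_trials: float = 1
    n_occasions: float | None = None
    n_splits: float | None = None
    n_trials_per_split: float | None = None
    cut_score: float | None = None
    coefficient: str = "G"

    def __post_init__(self) -> None:
        if self.coefficient not in COEFFICIENTS:
            raise ValueError(
                f"unknown coefficient {self.coefficient!r}; "
                f"choose one of {COEFFICIENTS}"
            )
        for name in ("n_trials", "n_occasions", "n_splits",
                     "n_trials_per_split"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")

    def replace(self, **kw) -> "DStudyScenario":
        d = self.__dict__ | kw
        return DStudyScenario(**d)


@dataclass
class ReliabilityEstimate:
    """A coefficient value with the error variances behind it."""

    value: float
    relative_error_variance: float
    absolute_error_variance: float
    sem_rel: float
    sem_abs: float
    kind: str
    scenario: DStudyScenario
    scale: str = "identity"
    interval: tuple[float, float] | None = None
    draws: np.ndarray | None = None
    level: object = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"coefficient value {self.value} outside [0,1]")
        if self.interval is not None:
            lo, hi = self.interval
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"malformed credible interval {self.interval}")

    def to_dict(self) -> dict:
        out = {
            "coefficient": self.kind,
            "value": float(self.value),
            "relative_error_variance": float(self.relative_error_variance),
            "absolute_error_variance": float(self.absolute_error_variance),
            "sem_rel": float(self.sem_rel),
            "sem_abs": float(self.sem_abs),
            "scale": self.scale,
            "scenario": {
                k: v for k, v in self.scenario.__dict__.items()
                if v is not None
            },
        }
        if self.interval is not None:
            out["credible_interval_95"] = list(self.interval)
        return out


@dataclass
class ProjectionResult:
    """Coefficient values over a grid of replicate counts."""

    table: pd.DataFrame
    target: float
    minimal_n: int | None
    reachable: bool
    asymptote: float
    varied: str = "n_trials"
    kind: str = "G"


def _get(comps: Mapping[str, object], label: str):
    try:
        return comps[label]
    except KeyError:
        raise IncompleteComponentsError(
            f"variance component {label!r} is missing from the fit; "
            "the design requires it"
        ) from None


def _counts(scenario: DStudyScenario, layout: str) -> dict[str, float]:
    need = {
        LAYOUT_ONE_FACET: ("n_trials",),
        LAYOUT_TWO_FACET: ("n_trials", "n_occasions"),
        LAYOUT_SPLITS: ("n_splits", "n_trials_per_split"),
        LAYOUT_SPLITS_OCCASIONS: ("n_splits", "n_trials_per_split",
                                  "n_occasions"),
    }[layout]
    out = {}
    for name in need:
        v = getattr(scenario, name)
        if v is None:
            raise DesignError(
                f"scenario lacks {name!r}, required for layout {layout!r}"
            )
        out[name] = float(v)
    return out


def _error_terms(comps: Mapping, scenario: DStudyScenario, layout: str):
    """Relative and absolute error variance per the design's table row."""
    n = _counts(scenario, layout)
    if layout == LAYOUT_ONE_FACET:
        ni = n["n_trials"]
        rel = _get(comps, "pi,e") / ni
        abso = rel + _get(comps, "i") / ni
    elif layout == LAYOUT_TWO_FACET:
        ni, no = n["n_trials"], n["n_occasions"]
        rel = (_get(comps, "pi") / ni + _get(comps, "po") / no
               + _get(comps, "pio,e") / (ni * no))
        abso = (rel + _get(comps, "o") / no + _get(comps, "i") / ni
                + _get(comps, "oi") / (ni * no))
    elif layout == LAYOUT_SPLITS:
        ns, k = n["n_splits"], n["n_trials_per_split"]
        rel = _get(comps, "ps") / ns + _get(comps, "p(i:s),e") / (k * ns)
        abso = (rel + _get(comps, "s") / ns
                + _get(comps, "i:s") / (k * ns))
    elif layout == LAYOUT_SPLITS_OCCASIONS:
        # experimental composition of the occasion and split designs
        ns, k, no = n["n_splits"], n["n_trials_per_split"], n["n_occasions"]
        rel = (_get(comps, "ps") / ns + _get(comps, "po") / no
               + _get(comps, "pso") / (ns * no)
               + _get(comps, "p(i:s)") / (k * ns)
               + _get(comps, "p(i:s)o,e") / (k * ns * no))
        abso = (rel + _get(comps, "s") / ns + _get(comps, "o") / no
                + _get(comps, "so") / (ns * no)
                + _get(comps, "i:s") / (k * ns)
                + _get(comps, "o(i:s)") / (k * ns * no))
    else:  # pragma: no cover
        raise DesignError(f"unknown layout {layout!r}")
    return rel, abso


def _numerator_denominator(comps: Mapping, scenario: DStudyScenario,
                           layout: str, kind: str, grand_mean=None):
    rel, abso = _error_terms(comps, scenario, layout)
    p = _get(comps, "p")
    if kind in ("G", "CES_G"):
        num, den = p, p + rel
    elif kind in ("D", "CES_D"):
        num, den = p, p + abso
    elif kind == "ICC_rel":
        one = scenario.replace(
            n_trials=1,
            n_occasions=1 if scenario.n_occasions is not None else None,
            n_splits=1 if scenario.n_splits is not None else None,
            n_trials_per_split=(1 if scenario.n_trials_per_split is not None
                                else None),
        )
        rel1, _ = _error_terms(comps, one, layout)
        num, den = p, p + rel1
    elif kind == "ICC_abs":
        one = scenario.replace(
            n_trials=1,
            n_occasions=1 if scenario.n_occasions is not None else None,
            n_splits=1 if scenario.n_splits is not None else None,
            n_trials_per_split=(1 if scenario.n_trials_per_split is not None
                                else None),
        )
        _, abs1 = _error_terms(comps, one, layout)
        num, den = p, p + abs1
    elif kind in ("CE_G", "CE_D", "CS_G", "CS_D"):
        if layout != LAYOUT_TWO_FACET:
            raise DesignError(
                f"{kind} requires the two-facet (trials x occasions) design"
            )
        n = _counts(scenario, layout)
        ni, no = n["n_trials"], n["n_occasions"]
        if kind.startswith("CE"):
            num = p + _get(comps, "po") / no
        else:
            num = p + _get(comps, "pi") / ni
        den = p + rel
        if kind.endswith("_D"):
            if kind.startswith("CE"):
                den = den + (_get(comps, "i") / ni
                             + _get(comps, "oi") / (ni * no))
            else:
                den = den + (_get(comps, "o") / no
                             + _get(comps, "oi") / (ni * no))
    elif kind == "CUT":
        if scenario.cut_score is None or grand_mean is None:
            raise DesignError(
                "the cut-score coefficient requires a cut score and a "
                "grand mean"
            )
        dev2 = (grand_mean - scenario.cut_score) ** 2
        num = p + dev2
        den = p + dev2 + abso
    else:  # pragma: no cover
        raise ValueError(kind)
    return num, den, rel, abso


def error_variances(vc: VarianceComponentSet, scenario: DStudyScenario,
                    design: DesignSpec | None = None) -> tuple[float, float]:
    """Relative and absolute error variance at the scenario's counts."""
    layout = design.layout if design is not None else vc.layout
    rel, abso = _error_terms(vc.components, scenario, layout)
    return float(rel), float(abso)


def coefficient(vc: VarianceComponentSet, scenario: DStudyScenario,
                design: DesignSpec | None = None) -> ReliabilityEstimate:
    """Evaluate one reliability coefficient for a D-study scenario.

    With posterior draws the coefficient is computed per draw and
    summarized by median and 95% credible interval; the point error
    variances are reported at the component point estimates.

    Raises :class:`UndefinedCoefficientError` when all components are
    zero (0/0 is a diagnostic state, not a value).
    """
    layout = design.layout if design is not None else vc.layout
    kind = scenario.coefficient

    num, den, rel, abso = _numerator_denominator(
        vc.components, scenario, layout, kind, grand_mean=vc.grand_mean
    )
    if den == 0:
        raise UndefinedCoefficientError(
            "all variance components are zero; the coefficient is 0/0 "
            "(undefined), not 0"
        )
    value = float(num / den)
    interval = None
    draw_values = None
    if vc.draws is not None:
        gm = (vc.grand_mean_draws if vc.grand_mean_draws is not None
              else vc.grand_mean)
        dnum, dden, _, _ = _numerator_denominator(
            vc.draws, scenario, layout, kind, grand_mean=gm
        )
        draw_values = np.asarray(dnum / dden, dtype=float)
        value = float(np.median(draw_values))
        interval = (
            float(np.quantile(draw_values, 0.025)),
            float(np.quantile(draw_values, 0.975)),
        )
    return ReliabilityEstimate(
        value=value,
        relative_error_variance=float(rel),
        absolute_error_variance=float(abso),
        sem_rel=float(np.sqrt(rel)),
        sem_abs=float(np.sqrt(abso)),
        kind=kind,
        scenario=scenario,
        scale=vc.scale,
        interval=interval,
        draws=draw_values,
    )


def cut_score_coefficient(vc: VarianceComponentSet, scenario: DStudyScenario,
                          design: DesignSpec | None = None
                          ) -> ReliabilityEstimate:
    """Dependability of classifications relative to a threshold C.

    Adds (mu - C)^2 to the signal: deviations of the cut score from the
    grand mean make threshold decisions easier to replicate.  When C
    equals the grand mean this reduces exactly to the global
    dependability coefficient.  The estimated grand mean is used with no
    small-sample bias correction.
    """
    return coefficient(vc, scenario.replace(coefficient="CUT"), design)


def project(
    vc: VarianceComponentSet,
    design: DesignSpec | None,
    kind: str,
    grid,
    target: float,
    *,
    vary: str = "n_trials",
    scenario: DStudyScenario | None = None,
) -> ProjectionResult:
    """Coefficient over a grid of replicate counts, with minimal n'.

    ``minimal_n`` is the smallest grid value whose coefficient reaches
    the target (ties break toward smaller n').  When even the asymptote
    (all varied counts at infinity) stays below the target, the result
    is flagged unreachable and carries that asymptote.
    """
    grid = sorted(int(g) for g in grid)
    if not grid:
        raise ValueError("projection grid is empty")
    if not (0.0 < target < 1.0):
        raise ValueError(f"target reliability must be in (0,1), got {target}")
    base = scenario or DStudyScenario()
    base = base.replace(coefficient=kind)
    rows = []
    minimal = None
    for n in grid:
        est = coefficient(vc, base.replace(**{vary: n}), design)
        rows.append({vary: n, "value": est.value,
                     "ci_low": est.interval[0] if est.interval else None,
                     "ci_high": est.interval[1] if est.interval else None})
        if minimal is None and est.value >= target:
            minimal = n
    asymptote = coefficient(vc, base.replace(**{vary: math.inf}),
                            design).value
    return ProjectionResult(
        table=pd.DataFrame(rows),
        target=target,
        minimal_n=minimal,
        reachable=minimal is not None or asymptote >= target,
        asymptote=float(asymptote),
        varied=vary,
        kind=kind,
    )


def contrast(estimates: Mapping[object, ReliabilityEstimate]
             ) -> pd.DataFrame:
    """Pairwise posterior contrasts between per-level coefficients.

    For each pair of levels the difference of per-draw coefficient
    values is summarized by its median, 95% credible interval, and the
    posterior probability that the difference is positive.  Requires
    estimates carrying draws (point-only estimates cannot quantify the
    contrast's uncertainty).
    """
    levels = list(estimates)
    if len(levels) < 2:
        raise ValueError("contrast requires at least two levels")
    for lev, est in estimates.items():
        if est.draws is None:
            raise ValueError(
                f"estimate for level {lev!r} has no posterior draws; "
                "contrasts require draw-level estimates"
            )
    rows = []
    for a_i in range(len(levels)):
        for b_i in range(a_i + 1, len(levels)):
            a, b = levels[a_i], levels[b_i]
            da, db = estimates[a].draws, estimates[b].draws
            if len(da) != len(db):
                raise ValueError("draw counts differ between levels")
            diff = da - db
            rows.append({
                "level_a": a,
                "level_b": b,
                "median_diff": float(np.median(diff)),
                "ci_low": float(np.quantile(diff, 0.025)),
                "ci_high": float(np.quantile(diff, 0.975)),
                # ties split evenly so identical draws give p = 0.5
                "p_gt_0": float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0)),
            })
    return pd.DataFrame(rows)
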