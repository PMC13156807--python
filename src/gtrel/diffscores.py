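"""Reliability of difference scores (condition contrasts, lateralized
indices, peak-to-peak amplitudes).

A difference score D = X - Y is only as reliable as the between-person
variance in true change: the universe-score variance of the difference
is sigma2_X(p) + sigma2_Y(p) - 2*sigmaXY(p), so highly correlated
constituents leave little signal.  Error covariances exist only when X
and Y are measured concurrently (same trials — e.g., ipsilateral vs.
contralateral); for non-concurrent contrasts (error minus correct
trials) they are structurally zero.  Covariance error terms are divided
by the harmonic mean of the per-measure replicate counts.

A numerator at or below zero is reported as an *undefined* result, not
an exception and not a value of zero: absence of between-person
variance in change is a diagnostic about the measure (or a genuinely
uniform change), not an estimation failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .core import LAYOUT_ONE_FACET, LAYOUT_TWO_FACET
from .exceptions import DesignError, IncompleteComponentsError
from .gstudy import CovarianceComponentSet, VarianceComponentSet

__all__ = [
    "DifferencePair",
    "DifferenceReliability",
    "difference_reliability",
    "ceiling_analysis",
]


def harmonic_mean(a: float, b: float) -> float:
    """n-dot-dot = 2 / (1/nX + 1/nY), the covariance replicate count."""
    return 2.0 / (1.0 / a + 1.0 / b)


@dataclass
class DifferencePair:
    """Everything needed to evaluate difference-score reliability.

    Components for each constituent measure, their covariance
    components, and per-measure replicate counts.  Harmonic-mean counts
    for the covariance terms are derived, never supplied.
    """

    components_x: VarianceComponentSet
    components_y: VarianceComponentSet
    covariances: CovarianceComponentSet
    n_trials_x: float = 1
    n_trials_y: float = 1
    n_occasions_x: float | None = None
    n_occasions_y: float | None = None

    @property
    def concurrent(self) -> bool:
        return self.covariances.concurrent

    @property
    def n_trials_harmonic(self) -> float:
        return harmonic_mean(self.n_trials_x, self.n_trials_y)

    @property
    def n_occasions_harmonic(self) -> float:
        if self.n_occasions_x is None or self.n_occasions_y is None:
            raise DesignError("occasion counts not set for this pair")
        return harmonic_mean(self.n_occasions_x, self.n_occasions_y)


@dataclass
class DifferenceReliability:
    """Result state: a coefficient value or an explicit undefined flag."""

    value: float | None
    undefined: bool
    numerator: float
    denominator: float
    kind: str
    message: str = ""
    terms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "coefficient": self.kind,
            "value": None if self.undefined else float(self.value),
            "undefined": self.undefined,
            "numerator": float(self.numerator),
            "denominator": float(self.denominator),
            "message": self.message,
        }


def _comp(vc: VarianceComponentSet, label: str) -> float:
    try:
        return float(vc.components[label])
    except KeyError:
        raise IncompleteComponentsError(
            f"component {label!r} missing from a constituent fit"
        ) from None


def _difference_terms(pair: DifferencePair, layout: str,
                      kind: str) -> tuple[float, float, dict]:
    """Reconstructed difference-score formula terms.

    The published formula bodies for difference scores are reconstructed
    from the table notes and the surrounding rules: the person-level
    covariance always enters the universe-score variance of the
    difference; error covariances enter only for concurrent measures;
    covariance terms are divided by harmonic-mean counts.  The CE
    variant adds the person-by-occasion terms
    ``sX2(po)/noX + sY2(po)/noY - 2sXY(po)/n..o`` to the numerator and
    the CS variant adds the person-by-trial terms
    ``sX2(pi)/niX + sY2(pi)/niY - 2sXY(pi)/n..i``.
    """
    X, Y, cov = pair.components_x, pair.components_y, pair.covariances

    def cov_of(label: str) -> float:
        if not cov.concurrent and label != "p":
            return 0.0
        return float(cov.covariances.get(label, 0.0))

    base = _comp(X, "p") + _comp(Y, "p") - 2.0 * cov_of("p")
    terms = {"universe_difference_variance": base}

    if layout == LAYOUT_ONE_FACET:
        if kind != "CE":
            raise DesignError(
                "the one-facet difference design yields a coefficient of "
                "equivalence (CE) only"
            )
        err = (
            _comp(X, "pi,e") / pair.n_trials_x
            + _comp(Y, "pi,e") / pair.n_trials_y
            - 2.0 * cov_of("pi,e") / pair.n_trials_harmonic
        )
        num = base
        den = base + err
        terms["error_trials"] = err
        return num, den, terms

    if layout != LAYOUT_TWO_FACET:
        raise DesignError(
            f"difference scores support one- and two-facet designs, "
            f"not {layout!r}"
        )
    if kind not in ("CE", "CS", "CES"):
        raise DesignError(f"unknown difference coefficient {kind!r}")
    if pair.n_occasions_x is None or pair.n_occasions_y is None:
        raise DesignError("two-facet difference pair needs occasion counts")
    ni_x, ni_y = pair.n_trials_x, pair.n_trials_y
    no_x, no_y = pair.n_occasions_x, pair.n_occasions_y
    nh_i, nh_o = pair.n_trials_harmonic, pair.n_occasions_harmonic

    t_pi = (_comp(X, "pi") / ni_x + _comp(Y, "pi") / ni_y
            - 2.0 * cov_of("pi") / nh_i)
    t_po = (_comp(X, "po") / no_x + _comp(Y, "po") / no_y
            - 2.0 * cov_of("po") / nh_o)
    t_pio = (_comp(X, "pio,e") / (ni_x * no_x)
             + _comp(Y, "pio,e") / (ni_y * no_y)
             - 2.0 * cov_of("pio,e") / (nh_i * nh_o))
    den = base + t_pi + t_po + t_pio
    num = base
    if kind == "CE":
        num = base + t_po
    elif kind == "CS":
        num = base + t_pi
    terms.update({"error_trials": t_pi, "error_occasions": t_po,
                  "error_residual": t_pio})
    return num, den, terms


def difference_reliability(pair: DifferencePair, layout: str = LAYOUT_ONE_FACET,
                           kind: str = "CE") -> DifferenceReliability:
    """Reliability of the difference between two measures.

    Parameters
    ----------
    pair : DifferencePair
    layout : {"one_facet", "two_facet"}
    kind : {"CE", "CS", "CES"}
        One-facet difference designs yield CE only; two-facet designs
        yield the stated relative (G-type) variants.

    Returns a :class:`DifferenceReliability`; when the universe-score
    variance of the difference is not positive the result is flagged
    undefined with a diagnostic message (between-person variance in
    change is absent — either nothing changes or everyone changes by
    the same amount).
    """
    num, den, terms = _difference_terms(pair, layout, kind)
    if num <= 0:
        return DifferenceReliability(
            value=None, undefined=True, numerator=float(num),
            denominator=float(den), kind=kind,
            message=(
                "between-person variance in the difference is absent "
                "(numerator <= 0): constituents are too highly "
                "correlated, or true change is uniform across persons; "
                "the reliability of this difference score is undefined"
            ),
            terms=terms,
        )
    value = float(num / den)
    if not (0.0 <= value <= 1.0 + 1e-12):
        raise ValueError(
            f"difference reliability evaluated to {value}, outside [0,1]; "
            "check covariance inputs (clipping is never silent)"
        )
    return DifferenceReliability(
        value=min(value, 1.0), undefined=False, numerator=float(num),
        denominator=float(den), kind=kind, terms=terms,
    )


def ceiling_analysis(pair: DifferencePair, n_sweep: int = 101) -> dict:
    """How the person-level correlation caps difference reliability.

    Reports each constituent's reliability at its own replicate count,
    the estimated person-level correlation, and the implied
    difference-score reliability across a sweep of that correlation
    from 0 to 1 (variances and error terms held fixed).  Correlations
    that leave no difference variance appear as NaN in the sweep.
    """
    X, Y = pair.components_x, pair.components_y
    vx, vy = _comp(X, "p"), _comp(Y, "p")
    ex = _comp(X, "pi,e") / pair.n_trials_x
    ey = _comp(Y, "pi,e") / pair.n_trials_y
    rho_x = vx / (vx + ex) if vx + ex > 0 else float("nan")
    rho_y = vy / (vy + ey) if vy + ey > 0 else float("nan")
    bound = float(np.sqrt(vx * vy))
    r_hat = (pair.covariances.covariances.get("p", 0.0) / bound
             if bound > 0 else float("nan"))

    rows = []
    for r in np.linspace(0.0, 1.0, n_sweep):
        cov_r = CovarianceComponentSet(
            covariances={**pair.covariances.covariances, "p": r * bound},
            concurrent=pair.concurrent,
            estimator=pair.covariances.estimator,
        )
        swept = DifferencePair(
            components_x=X, components_y=Y, covariances=cov_r,
            n_trials_x=pair.n_trials_x, n_trials_y=pair.n_trials_y,
            n_occasions_x=pair.n_occasions_x,
            n_occasions_y=pair.n_occasions_y,
        )
        res = difference_reliability(swept)
        rows.append({"person_correlation": float(r),
                     "difference_reliability":
                         np.nan if res.undefined else res.value})
    return {
        "reliability_x": float(rho_x),
        "reliability_y": float(rho_y),
        "person_correlation": float(r_hat),
        "sweep": pd.DataFrame(rows),
    }
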