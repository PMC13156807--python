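"""Data model, long-format I/O, and design validation.

The unit of analysis is an already-scored observation: one row per
person x trial (or split) x occasion x fixed-facet condition, with a
numeric score in the units of the modality (e.g., single-trial ERN
amplitude in uV, per-split RMSSD in ms).  Wide layouts must be melted to
long format before ingest; keeping the table long makes per-person
unbalance (e.g., from artifact rejection) explicit rather than hidden in
NaN cells.

Reserved column names
---------------------
``person``   categorical id of the object of measurement
``trial``    positive integer replicate index within a cell
``split``    positive integer block index (trials nested in splits)
``occasion`` categorical session/visit label
``measure``  optional label distinguishing two measures (X/Y) for
             difference-score data
``score``    the numeric observation

Any other column is treated as a fixed-facet condition label (e.g.,
``task``, ``event_type``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DesignError,
    EmptyDataError,
    IdentifiabilityError,
    SchemaError,
)

logger = logging.getLogger("gtrel")

PERSON = "person"
TRIAL = "trial"
SPLIT = "split"
OCCASION = "occasion"
MEASURE = "measure"
SCORE = "score"
RESERVED = (PERSON, TRIAL, SPLIT, OCCASION, MEASURE, SCORE)

#: design layouts supported by the estimators and the coefficient engine
LAYOUT_ONE_FACET = "one_facet"            # Persons x Trials
LAYOUT_TWO_FACET = "two_facet"            # Persons x Trials x Occasions
LAYOUT_SPLITS = "splits"                  # Persons x (Trials:Splits)
LAYOUT_SPLITS_OCCASIONS = "splits_occasions"  # experimental composition

#: effect labels per layout; the confounded residual is always last and
#: carries the ",e" suffix
LAYOUT_EFFECTS: dict[str, tuple[str, ...]] = {
    LAYOUT_ONE_FACET: ("p", "i", "pi,e"),
    LAYOUT_TWO_FACET: ("p", "i", "o", "pi", "po", "oi", "pio,e"),
    LAYOUT_SPLITS: ("p", "s", "i:s", "ps", "p(i:s),e"),
    LAYOUT_SPLITS_OCCASIONS: (
        "p", "s", "o", "i:s", "ps", "po", "so", "pso", "o(i:s)", "p(i:s)",
        "p(i:s)o,e",
    ),
}


@dataclass(frozen=True)
class Facet:
    """One source of measurement variation (a factor in the ANOVA sense).

    Parameters
    ----------
    name : str
        Column name in the observation table.  Random facets use the
        reserved names ``trial``, ``occasion``, ``split``; fixed facets
        may use any other name.
    status : {"random", "fixed"}
        Random facets are interchangeable draws from a larger universe;
        fixed facets exhaust the conditions of interest.
    nested_in : str, optional
        Name of the facet this one is nested in (e.g., trials nested in
        splits).  ``None`` means fully crossed.
    """

    name: str
    status: str = "random"
    nested_in: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("random", "fixed"):
            raise DesignError(
                f"facet {self.name!r}: status must be 'random' or 'fixed', "
                f"got {self.status!r}"
            )


@dataclass
class DesignSpec:
    """Declares the facets of a measurement design.

    The object of measurement (persons by default) is the entity whose
    differences the measure should capture; every other facet is a
    potential source of error variance.  A facet observed at a single
    condition is unidentifiable and must be listed in
    ``declared_hidden`` instead of being modeled; the resulting
    reliability is then conditional on that condition.
    """

    facets: list[Facet]
    object_of_measurement: str = PERSON
    family: str = "gaussian"
    declared_hidden: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "lognormal", "gamma_chisq"):
            raise DesignError(f"unknown family {self.family!r}")
        names = [f.name for f in self.facets]
        if len(set(names)) != len(names):
            raise DesignError("duplicate facet names in design")
        if self.object_of_measurement in names:
            raise DesignError(
                "the object of measurement is not listed among facets"
            )
        hidden_overlap = set(self.declared_hidden) & set(names)
        if hidden_overlap:
            raise DesignError(
                f"facets {sorted(hidden_overlap)} are both modeled and "
                "declared hidden; a hidden facet must not be modeled"
            )
        if not any(f.status == "random" for f in self.facets):
            raise DesignError(
                "at least one random facet besides the object of "
                "measurement is required"
            )
        self._check_nesting_acyclic()
        self.layout  # noqa: B018 -- raises early on unsupported layouts

    def _check_nesting_acyclic(self) -> None:
        parents = {f.name: f.nested_in for f in self.facets}
        for name in parents:
            seen = {name}
            cur = parents.get(name)
            while cur is not None:
                if cur not in parents:
                    raise DesignError(
                        f"facet {name!r} is nested in unknown facet {cur!r}"
                    )
                if cur in seen:
                    raise DesignError("nesting relations contain a cycle")
                seen.add(cur)
                cur = parents[cur]

    @property
    def random_facets(self) -> list[Facet]:
        return [f for f in self.facets if f.status == "random"]

    @property
    def fixed_facets(self) -> list[Facet]:
        return [f for f in self.facets if f.status == "fixed"]

    @property
    def layout(self) -> str:
        """Classify the random-facet structure into a supported layout."""
        names = {f.name for f in self.random_facets}
        nested = {f.name: f.nested_in for f in self.random_facets}
        if names == {TRIAL}:
            return LAYOUT_ONE_FACET
        if names == {TRIAL, OCCASION}:
            return LAYOUT_TWO_FACET
        if names == {TRIAL, SPLIT}:
            if nested.get(TRIAL) != SPLIT:
                raise DesignError(
                    "a split design requires trials nested in splits "
                    "(Facet('trial', nested_in='split'))"
                )
            return LAYOUT_SPLITS
        if names == {TRIAL, SPLIT, OCCASION}:
            if nested.get(TRIAL) != SPLIT:
                raise DesignError("trials must be nested in splits")
            return LAYOUT_SPLITS_OCCASIONS
        raise DesignError(
            f"unsupported random-facet combination {sorted(names)}; "
            "supported layouts: Persons x Trials, Persons x Trials x "
            "Occasions, Persons x (Trials:Splits), and Persons x "
            "(Trials:Splits) x Occasions"
        )

    @property
    def effects(self) -> tuple[str, ...]:
        return LAYOUT_EFFECTS[self.layout]

    @property
    def residual_effect(self) -> str:
        return self.effects[-1]

    # ------------------------------------------------------------------
    # YAML round trip
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "facets": [
                {"name": f.name, "status": f.status,
                 **({"nested_in": f.nested_in} if f.nested_in else {})}
                for f in self.facets
            ],
            "object_of_measurement": self.object_of_measurement,
            "family": self.family,
            "declared_hidden": list(self.declared_hidden),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        facets = [
            Facet(x["name"], x.get("status", "random"), x.get("nested_in"))
            for x in d["facets"]
        ]
        return cls(
            facets=facets,
            object_of_measurement=d.get("object_of_measurement", PERSON),
            family=d.get("family", "gaussian"),
            declared_hidden=list(d.get("declared_hidden", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class ObservationTable:
    """Validated long-format table of scored observations.

    Wraps a :class:`pandas.DataFrame` whose columns use the reserved
    names above.  Construction enforces the table invariants: non-missing
    person ids, finite scores, unique (person, facet-conditions, measure)
    keys, and — when a split column is present — each trial index nested
    in exactly one split.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if PERSON not in df.columns or SCORE not in df.columns:
            raise SchemaError("table must have 'person' and 'score' columns")
        if df[PERSON].isna().any():
            raise SchemaError("missing person id in table")
        scores = pd.to_numeric(df[SCORE], errors="coerce")
        if not np.isfinite(scores.to_numpy(dtype=float)).all():
            raise SchemaError("non-finite or non-numeric score in table")
        df[SCORE] = scores.astype(float)
        if len(df) == 0:
            raise EmptyDataError("table has zero usable rows")
        key_cols = [c for c in df.columns if c != SCORE]
        if df.duplicated(subset=key_cols).any():
            raise SchemaError(
                "duplicate (person, facet-condition, measure) combinations"
            )
        if SPLIT in df.columns and TRIAL in df.columns:
            per_trial = df.groupby(TRIAL, observed=True)[SPLIT].nunique()
            if (per_trial > 1).any():
                bad = per_trial[per_trial > 1].index.tolist()
                raise SchemaError(
                    f"trial indices {bad} map to more than one split"
                )
        self.data = df

    # -- introspection -------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fixed_facet_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED]

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def persons(self) -> np.ndarray:
        return self.data[PERSON].unique()

    def facet_conditions(self, facet: str) -> np.ndarray:
        if facet not in self.data.columns:
            raise SchemaError(f"facet column {facet!r} not in table")
        return self.data[facet].unique()

    def copy(self) -> "ObservationTable":
        return ObservationTable(self.data)

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table back out; ``read_long_table`` round-trips it."""
        self.data.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ObservationTable({self.n_obs} obs, "
            f"{len(self.persons)} persons, columns={self.columns})"
        )


def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> ObservationTable:
    """Read a long-format CSV/TSV of scored observations.

    Parameters
    ----------
    path : path
        UTF-8 text file with a header row; comma or tab delimited
        (sniffed), decimal point only.
    schema : mapping, optional
        Maps reserved role names (``person``, ``trial``, ``score``, ...)
        to the column names used in the file.  Roles absent from the
        mapping are taken verbatim when the column exists.  Unmapped
        extra columns are kept as fixed-facet conditions.

    Rows whose score is missing or non-numeric are dropped and the count
    is logged (they are never imputed at ingest; the Bayesian
    estimator's likelihood is the place for principled missing-data
    handling).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file {path} does not exist")
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    schema = dict(schema or {})
    rename = {}
    for role, col in schema.items():
        if role not in RESERVED:
            raise SchemaError(f"unknown role {role!r} in schema")
        if col not in df.columns:
            raise SchemaError(
                f"mapped column {col!r} for role {role!r} not in file"
            )
        rename[col] = role
    df = df.rename(columns=rename)
    for required in (PERSON, SCORE):
        if required not in df.columns:
            raise SchemaError(
                f"required column {required!r} missing after schema mapping"
            )
    scores = pd.to_numeric(df[SCORE], errors="coerce")
    keep = scores.notna() & np.isfinite(scores.fillna(np.nan))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_long_table: dropped %d rows with missing or "
                    "non-numeric scores", n_dropped)
    df = df.loc[keep].copy()
    df[SCORE] = scores.loc[keep].astype(float)
    if len(df) == 0:
        raise EmptyDataError(f"{path}: zero usable rows after ingest")
    return ObservationTable(df)


# ----------------------------------------------------------------------
# Design validation
# ----------------------------------------------------------------------
@dataclass
class ValidationReport:
    """Outcome of checking a table against a design.

    Attributes
    ----------
    hidden_facets : list of str
        Facets observed at a single condition; their variance is
        unidentifiable and reliability is conditional on that condition.
    balanced : dict
        Per-facet flag: equal replicate counts across persons/cells.
    balanced_overall : bool
    cell_counts : pandas.DataFrame
        Observation counts per person x facet-condition cell.
    persons_missing_conditions : list
        Persons with zero observations in some modeled condition (e.g.,
        all trials lost to artifact rejection); surfaced, not excluded.
    warnings : list of str
    """

    hidden_facets: list[str]
    balanced: dict[str, bool]
    balanced_overall: bool
    cell_counts: pd.DataFrame
    persons_missing_conditions: list
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "hidden_facets": self.hidden_facets,
            "balanced": self.balanced,
            "balanced_overall": self.balanced_overall,
            "cell_counts": self.cell_counts.to_dict(orient="records"),
            "persons_missing_conditions": [
                str(p) for p in self.persons_missing_conditions
            ],
            "warnings": self.warnings,
        }


def validate_design(table: ObservationTable,
                    design: DesignSpec) -> ValidationReport:
    """Check identifiability, balance, and cell coverage.

    Raises :class:`IdentifiabilityError` if a modeled facet has a single
    observed condition and is not declared hidden.  The call is pure:
    the table is not modified.
    """
    df = table.data
    for f in design.facets:
        if f.name not in df.columns:
            raise SchemaError(
                f"design facet {f.name!r} has no column in the table"
            )
        n_cond = df[f.name].nunique()
        if n_cond < 2:
            raise IdentifiabilityError(
                f"facet {f.name!r} has a single observed condition; its "
                "variance is unidentifiable. Either collect more "
                "conditions or declare it hidden (reliability is then "
                "conditional on the sampled condition)."
            )
    warnings: list[str] = []
    hidden: list[str] = []
    for name in design.declared_hidden:
        hidden.append(name)
        warnings.append(
            f"facet {name!r} is hidden (single sampled condition): its "
            "variance is unidentifiable and all reliability estimates "
            "are conditional on it"
        )
    # facets present as columns but neither modeled nor declared hidden
    modeled = {f.name for f in design.facets}
    for col in df.columns:
        if col in (PERSON, SCORE, MEASURE):
            continue
        if col not in modeled and col not in design.declared_hidden:
            if df[col].nunique() == 1:
                warnings.append(
                    f"column {col!r} has a single condition and is not "
                    "declared hidden; treating it as an undocumented "
                    "hidden facet"
                )

    balanced: dict[str, bool] = {}
    for f in design.facets:
        others = [g.name for g in design.facets if g.name != f.name]
        counts = df.groupby([PERSON] + others, observed=True)[f.name].nunique()
        balanced[f.name] = counts.nunique() == 1
    balanced_overall = all(balanced.values())

    cell_cols = [PERSON] + [f.name for f in design.facets
                            if f.name != TRIAL]
    if len(cell_cols) > 1:
        cell_counts = (
            df.groupby(cell_cols, observed=True)[SCORE]
            .size().rename("n_obs").reset_index()
        )
    else:
        cell_counts = (
            df.groupby(PERSON, observed=True)[SCORE]
            .size().rename("n_obs").reset_index()
        )

    missing_persons: list = []
    condition_cols = [c for c in cell_cols if c != PERSON]
    if condition_cols:
        full = pd.MultiIndex.from_product(
            [df[PERSON].unique()] + [df[c].unique() for c in condition_cols],
            names=[PERSON] + condition_cols,
        )
        observed = pd.MultiIndex.from_frame(df[cell_cols].drop_duplicates())
        absent = full.difference(observed)
        missing_persons = sorted({idx[0] for idx in absent})
        if missing_persons:
            warnings.append(
                f"persons {missing_persons} have no observations in at "
                "least one modeled condition; they are retained — decide "
                "explicitly whether to exclude them"
            )
    return ValidationReport(
        hidden_facets=hidden,
        balanced=balanced,
        balanced_overall=balanced_overall,
        cell_counts=cell_counts,
        persons_missing_conditions=missing_persons,
        warnings=warnings,
    )


def enforce_split_convention(table: ObservationTable,
                             trials_per_split: int) -> ObservationTable:
    """Assign consecutive trials to equal-size splits.

    The mapping from trial index to split is the same for every person:
    the sorted unique trial indices are blocked into groups of
    ``trials_per_split`` in recorded order.  Trial order is used purely
    as a grouping device (trials are exchangeable); the trailing partial
    block is dropped and logged.
    """
    if trials_per_split < 1:
        raise ValueError("trials_per_split must be a positive integer")
    df = table.data
    if TRIAL not in df.columns:
        raise SchemaError("table has no 'trial' column to split")
    per_person = df.groupby(PERSON, observed=True)[TRIAL].nunique()
    short = per_person[per_person < trials_per_split]
    if len(short):
        person = short.index[0]
        raise ValueError(
            f"trials_per_split={trials_per_split} exceeds the trial count "
            f"({short.iloc[0]}) of person {person!r}"
        )
    trials = np.sort(df[TRIAL].unique())
    n_keep = (len(trials) // trials_per_split) * trials_per_split
    kept, dropped = trials[:n_keep], trials[n_keep:]
    if len(dropped):
        logger.info(
            "enforce_split_convention: dropped trailing partial split "
            "(%d trials: %s)", len(dropped), dropped.tolist(),
        )
    split_of = {t: i // trials_per_split + 1 for i, t in enumerate(kept)}
    out = df[df[TRIAL].isin(kept)].copy()
    out[SPLIT] = out[TRIAL].map(split_of).astype(int)
    return ObservationTable(out)
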