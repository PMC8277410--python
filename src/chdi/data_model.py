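"""Indicator-table data model and delimited-text / configuration I/O.

A hospital scoring run starts from a rectangular table of hospitals x
indicators together with a configuration that declares, for every indicator,
its domain (research_and_development, academic_reputation, quality_and_safety),
its measurement scale (numeric, ordinal, nominal) and its direction (benefit:
larger is better; cost: larger is worse, e.g. the malpractice-compensation
ratio).  Everything downstream — diagnostics, dimension reduction, entropy
weighting, aggregation — consumes the validated :class:`IndicatorTable`
produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DOMAINS = (
    "research_and_development",
    "academic_reputation",
    "quality_and_safety",
)

SCALES = ("numeric", "ordinal", "nominal")
DIRECTIONS = ("benefit", "cost")


class ValidationError(ValueError):
    """Raised when a table or configuration violates the data contract."""


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for a single performance indicator.

    Parameters
    ----------
    name
        Column name, unique within a table.
    domain
        One of :data:`DOMAINS`.
    scale
        ``numeric`` for continuous/count indicators, ``ordinal`` /
        ``nominal`` for categorical ones.
    direction
        ``benefit`` if larger values indicate a stronger hospital,
        ``cost`` otherwise.
    levels
        Declared category levels for ordinal/nominal indicators, in order
        (order is meaningful for ordinal).  Values observed in the data must
        come from this set; they are mapped to integer codes ``0..L-1``.
    """

    name: str
    domain: str
    scale: str = "numeric"
    direction: str = "benefit"
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValidationError(
                f"indicator {self.name!r}: unknown domain {self.domain!r}; "
                f"expected one of {DOMAINS}"
            )
        if self.scale not in SCALES:
            raise ValidationError(
                f"indicator {self.name!r}: unknown scale {self.scale!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"indicator {self.name!r}: unknown direction {self.direction!r}"
            )
        if self.scale in ("ordinal", "nominal"):
            if not self.levels or len(self.levels) < 2:
                raise ValidationError(
                    f"indicator {self.name!r}: {self.scale} scale requires a "
                    "declared category set with >=2 levels"
                )
        if self.levels is not None and not isinstance(self.levels, tuple):
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_categorical(self) -> bool:
        return self.scale in ("ordinal", "nominal")


@dataclass
class ScoringConfig:
    """Parameters of the scoring chain.

    ``retention_rule`` selects how many principal components each domain
    keeps: ``"fixed"`` retains exactly ``n_components`` (default 2, the
    usual two-component structure of these domain models) while
    ``"cumulative_variance"`` retains the smallest leading set whose variance
    share reaches ``min_cumulative_variance``.  The same
    ``min_cumulative_variance`` doubles as the fit bar in the all-subset
    indicator search.  ``domain_weights`` are the expert weights of the three
    domains (normalised to sum to 1; equal by default because the original
    panel's weights were never published).
    """

    retention_rule: str = "fixed"
    n_components: int = 2
    min_cumulative_variance: float = 0.90
    domain_weights: dict = field(
        default_factory=lambda: {d: 1.0 / 3.0 for d in DOMAINS}
    )
    logit_variant: str = "scaled_logistic"
    subset_search: bool = True
    kmo_threshold: float = 0.7
    alpha_threshold: float = 0.7
    output_scale: float = 1.0
    seed: int = 0
    drop_incomplete_units: bool = False
    abort_on_diagnostic_failure: bool = False
    catpca_tol: float = 1e-7
    catpca_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.retention_rule not in ("fixed", "cumulative_variance"):
            raise ValidationError(
                f"unknown retention_rule {self.retention_rule!r}"
            )
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if not (0.0 < self.min_cumulative_variance < 1.0):
            raise ValidationError("min_cumulative_variance must lie in (0,1)")
        if not (0.0 < self.kmo_threshold < 1.0):
            raise ValidationError("kmo_threshold must lie in (0,1)")
        if self.logit_variant not in ("scaled_logistic", "plain_logistic"):
            raise ValidationError(
                f"unknown logit_variant {self.logit_variant!r}"
            )
        if self.output_scale not in (1, 1.0, 100, 100.0):
            raise ValidationError("output_scale must be 1 or 100")
        weights = {d: float(self.domain_weights.get(d, 0.0)) for d in DOMAINS}
        if any(w < 0 for w in weights.values()):
            raise ValidationError("domain weights must be nonnegative")
        total = sum(weights.values())
        if total <= 0:
            raise ValidationError("domain weights must not all be zero")
        self.domain_weights = {d: w / total for d, w in weights.items()}


@dataclass
class IndicatorTable:
    """Hospitals x indicators matrix plus per-indicator metadata.

    ``values`` is a DataFrame indexed by unit (hospital) identifier with one
    column per indicator; categorical indicators hold their integer category
    codes after :meth:`validate`.  ``direction_adjusted`` records whether
    cost indicators have already been negated, which makes
    :func:`apply_direction` idempotent.
    """

    values: pd.DataFrame
    specs: list[IndicatorSpec]
    direction_adjusted: bool = False
    validated: bool = False

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate indicator names in specs")
        if list(self.values.columns) != names:
            missing = set(names) - set(self.values.columns)
            extra = set(self.values.columns) - set(names)
            if missing or extra:
                raise ValidationError(
                    f"column/spec mismatch: missing={sorted(missing)}, "
                    f"undeclared={sorted(extra)}"
                )
            self.values = self.values[names]

    @property
    def units(self) -> list[str]:
        return [str(u) for u in self.values.index]

    @property
    def n_units(self) -> int:
        return len(self.values)

    def spec(self, name: str) -> IndicatorSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def domain_specs(self, domain: str) -> list[IndicatorSpec]:
        return [s for s in self.specs if s.domain == domain]

    def domain_slice(self, domain: str) -> pd.DataFrame:
        cols = [s.name for s in self.domain_specs(domain)]
        return self.values[cols]

    def validate(self, drop_incomplete_units: bool = False) -> "IndicatorTable":
        """Check the table contract and return a validated copy.

        Duplicate unit identifiers and empty domains are rejected; missing
        cells are rejected unless ``drop_incomplete_units`` removes the
        offending hospitals (logged).  Categorical values must come from the
        declared category set and are mapped to integer codes.
        """
        df = self.values.copy()
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit identifiers: {dupes}")
        for domain in DOMAINS:
            if not self.domain_specs(domain):
                raise ValidationError(f"domain {domain!r} has no indicators")
        if df.isna().any().any():
            if drop_incomplete_units:
                before = len(df)
                df = df.dropna(axis=0, how="any")
                logger.info(
                    "dropped %d units with missing cells (%d remain)",
                    before - len(df), len(df),
                )
                if df.empty:
                    raise ValidationError(
                        "all units removed by --drop-incomplete-units"
                    )
            else:
                bad = df.columns[df.isna().any()].tolist()
                raise ValidationError(
                    f"missing values in columns {bad}; no imputation is "
                    "performed (use drop_incomplete_units to remove those "
                    "hospitals)"
                )
        for s in self.specs:
            col = df[s.name]
            if s.is_categorical:
                codes = _encode_categories(col, s)
                df[s.name] = codes
            else:
                try:
                    df[s.name] = col.astype(float)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(
                        f"non-numeric cell in numeric indicator {s.name!r}"
                    ) from exc
        out = IndicatorTable(
            values=df,
            specs=list(self.specs),
            direction_adjusted=self.direction_adjusted,
            validated=True,
        )
        return out


def _encode_categories(col: pd.Series, spec: IndicatorSpec) -> pd.Series:
    """Map observed category values to their declared integer codes."""
    mapping = {}
    for code, level in enumerate(spec.levels):
        mapping[level] = code
        mapping[str(level)] = code
        try:
            mapping[float(level)] = code
        except (TypeError, ValueError):
            pass
    out = []
    for v in col:
        key = v
        if key not in mapping:
            try:
                key = float(v)
            except (TypeError, ValueError):
                key = str(v)
        if key not in mapping and isinstance(key, float) and key.is_integer():
            key = str(int(key))
        if key not in mapping:
            raise ValidationError(
                f"indicator {spec.name!r}: undeclared category level {v!r} "
                f"(declared levels: {list(spec.levels)})"
            )
        out.append(mapping[key])
    return pd.Series(out, index=col.index, dtype=float)


def load_config(config_path) -> tuple[list[IndicatorSpec], ScoringConfig]:
    """Read a YAML configuration declaring indicators and scoring parameters.

    Expected layout::

        indicators:
          - {name: sci_papers, domain: research_and_development,
             scale: numeric, direction: benefit}
          - {name: national_awards, domain: academic_reputation,
             scale: ordinal, direction: benefit, levels: [0,1,2,3,4]}
        scoring:
          retention_rule: fixed
          n_components: 2
          ...
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "indicators" not in raw:
        raise ValidationError("config must contain an 'indicators' section")
    specs = []
    for entry in raw["indicators"]:
        entry = dict(entry)
        if "levels" in entry and entry["levels"] is not None:
            entry["levels"] = tuple(entry["levels"])
        specs.append(IndicatorSpec(**entry))
    scoring = ScoringConfig(**(raw.get("scoring") or {}))
    return specs, scoring


def save_config(specs, scoring: ScoringConfig, config_path) -> None:
    """Write the YAML configuration consumed by :func:`load_config`."""
    payload = {
        "indicators": [
            {
                "name": s.name,
                "domain": s.domain,
                "scale": s.scale,
                "direction": s.direction,
                **({"levels": list(s.levels)} if s.levels else {}),
            }
            for s in specs
        ],
        "scoring": {
            "retention_rule": scoring.retention_rule,
            "n_components": scoring.n_components,
            "min_cumulative_variance": scoring.min_cumulative_variance,
            "domain_weights": dict(scoring.domain_weights),
            "logit_variant": scoring.logit_variant,
            "subset_search": scoring.subset_search,
            "kmo_threshold": scoring.kmo_threshold,
            "alpha_threshold": scoring.alpha_threshold,
            "output_scale": scoring.output_scale,
            "seed": scoring.seed,
            "drop_incomplete_units": scoring.drop_incomplete_units,
            "abort_on_diagnostic_failure":
                scoring.abort_on_diagnostic_failure,
            "catpca_tol": scoring.catpca_tol,
            "catpca_max_iter": scoring.catpca_max_iter,
        },
    }
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_indicator_table(path, config_path) -> IndicatorTable:
    """Read a UTF-8 CSV of hospitals x indicators and validate it.

    The file must have a header row of indicator names and a leading
    unit-identifier column; every header column must be declared in the
    configuration and vice versa.
    """
    specs, scoring = load_config(config_path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "unit"
    declared = {s.name for s in specs}
    present = set(df.columns)
    unknown = sorted(present - declared)
    if unknown:
        raise ValidationError(
            f"columns not declared in configuration: {unknown}"
        )
    absent = sorted(declared - present)
    if absent:
        raise ValidationError(
            f"indicators declared but absent from file: {absent}"
        )
    table = IndicatorTable(values=df[[s.name for s in specs]], specs=specs)
    validated = table.validate(
        drop_incomplete_units=scoring.drop_incomplete_units
    )
    logger.info(
        "read %d units x %d indicators from %s",
        validated.n_units, len(specs), path,
    )
    return validated


def write_table(table: IndicatorTable, path) -> None:
    """Write the table back out in the same CSV dialect it is read from."""
    table.values.to_csv(path, index_label="unit")


def apply_direction(table: IndicatorTable) -> IndicatorTable:
    """Negate every cost-direction indicator so larger is better everywhere.

    Negation (rather than a reciprocal) preserves the linear correlation
    structure PCA relies on.  The adjustment flag makes the operation
    idempotent: applying it to an already-adjusted table returns an equal
    table.
    """
    if table.direction_adjusted:
        return replace(table, values=table.values.copy())
    df = table.values.copy()
    for s in table.specs:
        if s.direction == "cost":
            df[s.name] = -df[s.name].astype(float)
    return replace(table, values=df, direction_adjusted=True)
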