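"""The composite-score chain: logit transform, entropy weights, aggregation.

Component scores from each domain model are squashed into (0,1) by a
logistic transform, combined within the domain by entropy weights (a
component that separates hospitals more gets more weight), aggregated across
the three domains by expert weights, and finally min-max rescaled so the top
hospital attains the maximum of the output scale — the composite development
index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ComponentModel, fit_domain, subset_search
from .data_model import (DOMAINS, IndicatorTable, ScoringConfig,
                         apply_direction)
from .diagnostics import DiagnosticsReport, diagnose

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    """Raised on invalid inputs to the scoring chain."""


@dataclass
class EntropyWeights:
    """Entropy-based diversification weights for one domain's components.

    ``entropy[i]`` is the normalised Shannon entropy e_i of component i's
    share distribution across hospitals (1 when every hospital gets the same
    share, i.e. the column is constant); ``diversification[i] = 1 - e_i``;
    weights are the diversifications renormalised to sum to 1.
    """

    entropy: np.ndarray
    diversification: np.ndarray
    weights: np.ndarray


def logit_transform(model: ComponentModel,
                    variant: str = "scaled_logistic") -> np.ndarray:
    """Map component scores into (0,1) with a logistic curve.

    ``scaled_logistic`` (default) slopes each component's curve by its
    relative variance contribution, S_hi = 1/(1+exp(-(C_i/G(m)) * F_hi)), so
    high-variance components spread hospitals over more of the unit
    interval; ``plain_logistic`` uses S_hi = 1/(1+exp(-F_hi)).  With a
    single retained component C_1/G(m) = 1 and the variants coincide.
    """
    f = model.scores
    if variant == "scaled_logistic":
        slope = model.variance_shares / model.cumulative_variance
        arg = f * slope[None, :]
    elif variant == "plain_logistic":
        arg = f
    else:
        raise ScoringError(f"unknown logit variant {variant!r}")
    return 1.0 / (1.0 + np.exp(-arg))


def entropy_weights(matrix) -> EntropyWeights:
    """Entropy weights over the components of one domain.

    For each component i, each hospital's share is
    p_hi = x_hi / sum_h x_hi; the normalised entropy is
    e_i = -(1/ln n) * sum_h p_hi ln p_hi (with 0 ln 0 := 0), the
    diversification degree d_i = 1 - e_i, and the weight
    w_i = d_i / sum_i d_i.  Components along which hospitals differ more
    have lower entropy and hence more weight; a constant column gets weight
    exactly 0.  If every column is constant the weights fall back to equal,
    with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ScoringError("expected a 2-D units x components matrix")
    n, m = x.shape
    if n < 2:
        raise ScoringError("entropy weights require at least 2 units")
    if np.any(x <= 0):
        raise ScoringError("entropy weights require strictly positive values")
    p = x / x.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    e = np.clip(e, 0.0, 1.0)
    # a constant column has maximal entropy exactly (uniform shares); snap
    # to 1 so its weight is exactly 0
    e[np.ptp(x, axis=0) == 0] = 1.0
    d = 1.0 - e
    total = d.sum()
    if total <= 0:
        warnings.warn(
            "all components are constant across units; "
            "falling back to equal entropy weights",
            RuntimeWarning,
        )
        w = np.full(m, 1.0 / m)
    else:
        w = d / total
    return EntropyWeights(entropy=e, diversification=d, weights=w)


def combine_domain(transformed, weights: EntropyWeights) -> np.ndarray:
    """Convex combination of transformed component scores per hospital."""
    s = np.asarray(transformed, dtype=float)
    w = weights.weights
    if s.shape[1] != len(w):
        raise ScoringError(
            f"dimension mismatch: {s.shape[1]} components vs {len(w)} weights"
        )
    return s @ w


@dataclass
class RankingResult:
    """Per-hospital domain scores, raw score, index value, and rank.

    ``ranking`` has one row per hospital: the three domain scores, the
    expert-weighted raw score, the min-max rescaled index (top hospital =
    ``output_scale``, bottom = 0), and the descending rank (average ranks on
    ties).  ``validation`` is the Pearson correlation matrix among the three
    domain scores and the raw total — positive, sizable correlations
    indicate the domains measure a coherent underlying construct.
    """

    ranking: pd.DataFrame
    domain_weights: dict
    validation: pd.DataFrame
    output_scale: float


def aggregate_chdi(domain_scores: dict, domain_weights: dict,
                   output_scale: float = 1.0) -> RankingResult:
    """Aggregate domain scores into the ranked composite index.

    raw_h = sum_d w_d * score_dh; index_h = (raw_h - min raw) / range,
    multiplied by ``output_scale``.  If all raw scores coincide the range is
    degenerate and every index value is 0, with a warning.
    """
    frames = {}
    unit_sets = set()
    for d in DOMAINS:
        if d not in domain_scores:
            raise ScoringError(f"missing domain scores for {d!r}")
        s = domain_scores[d]
        if not isinstance(s, pd.Series):
            raise ScoringError("domain scores must be pandas Series by unit")
        frames[d] = s
        unit_sets.add(tuple(s.index))
    if len(unit_sets) != 1:
        raise ScoringError("unit sets differ across domains")
    df = pd.DataFrame(frames)
    weights = {d: float(domain_weights.get(d, 0.0)) for d in DOMAINS}
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ScoringError("domain weights must not all be zero")
    weights = {d: w / total_w for d, w in weights.items()}
    raw = sum(weights[d] * df[d] for d in DOMAINS)
    rng_ = raw.max() - raw.min()
    if rng_ == 0:
        warnings.warn("degenerate raw-score range; all index values set to 0",
                      RuntimeWarning)
        index = raw * 0.0
    else:
        index = (raw - raw.min()) / rng_ * output_scale
    rank = index.rank(ascending=False, method="average")
    ranking = df.copy()
    ranking["raw_score"] = raw
    ranking["chdi"] = index
    ranking["rank"] = rank
    ranking = ranking.sort_values(["rank", "chdi"], kind="mergesort")
    val_input = df.copy()
    val_input["total"] = raw
    validation = val_input.corr(method="pearson")
    return RankingResult(
        ranking=ranking,
        domain_weights=weights,
        validation=validation,
        output_scale=output_scale,
    )


@dataclass
class PipelineResult:
    """Everything a full scoring run produces."""

    diagnostics: DiagnosticsReport
    searches: dict            # domain -> subset-search result or None
    models: dict              # domain -> ComponentModel
    entropy: dict             # domain -> EntropyWeights
    transformed: dict         # domain -> DataFrame of S_hi
    result: RankingResult
    config: ScoringConfig


def domain_method(table: IndicatorTable, domain: str) -> str:
    """PCA when every indicator in the domain is numeric, else CATPCA."""
    specs = table.domain_specs(domain)
    return "catpca" if any(s.is_categorical for s in specs) else "pca"


def run_pipeline(table: IndicatorTable, config: ScoringConfig,
                 methods: dict | None = None) -> PipelineResult:
    """Execute the full scoring chain on a validated indicator table.

    Stages, in order: direction adjustment, per-domain suitability
    diagnostics, optional all-subset indicator search, component-model fit,
    logistic transform, entropy weighting, cross-domain aggregation and
    ranking.  Fully deterministic given ``config.seed``.  A domain failing
    its diagnostic threshold aborts when
    ``config.abort_on_diagnostic_failure`` is set and otherwise proceeds
    flagged.

    ``methods`` optionally overrides the per-domain model dispatch
    (domain -> "pca" | "catpca").
    """
    if not table.validated:
        table = table.validate(config.drop_incomplete_units)
    table = apply_direction(table)
    report = diagnose(table, config)
    if not report.all_passed:
        failed = report.rows.loc[~report.rows["passed"], "domain"].tolist()
        msg = f"diagnostic threshold not met for domains: {failed}"
        if config.abort_on_diagnostic_failure:
            raise ScoringError(msg)
        logger.warning("%s; proceeding flagged", msg)
    searches: dict = {}
    models: dict = {}
    entropy: dict = {}
    transformed: dict = {}
    domain_scores: dict = {}
    units = table.values.index
    for domain in DOMAINS:
        frame = table.domain_slice(domain)
        scales = {s.name: s.scale for s in table.domain_specs(domain)}
        method = (methods or {}).get(domain) or domain_method(table, domain)
        if config.subset_search and frame.shape[1] > 2:
            search = subset_search(frame, scales, method, config)
            searches[domain] = search
            frame = frame[list(search.chosen)]
            if not search.acceptable:
                logger.warning(
                    "domain %s: %s", domain, search.rationale
                )
        else:
            searches[domain] = None
        model = fit_domain(frame, scales, method, config)
        models[domain] = model
        s = logit_transform(model, config.logit_variant)
        ew = entropy_weights(s)
        entropy[domain] = ew
        cols = [f"pc{i + 1}" for i in range(s.shape[1])]
        transformed[domain] = pd.DataFrame(s, index=units, columns=cols)
        domain_scores[domain] = pd.Series(
            combine_domain(s, ew), index=units, name=domain
        )
    result = aggregate_chdi(domain_scores, config.domain_weights,
                            config.output_scale)
    return PipelineResult(
        diagnostics=report,
        searches=searches,
        models=models,
        entropy=entropy,
        transformed=transformed,
        result=result,
        config=config,
    )
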