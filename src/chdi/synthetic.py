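"""Synthetic hospital-indicator tables with a known latent structure.

The original 310-hospital indicator dataset behind the composite index was
never published, so this module generates tables with the statistical
structure the analysis assumes: three correlated latent "strength" factors
(one per domain, plus a weaker secondary factor within each domain),
indicators loading on one or two of those factors, heavy-tailed count-like
bibliometric indicators, small-integer ordinal reputation indicators, and
two cost-direction malpractice ratios.  The generator records the ground
truth (factor scores, which indicators are pure noise), which is what makes
parameter-recovery testing possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DOMAINS, IndicatorSpec, IndicatorTable


@dataclass(frozen=True)
class IndicatorTemplate:
    """Recipe for one synthetic indicator.

    ``loading_primary`` / ``loading_secondary`` weight the domain's primary
    and secondary latent factors; ``noise_sd`` is the unique-noise standard
    deviation on the latent scale.  ``family`` shapes the marginal:
    ``count`` is lognormal-then-rounded (heavy-tailed, like publication or
    citation counts), ``proportion`` is a logistic squash into (0,1) (like a
    malpractice-compensation ratio), ``ordinal`` quantile-cuts the latent
    value into ``n_levels`` ordered categories (like award counts), and
    ``numeric`` leaves the latent value as is.  Cost-direction indicators
    are generated with reversed polarity (a stronger hospital gets a lower
    value).  A pure-noise indicator has both loadings 0.
    """

    name: str
    domain: str
    family: str = "numeric"            # numeric | count | proportion | ordinal
    direction: str = "benefit"
    loading_primary: float = 0.0
    loading_secondary: float = 0.0
    noise_sd: float = 1.0
    n_levels: int = 5
    log_mu: float = 4.0                # count family: log-scale location
    log_sigma: float = 0.5             # count family: log-scale spread
    prop_center: float = -2.0          # proportion family: logit-scale center
    prop_slope: float = 0.8            # proportion family: logit-scale slope

    @property
    def is_noise(self) -> bool:
        return self.loading_primary == 0.0 and self.loading_secondary == 0.0

    @property
    def scale(self) -> str:
        return "ordinal" if self.family == "ordinal" else "numeric"


@dataclass
class SimulationDesign:
    """Full recipe for a synthetic hospital table.

    ``latent_corr`` is the 3x3 correlation matrix of the domain primary
    factors (order: research_and_development, academic_reputation,
    quality_and_safety); ``secondary_rho`` is the within-domain correlation
    between a domain's secondary factor and its primary factor.
    """

    n_units: int = 310
    templates: list = field(default_factory=list)
    latent_corr: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.00, 0.75, 0.60],
             [0.75, 1.00, 0.62],
             [0.60, 0.62, 1.00]]
        )
    )
    secondary_rho: float = 0.4
    seed: int = 2021

    def __post_init__(self) -> None:
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        c = self.latent_corr
        if c.shape != (3, 3) or not np.allclose(c, c.T):
            raise ValueError("latent_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("latent_corr must have a unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("latent_corr must be positive semidefinite")
        if self.n_units < 10:
            raise ValueError("n_units must be >= 10")
        if not -1.0 < self.secondary_rho < 1.0:
            raise ValueError("secondary_rho must lie in (-1, 1)")
        for t in self.templates:
            if not np.isfinite([t.loading_primary, t.loading_secondary,
                                t.noise_sd]).all():
                raise ValueError(f"non-finite loadings in template {t.name!r}")

    def domain_templates(self, domain: str) -> list:
        return [t for t in self.templates if t.domain == domain]


@dataclass
class SimulationTruth:
    """Ground truth stored alongside every generated table."""

    factors: pd.DataFrame        # units x domains, primary factor scores
    secondary: pd.DataFrame      # units x domains, secondary factor scores
    noise_indicators: list       # names of pure-noise indicators
    design: SimulationDesign

    def to_csv(self, path) -> None:
        out = self.factors.copy()
        out.columns = [f"primary_{d}" for d in out.columns]
        for d in self.secondary.columns:
            out[f"secondary_{d}"] = self.secondary[d]
        out.to_csv(path, index_label="unit")


def _apply_family(latent: np.ndarray, t: IndicatorTemplate,
                  n_units: int) -> np.ndarray:
    y = latent / np.sqrt(
        t.loading_primary ** 2 + t.loading_secondary ** 2 + t.noise_sd ** 2
    )  # roughly unit scale regardless of loadings
    if t.family == "numeric":
        return y
    if t.family == "count":
        return np.round(np.exp(t.log_mu + t.log_sigma * y))
    if t.family == "proportion":
        return 1.0 / (1.0 + np.exp(-(t.prop_center + t.prop_slope * y)))
    if t.family == "ordinal":
        # quantile cut into n_levels ordered categories, codes 0..L-1
        edges = np.quantile(y, np.linspace(0, 1, t.n_levels + 1)[1:-1])
        return np.searchsorted(edges, y, side="right").astype(float)
    raise ValueError(f"unknown value family {t.family!r}")


def generate(design: SimulationDesign) -> tuple[IndicatorTable, SimulationTruth]:
    """Draw one synthetic hospital-indicator table.

    Primary factors are multivariate normal with the design's cross-domain
    correlation; each domain's secondary factor mixes its primary factor
    (``secondary_rho``) with fresh noise.  Each indicator is
    ``loading_primary * g + loading_secondary * s + noise_sd * e`` (negated
    for cost direction) pushed through its value family.  Deterministic
    under the design seed.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_units
    chol = np.linalg.cholesky(
        design.latent_corr + 1e-12 * np.eye(3)
    )
    g = rng.standard_normal((n, 3)) @ chol.T
    s = (design.secondary_rho * g
         + np.sqrt(1.0 - design.secondary_rho ** 2)
         * rng.standard_normal((n, 3)))
    units = [f"H{i + 1:03d}" for i in range(n)]
    factors = pd.DataFrame(g, index=units, columns=list(DOMAINS))
    secondary = pd.DataFrame(s, index=units, columns=list(DOMAINS))

    columns = {}
    specs = []
    noise_names = []
    for t in design.templates:
        d = DOMAINS.index(t.domain)
        structural = (t.loading_primary * g[:, d]
                      + t.loading_secondary * s[:, d])
        if t.direction == "cost":
            structural = -structural
        latent = structural + t.noise_sd * rng.standard_normal(n)
        columns[t.name] = _apply_family(latent, t, n)
        levels = tuple(range(t.n_levels)) if t.family == "ordinal" else None
        specs.append(IndicatorSpec(
            name=t.name, domain=t.domain, scale=t.scale,
            direction=t.direction, levels=levels,
        ))
        if t.is_noise:
            noise_names.append(t.name)
    table = IndicatorTable(
        values=pd.DataFrame(columns, index=units), specs=specs
    ).validate()
    truth = SimulationTruth(
        factors=factors, secondary=secondary,
        noise_indicators=noise_names, design=design,
    )
    return table, truth


def default_design(n_units: int = 310, seed: int = 2021) -> SimulationDesign:
    """The packaged study-scale design.

    310 hospitals; a research domain of 13 heavy-tailed count indicators
    (publication, citation, high-impact and trial-activity measures, 2 of
    them pure noise) on two factors; a reputation domain of 9 small-integer
    ordinal indicators (academicians, editors, association posts, awards; 3
    pure noise) on two factors; a quality domain of 3 indicators, two of
    them cost-direction malpractice ratios.  Cross-domain primary-factor
    correlations sit in the 0.6-0.8 band, with the quality domain the most
    weakly coupled.
    """
    t = []
    rd = "research_and_development"
    # volume measures: load on the primary research factor
    for name, mu in [("sci_papers_all", 6.0), ("sci_papers_first", 5.2),
                     ("sci_papers_corresponding", 5.0),
                     ("citations_all", 8.0), ("citations_first", 7.2),
                     ("citations_corresponding", 7.0)]:
        t.append(IndicatorTemplate(
            name=name, domain=rd, family="count",
            loading_primary=0.95, loading_secondary=0.08, noise_sd=0.28,
            log_mu=mu, log_sigma=0.55,
        ))
    # high-impact measures: load mostly on the secondary research factor
    for name, mu in [("high_if_papers_all", 3.4),
                     ("high_if_papers_first", 2.8),
                     ("high_if_papers_corresponding", 2.6),
                     ("top6_papers_all", 1.8),
                     ("top6_papers_first", 1.4)]:
        t.append(IndicatorTemplate(
            name=name, domain=rd, family="count",
            loading_primary=0.60, loading_secondary=0.74, noise_sd=0.28,
            log_mu=mu, log_sigma=0.65,
        ))
    # pure-noise research indicators
    for name, mu in [("top6_papers_corresponding", 1.2),
                     ("registered_trials", 4.0)]:
        t.append(IndicatorTemplate(
            name=name, domain=rd, family="count",
            loading_primary=0.0, loading_secondary=0.0, noise_sd=1.0,
            log_mu=mu, log_sigma=0.5,
        ))

    ar = "academic_reputation"
    # standing measures: primary reputation factor
    for name, levels in [("academicians_cas", 5), ("academicians_cae", 5),
                         ("state_science_awards", 6),
                         ("medical_science_awards", 7)]:
        t.append(IndicatorTemplate(
            name=name, domain=ar, family="ordinal", n_levels=levels,
            loading_primary=0.94, loading_secondary=0.10, noise_sd=0.30,
        ))
    # association measures: secondary reputation factor
    for name, levels in [("assoc_chairpersons", 7), ("assoc_members", 8)]:
        t.append(IndicatorTemplate(
            name=name, domain=ar, family="ordinal", n_levels=levels,
            loading_primary=0.58, loading_secondary=0.76, noise_sd=0.30,
        ))
    # pure-noise reputation indicators
    for name, levels in [("chief_editors", 5), ("doctor_awards", 6),
                         ("progress_awards", 6)]:
        t.append(IndicatorTemplate(
            name=name, domain=ar, family="ordinal", n_levels=levels,
            loading_primary=0.0, loading_secondary=0.0, noise_sd=1.0,
        ))

    qs = "quality_and_safety"
    # malpractice ratios: cost direction, share the secondary quality factor
    for name in ("compensation_case_ratio", "liability_ratio"):
        t.append(IndicatorTemplate(
            name=name, domain=qs, family="proportion", direction="cost",
            loading_primary=0.85, loading_secondary=0.22, noise_sd=0.32,
            prop_center=-2.0, prop_slope=1.5,
        ))
    t.append(IndicatorTemplate(
        name="key_specialties", domain=qs, family="count",
        loading_primary=0.90, loading_secondary=0.28, noise_sd=0.20,
        log_mu=1.8, log_sigma=0.35,
    ))
    return SimulationDesign(n_units=n_units, templates=t, seed=seed)


def default_fixture(seed: int = 2021,
                    n_units: int = 310) -> tuple[IndicatorTable, SimulationTruth]:
    """Generate the packaged default table (310 x 25) and its ground truth."""
    return generate(default_design(n_units=n_units, seed=seed))
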