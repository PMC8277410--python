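"""Per-domain dimension reduction: PCA, CATPCA, and the all-subset search.

Each performance domain is summarised by a small number of principal
components of its indicators.  Domains whose indicators are all numeric use
standard correlation-matrix PCA; domains with ordinal/nominal indicators use
categorical PCA (CATPCA), which assigns numeric quantifications to the
categories inside an alternating-least-squares loop so that the retained
components explain as much variance as possible (optimal scaling).  A model
for a domain is chosen by exhaustively fitting every nonempty indicator
subset and keeping the largest subset whose diagnostic and cumulative
variance clear the configured bars.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .data_model import ScoringConfig
from .diagnostics import DiagnosticError, cronbach_alpha, kmo


class FitError(ValueError):
    """Raised when a component model cannot be fitted on the given data."""


@dataclass
class ComponentModel:
    """A fitted PCA or CATPCA model for one domain.

    ``variance_shares`` holds C_i, the fraction of total (standardised)
    variance carried by each retained component, and ``cumulative_variance``
    their sum G(m).  ``scores`` are the per-hospital component scores F_hi
    (zero mean; variance equal to the component eigenvalue).  For CATPCA,
    ``quantifications`` maps each categorical indicator to its
    category-code -> numeric-value map; ordinal maps are monotone
    nondecreasing by construction.
    """

    method: str                        # "pca" | "catpca"
    indicator_names: list[str]
    means: np.ndarray                  # per-indicator mean of (quantified) data
    sds: np.ndarray                    # per-indicator sd (ddof=1)
    eigenvalues: np.ndarray            # all p eigenvalues, descending
    components: np.ndarray             # p x k unit-norm eigenvectors
    loadings: np.ndarray               # p x k, eigenvector * sqrt(eigenvalue)
    variance_shares: np.ndarray        # k, C_i = eigenvalue_i / p
    cumulative_variance: float         # G(m)
    scores: np.ndarray                 # n x k
    quantifications: dict | None = None
    converged: bool = True
    n_iter: int = 0
    vaf_history: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _retained(eigenvalues: np.ndarray, rule: str, k: int,
              min_cumvar: float) -> int:
    p = len(eigenvalues)
    if rule == "fixed":
        if k > p:
            raise FitError(
                f"retention rule asks for {k} components but only {p} "
                "indicators are available"
            )
        return k
    shares = np.cumsum(eigenvalues) / p
    return int(np.searchsorted(shares, min_cumvar - 1e-12) + 1)


def _fix_signs(components, loadings, scores):
    """Deterministic orientation: largest-|loading| entry positive."""
    for j in range(loadings.shape[1]):
        idx = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[idx, j] < 0:
            components[:, j] *= -1
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return components, loadings, scores


def pca_fit(matrix, retention_rule: str = "fixed", n_components: int = 2,
            min_cumulative_variance: float = 0.90,
            indicator_names=None) -> ComponentModel:
    """Correlation-matrix PCA with a retention rule.

    Columns are standardised to zero mean / unit variance, the correlation
    matrix is eigendecomposed, components are ordered by eigenvalue and
    retained either as a fixed number (default 2) or up to a cumulative
    variance threshold.  Scores are the standardised data projected onto the
    unit-norm eigenvectors, so the score of component i has variance equal
    to its eigenvalue.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise FitError("expected a 2-D units x indicators matrix")
    n, p = x.shape
    if p < 2:
        raise FitError("PCA requires at least 2 indicators")
    if n < 3:
        raise FitError("PCA requires at least 3 units")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = list(np.nonzero(sds == 0)[0])
        raise FitError(f"constant column(s) at positions {bad}")
    z = (x - means) / sds
    corr = (z.T @ z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    k = _retained(eigvals, retention_rule, n_components,
                  min_cumulative_variance)
    if n <= k:
        raise FitError("need more units than retained components")
    comps = eigvecs[:, :k].copy()
    loadings = comps * np.sqrt(eigvals[:k])
    scores = z @ comps
    comps, loadings, scores = _fix_signs(comps, loadings, scores)
    shares = eigvals[:k] / p
    names = (list(indicator_names) if indicator_names is not None
             else [f"x{j}" for j in range(p)])
    return ComponentModel(
        method="pca",
        indicator_names=names,
        means=means,
        sds=sds,
        eigenvalues=eigvals,
        components=comps,
        loadings=loadings,
        variance_shares=shares,
        cumulative_variance=float(shares.sum()),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# CATPCA: optimal scaling by alternating least squares
# ---------------------------------------------------------------------------

def _normalise(col: np.ndarray) -> np.ndarray:
    """Centre and scale to squared norm n (population variance 1)."""
    c = col - col.mean()
    norm = np.sqrt((c ** 2).sum())
    if norm == 0:
        raise FitError("degenerate quantified column (zero variance)")
    return c * np.sqrt(len(c)) / norm


def catpca_fit(frame: pd.DataFrame, scales: dict,
               retention_rule: str = "fixed", n_components: int = 2,
               min_cumulative_variance: float = 0.90, seed: int = 0,
               tol: float = 1e-7, max_iter: int = 2000) -> ComponentModel:
    """Categorical PCA by alternating least squares.

    Alternates (i) a PCA step on the currently quantified, standardised data
    and (ii) a least-squares update of every categorical variable's category
    quantifications against the rank-k model matrix, with a monotone
    projection for ordinal variables and free centroids for nominal ones.
    Iterates until the variance accounted for (VAF) by the retained
    components changes by less than ``tol``.  VAF is nondecreasing across
    iterations; non-convergence at ``max_iter`` returns the best iterate
    with a warning.

    ``scales`` maps column name -> "numeric" | "ordinal" | "nominal".
    Categorical columns must hold integer category codes with >= 2 observed
    levels; ordinal order is code order.  Ordinal variables start from their
    rank coding, nominal ones from seeded random quantifications.
    """
    if not isinstance(frame, pd.DataFrame):
        frame = pd.DataFrame(np.asarray(frame, dtype=float))
    names = list(frame.columns)
    x = frame.to_numpy(dtype=float)
    n, p = x.shape
    if p < 2:
        raise FitError("CATPCA requires at least 2 indicators")
    cat_cols = [j for j, c in enumerate(names)
                if scales.get(c, "numeric") in ("ordinal", "nominal")]
    if not cat_cols:
        raise FitError("CATPCA requires at least one ordinal/nominal column")
    codes = {}
    for j in cat_cols:
        cj = x[:, j]
        if not np.allclose(cj, np.round(cj)):
            raise FitError(
                f"categorical column {names[j]!r} must hold integer codes"
            )
        codes[j] = cj.astype(int)
        if len(np.unique(codes[j])) < 2:
            raise FitError(
                f"categorical column {names[j]!r} has <2 observed levels"
            )

    rng = np.random.default_rng(seed)
    z = np.empty_like(x)
    for j in range(p):
        if j in codes and scales[names[j]] == "nominal":
            # random starting quantification, remapped onto the codes
            cats = np.unique(codes[j])
            start = rng.standard_normal(len(cats))
            lookup = dict(zip(cats, start))
            z[:, j] = _normalise(np.array([lookup[c] for c in codes[j]]))
        else:
            # numeric and ordinal columns start from their given coding
            col = x[:, j]
            if col.std() == 0:
                raise FitError(f"constant column {names[j]!r}")
            z[:, j] = _normalise(col)

    if retention_rule == "fixed" and n_components > p:
        raise FitError("retention rule unsatisfiable")
    # category bookkeeping for the vectorised update step
    cat_info = {}
    for j in cat_cols:
        cats, inv = np.unique(codes[j], return_inverse=True)
        counts = np.bincount(inv).astype(float)
        cat_info[j] = (cats, inv, counts)

    vaf_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # PCA step on the p x p gram matrix of the quantified data
        gram = (z.T @ z) / n
        eigvals, eigvecs = np.linalg.eigh(gram)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        kk = (n_components if retention_rule == "fixed"
              else _retained(eigvals, retention_rule, n_components,
                             min_cumulative_variance))
        vaf = float(eigvals[:kk].sum() / p)
        vaf_history.append(vaf)
        if len(vaf_history) > 1 and abs(vaf_history[-1] - vaf_history[-2]) < tol:
            converged = True
            break
        # rank-kk model matrix F A^T = Z V_k V_k^T, column by column
        proj = eigvecs[:, :kk] @ eigvecs[:, :kk].T
        model = z @ proj
        for j in cat_cols:
            cats, inv, counts = cat_info[j]
            centroids = np.bincount(inv, weights=model[:, j]) / counts
            if scales[names[j]] == "ordinal":
                centroids = isotonic_regression(
                    centroids, weights=counts, increasing=True
                ).x
            if np.ptp(centroids) == 0:
                continue  # keep previous quantification
            z[:, j] = _normalise(centroids[inv])
    if not converged:
        warnings.warn(
            f"CATPCA did not converge in {max_iter} iterations "
            f"(last VAF change "
            f"{abs(vaf_history[-1] - vaf_history[-2]):.2e}); "
            "returning best iterate",
            RuntimeWarning,
        )

    # final model in pca_fit conventions on the quantified data
    final = pca_fit(z, retention_rule=retention_rule,
                    n_components=n_components,
                    min_cumulative_variance=min_cumulative_variance,
                    indicator_names=names)
    quantifications = {}
    for j in cat_cols:
        per_cat = {}
        for c in np.unique(codes[j]):
            per_cat[int(c)] = float(z[codes[j] == c, j][0])
        quantifications[names[j]] = per_cat
    return ComponentModel(
        method="catpca",
        indicator_names=names,
        means=final.means,
        sds=final.sds,
        eigenvalues=final.eigenvalues,
        components=final.components,
        loadings=final.loadings,
        variance_shares=final.variance_shares,
        cumulative_variance=final.cumulative_variance,
        scores=final.scores,
        quantifications=quantifications,
        converged=converged,
        n_iter=it,
        vaf_history=vaf_history,
        seed=seed,
    )


def fit_domain(frame: pd.DataFrame, scales: dict, method: str,
               config: ScoringConfig, names=None) -> ComponentModel:
    """Dispatch to :func:`pca_fit` or :func:`catpca_fit` per the method."""
    if method == "pca":
        return pca_fit(
            frame.to_numpy(dtype=float) if isinstance(frame, pd.DataFrame)
            else frame,
            retention_rule=config.retention_rule,
            n_components=config.n_components,
            min_cumulative_variance=config.min_cumulative_variance,
            indicator_names=(list(frame.columns)
                             if isinstance(frame, pd.DataFrame) else names),
        )
    if method == "catpca":
        return catpca_fit(
            frame, scales,
            retention_rule=config.retention_rule,
            n_components=config.n_components,
            min_cumulative_variance=config.min_cumulative_variance,
            seed=config.seed, tol=config.catpca_tol,
            max_iter=config.catpca_max_iter,
        )
    raise FitError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# All-subset indicator search
# ---------------------------------------------------------------------------

MAX_SEARCH_INDICATORS = 16


@dataclass
class SubsetSearchResult:
    """Outcome of the exhaustive indicator-subset enumeration."""

    records: pd.DataFrame   # subset, size, diagnostic, cumulative_variance,
                            # acceptable, reason
    chosen: tuple           # indicator names of the winning subset
    acceptable: bool        # False if no subset cleared the bars
    rationale: str


def subset_search(frame: pd.DataFrame, scales: dict, method: str,
                  config: ScoringConfig) -> SubsetSearchResult:
    """Enumerate every nonempty indicator subset and pick the best model.

    A subset is *acceptable* when its suitability diagnostic (KMO for PCA,
    Cronbach's alpha for CATPCA) strictly exceeds its threshold and the
    retained components' cumulative variance reaches
    ``config.min_cumulative_variance``.  Among acceptable subsets the
    largest wins (more indicators give more accurate component scores); ties
    on size go to higher cumulative variance, then lexicographic indicator
    order.  If nothing is acceptable the full set is returned, flagged.
    """
    names = list(frame.columns)
    p = len(names)
    if p > MAX_SEARCH_INDICATORS:
        raise FitError(
            f"subset search is exhaustive and limited to "
            f"{MAX_SEARCH_INDICATORS} indicators (got {p})"
        )
    threshold = (config.kmo_threshold if method == "pca"
                 else config.alpha_threshold)
    records = []
    best = None  # (size, cumvar, neg-lex key, subset)
    for r in range(1, p + 1):
        for subset in itertools.combinations(names, r):
            row = {"subset": ",".join(subset), "size": r,
                   "diagnostic": np.nan, "cumulative_variance": np.nan,
                   "acceptable": False, "reason": ""}
            sub = frame[list(subset)]
            if r < 2:
                row["reason"] = "diagnostic undefined for a single indicator"
                records.append(row)
                continue
            try:
                arr = sub.to_numpy(dtype=float)
                diag = (kmo(arr) if method == "pca"
                        else cronbach_alpha(arr))
                row["diagnostic"] = diag
                model = fit_domain(sub, scales, method, config)
                row["cumulative_variance"] = model.cumulative_variance
            except (DiagnosticError, FitError) as exc:
                row["reason"] = str(exc)
                records.append(row)
                continue
            if diag <= threshold:
                row["reason"] = (
                    f"diagnostic {diag:.3f} <= threshold {threshold}"
                )
            elif model.cumulative_variance < config.min_cumulative_variance:
                row["reason"] = (
                    f"cumulative variance {model.cumulative_variance:.3f} "
                    f"< {config.min_cumulative_variance}"
                )
            else:
                row["acceptable"] = True
            records.append(row)
            if row["acceptable"]:
                key = (r, model.cumulative_variance,
                       tuple(-ord(ch) for ch in ",".join(subset)))
                if best is None or key > best[0]:
                    best = (key, subset)
    if best is not None:
        chosen = best[1]
        rationale = (
            f"largest acceptable subset ({len(chosen)}/{p} indicators, "
            f"cumulative variance {best[0][1]:.3f})"
        )
        acceptable = True
    else:
        chosen = tuple(names)
        rationale = "no acceptable subset; full indicator set returned flagged"
        acceptable = False
    return SubsetSearchResult(
        records=pd.DataFrame.from_records(records),
        chosen=chosen,
        acceptable=acceptable,
        rationale=rationale,
    )


# ---------------------------------------------------------------------------
# Fixed-model projection and serialization
# ---------------------------------------------------------------------------

def score_new_units(model: ComponentModel, frame) -> np.ndarray:
    """Project new units through a fitted model without refitting.

    Applies the stored category quantifications (CATPCA), the stored
    standardisation, and the stored eigenvectors.  Columns must match the
    model's selected indicators by name and order (DataFrame input) or
    position (array input).
    """
    if isinstance(frame, pd.DataFrame):
        if list(frame.columns) != list(model.indicator_names):
            raise FitError(
                f"column mismatch: model expects {model.indicator_names}, "
                f"got {list(frame.columns)}"
            )
        x = frame.to_numpy(dtype=float)
    else:
        x = np.asarray(frame, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(model.indicator_names):
            raise FitError(
                f"expected {len(model.indicator_names)} columns, "
                f"got {x.shape[1]}"
            )
    x = x.copy()
    if model.quantifications:
        for j, name in enumerate(model.indicator_names):
            if name in model.quantifications:
                qmap = model.quantifications[name]
                col = x[:, j].astype(int)
                try:
                    x[:, j] = np.array([qmap[int(c)] for c in col])
                except KeyError as exc:
                    raise FitError(
                        f"unseen category {exc.args[0]} in column {name!r}"
                    ) from exc
    z = (x - model.means) / model.sds
    return z @ model.components


def write_model(model: ComponentModel, path) -> None:
    """Serialise a fitted model to a structured text file (JSON)."""
    payload = {
        "method": model.method,
        "indicator_names": list(model.indicator_names),
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "components": model.components.tolist(),
        "loadings": model.loadings.tolist(),
        "variance_shares": model.variance_shares.tolist(),
        "cumulative_variance": model.cumulative_variance,
        "scores": model.scores.tolist(),
        "quantifications": model.quantifications,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "vaf_history": list(model.vaf_history),
        "seed": model.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_model(path) -> ComponentModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    quant = payload["quantifications"]
    if quant is not None:
        quant = {name: {int(c): v for c, v in qmap.items()}
                 for name, qmap in quant.items()}
    return ComponentModel(
        method=payload["method"],
        indicator_names=payload["indicator_names"],
        means=np.asarray(payload["means"]),
        sds=np.asarray(payload["sds"]),
        eigenvalues=np.asarray(payload["eigenvalues"]),
        components=np.asarray(payload["components"]),
        loadings=np.asarray(payload["loadings"]),
        variance_shares=np.asarray(payload["variance_shares"]),
        cumulative_variance=payload["cumulative_variance"],
        scores=np.asarray(payload["scores"]),
        quantifications=quant,
        converged=payload["converged"],
        n_iter=payload["n_iter"],
        vaf_history=payload["vaf_history"],
        seed=payload["seed"],
    )
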