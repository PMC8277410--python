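"""Suitability diagnostics applied before dimension reduction.

Two statistics gate the per-domain models: the Kaiser-Meyer-Olkin (KMO)
measure of sampling adequacy for domains modelled with standard PCA, and
Cronbach's alpha internal-consistency coefficient for domains modelled with
categorical PCA.  A domain passes when its statistic strictly exceeds the
configured threshold (0.7 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IndicatorTable, ScoringConfig, DOMAINS


class DiagnosticError(ValueError):
    """Raised when a diagnostic cannot be computed on the given matrix."""


def _as_matrix(x) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2:
        raise DiagnosticError("expected a 2-D units x indicators matrix")
    return m


def kmo(matrix, return_per_variable: bool = False):
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Compares squared Pearson correlations between indicators with squared
    anti-image partial correlations:

        KMO = sum_{i != j} r_ij^2 / (sum_{i != j} r_ij^2 + sum_{i != j} u_ij^2)

    where ``u_ij = -q_ij / sqrt(q_ii q_jj)`` is the partial correlation of
    indicators i and j given all others, read off the inverse correlation
    matrix Q.  Values near 1 mean the indicators share enough common variance
    for PCA; here > 0.7 is treated as adequate.

    Parameters
    ----------
    matrix
        units x indicators array, >= 2 columns.
    return_per_variable
        Additionally return the per-variable measure of sampling adequacy
        (same formula restricted to one row of R), used by the subset search
        as an optional diagnostic.

    Raises
    ------
    DiagnosticError
        On a constant column or a singular correlation matrix (perfectly
        collinear indicators); the remedy is to drop indicators, e.g. via
        the subset search.
    """
    m = _as_matrix(matrix)
    n, p = m.shape
    if p < 2:
        raise DiagnosticError("KMO requires at least 2 indicators")
    if n < 3:
        raise DiagnosticError("KMO requires at least 3 units")
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(np.nonzero(sd == 0)[0])
        raise DiagnosticError(f"constant column(s) at positions {bad}")
    corr = np.corrcoef(m, rowvar=False)
    # cond() guards against numerically singular matrices that inv() would
    # silently "invert"
    if not np.all(np.isfinite(corr)) or np.linalg.cond(corr) > 1e12:
        raise DiagnosticError(
            "singular correlation matrix (perfectly collinear indicators); "
            "consider a subset search to drop redundant indicators"
        )
    q = np.linalg.inv(corr)
    d = np.sqrt(np.outer(np.diag(q), np.diag(q)))
    partial = -q / d
    off = ~np.eye(p, dtype=bool)
    r2 = corr[off] ** 2
    u2 = partial[off] ** 2
    overall = r2.sum() / (r2.sum() + u2.sum())
    if not return_per_variable:
        return float(overall)
    msa = np.empty(p)
    for j in range(p):
        mask = off[j]
        rj2 = corr[j, mask] ** 2
        uj2 = partial[j, mask] ** 2
        msa[j] = rj2.sum() / (rj2.sum() + uj2.sum())
    return float(overall), msa


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha internal-consistency reliability.

        alpha = k/(k-1) * (1 - sum_j var(x_j) / var(sum_j x_j))

    with k indicators and sample (ddof=1) variances.  Equals 1 for parallel
    items, approaches 0 for mutually independent items, and can be negative.
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    if k < 2:
        raise DiagnosticError("alpha requires at least 2 indicators")
    if n < 2:
        raise DiagnosticError("alpha requires at least 2 units")
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DiagnosticError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class DiagnosticsReport:
    """Per-domain suitability statistics with pass flags."""

    rows: pd.DataFrame  # columns: domain, statistic, value, threshold, passed

    @property
    def all_passed(self) -> bool:
        return bool(self.rows["passed"].all())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def diagnose(table: IndicatorTable, config: ScoringConfig) -> DiagnosticsReport:
    """Run the per-domain suitability checks.

    Domains whose indicators are all numeric get KMO (they will be modelled
    with PCA); domains containing any ordinal/nominal indicator get
    Cronbach's alpha (they will be modelled with CATPCA).  Both are compared
    strictly against their thresholds.
    """
    records = []
    for domain in DOMAINS:
        specs = table.domain_specs(domain)
        if not specs:
            continue
        slice_ = table.domain_slice(domain).to_numpy(dtype=float)
        categorical = any(s.is_categorical for s in specs)
        if categorical:
            value = cronbach_alpha(slice_)
            stat, threshold = "cronbach_alpha", config.alpha_threshold
        else:
            value = kmo(slice_)
            stat, threshold = "kmo", config.kmo_threshold
        records.append(
            {
                "domain": domain,
                "statistic": stat,
                "value": value,
                "threshold": threshold,
                "passed": value > threshold,
            }
        )
    return DiagnosticsReport(rows=pd.DataFrame.from_records(records))
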