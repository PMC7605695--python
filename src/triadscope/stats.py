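"""Inferential layer: AUDIT risk classification, chi-square association,
cross-layer Pearson correlation of transitive-triad profiles, and power.

Power for the two-sided test of ρ = 0 is computed by default from the exact
sampling distribution of the Pearson correlation under bivariate normality
(Hotelling's density), the same model G*Power's bivariate-correlation module
uses; the Fisher-z approximation (z = atanh r, SE = 1/√(n−3)) is selectable
and adequate for large n but optimistic-to-the-low-side at classroom sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .errors import DegenerateInputError, UsageError, ValidationError
from .model import Actor, AuditResponse, BinaryNetwork, align_orders
from .triads import DEFAULT_SCHEME, TRIAD_TYPES, TransitivityScheme, census, node_triad_profile

#: Conventional AUDIT cut-off: total >= 8 flags risky consumption.
DEFAULT_AUDIT_THRESHOLD = 8

CORRELATION_MODES = ("node_profile", "census_vector", "tie_level")


# ---------------------------------------------------------------------------
# AUDIT risk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskClassification:
    actor_id: str
    audit_total: int
    at_risk: bool
    threshold: int


def score_audit(
    resp: AuditResponse, threshold: int = DEFAULT_AUDIT_THRESHOLD
) -> RiskClassification:
    """Total the 10 AUDIT items and flag risk at ``total >= threshold``."""
    total = resp.total
    return RiskClassification(
        actor_id=resp.actor_id, audit_total=total,
        at_risk=total >= threshold, threshold=threshold,
    )


def risk_proportions(
    classifications: Sequence[RiskClassification],
    actors: Iterable[Actor] | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """Counts and percentages of at-risk vs no-risk actors.

    With ``by`` (an actor attribute such as ``gender`` or ``setting``) the
    table is stratified; percentages are per stratum row and sum to 100.
    """
    if not classifications:
        raise UsageError("risk_proportions needs at least one classification")
    frame = pd.DataFrame(
        {"actor_id": [c.actor_id for c in classifications],
         "at_risk": [c.at_risk for c in classifications]}
    )
    if by is not None:
        if actors is None:
            raise UsageError(f"stratifying by {by!r} requires the actor table")
        values = {a.id: getattr(a, by) for a in actors}
        try:
            frame[by] = [values[i] for i in frame["actor_id"]]
        except KeyError as exc:
            raise ValidationError(f"classification for unknown actor {exc}") from None
        groups = frame.groupby(by)["at_risk"]
    else:
        groups = frame.assign(_all="all").groupby("_all")["at_risk"]
    rows = []
    for key, series in groups:
        n = len(series)
        k = int(series.sum())
        rows.append({
            ("group" if by is None else by): key,
            "n": n, "at_risk": k, "no_risk": n - k,
            "pct_at_risk": 100.0 * k / n, "pct_no_risk": 100.0 * (n - k) / n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chi-square association
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    continuity_corrected: bool


def chi_square(table, continuity: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default; enable Yates' correction with
    ``continuity=True`` (2x2 tables only, as usual).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise UsageError(f"contingency table must be at least 2x2, got shape {table.shape}")
    if (table < 0).any():
        raise ValidationError("contingency counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("contingency table has a zero row or column margin")
    res = stats.chi2_contingency(table, correction=continuity)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue),
        table=table, continuity_corrected=continuity,
    )


# ---------------------------------------------------------------------------
# power of the Pearson correlation test
# ---------------------------------------------------------------------------

def _r_density(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Hotelling's exact density of the sample correlation coefficient."""
    log_f = (
        np.log(n - 2) + special.gammaln(n - 1)
        + (n - 1) / 2 * np.log1p(-rho ** 2) + (n - 4) / 2 * np.log1p(-np.square(r))
        - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(log_f) * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)


def power_for_r(
    r_true: float, n: int, alpha: float = 0.05, method: str = "exact"
) -> float:
    """Power of the two-sided test of ρ = 0 at level ``alpha``.

    ``method="exact"`` integrates the exact sample-correlation density over
    the rejection region of the t test; ``method="fisher_z"`` uses the
    normal approximation on atanh(r) with SE 1/√(n−3).
    """
    if n < 4:
        raise UsageError(f"power_for_r requires n >= 4, got {n}")
    if not 0 < alpha < 1:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    if abs(r_true) >= 1:
        raise UsageError(f"|r_true| must be < 1, got {r_true}")
    if method == "fisher_z":
        z_crit = stats.norm.ppf(1 - alpha / 2)
        shift = np.arctanh(r_true) * np.sqrt(n - 3)
        return float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))
    if method != "exact":
        raise UsageError(f"unknown power method {method!r}")
    t_crit = stats.t.ppf(1 - alpha / 2, n - 2)
    r_crit = t_crit / np.sqrt(t_crit ** 2 + n - 2)
    upper, _ = integrate.quad(_r_density, r_crit, 1, args=(r_true, n))
    lower, _ = integrate.quad(_r_density, -1, -r_crit, args=(r_true, n))
    return float(min(1.0, upper + lower))


# ---------------------------------------------------------------------------
# cross-layer correlation
# ---------------------------------------------------------------------------

@dataclass
class LayerCorrelation:
    classroom: str
    layer_pair: tuple[str, str]
    vector_mode: str
    r: float
    n: int
    p_value: float
    power: float
    alpha: float


def _vectors(
    net_a: BinaryNetwork, net_b: BinaryNetwork, scheme: TransitivityScheme, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    if mode == "node_profile":
        return tuple(
            node_triad_profile(net, scheme)["transitive"].to_numpy(dtype=float)
            for net in (net_a, net_b)
        )
    if mode == "census_vector":
        return tuple(
            np.array([census(net, scheme).counts[c] for c in TRIAD_TYPES], dtype=float)
            for net in (net_a, net_b)
        )
    if mode == "tie_level":
        n = net_a.n_actors
        off = ~np.eye(n, dtype=bool)
        return (net_a.adjacency[off].astype(float), net_b.adjacency[off].astype(float))
    raise UsageError(f"unknown correlation mode {mode!r}; expected one of {CORRELATION_MODES}")


def transitive_profile_correlation(
    net_a: BinaryNetwork,
    net_b: BinaryNetwork,
    scheme: TransitivityScheme = DEFAULT_SCHEME,
    mode: str = "node_profile",
    alpha: float = 0.05,
    power_method: str = "exact",
) -> LayerCorrelation:
    """Pearson correlation between two layers of one classroom, with power.

    The default vectors are the per-actor transitive-triad participation
    counts of each layer, so n equals classroom size and power varies with
    it.  A zero-variance vector raises :class:`DegenerateInputError` rather
    than silently producing NaN.
    """
    align_orders(net_a.actor_order, net_b.actor_order)
    x, y = _vectors(net_a, net_b, scheme, mode)
    if len(x) < 3:
        raise UsageError(f"correlation needs vectors of length >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            f"zero-variance {mode} vector in classroom {net_a.classroom!r} "
            f"({net_a.layer} vs {net_b.layer}); correlation undefined"
        )
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if abs(r) >= 1:
        power = 1.0
    elif n >= 4:
        power = power_for_r(abs(r), n, alpha, method=power_method)
    else:
        power = float("nan")
    return LayerCorrelation(
        classroom=net_a.classroom, layer_pair=(net_a.layer, net_b.layer),
        vector_mode=mode, r=float(r), n=n, p_value=float(p),
        power=power, alpha=alpha,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional extension column in reports)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
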