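"""Classification of RNA-sensitive cysteines from site-level SILAC ratios.

Sites whose mean competition-condition SR reaches the cutoff are flagged
RNA-sensitive; significance against the 1:1 mixing control comes from a
one-tailed Mann-Whitney U test computed by exhaustive enumeration of all
orderings for small designs (e.g. all C(9,3) = 84 arrangements for the
3-vs-6 replicate layout), so that the minimum attainable p at that design
is exactly 1/84.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm

from pacce.constants import DEFAULT_BASE_SR_THRESHOLD, DEFAULT_SR_THRESHOLD
from pacce.sites import ModifiedSite, SiteQuant

__all__ = [
    "MannWhitneyResult",
    "RsCysCall",
    "exact_mann_whitney_one_tailed",
    "call_rs_cys",
    "call_base_competition",
    "rnase_control_comparison",
    "calls_to_frame",
]

EXACT_ENUMERATION_LIMIT = 1_000_000


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # exact_enumeration | permutation | normal_approx


@dataclass(frozen=True)
class RsCysCall:
    """RS-Cys classification for one site."""

    site: ModifiedSite
    mean_sr_pacce: float
    mean_sr_mixing: float | None
    rs_flag: bool
    p_value: float | None
    u_statistic: float | None
    n_pacce: int
    n_mixing: int
    method: str

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value is not None and self.p_value < alpha


def _u_statistic(treatment: np.ndarray, control: np.ndarray) -> float:
    """Number of (treatment, control) pairs with treatment > control.

    Ties between groups contribute 1/2 per pair (midrank convention).
    """
    t = treatment[:, None]
    c = control[None, :]
    return float(np.sum(t > c) + 0.5 * np.sum(t == c))


def exact_mann_whitney_one_tailed(
    treatment_values, control_values, exact_limit: int = EXACT_ENUMERATION_LIMIT
) -> MannWhitneyResult:
    """One-tailed Mann-Whitney U test, alternative: treatment > control.

    U counts (treatment, control) pairs with treatment exceeding control;
    p = P(U_null >= U_obs) over all C(n1+n2, n1) equally likely group
    assignments, enumerated exhaustively when that count is at most
    ``exact_limit``. With ties the exact null is replaced by a midrank
    permutation enumeration (with a warning); beyond the enumeration limit
    a continuity-corrected normal approximation is used.
    """
    treatment = np.asarray(treatment_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if treatment.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = treatment.size, control.size
    u_obs = _u_statistic(treatment, control)
    pooled = np.concatenate([treatment, control])
    has_ties = np.unique(pooled).size < pooled.size
    n_arrangements = comb(n1 + n2, n1)

    if n_arrangements <= exact_limit:
        if not has_ties:
            # tie-free null depends only on positions in the sorted pool
            offset = n1 * (n1 - 1) // 2
            hits = sum(
                1
                for subset in combinations(range(n1 + n2), n1)
                if sum(subset) - offset >= u_obs
            )
            method = "exact_enumeration"
        else:
            warnings.warn(
                "ties present; exact null replaced by midrank permutation p-value"
            )
            idx = range(n1 + n2)
            hits = 0
            for subset in combinations(idx, n1):
                chosen = set(subset)
                t = pooled[list(subset)]
                c = pooled[[i for i in idx if i not in chosen]]
                if _u_statistic(t, c) >= u_obs:
                    hits += 1
            method = "permutation"
        p = hits / n_arrangements
    else:
        mu = n1 * n2 / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        z = (u_obs - mu - 0.5) / np.sqrt(sigma2)
        p = float(norm.sf(z))
        method = "normal_approx"

    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return MannWhitneyResult(u_statistic=u_obs, p_value=p, n1=n1, n2=n2, method=method)


def _index_by_site(quants: list[SiteQuant]) -> dict[tuple[str, str], SiteQuant]:
    return {(q.site.protein_id, q.site.site_key): q for q in quants}


def call_rs_cys(
    site_quants: list[SiteQuant],
    sr_threshold: float = DEFAULT_SR_THRESHOLD,
    strict_gt: bool = False,
    pacce_condition: str = "pacce",
    mixing_condition: str = "mixing",
) -> list[RsCysCall]:
    """Call RNA-sensitive cysteines from paired competition/mixing quants.

    ``rs_flag`` is a threshold call on the mean competition-condition SR
    (inclusive at the cutoff unless ``strict_gt``). When a mixing-control
    counterpart exists, the one-tailed exact Mann-Whitney p-value over the
    per-replicate site SRs is attached; otherwise the p-value is absent.
    """
    pacce = _index_by_site([q for q in site_quants if q.condition == pacce_condition])
    mixing = _index_by_site([q for q in site_quants if q.condition == mixing_condition])

    calls: list[RsCysCall] = []
    for key in sorted(pacce):
        q = pacce[key]
        mean_sr = q.mean_sr
        rs_flag = mean_sr > sr_threshold if strict_gt else mean_sr >= sr_threshold
        m = mixing.get(key)
        if m is not None:
            result = exact_mann_whitney_one_tailed(
                list(q.per_replicate_sr.values()), list(m.per_replicate_sr.values())
            )
            calls.append(
                RsCysCall(
                    site=q.site,
                    mean_sr_pacce=mean_sr,
                    mean_sr_mixing=m.mean_sr,
                    rs_flag=rs_flag,
                    p_value=result.p_value,
                    u_statistic=result.u_statistic,
                    n_pacce=q.n_replicates,
                    n_mixing=m.n_replicates,
                    method=result.method,
                )
            )
        else:
            calls.append(
                RsCysCall(
                    site=q.site,
                    mean_sr_pacce=mean_sr,
                    mean_sr_mixing=None,
                    rs_flag=rs_flag,
                    p_value=None,
                    u_statistic=None,
                    n_pacce=q.n_replicates,
                    n_mixing=0,
                    method="threshold_only",
                )
            )
    return calls


def call_base_competition(
    site_quants: list[SiteQuant],
    sr_threshold: float = DEFAULT_BASE_SR_THRESHOLD,
    condition: str = "base_competition",
) -> list[RsCysCall]:
    """Threshold-only competition calls (SR >= 5 by default), no test."""
    calls = []
    for q in sorted(
        (q for q in site_quants if q.condition == condition),
        key=lambda q: (q.site.protein_id, q.site.site_key),
    ):
        calls.append(
            RsCysCall(
                site=q.site,
                mean_sr_pacce=q.mean_sr,
                mean_sr_mixing=None,
                rs_flag=q.mean_sr >= sr_threshold,
                p_value=None,
                u_statistic=None,
                n_pacce=q.n_replicates,
                n_mixing=0,
                method="threshold_only",
            )
        )
    return calls


def rnase_control_comparison(
    calls_with_rnase: list[RsCysCall], calls_without: list[RsCysCall]
) -> dict:
    """Compare RS-Cys yield between an RNase-treated arm and its control.

    Counts RS calls per arm over the shared site universe and reports the
    fraction of control RS calls lost under RNase. Non-identical universes
    trigger a warning and are intersected.
    """
    with_index = {(c.site.protein_id, c.site.site_key): c for c in calls_with_rnase}
    without_index = {(c.site.protein_id, c.site.site_key): c for c in calls_without}
    shared = sorted(set(with_index) & set(without_index))
    if set(with_index) != set(without_index):
        warnings.warn(
            f"site universes differ ({len(with_index)} vs {len(without_index)} sites); "
            f"using the intersection of {len(shared)}"
        )
    n_rs_with = sum(1 for k in shared if with_index[k].rs_flag)
    n_rs_without = sum(1 for k in shared if without_index[k].rs_flag)
    fraction_lost = (
        (n_rs_without - n_rs_with) / n_rs_without if n_rs_without else 0.0
    )
    return {
        "n_sites": len(shared),
        "n_rs_with_rnase": n_rs_with,
        "n_rs_without_rnase": n_rs_without,
        "fraction_lost": fraction_lost,
    }


def calls_to_frame(calls: list[RsCysCall]):
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "protein_id": c.site.protein_id,
                "site_key": c.site.site_key,
                "mean_sr_pacce": c.mean_sr_pacce,
                "mean_sr_mixing": "" if c.mean_sr_mixing is None else c.mean_sr_mixing,
                "u": "" if c.u_statistic is None else c.u_statistic,
                "p": "" if c.p_value is None else c.p_value,
                "rs_flag": c.rs_flag,
                "method": c.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "site_key",
            "mean_sr_pacce",
            "mean_sr_mixing",
            "u",
            "p",
            "rs_flag",
            "method",
        ],
    )
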