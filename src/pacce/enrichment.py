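"""Enrichment statistics: binomial domain enrichment with BH correction,
hypergeometric set-overlap significance, and site-position harmonization
helpers for comparisons against peptide-resolution methods."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, hypergeom

from pacce.constants import DEFAULT_Q_CUTOFF, DEFAULT_RBD_NAMES

__all__ = [
    "DomainAnnotation",
    "EnrichmentResult",
    "read_domain_table",
    "benjamini_hochberg",
    "binomial_domain_enrichment",
    "hypergeometric_overlap",
    "average_down_site",
    "idr_annotation_join",
    "results_to_frame",
]

Site = tuple[str, int]  # (protein_id, 1-based position)


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated span (1-based inclusive) on a protein."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    category: str = "other"  # RBD | other | IDR

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} exceeds end {self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class EnrichmentResult:
    domain_name: str
    x: int
    n: int
    p0: float
    p_value: float
    q_value: float
    enriched: bool


def read_domain_table(path, rbd_names=DEFAULT_RBD_NAMES) -> list[DomainAnnotation]:
    """Read a domain annotation TSV (protein_id, domain_name, start, end[, category])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "domain_name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in domain table: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        category = getattr(row, "category", None)
        if not category or category != category:  # NaN check
            category = "RBD" if row.domain_name in rbd_names else "other"
        out.append(
            DomainAnnotation(
                row.protein_id, row.domain_name, int(row.start), int(row.end), category
            )
        )
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1;
    the adjustment is order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _sites_in_spans(sites: list[Site], spans: list[DomainAnnotation]) -> int:
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for span in spans:
        by_protein.setdefault(span.protein_id, []).append(span)
    return sum(
        1
        for pid, pos in sites
        if any(s.contains(pos) for s in by_protein.get(pid, ()))
    )


def binomial_domain_enrichment(
    site_set: list[Site],
    background_site_set: list[Site],
    annotations: list[DomainAnnotation],
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> list[EnrichmentResult]:
    """Two-sided exact binomial enrichment of sites per domain name, with BH.

    For each domain name: x = sites of ``site_set`` inside any of its spans,
    n = |site_set|, p0 = fraction of ``background_site_set`` inside those
    spans. The two-sided p sums binomial point masses not exceeding the
    observed mass (minimum-likelihood convention). Domains never hit in the
    background receive the conservative pseudo-background
    p0 = 0.5 / |background|. Enrichment requires q < ``q_cutoff`` and an
    observed proportion above p0.
    """
    if not site_set:
        raise ValueError("site_set must be non-empty")
    if not background_site_set:
        raise ValueError("background_site_set must be non-empty")
    n = len(site_set)
    names = sorted({a.domain_name for a in annotations})
    raw: list[tuple[str, int, float, float]] = []
    for name in names:
        spans = [a for a in annotations if a.domain_name == name]
        x = _sites_in_spans(site_set, spans)
        bg = _sites_in_spans(background_site_set, spans)
        p0 = bg / len(background_site_set)
        if p0 == 0.0:
            p0 = 0.5 / len(background_site_set)
        p0 = min(p0, 1.0)
        p = binomtest(x, n, p0, alternative="two-sided").pvalue
        raw.append((name, x, p0, float(p)))

    q_values = benjamini_hochberg([r[3] for r in raw]) if raw else np.array([])
    results = []
    for (name, x, p0, p), q in zip(raw, q_values):
        results.append(
            EnrichmentResult(
                domain_name=name,
                x=x,
                n=n,
                p0=p0,
                p_value=p,
                q_value=float(q),
                enriched=bool(q < q_cutoff and x / n > p0),
            )
        )
    return results


def hypergeometric_overlap(
    universe_size: int, set_a_size: int, set_b_size: int, overlap: int
) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    Models drawing ``set_b_size`` items without replacement from a universe
    containing ``set_a_size`` successes.
    """
    if not (0 <= set_a_size <= universe_size and 0 <= set_b_size <= universe_size):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= overlap <= min(set_a_size, set_b_size)):
        raise ValueError("overlap must not exceed the smaller set")
    return float(hypergeom.sf(overlap - 1, universe_size, set_a_size, set_b_size))


def average_down_site(peptide_start: int, peptide_end: int) -> int:
    """Approximate site position: floor of the mean of peptide start/end."""
    if peptide_start > peptide_end:
        raise ValueError("peptide start must not exceed end")
    return (peptide_start + peptide_end) // 2


def idr_annotation_join(
    sites: list[Site], idr_spans: list[DomainAnnotation]
) -> dict[Site, bool]:
    """Per-site membership in intrinsically disordered regions (inclusive ends)."""
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for span in idr_spans:
        by_protein.setdefault(span.protein_id, []).append(span)
    return {
        (pid, pos): any(s.contains(pos) for s in by_protein.get(pid, ()))
        for pid, pos in sites
    }


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_name": r.domain_name,
                "x": r.x,
                "n": r.n,
                "p0": r.p0,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "enriched": r.enriched,
            }
            for r in results
        ],
        columns=["domain_name", "x", "n", "p0", "p_value", "q_value", "enriched"],
    )
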