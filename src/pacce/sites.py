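"""Site-level SILAC quantification of probe-modified peptides.

Converts PSM-level observations into protein-coordinate modified sites:
per-replicate site ratios are the median over all peptide forms covering
the site (fully tryptic, half-tryptic, missed cleavage), and the site
summary is the arithmetic mean of the per-replicate medians.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pacce.constants import (
    ADDUCT_LABELS,
    ADDUCT_TOLERANCE_DA,
    DEFAULT_SCORE_THRESHOLD,
    DEFAULT_SR_CAP,
    NUCLEOPHILIC_RESIDUES,
)

__all__ = [
    "PsmRecord",
    "ModifiedSite",
    "SiteQuant",
    "SrValue",
    "SchemaError",
    "UndefinedRatioError",
    "UnmappedPeptideError",
    "read_psm_table",
    "write_psm_table",
    "label_adduct",
    "compute_sr",
    "map_peptide_to_site",
    "aggregate_site_sr",
    "site_quants_to_frame",
    "site_quants_from_frame",
    "residue_selectivity",
]

PSM_COLUMNS = [
    "peptide",
    "mod_index",
    "mod_mass",
    "protein_ids",
    "intensity_light",
    "intensity_heavy",
    "replicate_id",
    "condition",
    "score",
    "cleavage_class",
]


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


class UndefinedRatioError(ValueError):
    """Both SILAC channels are absent; no ratio is defined."""


class UnmappedPeptideError(ValueError):
    """Peptide is not a substring of any listed protein."""


@dataclass(frozen=True)
class PsmRecord:
    """One probe-modified peptide observation with SILAC channel intensities."""

    peptide: str
    mod_index: int
    mod_mass: float
    protein_ids: tuple[str, ...]
    intensity_light: float | None
    intensity_heavy: float | None
    replicate_id: str
    condition: str
    score: float
    cleavage_class: str = "unknown"

    def __post_init__(self) -> None:
        if not (1 <= self.mod_index <= len(self.peptide)):
            raise ValueError(
                f"mod_index {self.mod_index} outside peptide of length {len(self.peptide)}"
            )
        if self.intensity_light is None and self.intensity_heavy is None:
            raise ValueError("at least one channel intensity must be present")

    @property
    def modified_residue(self) -> str:
        return self.peptide[self.mod_index - 1]

    @property
    def adduct_label(self) -> str:
        return label_adduct(self.mod_mass)


@dataclass(frozen=True)
class ModifiedSite:
    """A protein-coordinate modified site, e.g. C957 of a given accession."""

    protein_id: str
    residue: str
    position: int
    ambiguous: bool = False

    @property
    def site_key(self) -> str:
        return f"{self.residue}{self.position}"


@dataclass(frozen=True)
class SrValue:
    value: float
    capped: bool = False


@dataclass
class SiteQuant:
    """Per-condition quantification of one modified site."""

    site: ModifiedSite
    condition: str
    per_replicate_sr: dict[str, float]
    n_forms: int
    capped: bool = False

    @property
    def mean_sr(self) -> float:
        return float(np.mean(list(self.per_replicate_sr.values())))

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate_sr)


def label_adduct(mod_mass: float, tolerance: float = ADDUCT_TOLERANCE_DA) -> str:
    """Match a modification mass to a known probe adduct within tolerance."""
    for label, mass in ADDUCT_LABELS.items():
        if abs(mod_mass - mass) <= tolerance:
            return label
    return "other"


def _parse_intensity(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    out = float(value)
    if out < 0:
        raise ValueError("negative intensity")
    return out


def read_psm_table(
    path, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[PsmRecord]:
    """Read a PSM TSV, dropping rows with ``score < score_threshold``.

    The score filter is inclusive at the threshold (score >= threshold is
    kept). Malformed rows (bad indices, negative intensities, missing
    channels) are rejected with a warning that carries the 1-based data
    line number. A missing required column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[PsmRecord] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            score = float(row.score)
            if score < score_threshold:
                continue
            records.append(
                PsmRecord(
                    peptide=row.peptide,
                    mod_index=int(row.mod_index),
                    mod_mass=float(row.mod_mass),
                    protein_ids=tuple(p for p in row.protein_ids.split(";") if p),
                    intensity_light=_parse_intensity(row.intensity_light),
                    intensity_heavy=_parse_intensity(row.intensity_heavy),
                    replicate_id=row.replicate_id,
                    condition=row.condition,
                    score=score,
                    cleavage_class=row.cleavage_class or "unknown",
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"rejected malformed row at data line {line_no}: {exc}")
    return records


def write_psm_table(records: list[PsmRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "peptide": r.peptide,
                "mod_index": r.mod_index,
                "mod_mass": r.mod_mass,
                "protein_ids": ";".join(r.protein_ids),
                "intensity_light": "" if r.intensity_light is None else repr(r.intensity_light),
                "intensity_heavy": "" if r.intensity_heavy is None else repr(r.intensity_heavy),
                "replicate_id": r.replicate_id,
                "condition": r.condition,
                "score": r.score,
                "cleavage_class": r.cleavage_class,
            }
        )
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def compute_sr(
    intensity_light: float | None,
    intensity_heavy: float | None,
    orientation: str = "light",
    cap: float = DEFAULT_SR_CAP,
) -> SrValue | None:
    """SILAC ratio = probe-only channel / competition channel.

    ``orientation`` names the probe-only channel ("light" or "heavy").
    A missing/zero competition channel with a present probe channel yields
    the capped ratio; a missing probe channel returns ``None`` (the record
    is dropped by callers); both channels absent is an error.
    """
    if orientation not in ("light", "heavy"):
        raise ValueError(f"orientation must be 'light' or 'heavy', got {orientation!r}")
    if intensity_light is None and intensity_heavy is None:
        raise UndefinedRatioError("both channel intensities are absent")
    probe, comp = (
        (intensity_light, intensity_heavy)
        if orientation == "light"
        else (intensity_heavy, intensity_light)
    )
    if probe is None or probe == 0:
        return None
    if comp is None or comp == 0:
        return SrValue(float(cap), capped=True)
    return SrValue(float(probe) / float(comp), capped=False)


def map_peptide_to_site(psm: PsmRecord, proteome: dict[str, str]) -> list[ModifiedSite]:
    """Locate the modified residue in protein coordinates.

    Searches every occurrence of the peptide in every listed protein; a
    peptide that maps to more than one (protein, offset) pair yields one
    site per mapping, all flagged ambiguous.
    """
    hits: list[tuple[str, int]] = []
    for pid in psm.protein_ids:
        seq = proteome.get(pid)
        if seq is None:
            continue
        offset = seq.find(psm.peptide)
        while offset != -1:
            hits.append((pid, offset))
            offset = seq.find(psm.peptide, offset + 1)
    if not hits:
        raise UnmappedPeptideError(
            f"peptide {psm.peptide!r} not found in proteins {psm.protein_ids}"
        )
    ambiguous = len(hits) > 1
    residue = psm.modified_residue
    return [
        ModifiedSite(pid, residue, offset + psm.mod_index, ambiguous=ambiguous)
        for pid, offset in hits
    ]


def aggregate_site_sr(
    records: list[PsmRecord],
    proteome: dict[str, str],
    orientation: str = "light",
    cap: float = DEFAULT_SR_CAP,
) -> list[SiteQuant]:
    """Aggregate PSM records into site-level quantifications.

    Within a (site, condition, replicate) group the site SR is the median
    of the SRs of all peptide forms covering the site; even-sized groups
    take the midpoint of the two central values. The result is invariant
    to record order.
    """
    groups: dict[tuple[str, str, int, bool, str], dict[str, list[SrValue]]] = {}
    for rec in records:
        sr = compute_sr(rec.intensity_light, rec.intensity_heavy, orientation, cap)
        if sr is None:
            continue
        for site in map_peptide_to_site(rec, proteome):
            key = (site.protein_id, site.residue, site.position, site.ambiguous, rec.condition)
            groups.setdefault(key, {}).setdefault(rec.replicate_id, []).append(sr)

    quants: list[SiteQuant] = []
    for (pid, residue, position, ambiguous, condition), by_rep in sorted(groups.items()):
        per_rep = {
            rep: float(np.median([s.value for s in values]))
            for rep, values in sorted(by_rep.items())
        }
        n_forms = sum(len(v) for v in by_rep.values())
        capped = any(s.capped for v in by_rep.values() for s in v)
        quants.append(
            SiteQuant(
                site=ModifiedSite(pid, residue, position, ambiguous),
                condition=condition,
                per_replicate_sr=per_rep,
                n_forms=n_forms,
                capped=capped,
            )
        )
    return quants


def site_quants_to_frame(quants: list[SiteQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        rows.append(
            {
                "protein_id": q.site.protein_id,
                "site_key": q.site.site_key,
                "condition": q.condition,
                "replicate_srs": json.dumps(q.per_replicate_sr, sort_keys=True),
                "mean_sr": q.mean_sr,
                "n_forms": q.n_forms,
                "ambiguous": q.site.ambiguous,
                "capped": q.capped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "site_key",
            "condition",
            "replicate_srs",
            "mean_sr",
            "n_forms",
            "ambiguous",
            "capped",
        ],
    )


def site_quants_from_frame(df: pd.DataFrame) -> list[SiteQuant]:
    """Inverse of :func:`site_quants_to_frame` (site_key parses as residue+position)."""
    quants = []
    for row in df.itertuples(index=False):
        key = str(row.site_key)
        quants.append(
            SiteQuant(
                site=ModifiedSite(
                    protein_id=str(row.protein_id),
                    residue=key[0],
                    position=int(key[1:]),
                    ambiguous=bool(row.ambiguous),
                ),
                condition=str(row.condition),
                per_replicate_sr=json.loads(row.replicate_srs),
                n_forms=int(row.n_forms),
                capped=bool(row.capped),
            )
        )
    return quants


def residue_selectivity(sites: list[ModifiedSite]) -> dict[str, float]:
    """Fraction of modified sites per residue, over the nucleophilic set.

    Only the 13 nucleophilic residues eligible for probe modification are
    counted; fractions sum to 1 over the residues observed. Empty input
    yields an empty table.
    """
    counted = [s for s in sites if s.residue in NUCLEOPHILIC_RESIDUES]
    if not counted:
        return {}
    total = len(counted)
    fractions: dict[str, float] = {}
    for s in counted:
        fractions[s.residue] = fractions.get(s.residue, 0.0) + 1.0
    return {res: n / total for res, n in sorted(fractions.items())}
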