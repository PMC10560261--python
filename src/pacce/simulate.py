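"""Synthetic ground-truth data for the competition-chemoproteomics pipeline.

Generates random proteomes with planted RNA-sensitive cysteines, in-silico
tryptic digests (fully tryptic, half-tryptic and missed-cleavage forms),
SILAC PSM tables with a multiplicative competition model, and toy
protein-RNA coordinate files with planted minimum Cys-RNA distances.
Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np

from pacce.constants import CEP_CYS_ADDUCT_DA, DEFAULT_RBD_NAMES, NUCLEOPHILIC_RESIDUES
from pacce.sites import PsmRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "PeptideForm",
    "generate_proteome",
    "digest_protein",
    "generate_psm_table",
    "generate_toy_structure",
    "proteome_to_fasta",
    "truths_to_frame",
    "domain_table",
    "rbp_table",
]

# Residues drawn for the sequence backbone; Cys is inserted explicitly so
# that cysteine placement is controlled.
_BACKBONE_ALPHABET = "ADEFGHIKLMNQRSTVWY"
_OTHER_DOMAIN_NAMES = ("Ubiquitin-like", "Zinc finger", "Protein kinase")


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration fails validation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study design of three mixing-control replicates
    and six competition (PACCE) replicates.
    """

    n_proteins: int = 20
    n_mix_replicates: int = 3
    n_pacce_replicates: int = 6
    noise_cv: float = 0.2
    half_tryptic_rate: float = 0.25
    max_missed_cleavages: int = 2
    rs_fraction: float = 0.2
    seed: int = 0
    competition_factor_range: tuple[float, float] = (2.0, 20.0)
    non_cys_rate: float = 0.0
    rnase_mode: bool = False
    min_length: int = 60
    max_length: int = 240
    cys_density: float = 0.04
    rbp_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise InvalidConfigError("n_proteins must be positive")
        if self.n_mix_replicates <= 0 or self.n_pacce_replicates <= 0:
            raise InvalidConfigError("replicate counts must be positive")
        if not 0.0 <= self.rs_fraction <= 1.0:
            raise InvalidConfigError("rs_fraction must lie in [0, 1]")
        if not 0.0 <= self.half_tryptic_rate <= 1.0:
            raise InvalidConfigError("half_tryptic_rate must lie in [0, 1]")
        if not 0.0 <= self.non_cys_rate < 1.0:
            raise InvalidConfigError("non_cys_rate must lie in [0, 1)")
        if self.noise_cv < 0.0:
            raise InvalidConfigError("noise_cv must be non-negative")
        if self.max_missed_cleavages < 0:
            raise InvalidConfigError("max_missed_cleavages must be non-negative")
        lo, hi = self.competition_factor_range
        if not 1.0 <= lo <= hi:
            raise InvalidConfigError("competition_factor_range must satisfy 1 <= lo <= hi")
        if not 1 <= self.min_length <= self.max_length:
            raise InvalidConfigError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic protein."""

    protein_id: str
    sequence: str
    cys_positions: tuple[int, ...]
    rs_cys_flags: tuple[bool, ...]
    competition_factor: tuple[float, ...]
    domain_spans: tuple[tuple[str, int, int], ...] = ()
    rbp_flag: bool = False

    def __post_init__(self) -> None:
        for pos in self.cys_positions:
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "C":
                raise ValueError(f"cys position {pos} does not point at a Cys")
        if not (len(self.cys_positions) == len(self.rs_cys_flags) == len(self.competition_factor)):
            raise ValueError("per-Cys vectors must have equal length")
        for flag, factor in zip(self.rs_cys_flags, self.competition_factor):
            if factor <= 0:
                raise ValueError("competition factors must be positive")
            if not flag and factor != 1.0:
                raise ValueError("insensitive Cys must have competition_factor 1.0")
        for name, start, end in self.domain_spans:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"domain span {name} [{start}, {end}] out of range")

    def factor_at(self, position: int) -> float:
        return self.competition_factor[self.cys_positions.index(position)]


@dataclass(frozen=True)
class PeptideForm:
    """One peptide form produced by the in-silico digest (start is 1-based)."""

    sequence: str
    start: int
    cleavage_class: str  # fully_tryptic | half_tryptic | missed_cleavage

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def generate_proteome(config: SimulationConfig) -> list[SyntheticTruth]:
    """Draw ``config.n_proteins`` random proteins with planted RS-Cys.

    Each protein carries at least one cysteine. A fraction ``rs_fraction``
    of all cysteines is flagged RNA-sensitive, with competition factors
    drawn uniformly from ``competition_factor_range``; in ``rnase_mode``
    the flags are kept but every factor is forced to 1.0 (no competition),
    emulating an RNase-treated control arm.
    """
    rng = np.random.default_rng(config.seed)
    truths: list[SyntheticTruth] = []
    for i in range(config.n_proteins):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        residues = list(rng.choice(list(_BACKBONE_ALPHABET), size=length))
        is_cys = rng.random(length) < config.cys_density
        if not is_cys.any():
            is_cys[int(rng.integers(0, length))] = True
        for j in np.flatnonzero(is_cys):
            residues[j] = "C"
        sequence = "".join(residues)
        cys_positions = tuple(int(j) + 1 for j in np.flatnonzero(is_cys))

        flags = tuple(bool(b) for b in rng.random(len(cys_positions)) < config.rs_fraction)
        lo, hi = config.competition_factor_range
        drawn = rng.uniform(lo, hi, size=len(cys_positions))
        factors = tuple(
            1.0 if (not f or config.rnase_mode) else float(x) for f, x in zip(flags, drawn)
        )
        if config.rnase_mode:
            flags = tuple(flags)  # flags preserved; only the effect is removed

        n_domains = int(rng.integers(0, 3))
        spans = []
        pool = DEFAULT_RBD_NAMES + _OTHER_DOMAIN_NAMES
        for _ in range(n_domains):
            name = str(rng.choice(pool))
            start = int(rng.integers(1, max(2, length - 20)))
            end = min(length, start + int(rng.integers(15, 60)))
            spans.append((name, start, end))
        rbp_flag = bool(rng.random() < config.rbp_fraction)

        truths.append(
            SyntheticTruth(
                protein_id=f"SYN{i + 1:04d}",
                sequence=sequence,
                cys_positions=cys_positions,
                rs_cys_flags=flags,
                competition_factor=factors,
                domain_spans=tuple(spans),
                rbp_flag=rbp_flag,
            )
        )
    return truths


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts after ``sequence[i]``.

    Cuts after K/R except when the next residue is proline.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_protein(truth: SyntheticTruth, config: SimulationConfig) -> list[PeptideForm]:
    """In-silico tryptic digest of one protein.

    Emits all fully tryptic segments, all missed-cleavage joins of up to
    ``max_missed_cleavages`` adjacent segments, and — for Cys-containing
    fully tryptic peptides, at rate ``half_tryptic_rate`` — one half-tryptic
    form with a single non-tryptic terminus that still covers a cysteine.
    Every cysteine is covered by at least one form (the tryptic tiling).
    """
    seq = truth.sequence
    if not seq:
        raise ValueError("sequence must be non-empty")
    cuts = cleavage_sites(seq)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    segments = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]

    forms: list[PeptideForm] = []
    for k, (a, b) in enumerate(segments):
        forms.append(PeptideForm(seq[a:b], a + 1, "fully_tryptic"))
        for m in range(1, config.max_missed_cleavages + 1):
            if k + m < len(segments):
                _, b2 = segments[k + m]
                forms.append(PeptideForm(seq[a:b2], a + 1, "missed_cleavage"))

    # Half-tryptic forms: deterministic per protein, independent of order.
    rng = np.random.default_rng([config.seed, zlib.crc32(truth.protein_id.encode())])
    for form in [f for f in forms if f.cleavage_class == "fully_tryptic"]:
        cys_local = [i for i, r in enumerate(form.sequence) if r == "C"]
        if not cys_local or len(form.sequence) < 2:
            continue
        if rng.random() >= config.half_tryptic_rate:
            continue
        # trim from the N terminus while keeping the first Cys, else from C.
        first, last = cys_local[0], cys_local[-1]
        if first >= 1:
            k = int(rng.integers(1, first + 1))
            forms.append(PeptideForm(form.sequence[k:], form.start + k, "half_tryptic"))
        elif last <= len(form.sequence) - 2:
            k = int(rng.integers(1, len(form.sequence) - last))
            forms.append(PeptideForm(form.sequence[:-k], form.start, "half_tryptic"))
    return forms


def _noise_sampler(rng: np.random.Generator, cv: float):
    if cv == 0.0:
        return lambda: 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = -0.5 * sigma * sigma  # mean-one multiplier with exact CV = cv
    return lambda: float(rng.lognormal(mu, sigma))


def generate_psm_table(
    truths: list[SyntheticTruth], config: SimulationConfig
) -> list[PsmRecord]:
    """Simulate the PSM-level SILAC table for a synthetic proteome.

    For each covered Cys, each peptide form yields one record per replicate
    in both conditions. The light channel is the probe-only channel; in the
    competition ("pacce") condition the heavy channel is divided by the
    site's planted competition factor, while in the 1:1 mixing control both
    channels share the same mean. A minority of records (``non_cys_rate``
    of emitted sites) carries non-Cys residue assignments to exercise
    residue-selectivity reporting.
    """
    rng = np.random.default_rng([config.seed, 1])
    noise = _noise_sampler(rng, config.noise_cv)
    records: list[PsmRecord] = []
    n_cys_sites = 0

    for truth in truths:
        forms = digest_protein(truth, config)
        for pos, factor in zip(truth.cys_positions, truth.competition_factor):
            covering = [f for f in forms if f.covers(pos)]
            n_cys_sites += 1
            for form in covering:
                base = float(10.0 ** rng.uniform(4.5, 6.5))
                for cond, n_reps, fold in (
                    ("mixing", config.n_mix_replicates, 1.0),
                    ("pacce", config.n_pacce_replicates, factor),
                ):
                    for r in range(1, n_reps + 1):
                        records.append(
                            PsmRecord(
                                peptide=form.sequence,
                                mod_index=pos - form.start + 1,
                                mod_mass=CEP_CYS_ADDUCT_DA,
                                protein_ids=(truth.protein_id,),
                                intensity_light=base * noise(),
                                intensity_heavy=(base / fold) * noise(),
                                replicate_id=f"{cond}_{r}",
                                condition=cond,
                                score=float(rng.uniform(650.0, 1000.0)),
                                cleavage_class=form.cleavage_class,
                            )
                        )

    if config.non_cys_rate > 0.0 and n_cys_sites:
        candidates = []
        for truth in truths:
            for i, res in enumerate(truth.sequence):
                if res != "C" and res in NUCLEOPHILIC_RESIDUES:
                    candidates.append((truth, i + 1))
        want = round(n_cys_sites * config.non_cys_rate / (1.0 - config.non_cys_rate))
        take = min(want, len(candidates))
        for idx in rng.choice(len(candidates), size=take, replace=False):
            truth, pos = candidates[int(idx)]
            form = next(
                f for f in digest_protein(truth, config)
                if f.covers(pos) and f.cleavage_class == "fully_tryptic"
            )
            base = float(10.0 ** rng.uniform(4.5, 6.5))
            records.append(
                PsmRecord(
                    peptide=form.sequence,
                    mod_index=pos - form.start + 1,
                    mod_mass=CEP_CYS_ADDUCT_DA,
                    protein_ids=(truth.protein_id,),
                    intensity_light=base * noise(),
                    intensity_heavy=base * noise(),
                    replicate_id="mixing_1",
                    condition="mixing",
                    score=float(rng.uniform(650.0, 1000.0)),
                    cleavage_class="fully_tryptic",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Toy protein-RNA structures


class InvalidPlantError(ValueError):
    """Raised on duplicate or invalid planted distance specifications."""


def _pdb_atom_line(serial, name, resname, chain, resseq, x, y, z, element) -> str:
    name4 = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name4} {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def generate_toy_structure(
    planted: list[tuple[str, int, float]], rna_chain: str = "R"
) -> str:
    """Build a PDB-format text with planted minimum Cys-RNA distances.

    ``planted`` holds (protein_chain_id, residue_number, target_distance)
    triples. For every planted site a CYS residue with an SG atom is placed
    far from all other sites, and the RNA chain carries exactly one atom at
    ``target_distance`` from that SG; all other RNA atoms are strictly
    farther from every SG, so the planted value is the unambiguous minimum.
    """
    seen = set()
    for chain, resnum, dist in planted:
        if dist <= 0:
            raise InvalidPlantError(f"target distance must be positive, got {dist}")
        if abs(dist - round(dist, 3)) > 1e-9:
            # PDB coordinates carry 3 decimals; finer targets cannot round-trip
            raise InvalidPlantError(
                f"target distance {dist} not representable at PDB precision (0.001 A)"
            )
        if (chain, resnum) in seen:
            raise InvalidPlantError(f"duplicate planted site ({chain}, {resnum})")
        if chain == rna_chain:
            raise InvalidPlantError("protein chain id collides with the RNA chain id")
        seen.add((chain, resnum))

    lines = ["HEADER    TOY PROTEIN/RNA COMPLEX"]
    serial = 1
    rna_atoms: list[tuple[str, str, int, float, float, float, str]] = []
    rna_names = "AUGC"

    if planted:
        spacing = 2.0 * max(d for _, _, d in planted) + 100.0
    else:
        spacing = 100.0

    by_chain: dict[str, list[tuple[int, float, float]]] = {}
    for i, (chain, resnum, dist) in enumerate(planted):
        by_chain.setdefault(chain, []).append((resnum, dist, i * spacing))

    for chain in sorted(by_chain):
        for resnum, dist, x0 in sorted(by_chain[chain]):
            for name, dx, dy, elem in (
                ("N", -2.4, 1.2, "N"),
                ("CA", -1.6, 0.3, "C"),
                ("CB", -0.8, 0.9, "C"),
                ("SG", 0.0, 0.0, "S"),
            ):
                lines.append(
                    _pdb_atom_line(serial, name, "CYS", chain, resnum, x0 + dx, dy, 0.0, elem)
                )
                serial += 1
            # planted nearest atom plus decoys well off the minimum
            k = len(rna_atoms)
            resname = rna_names[(k // 3) % 4]
            rna_atoms.append((resname, "O2'", k // 3 + 1, x0 + dist, 0.0, 0.0, "O"))
            rna_atoms.append((resname, "C1'", k // 3 + 1, x0 + dist, 60.0, 0.0, "C"))
            rna_atoms.append((resname, "P", k // 3 + 1, x0 + dist, 80.0, 0.0, "P"))
        lines.append(f"TER   {serial:5d}")
        serial += 1

    if not planted:
        # still a valid complex: one Gly residue, one RNA residue, zero Cys
        for name, x, elem in (("N", 0.0, "N"), ("CA", 1.4, "C"), ("C", 2.5, "C"), ("O", 3.6, "O")):
            lines.append(_pdb_atom_line(serial, name, "GLY", "A", 1, x, 0.0, 0.0, elem))
            serial += 1
        rna_atoms = [("A", "O2'", 1, 50.0, 0.0, 0.0, "O"), ("A", "C1'", 1, 51.5, 0.0, 0.0, "C")]

    for resname, name, resseq, x, y, z, elem in rna_atoms:
        lines.append(_pdb_atom_line(serial, name, resname, rna_chain, resseq, x, y, z, elem))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Serialization helpers


def proteome_to_fasta(truths: list[SyntheticTruth]) -> str:
    """Render the synthetic proteome as FASTA text."""
    chunks = []
    for t in truths:
        chunks.append(f">{t.protein_id}")
        for i in range(0, len(t.sequence), 60):
            chunks.append(t.sequence[i : i + 60])
    return "\n".join(chunks) + "\n"


def truths_to_frame(truths: list[SyntheticTruth]):
    """Ground-truth table with one row per planted Cys site."""
    import pandas as pd

    rows = []
    for t in truths:
        for pos, flag, factor in zip(t.cys_positions, t.rs_cys_flags, t.competition_factor):
            rows.append(
                {
                    "protein_id": t.protein_id,
                    "site_key": f"C{pos}",
                    "position": pos,
                    "rs_cys": flag,
                    "competition_factor": factor,
                    "rbp_flag": t.rbp_flag,
                }
            )
    return pd.DataFrame(rows)


def domain_table(truths: list[SyntheticTruth]):
    """UniProt-style domain annotation table for the synthetic proteome."""
    import pandas as pd

    rows = []
    for t in truths:
        for name, start, end in t.domain_spans:
            rows.append(
                {
                    "protein_id": t.protein_id,
                    "domain_name": name,
                    "start": start,
                    "end": end,
                    "category": "RBD" if name in DEFAULT_RBD_NAMES else "other",
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "domain_name", "start", "end", "category"])


def rbp_table(truths: list[SyntheticTruth]):
    """Reference RBP membership table (protein_id, source)."""
    import pandas as pd

    rows = [{"protein_id": t.protein_id, "source": "synthetic"} for t in truths if t.rbp_flag]
    return pd.DataFrame(rows, columns=["protein_id", "source"])


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a config from a parsed TOML/dict, ignoring unknown keys."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in mapping.items() if k in fields}
    if "competition_factor_range" in kwargs:
        kwargs["competition_factor_range"] = tuple(kwargs["competition_factor_range"])
    return SimulationConfig(**kwargs)
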