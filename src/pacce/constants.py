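"""Shared constants: probe adduct masses, residue sets, default thresholds."""

# Probe adduct monoisotopic masses (Da), matched within ADDUCT_TOLERANCE_DA.
CEP_CYS_ADDUCT_DA = 604.2637
IA_ALKYNE_ADDUCT_DA = 509.2962

# Desthiobiotin probe fragment peaks (Da).
FRAGMENT_ADDUCTS_DA = {
    "d1": 197.129,
    "d2": 240.1712,
    "d3": 425.2638,
    "d4": 453.2825,
}

ADDUCT_LABELS = {
    "CEP": CEP_CYS_ADDUCT_DA,
    "IA": IA_ALKYNE_ADDUCT_DA,
    **FRAGMENT_ADDUCTS_DA,
}

ADDUCT_TOLERANCE_DA = 0.01

# Nucleophilic residues considered for probe modification-site assignment.
NUCLEOPHILIC_RESIDUES = frozenset("CDEHKMNQRSTWY")

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL "
    "MSE SEC PYL".split()
)
RNA_RESIDUE_NAMES = frozenset({"A", "U", "G", "C", "I", "PSU", "4SU"})
DNA_RESIDUE_NAMES = frozenset({"DA", "DT", "DG", "DC", "DU", "DI"})

# Default analysis thresholds.
DEFAULT_SCORE_THRESHOLD = 600.0
DEFAULT_SR_CAP = 20.0
DEFAULT_SR_THRESHOLD = 2.0
DEFAULT_BASE_SR_THRESHOLD = 5.0
DEFAULT_Q_CUTOFF = 0.01
DEFAULT_RESOLUTION_MAX = 3.0

# Domain names treated as RNA-binding domains by default.
DEFAULT_RBD_NAMES = (
    "KH",
    "RRM",
    "Helicase C-terminal",
    "Helicase ATP-binding",
    "double-stranded RNA-binding",
)
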