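import numpy as np
import pytest

from pacce import simulate, sites


@pytest.fixture
def noise_free_config():
    return simulate.SimulationConfig(n_proteins=6, seed=11, noise_cv=0.0, rs_fraction=0.4)


@pytest.fixture
def noise_free_dataset(noise_free_config):
    truths = simulate.generate_proteome(noise_free_config)
    psms = simulate.generate_psm_table(truths, noise_free_config)
    proteome = {t.protein_id: t.sequence for t in truths}
    return truths, psms, proteome


def make_truth(sequence, protein_id="P1", factors=None):
    """Build a SyntheticTruth for a literal sequence; factors map position->fold."""
    cys = tuple(i + 1 for i, r in enumerate(sequence) if r == "C")
    factors = factors or {}
    comp = tuple(float(factors.get(p, 1.0)) for p in cys)
    flags = tuple(f != 1.0 for f in comp)
    return simulate.SyntheticTruth(
        protein_id=protein_id,
        sequence=sequence,
        cys_positions=cys,
        rs_cys_flags=flags,
        competition_factor=comp,
    )


def make_quant(protein_id, site_key, condition, replicate_srs, ambiguous=False):
    return sites.SiteQuant(
        site=sites.ModifiedSite(
            protein_id, site_key[0], int(site_key[1:]), ambiguous=ambiguous
        ),
        condition=condition,
        per_replicate_sr={f"{condition}_{i}": float(v) for i, v in enumerate(replicate_srs, 1)},
        n_forms=len(replicate_srs),
    )
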