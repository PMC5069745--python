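import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protsip.psm_io import PsmRecord, SampleTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_psm(
    enrichment: float,
    sample_id: str = "S1",
    spectrum_id: str = "s1",
    peptide: str = "PEPTIDEK",
    proteins: tuple[str, ...] = ("pA",),
    taxon_order: str | None = "OrderA",
    taxon_genus: str | None = "GenusA",
    cogs: frozenset[str] = frozenset(),
    weight: float = 1.0,
) -> PsmRecord:
    return PsmRecord(
        sample_id=sample_id,
        spectrum_id=spectrum_id,
        peptide=peptide,
        protein_ids=proteins,
        enrichment_pct=enrichment,
        taxon_order=taxon_order,
        taxon_genus=taxon_genus,
        cog_categories=cogs,
        balanced_weight=weight,
    )


def make_sample(enrichments, taxa=None, sample_id="S1") -> SampleTable:
    """Unit-weight sample with one PSM per enrichment value."""
    taxa = taxa or ["OrderA"] * len(enrichments)
    psms = [
        make_psm(
            e,
            sample_id=sample_id,
            spectrum_id=f"s{i}",
            taxon_order=t,
            taxon_genus=None if t is None else f"g_{t}",
        )
        for i, (e, t) in enumerate(zip(enrichments, taxa))
    ]
    return SampleTable(sample_id=sample_id, psms=psms)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_experiment():
    """A scaled-down default experiment shared across tests."""
    from protsip.synthetic import default_config, generate_experiment

    config = default_config(seed=42, n_psm=2000)
    frames, truth = generate_experiment(config)
    return config, frames, truth
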