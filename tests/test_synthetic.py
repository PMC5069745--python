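"""Generator determinism, distributional fidelity, and pipeline compatibility."""

import numpy as np
import pytest

from protsip.labeling import HISTOGRAM_BIN_EDGES, enrichment_histogram
from protsip.psm_io import tables_from_frame
from protsip.synthetic import (
    SyntheticConfig,
    SyntheticConfigError,
    TaxonProfile,
    config_from_yaml,
    default_config,
    generate_experiment,
    generate_sample,
    sample_enrichment,
)


def one_taxon_config(p_label, mixture, seed=0, n_psm=500):
    taxon = TaxonProfile(
        taxon_order="OrdA", taxon_genus="GenA", proportion=1.0,
        p_label=p_label, enrichment_mixture=mixture,
    )
    from protsip.synthetic import SamplePlan

    return SyntheticConfig(
        taxa=(taxon,), plans=(SamplePlan("S1", "X", 15),), n_psm=n_psm, seed=seed,
    )


class TestSampleEnrichment:
    def test_zero_spread_always_mode(self, rng):
        profile = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=1.0, p_label=1.0,
            enrichment_mixture=((1.0, 35.0, 0.0),),
        )
        assert all(
            sample_enrichment(profile, True, rng) == 35.0 for _ in range(50)
        )

    def test_unlabeled_always_below_threshold(self, rng):
        profile = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=1.0, p_label=0.0,
            enrichment_mixture=((1.0, 35.0, 0.0),),
        )
        draws = [sample_enrichment(profile, False, rng) for _ in range(500)]
        assert max(draws) < 2.0
        assert min(draws) > 0.0

    def test_labeled_on_grid_within_bounds(self, rng):
        profile = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=1.0, p_label=1.0,
            enrichment_mixture=((0.5, 17.0, 4.0), (0.5, 60.0, 10.0)),
        )
        draws = np.array([sample_enrichment(profile, True, rng) for _ in range(500)])
        assert np.all(draws == np.rint(draws))
        assert draws.min() >= 2.0 and draws.max() <= 100.0

    def test_bimodal_modes_recovered(self, rng):
        profile = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=1.0, p_label=1.0,
            enrichment_mixture=((0.5, 17.0, 4.0), (0.5, 60.0, 4.0)),
        )
        draws = np.array(
            [sample_enrichment(profile, True, rng) for _ in range(10_000)]
        )
        hist = enrichment_histogram(draws)
        for mode in (17.0, 60.0):
            i = int(np.searchsorted(HISTOGRAM_BIN_EDGES, mode, side="right")) - 1
            assert hist.proportions[i] >= hist.proportions[i - 1]
            assert hist.proportions[i] >= hist.proportions[i + 1]

    def test_bad_mixture_weights_rejected(self):
        profile = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=1.0, p_label=1.0,
            enrichment_mixture=((0.5, 17.0, 4.0), (0.2, 60.0, 4.0)),
        )
        with pytest.raises(SyntheticConfigError):
            profile.validate()


class TestGenerateSample:
    def test_p_label_zero_gives_zero_frequency(self):
        config = one_taxon_config(0.0, ((1.0, 35.0, 0.0),))
        frame, _ = generate_sample(config, config.plans[0])
        assert (frame["enrichment_pct"] < 2.0).all()

    def test_p_label_one_single_mode(self):
        config = one_taxon_config(1.0, ((1.0, 35.0, 0.0),))
        frame, truth = generate_sample(config, config.plans[0])
        assert (frame["enrichment_pct"] == 35.0).all()
        assert truth["n_labeled_realized"].iloc[0] == len(frame)

    def test_per_taxon_frequencies_within_3se(self):
        config = default_config(seed=9, n_psm=20_000)
        frame, truth = generate_sample(config, config.plans[0])
        labeled = frame["enrichment_pct"] >= 2.0
        for row in truth.itertuples():
            mask = (frame["taxon_order"] == row.taxon_order) & (
                frame["taxon_genus"] == row.taxon_genus
            )
            n = int(mask.sum())
            observed = labeled[mask].mean()
            se = np.sqrt(row.p_label * (1 - row.p_label) / n)
            assert observed == pytest.approx(row.p_label, abs=max(3 * se, 1e-3))

    def test_taxon_proportions_within_3se(self):
        config = default_config(seed=10, n_psm=20_000)
        frame, truth = generate_sample(config, config.plans[0])
        n = len(frame)
        for row in truth.itertuples():
            se = np.sqrt(row.proportion * (1 - row.proportion) / n)
            assert row.n_psm_realized / n == pytest.approx(
                row.proportion, abs=3 * se
            )

    def test_deterministic_under_seed(self):
        config = default_config(seed=5, n_psm=300)
        f1, t1 = generate_sample(config, config.plans[0])
        f2, t2 = generate_sample(config, config.plans[0])
        assert f1.equals(f2) and t1.equals(t2)

    def test_parses_through_psm_io_with_zero_rejects(self, small_experiment):
        _, frames, _ = small_experiment
        for frame in frames.values():
            parsed = tables_from_frame(frame)
            assert parsed.n_rejected == 0
            assert sum(len(t.psms) for t in parsed.tables) == len(frame)

    def test_bad_proportions_rejected(self):
        taxon = TaxonProfile(
            taxon_order="O", taxon_genus="G", proportion=0.6, p_label=0.1,
            enrichment_mixture=((1.0, 35.0, 5.0),),
        )
        from protsip.synthetic import SamplePlan

        config = SyntheticConfig(
            taxa=(taxon,), plans=(SamplePlan("S1", "X", 15),), n_psm=10,
        )
        with pytest.raises(SyntheticConfigError):
            config.validate()


class TestGenerateExperiment:
    def test_default_design_ids(self, small_experiment):
        _, frames, _ = small_experiment
        assert list(frames) == [
            "MB1a", "MB1b", "MB1c", "MB2a", "MB2b", "MB2c", "OR1", "OR2",
        ]

    def test_late_samples_bimodal(self, small_experiment):
        # bimodality at the region level: labeled mass concentrates around
        # the 17% and 60% modes with a dip between, unlike the early samples
        _, frames, _ = small_experiment

        def region_mass(sample_id):
            values = frames[sample_id]["enrichment_pct"].to_numpy()
            hist = enrichment_histogram(values)
            centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
            low = hist.proportions[(centers > 10) & (centers < 25)].sum()
            mid = hist.proportions[(centers > 30) & (centers < 45)].sum()
            high = hist.proportions[(centers > 50) & (centers < 75)].sum()
            return low, mid, high

        low, mid, high = region_mass("MB2a")
        assert low > mid and high > mid
        low1, mid1, high1 = region_mass("MB1a")
        assert mid1 > low1 and mid1 > high1

    def test_labeling_increases_at_late_timepoint(self, small_experiment):
        _, frames, _ = small_experiment
        freq = {
            sid: (f["enrichment_pct"] >= 2.0).mean() for sid, f in frames.items()
        }
        mb1 = np.mean([freq["MB1a"], freq["MB1b"], freq["MB1c"]])
        mb2 = np.mean([freq["MB2a"], freq["MB2b"], freq["MB2c"]])
        assert mb2 > mb1
        assert freq["OR1"] > mb1

    def test_truth_recorded_per_sample_taxon(self, small_experiment):
        config, frames, truth = small_experiment
        assert set(truth["sample_id"]) == set(frames)
        assert len(truth) == len(frames) * len(config.taxa)


def test_config_yaml_round_trip(tmp_path):
    doc = """
seed: 4
n_psm: 120
taxa:
  - taxon_order: OrdA
    taxon_genus: GenA
    proportion: 0.7
    p_label: 0.2
    enrichment_mixture: [[1.0, 35.0, 5.0]]
  - taxon_order: OrdB
    taxon_genus: GenB
    proportion: 0.3
    p_label: 0.05
    enrichment_mixture: [[0.5, 17.0, 3.0], [0.5, 60.0, 10.0]]
samples:
  - {sample_id: X1, location: X, incubation_h: 15}
  - {sample_id: X2, location: X, incubation_h: 32, p_label_factor: 2.0}
"""
    path = tmp_path / "config.yaml"
    path.write_text(doc)
    config = config_from_yaml(path)
    assert config.n_psm == 120
    assert len(config.taxa) == 2
    frames, truth = generate_experiment(config)
    assert list(frames) == ["X1", "X2"]
    # the factor doubles the second sample's true labeling probability
    t1 = truth[truth["sample_id"] == "X1"].set_index("taxon_order")
    t2 = truth[truth["sample_id"] == "X2"].set_index("taxon_order")
    assert t2.loc["OrdA", "p_label"] == pytest.approx(2 * t1.loc["OrdA", "p_label"])
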