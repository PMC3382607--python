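"""Density-valley thresholds, boolean assignment, bimodal splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

import cytoabc as ca
from cytoabc.errors import ConfigurationError
from cytoabc.gating import (ChannelThreshold, SubsetDefinition, ThresholdSet,
                            check_disjoint, split_bimodal)
from cytoabc.panels import MARKER_CHANNELS, THREE_LEVEL_CHANNELS

from conftest import make_config, make_table


def two_component_channel(rng, n=4000, lo=10.0, hi=1000.0, sigma10=0.15,
                          frac_hi=0.5):
    comp = rng.random(n) < frac_hi
    med = np.where(comp, hi, lo)
    return med * 10.0 ** (sigma10 * rng.standard_normal(n)), comp


class TestThresholds:
    def test_valley_matches_brute_force_kde_scan(self, rng):
        # overlapping components so the density minimum is unique
        x, _ = two_component_channel(rng, n=20_000, lo=10.0, hi=150.0,
                                     sigma10=0.2)
        table = make_table({"CD3": x})
        thr = ca.resolve_thresholds(table, ["CD3"])
        # independent oracle: gaussian KDE on a fine grid, global min
        # between the two modes
        lx = np.log10(x)
        kde = gaussian_kde(lx)
        grid = np.linspace(1.2, 2.0, 2000)  # between the mode locations
        oracle = 10.0 ** grid[np.argmin(kde(grid))]
        assert abs(np.log10(thr["CD3"].positivity) - np.log10(oracle)) < 0.1

    def test_misclassification_below_one_percent_at_100x_separation(self, rng):
        x, truth_hi = two_component_channel(rng, n=10_000)
        thr = ca.resolve_thresholds(make_table({"CD3": x}), ["CD3"])
        called_hi = x > thr["CD3"].positivity
        assert (called_hi != truth_hi).mean() < 0.01

    def test_three_level_channel_gets_two_cutoffs(self, rng):
        n = 6000
        level = rng.choice([10.0, 200.0, 3200.0], size=n,
                           p=[0.6, 0.2, 0.2])
        x = level * 10.0 ** (0.15 * rng.standard_normal(n))
        thr = ca.resolve_thresholds(make_table({"CD16": x}), ["CD16"],
                                    three_level={"CD16"})
        t = thr["CD16"]
        assert 10.0 < t.positivity < 200.0 < t.hi < 3200.0

    def test_nk_hi_lo_partition_agrees_with_truth(self):
        from cytoabc.config import SubsetSpec
        cfg = make_config(subsets=[
            SubsetSpec("CD16lo-NK", "lymphoid", 0.3,
                       {"CD3": "-", "CD19": "-", "CD56": "hi", "CD16": "lo"},
                       135_418.0, 0.0),
            SubsetSpec("CD16hi-NK", "lymphoid", 0.3,
                       {"CD3": "-", "CD19": "-", "CD56": "lo", "CD16": "hi"},
                       150_000.0, 0.0),
        ], events_per_subset=3000)
        table = ca.generate_donor_events(cfg, 0)
        with pytest.warns(UserWarning, match="unimodal"):
            # CD3/CD19 are all-negative in a pure-NK sample
            thr = ca.resolve_thresholds(table, ["CD3", "CD19", "CD56", "CD16"],
                                        three_level={"CD16", "CD56"})
        defs = [SubsetDefinition(s.name, s.profile) for s in cfg.subsets]
        labels = ca.assign_subsets(table, defs, thr, scatter_channel=None)
        cells = np.asarray(table.labels) != "debris"
        agree = (np.asarray(labels)[cells] == np.asarray(table.labels)[cells])
        assert agree.mean() > 0.95

    def test_unimodal_channel_flagged_with_quantile_fallback(self, rng):
        x = 50.0 * 10.0 ** (0.1 * rng.standard_normal(3000))
        with pytest.warns(UserWarning, match="unimodal"):
            thr = ca.resolve_thresholds(make_table({"CD4": x}), ["CD4"])
        assert thr["CD4"].unimodal
        assert thr["CD4"].positivity == pytest.approx(np.quantile(x, 0.99))

    def test_determinism(self, rng):
        x, _ = two_component_channel(rng)
        t1 = ca.resolve_thresholds(make_table({"CD3": x}), ["CD3"])
        t2 = ca.resolve_thresholds(make_table({"CD3": x}), ["CD3"])
        assert t1["CD3"].positivity == t2["CD3"].positivity


def manual_thresholds(channels, pos=100.0, hi=1000.0, three=()):
    return ThresholdSet({
        c: ChannelThreshold(pos, hi if c in three else None) for c in channels
    })


class TestAssignment:
    panel = ["CD3", "CD19", "CD27", "CD45RA", "CD4", "CD8", "CD56", "CD16",
             "CD14", "CD11c", "CD123", "HLADR", "BDCA2"]

    def event(self, **positive):
        row = {c: 10.0 for c in self.panel}
        row.update(positive)
        return make_table({c: [v] * 2 for c, v in row.items()})

    def thresholds(self):
        return manual_thresholds(self.panel, three=("CD16", "CD56"))

    def test_memory_b_phenotype(self):
        table = self.event(CD19=500.0, CD27=500.0, HLADR=500.0)
        labels = ca.assign_subsets(table, ca.load_subset_definitions(),
                                   self.thresholds(), scatter_channel=None,
                                   bead_channels=None)
        assert list(labels) == ["Memory-B", "Memory-B"]

    def test_basophil_phenotype(self):
        table = self.event(CD123=500.0)
        labels = ca.assign_subsets(table, ca.load_subset_definitions(),
                                   self.thresholds(), scatter_channel=None,
                                   bead_channels=None)
        assert list(labels) == ["Basophils", "Basophils"]

    def test_no_lineage_marker_is_unassigned(self):
        labels = ca.assign_subsets(self.event(), ca.load_subset_definitions(),
                                   self.thresholds(), scatter_channel=None,
                                   bead_channels=None)
        assert list(labels) == ["unassigned", "unassigned"]

    def test_shipped_definitions_are_pairwise_disjoint(self):
        check_disjoint(ca.load_subset_definitions())

    def test_overlapping_definitions_rejected_naming_pair(self):
        overlapping = [
            SubsetDefinition("alpha", {"CD3": "+"}),
            SubsetDefinition("beta", {"CD3": "+", "CD19": "-"}),
        ]
        with pytest.raises(ConfigurationError, match="alpha.*beta|beta.*alpha"):
            check_disjoint(overlapping)
        with pytest.raises(ConfigurationError):
            ca.assign_subsets(self.event(CD3=500.0), overlapping,
                              self.thresholds(), scatter_channel=None,
                              bead_channels=None)

    def test_event_exactly_at_cutoff_classifies_negative(self):
        table = self.event(CD123=100.0)  # == positivity cutoff
        labels = ca.assign_subsets(table, ca.load_subset_definitions(),
                                   self.thresholds(), scatter_channel=None,
                                   bead_channels=None)
        assert list(labels) == ["unassigned", "unassigned"]

    def test_partition_conserves_all_events(self):
        cfg = ca.study_scenario(n_donors=1, events_per_subset=400, seed=2)
        table = ca.spike_counting_beads(
            ca.generate_donor_events(cfg, 0), 300, cfg, rng=0)
        from cytoabc.gating import resolve_sample_thresholds
        thr = resolve_sample_thresholds(table, MARKER_CHANNELS + ["FSC"],
                                        three_level=THREE_LEVEL_CHANNELS)
        labels = ca.assign_subsets(table, ca.load_subset_definitions(), thr)
        counts = labels.value_counts()
        assert counts.sum() == table.n_events
        allowed = {d.name for d in ca.load_subset_definitions()} \
            | {"bead", "debris", "unassigned"}
        assert set(counts.index) <= allowed
        assert counts.get("bead", 0) == 300

    def test_accuracy_above_98_percent_on_study_panel(self):
        cfg = ca.study_scenario(n_donors=1, events_per_subset=5000, seed=4)
        table = ca.generate_donor_events(cfg, 0)
        thr = ca.resolve_thresholds(table, MARKER_CHANNELS + ["FSC"],
                                    three_level=THREE_LEVEL_CHANNELS)
        labels = ca.assign_subsets(table, ca.load_subset_definitions(), thr)
        truth = np.asarray(table.labels)
        for spec in cfg.subsets:
            mask = truth == spec.name
            assert (np.asarray(labels)[mask] == spec.name).mean() >= 0.98, \
                spec.name


class TestBimodalSplit:
    def make_mixture(self, rng, frac_hi=0.6, ratio=5.0, n=5000):
        comp = rng.random(n) < frac_hi
        med = np.where(comp, 4500.0, 4500.0 / ratio)
        x = med * np.exp(0.25 * rng.standard_normal(n))
        table = make_table({"CD52": x})
        return table, pd.Series(["Naive-B"] * n), comp

    def test_recovers_bright_fraction_within_five_points(self, rng):
        table, labels, _ = self.make_mixture(rng)
        split = split_bimodal(table, labels, "Naive-B")
        assert split.bimodal
        assert abs((split.labels == "hi").mean() - 0.6) < 0.05

    def test_unimodal_subset_not_flagged(self, rng):
        x = 500.0 * np.exp(0.25 * rng.standard_normal(3000))
        split = split_bimodal(make_table({"CD52": x}),
                              pd.Series(["pDC"] * 3000), "pDC")
        assert not split.bimodal
        assert set(split.labels) == {"single"}

    def test_pdc_split_found_in_every_simulated_donor(self):
        cfg = ca.study_scenario(n_donors=4, events_per_subset=2000, seed=6)
        for d in range(cfg.n_donors):
            table = ca.generate_donor_events(cfg, d)
            split = split_bimodal(table, table.labels, "pDC")
            assert split.bimodal

    def test_too_few_events_skips_with_warning(self, rng):
        table, labels, _ = self.make_mixture(rng, n=50)
        with pytest.warns(UserWarning, match="skipped"):
            split = split_bimodal(table, labels[:50], "Naive-B")
        assert not split.bimodal
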