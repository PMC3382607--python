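"""Viability classification, counting arithmetic, depletion statistics."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytoabc as ca
from cytoabc.cdc import (absolute_count, classify_viability, depletion_table,
                         percent_lysis, purified_population_cdc,
                         viability_percentages)
from cytoabc.config import CDCModelParams
from cytoabc.errors import ContractError
from cytoabc.gating import ChannelThreshold, SubsetDefinition, ThresholdSet
from cytoabc.simulate import death_probability

from conftest import make_table

VIA_THR = ThresholdSet({"AnnexinV": ChannelThreshold(200.0),
                        "7AAD": ChannelThreshold(200.0)})


class TestViability:
    @pytest.mark.parametrize("annexin,aad,expected", [
        (2000.0, 2000.0, "necrotic"),
        (2000.0, 20.0, "apoptotic"),
        (20.0, 20.0, "live"),
        (20.0, 2000.0, "necrotic"),  # 7-AAD+ alone still counts as dead
    ])
    def test_quadrant_classification(self, annexin, aad, expected):
        table = make_table({"AnnexinV": [annexin], "7AAD": [aad]})
        assert list(classify_viability(table, VIA_THR)) == [expected]

    def test_missing_viability_channel_is_contract_error(self):
        with pytest.raises(ContractError):
            classify_viability(make_table({"AnnexinV": [1.0]}), VIA_THR)

    def test_percentages_partition_exactly(self, rng):
        n = 997  # odd prime: fractions don't round nicely by accident
        table = make_table({
            "AnnexinV": rng.choice([20.0, 2000.0], n),
            "7AAD": rng.choice([20.0, 2000.0], n),
        })
        pct = viability_percentages(classify_viability(table, VIA_THR))
        assert pct["pct_live"] + pct["pct_apoptotic"] + pct["pct_necrotic"] \
            == 100.0
        assert pct["pct_lysis"] == pct["pct_apoptotic"] + pct["pct_necrotic"]

    def test_all_live_sample_has_zero_lysis(self):
        table = make_table({"AnnexinV": np.full(500, 20.0),
                            "7AAD": np.full(500, 20.0)})
        assert percent_lysis(classify_viability(table, VIA_THR)) == 0.0

    def test_half_necrotic_gives_fifty_percent(self):
        table = make_table({"AnnexinV": [2000.0, 20.0], "7AAD": [2000.0, 20.0]})
        via = classify_viability(table, VIA_THR)
        assert percent_lysis(via) == 50.0
        assert percent_lysis(via) == 100.0 - viability_percentages(via)["pct_live"]


class TestAbsoluteCount:
    def test_printed_formula_examples(self):
        assert absolute_count(5000, 2500, 25000) == 50_000.0
        assert absolute_count(1234, 1234, 25000) == 25_000.0

    def test_thousand_random_triples_match_exact_arithmetic(self, rng):
        for _ in range(1000):
            cells = int(rng.integers(0, 200_000))
            beads = int(rng.integers(1, 10_000))
            assigned = int(rng.integers(1, 100_000))
            oracle = Fraction(cells) * Fraction(assigned) / Fraction(beads)
            assert absolute_count(cells, beads, assigned) == \
                pytest.approx(float(oracle), rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(cells=st.integers(0, 10**6), beads=st.integers(1, 10**5),
           assigned=st.integers(1, 10**6))
    def test_exact_homogeneity(self, cells, beads, assigned):
        base = absolute_count(cells, beads, assigned)
        assert absolute_count(2 * cells, beads, assigned) == 2 * base
        assert absolute_count(cells, 2 * beads, assigned) == base / 2

    def test_zero_beads_raises_with_remediation(self):
        with pytest.raises(ContractError, match="bead"):
            absolute_count(100, 0, 25000)


def small_cdc_wells(seed=0, n_total=12_000, replicates=2):
    cfg = ca.cdc_scenario(n_donors=1, total_events=n_total, seed=seed)
    base = ca.generate_donor_events(cfg, 0)
    rng = np.random.default_rng(seed)
    controls, treateds = [], []
    for _ in range(replicates):
        for arm, bucket in (("control", controls), ("antibody", treateds)):
            well = ca.simulate_cdc(base, cfg.cdc, arm, rng=rng)
            bucket.append(ca.spike_counting_beads(well, 1500, cfg, rng=rng))
    return cfg, controls, treateds


class TestDepletion:
    def test_identical_samples_show_zero_depletion(self):
        cfg, controls, _ = small_cdc_wells()
        result = depletion_table(controls, controls,
                                 ca.load_subset_definitions(), seed=1)
        assert (result.counts.difference == 0).all()
        assert not (result.counts.flag == "depleted").any()
        assert not (result.counts.flag == "enriched").any()

    def test_single_well_reports_counts_but_skips_tests(self):
        cfg, controls, treateds = small_cdc_wells()
        with pytest.warns(UserWarning, match="skipped"):
            result = depletion_table(controls[0], treateds[0],
                                     ca.load_subset_definitions(), seed=1)
        assert (result.counts.flag == "untested").all()
        assert result.counts.control_mean.notna().all()

    def test_treated_lysis_exceeds_control_in_every_well(self):
        _, controls, treateds = small_cdc_wells()
        result = depletion_table(controls, treateds,
                                 ca.load_subset_definitions(), seed=1)
        via = result.viability
        worst_t = via[via.arm == "antibody"].pct_lysis.min()
        best_c = via[via.arm == "control"].pct_lysis.max()
        assert worst_t > best_c

    def test_counts_match_hand_computed_formula_on_toy_sample(self):
        """100 gated cells, 20 beads: recount by hand through the formula."""
        n = 100
        channels = {
            "FSC": np.full(n, 1000.0), "CD3": np.full(n, 10.0),
            "CD19": np.full(n, 10.0), "CD123": np.full(n, 1600.0),
            "HLADR": np.full(n, 10.0), "CD11c": np.full(n, 10.0),
            "CD14": np.full(n, 10.0),
            "AnnexinV": np.r_[np.full(40, 2000.0), np.full(60, 20.0)],
            "7AAD": np.full(n, 20.0),
        }
        table = make_table(channels, metadata={"counting_bead_assigned": 50_000})
        bead_rows = {c: np.full(20, 50_000.0) for c in channels}
        bead_rows["AnnexinV"] = bead_rows["7AAD"] = np.full(20, 20.0)
        well = table.concat(make_table(bead_rows))
        thr = ThresholdSet({c: ChannelThreshold(100.0) for c in channels})
        baso = SubsetDefinition("Basophils", {
            "CD3": "-", "CD19": "-", "HLADR": "-", "CD11c": "-", "CD14": "-",
            "CD123": "+"})
        with pytest.warns(UserWarning):
            result = depletion_table(well, well, [baso], thresholds=thr, seed=0)
        row = result.counts.iloc[0]
        # 60 live basophils x 50000 assigned / 20 bead events
        assert row.control_mean == 60 * 50_000 / 20

    def test_downsampling_preserves_proportions_in_expectation(self):
        cfg, controls, _ = small_cdc_wells(n_total=8000)
        well = controls[0]
        counts = []
        for s in range(40):
            result = depletion_table([well, well], [well, well],
                                     ca.load_subset_definitions(), seed=s)
            counts.append(result.counts.set_index("subset").control_mean)
        mean_counts = pd.concat(counts, axis=1).mean(axis=1)
        one = depletion_table([well, well], [well, well],
                              ca.load_subset_definitions(), seed=0)
        # full-sample proportions: no down-sampling happens for identical
        # wells (n_min == own gated count), so the single-run counts are the
        # full-sample reference
        ref = one.counts.set_index("subset").control_mean
        for subset in ref.index:
            if ref[subset] > 0:
                assert mean_counts[subset] == pytest.approx(ref[subset],
                                                            rel=0.02)


class TestPurified:
    def purified_subset(self, name, cfg):
        base = ca.generate_donor_events(cfg, 0)
        mask = np.asarray(base.labels) == name
        return base.select(np.flatnonzero(mask))

    def test_zero_blocking_efficiency_is_a_null_intervention(self):
        cfg = ca.cdc_scenario(n_donors=1, total_events=20_000, seed=3)
        params = CDCModelParams(cip_protection={"CD16neg-Mono": 0.85},
                                blocking_efficiency=0.0)
        mono = self.purified_subset("CD16neg-Mono", cfg)
        a = purified_population_cdc(mono, params, blocking=False,
                                    rng=np.random.default_rng(5))
        b = purified_population_cdc(mono, params, blocking=True,
                                    rng=np.random.default_rng(5))
        assert a == b  # identical randomness, identical probabilities

    def test_full_blocking_matches_unprotected_closed_form(self):
        cfg = ca.cdc_scenario(n_donors=1, total_events=40_000, seed=4)
        params = CDCModelParams(cip_protection={"CD16neg-Mono": 1.0},
                                blocking_efficiency=1.0, lysed_loss=0.0)
        mono = self.purified_subset("CD16neg-Mono", cfg)
        observed = purified_population_cdc(mono, params, blocking=True,
                                           rng=np.random.default_rng(6))
        p = death_probability(mono.truth_abc.to_numpy(), params, 0.0)
        predicted = 100.0 * (p.mean() - params.background_death)
        se = 100.0 * np.sqrt(2 * p.mean() * (1 - p.mean()) / mono.n_events)
        assert abs(observed - predicted) < 4 * se

    def test_t_cells_lyse_and_nk_cells_do_not_in_the_same_run(self):
        cfg = ca.cdc_scenario(n_donors=1, total_events=40_000, seed=5)
        t_lysis = purified_population_cdc(
            self.purified_subset("CD4-Naive", cfg), cfg.cdc,
            rng=np.random.default_rng(7))
        nk_lysis = purified_population_cdc(
            self.purified_subset("CD16hi-NK", cfg), cfg.cdc,
            rng=np.random.default_rng(8))
        assert t_lysis > 50.0
        assert nk_lysis < 10.0

    def test_missing_control_impossible_empty_population_rejected(self):
        cfg = ca.cdc_scenario(n_donors=1, seed=6)
        empty = self.purified_subset("no-such-subset", cfg)
        with pytest.raises(ContractError):
            purified_population_cdc(empty, cfg.cdc, rng=0)
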