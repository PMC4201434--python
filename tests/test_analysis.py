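"""Surface analysis: peak detection, breadth metrics, comparisons, sweeps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import duplipath as dp
from conftest import FLAT_COPY, brute_force_peaks, symmetric_copy


@pytest.fixture(scope="module")
def flat_surface():
    cfg = dp.PathwayConfig((FLAT_COPY,), (FLAT_COPY,), dp.SigmoidLink(1, 2),
                           dp.SigmoidLink(1, 2))
    return dp.evaluate_surface(cfg)


class TestPeakFinding:
    def test_matches_brute_force_on_every_panel(self, panel_surfaces):
        for fid, s in panel_surfaces.items():
            assert list(dp.find_local_maxima(s).peaks) == brute_force_peaks(s), fid

    def test_constant_surface_is_one_plateau_peak(self, flat_surface):
        peaks = dp.find_local_maxima(flat_surface)
        assert len(peaks) == 1
        # plateau reported at the lexicographically smallest cell
        assert peaks.cells == ((1.0, 1.0),)

    def test_large_prominence_discards_plateau(self, flat_surface):
        assert len(dp.find_local_maxima(flat_surface, min_prominence=0.9)) == 0

    def test_bimodal_panel_peak_cells(self, panel_surfaces):
        peaks = dp.find_local_maxima(panel_surfaces["5B"])
        assert peaks.cells == ((5.0, 8.0), (15.0, 16.0))

    def test_unimodal_panel_single_peak(self, panel_surfaces):
        peaks = dp.find_local_maxima(panel_surfaces["2D"])
        assert peaks.cells == ((10.0, 12.0),)

    def test_peaks_sorted_by_height_then_cell(self, panel_surfaces):
        peaks = dp.find_local_maxima(panel_surfaces["4B"]).peaks
        values = [p[2] for p in peaks]
        assert values == sorted(values, reverse=True)
        ties = [(p[0], p[1]) for p in peaks if p[2] == values[0]]
        assert ties == sorted(ties)


class TestBreadthMetrics:
    def test_flat_surface_flagged_full_grid(self, flat_surface):
        m = dp.breadth_metrics(flat_surface)
        assert m.flat and m.half_max_area == 400
        assert m.axis_halfwidths == (20, 20)

    def test_total_mass_is_cell_sum(self, panel_surfaces):
        s = panel_surfaces["2D"]
        m = dp.breadth_metrics(s)
        assert m.total_mass == pytest.approx(float(s.P.sum()))
        assert 0 < m.total_mass <= m.n_cells

    def test_value_at_query_cells(self, panel_surfaces):
        m = dp.breadth_metrics(panel_surfaces["5B"], query_cells=[(5, 8), (15, 16)])
        assert m.value_at[(5.0, 8.0)] == panel_surfaces["5B"].value_at(5, 8)
        assert len(m.value_at) == 2

    def test_halfwidths_bounded_by_grid(self, panel_surfaces):
        for fid, s in panel_surfaces.items():
            m = dp.breadth_metrics(s)
            assert 1 <= m.axis_halfwidths[0] <= 20
            assert 1 <= m.axis_halfwidths[1] <= 20
            assert 1 <= m.half_max_area <= 400

    def test_total_mass_invariant_under_axis_transposition(self):
        """Swapping the two environmental factors everywhere transposes P."""
        cfg = dp.get_figure_config("4A").config
        swapped = dataclasses.replace(
            cfg,
            upstream=tuple(
                dp.GeneCopyParams(g.response_e2, g.response_e1, g.label)
                for g in cfg.upstream
            ),
            downstream=tuple(
                dp.GeneCopyParams(g.response_e2, g.response_e1, g.label)
                for g in cfg.downstream
            ),
        )
        a, b = dp.evaluate_surface(cfg), dp.evaluate_surface(swapped)
        assert np.array_equal(b.P, a.P.T)
        assert dp.breadth_metrics(a).total_mass == pytest.approx(
            dp.breadth_metrics(b).total_mass
        )

    def test_total_mass_invariant_under_copy_permutation(self):
        cfg = dp.get_figure_config("5A").config
        flipped = dataclasses.replace(cfg, upstream=cfg.upstream[::-1],
                                      downstream=cfg.downstream[::-1])
        assert dp.breadth_metrics(dp.evaluate_surface(cfg)).total_mass == (
            dp.breadth_metrics(dp.evaluate_surface(flipped)).total_mass
        )


class TestCompareSurfaces:
    def test_self_comparison_is_all_zero(self, panel_surfaces):
        s = panel_surfaces["2D"]
        c = dp.compare_surfaces(s, s, query_cells=[(10, 12)])
        assert c.delta_total_mass == 0 and c.delta_max == 0
        assert c.delta_value_at[(10.0, 12.0)] == 0
        assert all(m["distance"] == 0 for m in c.peak_matching)

    def test_grid_mismatch_rejected(self, panel_surfaces):
        other = dp.evaluate_surface(dp.get_figure_config("2D").config,
                                    dp.default_grid(step=0.5))
        with pytest.raises(dp.ParameterError):
            dp.compare_surfaces(panel_surfaces["2D"], other)

    def test_compensation_lowers_peak_probability(self, panel_surfaces):
        """Displacing one tier (3B) and compensating with the other (3C)
        progressively lowers the attainable maximum."""
        c = dp.compare_surfaces(panel_surfaces["3C"], panel_surfaces["3A"])
        assert c.delta_max < 0
        c2 = dp.compare_surfaces(panel_surfaces["3C"], panel_surfaces["3B"])
        assert c2.delta_max < 0


class TestPeakOptimumMatch:
    def test_peak_on_optimum_has_zero_distance(self, panel_surfaces):
        peaks = dp.find_local_maxima(panel_surfaces["5B"])
        table = dp.peak_optimum_match(peaks, panel_surfaces["5B"].config)
        assert isinstance(table, pd.DataFrame)
        # each peak sits exactly on one upstream and one downstream optimum
        for cell in [(5.0, 8.0), (15.0, 16.0)]:
            sub = table[(table.peak_e1 == cell[0]) & (table.peak_e2 == cell[1])]
            assert (sub.groupby("tier").distance.min() == 0).all()

    def test_empty_peak_set_gives_empty_table(self, flat_surface):
        peaks = dp.find_local_maxima(flat_surface, min_prominence=0.9)
        table = dp.peak_optimum_match(peaks, flat_surface.config)
        assert table.empty

    def test_row_count_is_peaks_times_copies(self, panel_surfaces):
        s = panel_surfaces["4B"]
        peaks = dp.find_local_maxima(s)
        table = dp.peak_optimum_match(peaks, s.config)
        assert len(table) == len(peaks) * (s.config.n_upstream + s.config.n_downstream)


class TestParameterSweep:
    def test_single_value_equals_direct_evaluation(self):
        cfg = dp.get_figure_config("2C").config
        table = dp.parameter_sweep(cfg, "link_down_outcome.slope", [2.0])
        direct = dp.breadth_metrics(dp.evaluate_surface(cfg))
        row = table.iloc[0]
        assert row.total_mass == pytest.approx(direct.total_mass)
        assert row.half_max_area == direct.half_max_area
        assert row.n_peaks == direct.n_peaks

    def test_base_config_unmodified(self):
        cfg = dp.get_figure_config("2C").config
        dp.parameter_sweep(cfg, "link_down_outcome.slope", [9.0])
        assert cfg.link_down_outcome.slope == 2

    def test_unknown_path_rejected(self):
        cfg = dp.get_figure_config("2C").config
        with pytest.raises(KeyError):
            dp.parameter_sweep(cfg, "link_down_outcome.gain", [1.0])
        with pytest.raises(KeyError):
            dp.parameter_sweep(cfg, "upstream[9].response_e1.optimum", [1.0])

    def test_indexed_path_reaches_copy_fields(self):
        cfg = dp.get_figure_config("2C").config
        new = dp.set_parameter(cfg, "upstream[0].response_e1.optimum", 4.0)
        assert new.upstream[0].response_e1.optimum == 4.0
        assert cfg.upstream[0].response_e1.optimum == 10.0

    def test_upstream_divergence_splits_the_peak(self):
        """Identical copies give one peak; fully divergent upstream copies
        (downstream undiverged, independent wiring, steep upstream link)
        give two."""
        counts = {}
        for d in (0, 5):
            up = (symmetric_copy(10 - d, 12 - 0.8 * d),
                  symmetric_copy(10 + d, 12 + 0.8 * d))
            dn = (symmetric_copy(10, 12), symmetric_copy(10, 12))
            cfg = dp.PathwayConfig(up, dn, dp.SigmoidLink(5, 7),
                                   dp.SigmoidLink(1, 2), wiring="independent")
            counts[d] = len(dp.find_local_maxima(dp.evaluate_surface(cfg)))
        assert counts[0] == 1 and counts[5] == 2

    def test_sweep_is_deterministic(self):
        cfg = dp.get_figure_config("2C").config
        t1 = dp.parameter_sweep(cfg, "link_up_down.slope", [2, 4, 7])
        t2 = dp.parameter_sweep(cfg, "link_up_down.slope", [2, 4, 7])
        pd.testing.assert_frame_equal(t1, t2)
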