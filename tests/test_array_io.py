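"""Table round trips, spot reduction, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
import yaml

from gmapsolve.array_io import (PipelineError, gpr_to_spot_table,
                                read_enzyme_table, read_glycan_library,
                                read_lectin_table, read_panel_config,
                                read_spot_table, reduce_spot_table,
                                run_pipeline, write_enzyme_table,
                                write_glycan_library, write_lectin_table)
from gmapsolve.glycan_core import canonical_form
from gmapsolve.synthetic import (default_enzymes, default_lectins,
                                 default_panel)


def _spot_rows(values_by_channel, protein="P", arrays=("A1",), spots=2,
               background=50.0):
    rows = []
    for (condition, lectin), value in values_by_channel.items():
        for a in arrays:
            for s in range(spots):
                rows.append({"slide_id": "S1", "array_id": a,
                             "spot_id": f"{s}", "protein": protein,
                             "lectin": lectin, "condition": condition,
                             "median_signal": background + value,
                             "mean_background": background})
    return pd.DataFrame(rows)


class TestTableRoundTrips:
    def test_glycan_library(self, tmp_path, small_library):
        path = tmp_path / "lib.tsv"
        write_glycan_library(small_library, path)
        back = read_glycan_library(path)
        assert [canonical_form(g) for g in back] == \
            [canonical_form(g) for g in small_library]
        assert [g.id for g in back] == [g.id for g in small_library]

    def test_lectin_table(self, tmp_path):
        path = tmp_path / "lectins.tsv"
        lectins = list(default_lectins(extended=True))
        write_lectin_table(lectins, path)
        back = read_lectin_table(path)
        assert set(back) == {l.name for l in lectins}
        for l in lectins:
            got = back[l.name]
            assert [(str(m), s, m.terminal_required) for m, s in got.entries] \
                == [(str(m), s, m.terminal_required) for m, s in l.entries]

    def test_enzyme_table(self, tmp_path):
        path = tmp_path / "enzymes.tsv"
        enzymes = list(default_enzymes().values())
        write_enzyme_table(enzymes, path)
        back = read_enzyme_table(path)
        assert set(back) == {e.name for e in enzymes}

    def test_panel_resolution_and_unknown_names(self):
        lectins = {l.name: l for l in default_lectins(True)}
        enzymes = default_enzymes()
        cfg = {"conditions": [{"name": "untreated"},
                              {"name": "s", "enzymes": ["sialidase-broad"]}],
               "lectins": ["SNA-like", "ECL-like"]}
        panel = read_panel_config(cfg, lectins, enzymes)
        assert panel.n_channels == 4
        bad = {"conditions": [{"name": "x", "enzymes": ["no-such-enzyme"]}],
               "lectins": ["SNA-like"]}
        with pytest.raises(KeyError):
            read_panel_config(bad, lectins, enzymes)


class TestReduceSpotTable:
    def _tiny_panel(self):
        lectins = {l.name: l for l in default_lectins()}
        cfg = {"conditions": [{"name": "untreated"}],
               "lectins": ["SNA-like"]}
        return read_panel_config(cfg, lectins, default_enzymes())

    def test_single_spot_background_subtraction(self):
        panel = self._tiny_panel()
        df = _spot_rows({("untreated", "SNA-like"): 0.0})
        df = df.iloc[:1].assign(median_signal=100.0, mean_background=40.0)
        out = reduce_spot_table(df, panel)
        assert out["P"].iloc[0] == pytest.approx(60.0)

    def test_two_stage_mean(self):
        panel = self._tiny_panel()
        rows = []
        for array, nets in [("A1", [60, 80]), ("A2", [70, 110])]:
            for i, net in enumerate(nets):
                rows.append({"slide_id": "S1", "array_id": array,
                             "spot_id": str(i), "protein": "P",
                             "lectin": "SNA-like", "condition": "untreated",
                             "median_signal": 100.0 + net,
                             "mean_background": 100.0})
        out = reduce_spot_table(pd.DataFrame(rows), panel)
        # arrays average to 70 and 90; grand mean 80
        assert out["P"].iloc[0] == pytest.approx(80.0)

    def test_missing_channel_error_names_gap(self):
        lectins = {l.name: l for l in default_lectins()}
        cfg = {"conditions": [{"name": "untreated"},
                              {"name": "treated",
                               "enzymes": ["sialidase-broad"]}],
               "lectins": ["SNA-like"]}
        panel = read_panel_config(cfg, lectins, default_enzymes())
        df = _spot_rows({("untreated", "SNA-like"): 1.0})
        with pytest.raises(ValueError, match="SNA-like x treated"):
            reduce_spot_table(df, panel)

    def test_permutation_invariance(self):
        panel = self._tiny_panel()
        df = _spot_rows({("untreated", "SNA-like"): 5.0}, arrays=("A1", "A2"),
                        spots=3)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = reduce_spot_table(df, panel)["P"]
        b = reduce_spot_table(shuffled, panel)["P"]
        pd.testing.assert_series_equal(a, b)

    def test_negative_net_kept_by_default(self):
        panel = self._tiny_panel()
        df = _spot_rows({("untreated", "SNA-like"): -10.0})
        out = reduce_spot_table(df, panel)
        assert out["P"].iloc[0] == pytest.approx(-10.0)
        clamped = reduce_spot_table(df, panel, clamp_negative=True)
        assert clamped["P"].iloc[0] == 0.0


class TestGPRAdapter:
    def test_column_mapping(self):
        gpr = pd.DataFrame({"Block": [1, 1], "ID": ["s1", "s2"],
                            "Name": ["P", "P"],
                            "F635 Median": [500.0, 520.0],
                            "B635 Mean": [80.0, 90.0]})
        out = gpr_to_spot_table(gpr, lectin="SNA-like", condition="untreated")
        assert list(out["median_signal"]) == [500.0, 520.0]
        assert set(out["lectin"]) == {"SNA-like"}


@pytest.fixture
def toy_pipeline_config(tmp_path):
    """A 2-glycan fixture designed for a unique exact fit."""
    from gmapsolve.response_model import build_model_matrix, normalize_per_lectin
    from gmapsolve.synthetic import build_n_glycan, build_o_core1
    g1 = build_n_glycan([("a2-6", "b1-4"), ("a2-6", "b1-4")], id="bi")
    g2 = build_o_core1(sialylated=True, id="o1")
    write_glycan_library([g1, g2], tmp_path / "glycans.tsv")
    write_lectin_table(list(default_lectins(True)), tmp_path / "lectins.tsv")
    write_enzyme_table(list(default_enzymes().values()),
                       tmp_path / "enzymes.tsv")
    panel = default_panel(True)
    panel_doc = {"conditions": [{"name": c.name,
                                 "enzymes": [e.name for e in c.enzymes]}
                                for c in panel.conditions],
                 "lectins": [l.name for l in panel.lectins]}
    matrix = normalize_per_lectin(build_model_matrix([g1, g2], panel))
    d = matrix.to_numpy() @ np.array([0.7, 0.3])
    obs = pd.DataFrame({"protein": "toy",
                        "condition": [c for c, _ in matrix.index],
                        "lectin": [l for _, l in matrix.index],
                        "value": d})
    obs.to_csv(tmp_path / "observed.tsv", sep="\t", index=False)
    config = {
        "inputs": {"glycans": str(tmp_path / "glycans.tsv"),
                   "lectins": str(tmp_path / "lectins.tsv"),
                   "enzymes": str(tmp_path / "enzymes.tsv"),
                   "observed": str(tmp_path / "observed.tsv")},
        "panel": panel_doc,
        "normalize_observed": False,
    }
    (tmp_path / "config.yaml").write_text(yaml.safe_dump(config))
    return tmp_path


class TestRunPipeline:
    def test_toy_fixture_unique_exact_fit(self, toy_pipeline_config):
        out = toy_pipeline_config / "out"
        written = run_pipeline(toy_pipeline_config / "config.yaml", out)
        report = pd.read_csv(written["report_toy"], sep="\t")
        assert set(report["glycan_id"]) == {"bi", "o1"}
        assert (report["inclusion_frequency"] == 1.0).all()
        weights = report.set_index("glycan_id")["mean_weight"]
        assert weights["bi"] == pytest.approx(0.7, abs=1e-9)
        assert weights["o1"] == pytest.approx(0.3, abs=1e-9)

    def test_unknown_enzyme_fails_before_computation(self, toy_pipeline_config):
        cfg = yaml.safe_load((toy_pipeline_config / "config.yaml").read_text())
        cfg["panel"]["conditions"][1]["enzymes"] = ["bogus"]
        with pytest.raises(PipelineError) as err:
            run_pipeline(cfg, toy_pipeline_config / "out2")
        assert err.value.stage == "read-panel"

    def test_rerun_is_byte_identical(self, toy_pipeline_config):
        out1 = toy_pipeline_config / "r1"
        out2 = toy_pipeline_config / "r2"
        w1 = run_pipeline(toy_pipeline_config / "config.yaml", out1)
        w2 = run_pipeline(toy_pipeline_config / "config.yaml", out2)
        for key in w1:
            assert w1[key].read_bytes() == w2[key].read_bytes()
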