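"""Summaries and factorial ANOVA: closed-form oracles and invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cytomorph.stats import (
    AnalysisError,
    ModelSpec,
    one_way_anova,
    run_full_analysis,
    summarize_groups,
    two_way_anova,
)
from cytomorph.synth import default_config, simulate_table


def _toy_table(values, layers, sides):
    return pd.DataFrame({
        "area_um2": values, "perimeter_um": values, "aspect_ratio": values,
        "density": values, "layer_id": layers, "side": sides,
    })


def test_summary_closed_form_group():
    table = _toy_table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], ["left"] * 4)
    row = summarize_groups(table, "area", "layer").iloc[0]
    assert row["mean"] == pytest.approx(2.5)
    assert row["sem"] == pytest.approx(0.6455, abs=5e-5)
    assert row["q1"] == pytest.approx(1.75)
    assert row["q3"] == pytest.approx(3.25)
    assert row["n"] == 4


def test_summary_singleton_group():
    table = _toy_table([7.0], [3], ["right"])
    row = summarize_groups(table, "area", "layer_side").iloc[0]
    assert row["mean"] == 7.0 and row["sem"] == 0.0
    assert row["q1"] == 7.0 and row["q3"] == 7.0


def test_summary_rejects_bad_grouping():
    table = _toy_table([1.0, 2.0], [1, 2], ["left", "left"])
    with pytest.raises(AnalysisError):
        summarize_groups(table, "area", "specimen")


def test_group_means_recover_generator_parameters(rng):
    """12 layer x side group means land within 3 SEM of the configured ones."""
    cfg = default_config()
    table = simulate_table(cfg, 6000, rng)
    summary = summarize_groups(table, "area", "layer_side")
    for _, row in summary.iterrows():
        spec = cfg.layers(row["side"])[int(row["layer_id"]) - 1]
        assert abs(row["mean"] - spec.area_mean) < 3 * row["sem"] + 1e-9


def test_one_way_matches_scipy_oracle(rng):
    layers = np.repeat([1, 2, 3, 4, 5, 6], 15)
    vals = rng.normal(10, 2, size=layers.size) + layers * 0.3
    table = _toy_table(vals, layers, ["left"] * layers.size)
    row = one_way_anova(table, "area", "layer")
    f_ref, p_ref = sps.f_oneway(*[vals[layers == l] for l in range(1, 7)])
    assert row.f == pytest.approx(f_ref, abs=1e-10)
    assert row.p == pytest.approx(p_ref, abs=1e-10)
    assert row.df == 5


def test_one_way_degenerate_zero_variance_flagged():
    table = _toy_table([5.0] * 6, [1, 1, 1, 2, 2, 2], ["left"] * 6)
    row = one_way_anova(table, "area", "layer")
    assert math.isnan(row.f) and math.isnan(row.p)


def test_one_way_design_errors():
    table = _toy_table([1.0, 2.0, 3.0], [1, 1, 1], ["left"] * 3)
    with pytest.raises(AnalysisError, match="fewer than 2"):
        one_way_anova(table, "area", "layer")
    table = _toy_table([1.0, 2.0, 3.0], [1, 1, 2], ["left"] * 3)
    with pytest.raises(AnalysisError, match="level"):
        one_way_anova(table, "area", "layer")


def _closed_form_two_way(table, col="area_um2"):
    """Textbook balanced two-way ANOVA with interaction (independent oracle)."""
    layers = sorted(table.layer_id.unique())
    sides = sorted(table.side.unique())
    y = table[col].to_numpy(float)
    grand = y.mean()
    n = len(table) // (len(layers) * len(sides))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    cell_means = {}
    for i in layers:
        for j in sides:
            cell = table[(table.layer_id == i) & (table.side == j)][col].to_numpy()
            cell_means[i, j] = cell.mean()
            ss_e += ((cell - cell.mean()) ** 2).sum()
    for i in layers:
        mi = table[table.layer_id == i][col].mean()
        ss_a += len(sides) * n * (mi - grand) ** 2
    for j in sides:
        mj = table[table.side == j][col].mean()
        ss_b += len(layers) * n * (mj - grand) ** 2
    for i in layers:
        for j in sides:
            mi = table[table.layer_id == i][col].mean()
            mj = table[table.side == j][col].mean()
            ss_ab += n * (cell_means[i, j] - mi - mj + grand) ** 2
    df_a, df_b = len(layers) - 1, len(sides) - 1
    df_ab = df_a * df_b
    df_e = len(table) - len(layers) * len(sides)
    ms_e = ss_e / df_e
    out = {}
    for name, ss, df in (("layer", ss_a, df_a), ("side", ss_b, df_b),
                         ("layer:side", ss_ab, df_ab)):
        f = (ss / df) / ms_e
        out[name] = (ss, df, f, float(sps.f.sf(f, df, df_e)))
    out["residual"] = (ss_e, df_e, None, None)
    return out


def _balanced_table(rng, n_per_cell=8):
    rows = []
    for i in range(1, 7):
        for j, side in enumerate(("left", "right")):
            mu = 10 + 2 * i + 1.5 * j + (0.8 if (i, side) == (2, "right") else 0.0)
            for v in rng.normal(mu, 1.0, size=n_per_cell):
                rows.append({"area_um2": v, "perimeter_um": v, "aspect_ratio": v,
                             "density": v, "layer_id": i, "side": side})
    return pd.DataFrame(rows)


def test_two_way_matches_closed_form_oracle(rng):
    table = _balanced_table(rng)
    report = two_way_anova(table, "area")
    oracle = _closed_form_two_way(table)
    total = ((table.area_um2 - table.area_um2.mean()) ** 2).sum()
    ss_sum = 0.0
    for effect in ("layer", "side", "layer:side"):
        row = report.row(effect)
        ss, df, f, p = oracle[effect]
        assert row.ss == pytest.approx(ss, rel=1e-8)
        assert row.df == df
        assert row.f == pytest.approx(f, rel=1e-8)
        assert row.p == pytest.approx(p, rel=1e-6, abs=1e-12)
        ss_sum += row.ss
    ss_sum += report.row("residual").ss
    assert ss_sum == pytest.approx(total, rel=1e-8)


def test_two_way_type_iii_equals_type_ii_when_balanced(rng):
    table = _balanced_table(rng)
    r2 = two_way_anova(table, "area", ModelSpec(ss_type=2))
    r3 = two_way_anova(table, "area", ModelSpec(ss_type=3))
    for effect in ("layer", "side", "layer:side"):
        assert r2.row(effect).f == pytest.approx(r3.row(effect).f, rel=1e-8)


def test_two_way_empty_cell_is_named_error(rng):
    table = _balanced_table(rng)
    table = table[~((table.layer_id == 4) & (table.side == "right"))]
    with pytest.raises(AnalysisError, match="layer 4, side 'right'"):
        two_way_anova(table, "area")


def test_full_analysis_single_side_skips_side_tests(rng):
    table = _balanced_table(rng)
    table = table[table.side == "left"]
    bundle = run_full_analysis(table)
    assert any("skipped" in n for n in bundle.notices)
    assert bundle.reports["area"] is None
    assert "side" not in bundle.one_way["area"]
    assert bundle.one_way["area"]["layer"].p < 1


def test_full_analysis_missing_response_errors(rng):
    table = _balanced_table(rng).drop(columns=["density"])
    with pytest.raises(AnalysisError, match="density"):
        run_full_analysis(table)


def test_row_order_invariance(rng):
    table = _balanced_table(rng)
    shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = two_way_anova(table, "area")
    b = two_way_anova(shuffled, "area")
    for effect in ("layer", "side", "layer:side"):
        assert a.row(effect).f == pytest.approx(b.row(effect).f, rel=1e-12)
    sa = summarize_groups(table, "area", "layer_side")
    sb = summarize_groups(shuffled, "area", "layer_side")
    pd.testing.assert_frame_equal(sa, sb)


def test_full_analysis_bundle_serializes(tmp_path, rng):
    table = _balanced_table(rng)
    bundle = run_full_analysis(table)
    out = tmp_path / "anova.json"
    bundle.to_json(out)
    assert out.exists() and "layer:side" in out.read_text()
    written = bundle.summaries_to_csv(tmp_path)
    assert len(written) == 12  # 4 responses x 3 groupings


def test_side_effect_direction_recovered(rng):
    """Under the published per-side means the right hemisphere is larger."""
    table = simulate_table(default_config(), 4000, rng)
    rep = two_way_anova(table, "area")
    assert rep.side_means["right"] > rep.side_means["left"]
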