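"""Figures mirroring the standard laminar-asymmetry plots.

Per response: per-layer boxplots (pooled and split by side), main-effect
plots for layer and side, and the layer x side interaction plot with one
line per side.  Every figure's plotted values are also written as CSV next
to the image so that downstream checks assert on numbers, never on pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import RESPONSE_COLUMNS, AnalysisBundle, _response_column

_UNITS = {"area": "μm²", "perimeter": "μm", "aspect_ratio": "", "density": "cells / 50 μm"}


def _save(fig, path: Path) -> Path:
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def boxplot_by_layer(
    table: pd.DataFrame, response: str, out: Path, by_side: bool = False
) -> tuple[Path, Path]:
    col = _response_column(table, response)
    layers = sorted(table["layer_id"].unique())
    fig, ax = plt.subplots(figsize=(7, 4))
    rows = []
    if by_side:
        sides = sorted(table["side"].unique())
        data, labels = [], []
        for lid in layers:
            for side in sides:
                vals = table.loc[(table["layer_id"] == lid) & (table["side"] == side), col]
                data.append(vals.to_numpy())
                labels.append(f"L{lid}\n{side[0].upper()}")
                rows.append({"layer_id": lid, "side": side,
                             "median": float(vals.median()),
                             "q1": float(vals.quantile(0.25)),
                             "q3": float(vals.quantile(0.75)), "n": len(vals)})
    else:
        data = [table.loc[table["layer_id"] == lid, col].to_numpy() for lid in layers]
        labels = [f"L{lid}" for lid in layers]
        for lid, vals in zip(layers, data):
            s = pd.Series(vals)
            rows.append({"layer_id": lid, "median": float(s.median()),
                         "q1": float(s.quantile(0.25)), "q3": float(s.quantile(0.75)),
                         "n": len(s)})
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel(f"{response} {_UNITS[response]}".strip())
    ax.set_title(f"{response} per layer" + (" and side" if by_side else ""))
    fig.tight_layout()
    csv = out.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv, index=False, float_format="%.6g")
    return _save(fig, out), csv


def main_effect_plot(
    table: pd.DataFrame, response: str, factor: str, out: Path
) -> tuple[Path, Path]:
    col = _response_column(table, response)
    key = {"layer": "layer_id", "side": "side"}[factor]
    means = table.groupby(key, observed=True)[col].mean().sort_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(range(len(means)), means.to_numpy(), "o-")
    ax.set_xticks(range(len(means)))
    ax.set_xticklabels([f"L{v}" if key == "layer_id" else str(v) for v in means.index])
    ax.set_ylabel(f"mean {response} {_UNITS[response]}".strip())
    ax.set_title(f"Main effect of {factor} on {response}")
    fig.tight_layout()
    csv = out.with_suffix(".csv")
    means.rename("mean").reset_index().to_csv(csv, index=False, float_format="%.6g")
    return _save(fig, out), csv


def interaction_plot(
    table: pd.DataFrame, response: str, out: Path
) -> tuple[Path, Path]:
    col = _response_column(table, response)
    cell = (
        table.groupby(["layer_id", "side"], observed=True)[col].mean().unstack("side")
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    for side in cell.columns:
        ax.plot(cell.index, cell[side], "o-", label=side)
    ax.set_xlabel("layer")
    ax.set_xticks(list(cell.index))
    ax.set_xticklabels([f"L{v}" for v in cell.index])
    ax.set_ylabel(f"mean {response} {_UNITS[response]}".strip())
    ax.set_title(f"Layer × side interaction: {response}")
    ax.legend(title="side")
    fig.tight_layout()
    csv = out.with_suffix(".csv")
    cell.reset_index().to_csv(csv, index=False, float_format="%.6g")
    return _save(fig, out), csv


def render_figures(
    table: pd.DataFrame, bundle: AnalysisBundle | None, out_dir: str | Path
) -> list[Path]:
    """All figures for all four responses; returns written image paths.

    With a single observed side, the split boxplot, side main-effect and
    interaction plots are skipped with a notice on the returned bundle.
    """
    if len(table) == 0:
        raise ValueError("empty morphometry table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    two_sided = table["side"].nunique() >= 2
    written: list[Path] = []
    for resp in RESPONSE_COLUMNS:
        written.append(boxplot_by_layer(table, resp, out_dir / f"box_{resp}_layer.png")[0])
        written.append(
            main_effect_plot(table, resp, "layer", out_dir / f"main_{resp}_layer.png")[0]
        )
        if two_sided:
            written.append(
                boxplot_by_layer(table, resp, out_dir / f"box_{resp}_layer_side.png",
                                 by_side=True)[0]
            )
            written.append(
                main_effect_plot(table, resp, "side", out_dir / f"main_{resp}_side.png")[0]
            )
            written.append(
                interaction_plot(table, resp, out_dir / f"interaction_{resp}.png")[0]
            )
        elif bundle is not None:
            bundle.notices.append(
                f"single-side table: side/interaction plots for {resp} skipped"
            )
    return written
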