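"""Group summaries and factorial ANOVA for laminar asymmetry.

Each response Y in {area, perimeter, aspect ratio, density} is analysed
under the two-factor linear model

    Y_ijk = mu + tau_i + beta_j + (tau beta)_ij + eps_ijk,   eps ~ N(0, s²)

where tau is the cortical layer (L1..L6), beta the hemisphere side
(left/right) and (tau beta) their interaction — the departure of the twelve
layer-by-side cell means from additivity.  The analysis reports, per
response: group summaries (n, mean, SEM, Q1, Q3) for the per-layer,
per-side and per-layer-and-side groupings; one-way F tests for each factor
alone; and the two-way ANOVA with interaction.  Because segmentation yields
unequal cell counts per design cell, Type II sums of squares are the
default (invariant to factor order); Type III with sum contrasts is
available.  The observational unit is the individual cell.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

#: Short response names -> morphometry table columns.
RESPONSE_COLUMNS = {
    "area": "area_um2",
    "perimeter": "perimeter_um",
    "aspect_ratio": "aspect_ratio",
    "density": "density",
}
GROUPINGS = ("layer", "side", "layer_side")


class AnalysisError(ValueError):
    """Design or input problem that prevents a valid analysis."""


def _response_column(table: pd.DataFrame, response: str) -> str:
    col = RESPONSE_COLUMNS.get(response, response)
    if col not in table.columns:
        raise AnalysisError(f"response column {col!r} missing from table")
    return col


@dataclasses.dataclass
class ModelSpec:
    """Configuration of the factorial analysis."""

    include_interaction: bool = True
    ss_type: int = 2  # Type II default for unbalanced cells; 3 optional
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.ss_type not in (2, 3):
            raise AnalysisError("ss_type must be 2 or 3")
        if not 0 < self.alpha < 1:
            raise AnalysisError("alpha must lie in (0, 1)")


@dataclasses.dataclass
class EffectRow:
    """One line of an ANOVA table."""

    effect: str
    df: float
    ss: float
    f: float
    p: float


@dataclasses.dataclass
class AnovaReport:
    """Factorial ANOVA result for one response."""

    response: str
    rows: list[EffectRow]
    cell_means: pd.DataFrame  # layer x side means for interaction plots
    layer_means: pd.Series
    side_means: pd.Series
    ss_type: int
    degenerate: bool = False

    def row(self, effect: str) -> EffectRow:
        for r in self.rows:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "ss_type": self.ss_type,
            "degenerate": bool(self.degenerate),
            "effects": [dataclasses.asdict(r) for r in self.rows],
            "side_means": {str(k): float(v) for k, v in self.side_means.items()},
            "layer_means": {str(k): float(v) for k, v in self.layer_means.items()},
        }


def summarize_groups(
    table: pd.DataFrame, response: str, grouping: str
) -> pd.DataFrame:
    """Per-group n, mean, SEM, Q1 and Q3 of one response.

    ``grouping`` is ``"layer"``, ``"side"`` or ``"layer_side"``.  SEM is the
    sample standard deviation (ddof = 1) over sqrt(n), zero for singleton
    groups; quartiles interpolate linearly between order statistics.
    """
    col = _response_column(table, response)
    if grouping not in GROUPINGS:
        raise AnalysisError(f"grouping must be one of {GROUPINGS}")
    keys = {"layer": ["layer_id"], "side": ["side"],
            "layer_side": ["layer_id", "side"]}[grouping]
    for key in keys:
        if key not in table.columns:
            raise AnalysisError(f"grouping column {key!r} missing from table")
    rows = []
    for name, grp in table.groupby(keys, sort=True, observed=True):
        vals = grp[col].to_numpy(float)
        n = vals.size
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        labels = name if isinstance(name, tuple) else (name,)
        rows.append({
            **dict(zip(keys, labels)),
            "n": n,
            "mean": float(vals.mean()),
            "sem": sem,
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
        })
    out = pd.DataFrame(rows)
    out.attrs["response"] = response
    out.attrs["grouping"] = grouping
    return out


def one_way_anova(table: pd.DataFrame, response: str, factor: str) -> EffectRow:
    """One-way F test of group-mean equality for one factor.

    ``factor`` is ``"layer"`` or ``"side"``.  Uses the textbook
    between/within sum-of-squares decomposition.  A design with zero
    within-group variance is degenerate: F is undefined (NaN) when the
    group means also coincide, infinite otherwise.
    """
    col = _response_column(table, response)
    key = {"layer": "layer_id", "side": "side"}.get(factor, factor)
    if key not in table.columns:
        raise AnalysisError(f"factor column {key!r} missing from table")
    groups = [g[col].to_numpy(float) for _, g in table.groupby(key, observed=True)]
    names = [n for n, _ in table.groupby(key, observed=True)]
    if len(groups) < 2:
        raise AnalysisError(f"factor {factor!r} has fewer than 2 observed levels")
    for name, g in zip(names, groups):
        if g.size < 2:
            raise AnalysisError(f"level {name!r} of factor {factor!r} has < 2 observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return EffectRow(factor, df_b, 0.0, float("nan"), float("nan"))
        return EffectRow(factor, df_b, float(ss_between), float("inf"), 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return EffectRow(factor, df_b, float(ss_between), float(f), p)


def two_way_anova(
    table: pd.DataFrame, response: str, spec: ModelSpec | None = None
) -> AnovaReport:
    """Two-way layer x side ANOVA with interaction.

    Fits the full factorial model by least squares and reports F and p for
    layer, side and their interaction under the configured sum-of-squares
    type (Type III uses sum-to-zero contrasts).  Every layer x side design
    cell must be populated.
    """
    spec = spec or ModelSpec()
    col = _response_column(table, response)
    for key in ("layer_id", "side"):
        if key not in table.columns:
            raise AnalysisError(f"column {key!r} missing from table")
    data = table[[col, "layer_id", "side"]].rename(columns={col: "y"}).copy()
    layers = sorted(data["layer_id"].unique())
    sides = sorted(data["side"].unique())
    if len(layers) < 2 or len(sides) < 2:
        raise AnalysisError("two-way ANOVA needs >= 2 levels of both factors")
    counts = data.groupby(["layer_id", "side"], observed=True).size()
    for lid in layers:
        for side in sides:
            if (lid, side) not in counts.index:
                raise AnalysisError(f"empty design cell: layer {lid}, side {side!r}")

    if spec.ss_type == 3:
        terms = "C(layer_id, Sum)", "C(side, Sum)"
    else:
        terms = "C(layer_id)", "C(side)"
    formula = f"y ~ {terms[0]} + {terms[1]}"
    if spec.include_interaction:
        formula += f" + {terms[0]}:{terms[1]}"
    fit = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=spec.ss_type)

    rows = []
    pairs = [("layer", "C(layer_id"), ("side", "C(side")]
    if spec.include_interaction:
        pairs.append(("layer:side", ":"))
    for name, token in pairs:
        if name != "layer:side":
            hits = [ix for ix in anova.index if ix.startswith(token) and ":" not in ix]
        else:
            hits = [ix for ix in anova.index if ":" in ix]
        if len(hits) != 1:
            raise RuntimeError(f"cannot locate effect {name!r} in ANOVA table")
        row = anova.loc[hits[0]]
        rows.append(EffectRow(name, float(row["df"]), float(row["sum_sq"]),
                              float(row["F"]), float(row["PR(>F)"])))
    resid = anova.loc["Residual"]
    rows.append(EffectRow("residual", float(resid["df"]), float(resid["sum_sq"]),
                          float("nan"), float("nan")))

    cell_means = (
        data.groupby(["layer_id", "side"], observed=True)["y"].mean().unstack("side")
    )
    return AnovaReport(
        response=response,
        rows=rows,
        cell_means=cell_means,
        layer_means=data.groupby("layer_id", observed=True)["y"].mean(),
        side_means=data.groupby("side", observed=True)["y"].mean(),
        ss_type=spec.ss_type,
        degenerate=not np.isfinite(resid["sum_sq"]) or resid["sum_sq"] <= 0,
    )


@dataclasses.dataclass
class AnalysisBundle:
    """Full statistical output: per-response reports and summaries."""

    reports: dict          # response -> AnovaReport (or None when skipped)
    one_way: dict          # response -> {factor: EffectRow}
    summaries: dict        # response -> {grouping: DataFrame}
    notices: list

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "notices": self.notices,
            "one_way": {
                resp: {fac: dataclasses.asdict(row) for fac, row in rows.items()}
                for resp, rows in self.one_way.items()
            },
            "two_way": {
                resp: (rep.to_dict() if rep is not None else None)
                for resp, rep in self.reports.items()
            },
        }
        text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summaries_to_csv(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for resp, by_grouping in self.summaries.items():
            for grouping, df in by_grouping.items():
                path = out_dir / f"summary_{resp}_{grouping}.csv"
                df.to_csv(path, index=False, float_format="%.6g")
                written.append(path)
        return written


def run_full_analysis(
    table: pd.DataFrame, spec: ModelSpec | None = None
) -> AnalysisBundle:
    """Summaries plus one-way and two-way ANOVA for all four responses.

    With a single observed hemisphere side the side and interaction tests
    are skipped with an explicit notice rather than an error.
    """
    spec = spec or ModelSpec()
    if len(table) == 0:
        raise AnalysisError("empty morphometry table")
    for resp in RESPONSE_COLUMNS:
        _response_column(table, resp)

    sides = sorted(table["side"].unique())
    two_sided = len(sides) >= 2
    notices: list[str] = []
    if not two_sided:
        notices.append(
            f"single hemisphere side {sides[0]!r} observed: side and "
            "interaction tests skipped"
        )
    reports: dict = {}
    one_way: dict = {}
    summaries: dict = {}
    for resp in RESPONSE_COLUMNS:
        summaries[resp] = {
            g: summarize_groups(table, resp, g)
            for g in (GROUPINGS if two_sided else ("layer",))
        }
        one_way[resp] = {"layer": one_way_anova(table, resp, "layer")}
        if two_sided:
            one_way[resp]["side"] = one_way_anova(table, resp, "side")
            reports[resp] = two_way_anova(table, resp, spec)
        else:
            reports[resp] = None
    return AnalysisBundle(reports=reports, one_way=one_way,
                          summaries=summaries, notices=notices)
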