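"""Raster prediction, binary maps, response curves and the model report."""

from __future__ import annotations

import html
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import evaluate, select_threshold, tss
from .models import TrainedModel
from .raster import RasterStack, write_ascii_grid
from .swd import SWDTable

__all__ = ["predict_raster", "binarize", "response_curve", "model_report"]


def predict_raster(model: TrainedModel, stack: RasterStack, output: str = "default") -> np.ndarray:
    """Project the model over a raster stack.

    Every finite cell equals ``model.predict`` on that cell's covariate
    vector; cells with any missing covariate are NaN. ``output="raw"``
    renormalises the Maxent raw output to sum 1 over the full extent
    (the AICc convention).
    """
    missing = [v for v in model.variable_names if v not in stack.names]
    if missing:
        raise KeyError(f"stack lacks layers for variables: {missing}")
    mask = stack.valid_mask()
    table = stack.flat_table()[model.variable_names]
    out = np.full(stack.shape, np.nan).ravel()
    flat_mask = mask.ravel()
    scores = model.predict(table.iloc[flat_mask], output=output)
    if output == "raw":
        scores = scores / scores.sum()
    out[flat_mask] = scores
    return out.reshape(stack.shape)


def binarize(raster: np.ndarray, threshold: float) -> np.ndarray:
    """Presence(1)/absence(0) map: cell >= threshold; NaN preserved."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = np.where(np.asarray(raster, float) >= threshold, 1.0, 0.0)
    out[np.isnan(raster)] = np.nan
    return out


def response_curve(
    model: TrainedModel, table: SWDTable, variable: str, n_points: int = 100
) -> pd.DataFrame:
    """Marginal response: vary one variable over its training range with
    all others held at their training means."""
    if variable not in model.variable_names:
        raise KeyError(f"unknown variable {variable!r}")
    col = table.data[variable].to_numpy(float)
    grid = np.linspace(np.nanmin(col), np.nanmax(col), n_points)
    probe = pd.DataFrame(
        {v: np.full(n_points, float(np.nanmean(table.data[v]))) for v in model.variable_names}
    )
    probe[variable] = grid
    return pd.DataFrame({"value": grid, "prediction": model.predict(probe)})


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _metric_table(model, metric, train, validation, test, fold):
    rows = []
    res = evaluate(model, train, metric, validation=validation)
    rows.append(("train", res.train_value))
    if res.validation_value is not None:
        rows.append(("validation", res.validation_value))
    if test is not None:
        rows.append(("test", evaluate(model, test, metric).train_value))
    return rows


def model_report(
    model: TrainedModel,
    train_table: SWDTable,
    out_dir,
    metric: str = "auc",
    validation: SWDTable | None = None,
    test: SWDTable | None = None,
    importance=None,
    selection_trace=None,
    tune_result=None,
    seed: int = 0,
    make_figures: bool = True,
) -> Path:
    """Write a self-contained model report.

    Produces ``report.md`` and ``report.html`` plus machine-readable
    sidecars (metrics.csv, importance.csv, thresholds.csv, optional
    trace.csv / tuning.csv) and static ROC / response-curve figures.
    Byte-identical sidecars under identical inputs and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = _metric_table(model, metric, train_table, validation, test, None)
    metrics_df = pd.DataFrame(rows, columns=["dataset", metric])
    metrics_df.to_csv(out_dir / "metrics.csv", index=False)

    if importance is None:
        from .importance import permutation_importance

        importance = permutation_importance(model, train_table, metric="auc" if metric == "aicc" else metric, seed=seed)
    imp_df = importance.to_frame()
    imp_df.to_csv(out_dir / "importance.csv", index=False)

    scores = model.predict(train_table)
    p = scores[train_table.labels == 1]
    c = scores[train_table.labels == 0]
    thr_df = pd.DataFrame(
        [(rule, select_threshold(p, c, rule))
         for rule in ("max_tss", "equal_sens_spec", "min_training_presence")],
        columns=["rule", "threshold"],
    )
    thr_df.to_csv(out_dir / "thresholds.csv", index=False)

    if selection_trace is not None:
        selection_trace.to_frame().to_csv(out_dir / "trace.csv", index=False)
    if tune_result is not None:
        tune_result.to_frame().to_csv(out_dir / "tuning.csv", index=False)
        (out_dir / "tuning.json").write_text(tune_result.to_json())

    figures = []
    if make_figures:
        figures = _figures(model, train_table, p, c, out_dir)

    md = _markdown(model, metric, metrics_df, imp_df, thr_df,
                   selection_trace, tune_result, figures)
    (out_dir / "report.md").write_text(md)
    (out_dir / "report.html").write_text(_to_html(md))
    return out_dir / "report.md"


def _figures(model, train_table, p, c, out_dir) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    # ROC curve
    thresholds = np.unique(np.concatenate([p, c]))[::-1]
    tpr = [(p >= t).mean() for t in thresholds] + [1.0]
    fpr = [(c >= t).mean() for t in thresholds] + [1.0]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("ROC (training data)")
    fig.tight_layout()
    fig.savefig(out_dir / "roc.png", dpi=100)
    plt.close(fig)
    names.append("roc.png")
    # response curves
    for v in model.variable_names:
        curve = response_curve(model, train_table, v, n_points=50)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(curve["value"], curve["prediction"])
        ax.set_xlabel(v)
        ax.set_ylabel("prediction")
        fig.tight_layout()
        fname = f"response_{v}.png"
        fig.savefig(out_dir / fname, dpi=100)
        plt.close(fig)
        names.append(fname)
    return names


def _df_to_md(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = [
        "| " + " | ".join(
            f"{v:.4f}" if isinstance(v, float) else str(v) for v in row
        ) + " |"
        for row in df.itertuples(index=False)
    ]
    return "\n".join([header, sep, *body])


def _markdown(model, metric, metrics_df, imp_df, thr_df, trace, tune, figures) -> str:
    parts = [
        "# Species distribution model report",
        "",
        "## Model",
        "",
        "```",
        model.summary(),
        "```",
        "",
        f"## Performance ({metric.upper()})",
        "",
        _df_to_md(metrics_df),
        "",
        "## Permutation importance",
        "",
        _df_to_md(imp_df),
        "",
        "## Thresholds",
        "",
        _df_to_md(thr_df),
    ]
    if trace is not None and len(trace.steps):
        parts += ["", "## Variable selection trace", "", _df_to_md(trace.to_frame())]
    if tune is not None:
        parts += ["", "## Hyperparameter tuning", "",
                  f"Trainings performed: {tune.trainings_performed} "
                  f"(cache hits: {tune.cache_hits})", "",
                  _df_to_md(tune.to_frame().head(10))]
    if figures:
        parts += ["", "## Figures", ""]
        parts += [f"![{f}]({f})" for f in figures]
    return "\n".join(parts) + "\n"


def _to_html(md: str) -> str:
    """Minimal standalone HTML rendering (tables, headers, images, code)."""
    lines_out = []
    in_code = False
    in_table = False
    for line in md.splitlines():
        if line.startswith("```"):
            lines_out.append("<pre>" if not in_code else "</pre>")
            in_code = not in_code
            continue
        if in_code:
            lines_out.append(html.escape(line))
            continue
        if line.startswith("|"):
            cells = [c.strip() for c in line.strip("|").split("|")]
            if set("".join(cells)) <= {"-"}:
                continue
            tag = "th" if not in_table else "td"
            if not in_table:
                lines_out.append("<table border='1'>")
                in_table = True
            lines_out.append(
                "<tr>" + "".join(f"<{tag}>{html.escape(c)}</{tag}>" for c in cells) + "</tr>"
            )
            continue
        if in_table:
            lines_out.append("</table>")
            in_table = False
        if line.startswith("# "):
            lines_out.append(f"<h1>{html.escape(line[2:])}</h1>")
        elif line.startswith("## "):
            lines_out.append(f"<h2>{html.escape(line[3:])}</h2>")
        elif line.startswith("!["):
            src = line[line.index("(") + 1 : line.rindex(")")]
            lines_out.append(f"<img src='{html.escape(src)}' />")
        elif line.strip():
            lines_out.append(f"<p>{html.escape(line)}</p>")
    if in_table:
        lines_out.append("</table>")
    body = "\n".join(lines_out)
    return f"<!DOCTYPE html><html><head><meta charset='utf-8'><title>SDM report</title></head><body>\n{body}\n</body></html>\n"
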