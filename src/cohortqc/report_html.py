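"""Minimal HTML rendering for intra and inter QC reports.

Pages are self-contained (inline CSS, no external assets) and every number
shown also exists in a machine-readable TSV written alongside — the HTML is
a view, never the only record.  Scores in [1, 5] are colour-coded from red
(1) through yellow (3) to green (5), the same scale as the cohort heatmap.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
h1 {{ font-size: 1.4em; }} h2 {{ font-size: 1.1em; margin-top: 1.6em; }}
table {{ border-collapse: collapse; font-size: 0.85em; }}
th, td {{ border: 1px solid #ccc; padding: 3px 8px; text-align: right; }}
th {{ background: #f0f0f0; }} td.t {{ text-align: left; }}
.note {{ color: #666; font-size: 0.85em; }}
</style></head><body>
<h1>{title}</h1>
{body}
</body></html>
"""


def _score_color(score: float) -> str:
    if score != score:  # NaN
        return "#eeeeee"
    x = (min(max(score, 1.0), 5.0) - 1.0) / 4.0
    if x < 0.5:
        r, g = 230, int(60 + 170 * (x / 0.5))
    else:
        r, g = int(230 - 180 * ((x - 0.5) / 0.5)), 200
    return f"rgb({r},{g},60)"


def _score_cell(score: float, text: str | None = None) -> str:
    label = text if text is not None else ("" if score != score else f"{score:.2f}")
    return f'<td style="background:{_score_color(score)}">{label}</td>'


def render_intra_page(run_id: str, metrics, scorecard, decomposition=None) -> str:
    """Metric-score diagram for one run."""
    rows = []
    for m in metrics:
        val = "n/a" if not m.computable else f"{m.value:.4g}"
        cell = _score_cell(float("nan"), "-") if m.score is None else _score_cell(m.score)
        note = m.reason or ""
        rows.append(
            f'<tr><td class="t">{m.metric_id}</td><td class="t">{m.category}</td>'
            f'<td>{val}</td><td class="t">{m.unit}</td>{cell}<td class="t">{note}</td></tr>'
        )
    body = [
        "<h2>Second-level metric scores</h2>",
        "<table><tr><th>metric</th><th>category</th><th>value</th><th>unit</th>"
        "<th>score</th><th>note</th></tr>",
        *rows,
        "</table>",
    ]
    if scorecard is not None:
        body.append("<h2>First-level scores</h2><table><tr><th>factor</th><th>score</th></tr>")
        for cat, s in sorted(scorecard.first_level.items()):
            body.append(f'<tr><td class="t">{cat}</td>{_score_cell(s)}</tr>')
        body.append(f'<tr><td class="t"><b>total</b></td>{_score_cell(scorecard.total)}</tr>')
        body.append("</table>")
        if scorecard.flags:
            body.append(
                f'<p class="note">Flagged (score &lt; 3): {", ".join(scorecard.flags)}</p>'
            )
    if decomposition is not None:
        d = decomposition
        body.append(
            "<h2>MS2 utilization decomposition</h2>"
            "<table><tr><th>acquired MS2</th><th>identified MS2</th><th>Q_MS2</th>"
            "<th>complexity</th><th>duplicate rate</th><th>utilization</th>"
            "<th>unique precursors</th></tr>"
            f"<tr><td>{d.n_acquired_ms2}</td><td>{d.n_identified_ms2}</td>"
            f"<td>{d.q_ms2:.3f}</td><td>{d.spectra_complexity:.2f}</td>"
            f"<td>{d.dup_rate:.2f}</td><td>{d.utilization:.2f}</td>"
            f"<td>{d.n_unique_precursors}</td></tr></table>"
        )
    return _PAGE.format(title=f"Run QC report — {run_id}", body="\n".join(body))


def render_inter_page(matrix, outlier_report: pd.DataFrame) -> str:
    """Cohort score heatmap plus the outlier table."""
    body = ["<h2>Cohort score heatmap (metrics x runs)</h2>"]
    header = "".join(f"<th>{r}</th>" for r in matrix.runs)
    lines = [f"<table><tr><th>metric</th>{header}</tr>"]
    for mid in matrix.scores.index:
        cells = []
        for run in matrix.runs:
            s = float(matrix.scores.loc[mid, run])
            v = matrix.values.loc[mid, run]
            flagged = bool(matrix.flags.loc[mid, run])
            label = f"{v:.3g}" + ("*" if flagged else "")
            cells.append(_score_cell(s, label))
        lines.append(f'<tr><td class="t">{mid}</td>{"".join(cells)}</tr>')
    lines.append("</table>")
    body.extend(lines)
    body.append('<p class="note">Cell text is the metric value; * marks a 2-SD flag; '
                "colour is the 1-5 score.</p>")
    body.append("<h2>Reported low-quality runs</h2>")
    if outlier_report.empty:
        body.append("<p>None.</p>")
    else:
        body.append("<table><tr><th>run</th><th>anomaly score</th>"
                    "<th>flagged metrics (n)</th><th>which</th></tr>")
        for row in outlier_report.itertuples():
            body.append(
                f'<tr><td class="t">{row.run_id}</td><td>{row.anomaly_score:.3f}</td>'
                f'<td>{row.n_flagged_metrics}</td><td class="t">{row.flagged_metrics}</td></tr>'
            )
        body.append("</table>")
    return _PAGE.format(title="Cohort QC report", body="\n".join(body))


def write_text(path: str | Path, text: str) -> Path:
    path = Path(path)
    path.write_text(text)
    return path
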