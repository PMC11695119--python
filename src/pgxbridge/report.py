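"""Internal laboratory review document.

Before results file to the EHR, the performing technologist reviews a
per-run document listing every sample's calls — genotype, phenotype,
activity score, abnormal flag, comment — with provenance: the generation
date and the raw instrument file names the data came from. The plain-text
rendering is canonical (deterministic given results, export and clock); the
PDF is a formatting layer over it, rendered with matplotlib.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Callable, Sequence

from .engine import ContractError, InstrumentExport, SampleGeneResult

_COLUMNS = ("Sample", "Gene", "Genotype", "Phenotype", "Activity", "Abn", "Comment")


@dataclass
class ReviewDocument:
    generated_at: datetime
    source_files: list[str]
    rows: list[tuple[str, str, str, str, str, str, str]]
    text: str


def _result_row(r: SampleGeneResult) -> tuple[str, str, str, str, str, str, str]:
    if r.resulted:
        return (
            r.sample_id,
            r.gene,
            r.diplotype or "",
            r.phenotype or "",
            "" if r.activity_score is None else f"{r.activity_score:g}",
            "A" if r.abnormal else "",
            r.comment,
        )
    return (r.sample_id, r.gene, r.status.value, "", "", "", "")


def render_review_text(
    results: Sequence[SampleGeneResult],
    export: InstrumentExport,
    generated_at: datetime,
) -> tuple[str, list[tuple[str, str, str, str, str, str, str]]]:
    rows = [_result_row(r) for r in results]
    widths = [
        max(len(_COLUMNS[i]), max((len(row[i]) for row in rows), default=0))
        for i in range(len(_COLUMNS))
    ]

    def fmt(cells: Sequence[str]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()

    lines = [
        "PGx LABORATORY REVIEW DOCUMENT",
        f"Generated: {generated_at.strftime('%Y-%m-%d %H:%M:%S')}",
        "Raw data files: " + ", ".join(export.source_files),
        "",
        fmt(_COLUMNS),
        fmt(["-" * w for w in widths]),
    ]
    lines.extend(fmt(row) for row in rows)
    n_resulted = sum(1 for r in results if r.resulted)
    lines += ["", f"Rows: {len(rows)}  Resulted: {n_resulted}  Not resulted: {len(rows) - n_resulted}"]
    return "\n".join(lines) + "\n", rows


def write_review_pdf(text: str, pdf_path: str | Path, lines_per_page: int = 60) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    lines = text.splitlines()
    with PdfPages(pdf_path) as pdf:
        for start in range(0, max(len(lines), 1), lines_per_page):
            fig = plt.figure(figsize=(8.5, 11))
            fig.text(
                0.05,
                0.97,
                "\n".join(lines[start : start + lines_per_page]),
                family="monospace",
                fontsize=7,
                va="top",
            )
            pdf.savefig(fig)
            plt.close(fig)


def generate_review_document(
    results: Sequence[SampleGeneResult],
    export: InstrumentExport,
    clock: Callable[[], datetime],
    out_path: str | Path,
    pdf: bool = True,
) -> ReviewDocument:
    """Render and write the review document.

    ``out_path`` is the stem: ``<out_path>.txt`` is always written (the
    canonical, diffable rendering); ``<out_path>.pdf`` is written unless
    ``pdf`` is disabled. One row per result, non-Resulted results rendered
    with their status string in the genotype column.
    """
    if not results:
        raise ContractError("cannot generate a review document for zero results")
    generated_at = clock()
    text, rows = render_review_text(results, export, generated_at)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.with_suffix(".txt").write_text(text, encoding="utf-8")
    if pdf:
        write_review_pdf(text, out_path.with_suffix(".pdf"))
    return ReviewDocument(
        generated_at=generated_at,
        source_files=list(export.source_files),
        rows=rows,
        text=text,
    )
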