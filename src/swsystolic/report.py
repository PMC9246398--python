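"""Result serialization: plain-text alignment rendering, JSON and TSV."""

from __future__ import annotations

import json

from .aligner import Alignment, ForwardResult
from .errors import ConfigurationError
from .metrics import PerfReport

__all__ = ["write_result", "OUTPUT_FORMATS"]

OUTPUT_FORMATS = ("text", "json", "tsv")


def _result_dict(
    fw: ForwardResult,
    aln: Alignment,
    perf: PerfReport | None,
    extra: dict | None,
) -> dict:
    out = {
        "score": aln.score,
        "max_value": int(fw.max_value),
        "max_row": int(fw.max_row),
        "max_col": int(fw.max_col),
        "start_row": aln.start_row,
        "start_col": aln.start_col,
        "end_row": aln.end_row,
        "end_col": aln.end_col,
        "cigar": aln.cigar,
        "aligned_query": aln.aligned_query,
        "aligned_database": aln.aligned_database,
        "path_codes": list(aln.path_codes),
        "cell_count": fw.cell_count,
    }
    if perf is not None:
        out["performance"] = perf.to_dict()
    if extra:
        out.update(extra)
    return out


def _render_text(
    fw: ForwardResult,
    aln: Alignment,
    perf: PerfReport | None,
    extra: dict | None,
) -> str:
    lines = []
    if aln.pairs:
        lines.append(f"Query:    {aln.aligned_query}")
        lines.append(f"          {aln.match_line()}")
        lines.append(f"Database: {aln.aligned_database}")
    else:
        lines.append("(empty alignment)")
    # Row/Column: 1-based matrix position where the alignment starts
    # (row indexes the database s, column the query q).
    lines.append(f"Row: {aln.start_row}")
    lines.append(f"Column: {aln.start_col}")
    lines.append(f"Maximum Value: {aln.score}")
    lines.append(f"CIGAR: {aln.cigar}")
    if perf is not None:
        lines.append(f"GCUPS: {perf.gcups:g}")
    if extra:
        for key, value in extra.items():
            lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"


def _render_tsv(
    fw: ForwardResult,
    aln: Alignment,
    perf: PerfReport | None,
    extra: dict | None,
) -> str:
    columns = [
        ("score", aln.score),
        ("start_row", aln.start_row),
        ("start_col", aln.start_col),
        ("end_row", aln.end_row),
        ("end_col", aln.end_col),
        ("cigar", aln.cigar),
        ("aligned_query", aln.aligned_query),
        ("aligned_database", aln.aligned_database),
    ]
    if perf is not None:
        columns.append(("gcups", perf.gcups))
    if extra:
        columns.extend(extra.items())
    header = "\t".join(str(k) for k, _ in columns)
    row = "\t".join(str(v) for _, v in columns)
    return header + "\n" + row + "\n"


def write_result(
    fw: ForwardResult,
    aln: Alignment,
    perf: PerfReport | None = None,
    fmt: str = "text",
    extra: dict | None = None,
) -> str:
    """Serialize an alignment result.

    ``text`` shows the two gapped rows with a match line plus the start
    Row/Column, Maximum Value and CIGAR; ``json`` carries every field
    machine-readably; ``tsv`` emits a header plus one row per alignment.
    ``extra`` entries (e.g. seed, cycle counts) are merged into the output.
    """
    if fmt == "text":
        return _render_text(fw, aln, perf, extra)
    if fmt == "json":
        return json.dumps(_result_dict(fw, aln, perf, extra), indent=2) + "\n"
    if fmt == "tsv":
        return _render_tsv(fw, aln, perf, extra)
    raise ConfigurationError(
        f"unknown output format {fmt!r}; choose one of {OUTPUT_FORMATS}"
    )
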