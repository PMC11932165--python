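"""Human- and machine-readable screen reports.

The presence matrix mirrors the familiar filled/half-filled/empty-square
figure: rows are genomes (lexicographic), columns are enzymes in catalog
order, and cells are 2 (fully recovered), 1 (partially recovered) or 0
(absent).  The matrix is lossless at the enzyme level: re-parsing it
recovers each enzyme's status exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Mapping, Sequence

from .screening import EnzymeStatus, PathwayProfile, ScreenReport

_CELL = {"full": "2", "partial": "1", "absent": "0"}
_STATUS = {v: k for k, v in _CELL.items()}


class ReportError(ValueError):
    pass


def render_matrix(profiles: Sequence[PathwayProfile]) -> str:
    """Render pathway profiles as a genome x enzyme presence matrix (TSV).

    Profiles of several pathways for the same genome are merged into one
    row; all genomes must share the same catalogs (same enzyme columns per
    pathway name).
    """
    columns: list[str] = []
    col_order: dict[str, list[str]] = {}
    for p in profiles:
        names = [st.enzyme_name for st in p.statuses]
        if p.pathway_name in col_order:
            if col_order[p.pathway_name] != names:
                raise ReportError(
                    f"profiles disagree on enzyme order for pathway "
                    f"{p.pathway_name!r}"
                )
        else:
            col_order[p.pathway_name] = names
            columns.extend(names)

    rows: dict[str, dict[str, str]] = {}
    for p in profiles:
        row = rows.setdefault(p.genome_id, {})
        for st in p.statuses:
            row[st.enzyme_name] = _CELL[st.status]

    lines = ["genome_id\t" + "\t".join(columns) if columns else "genome_id"]
    for gid in sorted(rows):
        cells = [rows[gid].get(col, "0") for col in columns]
        lines.append("\t".join([gid] + cells))
    return "\n".join(lines) + "\n"


def parse_matrix(text: str) -> dict[str, dict[str, str]]:
    """Parse a presence matrix back into genome -> enzyme -> status."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ReportError("empty matrix")
    header = lines[0].split("\t")
    if header[0] != "genome_id":
        raise ReportError("matrix header must start with 'genome_id'")
    enzymes = header[1:]
    out: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ReportError(f"matrix line {lineno}: wrong column count")
        gid = cells[0]
        out[gid] = {}
        for enz, cell in zip(enzymes, cells[1:]):
            if cell not in _STATUS:
                raise ReportError(
                    f"matrix line {lineno}: invalid cell {cell!r} "
                    "(expected 2, 1 or 0)"
                )
            out[gid][enz] = _STATUS[cell]
    return out


def _status_dict(st: EnzymeStatus) -> dict:
    return {
        "enzyme": st.enzyme_name,
        "branch": st.branch,
        "status": st.status,
        "present_subunits": sorted(st.present_subunits),
        "missing_subunits": sorted(st.missing_subunits),
    }


def report_to_json(report: ScreenReport, include_timestamp: bool = True) -> str:
    """Serialize a ScreenReport; timestamps live only in provenance."""
    provenance = dict(report.provenance)
    provenance["schema"] = "syntroscreen-report/1"
    if include_timestamp:
        import datetime

        provenance["generated_at"] = (
            datetime.datetime.now(datetime.timezone.utc).isoformat())
    doc = {
        "calls": [asdict(c) for c in report.calls],
        "profiles": {
            gid: {
                pw: {
                    "gate_passed": p.gate_passed,
                    "n_missing_genes": p.n_missing_genes,
                    "branch_completeness": p.branch_completeness,
                    "statuses": [_status_dict(st) for st in p.statuses],
                }
                for pw, p in pws.items()
            }
            for gid, pws in report.profiles.items()
        },
        "markers": {
            gid: {name: _status_dict(st) for name, st in mstat.items()}
            for gid, mstat in report.marker_statuses.items()
        },
        "tiers": report.tiers,
        "abundances": report.abundances,
        "unbinned_hits": report.unbinned_hits,
        "warnings": report.warnings,
        "provenance": provenance,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def summarize_calls(report: ScreenReport) -> str:
    """Small fixed-width text summary of the candidate calls."""
    lines = [f"{'genome':<32} {'tier':<8} {'WLP':<14} {'GSRP':<9} "
             f"{'label':<20} pntAB"]
    for call in report.calls:
        tier = report.tiers.get(call.genome_id, "unknown")
        lines.append(
            f"{call.genome_id:<32} {tier:<8} {call.wlp_state:<14} "
            f"{call.gsrp_state:<9} {call.label:<20} "
            f"{'yes' if call.saob_support else 'no'}"
        )
    return "\n".join(lines)
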