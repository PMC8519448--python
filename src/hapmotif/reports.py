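"""Report writers: TSV, GFF3 (UCSC custom track) and HTML.

Column layout follows FIMO's TSV where the fields overlap, with three extra
columns (haplotype frequency, raw haplotype count in GFF3 attributes, and
the ref / non.ref flag) appended last, so downstream FIMO consumers keep
working. All output coordinates are 1-based inclusive.
"""

from __future__ import annotations

import html as _html
import os
from dataclasses import dataclass, field

from .pipeline import MotifOccurrence

TSV_COLUMNS = [
    "motif_id",
    "motif_alt_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
    "matched_sequence",
    "haplotype_frequency",
    "reference",
]

GFF_SOURCE = "hapmotif"
GFF_TYPE = "nucleotide_motif"


@dataclass
class ReportConfig:
    out_dir: str = "."
    prefix: str = "hapmotif"
    formats: tuple = ("tsv", "gff3", "html")
    score_decimals: int = 3

    def __post_init__(self) -> None:
        if not self.formats:
            raise ValueError("at least one report format is required")
        unknown = set(self.formats) - {"tsv", "gff3", "html"}
        if unknown:
            raise ValueError(f"unknown report formats: {sorted(unknown)}")

    def path(self, ext: str) -> str:
        return os.path.join(self.out_dir, f"{self.prefix}.{ext}")


def _fmt_score(value: float, config: ReportConfig) -> str:
    return f"{value:.{config.score_decimals}f}"


def _fmt_p(value: float) -> str:
    return "NA" if value != value else f"{value:.3e}"  # NaN when q disabled


def _fmt_frac(value: float) -> str:
    return f"{value:.6g}"


def _row_fields(occ: MotifOccurrence, config: ReportConfig) -> list[str]:
    return [
        occ.motif_id,
        occ.motif_name,
        occ.region_id,
        str(occ.start),
        str(occ.stop),
        occ.strand,
        _fmt_score(occ.score, config),
        _fmt_p(occ.pvalue),
        _fmt_p(occ.qvalue),
        occ.sequence,
        _fmt_frac(occ.haplotype_fraction),
        occ.flag,
    ]


def write_tsv(occurrences: list[MotifOccurrence], config: ReportConfig) -> str:
    path = config.path("tsv")
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for occ in occurrences:
            fh.write("\t".join(_row_fields(occ, config)) + "\n")
    return path


_GFF_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _gff_escape(value: str) -> str:
    out = value.replace("%", "%25")
    for ch, esc in _GFF_ESCAPES.items():
        if ch != "%":
            out = out.replace(ch, esc)
    return out


def write_gff3(occurrences: list[MotifOccurrence], config: ReportConfig) -> str:
    path = config.path("gff3")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, occ in enumerate(occurrences):
            attrs = {
                "Name": occ.motif_name,
                "ID": f"{occ.motif_id}_{occ.chrom}_{occ.start}_{occ.strand}_{i}",
                "pvalue": _fmt_p(occ.pvalue),
                "qvalue": _fmt_p(occ.qvalue),
                "sequence": occ.sequence,
                "haplotype_frequency": _fmt_frac(occ.haplotype_fraction),
                "haplotype_count": str(occ.haplotype_count),
                "reference": occ.flag,
            }
            attr_str = ";".join(
                f"{k}={_gff_escape(v)}" for k, v in attrs.items()
            )
            fh.write(
                "\t".join(
                    [
                        occ.chrom,
                        GFF_SOURCE,
                        GFF_TYPE,
                        str(occ.start),
                        str(occ.stop),
                        _fmt_score(occ.score, config),
                        occ.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )
    return path


_HTML_HEAD = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>Motif occurrence report</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 4px 8px; font-size: 0.9em; }
th { background: #eee; }
</style>
</head>
<body>
<h1>Motif occurrence report</h1>
"""


def write_html(occurrences: list[MotifOccurrence], config: ReportConfig) -> str:
    path = config.path("html")
    with open(path, "w") as fh:
        fh.write(_HTML_HEAD)
        fh.write(f"<p>{len(occurrences)} occurrences</p>\n<table>\n<thead><tr>")
        for col in TSV_COLUMNS:
            fh.write(f"<th>{_html.escape(col)}</th>")
        fh.write("</tr></thead>\n<tbody>\n")
        for occ in occurrences:
            fh.write("<tr>")
            for val in _row_fields(occ, config):
                fh.write(f"<td>{_html.escape(val)}</td>")
            fh.write("</tr>\n")
        fh.write("</tbody>\n</table>\n</body>\n</html>\n")
    return path


def write_reports(occurrences: list[MotifOccurrence], config: ReportConfig) -> dict:
    """Emit every configured format; returns {format: path}."""
    writers = {"tsv": write_tsv, "gff3": write_gff3, "html": write_html}
    return {fmt: writers[fmt](occurrences, config) for fmt in config.formats}
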