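"""Rendering of precursor annotations and machine-readable exports.

The renderer follows the conventional colour scheme for precursor figures:
signal peptide blue, putative peptides red, amide-donor glycines orange,
basic cleavage sites green, neurophysin domain purple; the connecting
C-peptide of insulin-layout precursors is shown cyan.  The ``plain`` format
uses bracket tags instead of colour and parses back to spans losslessly;
every residue appears in exactly one span (the spans tile the protein).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .maturation import MaturePeptide, PrecursorAnnotation

STYLES = (
    "signal", "peptide", "cleavage", "amide_gly", "cys_underline",
    "neurophysin", "c_peptide", "plain",
)

_ANSI = {
    "signal": "\x1b[34m",      # blue
    "peptide": "\x1b[31m",     # red
    "cleavage": "\x1b[32m",    # green
    "amide_gly": "\x1b[33m",   # orange/yellow
    "neurophysin": "\x1b[35m", # purple
    "c_peptide": "\x1b[36m",   # cyan
    "plain": "",
}
_ANSI_RESET = "\x1b[0m"
_ANSI_UNDERLINE = "\x1b[4m"

_PLAIN_TAG_RE = re.compile(r"\[(\w+)\](.*?)\[/\1\]", re.S)

_FEATURE_STYLE = {"neurophysin_domain": "neurophysin", "C_peptide": "c_peptide"}


@dataclass(frozen=True)
class RenderSpan:
    start: int  # 1-based inclusive residue coords
    end: int
    style: str


class RenderError(ValueError):
    """Annotation violates the tiling invariant (overlapping spans)."""


def _validate(annotation: PrecursorAnnotation) -> None:
    n = len(annotation.protein)
    regions = []
    if annotation.signal.present:
        if not (1 <= annotation.signal.cleave_after <= n):
            raise RenderError("signal peptide extends outside the protein")
    for pep in annotation.peptides:
        a, b = pep.precursor_coords
        if not (1 <= a <= b <= n):
            raise RenderError(f"peptide coords {a}-{b} outside protein")
        regions.append((a, b))
    for site in annotation.sites:
        if not (1 <= site.start <= site.end <= n):
            raise RenderError(f"site coords {site.start}-{site.end} outside protein")
        regions.append((site.start, site.end))
    regions.sort()
    for (a1, b1), (a2, b2) in zip(regions, regions[1:]):
        if a2 <= b1:
            raise RenderError(f"overlapping spans {a1}-{b1} and {a2}-{b2}")


def build_spans(annotation: PrecursorAnnotation) -> list[RenderSpan]:
    """Assign one style per residue and compress into tiling spans."""
    _validate(annotation)
    n = len(annotation.protein)
    styles = ["plain"] * n
    if annotation.signal.present:
        for i in range(annotation.signal.cleave_after):
            styles[i] = "signal"
    for pep in annotation.peptides:
        a, b = pep.precursor_coords
        for i in range(a - 1, b):
            styles[i] = "peptide"
    for feat in annotation.features:
        style = _FEATURE_STYLE.get(feat.kind)
        if style:
            a, b = feat.coords
            for i in range(a - 1, b):
                styles[i] = style
    for pep in annotation.peptides:
        if pep.cterm_amide:
            a, b = pep.precursor_coords
            if annotation.protein[b - 1] == "G":
                styles[b - 1] = "amide_gly"
    for site in annotation.sites:
        for i in range(site.start - 1, site.end):
            styles[i] = "cleavage"
    spans: list[RenderSpan] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or styles[i] != styles[start]:
            spans.append(RenderSpan(start + 1, i, styles[start]))
            start = i
    return spans


def render(annotation: PrecursorAnnotation, format: str = "plain") -> str:
    """Render an annotation as tagged plain text, ANSI colour, or HTML."""
    spans = build_spans(annotation)
    prot = annotation.protein
    if format == "plain":
        return "".join(f"[{s.style}]{prot[s.start - 1:s.end]}[/{s.style}]" for s in spans)
    if format == "ansi":
        parts = []
        for s in spans:
            text = prot[s.start - 1 : s.end]
            code = _ANSI[s.style]
            if s.style == "peptide":  # underline disulfide-capable cysteines
                text = text.replace("C", f"{_ANSI_UNDERLINE}C{_ANSI_RESET}{code}")
            parts.append(f"{code}{text}{_ANSI_RESET}" if code else text)
        return "".join(parts)
    if format == "html":
        parts = []
        for s in spans:
            text = prot[s.start - 1 : s.end]
            if s.style == "peptide":
                text = text.replace("C", '<span class="cys_underline">C</span>')
            parts.append(f'<span class="{s.style}">{text}</span>')
        return "".join(parts)
    raise ValueError(f"unknown format {format!r}")


def parse_plain(text: str) -> tuple[str, list[RenderSpan]]:
    """Parse the bracket-tag plain rendering back into (protein, spans)."""
    spans: list[RenderSpan] = []
    protein = []
    pos = 0
    idx = 0
    for m in _PLAIN_TAG_RE.finditer(text):
        if m.start() != idx:
            raise RenderError(f"unparseable rendering near offset {idx}")
        style, chunk = m.group(1), m.group(2)
        if style not in STYLES:
            raise RenderError(f"unknown style tag {style!r}")
        spans.append(RenderSpan(pos + 1, pos + len(chunk), style))
        protein.append(chunk)
        pos += len(chunk)
        idx = m.end()
    if idx != len(text):
        raise RenderError(f"trailing unparseable text at offset {idx}")
    return "".join(protein), spans


PRECURSOR_COLUMNS = [
    "protein_id", "length", "signal_present", "signal_end", "n_sites",
    "n_peptides", "score", "families",
]
PEPTIDE_COLUMNS = [
    "protein_id", "start", "end", "seq", "cterm_amide", "nterm_pyroglu",
    "copy_id", "cys_positions", "sulfation_candidates", "families", "display",
]


def _join(values) -> str:
    return ";".join(str(v) for v in values)


def export_tables(
    annotations: list[PrecursorAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Export (precursor table, peptide table, peptide FASTA).

    FASTA descriptions carry the maturation conventions: ``-NH2`` appended for
    amidated peptides, ``pQ`` noted for pyroglutamate.
    """
    prec_rows, pep_rows, fasta = [], [], []
    for ann in annotations:
        fam_by_pep: dict[int, list[str]] = {}
        for idx, fam in ann.family_hits:
            fam_by_pep.setdefault(idx, []).append(fam)
        prec_rows.append(
            {
                "protein_id": ann.protein_id,
                "length": len(ann.protein),
                "signal_present": ann.signal.present,
                "signal_end": ann.signal.cleave_after if ann.signal.present else 0,
                "n_sites": len(ann.sites),
                "n_peptides": len(ann.peptides),
                "score": ann.score,
                "families": _join(sorted({f for _, f in ann.family_hits})),
            }
        )
        for idx, pep in enumerate(ann.peptides):
            a, b = pep.precursor_coords
            pep_rows.append(
                {
                    "protein_id": ann.protein_id,
                    "start": a, "end": b, "seq": pep.seq,
                    "cterm_amide": pep.cterm_amide,
                    "nterm_pyroglu": pep.nterm_pyroglu,
                    "copy_id": pep.copy_id,
                    "cys_positions": _join(pep.cys_positions),
                    "sulfation_candidates": _join(pep.sulfation_candidates),
                    "families": _join(fam_by_pep.get(idx, [])),
                    "display": pep.display(),
                }
            )
            fasta.append(f">{ann.protein_id}:{a}-{b} {pep.display()}")
            fasta.append(pep.seq)
    prec_df = pd.DataFrame(prec_rows, columns=PRECURSOR_COLUMNS)
    pep_df = pd.DataFrame(pep_rows, columns=PEPTIDE_COLUMNS)
    fasta_str = "\n".join(fasta) + ("\n" if fasta else "")
    return prec_df, pep_df, fasta_str


def write_tables(annotations: list[PrecursorAnnotation], prefix) -> dict[str, Path]:
    """Write the exports next to ``prefix``; returns the paths written."""
    prec_df, pep_df, fasta = export_tables(annotations)
    paths = {
        "precursors": Path(f"{prefix}.precursors.tsv"),
        "peptides": Path(f"{prefix}.peptides.tsv"),
        "fasta": Path(f"{prefix}.peptides.fasta"),
    }
    prec_df.to_csv(paths["precursors"], sep="\t", index=False)
    pep_df.to_csv(paths["peptides"], sep="\t", index=False)
    paths["fasta"].write_text(fasta)
    return paths


def _split_ints(raw) -> list[int]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return []
    return [int(x) for x in str(raw).split(";")]


def read_peptide_table(source) -> dict[str, list[MaturePeptide]]:
    """Reconstruct mature peptides from an exported peptide table (path or DataFrame)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    out: dict[str, list[MaturePeptide]] = {}
    for row in df.itertuples(index=False):
        amide = str(row.cterm_amide).lower() in ("true", "1")
        pyro = str(row.nterm_pyroglu).lower() in ("true", "1")
        pep = MaturePeptide(
            seq=row.seq,
            precursor_coords=(int(row.start), int(row.end)),
            cterm_amide=amide,
            nterm_pyroglu=pyro,
            cys_positions=_split_ints(row.cys_positions),
            sulfation_candidates=_split_ints(row.sulfation_candidates),
            copy_id=int(row.copy_id),
        )
        out.setdefault(str(row.protein_id), []).append(pep)
    return out
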