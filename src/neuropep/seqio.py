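"""Sequence I/O, six-frame translation and ORF extraction.

Nucleotide coordinates are 0-based half-open everywhere inside the package
and are always expressed on the forward strand; they become 1-based inclusive
only at GFF3 emission.  Ambiguity codes other than N are rejected; N
translates to X and X never matches downstream motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> tuple of synonymous codons (used by the fixture generator)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, tuple())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DuplicateIdError(FastaFormatError):
    """Two records share an identifier."""


@dataclass(frozen=True)
class TranscriptContig:
    """A nucleotide (or, in protein mode, amino-acid) sequence record."""

    id: str
    seq: str


@dataclass(frozen=True)
class OpenReadingFrame:
    """A candidate coding region from a six-frame scan.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the forward
    strand; the stop codon is excluded, so ``nt_end - nt_start == 3 * len(protein)``.
    """

    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 on the scanned strand
    nt_start: int
    nt_end: int
    protein: str
    partial5: bool = False
    partial3: bool = False

    @property
    def id(self) -> str:
        return f"{self.contig_id}|{self.strand}|f{self.frame}|{self.nt_start}-{self.nt_end}"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Codon-wise translation; trailing partial codon dropped; N-containing codons -> X."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def read_fasta(path, alphabet: str = "nucleotide") -> list[TranscriptContig]:
    """Read a FASTA file into records, preserving order.

    ``alphabet`` is ``"nucleotide"`` (uppercased, U->T, restricted to ACGTN)
    or ``"protein"`` (20 residues + X; a single trailing ``*`` is stripped).
    Errors name the offending line.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = NT_ALPHABET if alphabet == "nucleotide" else AA_ALPHABET
    records: list[TranscriptContig] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaFormatError(f"line {cur_line}: record {cur_id!r} has empty sequence")
        records.append(TranscriptContig(cur_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                rec_id = header.split()[0]
                if rec_id in seen:
                    raise DuplicateIdError(f"line {lineno}: duplicate record id {rec_id!r}")
                seen.add(rec_id)
                cur_id, cur_line, chunks = rec_id, lineno, []
            else:
                if cur_id is None:
                    raise FastaFormatError(f"line {lineno}: sequence data before first header")
                part = line.upper()
                if alphabet == "nucleotide":
                    part = part.replace("U", "T")
                bad = set(part) - allowed - ({"*"} if alphabet == "protein" else set())
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: illegal character(s) {sorted(bad)!r} for "
                        f"{alphabet} alphabet (ambiguity codes other than N are rejected)"
                    )
                chunks.append(part)
        flush()
    return records


def write_fasta(records: Iterable, path=None, width: int = 60) -> str:
    """Write records (objects with ``.id``/``.seq`` or ``(id, seq)`` pairs) as FASTA."""
    lines = []
    for rec in records:
        rid, seq = (rec.id, rec.seq) if hasattr(rec, "id") else rec
        lines.append(f">{rid}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def six_frame_orfs(
    contig: TranscriptContig, min_len: int = 60, allow_partial: bool = False
) -> list[OpenReadingFrame]:
    """Extract candidate ORFs from all six reading frames.

    Every maximal stop-to-stop segment is considered.  Within a segment the
    reported ORF starts at the first M (leftmost-longest rule); when
    ``allow_partial`` is set, a segment abutting the 5' contig edge is reported
    from the segment start and a segment running off the 3' edge (no stop) is
    reported as 3'-partial.  Without ``allow_partial`` only complete ORFs
    (M start, terminating stop) are returned.  ORFs whose translation is
    entirely X (e.g. all-N contigs) are dropped.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    L = len(contig.seq)
    orfs: list[OpenReadingFrame] = []
    for strand in "+-":
        s = contig.seq if strand == "+" else revcomp(contig.seq)
        for frame in range(3):
            aa = translate(s[frame:])
            n = len(aa)
            i = 0
            while i <= n:
                j = aa.find("*", i)
                stopped = j != -1
                end = j if stopped else n
                seg = aa[i:end]
                if seg:
                    start_rel: int | None = None
                    partial5 = False
                    if allow_partial and i == 0:
                        start_rel = 0
                        partial5 = seg[0] != "M"
                    else:
                        m = seg.find("M")
                        if m != -1:
                            start_rel = m
                    if start_rel is not None and (stopped or allow_partial):
                        prot = seg[start_rel:]
                        if len(prot) >= min_len and set(prot) != {"X"}:
                            aa_start = i + start_rel
                            nt_s = frame + 3 * aa_start
                            nt_e = nt_s + 3 * len(prot)
                            if strand == "+":
                                fs, fe = nt_s, nt_e
                            else:
                                fs, fe = L - nt_e, L - nt_s
                            orfs.append(
                                OpenReadingFrame(
                                    contig.id, strand, frame, fs, fe, prot,
                                    partial5=partial5, partial3=not stopped,
                                )
                            )
                if not stopped:
                    break
                i = j + 1
    orfs.sort(key=lambda o: (o.nt_start, o.strand, o.frame))
    return orfs


def residues_to_nt(orf: OpenReadingFrame, res_start: int, res_end: int) -> tuple[int, int]:
    """Project a 1-based inclusive residue range onto 1-based inclusive forward-strand
    nucleotide coordinates (GFF3 convention)."""
    if not (1 <= res_start <= res_end <= len(orf.protein)):
        raise ValueError(
            f"residue range {res_start}-{res_end} outside ORF protein of length {len(orf.protein)}"
        )
    if orf.strand == "+":
        return orf.nt_start + 3 * (res_start - 1) + 1, orf.nt_start + 3 * res_end
    return orf.nt_end - 3 * res_end + 1, orf.nt_end - 3 * (res_start - 1)


def write_gff3(annotations: Sequence, orf_map: Mapping[str, OpenReadingFrame]) -> str:
    """Emit precursor annotations as GFF3 in nucleotide coordinates.

    ``orf_map`` maps each annotation's ``protein_id`` to its ORF; an unknown
    id is an error.  Features: signal_peptide, cleavage_site, mature_peptide,
    domain.
    """
    lines = ["##gff-version 3"]
    for ann in annotations:
        orf = orf_map.get(ann.protein_id)
        if orf is None:
            raise ValueError(f"annotation references unknown ORF {ann.protein_id!r}")

        def emit(ftype: str, a: int, b: int, attrs: str) -> None:
            s, e = residues_to_nt(orf, a, b)
            lines.append(
                "\t".join(
                    [orf.contig_id, "neuropep", ftype, str(s), str(e), ".", orf.strand, ".", attrs]
                )
            )

        pid = ann.protein_id
        if ann.signal is not None and ann.signal.present:
            emit("signal_peptide", 1, ann.signal.cleave_after, f"ID={pid}.signal")
        for k, site in enumerate(ann.sites, 1):
            emit(
                "cleavage_site", site.start, site.end,
                f"ID={pid}.site{k};kind={site.kind};motif={site.motif}",
            )
        for k, pep in enumerate(ann.peptides, 1):
            a, b = pep.precursor_coords
            flags = []
            if pep.cterm_amide:
                flags.append("amide")
            if pep.nterm_pyroglu:
                flags.append("pyroglu")
            mods = ",".join(flags) if flags else "none"
            emit("mature_peptide", a, b, f"ID={pid}.pep{k};seq={pep.seq};mods={mods}")
        for k, feat in enumerate(ann.features, 1):
            a, b = feat.coords
            emit("domain", a, b, f"ID={pid}.dom{k};kind={feat.kind}")
    return "\n".join(lines) + "\n"
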