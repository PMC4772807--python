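"""Post-translational maturation of excised peptides and structural feature detection.

A raw inter-site segment becomes a predicted mature peptide by applying the
standard maturation rules of the secretory pathway: a C-terminal glycine is
the amide donor (removed, peptide flagged amidated), an N-terminal glutamine
may cyclise to pyroglutamate (flag only, sequence unchanged), cysteines set
the disulfide capacity, and tyrosines can be flagged as sulfation candidates.
Detectors for precursor-level architecture (neurophysin domain, acidic spacer,
insulin/relaxin A-chain/B-chain/C-peptide layout) live here as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .cleavage import CleavageSite, Segment, segment_between_sites
from .signalpep import SignalPrediction

_B_CHAIN_RE = re.compile(r"C[^C]{11}C")
_A_CHAIN_RE = re.compile(r"CC[^C]{3}C[^C]{8}C")


@dataclass
class MaturePeptide:
    """An excised peptide after maturation.

    ``precursor_coords`` is the 1-based inclusive residue range of the *raw*
    segment on the precursor (including a trimmed amide-donor glycine);
    ``cys_positions`` and ``sulfation_candidates`` are 1-based within ``seq``.
    """

    seq: str
    precursor_coords: tuple[int, int]
    cterm_amide: bool = False
    nterm_pyroglu: bool = False
    cys_positions: list[int] = field(default_factory=list)
    sulfation_candidates: list[int] = field(default_factory=list)
    copy_id: int = 1

    @property
    def max_disulfides(self) -> int:
        return len(self.cys_positions) // 2

    def display(self) -> str:
        """Conventional rendering, e.g. ``pQWYT-NH2``."""
        return ("p" if self.nterm_pyroglu else "") + self.seq + ("-NH2" if self.cterm_amide else "")


@dataclass
class StructuralFeature:
    kind: str  # neurophysin_domain | acidic_spacer | insulin_A_chain | insulin_B_chain | C_peptide
    coords: tuple[int, int]  # 1-based inclusive on the precursor
    evidence: str = ""


@dataclass
class PrecursorAnnotation:
    """A precursor protein together with everything predicted about it."""

    protein_id: str
    protein: str
    signal: SignalPrediction
    sites: list[CleavageSite] = field(default_factory=list)
    peptides: list[MaturePeptide] = field(default_factory=list)
    features: list[StructuralFeature] = field(default_factory=list)
    score: float = 0.0
    family_hits: list[tuple[int, str]] = field(default_factory=list)  # (peptide index, family)

    @property
    def signal_end(self) -> int:
        return self.signal.cleave_after if self.signal.present else 0


def mature(
    segment: Segment,
    pyroglu: bool = True,
    sulfation: bool = False,
    amide_without_g: bool = False,
) -> MaturePeptide:
    """Apply maturation rules to a raw segment.

    A single terminal G is consumed as the amide donor.  ``amide_without_g``
    (curation use) marks C-terminal amidation without removing a residue, for
    the rare annotations where the amidated form is reported with the glycine
    retained.  Pyroglutamate applies only to an N-terminal Q and changes the
    flag, not the sequence.  Y positions are flagged as sulfation candidates
    only when the sulfation rule is enabled (the pipeline enables it for
    CCK-type peptides).
    """
    if not segment.seq:
        raise ValueError("cannot mature an empty segment")
    seq = segment.seq
    amide = False
    if seq.endswith("G") and not amide_without_g:
        seq = seq[:-1]
        amide = True
    elif amide_without_g:
        amide = True
    pyro = pyroglu and seq.startswith("Q")
    cys = [i + 1 for i, c in enumerate(seq) if c == "C"]
    sulf = [i + 1 for i, c in enumerate(seq) if c == "Y"] if sulfation else []
    return MaturePeptide(
        seq=seq,
        precursor_coords=(segment.start, segment.end),
        cterm_amide=amide,
        nterm_pyroglu=pyro,
        cys_positions=cys,
        sulfation_candidates=sulf,
    )


def assign_copy_ids(peptides: list[MaturePeptide]) -> None:
    """Group identical peptide sequences within one precursor under one copy_id (in place)."""
    ids: dict[str, int] = {}
    for p in peptides:
        if p.seq not in ids:
            ids[p.seq] = len(ids) + 1
        p.copy_id = ids[p.seq]


def copy_counts(peptides: list[MaturePeptide]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for p in peptides:
        counts[p.copy_id] = counts.get(p.copy_id, 0) + 1
    return counts


def detect_neurophysin(protein: str, start_hint: int) -> StructuralFeature | None:
    """Report a C-terminal neurophysin domain: the region downstream of the last
    cleavage site containing exactly 14 cysteines (the conserved neurophysin
    cysteine count).  ``start_hint`` is the 0-based start of the region
    (typically the end of the last cleavage site)."""
    if len(protein) < 60:
        return None
    region = protein[start_hint:]
    if region.count("C") == 14:
        return StructuralFeature(
            "neurophysin_domain",
            (start_hint + 1, len(protein)),
            evidence="14 cysteines downstream of last cleavage site",
        )
    return None


def detect_acidic_spacer(segment_seq: str, min_acidic: int = 6, min_fraction: float = 0.2) -> bool:
    """True iff the segment has >= ``min_acidic`` D/E residues making up at least
    ``min_fraction`` of its length."""
    if not segment_seq:
        return False
    acidic = sum(segment_seq.count(c) for c in "DE")
    return acidic >= min_acidic and acidic / len(segment_seq) >= min_fraction


def detect_insulin_architecture(
    protein: str, sites: list[CleavageSite], signal_end: int = 0
) -> list[StructuralFeature]:
    """Detect the insulin/relaxin-superfamily precursor layout B-chain | site |
    C-peptide | site | A-chain.

    The B-chain carries exactly two cysteines spaced C-x(11)-C; the A-chain
    carries exactly four cysteines in the CC-x(3)-C-x(8)-C arrangement; the
    single segment between them is the connecting C-peptide.  Returns the
    features in precursor order, or an empty list when the motifs are absent.
    """
    if "C" not in protein:
        return []
    segments = segment_between_sites(protein, signal_end, sites)
    for bi, bseg in enumerate(segments):
        if bseg.seq.count("C") == 2 and _B_CHAIN_RE.search(bseg.seq):
            ai = bi + 2
            if ai < len(segments):
                aseg = segments[ai]
                if aseg.seq.count("C") == 4 and _A_CHAIN_RE.search(aseg.seq):
                    cseg = segments[bi + 1]
                    return [
                        StructuralFeature(
                            "insulin_B_chain", (bseg.start, bseg.end),
                            evidence="2 cysteines, C-x(11)-C spacing",
                        ),
                        StructuralFeature(
                            "C_peptide", (cseg.start, cseg.end),
                            evidence="connecting peptide between dibasic sites",
                        ),
                        StructuralFeature(
                            "insulin_A_chain", (aseg.start, aseg.end),
                            evidence="4 cysteines, CC-x(3)-C-x(8)-C spacing",
                        ),
                    ]
    return []
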