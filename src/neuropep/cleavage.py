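"""Prohormone-convertase cleavage-site grammar.

Bioactive peptides are excised from their precursor at basic residues:
dibasic pairs (KR dominating), tribasic runs, and — under the extended rule —
monobasic R positions with another basic residue 2, 4 or 6 positions upstream.
Segmentation between sites is exact: signal peptide + site motifs + segments
tile the precursor with no residue lost or duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_BASIC = frozenset("KR")
_KIND_BY_LEN = {1: "monobasic", 2: "dibasic", 3: "tribasic"}


@dataclass
class CleavageRules:
    """Which basic-site forms are recognised.

    ``pairs`` are the accepted dibasic motifs (KR is canonical; the others are
    flagged extended).  ``monobasic`` enables the single-R rule (off by default
    in de novo scans, on in curation mode).
    """

    pairs: tuple[str, ...] = ("KR", "RR", "KK", "RK")
    allow_tribasic: bool = True
    monobasic: bool = False


@dataclass(frozen=True)
class CleavageSite:
    start: int  # 1-based inclusive coords of the basic motif
    end: int
    kind: str  # dibasic | tribasic | monobasic
    motif: str
    confidence: str  # canonical | extended

    def __post_init__(self) -> None:
        if set(self.motif) - _BASIC:
            raise ValueError(f"cleavage motif {self.motif!r} contains non-basic residues")
        if len(self.motif) != self.end - self.start + 1 or _KIND_BY_LEN[len(self.motif)] != self.kind:
            raise ValueError("motif length inconsistent with kind/coords")


@dataclass(frozen=True)
class Segment:
    """A raw inter-site stretch (1-based inclusive coords on the precursor)."""

    start: int
    end: int
    seq: str


def find_cleavage_sites(
    protein: str, signal_end: int, rules: CleavageRules | None = None
) -> list[CleavageSite]:
    """Locate processing sites downstream of the signal peptide.

    Maximal runs of K/R are decomposed deterministically: runs of three become
    one tribasic site (not nested dibasics); runs of four or more yield the
    leftmost three as tribasic and the remainder is re-examined.  A lone basic
    residue is reported only when the monobasic rule is enabled, the residue is
    R, and another basic residue lies 2, 4 or 6 positions upstream.
    """
    rules = rules or CleavageRules()
    if signal_end >= len(protein):
        raise ValueError("signal_end must be < protein length")
    sites: list[CleavageSite] = []
    i = signal_end
    n = len(protein)
    while i < n:
        if protein[i] not in _BASIC:
            i += 1
            continue
        j = i
        while j < n and protein[j] in _BASIC:
            j += 1
        # decompose the run [i, j)
        k = i
        run_len = j - i
        while run_len > 0:
            if run_len >= 3 and rules.allow_tribasic:
                motif = protein[k : k + 3]
                sites.append(CleavageSite(k + 1, k + 3, "tribasic", motif, "canonical"))
                k += 3
                run_len -= 3
            elif run_len >= 2:
                motif = protein[k : k + 2]
                if motif in rules.pairs:
                    conf = "canonical" if motif == "KR" else "extended"
                    sites.append(CleavageSite(k + 1, k + 2, "dibasic", motif, conf))
                k += 2
                run_len -= 2
            else:
                if (
                    rules.monobasic
                    and protein[k] == "R"
                    and any(k - d >= 0 and protein[k - d] in _BASIC for d in (2, 4, 6))
                ):
                    sites.append(CleavageSite(k + 1, k + 1, "monobasic", "R", "extended"))
                k += 1
                run_len -= 1
        i = j
    sites.sort(key=lambda s: s.start)
    return sites


def segment_between_sites(
    protein: str, signal_end: int, sites: list[CleavageSite]
) -> list[Segment]:
    """Return the maximal stretches strictly between signal end, sites and C-terminus.

    Basic residues belonging to the sites are excluded from every segment;
    placing signal peptide, site motifs and segments back at their coordinates
    reconstructs the precursor exactly.  Overlapping or unsorted sites are an
    upstream invariant violation and raise.
    """
    prev_end = signal_end  # 0-based exclusive
    for s in sites:
        if s.start - 1 < prev_end:
            raise ValueError(f"cleavage sites overlap or precede the signal at {s.start}")
        prev_end = s.end
    segments: list[Segment] = []
    prev = signal_end
    for s in sites:
        if s.start - 1 > prev:
            segments.append(Segment(prev + 1, s.start - 1, protein[prev : s.start - 1]))
        prev = s.end
    if prev < len(protein):
        segments.append(Segment(prev + 1, len(protein), protein[prev:]))
    return segments
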