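"""Neuropeptide family classification via an extensible registry of anchored motifs.

Each registry entry encodes one family signature: an anchored residue-class
pattern plus optional structural constraints (amidation, pyroglutamate,
cysteine count/placement, length range).  Pattern mini-language:

* an uppercase letter is a literal residue;
* ``x`` matches any of the 20 standard residues (never X);
* ``h`` matches a hydrophobic residue (AVLIMFWY);
* ``[ST]`` is a residue class;
* the pattern is anchored at exactly one terminus: leading ``^`` (N-terminal)
  or trailing ``$`` (C-terminal).

Classification is multi-label: a peptide may match several families and
arbitration is left to the analyst.  Families for which no sequence motif is
known (e.g. PDF-, CRH-, orexin-type) are assigned by homology screening, not
by motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .maturation import MaturePeptide

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "AVLIMFWY"

_ANY_CLASS = f"[{STANDARD_AA}]"
_H_CLASS = f"[{HYDROPHOBIC}]"


class PatternError(ValueError):
    """Malformed motif pattern; the message carries the pattern text."""


class RegistryError(ValueError):
    """Malformed registry configuration."""


def compile_pattern(pattern: str) -> tuple[re.Pattern, str]:
    """Compile a motif pattern into a regex and its anchor ('nterm' or 'cterm')."""
    starts, ends = pattern.startswith("^"), pattern.endswith("$")
    if starts == ends:  # both or neither
        raise PatternError(f"pattern {pattern!r} must be anchored at exactly one terminus")
    anchor = "nterm" if starts else "cterm"
    core = pattern[1:] if starts else pattern[:-1]
    if not core:
        raise PatternError(f"pattern {pattern!r} has no residue tokens")
    parts: list[str] = []
    i = 0
    while i < len(core):
        c = core[i]
        if c == "[":
            j = core.find("]", i)
            if j == -1:
                raise PatternError(f"pattern {pattern!r}: unterminated class at position {i}")
            cls = core[i + 1 : j]
            if not cls or set(cls) - set(STANDARD_AA):
                raise PatternError(f"pattern {pattern!r}: invalid residue class [{cls}]")
            parts.append(f"[{cls}]")
            i = j + 1
        elif c == "x":
            parts.append(_ANY_CLASS)
            i += 1
        elif c == "h":
            parts.append(_H_CLASS)
            i += 1
        elif c in STANDARD_AA:
            parts.append(c)
            i += 1
        else:
            raise PatternError(f"pattern {pattern!r}: unexpected character {c!r}")
    body = "".join(parts)
    regex = re.compile(r"\A" + body if anchor == "nterm" else body + r"\Z")
    return regex, anchor


@dataclass(frozen=True)
class FamilyMotif:
    """One family signature.

    ``cys_constraint`` options: ``count`` (exact cysteine count), ``positions``
    (exact 1-based cysteine positions), ``within_first`` (all cysteines inside
    the first k residues).  ``provenance`` records, in the package's own words,
    which reported family signature the entry encodes.
    """

    family: str
    pattern: str
    requires_amide: bool = False
    requires_pyroglu: bool = False
    cys_constraint: dict | None = None
    length_range: tuple[int, int] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        regex, anchor = compile_pattern(self.pattern)
        object.__setattr__(self, "_regex", regex)
        object.__setattr__(self, "anchor", anchor)

    def matches(self, peptide: MaturePeptide) -> bool:
        if self.requires_amide and not peptide.cterm_amide:
            return False
        if self.requires_pyroglu and not peptide.nterm_pyroglu:
            return False
        seq = peptide.seq
        if self.length_range is not None:
            lo, hi = self.length_range
            if not (lo <= len(seq) <= hi):
                return False
        cc = self.cys_constraint
        if cc:
            cys = peptide.cys_positions
            if "count" in cc and len(cys) != cc["count"]:
                return False
            if "positions" in cc and cys != list(cc["positions"]):
                return False
            if "within_first" in cc and any(p > cc["within_first"] for p in cys):
                return False
        return self._regex.search(seq) is not None


def default_registry() -> list[FamilyMotif]:
    """The built-in family signatures for the starfish neuropeptide families."""
    return [
        FamilyMotif(
            "SALMFamide-L", "[ST]xLx[FY]$", requires_amide=True,
            provenance="L-type SALMFamide C-terminal S/TxLxF/Y-amide motif",
        ),
        FamilyMotif(
            "SALMFamide-F", "[FY]x[FY]$", requires_amide=True,
            provenance="F-type SALMFamide C-terminal F/YxF/Y-amide motif",
        ),
        FamilyMotif(
            "kisspeptin", "NxxSxxLxF$", requires_amide=True,
            provenance="kisspeptin-type C-terminal NxxSxxLxF-amide motif",
        ),
        FamilyMotif(
            "tachykinin", "GhF$", requires_amide=True,
            provenance="tachykinin-type C-terminal GxF-amide motif (x hydrophobic; "
            "L/I observed, wider hydrophobic class accepted as an extension)",
        ),
        FamilyMotif(
            "luqin", "KFMRW$", requires_amide=True,
            provenance="luqin-type C-terminal KFMRW-amide shared across echinoderms",
        ),
        FamilyMotif(
            "CCK-type", "[DQ]YGxGLF[WF]$", requires_amide=True,
            provenance="generalisation of the two starfish CCK-type C-terminal "
            "octapeptides DYGHGLFW-amide and QYGFGLFF-amide (extended)",
        ),
        FamilyMotif(
            "GnRH-type", "WxxG$", requires_amide=True,
            provenance="GnRH-type C-terminal WxxG-amide motif",
        ),
        FamilyMotif(
            "TRH-type", "^Q", requires_amide=True, requires_pyroglu=True,
            length_range=(4, 4),
            provenance="echinoderm TRH-type tetrapeptide with N-terminal "
            "pyroglutamate and C-terminal amide",
        ),
        FamilyMotif(
            "VP/OT-type", "^CxxxxC", requires_amide=True,
            cys_constraint={"count": 2, "positions": (1, 6)}, length_range=(9, 9),
            provenance="nine-residue amidated peptide with disulfide-capable "
            "cysteines at positions 1 and 6",
        ),
        FamilyMotif(
            "calcitonin-type", "^x", requires_amide=True,
            cys_constraint={"count": 2, "within_first": 10}, length_range=(20, 60),
            provenance="amidated peptide with a cysteine pair in the N-terminal region",
        ),
        FamilyMotif(
            "insulin-A-chain", "CCxxxCxxxxxxxxC$",
            cys_constraint={"count": 4},
            provenance="insulin/IGF/relaxin A-chain cysteine motif CCxxxCxxxxxxxxC "
            "(C-terminal cysteine marks the relaxin/INSL sub-class)",
        ),
        FamilyMotif(
            "insulin-B-chain", "^xxxxCxxxxxxxxxxxC",
            cys_constraint={"count": 2},
            provenance="insulin/IGF/relaxin B-chain cysteine motif CxxxxxxxxxxxC "
            "(position within the chain fixed for the fixture layout)",
        ),
        FamilyMotif(
            "relaxin-RBM", "RxxxRxx[IV]$",
            provenance="relaxin receptor-binding motif RxxxRxxI/V (approximated "
            "as a C-terminal signature)",
        ),
        FamilyMotif(
            "AN-peptide", "^AN",
            provenance="AN-peptide N-terminal Ala-Asn motif",
        ),
    ]


def classify(peptide: MaturePeptide, registry: list[FamilyMotif] | None = None) -> list[str]:
    """Return every family whose pattern and constraints all hold, in registry order."""
    registry = registry if registry is not None else default_registry()
    if not registry:
        raise RegistryError("registry is empty")
    return [m.family for m in registry if m.matches(peptide)]


def _entry_from_dict(d: dict) -> FamilyMotif:
    try:
        lr = d.get("length_range")
        return FamilyMotif(
            family=d["family"],
            pattern=d["pattern"],
            requires_amide=bool(d.get("requires_amide", False)),
            requires_pyroglu=bool(d.get("requires_pyroglu", False)),
            cys_constraint=d.get("cys_constraint"),
            length_range=tuple(lr) if lr else None,
            provenance=d.get("provenance", "user entry"),
        )
    except KeyError as e:
        raise RegistryError(f"registry entry missing required key {e}") from None


def registry_load(path=None) -> list[FamilyMotif]:
    """Load the registry: built-in defaults merged with user entries.

    The user file is YAML — either a list of entries or ``{families: [...]}``.
    A user entry with an existing family name overrides the default in place;
    duplicate family names *within* the user file are an error.
    """
    registry = default_registry()
    if path is None:
        return registry
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return registry
    if isinstance(data, dict):
        data = data.get("families", [])
    names_seen: set[str] = set()
    by_name = {m.family: i for i, m in enumerate(registry)}
    for raw in data:
        entry = _entry_from_dict(raw)
        if entry.family in names_seen:
            raise RegistryError(f"duplicate family name {entry.family!r} in user registry")
        names_seen.add(entry.family)
        if entry.family in by_name:
            registry[by_name[entry.family]] = entry
        else:
            by_name[entry.family] = len(registry)
            registry.append(entry)
    return registry
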