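"""Family motif registry and classification."""

import random
import re

import pytest

from neuropep import FamilyMotif, classify, default_registry, registry_load
from neuropep.families import PatternError, RegistryError, compile_pattern
from conftest import make_peptide

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- worked classifications


@pytest.mark.parametrize(
    "seq, amide, pyro, expected",
    [
        ("GFNSALMF", True, False, "SALMFamide-L"),
        ("AFGDFSF", True, False, "SALMFamide-F"),
        ("EEKTRFPKFMRW", True, False, "luqin"),
        ("QWYT", True, True, "TRH-type"),
        ("CLVQDCPEG", True, False, "VP/OT-type"),
        ("HNTFTMGGQNRWKAG", True, False, "GnRH-type"),
        ("DYGHGLFW", True, False, "CCK-type"),
        ("QYGFGLFF", True, False, "CCK-type"),
        ("QSGLF", True, False, "tachykinin"),
        ("QSGGIF", True, False, "tachykinin"),
        ("ANAQSTDLE", False, False, "AN-peptide"),
    ],
)
def test_reported_family_assignments(seq, amide, pyro, expected):
    assert expected in classify(make_peptide(seq, amide=amide, pyro=pyro))


def test_unremarkable_peptide_matches_nothing():
    assert classify(make_peptide("AAAAA", amide=False)) == []


def test_amide_requirement_gates_matches():
    assert "luqin" in classify(make_peptide("EEKTRFPKFMRW", amide=True))
    assert "luqin" not in classify(make_peptide("EEKTRFPKFMRW", amide=False))


# ---------------------------------------------------------------- pattern language


def test_pattern_must_be_anchored_at_one_terminus():
    with pytest.raises(PatternError):
        compile_pattern("KFMRW")
    with pytest.raises(PatternError):
        compile_pattern("^KFMRW$")


def test_malformed_pattern_reports_text():
    with pytest.raises(PatternError, match="K.MRW"):
        compile_pattern("K.MRW$")
    with pytest.raises(PatternError, match=r"\[ST"):
        compile_pattern("[STxL$")


# ---------------------------------------------------------------- independent regex oracle


ORACLE = {
    "SALMFamide-L": lambda p: p.cterm_amide and re.search(r"[ST].L.[FY]$", p.seq),
    "SALMFamide-F": lambda p: p.cterm_amide and re.search(r"[FY].[FY]$", p.seq),
    "kisspeptin": lambda p: p.cterm_amide and re.search(r"N..S..L.F$", p.seq),
    "tachykinin": lambda p: p.cterm_amide and re.search(r"G[AVLIMFWY]F$", p.seq),
    "luqin": lambda p: p.cterm_amide and p.seq.endswith("KFMRW"),
    "CCK-type": lambda p: p.cterm_amide and re.search(r"[DQ]YG.GLF[WF]$", p.seq),
    "GnRH-type": lambda p: p.cterm_amide and re.search(r"W..G$", p.seq),
    "TRH-type": lambda p: p.cterm_amide and p.nterm_pyroglu and len(p.seq) == 4
    and p.seq.startswith("Q"),
    "VP/OT-type": lambda p: p.cterm_amide and len(p.seq) == 9
    and p.cys_positions == [1, 6] and re.match(r"C....C", p.seq),
    "calcitonin-type": lambda p: p.cterm_amide and 20 <= len(p.seq) <= 60
    and len(p.cys_positions) == 2 and all(c <= 10 for c in p.cys_positions),
    "insulin-A-chain": lambda p: len(p.cys_positions) == 4
    and re.search(r"CC...C.{8}C$", p.seq),
    "insulin-B-chain": lambda p: len(p.cys_positions) == 2
    and re.match(r"....C.{11}C", p.seq),
    "relaxin-RBM": lambda p: re.search(r"R...R..[IV]$", p.seq),
    "AN-peptide": lambda p: p.seq.startswith("AN"),
}


def fuzz_peptides(n, rng, min_len=1, max_len=25):
    for _ in range(n):
        seq = "".join(rng.choice(AA) for _ in range(rng.randint(min_len, max_len)))
        yield make_peptide(seq, amide=rng.random() < 0.5, pyro=rng.random() < 0.5)


def oracle_classify(pep):
    return [fam for fam in (m.family for m in default_registry()) if ORACLE[fam](pep)]


def test_classification_agrees_with_regex_oracle_on_fuzz():
    rng = random.Random(17)
    registry = default_registry()
    for pep in fuzz_peptides(3000, rng):
        assert classify(pep, registry) == oracle_classify(pep)


def test_classification_agrees_with_oracle_near_motifs():
    """Fuzz around true motif instances so positives are actually exercised."""
    rng = random.Random(23)
    seeds = ["GFNSALMF", "AFGDFSF", "NAASAALAF", "QSGLF", "EEKTRFPKFMRW",
             "DYGHGLFW", "WKAG", "QWYT", "CLVQDCPEG", "ANAA", "RAAARAAI"]
    registry = default_registry()
    for _ in range(2000):
        base = rng.choice(seeds)
        seq = list(base)
        if rng.random() < 0.6:  # point mutation
            seq[rng.randrange(len(seq))] = rng.choice(AA)
        if rng.random() < 0.4:  # random N-terminal extension
            seq = list("".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))) + seq
        pep = make_peptide("".join(seq), amide=rng.random() < 0.8, pyro=rng.random() < 0.5)
        assert classify(pep, registry) == oracle_classify(pep)


def test_requires_amide_entries_never_match_unamidated():
    rng = random.Random(29)
    amide_requiring = {m.family for m in default_registry() if m.requires_amide}
    for pep in fuzz_peptides(500, rng):
        pep.cterm_amide = False
        assert not amide_requiring & set(classify(pep))


def test_adding_registry_entry_does_not_change_other_matches():
    rng = random.Random(31)
    base = default_registry()
    extended = base + [FamilyMotif("novel-RGW", "NQRGW$", provenance="test entry")]
    for pep in fuzz_peptides(300, rng):
        assert [f for f in classify(pep, extended) if f != "novel-RGW"] == classify(pep, base)


# ---------------------------------------------------------------- registry loading


def test_empty_user_file_gives_defaults(tmp_path):
    p = tmp_path / "registry.yaml"
    p.write_text("")
    assert registry_load(p) == default_registry()


def test_user_entry_with_cterminal_rgw(tmp_path):
    p = tmp_path / "registry.yaml"
    p.write_text("- family: Arnp22-like\n  pattern: NQRGW$\n")
    registry = registry_load(p)
    pep = make_peptide("ASTNQRGW", amide=False)
    assert "Arnp22-like" in classify(pep, registry)


def test_user_override_changes_matches(tmp_path):
    p = tmp_path / "registry.yaml"
    p.write_text("- family: luqin\n  pattern: RW$\n  requires_amide: true\n")
    registry = registry_load(p)
    pep = make_peptide("AAAARW", amide=True)
    assert "luqin" in classify(pep, registry)
    assert "luqin" not in classify(pep, default_registry())


def test_duplicate_family_in_user_file_is_error(tmp_path):
    p = tmp_path / "registry.yaml"
    p.write_text(
        "- family: a\n  pattern: RW$\n- family: a\n  pattern: KW$\n"
    )
    with pytest.raises(RegistryError, match="duplicate"):
        registry_load(p)


def test_empty_registry_rejected():
    with pytest.raises(RegistryError):
        classify(make_peptide("QWYT"), [])
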