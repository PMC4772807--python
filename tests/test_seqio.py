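"""Sequence I/O, six-frame ORF extraction and GFF3 projection."""

import random
import re

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from neuropep import (
    OpenReadingFrame,
    PrecursorAnnotation,
    SignalPrediction,
    TranscriptContig,
    read_fasta,
    revcomp,
    six_frame_orfs,
    write_fasta,
    write_gff3,
)
from neuropep.cleavage import CleavageSite
from neuropep.maturation import MaturePeptide
from neuropep.seqio import DuplicateIdError, FastaFormatError, residues_to_nt

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


# ---------------------------------------------------------------- FASTA


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "one.fasta"
    p.write_text(">c1\nATGC\n")
    assert read_fasta(p) == [TranscriptContig("c1", "ATGC")]


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


def test_read_fasta_duplicate_id_error(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(DuplicateIdError, match="line 3"):
        read_fasta(p)


def test_read_fasta_illegal_character_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nACGT\nACRT\n")  # R is a rejected ambiguity code
    with pytest.raises(FastaFormatError, match="line 3"):
        read_fasta(p)


def test_read_fasta_normalises_case_and_uracil(tmp_path):
    p = tmp_path / "rna.fasta"
    p.write_text(">a\nacgu\n")
    assert read_fasta(p)[0].seq == "ACGT"


@given(st.lists(st.tuples(st.integers(0, 10**6), dna), min_size=0, max_size=8, unique_by=lambda t: t[0]))
def test_fasta_round_trip_identity(tmp_path_factory, pairs):
    records = [TranscriptContig(f"id{i}", seq) for i, seq in pairs]
    path = tmp_path_factory.mktemp("fa") / "rt.fasta"
    write_fasta(records, path)
    assert read_fasta(path) == records


# ---------------------------------------------------------------- six-frame ORFs


def brute_force_orfs(contig, min_len, allow_partial=False):
    """Independent six-frame enumeration using Biopython translation."""
    L = len(contig.seq)
    found = set()
    for strand in "+-":
        s = contig.seq if strand == "+" else str(Seq(contig.seq).reverse_complement())
        for frame in range(3):
            trimmed = s[frame:]
            trimmed = trimmed[: len(trimmed) // 3 * 3]
            if not trimmed:
                continue
            aa = str(Seq(trimmed).translate())
            pos = 0
            for k, seg in enumerate(aa.split("*")):
                is_first = k == 0
                is_last = pos + len(seg) == len(aa)  # no stop terminates it
                if seg:
                    if allow_partial and is_first:
                        start_rel, partial5 = 0, not seg.startswith("M")
                    elif "M" in seg:
                        start_rel, partial5 = seg.index("M"), False
                    else:
                        start_rel = None
                    complete_ok = (not is_last) or allow_partial
                    if start_rel is not None and complete_ok:
                        prot = seg[start_rel:]
                        if len(prot) >= min_len:
                            a = pos + start_rel
                            nt_s, nt_e = frame + 3 * a, frame + 3 * (a + len(prot))
                            if strand == "-":
                                nt_s, nt_e = L - nt_e, L - nt_s
                            found.add((strand, frame, nt_s, nt_e, prot, partial5, is_last))
                pos += len(seg) + 1
    return found


def as_tuples(orfs):
    return {
        (o.strand, o.frame, o.nt_start, o.nt_end, o.protein, o.partial5, o.partial3)
        for o in orfs
    }


def test_forward_orf_example():
    orfs = six_frame_orfs(TranscriptContig("c", "ATGGCTAAATAA"), min_len=1)
    assert len(orfs) == 1
    o = orfs[0]
    assert (o.protein, o.strand, o.frame, o.partial5) == ("MAK", "+", 0, False)
    assert (o.nt_start, o.nt_end) == (0, 9)


def test_reverse_orf_example():
    orfs = six_frame_orfs(TranscriptContig("c", "TTATTTAGCCAT"), min_len=1)
    assert len(orfs) == 1
    assert (orfs[0].protein, orfs[0].strand) == ("MAK", "-")


def test_all_n_contig_yields_nothing():
    assert six_frame_orfs(TranscriptContig("c", "N" * 90), min_len=1) == []


@pytest.mark.parametrize("allow_partial", [False, True])
def test_orfs_match_brute_force_enumeration(allow_partial):
    rng = random.Random(7)
    for _ in range(25):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 400)))
        contig = TranscriptContig("r", seq)
        got = as_tuples(six_frame_orfs(contig, min_len=5, allow_partial=allow_partial))
        assert got == brute_force_orfs(contig, 5, allow_partial)


@given(dna)
def test_revcomp_symmetry(seq):
    contig = TranscriptContig("c", seq)
    mirrored = TranscriptContig("c", revcomp(seq))
    L = len(seq)
    flip = {"+": "-", "-": "+"}
    direct = as_tuples(six_frame_orfs(contig, min_len=1, allow_partial=True))
    via_rc = {
        (flip[s], f, L - e, L - b, p, p5, p3)
        for (s, f, b, e, p, p5, p3) in as_tuples(
            six_frame_orfs(mirrored, min_len=1, allow_partial=True)
        )
    }
    # frames permute under mirroring, so compare frame-insensitively
    strip = lambda items: {(s, b, e, p, p5, p3) for (s, f, b, e, p, p5, p3) in items}
    assert strip(direct) == strip(via_rc)


@given(dna)
def test_orf_codons_retranslate_to_protein(seq):
    from neuropep.seqio import translate

    contig = TranscriptContig("c", seq)
    for o in six_frame_orfs(contig, min_len=1, allow_partial=True):
        sub = contig.seq[o.nt_start : o.nt_end]
        if o.strand == "-":
            sub = revcomp(sub)
        assert translate(sub) == o.protein
        assert "*" not in o.protein
        assert (o.nt_end - o.nt_start) == 3 * len(o.protein)
        if not o.partial5:
            assert o.protein.startswith("M")


# ---------------------------------------------------------------- GFF3


def _annotation(protein_id, protein, signal_end=0, sites=(), peptides=()):
    signal = (
        SignalPrediction(True, signal_end, 1.0)
        if signal_end
        else SignalPrediction(False, None, 0.0)
    )
    return PrecursorAnnotation(
        protein_id, protein, signal, sites=list(sites), peptides=list(peptides)
    )


def test_gff3_empty_is_header_only():
    assert write_gff3([], {}) == "##gff-version 3\n"


def test_gff3_forward_coordinate_projection():
    orf = OpenReadingFrame("ctg", "+", 0, 0, 120, "M" * 40)
    pep = MaturePeptide("X" * 9, (25, 33))
    ann = _annotation(orf.id, orf.protein, peptides=[pep])
    gff = write_gff3([ann], {orf.id: orf})
    row = [l for l in gff.splitlines() if "mature_peptide" in l][0].split("\t")
    assert (int(row[3]), int(row[4])) == (73, 99)
    assert row[6] == "+"


def test_gff3_reverse_projection_matches_per_residue_mapping():
    # ORF on the minus strand occupying forward nts [6, 126)
    orf = OpenReadingFrame("ctg", "-", 0, 6, 126, "M" * 40)
    for a, b in [(1, 1), (1, 40), (7, 12), (40, 40)]:
        s, e = residues_to_nt(orf, a, b)
        # brute force: forward coords of every codon of residues a..b
        nts = []
        for r in range(a, b + 1):
            # residue r occupies forward nts [nt_end - 3r, nt_end - 3(r-1))
            nts.extend(range(orf.nt_end - 3 * r, orf.nt_end - 3 * (r - 1)))
        assert s == min(nts) + 1 and e == max(nts) + 1


def test_gff3_round_trips_through_parser(tmp_path):
    gffutils = pytest.importorskip("gffutils")
    orf = OpenReadingFrame("ctg", "+", 1, 12, 192, "M" + "A" * 59)
    site = CleavageSite(20, 21, "dibasic", "KR", "canonical")
    pep = MaturePeptide("A" * 8, (22, 30))
    ann = _annotation(orf.id, orf.protein, signal_end=16, sites=[site], peptides=[pep])
    gff = write_gff3([ann], {orf.id: orf})
    db = gffutils.create_db(gff, ":memory:", from_string=True)
    feats = {f.featuretype: f for f in db.all_features()}
    assert set(feats) == {"signal_peptide", "cleavage_site", "mature_peptide"}
    assert (feats["signal_peptide"].start, feats["signal_peptide"].end) == (13, 60)
    assert (feats["cleavage_site"].start, feats["cleavage_site"].end) == (12 + 3 * 19 + 1, 12 + 63)


def test_gff3_unknown_orf_is_error():
    ann = _annotation("missing", "MAAA")
    with pytest.raises(ValueError, match="unknown ORF"):
        write_gff3([ann], {})
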