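"""Synthetic fixtures: contigs with planted precursor genes, decoys, and ground truth.

Each planted precursor is a synthetic signal peptide (passing the built-in
heuristic by construction) followed by alternating peptides/spacers and
dibasic KR sites, reverse-translated with seeded uniform codon choice into a
contig with flanking UTRs (an in-frame stop codon is placed directly upstream
of the start codon so the planted ORF is maximal).  Decoys are length-matched
random ORFs without signal or cleavage architecture.  The default
architectures mirror the classic precursor layouts — a multi-copy tetrapeptide
precursor, a neurophysin-bearing amidated-peptide precursor, an insulin/relaxin
B-C-A layout, and an acidic-spacer precursor — so every detector has a
positive control.

The generator certifies every emitted contig: the de novo pipeline run on the
contig must recover exactly the planted peptides (and nothing on decoys);
codon/UTR choices are re-sampled otherwise.  Re-generation with the same seed
is byte-identical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .cleavage import CleavageSite, Segment
from .families import classify, default_registry
from .maturation import (
    PrecursorAnnotation,
    StructuralFeature,
    assign_copy_ids,
    detect_acidic_spacer,
    detect_insulin_architecture,
    detect_neurophysin,
    mature,
)
from .pipeline import Candidate, DiscoveryResult, PipelineConfig, annotate_protein, discover
from .ranking import score_precursor
from .seqio import AA_TO_CODONS, TranscriptContig, revcomp, six_frame_orfs
from .signalpep import predict_signal

#: a synthetic signal peptide the heuristic cleaves after residue 16
DEFAULT_SIGNAL = "MKTLLILAVLAAVSSA"

_NEUROPHYSIN = "CTASDLN" * 14  # 98 residues, exactly 14 cysteines, no K/R
_B_CHAIN = "TNEACADDLQSTFEAVCWSE"  # 20 residues, Cys 5 and 17
_C_PEPTIDE = "SDNSLEALQSTE"
_A_CHAIN = "TDSENLAVQS" + "CC" + "AST" + "C" + "SEDNAVLQ" + "C"  # 25 res, Cys 11,12,16,25
_ACIDIC_SPACER = "ASDEEDSTEELNAFMDSSTQAVW"  # 23 residues, 7 D/E
_SPACER_CORE = "ASTNLVC" * 6 + "ASTNLVWPMHQF"  # 54 residues, 6 cysteines


class GenerationError(ValueError):
    """The generator spec cannot be realised (e.g. a peptide containing K/R)."""


@dataclass(frozen=True)
class Architecture:
    """A planted precursor layout: signal peptide + alternating segments and sites."""

    name: str
    signal: str = DEFAULT_SIGNAL
    elements: tuple[tuple[str, str], ...] = ()  # ("segment"|"site", residues)

    def __post_init__(self) -> None:
        for kind, seq in self.elements:
            if kind == "site":
                if set(seq) - set("KR"):
                    raise GenerationError(f"site motif {seq!r} must be basic residues")
            elif kind == "segment":
                if not seq:
                    raise GenerationError("empty planted segment")
                if set(seq) & set("KR"):
                    raise GenerationError(
                        f"planted peptide {seq!r} contains K/R, impossible under the "
                        "dibasic-only cleavage grammar"
                    )
            else:
                raise GenerationError(f"unknown element kind {kind!r}")

    @classmethod
    def from_peptides(cls, name: str, peptides: list[str], signal: str = DEFAULT_SIGNAL):
        """Interleave peptides with canonical KR sites (one site after each peptide)."""
        elements: list[tuple[str, str]] = []
        for pep in peptides:
            elements.append(("segment", pep))
            elements.append(("site", "KR"))
        return cls(name=name, signal=signal, elements=tuple(elements))

    @property
    def protein(self) -> str:
        return self.signal + "".join(seq for _, seq in self.elements)


def default_architectures() -> list[Architecture]:
    return [
        Architecture.from_peptides("multicopy", ["QYPGGAPIGLDG"] + ["QWYTG"] * 11),
        Architecture(
            "neurophysin",
            elements=(
                ("segment", "NGFFYG"), ("site", "KR"),
                ("segment", "NGFFYG"), ("site", "KR"),
                ("segment", _NEUROPHYSIN),
            ),
        ),
        Architecture(
            "insulin",
            elements=(
                ("segment", _B_CHAIN), ("site", "KR"),
                ("segment", _C_PEPTIDE), ("site", "KR"),
                ("segment", _A_CHAIN),
            ),
        ),
        Architecture(
            "acidic_spacer",
            elements=(
                ("segment", _ACIDIC_SPACER), ("site", "KR"),
                ("segment", _SPACER_CORE),
            ),
        ),
    ]


@dataclass
class GeneratorConfig:
    architectures: list[Architecture] = field(default_factory=default_architectures)
    n_decoys: int = 8
    utr_len: tuple[int, int] = (20, 60)
    decoy_len: tuple[int, int] = (80, 200)
    plant_reverse_strand: bool = True
    max_attempts: int = 100


@dataclass
class SyntheticTruth:
    contigs: list[TranscriptContig]
    truths: dict[str, PrecursorAnnotation]  # contig id -> ground-truth annotation
    decoy_ids: list[str]
    seed: int
    config: GeneratorConfig


def _truth_annotation(protein_id: str, arch: Architecture) -> PrecursorAnnotation:
    protein = arch.protein
    signal = predict_signal(protein)
    if not signal.present or signal.cleave_after != len(arch.signal):
        raise GenerationError(
            f"architecture {arch.name!r}: planted signal peptide not recovered by the "
            f"heuristic (got {signal})"
        )
    pos = len(arch.signal)
    sites: list[CleavageSite] = []
    segments: list[Segment] = []
    for kind, seq in arch.elements:
        if kind == "site":
            kinds = {1: "monobasic", 2: "dibasic", 3: "tribasic"}
            conf = "canonical" if seq in ("KR",) or len(seq) == 3 else "extended"
            sites.append(CleavageSite(pos + 1, pos + len(seq), kinds[len(seq)], seq, conf))
        else:
            segments.append(Segment(pos + 1, pos + len(seq), seq))
        pos += len(seq)
    peptides = [mature(seg) for seg in segments]
    if any(len(p.seq) < 3 for p in peptides):
        raise GenerationError(f"architecture {arch.name!r}: planted peptide matures below 3 residues")
    assign_copy_ids(peptides)
    ann = PrecursorAnnotation(protein_id, protein, signal, sites=sites, peptides=peptides)
    for seg in segments:
        if detect_acidic_spacer(seg.seq):
            ann.features.append(
                StructuralFeature("acidic_spacer", (seg.start, seg.end),
                                  evidence="planted acidic spacer")
            )
    if sites:
        neuro = detect_neurophysin(protein, sites[-1].end)
        if neuro is not None:
            ann.features.append(neuro)
    ann.features.extend(detect_insulin_architecture(protein, sites, len(arch.signal)))
    registry = default_registry()
    for idx, pep in enumerate(peptides):
        for fam in classify(pep, registry):
            ann.family_hits.append((idx, fam))
    ann.score = score_precursor(ann).total
    return ann


def _reverse_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(AA_TO_CODONS[aa]) for aa in protein)


def _rand_nt(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _peptide_keys(ann: PrecursorAnnotation) -> set[tuple[int, int, str]]:
    return {(a, b, p.seq) for p in ann.peptides for a, b in [p.precursor_coords]}


def _contig_predictions(contig: TranscriptContig, config: PipelineConfig) -> set:
    keys = set()
    for orf in six_frame_orfs(contig, min_len=60, allow_partial=False):
        ann = annotate_protein(orf.id, orf.protein, config)
        keys |= _peptide_keys(ann)
    return keys


def _build_contig(
    protein: str, cid: str, cfg: GeneratorConfig, rng: random.Random,
    expected_keys: set, pipeline_cfg: PipelineConfig,
) -> TranscriptContig:
    for _ in range(cfg.max_attempts):
        cds = _reverse_translate(protein, rng) + rng.choice(("TAA", "TAG", "TGA"))
        utr5 = _rand_nt(rng.randint(*cfg.utr_len), rng) + "TAA"
        utr3 = _rand_nt(rng.randint(*cfg.utr_len), rng)
        seq = utr5 + cds + utr3
        if cfg.plant_reverse_strand and rng.random() < 0.5:
            seq = revcomp(seq)
        contig = TranscriptContig(cid, seq)
        if _contig_predictions(contig, pipeline_cfg) == expected_keys:
            return contig
    raise GenerationError(f"could not realise contig {cid!r} in {cfg.max_attempts} attempts")


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Generate contigs with planted precursors plus decoys and their ground truth."""
    cfg = config or GeneratorConfig()
    rng = random.Random(seed)
    pipeline_cfg = PipelineConfig()
    contigs: list[TranscriptContig] = []
    truths: dict[str, PrecursorAnnotation] = {}
    decoy_ids: list[str] = []
    planted_segments: list[str] = []

    for idx, arch in enumerate(cfg.architectures, 1):
        cid = f"precursor_{arch.name}_{idx}"
        truth = _truth_annotation(cid, arch)
        contig = _build_contig(
            arch.protein, cid, cfg, rng, _peptide_keys(truth), pipeline_cfg
        )
        contigs.append(contig)
        truths[cid] = truth
        planted_segments.extend(seq for kind, seq in arch.elements if kind == "segment")

    aa_pool = "ACDEFGHILMNPQSTVWY"  # decoy bodies avoid K/R so no spurious sites
    for d in range(cfg.n_decoys):
        cid = f"decoy_{d + 1}"
        for _ in range(cfg.max_attempts):
            length = rng.randint(*cfg.decoy_len)
            protein = "M" + "".join(rng.choice(aa_pool) for _ in range(length - 1))
            if predict_signal(protein).present:
                continue
            if any(seg in protein for seg in planted_segments):
                continue
            try:
                contig = _build_contig(protein, cid, cfg, rng, set(), pipeline_cfg)
            except GenerationError:
                continue
            contigs.append(contig)
            decoy_ids.append(cid)
            break
        else:
            raise GenerationError(f"could not generate decoy {cid!r}")

    return SyntheticTruth(contigs=contigs, truths=truths, decoy_ids=decoy_ids,
                          seed=seed, config=cfg)


def evaluate(result: DiscoveryResult | list[Candidate], truth: SyntheticTruth) -> dict:
    """Peptide- and site-level precision/recall/F1 against the planted ground truth.

    Matching is exact: a predicted peptide counts as a true positive only when
    its precursor coordinates and sequence equal a planted one on the same
    contig.  Predictions on decoy contigs are false positives.  An empty
    prediction set reports precision 0 with ``no_predictions`` flagged.
    """
    candidates = result.candidates if isinstance(result, DiscoveryResult) else result
    pred_peps: dict[str, set] = {}
    pred_sites: dict[str, set] = {}
    for cand in candidates:
        pred_peps.setdefault(cand.contig_id, set()).update(_peptide_keys(cand.annotation))
        pred_sites.setdefault(cand.contig_id, set()).update(
            (s.start, s.end, s.kind) for s in cand.annotation.sites
        )
    true_peps = {cid: _peptide_keys(ann) for cid, ann in truth.truths.items()}
    true_sites = {
        cid: {(s.start, s.end, s.kind) for s in ann.sites} for cid, ann in truth.truths.items()
    }
    for cid in truth.decoy_ids:
        true_peps.setdefault(cid, set())
        true_sites.setdefault(cid, set())

    def metrics(pred: dict, true: dict) -> dict:
        tp = fp = fn = 0
        for cid in set(pred) | set(true):
            p, t = pred.get(cid, set()), true.get(cid, set())
            tp += len(p & t)
            fp += len(p - t)
            fn += len(t - p)
        no_pred = (tp + fp) == 0
        precision = tp / (tp + fp) if not no_pred else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
        return {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
            "no_predictions": no_pred,
        }

    return {"peptide": metrics(pred_peps, true_peps), "site": metrics(pred_sites, true_sites)}


def separation_holds(result: DiscoveryResult, truth: SyntheticTruth) -> bool:
    """True iff every planted precursor outranks (scores above) every decoy candidate."""
    planted_scores: list[float] = []
    decoy_scores: list[float] = []
    for cand in result.candidates:
        if cand.contig_id in truth.truths and cand.annotation.protein == truth.truths[
            cand.contig_id
        ].protein:
            planted_scores.append(cand.annotation.score)
        elif cand.contig_id in truth.decoy_ids:
            decoy_scores.append(cand.annotation.score)
    if len(planted_scores) < len(truth.truths):
        return False
    if not decoy_scores:
        return True
    return min(planted_scores) > max(decoy_scores)
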