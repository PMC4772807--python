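"""The discovery pipeline: fixed stage order, individually invokable stages.

``annotate_protein`` runs signal prediction -> cleavage-site detection ->
segmentation -> maturation -> structural features -> family classification ->
composite scoring on one protein.  ``discover`` runs the six-frame ORF scan
over contigs, annotates every ORF and returns the ranked candidate list.

Two modes:

* ``de_novo`` (default): precision-oriented blind scanning.  Monobasic sites
  off, mature peptides shorter than 3 residues discarded, and peptides are
  only excised when a signal peptide is present (a precursor without one
  cannot enter the secretory pathway).
* ``curation``: agreement-oriented annotation of known precursors.  Monobasic
  sites on, no length floor, excision proceeds even without a detected signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .cleavage import CleavageRules, find_cleavage_sites, segment_between_sites
from .families import FamilyMotif, classify, default_registry
from .maturation import (
    PrecursorAnnotation,
    StructuralFeature,
    assign_copy_ids,
    detect_acidic_spacer,
    detect_insulin_architecture,
    detect_neurophysin,
    mature,
)
from .ranking import DEFAULT_WEIGHTS, rank_candidates, score_precursor
from .seqio import OpenReadingFrame, TranscriptContig, six_frame_orfs
from .signalpep import SignalParams, SignalPrediction, predict_signal


@dataclass
class PipelineConfig:
    mode: str = "de_novo"  # or "curation"
    signal_params: SignalParams = field(default_factory=SignalParams)
    cleavage_rules: CleavageRules | None = None  # derived from mode when None
    min_peptide_len: int | None = None  # derived from mode when None
    pyroglu: bool = True
    sulfation_global: bool = False
    registry: list[FamilyMotif] | None = None  # defaults when None
    weights: dict[str, float] = field(default_factory=dict)
    signal_table: dict[str, SignalPrediction] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("de_novo", "curation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cleavage_rules is None:
            self.cleavage_rules = CleavageRules(monobasic=(self.mode == "curation"))
        if self.min_peptide_len is None:
            self.min_peptide_len = 3 if self.mode == "de_novo" else 1
        if self.registry is None:
            self.registry = default_registry()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file with optional ``mode``, ``signal:``,
        ``cleavage:`` and ``weights:`` blocks."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "mode" in data:
            kwargs["mode"] = data["mode"]
        if "signal" in data:
            kwargs["signal_params"] = SignalParams(**data["signal"])
        if "cleavage" in data:
            c = dict(data["cleavage"])
            if "pairs" in c:
                c["pairs"] = tuple(c["pairs"])
            kwargs["cleavage_rules"] = CleavageRules(**c)
        if "weights" in data:
            kwargs["weights"] = dict(data["weights"])
        return cls(**kwargs)


@dataclass
class Candidate:
    """One ranked discovery candidate: the ORF and its annotation."""

    contig_id: str
    orf: OpenReadingFrame
    annotation: PrecursorAnnotation


@dataclass
class DiscoveryResult:
    candidates: list[Candidate]  # ranked
    orf_map: dict[str, OpenReadingFrame]

    @property
    def annotations(self) -> list[PrecursorAnnotation]:
        return [c.annotation for c in self.candidates]


def annotate_protein(
    protein_id: str, protein: str, config: PipelineConfig | None = None
) -> PrecursorAnnotation:
    """Annotate one protein as a candidate neuropeptide precursor."""
    config = config or PipelineConfig()
    signal = None
    if config.signal_table is not None:
        signal = config.signal_table.get(protein_id)
    if signal is None:
        signal = predict_signal(protein, config.signal_params)
    signal_end = signal.cleave_after if signal.present else 0

    ann = PrecursorAnnotation(protein_id=protein_id, protein=protein, signal=signal)
    excise = signal.present or config.mode == "curation"
    if excise and signal_end < len(protein):
        ann.sites = find_cleavage_sites(protein, signal_end, config.cleavage_rules)
        segments = segment_between_sites(protein, signal_end, ann.sites)
        peptides = []
        kept_segments = []
        for seg in segments:
            pep = mature(seg, pyroglu=config.pyroglu, sulfation=config.sulfation_global)
            if len(pep.seq) >= config.min_peptide_len:
                peptides.append(pep)
                kept_segments.append(seg)
        assign_copy_ids(peptides)
        ann.peptides = peptides

        for seg in kept_segments:
            if detect_acidic_spacer(seg.seq):
                ann.features.append(
                    StructuralFeature(
                        "acidic_spacer", (seg.start, seg.end),
                        evidence="aspartate/glutamate-rich inter-peptide segment",
                    )
                )
        if ann.sites:
            neuro = detect_neurophysin(protein, ann.sites[-1].end)
            if neuro is not None:
                ann.features.append(neuro)
        ann.features.extend(detect_insulin_architecture(protein, ann.sites, signal_end))

        for idx, pep in enumerate(ann.peptides):
            fams = classify(pep, config.registry)
            for fam in fams:
                ann.family_hits.append((idx, fam))
            # sulfation is raised specifically for CCK-type peptides
            if not config.sulfation_global and "CCK-type" in fams:
                pep.sulfation_candidates = [i + 1 for i, c in enumerate(pep.seq) if c == "Y"]

    ann.score = score_precursor(ann, config.weights).total
    return ann


def discover(
    contigs: list[TranscriptContig],
    config: PipelineConfig | None = None,
    min_orf_len: int = 60,
    allow_partial: bool = False,
    top_n: int = 500,
) -> DiscoveryResult:
    """Six-frame ORF scan -> per-ORF annotation -> composite ranking."""
    config = config or PipelineConfig()
    orf_map: dict[str, OpenReadingFrame] = {}
    candidates: list[Candidate] = []
    for contig in contigs:
        for orf in six_frame_orfs(contig, min_len=min_orf_len, allow_partial=allow_partial):
            ann = annotate_protein(orf.id, orf.protein, config)
            orf_map[orf.id] = orf
            candidates.append(Candidate(contig.id, orf, ann))
    ranked_ann = rank_candidates([c.annotation for c in candidates], top_n=top_n)
    order = {id(a): i for i, a in enumerate(ranked_ann)}
    kept = [c for c in candidates if id(c.annotation) in order]
    kept.sort(key=lambda c: order[id(c.annotation)])
    return DiscoveryResult(candidates=kept, orf_map=orf_map)
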