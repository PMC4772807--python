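"""Composite precursor-likeness scoring and candidate ranking.

De novo discovery needs a way to sort thousands of ORFs by how much they look
like neuropeptide precursors.  The score is a transparent weighted sum of
evidence that is monotone in each feature: signal peptide present, number of
cleavage sites (capped), number of amide-donor glycines, fraction of the
post-signal protein covered by predicted peptides, extra identical peptide
copies, an acidic spacer, and a mild penalty for very long proteins.  All
weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .maturation import PrecursorAnnotation, copy_counts, detect_acidic_spacer

FEATURE_ORDER = (
    "has_signal",
    "n_sites",
    "n_amide_gly",
    "peptide_coverage",
    "extra_copies",
    "has_acidic_spacer",
    "length_penalty",
)

DEFAULT_WEIGHTS: dict[str, float] = {
    "has_signal": 3.0,
    "n_sites": 1.0,
    "n_amide_gly": 1.0,
    "peptide_coverage": 2.0,
    "extra_copies": 2.0,
    "has_acidic_spacer": 0.5,
    "length_penalty": 1.0,
}

SITE_CAP = 10
LENGTH_SOFT_CAP = 500
LENGTH_PENALTY_PER_RESIDUE = 0.01


class WeightError(ValueError):
    """Invalid score weights."""


@dataclass
class ScoreBreakdown:
    features: dict[str, float]
    weights: dict[str, float]
    total: float


def _validate_weights(weights: dict[str, float]) -> dict[str, float]:
    merged = dict(DEFAULT_WEIGHTS)
    unknown = set(weights) - set(DEFAULT_WEIGHTS)
    if unknown:
        raise WeightError(f"unknown weight(s): {sorted(unknown)}")
    merged.update(weights)
    for k, v in merged.items():
        if v < 0:
            raise WeightError(f"weight {k!r} must be non-negative (got {v})")
    return merged


def n_amide_gly(annotation: PrecursorAnnotation) -> int:
    return sum(1 for p in annotation.peptides if p.cterm_amide)


def score_precursor(
    annotation: PrecursorAnnotation, weights: dict[str, float] | None = None
) -> ScoreBreakdown:
    """Compute the composite score; the breakdown sums exactly to the total.

    Feature values: ``has_signal`` 0/1; ``n_sites`` capped at 10;
    ``n_amide_gly`` count of amidated peptides; ``peptide_coverage`` fraction of
    post-signal residues inside raw peptide segments; ``extra_copies`` max copy
    count minus one; ``has_acidic_spacer`` 0/1; ``length_penalty`` -0.01 per
    residue over 500 (the only non-positive feature).
    """
    weights = _validate_weights(weights or {})
    protein_len = len(annotation.protein)
    signal_len = annotation.signal_end
    post_signal = protein_len - signal_len
    covered = sum(b - a + 1 for a, b in (p.precursor_coords for p in annotation.peptides))
    counts = copy_counts(annotation.peptides)
    max_copies = max(counts.values()) if counts else 0
    has_spacer = any(f.kind == "acidic_spacer" for f in annotation.features) or any(
        detect_acidic_spacer(annotation.protein[a - 1 : b])
        for a, b in (p.precursor_coords for p in annotation.peptides)
    )
    features = {
        "has_signal": 1.0 if annotation.signal.present else 0.0,
        "n_sites": float(min(len(annotation.sites), SITE_CAP)),
        "n_amide_gly": float(n_amide_gly(annotation)),
        "peptide_coverage": covered / post_signal if post_signal > 0 else 0.0,
        "extra_copies": float(max_copies - 1) if max_copies > 1 else 0.0,
        "has_acidic_spacer": 1.0 if has_spacer else 0.0,
        "length_penalty": -LENGTH_PENALTY_PER_RESIDUE * max(0, protein_len - LENGTH_SOFT_CAP),
    }
    total = sum(weights[k] * features[k] for k in FEATURE_ORDER)
    return ScoreBreakdown(features=features, weights=weights, total=total)


def rank_candidates(
    annotations: list[PrecursorAnnotation], top_n: int = 500
) -> list[PrecursorAnnotation]:
    """Sort by score descending, ties by (amide-glycine count desc, protein id asc),
    truncated to ``top_n``."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(
        annotations, key=lambda a: (-a.score, -n_amide_gly(a), a.protein_id)
    )
    return ranked[:top_n]
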