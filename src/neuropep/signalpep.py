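"""N-terminal signal peptide detection.

A desk-scale heuristic built around the classical tripartite architecture of
secretory signal peptides: a positively charged n-region, a hydrophobic
h-region, and a short c-region ending in small residues at the -3 and -1
positions relative to the cleavage point.  The heuristic is deliberately
simple; externally produced predictions (e.g. from a dedicated predictor) can
be imported from a TSV table and always take precedence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


class SignalTableError(ValueError):
    """Malformed imported signal-prediction table."""


@dataclass
class SignalParams:
    """Tunable knobs of the heuristic.

    ``min_pos``/``max_pos`` bound the candidate cleavage position (last residue
    of the signal peptide); ``h_window`` is the minimum hydrophobic-core length;
    ``c_region`` bounds how far the core may end before the cleavage point
    (3..c_region residues upstream); ``small_set`` are the residues accepted at
    the -3 and -1 positions.
    """

    min_pos: int = 15
    max_pos: int = 45
    hydropathy_threshold: float = 1.5
    h_window: int = 7
    c_region: int = 6
    small_set: str = "AGSCTV"
    min_protein_len: int = 25


@dataclass
class SignalPrediction:
    present: bool
    cleave_after: int | None  # 1-based index of the last signal-peptide residue
    score: float
    source: str = "heuristic"  # or "imported"
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.present and self.cleave_after is not None:
            raise ValueError("cleave_after must be null when no signal peptide is present")


def predict_signal(protein: str, params: SignalParams | None = None) -> SignalPrediction:
    """Scan candidate cleavage positions and return the best-scoring one.

    A candidate position p (signal peptide = residues 1..p) passes when:

    1. the n-region (residues before the hydrophobic core) has net charge >= 0;
    2. a hydrophobic core of >= ``h_window`` consecutive residues ending 3 to
       ``c_region`` residues before p has mean Kyte-Doolittle hydropathy >=
       ``hydropathy_threshold``;
    3. the residues at -3 and -1 relative to cleavage are small (``small_set``).

    Score = best core mean hydropathy + 1 per satisfied small-residue position.
    Ties are resolved toward the larger position (the longer signal peptide).
    Deterministic.  Proteins shorter than ``min_protein_len`` return
    ``present=False`` with a warning flag rather than raising.
    """
    params = params or SignalParams()
    n = len(protein)
    if n < params.min_protein_len:
        return SignalPrediction(
            False, None, 0.0,
            warning=f"protein length {n} below minimum {params.min_protein_len}",
        )
    max_pos = min(params.max_pos, n - 5)
    small = set(params.small_set)
    kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in protein]
    prefix = [0.0]
    for v in kd:
        prefix.append(prefix[-1] + v)

    def window_mean(a: int, b: int) -> float:  # 1-based inclusive residues
        return (prefix[b] - prefix[a - 1]) / (b - a + 1)

    best: tuple[float, int, int] | None = None  # (score, position, h_start)
    for p in range(params.min_pos, max_pos + 1):
        if protein[p - 1] not in small or protein[p - 3] not in small:
            continue
        # hydrophobic core: >=h_window residues within 2..p-3, ending 3..c_region
        # residues before the cleavage point
        h_best = None
        h_start_best = None
        for end in range(p - params.c_region, p - 2):  # 1-based window end
            if end < params.h_window + 1:  # window must start at residue >= 2
                continue
            for start in range(2, end - params.h_window + 2):
                m = window_mean(start, end)
                if h_best is None or m > h_best:
                    h_best, h_start_best = m, start
        if h_best is None or h_best < params.hydropathy_threshold:
            continue
        n_charge = sum(_CHARGE.get(c, 0.0) for c in protein[: h_start_best - 1])
        if n_charge < 0:
            continue
        score = h_best + 2.0  # +1 per small residue at -3 and -1 (both required)
        if best is None or score >= best[0]:
            best = (score, p, h_start_best)
    if best is None:
        return SignalPrediction(False, None, 0.0)
    return SignalPrediction(True, best[1], best[0])


def import_signal_table(path, lengths: dict[str, int] | None = None) -> dict[str, SignalPrediction]:
    """Parse externally produced signal predictions from a TSV file.

    Required columns: ``id``, ``present``, ``cleave_after``.  Entries get
    ``source="imported"`` and override heuristic results downstream.  When a
    ``lengths`` map is given, ``cleave_after`` must lie in [1, length).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "present", "cleave_after"} - set(df.columns)
    if missing:
        raise SignalTableError(f"missing column(s): {sorted(missing)}")
    out: dict[str, SignalPrediction] = {}
    for row in df.itertuples(index=False):
        rid = str(row.id)
        pres_raw = str(row.present).strip().lower()
        if pres_raw in ("true", "1", "yes"):
            present = True
        elif pres_raw in ("false", "0", "no"):
            present = False
        else:
            raise SignalTableError(f"record {rid!r}: cannot parse present={row.present!r}")
        cleave: int | None = None
        if present:
            raw = "" if pd.isna(row.cleave_after) else str(row.cleave_after).strip()
            try:
                cleave = int(raw)
            except ValueError:
                raise SignalTableError(
                    f"record {rid!r}: cleave_after {raw!r} is not an integer"
                ) from None
            if cleave < 1:
                raise SignalTableError(f"record {rid!r}: cleave_after must be >= 1")
            if lengths is not None and rid in lengths and not (1 <= cleave < lengths[rid]):
                raise SignalTableError(
                    f"record {rid!r}: cleave_after {cleave} outside [1, {lengths[rid]})"
                )
        out[rid] = SignalPrediction(present, cleave, 0.0, source="imported")
    return out
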