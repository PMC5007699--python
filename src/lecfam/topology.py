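"""Membrane topology handling and the eight-class orientation classifier.

Receptor-like kinases are classified by (i) the number of accepted
transmembrane (TM) segments and (ii) which side of the membrane the
lectin and kinase domains sit on.  Classes I-III have one TM, IV-VI two,
VII-VIII three; combinations never observed in the reference catalogues
(both domains inside with one TM, four or more TMs, membrane-spanning
domains) are reported as UNCLASSIFIED, and proteins without an accepted
TM as NO_TM.

Topology normally arrives as a segment table (inside/membrane/outside
rows with posterior-style scores plus a signal-peptide score) emulating
TMHMM/SignalP output.  TM segments below probability 0.8 are dropped;
a signal-peptide score >= 0.7 takes priority over an overlapping
N-terminal TM, which is then reinterpreted as the signal peptide and
excluded from the TM count.  A simple hydropathy sliding-window
predictor is provided as a built-in stand-in when no table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

SegmentLabel = Literal["inside", "membrane", "outside"]
Side = Literal["extracellular", "intracellular", "membrane_spanning"]

ORIENTATION_CLASSES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "NO_TM", "UNCLASSIFIED")


@dataclass(frozen=True)
class Segment:
    label: SegmentLabel
    start: int  # 1-based inclusive
    end: int
    score: float = 1.0

    def __post_init__(self):
        if self.label not in ("inside", "membrane", "outside"):
            raise ValueError(f"bad segment label {self.label!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment coordinates [{self.start}, {self.end}]")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("segment score must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyModel:
    protein_id: str
    segments: tuple[Segment, ...]
    sp_score: Optional[float] = None
    sp_end: Optional[int] = None
    contradictory: bool = False

    def __post_init__(self):
        if not self.segments:
            raise ValueError("a topology model needs at least one segment")
        pos = 1
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(
                    f"{self.protein_id}: segments must tile the sequence; expected start {pos}, got {seg.start}"
                )
            pos = seg.end + 1
        if self.sp_score is not None and not (0.0 <= self.sp_score <= 1.0):
            raise ValueError("sp_score must lie in [0, 1]")
        self._check_alternation()

    def _check_alternation(self):
        sides = [s.label for s in self.segments if s.label != "membrane"]
        # between consecutive membranes the side must flip; equivalently
        # consecutive non-membrane segments separated by one membrane differ
        labels = [s.label for s in self.segments]
        for i in range(1, len(labels) - 1):
            if labels[i] == "membrane" and labels[i - 1] != "membrane" and labels[i + 1] != "membrane":
                if labels[i - 1] == labels[i + 1] and not self.contradictory:
                    raise ValueError(f"{self.protein_id}: sides do not alternate across a membrane segment")
        del sides

    @property
    def length(self) -> int:
        return self.segments[-1].end

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.segments if s.label == "membrane")

    def membrane_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label == "membrane"]


def _merge_sides(segments: list[Segment]) -> tuple[list[Segment], bool]:
    """Merge runs of adjacent non-membrane segments.

    The merged segment takes the label of the longest contributor (ties:
    the earlier one).  Returns the new segment list and whether any merge
    combined contradictory side labels that still matter (checked later
    against alternation).
    """
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].label != "membrane" and seg.label != "membrane":
            prev = merged.pop()
            label = prev.label if prev.length >= seg.length else seg.label
            merged.append(Segment(label, prev.start, seg.end, max(prev.score, seg.score)))
        else:
            merged.append(seg)
    return merged, False


def _alternation_ok(segments: Sequence[Segment]) -> bool:
    labels = [s.label for s in segments]
    for i, lab in enumerate(labels):
        if lab == "membrane":
            before = labels[i - 1] if i > 0 else None
            after = labels[i + 1] if i + 1 < len(labels) else None
            if before is not None and after is not None and before == after:
                return False
    return True


def accept_tm_segments(model: TopologyModel, tm_threshold: float = 0.8) -> TopologyModel:
    """Drop TM segments scoring below the acceptance threshold.

    Removed TM spans are absorbed into the surrounding side segments,
    which merge under the longest-flank label.  If the merge breaks side
    alternation across a surviving TM the model is flagged contradictory
    (classified UNCLASSIFIED downstream).
    """
    kept: list[Segment] = []
    for seg in model.segments:
        if seg.label == "membrane" and seg.score < tm_threshold:
            # reassign the span to a neighbour; temporarily label it after
            # the previous side segment (or the next one at the N-terminus)
            neighbour = kept[-1].label if kept and kept[-1].label != "membrane" else None
            if neighbour is None:
                kept.append(Segment("outside", seg.start, seg.end, 0.0))
            else:
                kept.append(Segment(neighbour, seg.start, seg.end, 0.0))
        else:
            kept.append(seg)
    merged, _ = _merge_sides(kept)
    contradictory = not _alternation_ok(merged)
    if contradictory:
        # re-merge is impossible without inventing sides; keep segments,
        # flag the model so classification reports UNCLASSIFIED
        return TopologyModel(model.protein_id, tuple(merged), model.sp_score, model.sp_end, True)
    return TopologyModel(model.protein_id, tuple(merged), model.sp_score, model.sp_end, False)


def resolve_signal_peptide(model: TopologyModel, sp_threshold: float = 0.7) -> TopologyModel:
    """Give priority to a predicted signal peptide over an N-terminal TM.

    If the signal-peptide score reaches the threshold and the first TM
    segment overlaps the signal region (positions 1..sp_end), that TM is
    reinterpreted as the signal peptide: it leaves the TM count and the
    mature chain starts extracellular.  Never increases the TM count.
    """
    if model.sp_score is None or model.sp_score < sp_threshold:
        return model
    membranes = model.membrane_segments()
    if not membranes:
        return model
    first_tm = membranes[0]
    sp_end = model.sp_end
    if sp_end is None:
        # cleavage site unknown: treat a TM starting within the first 40
        # residues as the candidate signal anchor
        sp_end = first_tm.end if first_tm.start <= 40 else 0
    if first_tm.start > sp_end:
        return model
    # remove the first TM; everything up to its end becomes extracellular
    new_segments: list[Segment] = []
    for seg in model.segments:
        if seg == first_tm:
            new_segments.append(Segment("outside", seg.start, seg.end, seg.score))
        else:
            new_segments.append(seg)
    merged, _ = _merge_sides(new_segments)
    # the mature chain starts extracellular: relabel the leading run
    lead = merged[0]
    if lead.label != "membrane" and lead.label != "outside":
        merged[0] = Segment("outside", lead.start, lead.end, lead.score)
        merged, _ = _merge_sides(merged)
    contradictory = not _alternation_ok(merged)
    return TopologyModel(model.protein_id, tuple(merged), model.sp_score, model.sp_end, contradictory)


def domain_side(hit, model: TopologyModel) -> Side:
    """Which side of the membrane a domain sits on.

    The side whose segments cover a strict majority (> 50%) of the
    domain's residues wins; otherwise — e.g. a TM splitting the domain
    50/50 — the domain is membrane_spanning.
    """
    if hit.start < 1 or hit.end > model.length:
        raise ValueError(
            f"domain [{hit.start}, {hit.end}] outside sequence bounds 1..{model.length} of {model.protein_id}"
        )
    inside = outside = 0
    for seg in model.segments:
        overlap = min(seg.end, hit.end) - max(seg.start, hit.start) + 1
        if overlap <= 0:
            continue
        if seg.label == "inside":
            inside += overlap
        elif seg.label == "outside":
            outside += overlap
    total = hit.end - hit.start + 1
    if outside * 2 > total:
        return "extracellular"
    if inside * 2 > total:
        return "intracellular"
    return "membrane_spanning"


# (n_tm, lectin side, kinase side) -> class, exactly the eight observed
# patterns; everything else is NO_TM (n_tm == 0) or UNCLASSIFIED.
_CLASS_TABLE = {
    (1, "extracellular", "intracellular"): "I",
    (1, "intracellular", "extracellular"): "II",
    (1, "extracellular", "extracellular"): "III",
    (2, "extracellular", "extracellular"): "IV",
    (2, "intracellular", "extracellular"): "V",
    (2, "extracellular", "intracellular"): "VI",
    (3, "extracellular", "intracellular"): "VII",
    (3, "intracellular", "extracellular"): "VIII",
}


def classify_orientation(n_tm: int, lectin_side: Optional[Side], kinase_side: Optional[Side]) -> str:
    """Total classifier over TM count and domain sides.

    For multi-copy architectures (class VII/VIII fusions) the caller
    passes the sides of the first lectin and first kinase by coordinate.
    """
    if n_tm < 0:
        raise ValueError("negative TM count")
    if n_tm == 0:
        return "NO_TM"
    return _CLASS_TABLE.get((n_tm, lectin_side, kinase_side), "UNCLASSIFIED")


def classify_protein(
    model: TopologyModel,
    lectin_hit,
    kinase_hit,
    tm_threshold: float = 0.8,
    sp_threshold: float = 0.7,
) -> tuple[str, TopologyModel]:
    """Full per-protein pipeline: TM acceptance, SP priority, sides, class."""
    resolved = resolve_signal_peptide(accept_tm_segments(model, tm_threshold), sp_threshold)
    if resolved.contradictory:
        return "UNCLASSIFIED", resolved
    if resolved.n_tm == 0:
        return "NO_TM", resolved
    lectin = domain_side(lectin_hit, resolved)
    kinase = domain_side(kinase_hit, resolved)
    return classify_orientation(resolved.n_tm, lectin, kinase), resolved


# --- built-in fallback TM predictor -----------------------------------------

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


def _logistic_score(h: float, midpoint: float = 1.0, slope: float = 3.0) -> float:
    return float(1.0 / (1.0 + np.exp(-slope * (h - midpoint))))


def predict_tm_fallback(
    sequence: str,
    protein_id: str = "query",
    window: int = 19,
    hydropathy_cutoff: float = 1.5,
    min_tm_length: int = 15,
) -> TopologyModel:
    """Sliding-window hydropathy stand-in for an HMM topology predictor.

    Windows whose mean Kyte-Doolittle hydropathy reaches the cutoff seed
    membrane segments; the peak window mean maps to a [0, 1] score
    through a fixed logistic.  Side labels alternate, starting from the
    positive-inside heuristic: the flank richer in Arg+Lys before the
    first TM is taken as cytoplasmic.  This is a calibrated stand-in,
    not a reimplementation of an HMM predictor.
    """
    n = len(sequence)
    if n <= window:
        raise ValueError(f"sequence length {n} must exceed window {window}")
    h = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in sequence])
    means = np.convolve(h, np.ones(window) / window, mode="valid")  # centre i -> window [i, i+window)
    above = means >= hydropathy_cutoff

    # maximal runs of qualifying window starts -> candidate segments
    segments: list[tuple[int, int, float]] = []  # (start, end, peak mean) 1-based
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            start = i + 1
            end = j + window  # last window [j, j+window)
            peak = float(means[i : j + 1].max())
            segments.append((start, end, peak))
            i = j + 1
        else:
            i += 1

    # merge overlapping candidates, drop short ones, clip to sequence
    merged: list[list] = []
    for start, end, peak in segments:
        end = min(end, n)
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])
    tms = [(s, e, p) for s, e, p in merged if e - s + 1 >= min_tm_length]

    if not tms:
        return TopologyModel(protein_id, (Segment("outside", 1, n, 1.0),))

    # positive-inside heuristic on the flanks of the first TM
    def rk_fraction(a: int, b: int) -> float:
        if b < a:
            return 0.0
        span = sequence[a - 1 : b]
        return sum(1 for c in span if c in "RK") / len(span)

    first_start = tms[0][0]
    after_end = tms[0][1]
    next_start = tms[1][0] if len(tms) > 1 else n + 1
    before = rk_fraction(1, first_start - 1)
    after = rk_fraction(after_end + 1, next_start - 1)
    first_side = "inside" if before > after else "outside"

    sides = ["inside", "outside"]
    side = first_side
    out: list[Segment] = []
    pos = 1
    for s, e, p in tms:
        if s > pos:
            out.append(Segment(side, pos, s - 1, 0.9))
        out.append(Segment("membrane", s, e, _logistic_score(p)))
        side = sides[1 - sides.index(side)]
        pos = e + 1
    if pos <= n:
        out.append(Segment(side, pos, n, 0.9))
    # handle a TM starting at position 1: no leading side segment
    return TopologyModel(protein_id, tuple(out))
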