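"""Selection and promoter-slot assignment of guide pairs bracketing a deletion.

Candidates are drawn from windows (default 200 bp, centered) around the two
boundaries of the target region. The U6-driven guide must start with G; the
H1-driven guide may start with any base. Pairs are ranked by the weaker
member's specificity score — a deletion fails if either cut fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import GenomeRegion, SequenceRecord, as_genome_dict
from .guide_finder import (GuideCandidate, annotate_scores, filter_candidates,
                           find_protospacers)


class DesignError(ValueError):
    pass


class EmptyWindowError(DesignError):
    """No usable guide candidate in one of the boundary windows."""

    def __init__(self, side: str, window: GenomeRegion):
        self.side = side
        super().__init__(
            f"no usable guide candidate in the {side} window "
            f"{window.chrom}:{window.start}-{window.end}"
        )


class SlotRejection(DesignError):
    """Neither guide starts with G and prepending is disabled."""


class DegeneratePairError(DesignError):
    """Both guides cut at the same coordinate; no deletion results."""


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of pair design.

    window_bp: width of the candidate window at each target boundary (the
    published design drew the highest-scoring guides from 200-bp windows).
    window_mode: "centered" places the window +-window_bp/2 around each
    boundary; "inside"/"outside" place it entirely within/without the target.
    """

    window_bp: int = 200
    max_pairs: int = 10
    require_g_for_u6: bool = True
    allow_prepend_g: bool = False
    min_pair_score: float = 0.0
    max_mm: int = 3
    window_mode: str = "centered"

    def __post_init__(self) -> None:
        if self.window_bp < 23:
            raise DesignError("window_bp must be >= 23 (one full guide site)")
        if self.max_pairs < 1:
            raise DesignError("max_pairs must be >= 1")
        if self.window_mode not in {"centered", "inside", "outside"}:
            raise DesignError(f"unknown window_mode {self.window_mode!r}")


@dataclass(frozen=True)
class GuidePair:
    """Two slotted guides and the deletion interval between their cut sites."""

    u6_guide: GuideCandidate
    h1_guide: GuideCandidate
    deletion: GenomeRegion
    deletion_len: int
    pair_score: float
    u6_prepended_g: bool = False

    def __post_init__(self) -> None:
        cuts = sorted([self.u6_guide.cut_pos, self.h1_guide.cut_pos])
        if self.deletion.start != cuts[0] or self.deletion.end != cuts[1]:
            raise DesignError("deletion interval must span the two cut sites")
        if self.deletion_len != self.deletion.end - self.deletion.start:
            raise DesignError("deletion_len inconsistent with deletion interval")

    @property
    def left_guide(self) -> GuideCandidate:
        return min(self.u6_guide, self.h1_guide, key=lambda c: c.cut_pos)

    @property
    def right_guide(self) -> GuideCandidate:
        return max(self.u6_guide, self.h1_guide, key=lambda c: c.cut_pos)

    @property
    def u6_transcript_spacer(self) -> str:
        """The 20- or 21-nt targeting region as transcribed from the U6 cassette."""
        if self.u6_prepended_g:
            return "G" + self.u6_guide.protospacer
        return self.u6_guide.protospacer


def predicted_deletion(pair_or_left, right: GuideCandidate | None = None
                       ) -> tuple[GenomeRegion, int]:
    """Deletion interval between the two blunt-cut coordinates and its length.

    Accepts a GuidePair or two GuideCandidates. Identical cut sites are a
    degenerate (zero-length) deletion and raise DegeneratePairError.
    """
    if right is None:
        left_cut = pair_or_left.u6_guide.cut_pos
        right_cut = pair_or_left.h1_guide.cut_pos
        chrom = pair_or_left.u6_guide.region.chrom
    else:
        left_cut = pair_or_left.cut_pos
        right_cut = right.cut_pos
        chrom = pair_or_left.region.chrom
    lo, hi = sorted([left_cut, right_cut])
    if lo == hi:
        raise DegeneratePairError(f"both guides cut at coordinate {lo}")
    region = GenomeRegion(chrom, lo, hi, ".")
    return region, hi - lo


def assign_slots(left: GuideCandidate, right: GuideCandidate,
                 cfg: DesignConfig) -> GuidePair:
    """Place guides into U6/H1 promoter slots under the G-start rule.

    The G-starting guide takes the U6 slot (U6 transcripts conventionally
    start with G); if both start with G the left (lower-coordinate) guide
    takes U6; if neither does, the pair is rejected unless allow_prepend_g,
    in which case the left guide takes U6 with a G prepended on the
    transcript only (the oligo still carries the 20-nt genomic match).
    """
    deletion, dlen = predicted_deletion(left, right)
    prepended = False
    if not cfg.require_g_for_u6:
        u6, h1 = left, right
    elif left.starts_with_g:
        u6, h1 = left, right
    elif right.starts_with_g:
        u6, h1 = right, left
    elif cfg.allow_prepend_g:
        u6, h1 = left, right
        prepended = True
    else:
        raise SlotRejection(
            "neither guide starts with G; enable allow_prepend_g to model a "
            "prepended transcript G for the U6 slot"
        )
    scores = [s for s in (left.score, right.score) if s is not None]
    pair_score = min(scores) if len(scores) == 2 else 0.0
    return GuidePair(u6_guide=u6, h1_guide=h1, deletion=deletion,
                     deletion_len=dlen, pair_score=pair_score,
                     u6_prepended_g=prepended)


def boundary_window(boundary: int, cfg: DesignConfig, side: str,
                    seq_len: int, chrom: str) -> GenomeRegion:
    w = cfg.window_bp
    if cfg.window_mode == "centered":
        start, end = boundary - w // 2, boundary + w - w // 2
    elif cfg.window_mode == "inside":
        start, end = (boundary, boundary + w) if side == "left" else (boundary - w, boundary)
    else:  # outside
        start, end = (boundary - w, boundary) if side == "left" else (boundary, boundary + w)
    start = max(0, start)
    end = min(seq_len, end)
    if end - start < 23:
        raise DesignError(
            f"{side} window at {chrom}:{boundary} does not fit in the sequence"
        )
    return GenomeRegion(chrom, start, end, ".")


def _window_candidates(seq: SequenceRecord, window: GenomeRegion,
                       genome, cfg: DesignConfig, side: str) -> list[GuideCandidate]:
    cands = filter_candidates(find_protospacers(seq, window))
    if not cands:
        raise EmptyWindowError(side, window)
    return annotate_scores(cands, genome, cfg.max_mm)


def design_pairs(genome: Iterable[SequenceRecord] | SequenceRecord,
                 target: GenomeRegion,
                 cfg: DesignConfig = DesignConfig()) -> list[GuidePair]:
    """Ranked guide pairs whose cuts bracket (the interior of) `target`.

    Left candidates come from a window at target.start, right candidates from
    a window at target.end. A pair is kept when the left cut precedes the
    right cut, the protospacer intervals do not overlap, and the resulting
    deletion interval contains the target midpoint. Ranking: pair_score
    descending (min of member scores), then closeness of deletion_len to the
    requested target length, then genomic position. Deterministic throughout.
    """
    recs = as_genome_dict(genome)
    if target.chrom not in recs:
        raise DesignError(f"target chrom {target.chrom!r} not in genome")
    seq = recs[target.chrom]
    target_len = len(target)

    left_w = boundary_window(target.start, cfg, "left", len(seq), target.chrom)
    right_w = boundary_window(target.end, cfg, "right", len(seq), target.chrom)
    lefts = _window_candidates(seq, left_w, genome, cfg, "left")
    rights = _window_candidates(seq, right_w, genome, cfg, "right")

    pairs: list[GuidePair] = []
    saw_rejection = False
    for lc in lefts:
        for rc in rights:
            if lc.cut_pos >= rc.cut_pos:
                continue
            if lc.region.end > rc.region.start:  # overlapping protospacers
                continue
            try:
                pair = assign_slots(lc, rc, cfg)
            except SlotRejection:
                saw_rejection = True
                continue
            except DegeneratePairError:
                continue
            if not (pair.deletion.start <= target.midpoint < pair.deletion.end):
                continue
            if pair.pair_score < cfg.min_pair_score:
                continue
            pairs.append(pair)
    if not pairs:
        if saw_rejection:
            raise SlotRejection(
                "no slottable pair: no candidate starting with G in either "
                "window; consider allow_prepend_g=True"
            )
        raise DesignError(
            f"no valid guide pair found for target "
            f"{target.chrom}:{target.start}-{target.end}"
        )
    pairs.sort(key=lambda p: (
        -p.pair_score,
        abs(p.deletion_len - target_len),
        p.deletion.start,
        p.deletion.end,
    ))
    return pairs[:cfg.max_pairs]


def pairs_to_table(pairs: Sequence[GuidePair], target_name: str = ".") -> pd.DataFrame:
    """Design report: one row per pair."""
    return pd.DataFrame([
        {
            "target": target_name,
            "rank": i + 1,
            "u6_protospacer": p.u6_guide.protospacer,
            "u6_pam": p.u6_guide.pam,
            "u6_strand": p.u6_guide.strand,
            "u6_cut": p.u6_guide.cut_pos,
            "h1_protospacer": p.h1_guide.protospacer,
            "h1_pam": p.h1_guide.pam,
            "h1_strand": p.h1_guide.strand,
            "h1_cut": p.h1_guide.cut_pos,
            "deletion_start": p.deletion.start,
            "deletion_end": p.deletion.end,
            "deletion_len": p.deletion_len,
            "pair_score": p.pair_score,
            "u6_prepended_g": p.u6_prepended_g,
        }
        for i, p in enumerate(pairs)
    ])
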