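"""Majority-voting fusion of single-modality laterality decisions.

Two to five five-level decisions (one per imaging modality; not-performed
and failed metrics dropped beforehand) are fused into a multimodal decision
in {L, R, U}.  With ``m`` outcomes, writing ``nX`` for the number of
definitive votes for side X, ``nUX`` for weak votes toward X, the decision
is X when any of the following holds:

* R1 — three or more definitive votes for X;
* R2 — two definitive votes for X with at most one other outcome (m ≤ 3);
* R3 — two definitive votes for X among four or five outcomes, with at
  most one of the remaining outcomes a definitive vote for the other side
  (the rest uncertain-type);
* R4 — a single definitive vote for X with every remaining outcome either
  weakly toward X or indeterminate.

Otherwise (neither side, or degenerately both) the decision is U.  R4 is an
amended form of the published rule: as printed it requires at least one weak
same-side vote, which contradicts several published per-patient fusions
(e.g. {R, U, U} → R); the amended form reproduces every published row.  The
printed variant is available via ``strict_printed_rule4=True``.

The voting score of a declared side X is ``(nX + 0.5 nUX) / m`` and is only
defined when the decision is L or R.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from . import decisions as dec

MIN_OUTCOMES = 2
MAX_OUTCOMES = 5


@dataclass(frozen=True)
class FusionResult:
    """Fused decision, voting score (L/R only) and the rule that fired."""

    decision: str            # "L", "R" or "U"
    score: float | None      # in [0, 1]; None when decision is "U"
    rule_fired: str          # "R1".."R4" or "none"
    m: int                   # number of outcomes fused

    def __post_init__(self) -> None:
        if self.decision not in (dec.L, dec.R, dec.U):
            raise ValueError(f"bad fused decision {self.decision!r}")
        if (self.score is None) != (self.decision == dec.U):
            raise ValueError("score defined iff decision is L or R")


def clean_outcomes(outcomes: Iterable[str]) -> list[str]:
    """Drop not-performed/failed tokens; validate the rest."""
    kept = []
    for token in outcomes:
        dec.validate(token, allow_special=True)
        if token not in (dec.MISSING, dec.FAILED):
            kept.append(token)
    return kept


def voting_score(outcomes: Sequence[str], side: str) -> float:
    """Voting score (nX + 0.5 nUX)/m toward *side* ("L" or "R")."""
    if side not in (dec.L, dec.R):
        raise ValueError("voting score side must be 'L' or 'R'")
    counts = Counter(outcomes)
    weak = dec.UL if side == dec.L else dec.UR
    m = len(outcomes)
    if m == 0:
        raise ValueError("voting score undefined for an empty decision set")
    return (counts[side] + 0.5 * counts[weak]) / m


def _side_fires(counts: Counter, m: int, side: str,
                strict_printed_rule4: bool) -> str | None:
    """Name of the first rule that declares *side*, else None."""
    opp = dec.mirror(side)
    n_x = counts[side]
    n_ux = counts[dec.UL if side == dec.L else dec.UR]
    n_u = counts[dec.U]
    n_opp_def = counts[opp]
    if n_x >= 3:
        return "R1"
    if n_x == 2 and m <= 3:
        return "R2"
    if n_x == 2 and m >= 4 and n_opp_def <= 1:
        return "R3"
    if n_x == 1:
        if strict_printed_rule4:
            # printed form: (X)^1 (UX)^{1..4} (U)^{0,1}
            if n_ux >= 1 and n_u <= 1 and n_x + n_ux + n_u == m:
                return "R4"
        elif n_x + n_ux + n_u == m:
            return "R4"
    return None


def fuse(outcomes: Iterable[str], *, drop_special: bool = True,
         strict_printed_rule4: bool = False) -> FusionResult:
    """Fuse 2–5 single-modality decisions into a multimodal decision.

    Parameters
    ----------
    outcomes
        Decision tokens; with ``drop_special`` (default) the not-performed
        (``_``) and failed (``F``) tokens are removed before counting.
    strict_printed_rule4
        Use the stricter published single-definitive rule (requires at
        least one weak same-side vote) instead of the amended form.
    """
    kept = clean_outcomes(outcomes) if drop_special else [
        dec.validate(t) for t in outcomes]
    m = len(kept)
    if not MIN_OUTCOMES <= m <= MAX_OUTCOMES:
        raise ValueError(
            f"fusion needs {MIN_OUTCOMES}–{MAX_OUTCOMES} usable outcomes, "
            f"got {m}")
    counts = Counter(kept)
    fired = {side: _side_fires(counts, m, side, strict_printed_rule4)
             for side in (dec.L, dec.R)}
    declared = [side for side, rule in fired.items() if rule is not None]
    if len(declared) == 1:
        side = declared[0]
        return FusionResult(decision=side, score=voting_score(kept, side),
                            rule_fired=fired[side], m=m)
    # neither side, or a symmetric double fire: indeterminate
    return FusionResult(decision=dec.U, score=None, rule_fired="none", m=m)


def fuse_record(record, modalities: Sequence[str] = (
        "volumetry", "flair", "msa", "pet"), **kwargs) -> FusionResult:
    """Fuse the single-modality outcomes of a cohort record.

    By default the four modalities that feed the multimodal model
    (volumetry, FLAIR, multistructural, PET) are used; not-performed and
    failed entries are dropped.
    """
    return fuse([record.decision(m) for m in modalities], **kwargs)
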