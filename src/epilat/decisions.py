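"""Five-level laterality decision alphabet.

Decisions are plain strings drawn from ``{L, UL, U, UR, R}``:

* ``L`` / ``R`` — confident left / right lateralization,
* ``UL`` / ``UR`` — weak tendency left / right,
* ``U`` — indeterminate.

Two extra table tokens are distinguished from real decisions: ``_`` (metric
not performed, :data:`MISSING`) and ``F`` (metric failed, e.g. a segmentation
failure, :data:`FAILED`).
"""

from __future__ import annotations

L = "L"
UL = "UL"
U = "U"
UR = "UR"
R = "R"

MISSING = "_"
FAILED = "F"

DECISIONS = (L, UL, U, UR, R)
TOKENS = DECISIONS + (MISSING, FAILED)

#: Left↔right reflection of each decision token.
_MIRROR = {L: R, UL: UR, U: U, UR: UL, R: L, MISSING: MISSING, FAILED: FAILED}

#: Side (``left``/``right``) a decision points to, ``None`` for U.
_SIDE = {L: "left", UL: "left", R: "right", UR: "right"}


def validate(token: str, *, allow_special: bool = False) -> str:
    """Return *token* if it is a legal decision, else raise ``ValueError``."""
    alphabet = TOKENS if allow_special else DECISIONS
    if token not in alphabet:
        raise ValueError(f"not a five-level decision token: {token!r}")
    return token


def mirror(token: str) -> str:
    """Reflect a decision left↔right (``U``, ``_`` and ``F`` are fixed)."""
    return _MIRROR[validate(token, allow_special=True)]


def side_of(token: str) -> str | None:
    """Side a decision points to: ``"left"``, ``"right"`` or ``None`` (U)."""
    validate(token)
    return _SIDE.get(token)


def is_definitive(token: str) -> bool:
    return token in (L, R)


def is_uncertain(token: str) -> bool:
    """True for the uncertain-type outcomes U, UL, UR."""
    return token in (UL, U, UR)


def banded_decision(value: float, inner: float, outer: float,
                    *, positive: str = R) -> str:
    """Map a signed score to a five-level decision by symmetric bands.

    ``|value| < inner`` (or value exactly 0) → U;
    ``inner <= |value| < outer`` → UL/UR; ``|value| >= outer`` → L/R.
    A value sitting exactly on a band edge therefore takes the more
    lateralized label of the two bands it separates.  *positive* names the
    decision assigned to positive values (``R`` by default).
    """
    if not 0 <= inner <= outer:
        raise ValueError("need 0 <= inner <= outer band edges")
    if positive not in (L, R):
        raise ValueError("positive side must be 'L' or 'R'")
    mag = abs(value)
    if value == 0 or mag < inner:
        return U
    toward = positive if value > 0 else _MIRROR[positive]
    if mag < outer:
        return UL if toward == L else UR
    return toward
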