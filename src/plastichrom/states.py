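"""The four promoter chromatin states and the two-mark truth table.

A promoter is classified from the presence/absence of the activating
H3K4me3 and the Polycomb-deposited repressive H3K27me3 mark:

========  ========  ==========
H3K4me3   H3K27me3  state
========  ========  ==========
yes       no        Active
no        yes       Repressed
yes       yes       Bivalent
no        no        Unmarked
========  ========  ==========

Bivalent ("poised") promoters carry both marks, a configuration typical of
developmental genes held ready for activation.
"""

from __future__ import annotations

ACTIVE = "Active"
REPRESSED = "Repressed"
BIVALENT = "Bivalent"
UNMARKED = "Unmarked"

#: Canonical state order used for every 4-vector / 4x4 matrix in the package.
STATES: tuple[str, str, str, str] = (ACTIVE, REPRESSED, BIVALENT, UNMARKED)

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}


def classify(has_k4: bool, has_k27: bool) -> str:
    """Map a (H3K4me3, H3K27me3) presence pair to its chromatin state."""
    if has_k4 and has_k27:
        return BIVALENT
    if has_k4:
        return ACTIVE
    if has_k27:
        return REPRESSED
    return UNMARKED


def marks_for_state(state: str) -> tuple[bool, bool]:
    """Inverse of :func:`classify`: which marks a state implies."""
    if state not in STATE_INDEX:
        raise ValueError(f"unknown chromatin state: {state!r}")
    return (state in (ACTIVE, BIVALENT), state in (REPRESSED, BIVALENT))
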