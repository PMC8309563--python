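"""Activity class vocabulary shared by every stage.

Ten activity classes are recognised: stair ascent/descent, walking,
running, sitting, four directed falls and lying.  An eleventh
``transition`` label marks the stretches between scripted activities;
it is written to disk by the generator but removed before any model
sees a window.
"""

from __future__ import annotations

#: Canonical class order used for confusion matrices, reports and the
#: CNN output layer.  A1..A10 match the acquisition protocol order.
ACTIVITY_CLASSES: tuple[str, ...] = (
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9", "A10",
)

#: Human-readable names, in the same order as :data:`ACTIVITY_CLASSES`.
ACTIVITY_NAMES: dict[str, str] = {
    "A1": "up the stairs",
    "A2": "down the stairs",
    "A3": "walk",
    "A4": "run",
    "A5": "sit",
    "A6": "fall-right",
    "A7": "fall-left",
    "A8": "fall-front",
    "A9": "fall-back",
    "A10": "lying",
}

#: Label given to samples between scripted activities; always discarded
#: before training.
TRANSITION_LABEL: str = "transition"

#: Channel order of the windowed tensor (m = 4).
CHANNELS: tuple[str, ...] = ("Ax", "Ay", "Az", "An")
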