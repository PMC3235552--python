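"""Shared hit-class vocabulary for the dual-target screen.

Target A is the GPCR-like screen (histamine H4-style recognition), target B
the ion-channel-like screen (serotonin 5-HT3A-style recognition); the labels
stay generic so the pipeline applies to any two-target fragment screen.
"""

A_SELECTIVE = "A-selective"
B_SELECTIVE = "B-selective"
DUAL = "dual"
INACTIVE = "inactive"
UNLABELED = "unlabeled"

HIT_CLASSES = (A_SELECTIVE, B_SELECTIVE, DUAL, INACTIVE)
ALL_LABELS = HIT_CLASSES + (UNLABELED,)
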