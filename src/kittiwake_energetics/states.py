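"""Canonical behaviour labels shared across the pipeline."""

BEHAVIOURS: tuple[str, ...] = ("colony", "rest_land", "swimming", "flapping", "gliding")

N_BEHAVIOURS = len(BEHAVIOURS)

BEHAVIOUR_INDEX = {b: i for i, b in enumerate(BEHAVIOURS)}
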