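"""Shared vocabulary for the modified Hole Board (mHB) pipeline."""

#: Behavioral dimensions, in canonical column order.
DIMENSIONS = ("avoidance", "exploration", "locomotion")

#: Wide-table z-score column per dimension.
DIMENSION_COLUMNS = tuple(f"{d}_z" for d in DIMENSIONS)

#: Inbred strains of the characterization cohort.
STRAINS = ("C", "B6N", "129S2")

#: The two observers; each mouse is always scored by the same one.
EXPERIMENTERS = ("E1", "E2")

#: Repeated mHB exposures in the characterization phase.
N_TRIALS = 5

#: Latency scores are capped at the trial length ceiling (seconds).
LATENCY_CEILING = 300.0

#: Latent response types (avoidance sensitizers vs. habituators).
RESPONSE_TYPES = ("A", "B")
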