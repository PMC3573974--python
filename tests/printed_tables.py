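"""The published attractor/basin tables for the three bundled models.

Basin sizes and fixed-point state vectors in canonical node order
(Cln3, MBF, SBF, Cln2, Cdh1, Swi5, Cdc20, Clb5, Sic1, Clb2, Mcm1),
sorted by descending basin.  These are the transcription checksums the
acceptance tests hold the fixtures to.
"""

LI_TABLE = [
    (1764, (0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (151, (0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
    (109, (0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (9, (0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
    (7, (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)),
    (7, (0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
    (1, (0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0)),
]

MANGLA_TABLE = [
    (2769, (0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (159, (0, 1, 1, 1, 0, 1, 1, 0, 1, 0, 0)),
    (52, (0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
    (44, (0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (18, (0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0)),
    (17, (0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
    (7, (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)),
    (5, (0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
    (1, (0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0)),
]

PROPOSED_TABLE = [
    (4323, (0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (87, (0, 1, 1, 1, 0, 2, 1, 0, 1, 0, 0)),
    (68, (0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0)),
    (46, (0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 0)),
    (44, (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)),
    (16, (0, 0, 1, 1, 0, 2, 1, 0, 1, 0, 0)),
    (12, (0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0)),
    (10, (0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
    (2, (0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0)),
]
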