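"""Word stimulus lexicon of the auditory oddball paradigm.

Monosyllabic, emotionally neutral English words with their spoken durations
in milliseconds.  ``YES`` and ``NO`` are the two target words; the remaining
50 entries form the distractor lexicon.
"""

TARGET_DURATIONS_MS = {
    "YES": 525,
    "NO": 520,
}

DISTRACTOR_DURATIONS_MS = {
    "GOWN": 571,
    "MOP": 576,
    "MOSS": 590,
    "MOTH": 499,
    "MUG": 542,
    "NAIL": 595,
    "NEWT": 637,
    "OAK": 470,
    "OAT": 537,
    "OWL": 599,
    "OX": 572,
    "PAN": 569,
    "PEAR": 503,
    "PEA": 480,
    "PEN": 450,
    "PIG": 490,
    "PILL": 528,
    "PINE": 607,
    "PIN": 478,
    "PLUM": 537,
    "PRAM": 552,
    "PUNT": 582,
    "RAFT": 639,
    "RAKE": 600,
    "RAT": 618,
    "RICE": 637,
    "ROBE": 543,
    "ROCK": 587,
    "ROOF": 591,
    "ROPE": 501,
    "RUG": 540,
    "SHED": 554,
    "SHIP": 525,
    "SOCK": 633,
    "TAPE": 520,
    "TOAD": 543,
    "TRAM": 579,
    "TUB": 455,
    "VAN": 596,
    "VAT": 592,
    "VINE": 638,
    "WASP": 627,
    "WIG": 549,
    "WINE": 535,
    "WOLF": 521,
    "WOOD": 443,
    "WOOL": 572,
    "WORM": 625,
    "WREN": 507,
    "YAK": 540,
}

DISTRACTOR_WORDS = tuple(DISTRACTOR_DURATIONS_MS)

assert len(DISTRACTOR_WORDS) == 50
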