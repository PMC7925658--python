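"""Published reference-gene stability rankings for two licorice species.

Per-method competition ranks (geNorm, NormFinder, BestKeeper, comparative
ΔCt) and the published comprehensive (geometric-mean) value with its final
rank, for 14 candidate genes under three experimental conditions
(developmental stages, tissues, tissue × stage interaction) in
G. uralensis and G. inflata.  Where the published table ties two genes at
the same rounded stability value, the rank consistent with the published
geometric mean is used (the published aggregation evidently tie-broke on
unrounded values).

Each row: gene -> (genorm_rank, normfinder_rank, bestkeeper_rank,
deltact_rank, reffinder_value, reffinder_rank).
"""

PUBLISHED_RANKINGS = {
    ("G. uralensis", "stages"): {
        "ACT": (7, 5, 4, 6, 5.38, 7),
        "CAC": (1, 1, 3, 1, 1.32, 1),
        "CYP": (1, 3, 5, 4, 2.78, 2),
        "DNAJ": (9, 9, 1, 9, 5.20, 6),
        "DREB": (5, 4, 11, 3, 5.07, 5),
        "EF1": (13, 14, 14, 13, 13.49, 14),
        "RAN": (8, 7, 6, 8, 7.20, 9),
        "TIF1": (14, 13, 10, 14, 12.63, 13),
        "TUB": (10, 10, 13, 10, 10.68, 10),
        "UBC2": (12, 12, 8, 12, 10.84, 11),
        "ABCC2": (4, 2, 9, 2, 3.46, 3),
        "COPS3": (3, 6, 2, 5, 3.66, 4),
        "CS": (11, 11, 12, 11, 11.24, 12),
        "R3HDM2": (6, 8, 7, 7, 6.96, 8),
    },
    ("G. uralensis", "tissues"): {
        "ACT": (6, 7, 10, 7, 7.36, 8),
        "CAC": (1, 1, 6, 3, 2.06, 2),
        "CYP": (9, 10, 11, 10, 9.97, 13),
        "DNAJ": (4, 4, 5, 4, 4.23, 4),
        "DREB": (7, 8, 12, 6, 7.97, 9),
        "EF1": (10, 12, 14, 12, 11.92, 14),
        "RAN": (11, 6, 2, 8, 5.70, 5),
        "TIF1": (13, 13, 3, 13, 9.01, 11),
        "TUB": (3, 3, 8, 2, 3.46, 3),
        "UBC2": (12, 11, 4, 11, 8.73, 10),
        "ABCC2": (5, 5, 9, 5, 5.79, 6),
        "COPS3": (14, 14, 1, 14, 7.24, 7),
        "CS": (8, 9, 13, 9, 9.58, 12),
        "R3HDM2": (1, 2, 7, 1, 1.93, 1),
    },
    ("G. uralensis", "interaction"): {
        "ACT": (8, 6, 13, 7, 8.13, 11),
        "CAC": (1, 2, 5, 1, 1.78, 1),
        "CYP": (7, 10, 9, 9, 8.68, 13),
        "DNAJ": (6, 1, 6, 3, 3.22, 3),
        "DREB": (5, 4, 11, 4, 5.45, 5),
        "EF1": (14, 14, 14, 14, 14.00, 14),
        "RAN": (10, 8, 4, 10, 7.52, 9),
        "TIF1": (12, 12, 3, 12, 8.49, 12),
        "TUB": (9, 7, 8, 8, 7.97, 10),
        "UBC2": (11, 11, 2, 11, 7.18, 8),
        "ABCC2": (3, 5, 10, 5, 5.23, 4),
        "COPS3": (13, 13, 1, 13, 6.85, 6),
        "CS": (4, 9, 12, 6, 7.14, 7),
        "R3HDM2": (1, 3, 7, 2, 2.55, 2),
    },
    ("G. inflata", "stages"): {
        "ACT": (14, 14, 14, 14, 14.00, 14),
        "CAC": (8, 7, 11, 7, 8.10, 7),
        "CYP": (12, 13, 7, 12, 10.70, 12),
        "DNAJ": (9, 8, 10, 8, 8.71, 8),
        "DREB": (5, 4, 5, 4, 4.47, 4),
        "EF1": (6, 6, 4, 6, 5.42, 6),
        "RAN": (1, 1, 2, 1, 1.19, 1),
        "TIF1": (13, 12, 12, 13, 12.49, 13),
        "TUB": (7, 11, 9, 11, 9.34, 10),
        "UBC2": (11, 9, 13, 10, 10.65, 11),
        "ABCC2": (4, 5, 6, 5, 4.95, 5),
        "COPS3": (1, 2, 1, 2, 1.41, 2),
        "CS": (3, 3, 3, 3, 3.00, 3),
        "R3HDM2": (10, 10, 8, 9, 9.21, 9),
    },
    ("G. inflata", "tissues"): {
        "ACT": (4, 6, 9, 6, 6.00, 8),
        "CAC": (10, 9, 1, 10, 5.48, 6),
        "CYP": (13, 13, 14, 13, 13.24, 14),
        "DNAJ": (8, 7, 3, 7, 5.86, 7),
        "DREB": (1, 4, 8, 4, 3.36, 3),
        "EF1": (12, 12, 13, 12, 12.24, 12),
        "RAN": (9, 8, 5, 8, 7.33, 10),
        "TIF1": (14, 14, 11, 14, 13.18, 13),
        "TUB": (3, 5, 10, 5, 5.23, 5),
        "UBC2": (11, 11, 2, 11, 7.18, 9),
        "ABCC2": (6, 2, 4, 3, 3.46, 4),
        "COPS3": (5, 1, 6, 1, 2.34, 1),
        "CS": (7, 10, 12, 9, 9.32, 11),
        "R3HDM2": (1, 3, 7, 2, 2.55, 2),
    },
    ("G. inflata", "interaction"): {
        "ACT": (14, 13, 14, 14, 13.74, 14),
        "CAC": (5, 3, 4, 3, 3.66, 4),
        "CYP": (12, 12, 10, 12, 11.47, 12),
        "DNAJ": (6, 5, 8, 5, 5.89, 6),
        "DREB": (1, 2, 3, 2, 1.86, 2),
        "EF1": (10, 9, 13, 9, 10.13, 10),
        "RAN": (7, 7, 7, 7, 7.00, 7),
        "TIF1": (13, 14, 11, 13, 12.70, 13),
        "TUB": (11, 11, 12, 11, 11.24, 11),
        "UBC2": (9, 10, 6, 10, 8.57, 9),
        "ABCC2": (1, 6, 1, 6, 2.45, 3),
        "COPS3": (4, 1, 2, 1, 1.68, 1),
        "CS": (3, 4, 5, 4, 3.94, 5),
        "R3HDM2": (8, 8, 9, 8, 8.24, 8),
    },
}

#: Published top-3 comprehensive recommendations per species and condition.
PUBLISHED_TOP3 = {
    "G. uralensis": {
        "tissues": ["R3HDM2", "CAC", "TUB"],
        "stages": ["CAC", "CYP", "ABCC2"],
        "interaction": ["CAC", "R3HDM2", "DNAJ"],
    },
    "G. inflata": {
        "tissues": ["COPS3", "R3HDM2", "DREB"],
        "stages": ["RAN", "COPS3", "CS"],
        "interaction": ["COPS3", "DREB", "ABCC2"],
    },
}
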