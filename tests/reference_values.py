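"""Published reference values for the bundled N5/N6 nymphal comparison.

The 40 differentially expressed miRNAs with their published probability,
M-value (3 decimals) and D-value (2 decimals): 3 up in the pre-metamorphic
library (N5), 37 up in the metamorphic library (N6). Used as a regression
surface: recomputing M and D from the bundled counts/RPKM table must
reproduce every row to its printed precision.
"""

# name -> (P, M, D); M > 0 means higher in N5
UP_IN_N5 = {
    "miR-252-3p": (0.917, 5.260, 2118.72),
    "miR-276-5p": (0.852, 4.037, 847.99),
    "miR-190-5p": (0.912, 1.632, 1963.06),
}

UP_IN_N6 = {
    "bantam-3p": (0.988, -2.026, 18256.44),
    "miR-100-5p": (0.988, -1.680, 18098.63),
    "miR-125-5p": (0.987, -1.576, 14554.33),
    "let-7-5p": (0.986, -1.402, 14145.59),
    "miR-9c-5p": (0.959, -1.318, 5574.70),
    "miR-87-3p": (0.973, -1.221, 9587.67),
    "miR-8-3p": (0.999, -1.209, 227890.78),
    "miR-2765-5p": (0.830, -1.164, 670.30),
    "miR-279-3p": (0.994, -1.069, 51846.89),
    "miR-2796-3p": (0.884, -1.068, 1333.63),
    "miR-276-3p": (0.998, -1.039, 202494.24),
    "miR-277-3p": (0.956, -1.025, 5530.26),
    "miR-307-3p": (0.923, -1.003, 2566.67),
    "miR-12-5p": (0.837, -0.928, 732.12),
    "miR-263b-5p": (0.895, -0.883, 1619.55),
    "miR-263a-5p": (0.986, -0.869, 31903.3),
    "miR-283-5p": (0.907, -0.860, 1927.11),
    "miR-281-5p": (0.918, -0.823, 2535.60),
    "miR-278-3p": (0.821, -0.809, 640.69),
    "miR-31-5p": (0.951, -0.797, 5164.45),
    "miR-8-5p": (0.984, -0.740, 33628.01),
    "miR-13a-3p": (0.840, -0.720, 821.27),
    "miR-13b-3p": (0.904, -0.697, 1939.84),
    "miR-375-3p": (0.914, -0.672, 2346.33),
    "miR-1-3p": (0.990, -0.622, 902554.68),
    "miR-10-5p": (0.960, -0.617, 7573.40),
    "miR-252-5p": (0.977, -0.609, 15592.09),
    "miR-9a-5p": (0.947, -0.581, 5214.83),
    "miR-71-5p": (0.977, -0.556, 20461.24),
    "miR-2-3p": (0.974, -0.556, 14328.10),
    "miR-316-5p": (0.878, -0.540, 1350.32),
    "miR-305-5p": (0.910, -0.492, 2562.49),
    "miR-3770-5p": (0.813, -0.424, 713.61),
    "miR-71-3p": (0.8201, -0.304, 1636.54),
    "miR-184-3p": (0.870, -0.264, 33567.51),
    "miR-317-3p": (0.865, -0.248, 80584.11),
    "miR-306-5p": (0.815, -0.244, 11421.52),
}

DE_TABLE = {**UP_IN_N5, **UP_IN_N6}
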