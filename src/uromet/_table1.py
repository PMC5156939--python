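"""Published per-metabolite screening results bundled as a test fixture.

Thirty urinary metabolites passed the raw p < 0.05 screen in the original
interstitial-cystitis cohort (42 cases, 21 controls; 490 detected
features).  Each row carries the printed linear fold change (case mean /
control mean), the two-sided pooled-variance t-test p-value on log2
intensities, and the Benjamini-Hochberg adjusted value computed over all
490 tests.  Twelve of the thirty are library-annotated compounds; the
rest are unidentified "Unknown BB_*" signals.
"""

ROWS = (
    (1, "Unknown BB_31554", 2.56, 0.000132, 0.064576),
    (2, "Unknown BB_34163", 0.55, 0.000514, 0.12586),
    (3, "oleic acid", 0.63, 0.001933, 0.315675),
    (4, "2-deoxytetronic acid", 1.26, 0.008732, 0.571396),
    (5, "Unknown BB_17651", 0.66, 0.009136, 0.571396),
    (6, "saccharic acid", 0.80, 0.012642, 0.571396),
    (7, "Unknown BB_17140", 1.44, 0.015588, 0.571396),
    (8, "phosphate", 0.70, 0.016252, 0.571396),
    (9, "trehalose", 1.79, 0.017026, 0.571396),
    (10, "Unknown BB_5900", 0.81, 0.017487, 0.571396),
    (11, "erythronic acid", 2.25, 0.018393, 0.571396),
    (12, "Unknown BB_109809", 0.56, 0.018576, 0.571396),
    (13, "oxalic acid", 0.48, 0.018665, 0.571396),
    (14, "Unknown BB_34027", 0.44, 0.019904, 0.571396),
    (15, "Unknown BB_1704", 0.63, 0.020865, 0.571396),
    (16, "sulfuric acid", 0.31, 0.021197, 0.571396),
    (17, "Unknown BB_23635", 0.69, 0.02138, 0.571396),
    (18, "cystine", 1.47, 0.021607, 0.571396),
    (19, "Unknown BB_3029", 0.70, 0.022156, 0.571396),
    (20, "Unknown BB_12330", 2.19, 0.02596, 0.614149),
    (21, "Unknown BB_31549", 0.37, 0.026702, 0.614149),
    (22, "lyxitol", 1.42, 0.028288, 0.614149),
    (23, "Unknown BB_31756", 1.74, 0.028827, 0.614149),
    (24, "lysine", 1.49, 0.034624, 0.706901),
    (25, "histidine", 1.79, 0.040576, 0.743323),
    (26, "Unknown BB_31359", 0.81, 0.043988, 0.743323),
    (27, "Unknown BB_5121", 0.64, 0.045462, 0.743323),
    (28, "Unknown BB_100869", 1.58, 0.046685, 0.743323),
    (29, "Unknown BB_3294", 1.37, 0.046907, 0.743323),
    (30, "Unknown BB_31764", 1.33, 0.048566, 0.743323),
)

#: Total number of detected features behind the adjusted column.
M_TOTAL = 490
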