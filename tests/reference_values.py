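"""Reference fixtures: reported Relief rankings and classifier performance rows.

``RELIEF_TOP10``: per treatment period, the ten highest-weighted simple-ratio
indices with their Relief weights.  ``PERFORMANCE_ROWS``: per-period per-class
detection accuracies (%) with the overall accuracy (%), precision (%) and F1
each row implies, at per-period validation class sizes of 104 control and 100
salt images (26 + 25 pots x 4 views).
"""

RELIEF_TOP10 = {
    5: [
        ("R520/R730", 0.009377), ("R520/R850", 0.006789), ("R590/R710", 0.006761),
        ("R660/R730", 0.006675), ("R520/R910", 0.006542), ("R520/R660", 0.006372),
        ("R520/R780", 0.006123), ("R520/R820", 0.00609), ("R460/R710", 0.006087),
        ("R520/R760", 0.006038),
    ],
    10: [
        ("R520/R660", 0.021317), ("R460/R590", 0.019582), ("R460/R520", 0.019379),
        ("R520/R710", 0.018775), ("R660/R730", 0.018075), ("R520/R590", 0.016023),
        ("R590/R710", 0.015362), ("R660/R760", 0.014584), ("R520/R910", 0.012751),
        ("R460/R730", 0.012533),
    ],
    17: [
        ("R460/R520", 0.047395), ("R520/R710", 0.04658), ("R590/R710", 0.044099),
        ("R710/R730", 0.042844), ("R460/R730", 0.041924), ("R460/R590", 0.028346),
        ("R520/R910", 0.026957), ("R710/R780", 0.026881), ("R520/R850", 0.025527),
        ("R710/R760", 0.024179),
    ],
}

#: The 11-parameter union of the per-period top-5 rankings above.
SR_UNION_11 = [
    "R460/R520", "R460/R590", "R460/R730", "R520/R660", "R520/R710",
    "R520/R730", "R520/R850", "R520/R910", "R590/R710", "R660/R730",
    "R710/R730",
]

#: (period, acc_control %, acc_salt %, n_control, n_salt,
#:  accuracy %, precision %, f1)
PERFORMANCE_ROWS = [
    (5, 88.46, 81.00, 104, 100, 84.80, 87.10, 0.839),
    (10, 94.23, 88.00, 104, 100, 91.18, 93.62, 0.907),
    (17, 93.27, 97.00, 104, 100, 95.10, 93.27, 0.951),
    ("5-17", 91.99, 88.67, 312, 300, 90.36, 91.41, 0.900),
]
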