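"""Fickett (1982) TESTCODE lookup tables.

Constants from Fickett, "Recognition of protein coding regions in DNA
sequences", Nucleic Acids Research 10(17):5303-5318 (1982): for each base,
a probability-of-coding lookup indexed by the position parameter
(asymmetry across the three codon positions) or the content parameter
(base proportion), plus the per-parameter weights.

Lookup rule: walk the threshold list top-down and take the probability at
the first threshold the parameter value reaches.
"""

# Thresholds for the position parameter MAX(N1,N2,N3)/(MIN(N1,N2,N3)+1).
POSITION_THRESHOLDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}

POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

# Thresholds for the content parameter (base proportion in the sequence).
CONTENT_THRESHOLDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.58, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}

CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def lookup(value: float, thresholds: list[float], probs: list[float]) -> float:
    for thr, prob in zip(thresholds, probs):
        if value >= thr:
            return prob
    return probs[-1]
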