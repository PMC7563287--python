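"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and string
operations, sharing no code path with the package internals.
"""

from lncsift import _fickett

STOPS = {"TAA", "TAG", "TGA"}


def orf_oracle(seq: str):
    """Enumerate every (start, stop) pair in all frames and apply the
    priority complete > ATG-initiated open > stop-free stretch, ties to
    (longer, smaller start, smaller frame). Returns
    (start, end, frame, has_start, has_stop)."""
    L = len(seq)
    complete, open_stretch, stop_free = [], [], []
    for f in range(3):
        codons = [seq[i : i + 3] for i in range(f, L - 2, 3)]
        starts = [f + 3 * i for i in range(len(codons))]
        for ci, c in enumerate(codons):
            if c == "ATG":
                stop_ci = next((j for j in range(ci, len(codons)) if codons[j] in STOPS), None)
                if stop_ci is not None:
                    complete.append((3 * (stop_ci - ci + 1), starts[ci], f))
                else:
                    open_stretch.append((3 * (len(codons) - ci), starts[ci], f))
        run_start = 0
        for j in range(len(codons) + 1):
            if j == len(codons) or codons[j] in STOPS:
                if j > run_start:
                    stop_free.append((3 * (j - run_start), starts[run_start], f))
                run_start = j + 1
    key = lambda c: (c[0], -c[1], -c[2])
    for cands, (hs, hp) in (
        (complete, (True, True)),
        (open_stretch, (True, False)),
        (stop_free, (False, False)),
    ):
        if cands:
            ln, s, f = max(cands, key=key)
            return (s, s + ln, f, hs, hp)
    return (0, 0, 0, False, False)


def fickett_oracle(seq: str) -> float:
    """Straight-from-the-tables TESTCODE evaluation via string counting."""

    def grab(value, thresholds, probs):
        # scan from the small end, keeping the last threshold satisfied
        chosen = probs[-1]
        for t, pr in reversed(list(zip(thresholds, probs))):
            if value >= t:
                chosen = pr
        return chosen

    total = sum(seq.count(b) for b in "ACGT")
    score = 0.0
    for base in "ACGT":
        counts = [
            sum(1 for i in range(off, len(seq), 3) if seq[i] == base) for off in range(3)
        ]
        pos_param = max(counts) / (min(counts) + 1.0)
        content = seq.count(base) / total if total else 0.0
        score += (
            grab(pos_param, _fickett.POSITION_THRESHOLDS, _fickett.POSITION_PROB[base])
            * _fickett.POSITION_WEIGHT[base]
        )
        score += (
            grab(content, _fickett.CONTENT_THRESHOLDS, _fickett.CONTENT_PROB[base])
            * _fickett.CONTENT_WEIGHT[base]
        )
    return score


def hexamer_oracle(seq: str, start: int, end: int, coding, noncoding) -> float:
    """Per-window log-ratio average over step-3 6-mers of seq[start:end]."""
    import math

    vals = []
    for i in range(start, end - 5, 3):
        hx = seq[i : i + 6]
        if "N" in hx:
            continue
        idx = 0
        for b in hx:
            idx = idx * 4 + "ACGT".index(b)
        vals.append(math.log(coding[idx] / noncoding[idx]))
    return sum(vals) / len(vals) if vals else 0.0


def bh_oracle(pvals):
    """Step-up definition: adj for the i-th smallest p is
    min over j >= i of p_(j) * m / j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    for pos, i in enumerate(order):
        out[i] = min(
            min(pvals[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0
        )
    return out


def auc_oracle(scores, labels) -> float:
    """O(n^2) Mann-Whitney pair count with 1/2 for score ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def peptide_charge_grid_pi(peptide: str, step: float = 1e-4) -> float:
    """Isoelectric point by direct charge-sum evaluation on a pH grid."""
    pos = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
    neg = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

    def charge(ph):
        q = 0.0
        for grp, pk in pos.items():
            n = 1 if grp == "Nterm" else peptide.count(grp)
            q += n * 10.0**pk / (10.0**pk + 10.0**ph)
        for grp, pk in neg.items():
            n = 1 if grp == "Cterm" else peptide.count(grp)
            q -= n * 10.0**ph / (10.0**pk + 10.0**ph)
        return q

    best_ph, best_q = 0.0, abs(charge(0.0))
    ph = 0.0
    while ph <= 14.0:
        q = abs(charge(ph))
        if q < best_q:
            best_ph, best_q = ph, q
        ph += step
    return best_ph
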