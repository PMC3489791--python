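"""Confusion-matrix metrics, hypergeometric prediction probability, and the
three-of-four system comparison rule.

The prediction probability is the exact upper hypergeometric tail: drawing
C predicted positions out of an alignment of length L that contains E
experimentally validated positions, the probability of hitting at least TP
of them is

    P(X >= TP) = sum_{k=TP}^{min(E,C)} C(E,k) C(L-E, C-k) / C(L,C)

computed in exact integer arithmetic (the published values reach 1e-17).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import comb


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Sensitivity, specificity, accuracy, positive predictive value.

    A metric with a zero denominator is ``None`` (undefined), not an error.
    """

    sen: float | None
    spe: float | None
    acc: float | None
    ppv: float | None

    def rounded(self) -> tuple[float | None, ...]:
        """Two-decimal, half-up rounding for table parity (0.995 prints as 1)."""
        return tuple(None if v is None else _round2(v) for v in
                     (self.sen, self.spe, self.acc, self.ppv))


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion(predicted, validated, length: int) -> Confusion:
    """2x2 counts over all ``length`` alignment positions (1-based)."""
    predicted = set(predicted)
    validated = set(validated)
    for name, s in (("predicted", predicted), ("validated", validated)):
        bad = [p for p in s if not 1 <= p <= length]
        if bad:
            raise IndexError(f"{name} positions outside 1..{length}: {sorted(bad)[:5]}")
    tp = len(predicted & validated)
    fp = len(predicted - validated)
    fn = len(validated - predicted)
    tn = length - tp - fp - fn
    return Confusion(tp, fp, fn, tn)


def metrics(c: Confusion) -> Metrics:
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    return Metrics(
        sen=ratio(c.tp, c.tp + c.fn),
        spe=ratio(c.tn, c.tn + c.fp),
        acc=ratio(c.tp + c.tn, c.total) if c.total else None,
        ppv=ratio(c.tp, c.tp + c.fp),
    )


def prediction_probability(length: int, n_validated: int, n_predicted: int, tp: int) -> float:
    """Exact hypergeometric upper tail P(X >= tp)."""
    L, E, C, TP = length, n_validated, n_predicted, tp
    if not (0 <= E <= L and 0 <= C <= L):
        raise ValueError("validated/predicted counts exceed the alignment length")
    if TP < 0 or TP > min(E, C):
        raise ValueError(f"TP={TP} inconsistent with E={E}, C={C}")
    numerator = sum(comb(E, k) * comb(L - E, C - k) for k in range(TP, min(E, C) + 1))
    return numerator / comb(L, C)


def compare_systems(a: Metrics, b: Metrics, tol: float = 0.05) -> str:
    """'a_better', 'b_better' or 'comparable' under the 3-of-4 rule.

    One system is better when it exceeds the other on at least three of the
    four measures; with a 2-2 outcome the sign of the summed differences
    decides.  The systems are comparable when every difference and their sum
    are within ``tol`` in absolute value.  Measures undefined on either side
    are skipped.
    """
    diffs = []
    for va, vb in zip((a.sen, a.spe, a.acc, a.ppv), (b.sen, b.spe, b.acc, b.ppv)):
        if va is None or vb is None:
            continue
        diffs.append(va - vb)
    if not diffs:
        return "comparable"
    if all(abs(d) <= tol for d in diffs) and abs(sum(diffs)) <= tol:
        return "comparable"
    wins_a = sum(1 for d in diffs if d > 0)
    wins_b = sum(1 for d in diffs if d < 0)
    if wins_a >= 3:
        return "a_better"
    if wins_b >= 3:
        return "b_better"
    total = sum(diffs)
    if total > 0:
        return "a_better"
    if total < 0:
        return "b_better"
    return "comparable"


def read_validated_positions(path) -> list[int]:
    """One 1-based position per line; '#' starts a comment."""
    out = []
    with open(path) as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            out.append(int(text))
    if not out:
        raise ValueError(f"no positions in {path}")
    return sorted(set(out))
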