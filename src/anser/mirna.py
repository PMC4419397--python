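"""miRNA expression normalization and rule-based target prediction.

Expression of a miRNA is normalized to transcripts per million clean
reads: ``normalized = raw_count / total_clean_reads * 1e6``; fold change
between conditions is ``log2(treatment / control)``.

Target sites are called on gapless antiparallel miRNA:site duplexes.
Six rules, all of which must hold for a site to be accepted
(positions are counted 1-based from the miRNA 5' end; a G:U wobble
counts as half a mismatch in the scoring rules):

1. total mismatch score <= 4 (Watson-Crick 0, G:U 0.5, mismatch 1);
2. no more than two adjacent mismatches anywhere in the duplex;
3. no adjacent mismatches within positions 2-12;
4. no mismatch at position 10 or 11;
5. mismatch score over positions 1-12 <= 2.5;
6. duplex minimum free energy at least 75% of the energy of the miRNA
   bound to its perfect complement (compared on absolute values).

By default a G:U wobble is treated as a (half-scored) *pair* for the
adjacency/position rules 2-4; ``gu_strict=True`` treats it as a full
mismatch there instead.

The free-energy model is a nearest-neighbor sum over consecutive paired
dinucleotide stacks, using the published Turner 2004 RNA stack table
(Watson-Crick and wobble pairs) embedded below; internal mismatches
break stacking and contribute no loop terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger("anser")

WC = 0.0
GU_SCORE = 0.5
MM_SCORE = 1.0


class PairState(Enum):
    WATSON_CRICK = "WC"
    GU = "GU"
    MISMATCH = "MM"


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Turner 2004 nearest-neighbor stack free energies, kcal/mol at 37 C,
# indexed as dg = _STACK[(p1, p2)] for the stacked pairs
# 5'-a b-3' / 3'-c d-5' with p1 = a+c and p2 = d+b.  The two
# destabilizing tandem-wobble entries are truncated at zero so that
# stacking is never destabilizing (monotone under pair removal).
_STACK_RAW: dict[tuple[str, str], float] = {
    ("CG", "CG"): -2.40, ("CG", "GC"): -3.30, ("CG", "GU"): -2.10,
    ("CG", "UG"): -1.40, ("CG", "AU"): -2.10, ("CG", "UA"): -2.10,
    ("GC", "CG"): -3.30, ("GC", "GC"): -3.40, ("GC", "GU"): -2.50,
    ("GC", "UG"): -1.50, ("GC", "AU"): -2.20, ("GC", "UA"): -2.40,
    ("GU", "CG"): -2.10, ("GU", "GC"): -2.50, ("GU", "GU"): 0.00,
    ("GU", "UG"): -0.50, ("GU", "AU"): -1.40, ("GU", "UA"): -1.30,
    ("UG", "CG"): -1.40, ("UG", "GC"): -1.50, ("UG", "GU"): -0.50,
    ("UG", "UG"): 0.00, ("UG", "AU"): -0.60, ("UG", "UA"): -1.00,
    ("AU", "CG"): -2.10, ("AU", "GC"): -2.20, ("AU", "GU"): -1.40,
    ("AU", "UG"): -0.60, ("AU", "AU"): -1.10, ("AU", "UA"): -0.90,
    ("UA", "CG"): -2.10, ("UA", "GC"): -2.40, ("UA", "GU"): -1.30,
    ("UA", "UG"): -1.00, ("UA", "AU"): -0.90, ("UA", "UA"): -1.30,
}
STACK_TABLE = dict(_STACK_RAW)

#: duplex initiation free energy, kcal/mol.  The published Turner 2004
#: value is +4.09; the default here is 0 because the rule-6 criterion is
#: a ratio of two same-length duplexes, which a shared constant offset
#: only distorts, and a zero initiation keeps every stacked duplex at
#: non-positive energy.
DUPLEX_INIT = 0.0


@dataclass
class MirnaExpression:
    """Normalized miRNA expression and between-condition fold change."""

    mirna_id: str
    raw_count: int
    total_clean_reads: int
    normalized: float
    fold_change: float | None = None


def normalize_expression(raw_count: int, total_clean_reads: int) -> float:
    """Transcripts per million clean reads: count / total * 1e6."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return raw_count / total_clean_reads * 1e6


def fold_change(normalized_treatment: float, normalized_control: float) -> float:
    """log2(treatment / control) of normalized expressions."""
    import math
    if normalized_treatment <= 0 or normalized_control <= 0:
        raise ValueError("fold change requires positive normalized expressions")
    return math.log2(normalized_treatment / normalized_control)


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(_to_rna(seq)))


def _pair_state(m: str, s: str) -> PairState:
    pair = {m, s}
    if pair == {"A", "U"} or pair == {"G", "C"}:
        return PairState.WATSON_CRICK
    if pair == {"G", "U"}:
        return PairState.GU
    return PairState.MISMATCH


@dataclass
class DuplexAlignment:
    """A gapless antiparallel miRNA:site pairing.

    miRNA position i (1-based from its 5' end) pairs with site position
    L + 1 - i; both sequences are stored 5'->3' in the RNA alphabet.
    """

    mirna: str
    site: str
    states: list[PairState]
    mismatch_score: float
    mfe: float | None
    mfe_perfect: float | None

    def score_of(self, position: int) -> float:
        """Mismatch-score contribution of a 1-based miRNA position."""
        st = self.states[position - 1]
        return {PairState.WATSON_CRICK: WC, PairState.GU: GU_SCORE,
                PairState.MISMATCH: MM_SCORE}[st]


def states_of(mirna: str, site: str) -> list[PairState]:
    """Per-position pair states of the antiparallel duplex."""
    m, s = _to_rna(mirna), _to_rna(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length (gapless duplex)")
    length = len(m)
    return [_pair_state(m[i], s[length - 1 - i]) for i in range(length)]


def mismatch_score(states: list[PairState]) -> float:
    return sum({PairState.WATSON_CRICK: WC, PairState.GU: GU_SCORE,
                PairState.MISMATCH: MM_SCORE}[st] for st in states)


def stack_energy(mirna: str, site: str, states: list[PairState] | None = None,
                 init: float = DUPLEX_INIT) -> float:
    """Nearest-neighbor free energy of the gapless duplex, kcal/mol.

    Sums stack terms over consecutive paired (WC or G:U) positions plus
    the initiation term; a duplex with no paired positions is assigned
    0 (no stable duplex) and logged.
    """
    m, s = _to_rna(mirna), _to_rna(site)
    if states is None:
        states = states_of(m, s)
    length = len(m)
    paired = [st is not PairState.MISMATCH for st in states]
    if not any(paired):
        logger.debug("duplex with no paired positions; energy set to 0")
        return 0.0
    dg = init
    for i in range(length - 1):
        if paired[i] and paired[i + 1]:
            p1 = m[i] + s[length - 1 - i]
            p2 = s[length - 2 - i] + m[i + 1]
            dg += STACK_TABLE[(p1, p2)]
    return dg


def pair_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Construct the duplex with pair states, score and free energies."""
    m, s = _to_rna(mirna), _to_rna(site)
    states = states_of(m, s)
    mfe = stack_energy(m, s, states)
    perfect = reverse_complement(m)
    mfe_perfect = stack_energy(m, perfect)
    return DuplexAlignment(m, s, states, mismatch_score(states), mfe, mfe_perfect)


@dataclass
class RuleVerdicts:
    max_total_score: bool       # rule 1
    max_adjacent_run: bool      # rule 2
    no_adjacent_2_12: bool      # rule 3
    paired_10_11: bool          # rule 4
    max_score_1_12: bool        # rule 5
    mfe_ratio: bool             # rule 6
    accepted: bool = False

    def as_tuple(self) -> tuple[bool, ...]:
        return (self.max_total_score, self.max_adjacent_run, self.no_adjacent_2_12,
                self.paired_10_11, self.max_score_1_12, self.mfe_ratio)


def check_rules(duplex: DuplexAlignment, gu_strict: bool = False,
                mfe_ratio: float = 0.75) -> RuleVerdicts:
    """Evaluate the six target-prediction rules on a duplex.

    ``gu_strict`` controls whether a G:U wobble counts as a mismatch in
    the adjacency/position rules 2-4 (it always scores 0.5 in rules 1
    and 5).  Rule 6 compares absolute free energies so that "at least
    75% of the perfect-complement energy" keeps its intended meaning on
    negative numbers.
    """
    states = duplex.states
    length = len(states)

    def is_mm(st: PairState) -> bool:
        return st is PairState.MISMATCH or (gu_strict and st is PairState.GU)

    scores = [duplex.score_of(i) for i in range(1, length + 1)]
    mm = [is_mm(st) for st in states]

    r1 = sum(scores) <= 4.0

    r2 = True
    run = 0
    for flag in mm:
        run = run + 1 if flag else 0
        if run > 2:
            r2 = False
            break

    r3 = True
    for i in range(1, min(12, length)):  # 1-based positions i+1 in 2..12
        if i + 2 <= 12 and i + 2 <= length and mm[i] and mm[i + 1]:
            r3 = False
            break

    r4 = True
    for pos in (10, 11):
        if pos <= length and mm[pos - 1]:
            r4 = False

    r5 = sum(scores[:min(12, length)]) <= 2.5

    if duplex.mfe is None or duplex.mfe_perfect is None:
        r6 = False
    else:
        r6 = abs(duplex.mfe) >= mfe_ratio * abs(duplex.mfe_perfect)

    verdicts = RuleVerdicts(r1, r2, r3, r4, r5, r6)
    verdicts.accepted = all(verdicts.as_tuple())
    return verdicts


@dataclass
class TargetCall:
    """An accepted (or evaluated) miRNA target site on a transcript."""

    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    mismatch_score: float
    mfe: float
    mfe_perfect: float
    verdicts: RuleVerdicts

    @property
    def accepted(self) -> bool:
        return self.verdicts.accepted


def scan_targets(mirna_id: str, mirna_seq: str,
                 transcripts: list[tuple[str, str]],
                 gu_strict: bool = False, mfe_ratio: float = 0.75,
                 keep_rejected: bool = False) -> list[TargetCall]:
    """Slide the miRNA over every transcript window and apply the rules.

    Every window of the miRNA's length on the transcript sense strand is
    evaluated; all accepted windows are reported (overlaps included)
    with 0-based half-open coordinates.  Transcripts shorter than the
    miRNA are skipped with a log entry.
    """
    m = _to_rna(mirna_seq)
    length = len(m)
    perfect = reverse_complement(m)
    mfe_perfect = stack_energy(m, perfect)
    calls: list[TargetCall] = []
    for tid, tseq in transcripts:
        t = _to_rna(tseq)
        if len(t) < length:
            logger.info("transcript %s shorter than miRNA %s; skipped", tid, mirna_id)
            continue
        for start in range(len(t) - length + 1):
            site = t[start:start + length]
            states = states_of(m, site)
            score = mismatch_score(states)
            # rules 1-5 are cheap; only compute the energy if they pass
            probe = DuplexAlignment(m, site, states, score, 0.0, mfe_perfect)
            verdicts = check_rules(probe, gu_strict=gu_strict, mfe_ratio=mfe_ratio)
            partial_ok = all(verdicts.as_tuple()[:5])
            if partial_ok or keep_rejected:
                mfe = stack_energy(m, site, states)
                duplex = DuplexAlignment(m, site, states, score, mfe, mfe_perfect)
                verdicts = check_rules(duplex, gu_strict=gu_strict, mfe_ratio=mfe_ratio)
            else:
                mfe = 0.0
            if verdicts.accepted or keep_rejected:
                calls.append(TargetCall(mirna_id, tid, start, start + length,
                                        score, mfe, mfe_perfect, verdicts))
    return calls
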