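"""Primer thermodynamics and secondary-structure screens.

Melting temperatures use unified nearest-neighbor parameters (SantaLucia-style
duplex ΔH/ΔS with initiation and terminal-AT terms), an entropic monovalent-salt
correction, and the two-state formula

    Tm = ΔH / (ΔS_salt + R ln(C_T/4)) − 273.15

for non-self-complementary duplexes at total oligo concentration C_T.

Hairpin and dimer screens are deterministic ungapped complementary-run
heuristics, not free-energy minimization: a primer is flagged when it contains
(or shares with a partner) an antiparallel Watson-Crick run at least as long as
the configured threshold, with a shorter threshold for runs that involve a
3'-terminal base, where extension by polymerase makes short anneals dangerous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seq import is_dna, revcomp

R_GAS = 1.987  # cal / (mol K)

# Unified nearest-neighbor duplex parameters: ΔH kcal/mol, ΔS cal/(mol K).
# Keyed by the top-strand dimer; values are invariant under reverse complement.
_NN_CORE = {
    "AA": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
NN_TABLE = {}
for _d, _v in _NN_CORE.items():
    NN_TABLE[_d] = _v
    NN_TABLE[revcomp(_d)] = _v

_INIT = (0.2, -5.7)
_TERMINAL_AT = (2.2, 6.9)  # per terminal A or T base pair


@dataclass(frozen=True)
class ThermoConditions:
    """Solution conditions for the nearest-neighbor Tm model.

    monovalent
        Monovalent cation concentration in mol/L (default 50 mM).
    oligo_conc
        Total primer strand concentration C_T in mol/L (default 250 nM);
        the template is assumed not self-complementary, so C_T/4 enters the
        two-state formula.
    """

    monovalent: float = 0.05
    oligo_conc: float = 2.5e-7
    nn_set: str = "unified"

    def __post_init__(self) -> None:
        if self.monovalent <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class StructureParams:
    """Thresholds for the run-length secondary-structure screens (all in bases)."""

    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_min_run: int = 8
    dimer_min_run_3p: int = 5
    self_anneal_word: int = 7

    def __post_init__(self) -> None:
        for f in (self.hairpin_min_stem, self.hairpin_min_loop,
                  self.dimer_min_run, self.dimer_min_run_3p, self.self_anneal_word):
            if f < 1:
                raise ValueError("structure thresholds must be >= 1")


DEFAULT_CONDITIONS = ThermoConditions()
DEFAULT_STRUCTURE = StructureParams()


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in an uppercase ACGT sequence."""
    if not is_dna(seq):
        raise ValueError(f"not a nonempty ACGT sequence: {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def duplex_dh_ds(seq: str) -> tuple[float, float]:
    """Nearest-neighbor ΔH (kcal/mol) and ΔS (cal/mol/K) for seq vs its perfect complement."""
    dh, ds = _INIT
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i:i + 2]]
        dh += h
        ds += s
    for base in (seq[0], seq[-1]):
        if base in "AT":
            dh += _TERMINAL_AT[0]
            ds += _TERMINAL_AT[1]
    return dh, ds


def melting_temperature(seq: str, cond: ThermoConditions | None = None) -> float:
    """Two-state nearest-neighbor melting temperature in °C.

    The salt correction is entropic: ΔS_salt = ΔS + 0.368 (N−1) ln[Na+], where
    N−1 is the number of phosphate-bridged stacks.
    """
    cond = cond or DEFAULT_CONDITIONS
    if not is_dna(seq):
        raise ValueError(f"not a nonempty ACGT sequence: {seq!r}")
    n = len(seq)
    if not 8 <= n <= 40:
        raise ValueError(f"sequence length {n} outside supported range 8-40")
    dh, ds = duplex_dh_ds(seq)
    ds_salt = ds + 0.368 * (n - 1) * math.log(cond.monovalent)
    return 1000.0 * dh / (ds_salt + R_GAS * math.log(cond.oligo_conc / 4.0)) - 273.15


def forms_hairpin(seq: str, sp: StructureParams | None = None) -> bool:
    """True if the primer can fold back on itself.

    A hairpin requires two ungapped reverse-complementary runs of at least
    ``hairpin_min_stem`` bases separated by a loop of at least
    ``hairpin_min_loop`` bases.  Any longer stem contains a minimal-length
    stem with at least as long a loop, so scanning minimal stems suffices.
    """
    sp = sp or DEFAULT_STRUCTURE
    s = seq.upper()
    stem, loop = sp.hairpin_min_stem, sp.hairpin_min_loop
    n = len(s)
    for i in range(n - 2 * stem - loop + 1):
        probe = revcomp(s[i:i + stem])
        if s.find(probe, i + stem + loop) != -1:
            return True
    return False


def dimerizes(a: str, b: str, sp: StructureParams | None = None) -> bool:
    """True if two primers can anneal to each other (a == b screens self-dimers).

    Flags an ungapped antiparallel complementary run of at least
    ``dimer_min_run`` bases anywhere, or of at least ``dimer_min_run_3p``
    bases involving the 3'-terminal base of either primer.
    """
    sp = sp or DEFAULT_STRUCTURE
    ua, ub = a.upper(), b.upper()
    rb = revcomp(ub)  # substring match between ua and rb == complementary run
    k = sp.dimer_min_run
    if len(ua) >= k and len(rb) >= k:
        words = {ua[i:i + k] for i in range(len(ua) - k + 1)}
        for j in range(len(rb) - k + 1):
            if rb[j:j + k] in words:
                return True
    d = sp.dimer_min_run_3p
    if len(ua) >= d and len(ub) >= d:
        # run covering a's 3' base == common substring ending at a's end
        if ua[-d:] in rb:
            return True
        # run covering b's 3' base == prefix of revcomp(b) inside a
        if rb[:d] in ua:
            return True
    return False


def three_prime_anneals_within(primer: str, interior: str, word: int = 7) -> bool:
    """True if the primer's 3'-terminal *word* can anneal inside an amplicon interior.

    Both strands of the (double-stranded) product are considered, so both the
    suffix and its reverse complement are searched.
    """
    p = primer.upper()
    if len(p) < word:
        raise ValueError(f"primer shorter than {word} bases")
    suffix = p[-word:]
    interior = interior.upper()
    return suffix in interior or revcomp(suffix) in interior


# --- brute-force run scans -------------------------------------------------
# Independent O(n*m) dynamic scans used by the pool validator and as oracles;
# deliberately a different code path from the set/substring methods above.

def max_complementary_run(a: str, b: str) -> int:
    """Length of the longest ungapped antiparallel complementary run between a and b."""
    ua, rb = a.upper(), revcomp(b.upper())
    best = 0
    prev = [0] * (len(rb) + 1)
    for i in range(1, len(ua) + 1):
        cur = [0] * (len(rb) + 1)
        ai = ua[i - 1]
        for j in range(1, len(rb) + 1):
            if ai == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def max_3prime_complementary_run(a: str, b: str) -> int:
    """Longest complementary run between a and b that includes a's 3'-terminal base."""
    ua, rb = a.upper(), revcomp(b.upper())
    best = 0
    for j in range(len(rb)):
        # run ending at ua[-1] aligned against rb ending at position j
        length = 0
        i, jj = len(ua) - 1, j
        while i >= 0 and jj >= 0 and ua[i] == rb[jj]:
            length += 1
            i -= 1
            jj -= 1
        best = max(best, length)
    return best
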