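"""Nearest-neighbor DNA duplex melting temperatures with salt correction.

Implements the unified DNA/DNA nearest-neighbor thermodynamics (SantaLucia,
PNAS 1998) and the monovalent/divalent salt correction of Owczarzy et al.
(Biochemistry 2008), including dNTP chelation of Mg2+. These are the documented
model behind the common online oligo calculators, evaluated here at reverse-
transcription reaction conditions (75 mM Na+, 3 mM Mg2+, 0.5 mM dNTPs,
12.5 nM oligo) by default.

The primer anneals to RNA in the actual reaction; DNA/DNA parameters are used
as a deliberate simplification matching standard calculator practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .panel import reverse_complement

R_GAS = 1.987  # cal / (mol K)

# Unified NN stack parameters: dH kcal/mol, dS cal/(mol K) (SantaLucia 1998).
# Keys are 5'->3' top-strand dinucleotides; a stack and its reverse complement
# share parameters (same duplex read from the other strand).
NN_STACKS = {
    "AA": (-7.9, -22.2),  # == TT
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),  # == TG
    "GT": (-8.4, -22.4),  # == AC
    "CT": (-7.8, -21.0),  # == AG
    "GA": (-8.2, -22.2),  # == TC
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),  # == CC
}

# Duplex initiation per terminal base pair.
INIT_TERMINAL = {
    "A": (2.3, 4.1),
    "T": (2.3, 4.1),
    "G": (0.1, -2.8),
    "C": (0.1, -2.8),
}

MG_DNTP_KA = 3e4  # Mg:dNTP association constant, 1/M (Owczarzy 2008)


class ThermoError(ValueError):
    """Invalid sequence or reaction conditions."""


@dataclass(frozen=True)
class ThermoConditions:
    """Reaction conditions for Tm evaluation.

    Concentrations: na_mM monovalent cations (mM), mg_mM total Mg2+ (mM),
    dntp_mM total dNTPs (mM), oligo_uM total oligo (µM). reaction_temp_C and
    tm_tolerance_C define the target Tm window for primer design.
    """

    na_mM: float = 75.0
    mg_mM: float = 3.0
    dntp_mM: float = 0.5
    oligo_uM: float = 0.0125
    reaction_temp_C: float = 50.0
    tm_tolerance_C: float = 2.0

    def __post_init__(self) -> None:
        for name in ("na_mM", "mg_mM", "dntp_mM", "oligo_uM"):
            if getattr(self, name) <= 0:
                raise ThermoError(f"{name} must be > 0")
        if self.tm_tolerance_C <= 0:
            raise ThermoError("tm_tolerance_C must be > 0")

    @property
    def tm_window(self) -> tuple[float, float]:
        return (
            self.reaction_temp_C - self.tm_tolerance_C,
            self.reaction_temp_C + self.tm_tolerance_C,
        )


#: conditions the qPCR assay primers are designed for (SYBR-green style mix)
QPCR_CONDITIONS = ThermoConditions(
    na_mM=50.0, mg_mM=3.0, dntp_mM=0.8, oligo_uM=0.4,
    reaction_temp_C=56.0, tm_tolerance_C=1.0,
)


@dataclass(frozen=True)
class ThermoResult:
    dH: float  # kcal/mol
    dS: float  # cal/(mol K)
    tm_C: float


def _clean(sequence: str) -> str:
    seq = sequence.strip().upper()
    if len(seq) < 8:
        raise ThermoError(f"sequence too short for NN model ({len(seq)} < 8 nt)")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ThermoError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def nn_sums(sequence: str) -> tuple[float, float]:
    """Sum stacked-pair and initiation terms; returns (dH kcal/mol, dS cal/mol/K)."""
    seq = _clean(sequence)
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in NN_STACKS:
            pair = reverse_complement(pair)
        h, s = NN_STACKS[pair]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_TERMINAL[terminal]
        dh += h
        ds += s
    return dh, ds


def free_magnesium_M(mg_mM: float, dntp_mM: float) -> float:
    """Free Mg2+ (molar) after dNTP chelation at Ka = 3e4 /M."""
    if dntp_mM > mg_mM:
        raise ThermoError(
            "dNTP concentration exceeds Mg2+; fully chelated divalent is not supported"
        )
    mg, dntp = mg_mM * 1e-3, dntp_mM * 1e-3
    b = MG_DNTP_KA * dntp - MG_DNTP_KA * mg + 1.0
    return (-b + math.sqrt(b * b + 4.0 * MG_DNTP_KA * mg)) / (2.0 * MG_DNTP_KA)


def _owczarzy_inverse_tm_correction(seq: str, cond: ThermoConditions) -> float:
    """Additive correction to 1/Tm (1/K) for monovalent + divalent cations."""
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    nbp = len(seq)
    mon = cond.na_mM * 1e-3
    mg = free_magnesium_M(cond.mg_mM, cond.dntp_mM)
    lnmon = math.log(mon)
    ratio = math.sqrt(mg) / mon
    if ratio < 0.22:
        # monovalent-dominated regime (Owczarzy 2004)
        return (4.29 * fgc - 3.95) * 1e-5 * lnmon + 9.40e-6 * lnmon**2
    a, b, c, d = 3.92, -0.911, 6.26, 1.42
    e, f, g = -48.2, 52.5, 8.31
    if ratio < 6.0:
        # mixed regime: monovalent-dependent coefficients
        a = 3.92 * (0.843 - 0.352 * math.sqrt(mon) * lnmon)
        d = 1.42 * (1.279 - 4.03e-3 * lnmon - 8.03e-3 * lnmon**2)
        g = 8.31 * (0.486 - 0.258 * lnmon + 5.25e-3 * lnmon**3)
    lnmg = math.log(mg)
    return (
        a
        + b * lnmg
        + fgc * (c + d * lnmg)
        + (1.0 / (2.0 * (nbp - 1))) * (e + f * lnmg + g * lnmg**2)
    ) * 1e-5


def tm(
    sequence: str,
    cond: ThermoConditions | None = None,
    ct_divisor: float = 4.0,
) -> ThermoResult:
    """Salt-corrected duplex Tm (°C) of an oligo against its perfect complement.

    ct_divisor=4 assumes primer and template at comparable concentration
    (non-self-complementary duplex); use 1 for primer-excess mode.
    """
    cond = cond or ThermoConditions()
    seq = _clean(sequence)
    dh, ds = nn_sums(seq)
    ct = cond.oligo_uM * 1e-6
    tm_1m_K = (dh * 1000.0) / (ds + R_GAS * math.log(ct / ct_divisor))
    corr = _owczarzy_inverse_tm_correction(seq, cond)
    tm_K = 1.0 / (1.0 / tm_1m_K + corr)
    return ThermoResult(dH=dh, dS=ds, tm_C=tm_K - 273.15)


def gc_fraction(sequence: str) -> float:
    seq = sequence.strip().upper()
    if not seq:
        raise ThermoError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)
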