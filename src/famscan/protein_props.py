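"""Physicochemical parameter panel for family proteins.

Computes, for each protein, the panel conventionally reported for a
transcription-factor family census: length (AA), molecular weight (Da,
average residue masses), theoretical isoelectric point (Henderson-
Hasselbalch net-charge root, Bjellqvist-style pKa set), Guruprasad
instability index (II; > 40 predicts in-vitro instability), Ikai
aliphatic index (AI) and Kyte-Doolittle GRAVY, plus an acidic/basic
class from the pI.

The pKa and residue-mass tables are committed under ``data/`` so the
charge model is explicit; the Guruprasad DIWV dipeptide weights and
Kyte-Doolittle hydropathy values come from Bio.SeqUtils.ProtParamData.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from Bio.SeqUtils.ProtParamData import DIWV, kd

logger = logging.getLogger(__name__)

_TABLES = json.loads(
    resources.files("famscan.data").joinpath("protparam_tables.json").read_text()
)
RESIDUE_MASS: dict[str, float] = _TABLES["average_residue_mass"]
WATER_MASS: float = _TABLES["water_mass"]
PKA_POSITIVE: dict[str, float] = _TABLES["pka_positive"]
PKA_NEGATIVE: dict[str, float] = _TABLES["pka_negative"]

_PI_CHARGE_TOL = 1e-4


@dataclass
class ProteinProperties:
    length: int
    mw: float  # Daltons
    pi: float
    instability: float | None  # undefined for length < 2
    aliphatic: float
    gravy: float
    charge_class: str  # acidic | basic | neutral


def net_charge(seq: str, ph: float) -> float:
    """Net charge at a given pH under the committed pKa set.

    Positive groups (N-terminus, K, R, H) contribute
    1/(1+10^(pH-pKa)); negative groups (C-terminus, D, E, C, Y)
    contribute -1/(1+10^(pKa-pH)).
    """
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa, pka in PKA_POSITIVE.items():
        if aa == "Nterm":
            continue
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa == "Cterm":
            continue
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(seq: str) -> float:
    """pH where net charge crosses zero, by bisection on (0, 14).

    The charge function is strictly decreasing in pH, so the root is
    unique; bisection runs until |charge| < 1e-4.
    """
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid)
        if abs(q) < _PI_CHARGE_TOL:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def molecular_weight(seq: str) -> float:
    return sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def gravy(seq: str) -> float:
    # X contributes zero hydropathy but still counts toward length
    return sum(kd.get(aa, 0.0) for aa in seq) / len(seq)


def instability_index(seq: str) -> float | None:
    if len(seq) < 2:
        return None
    total = 0.0
    for i in range(len(seq) - 1):
        total += DIWV.get(seq[i], {}).get(seq[i + 1], 0.0)
    return total * 10.0 / len(seq)


def aliphatic_index(seq: str) -> float:
    L = len(seq)
    x_ala = 100.0 * seq.count("A") / L
    x_val = 100.0 * seq.count("V") / L
    x_ile_leu = 100.0 * (seq.count("I") + seq.count("L")) / L
    return x_ala + 2.9 * x_val + 3.9 * x_ile_leu


def compute_protparam(protein_seq: str) -> ProteinProperties:
    """Compute the full physicochemical panel for one protein."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein_seq):
        if aa not in RESIDUE_MASS:
            raise ValueError(f"invalid amino-acid character {protein_seq[i]!r} at position {i}")
    if "X" in protein_seq:
        logger.info("sequence contains X residues (zero hydropathy/DIWV weight)")
    pi = isoelectric_point(protein_seq)
    if pi < 7:
        charge_class = "acidic"
    elif pi > 7:
        charge_class = "basic"
    else:
        charge_class = "neutral"
    ii = instability_index(protein_seq)
    if ii is None:
        logger.warning("instability index undefined for length-1 sequence")
    return ProteinProperties(
        length=len(protein_seq),
        mw=molecular_weight(protein_seq),
        pi=pi,
        instability=ii,
        aliphatic=aliphatic_index(protein_seq),
        gravy=gravy(protein_seq),
        charge_class=charge_class,
    )


@dataclass
class FamilySummary:
    n: int
    minima: dict[str, float]
    maxima: dict[str, float]
    means: dict[str, float]
    n_unstable: int  # II > 40
    charge_counts: dict[str, int]


_SUMMARY_FIELDS = ("length", "mw", "pi", "instability", "aliphatic", "gravy")


def summarize_family(props: Sequence[ProteinProperties]) -> FamilySummary:
    """Order statistics and means across a family's property panel."""
    if not props:
        raise ValueError("summarize_family requires a non-empty list")
    minima, maxima, means = {}, {}, {}
    for name in _SUMMARY_FIELDS:
        values = [getattr(p, name) for p in props if getattr(p, name) is not None]
        if not values:
            continue
        minima[name] = min(values)
        maxima[name] = max(values)
        means[name] = math.fsum(values) / len(values)
    charge_counts = {"acidic": 0, "basic": 0, "neutral": 0}
    for p in props:
        charge_counts[p.charge_class] += 1
    return FamilySummary(
        n=len(props),
        minima=minima,
        maxima=maxima,
        means=means,
        n_unstable=sum(1 for p in props if p.instability is not None and p.instability > 40),
        charge_counts=charge_counts,
    )
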