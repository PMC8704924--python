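"""Resolve which molecular species a precursor signal represents.

Carotenoids ionize in positive ESI both as radical cations M(.+) and as
protonated molecules [M+H]+, and apocarotenoids additionally show protonated
dimers [2M+H]+. On a unit-resolution trap the only desk-side evidence that
distinguishes them is arithmetic between co-eluting signals: a pair (a, b)
with b ~= 2(a - p) + p marks a as the protonated monomer and b as its
protonated dimer. Lone signals keep BOTH the M(.+) and [M+H]+ hypotheses;
this module never picks between them — downstream candidate matching
resolves the ambiguity by which neutral mass hits a database record.

Arithmetic is nominal by default (proton mass 1.0, matching unit-resolution
practice); pass ``proton_mass=PROTON_MONOISOTOPIC`` for high-resolution data.
"""

from __future__ import annotations

from dataclasses import dataclass

PROTON_NOMINAL = 1.0
PROTON_MONOISOTOPIC = 1.00728

SPECIES = ("radical_cation", "protonated", "protonated_dimer")


@dataclass(frozen=True)
class IonSpeciesAssignment:
    """One (signal, species) hypothesis with its implied neutral mass.

    ``mass_error`` is the residual of the monomer/dimer relation that
    justified a paired assignment (None for lone hypotheses); ``partner_mz``
    is the co-eluting signal on the other side of that relation.
    """

    observed_mz: float
    species: str
    neutral_mass: float
    mass_error: float | None = None
    partner_mz: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown ion species {self.species!r}")
        if not self.neutral_mass > 0:
            raise ValueError("neutral mass must be positive")


def neutral_mass_from(mz: float, species: str, proton_mass: float = PROTON_NOMINAL) -> float:
    """Neutral mass implied by an observed m/z under a species hypothesis."""
    if not mz > 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if species == "radical_cation":
        return mz
    if species == "protonated":
        return mz - proton_mass
    if species == "protonated_dimer":
        return (mz - proton_mass) / 2.0
    raise ValueError(f"unknown ion species {species!r}")


def predicted_mz(neutral_mass: float, species: str,
                 proton_mass: float = PROTON_NOMINAL) -> float:
    """Inverse of :func:`neutral_mass_from` (exact round trip)."""
    if species == "radical_cation":
        return neutral_mass
    if species == "protonated":
        return neutral_mass + proton_mass
    if species == "protonated_dimer":
        return 2.0 * neutral_mass + proton_mass
    raise ValueError(f"unknown ion species {species!r}")


def infer_ion_species(signals: list[float], tol: float = 1.5,
                      proton_mass: float = PROTON_NOMINAL) -> list[IonSpeciesAssignment]:
    """Assign species hypotheses to a set of co-eluting precursor signals.

    Every signal receives at least one assignment. For each pair (a, b)
    satisfying |b - (2(a - p) + p)| <= 2*tol, a's protonated hypothesis and
    b's protonated-dimer hypothesis are emitted first (promoted); all signals
    additionally keep their lone radical-cation and protonated hypotheses so
    that ambiguity is preserved. The pairing test is symmetric in the input
    order and every consistent pairing is reported.
    """
    if not signals:
        raise ValueError("at least one precursor signal is required")
    if not tol > 0:
        raise ValueError("tolerance must be positive")

    monomer_partners: dict[int, list[tuple[float, float]]] = {}
    dimer_partners: dict[int, list[tuple[float, float]]] = {}
    for i, a in enumerate(signals):
        for j, b in enumerate(signals):
            if i == j:
                continue
            predicted_dimer = 2.0 * (a - proton_mass) + proton_mass
            err = b - predicted_dimer
            if abs(err) <= 2.0 * tol:
                monomer_partners.setdefault(i, []).append((b, err))
                dimer_partners.setdefault(j, []).append((a, err))

    out: list[IonSpeciesAssignment] = []
    for i, mz in enumerate(signals):
        promoted: list[IonSpeciesAssignment] = []
        for partner, err in monomer_partners.get(i, []):
            promoted.append(IonSpeciesAssignment(
                mz, "protonated", neutral_mass_from(mz, "protonated", proton_mass),
                mass_error=err, partner_mz=partner))
        for partner, err in dimer_partners.get(i, []):
            promoted.append(IonSpeciesAssignment(
                mz, "protonated_dimer",
                neutral_mass_from(mz, "protonated_dimer", proton_mass),
                mass_error=err, partner_mz=partner))
        lone = [
            IonSpeciesAssignment(mz, "radical_cation", mz),
            IonSpeciesAssignment(mz, "protonated",
                                 neutral_mass_from(mz, "protonated", proton_mass)),
        ]
        promoted_species = {a.species for a in promoted}
        out.extend(promoted)
        out.extend(a for a in lone if a.species not in promoted_species)
    return out


def assignments_for_signal(assignments: list[IonSpeciesAssignment],
                           mz: float) -> list[IonSpeciesAssignment]:
    """Hypotheses for one observed signal, promoted ones first (input order kept)."""
    return [a for a in assignments if a.observed_mz == mz]
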