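"""Explain MS2 fragments as combinations of canonical carotenoid neutral losses.

The default loss grammar is the one that carries almost all identification
power for carotenoids on unit-resolution instruments:

======== ===== ========== ===========================================
loss      Da    implies    chemistry
======== ===== ========== ===========================================
water     18    hydroxyl   dehydration of an -OH substituent
methanol  32    methoxy    elimination from a methoxy group
toluene   92    polyene    retro-Diels-Alder-type chain elimination
xylene    106   polyene    chain elimination one C-unit longer
======== ===== ========== ===========================================

Fragments are matched against all multisets of these losses up to a
configurable combination depth (water up to x3 for tri-hydroxylated
xanthophylls, the others up to x1); the multiset minimizing |mass error|
wins, with ties broken by fewest components then lexicographic loss names.
Hydroxyl counting uses the *maximum* observed water multiplicity rather than
requiring a complete ladder, because intermediate rungs are routinely weak
or missing in trap data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "CanonicalLoss", "LossAnnotation", "FunctionalGroupProfile",
    "DEFAULT_LOSSES", "match_losses", "infer_profile",
]


@dataclass(frozen=True)
class CanonicalLoss:
    name: str
    nominal_mass: float
    implies: str  # hydroxyl | methoxy | polyene
    max_multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.nominal_mass <= 0 or self.max_multiplicity < 1:
            raise ValueError("loss mass and multiplicity must be positive")


WATER = CanonicalLoss("water", 18.0, "hydroxyl", max_multiplicity=3)
METHANOL = CanonicalLoss("methanol", 32.0, "methoxy")
TOLUENE = CanonicalLoss("toluene", 92.0, "polyene")
XYLENE = CanonicalLoss("xylene", 106.0, "polyene")

DEFAULT_LOSSES = (WATER, METHANOL, TOLUENE, XYLENE)

#: monoisotopic alternatives for high-resolution data
MONOISOTOPIC_LOSSES = (
    CanonicalLoss("water", 18.0106, "hydroxyl", max_multiplicity=3),
    CanonicalLoss("methanol", 32.0262, "methoxy"),
    CanonicalLoss("toluene", 92.0626, "polyene"),
    CanonicalLoss("xylene", 106.0783, "polyene"),
)


@dataclass(frozen=True)
class LossAnnotation:
    """A fragment explained as a multiset of canonical losses.

    Invariant: fragment_mz + total_loss + mass_error == precursor exactly,
    because mass_error is defined as (precursor - fragment) - total_loss.
    """

    fragment_mz: float
    components: tuple[CanonicalLoss, ...]
    total_loss: float
    mass_error: float

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("an annotation needs at least one loss component")

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)


@dataclass
class FunctionalGroupProfile:
    """Functional groups inferred purely from annotated losses (never from a DB)."""

    n_hydroxyl_observed: int = 0
    methoxy_observed: bool = False
    polyene_observed: bool = False
    unexplained_fragments: tuple[float, ...] = ()


def _combinations(losses: tuple[CanonicalLoss, ...], max_components: int):
    """All loss multisets of size 1..max_components respecting multiplicities.

    Yields (components sorted by name, total mass). Small by construction
    (the default grammar gives < 50 multisets at depth 3).
    """
    ranges = [range(0, min(l.max_multiplicity, max_components) + 1) for l in losses]
    for counts in product(*ranges):
        size = sum(counts)
        if not 1 <= size <= max_components:
            continue
        comps: list[CanonicalLoss] = []
        for loss, k in zip(losses, counts):
            comps.extend([loss] * k)
        comps.sort(key=lambda l: l.name)
        yield tuple(comps), sum(c.nominal_mass for c in comps)


def match_losses(precursor: float, fragments, tol: float = 1.5,
                 max_components: int = 3,
                 losses: tuple[CanonicalLoss, ...] = DEFAULT_LOSSES,
                 ) -> tuple[list[LossAnnotation], list[float]]:
    """Annotate each fragment with its best loss combination.

    Parameters mirror the instrument reality: ``tol`` is the fragment mass
    tolerance in Da (default 1.5 for a unit-resolution trap) and
    ``max_components`` caps combination depth (default 3).

    Returns (annotations, unexplained_mzs); fragments with no combination
    within ``tol`` are not errors, they are simply reported unexplained.
    """
    if not tol > 0:
        raise ValueError("tolerance must be positive")
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    combos = list(_combinations(losses, max_components))
    annotations: list[LossAnnotation] = []
    unexplained: list[float] = []
    for frag in fragments:
        mz = frag.mz if hasattr(frag, "mz") else float(frag)
        delta = precursor - mz
        best = None
        for comps, total in combos:
            err = delta - total
            key = (abs(err), len(comps), tuple(c.name for c in comps))
            if best is None or key < best[0]:
                best = (key, comps, total, err)
        if best is not None and abs(best[3]) <= tol:
            annotations.append(LossAnnotation(mz, best[1], best[2], best[3]))
        else:
            unexplained.append(mz)
    return annotations, unexplained


def infer_profile(annotations, unexplained=()) -> FunctionalGroupProfile:
    """Collapse loss annotations into a functional-group profile.

    The hydroxyl count is the largest k for which a pure water-x-k annotation
    exists (an incomplete ladder still counts its deepest rung); methoxy and
    polyene are flags raised by any annotation containing the corresponding
    loss.
    """
    n_hydroxyl = 0
    methoxy = False
    polyene = False
    for ann in annotations:
        names = set(ann.component_names)
        if names == {"water"}:
            n_hydroxyl = max(n_hydroxyl, len(ann.components))
        if "methanol" in names:
            methoxy = True
        if "toluene" in names or "xylene" in names:
            polyene = True
    return FunctionalGroupProfile(
        n_hydroxyl_observed=n_hydroxyl,
        methoxy_observed=methoxy,
        polyene_observed=polyene,
        unexplained_fragments=tuple(unexplained),
    )


def load_loss_table(path) -> tuple[CanonicalLoss, ...]:
    """Load a user loss grammar from CSV (columns: name, mass, implies[, max_mult])."""
    import pandas as pd

    df = pd.read_csv(path)
    losses = []
    for _, row in df.iterrows():
        losses.append(CanonicalLoss(
            str(row["name"]), float(row["mass"]), str(row["implies"]),
            int(row["max_mult"]) if "max_mult" in df.columns else 1,
        ))
    return tuple(losses)
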