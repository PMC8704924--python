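"""Ranked carotenoid identification with an explicit evidence trail.

For each chromatographic peak, every co-eluting precursor is taken through
the same argument a spectroscopist would make at the desk:

1. ion-species hypotheses (radical cation / protonated / protonated dimer,
   the last only when a co-eluting partner satisfies the dimer arithmetic)
   give neutral-mass hypotheses;
2. each neutral mass is looked up in the reference table;
3. each candidate accumulates weighted evidence: the mass match itself,
   consistency of the loss-derived functional-group profile with the
   record (observed hydroxyl count is a *lower* bound — trap spectra
   under-report), producer plausibility for the source taxon (a demotion,
   never a rejection), the lutein/zeaxanthin isomer fragment rule, UV-vis
   fine-structure agreement, and corroborating dimer pairing.

Candidates are ranked by total score (ties by name, so output is stable and
deterministic); precursors with no candidate at all are first-class
"unknown" results, mirroring how such tables are published.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .carotenoid_db import CarotenoidRecord, candidates_by_mass, producer_compatible
from .ion_species import (IonSpeciesAssignment, PROTON_NOMINAL,
                          assignments_for_signal, infer_ion_species)
from .neutral_loss import DEFAULT_LOSSES, infer_profile, match_losses
from .spectra_model import ChromPeak, Dataset, Ms2Spectrum
from .uvvis_features import fine_structure

logger = logging.getLogger(__name__)

EVIDENCE_KINDS = ("mass_match", "group_consistency", "producer", "isomer_fragment",
                  "uvvis_fine_structure", "uvvis_shift", "dimer")

DEFAULT_WEIGHTS = {
    "mass_match": 2.0,
    "group_consistency": 2.0,
    "producer": 1.0,
    "isomer_fragment": 1.0,
    "uvvis_fine_structure": 1.0,
    "dimer": 0.5,
}


@dataclass(frozen=True)
class Evidence:
    kind: str
    weight: float
    note: str

    def __post_init__(self) -> None:
        if self.kind not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("evidence weight must be >= 0")


@dataclass
class Candidate:
    record: CarotenoidRecord
    species: IonSpeciesAssignment
    score: float
    evidence: list[Evidence]
    status: str = "accepted"  # accepted | demoted | rejected

    def audit(self) -> bool:
        """Score must equal the sum of evidence weights exactly."""
        return abs(self.score - sum(e.weight for e in self.evidence)) < 1e-9


@dataclass
class Identification:
    peak_id: str
    candidates: list[Candidate]
    unexplained_signals: list[float] = field(default_factory=list)

    def top(self) -> Candidate | None:
        return self.candidates[0] if self.candidates else None


@dataclass
class IdentifyConfig:
    """All thresholds of the scoring pipeline, overridable via YAML/CLI."""

    precursor_tol: float = 1.5
    fragment_tol: float = 1.5
    max_loss_depth: int = 3
    proton_mass: float = PROTON_NOMINAL
    mass_scale: str = "nominal"
    losses: tuple = DEFAULT_LOSSES
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    #: intensity (% base peak) above which a water-loss fragment reads "lutein-like"
    isomer_intensity_threshold: float = 20.0
    isomer_pair: tuple[str, str] = ("lutein", "zeaxanthin")
    diagnostic_tol: float = 1.5

    @classmethod
    def from_dict(cls, d: dict) -> "IdentifyConfig":
        cfg = cls()
        for key, value in d.items():
            if key == "weights":
                cfg.weights.update(value)
            elif hasattr(cfg, key):
                setattr(cfg, key, value)
            else:
                raise KeyError(f"unknown config key {key!r}")
        return cfg


def discriminate_lutein_zeaxanthin(spectrum: Ms2Spectrum,
                                   threshold_pct: float = 20.0,
                                   tol: float = 1.5,
                                   diagnostic_mzs: tuple[float, ...] = (430.0, 494.0, 495.0),
                                   ) -> str:
    """Isomer call for a lutein/zeaxanthin-mass precursor.

    Lutein's allylic 3'-hydroxyl makes its water-loss fragment (the m/z 551
    region, i.e. precursor - 18) intense and produces characteristic
    fragments near m/z 430/494/495; zeaxanthin's water loss stays weak.
    Returns "lutein", "zeaxanthin" or "indeterminate" (e.g. when no
    intensities were recorded).
    """
    water_loss_mz = spectrum.precursor_mz - 18.0
    region = [f for f in spectrum.fragments if abs(f.mz - water_loss_mz) <= tol]
    diagnostic = any(
        abs(f.mz - d) <= tol for f in spectrum.fragments for d in diagnostic_mzs
    )
    if diagnostic:
        return "lutein"
    with_intensity = [f for f in region if f.rel_intensity is not None]
    if not with_intensity:
        return "indeterminate"
    best = max(f.rel_intensity for f in with_intensity)
    return "lutein" if best >= threshold_pct else "zeaxanthin"


def _measured_fine_structure(peak: ChromPeak) -> float | None:
    if peak.percent_iii_ii is not None:
        return peak.percent_iii_ii
    if peak.dad is not None:
        return fine_structure(peak.dad)
    return None


def _score_candidate(record: CarotenoidRecord, assignment: IonSpeciesAssignment,
                     spectrum: Ms2Spectrum, peak: ChromPeak, taxon: str,
                     cfg: IdentifyConfig, profile, lutein_diags) -> Candidate:
    w = cfg.weights
    evidence: list[Evidence] = []
    status = "accepted"

    err = record.mass(cfg.mass_scale) - assignment.neutral_mass
    evidence.append(Evidence(
        "mass_match", w["mass_match"],
        f"neutral mass {assignment.neutral_mass:g} ({assignment.species} of m/z "
        f"{assignment.observed_mz:g}) matches {record.name} "
        f"{record.mass(cfg.mass_scale):g} Da within {abs(err):.1f} Da"))

    hydroxyl_ok = profile.n_hydroxyl_observed <= record.n_hydroxyl
    methoxy_ok = (not profile.methoxy_observed) or record.n_methoxy >= 1
    # every carotenoid carries a polyene chain, so observed 92/106 losses are
    # consistent with any record
    if hydroxyl_ok and methoxy_ok:
        evidence.append(Evidence(
            "group_consistency", w["group_consistency"],
            f"observed groups ({profile.n_hydroxyl_observed} hydroxyl, "
            f"methoxy={profile.methoxy_observed}, polyene={profile.polyene_observed}) "
            f"are consistent with {record.name} ({record.n_hydroxyl} OH, "
            f"{record.n_methoxy} OMe)"))
    else:
        reason = (f"{profile.n_hydroxyl_observed} water losses exceed the "
                  f"{record.n_hydroxyl} hydroxyls of {record.name}"
                  if not hydroxyl_ok else
                  f"methanol loss observed but {record.name} has no methoxy group")
        evidence.append(Evidence("group_consistency", 0.0, f"inconsistent: {reason}"))

    if producer_compatible(record, taxon):
        evidence.append(Evidence(
            "producer", w["producer"],
            f"{record.name} is described for {taxon}" if taxon != "unknown"
            else "source taxon unknown; producer filter disabled"))
    else:
        status = "demoted"
        evidence.append(Evidence(
            "producer", 0.0,
            f"{record.name} is not described for {taxon} "
            f"(known producers: {', '.join(sorted(record.producers))}); demoted"))

    if record.name in cfg.isomer_pair:
        verdict = discriminate_lutein_zeaxanthin(
            spectrum, cfg.isomer_intensity_threshold, cfg.diagnostic_tol, lutein_diags)
        if verdict == record.name:
            evidence.append(Evidence(
                "isomer_fragment", w["isomer_fragment"],
                f"water-loss intensity / diagnostic-fragment rule reads "
                f"{verdict} for m/z {spectrum.precursor_mz:g}"))

    measured = _measured_fine_structure(peak)
    if measured is not None and record.fine_structure_range is not None:
        lo, hi = record.fine_structure_range
        if lo <= measured <= hi:
            evidence.append(Evidence(
                "uvvis_fine_structure", w["uvvis_fine_structure"],
                f"%III/II = {measured:g} lies in the {record.name} "
                f"range [{lo:g}, {hi:g}]"))

    if assignment.partner_mz is not None and assignment.species in (
            "protonated", "protonated_dimer"):
        evidence.append(Evidence(
            "dimer", w["dimer"],
            f"monomer/dimer pair with co-eluting m/z {assignment.partner_mz:g} "
            f"corroborates the {assignment.species} assignment"))

    score = sum(e.weight for e in evidence)
    return Candidate(record, assignment, score, evidence, status)


def identify_peak(peak: ChromPeak, db: list[CarotenoidRecord], taxon: str = "unknown",
                  config: IdentifyConfig | None = None) -> Identification:
    """Rank reference candidates for one chromatographic peak.

    Co-eluting precursors are identified independently (no deconvolution);
    within one precursor a record is kept once, under its best-scoring
    species hypothesis. Output is deterministic for fixed input and config.
    """
    if not db:
        raise ValueError("reference database is empty")
    cfg = config or IdentifyConfig()
    lutein_diags = tuple(
        mz for r in db if r.name == cfg.isomer_pair[0]
        for mz, note in r.diagnostic_fragments if "water loss" not in note
    ) or (430.0, 494.0, 495.0)

    assignments = infer_ion_species(peak.precursor_mzs, cfg.precursor_tol,
                                    cfg.proton_mass)
    candidates: list[Candidate] = []
    unexplained: list[float] = []
    for spectrum in peak.spectra:
        annotations, unexp = match_losses(
            spectrum.precursor_mz, spectrum.fragments, cfg.fragment_tol,
            cfg.max_loss_depth, cfg.losses)
        profile = infer_profile(annotations, unexp)
        per_record: dict[str, Candidate] = {}
        for assignment in assignments_for_signal(assignments, spectrum.precursor_mz):
            for record in candidates_by_mass(assignment.neutral_mass,
                                             cfg.precursor_tol, db, cfg.mass_scale):
                cand = _score_candidate(record, assignment, spectrum, peak, taxon,
                                        cfg, profile, lutein_diags)
                logger.debug("peak %s m/z %g: %s via %s -> score %.2f",
                             peak.peak_id, spectrum.precursor_mz, record.name,
                             assignment.species, cand.score)
                prev = per_record.get(record.name)
                if prev is None or (cand.score, -_abs_mass_err(cand, cfg)) > (
                        prev.score, -_abs_mass_err(prev, cfg)):
                    per_record[record.name] = cand
        if per_record:
            candidates.extend(per_record.values())
        else:
            unexplained.append(spectrum.precursor_mz)
            logger.debug("peak %s m/z %g: no candidate (unexplained)",
                         peak.peak_id, spectrum.precursor_mz)
    candidates.sort(key=lambda c: (-c.score, c.record.name))
    return Identification(peak.peak_id, candidates, unexplained)


def _abs_mass_err(cand: Candidate, cfg: IdentifyConfig) -> float:
    return abs(cand.record.mass(cfg.mass_scale) - cand.species.neutral_mass)


REPORT_COLUMNS = ("peak_id", "rt_min", "area_percent", "precursor_mz", "rank",
                  "compound", "score", "species", "evidence")


def annotate_dataset(dataset: Dataset, db: list[CarotenoidRecord],
                     taxon: str | None = None,
                     config: IdentifyConfig | None = None,
                     top_k: int = 3) -> pd.DataFrame:
    """Annotate every peak and lay the result out as a publishable table.

    One row per (peak, precursor, candidate rank), rows ordered by retention
    time; precursors with no candidate get a single "Unknown" row. The frame
    is TSV-serializable and byte-identical across runs on identical input.
    """
    taxon = dataset.source_taxon if taxon is None else taxon
    cfg = config or IdentifyConfig()
    rows = []
    for peak in sorted(dataset.peaks, key=lambda p: p.rt_min):
        ident = identify_peak(peak, db, taxon, cfg)
        for spectrum in peak.spectra:
            cands = [c for c in ident.candidates
                     if c.species.observed_mz == spectrum.precursor_mz]
            base = {
                "peak_id": peak.peak_id,
                "rt_min": f"{peak.rt_min:g}",
                "area_percent": f"{peak.area_percent:g}",
                "precursor_mz": f"{spectrum.precursor_mz:g}",
            }
            if not cands:
                rows.append({**base, "rank": 1, "compound": "Unknown", "score": "",
                             "species": "", "evidence": "no reference mass within "
                             f"{cfg.precursor_tol:g} Da under any species hypothesis"})
                continue
            for rank, cand in enumerate(cands[:top_k], start=1):
                rows.append({**base, "rank": rank, "compound": cand.record.name,
                             "score": f"{cand.score:.2f}",
                             "species": cand.species.species,
                             "evidence": " | ".join(
                                 f"{e.kind}({e.weight:g}): {e.note}"
                                 for e in cand.evidence)})
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def report_to_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
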