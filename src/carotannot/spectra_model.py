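"""Core containers for LC-MS/MS + DAD carotenoid data and readers/writers.

The pipeline works on unit-resolution ion-trap data, so m/z values are
Thomson at ~1 Da accuracy and are stored at full float precision while
printed at one decimal. Retention times are minutes throughout; MGF
RTINSECONDS is converted on read. Fragment relative intensities (percent of
base peak) are optional everywhere: most published tables omit them, and
absent intensities disable intensity-dependent rules downstream instead of
failing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: closed vocabulary for producer taxa / dataset sources
TAXA = frozenset({"bacteria", "cyanobacteria", "plant", "fungi", "unknown"})

#: slack allowed for a fragment m/z above its precursor (instrument jitter)
FRAGMENT_MZ_SLACK = 2.0


@dataclass(frozen=True)
class MzPeak:
    """One fragment signal: m/z plus optional relative intensity (% of base peak)."""

    mz: float
    rel_intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if self.rel_intensity is not None and not 0 <= self.rel_intensity <= 100:
            raise ValueError(
                f"relative intensity must be in [0, 100], got {self.rel_intensity}"
            )


@dataclass
class Ms2Spectrum:
    """A precursor with its MS2 fragment list (file order preserved)."""

    precursor_mz: float
    fragments: list[MzPeak] = field(default_factory=list)
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity}")
        for f in self.fragments:
            if f.mz >= self.precursor_mz + FRAGMENT_MZ_SLACK:
                raise ValueError(
                    f"fragment m/z {f.mz} exceeds precursor "
                    f"{self.precursor_mz} + {FRAGMENT_MZ_SLACK} Da slack"
                )

    @property
    def fragment_mzs(self) -> list[float]:
        return [f.mz for f in self.fragments]


@dataclass
class DadSpectrum:
    """Diode-array absorption spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.shape != self.absorbances.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbances must be 1-D and equal length")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbances)):
            raise ValueError("absorbances must be finite")

    def covers(self, low_nm: float, high_nm: float) -> bool:
        if self.wavelengths.size == 0:
            return False
        return self.wavelengths[0] <= low_nm and self.wavelengths[-1] >= high_nm


@dataclass
class ChromPeak:
    """A chromatographic peak: retention time, area share, co-eluting MS2 spectra.

    ``percent_iii_ii`` lets a curated fine-structure value ride along when the
    underlying DAD trace is unavailable (e.g. values read off published figure
    inserts); when both are present the explicit value wins downstream.
    """

    peak_id: str
    rt_min: float
    area_percent: float
    spectra: list[Ms2Spectrum]
    dad: DadSpectrum | None = None
    percent_iii_ii: float | None = None

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError(f"retention time must be >= 0, got {self.rt_min}")
        if not 0 <= self.area_percent <= 100:
            raise ValueError(f"area percent must be in [0, 100], got {self.area_percent}")
        if not self.spectra:
            raise ValueError(f"peak {self.peak_id!r} must carry at least one spectrum")

    @property
    def precursor_mzs(self) -> list[float]:
        return [s.precursor_mz for s in self.spectra]


@dataclass
class Dataset:
    """Ordered peaks plus the source organism class used by the producer filter."""

    peaks: list[ChromPeak]
    source_taxon: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_taxon not in TAXA:
            raise ValueError(
                f"source_taxon must be one of {sorted(TAXA)}, got {self.source_taxon!r}"
            )
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError("peak ids must be unique")
        total = sum(p.area_percent for p in self.peaks)
        if total > 100 + 0.5:
            raise ValueError(f"peak areas sum to {total:.2f} > 100.5%")

    def __len__(self) -> int:
        return len(self.peaks)

    def peak(self, peak_id: str) -> ChromPeak:
        for p in self.peaks:
            if p.peak_id == peak_id:
                return p
        raise KeyError(peak_id)


# ---------------------------------------------------------------------------
# MGF interchange
# ---------------------------------------------------------------------------

def _peak_id_from_title(title: str | None, fallback: str) -> str:
    """TITLE convention ``peak=<id>``; anything else becomes its own peak."""
    if title:
        for token in str(title).replace(";", " ").split():
            if token.startswith("peak="):
                return token[len("peak="):]
    return fallback


def read_mgf(path: str | Path, source_taxon: str = "unknown") -> Dataset:
    """Read an MGF file into a Dataset.

    Blocks sharing a ``TITLE peak=<id>`` label merge into one chromatographic
    peak; blocks lacking PEPMASS are skipped with a warning. An empty file
    yields an empty Dataset.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    order: list[str] = []
    n_blocks = 0
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for i, entry in enumerate(reader):
                n_blocks += 1
                params = entry.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None or pepmass[0] is None:
                    warnings.warn(f"{path.name}: block {i + 1} has no PEPMASS; skipped")
                    continue
                precursor = float(pepmass[0])
                mzs = np.asarray(entry.get("m/z array", []), dtype=float)
                intens = entry.get("intensity array")
                frags: list[MzPeak] = []
                base = float(np.max(intens)) if intens is not None and len(intens) else 0.0
                for j, mz in enumerate(mzs):
                    rel = None
                    if intens is not None and base > 0:
                        rel = 100.0 * float(intens[j]) / base
                    frags.append(MzPeak(float(mz), rel))
                pid = _peak_id_from_title(params.get("title"), fallback=f"spectrum_{i + 1}")
                rt_min = 0.0
                if "rtinseconds" in params:
                    rt_min = float(params["rtinseconds"]) / 60.0
                g = groups.setdefault(pid, {"rt": rt_min, "spectra": []})
                if pid not in order:
                    order.append(pid)
                if rt_min:
                    g["rt"] = rt_min
                g["spectra"].append(Ms2Spectrum(precursor, frags))
    except Exception as exc:  # pragma: no cover - exercised via malformed input test
        if isinstance(exc, (ValueError, KeyError)) and not isinstance(exc, FileNotFoundError):
            raise ValueError(f"malformed MGF block in {path}: {exc}") from exc
        raise
    if n_blocks == 0:
        warnings.warn(f"{path.name}: empty MGF, returning empty dataset")
    peaks = [
        ChromPeak(pid, groups[pid]["rt"], 0.0, groups[pid]["spectra"])
        for pid in order
        if groups[pid]["spectra"]
    ]
    peaks.sort(key=lambda p: p.rt_min)
    return Dataset(peaks, source_taxon=source_taxon)


def write_mgf(dataset: Dataset, path: str | Path) -> None:
    """Write every spectrum as one MGF block with the ``peak=<id>`` TITLE tag."""
    spectra = []
    for peak in dataset.peaks:
        for spec in peak.spectra:
            has_int = any(f.rel_intensity is not None for f in spec.fragments)
            entry = {
                "m/z array": np.array([f.mz for f in spec.fragments]),
                "intensity array": np.array(
                    [f.rel_intensity if f.rel_intensity is not None else 0.0
                     for f in spec.fragments]
                ) if has_int else np.zeros(len(spec.fragments)),
                "params": {
                    "title": f"peak={peak.peak_id}",
                    "pepmass": spec.precursor_mz,
                    "rtinseconds": peak.rt_min * 60.0,
                },
            }
            spectra.append(entry)
    _mgf.write(spectra, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# CSV peak table (mirrors the layout of a published identification table)
# ---------------------------------------------------------------------------

PEAK_TABLE_COLUMNS = ("peak_id", "rt_min", "area_percent", "precursor_mz", "fragments")


def _parse_fragment_tokens(cell: str, row: int) -> list[MzPeak]:
    frags: list[MzPeak] = []
    cell = "" if pd.isna(cell) else str(cell).strip()
    if not cell:
        return frags
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            if ":" in token:
                mz_s, int_s = token.split(":", 1)
                frags.append(MzPeak(float(mz_s), float(int_s)))
            else:
                frags.append(MzPeak(float(token), None))
        except ValueError as exc:
            raise ValueError(f"row {row}: bad fragment token {token!r}") from exc
    return frags


def _dedupe_fragments(frags: list[MzPeak], tol: float = 0.01) -> list[MzPeak]:
    out: list[MzPeak] = []
    for f in frags:
        dup = next((i for i, g in enumerate(out) if abs(g.mz - f.mz) <= tol), None)
        if dup is None:
            out.append(f)
        elif out[dup].rel_intensity is None and f.rel_intensity is not None:
            out[dup] = f
    return out


def read_peak_table(path: str | Path, source_taxon: str = "unknown") -> Dataset:
    """Read the CSV peak table; rows sharing peak_id merge into one peak.

    Duplicate (peak_id, precursor_mz) rows have their fragment lists unioned,
    de-duplicated by m/z within 0.01 Th. An optional ``percent_iii_ii`` column
    attaches a curated fine-structure value to a peak.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected header {list(PEAK_TABLE_COLUMNS)}"
        )
    peaks: dict[str, dict] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        pid = str(row["peak_id"]).strip()
        try:
            rt = float(row["rt_min"])
            area = float(row["area_percent"])
            prec = float(row["precursor_mz"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name} row {rownum}: non-numeric cell ({exc})") from exc
        frags = _parse_fragment_tokens(row.get("fragments", ""), rownum)
        fs = None
        if "percent_iii_ii" in df.columns and not pd.isna(row["percent_iii_ii"]):
            cell = str(row["percent_iii_ii"]).strip()
            if cell:
                fs = float(cell)
        g = peaks.setdefault(pid, {"rt": rt, "area": area, "spectra": {}, "sorder": [],
                                   "fs": fs})
        if pid not in order:
            order.append(pid)
        if fs is not None:
            g["fs"] = fs
        key = round(prec, 4)
        if key in g["spectra"]:
            g["spectra"][key] = _dedupe_fragments(g["spectra"][key] + frags)
        else:
            g["spectra"][key] = _dedupe_fragments(frags)
            g["sorder"].append(key)
    chrom = []
    for pid in order:
        g = peaks[pid]
        spectra = [Ms2Spectrum(prec, g["spectra"][prec]) for prec in g["sorder"]]
        chrom.append(ChromPeak(pid, g["rt"], g["area"], spectra,
                               percent_iii_ii=g["fs"]))
    chrom.sort(key=lambda p: p.rt_min)
    return Dataset(chrom, source_taxon=source_taxon)


def write_peak_table(dataset: Dataset, path: str | Path) -> None:
    """Companion writer; round-trips numeric fields at the precision written."""
    rows = []
    for peak in dataset.peaks:
        for spec in peak.spectra:
            tokens = []
            for f in spec.fragments:
                if f.rel_intensity is None:
                    tokens.append(f"{f.mz:g}")
                else:
                    tokens.append(f"{f.mz:g}:{f.rel_intensity:g}")
            rows.append({
                "peak_id": peak.peak_id,
                "rt_min": f"{peak.rt_min:g}",
                "area_percent": f"{peak.area_percent:g}",
                "precursor_mz": f"{spec.precursor_mz:g}",
                "fragments": ";".join(tokens),
                "percent_iii_ii": (
                    "" if peak.percent_iii_ii is None else f"{peak.percent_iii_ii:g}"
                ),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dad_csv(path: str | Path) -> DadSpectrum:
    """Read a DAD spectrum CSV with columns wavelength_nm, absorbance."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return DadSpectrum(df["wavelength_nm"].to_numpy(float),
                       df["absorbance"].to_numpy(float))


def write_dad_csv(spectrum: DadSpectrum, path: str | Path) -> None:
    pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths,
        "absorbance": spectrum.absorbances,
    }).to_csv(path, index=False)
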