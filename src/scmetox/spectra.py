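"""Peak-list I/O, candidate-to-spectrum matching, artifact flagging, ranking.

Spectra are one HRMS2 record per incubation analyte: a protonated precursor
with its fragment peaks.  Two plain-text formats are supported:

* **MGF** (standard ``BEGIN IONS``/``PEPMASS``/``END IONS`` dialect, read and
  written with :mod:`pyteomics.mgf`); analyte id and incubation label are
  carried in the ``TITLE`` line as ``analyte=<id> incubation=<label>``.
* **CSV** with header ``analyte_id, incubation, precursor_mz, rt_min,
  precursor_intensity, fragment_mz_list, fragment_intensity_list`` where the
  two list columns are ``;``-separated numbers.

Fragment intensities are stored relative to the base peak (0-100); precursor
intensities stay in arbitrary instrument units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .formula import mda_error, ppm_error
from .rules import MetaboliteCandidate

__all__ = [
    "SpectrumRecord",
    "PeakMatch",
    "PeakListError",
    "read_peaklists",
    "write_peaklists",
    "match_candidates",
    "flag_artifacts",
    "rank_abundance",
    "matches_to_frame",
]

CSV_COLUMNS = [
    "analyte_id",
    "incubation",
    "precursor_mz",
    "rt_min",
    "precursor_intensity",
    "fragment_mz_list",
    "fragment_intensity_list",
]

DEFAULT_TOL_MDA = 5.0


class PeakListError(ValueError):
    """Malformed peak-list file; message includes the location."""


@dataclass
class SpectrumRecord:
    """Precursor + fragment peaks of one incubation analyte."""

    analyte_id: str
    incubation: str
    precursor_mz: float
    rt_min: float = 0.0
    precursor_intensity: float = 0.0
    fragments: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        for mz, inten in self.fragments:
            if not (0.0 <= inten <= 100.0):
                raise ValueError(
                    f"fragment intensity {inten} outside [0, 100] at m/z {mz}"
                )

    @property
    def spectrum_id(self) -> str:
        return f"{self.analyte_id}/{self.incubation}"

    @classmethod
    def with_relative_fragments(
        cls,
        analyte_id: str,
        incubation: str,
        precursor_mz: float,
        fragment_mz: Sequence[float],
        fragment_intensity: Sequence[float],
        rt_min: float = 0.0,
        precursor_intensity: float = 0.0,
    ) -> "SpectrumRecord":
        """Build a record rescaling raw fragment intensities to base peak 100."""
        inten = np.asarray(fragment_intensity, dtype=float)
        if inten.size and inten.max() > 0:
            inten = np.clip(100.0 * inten / inten.max(), 0.0, 100.0)
        frags = sorted(zip((float(m) for m in fragment_mz), inten.tolist()))
        return cls(analyte_id, incubation, precursor_mz, rt_min,
                   precursor_intensity, frags)


@dataclass(frozen=True)
class PeakMatch:
    """One candidate explaining one spectrum's precursor within tolerance."""

    spectrum_id: str
    analyte_id: str
    incubation: str
    candidate_id: str
    error_mda: float
    error_ppm: float
    depth: int
    precursor_intensity: float = 0.0
    matched_fragments: int = 0


# -- I/O ----------------------------------------------------------------------

def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mgf":
        return "mgf"
    if ext == ".csv":
        return "csv"
    raise PeakListError(f"cannot infer peak-list format from {path!r}")


def _parse_title(title: str) -> Tuple[str, str]:
    fields = dict(
        part.split("=", 1) for part in title.split() if "=" in part
    )
    return fields.get("analyte", title or "unknown"), fields.get("incubation", "unknown")


def _check_mgf_blocks(path: str) -> None:
    depth = 0
    open_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if depth:
                    raise PeakListError(
                        f"{path}:{lineno}: nested BEGIN IONS (block from line "
                        f"{open_line} not closed)"
                    )
                depth, open_line = 1, lineno
            elif token == "END IONS":
                if not depth:
                    raise PeakListError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                depth = 0
    if depth:
        raise PeakListError(
            f"{path}: truncated MGF, BEGIN IONS at line {open_line} never closed"
        )


def read_peaklists(path: str, fmt: Optional[str] = None) -> List[SpectrumRecord]:
    """Read spectra from an MGF or CSV peak-list file."""
    kind = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if kind == "mgf":
        _check_mgf_blocks(path)
        records = []
        with _mgf.MGF(path) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                try:
                    pepmass = params["pepmass"]
                    precursor_mz = float(pepmass[0])
                    precursor_intensity = float(pepmass[1] or 0.0) if len(pepmass) > 1 else 0.0
                    analyte, incubation = _parse_title(str(params.get("title", "")))
                    rt = float(params.get("rtinseconds", 0.0)) / 60.0
                    records.append(
                        SpectrumRecord.with_relative_fragments(
                            analyte, incubation, precursor_mz,
                            entry["m/z array"], entry["intensity array"],
                            rt_min=rt, precursor_intensity=precursor_intensity,
                        )
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    raise PeakListError(f"{path}: malformed MGF entry {i + 1}: {exc}") from exc
        return records
    if kind == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise PeakListError(f"{path}: missing CSV columns {missing}")
        records = []
        for idx, row in frame.iterrows():
            lineno = idx + 2  # header is line 1
            try:
                frag_mz = [float(x) for x in row["fragment_mz_list"].split(";") if x]
                frag_in = [float(x) for x in row["fragment_intensity_list"].split(";") if x]
                if len(frag_mz) != len(frag_in):
                    raise ValueError("fragment m/z and intensity lists differ in length")
                records.append(
                    SpectrumRecord.with_relative_fragments(
                        row["analyte_id"], row["incubation"],
                        float(row["precursor_mz"]), frag_mz, frag_in,
                        rt_min=float(row["rt_min"] or 0.0),
                        precursor_intensity=float(row["precursor_intensity"] or 0.0),
                    )
                )
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: {exc}") from exc
        return records
    raise PeakListError(f"unsupported peak-list format {kind!r}")


def write_peaklists(records: Iterable[SpectrumRecord], path: str,
                    fmt: Optional[str] = None) -> None:
    """Write spectra to MGF or CSV, 4-decimal m/z (lossless round-trip)."""
    kind = _infer_format(path, fmt)
    records = list(records)
    if kind == "mgf":
        entries = [
            {
                "m/z array": np.round([mz for mz, _ in r.fragments], 4),
                "intensity array": np.round([i for _, i in r.fragments], 4),
                "params": {
                    "title": f"analyte={r.analyte_id} incubation={r.incubation}",
                    "pepmass": (round(r.precursor_mz, 4), round(r.precursor_intensity, 4)),
                    "rtinseconds": round(r.rt_min * 60.0, 4),
                    "charge": "1+",
                },
            }
            for r in records
        ]
        _mgf.write(entries, output=path, file_mode="w")
        return
    if kind == "csv":
        rows = [
            {
                "analyte_id": r.analyte_id,
                "incubation": r.incubation,
                "precursor_mz": round(r.precursor_mz, 4),
                "rt_min": round(r.rt_min, 4),
                "precursor_intensity": round(r.precursor_intensity, 4),
                "fragment_mz_list": ";".join(f"{mz:.4f}" for mz, _ in r.fragments),
                "fragment_intensity_list": ";".join(f"{i:.4f}" for _, i in r.fragments),
            }
            for r in records
        ]
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
        return
    raise PeakListError(f"unsupported peak-list format {kind!r}")


# -- matching -----------------------------------------------------------------

def match_candidates(
    spectra: Iterable[SpectrumRecord],
    candidates: Sequence[MetaboliteCandidate],
    tol_mda: float = DEFAULT_TOL_MDA,
) -> List[PeakMatch]:
    """Match each spectrum precursor against all candidate [M+H]+ values.

    Every candidate within ``tol_mda`` of a spectrum's precursor yields a
    match; per spectrum, matches are ranked by |mass error| then pathway
    depth, so the first match is the preferred identification.
    """
    if tol_mda <= 0:
        raise ValueError("tol_mda must be positive")
    out: List[PeakMatch] = []
    for spectrum in spectra:
        hits = []
        for cand in candidates:
            err = mda_error(spectrum.precursor_mz, cand.predicted_mz)
            if abs(err) <= tol_mda:
                hits.append(
                    PeakMatch(
                        spectrum_id=spectrum.spectrum_id,
                        analyte_id=spectrum.analyte_id,
                        incubation=spectrum.incubation,
                        candidate_id=cand.candidate_id,
                        error_mda=err,
                        error_ppm=ppm_error(spectrum.precursor_mz, cand.predicted_mz),
                        depth=cand.depth,
                        precursor_intensity=spectrum.precursor_intensity,
                    )
                )
        hits.sort(key=lambda m: (abs(m.error_mda), m.depth, m.candidate_id))
        out.extend(hits)
    return out


def flag_artifacts(
    treated: Iterable[SpectrumRecord],
    negative_controls: Iterable[SpectrumRecord],
    intensity_ratio_band: Tuple[float, float] = (0.5, 2.0),
    tol_mda: float = DEFAULT_TOL_MDA,
    rt_tol_min: Optional[float] = None,
) -> Set[str]:
    """Analytes present in negative controls at a treated-like intensity.

    A peak that appears in the negative control at an intensity within
    ``intensity_ratio_band`` (control/treated) of the treated incubation is
    most likely of artificial (non-enzymatic) origin.  The comparison is a
    ratio, so rescaling the intensity units of both sets leaves the flags
    unchanged.  ``rt_tol_min`` optionally requires the control peak to also
    co-elute (isobaric isomers are otherwise indistinguishable by exact
    mass alone); retention time is ignored by default.
    """
    lo, hi = intensity_ratio_band
    controls = list(negative_controls)
    flagged: Set[str] = set()
    for rec in treated:
        if rec.precursor_intensity <= 0:
            continue
        for ctl in controls:
            if abs(mda_error(ctl.precursor_mz, rec.precursor_mz)) > tol_mda:
                continue
            if rt_tol_min is not None and abs(ctl.rt_min - rec.rt_min) > rt_tol_min:
                continue
            ratio = ctl.precursor_intensity / rec.precursor_intensity
            if lo <= ratio <= hi:
                flagged.add(rec.analyte_id)
                break
    return flagged


def rank_abundance(
    matches: Iterable[PeakMatch],
    spectra: Iterable[SpectrumRecord],
    top_n: int,
) -> List[str]:
    """Matched analytes ordered by descending precursor intensity.

    Ties break deterministically by ascending precursor m/z, then id.
    ``top_n`` larger than the number of analytes returns all of them.
    """
    by_id: Dict[str, SpectrumRecord] = {}
    for rec in spectra:
        prev = by_id.get(rec.analyte_id)
        if prev is None or rec.precursor_intensity > prev.precursor_intensity:
            by_id[rec.analyte_id] = rec
    matched = {m.analyte_id for m in matches}
    ranked = sorted(
        (rec for aid, rec in by_id.items() if aid in matched),
        key=lambda r: (-r.precursor_intensity, r.precursor_mz, r.analyte_id),
    )
    return [r.analyte_id for r in ranked[: max(top_n, 0)]]


def matches_to_frame(matches: Iterable[PeakMatch]) -> pd.DataFrame:
    rows = [
        {
            "spectrum_id": m.spectrum_id,
            "analyte_id": m.analyte_id,
            "incubation": m.incubation,
            "candidate_id": m.candidate_id,
            "error_mda": round(m.error_mda, 4),
            "error_ppm": round(m.error_ppm, 2),
            "depth": m.depth,
            "precursor_intensity": m.precursor_intensity,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id", "analyte_id", "incubation", "candidate_id",
            "error_mda", "error_ppm", "depth", "precursor_intensity",
        ],
    )
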