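"""Compound annotation by exact mass (LC-MS) or spectral similarity (GC-MS).

LC-MS features carry an m/z value and are matched against library
monoisotopic masses within a ppm (or Dalton) tolerance, optionally after
applying adduct mass shifts and an RT gate.  GC-MS features carry a
centroided spectrum and are matched by cosine similarity of
square-root-intensity-weighted, unit-Dalton-binned spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import PeakTable

__all__ = [
    "CompoundLibrary",
    "AnnotationHit",
    "ADDUCTS",
    "read_compound_library",
    "match_by_mass",
    "match_by_spectrum",
    "spectral_similarity",
    "hits_to_frame",
]

PROTON = 1.007276466

#: default adduct mass shifts (observed m/z = M + shift), in Dalton
ADDUCTS: dict[str, float] = {
    "[M+H]+": PROTON,
    "[M-H]-": -PROTON,
    "[M+Na]+": 22.989218,
}


@dataclass
class LibraryEntry:
    compound_id: str
    name: str
    monoisotopic_mass: float
    rt: float | None = None
    spectrum: list[tuple[float, float]] | None = None


@dataclass
class CompoundLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.compound_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids in library: {dup}")
        for e in self.entries:
            if not e.monoisotopic_mass > 0:
                raise ValueError(
                    f"non-positive mass for {e.compound_id}: {e.monoisotopic_mass}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnnotationHit:
    variable_id: str
    compound_id: str
    name: str
    rank: int
    mz_error_ppm: float | None = None
    mz_error_da: float | None = None
    rt_error_s: float | None = None
    spectral_similarity: float | None = None
    adduct: str | None = None


def read_compound_library(path) -> CompoundLibrary:
    """Read a tab-delimited library: columns id, name, mass, rt, spectrum
    (``mz:int,mz:int,...``); rt and spectrum may be empty."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "name", "mass"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"library file lacks columns: {sorted(missing)}")
    entries = []
    for _, row in frame.iterrows():
        rt = float(row["rt"]) if row.get("rt", "").strip() else None
        spectrum = _parse_spectrum(row.get("spectrum", ""))
        entries.append(LibraryEntry(row["id"], row["name"], float(row["mass"]),
                                    rt, spectrum))
    return CompoundLibrary(entries)


def _parse_spectrum(text: str) -> list[tuple[float, float]] | None:
    text = text.strip()
    if not text:
        return None
    peaks = []
    for token in text.split(","):
        mz, intensity = token.split(":")
        peaks.append((float(mz), float(intensity)))
    return peaks


def match_by_mass(
    table: PeakTable,
    lib: CompoundLibrary,
    tol_ppm: float = 10.0,
    tol_da: float | None = None,
    rt_tol_s: float | None = None,
    top_n: int = 5,
    adducts: dict[str, float] | None = None,
) -> list[AnnotationHit]:
    """Match features to library compounds by exact mass.

    The ppm error convention is (observed - reference) / reference * 1e6.
    Candidates within the tolerance (|ppm| <= tol_ppm, or |Da| <= tol_da
    when given) and, when both RTs exist, |RT error| < rt_tol_s, are ranked
    by |ppm error| ascending with ties broken by |RT error| then compound
    id.  Up to ``top_n`` candidates are reported per feature; rank 1 is the
    best hit.  Neutral masses are shifted by each adduct before comparison;
    pass ``adducts={}`` for no shift (direct neutral-mass matching).
    """
    mz = table.mz()
    if mz is None:
        raise ValueError("peak table has no m/z metadata; cannot mass-match")
    rt = table.rt()
    shifts = ADDUCTS if adducts is None else adducts
    if not shifts:
        shifts = {"M": 0.0}
    hits: list[AnnotationHit] = []
    for var in table.variable_ids:
        q_mz = mz.get(var)
        if q_mz is None or not np.isfinite(q_mz):
            continue
        q_rt = rt.get(var) if rt is not None else None
        candidates = []
        for entry in lib.entries:
            for adduct_name, shift in shifts.items():
                ref = entry.monoisotopic_mass + shift
                err_da = q_mz - ref
                err_ppm = err_da / ref * 1e6
                if tol_da is not None:
                    if abs(err_da) > tol_da:
                        continue
                elif abs(err_ppm) > tol_ppm:
                    continue
                rt_err = None
                if (rt_tol_s is not None and q_rt is not None
                        and np.isfinite(q_rt) and entry.rt is not None):
                    rt_err = q_rt - entry.rt
                    if abs(rt_err) >= rt_tol_s:
                        continue
                candidates.append((entry, adduct_name, err_ppm, err_da, rt_err))
        candidates.sort(key=lambda c: (abs(c[2]),
                                       abs(c[4]) if c[4] is not None else 0.0,
                                       c[0].compound_id))
        for rank, (entry, adduct_name, err_ppm, err_da, rt_err) in enumerate(
                candidates[:top_n], start=1):
            hits.append(AnnotationHit(
                variable_id=var, compound_id=entry.compound_id, name=entry.name,
                rank=rank, mz_error_ppm=err_ppm, mz_error_da=err_da,
                rt_error_s=rt_err,
                adduct=None if adduct_name == "M" else adduct_name))
    return hits


def spectral_similarity(
    spec_a: list[tuple[float, float]],
    spec_b: list[tuple[float, float]],
    bin_width: float = 1.0,
) -> float:
    """Cosine similarity of sqrt-intensity-weighted, binned spectra.

    Peaks are binned to the nearest integer multiple of ``bin_width``
    (unit-mass GC-MS convention for the default) and intensities within a
    bin summed before the square root.
    """
    va = _binned_vector(spec_a, bin_width)
    vb = _binned_vector(spec_b, bin_width)
    common = set(va) | set(vb)
    a = np.array([va.get(b, 0.0) for b in common])
    b = np.array([vb.get(b, 0.0) for b in common])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _binned_vector(spectrum, bin_width: float) -> dict[int, float]:
    bins: dict[int, float] = {}
    for mz, intensity in spectrum:
        key = int(round(mz / bin_width))
        bins[key] = bins.get(key, 0.0) + max(intensity, 0.0)
    return {k: np.sqrt(v) for k, v in bins.items()}


def match_by_spectrum(
    spectra: dict[str, list[tuple[float, float]]],
    lib: CompoundLibrary,
    min_similarity: float = 0.7,
    rt_tol: float = 0.3,
    rts: dict[str, float] | None = None,
    bin_width: float = 1.0,
    top_n: int = 5,
) -> list[AnnotationHit]:
    """Match centroided feature spectra to library spectra.

    Candidates require similarity strictly greater than ``min_similarity``
    and, when both RTs are known, |RT difference| strictly less than
    ``rt_tol`` (minutes).  Ranking is by similarity descending, ties broken
    by compound id.
    """
    if not spectra:
        raise ValueError("no feature spectra supplied")
    lib_entries = [e for e in lib.entries if e.spectrum]
    if not lib_entries:
        raise ValueError("library has no spectra")
    hits: list[AnnotationHit] = []
    for var, spec in spectra.items():
        if not spec:
            raise ValueError(f"feature {var!r} has an empty spectrum")
        q_rt = rts.get(var) if rts else None
        candidates = []
        for entry in lib_entries:
            sim = spectral_similarity(spec, entry.spectrum, bin_width)
            if sim <= min_similarity:
                continue
            rt_err = None
            if q_rt is not None and entry.rt is not None:
                rt_err = q_rt - entry.rt
                if abs(rt_err) >= rt_tol:
                    continue
            candidates.append((entry, sim, rt_err))
        candidates.sort(key=lambda c: (-c[1], c[0].compound_id))
        for rank, (entry, sim, rt_err) in enumerate(candidates[:top_n], start=1):
            hits.append(AnnotationHit(
                variable_id=var, compound_id=entry.compound_id, name=entry.name,
                rank=rank, spectral_similarity=sim, rt_error_s=rt_err))
    return hits


def hits_to_frame(hits: list[AnnotationHit], best_only: bool = False
                  ) -> pd.DataFrame:
    """Annotation hits as a result table (rank-1 rows only if ``best_only``)."""
    rows = [h.__dict__ for h in hits if not best_only or h.rank == 1]
    frame = pd.DataFrame(rows, columns=[
        "variable_id", "compound_id", "name", "rank", "mz_error_ppm",
        "mz_error_da", "rt_error_s", "spectral_similarity", "adduct"])
    return frame.set_index("variable_id") if len(frame) else frame
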