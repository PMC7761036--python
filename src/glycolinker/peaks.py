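"""GC-MS PMAA peak tables, reference spectrum libraries and linkage assignment.

Peaks from a total-ion-current chromatogram are identified by comparing
their EI fragmentation spectra and retention times against a library of
standards: the similarity is a cosine over greedily paired peak
intensities, and the top hit is assigned only when it clears a similarity
threshold and (when the library entry provides one) a retention window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .linkage import LinkageCode

Spectrum = list[tuple[float, float]]  # (m/z, relative intensity), m/z increasing


@dataclass
class PeakRecord:
    """One chromatographic peak, optionally carrying a centroided spectrum."""

    peak_id: str
    retention_time: float  # minutes
    area: float  # arbitrary detector units, >= 0
    spectrum: Spectrum | None = None
    assigned_linkage: LinkageCode | None = None
    match_score: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError(f"peak {self.peak_id!r}: area must be >= 0, got {self.area}")
        if self.spectrum is not None:
            _validate_spectrum(self.spectrum, context=f"peak {self.peak_id!r}")


def _validate_spectrum(spectrum: Spectrum, context: str = "spectrum") -> None:
    if any(i < 0 for _, i in spectrum):
        raise ValidationError(f"{context}: intensities must be >= 0")
    mzs = [mz for mz, _ in spectrum]
    if any(b <= a for a, b in zip(mzs, mzs[1:])):
        raise ValidationError(f"{context}: m/z values must be strictly increasing")


def parse_spectrum_cell(text: str) -> Spectrum:
    """Parse the ``mz:intensity;mz:intensity`` cell syntax."""
    pairs = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            mz, inten = token.split(":")
            pairs.append((float(mz), float(inten)))
        except ValueError as exc:
            raise FormatError(f"bad spectrum token {token!r}") from exc
    return pairs


def format_spectrum_cell(spectrum: Spectrum) -> str:
    return ";".join(f"{mz:g}:{i:g}" for mz, i in spectrum)


#: Default column names of the peak-table dialect.
DEFAULT_DIALECT = {
    "peak_id": "peak_id",
    "rt": "rt_min",
    "area": "area",
    "spectrum": "spectrum",
    "linkage": "linkage",
}


def parse_peak_table(path: str | Path, dialect: dict[str, str] | None = None) -> list[PeakRecord]:
    """Read a CSV/TSV peak table into :class:`PeakRecord` rows, order preserved.

    Required columns: id, retention time, area.  Optional: a spectrum column
    (``mz:int;mz:int`` cells) and a pre-assigned linkage column.
    """
    path = Path(path)
    cols = dict(DEFAULT_DIALECT, **(dialect or {}))
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    for key in ("peak_id", "rt", "area"):
        if cols[key] not in df.columns:
            raise FormatError(f"{path.name}: missing required column {cols[key]!r}")
    records: list[PeakRecord] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        area = float(row[cols["area"]])
        if area < 0:
            raise ValidationError(f"{path.name} row {row_number}: negative area {area}")
        spectrum = None
        if cols["spectrum"] in df.columns and row[cols["spectrum"]]:
            spectrum = parse_spectrum_cell(row[cols["spectrum"]])
        linkage = None
        if cols["linkage"] in df.columns and row[cols["linkage"]]:
            linkage = LinkageCode.parse(row[cols["linkage"]])
        records.append(
            PeakRecord(
                peak_id=str(row[cols["peak_id"]]),
                retention_time=float(row[cols["rt"]]),
                area=area,
                spectrum=spectrum,
                assigned_linkage=linkage,
            )
        )
    return records


def write_peak_table(records: list[PeakRecord], path: str | Path) -> None:
    """Inverse of :func:`parse_peak_table` (round-trips records losslessly)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "peak_id": r.peak_id,
                "rt_min": r.retention_time,
                "area": r.area,
                "spectrum": format_spectrum_cell(r.spectrum) if r.spectrum else "",
                "linkage": str(r.assigned_linkage) if r.assigned_linkage else "",
            }
        )
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class LibraryEntry:
    """A reference PMAA standard: linkage, spectrum, optional retention window."""

    linkage: LinkageCode
    spectrum: tuple[tuple[float, float], ...]
    retention_time: float | None = None
    retention_window: float | None = None  # +/- minutes around retention_time

    def rt_matches(self, rt: float) -> bool:
        if self.retention_time is None or self.retention_window is None:
            return True
        return abs(rt - self.retention_time) <= self.retention_window


def load_library(path: str | Path) -> list[LibraryEntry]:
    """Load a spectrum library from MSP-style text or a JSON array.

    MSP blocks::

        NAME: 4-Glcp
        RT: 21.4
        RTWIN: 0.3
        Num Peaks: 2
        118 100
        233 45

    JSON: ``[{"linkage": "4-Glcp", "spectrum": [[118, 100], [233, 45]],
    "rt": 21.4, "rt_window": 0.3}, ...]``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        entries = []
        for obj in json.loads(text):
            entries.append(
                LibraryEntry(
                    linkage=LinkageCode.parse(obj["linkage"]),
                    spectrum=tuple((float(m), float(i)) for m, i in obj["spectrum"]),
                    retention_time=obj.get("rt"),
                    retention_window=obj.get("rt_window"),
                )
            )
        return entries
    return _parse_msp(text)


def _parse_msp(text: str) -> list[LibraryEntry]:
    entries: list[LibraryEntry] = []
    name = rt = rtwin = None
    peaks: Spectrum = []
    expecting = 0

    def flush() -> None:
        nonlocal name, rt, rtwin, peaks
        if name is not None:
            _validate_spectrum(peaks, context=f"library entry {name!r}")
            entries.append(
                LibraryEntry(LinkageCode.parse(name), tuple(peaks), rt, rtwin)
            )
        name = rt = rtwin = None
        peaks = []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("NAME:"):
            flush()
            name = line.split(":", 1)[1].strip()
        elif upper.startswith("RTWIN:"):
            rtwin = float(line.split(":", 1)[1])
        elif upper.startswith("RT:"):
            rt = float(line.split(":", 1)[1])
        elif upper.startswith("NUM PEAKS:"):
            expecting = int(line.split(":", 1)[1])
        else:
            parts = line.replace(",", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    flush()
    del expecting
    return entries


def cosine_similarity(
    query: Spectrum, reference: Spectrum, mz_tolerance: float = 0.5
) -> float:
    """Cosine similarity with greedy nearest-peak pairing within ``mz_tolerance``.

    Candidate pairs are ranked by m/z distance; each query/reference peak is
    used at most once.  Norms run over *all* peaks, so unmatched intensity
    lowers the score.  Identical spectra score 1.0; spectra sharing no m/z
    within tolerance score 0.0.
    """
    if mz_tolerance <= 0:
        raise ValidationError("mz_tolerance must be > 0")
    candidates = []
    for qi, (qmz, qint) in enumerate(query):
        for ri, (rmz, rint) in enumerate(reference):
            d = abs(qmz - rmz)
            if d <= mz_tolerance:
                candidates.append((d, qi, ri, qint * rint))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_q: set[int] = set()
    used_r: set[int] = set()
    dot = 0.0
    for _, qi, ri, prod in candidates:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        dot += prod
    qnorm = sum(i * i for _, i in query) ** 0.5
    rnorm = sum(i * i for _, i in reference) ** 0.5
    if qnorm == 0 or rnorm == 0:
        return 0.0
    return dot / (qnorm * rnorm)


def match_spectrum(
    query: Spectrum,
    library: list[LibraryEntry],
    mz_tolerance: float = 0.5,
) -> list[tuple[LinkageCode, float]]:
    """Rank library linkages by spectral similarity to ``query``.

    Descending by similarity; ties broken by canonical linkage string.
    """
    if not query:
        raise ValidationError("query spectrum is empty")
    if not library:
        raise ValidationError("spectrum library is empty")
    _validate_spectrum(query, context="query")
    scored = [
        (entry.linkage, cosine_similarity(query, list(entry.spectrum), mz_tolerance))
        for entry in library
    ]
    scored.sort(key=lambda t: (-t[1], str(t[0])))
    return scored


def assign_peaks(
    peaks: list[PeakRecord],
    library: list[LibraryEntry],
    mz_tolerance: float = 0.5,
    threshold: float = 0.7,
) -> list[PeakRecord]:
    """Assign each peak's best library match when it clears the gates.

    The top hit is accepted only if similarity >= ``threshold`` and the
    peak's retention time falls inside the library entry's retention window
    (when the entry defines one).  Peaks without spectra, or whose top hit
    fails a gate, are returned unassigned.  Input records are not mutated.
    """
    by_linkage = {entry.linkage: entry for entry in library}
    out = []
    for peak in peaks:
        if peak.spectrum is None or peak.assigned_linkage is not None:
            out.append(replace(peak))
            continue
        assigned = None
        score = None
        for linkage, sim in match_spectrum(peak.spectrum, library, mz_tolerance):
            if sim < threshold:
                break
            if by_linkage[linkage].rt_matches(peak.retention_time):
                assigned, score = linkage, sim
                break
        out.append(replace(peak, assigned_linkage=assigned, match_score=score))
    return out
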