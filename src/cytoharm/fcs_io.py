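"""Reading and writing flow cytometry standard files (FCS 2.0/3.0/3.1 and LMD).

The central container is :class:`EventMatrix`: an events x channels matrix of
*linear-scale* intensities plus acquisition metadata. Whatever amplification was
used on disk (log-amplified integer channels with ``$PnE = "d,f"``), values are
linearized at read time, so downstream code never sees display scales.

Beckman Coulter LMD files store two concatenated datasets (an FCS 2.0 segment
followed by an FCS 3.0 segment with the full-resolution data). All byte offsets
in a segment's HEADER and TEXT — including ``$NEXTDATA`` — are interpreted
relative to the start of that segment, and by default the *last* segment is
returned.

CSV round-tripping of the cohort feature table lives here too
(:func:`read_table` / :func:`write_table`) because it is the other on-disk
artifact of the workflow.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguousDateError,
    ChannelMappingError,
    CytoharmError,
    EmptyFCSError,
    FCSFormatError,
    FCSMetadataError,
)

_FCS_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")

_MONTHS = {m: i + 1 for i, m in enumerate(
    ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
     "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"])}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EventMatrix:
    """Events x channels of linear-scale intensities with acquisition metadata.

    Parameters
    ----------
    values : ndarray of shape (n_events, n_channels)
        Linear-scale intensities. Raw data is >= 0; compensated data may dip
        below zero and is deliberately not clipped.
    channel_names : list of str
        One unique name per column.
    meta : dict
        Free-form acquisition metadata. Recognized keys: ``instrument_id``,
        ``center_id``, ``acquisition_date`` (ISO string or ``datetime.date``),
        ``panel_id`` (``panel1`` / ``panel2`` / ``beads``), ``sample_id``,
        ``vendor`` (``BC`` / ``BD``), ``keywords`` (raw FCS TEXT keywords).
    """

    values: np.ndarray
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CytoharmError("values must be 2-D (events x channels)")
        self.channel_names = list(self.channel_names)
        if self.values.shape[1] != len(self.channel_names):
            raise CytoharmError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.channel_names)} channel names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise CytoharmError(f"duplicate channel names: {self.channel_names}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.channel_names.index(name)]
        except ValueError:
            raise CytoharmError(f"no channel named {name!r}; "
                                f"have {self.channel_names}") from None

    def with_values(self, values: np.ndarray) -> "EventMatrix":
        """Copy carrying new values but the same channels/metadata."""
        return EventMatrix(np.asarray(values, dtype=float),
                           list(self.channel_names), dict(self.meta))

    def copy(self) -> "EventMatrix":
        return self.with_values(self.values.copy())


@dataclass(frozen=True)
class ChannelMap:
    """Detector-name patterns -> canonical channel names for one panel.

    ``entries`` maps regular-expression patterns (matched case-insensitively
    against the full detector name) to canonical names. ``canonical_order``
    fixes the column order every standardized matrix uses, which is what makes
    matrices from Beckman and BD instruments column-compatible.
    """

    panel_id: str
    entries: dict[str, str]
    canonical_order: tuple[str, ...]
    scatter_channels: frozenset = frozenset({"FSC", "SSC"})

    def match(self, detector: str) -> str | None:
        """Canonical name for a detector, or None if nothing matches."""
        if detector in self.canonical_order:
            return detector
        hits = {canon for pat, canon in self.entries.items()
                if re.fullmatch(pat, detector, flags=re.IGNORECASE)}
        if len(hits) == 1:
            return hits.pop()
        if len(hits) > 1:
            raise ChannelMappingError(
                f"detector {detector!r} matches several canonical names: "
                f"{sorted(hits)}")
        return None


# ---------------------------------------------------------------------------
# date handling
# ---------------------------------------------------------------------------

def parse_fcs_date(text: str) -> _dt.date:
    """Parse a $DATE keyword; ISO (2015-03-04) and DD-MON-YYYY (04-MAR-2015).

    Purely numeric day/month forms are rejected rather than guessed: a file
    dated "03-04-2015" is ambiguous between vendors and picking a convention
    silently corrupts the batch assignment downstream.
    """
    text = text.strip()
    m = re.fullmatch(r"(\d{4})-(\d{2})-(\d{2})", text)
    if m:
        return _dt.date(int(m[1]), int(m[2]), int(m[3]))
    m = re.fullmatch(r"(\d{1,2})-([A-Za-z]{3})-(\d{4})", text)
    if m and m[2].upper() in _MONTHS:
        return _dt.date(int(m[3]), _MONTHS[m[2].upper()], int(m[1]))
    raise AmbiguousDateError(f"cannot parse acquisition date {text!r} "
                             "unambiguously")


def _coerce_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return parse_fcs_date(str(value))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty (leading delimiter); trailing delimiter leaves an
    # empty tail. Doubled-delimiter escaping is not produced by this writer
    # and not supported.
    items = [p for p in parts[1:]]
    if items and items[-1] == "":
        items = items[:-1]
    kw = {}
    for i in range(0, len(items) - 1, 2):
        kw[items[i].strip().upper()] = items[i + 1]
    return kw


def _infer_vendor(keywords: dict[str, str]) -> str | None:
    explicit = keywords.get("CYTOHARM_VENDOR")
    if explicit in ("BC", "BD"):
        return explicit
    cyt = keywords.get("$CYT", "").upper()
    if any(s in cyt for s in ("NAVIOS", "GALLIOS", "CYTOFLEX", "FC500")):
        return "BC"
    if any(s in cyt for s in ("CANTO", "FORTESSA", "VERSE", "ARIA", "LSR",
                              "FACS")):
        return "BD"
    return None


def _read_dataset(buf: bytes, offset: int) -> tuple[EventMatrix, int]:
    """Read one dataset starting at ``offset``; return (matrix, next_offset).

    ``next_offset`` is absolute (0 means no further dataset). All offsets
    inside the segment are relative to ``offset``.
    """
    header = buf[offset:offset + 58]
    if len(header) < 58:
        raise FCSFormatError("file too short for an FCS header")
    version = header[0:6].decode("latin-1", errors="replace")
    if version not in _FCS_VERSIONS:
        raise FCSFormatError(f"not an FCS file (header {version!r})")

    def _hdr(i):
        fieldtxt = header[10 + 8 * i:18 + 8 * i].decode("latin-1").strip()
        return int(fieldtxt) if fieldtxt else 0

    text_beg, text_end = _hdr(0), _hdr(1)
    data_beg, data_end = _hdr(2), _hdr(3)
    kw = _parse_text_segment(buf[offset + text_beg:offset + text_end + 1])

    for required in ("$PAR", "$TOT"):
        if required not in kw:
            raise FCSMetadataError(f"missing required keyword {required}")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if n_tot == 0:
        raise EmptyFCSError("file contains zero events")

    if "$BEGINDATA" in kw and int(kw["$BEGINDATA"]) > 0:
        data_beg = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])

    names = []
    for i in range(1, n_par + 1):
        if f"$P{i}N" not in kw:
            raise FCSMetadataError(f"missing required keyword $P{i}N")
        names.append(kw[f"$P{i}N"])

    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    raw = buf[offset + data_beg:offset + data_end + 1]

    if datatype == "F":
        arr = np.frombuffer(raw, dtype=f"{endian}f4", count=n_tot * n_par)
        values = arr.reshape(n_tot, n_par).astype(float)
    elif datatype == "I":
        bits = {int(kw.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FCSMetadataError("only uniform 16/32-bit integer data "
                                   "is supported")
        width = int(kw.get("$P1B", 32)) // 8
        arr = np.frombuffer(raw, dtype=f"{endian}u{width}",
                            count=n_tot * n_par)
        values = arr.reshape(n_tot, n_par).astype(float)
    else:
        raise FCSMetadataError(f"unsupported $DATATYPE {datatype!r}")

    # Linearize log-amplified channels: stored v with $PnE="d,f" and range R
    # maps to f * 10^(d * v / R); f = 0 is treated as 1 per the standard.
    for i in range(1, n_par + 1):
        pne = kw.get(f"$P{i}E", "0,0")
        try:
            decades, f1 = (float(x) for x in pne.split(","))
        except ValueError:
            raise FCSMetadataError(f"unparseable $P{i}E = {pne!r}") from None
        if decades > 0:
            rng = float(kw.get(f"$P{i}R", 1024))
            f1 = f1 if f1 > 0 else 1.0
            values[:, i - 1] = f1 * 10.0 ** (decades * values[:, i - 1] / rng)

    meta: dict = {"keywords": kw, "fcs_version": version}
    if "$DATE" in kw:
        meta["acquisition_date"] = parse_fcs_date(kw["$DATE"])
    for src, dst in (("CYTOHARM_INSTRUMENT", "instrument_id"),
                     ("CYTOHARM_CENTER", "center_id"),
                     ("CYTOHARM_PANEL", "panel_id"),
                     ("CYTOHARM_SAMPLE", "sample_id"),
                     ("CYTOHARM_GROUP", "group")):
        if src in kw:
            meta[dst] = kw[src]
    if "instrument_id" not in meta and "$CYT" in kw:
        meta["instrument_id"] = kw["$CYT"]
    vendor = _infer_vendor(kw)
    if vendor:
        meta["vendor"] = vendor

    nxt = int(kw.get("$NEXTDATA", 0) or 0)
    return EventMatrix(values, names, meta), (offset + nxt if nxt else 0)


def read_fcs(path, dataset: str | int = "last") -> EventMatrix:
    """Read an FCS or LMD file into an :class:`EventMatrix`.

    Parameters
    ----------
    path : path-like
        File starting with an ``FCS2.0`` / ``FCS3.0`` / ``FCS3.1`` header.
    dataset : "last", "first" or int
        Which dataset to return when the file holds several (LMD). The
        default "last" returns the FCS 3.0 segment of an LMD file, which
        carries the full-resolution Beckman data.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    matrices = []
    offset = 0
    seen = set()
    while True:
        em, nxt = _read_dataset(buf, offset)
        matrices.append(em)
        if nxt == 0 or nxt in seen or nxt >= len(buf):
            break
        seen.add(nxt)
        offset = nxt
    if len(matrices) > 1:
        # dual-dataset container -> Beckman LMD dialect
        for em in matrices:
            em.meta.setdefault("vendor", "BC")
    if dataset == "last":
        return matrices[-1]
    if dataset == "first":
        return matrices[0]
    return matrices[int(dataset)]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_keyword_value(v) -> str:
    s = str(v)
    return s.replace("/", "_") or " "


def _build_dataset(em: EventMatrix, version: str = "FCS3.1",
                   datatype: str = "F", pne: list[str] | None = None,
                   next_data: int = 0) -> bytes:
    n_tot, n_par = em.values.shape
    if datatype == "F":
        data = em.values.astype("<f4").tobytes()
    elif datatype == "I":
        data = np.round(em.values).astype("<u4").tobytes()
    else:  # pragma: no cover - guarded by callers
        raise CytoharmError(f"unsupported datatype {datatype!r}")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": "00000000", "$ENDDATA": "00000000",
        "$NEXTDATA": f"{next_data:08d}",
        "$MODE": "L", "$DATATYPE": datatype, "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(em.channel_names, start=1):
        col = em.values[:, i - 1]
        kw[f"$P{i}N"] = _format_keyword_value(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = pne[i - 1] if pne else "0,0"
        kw[f"$P{i}R"] = str(int(max(1024, np.ceil(col.max() + 1)))
                            if n_tot else 1024)

    meta = em.meta
    if meta.get("acquisition_date"):
        kw["$DATE"] = _coerce_date(meta["acquisition_date"]).isoformat()
    if meta.get("instrument_id"):
        kw["$CYT"] = _format_keyword_value(meta["instrument_id"])
        kw["CYTOHARM_INSTRUMENT"] = _format_keyword_value(meta["instrument_id"])
    for dst, src in (("CYTOHARM_CENTER", "center_id"),
                     ("CYTOHARM_PANEL", "panel_id"),
                     ("CYTOHARM_SAMPLE", "sample_id"),
                     ("CYTOHARM_GROUP", "group"),
                     ("CYTOHARM_VENDOR", "vendor")):
        if meta.get(src):
            kw[dst] = _format_keyword_value(meta[src])
    spill = meta.get("keywords", {}).get("$SPILLOVER")
    if spill:
        kw["$SPILLOVER"] = spill

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw.items()) + delim
    text_beg = 58
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_end = data_beg + len(data) - 1
    text = text.replace(f"$BEGINDATA{delim}00000000",
                        f"$BEGINDATA{delim}{data_beg:08d}")
    text = text.replace(f"$ENDDATA{delim}00000000",
                        f"$ENDDATA{delim}{data_end:08d}")

    header = (version.ljust(10)
              + f"{text_beg:8d}{text_end:8d}{data_beg:8d}{data_end:8d}"
              + f"{0:8d}{0:8d}")
    out = header.encode("latin-1") + text.encode("latin-1") + data
    if next_data:
        # next_data was declared as the byte length of this dataset; verify.
        assert next_data == len(out), "internal offset bookkeeping error"
    return out


def write_fcs(em: EventMatrix, path, version: str = "FCS3.1",
              datatype: str = "F", pne: list[str] | None = None) -> None:
    """Write an :class:`EventMatrix` as a single-dataset FCS file.

    Float32 storage by default; ``datatype="I"`` with per-channel ``pne``
    strings writes raw integer channels (used to exercise log linearization).
    """
    if em.n_events == 0:
        raise EmptyFCSError("refusing to write a zero-event FCS file")
    with open(path, "wb") as fh:
        fh.write(_build_dataset(em, version=version, datatype=datatype,
                                pne=pne))


def write_lmd(segments: list[EventMatrix], path) -> None:
    """Write a multi-dataset LMD-style container.

    The first segment is labelled FCS2.0 and subsequent ones FCS3.0,
    mirroring Beckman's layout; each segment's ``$NEXTDATA`` holds the byte
    length of the segment (offset from its own start to the next segment).
    """
    if not segments:
        raise CytoharmError("need at least one segment")
    blobs = []
    for i, em in enumerate(segments):
        version = "FCS2.0" if i == 0 else "FCS3.0"
        last = i == len(segments) - 1
        # two passes: sizes are stable because $NEXTDATA is fixed-width
        blob = _build_dataset(em, version=version, next_data=0)
        if not last:
            blob = _build_dataset(em, version=version, next_data=len(blob))
        blobs.append(blob)
    with open(path, "wb") as fh:
        for blob in blobs:
            fh.write(blob)


# ---------------------------------------------------------------------------
# channel standardization
# ---------------------------------------------------------------------------

def standardize_channels(em: EventMatrix, cmap: ChannelMap) -> EventMatrix:
    """Rename detectors to canonical marker names and fix the column order.

    Every fluorescence channel must match exactly one map pattern; unmatched
    detectors are reported together in a :class:`ChannelMappingError` so a
    mis-labelled file can be fixed rather than excluded. Channels such as TIME
    that map to nothing and are not in the canonical order are dropped.
    Idempotent: standardizing an already-canonical matrix is the identity.
    """
    resolved: dict[str, int] = {}
    unmatched = []
    for idx, name in enumerate(em.channel_names):
        canon = cmap.match(name)
        if canon is None:
            if re.fullmatch(r"time(\s.*)?", name, flags=re.IGNORECASE):
                continue  # acquisition clock, not a detector
            unmatched.append(name)
            continue
        if canon in resolved:
            raise ChannelMappingError(
                f"two detectors map to {canon!r}: "
                f"{em.channel_names[resolved[canon]]!r} and {name!r}")
        resolved[canon] = idx
    if unmatched:
        raise ChannelMappingError(
            f"unmapped detector name(s) {unmatched} for panel "
            f"{cmap.panel_id!r}")
    missing = [c for c in cmap.canonical_order if c not in resolved]
    if missing:
        raise ChannelMappingError(
            f"panel {cmap.panel_id!r} channels absent from file: {missing}")
    order = [resolved[c] for c in cmap.canonical_order]
    out = EventMatrix(em.values[:, order], list(cmap.canonical_order),
                      dict(em.meta))
    out.meta["panel_id"] = em.meta.get("panel_id", cmap.panel_id)
    return out


# ---------------------------------------------------------------------------
# cohort table CSV
# ---------------------------------------------------------------------------

#: columns every cohort table carries ahead of its feature columns
META_COLUMNS = ("sample_id", "center_id", "instrument_id",
                "acquisition_date", "batch_id", "group", "panel_id")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a cohort feature table to CSV (header row, no index)."""
    if table.shape[0] == 0:
        raise CytoharmError("refusing to write an empty cohort table")
    out = table.copy()
    corrections = table.attrs.get("corrections")
    with open(path, "w") as fh:
        if corrections:
            fh.write(f"#corrections={','.join(corrections)}\n")
        out.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a cohort feature table written by :func:`write_table`."""
    corrections: list[str] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#corrections="):
            corrections = first.strip().split("=", 1)[1].split(",")
        else:
            fh.seek(0)
        table = pd.read_csv(fh)
    if "acquisition_date" in table.columns:
        table["acquisition_date"] = pd.to_datetime(
            table["acquisition_date"]).dt.date
    table.attrs["corrections"] = corrections
    return table
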