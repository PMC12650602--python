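"""Reading and writing MIT-BIH-style WFDB records and beat annotations.

Implements the subset of the WFDB family the arrhythmia pipeline needs:
``.hea`` headers, ``.dat`` signal files in format 212 (two 12-bit two's
complement samples packed into three bytes), and ``.atr`` annotation files in
the MIT annotation format.  Lead selection prefers the modified limb lead II
(MLII), the conventional upper channel of the MIT-BIH recordings; records
without an MLII channel fall back to their first channel with a provenance
warning rather than being dropped.

Beat annotation symbols are merged into the five AAMI heartbeat classes:

====== ==========================================================
class  MIT-BIH symbols
====== ==========================================================
N      N, L, R, e, j   (normal, bundle-branch block, escape beats)
S      A, a, J, S      (supraventricular ectopic beats)
V      V, E            (ventricular ectopic beats)
F      F               (fusion of ventricular and normal)
Q      Q, ?, /, f      (unknown, unclassifiable and paced beats)
====== ==========================================================

Every non-beat annotation (rhythm changes, artifacts, comments, ...) maps to
the sentinel ``EXCLUDED`` and is skipped during segmentation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Fixed class display order (used for confusion matrices and reports).
CLASSES = ("N", "S", "V", "F", "Q")

#: Sentinel returned for annotation symbols that are not heartbeats.
EXCLUDED = "EXCLUDED"

#: AAMI merge of MIT-BIH beat symbols into five classes.
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "Q": "Q", "?": "Q", "/": "Q", "f": "Q",
}

#: Symbols usable when synthesising annotations for a given class.
CLASS_SYMBOLS = {
    "N": ("N", "L", "R", "e", "j"),
    "S": ("A", "a", "J", "S"),
    "V": ("V", "E"),
    "F": ("F",),
    "Q": ("Q", "/", "f"),
}

# MIT annotation code numbers <-> symbols (ecgcodes subset).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    22: '"', 28: "+", 30: "?", 34: "e", 37: "x", 38: "f",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP_CODE = 59  # pseudo-annotation: 4-byte time offset follows


def map_annotation_symbol(symbol: str) -> str:
    """Map one MIT-BIH annotation symbol to its AAMI class or ``EXCLUDED``.

    Total function: any symbol that is not a recognised beat annotation
    (rhythm markers such as ``+``, artifacts, comments) returns ``EXCLUDED``.
    """
    return AAMI_MAP.get(symbol, EXCLUDED)


@dataclass
class EcgRecord:
    """A single-lead sampled ECG trace with beat annotations.

    Annotation sample indices are 0-based positions into ``samples`` at the
    record's native sampling rate; they are kept sorted ascending.
    """

    samples: np.ndarray          # millivolts
    fs: float                    # Hz
    lead_name: str
    annotations: list[tuple[int, str]]
    record_id: str
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.annotations = sorted(self.annotations, key=lambda a: a[0])
        for idx, _sym in self.annotations:
            if not 0 <= idx < len(self.samples):
                raise ValueError(
                    f"annotation index {idx} outside signal of length {len(self.samples)}")
        prev = -1
        for idx, _sym in self.annotations:
            if idx == prev:
                raise ValueError(f"duplicate annotation index {idx}")
            prev = idx


# ---------------------------------------------------------------------------
# Format 212 signal packing
# ---------------------------------------------------------------------------

def _pack_212(flat: np.ndarray) -> bytes:
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    a = flat[0::2].astype(np.int32) & 0xFFF
    b = flat[1::2].astype(np.int32) & 0xFFF
    out = np.empty(3 * a.size, dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((b >> 8) << 4) | (a >> 8)
    out[2::3] = b & 0xFF
    return out.tobytes()


def _unpack_212(raw: bytes, n_samples: int) -> np.ndarray:
    buf = np.frombuffer(raw, dtype=np.uint8)
    buf = buf[: (len(buf) // 3) * 3].reshape(-1, 3).astype(np.int32)
    a = ((buf[:, 1] & 0x0F) << 8) | buf[:, 0]
    b = ((buf[:, 1] & 0xF0) << 4) | buf[:, 2]
    flat = np.empty(2 * len(buf), dtype=np.int32)
    flat[0::2] = a
    flat[1::2] = b
    flat = np.where(flat > 2047, flat - 4096, flat)  # 12-bit two's complement
    return flat[:n_samples]


# ---------------------------------------------------------------------------
# Record write / read
# ---------------------------------------------------------------------------

def write_record(record: EcgRecord, directory: str | os.PathLike,
                 extra_leads: dict[str, np.ndarray] | None = None,
                 gain: float = 200.0) -> Path:
    """Write an :class:`EcgRecord` as ``<id>.hea`` / ``<id>.dat`` / ``<id>.atr``.

    ``extra_leads`` adds further channels (name -> mV samples of equal length),
    useful for exercising lead selection.  Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    leads: list[tuple[str, np.ndarray]] = []
    if extra_leads:
        # caller-supplied channel ordering; the record's own lead may appear
        # anywhere in it (exercises lead selection on read)
        for name, s in extra_leads.items():
            if name == record.lead_name:
                leads.append((name, record.samples))
            else:
                leads.append((name, np.asarray(s, dtype=float)))
        if record.lead_name not in extra_leads:
            leads.insert(0, (record.lead_name, record.samples))
    else:
        leads.append((record.lead_name, record.samples))
    n_samples = len(record.samples)
    for name, s in leads:
        if len(s) != n_samples:
            raise ValueError(f"lead {name!r} length {len(s)} != {n_samples}")
    digital = [np.clip(np.rint(s * gain), -2048, 2047).astype(np.int32)
               for _n, s in leads]
    flat = np.empty(n_samples * len(leads), dtype=np.int32)
    for ch, d in enumerate(digital):
        flat[ch::len(leads)] = d
    dat_name = f"{record.record_id}.dat"
    (directory / dat_name).write_bytes(_pack_212(flat))
    # header: record line then one line per signal
    lines = [f"{record.record_id} {len(leads)} {record.fs:g} {n_samples}"]
    for (name, _s), d in zip(leads, digital):
        init = int(d[0]) if n_samples else 0
        lines.append(f"{dat_name} 212 {gain:g} 12 0 {init} 0 0 {name}")
    (directory / f"{record.record_id}.hea").write_text("\n".join(lines) + "\n")
    _write_annotations(directory / f"{record.record_id}.atr", record.annotations)
    return directory / f"{record.record_id}.hea"


def _write_annotations(path: Path, annotations: list[tuple[int, str]]) -> None:
    words = bytearray()
    prev = 0
    for idx, sym in sorted(annotations, key=lambda a: a[0]):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"cannot encode annotation symbol {sym!r}")
        dt = idx - prev
        if dt < 0:
            raise ValueError("annotations must be sorted ascending")
        if dt > 1023:
            words += int.to_bytes((_SKIP_CODE << 10), 2, "little")
            words += int.to_bytes((dt >> 16) & 0xFFFF, 2, "little")
            words += int.to_bytes(dt & 0xFFFF, 2, "little")
            dt = 0
        words += int.to_bytes((code << 10) | dt, 2, "little")
        prev = idx
    words += b"\x00\x00"  # EOF
    path.write_bytes(bytes(words))


def _read_annotations(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 2 <= len(raw):
        word = int.from_bytes(raw[i:i + 2], "little")
        i += 2
        code = word >> 10
        dt = word & 0x3FF
        if code == 0 and dt == 0:
            break  # EOF
        if code == _SKIP_CODE:
            if i + 4 > len(raw):
                raise ValueError(f"truncated SKIP operand in {path}")
            hi = int.from_bytes(raw[i:i + 2], "little")
            lo = int.from_bytes(raw[i + 2:i + 4], "little")
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code in (60, 61, 62, 63):  # NUM/SUB/AUX pseudo-annotations
            if code == 63:  # AUX: dt holds byte count, padded to even
                i += dt + (dt & 1)
            continue
        t += pending_skip + dt
        pending_skip = 0
        sym = _CODE_TO_SYMBOL.get(code)
        if sym is None:
            continue  # unknown code: not a beat we model
        out.append((t, sym))
    return sorted(out, key=lambda a: a[0])


def read_record(path: str | os.PathLike, preferred_lead: str = "MLII") -> EcgRecord:
    """Read a WFDB record, selecting ``preferred_lead`` (default MLII).

    ``path`` may point at the ``.hea`` file or be the extensionless record
    path.  If the preferred lead is absent the first channel is returned and a
    warning is recorded in the result's provenance.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_id, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if n_sig < 1:
        raise ValueError(f"record {record_id} declares no signal channels")
    sig_lines = lines[1:1 + n_sig]
    leads, gains, baselines, dat_names = [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        dat_names.append(parts[0])
        if parts[1].split("x")[0] != "212":
            raise ValueError(f"unsupported WFDB signal format {parts[1]!r} "
                             f"(only format 212 is handled)")
        gain_field = parts[2] if len(parts) > 2 else "200"
        baseline = 0.0
        if "(" in gain_field:  # gain(baseline)[/units]
            gain_val, rest = gain_field.split("(", 1)
            baseline = float(rest.split(")")[0])
        else:
            gain_val = gain_field
        gain_val = gain_val.split("/")[0]
        gains.append(float(gain_val) or 200.0)
        if "(" not in gain_field and len(parts) > 4:
            baseline = float(parts[4])  # ADC zero column
        baselines.append(baseline)
        leads.append(parts[-1])
    dat_path = hea.parent / dat_names[0]
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    flat = _unpack_212(dat_path.read_bytes(), n_samples * n_sig if n_samples else -1)
    if n_samples == 0:
        n_samples = len(flat) // n_sig
    provenance: list[str] = []
    if preferred_lead in leads:
        ch = leads.index(preferred_lead)
    else:
        ch = 0
        provenance.append(
            f"preferred lead {preferred_lead!r} absent; using first channel "
            f"{leads[0]!r}")
    digital = flat[ch::n_sig][:n_samples].astype(float)
    samples = (digital - baselines[ch]) / gains[ch]
    atr = hea.with_suffix(".atr")
    annotations = _read_annotations(atr) if atr.exists() else []
    annotations = [(i, s) for i, s in annotations if 0 <= i < n_samples]
    return EcgRecord(samples=samples, fs=fs, lead_name=leads[ch],
                     annotations=annotations, record_id=record_id,
                     provenance=provenance)
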