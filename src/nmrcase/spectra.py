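"""Peak lists, literature-string parsing, shift multisets, and the
Gaussian-convolution vector encoding.

The universal spectrum representation is an unordered multiset of
chemical shifts: one entry per hydrogen nucleus for 1H (integration is
encoded by repetition), and one entry per distinct carbon resonance for
13C (symmetry-equivalent carbons coalesce into a single signal).

Encoding: a multiset X = {x_1..x_n} is smoothed with a Gaussian of width
sigma, g(t) = sum_i exp(-(t - x_i)^2 / (2 sigma^2)), and sampled at 128
uniformly spaced points across the nucleus window; the full-spectrum
vector concatenates the 1H and 13C parts (length 256).  The encoding is
linear in multiset union — the property that lets fragment spectra be
combined additively.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .config import SpectrumConfig
from .predictor import ShiftPrediction

__all__ = [
    "Peak",
    "PeakParseError",
    "ShiftMultiset",
    "parse_peak_string",
    "format_peak",
    "to_multiset",
    "simulate_multiset",
    "encode",
    "encode_full",
    "load_peaks_json",
    "save_peaks_json",
    "load_peaks_csv",
]

MULTIPLICITIES = {
    "s", "d", "t", "q", "p", "quin", "sext", "sept", "m", "br", "brs", "bs",
    "dd", "dt", "td", "tt", "ddd", "dq", "qd", "ddt", "dtd", "dddd",
}


class PeakParseError(ValueError):
    """Malformed peak entry; carries the offending span of the input."""

    def __init__(self, message: str, span: tuple[int, int], text: str):
        self.span = span
        self.offending = text[span[0]:span[1]]
        super().__init__(f"{message} at chars {span[0]}-{span[1]}: {self.offending!r}")


@dataclass(frozen=True)
class Peak:
    """One resolved resonance from a peak list.

    Either ``shift`` or ``shift_range`` is set.  ``integration`` (proton
    count) and ``multiplicity`` apply to 1H peaks only.
    """

    shift: float | None = None
    shift_range: tuple[float, float] | None = None
    integration: int | None = None
    multiplicity: str | None = None
    j_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if (self.shift is None) == (self.shift_range is None):
            raise ValueError("exactly one of shift / shift_range must be set")
        if self.integration is not None and self.integration < 1:
            raise ValueError("integration must be >= 1")

    @property
    def representative_shift(self) -> float:
        """The shift, or the midpoint for a range peak."""
        if self.shift is not None:
            return self.shift
        lo, hi = self.shift_range  # type: ignore[misc]
        return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# literature-string parsing

_NUM = r"[-+]?\d+(?:\.\d+)?"
_RANGE_SEP = r"(?:[-‐‑‒–—]|to)"
_SHIFT_PART = rf"(?P<lo>{_NUM})(?:\s*{_RANGE_SEP}\s*(?P<hi>{_NUM}))?"
_PAREN_PART = r"(?:\s*\((?P<paren>[^)]*)\))?"
_ENTRY_RE = re.compile(rf"^\s*{_SHIFT_PART}{_PAREN_PART}\s*$")
_J_RE = re.compile(rf"^J\s*=\s*(?P<vals>{_NUM}(?:\s*,\s*{_NUM})*)\s*(?:Hz)?$", re.I)
_INT_RE = re.compile(r"^(\d+)\s*H$", re.I)


def _split_entries(text: str) -> list[tuple[int, int]]:
    """Split on top-level commas/semicolons (not inside parentheses)."""
    spans, depth, start = [], 0, 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif ch in ",;" and depth == 0:
            spans.append((start, pos))
            start = pos + 1
    spans.append((start, len(text)))
    return [(a, b) for a, b in spans if text[a:b].strip()]


def _parse_paren(content: str, span: tuple[int, int], text: str):
    mult = None
    integ = None
    j_vals: tuple[float, ...] = ()
    for part in (p.strip() for p in content.split(",")):
        if not part:
            continue
        j_match = _J_RE.match(part)
        if j_match:
            j_vals = j_vals + tuple(
                float(v) for v in re.findall(_NUM, j_match.group("vals"))
            )
            continue
        # J values may continue without a new "J =" prefix: "J = 8.0, 2.0 Hz"
        if j_vals and re.fullmatch(rf"{_NUM}\s*(?:Hz)?", part, re.I):
            j_vals = j_vals + (float(re.match(_NUM, part).group()),)
            continue
        i_match = _INT_RE.match(part)
        if i_match:
            integ = int(i_match.group(1))
            continue
        if part.lower() in MULTIPLICITIES:
            mult = part.lower()
            continue
        raise PeakParseError(f"unrecognized annotation {part!r}", span, text)
    return mult, integ, j_vals


def parse_peak_string(text: str, nucleus: str) -> list[Peak]:
    """Parse a journal-style peak string into :class:`Peak` objects.

    1H example: ``"δ 7.35 – 7.28 (m, 5H), 4.58 (s, 2H)"``; 13C example:
    ``"δ 170.9, 128.4, 60.8"``.  Accepted dialects: en/em dashes, plain
    hyphens or ``to`` as range separators; comma or semicolon entry
    delimiters; optional ``Hz``/``H`` units.  Unparsable entries raise
    :class:`PeakParseError` naming the offending span.
    """
    if nucleus not in ("1H", "13C"):
        raise ValueError(f"unknown nucleus {nucleus!r}")
    body = text.strip()
    offset = 0
    for prefix in ("δ", "delta"):
        if body.startswith(prefix):
            offset = text.index(prefix) + len(prefix)
            body = text[offset:]
            break

    # protect range-separating hyphens from being read as minus signs:
    # split first, regex handles each entry
    peaks: list[Peak] = []
    for a, b in _split_entries(body):
        span = (offset + a, offset + b)
        entry = body[a:b].strip()
        match = _ENTRY_RE.match(entry)
        if not match:
            raise PeakParseError("malformed peak entry", span, text)
        lo = float(match.group("lo"))
        hi = match.group("hi")
        paren = match.group("paren")
        mult, integ, j_vals = (None, None, ())
        if paren is not None:
            if nucleus == "13C":
                raise PeakParseError("13C peaks carry no annotations", span, text)
            mult, integ, j_vals = _parse_paren(paren, span, text)
        if nucleus == "13C" and (integ is not None or mult):
            raise PeakParseError("13C peaks carry no annotations", span, text)
        if hi is not None:
            peaks.append(Peak(shift_range=(lo, float(hi)), integration=integ,
                              multiplicity=mult, j_values=j_vals))
        else:
            peaks.append(Peak(shift=lo, integration=integ,
                              multiplicity=mult, j_values=j_vals))
    if not peaks:
        raise PeakParseError("no peaks found", (0, len(text)), text)
    return peaks


def format_peak(peak: Peak, nucleus: str = "1H") -> str:
    """Render a peak back to journal style (inverse of the parser)."""
    if peak.shift_range is not None:
        head = f"{peak.shift_range[0]:g} – {peak.shift_range[1]:g}"
    else:
        head = f"{peak.shift:g}"
    if nucleus == "13C":
        return head
    parts = []
    if peak.multiplicity:
        parts.append(peak.multiplicity)
    if peak.j_values:
        parts.append("J = " + ", ".join(f"{j:g}" for j in peak.j_values) + " Hz")
    if peak.integration is not None:
        parts.append(f"{peak.integration}H")
    return head + (f" ({', '.join(parts)})" if parts else "")


# ---------------------------------------------------------------------------
# multisets

@dataclass(frozen=True)
class ShiftMultiset:
    """Unordered multiset of chemical shifts for one nucleus.

    Stored sorted for canonical equality; ``tags`` optionally carries a
    multiplicity label per entry (1H literature data only).
    """

    nucleus: str
    shifts: tuple[float, ...]
    tags: tuple[str | None, ...] | None = None

    def __post_init__(self) -> None:
        if self.nucleus not in ("1H", "13C"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.tags is not None and len(self.tags) != len(self.shifts):
            raise ValueError("tags must align with shifts")
        order = np.argsort(np.asarray(self.shifts, dtype=float), kind="stable")
        object.__setattr__(self, "shifts", tuple(self.shifts[i] for i in order))
        if self.tags is not None:
            object.__setattr__(self, "tags", tuple(self.tags[i] for i in order))

    def __len__(self) -> int:
        return len(self.shifts)

    def union(self, other: "ShiftMultiset", coalesce: bool = False) -> "ShiftMultiset":
        """Multiset union; with ``coalesce`` equal values merge into one
        entry (the 13C convention for symmetry-coalesced signals)."""
        if other.nucleus != self.nucleus:
            raise ValueError("cannot union multisets of different nuclei")
        values: tuple[float, ...] = self.shifts + other.shifts
        if coalesce:
            values = tuple(sorted(set(values)))
            return ShiftMultiset(self.nucleus, values)
        tags = None
        if self.tags is not None or other.tags is not None:
            tags = (self.tags or (None,) * len(self)) + \
                (other.tags or (None,) * len(other))
        return ShiftMultiset(self.nucleus, values, tags)


def to_multiset(peaks: list[Peak], nucleus: str) -> ShiftMultiset:
    """Convert a peak list into the multiset representation.

    1H: each representative shift is repeated ``integration`` times
    (default 1) with its multiplicity tag attached; range peaks use the
    range midpoint.  13C: one entry per peak.
    """
    shifts: list[float] = []
    tags: list[str | None] = []
    for peak in peaks:
        value = peak.representative_shift
        if nucleus == "1H":
            count = peak.integration if peak.integration is not None else 1
            shifts.extend([value] * count)
            tags.extend([peak.multiplicity] * count)
        else:
            shifts.append(value)
    if nucleus == "1H" and any(t is not None for t in tags):
        return ShiftMultiset(nucleus, tuple(shifts), tuple(tags))
    return ShiftMultiset(nucleus, tuple(shifts))


def simulate_multiset(mol: Chem.Mol, predictor) -> tuple[ShiftMultiset, ShiftMultiset]:
    """Predict and convert a molecule's spectra to multisets.

    The 1H multiset has one entry per hydrogen nucleus.  The 13C multiset
    has one entry per distinct carbon resonance: symmetry-equivalent
    carbons carry identical predicted shifts and coalesce into a single
    entry (their average — trivially the shared value)."""
    pred: ShiftPrediction = predictor.predict(mol)
    h_ms = ShiftMultiset("1H", tuple(pred.all_h_values()))
    c_ms = ShiftMultiset("13C", tuple(sorted(set(pred.c_shifts.values()))))
    return h_ms, c_ms


# ---------------------------------------------------------------------------
# encoding

def _grid(window: tuple[float, float], n: int) -> np.ndarray:
    return np.linspace(window[0], window[1], n)


def encode(ms: ShiftMultiset, window: tuple[float, float],
           sigma: float, n_grid: int = 128) -> np.ndarray:
    """Gaussian-smoothed sampled encoding of one nucleus.

    Shifts outside the window still contribute through their tails (no
    clipping); an empty multiset encodes to the zero vector.
    """
    if not window[0] < window[1]:
        raise ValueError("window.low must be < window.high")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = _grid(window, n_grid)
    if not ms.shifts:
        return np.zeros(n_grid)
    x = np.asarray(ms.shifts, dtype=float)
    return np.exp(-((t[:, None] - x[None, :]) ** 2) / (2.0 * sigma**2)).sum(axis=1)


def encode_full(h: ShiftMultiset | None, c: ShiftMultiset | None,
                cfg: SpectrumConfig) -> np.ndarray:
    """Concatenated [v_H ; v_C] encoding; a missing nucleus contributes
    its zero vector."""
    v_h = (encode(h, cfg.h_window, cfg.sigma_encode_h, cfg.n_grid)
           if h is not None else np.zeros(cfg.n_grid))
    v_c = (encode(c, cfg.c_window, cfg.sigma_encode_c, cfg.n_grid)
           if c is not None else np.zeros(cfg.n_grid))
    return np.concatenate([v_h, v_c])


# ---------------------------------------------------------------------------
# peak-list IO

def _peak_to_dict(peak: Peak) -> dict:
    out: dict = {}
    if peak.shift is not None:
        out["shift"] = peak.shift
    else:
        out["shift_range"] = list(peak.shift_range)
    if peak.integration is not None:
        out["integration"] = peak.integration
    if peak.multiplicity is not None:
        out["multiplicity"] = peak.multiplicity
    if peak.j_values:
        out["j_values"] = list(peak.j_values)
    return out


def _peak_from_dict(d: dict) -> Peak:
    return Peak(
        shift=d.get("shift"),
        shift_range=tuple(d["shift_range"]) if "shift_range" in d else None,
        integration=d.get("integration"),
        multiplicity=d.get("multiplicity"),
        j_values=tuple(d.get("j_values", ())),
    )


def save_peaks_json(path: str, peaks: list[Peak], nucleus: str) -> None:
    with open(path, "w") as fh:
        json.dump({"nucleus": nucleus, "peaks": [_peak_to_dict(p) for p in peaks]},
                  fh, indent=1)


def load_peaks_json(path: str) -> tuple[list[Peak], str]:
    with open(path) as fh:
        data = json.load(fh)
    return [_peak_from_dict(d) for d in data["peaks"]], data["nucleus"]


def load_peaks_csv(path: str, nucleus: str) -> list[Peak]:
    """CSV with one peak per row; columns: shift or shift_low/shift_high,
    integration, multiplicity, j_values (semicolon-separated Hz)."""
    peaks = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            shift = row.get("shift") or None
            lo, hi = row.get("shift_low") or None, row.get("shift_high") or None
            peaks.append(Peak(
                shift=float(shift) if shift else None,
                shift_range=(float(lo), float(hi)) if lo and hi else None,
                integration=int(row["integration"]) if row.get("integration") else None,
                multiplicity=row.get("multiplicity") or None,
                j_values=tuple(float(j) for j in
                               (row.get("j_values") or "").split(";") if j),
            ))
    return peaks
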