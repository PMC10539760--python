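"""Parsing of printed 1H shift lists (ACD-style) and rotamer accounting.

The dialect is the one used in experimental sections:

    1H NMR (500 MHz, DMSO-d6) Shift 10.18 (s, 0.5H, isomer1), 10.14
    (s, 0.5H, isomer2), 4.51 (dt, J = 47.5, 6.1 Hz, 2H), 3.37-3.33 (m, 1H), ...

Each parenthesized group becomes one :class:`ShiftEntry`; delta ranges keep
their bounds and report the midpoint; integrals are exact rationals so the
half-proton arithmetic of a 1:1 rotamer mixture stays exact; entries may
carry ``isomer1``/``isomer2``/``isomer1+isomer2`` tags marking resolved or
coincident rotamer signals.

Rotamer populations are estimated two ways (see :func:`rotamer_fractions`):
a plain sum of singly-tagged integrals, and the counterpart-pair method
that mirrors how an NMR spectroscopist reads a rotamer ratio — integrate
resolved signal pairs belonging to the same proton site in the two
rotamers, recognized by matching multiplicity, J values and proximity in
delta.  Entries with no recognizable counterpart (including misprinted
tags) are excluded from the paired estimate and flagged, never re-tagged.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

__all__ = [
    "ShiftEntry",
    "ShiftList",
    "RotamerAnalysis",
    "ShiftListWarning",
    "parse_shift_list",
    "rotamer_fractions",
    "total_protons",
    "load_compound",
]

KNOWN_MULTIPLICITIES = {
    "s", "d", "t", "q", "quin", "m",
    "dd", "dt", "td", "qd", "dq", "dqd", "dquin",
}

_TAGS = {"isomer1": frozenset({"isomer1"}),
         "isomer2": frozenset({"isomer2"}),
         "isomer1+isomer2": frozenset({"isomer1", "isomer2"})}


class ShiftListWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ShiftEntry:
    """One parenthesized shift-list group."""

    delta: float                      # ppm; midpoint for ranges
    multiplicity: str                 # verbatim token, e.g. "br dt"
    integral: Fraction                # proton count, exact
    j_values: tuple = ()              # Hz
    isomer_tags: frozenset = frozenset()
    delta_range: Optional[tuple] = None  # (high, low) as printed

    def __post_init__(self) -> None:
        if self.integral <= 0:
            raise ValueError("integral must be positive")
        if any(j < 0 for j in self.j_values):
            raise ValueError("J values must be non-negative")
        if self.delta_range is not None and self.delta_range[0] < self.delta_range[1]:
            raise ValueError("delta range must be printed high-to-low")

    @property
    def base_multiplicity(self) -> str:
        """Multiplicity with any broadening prefix stripped."""
        return self.multiplicity.removeprefix("br ").strip()

    @property
    def single_tag(self) -> Optional[str]:
        if len(self.isomer_tags) == 1:
            return next(iter(self.isomer_tags))
        return None

    def to_text(self) -> str:
        if self.delta_range is not None:
            head = f"{self.delta_range[0]:.2f}–{self.delta_range[1]:.2f}"
        else:
            head = f"{self.delta:.2f}"
        parts = [self.multiplicity]
        if self.j_values:
            parts.append("J = " + ", ".join(f"{j:g}" for j in self.j_values) + " Hz")
        n = self.integral
        parts.append((f"{float(n):g}" if n.denominator != 1 else f"{n}") + "H")
        if self.isomer_tags:
            parts.append("+".join(sorted(self.isomer_tags)))
        return f"{head} ({', '.join(parts)})"


@dataclass(frozen=True)
class ShiftList:
    """A parsed 1H shift list."""

    compound: str
    frequency_mhz: float
    solvent: str
    entries: tuple
    parse_warnings: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    def to_text(self) -> str:
        body = ", ".join(e.to_text() for e in self.entries)
        return f"1H NMR ({self.frequency_mhz:g} MHz, {self.solvent}) Shift {body}"

    def as_dict(self) -> dict:
        return {
            "compound": self.compound,
            "frequency_mhz": self.frequency_mhz,
            "solvent": self.solvent,
            "entries": [
                {
                    "delta_ppm": e.delta,
                    "delta_range": list(e.delta_range) if e.delta_range else None,
                    "multiplicity": e.multiplicity,
                    "j_hz": list(e.j_values),
                    "integral_h": str(e.integral),
                    "isomer_tags": sorted(e.isomer_tags),
                }
                for e in self.entries
            ],
        }


_HEADER_RE = re.compile(
    r"1H\s+NMR\s*\(\s*(?P<freq>\d+(?:\.\d+)?)\s*MHz\s*,\s*(?P<solvent>[^)]+?)\s*\)\s*Shift\s*",
    re.IGNORECASE,
)
_ENTRY_RE = re.compile(
    r"(?P<delta>\d+\.\d+(?:\s*[–—-]\s*\d+\.\d+)?)\s*\((?P<body>[^)]*)\)"
)
_INTEGRAL_RE = re.compile(r"^(\d+(?:\.\d+)?)H$")


def _parse_body(body: str, span: str, warn: list):
    """Parse the inside of one parenthesized group."""
    tokens = [t.strip() for t in body.split(",")]
    if not tokens or not tokens[0]:
        raise ValueError(f"malformed shift entry: '{span}'")
    mult = tokens[0]
    base = mult.removeprefix("br ").strip()
    if base not in KNOWN_MULTIPLICITIES:
        warn.append(f"unknown multiplicity token '{mult}' in '{span}'")
    idx = 1
    j_values = []
    if idx < len(tokens) and tokens[idx].replace(" ", "").startswith("J="):
        jtok = tokens[idx].split("=", 1)[1]
        while True:
            jtok = jtok.strip()
            done = jtok.endswith("Hz")
            if done:
                jtok = jtok[:-2].strip()
            j_values.append(float(jtok))
            idx += 1
            if done or idx >= len(tokens):
                break
            jtok = tokens[idx]
    integral = None
    if idx < len(tokens):
        m = _INTEGRAL_RE.match(tokens[idx])
        if m:
            integral = Fraction(m.group(1))
            idx += 1
    if integral is None:
        raise ValueError(f"missing integral in shift entry: '{span}'")
    tags = frozenset()
    if idx < len(tokens):
        tag_tok = tokens[idx].replace(" ", "")
        if tag_tok not in _TAGS:
            raise ValueError(f"unrecognized trailing token '{tokens[idx]}' in '{span}'")
        tags = _TAGS[tag_tok]
        idx += 1
    if idx != len(tokens):
        raise ValueError(f"unparsed tokens {tokens[idx:]} in '{span}'")
    return mult, tuple(j_values), integral, tags


def parse_shift_list(text: str, compound: str = "") -> ShiftList:
    """Parse printed shift-list text into a :class:`ShiftList`.

    Malformed groups raise with the offending span named; unknown
    multiplicity tokens are kept verbatim and reported as warnings (also
    emitted as :class:`ShiftListWarning`).  No parenthesized group is ever
    silently dropped: every group either becomes an entry or raises.
    """
    text = " ".join(text.split())
    header = _HEADER_RE.search(text)
    if not header:
        raise ValueError("missing '1H NMR (<freq> MHz, <solvent>) Shift' header")
    body_text = text[header.end():]

    n_groups = body_text.count("(")
    entries = []
    warn: list = []
    pos = 0
    for m in _ENTRY_RE.finditer(body_text):
        between = body_text[pos:m.start()].strip(" ,")
        if between:
            raise ValueError(f"unparseable text before entry: '{between}'")
        pos = m.end()
        delta_txt = m.group("delta")
        rng = re.split(r"\s*[–—-]\s*", delta_txt)
        if len(rng) == 2:
            hi, lo = float(rng[0]), float(rng[1])
            delta, delta_range = (hi + lo) / 2.0, (hi, lo)
        else:
            delta, delta_range = float(delta_txt), None
        mult, j_values, integral, tags = _parse_body(m.group("body"), m.group(0), warn)
        entries.append(
            ShiftEntry(
                delta=delta,
                multiplicity=mult,
                integral=integral,
                j_values=j_values,
                isomer_tags=tags,
                delta_range=delta_range,
            )
        )
    trailing = body_text[pos:].strip(" ,.")
    if trailing:
        raise ValueError(f"unparseable trailing text: '{trailing}'")
    if len(entries) != n_groups:
        raise ValueError(
            f"group accounting mismatch: {n_groups} '(' groups but {len(entries)} entries"
        )
    for w in warn:
        warnings.warn(w, ShiftListWarning, stacklevel=2)
    return ShiftList(
        compound=compound,
        frequency_mhz=float(header.group("freq")),
        solvent=header.group("solvent"),
        entries=tuple(entries),
        parse_warnings=tuple(warn),
    )


@dataclass(frozen=True)
class RotamerAnalysis:
    """Per-isomer population estimate from resolved rotamer signals.

    ``fractions`` is the primary estimate: integrals summed over matched
    counterpart pairs only.  ``raw_fractions`` sums every singly-tagged
    entry (sensitive to tag misprints).  ``balanced`` reports whether the
    raw per-isomer sums agree; when they do not, the discrepancy is carried
    in ``messages`` together with the unpaired entries.
    """

    fractions: dict
    raw_fractions: dict
    pairs: tuple
    unpaired: tuple
    balanced: bool
    messages: tuple


def _pairable(a: ShiftEntry, b: ShiftEntry, delta_window: float, j_tol: float) -> bool:
    if a.single_tag is None or b.single_tag is None or a.single_tag == b.single_tag:
        return False
    if a.base_multiplicity != b.base_multiplicity:
        return False
    if len(a.j_values) != len(b.j_values):
        return False
    if any(abs(x - y) > j_tol for x, y in zip(a.j_values, b.j_values)):
        return False
    return abs(a.delta - b.delta) <= delta_window


def rotamer_fractions(
    shift_list: ShiftList,
    delta_window: float = 0.5,
    j_tol: float = 2.0,
) -> RotamerAnalysis:
    """Estimate rotamer populations from singly-tagged entries.

    Counterpart pairs — the same proton site resolved in the two rotamers —
    are recognized greedily in printed order as two singly-tagged entries
    with opposite tags, identical base multiplicity, J values within
    ``j_tol`` Hz and deltas within ``delta_window`` ppm.  The primary
    ``fractions`` sum integrals over paired entries (exact rational
    arithmetic); singly-tagged entries without a counterpart are excluded
    and flagged.  The plain per-tag sums over *all* singly-tagged entries
    are reported as ``raw_fractions``, with an imbalance message when the
    two disagree (e.g. from printed tag typos).
    """
    singles = [e for e in shift_list.entries if e.single_tag is not None]
    if not singles:
        raise ValueError("no resolved rotamer signals")
    tags = sorted({e.single_tag for e in singles})

    raw = {t: Fraction(0) for t in tags}
    for e in singles:
        raw[e.single_tag] += e.integral
    raw_total = sum(raw.values())
    raw_fractions = {t: raw[t] / raw_total for t in tags}
    balanced = len(set(raw.values())) == 1

    matched = [False] * len(singles)
    pairs = []
    for i, a in enumerate(singles):
        if matched[i]:
            continue
        candidates = [
            (abs(a.delta - singles[j].delta), j)
            for j in range(i + 1, len(singles))
            if not matched[j] and _pairable(a, singles[j], delta_window, j_tol)
        ]
        if candidates:
            _, j = min(candidates)
            matched[i] = matched[j] = True
            pairs.append((a, singles[j]))
    unpaired = tuple(e for e, m in zip(singles, matched) if not m)

    messages = []
    if not balanced:
        messages.append(
            "singly-tagged integrals are imbalanced across isomers: "
            + ", ".join(f"{t}={raw[t]}H" for t in tags)
            + " (possible tag misprint)"
        )
    for e in unpaired:
        messages.append(f"no counterpart for {e.to_text()}; excluded from paired estimate")

    if pairs:
        paired_sum = {t: Fraction(0) for t in tags}
        for a, b in pairs:
            paired_sum[a.single_tag] += a.integral
            paired_sum[b.single_tag] += b.integral
        tot = sum(paired_sum.values())
        fractions = {t: paired_sum[t] / tot for t in tags}
    else:
        fractions = dict(raw_fractions)
        messages.append("no counterpart pairs found; falling back to raw per-tag sums")

    if messages:
        warnings.warn("; ".join(messages), ShiftListWarning, stacklevel=2)
    return RotamerAnalysis(
        fractions=fractions,
        raw_fractions=raw_fractions,
        pairs=tuple(pairs),
        unpaired=unpaired,
        balanced=balanced,
        messages=tuple(messages),
    )


def total_protons(shift_list: ShiftList) -> Fraction:
    """Sum of all integrals, exact rational arithmetic."""
    return sum((e.integral for e in shift_list.entries), Fraction(0))


def load_compound(n: int) -> ShiftList:
    """Load one of the packaged compound shift lists (1, 2 or 3)."""
    from importlib.resources import files

    if n not in (1, 2, 3):
        raise ValueError("compound must be 1, 2 or 3")
    text = files("ligandconf").joinpath("data", f"compound{n}.txt").read_text()
    return parse_shift_list(text, compound=f"compound{n}")
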