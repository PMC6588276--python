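"""Bohlen-Pierce scale construction, triad enumeration, and Scala file I/O.

The Bohlen-Pierce (BP) system divides the *tritave* (the 3:1 frequency
ratio, ~1901.955 cents) into 13 chromatic steps.  Two variants are built
in: an equal-tempered scale (13 equal steps) and Bohlen's just-intonation
scale whose steps are small odd-integer frequency ratios.  Chords are
expressed as step patterns ``{0, a, b}`` and realized as continuous MIDI
pitches (1 MIDI unit = 100 cents, A4 = 69 = 440 Hz).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "TRITAVE_CENTS",
    "JI_RATIOS",
    "ScaleDef",
    "ChordPattern",
    "RealizedChord",
    "ScalaFormatError",
    "build_et_scale",
    "build_ji_scale",
    "enumerate_patterns",
    "realize_chord",
    "enumerate_unique_ji_triads",
    "read_scl",
    "write_scl",
    "midi_to_freq",
    "cents_to_ratio",
]

#: Cents of the 3:1 repetition interval.
TRITAVE_CENTS: float = 1200.0 * math.log2(3.0)

#: Bohlen's just ratios for chromatic steps 1..13 (step 0 is 1/1).
JI_RATIOS: tuple[Fraction, ...] = tuple(
    Fraction(p, q)
    for p, q in [
        (27, 25), (25, 21), (9, 7), (7, 5), (75, 49), (5, 3), (9, 5),
        (49, 25), (15, 7), (7, 3), (63, 25), (25, 9), (3, 1),
    ]
)

STEPS_PER_TRITAVE = 13


def cents_to_ratio(cents: float) -> float:
    return 2.0 ** (cents / 1200.0)


def midi_to_freq(pitch: float | np.ndarray) -> float | np.ndarray:
    """Frequency in Hz of a continuous MIDI pitch (A4 = 69 = 440 Hz)."""
    return 440.0 * 2.0 ** ((np.asarray(pitch, dtype=float) - 69.0) / 12.0)


class ScalaFormatError(ValueError):
    """Raised when a `.scl` file violates the Scala dialect."""


@dataclass(frozen=True)
class ScaleDef:
    """A tritave-periodic tuning given by cumulative cents per chromatic step.

    ``steps_cents`` has length 14: step 0 is 0.0 and step 13 is the
    repetition interval (the tritave for the built-in scales).
    """

    name: str
    steps_cents: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps_cents) != STEPS_PER_TRITAVE + 1:
            raise ValueError(
                f"expected {STEPS_PER_TRITAVE + 1} cumulative positions, "
                f"got {len(self.steps_cents)}"
            )
        if self.steps_cents[0] != 0.0:
            raise ValueError("step 0 must sit at 0.0 cents")
        diffs = np.diff(self.steps_cents)
        if np.any(diffs <= 0):
            raise ValueError("steps_cents must be strictly increasing")

    @property
    def tritave_cents(self) -> float:
        return self.steps_cents[-1]

    def step_cents(self, index: int) -> float:
        """Cumulative cents of an arbitrary (possibly wrapped) scale index."""
        octaves, step = divmod(index, STEPS_PER_TRITAVE)
        return self.steps_cents[step] + octaves * self.tritave_cents


@dataclass(frozen=True, order=True)
class ChordPattern:
    """Triad ``{0, a, b}`` in BP chromatic steps, ``0 < a < b``."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not (0 < self.a < self.b):
            raise ValueError(f"need 0 < a < b, got ({self.a}, {self.b})")
        if self.b > STEPS_PER_TRITAVE:
            raise ValueError(f"b must not exceed {STEPS_PER_TRITAVE}")

    @property
    def label(self) -> str:
        return f"0 {self.a} {self.b}"


@dataclass(frozen=True)
class RealizedChord:
    """A chord pattern rooted on a chromatic degree, as MIDI pitches."""

    pattern: ChordPattern
    root_step: int
    pitches_midi: tuple[float, float, float]
    scale_name: str

    def __post_init__(self) -> None:
        p = self.pitches_midi
        if not (p[0] < p[1] < p[2]):
            raise ValueError("pitches must be strictly ascending")

    @property
    def intervals_cents(self) -> tuple[float, float]:
        """(lower, outer) intervals above the bass, in cents."""
        p = self.pitches_midi
        return (100.0 * (p[1] - p[0]), 100.0 * (p[2] - p[0]))


def build_et_scale() -> ScaleDef:
    """Equal-tempered BP scale: 13 equal divisions of the tritave."""
    step = TRITAVE_CENTS / STEPS_PER_TRITAVE
    return ScaleDef("bp_et", tuple(k * step for k in range(STEPS_PER_TRITAVE + 1)))


def build_ji_scale() -> ScaleDef:
    """Just-intonation BP scale from Bohlen's odd-integer ratios."""
    cents = (0.0,) + tuple(1200.0 * math.log2(float(r)) for r in JI_RATIOS)
    return ScaleDef("bp_ji", cents)


def enumerate_patterns(include_tritave: bool = False) -> list[ChordPattern]:
    """All triad step patterns within one tritave, lexicographically.

    78 patterns when the tritave (step 13) may participate, 66 otherwise.
    """
    top = STEPS_PER_TRITAVE if include_tritave else STEPS_PER_TRITAVE - 1
    return [ChordPattern(a, b) for a, b in combinations(range(1, top + 1), 2)]


def realize_chord(
    scale: ScaleDef,
    pattern: ChordPattern,
    root_step: int,
    base_midi: float = 52.0,
) -> RealizedChord:
    """Root a pattern on a chromatic degree, wrapping through the tritave.

    Scale index ``i`` maps to pitch ``base_midi + cumulative_cents(i)/100``,
    so ``base_midi`` is the pitch of degree 0 and the experiment's bass
    note is ``base_midi`` shifted by the root degree's cents.
    """
    if not 0 <= root_step <= STEPS_PER_TRITAVE - 1:
        raise ValueError(f"root_step must be in 0..12, got {root_step}")
    idx = (root_step, root_step + pattern.a, root_step + pattern.b)
    pitches = tuple(base_midi + scale.step_cents(i) / 100.0 for i in idx)
    return RealizedChord(pattern, root_step, pitches, scale.name)


def enumerate_unique_ji_triads(
    scale: ScaleDef | None = None,
    decimals: int = 1,
) -> dict[tuple[float, float], list[tuple[ChordPattern, int]]]:
    """Distinct interval-content realizations of the 66 tritave-free patterns.

    Each of the 66 patterns is rooted on all 13 chromatic degrees; a chord
    is identified by its (lower, outer) intervals above the bass rounded to
    ``decimals`` (0.1 cent by default, the precision of the published
    tuning table).  In equal temperament transposition leaves intervals
    unchanged and 66 classes remain; the unequal just steps split them
    into 414.

    Returns a mapping from interval pair to the (pattern, root) pairs that
    produce it.
    """
    scale = scale or build_ji_scale()
    out: dict[tuple[float, float], list[tuple[ChordPattern, int]]] = {}
    for pattern in enumerate_patterns(include_tritave=False):
        for root in range(STEPS_PER_TRITAVE):
            chord = realize_chord(scale, pattern, root)
            lo, hi = chord.intervals_cents
            key = (round(lo, decimals), round(hi, decimals))
            out.setdefault(key, []).append((pattern, root))
    return out


# --- Scala .scl files -------------------------------------------------------

_RATIO_RE = re.compile(r"^(\d+)\s*/\s*(\d+)$")


def _parse_pitch_line(line: str, lineno: int) -> float:
    token = line.split()[0]
    if "." in token:
        try:
            return float(token)
        except ValueError:
            pass
    else:
        m = _RATIO_RE.match(token)
        if m:
            num, den = int(m.group(1)), int(m.group(2))
            if den == 0:
                raise ScalaFormatError(f"line {lineno}: zero denominator")
            return 1200.0 * math.log2(num / den)
        if token.isdigit():  # bare integer is a ratio n/1
            return 1200.0 * math.log2(int(token))
    raise ScalaFormatError(f"line {lineno}: unparseable pitch {line!r}")


def read_scl(path: str | Path) -> ScaleDef:
    """Read a Scala `.scl` tuning file (cents and ratio pitch lines)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    body = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines) if not ln.startswith("!")
    ]
    if len(body) < 2:
        raise ScalaFormatError("missing description or count line")
    description = body[0][1]
    count_no, count_line = body[1]
    try:
        declared = int(count_line.split()[0])
    except (ValueError, IndexError):
        raise ScalaFormatError(f"line {count_no}: malformed note count") from None
    pitch_lines = [(no, ln) for no, ln in body[2:] if ln]
    if len(pitch_lines) != declared:
        raise ScalaFormatError(
            f"declared {declared} pitches but found {len(pitch_lines)}"
        )
    cents = [0.0] + [_parse_pitch_line(ln, no) for no, ln in pitch_lines]
    return ScaleDef(description or path.stem, tuple(cents))


def write_scl(scale: ScaleDef, path: str | Path) -> None:
    """Write a ScaleDef as a Scala `.scl` file using cents lines."""
    path = Path(path)
    n = len(scale.steps_cents) - 1
    lines = [f"! {path.name}", scale.name, f" {n}", "!"]
    lines += [f" {c:.6f}" for c in scale.steps_cents[1:]]
    path.write_text("\n".join(lines) + "\n")


def chords_from_table(rows: Sequence[Sequence]) -> list[tuple[ChordPattern, int, float]]:
    """Parse `(pattern_a, pattern_b, root_step, base_midi)` rows."""
    out = []
    for r in rows:
        a, b, root, base = int(r[0]), int(r[1]), int(r[2]), float(r[3])
        out.append((ChordPattern(a, b), root, base))
    return out
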