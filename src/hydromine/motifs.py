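"""PROSITE-style sequence-signature parsing and scanning.

Signatures are written in the dash-separated dialect used throughout the
hydrogenase literature, e.g. ``C-x(2)-C-x(22)-C`` (HydG C-terminal Fe-S
triad), ``C-x-H-x(46-53)-C-x(2)-C`` (HydF [4Fe-4S] ligand set),
``G-x(4)-G-K-[S/T]`` (Walker A P-loop), or ``h(4)-D-x(2)-G`` with ``h``
the hydrophobic class.

Scanning reports *every* distinct (start, end) occurrence: variable-width
gaps are enumerated over all admissible widths and overlapping or nested
matches are all kept.  An unknown residue ``X`` in the scanned sequence
matches no pattern position, including the wildcard ``x`` — validation is
deliberately conservative about ambiguous sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .core import AMINO_ACIDS, ConfigurationError

#: Default hydrophobic residue class for the 'h' pattern element.
HYDROPHOBIC = frozenset("AVLIMFWY")

#: Default region window (residues) for N-terminal patterns (signal
#: peptides and GTPase nucleotide-binding elements are near the start).
DEFAULT_NTERM_WINDOW = 60

ALL_RESIDUES = frozenset(AMINO_ACIDS)

_TOKEN_RE = re.compile(
    r"^(?P<elem>[A-Z]|x|h|\[[A-Z/]+\])(?:\((?P<lo>\d+)(?:-(?P<hi>\d+))?\))?$"
)


class PatternSyntaxError(ValueError):
    """Raised when a signature string cannot be parsed."""


@dataclass(frozen=True)
class MotifToken:
    """One pattern element: a residue set repeated min..max times."""

    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise PatternSyntaxError("empty residue set")
        if not (1 <= self.min_repeat <= self.max_repeat):
            raise PatternSyntaxError(
                f"bad repeat range ({self.min_repeat},{self.max_repeat})"
            )


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern; coordinates 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    matched_subsequence: str


@dataclass
class MotifPattern:
    """A parsed signature with an optional sequence-region constraint.

    ``region`` is one of ``any``, ``N-terminal``, ``C-terminal``.  When
    ``region_window`` is None a default applies: 60 residues for
    N-terminal patterns, max(80, 40% of sequence length) for C-terminal
    ones (terminal ends are qualitative notions; the windows make them
    operational and are configurable per pattern).
    """

    name: str
    tokens: tuple[MotifToken, ...]
    region: str = "any"
    region_window: int | None = None
    role: str = ""
    source: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        if self.region not in ("any", "N-terminal", "C-terminal"):
            raise ConfigurationError(f"{self.name}: unknown region {self.region!r}")

    @property
    def min_length(self) -> int:
        return sum(t.min_repeat for t in self.tokens)

    @property
    def max_length(self) -> int:
        return sum(t.max_repeat for t in self.tokens)

    def effective_window(self, seq_len: int) -> int:
        if self.region == "any":
            return seq_len
        if self.region_window is not None:
            return self.region_window
        if self.region == "N-terminal":
            return DEFAULT_NTERM_WINDOW
        return max(80, int(0.4 * seq_len))


def _parse_element(elem: str, hydrophobic: frozenset[str]) -> frozenset[str]:
    if elem == "x":
        return ALL_RESIDUES
    if elem == "h":
        return hydrophobic
    if elem.startswith("["):
        letters = [c for c in elem[1:-1] if c != "/"]
        if not letters:
            raise PatternSyntaxError(f"empty alternative {elem!r}")
        bad = [c for c in letters if c not in ALL_RESIDUES]
        if bad:
            raise PatternSyntaxError(f"unknown residue(s) {bad} in {elem!r}")
        return frozenset(letters)
    if elem in ALL_RESIDUES:
        return frozenset(elem)
    raise PatternSyntaxError(f"unknown element {elem!r}")


def _split_elements(text: str) -> list[str]:
    """Split on dashes that separate elements (not dashes inside (n-m) or [..])."""
    parts: list[str] = []
    buf: list[str] = []
    depth = 0
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        if ch == "-" and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def parse_pattern(
    text: str,
    name: str = "",
    region: str = "any",
    region_window: int | None = None,
    role: str = "",
    source: str = "",
    hydrophobic: frozenset[str] = HYDROPHOBIC,
) -> MotifPattern:
    """Parse a dash-separated signature string into a MotifPattern."""
    tokens: list[MotifToken] = []
    for pos, raw in enumerate(_split_elements(text.strip())):
        m = _TOKEN_RE.match(raw.strip())
        if m is None:
            raise PatternSyntaxError(f"{text!r}: cannot parse element {pos + 1} ({raw!r})")
        lo = int(m.group("lo")) if m.group("lo") else 1
        hi = int(m.group("hi")) if m.group("hi") else lo
        if lo > hi:
            raise PatternSyntaxError(f"{text!r}: repeat range {lo}>{hi} at element {pos + 1}")
        try:
            residues = _parse_element(m.group("elem"), hydrophobic)
        except PatternSyntaxError as exc:
            raise PatternSyntaxError(f"{text!r}: element {pos + 1}: {exc}") from exc
        tokens.append(MotifToken(residues=residues, min_repeat=lo, max_repeat=hi))
    if not tokens:
        raise PatternSyntaxError("empty pattern")
    return MotifPattern(
        name=name or text,
        tokens=tuple(tokens),
        region=region,
        region_window=region_window,
        role=role,
        source=source,
        text=text,
    )


def render_pattern(pattern: MotifPattern) -> str:
    """Inverse of :func:`parse_pattern` for the bundled dialect."""
    parts = []
    for tok in pattern.tokens:
        if tok.residues == ALL_RESIDUES:
            elem = "x"
        elif tok.residues == HYDROPHOBIC:
            elem = "h"
        elif len(tok.residues) == 1:
            elem = next(iter(tok.residues))
        else:
            elem = "[" + "/".join(sorted(tok.residues)) + "]"
        if tok.min_repeat == tok.max_repeat == 1:
            parts.append(elem)
        elif tok.min_repeat == tok.max_repeat:
            parts.append(f"{elem}({tok.min_repeat})")
        else:
            parts.append(f"{elem}({tok.min_repeat}-{tok.max_repeat})")
    return "-".join(parts)


def region_slice(sequence: str, region: str, window: int) -> tuple[int, str]:
    """Return (0-based offset, subsequence) for a region constraint.

    Match coordinates found inside the slice are reported in the frame of
    the full sequence by adding the offset.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(sequence)
    if region == "N-terminal":
        return 0, sequence[: min(window, n)]
    if region == "C-terminal":
        off = max(0, n - window)
        return off, sequence[off:]
    return 0, sequence


def scan(sequence: str, pattern: MotifPattern) -> list[MotifMatch]:
    """Find all distinct occurrences of ``pattern`` within its region window.

    For every start position the token list is advanced over a frontier of
    reachable offsets, enumerating each admissible width of every
    variable-gap token; all (start, end) pairs reaching the end of the
    token list are reported.  Overlapping and nested matches are kept.
    """
    if not sequence:
        raise ValueError("empty sequence")
    offset, sub = region_slice(sequence, pattern.region, pattern.effective_window(len(sequence)))
    n = len(sub)
    found: set[tuple[int, int]] = set()
    min_len = pattern.min_length
    for start in range(0, n - min_len + 1):
        frontier = {start}
        for tok in pattern.tokens:
            nxt: set[int] = set()
            for p in frontier:
                # widths min..max share a prefix, so extend incrementally
                q = p
                for w in range(1, tok.max_repeat + 1):
                    if q >= n or sub[q] not in tok.residues:
                        break
                    q += 1
                    if w >= tok.min_repeat:
                        nxt.add(q)
            frontier = nxt
            if not frontier:
                break
        for end in frontier:
            found.add((start, end))
    matches = [
        MotifMatch(
            pattern_name=pattern.name,
            start=offset + s + 1,
            end=offset + e,
            matched_subsequence=sequence[offset + s : offset + e],
        )
        for s, e in sorted(found)
    ]
    return matches


@dataclass
class MotifCatalog:
    """A named collection of signatures grouped by functional role."""

    patterns: dict[str, MotifPattern] = field(default_factory=dict)
    hydrophobic: frozenset[str] = HYDROPHOBIC

    def add(self, pattern: MotifPattern) -> None:
        if pattern.name in self.patterns:
            raise ConfigurationError(f"duplicate pattern name {pattern.name!r}")
        self.patterns[pattern.name] = pattern

    def __getitem__(self, name: str) -> MotifPattern:
        return self.patterns[name]

    def by_role(self, role: str) -> list[MotifPattern]:
        return [p for p in self.patterns.values() if p.role == role]

    def require_role(self, role: str) -> list[MotifPattern]:
        pats = self.by_role(role)
        if not pats:
            raise ConfigurationError(f"motif catalog has no patterns for role {role!r}")
        return pats

    def scan_role(self, sequence: str, role: str) -> list[MotifMatch]:
        """All matches of any pattern carrying ``role``."""
        out: list[MotifMatch] = []
        for pat in self.require_role(role):
            out.extend(scan(sequence, pat))
        return out


def load_motif_catalog(path: str | Path | None = None) -> MotifCatalog:
    """Load the motif catalog from YAML (the bundled default if no path).

    The bundled file carries every signature used by the validators; the
    H-cluster (P1/P2/P3) and [NiFe] L1/L2 entries are editable literature
    consensus strings (see the file's own source annotations).
    """
    if path is None:
        data = yaml.safe_load(
            resources.files("hydromine.data").joinpath("motif_catalog.yaml").read_text()
        )
    else:
        data = yaml.safe_load(Path(path).read_text())
    hydrophobic = frozenset(data.get("hydrophobic", "".join(sorted(HYDROPHOBIC))))
    catalog = MotifCatalog(hydrophobic=hydrophobic)
    for entry in data["patterns"]:
        catalog.add(
            parse_pattern(
                entry["pattern"],
                name=entry["name"],
                region=entry.get("region", "any"),
                region_window=entry.get("window"),
                role=entry.get("role", entry["name"]),
                source=entry.get("source", ""),
                hydrophobic=hydrophobic,
            )
        )
    return catalog
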