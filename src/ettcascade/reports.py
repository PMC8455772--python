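"""Regex parsing of radiology report text.

Two jobs: decide whether a report describes an endotracheal tube as
present, absent, or uncertain (conflicting statements), and pull out a
documented tip–carina distance.  Pattern families, the 5-token negation
window and the 15 cm plausibility bound are configurable module defaults.
Parsing is pure — same text, same result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import pandas as pd


class EttStatus(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    UNCERTAIN = "UNCERTAIN"


@dataclass(frozen=True)
class ReportParse:
    ett_status: EttStatus
    distance_cm: float | None
    matched_span: tuple[int, int] | None
    implausible: bool = False


# "ET tube", "ETT", "endotracheal tube" — but not "nasogastric tube" etc.
ETT_PATTERN = re.compile(
    r"endo[\s-]?tracheal\s+tube|\bET\s+tube\b|\bETT\b",
    re.IGNORECASE,
)

NEGATION_TOKENS = frozenset({
    "no", "not", "without", "absent", "removed", "removal",
    "extubated", "extubation", "discontinued", "withdrawn",
})

_TOKEN = re.compile(r"[A-Za-z0-9.']+")

# Sentence boundaries: ., !, ?, ; followed by whitespace (decimals survive).
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?;])\s+")

DISTANCE_PATTERN = re.compile(
    r"(\d+(?:\.\d+)?)\s*(cm|mm)\s+"
    r"(?:above|from|below|beyond|proximal\s+to)\s+"
    r"(?:the\s+)?(?:level\s+of\s+the\s+)?carina",
    re.IGNORECASE,
)

PLAUSIBLE_MAX_CM = 15.0


def detect_ett(
    text: str,
    negation_window: int = 5,
    negation_tokens: frozenset[str] = NEGATION_TOKENS,
) -> tuple[EttStatus, tuple[int, int] | None]:
    """Classify ETT presence from free text.

    Each mention is negated if a negation/removal token occurs within
    ``negation_window`` tokens before or after it *inside the same
    sentence*.  All mentions positive -> PRESENT; all negated (or none
    found) -> ABSENT; a mix -> UNCERTAIN.  Returns the span of the first
    triggering mention.
    """
    if not text:
        raise ValueError("text must be non-empty")
    statuses: list[bool] = []  # True = affirmed mention
    first_span: tuple[int, int] | None = None
    bounds = [0] + [m.end() for m in _SENTENCE_SPLIT.finditer(text)] + [len(text)]
    for start, stop in zip(bounds, bounds[1:]):
        sentence = text[start:stop]
        tokens = [(m.group(0).lower().rstrip("."), m.start(), m.end())
                  for m in _TOKEN.finditer(sentence)]
        for m in ETT_PATTERN.finditer(sentence):
            if first_span is None:
                first_span = (start + m.start(), start + m.end())
            before = [t for t in tokens if t[2] <= m.start()][-negation_window:]
            after = [t for t in tokens if t[1] >= m.end()][:negation_window]
            negated = any(t[0] in negation_tokens for t in before + after)
            statuses.append(not negated)
    if not statuses:
        return EttStatus.ABSENT, None
    if all(statuses):
        return EttStatus.PRESENT, first_span
    if not any(statuses):
        return EttStatus.ABSENT, first_span
    return EttStatus.UNCERTAIN, first_span


def extract_distance_cm(text: str, max_cm: float = PLAUSIBLE_MAX_CM) -> float | None:
    """First plausible numeric tip–carina distance in the text, in cm."""
    if not text:
        raise ValueError("text must be non-empty")
    for m in DISTANCE_PATTERN.finditer(text):
        value = float(m.group(1))
        if m.group(2).lower() == "mm":
            value /= 10.0
        if 0.0 < value <= max_cm:
            return value
    return None


def parse_report(text: str, negation_window: int = 5,
                 max_cm: float = PLAUSIBLE_MAX_CM) -> ReportParse:
    status, span = detect_ett(text, negation_window=negation_window)
    distance = None
    implausible = False
    if status is EttStatus.PRESENT:
        distance = extract_distance_cm(text, max_cm=max_cm)
        if distance is None and DISTANCE_PATTERN.search(text):
            implausible = True  # matched a distance phrase but value out of range
    return ReportParse(ett_status=status, distance_cm=distance,
                       matched_span=span, implausible=implausible)


def parse_reports_frame(df: pd.DataFrame) -> pd.DataFrame:
    """CSV contract: (exam_id, report_text) in -> parse columns out."""
    if not {"exam_id", "report_text"}.issubset(df.columns):
        raise ValueError("input must have exam_id and report_text columns")
    rows = []
    for _, row in df.iterrows():
        p = parse_report(str(row["report_text"]))
        rows.append({
            "exam_id": row["exam_id"],
            "ett_status": p.ett_status.value,
            "distance_cm": p.distance_cm,
            "matched_span": "" if p.matched_span is None
                            else f"{p.matched_span[0]}:{p.matched_span[1]}",
        })
    return pd.DataFrame(rows)
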