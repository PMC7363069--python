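"""Reading and writing World-Color-Survey-style files.

Two tab-separated dialects are supported for chip charts:

* ``wcs_lab_table`` — the survey's chart file (``cnum-vhcm-lab.txt``): one row
  per chip with the 1-based chip number first, Munsell codes in the middle and
  L*, a*, b* as the last three columns.
* ``generic_tsv`` — a minimal ``chip_id  L  a  b`` table with a header row.

Naming data uses the survey's term-file layout: one response per row,
``language  speaker  chip  term``, with 1-based chip numbers.  Chip numbers
are converted to the package's 0-based ids on read and back on write.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

from .color_domain import ChipChart, ColorChip
from .partitioning import Partition

__all__ = [
    "ParseError",
    "IntegrityError",
    "CoverageError",
    "SpeakerResponses",
    "LanguageNamingData",
    "read_chip_chart",
    "write_chip_chart",
    "read_naming_data",
    "write_naming_data",
    "human_mode_map",
    "estimate_p_w_given_c",
    "naming_model_from_language",
]


class ParseError(ValueError):
    """A file row could not be parsed; the message names the line."""


class IntegrityError(ValueError):
    """Parsed data is internally inconsistent (duplicate or out-of-range ids)."""


class CoverageError(ValueError):
    """A chart chip has no naming responses; the message lists the chips."""


@dataclass
class SpeakerResponses:
    """One speaker's naming responses: chip_id (0-based) -> term label."""

    language_id: int
    speaker_id: int
    responses: dict[int, str] = field(default_factory=dict)


@dataclass
class LanguageNamingData:
    """All speakers of one language plus the language's term inventory."""

    language_id: int
    speakers: list[SpeakerResponses] = field(default_factory=list)
    term_inventory: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        used = {t for s in self.speakers for t in s.responses.values()}
        if not used <= self.term_inventory:
            raise IntegrityError(
                f"language {self.language_id}: responses use terms outside the "
                f"inventory: {sorted(used - self.term_inventory)}"
            )

    def responses_for_chip(self, chip_id: int) -> list[str]:
        return [s.responses[chip_id] for s in self.speakers if chip_id in s.responses]


def _rows(path: str | Path) -> list[tuple[int, list[str]]]:
    text = Path(path).read_text()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        rows.append((lineno, line.split("\t")))
    return rows


def read_chip_chart(
    path: str | Path, dialect: str = "wcs_lab_table", name: str | None = None
) -> ChipChart:
    """Read a chip chart; chips are re-indexed 0-based in chip-number order."""
    if dialect not in ("wcs_lab_table", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = _rows(path)
    if not rows:
        raise ParseError(f"{path}: file is empty")

    records: dict[int, tuple] = {}
    for lineno, fields in rows:
        try:
            number = int(fields[0])
        except ValueError:
            if lineno == rows[0][0]:  # tolerate one header row
                continue
            raise ParseError(f"{path}:{lineno}: chip number {fields[0]!r} is not an integer")
        try:
            lab = tuple(float(v) for v in fields[-3:])
            if len(fields) < 4:
                raise ValueError
        except ValueError:
            raise ParseError(f"{path}:{lineno}: expected three L*, a*, b* columns")
        hue = value = None
        if dialect == "wcs_lab_table" and len(fields) >= 9:
            hue, value = fields[4], fields[5]
        if number in records:
            raise IntegrityError(f"{path}:{lineno}: duplicate chip number {number}")
        records[number] = (lab, hue, value)
    if not records:
        raise ParseError(f"{path}: no chip rows found")

    chips = [
        ColorChip(i, lab, munsell_hue=hue, munsell_value=value)
        for i, (_, (lab, hue, value)) in enumerate(sorted(records.items()))
    ]
    return ChipChart(chips=chips, name=name or Path(path).stem)


def write_chip_chart(chart: ChipChart, path: str | Path) -> None:
    """Write a chart in the generic dialect (1-based chip numbers, header row)."""
    lines = ["chip\tL\ta\tb"]
    for chip in chart:
        l_, a_, b_ = chip.coords
        lines.append(f"{chip.chip_id + 1}\t{l_:.6g}\t{a_:.6g}\t{b_:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_naming_data(
    path: str | Path, chart: ChipChart | None = None
) -> list[LanguageNamingData]:
    """Read a term file; responses referencing chips outside ``chart`` are rejected."""
    rows = _rows(path)
    if not rows:
        raise ParseError(f"{path}: file is empty")
    n = len(chart) if chart is not None else None

    speakers: dict[tuple[int, int], SpeakerResponses] = {}
    langs: dict[int, list[SpeakerResponses]] = collections.defaultdict(list)
    for lineno, fields in rows:
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        try:
            lang_id, speaker_id, chip_number = (int(fields[i]) for i in range(3))
        except ValueError:
            if lineno == rows[0][0]:
                continue
            raise ParseError(f"{path}:{lineno}: non-integer language/speaker/chip field")
        term = fields[3]
        chip_id = chip_number - 1
        if chip_id < 0 or (n is not None and chip_id >= n):
            raise IntegrityError(
                f"{path}:{lineno}: chip {chip_number} outside the "
                f"{n if n is not None else '?'}-chip chart"
            )
        key = (lang_id, speaker_id)
        if key not in speakers:
            speakers[key] = SpeakerResponses(lang_id, speaker_id)
            langs[lang_id].append(speakers[key])
        if chip_id in speakers[key].responses:
            raise IntegrityError(
                f"{path}:{lineno}: speaker {speaker_id} of language {lang_id} "
                f"names chip {chip_number} twice"
            )
        speakers[key].responses[chip_id] = term

    out = []
    for lang_id in sorted(langs):
        spk = sorted(langs[lang_id], key=lambda s: s.speaker_id)
        inventory = {t for s in spk for t in s.responses.values()}
        out.append(LanguageNamingData(lang_id, spk, inventory))
    return out


def write_naming_data(languages: list[LanguageNamingData], path: str | Path) -> None:
    """Write term-file rows (1-based chip numbers), sorted for reproducibility."""
    lines = []
    for lang in sorted(languages, key=lambda g: g.language_id):
        for s in sorted(lang.speakers, key=lambda s: s.speaker_id):
            for chip_id in sorted(s.responses):
                lines.append(
                    f"{lang.language_id}\t{s.speaker_id}\t{chip_id + 1}\t{s.responses[chip_id]}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _chip_counts(lang: LanguageNamingData, chip_id: int) -> collections.Counter:
    return collections.Counter(lang.responses_for_chip(chip_id))


def human_mode_map(lang: LanguageNamingData, chart: ChipChart) -> Partition:
    """Modal term per chip across speakers; ties go to the lexicographically
    smallest term.  Every chart chip must have at least one response."""
    uncovered = [c.chip_id for c in chart if not lang.responses_for_chip(c.chip_id)]
    if uncovered:
        raise CoverageError(
            f"language {lang.language_id}: no responses for chips {uncovered}"
        )
    labels: dict[int, Hashable] = {}
    for chip in chart:
        counts = _chip_counts(lang, chip.chip_id)
        top = max(counts.values())
        labels[chip.chip_id] = min(t for t, c in counts.items() if c == top)
    return Partition(labels=labels, chart_ref=chart.name, n_chips=len(chart))


def estimate_p_w_given_c(lang: LanguageNamingData, chip_id: int) -> dict[str, float]:
    """Empirical term distribution at one chip: fraction of respondents per term."""
    counts = _chip_counts(lang, chip_id)
    total = sum(counts.values())
    if total == 0:
        raise CoverageError(f"language {lang.language_id}: no responses for chip {chip_id}")
    return {t: c / total for t, c in counts.items()}


def naming_model_from_language(lang: LanguageNamingData, chart: ChipChart):
    """Empirical :class:`~colorgame.metrics.NamingModel` over the whole chart."""
    from .metrics import NamingModel

    return NamingModel(
        {chip.chip_id: estimate_p_w_given_c(lang, chip.chip_id) for chip in chart}
    )
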