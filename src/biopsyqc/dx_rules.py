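"""Keyword rule engine for pathology report text.

Free-text pathologic diagnoses of gastrointestinal endoscopic biopsies are
mapped onto four QC classes:

* ``M`` — malignancy or high-grade dysplasia cannot be ruled out
* ``D`` — low-grade dysplasia cannot be ruled out
* ``N`` — negative for dysplasia
* ``U`` — uncategorized (neuroendocrine tumor G1/G2 cannot be ruled out)

Classification is by keyword phrase lists evaluated in priority order
M > U > D > N, with one carve-out: the sessile-serrated phrases
("sessile serrated adenoma/polyp", "sessile serrated adenoma",
"sessile serrated lesion") force class N even though they contain the
class-D keyword "adenoma".  Matching is case-insensitive on word
boundaries — "high" fires as a token, never inside "higher" — except
"NET", which only fires as a standalone all-uppercase token so that
"net" inside ordinary prose cannot flag a neuroendocrine tumor.

The same priority order doubles as the aggregation rule when several
serial slides of one specimen (paraffin block) carry different classes:
the most clinically serious class wins, never the most frequent one.

Specimen routing to the gastric or colorectal image model uses a second
phrase table applied to the specimen heading; headings matching neither
organ (esophagus, duodenum, anus, ...) are *unrouted* and no image model
is run for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

CLASSES = ("M", "D", "N", "U")

#: total severity order used both for keyword priority and for serial-slide
#: aggregation: Malignant > Uncategorized > Dysplasia > Negative.
CLASS_PRIORITY = {"M": 3, "U": 2, "D": 1, "N": 0}

DEFAULT_KEYWORDS: dict[str, list[str]] = {
    "M": [
        "carcinoma", "high", "grade undetermined", "grade uncertain",
        "favor neoplastic", "sarcoma", "lymphoma", "malignant",
        "malignancy", "cancer",
    ],
    "U": ["neuroendocrine", "carcinoid", "NET"],
    "N_OVERRIDE": [
        "sessile serrated adenoma/polyp",
        "sessile serrated adenoma",
        "sessile serrated lesion",
    ],
    "D": ["dysplasia", "adenoma", "low", "indefinite for dysplasia",
          "undetermined significance"],
}

#: phrases flagged case-sensitive: match only as the exact standalone token
CASE_SENSITIVE = {"NET"}

ORGAN_KEYWORDS: dict[str, list[str]] = {
    "gastric": ["stomach", "esophagogastric junction", "gastroesophageal junction"],
    "colorectal": [
        "terminal ileum", "ileocecal valve", "cecum", "colon",
        "large intestine", "rectosigmoid junction", "colon and rectum",
        "rectum",
    ],
}

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

#: derivational suffixes a keyword token may carry in report prose:
#: plurals ("carcinomas") and the adjectival "-tous" ("carcinomatous").
#: Comparative forms are deliberately NOT included, so the grading
#: keyword "high" never fires inside "higher".
_KEYWORD_SUFFIXES = ("", "s", "tous")

#: minimum keyword length for compound-term matching, where the keyword
#: may sit at the end of a longer token ("adenocarcinoma" fires
#: "carcinoma", "leiomyosarcoma" fires "sarcoma"); short grading words
#: stay exact so "yellow" can never fire "low".
_COMPOUND_MIN_LEN = 6


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def _token_matches(token: str, keyword_token: str) -> bool:
    for suf in _KEYWORD_SUFFIXES:
        if token == keyword_token + suf:
            return True
        if len(keyword_token) >= _COMPOUND_MIN_LEN and \
                token.endswith(keyword_token + suf):
            return True
    return False


def _contains_phrase(tokens_lower: Sequence[str], tokens_raw: Sequence[str],
                     phrase: str) -> bool:
    """Contiguous token-sequence match, whitespace/punctuation-insensitive."""
    if phrase in CASE_SENSITIVE:
        return phrase in tokens_raw
    ptoks = [t.lower() for t in _tokens(phrase)]
    n = len(ptoks)
    if n == 0:
        return False
    return any(
        all(_token_matches(tokens_lower[i + j], ptoks[j]) for j in range(n))
        for i in range(len(tokens_lower) - n + 1)
    )


@dataclass
class KeywordTable:
    """Ordered phrase lists per class, loadable from YAML config."""

    m_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS["M"]))
    u_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS["U"]))
    n_overrides: list[str] = field(
        default_factory=lambda: list(DEFAULT_KEYWORDS["N_OVERRIDE"]))
    d_phrases: list[str] = field(default_factory=lambda: list(DEFAULT_KEYWORDS["D"]))
    case_sensitive: set[str] = field(default_factory=lambda: set(CASE_SENSITIVE))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KeywordTable":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            m_phrases=list(data.get("M", DEFAULT_KEYWORDS["M"])),
            u_phrases=list(data.get("U", DEFAULT_KEYWORDS["U"])),
            n_overrides=list(data.get("N_OVERRIDE", DEFAULT_KEYWORDS["N_OVERRIDE"])),
            d_phrases=list(data.get("D", DEFAULT_KEYWORDS["D"])),
            case_sensitive=set(data.get("case_sensitive", CASE_SENSITIVE)),
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = {"M": self.m_phrases, "U": self.u_phrases,
                "N_OVERRIDE": self.n_overrides, "D": self.d_phrases,
                "case_sensitive": sorted(self.case_sensitive)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class DxRecord:
    """One diagnosis record: accession + heading + free-text diagnosis."""

    accession: str
    block_id: str
    heading: str
    diagnosis_text: str
    organ: str | None = None
    dx_class: str | None = None  # derived from diagnosis_text

    def classified(self, table: KeywordTable | None = None) -> "DxRecord":
        self.dx_class = classify_dx(self.diagnosis_text, table)
        return self


def classify_dx(diagnosis_text: str, table: KeywordTable | None = None) -> str:
    """Classify free diagnosis text into {M, D, N, U}.

    Total function: any string gets exactly one class, defaulting to N
    ("other") when no keyword fires.  Evaluation order M > U >
    sessile-serrated override (N) > D.
    """
    table = table or KeywordTable()
    raw = _tokens(diagnosis_text)
    low = [t.lower() for t in raw]

    def hit(phrases: Iterable[str]) -> bool:
        return any(
            (p in table.case_sensitive and p in raw)
            or (p not in table.case_sensitive and _contains_phrase(low, raw, p))
            for p in phrases
        )

    if hit(table.m_phrases):
        return "M"
    if hit(table.u_phrases):
        return "U"
    if hit(table.n_overrides):
        return "N"
    if hit(table.d_phrases):
        return "D"
    return "N"


def route_organ(heading: str) -> str:
    """Route a specimen heading to {gastric, colorectal, unrouted}.

    Case-insensitive phrase match against the organ keyword table.  A
    heading line matching both organ lists, or lines matching different
    organs, cannot be served by a single model and returns ``unrouted``;
    so do headings for organs with no model (esophagus, duodenum, anus).
    """
    line_routes: set[str] = set()
    for line in heading.splitlines() or [""]:
        raw = _tokens(line)
        low = [t.lower() for t in raw]
        matched = {organ for organ, phrases in ORGAN_KEYWORDS.items()
                   if any(_contains_phrase(low, raw, p) for p in phrases)}
        if len(matched) > 1:
            return "unrouted"
        line_routes |= matched
    if len(line_routes) == 1:
        return next(iter(line_routes))
    return "unrouted"


def aggregate_classes(classes: Sequence[str]) -> str:
    """Final class of a multi-slide specimen: worst class wins (M>U>D>N)."""
    if not classes:
        raise ValueError("cannot aggregate an empty class list")
    bad = set(classes) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown classes: {sorted(bad)}")
    return max(classes, key=CLASS_PRIORITY.__getitem__)


@dataclass
class SpecimenGroup:
    """Slides cut from one paraffin block, with their per-slide classes."""

    block_id: str
    slide_ids: list[str]
    ai_classes: list[str | None] = field(default_factory=list)
    dx_classes: list[str | None] = field(default_factory=list)

    def aggregate_ai(self) -> str:
        return aggregate_classes([c for c in self.ai_classes if c])

    def aggregate_dx(self) -> str:
        return aggregate_classes([c for c in self.dx_classes if c])


def group_specimens(slides: Sequence[dict]) -> list[SpecimenGroup]:
    """Group slide entries by block_id.

    Each entry is a mapping with keys ``slide_id``, ``block_id`` and
    optionally ``ai_class`` / ``dx_class``.  Slides missing a block_id go
    into their own singleton group (warned), since serial aggregation is
    impossible without block identity.
    """
    import warnings

    groups: dict[str, SpecimenGroup] = {}
    singletons: list[SpecimenGroup] = []
    for s in slides:
        bid = s.get("block_id")
        if not bid:
            warnings.warn(f"slide {s.get('slide_id')} has no block_id; "
                          "treated as its own specimen")
            g = SpecimenGroup(block_id=f"_solo_{s.get('slide_id')}",
                              slide_ids=[s["slide_id"]])
            g.ai_classes.append(s.get("ai_class"))
            g.dx_classes.append(s.get("dx_class"))
            singletons.append(g)
            continue
        g = groups.setdefault(bid, SpecimenGroup(block_id=bid, slide_ids=[]))
        g.slide_ids.append(s["slide_id"])
        g.ai_classes.append(s.get("ai_class"))
        g.dx_classes.append(s.get("dx_class"))
    return list(groups.values()) + singletons


# -- record IO ----------------------------------------------------------

def read_records(path: str | Path, table: KeywordTable | None = None) -> list[DxRecord]:
    """Read DxRecords from JSONL (or CSV) and derive dx_class for each."""
    import json

    path = Path(path)
    records: list[DxRecord] = []
    if path.suffix.lower() == ".csv":
        import pandas as pd

        for row in pd.read_csv(path).to_dict("records"):
            records.append(DxRecord(
                accession=str(row["accession"]), block_id=str(row["block_id"]),
                heading=str(row["heading"]), diagnosis_text=str(row["diagnosis"]),
                organ=row.get("organ")))
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                row = json.loads(line)
                records.append(DxRecord(
                    accession=row["accession"], block_id=row["block_id"],
                    heading=row["heading"], diagnosis_text=row["diagnosis"],
                    organ=row.get("organ")))
    for r in records:
        r.classified(table)
    return records


def write_records(records: Sequence[DxRecord], path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({
                "accession": r.accession, "block_id": r.block_id,
                "heading": r.heading, "diagnosis": r.diagnosis_text,
                "organ": r.organ, "dx_class": r.dx_class,
            }) + "\n")
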