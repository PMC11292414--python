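"""Parsing and labelling of ISCN-style karyotype records.

Cancer cell line vendors and the cytogenetics literature describe karyotypes
in a loosely standardised text notation (ISCN), e.g. ``"46,XY,del(9)(p21)"``.
This module parses a pragmatic subset of that notation into a structured
:class:`CytogeneticProfile`, scores how much confidence the record supports
(0 = no data ... 3 = direct double-minute/HSR language), and turns profiles
into extrachromosomal-DNA (ecDNA) and homogeneously-staining-region (HSR)
labels.

Double minutes ("dmin") are the metaphase manifestation of ecDNA, so a
karyotype that reports them is direct evidence of ecDNA; a detailed karyotype
that is silent about dmin/HSR is treated as a medium-confidence negative,
and a minimal record (say, only a modal chromosome number) supports no call
at all.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Valid human chromosome names, in karyotype order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_SET = frozenset(CHROMOSOMES)

#: Record-source precedence used for tie-breaking (lower wins).
SOURCE_PRECEDENCE: Mapping[str, int] = {"literature": 0, "vendor": 1, "registry": 2}

PLOIDY_CLASSES: tuple[str, ...] = (
    "near-haploid",
    "near-diploid",
    "near-triploid",
    "near-tetraploid",
    "hyperploid",
    "unknown",
)


class KaryotypeParseError(ValueError):
    """A karyotype token is structurally malformed (e.g. inverted range)."""


def chrom_sort_key(chrom: str) -> int:
    return CHROMOSOMES.index(chrom)


@dataclass(frozen=True)
class KaryotypeRecord:
    """One raw karyotype record for a cell line, with provenance."""

    cell_line_id: str
    source: str  # literature | vendor | registry
    raw_text: str
    validation_source: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCE_PRECEDENCE:
            raise ValueError(f"unknown record source: {self.source!r}")


@dataclass
class CytogeneticProfile:
    """Structured cytogenetic features extracted from one karyotype record."""

    modal_number: int | None = None
    modal_range: tuple[int, int] | None = None
    ploidy_class: str = "unknown"
    percent_polyploidy: float = 0.0
    sex_complement: str = ""
    dmin_range: tuple[int, int] = (0, 0)
    hsr_count: int = 0
    chrom_gains: dict[str, int] = field(default_factory=dict)
    chrom_losses: dict[str, int] = field(default_factory=dict)
    marker_range: tuple[int, int] = (0, 0)
    derivative_chroms: set[str] = field(default_factory=set)
    translocation_chroms: set[tuple[str, str]] = field(default_factory=set)
    structural_variant_total: int = 0
    unparsed_token_count: int = 0
    # Direct-language flags: a dmin/hsr token (or its explicit negation) was seen.
    dmin_observed: bool = False
    dmin_negated: bool = False
    hsr_observed: bool = False
    hsr_negated: bool = False
    composite_count: int = 0
    # Per-chromosome counts of add/del/dup/iso events (der and t have their own sets).
    event_chroms: dict[str, Counter] = field(
        default_factory=lambda: {k: Counter() for k in ("add", "del", "dup", "iso")}
    )

    def __post_init__(self) -> None:
        for rng, name in (
            (self.modal_range, "modal_range"),
            (self.dmin_range, "dmin_range"),
            (self.marker_range, "marker_range"),
        ):
            if rng is not None and rng[1] < rng[0]:
                raise KaryotypeParseError(f"{name} has high < low: {rng}")
        if not 0.0 <= self.percent_polyploidy <= 100.0:
            raise ValueError("percent_polyploidy must lie in [0, 100]")
        if self.hsr_count < 0 or self.structural_variant_total < 0:
            raise ValueError("counts must be non-negative")

    @property
    def modal_midpoint(self) -> float | None:
        if self.modal_range is not None:
            return (self.modal_range[0] + self.modal_range[1]) / 2.0
        if self.modal_number is not None:
            return float(self.modal_number)
        return None


@dataclass(frozen=True)
class AmplificationLabel:
    """ecDNA / HSR call for one cell line: positive, negative or unknown."""

    ecdna: str
    hsr: str

    _ALLOWED = frozenset({"positive", "negative", "unknown"})

    def __post_init__(self) -> None:
        if self.ecdna not in self._ALLOWED or self.hsr not in self._ALLOWED:
            raise ValueError("labels must be positive/negative/unknown")


@dataclass(frozen=True)
class MetaphasePanel:
    """Per-metaphase-image ecDNA counts for one sample."""

    image_counts: tuple[int, ...]

    @property
    def n_images(self) -> int:
        return len(self.image_counts)


# --- token grammar -----------------------------------------------------------

_CHROM_RE = r"(\d{1,2}|X|Y)"
_MODAL_RE = re.compile(r"^(\d+)(?:\s*[~–-]\s*(\d+))?(?:<(\d+)n[+-]?>)?$")
_PLOIDY_TAG_RE = re.compile(r"^<(\d+)n[+-]?>$")
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_GAIN_RE = re.compile(rf"^\+{_CHROM_RE}$")
_LOSS_RE = re.compile(rf"^[-−]{_CHROM_RE}$")
_ADD_RE = re.compile(rf"^add\({_CHROM_RE}\)(?:\([^()]*\))?$")
_DEL_RE = re.compile(rf"^del\({_CHROM_RE}\)(?:\([^()]*\))?$")
_DUP_RE = re.compile(rf"^dup\({_CHROM_RE}\)(?:\([^()]*\))?$")
_ISO_RE = re.compile(rf"^i\({_CHROM_RE}\)(?:\([^()]*\))?$")
_DER_RE = re.compile(rf"^der\({_CHROM_RE}\)(.*)$")
_T_RE = re.compile(rf"^t\({_CHROM_RE};{_CHROM_RE}\)(?:\([^()]*\))?$")
_EMBEDDED_T_RE = re.compile(rf"t\({_CHROM_RE};{_CHROM_RE}\)")
_DMIN_RE = re.compile(r"^(?:(\d+)(?:[~–-](\d+))?)?dmin$")
_HSR_RE = re.compile(rf"^(\d+)?hsr(?:\({_CHROM_RE}\)(?:\([^()]*\))?)?$")
_MAR_RE = re.compile(r"^\+?(?:(\d+)(?:[~–-](\d+))?)?mar$")
_POLY_RE = re.compile(r"^(\d+(?:\.\d+)?)%\s*poly(?:ploidy?)?$", re.IGNORECASE)
_CP_RE = re.compile(r"^\[cp\d*\]$")
_NO_DMIN_RE = re.compile(r"^no\s+dmin$", re.IGNORECASE)
_NO_HSR_RE = re.compile(r"^no\s+hsr$", re.IGNORECASE)


def _ordered_range(low: str, high: str | None, token: str) -> tuple[int, int]:
    lo = int(low)
    hi = int(high) if high is not None else lo
    if hi < lo:
        raise KaryotypeParseError(f"malformed range in token {token!r}: {hi} < {lo}")
    return lo, hi


def ploidy_class_from_modal(midpoint: float | None) -> str:
    """Bucket a modal chromosome count into a ploidy class (bands centred on 23n)."""
    if midpoint is None:
        return "unknown"
    if midpoint < 35:
        return "near-haploid"
    if midpoint <= 57:
        return "near-diploid"
    if midpoint <= 80:
        return "near-triploid"
    if midpoint <= 103:
        return "near-tetraploid"
    return "hyperploid"


_PLOIDY_TAG_MAP = {
    1: "near-haploid",
    2: "near-diploid",
    3: "near-triploid",
    4: "near-tetraploid",
}


def parse_karyotype(raw_text: str) -> CytogeneticProfile:
    """Parse an ISCN-like karyotype string into a :class:`CytogeneticProfile`.

    Every supported token is consumed exactly once; tokens outside the
    supported grammar increment ``unparsed_token_count`` and are logged,
    never silently dropped.

    Raises
    ------
    KaryotypeParseError
        For an empty string or a structurally malformed token
        (e.g. a count range with high < low).
    """
    if not raw_text or not raw_text.strip():
        raise KaryotypeParseError("empty karyotype string")

    prof = CytogeneticProfile()
    tokens = [t.strip() for t in raw_text.split(",") if t.strip()]
    n_events = dict.fromkeys(("add", "del", "dup", "iso", "der", "t"), 0)
    ploidy_tag: int | None = None

    for pos, token in enumerate(tokens):
        if pos == 0:
            m = _MODAL_RE.match(token)
            if m is not None:
                lo, hi = _ordered_range(m.group(1), m.group(2), token)
                if m.group(2) is not None:
                    prof.modal_range = (lo, hi)
                else:
                    prof.modal_number = lo
                if m.group(3) is not None:
                    ploidy_tag = int(m.group(3))
                continue
        m = _PLOIDY_TAG_RE.match(token)
        if m:
            ploidy_tag = int(m.group(1))
            continue
        if _SEX_RE.match(token):
            prof.sex_complement = token
            continue
        m = _GAIN_RE.match(token)
        if m and m.group(1) in _CHROM_SET:
            prof.chrom_gains[m.group(1)] = prof.chrom_gains.get(m.group(1), 0) + 1
            continue
        m = _LOSS_RE.match(token)
        if m and m.group(1) in _CHROM_SET:
            prof.chrom_losses[m.group(1)] = prof.chrom_losses.get(m.group(1), 0) + 1
            continue
        matched_event = False
        for name, rex in (("add", _ADD_RE), ("del", _DEL_RE), ("dup", _DUP_RE), ("iso", _ISO_RE)):
            m = rex.match(token)
            if m and m.group(1) in _CHROM_SET:
                prof.event_chroms[name][m.group(1)] += 1
                n_events[name] += 1
                matched_event = True
                break
        if matched_event:
            continue
        m = _T_RE.match(token)
        if m and m.group(1) in _CHROM_SET and m.group(2) in _CHROM_SET:
            pair = tuple(sorted((m.group(1), m.group(2)), key=chrom_sort_key))
            prof.translocation_chroms.add(pair)  # type: ignore[arg-type]
            n_events["t"] += 1
            continue
        m = _DER_RE.match(token)
        if m and m.group(1) in _CHROM_SET:
            prof.derivative_chroms.add(m.group(1))
            n_events["der"] += 1
            for em in _EMBEDDED_T_RE.finditer(m.group(2) or ""):
                if em.group(1) in _CHROM_SET and em.group(2) in _CHROM_SET:
                    pair = tuple(sorted((em.group(1), em.group(2)), key=chrom_sort_key))
                    prof.translocation_chroms.add(pair)  # type: ignore[arg-type]
            continue
        if _NO_DMIN_RE.match(token):
            prof.dmin_negated = True
            continue
        if _NO_HSR_RE.match(token):
            prof.hsr_negated = True
            continue
        m = _DMIN_RE.match(token)
        if m:
            if m.group(1) is None:
                prof.dmin_range = (1, 1)
            else:
                prof.dmin_range = _ordered_range(m.group(1), m.group(2), token)
            prof.dmin_observed = True
            continue
        m = _HSR_RE.match(token)
        if m:
            prof.hsr_count = int(m.group(1)) if m.group(1) else 1
            prof.hsr_observed = True
            continue
        m = _MAR_RE.match(token)
        if m:
            if m.group(1) is None:
                prof.marker_range = (1, 1)
            else:
                prof.marker_range = _ordered_range(m.group(1), m.group(2), token)
            continue
        m = _POLY_RE.match(token)
        if m:
            pct = float(m.group(1))
            if pct > 100:
                raise KaryotypeParseError(f"polyploidy percentage out of range: {token!r}")
            prof.percent_polyploidy = pct
            continue
        if _CP_RE.match(token):
            prof.composite_count += 1
            continue
        logger.debug("unparsed karyotype token: %r", token)
        prof.unparsed_token_count += 1

    prof.structural_variant_total = sum(n_events.values())
    if ploidy_tag is not None:
        prof.ploidy_class = _PLOIDY_TAG_MAP.get(ploidy_tag, "hyperploid")
    else:
        prof.ploidy_class = ploidy_class_from_modal(prof.modal_midpoint)
    return prof


# --- confidence and labels ---------------------------------------------------

#: Feature families counted towards the "detailed record" criterion.
def _populated_families(profile: CytogeneticProfile) -> int:
    families = (
        profile.modal_number is not None or profile.modal_range is not None,
        profile.ploidy_class != "unknown",
        profile.percent_polyploidy > 0,
        bool(profile.sex_complement),
        bool(profile.chrom_gains) or bool(profile.chrom_losses),
        profile.marker_range[1] > 0,
        profile.structural_variant_total > 0,
    )
    return sum(families)


def score_confidence(
    profile: CytogeneticProfile | None,
    record: KaryotypeRecord | None,
    detail_threshold: int = 3,
) -> int:
    """Score record confidence on the 0–3 scale.

    3 — direct dmin/HSR language (presence or explicit negation);
    2 — detailed record (>= ``detail_threshold`` populated feature families)
    without dmin/HSR language; 1 — minimal detail; 0 — no karyotype data.
    """
    if record is None or not record.raw_text.strip():
        return 0
    if profile is None:
        return 0
    if profile.dmin_observed or profile.hsr_observed or profile.dmin_negated or profile.hsr_negated:
        return 3
    if _populated_families(profile) >= detail_threshold:
        return 2
    return 1


def assign_labels(profile: CytogeneticProfile, confidence: int) -> AmplificationLabel:
    """Turn a profile + confidence score into ecDNA / HSR labels.

    Positive requires the corresponding token to have been observed; negative
    requires confidence >= 2 with the token absent (or explicitly negated);
    low-confidence records stay unknown — silence in a sketchy record is not
    evidence of absence.
    """
    if profile.dmin_observed and not profile.dmin_negated:
        ecdna = "positive"
    elif confidence >= 2:
        ecdna = "negative"
    else:
        ecdna = "unknown"
    if profile.hsr_observed and not profile.hsr_negated:
        hsr = "positive"
    elif confidence >= 2:
        hsr = "negative"
    else:
        hsr = "unknown"
    return AmplificationLabel(ecdna=ecdna, hsr=hsr)


def classify_metaphase_panel(
    panel: MetaphasePanel | Sequence[int],
    min_count: int = 2,
    min_images: int = 2,
) -> bool:
    """Pathology standard: positive iff >= ``min_images`` images show
    >= ``min_count`` ecDNA (default: >=2 ecDNA in >=2 of the images)."""
    counts = panel.image_counts if isinstance(panel, MetaphasePanel) else tuple(panel)
    if len(counts) < 1:
        raise ValueError("panel must contain at least one image")
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError("image counts must be non-negative integers")
    return sum(1 for c in counts if c >= min_count) >= min_images


def select_best_record(records: Sequence[KaryotypeRecord]) -> KaryotypeRecord:
    """Pick the single record to classify a cell line from.

    Any record mentioning double minutes outranks all others; otherwise the
    highest-confidence record wins, with ties broken by source precedence
    (literature > vendor > registry), then lexicographic validation_source,
    then raw_text. Deterministic and invariant to input order.
    """
    if not records:
        raise ValueError("no records supplied")

    def key(rec: KaryotypeRecord):
        prof = parse_karyotype(rec.raw_text) if rec.raw_text.strip() else None
        conf = score_confidence(prof, rec)
        dmin = prof is not None and prof.dmin_observed
        return (
            0 if dmin else 1,
            -conf,
            SOURCE_PRECEDENCE[rec.source],
            rec.validation_source,
            rec.raw_text,
        )

    return min(records, key=key)


def aberrant_chromosomes(profile: CytogeneticProfile) -> set[str]:
    """Chromosomes with any reported aberration (gain, loss, translocation,
    derivative, or add/del/dup/iso event) — used for overlap with external
    chromothripsis predictions."""
    out: set[str] = set(profile.chrom_gains) | set(profile.chrom_losses)
    out |= profile.derivative_chroms
    for pair in profile.translocation_chroms:
        out.update(pair)
    for counter in profile.event_chroms.values():
        out.update(counter)
    return out
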