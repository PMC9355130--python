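"""Family-history-based genetic-testing eligibility.

A data-driven rule engine deciding whether a person's personal and family
cancer history would have qualified them for clinical germline testing.  The
rule set ships as a versioned TSV (see ``data/rules.tsv``): the *base*
version codifies 2018-era familial breast-cancer testing criteria; the
*adjusted* version additionally fires on any close-relative prostate or
pancreatic cancer and on relative breast-cancer onset up to age 60.  The
adjusted rule set is a strict superset of the base set, and every rule is
monotone: adding a cancer event can never remove eligibility.

"Close relative" means first or second degree.  An unknown onset age never
satisfies an age-limited rule (conservative) but does satisfy any-age rules.

``parse_family_history`` turns free-text family-history strings in the
published tables' abbreviation grammar ("Mother's side: BC, 38, 46; OC, 56")
into structured events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .domain import CancerType, FamilyCancerEvent, PersonalHistory

_FH_ADJACENT_TYPES = {
    CancerType.BREAST,
    CancerType.OVARIAN,
    CancerType.PANCREATIC,
    CancerType.PROSTATE,
}

_TYPE_TOKENS = {
    "male bc": CancerType.MALE_BREAST,
    "bc": CancerType.BREAST,
    "oc": CancerType.OVARIAN,
    "pc": CancerType.PROSTATE,
    "pac": CancerType.PANCREATIC,
    "gc": CancerType.GASTRIC,
}

_CANCER_TYPE_NAMES = {t.value: t for t in CancerType}


@dataclass
class Rule:
    rule_id: str
    kind: str  # simple | bc50_combo | tnbc | multi_bc_lineage
    scope: str  # personal | family
    cancer_type: CancerType | None
    max_onset_age: float | None
    min_count: int
    versions: str  # both | base | adjusted

    def applies_to(self, version: str) -> bool:
        return self.versions in ("both", version)


@dataclass
class EligibilityResult:
    eligible: bool
    fired_rules: list[str]
    version: str


def load_rules(path=None) -> list[Rule]:
    if path is None:
        ref = resources.files("genofirst.data").joinpath("rules.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    rules = []
    for _, r in df.iterrows():
        ct = None
        if isinstance(r.cancer_type, str) and r.cancer_type.strip():
            token = r.cancer_type.strip()
            if token not in _CANCER_TYPE_NAMES:
                raise ValueError(f"unknown cancer_type token in rule table: {token!r}")
            ct = _CANCER_TYPE_NAMES[token]
        age = None if pd.isna(r.max_onset_age) else float(r.max_onset_age)
        rules.append(
            Rule(
                rule_id=r.rule_id,
                kind=r.kind,
                scope=r.scope,
                cancer_type=ct,
                max_onset_age=age,
                min_count=int(r.min_count),
                versions=r.versions,
            )
        )
    return rules


_DEFAULT_RULES: list[Rule] | None = None


def default_rules() -> list[Rule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def _age_ok(onset_age: float | None, max_age: float | None) -> bool:
    if max_age is None:
        return True
    return onset_age is not None and onset_age <= max_age


def _fires(
    rule: Rule, personal: PersonalHistory, family: list[FamilyCancerEvent]
) -> bool:
    if rule.kind == "simple":
        if rule.scope == "personal":
            hits = sum(
                1
                for c in personal.cancers
                if c.cancer_type == rule.cancer_type and _age_ok(c.onset_age, rule.max_onset_age)
            )
        else:
            hits = sum(
                1
                for e in family
                if e.cancer_type == rule.cancer_type and _age_ok(e.onset_age, rule.max_onset_age)
            )
        return hits >= rule.min_count

    if rule.kind == "tnbc":
        return any(
            c.cancer_type == CancerType.BREAST
            and c.triple_negative
            and _age_ok(c.onset_age, rule.max_onset_age)
            for c in personal.cancers
        )

    if rule.kind == "bc50_combo":
        # personal BC <= 50 together with a second BC or any close relative
        # with breast/ovarian/pancreatic/prostate cancer
        bc = [c for c in personal.cancers if c.cancer_type == CancerType.BREAST]
        if not any(_age_ok(c.onset_age, rule.max_onset_age) for c in bc):
            return False
        if len(bc) >= 2:
            return True
        return any(e.cancer_type in _FH_ADJACENT_TYPES for e in family)

    if rule.kind == "multi_bc_lineage":
        # >= min_count breast cancers among the participant plus same-side
        # relatives; the participant counts with either side, unknown-side
        # relatives count toward both lineages
        personal_bc = sum(1 for c in personal.cancers if c.cancer_type == CancerType.BREAST)
        for lineage in ("maternal", "paternal"):
            fam_bc = sum(
                1
                for e in family
                if e.cancer_type == CancerType.BREAST and e.side in (lineage, "unknown")
            )
            if personal_bc + fam_bc >= rule.min_count:
                return True
        return False

    raise ValueError(f"unknown rule kind: {rule.kind!r}")


def evaluate_eligibility(
    personal: PersonalHistory,
    family: list[FamilyCancerEvent],
    version: str = "base",
    rules: list[Rule] | None = None,
    include_personal: bool = True,
) -> EligibilityResult:
    """Apply the versioned rule table to one person's histories.

    ``include_personal=False`` restricts to family-history rules, the mode
    used when asking whether a carrier's FH alone was indicative.
    """
    if version not in ("base", "adjusted"):
        raise ValueError(f"unknown criteria version: {version!r}")
    if rules is None:
        rules = default_rules()
    for e in family:
        if not isinstance(e.cancer_type, CancerType):
            raise ValueError(f"unknown cancer_type token: {e.cancer_type!r}")
    fired = []
    for rule in rules:
        if not rule.applies_to(version):
            continue
        if not include_personal and rule.scope == "personal":
            continue
        if _fires(rule, personal, family):
            fired.append(rule.rule_id)
    return EligibilityResult(eligible=bool(fired), fired_rules=fired, version=version)


def detection_rate(results: list[EligibilityResult]) -> tuple[float, int, int]:
    """Fraction of evaluated carriers who are testing-eligible.

    Returns (fraction, numerator, denominator); empty input is an error.
    """
    if not results:
        raise ValueError("detection_rate of an empty carrier list is undefined")
    versions = {r.version for r in results}
    if len(versions) > 1:
        raise ValueError("all carriers must be evaluated under one criteria version")
    n_eligible = sum(r.eligible for r in results)
    return n_eligible / len(results), n_eligible, len(results)


# --------------------------------------------------------------- FH parser

_SIDE_PREFIXES = (
    # pattern, side, degree
    (re.compile(r"^mothers mother\b"), "maternal", 2),
    (re.compile(r"^fathers father\b"), "paternal", 2),
    (re.compile(r"^mother'?s? side\b"), "maternal", 2),
    (re.compile(r"^father'?s? side\b"), "paternal", 2),
    (re.compile(r"^(grandmother|grandma)\b"), "unknown", 2),
    (re.compile(r"^mother\b"), "maternal", 1),
    (re.compile(r"^father\b"), "paternal", 1),
    (re.compile(r"^(sister|brother|daughter|son)\b"), "unknown", 1),
)

_TOKEN_RE = re.compile(r"\b(male bc|bc|oc|pc|pac|gc)\b")
_OTHER_RE = re.compile(r"\b(gyn|unk|unknown|cancers?|malignanc\w*|primary)\b")
_AGE_RE = re.compile(r"\b([1-9]\d)\b(?!\s*-?s\b)")
_DECADE_RE = re.compile(r"\b([1-9]0)\s*-?s\b")
_COUNT_RE = re.compile(r"\b([1-9])\b(?!\d)")


def _normalize(text: str) -> str:
    text = text.replace("´", "'").replace("’", "'").replace("‘", "'")
    text = re.sub(r"\([^)]*\)", " ", text)  # drop parentheticals
    return text.lower().strip()


def parse_family_history(text: str) -> tuple[list[FamilyCancerEvent], list[str]]:
    """Parse a table-style FH string into events plus parse warnings.

    Grammar conventions: a leading relative phrase sets the current side and
    degree, which persist across ";"-separated segments; each cancer-type
    token owns the ages that follow it; decade tokens ("40-s") and phrases
    like "older age" give events with unknown onset; a leading small count
    ("2 unk. cancers") multiplies the event; unrecognizable fragments yield
    type ``other`` with a warning.
    """
    warnings: list[str] = []
    events: list[FamilyCancerEvent] = []
    norm = _normalize(text)
    if norm in ("", "no", "none", "-"):
        return events, warnings

    side, degree = "unknown", 2
    for segment in norm.split(";"):
        segment = segment.strip()
        if not segment:
            continue
        for pat, s, d in _SIDE_PREFIXES:
            m = pat.match(segment)
            if m:
                side, degree = s, d
                segment = segment[m.end():].lstrip(" :,.-")
                # "mother's side" relatives are unspecified: close but not
                # necessarily first degree
                break
        if not segment:
            continue
        chunks = _chunk_by_type(segment)
        if not chunks:
            warnings.append(f"unparseable fragment: {segment!r}")
            continue
        for ctype, chunk in chunks:
            ages = [float(a) for a in _AGE_RE.findall(chunk)]
            decades = _DECADE_RE.findall(chunk)
            count_m = _COUNT_RE.search(chunk)
            n_events = len(ages) + len(decades)
            if count_m:
                n_events = max(n_events, int(count_m.group(1)))
            n_events = max(n_events, 1)
            if ctype is CancerType.OTHER:
                warnings.append(f"unrecognized cancer type in: {chunk!r}")
            for k in range(n_events):
                onset = ages[k] if k < len(ages) else None
                events.append(
                    FamilyCancerEvent(
                        degree=degree, side=side, cancer_type=ctype, onset_age=onset
                    )
                )
    return events, warnings


def _chunk_by_type(segment: str) -> list[tuple[CancerType, str]]:
    """Split a segment at cancer-type tokens; each token owns trailing text."""
    matches = list(_TOKEN_RE.finditer(segment))
    if not matches:
        if _OTHER_RE.search(segment):
            return [(CancerType.OTHER, segment)]
        return []
    chunks = []
    for i, m in enumerate(matches):
        # the first chunk keeps the leading text: counts precede the type
        # token in the source grammar ("3-cases of OC")
        start = 0 if i == 0 else m.start()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(segment)
        chunks.append((_TYPE_TOKENS[m.group(1)], segment[start:end]))
    return chunks


def personal_history_from_row(age_at_dx: float, morphology: str) -> PersonalHistory:
    """Personal breast-cancer history from a case-table row."""
    from .domain import PersonalCancer

    tn = "tnbc" in str(morphology).lower()
    return PersonalHistory(
        cancers=[
            PersonalCancer(
                cancer_type=CancerType.BREAST, onset_age=float(age_at_dx), triple_negative=tn
            )
        ]
    )
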