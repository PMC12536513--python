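"""PHI category catalog and per-category surrogate makers.

The catalog covers the HIPAA Safe Harbor identifier classes used in clinical
de-identification (a superset of the i2b2 2014 tag set). Each category
carries a *critical* flag — a category is critical when a single missed
mention (false negative) suffices to re-identify the patient, e.g. a patient
name, MRN or SSN — and a replacement kind that selects how a surrogate is
produced:

``list-based``
    drawn from a seeded pool of candidate values (names, cities, ...);
    critical list-based categories use a pool of exactly ``pool_size``
    (default 1000) values, which is what bounds surrogate collisions and
    therefore the masking statistics downstream.
``regex-format-preserving``
    the surrogate mirrors the original's character classes (digit→digit,
    letter→letter, case preserved), so phone numbers, SSNs and IDs keep
    their formatting.
``alphanumeric``
    format-preserving over alphanumeric identifiers (MRNs, device IDs).
``offset-date`` / ``offset-age``
    the original is parsed and shifted by a per-document random offset,
    re-emitted in the same textual format, so within-document chronology
    and age structure are preserved.

All randomness flows through a caller-supplied ``numpy.random.Generator``;
identical seeds give identical surrogates.
"""

from __future__ import annotations

import datetime
import logging
import re
import zlib
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PHICategory",
    "MakerConfig",
    "SurrogateMaker",
    "UnknownCategoryError",
    "category_info",
    "full_catalog",
    "DEFAULT_LABEL_MAP",
    "CRITICAL_CATEGORIES",
]

LIST_BASED = "list-based"
FORMAT = "regex-format-preserving"
ALNUM = "alphanumeric"
OFFSET_DATE = "offset-date"
OFFSET_AGE = "offset-age"


class UnknownCategoryError(KeyError):
    """Raised when an annotation category has no catalog entry."""


@dataclass(frozen=True)
class PHICategory:
    name: str
    critical: bool
    replacement_kind: str


_CATALOG_ROWS: list[tuple[str, bool, str]] = [
    ("PATIENT", True, LIST_BASED),
    ("DOCTOR", False, LIST_BASED),
    ("USERNAME", False, ALNUM),
    ("LOCATION-OTHER", False, LIST_BASED),
    ("HOSPITAL", False, LIST_BASED),
    ("ZIP", False, FORMAT),
    ("ORGANIZATION", False, LIST_BASED),
    ("COUNTRY", False, LIST_BASED),
    ("STATE", False, LIST_BASED),
    ("CITY", False, LIST_BASED),
    ("STREET", False, LIST_BASED),
    ("DATE", False, OFFSET_DATE),
    ("HOLIDAY", False, LIST_BASED),
    ("AGE", False, OFFSET_AGE),
    ("PHONE", True, FORMAT),
    ("FAX", True, FORMAT),
    ("VEHICLE_ID", True, FORMAT),
    ("DEVICE", True, ALNUM),
    ("IDNUM", True, FORMAT),
    ("MEDICALRECORD", True, ALNUM),
    ("SSN", True, FORMAT),
    ("ACCOUNT-ID", True, ALNUM),
    ("EMAIL", True, LIST_BASED),
    ("URL", False, LIST_BASED),
    ("BIOID", False, ALNUM),
    ("IPADDRESS", False, FORMAT),
    ("PROFESSION", False, LIST_BASED),
    ("TIME", False, FORMAT),
]

_CATALOG: dict[str, PHICategory] = {
    name: PHICategory(name, critical, kind)
    for name, critical, kind in _CATALOG_ROWS
}

CRITICAL_CATEGORIES = frozenset(
    name for name, crit, _ in _CATALOG_ROWS if crit)

#: Raw annotation labels (i2b2-style dialects) mapped onto catalog tokens.
#: User-extensible via :class:`MakerConfig.label_map`.
DEFAULT_LABEL_MAP: dict[str, str] = {
    "MEDICAL RECORD": "MEDICALRECORD",
    "MEDICALRECORD": "MEDICALRECORD",
    "MRN": "MEDICALRECORD",
    "DEVICE IDS": "DEVICE",
    "DEVICE_ID": "DEVICE",
    "ACCOUNT ID": "ACCOUNT-ID",
    "ACCOUNT_ID": "ACCOUNT-ID",
    "LOC-OTHER": "LOCATION-OTHER",
    "LOCATION_OTHER": "LOCATION-OTHER",
    "IP ADDRESS": "IPADDRESS",
    "IP_ADDRESS": "IPADDRESS",
    "VEHICLE IDS": "VEHICLE_ID",
    "HCPNAME": "DOCTOR",
    "PTNAME": "PATIENT",
    "PHONE NUMBER": "PHONE",
}


def full_catalog() -> dict[str, PHICategory]:
    """The full category catalog, keyed by canonical token."""
    return dict(_CATALOG)


def category_info(
    name: str, label_map: dict[str, str] | None = None
) -> PHICategory:
    """Resolve an annotation label to its catalog record.

    Raw labels are first passed through ``label_map`` (defaults to
    :data:`DEFAULT_LABEL_MAP`); unknown tokens raise
    :class:`UnknownCategoryError` naming the offending label.
    """
    mapping = DEFAULT_LABEL_MAP if label_map is None else label_map
    token = mapping.get(name, mapping.get(name.upper(), name))
    try:
        return _CATALOG[token]
    except KeyError:
        raise UnknownCategoryError(
            f"unknown PHI category {name!r} (resolved to {token!r}); "
            f"known categories: {sorted(_CATALOG)}") from None


# ---------------------------------------------------------------------------
# Base value lists for list-based categories
# ---------------------------------------------------------------------------
# Hand-curated seeded lists; pools are expanded combinatorially (e.g. first
# x last names) to reach pool_size distinct values per critical category.

_FIRST_NAMES = [
    "Sara", "Kim", "Nisha", "Cathy", "Maria", "Hannah", "Lin", "Ann",
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael",
    "Linda", "David", "Elizabeth", "William", "Barbara", "Richard", "Susan",
    "Joseph", "Jessica", "Thomas", "Karen", "Charles", "Lisa", "Daniel",
    "Nancy", "Matthew", "Betty", "Anthony", "Sandra", "Mark", "Margaret",
    "Donald", "Ashley", "Steven", "Kimberly", "Andrew", "Emily", "Paul",
    "Donna", "Joshua", "Michelle", "Kenneth", "Carol", "Kevin", "Amanda",
    "Brian", "Melissa", "George", "Deborah", "Timothy", "Stephanie",
    "Ronald", "Rebecca", "Jason", "Sharon", "Edward", "Laura", "Jeffrey",
    "Cynthia", "Ryan", "Dorothy", "Jacob", "Amy", "Gary", "Kathleen",
    "Nicholas", "Angela", "Eric", "Shirley", "Jonathan", "Emma", "Stephen",
    "Brenda", "Larry", "Pamela", "Justin", "Nicole", "Scott", "Anna",
    "Brandon", "Samantha", "Benjamin", "Katherine", "Samuel", "Christine",
    "Gregory", "Debra", "Alexander", "Rachel", "Patrick", "Carolyn",
    "Frank", "Janet", "Raymond", "Catherine", "Jack", "Heather", "Dennis",
    "Diane", "Jerry", "Ruth", "Tyler", "Julie", "Aaron", "Olivia", "Jose",
    "Joyce", "Adam", "Virginia", "Nathan", "Victoria", "Henry", "Kelly",
    "Zachary", "Lauren", "Douglas", "Christina", "Peter", "Joan", "Kyle",
    "Evelyn", "Noah", "Judith", "Ethan", "Megan", "Jeremy", "Andrea",
    "Walter", "Cheryl", "Christian", "Jacqueline", "Keith", "Madison",
]

_LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts", "Gomez", "Phillips", "Evans", "Turner", "Diaz",
    "Parker", "Cruz", "Edwards", "Collins", "Reyes", "Stewart", "Morris",
    "Morales", "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan",
    "Cooper", "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos",
    "Kim", "Cox", "Ward", "Richardson", "Watson", "Brooks", "Chavez",
    "Wood", "James", "Bennett", "Gray", "Mendoza", "Ruiz", "Hughes",
    "Price", "Alvarez", "Castillo", "Sanders", "Patel", "Myers", "Long",
    "Ross", "Foster", "Jimenez",
]

_CITIES = [
    "Springfield", "Riverton", "Fairview", "Georgetown", "Salem", "Madison",
    "Clinton", "Franklin", "Greenville", "Bristol", "Dover", "Hudson",
    "Kingston", "Milton", "Newport", "Oxford", "Ashland", "Burlington",
    "Clayton", "Dayton", "Easton", "Florence", "Glendale", "Hamilton",
    "Jackson", "Lancaster", "Manchester", "Norwood", "Oakland", "Princeton",
    "Quincy", "Richmond", "Sheffield", "Trenton", "Union City", "Vernon",
    "Waverly", "Yorktown", "Auburn", "Brookfield",
]

_STATES = [
    "Alabama", "Alaska", "Arizona", "Arkansas", "California", "Colorado",
    "Connecticut", "Delaware", "Florida", "Georgia", "Hawaii", "Idaho",
    "Illinois", "Indiana", "Iowa", "Kansas", "Kentucky", "Louisiana",
    "Maine", "Maryland", "Massachusetts", "Michigan", "Minnesota",
    "Mississippi", "Missouri", "Montana", "Nebraska", "Nevada",
    "New Hampshire", "New Jersey", "New Mexico", "New York",
    "North Carolina", "North Dakota", "Ohio", "Oklahoma", "Oregon",
    "Pennsylvania", "Rhode Island", "South Carolina", "South Dakota",
    "Tennessee", "Texas", "Utah", "Vermont", "Virginia", "Washington",
    "West Virginia", "Wisconsin", "Wyoming",
]

_COUNTRIES = [
    "Canada", "Mexico", "Brazil", "France", "Germany", "Spain", "Italy",
    "Portugal", "Ireland", "Norway", "Sweden", "Finland", "Denmark",
    "Poland", "Austria", "Greece", "Turkey", "Egypt", "Kenya", "Ghana",
    "India", "Japan", "Vietnam", "Thailand", "Australia", "New Zealand",
    "Chile", "Peru", "Argentina", "Colombia",
]

_HOSPITALS = [
    "St. Mary's Hospital", "General Hospital", "Memorial Medical Center",
    "University Medical Center", "Mercy Hospital", "Sacred Heart Hospital",
    "Riverside Medical Center", "Lakeview Hospital", "Community Hospital",
    "Regional Medical Center", "Good Samaritan Hospital",
    "Baptist Medical Center", "Methodist Hospital", "Providence Hospital",
    "Valley View Medical Center", "Summit Health Center",
    "Crestwood Hospital", "Northside Medical Center",
    "Eastview Regional Hospital", "Pinecrest Medical Center",
]

_ORGANIZATIONS = [
    "Acme Manufacturing", "Globex Corporation", "Initech", "Umbrella Corp",
    "Stark Industries", "Wayne Enterprises", "Cyberdyne Systems",
    "Pied Piper", "Hooli", "Vandelay Industries", "Dunder Mifflin",
    "Sterling Cooper", "Wonka Industries", "Tyrell Corporation",
    "Soylent Corp", "Massive Dynamic", "Oceanic Airlines",
    "Virtucon", "Monarch Solutions", "Aperture Science",
]

_STREETS = [
    "123 Main St", "45 Oak Ave", "67 Maple Dr", "890 Pine Ln",
    "12 Cedar Ct", "34 Elm St", "56 Birch Rd", "78 Walnut Blvd",
    "910 Chestnut Way", "11 Spruce Ter", "22 Willow Pl", "33 Ash St",
    "44 Poplar Ave", "55 Sycamore Dr", "66 Magnolia Ln", "77 Dogwood Ct",
    "88 Hickory Rd", "99 Juniper Blvd", "101 Laurel Way", "202 Hawthorn St",
]

_LOCATIONS_OTHER = [
    "the city park", "the downtown library", "the county fairgrounds",
    "the riverside trail", "the community center", "the farmers market",
    "the old mill", "the train depot", "the botanical gardens",
    "the lakeside pier", "the convention hall", "the civic auditorium",
]

_HOLIDAYS = [
    "Christmas", "Thanksgiving", "New Year's Day", "Independence Day",
    "Labor Day", "Memorial Day", "Easter", "Halloween", "Veterans Day",
    "Valentine's Day", "St. Patrick's Day", "Mother's Day", "Father's Day",
]

_PROFESSIONS = [
    "teacher", "carpenter", "electrician", "accountant", "librarian",
    "plumber", "mechanic", "farmer", "welder", "chef", "cashier",
    "janitor", "barber", "tailor", "florist", "painter", "roofer",
    "machinist", "clerk", "driver", "engineer", "dispatcher",
]

_URLS = [
    "www.example.com", "www.healthportal.org", "www.myclinic.net",
    "www.patientinfo.org", "www.medrecords.com", "www.carelink.net",
    "www.wellness-hub.org", "www.clinicnotes.com", "www.labresults.net",
    "www.followupcare.org",
]

_EMAIL_DOMAINS = [
    "example.com", "mail.com", "postbox.net", "inbox.org", "webmail.com",
]

# Syllable fragments for synthesizing large unique given-name pools.
# Surrogate pools need pool_size (1000) *distinct* single-token given names
# so that a chain over a single-token original (e.g. "Sandy") really draws
# from pool_size values; curated lists alone are too small.
_NAME_ONSETS = ["B", "Br", "C", "Ch", "Cl", "D", "Dr", "F", "Fr", "G", "Gr",
                "H", "J", "K", "Kr", "L", "M", "N", "P", "Pr", "R", "S",
                "Sh", "St", "T", "Th", "Tr", "V", "W", "Y", "Z", "Al"]
_NAME_NUCLEI = ["a", "e", "i", "o", "u", "ai", "ay", "ee", "ia", "io"]
_NAME_CODAS = ["n", "na", "ne", "ra", "la", "sa", "ta", "lle", "nne", "th",
               "s", "ll", "ris", "don", "mar", "vin"]


def _synthetic_given_names(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct plausible given names from syllable combinations."""
    total = len(_NAME_ONSETS) * len(_NAME_NUCLEI) * len(_NAME_CODAS)
    if n > total:
        raise ValueError(f"cannot synthesize {n} unique names (max {total})")
    idx = rng.choice(total, size=n, replace=False)
    names = []
    for i in idx:
        i = int(i)
        onset = _NAME_ONSETS[i // (len(_NAME_NUCLEI) * len(_NAME_CODAS))]
        rest = i % (len(_NAME_NUCLEI) * len(_NAME_CODAS))
        nucleus = _NAME_NUCLEI[rest // len(_NAME_CODAS)]
        coda = _NAME_CODAS[rest % len(_NAME_CODAS)]
        names.append((onset + nucleus + coda).capitalize())
    return names


_WEEKDAYS_FULL = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
                  "Saturday", "Sunday"]
_WEEKDAYS_ABBR = [d[:3] for d in _WEEKDAYS_FULL]
_MONTHS_FULL = ["January", "February", "March", "April", "May", "June",
                "July", "August", "September", "October", "November",
                "December"]
_MONTHS_ABBR = [m[:3] for m in _MONTHS_FULL]


def _crc(token: str) -> int:
    return zlib.crc32(token.encode("utf-8"))


# ---------------------------------------------------------------------------
# Maker configuration
# ---------------------------------------------------------------------------

@dataclass
class MakerConfig:
    """Seeded configuration for surrogate generation.

    ``pool_size`` bounds the number of distinct surrogate values available
    per critical category (default 1000). ``date_offset_range`` /
    ``age_offset_range`` bound the per-document random shifts, drawn once
    per document so within-document chronology is preserved. ``pool_files``
    optionally maps a category token to a plain-text file of private pool
    values (one per line) that replaces the built-in pool.
    """

    seed: int = 0
    pool_size: int = 1000
    date_offset_range: tuple[int, int] = (1, 30)
    age_offset_range: tuple[int, int] = (1, 5)
    label_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    pool_files: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Date / time / age parsing helpers
# ---------------------------------------------------------------------------

_SLASH_DATE = re.compile(
    r"^(?P<m>\d{1,2})(?P<sep>[/-])(?P<d>\d{1,2})(?:(?P=sep)(?P<y>\d{2}|\d{4}))?$")
_ISO_DATE = re.compile(r"^(?P<y>\d{4})-(?P<m>\d{2})-(?P<d>\d{2})$")
_YEAR_ONLY = re.compile(r"^(19|20)\d{2}$")
_TEXT_DATE = re.compile(
    r"^(?P<mon>[A-Za-z]+)\.? (?P<d>\d{1,2})(?:st|nd|rd|th)?(?:,? (?P<y>\d{4}))?$")
_TIME_PAT = re.compile(
    r"(?P<h>\d{1,2}):(?P<min>\d{2})(?::(?P<s>\d{2}))?"
    r"(?P<ampm>\s?[APap]\.?[Mm]\.?)?")

_REFERENCE_YEAR = 2020  # leap-safe anchor for dates printed without a year


def _month_index(token: str) -> int | None:
    t = token.rstrip(".").capitalize()
    if t in _MONTHS_FULL:
        return _MONTHS_FULL.index(t) + 1
    if t in _MONTHS_ABBR:
        return _MONTHS_ABBR.index(t) + 1
    return None


def _shift_slash_date(m: re.Match, offset_days: int) -> str | None:
    month, day = int(m["m"]), int(m["d"])
    sep = m["sep"]
    ytext = m["y"]
    year = (_REFERENCE_YEAR if ytext is None
            else int(ytext) + (2000 if len(ytext) == 2 else 0))
    try:
        date = datetime.date(year, month, day)
    except ValueError:
        return None
    new = date + datetime.timedelta(days=offset_days)
    pad_m = len(m["m"]) == 2
    pad_d = len(m["d"]) == 2
    parts = [f"{new.month:02d}" if pad_m else str(new.month),
             f"{new.day:02d}" if pad_d else str(new.day)]
    out = sep.join(parts)
    if ytext is not None:
        out += sep + (f"{new.year % 100:02d}" if len(ytext) == 2
                      else f"{new.year:04d}")
    return out


def shift_date_text(original: str, offset_days: int) -> str | None:
    """Shift a date string by ``offset_days``, re-emitting the same format.

    Handles MM/DD[/YY[YY]] and MM-DD[-YY[YY]] (zero-padding preserved),
    ISO dates, bare years, month-name dates ("July 17, 2019", "Jul 17")
    and weekday names. Returns ``None`` when no pattern matches.
    """
    s = original.strip()
    m = _SLASH_DATE.match(s)
    if m:
        return _shift_slash_date(m, offset_days)
    m = _ISO_DATE.match(s)
    if m:
        try:
            date = datetime.date(int(m["y"]), int(m["m"]), int(m["d"]))
        except ValueError:
            return None
        new = date + datetime.timedelta(days=offset_days)
        return f"{new.year:04d}-{new.month:02d}-{new.day:02d}"
    if _YEAR_ONLY.match(s):
        new = (datetime.date(int(s), 7, 1)
               + datetime.timedelta(days=offset_days))
        return f"{new.year:04d}"
    if s.capitalize() in _WEEKDAYS_FULL:
        i = _WEEKDAYS_FULL.index(s.capitalize())
        out = _WEEKDAYS_FULL[(i + offset_days) % 7]
        return out.upper() if s.isupper() else out
    if s.rstrip(".").capitalize() in _WEEKDAYS_ABBR:
        i = _WEEKDAYS_ABBR.index(s.rstrip(".").capitalize())
        out = _WEEKDAYS_ABBR[(i + offset_days) % 7]
        if s.endswith("."):
            out += "."
        return out.upper() if s.isupper() else out
    m = _TEXT_DATE.match(s)
    if m:
        month = _month_index(m["mon"])
        if month is None:
            return None
        year = int(m["y"]) if m["y"] else _REFERENCE_YEAR
        try:
            date = datetime.date(year, month, int(m["d"]))
        except ValueError:
            return None
        new = date + datetime.timedelta(days=offset_days)
        abbreviated = m["mon"].rstrip(".").capitalize() in _MONTHS_ABBR
        mon_out = (_MONTHS_ABBR if abbreviated else _MONTHS_FULL)[new.month - 1]
        if m["mon"].endswith("."):
            mon_out += "."
        if m["mon"].isupper():
            mon_out = mon_out.upper()
        out = f"{mon_out} {new.day}"
        if m["y"]:
            out += f", {new.year:04d}" if ", " in s else f" {new.year:04d}"
        return out
    return None


def match_case(surrogate: str, original: str) -> str:
    """Render ``surrogate`` in the case pattern of ``original``."""
    if original.isupper():
        return surrogate.upper()
    if original.islower():
        return surrogate.lower()
    return surrogate


# ---------------------------------------------------------------------------
# Surrogate maker
# ---------------------------------------------------------------------------

class SurrogateMaker:
    """Generates a surrogate surface per category, format- and case-preserving.

    Pools for list-based categories are materialized once at construction
    from ``config.seed``; every critical category's pool holds exactly
    ``config.pool_size`` values. Format-preserving critical categories
    (PHONE, SSN, MRN, ...) keep the same collision structure by drawing a
    pool *index* in ``[0, pool_size)`` and deriving the character fill
    deterministically from (category, original, index).
    """

    def __init__(self, config: MakerConfig | None = None):
        self.config = config or MakerConfig()
        self.fallback_count = 0
        self._pools: dict[str, list[str]] = {}
        self._build_pools()

    # -- pools ------------------------------------------------------------

    def _build_pools(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, _crc("pools")]))
        # Person pools carry pool_size *unique* first names so that chains
        # over single-token originals still draw from pool_size distinct
        # surrogates after rendering.
        n_persons = max(cfg.pool_size, 100)
        firsts = _synthetic_given_names(n_persons, rng)
        person_names = [f"{f} {_LAST_NAMES[i % len(_LAST_NAMES)]}"
                        for i, f in enumerate(firsts)]
        doctor_firsts = _synthetic_given_names(n_persons, rng)
        doctor_names = [f"{f} {_LAST_NAMES[(i + 37) % len(_LAST_NAMES)]}"
                        for i, f in enumerate(doctor_firsts)]
        base: dict[str, list[str]] = {
            "PATIENT": person_names,
            "DOCTOR": doctor_names,
            "CITY": _CITIES,
            "STATE": _STATES,
            "COUNTRY": _COUNTRIES,
            "HOSPITAL": _HOSPITALS,
            "ORGANIZATION": _ORGANIZATIONS,
            "STREET": _STREETS,
            "LOCATION-OTHER": _LOCATIONS_OTHER,
            "HOLIDAY": _HOLIDAYS,
            "PROFESSION": _PROFESSIONS,
            "URL": _URLS,
            "EMAIL": [
                f"{f.lower()}.{l.lower()}@{_EMAIL_DOMAINS[i % len(_EMAIL_DOMAINS)]}"
                for i, (f, l) in enumerate(
                    (f, l) for f in _FIRST_NAMES for l in _LAST_NAMES)
            ],
        }
        for name, values in base.items():
            cat = _CATALOG[name]
            if name in self.config.pool_files:
                with open(self.config.pool_files[name],
                          encoding="utf-8") as fh:
                    values = [ln.strip() for ln in fh if ln.strip()]
            if cat.critical:
                if len(values) < cfg.pool_size:
                    raise ValueError(
                        f"pool for critical category {name} has only "
                        f"{len(values)} values (< pool_size={cfg.pool_size})")
                idx = rng.choice(len(values), size=cfg.pool_size,
                                 replace=False)
                values = [values[i] for i in idx]
            self._pools[name] = list(values)

    def pool(self, category: str) -> list[str]:
        """The materialized value pool for a list-based category."""
        return list(self._pools[category])

    # -- per-document offsets ---------------------------------------------

    def document_offsets(self, rng: np.random.Generator) -> tuple[int, int]:
        """Draw the (date, age) offsets used for every mention of a document."""
        lo, hi = self.config.date_offset_range
        date_off = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
        lo, hi = self.config.age_offset_range
        age_off = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
        return date_off, age_off

    # -- surrogate generation ---------------------------------------------

    def make(
        self,
        category: str,
        original: str | None,
        rng: np.random.Generator,
        date_offset: int = 0,
        age_offset: int = 0,
    ) -> str:
        """Draw one fresh surrogate for ``category``.

        ``original`` may be ``None`` (annotation-only mode, no ``.txt``):
        format preservation then falls back to a canonical per-category
        shape.
        """
        cat = category_info(category, self.config.label_map)
        kind = cat.replacement_kind
        if kind == LIST_BASED:
            return self._make_from_pool(cat, original, rng)
        if kind == OFFSET_DATE:
            return self._make_date(original, rng, date_offset)
        if kind == OFFSET_AGE:
            return self._make_age(original, rng, age_offset)
        if cat.name == "TIME":
            return self._make_time(original, rng)
        # FORMAT and ALNUM: character-class preserving
        return self._make_format_preserving(cat, original, rng)

    def _make_from_pool(
        self, cat: PHICategory, original: str | None,
        rng: np.random.Generator,
    ) -> str:
        pool = self._pools[cat.name]
        value = pool[int(rng.integers(len(pool)))]
        if original is None:
            return value
        if cat.name in ("PATIENT", "DOCTOR"):
            # Mirror the original's token count: a single-token original
            # gets a first name only.
            if len(original.split()) == 1:
                value = value.split()[0]
        return match_case(value, original)

    def _make_date(
        self, original: str | None, rng: np.random.Generator,
        date_offset: int,
    ) -> str:
        if original is not None:
            shifted = shift_date_text(original, date_offset)
            if shifted is not None:
                return shifted
            self.fallback_count += 1
            logger.info("unparseable date %r; emitting canonical surrogate",
                        original)
        base = datetime.date(_REFERENCE_YEAR, 1, 1) + datetime.timedelta(
            days=int(rng.integers(0, 365)))
        return base.strftime("%m/%d/%Y")

    def _make_age(
        self, original: str | None, rng: np.random.Generator,
        age_offset: int,
    ) -> str:
        if original is not None:
            m = re.search(r"\d+", original)
            if m:
                age = int(m.group())
                new = age + age_offset
                # Safe Harbor treats >=90 separately: never cross the
                # boundary in either direction.
                if age >= 90:
                    new = max(new, 90)
                else:
                    new = min(max(new, 0), 89)
                return original[:m.start()] + str(new) + original[m.end():]
            self.fallback_count += 1
        return str(int(rng.integers(20, 90)))

    def _make_time(
        self, original: str | None, rng: np.random.Generator
    ) -> str:
        minute_of_day = int(rng.integers(0, 24 * 60))
        hh, mm = divmod(minute_of_day, 60)
        if original is not None:
            m = _TIME_PAT.search(original)
            if m:
                ampm = m["ampm"]
                if ampm:
                    h12 = hh % 12 or 12
                    marker = ampm.replace("A", "P").replace("a", "p") \
                        if hh >= 12 else ampm.replace("P", "A").replace("p", "a")
                    h_out = (f"{h12:02d}" if len(m["h"]) == 2 else str(h12))
                else:
                    marker = ""
                    h_out = f"{hh:02d}" if len(m["h"]) == 2 else str(hh)
                sec = f":{int(rng.integers(0, 60)):02d}" if m["s"] else ""
                repl = f"{h_out}:{mm:02d}{sec}{marker}"
                return original[:m.start()] + repl + original[m.end():]
            self.fallback_count += 1
        return f"{hh:02d}:{mm:02d}"

    def _make_format_preserving(
        self, cat: PHICategory, original: str | None,
        rng: np.random.Generator,
    ) -> str:
        if original is None or not original:
            original = self._canonical_shape(cat.name)
        if cat.critical:
            # Pool semantics: at most pool_size distinct surrogates per
            # (category, original) chain, deterministic per pool index.
            idx = int(rng.integers(self.config.pool_size))
            fill = np.random.default_rng(np.random.SeedSequence(
                [self.config.seed & 0x7FFFFFFF, _crc(cat.name),
                 _crc(original), idx]))
            out = self._fill_pattern(original, fill)
            if out == original:
                fill = np.random.default_rng(np.random.SeedSequence(
                    [self.config.seed & 0x7FFFFFFF, _crc(cat.name),
                     _crc(original), idx, 1]))
                out = self._fill_pattern(original, fill)
            return out
        return self._fill_pattern(original, rng)

    @staticmethod
    def _canonical_shape(name: str) -> str:
        return {
            "PHONE": "555-555-0100",
            "FAX": "555-555-0100",
            "SSN": "000-00-0000",
            "IDNUM": "AB123456",
            "VEHICLE_ID": "1ABCD23EFG4567890",
            "MEDICALRECORD": "00000000",
            "DEVICE": "DEV-0000000",
            "ACCOUNT-ID": "ACCT0000000",
            "BIOID": "BIO0000000",
            "USERNAME": "user0000",
            "ZIP": "00000",
            "IPADDRESS": "10.0.0.1",
        }.get(name, "00000000")

    @staticmethod
    def _fill_pattern(original: str, rng: np.random.Generator) -> str:
        """Digit→digit, letter→letter (case kept), everything else verbatim."""
        digits = "0123456789"
        upper = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        lower = upper.lower()
        out = []
        for ch in original:
            if ch.isdigit():
                out.append(digits[int(rng.integers(10))])
            elif ch.isalpha() and ch.isupper():
                out.append(upper[int(rng.integers(26))])
            elif ch.isalpha() and ch.islower():
                out.append(lower[int(rng.integers(26))])
            else:
                out.append(ch)
        return "".join(out)


def make_surrogate(
    category: str,
    original: str | None,
    config: MakerConfig,
    rng: np.random.Generator,
    date_offset: int = 0,
    age_offset: int = 0,
) -> str:
    """Functional wrapper over :class:`SurrogateMaker` for one-off draws."""
    return SurrogateMaker(config).make(
        category, original, rng, date_offset, age_offset)
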