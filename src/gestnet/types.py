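"""Domain types for focal-follow observation data.

The observational unit is the *focal follow*: a standardised 18-minute
observation of one individual, sampled instantaneously every 2 minutes
(9 scans per follow).  Each scan records the focal's party (individuals
within a ~35 m spread), the subset of the party within 10 m of the focal,
the nearest neighbour, the focal's activity, and visual-attention flags.
Gestural communication events are recorded separately, each directed from
a signaller to a recipient and classified by modality and social function.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InputError

#: Minutes represented by one instantaneous scan (the sampling interval).
SCAN_MINUTES = 2.0
#: Scans per standardised focal follow.
SCANS_PER_FOLLOW = 9
#: Minutes per standardised focal follow.
FOLLOW_MINUTES = SCAN_MINUTES * SCANS_PER_FOLLOW


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class ReproductiveState(str, enum.Enum):
    oestrus = "oestrus"
    non_oestrus = "non_oestrus"
    male = "male"


class Activity(str, enum.Enum):
    travel = "travel"
    rest = "rest"
    feed = "feed"
    groom_give = "groom_give"
    groom_receive = "groom_receive"
    groom_mutual = "groom_mutual"
    other = "other"


#: Activities during which the focal has a grooming partner.
GROOMING_ACTIVITIES = frozenset(
    {Activity.groom_give, Activity.groom_receive, Activity.groom_mutual}
)


class Modality(str, enum.Enum):
    """Gesture modality, ordered from least to most intense."""

    visual = "visual"
    tactile = "tactile"
    auditory_short = "auditory_short"
    auditory_long = "auditory_long"


MODALITIES = tuple(Modality)


class Context(str, enum.Enum):
    """Social function of a gesture (12 categories)."""

    threat_to_dominate = "threat_to_dominate"
    food_sharing = "food_sharing"
    other_threat = "other_threat"
    travel = "travel"
    copulation = "copulation"
    reassurance = "reassurance"
    greeting = "greeting"
    mutual_groom = "mutual_groom"
    receive_groom = "receive_groom"
    give_groom = "give_groom"
    play = "play"
    pant_hoot = "pant_hoot"


CONTEXTS = tuple(Context)


@dataclass(frozen=True)
class IndividualAttributes:
    """Static attributes of one study subject."""

    id: str
    sex: Sex
    age: float
    matriline: str
    reproductive_state: ReproductiveState
    observation_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise InputError(f"{self.id}: age must be positive, got {self.age}")
        if self.sex is Sex.male and self.reproductive_state is ReproductiveState.oestrus:
            raise InputError(f"{self.id}: males cannot be in oestrus")
        if self.sex is Sex.female and self.reproductive_state is ReproductiveState.male:
            raise InputError(f"{self.id}: females need a female reproductive state")
        if self.observation_hours < 0:
            raise InputError(f"{self.id}: observation_hours must be nonnegative")


@dataclass(frozen=True)
class FocalScan:
    """One instantaneous 2-minute sample within a focal follow.

    ``party`` and ``within_10m`` never contain the focal; ``within_10m``
    is a subset of ``party``.  ``groom_partner`` is set exactly when the
    activity is a grooming state.
    """

    follow_id: str
    focal: str
    scan_index: int
    party: frozenset[str]
    within_10m: frozenset[str]
    nearest_neighbour: str | None
    activity: Activity
    groom_partner: str | None = None
    attention_given: bool = False
    attention_received: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.scan_index <= SCANS_PER_FOLLOW:
            raise InputError(
                f"scan_index must be in 1..{SCANS_PER_FOLLOW}, got {self.scan_index}"
            )
        if self.focal in self.party:
            raise InputError(f"focal {self.focal} cannot be a member of its own party")
        if not self.within_10m <= self.party:
            raise InputError("within_10m must be a subset of party")
        grooming = self.activity in GROOMING_ACTIVITIES
        if grooming != (self.groom_partner is not None):
            raise InputError(
                "groom_partner must be set exactly when activity is a grooming state"
            )
        if self.nearest_neighbour is not None and self.nearest_neighbour not in self.within_10m:
            raise InputError("nearest_neighbour must be within 10 m")


@dataclass(frozen=True)
class GestureEvent:
    """One directed communication event (single gesture)."""

    event_id: str
    signaller: str
    recipient: str
    modality: Modality
    context: Context
    distance_m: float
    within_10m: bool = True

    def __post_init__(self) -> None:
        if self.signaller == self.recipient:
            raise InputError(f"{self.event_id}: signaller equals recipient")
        if self.distance_m < 0:
            raise InputError(f"{self.event_id}: distance must be nonnegative")


@dataclass
class Dataset:
    """A complete observational dataset: subjects, scan log and event log."""

    attributes: list[IndividualAttributes]
    scans: list[FocalScan]
    events: list[GestureEvent]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.attributes)
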