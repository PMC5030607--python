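"""From observation logs to dyadic matrices, bond classes and node covariates.

All duration measures use the standard instantaneous-scan estimator: each
scan stands for 2 minutes, so a dyad's minutes-per-hour rate is
``60 * (scans meeting the numerator condition) / (scans meeting the
denominator condition)``.  Rates are directed: cell (A, B) is computed from
A's focal follows only.  Dyads whose denominator is zero are recorded as 0
and listed in the matrix's ``flagged`` set (the permutation machinery needs
complete matrices; deleting dyads would change the permutation group).
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .matrices import DyadicMatrix, MatrixKind, offdiag_indices
from .types import (
    Activity,
    Context,
    FocalScan,
    GestureEvent,
    GROOMING_ACTIVITIES,
    IndividualAttributes,
    Modality,
    ReproductiveState,
    SCAN_MINUTES,
)

__all__ = [
    "Behaviour",
    "BondClass",
    "BondNetwork",
    "proximity_duration_matrix",
    "behaviour_duration_matrix",
    "gesture_rate_matrix",
    "similarity_matrices",
    "classify_bonds",
    "node_covariates",
]


def _resolve_labels(
    scans: Sequence[FocalScan], labels: Sequence[str] | None
) -> tuple[str, ...]:
    if labels is not None:
        return tuple(labels)
    seen: set[str] = set()
    for s in scans:
        seen.add(s.focal)
        seen.update(s.party)
    return tuple(sorted(seen))


def _ratio_matrix(
    numerator: np.ndarray,
    denominator: np.ndarray,
    labels: tuple[str, ...],
    *,
    kind: MatrixKind,
    units: str,
    name: str,
) -> DyadicMatrix:
    n = len(labels)
    vals = np.zeros_like(numerator, dtype=float)
    np.divide(numerator, denominator, out=vals, where=denominator > 0)
    rows, cols = offdiag_indices(n)
    flagged = frozenset(
        (labels[r], labels[c]) for r, c in zip(rows, cols) if denominator[r, c] == 0
    )
    return DyadicMatrix(
        labels=labels, values=vals, directed=True, kind=kind, units=units,
        flagged=flagged, name=name,
    )


def _scan_counts(
    scans: Sequence[FocalScan],
    labels: tuple[str, ...],
    numerator_hit,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-dyad counts of (numerator, co-party, within-10m) scans."""
    idx = {l: k for k, l in enumerate(labels)}
    n = len(labels)
    num = np.zeros((n, n))
    co_party = np.zeros((n, n))
    within = np.zeros((n, n))
    focals_seen: set[str] = set()
    for s in scans:
        if s.focal not in idx:
            raise InputError(f"scan focal {s.focal!r} not among matrix labels")
        a = idx[s.focal]
        focals_seen.add(s.focal)
        for b_label in s.party:
            if b_label not in idx:
                raise InputError(f"party member {b_label!r} not among matrix labels")
            co_party[a, idx[b_label]] += 1
        for b_label in s.within_10m:
            b = idx[b_label]
            within[a, b] += 1
            if numerator_hit(s, b_label):
                num[a, b] += 1
    missing = set(labels) - focals_seen
    if missing:
        warnings.warn(
            f"no focal scans for {sorted(missing)}; their rows are zero-filled",
            stacklevel=3,
        )
    return num, co_party, within


def proximity_duration_matrix(
    scans: Sequence[FocalScan], labels: Sequence[str] | None = None
) -> DyadicMatrix:
    """Minutes B spent within 10 m of focal A, per hour A and B were co-party.

    Cell (A, B) = 60 * #(A-focal scans with B within 10 m) /
    #(A-focal scans with B in the party); values lie in [0, 60].
    """
    if not scans:
        raise InputError("scans must be nonempty")
    lab = _resolve_labels(scans, labels)
    _, co_party, within = _scan_counts(scans, lab, lambda s, b: False)
    return _ratio_matrix(60.0 * within, co_party, lab,
                         kind=MatrixKind.duration_rate, units="min/hr",
                         name="proximity")


class Behaviour(str, enum.Enum):
    """Dyadic bonding behaviours measurable from the scan log."""

    travel = "travel"
    rest = "rest"
    feed = "feed"
    groom_give = "groom_give"
    groom_receive = "groom_receive"
    groom_mutual = "groom_mutual"
    attention_given = "attention_given"
    attention_received = "attention_received"


def behaviour_duration_matrix(
    scans: Sequence[FocalScan],
    behaviour: Behaviour | str,
    labels: Sequence[str] | None = None,
) -> DyadicMatrix:
    """Minutes per co-party hour that focal A spent in ``behaviour`` with B within 10 m.

    Activity behaviours require the focal's activity to match (grooming ones
    additionally require B to be the grooming partner); attention behaviours
    require B to be the nearest neighbour, within 10 m, with the flag set.
    """
    if not scans:
        raise InputError("scans must be nonempty")
    try:
        behaviour = Behaviour(behaviour)
    except ValueError:
        raise InputError(f"unknown behaviour {behaviour!r}") from None
    lab = _resolve_labels(scans, labels)

    if behaviour is Behaviour.attention_given:
        hit = lambda s, b: s.nearest_neighbour == b and s.attention_given
    elif behaviour is Behaviour.attention_received:
        hit = lambda s, b: s.nearest_neighbour == b and s.attention_received
    elif behaviour in (Behaviour.groom_give, Behaviour.groom_receive, Behaviour.groom_mutual):
        act = Activity(behaviour.value)
        hit = lambda s, b: s.activity is act and s.groom_partner == b
    else:
        act = Activity(behaviour.value)
        hit = lambda s, b: s.activity is act

    num, co_party, _ = _scan_counts(scans, lab, hit)
    return _ratio_matrix(60.0 * num, co_party, lab,
                         kind=MatrixKind.duration_rate, units="min/hr",
                         name=behaviour.value)


def gesture_rate_matrix(
    events: Sequence[GestureEvent],
    scans: Sequence[FocalScan],
    modality: Modality | str | None = None,
    context: Context | str | None = None,
    labels: Sequence[str] | None = None,
) -> DyadicMatrix:
    """Gestures A directed at B per hour B spent within 10 m of focal A.

    Only events with ``within_10m=True`` are analysis-eligible; others are
    excluded.  Optional modality/context filters restrict the numerator.
    """
    if not scans:
        raise InputError("scans must be nonempty")
    modality = Modality(modality) if modality is not None else None
    context = Context(context) if context is not None else None
    lab = _resolve_labels(scans, labels)
    idx = {l: k for k, l in enumerate(lab)}
    n = len(lab)

    counts = np.zeros((n, n))
    for e in events:
        if e.signaller not in idx or e.recipient not in idx:
            raise InputError(
                f"event {e.event_id}: {e.signaller}->{e.recipient} not among matrix labels"
            )
        if not e.within_10m:
            continue
        if modality is not None and e.modality is not modality:
            continue
        if context is not None and e.context is not context:
            continue
        counts[idx[e.signaller], idx[e.recipient]] += 1

    _, _, within = _scan_counts(scans, lab, lambda s, b: False)
    hours = within * SCAN_MINUTES / 60.0
    name = "gesture_rate"
    if modality is not None:
        name = f"{modality.value}_rate"
    if context is not None:
        name = f"{name}_{context.value}" if modality is not None else f"{context.value}_rate"
    return _ratio_matrix(counts, hours, lab,
                         kind=MatrixKind.event_rate, units="events/hr", name=name)


def similarity_matrices(
    attributes: Sequence[IndividualAttributes],
) -> dict[str, DyadicMatrix]:
    """Dyadic control matrices: sex, kinship, reproductive similarity, age proximity.

    The first three are 0/1 same-category indicators; age proximity is
    ``-|age_i - age_j|`` standardized over off-diagonal cells (larger means
    closer in age).  All four are symmetric.
    """
    if not attributes:
        raise InputError("attributes must be nonempty")
    lab = tuple(a.id for a in attributes)
    n = len(lab)
    sex = np.zeros((n, n)); kin = np.zeros((n, n)); rep = np.zeros((n, n))
    aged = np.zeros((n, n))
    for i, a in enumerate(attributes):
        for j, b in enumerate(attributes):
            if i == j:
                continue
            sex[i, j] = float(a.sex == b.sex)
            kin[i, j] = float(a.matriline == b.matriline)
            rep[i, j] = float(a.reproductive_state == b.reproductive_state)
            aged[i, j] = -abs(a.age - b.age)
    rows, cols = offdiag_indices(n)
    off = aged[rows, cols]
    sd = off.std()
    if sd > 0:
        aged[rows, cols] = (off - off.mean()) / sd
    else:
        warnings.warn("all ages equal; age_proximity is constant zero", stacklevel=2)
        aged[rows, cols] = 0.0
    mk = lambda v, nm, u: DyadicMatrix(labels=lab, values=v, directed=False,
                                       kind=MatrixKind.similarity, units=u, name=nm)
    return {
        "sex_similarity": mk(sex, "sex_similarity", "0/1"),
        "kinship": mk(kin, "kinship", "0/1"),
        "age_proximity": mk(aged, "age_proximity", "z-score"),
        "reproductive_similarity": mk(rep, "reproductive_similarity", "0/1"),
    }


class BondClass(str, enum.Enum):
    """Proximity-bond classes defined by mean +/- half-SD thresholds."""

    strong = "strong"
    preferred_reciprocated = "preferred_reciprocated"
    preferred_nonreciprocated = "preferred_nonreciprocated"
    non_preferred = "non_preferred"


@dataclass(frozen=True)
class BondNetwork:
    """Binary bond network plus the thresholds that produced it (min/hr)."""

    base: DyadicMatrix
    bond_class: BondClass
    upper_threshold: float
    lower_threshold: float


def classify_bonds(
    proximity: DyadicMatrix, bond_class: BondClass | str
) -> BondNetwork:
    """Classify directed dyads of a proximity duration matrix into bond classes.

    Thresholds are computed over all off-diagonal directed values (zeros
    included, population SD): upper = mean + SD/2, lower = mean - SD/2.

    * ``strong``: value >= upper (directed).
    * ``preferred_reciprocated``: both directions >= upper (symmetric).
    * ``preferred_nonreciprocated``: this direction >= upper, reverse < upper.
    * ``non_preferred``: value <= lower.
    """
    if proximity.kind is not MatrixKind.duration_rate:
        raise InputError("classify_bonds requires a duration_rate matrix")
    bond_class = BondClass(bond_class)
    off = proximity.offdiag_values()
    sd = off.std()
    if sd == 0:
        raise DegenerateInputError(
            "proximity matrix is constant; bond thresholds are degenerate"
        )
    upper = off.mean() + sd / 2.0
    lower = off.mean() - sd / 2.0

    v = proximity.values
    with np.errstate(invalid="ignore"):
        hi = v >= upper
        hi_t = v.T >= upper
        if bond_class is BondClass.strong:
            ties = hi
        elif bond_class is BondClass.preferred_reciprocated:
            ties = hi & hi_t
        elif bond_class is BondClass.preferred_nonreciprocated:
            ties = hi & ~hi_t
        else:
            ties = v <= lower
    base = DyadicMatrix(
        labels=proximity.labels,
        values=ties.astype(float),
        directed=bond_class is not BondClass.preferred_reciprocated,
        kind=MatrixKind.binary,
        units="0/1",
        name=bond_class.value,
    )
    return BondNetwork(base=base, bond_class=bond_class,
                       upper_threshold=float(upper), lower_threshold=float(lower))


def node_covariates(
    scans: Sequence[FocalScan], attributes: Sequence[IndividualAttributes]
) -> pd.DataFrame:
    """Per-individual controls: hours near oestrus females, hours near kin, age, sex.

    ``hours_near_oestrus`` counts focal scans with at least one oestrus
    female within 10 m (2 minutes per scan); ``hours_near_kin`` analogously
    for matriline kin of the focal.
    """
    by_id = {a.id: a for a in attributes}
    oestrus = {a.id for a in attributes if a.reproductive_state is ReproductiveState.oestrus}
    near_oestrus = {a.id: 0 for a in attributes}
    near_kin = {a.id: 0 for a in attributes}
    for s in scans:
        if s.focal not in by_id:
            raise InputError(f"scan focal {s.focal!r} has no attribute record")
        if s.within_10m & oestrus:
            near_oestrus[s.focal] += 1
        kin = {i for i in s.within_10m
               if i in by_id and by_id[i].matriline == by_id[s.focal].matriline}
        if kin:
            near_kin[s.focal] += 1
    hours = SCAN_MINUTES / 60.0
    return pd.DataFrame(
        {
            "hours_near_oestrus": [near_oestrus[a.id] * hours for a in attributes],
            "hours_near_kin": [near_kin[a.id] * hours for a in attributes],
            "age": [a.age for a in attributes],
            "sex": [a.sex.value for a in attributes],
        },
        index=[a.id for a in attributes],
    )
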