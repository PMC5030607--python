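"""CSV serialization of attribute tables, scan logs and event logs.

Formats (all plain CSV, one header row):

* ``attributes.csv`` — id, sex, age, matriline, reproductive_state,
  observation_hours.
* ``scans.csv`` — follow_id, focal, scan_index, party, within_10m,
  nearest_neighbour, activity, groom_partner, attention_given,
  attention_received.  Membership sets are semicolon-joined id lists;
  empty fields mean empty set / none.
* ``events.csv`` — event_id, signaller, recipient, modality, context,
  distance_m, within_10m.
* ``truth.json`` — planted generator parameters (synthetic datasets only).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulate import SyntheticDataset, planted_truth
from .types import (
    Activity,
    Context,
    Dataset,
    FocalScan,
    GestureEvent,
    IndividualAttributes,
    Modality,
    ReproductiveState,
    Sex,
)


def _join(ids) -> str:
    return ";".join(sorted(ids))


def write_attributes(attributes: Sequence[IndividualAttributes], path) -> None:
    pd.DataFrame(
        [
            {
                "id": a.id, "sex": a.sex.value, "age": a.age,
                "matriline": a.matriline,
                "reproductive_state": a.reproductive_state.value,
                "observation_hours": a.observation_hours,
            }
            for a in attributes
        ]
    ).to_csv(path, index=False)


def load_attributes(path) -> list[IndividualAttributes]:
    df = pd.read_csv(path, dtype={"id": str, "matriline": str},
                     float_precision="round_trip")
    return [
        IndividualAttributes(
            id=r.id, sex=Sex(r.sex), age=float(r.age), matriline=r.matriline,
            reproductive_state=ReproductiveState(r.reproductive_state),
            observation_hours=float(r.observation_hours),
        )
        for r in df.itertuples()
    ]


def write_scans(scans: Sequence[FocalScan], path) -> None:
    pd.DataFrame(
        [
            {
                "follow_id": s.follow_id, "focal": s.focal, "scan_index": s.scan_index,
                "party": _join(s.party), "within_10m": _join(s.within_10m),
                "nearest_neighbour": s.nearest_neighbour or "",
                "activity": s.activity.value, "groom_partner": s.groom_partner or "",
                "attention_given": int(s.attention_given),
                "attention_received": int(s.attention_received),
            }
            for s in scans
        ]
    ).to_csv(path, index=False)


def load_scans(path) -> list[FocalScan]:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    out = []
    for r in df.itertuples():
        out.append(
            FocalScan(
                follow_id=r.follow_id,
                focal=r.focal,
                scan_index=int(r.scan_index),
                party=frozenset(x for x in r.party.split(";") if x),
                within_10m=frozenset(x for x in r.within_10m.split(";") if x),
                nearest_neighbour=r.nearest_neighbour or None,
                activity=Activity(r.activity),
                groom_partner=r.groom_partner or None,
                attention_given=bool(int(r.attention_given)),
                attention_received=bool(int(r.attention_received)),
            )
        )
    return out


def write_events(events: Sequence[GestureEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "event_id": e.event_id, "signaller": e.signaller,
                "recipient": e.recipient, "modality": e.modality.value,
                "context": e.context.value, "distance_m": e.distance_m,
                "within_10m": int(e.within_10m),
            }
            for e in events
        ],
        columns=["event_id", "signaller", "recipient", "modality", "context",
                 "distance_m", "within_10m"],
    ).to_csv(path, index=False)


def load_events(path) -> list[GestureEvent]:
    df = pd.read_csv(path, dtype={"event_id": str, "signaller": str, "recipient": str},
                     float_precision="round_trip")
    return [
        GestureEvent(
            event_id=r.event_id, signaller=r.signaller, recipient=r.recipient,
            modality=Modality(r.modality), context=Context(r.context),
            distance_m=float(r.distance_m), within_10m=bool(int(r.within_10m)),
        )
        for r in df.itertuples()
    ]


def write_dataset(dataset: Dataset, directory) -> None:
    """Write attributes/scans/events CSVs (plus truth.json if synthetic)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_attributes(dataset.attributes, directory / "attributes.csv")
    write_scans(dataset.scans, directory / "scans.csv")
    write_events(dataset.events, directory / "events.csv")
    if isinstance(dataset, SyntheticDataset):
        (directory / "truth.json").write_text(
            json.dumps(planted_truth(dataset.model), indent=2)
        )


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    return Dataset(
        attributes=load_attributes(directory / "attributes.csv"),
        scans=load_scans(directory / "scans.csv"),
        events=load_events(directory / "events.csv"),
    )
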