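"""End-to-end study orchestration: simulate/load -> networks -> inference -> report.

Four analyses mirror the structure of a dyadic gestural-communication study:

1. *bond/modality* — for each proximity-bond class (as binary outcome
   network), MRQAP on the four modality gesture-rate networks plus the four
   dyadic similarity controls;
2. *context/modality* — for each modality rate network (outcome), MRQAP on
   the twelve context rate networks plus the similarity controls;
3. *centrality* — node-level permutation regression of strong-bond
   out-degree on in-/out-degrees of each modality network plus individual
   controls (hours near oestrus females, hours near kin, age, sex);
4. *sampling effort* — Geary's C between per-individual observation hours
   and each modality network.

Every reported p-value carries its permutation count and seed; sub-seeds
are derived deterministically from one master seed (SeedSequence spawn
key per analysis), so a report is byte-reproducible from its config.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .errors import DegenerateInputError, InputError
from .io import load_dataset, write_dataset
from .matrices import DyadicMatrix, dichotomize, normalized_degree, symmetrize_max
from .measures import (
    BondClass,
    classify_bonds,
    gesture_rate_matrix,
    node_covariates,
    proximity_duration_matrix,
    similarity_matrices,
)
from .inference import geary_c, mrqap_dsp, node_regression
from .simulate import BondParams, PopulationConfig, simulate_dataset
from .types import CONTEXTS, Dataset, MODALITIES, Sex

log = logging.getLogger("gestnet")

# fixed spawn keys: master_seed -> per-analysis substream
_SEED_KEYS = {
    "simulate": 0,
    "bond_modality": 1,
    "context_modality": 2,
    "centrality": 3,
    "sampling_effort": 4,
}


def subseed(master_seed: int, analysis: str) -> int:
    """Deterministic 31-bit sub-seed for one named analysis."""
    state = np.random.SeedSequence([int(master_seed), _SEED_KEYS[analysis]]).generate_state(1)
    return int(state[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Configuration for :func:`run_study` (file mode or generator mode)."""

    data_dir: str | None = None          # existing attributes/scans/events CSVs
    n_individuals: int = 12              # generator mode
    follows_per_focal: int | None = None
    master_seed: int = 0
    n_perm_dyadic: int = 2000
    n_perm_node: int = 10000
    bond_classes: tuple[str, ...] = (
        BondClass.preferred_reciprocated.value,
        BondClass.preferred_nonreciprocated.value,
        BondClass.non_preferred.value,
    )
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm_dyadic < 1 or self.n_perm_node < 1:
            raise InputError("permutation counts must be >= 1")
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise InputError(f"data_dir {self.data_dir!r} does not exist")
        self.bond_classes = tuple(BondClass(b).value for b in self.bond_classes)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "bond_classes" in raw:
            raw["bond_classes"] = tuple(raw["bond_classes"])
        return cls(**raw)


@dataclass
class StudyReport:
    """All analysis tables plus a provenance block."""

    bond_modality: pd.DataFrame
    context_modality: pd.DataFrame
    centrality: pd.DataFrame
    sampling_effort: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bond_modality": self.bond_modality.to_dict(orient="records"),
            "context_modality": self.context_modality.to_dict(orient="records"),
            "centrality": self.centrality.to_dict(orient="records"),
            "sampling_effort": self.sampling_effort.to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json(indent=2))
        for name in ("bond_modality", "context_modality", "centrality", "sampling_effort"):
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# matrix preparation shared by the analyses


def build_matrices(dataset: Dataset) -> dict:
    """All networks and covariates the four analyses consume."""
    labels = dataset.labels
    prox = proximity_duration_matrix(dataset.scans, labels)
    modality_rates = {
        m: gesture_rate_matrix(dataset.events, dataset.scans, modality=m, labels=labels)
        for m in MODALITIES
    }
    context_rates = {
        c: gesture_rate_matrix(dataset.events, dataset.scans, context=c, labels=labels)
        for c in CONTEXTS
    }
    return {
        "labels": labels,
        "proximity": prox,
        "modality_rates": modality_rates,
        "context_rates": context_rates,
        "similarity": similarity_matrices(dataset.attributes),
        "covariates": node_covariates(dataset.scans, dataset.attributes),
    }


def _drop_constant(named: list[tuple[str, DyadicMatrix]]) -> list[tuple[str, DyadicMatrix]]:
    kept = []
    for name, m in named:
        if m.offdiag_values().std() == 0:
            log.warning("dropping constant predictor network %r", name)
            warnings.warn(f"dropping constant predictor network {name!r}", stacklevel=3)
        else:
            kept.append((name, m))
    return kept


# ---------------------------------------------------------------------------
# analyses


def run_bond_modality_analysis(
    dataset: Dataset, config: AnalysisConfig, mats: dict | None = None
) -> pd.DataFrame:
    """MRQAP of each bond-class network on modality rates + similarity controls."""
    mats = mats or build_matrices(dataset)
    seed = subseed(config.master_seed, "bond_modality")
    preds = [(f"{m.value}_rate", mats["modality_rates"][m]) for m in MODALITIES]
    preds += [(k, v) for k, v in mats["similarity"].items()]
    rows = []
    for k, bc in enumerate(config.bond_classes):
        bonds = classify_bonds(mats["proximity"], bc)
        kept = _drop_constant(preds)
        res = mrqap_dsp(
            bonds.base, [m for _, m in kept],
            n_perm=config.n_perm_dyadic, seed=seed + k,
            predictor_names=[n for n, _ in kept], outcome_name=bc,
        )
        df = res.to_frame()
        df["upper_threshold_min_hr"] = bonds.upper_threshold
        df["lower_threshold_min_hr"] = bonds.lower_threshold
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def run_context_modality_analysis(
    dataset: Dataset, config: AnalysisConfig, mats: dict | None = None
) -> pd.DataFrame:
    """MRQAP of each modality rate network on context rates + similarity controls."""
    mats = mats or build_matrices(dataset)
    seed = subseed(config.master_seed, "context_modality")
    rows = []
    for k, m in enumerate(MODALITIES):
        preds = [(f"{c.value}_rate", mats["context_rates"][c]) for c in CONTEXTS]
        preds += [(kk, v) for kk, v in mats["similarity"].items()]
        kept = _drop_constant(preds)
        res = mrqap_dsp(
            mats["modality_rates"][m], [x for _, x in kept],
            n_perm=config.n_perm_dyadic, seed=seed + k,
            predictor_names=[n for n, _ in kept], outcome_name=f"{m.value}_rate",
        )
        rows.append(res.to_frame())
    return pd.concat(rows, ignore_index=True)


def run_centrality_analysis(
    dataset: Dataset, config: AnalysisConfig, mats: dict | None = None
) -> pd.DataFrame:
    """Node-level regression of strong-bond out-degree on modality degrees + controls.

    Sex enters as a 0/1 indicator (male = 1).  Constant covariate columns
    are dropped with a warning.
    """
    mats = mats or build_matrices(dataset)
    seed = subseed(config.master_seed, "centrality")
    strong = classify_bonds(mats["proximity"], BondClass.strong)
    y = normalized_degree(strong.base, "out")
    cols: dict[str, pd.Series] = {}
    for m in MODALITIES:
        cols[f"{m.value}_out_degree"] = normalized_degree(mats["modality_rates"][m], "out")
        cols[f"{m.value}_in_degree"] = normalized_degree(mats["modality_rates"][m], "in")
    cov = mats["covariates"]
    cols["hours_near_oestrus"] = cov["hours_near_oestrus"]
    cols["hours_near_kin"] = cov["hours_near_kin"]
    cols["age"] = cov["age"]
    cols["sex_male"] = (cov["sex"] == Sex.male.value).astype(float)
    X = pd.DataFrame(cols)
    keep = [c for c in X.columns if X[c].std(ddof=0) > 0]
    for c in X.columns:
        if c not in keep:
            log.warning("dropping constant covariate %r", c)
            warnings.warn(f"dropping constant covariate {c!r}", stacklevel=2)
    res = node_regression(
        y, X[keep], n_perm=config.n_perm_node, seed=seed,
        predictor_names=keep, outcome_name="strong_bond_out_degree",
    )
    return res.to_frame()


def run_sampling_effort_check(
    dataset: Dataset, config: AnalysisConfig, mats: dict | None = None
) -> pd.DataFrame:
    """Geary's C between observation hours and each modality network.

    A degenerate attribute (equal observation hours for everyone) is
    reported as an error row rather than aborting the study.
    """
    mats = mats or build_matrices(dataset)
    seed = subseed(config.master_seed, "sampling_effort")
    hours = pd.Series(
        {a.id: a.observation_hours for a in dataset.attributes}, name="observation_hours"
    )
    rows = []
    for k, m in enumerate(MODALITIES):
        net = mats["modality_rates"][m]
        try:
            # weighted mode: the benchmark rate networks are dense, so a
            # binary dichotomization would leave Geary's C nearly constant
            res = geary_c(hours, net, n_perm=config.n_perm_node, seed=seed + k,
                          weights="weighted")
            rows.append(
                {"network": f"{m.value}_rate", "geary_c": res.c, "p": res.p,
                 "n_perm": res.n_perm, "seed": res.seed, "error": ""}
            )
        except (DegenerateInputError, InputError) as exc:
            rows.append(
                {"network": f"{m.value}_rate", "geary_c": float("nan"),
                 "p": float("nan"), "n_perm": config.n_perm_node, "seed": seed + k,
                 "error": str(exc)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


def _obtain_dataset(config: AnalysisConfig) -> Dataset:
    if config.data_dir is not None:
        return load_dataset(config.data_dir)
    return simulate_dataset(
        n=config.n_individuals,
        seed=subseed(config.master_seed, "simulate"),
        follows_per_focal=config.follows_per_focal,
    )


def run_study(config: AnalysisConfig, dataset: Dataset | None = None) -> StudyReport:
    """Run all four analyses and assemble a reproducible report."""
    dataset = dataset if dataset is not None else _obtain_dataset(config)
    mats = build_matrices(dataset)
    n_flagged = {
        "proximity": len(mats["proximity"].flagged),
        **{f"{m.value}_rate": len(mats["modality_rates"][m].flagged) for m in MODALITIES},
    }
    report = StudyReport(
        bond_modality=run_bond_modality_analysis(dataset, config, mats),
        context_modality=run_context_modality_analysis(dataset, config, mats),
        centrality=run_centrality_analysis(dataset, config, mats),
        sampling_effort=run_sampling_effort_check(dataset, config, mats),
        provenance={
            "gestnet_version": _version,
            "master_seed": config.master_seed,
            "sub_seeds": {k: subseed(config.master_seed, k) for k in _SEED_KEYS},
            "n_perm_dyadic": config.n_perm_dyadic,
            "n_perm_node": config.n_perm_node,
            "n_individuals": len(dataset.labels),
            "n_scans": len(dataset.scans),
            "n_events": len(dataset.events),
            "zero_denominator_cells": n_flagged,
            "data_dir": config.data_dir,
        },
    )
    if config.output_dir:
        report.write(config.output_dir)
        if config.data_dir is None:
            write_dataset(dataset, Path(config.output_dir) / "data")
    return report
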