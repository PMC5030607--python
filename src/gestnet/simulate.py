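"""Synthetic focal-follow generator with a latent bond model.

The generator emulates a small fission--fusion community (default: 12
adults, six of each sex) observed by standardised 18-minute focal follows
of 9 instantaneous scans at 2-minute intervals.  A symmetric latent
*affinity* matrix drives everything dyadic:

* party membership  -- each non-focal joins the focal's party with a
  logistic probability increasing in the realized bond latent;
* close proximity   -- given co-party membership, an individual is within
  10 m of the focal with probability ``logistic(b0 + b1 * z_bond)``;
* gestures          -- for every 2-minute scan in which B is within 10 m of
  focal A, the number of gestures A directs at B in modality m is Poisson
  with mean ``(2/60) * exp(alpha_m + gamma_m * z + tau * u_m - tau^2/2)``,
  where ``z`` is the standardized log-affinity and ``u_m`` a dyad-specific
  modality propensity.

The realized bond latent couples the channels back into proximity,
``z_bond = standardize(z + kappa * sum_m gamma_m * u_m)``, so the planted
slopes ``gamma_m`` control both the marginal and the partial
(per-modality) dependence of gesture rates on bond strength: by default
visual gestures increase with bond strength while tactile and long-range
auditory gestures decrease, the modality/bond pattern the pipeline is
designed to detect.  All planted parameters are retrievable for recovery
tests via :func:`planted_truth`.

One master seed reproduces a whole dataset; sub-streams for the population,
the affinity draw, the scan log and the event log are derived with
``numpy.random.SeedSequence.spawn``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, SizeError
from .matrices import offdiag_indices
from .types import (
    Activity,
    Context,
    Dataset,
    FocalScan,
    GestureEvent,
    GROOMING_ACTIVITIES,
    IndividualAttributes,
    Modality,
    ReproductiveState,
    SCAN_MINUTES,
    SCANS_PER_FOLLOW,
    Sex,
)

__all__ = [
    "PopulationConfig",
    "BondParams",
    "LatentBondModel",
    "make_population",
    "make_latent_bonds",
    "simulate_observations",
    "simulate_gestures",
    "simulate_dataset",
    "planted_truth",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# population


@dataclass(frozen=True)
class PopulationConfig:
    """Attribute proportions for :func:`make_population`.

    Defaults describe the emulated community: equal sex ratio, adult ages,
    roughly one in ten dyads maternally related, a third of females in
    oestrus, and per-individual focal-sampling effort drawn uniformly from
    8.33--18.63 hours.
    """

    female_fraction: float = 0.5
    kin_dyad_fraction: float = 0.10
    age_range: tuple[float, float] = (15.0, 40.0)
    oestrus_fraction: float = 1.0 / 3.0
    observation_hours_range: tuple[float, float] = (8.33, 18.63)


def _matriline_sizes(n: int, target_pairs: int) -> list[int]:
    """Greedy matriline sizes so that ~target_pairs dyads share a matriline."""
    sizes: list[int] = []
    remaining, pairs_needed = n, target_pairs
    while pairs_needed > 0 and remaining >= 2:
        # largest group whose internal pair count does not overshoot
        s = 2
        while s < remaining and (s + 1) * s // 2 <= pairs_needed:
            s += 1
        sizes.append(s)
        remaining -= s
        pairs_needed -= s * (s - 1) // 2
    sizes.extend([1] * remaining)
    return sizes


def make_population(
    n: int, seed=0, config: PopulationConfig | None = None
) -> list[IndividualAttributes]:
    """Create ``n`` individuals with ids, sex, age, matriline and oestrus state.

    Sex counts match ``config.female_fraction`` exactly (rounded); matrilines
    are sized so that approximately ``config.kin_dyad_fraction`` of all dyads
    are maternal kin.  Deterministic for a fixed seed and config.
    """
    if n < 4:
        raise SizeError(
            f"need at least 4 individuals for downstream permutation tests, got {n}"
        )
    cfg = config or PopulationConfig()
    rng = _rng(seed)
    ids = [f"c{i + 1:02d}" for i in range(n)]

    n_female = round(n * cfg.female_fraction)
    sexes = np.array([Sex.female] * n_female + [Sex.male] * (n - n_female), dtype=object)
    rng.shuffle(sexes)

    total_pairs = n * (n - 1) // 2
    sizes = _matriline_sizes(n, round(cfg.kin_dyad_fraction * total_pairs))
    matrilines = np.concatenate(
        [np.full(s, f"M{k + 1}") for k, s in enumerate(sizes)]
    )
    rng.shuffle(matrilines)

    ages = rng.uniform(*cfg.age_range, size=n)
    hours = rng.uniform(*cfg.observation_hours_range, size=n)

    female_idx = [i for i in range(n) if sexes[i] is Sex.female]
    n_oestrus = round(cfg.oestrus_fraction * len(female_idx))
    oestrus = set(rng.choice(female_idx, size=n_oestrus, replace=False)) if n_oestrus else set()

    out = []
    for i in range(n):
        if sexes[i] is Sex.male:
            state = ReproductiveState.male
        elif i in oestrus:
            state = ReproductiveState.oestrus
        else:
            state = ReproductiveState.non_oestrus
        out.append(
            IndividualAttributes(
                id=ids[i],
                sex=sexes[i],
                age=float(ages[i]),
                matriline=str(matrilines[i]),
                reproductive_state=state,
                observation_hours=float(hours[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# latent bonds


def _default_intercepts() -> dict[Modality, float]:
    """Per-modality log gesture rates at average bond strength (events/hr within 10 m).

    Benchmark rates are deliberately high (12/hr for the three bond-coupled
    modalities) so that per-dyad rates are estimated with low sampling noise
    from ~12 hours of focal observation per subject; field rates are an
    order of magnitude lower and would require far longer observation for
    resampling-stable dyadic estimates.
    """
    return {
        Modality.visual: math.log(12.0),
        Modality.tactile: math.log(12.0),
        Modality.auditory_short: math.log(0.4),
        Modality.auditory_long: math.log(12.0),
    }


def _default_slopes() -> dict[Modality, float]:
    # planted signs: visual rates rise with bond strength, tactile and
    # long-range auditory rates fall; short-range auditory weakly negative.
    # magnitudes are small because the slope acts on the log-rate of a
    # high-rate process measured with little noise; large slopes would make
    # the raw rate matrices so skewed that linear network regression loses
    # the planted signal to single extreme dyads.
    return {
        Modality.visual: 0.18,
        Modality.tactile: -0.18,
        Modality.auditory_short: -0.06,
        Modality.auditory_long: -0.18,
    }


def _default_activity_probs() -> dict[Activity, float]:
    return {
        Activity.rest: 0.30,
        Activity.feed: 0.30,
        Activity.travel: 0.15,
        Activity.groom_give: 0.07,
        Activity.groom_receive: 0.07,
        Activity.groom_mutual: 0.06,
        Activity.other: 0.05,
    }


#: Modality-specific context distributions.  Mass is placed on the contexts
#: in which each modality characteristically occurs (tactile on affiliative
#: close-contact contexts; long-range auditory on threat/travel/display
#: contexts; visual spread broadly over both).
DEFAULT_CONTEXT_TABLES: dict[Modality, dict[Context, float]] = {
    Modality.visual: {
        Context.threat_to_dominate: 0.10, Context.food_sharing: 0.05,
        Context.other_threat: 0.10, Context.travel: 0.10,
        Context.copulation: 0.10, Context.greeting: 0.15,
        Context.mutual_groom: 0.10, Context.receive_groom: 0.10,
        Context.play: 0.10, Context.pant_hoot: 0.10,
    },
    Modality.tactile: {
        Context.reassurance: 0.20, Context.greeting: 0.25,
        Context.give_groom: 0.15, Context.play: 0.40,
    },
    Modality.auditory_short: {
        Context.threat_to_dominate: 0.30, Context.copulation: 0.15,
        Context.greeting: 0.25, Context.give_groom: 0.30,
    },
    Modality.auditory_long: {
        Context.threat_to_dominate: 0.25, Context.other_threat: 0.20,
        Context.travel: 0.15, Context.copulation: 0.10,
        Context.pant_hoot: 0.30,
    },
}

#: Signaller-recipient distance (mean, SD) in metres by modality; draws are
#: clipped to [0, 10] since analysis-eligible events are within 10 m.
DISTANCE_PARAMS: dict[Modality, tuple[float, float]] = {
    Modality.visual: (3.03, 4.15),
    Modality.tactile: (1.76, 3.46),
    Modality.auditory_short: (0.19, 0.74),
    Modality.auditory_long: (5.47, 3.04),
}


@dataclass(frozen=True)
class BondParams:
    """Priors for :func:`make_latent_bonds` and observation parameters.

    Affinity is ``exp(noise + effect_kin * kin + effect_sex * same_sex)``
    with symmetric Gaussian log-noise.  ``party_base_prob``/``party_slope``
    set the logistic co-party probability; ``proximity_intercept``/
    ``proximity_slope`` the within-10m probability given co-party.

    Bonds are expressed through partially independent modality channels:
    each dyad carries a per-modality propensity ``u_m`` (SD ``channel_sd``
    on the log-rate scale, mean-corrected so intercept calibration is
    unaffected), and the realized proximity latent is the shared affinity
    axis plus ``channel_coupling * gamma_m * u_m`` summed over modalities.
    Dyads idiosyncratically fond of a modality therefore shift their
    proximity in the direction of that modality's planted slope — the
    partial, modality-specific bond/communication association the
    inference stage is designed to recover.  ``channel_sd=0`` or
    ``channel_coupling=0`` switches this off.
    """

    effect_kin: float = 0.5
    effect_sex: float = 0.3
    noise_sd: float = 0.8
    gesture_intercepts: Mapping[Modality, float] = field(default_factory=_default_intercepts)
    gesture_slopes: Mapping[Modality, float] = field(default_factory=_default_slopes)
    party_base_prob: float = 0.7
    party_slope: float = 0.5
    proximity_intercept: float = -0.45
    proximity_slope: float = 0.65
    attention_intercept: float = -0.5
    attention_slope: float = 1.0
    channel_sd: float = 0.55
    channel_coupling: float = 10.0
    overdispersion: float = 0.0
    activity_probs: Mapping[Activity, float] = field(default_factory=_default_activity_probs)

    def with_slopes(self, **by_name: float) -> "BondParams":
        """Convenience copy with some gesture slopes replaced (by modality name)."""
        slopes = dict(self.gesture_slopes)
        for name, val in by_name.items():
            slopes[Modality(name)] = val
        from dataclasses import replace

        return replace(self, gesture_slopes=slopes)


@dataclass
class LatentBondModel:
    """A realised latent bond structure plus all generative parameters."""

    labels: tuple[str, ...]
    affinity: np.ndarray  # symmetric, nonnegative off-diagonal, NaN diagonal
    params: BondParams
    channels: dict[Modality, np.ndarray] | None = None  # symmetric u_m draws
    seed: int | None = None

    def __post_init__(self) -> None:
        self.affinity = np.array(self.affinity, dtype=float)
        np.fill_diagonal(self.affinity, np.nan)
        off = self.affinity[~np.isnan(self.affinity)]
        if off.size and (not np.isfinite(off).all() or off.min() < 0):
            raise InputError("affinity must be finite and nonnegative off-diagonal")
        if set(self.params.gesture_intercepts) != set(Modality) or set(
            self.params.gesture_slopes
        ) != set(Modality):
            raise InputError("gesture intercepts/slopes must key exactly the four modalities")

    @property
    def n(self) -> int:
        return len(self.labels)

    def z_affinity(self) -> np.ndarray:
        """Standardized latent bond strength: z-scored log-affinity.

        Affinity is multiplicative (log-normal), so the symmetric Gaussian
        scale on which planted effects act is log-affinity; it is z-scored
        (mean 0, SD 1) over off-diagonal cells.  A constant affinity matrix
        standardizes to all zeros.
        """
        z = self.affinity.copy()
        rows, cols = offdiag_indices(self.n)
        off = np.log(np.maximum(z[rows, cols], 1e-300))
        sd = off.std()
        z[rows, cols] = (off - off.mean()) / sd if sd > 0 else 0.0
        return z

    def channel_effect(self, modality: Modality) -> np.ndarray:
        """The dyadic channel propensity u_m (zeros when channels are off)."""
        if self.channels is None or self.params.channel_sd == 0:
            return np.zeros_like(self.affinity)
        return self.channels[modality]

    def z_bond(self) -> np.ndarray:
        """Realized proximity latent: shared affinity axis plus coupled channels.

        ``standardize(z_affinity + coupling * sum_m gamma_m * u_m)`` over
        off-diagonal cells; this is what party membership and within-10m
        proximity respond to.
        """
        comb = self.z_affinity()
        kappa = self.params.channel_coupling
        if self.channels is not None and kappa != 0 and self.params.channel_sd != 0:
            for m, u in self.channels.items():
                comb = comb + kappa * self.params.gesture_slopes[m] * np.nan_to_num(u)
        rows, cols = offdiag_indices(self.n)
        off = comb[rows, cols]
        sd = off.std()
        comb[rows, cols] = (off - off.mean()) / sd if sd > 0 else 0.0
        return comb


def make_latent_bonds(
    attributes: Sequence[IndividualAttributes],
    params: BondParams | None = None,
    seed=0,
) -> LatentBondModel:
    """Draw a symmetric latent affinity matrix from kin/sex effects plus noise."""
    if not attributes:
        raise InputError("attributes must be nonempty")
    params = params or BondParams()
    rng = _rng(seed)
    n = len(attributes)
    kin = np.zeros((n, n))
    same_sex = np.zeros((n, n))
    for i, a in enumerate(attributes):
        for j, b in enumerate(attributes):
            if i != j:
                kin[i, j] = float(a.matriline == b.matriline)
                same_sex[i, j] = float(a.sex == b.sex)
    noise = rng.normal(0.0, params.noise_sd, size=(n, n))
    noise = np.triu(noise, 1) + np.triu(noise, 1).T  # symmetric dyadic noise
    affinity = np.exp(noise + params.effect_kin * kin + params.effect_sex * same_sex)
    channels = None
    if params.channel_sd > 0:
        channels = {}
        for m in Modality:
            u = rng.normal(0.0, 1.0, size=(n, n))
            channels[m] = np.triu(u, 1) + np.triu(u, 1).T
    return LatentBondModel(
        labels=tuple(a.id for a in attributes),
        affinity=affinity,
        params=params,
        channels=channels,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# observations


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return math.log(p / (1.0 - p))


def simulate_observations(
    model: LatentBondModel,
    follows_per_focal: int | Sequence[int] | None = None,
    seed=0,
    attributes: Sequence[IndividualAttributes] | None = None,
) -> list[FocalScan]:
    """Simulate focal follows (9 scans each) for every individual.

    ``follows_per_focal`` may be a single count, a per-focal sequence, or
    ``None`` — in which case each focal's count is derived from its
    ``observation_hours`` attribute (one follow covers 18 min = 0.3 hr).
    """
    p = model.params
    n = model.n
    if follows_per_focal is None:
        if attributes is None:
            raise InputError("follows_per_focal=None requires attributes with observation_hours")
        counts = [max(1, round(a.observation_hours / (SCANS_PER_FOLLOW * SCAN_MINUTES / 60)))
                  for a in attributes]
    elif np.isscalar(follows_per_focal):
        if follows_per_focal < 1:
            raise InputError("follows_per_focal must be >= 1")
        counts = [int(follows_per_focal)] * n
    else:
        counts = [int(c) for c in follows_per_focal]
        if len(counts) != n or min(counts) < 1:
            raise InputError("per-focal follow counts must list >= 1 follow per focal")

    rng = _rng(seed)
    z = model.z_bond()
    base_logit = _logit(p.party_base_prob)
    activities = list(p.activity_probs)
    act_probs = np.array([p.activity_probs[a] for a in activities], dtype=float)
    act_probs = act_probs / act_probs.sum()

    scans: list[FocalScan] = []
    for i, focal in enumerate(model.labels):
        others = [j for j in range(n) if j != i]
        zi = z[i, others]
        with np.errstate(invalid="ignore"):
            p_party = _sigmoid(base_logit + p.party_slope * zi)
            p_within = _sigmoid(p.proximity_intercept + p.proximity_slope * zi)
            p_att = _sigmoid(p.attention_intercept + p.attention_slope * zi)
        p_party = np.nan_to_num(p_party, nan=0.0)
        aff_i = model.affinity[i, others]
        for f in range(counts[i]):
            in_party = rng.random((SCANS_PER_FOLLOW, len(others))) < p_party
            in_10m = in_party & (rng.random(in_party.shape) < p_within)
            acts = rng.choice(len(activities), size=SCANS_PER_FOLLOW, p=act_probs)
            att_draw = rng.random((SCANS_PER_FOLLOW, 2))
            for s in range(SCANS_PER_FOLLOW):
                party = frozenset(model.labels[others[k]] for k in np.nonzero(in_party[s])[0])
                near = np.nonzero(in_10m[s])[0]
                within = frozenset(model.labels[others[k]] for k in near)
                if near.size:
                    # highest-affinity neighbour; ties resolved by id order
                    nn = model.labels[others[int(near[np.argmax(aff_i[near])])]]
                else:
                    nn = None
                activity = activities[acts[s]]
                groom_partner = None
                if activity in GROOMING_ACTIVITIES:
                    if nn is None:
                        activity = Activity.other  # nobody close enough to groom
                    else:
                        groom_partner = nn
                if nn is not None:
                    k_nn = others.index(model.labels.index(nn))
                    att_g = bool(att_draw[s, 0] < p_att[k_nn])
                    att_r = bool(att_draw[s, 1] < p_att[k_nn])
                else:
                    att_g, att_r = False, False
                scans.append(
                    FocalScan(
                        follow_id=f"{focal}_F{f + 1:03d}",
                        focal=focal,
                        scan_index=s + 1,
                        party=party,
                        within_10m=within,
                        nearest_neighbour=nn,
                        activity=activity,
                        groom_partner=groom_partner,
                        attention_given=att_g,
                        attention_received=att_r,
                    )
                )
    return scans


# ---------------------------------------------------------------------------
# gestures


def simulate_gestures(
    model: LatentBondModel, scans: Sequence[FocalScan], seed=0
) -> list[GestureEvent]:
    """Emit gesture events from every (scan, within-10m neighbour) exposure.

    Counts are Poisson with dyadic mean ``(2/60) * exp(alpha_m + gamma_m*z)``
    per modality (gamma-mixed for overdispersion > 0); contexts follow the
    modality-specific tables; all events carry ``within_10m=True``.
    """
    if not scans:
        raise InputError("scans must be nonempty")
    p = model.params
    z = model.z_affinity()
    idx = {l: k for k, l in enumerate(model.labels)}
    rng = _rng(seed)

    pairs: list[tuple[int, int]] = []
    for scan in scans:
        a = idx[scan.focal]
        for b_label in sorted(scan.within_10m):
            pairs.append((a, idx[b_label]))
    if not pairs:
        return []
    pair_arr = np.array(pairs)
    zvals = z[pair_arr[:, 0], pair_arr[:, 1]]
    exposure_hr = SCAN_MINUTES / 60.0
    tau = p.channel_sd

    events: list[GestureEvent] = []
    eid = 0
    for m in Modality:
        alpha = p.gesture_intercepts[m]
        gamma = p.gesture_slopes[m]
        u = model.channel_effect(m)[pair_arr[:, 0], pair_arr[:, 1]]
        with np.errstate(over="ignore"):
            # tau*u is mean-corrected so E[rate | z] = exp(alpha + gamma*z)
            lam = exposure_hr * np.exp(alpha + gamma * zvals + tau * u - tau**2 / 2.0)
        lam = np.nan_to_num(lam, nan=0.0)
        if p.overdispersion > 0:
            shape = 1.0 / p.overdispersion
            lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
        counts = rng.poisson(lam)
        nz = np.nonzero(counts)[0]
        ctx_table = DEFAULT_CONTEXT_TABLES[m]
        ctxs = list(ctx_table)
        ctx_p = np.array([ctx_table[c] for c in ctxs], dtype=float)
        ctx_p = ctx_p / ctx_p.sum()
        mu, sd = DISTANCE_PARAMS[m]
        for k in nz:
            a, b = pair_arr[k]
            for _ in range(int(counts[k])):
                eid += 1
                ctx = ctxs[rng.choice(len(ctxs), p=ctx_p)]
                dist = float(np.clip(rng.normal(mu, sd), 0.0, 10.0))
                events.append(
                    GestureEvent(
                        event_id=f"g{eid:06d}",
                        signaller=model.labels[a],
                        recipient=model.labels[b],
                        modality=m,
                        context=ctx,
                        distance_m=dist,
                        within_10m=True,
                    )
                )
    return events


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset(Dataset):
    """A generated dataset together with its generative model."""

    model: LatentBondModel = None  # type: ignore[assignment]
    master_seed: int = 0


def simulate_dataset(
    n: int = 12,
    seed: int = 0,
    follows_per_focal: int | None = None,
    population: PopulationConfig | None = None,
    params: BondParams | None = None,
) -> SyntheticDataset:
    """Generate a full dataset (attributes, scans, events) from one master seed.

    With ``follows_per_focal=None`` sampling effort varies across focals
    according to their drawn observation hours, as in real focal sampling;
    an integer forces equal effort (observation hours are set to match).
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_bond, s_obs, s_gest = ss.spawn(4)
    attributes = make_population(n, np.random.default_rng(s_pop), population)
    model = make_latent_bonds(attributes, params, np.random.default_rng(s_bond))
    model.seed = seed
    scans = simulate_observations(
        model, follows_per_focal, np.random.default_rng(s_obs), attributes=attributes
    )
    if follows_per_focal is not None:
        hours = follows_per_focal * SCANS_PER_FOLLOW * SCAN_MINUTES / 60.0
        from dataclasses import replace

        attributes = [replace(a, observation_hours=hours) for a in attributes]
    events = simulate_gestures(model, scans, np.random.default_rng(s_gest))
    return SyntheticDataset(
        attributes=attributes, scans=scans, events=events, model=model, master_seed=seed
    )


def planted_truth(model: LatentBondModel) -> dict:
    """Planted parameters in JSON-ready form, for parameter-recovery tests."""
    p = model.params
    return {
        "seed": model.seed,
        "effect_kin": p.effect_kin,
        "effect_sex": p.effect_sex,
        "noise_sd": p.noise_sd,
        "gesture_intercepts": {m.value: p.gesture_intercepts[m] for m in Modality},
        "gesture_slopes": {m.value: p.gesture_slopes[m] for m in Modality},
        "party_base_prob": p.party_base_prob,
        "party_slope": p.party_slope,
        "proximity_intercept": p.proximity_intercept,
        "proximity_slope": p.proximity_slope,
        "channel_sd": p.channel_sd,
        "channel_coupling": p.channel_coupling,
        "overdispersion": p.overdispersion,
    }
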