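"""Seeded synthetic hospital stay records with planted modular structure.

Real patient administrative extracts are private, so the pipeline is
exercised on a generator that emulates their qualitative structure:

* wards and clinical units are grouped into planted modules — a small set of
  *stable* specialty modules (mental health, women's health, ... ) whose
  composition barely changes month to month, and a larger set of *general*
  medical/surgical modules whose composition varies;
* each synthetic patient is attached to one module and, with high
  probability, draws both ward and unit from it; with a small *cross rate*
  the ward and unit come from different modules;
* a per-snapshot *disorganization* value in [0, 1] raises the cross rate of
  the general modules only — stable modules are untouched — interpolating
  between the baseline cross rate and the maximum ``1 - p_within``;
* a delayed-placement count (patients accepted for admission but without a
  bed at midnight, the congestion surrogate) is an affine function of the
  same latent disorganization plus Gaussian noise.  Congestion is driven by
  the latent dial, not by modularity itself, so any modularity-congestion
  correlation downstream is an emergent, recoverable property.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .build import AdmissionType, StayRecord
from .errors import ConfigurationError

#: Default per-snapshot disorganization: 21 monthly values spanning [0.1, 0.9]
#: in a fixed varied order, emulating month-to-month operational pressure
#: including a disrupted stretch (the 2020 pandemic months at the end).
DEFAULT_DISORGANIZATION = (
    0.20, 0.50, 0.80, 0.35, 0.65, 0.15, 0.90, 0.45, 0.70, 0.25, 0.55, 0.85,
    0.30, 0.60, 0.10, 0.75, 0.40, 0.50, 0.80, 0.20, 0.60,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic hospital.

    Defaults describe a mid-sized hospital: 8 planted modules (3 stable
    specialty + 5 general medical/surgical) over 32 wards and 40 units, 360
    inpatients per monthly snapshot, 21 monthly snapshots (a full calendar
    year plus nine months of the next), and delayed-placement counts spanning
    roughly 9-24 patients.
    """

    n_stable_modules: int = 3
    n_general_modules: int = 5
    wards_per_module: int = 4
    units_per_module: int = 5
    patients_per_snapshot: int = 360
    #: Probability floor that a patient's ward and unit share a module; the
    #: general-module cross rate never exceeds ``1 - p_within``.
    p_within: float = 0.65
    #: Baseline probability of a cross-module ward-unit pairing (all modules).
    p_cross_base: float = 0.02
    emergency_fraction: float = 0.65
    #: Amplitude of the month-to-month swing in the stable (specialty)
    #: modules' cross-linkage, as a fraction of the same ``1 - p_within``
    #: ceiling the general modules use.  Specialty services place outliers
    #: and consult patients across the hospital at a rate that varies
    #: seasonally and is unrelated to general bed pressure; this is the
    #: congestion-unrelated modularity variance that full-graph analysis
    #: picks up and exclusion of the high-coherence modules removes.  The
    #: swing is a single shared uniform draw per snapshot, independent of
    #: the disorganization series.  0 disables.
    stable_cross_volatility: float = 0.5
    n_snapshots: int = 21
    disorganization_series: tuple[float, ...] = DEFAULT_DISORGANIZATION
    congestion_intercept: float = 8.0
    congestion_slope: float = 15.0
    congestion_noise_sd: float = 1.5
    #: If set, elective patients are confined to these planted module ids.
    elective_modules: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_stable_modules": self.n_stable_modules,
            "n_general_modules": self.n_general_modules,
            "wards_per_module": self.wards_per_module,
            "units_per_module": self.units_per_module,
            "patients_per_snapshot": self.patients_per_snapshot,
            "n_snapshots": self.n_snapshots,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        probs = {
            "p_within": self.p_within,
            "p_cross_base": self.p_cross_base,
            "emergency_fraction": self.emergency_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        if len(self.disorganization_series) != self.n_snapshots:
            raise ConfigurationError(
                "disorganization_series length "
                f"{len(self.disorganization_series)} != n_snapshots {self.n_snapshots}"
            )
        for i, v in enumerate(self.disorganization_series):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"disorganization_series[{i}] must be in [0, 1], got {v!r}"
                )
        if self.congestion_noise_sd < 0:
            raise ConfigurationError(
                f"congestion_noise_sd must be >= 0, got {self.congestion_noise_sd!r}"
            )
        if not 0.0 <= self.stable_cross_volatility <= 1.0:
            raise ConfigurationError(
                f"stable_cross_volatility must be in [0, 1], got {self.stable_cross_volatility!r}"
            )
        n_mod = self.n_stable_modules + self.n_general_modules
        if self.elective_modules is not None:
            bad = [m for m in self.elective_modules if not 0 <= m < n_mod]
            if bad or not self.elective_modules:
                raise ConfigurationError(
                    f"elective_modules must be a non-empty subset of 0..{n_mod - 1}"
                )

    @property
    def n_modules(self) -> int:
        return self.n_stable_modules + self.n_general_modules


@dataclass
class GroundTruth:
    """Planted structure behind a generated data set."""

    #: node label -> planted module id (stable modules take ids 0..n_stable-1)
    planted_membership: dict[str, int]
    stable_module_ids: frozenset[int]
    disorganization: tuple[float, ...]
    module_wards: dict[int, list[str]]
    module_units: dict[int, list[str]]
    #: realized per-snapshot specialty disruption draws (filled by generate_stays)
    stable_disruption: tuple[float, ...] = ()

    def is_stable(self, module_id: int) -> bool:
        return module_id in self.stable_module_ids

    def cross_fraction(self, records: Sequence[StayRecord], general_only: bool = False) -> float:
        """Fraction of stays whose ward and unit belong to different planted
        modules; optionally restricted to stays whose ward is in a general
        module."""
        pm = self.planted_membership
        pool = [
            r for r in records
            if not general_only or pm[r.ward_id] not in self.stable_module_ids
        ]
        if not pool:
            return 0.0
        crossed = sum(1 for r in pool if pm[r.ward_id] != pm[r.unit_id])
        return crossed / len(pool)


def snapshot_dates(config: GeneratorConfig) -> list[datetime.date]:
    """Monthly extraction dates (the 15th), starting January 2019."""
    dates = []
    for t in range(config.n_snapshots):
        dates.append(datetime.date(2019 + t // 12, t % 12 + 1, 15))
    return dates


def _layout(config: GeneratorConfig) -> GroundTruth:
    membership: dict[str, int] = {}
    module_wards: dict[int, list[str]] = {}
    module_units: dict[int, list[str]] = {}
    for m in range(config.n_modules):
        module_wards[m] = [f"W{m:02d}{i:02d}" for i in range(config.wards_per_module)]
        module_units[m] = [f"U{m:02d}{j:02d}" for j in range(config.units_per_module)]
        for n in module_wards[m] + module_units[m]:
            membership[n] = m
    return GroundTruth(
        planted_membership=membership,
        stable_module_ids=frozenset(range(config.n_stable_modules)),
        disorganization=tuple(config.disorganization_series),
        module_wards=module_wards,
        module_units=module_units,
    )


def _cross_rate(
    config: GeneratorConfig,
    module_id: int,
    disorganization: float,
    stable_disruption: float,
) -> float:
    """Per-stay probability of a cross-module ward-unit pairing.

    General modules interpolate from the baseline toward ``1 - p_within`` as
    the snapshot's disorganization rises, so a fully disorganized month mixes
    general patients across modules at the maximum rate the config allows.
    Stable modules interpolate along the same ceiling but driven by the
    snapshot's specialty disruption draw (independent of disorganization)
    scaled by ``stable_cross_volatility``.
    """
    base = config.p_cross_base
    ceiling = max(base, 1.0 - config.p_within)
    if module_id < config.n_stable_modules:
        dial = config.stable_cross_volatility * stable_disruption
    else:
        dial = disorganization
    return base + dial * (ceiling - base)


#: Of a general module's cross stays, this fraction is diffuse consult-style
#: linkage; the rest is boarding in an overflow ward.  Stable (specialty)
#: modules are diffuse-only.
DIFFUSE_CROSS_FRACTION = 0.15

#: Length of each module's ranked escalation list of overflow wards.  Under
#: light pressure boarded patients go to the primary overflow ward; rising
#: disorganization spreads boarding progressively deeper down the list.
N_OVERFLOW_WARDS = 6
ESCALATION_BASE = 0.5
ESCALATION_GAIN = 3.0

#: Number of persistent consult ward-unit pairs per module used for diffuse
#: cross stays; spread round-robin over the general modules so no single
#: module pair ever accrues enough links to merge.
DIFFUSE_POOL_SIZE = 6


def generate_stays(config: GeneratorConfig) -> tuple[list[StayRecord], GroundTruth]:
    """Generate the full stay-record list and its ground truth.

    Per snapshot, each of ``patients_per_snapshot`` synthetic patients is
    assigned an admission designation, a home module, and a ward-unit pair.
    With probability ``1 - cross_rate`` both ward and unit come from the home
    module.  A cross-module stay is, most of the time, a *boarded* patient:
    the unit is the home unit but the ward is one of a few overflow wards
    (re-drawn each snapshot from other modules) where the module's excess
    patients are placed — the physical signature of bed pressure, which lets
    single ward nodes drift between communities as disorganization rises.  A
    small remainder of cross stays is diffuse mixing with a uniformly chosen
    foreign ward or unit.
    """
    truth = _layout(config)
    rng = np.random.default_rng(config.seed)
    dates = snapshot_dates(config)
    n_mod = config.n_modules
    records: list[StayRecord] = []
    disruptions: list[float] = []
    all_wards = [w for m in range(n_mod) for w in truth.module_wards[m]]

    # Each module's overflow wards, fixed for the whole study period:
    # hospitals board excess patients into the same few escalation/outlier
    # wards month after month, which keeps cumulative (composite) graphs as
    # modular as the monthly ones.  Only general-module wards can host
    # boarded patients — specialty wards (mental health, obstetrics, ...)
    # are protected environments that do not take general overflow.
    general_wards = [
        w for w in all_wards
        if truth.planted_membership[w] >= config.n_stable_modules
    ]
    overflow: dict[int, list[str]] = {}
    for m in range(n_mod):
        foreign = [w for w in general_wards if truth.planted_membership[w] != m]
        n_pick = min(N_OVERFLOW_WARDS, len(foreign))
        if n_pick:
            picks = rng.choice(len(foreign), size=n_pick, replace=False)
            overflow[m] = [foreign[i] for i in picks]
        else:
            overflow[m] = []

    # Each module's persistent consult pairs: like overflow wards these are
    # stable relationships (the same liaison services visit the same wards),
    # alternating between a foreign ward hosting a home unit's patient and a
    # home ward hosting a foreign unit's patient, with partners rotating
    # through the general modules.
    diffuse_pairs: dict[int, list[tuple[str, str]]] = {}
    general_mods = list(range(config.n_stable_modules, n_mod))
    for m in range(n_mod):
        partners = [g for g in general_mods if g != m] or [
            g for g in range(n_mod) if g != m
        ]
        pairs = []
        for k in range(DIFFUSE_POOL_SIZE):
            partner = partners[k % len(partners)]
            if k % 2 == 0:
                w = truth.module_wards[partner][rng.integers(config.wards_per_module)]
                u = truth.module_units[m][rng.integers(config.units_per_module)]
            else:
                w = truth.module_wards[m][rng.integers(config.wards_per_module)]
                u = truth.module_units[partner][rng.integers(config.units_per_module)]
            pairs.append((w, u))
        diffuse_pairs[m] = pairs

    for t, date in enumerate(dates):
        d = truth.disorganization[t]
        # one shared specialty-disruption draw per month, independent of d
        stable_disruption = float(rng.random())
        disruptions.append(stable_disruption)
        for p in range(config.patients_per_snapshot):
            emergency = rng.random() < config.emergency_fraction
            if not emergency and config.elective_modules is not None:
                m = int(config.elective_modules[rng.integers(len(config.elective_modules))])
            else:
                m = int(rng.integers(n_mod))
            ward = unit = None
            if rng.random() < _cross_rate(config, m, d, stable_disruption):
                # Stable (specialty) modules spread their cross-hospital
                # patients thinly over their consult pairs, so their
                # communities never accrete or merge; general modules under
                # pressure mostly board concentrated blocks of patients
                # into their overflow wards.
                diffuse = (
                    m < config.n_stable_modules
                    or not overflow[m]
                    or rng.random() < DIFFUSE_CROSS_FRACTION
                )
                if diffuse:
                    ward, unit = diffuse_pairs[m][
                        int(rng.integers(len(diffuse_pairs[m])))
                    ]
                else:
                    # escalation depth grows with this month's pressure
                    rank = min(
                        len(overflow[m]) - 1,
                        int(rng.exponential(ESCALATION_BASE + ESCALATION_GAIN * d)),
                    )
                    ward = overflow[m][rank]
            if ward is None:
                ward = truth.module_wards[m][rng.integers(config.wards_per_module)]
            if unit is None:
                unit = truth.module_units[m][rng.integers(config.units_per_module)]
            records.append(
                StayRecord(
                    snapshot_date=date,
                    patient_id=f"P{t:03d}{p:05d}",
                    ward_id=ward,
                    unit_id=unit,
                    admission_type=(
                        AdmissionType.EMERGENCY if emergency else AdmissionType.ELECTIVE
                    ),
                )
            )
    truth.stable_disruption = tuple(disruptions)
    return records, truth


def generate_congestion(config: GeneratorConfig, truth: GroundTruth) -> list[int]:
    """Per-snapshot delayed-placement counts from the latent disorganization.

    ``count(t) = round(max(0, intercept + slope * d(t) + N(0, sd)))`` — a
    noisy affine readout of the same dial that drives general-module mixing.
    At defaults the counts span roughly 9 to 24 patients.
    """
    if len(truth.disorganization) != config.n_snapshots:
        raise ConfigurationError(
            "ground truth disorganization length "
            f"{len(truth.disorganization)} != n_snapshots {config.n_snapshots}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 211]))
    counts = []
    for d in truth.disorganization:
        raw = (
            config.congestion_intercept
            + config.congestion_slope * d
            + rng.normal(0.0, config.congestion_noise_sd)
        )
        counts.append(int(round(max(0.0, raw))))
    return counts
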