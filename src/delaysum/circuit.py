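"""Ground-truth glutamatergic input circuits for an ON DS cell.

Six functional groups of glutamatergic units (G1-G6) are distinguished by
their release kinetics: G1 fast-transient, G2 fast-sustained, G3 medium,
G4 slow-transient, G5 slow-sustained, G6 slowest latency (putative
glutamatergic amacrine cell). Their positions on the dendritic plane carry a
double gradient along the motion-preference axis (u): sustained/slow groups
on the preferred side (u < 0, where preferred-direction motion enters the
field first), transient/fast groups on the null side.

Latency scheme (a calibration, not a measurement). Within the dendritic
field, effective response delay decreases continuously from the preferred to
the null side with slope 5 ms/um, i.e. dS/dT = 200 um/s: this is the
diagonal space-time tilt that makes the delay-and-summate population most
sensitive to preferred-direction motion at 200 um/s. A unit's kernel peak
latency is that positional ramp, plus a per-group adjustment compensating
the group's intrinsic lag-to-peak (sustained units peak late within their
own wide responses, so their kernels need less explicit delay), plus
Gaussian unit-to-unit jitter. G6, the putative glutamatergic amacrine
pathway, does not follow the ramp: it has a fixed slow latency and acts as a
direction-neutral background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GROUPS",
    "DEFAULT_GROUP_COUNTS",
    "DEFAULT_GROUP_U_OFFSETS",
    "DEFAULT_GROUP_KINETICS",
    "TemporalKinetics",
    "GlutUnit",
    "CircuitModel",
    "group_kinetics_at",
    "make_ground_truth_cell",
    "apply_condition",
    "CONDITIONS",
]

GROUPS = ("G1", "G2", "G3", "G4", "G5", "G6")

#: per-group unit counts of the reference cell (32 G1 ... 20 G6 ROIs)
DEFAULT_GROUP_COUNTS = {"G1": 32, "G2": 25, "G3": 26, "G4": 34, "G5": 56, "G6": 20}

#: mean u position of each group relative to the dendritic-field centre (um);
#: preferred side is negative. Reproduces the observed ordering
#: mean u(G1) > u(G2) > u(G4) > u(G3) ~ 0 > u(G6) > u(G5).
DEFAULT_GROUP_U_OFFSETS = {
    "G1": 100.0,
    "G2": 60.0,
    "G3": 0.0,
    "G4": 40.0,
    "G5": -80.0,
    "G6": -40.0,
}

#: positional scatter of units around their group mean (um)
DEFAULT_SCATTER_SD_UM = 60.0

DEFAULT_DENDRITIC_DIAMETER_UM = 400.0

#: latency ramp of the calibration: d(latency)/du = -5 ms/um  =>  dS/dT = 200 um/s
LATENCY_SLOPE_S_PER_UM = 0.005
LATENCY_AT_CENTER_S = 1.10

#: unit-to-unit latency jitter (s); emulates biological variability within a group
LATENCY_JITTER_SD_S = 0.25

#: minimum kernel peak latency (s)
LATENCY_FLOOR_S = 0.05

#: per-group latency adjustment (s) compensating the group's intrinsic
#: lag-to-peak under motion, so that effective delays follow the positional
#: ramp; calibrated on single-unit moving-bar responses at 200 um/s
GROUP_LATENCY_ADJUST_S = {
    "G1": 0.048,
    "G2": -0.057,
    "G3": 0.0,
    "G4": 0.039,
    "G5": -0.075,
    "G6": 0.0,
}

#: fixed latency of the G6 (glutamatergic amacrine) pathway (s). G6 rides a
#: multi-synaptic route and does not follow the bipolar positional delay
#: ramp: it contributes a slow, direction-neutral background.
G6_LATENCY_S = 1.35

#: G6 boutons deliver larger unitary input than bipolar boutons
GROUP_GAINS = {"G1": 1.0, "G2": 1.0, "G3": 1.0, "G4": 1.0, "G5": 1.0, "G6": 2.0}

#: kinetic shape parameters per group: (rise tau, envelope tau1 slow,
#: envelope tau2 fast, transience); transient groups have short envelopes,
#: sustained groups long ones
GROUP_SHAPE_PARAMS = {
    "G1": (0.020, 0.18, 0.030, 0.90),
    "G2": (0.030, 0.60, 0.060, 0.45),
    "G3": (0.025, 0.40, 0.050, 0.65),
    "G4": (0.022, 0.22, 0.040, 0.85),
    "G5": (0.035, 0.70, 0.080, 0.40),
    "G6": (0.035, 1.20, 0.070, 0.30),
}

DEFAULT_RF_SIGMA_UM = (4.0, 4.0)


@dataclass(frozen=True)
class TemporalKinetics:
    """Release kinetics of one glutamatergic unit.

    ``decay_tau1_s`` (slow) and ``decay_tau2_s`` (fast) are the double-decay
    constants of the post-peak envelope ``exp(-t/tau1) - exp(-t/tau2)``;
    ``transience`` in [0, 1] summarises how transient the release is (1 = most
    transient): it weights the negative lobe of the linear kernel and, via
    the envelope constants of its group, the post-peak decay.
    """

    peak_latency_s: float
    rise_tau_s: float
    decay_tau1_s: float
    decay_tau2_s: float
    transience: float

    def __post_init__(self) -> None:
        if not (self.decay_tau1_s > self.decay_tau2_s > 0):
            raise ValueError("need decay_tau1_s > decay_tau2_s > 0")
        if self.peak_latency_s <= 0:
            raise ValueError("peak_latency_s must be positive")
        if not (0.0 <= self.transience <= 1.0):
            raise ValueError("transience must lie in [0, 1]")

    @property
    def filter_decay_tau_s(self) -> float:
        """Decay constant of the linear kernel's positive lobe (sustained
        units track the stimulus slightly more sluggishly; all kernels are
        fast relative to stimulus passage, so unit amplitude is speed-flat)."""
        return 0.03 + 0.03 * (1.0 - self.transience)


def group_kinetics_at(group: str, u_um: float, latency_jitter_s: float = 0.0) -> TemporalKinetics:
    """Kinetics of a unit of ``group`` at position ``u_um`` on the preference axis."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rise, tau1, tau2, tr = GROUP_SHAPE_PARAMS[group]
    if group == "G6":
        lat = G6_LATENCY_S + latency_jitter_s
    else:
        lat = (
            LATENCY_AT_CENTER_S
            - LATENCY_SLOPE_S_PER_UM * u_um
            + GROUP_LATENCY_ADJUST_S[group]
            + latency_jitter_s
        )
    return TemporalKinetics(max(lat, LATENCY_FLOOR_S), rise, tau1, tau2, tr)


#: group archetype kinetics: each group evaluated at its mean position with no
#: jitter. Used for clustering archetypes, pharmacology emulation and as
#: donors for the sustained model variant.
DEFAULT_GROUP_KINETICS = {
    g: group_kinetics_at(g, DEFAULT_GROUP_U_OFFSETS[g]) for g in GROUPS
}


@dataclass
class GlutUnit:
    """One glutamatergic input: group label, position, spatial RF and kinetics."""

    group: str
    pos_um: tuple[float, float]
    kinetics: TemporalKinetics
    rf_center_um: tuple[float, float] | None = None
    rf_sigma_um: tuple[float, float] = DEFAULT_RF_SIGMA_UM
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.rf_center_um is None:
            self.rf_center_um = tuple(self.pos_um)
        if not all(s > 0 for s in self.rf_sigma_um):
            raise ValueError("rf_sigma_um components must be positive")


@dataclass
class CircuitModel:
    """A population of glutamatergic units on one dendritic field.

    The u axis points along the preferred direction of motion; the preferred
    side (u < 0 relative to the centre) is the side a preferred-direction
    stimulus enters first.
    """

    units: list[GlutUnit]
    dendritic_center_um: tuple[float, float] = (0.0, 0.0)
    dendritic_diameter_um: float = DEFAULT_DENDRITIC_DIAMETER_UM
    preferred_direction_deg: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        r = self.dendritic_diameter_um / 2.0
        cx, cy = self.dendritic_center_um
        for u in self.units:
            if (u.pos_um[0] - cx) ** 2 + (u.pos_um[1] - cy) ** 2 > (r + 1e-6) ** 2:
                raise ValueError("unit position outside the dendritic disc")

    def __len__(self) -> int:
        return len(self.units)

    def groups(self) -> np.ndarray:
        return np.array([u.group for u in self.units])

    def positions(self) -> np.ndarray:
        return np.array([u.pos_um for u in self.units])

    def mean_u_by_group(self) -> dict[str, float]:
        pos = self.positions()
        g = self.groups()
        return {
            name: float(pos[g == name, 0].mean())
            for name in GROUPS
            if np.any(g == name)
        }


def make_ground_truth_cell(
    counts_by_group: dict[str, int] | None = None,
    gradient_params: dict[str, float] | None = None,
    seed: int = 0,
    scatter_sd_um: float = DEFAULT_SCATTER_SD_UM,
    dendritic_diameter_um: float = DEFAULT_DENDRITIC_DIAMETER_UM,
    kinetics_by_group: dict[str, TemporalKinetics] | None = None,
    rf_sigma_um: tuple[float, float] = DEFAULT_RF_SIGMA_UM,
    latency_jitter_sd_s: float | None = None,
) -> CircuitModel:
    """Draw a ground-truth circuit with the default spatial double gradient.

    Unit u positions are Gaussian around per-group means (``gradient_params``,
    default :data:`DEFAULT_GROUP_U_OFFSETS`), v positions Gaussian around 0;
    draws are rejected-and-redrawn until they fall inside the dendritic disc.
    Unit kinetics follow the positional latency ramp with per-unit jitter
    unless ``kinetics_by_group`` pins each group to fixed kinetics.
    Deterministic given ``seed``.
    """
    counts = dict(DEFAULT_GROUP_COUNTS if counts_by_group is None else counts_by_group)
    for g, n in counts.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 0:
            raise ValueError("counts must be non-negative")
    offsets = dict(DEFAULT_GROUP_U_OFFSETS)
    if gradient_params is not None:
        offsets.update(gradient_params)
    if latency_jitter_sd_s is None:
        latency_jitter_sd_s = LATENCY_JITTER_SD_S

    rng = np.random.default_rng(seed)
    radius = dendritic_diameter_um / 2.0
    units: list[GlutUnit] = []
    for g in GROUPS:
        n = counts.get(g, 0)
        mu = offsets[g]
        for _ in range(n):
            for _attempt in range(1000):
                u = rng.normal(mu, scatter_sd_um)
                v = rng.normal(0.0, scatter_sd_um)
                if u * u + v * v <= radius * radius:
                    break
            else:  # pragma: no cover - pathological parameters
                u = float(np.clip(mu, -radius, radius))
                v = 0.0
            if kinetics_by_group is not None:
                kin = kinetics_by_group[g]
            else:
                jit = rng.normal(0.0, latency_jitter_sd_s) if latency_jitter_sd_s > 0 else 0.0
                kin = group_kinetics_at(g, float(u), jit)
            units.append(
                GlutUnit(group=g, pos_um=(float(u), float(v)), kinetics=kin,
                         rf_sigma_um=rf_sigma_um, gain=GROUP_GAINS[g])
            )
    return CircuitModel(
        units=units,
        dendritic_diameter_um=dendritic_diameter_um,
        seed=seed,
    )


#: pharmacological-condition emulation: which groups each blocker touches and how
CONDITIONS = {
    "identity": {},
    # small-field GABAergic amacrine cells shorten the decay of G1, G3, G4, G6;
    # blocking GABA receptors prolongs their decay
    "gaba_block": {"decay_factor": 3.0, "decay_groups": ("G1", "G3", "G4", "G6")},
    # small-field glycinergic cells inhibit G3 and G6
    "glycine_block": {"decay_factor": 2.0, "decay_groups": ("G3", "G6")},
    # Nav block (TTX) removes a fast conduction component, adding a fixed
    # delay to the fast groups G1, G2
    "nav_block": {"latency_increment_s": 0.6, "latency_groups": ("G1", "G2")},
}


def _modify_kinetics(k: TemporalKinetics, decay_factor: float, latency_shift_s: float
                     ) -> TemporalKinetics:
    # a prolonged decay also makes the release less transient
    return TemporalKinetics(
        peak_latency_s=k.peak_latency_s + latency_shift_s,
        rise_tau_s=k.rise_tau_s,
        decay_tau1_s=k.decay_tau1_s * decay_factor,
        decay_tau2_s=k.decay_tau2_s,
        transience=k.transience / decay_factor if decay_factor > 1.0 else k.transience,
    )


def apply_condition(
    circuit: CircuitModel,
    condition: str | list[str],
    decay_factor: float | None = None,
    latency_increment_s: float | None = None,
) -> CircuitModel:
    """Return a copy of the circuit with blocker-modified kinetics.

    ``condition`` is one of :data:`CONDITIONS` (or a list to combine, e.g.
    ``["gaba_block", "nav_block"]``). Parameters are configurable; the
    defaults triple affected decay constants and add 0.6 s to affected
    latencies.
    """
    names = [condition] if isinstance(condition, str) else list(condition)
    for name in names:
        if name not in CONDITIONS:
            raise ValueError(f"unknown condition {name!r}")
    new_units = []
    for unit in circuit.units:
        df, shift = 1.0, 0.0
        for name in names:
            spec = CONDITIONS[name]
            if unit.group in spec.get("decay_groups", ()):
                df *= decay_factor if decay_factor is not None else spec["decay_factor"]
            if unit.group in spec.get("latency_groups", ()):
                shift += (latency_increment_s if latency_increment_s is not None
                          else spec["latency_increment_s"])
        if df == 1.0 and shift == 0.0:
            new_units.append(replace(unit))
        else:
            new_units.append(replace(unit, kinetics=_modify_kinetics(unit.kinetics, df, shift)))
    return CircuitModel(
        units=new_units,
        dendritic_center_um=circuit.dendritic_center_um,
        dendritic_diameter_um=circuit.dendritic_diameter_um,
        preferred_direction_deg=circuit.preferred_direction_deg,
        seed=circuit.seed,
    )
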