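"""Stochastic multi-round biopanning simulator.

Each round of ribosome-display selection is modelled as a chain of
binomial thinning steps applied per clone:

1. complex formation: an input mRNA molecule yields a functional
   ribosome-mRNA-protein (RMP) complex with probability
   ``display_efficiency * (1 - incubation_release)``;
2. optional pre-incubation depletion: streptavidin-motif binders are
   captured on a bare streptavidin surface and removed before the target
   is seen;
3. capture: a complex attaches to the target-coated surface with a
   class- and surface-dependent probability; unattached complexes leave in
   the flow-through;
4. washing: each wash retains a captured complex with its class's
   per-wash survival probability;
5. elution: EDTA disassembly recovers everything still captured, whereas
   biotin elution followed by EDTA recovers only complexes held through
   the target or the streptavidin biotin pocket, discarding surface
   stickers;
6. amplification: every recovered molecule is reverse-transcribed and
   re-amplified, Poisson with a configurable mean (T7 transcription gives
   roughly 50 transcripts per template).

Affinity is abstracted into per-class capture and wash-survival
probabilities; no kinetic constants are modelled.  A deterministic
expectation mode propagates mean counts through the identical arithmetic
and serves as the analytic twin of the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .quantify import PcrModel, detection_cycles

__all__ = [
    "SURFACES",
    "CLASS_IDS",
    "CloneClass",
    "ClonePopulation",
    "PanningConfig",
    "RoundResult",
    "CampaignResult",
    "simulate_round",
    "run_campaign",
    "expectation_mode",
]

SURFACES = ("streptavidin_beads", "streptavidin_plate", "ni_nta")
CLASS_IDS = ("target_binder", "streptavidin_motif_binder", "surface_sticker", "nonbinder")

#: Classes recovered by biotin elution: complexes held via the target
#: (displaced when the SBP-tagged target is competed off by biotin) and
#: HPQ/M-motif binders sitting in streptavidin's biotin pocket.
_BIOTIN_ELUTABLE = frozenset({"target_binder", "streptavidin_motif_binder"})

#: Total RT-PCR template mass (ng) assumed when converting a spike fraction
#: into a template mass for gel-detection cycle counts.
RT_TEMPLATE_MASS_NG = 0.1


@dataclass(frozen=True)
class CloneClass:
    """Binding behaviour shared by all clones of one class."""

    class_id: str
    retention: float  # per-wash survival probability of a captured complex
    capture: Mapping[str, float]  # surface -> capture probability

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"unknown clone class {self.class_id!r}")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")
        for surface, p in self.capture.items():
            if surface not in SURFACES:
                raise ValueError(f"unknown surface {surface!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"capture probability for {surface!r} outside [0, 1]")

    def capture_on(self, surface: str) -> float:
        if surface not in SURFACES:
            raise ValueError(f"unknown surface {surface!r}")
        try:
            return self.capture[surface]
        except KeyError:
            raise ValueError(
                f"class {self.class_id!r} has no capture probability for surface {surface!r}"
            ) from None


@dataclass
class ClonePopulation:
    """Per-clone mRNA copy counts plus class definitions.

    At most one clone is flagged as the spike-in; its trajectory is what a
    real-time enrichment PCR would track.
    """

    ids: tuple[str, ...]
    class_ids: tuple[str, ...]
    counts: np.ndarray  # int64 (stochastic) or float64 (expectation mode)
    spike: np.ndarray  # bool
    classes: Mapping[str, CloneClass]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.spike = np.asarray(self.spike, dtype=bool)
        n = len(self.ids)
        if not (len(self.class_ids) == self.counts.size == self.spike.size == n):
            raise ValueError("per-clone fields must have equal length")
        if n == 0:
            raise ValueError("population is empty")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.spike.sum()) > 1:
            raise ValueError("at most one spike clone allowed")
        for cid in self.class_ids:
            if cid not in self.classes:
                raise ValueError(f"no class definition for {cid!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def spike_fraction(self) -> float | None:
        if not self.spike.any():
            return None
        total = self.counts.sum()
        if total == 0:
            return 0.0
        return float(self.counts[self.spike].sum() / total)

    def with_counts(self, counts: np.ndarray) -> "ClonePopulation":
        return ClonePopulation(self.ids, self.class_ids, counts, self.spike.copy(), self.classes)


@dataclass(frozen=True)
class PanningConfig:
    """Parameters of one selection round."""

    display_efficiency: float
    incubation_release: float = 0.0
    surface: str = "streptavidin_beads"
    preincubation_depletion: float = 0.0
    washes: int = 2
    elution: Literal["edta", "biotin_then_edta"] = "edta"
    amplification_factor: float = 50.0
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "display_efficiency",
            "incubation_release",
            "preincubation_depletion",
            "mutation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")
        if self.elution not in ("edta", "biotin_then_edta"):
            raise ValueError(f"unknown elution mode {self.elution!r}")
        if self.washes < 0:
            raise ValueError("washes must be >= 0")
        if self.amplification_factor < 0:
            raise ValueError("amplification_factor must be >= 0")


@dataclass
class RoundResult:
    """Per-clone molecule counts through the fractions of one round.

    Conservation: ``functional == flow_through + washes.sum + eluted +
    discarded`` exactly (``discarded`` is non-zero only under biotin
    elution, which leaves surface stickers on the support).
    """

    clone_ids: tuple[str, ...]
    input_counts: np.ndarray
    functional: np.ndarray
    flow_through: np.ndarray
    washes: np.ndarray  # shape (n_clones, n_washes)
    eluted: np.ndarray
    discarded: np.ndarray
    amplified: np.ndarray
    spike_fractions: dict[str, float | None] = field(default_factory=dict)
    spike_detection_cycles: int | None = None

    def conservation_ok(self) -> bool:
        lhs = self.functional
        rhs = self.flow_through + self.washes.sum(axis=1) + self.eluted + self.discarded
        return bool(np.allclose(lhs, rhs))


@dataclass
class CampaignResult:
    rounds: list[RoundResult]
    spike_trajectory: list[float | None]
    status: Literal["completed", "extinct"]
    final_population: ClonePopulation


def _spike_frac(counts: np.ndarray, spike: np.ndarray) -> float | None:
    if not spike.any():
        return None
    total = counts.sum()
    if total == 0:
        return 0.0
    return float(counts[spike].sum() / total)


def _class_arrays(pop: ClonePopulation, cfg: PanningConfig):
    cap = np.array([pop.classes[c].capture_on(cfg.surface) for c in pop.class_ids])
    ret = np.array([pop.classes[c].retention for c in pop.class_ids])
    strep = np.array([c == "streptavidin_motif_binder" for c in pop.class_ids])
    elutable = np.array(
        [cfg.elution == "edta" or c in _BIOTIN_ELUTABLE for c in pop.class_ids]
    )
    return cap, ret, strep, elutable


def simulate_round(
    pop: ClonePopulation,
    cfg: PanningConfig,
    rng: np.random.Generator,
) -> RoundResult:
    """Sample one selection round (see module docstring for the chain)."""
    counts = np.asarray(pop.counts, dtype=np.int64)
    cap, ret, strep, elutable = _class_arrays(pop, cfg)

    p_func = cfg.display_efficiency * (1.0 - cfg.incubation_release)
    functional = rng.binomial(counts, p_func)

    depleted = np.zeros_like(functional)
    if cfg.preincubation_depletion > 0.0 and strep.any():
        depleted[strep] = rng.binomial(functional[strep], cfg.preincubation_depletion)
    at_target = functional - depleted

    captured = rng.binomial(at_target, cap)
    flow_through = depleted + (at_target - captured)

    washes = np.zeros((counts.size, cfg.washes), dtype=np.int64)
    for w in range(cfg.washes):
        survive = rng.binomial(captured, ret)
        washes[:, w] = captured - survive
        captured = survive

    eluted = np.where(elutable, captured, 0)
    discarded = captured - eluted

    # factor 1.0 means the amplification step is skipped entirely
    if cfg.amplification_factor == 1.0:
        amplified = eluted.copy()
    else:
        amplified = rng.poisson(eluted * cfg.amplification_factor)

    fractions = {
        "input": _spike_frac(counts, pop.spike),
        "functional": _spike_frac(functional, pop.spike),
        "eluted": _spike_frac(eluted, pop.spike),
        "amplified": _spike_frac(amplified, pop.spike),
    }
    return RoundResult(
        clone_ids=pop.ids,
        input_counts=counts,
        functional=functional,
        flow_through=flow_through,
        washes=washes,
        eluted=eluted,
        discarded=discarded,
        amplified=amplified,
        spike_fractions=fractions,
        spike_detection_cycles=_detection_for_fraction(fractions["eluted"]),
    )


def _expect_round(pop: ClonePopulation, cfg: PanningConfig) -> RoundResult:
    counts = np.asarray(pop.counts, dtype=np.float64)
    cap, ret, strep, elutable = _class_arrays(pop, cfg)

    functional = counts * cfg.display_efficiency * (1.0 - cfg.incubation_release)
    depleted = np.where(strep, functional * cfg.preincubation_depletion, 0.0)
    at_target = functional - depleted
    captured = at_target * cap
    flow_through = depleted + at_target - captured

    washes = np.zeros((counts.size, cfg.washes), dtype=np.float64)
    for w in range(cfg.washes):
        survive = captured * ret
        washes[:, w] = captured - survive
        captured = survive

    eluted = np.where(elutable, captured, 0.0)
    discarded = captured - eluted
    amplified = eluted * cfg.amplification_factor

    fractions = {
        "input": _spike_frac(counts, pop.spike),
        "functional": _spike_frac(functional, pop.spike),
        "eluted": _spike_frac(eluted, pop.spike),
        "amplified": _spike_frac(amplified, pop.spike),
    }
    return RoundResult(
        clone_ids=pop.ids,
        input_counts=counts,
        functional=functional,
        flow_through=flow_through,
        washes=washes,
        eluted=eluted,
        discarded=discarded,
        amplified=amplified,
        spike_fractions=fractions,
        spike_detection_cycles=_detection_for_fraction(fractions["eluted"]),
    )


def _detection_for_fraction(
    spike_fraction: float | None,
    template_mass_ng: float = RT_TEMPLATE_MASS_NG,
    model: PcrModel = PcrModel(),
) -> int | None:
    """PCR cycles to see the spike band, given its share of the template."""
    if spike_fraction is None or spike_fraction <= 0.0:
        return None
    return detection_cycles(template_mass_ng * spike_fraction, model)


def _run(
    pop: ClonePopulation,
    configs: Sequence[PanningConfig],
    rng: np.random.Generator | None,
) -> CampaignResult:
    if not configs:
        raise ValueError("need at least one round configuration")
    rounds: list[RoundResult] = []
    trajectory: list[float | None] = []
    current = pop
    status: Literal["completed", "extinct"] = "completed"
    for cfg in configs:
        if current.counts.sum() == 0:
            status = "extinct"
            break
        result = simulate_round(current, cfg, rng) if rng is not None else _expect_round(current, cfg)
        rounds.append(result)
        trajectory.append(result.spike_fractions["amplified"])
        current = current.with_counts(result.amplified)
        if rng is not None and cfg.mutation_rate > 0.0:
            current = _apply_mutation(current, cfg.mutation_rate, rng)
    if current.counts.sum() == 0 and status == "completed":
        status = "extinct"
    return CampaignResult(rounds, trajectory, status, current)


def _apply_mutation(
    pop: ClonePopulation, rate: float, rng: np.random.Generator
) -> ClonePopulation:
    """Split off amplification-induced variant clones (e.g. Taq errors).

    Each molecule independently founds a variant lineage with probability
    ``rate``; variants keep their parent's binding class but lose the spike
    flag (a mutated spike is no longer the tracked sequence).  Off by
    default.
    """
    counts = np.asarray(pop.counts, dtype=np.int64)
    mutated = rng.binomial(counts, rate)
    if mutated.sum() == 0:
        return pop
    keep = counts - mutated
    new_ids = list(pop.ids)
    new_classes = list(pop.class_ids)
    new_counts = list(keep)
    new_spike = list(pop.spike)
    for i in np.nonzero(mutated)[0]:
        new_ids.append(f"{pop.ids[i]}_mut")
        new_classes.append(pop.class_ids[i])
        new_counts.append(int(mutated[i]))
        new_spike.append(False)
    return ClonePopulation(
        tuple(new_ids),
        tuple(new_classes),
        np.asarray(new_counts, dtype=np.int64),
        np.asarray(new_spike, dtype=bool),
        pop.classes,
    )


def run_campaign(
    pop: ClonePopulation,
    configs: Sequence[PanningConfig],
    rng: np.random.Generator | int | None = None,
) -> CampaignResult:
    """Chain stochastic rounds, feeding each round's amplified pool forward.

    Terminates early with status ``"extinct"`` if every clone count reaches
    zero.  Reproducible for a given seed or generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _run(pop, configs, rng)


def expectation_mode(
    pop: ClonePopulation,
    configs: Sequence[PanningConfig],
) -> CampaignResult:
    """Propagate expected counts through the same arithmetic, no sampling.

    Sampler means converge to these trajectories; counts are float and may
    be fractional.  Safe at full experimental scale (1e13 molecules).
    """
    float_pop = pop.with_counts(np.asarray(pop.counts, dtype=np.float64))
    return _run(float_pop, configs, None)
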