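"""Stochastic sorting simulator with a known true critical diameter.

The simulator produces complete synthetic experiments -- an inlet sample and
three sorted outlets -- from a generative model whose ground truth is known,
so every stage of the routing-probability pipeline can be validated without
laboratory data.

Particles are drawn from a mixture of nominal-diameter populations with
stated coefficients of variation (defaults: 7, 10 and 16 μm microspheres
with CVs of 13%, 12% and 12%, the certificate values of typical polystyrene
size standards).  A particle may be a cluster of ``c`` equal spheres: its
*observed* major axis is the linear-chain length ``c·d0``, while the size
that matters for routing is a damped effective diameter
``d_eff = d0·(1 + beta·(c-1))`` -- a chain presents a smaller hydrodynamic
cross-section than its length suggests, which is how sphere pairs end up in
the intermediate outlet while singlets of the same length would be displaced.

Routing is a smooth three-outlet law centred on the true critical diameter
``dc_true``: a Gaussian bump of amplitude ``A`` routes near-critical
particles to the Medium outlet, and a logistic switch of width ``w`` divides
the rest between Small and Large,

    P(M | d) = A exp(-(d - dc_true)^2 / (2 s^2))
    P(L | d) = (1 - P(M | d)) / (1 + exp(-(d - dc_true) / w))
    P(S | d) = 1 - P(M | d) - P(L | d).

At ``d = dc_true`` the Small and Large probabilities are equal by
construction, so the pipeline's crossover estimate can be compared with the
configured truth.  No hydrodynamics is modelled; the law only emulates the
gradual zigzag/displacement transition that diffusion produces in a real
post array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from dldroute.io import OUTLETS, ParticleRecord, ReservoirSet

__all__ = [
    "SimulationConfig",
    "SimulatedParticle",
    "sample_particles",
    "routing_law",
    "simulate_experiment",
    "read_config",
    "write_config",
]

#: Default population mixture: (nominal diameter μm, CV fraction, weight).
DEFAULT_POPULATIONS: tuple[tuple[float, float, float], ...] = (
    (7.0, 0.13, 1.0 / 3.0),
    (10.0, 0.12, 1.0 / 3.0),
    (16.0, 0.12, 1.0 / 3.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model of one sorting experiment.

    All sizes in μm.  ``transition_width`` is the logistic scale of the
    Small/Large switch; ``intermediate_amplitude`` and ``intermediate_width``
    shape the Gaussian Medium bump; ``cluster_prob`` is the chance a drawn
    object is a cluster, uniform on sizes 2..``max_cluster_size``;
    ``beta`` damps the effective routing size of chains.
    """

    populations: tuple[tuple[float, float, float], ...] = DEFAULT_POPULATIONS
    cluster_prob: float = 0.05
    max_cluster_size: int = 3
    beta: float = 0.6
    dc_true: float = 11.0
    transition_width: float = 0.5
    intermediate_amplitude: float = 0.2
    intermediate_width: float = 1.0
    n_particles: int = 10_000
    seed: int = 0

    def __post_init__(self):
        pops = tuple((float(d), float(cv), float(w)) for d, cv, w in self.populations)
        object.__setattr__(self, "populations", pops)
        if not pops:
            raise ValueError("populations: need at least one population")
        for d, cv, w in pops:
            if d <= 0:
                raise ValueError(f"populations: nominal diameter must be > 0, got {d}")
            if cv < 0:
                raise ValueError(f"populations: CV must be >= 0, got {cv}")
            if w < 0:
                raise ValueError(f"populations: mixture weight must be >= 0, got {w}")
        if abs(sum(w for _, _, w in pops) - 1.0) > 1e-12:
            raise ValueError("populations: mixture weights must sum to 1")
        if not (0.0 <= self.cluster_prob <= 1.0):
            raise ValueError("cluster_prob must be in [0, 1]")
        if self.max_cluster_size < 2:
            raise ValueError("max_cluster_size must be >= 2")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.dc_true <= 0:
            raise ValueError("dc_true must be > 0")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")
        if not (0.0 <= self.intermediate_amplitude < 1.0):
            raise ValueError("intermediate_amplitude must be in [0, 1)")
        if self.intermediate_width <= 0:
            raise ValueError("intermediate_width must be > 0")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    def population_label(self, index: int) -> str:
        d = self.populations[index][0]
        return f"{d:g}um"


@dataclass(frozen=True)
class SimulatedParticle:
    """One simulated object with its latent ground truth."""

    d0: float
    cluster_size: int
    observed_major_axis: float
    effective_size: float
    population: str
    assigned_outlet: str | None = None


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0.1·mean."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.1 * mean - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def sample_particles(config: SimulationConfig, rng: np.random.Generator) -> list[SimulatedParticle]:
    """Draw the inlet population: mixture sizes, cluster formation, latents."""
    n = config.n_particles
    weights = np.array([w for _, _, w in config.populations])
    pop_idx = rng.choice(len(config.populations), size=n, p=weights)
    d0 = np.empty(n)
    for j, (nominal, cv, _) in enumerate(config.populations):
        mask = pop_idx == j
        d0[mask] = _truncated_normal(rng, nominal, cv * nominal, int(mask.sum()))
    c = np.ones(n, dtype=int)
    is_cluster = rng.random(n) < config.cluster_prob
    c[is_cluster] = rng.integers(2, config.max_cluster_size + 1, size=int(is_cluster.sum()))
    observed = c * d0
    d_eff = d0 * (1.0 + config.beta * (c - 1))
    return [
        SimulatedParticle(
            d0=float(d0[i]),
            cluster_size=int(c[i]),
            observed_major_axis=float(observed[i]),
            effective_size=float(d_eff[i]),
            population=config.population_label(int(pop_idx[i])),
        )
        for i in range(n)
    ]


def routing_law(d_eff, config: SimulationConfig) -> np.ndarray:
    """True routing probabilities (S, M, L) for effective size(s) ``d_eff``.

    Returns an array of shape ``(..., 3)`` summing to 1 exactly along the
    last axis.  At ``d_eff = dc_true``, P(S) = P(L) = (1 - A)/2.
    """
    d = np.asarray(d_eff, dtype=float)
    if np.any(d <= 0):
        raise ValueError("effective size must be > 0")
    a = config.intermediate_amplitude
    p_m = a * np.exp(-((d - config.dc_true) ** 2) / (2.0 * config.intermediate_width**2))
    lam = expit((d - config.dc_true) / config.transition_width)
    p_l = lam * (1.0 - p_m)
    p_s = 1.0 - p_m - p_l
    return np.stack([p_s, p_m, p_l], axis=-1)


def simulate_experiment(
    config: SimulationConfig, include_latents: bool = False
) -> tuple[ReservoirSet, dict]:
    """Run one full synthetic sorting experiment.

    Every inlet particle is routed to exactly one outlet by a categorical
    draw from the routing law at its effective size, so particle number is
    conserved (the no-loss assumption holds by construction).  The inlet
    records are the full pre-sorting particle list; the outlet fractions are
    the realized count fractions.  Returns the reservoir set and a
    ground-truth dictionary (configuration echo, true critical diameter,
    realized per-outlet counts, optional per-particle latents).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    particles = sample_particles(config, rng)
    d_eff = np.array([p.effective_size for p in particles])
    probs = routing_law(d_eff, config)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(len(particles))
    outlet_idx = np.minimum((u[:, None] >= cum).sum(axis=1), len(OUTLETS) - 1)
    records: list[ParticleRecord] = []
    assigned: list[SimulatedParticle] = []
    for i, p in enumerate(particles):
        outlet = OUTLETS[int(outlet_idx[i])]
        assigned.append(
            SimulatedParticle(
                d0=p.d0,
                cluster_size=p.cluster_size,
                observed_major_axis=p.observed_major_axis,
                effective_size=p.effective_size,
                population=p.population,
                assigned_outlet=outlet,
            )
        )
        common = dict(
            size=p.observed_major_axis,
            is_cluster=p.cluster_size > 1,
            population=p.population,
        )
        records.append(ParticleRecord(reservoir="inlet", object_id=f"p{i}", **common))
        records.append(ParticleRecord(reservoir=outlet, object_id=f"p{i}", **common))
    reservoirs = ReservoirSet.from_records(records)
    counts = {k: len(reservoirs.records[k]) for k in OUTLETS}
    truth: dict = {
        "dc_true": config.dc_true,
        "config": _config_to_dict(config),
        "outlet_counts": counts,
        "n_particles": config.n_particles,
    }
    if include_latents:
        truth["particles"] = [asdict(p) for p in assigned]
    return reservoirs, truth


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["populations"] = [list(p) for p in config.populations]
    return d


def _parse_populations(text: str) -> tuple[tuple[float, float, float], ...]:
    pops = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = [float(v) for v in chunk.split(",")]
        if len(parts) != 3:
            raise ValueError(
                "populations: each entry must be 'diameter,cv,weight' separated by ';'"
            )
        pops.append(tuple(parts))
    return tuple(pops)


_INT_KEYS = {"max_cluster_size", "n_particles", "seed"}
_FLOAT_KEYS = {
    "cluster_prob",
    "beta",
    "dc_true",
    "transition_width",
    "intermediate_amplitude",
    "intermediate_width",
}


def read_config(source: str) -> SimulationConfig:
    """Parse a flat ``key = value`` configuration file.

    Keys are exactly the :class:`SimulationConfig` field names; ``#`` starts
    a comment; ``populations`` is a ``;``-separated list of
    ``diameter,cv,weight`` triples.  Unknown keys raise a ``ValueError``
    naming the key.
    """
    kwargs: dict = {}
    with open(source, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {line_no}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "populations":
                kwargs[key] = _parse_populations(value)
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
    return SimulationConfig(**kwargs)


def write_config(config: SimulationConfig, target: str) -> None:
    """Write a configuration in the flat format read by :func:`read_config`."""
    pops = "; ".join(f"{d!r},{cv!r},{w!r}" for d, cv, w in config.populations)
    lines = [f"populations = {pops}"]
    for key in sorted(_FLOAT_KEYS | _INT_KEYS):
        lines.append(f"{key} = {getattr(config, key)}")
    with open(target, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
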