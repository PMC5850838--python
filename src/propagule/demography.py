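"""Piecewise-exponential demographies for a two-deme island-colonization model.

The model world is a small oceanic island deme and a large mainland deme.
Going back in time, island lineages reside in the mainland deme before the
colonization split.  Effective population size through time, ``Ne(t)``, is
represented as a set of anchors connected by exponential interpolation, the
standard way sequentially-Markovian-coalescent output is turned back into a
simulable demography.  Times are years before present throughout and are
converted to generations (default generation time: 1 year, appropriate for an
annual selfer such as *Arabidopsis thaliana*) only at the simulator boundary.

Bottleneck strength uses the dimensionless *severity* = duration / size
(duration in generations, size in individuals): a one-generation bottleneck of
severity 0.1 corresponds to ten founding individuals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "NeTrajectory",
    "BottleneckSpec",
    "MigrationPulse",
    "Chromosome",
    "GenomeLayout",
    "DemographicScenario",
    "log_grid",
    "eval_ne",
    "founders_from_severity",
    "coalescent_units",
    "build_baseline",
    "candidate_models",
    "TAIR10_CHROMOSOMES",
    "MU_ACCUMULATION",
    "MU_NATURAL",
    "DEFAULT_SPLIT_TIME",
]

#: Mutation rate per bp per generation from mutation-accumulation lines.
MU_ACCUMULATION = 7.1e-9
#: Mutation rate per bp per generation estimated from a natural population.
MU_NATURAL = 2.2e-9
#: Default colonization time (years before present).
DEFAULT_SPLIT_TIME = 85.4e3
#: Nuclear chromosome lengths of the TAIR10 assembly (bp).
TAIR10_CHROMOSOMES = (
    ("1", 30_427_671),
    ("2", 19_698_289),
    ("3", 23_459_830),
    ("4", 18_585_056),
    ("5", 26_975_502),
)


class ConfigError(ValueError):
    """Raised when a scenario configuration is malformed or incomplete."""


def log_grid(t_min: float, t_max: float, k: int) -> np.ndarray:
    """Return ``k`` time points evenly spaced on a logarithmic scale.

    Consecutive ratios are equal; the first point is ``t_min`` and the last
    ``t_max``.  Used to anchor Ne(t) on a 23-point grid between 3 ka and 2 Ma.
    """
    if t_min <= 0:
        raise ValueError("t_min must be positive for a logarithmic grid")
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    if k < 2:
        raise ValueError("need at least two grid points")
    return np.geomspace(float(t_min), float(t_max), int(k))


def founders_from_severity(severity: float, duration: float) -> float:
    """Bottleneck size (founder count) implied by severity = duration / size."""
    if severity <= 0:
        raise ValueError("severity must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return duration / severity


def coalescent_units(time_years: float, ne: float, generation_time: float = 1.0) -> float:
    """Express a time in units of Ne generations (e.g. 75.9 ka / 30 K ~ 2.5)."""
    if ne <= 0 or generation_time <= 0:
        raise ValueError("ne and generation_time must be positive")
    return time_years / generation_time / ne


@dataclass(frozen=True)
class NeTrajectory:
    """Effective population size through time, anchored and exponentially
    interpolated between anchors; constant beyond the anchored range."""

    times: np.ndarray  # years BP, strictly increasing
    sizes: np.ndarray  # individuals, > 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.sizes, dtype=float)
        if t.ndim != 1 or t.shape != n.shape or t.size == 0:
            raise ValueError("times and sizes must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("anchor times must be non-negative")
        if np.any(n <= 0):
            raise ValueError("all Ne values must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes", n)

    @classmethod
    def from_anchors(cls, anchors: Iterable[Sequence[float]]) -> "NeTrajectory":
        pairs = [(float(t), float(n)) for t, n in anchors]
        if not pairs:
            raise ConfigError("empty anchor list")
        t, n = zip(*pairs)
        return cls(np.array(t), np.array(n))

    @classmethod
    def constant(cls, ne: float) -> "NeTrajectory":
        return cls(np.array([0.0]), np.array([float(ne)]))

    def ne(self, t) -> np.ndarray | float:
        """Evaluate Ne at time(s) ``t`` (years BP).

        Within a span the interpolation is
        ``N(t) = N_i * exp(ln(N_{i+1}/N_i) * (t - t_i) / (t_{i+1} - t_i))``,
        i.e. linear in log Ne; outside the anchored range the trajectory is
        constant at the nearest anchor value.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time before present must be non-negative")
        out = np.exp(np.interp(t_arr, self.times, np.log(self.sizes)))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def anchors(self) -> list[tuple[float, float]]:
        return [(float(t), float(n)) for t, n in zip(self.times, self.sizes)]


def eval_ne(traj: NeTrajectory, t) -> np.ndarray | float:
    """Evaluate a trajectory at time(s) ``t`` years before present."""
    return traj.ne(t)


@dataclass(frozen=True)
class BottleneckSpec:
    """A transient reduction of Ne to ``size`` individuals.

    ``onset_time`` is the *ancient* edge (years BP): forward in time the
    bottleneck begins at ``onset_time`` and lasts ``duration`` generations, so
    it occupies ``[onset_time - duration * generation_time, onset_time]`` years
    BP.  Exactly one of ``size`` / ``severity`` is given; the other is derived
    from severity = duration / size.  ``recovery`` is how Ne returns to the
    background trajectory forward in time: ``"instantaneous"`` or ``"smooth"``
    (exponential regrowth over ``recovery_span`` years).
    """

    onset_time: float
    duration: float  # generations
    size: float | None = None
    severity: float | None = None
    recovery: str = "instantaneous"
    recovery_span: float = 15e3  # years, used only for smooth recovery

    def __post_init__(self):
        if (self.size is None) == (self.severity is None):
            raise ValueError("give exactly one of size or severity")
        if self.duration <= 0:
            raise ValueError("duration must be positive (generations)")
        if self.size is None:
            if self.severity <= 0:
                raise ValueError("severity must be positive")
            object.__setattr__(self, "size", self.duration / self.severity)
        else:
            if self.size <= 0:
                raise ValueError("size must be positive")
            object.__setattr__(self, "severity", self.duration / self.size)
        if self.recovery not in ("instantaneous", "smooth"):
            raise ValueError("recovery must be 'instantaneous' or 'smooth'")
        if self.onset_time <= 0:
            raise ValueError("onset_time must be positive")


@dataclass(frozen=True)
class MigrationPulse:
    """An instantaneous movement of a fraction of island lineages into the
    mainland deme at ``time`` years BP (a secondary-contact event)."""

    time: float
    fraction: float

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.time <= 0:
            raise ValueError("pulse time must be positive")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    mutation_rate: float
    recombination_rate: float

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigError(f"chromosome {self.name}: non-positive length")
        if self.mutation_rate <= 0 or self.recombination_rate < 0:
            raise ConfigError(f"chromosome {self.name}: invalid rates")


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes and per-chromosome rates.

    Recombination is scaled by the outcrossing factor (predominantly selfing
    populations realise only a small fraction of the map rate as effective
    crossovers between distinct genomes).
    """

    chromosomes: tuple[Chromosome, ...]
    outcrossing: float = 0.02

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigError("layout needs at least one chromosome")
        if not (0 < self.outcrossing <= 1):
            raise ConfigError("outcrossing factor must be in (0, 1]")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate chromosome names")

    @classmethod
    def default(
        cls,
        mu: float = MU_ACCUMULATION,
        recombination_rate: float = 3.6e-8,
        outcrossing: float = 0.02,
    ) -> "GenomeLayout":
        """Five chromosomes at the TAIR10 assembly lengths, uniform rates."""
        chroms = tuple(
            Chromosome(name, length, mu, recombination_rate)
            for name, length in TAIR10_CHROMOSOMES
        )
        return cls(chroms, outcrossing)

    @classmethod
    def variable_mu(
        cls,
        mu_min: float = MU_NATURAL,
        mu_max: float = MU_ACCUMULATION,
        recombination_rate: float = 3.6e-8,
        outcrossing: float = 0.02,
    ) -> "GenomeLayout":
        """Assign each of the five chromosomes a mutation rate spanning
        [mu_min, mu_max] (models genome-wide mutation-rate heterogeneity)."""
        mus = np.linspace(mu_min, mu_max, len(TAIR10_CHROMOSOMES))
        chroms = tuple(
            Chromosome(name, length, float(m), recombination_rate)
            for (name, length), m in zip(TAIR10_CHROMOSOMES, mus)
        )
        return cls(chroms, outcrossing)

    @classmethod
    def reduced(
        cls,
        n_chromosomes: int = 2,
        length: int = 5_000_000,
        mu: float = MU_ACCUMULATION,
        recombination_rate: float = 3.6e-8,
        outcrossing: float = 0.02,
    ) -> "GenomeLayout":
        """A scaled-down genome for desk-scale simulation studies."""
        chroms = tuple(
            Chromosome(str(i + 1), length, mu, recombination_rate)
            for i in range(n_chromosomes)
        )
        return cls(chroms, outcrossing)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def effective_recombination(self, chrom: Chromosome) -> float:
        return chrom.recombination_rate * self.outcrossing

    def mean_mutation_rate(self) -> float:
        """Length-weighted mean mutation rate across chromosomes."""
        w = np.array([c.length for c in self.chromosomes], dtype=float)
        m = np.array([c.mutation_rate for c in self.chromosomes])
        return float(np.sum(w * m) / np.sum(w))


@dataclass(frozen=True)
class DemographicScenario:
    """Two-deme demography: island and mainland Ne(t), a colonization split,
    optional bottlenecks (island deme) and migration pulses, and the genome
    layout used to turn the demography into sequence data."""

    island: NeTrajectory
    mainland: NeTrajectory
    split_time: float  # years BP
    bottlenecks: tuple[BottleneckSpec, ...] = ()
    pulses: tuple[MigrationPulse, ...] = ()
    layout: GenomeLayout = field(default_factory=GenomeLayout.default)
    generation_time: float = 1.0
    name: str = "scenario"

    def __post_init__(self):
        if self.split_time <= 0:
            raise ValueError("split_time must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        for p in self.pulses:
            if p.time >= self.split_time:
                raise ValueError(
                    "migration pulses must be more recent than the split"
                )
        for b in self.bottlenecks:
            if b.onset_time - b.duration * self.generation_time < 0:
                raise ValueError("bottleneck extends beyond the present")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "split_time": self.split_time,
            "generation_time": self.generation_time,
            "island": [list(a) for a in self.island.anchors()],
            "mainland": [list(a) for a in self.mainland.anchors()],
            "bottlenecks": [
                {
                    "onset_time": b.onset_time,
                    "duration": b.duration,
                    "size": b.size,
                    "recovery": b.recovery,
                    "recovery_span": b.recovery_span,
                }
                for b in self.bottlenecks
            ],
            "pulses": [
                {"time": p.time, "fraction": p.fraction} for p in self.pulses
            ],
            "layout": {
                "outcrossing": self.layout.outcrossing,
                "chromosomes": [
                    {
                        "name": c.name,
                        "length": c.length,
                        "mutation_rate": c.mutation_rate,
                        "recombination_rate": c.recombination_rate,
                    }
                    for c in self.layout.chromosomes
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicScenario":
        try:
            layout = GenomeLayout(
                tuple(Chromosome(**c) for c in d["layout"]["chromosomes"]),
                d["layout"]["outcrossing"],
            )
            return cls(
                island=NeTrajectory.from_anchors(d["island"]),
                mainland=NeTrajectory.from_anchors(d["mainland"]),
                split_time=float(d["split_time"]),
                bottlenecks=tuple(
                    BottleneckSpec(**b) for b in d.get("bottlenecks", [])
                ),
                pulses=tuple(MigrationPulse(**p) for p in d.get("pulses", [])),
                layout=layout,
                generation_time=float(d.get("generation_time", 1.0)),
                name=str(d.get("name", "scenario")),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed scenario config: {exc}") from exc

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DemographicScenario":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                d = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def replace(self, **kwargs) -> "DemographicScenario":
        return dataclasses.replace(self, **kwargs)


def _load_default_anchors() -> dict:
    ref = resources.files("propagule.data").joinpath("baseline_anchors.yaml")
    with ref.open() as fh:
        return yaml.safe_load(fh)


def build_baseline(
    anchors: dict | None = None,
    layout: GenomeLayout | None = None,
    split_time: float | None = None,
    generation_time: float | None = None,
) -> DemographicScenario:
    """The baseline two-deme scenario.

    Anchored Ne values ship as an editable fixture on the 23-point log grid
    between 3 ka and 2 Ma; the island trajectory is spliced onto the mainland
    (ancestral) one at 200 ka.  Pass ``anchors`` (a mapping with ``island`` and
    ``mainland`` anchor lists, optionally ``split_time``/``generation_time``)
    to substitute your own point estimates.
    """
    cfg = _load_default_anchors()
    if anchors is not None:
        cfg = {**cfg, **anchors}
    for key in ("island", "mainland"):
        if key not in cfg or not cfg[key]:
            raise ConfigError(f"baseline config missing '{key}' anchors")
    return DemographicScenario(
        island=NeTrajectory.from_anchors(cfg["island"]),
        mainland=NeTrajectory.from_anchors(cfg["mainland"]),
        split_time=float(
            split_time if split_time is not None else cfg.get("split_time", DEFAULT_SPLIT_TIME)
        ),
        layout=layout if layout is not None else GenomeLayout.default(),
        generation_time=float(
            generation_time
            if generation_time is not None
            else cfg.get("generation_time", 1.0)
        ),
        name="baseline",
    )


def _plateau_island(smooth: bool, carrying: float = 30e3, trough: float = 10e3):
    """Island trajectory: constant carrying capacity with a glacial trough
    (Ne = 10 K between 15 and 40 ka) and either a sudden or a smooth
    (exponential, 15 ka to present) recovery to carrying capacity."""
    eps = 1.0
    if smooth:
        anchors = [(1.0, carrying), (15e3, trough)]
    else:
        anchors = [(1.0, carrying), (15e3 - eps, carrying), (15e3, trough)]
    anchors += [(40e3, trough), (40e3 + eps, carrying), (2e6, carrying)]
    return NeTrajectory.from_anchors(anchors)


def candidate_models(
    split_time: float = DEFAULT_SPLIT_TIME,
    layout: GenomeLayout | None = None,
    bottleneck_severity: float = 0.1,
    bottleneck_duration: float = 1.0,
) -> list[DemographicScenario]:
    """The six candidate demographies consistent with the observed data.

    {baseline Ne(t); 30 K plateau with a 10 K glacial trough (40-15 ka) and
    instantaneous recovery; the same with smooth recovery} x {no colonization
    bottleneck; a severity-0.1 bottleneck at the split}.  The colonization
    bottleneck defaults to a single generation, i.e. a founding propagule of
    duration/severity = 10 individuals.
    """
    layout = layout if layout is not None else GenomeLayout.default()
    base = build_baseline(layout=layout, split_time=split_time)
    mainland = base.mainland
    bn = BottleneckSpec(
        onset_time=split_time,
        duration=bottleneck_duration,
        severity=bottleneck_severity,
    )
    variants = [
        ("baseline", base.island),
        ("plateau-instant", _plateau_island(smooth=False)),
        ("plateau-smooth", _plateau_island(smooth=True)),
    ]
    out = []
    for name, island in variants:
        for with_bn in (False, True):
            out.append(
                DemographicScenario(
                    island=island,
                    mainland=mainland,
                    split_time=split_time,
                    bottlenecks=(bn,) if with_bn else (),
                    layout=layout,
                    name=name + ("+bottleneck" if with_bn else ""),
                )
            )
    return out
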