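"""Physics of the ²²⁵Ac decay chain.

²²⁵Ac (T½ = 9.92 d) decays through ²²¹Fr (4.8 min), ²¹⁷At (32 ms) and
²¹³Bi (45.6 min) down to long-lived ²⁰⁹Pb.  Four alpha particles are emitted
per ²²⁵Ac decay: 5.8, 6.3 and 7.1 MeV from the top of the chain, and then
either 8.4 MeV (via the ²¹³Bi → ²¹³Po beta branch, 97.8 %) or 5.9 MeV
(the direct ²¹³Bi alpha to ²⁰⁹Tl, 2.2 %).

Because ²²¹Fr and ²¹⁷At are short-lived relative to imaging time scales,
the chain is conventionally split into two segments, each represented by the
nuclide whose photopeak is imaged:

* the **Fr segment** {²²⁵Ac, ²²¹Fr, ²¹⁷At}, surrogate ²²¹Fr (218 keV), and
* the **Bi segment** {²¹³Bi, ²¹³Po, ²⁰⁹Tl, ²⁰⁹Pb}, surrogate ²¹³Bi (440 keV).

The module also provides the two-member Bateman solution for ²¹³Bi ingrowth
from ²²⁵Ac, used to fit urine gamma-counter series: treating the short-lived
intermediates as instantaneous,

    A_Bi(t) = A_Ac(0) · λ_Bi/(λ_Bi − λ_Ac) · (exp(−λ_Ac t) − exp(−λ_Bi t))
              + A_Bi(0) · exp(−λ_Bi t).

Nuclide constants are loaded from the packaged ``data/nuclides.csv`` so
nuclear-data updates require no code change.  The canonical internal time
unit is hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DegenerateChainError, InvalidInputError

LN2 = math.log(2.0)

#: hours per unit, for half-life ingestion
_TIME_UNITS = {
    "h": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "d": 24.0,
    "day": 24.0,
    "days": 24.0,
    "min": 1.0 / 60.0,
    "s": 1.0 / 3600.0,
    "ms": 1.0 / 3.6e6,
    "us": 1.0 / 3.6e9,
}


def to_hours(value: float, unit: str) -> float:
    """Convert a duration to hours. Raises for unknown units."""
    try:
        return float(value) * _TIME_UNITS[unit.strip().lower()]
    except KeyError:
        raise InvalidInputError(f"unknown time unit {unit!r}") from None


def decay_constant(half_life_h: float) -> float:
    """Decay constant λ = ln2 / T½ in h⁻¹ for a half-life given in hours."""
    if not half_life_h > 0:
        raise InvalidInputError(f"half-life must be positive, got {half_life_h}")
    return LN2 / half_life_h


@dataclass(frozen=True)
class Nuclide:
    """One member of the decay chain.

    ``alpha_emissions`` lists (energy MeV, probability per decay) pairs;
    probability is the fraction of this nuclide's decays emitting that alpha.
    """

    name: str
    half_life: float  # hours
    alpha_emissions: tuple[tuple[float, float], ...] = ()
    gamma_emission_probability: float = 0.0
    photopeak_energy: float | None = None  # keV
    reference: str = ""

    def __post_init__(self):
        if not self.half_life > 0:
            raise InvalidInputError(f"{self.name}: half-life must be positive")
        for energy, prob in self.alpha_emissions:
            if not (0.0 <= prob <= 1.0):
                raise InvalidInputError(f"{self.name}: alpha probability {prob} outside [0, 1]")
            if energy <= 0:
                raise InvalidInputError(f"{self.name}: alpha energy must be positive")
        if not (0.0 <= self.gamma_emission_probability <= 1.0):
            raise InvalidInputError(f"{self.name}: gamma probability outside [0, 1]")

    @property
    def decay_constant(self) -> float:
        """λ in h⁻¹."""
        return LN2 / self.half_life

    @property
    def alpha_energy_per_decay(self) -> float:
        """Probability-weighted alpha energy (MeV) per decay of this nuclide."""
        return sum(e * p for e, p in self.alpha_emissions)


def _parse_alpha_field(text: str) -> tuple[tuple[float, float], ...]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return ()
    pairs = []
    for chunk in str(text).split(";"):
        energy, prob = chunk.split(":")
        pairs.append((float(energy), float(prob)))
    return tuple(pairs)


def load_nuclides(path=None) -> dict[str, Nuclide]:
    """Load the nuclide-constants table (packaged CSV by default)."""
    if path is None:
        with resources.files("acdose.data").joinpath("nuclides.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    nuclides = {}
    for row in table.itertuples(index=False):
        nuclides[row.name] = Nuclide(
            name=row.name,
            half_life=to_hours(row.half_life_value, row.half_life_unit),
            alpha_emissions=_parse_alpha_field(row.alpha_energies),
            gamma_emission_probability=float(row.gamma_probability),
            photopeak_energy=None if pd.isna(row.photopeak_keV) else float(row.photopeak_keV),
            reference=str(row.reference),
        )
    return nuclides


#: decay order of the chain from ²²⁵Ac down to ²⁰⁹Pb
CHAIN_ORDER = ("Ac-225", "Fr-221", "At-217", "Bi-213", "Po-213", "Tl-209", "Pb-209")

#: per-decay branching fractions (parent, daughter) -> fraction
CHAIN_BRANCHES = {
    ("Ac-225", "Fr-221"): 1.0,
    ("Fr-221", "At-217"): 1.0,
    ("At-217", "Bi-213"): 1.0,
    ("Bi-213", "Po-213"): 0.978,  # beta branch, followed by the 8.4 MeV alpha
    ("Bi-213", "Tl-209"): 0.022,  # direct 5.9 MeV alpha branch
    ("Po-213", "Pb-209"): 1.0,
    ("Tl-209", "Pb-209"): 1.0,
}


@dataclass(frozen=True)
class DecayChain:
    """Ordered ²²⁵Ac chain with branching fractions."""

    members: tuple[Nuclide, ...]
    branches: dict[tuple[str, str], float] = field(default_factory=lambda: dict(CHAIN_BRANCHES))

    def __post_init__(self):
        names = [n.name for n in self.members]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate chain members")
        # branch fractions out of any member must sum to 1 (terminal member excepted)
        for name in names[:-1]:
            total = sum(f for (p, _), f in self.branches.items() if p == name)
            if abs(total - 1.0) > 1e-9:
                raise InvalidInputError(f"branches out of {name} sum to {total}, not 1")

    def __getitem__(self, name: str) -> Nuclide:
        for nuc in self.members:
            if nuc.name == name:
                return nuc
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.members)

    def reach_probability(self, head: str, target: str) -> float:
        """Probability that a decay starting at ``head`` passes through ``target``."""
        if target == head:
            return 1.0
        total = 0.0
        for (parent, child), frac in self.branches.items():
            if child == target:
                if parent in self.names:
                    total += frac * self.reach_probability(head, parent)
        return total


def default_chain(constants_path=None) -> DecayChain:
    """The full ²²⁵Ac → ²⁰⁹Pb chain from the packaged constants table."""
    nuclides = load_nuclides(constants_path)
    return DecayChain(members=tuple(nuclides[name] for name in CHAIN_ORDER))


@dataclass(frozen=True)
class ChainSegment:
    """A contiguous subset of the chain represented by one imaged surrogate."""

    label: str
    members: tuple[str, ...]
    surrogate: str
    chain: DecayChain

    def __post_init__(self):
        if not self.members:
            raise InvalidInputError("segment must be nonempty")
        for name in self.members:
            if name not in self.chain.names:
                raise InvalidInputError(f"unknown nuclide {name!r} in segment {self.label!r}")


def fr_segment(chain: DecayChain | None = None) -> ChainSegment:
    """{²²⁵Ac, ²²¹Fr, ²¹⁷At}, imaged via the 218 keV ²²¹Fr photopeak."""
    chain = chain or default_chain()
    return ChainSegment("Fr-segment", ("Ac-225", "Fr-221", "At-217"), "Fr-221", chain)


def bi_segment(chain: DecayChain | None = None) -> ChainSegment:
    """{²¹³Bi, ²¹³Po, ²⁰⁹Tl, ²⁰⁹Pb}, imaged via the 440 keV ²¹³Bi photopeak."""
    chain = chain or default_chain()
    return ChainSegment("Bi-segment", ("Bi-213", "Po-213", "Tl-209", "Pb-209"), "Bi-213", chain)


def full_segment(chain: DecayChain | None = None) -> ChainSegment:
    """The whole alpha-emitting chain, used when a single TAC stands for all of it."""
    chain = chain or default_chain()
    return ChainSegment("full-chain", chain.names, "Ac-225", chain)


def alpha_energy_per_decay(segment: ChainSegment) -> float:
    """Branching-weighted alpha energy (MeV) released in ``segment`` per decay
    of the segment head.

    Each member contributes its alpha energy weighted by the probability that
    a decay of the segment head passes through it; e.g. the Bi segment yields
    0.978·8.4 + 0.022·5.9 = 8.345 MeV and the Fr segment 5.8+6.3+7.1 = 19.2 MeV.
    Additive over disjoint segments that partition the chain.
    """
    head = segment.members[0]
    total = 0.0
    for name in segment.members:
        nuc = segment.chain[name]  # raises KeyError for unknown nuclides
        total += segment.chain.reach_probability(head, name) * nuc.alpha_energy_per_decay
    return total


def bateman_bi_activity(
    t,
    a_ac0: float,
    a_bi0: float,
    chain: DecayChain | None = None,
):
    """²¹³Bi activity at time(s) ``t`` hours after sample collection.

    Two-member Bateman solution with the short-lived intermediates ²²¹Fr and
    ²¹⁷At treated as instantaneous: the first term is ²¹³Bi grown in from the
    ²²⁵Ac present at collection, the second the decay of the ²¹³Bi already
    there.  Accepts scalar or array ``t``; activities in Bq.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("t must be non-negative")
    if a_ac0 < 0 or a_bi0 < 0:
        raise InvalidInputError("activities must be non-negative")
    chain = chain or default_chain()
    lam_ac = chain["Ac-225"].decay_constant
    lam_bi = chain["Bi-213"].decay_constant
    ingrowth = a_ac0 * (lam_bi / (lam_bi - lam_ac)) * (np.exp(-lam_ac * t) - np.exp(-lam_bi * t))
    decay = a_bi0 * np.exp(-lam_bi * t)
    result = ingrowth + decay
    return float(result) if result.ndim == 0 else result


def equilibrium_ratio(chain: DecayChain | None = None) -> float:
    """Secular-equilibrium ²¹³Bi/²²⁵Ac activity ratio, λ_Bi/(λ_Bi − λ_Ac) ≈ 1.0032."""
    chain = chain or default_chain()
    lam_ac = chain["Ac-225"].decay_constant
    lam_bi = chain["Bi-213"].decay_constant
    if lam_bi <= lam_ac:
        raise DegenerateChainError("equilibrium requires λ_Bi > λ_Ac")
    return lam_bi / (lam_bi - lam_ac)


def time_to_equilibrium(fraction_remaining: float, chain: DecayChain | None = None) -> float:
    """Hours until the transient ²¹³Bi term has decayed to ``fraction_remaining``.

    Smallest t with exp(−λ_Bi t) ≤ fraction.  The threshold defining
    "equilibrium reached" is a convention: 0.003 gives ≈ 6.4 h, 0.01 ≈ 5.05 h.
    """
    if not (0.0 < fraction_remaining < 1.0):
        raise InvalidInputError("fraction_remaining must lie in (0, 1)")
    chain = chain or default_chain()
    return -math.log(fraction_remaining) / chain["Bi-213"].decay_constant
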