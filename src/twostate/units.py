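"""Reaction networks, rate constants and unit conversions.

The two-state protein motif interconverts an unmodified protein P and a
modified form Pm.  Synthesis (ks), basal forward/reverse switching (kf, kr),
signal-coupled switching (ka*A) and state-specific degradation (dP, dPm)
complete the scheme.  A mediator extension replaces the direct signal
coupling by explicit kinase/phosphatase enzymes acting through
Michaelis-Menten-type binding, unbinding and catalysis.

Macroscopic rate constants are expressed in uM and 1/time.  In the
stochastic (molecule-count) regime, zeroth-order rates are multiplied by
V*Av (per uM) and second-order rates divided by it; first-order rates are
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

AVOGADRO = 6.02214179e23


@dataclass(frozen=True)
class VolumeContext:
    """System volume and Avogadro's constant.

    ``molecules_per_micromolar`` is the factor V*Av (per uM): the number of
    molecules corresponding to a 1 uM concentration in this volume.  The
    default 1 fL gives 602.2 molecules/uM, so 0.1 uM ~ 60 molecules.
    """

    volume: float = 1e-15  # liters
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")

    @property
    def molecules_per_micromolar(self) -> float:
        return self.volume * self.avogadro * 1e-6


DEFAULT_CONTEXT = VolumeContext()


def to_molecules(conc: float, ctx: VolumeContext = DEFAULT_CONTEXT) -> int:
    """Convert a concentration in uM to a molecule count (nearest integer)."""
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return int(round(conc * ctx.molecules_per_micromolar))


def to_concentration(count: float, ctx: VolumeContext = DEFAULT_CONTEXT) -> float:
    """Convert a molecule count to a concentration in uM."""
    if count < 0:
        raise ValueError(f"molecule count must be non-negative, got {count}")
    return count / ctx.molecules_per_micromolar


def _check_non_negative(obj, names: Sequence[str]) -> None:
    for n in names:
        v = getattr(obj, n)
        if v < 0:
            raise ValueError(f"rate constant {n} must be non-negative, got {v}")


@dataclass(frozen=True)
class RateSet:
    """Macroscopic rate constants of the linear two-state model.

    Defaults are the published parameterization; ``dP=0`` yields perfect
    adaptation (Pm* = ks/dPm independent of the signal), ``dP=0.01``
    near-perfect adaptation.
    """

    ks: float = 0.01  # uM / time, synthesis of P
    ka: float = 1.0   # 1 / (uM * time), signal-coupled P -> Pm
    kf: float = 1.0   # 1 / time, basal P -> Pm
    kr: float = 10.0  # 1 / time, Pm -> P
    dP: float = 0.01  # 1 / time, degradation of P
    dPm: float = 1.0  # 1 / time, degradation of Pm

    def __post_init__(self) -> None:
        _check_non_negative(self, ("ks", "ka", "kf", "kr", "dP", "dPm"))

    @classmethod
    def perfect_adaptation(cls) -> "RateSet":
        return cls(dP=0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MediatorRateSet:
    """Rate constants of the kinase/phosphatase-mediated extension.

    The kinase (A_kin) binds P (ka1), the complex AP unbinds (ka2) or
    converts catalytically to Pm (ka3); symmetrically the phosphatase
    (B_phos) acts on Pm through kd1/kd2/kd3.  Defaults follow the published
    mediator parameterization.
    """

    ks: float = 0.05
    kf: float = 1.0
    kr: float = 0.1
    dP: float = 0.01
    dPm: float = 10.0
    ka1: float = 1e3   # 1/(uM*time), kinase + P binding
    ka2: float = 10.0  # 1/time, AP unbinding
    ka3: float = 10.0  # 1/time, AP -> kinase + Pm catalysis
    kd1: float = 10.0  # 1/(uM*time), phosphatase + Pm binding
    kd2: float = 10.0  # 1/time, BPm unbinding
    kd3: float = 10.0  # 1/time, BPm -> phosphatase + P catalysis

    def __post_init__(self) -> None:
        _check_non_negative(
            self,
            ("ks", "kf", "kr", "dP", "dPm", "ka1", "ka2", "ka3", "kd1", "kd2", "kd3"),
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``change`` is the stoichiometric change vector over the network's species
    order; ``reactants`` lists (species index, order) pairs defining the
    mass-action propensity; ``rate_name`` references a constant in the rate
    set.  ``signal_bound`` marks the propensity as multiplied by the external
    signal level A(t) in uM.
    """

    name: str
    change: tuple
    rate_name: str
    rate_value: float
    reactants: tuple  # ((species_index, order), ...)
    signal_bound: bool = False

    def __post_init__(self) -> None:
        if not any(self.change):
            raise ValueError(f"reaction {self.name} has a zero change vector")

    @property
    def order(self) -> int:
        return sum(o for _, o in self.reactants)


@dataclass(frozen=True)
class ReactionNetwork:
    """A mass-action reaction network with an external piecewise signal.

    ``signal_species`` is None when the signal enters as a time-varying rate
    (linear model) and names a species whose unbound copy number is set by
    the signal (mediator model).
    """

    species: tuple
    reactions: tuple
    signal_species: str | None = None

    def __post_init__(self) -> None:
        ns = len(self.species)
        for r in self.reactions:
            if len(r.change) != ns:
                raise ValueError(f"reaction {r.name}: change vector length mismatch")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}; have {self.species}") from None

    def stoichiometry(self):
        import numpy as np

        return np.array([r.change for r in self.reactions], dtype=np.int64)

    def reactant_orders(self):
        import numpy as np

        mat = np.zeros((len(self.reactions), self.n_species), dtype=np.int64)
        for i, r in enumerate(self.reactions):
            for s, o in r.reactants:
                mat[i, s] = o
        return mat

    def stochastic_rate_constants(self, ctx: VolumeContext = DEFAULT_CONTEXT):
        """Per-reaction stochastic rate constants in molecule units.

        Zeroth-order: rate * V*Av (molecules/time).  Second-order:
        rate / (V*Av).  First-order: unchanged.  A signal-bound first-order
        channel keeps its per-uM constant; the simulator multiplies it by
        the signal level in uM, which is already a first-order rate.
        """
        import numpy as np

        scale = ctx.molecules_per_micromolar
        out = np.empty(len(self.reactions))
        for i, r in enumerate(self.reactions):
            order = r.order
            c = r.rate_value
            if order == 0:
                c *= scale
            elif order == 2:
                c /= scale
            out[i] = c
        return out

    def signal_flags(self):
        import numpy as np

        return np.array([1 if r.signal_bound else 0 for r in self.reactions], dtype=np.int64)


def build_two_state_network(rates: RateSet) -> ReactionNetwork:
    """The six elementary reactions of the linear two-state model.

    The external signal is not a molecular species here: the ka channel is
    a first-order conversion of P whose rate ka*A(t) follows the signal.
    """
    P, Pm = 0, 1
    rx = (
        Reaction("synthesis", (1, 0), "ks", rates.ks, ()),
        Reaction("forward", (-1, 1), "kf", rates.kf, ((P, 1),)),
        Reaction("signal_forward", (-1, 1), "ka", rates.ka, ((P, 1),), signal_bound=True),
        Reaction("reverse", (1, -1), "kr", rates.kr, ((Pm, 1),)),
        Reaction("degrade_P", (-1, 0), "dP", rates.dP, ((P, 1),)),
        Reaction("degrade_Pm", (0, -1), "dPm", rates.dPm, ((Pm, 1),)),
    )
    return ReactionNetwork(species=("P", "Pm"), reactions=rx)


def build_mediator_network(rates: MediatorRateSet) -> ReactionNetwork:
    """Two-state model with explicit kinase/phosphatase mediators.

    Species order: (P, Pm, A_kin, B_phos, AP, BPm).  Signal steps set the
    unbound kinase copy number (species ``A_kin``); bound complexes are
    untouched by signal changes and can accumulate mediator molecules.
    """
    P, Pm, A, B, AP, BPm = range(6)

    def ch(**kw):
        v = [0] * 6
        for k, x in kw.items():
            v[{"P": P, "Pm": Pm, "A": A, "B": B, "AP": AP, "BPm": BPm}[k]] = x
        return tuple(v)

    rx = (
        Reaction("synthesis", ch(P=1), "ks", rates.ks, ()),
        Reaction("forward", ch(P=-1, Pm=1), "kf", rates.kf, ((P, 1),)),
        Reaction("reverse", ch(P=1, Pm=-1), "kr", rates.kr, ((Pm, 1),)),
        Reaction("degrade_P", ch(P=-1), "dP", rates.dP, ((P, 1),)),
        Reaction("degrade_Pm", ch(Pm=-1), "dPm", rates.dPm, ((Pm, 1),)),
        Reaction("kinase_bind", ch(A=-1, P=-1, AP=1), "ka1", rates.ka1, ((A, 1), (P, 1))),
        Reaction("kinase_unbind", ch(A=1, P=1, AP=-1), "ka2", rates.ka2, ((AP, 1),)),
        Reaction("kinase_cat", ch(A=1, Pm=1, AP=-1), "ka3", rates.ka3, ((AP, 1),)),
        Reaction("phosphatase_bind", ch(B=-1, Pm=-1, BPm=1), "kd1", rates.kd1, ((B, 1), (Pm, 1))),
        Reaction("phosphatase_unbind", ch(B=1, Pm=1, BPm=-1), "kd2", rates.kd2, ((BPm, 1),)),
        Reaction("phosphatase_cat", ch(B=1, P=1, BPm=-1), "kd3", rates.kd3, ((BPm, 1),)),
    )
    return ReactionNetwork(species=("P", "Pm", "A_kin", "B_phos", "AP", "BPm"),
                           reactions=rx, signal_species="A_kin")
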